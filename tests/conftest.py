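import pytest

import allelotrace as at


def pipeline_config_from_paths(paths, out_dir, seed=0, **overrides):
    """Build a PipelineConfig pointing at a written SyntheticDataset."""
    kwargs = dict(
        mutations=str(paths["mutations"]),
        rna_counts=str(paths["rna_counts"]),
        protein_counts=str(paths["protein_counts"]),
        rna_expression=str(paths["rna_expression"]),
        protein_expression=str(paths["protein_expression"]),
        germline_genes=str(paths["germline_genes"]),
        driver_genes=str(paths["driver_genes"]),
        pathway_genes=str(paths["pathway_genes"]),
        out_dir=str(out_dir),
        seed=seed,
    )
    kwargs.update(overrides)
    return at.PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    """The default hyper-mutated-tumor study conditions, one fixed seed."""
    return at.generate_dataset(at.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_dataset, tmp_path_factory):
    """The default dataset written to disk and run end to end."""
    data_dir = tmp_path_factory.mktemp("default_data")
    paths = default_dataset.write(data_dir)
    config = pipeline_config_from_paths(paths, data_dir / "out", seed=11)
    result = at.run_pipeline(config)
    return default_dataset, config, result


@pytest.fixture(scope="session")
def proportions_dataset():
    """257 sites with planted cluster memberships (27/45/33/152)."""
    return at.generate_dataset(at.GeneratorConfig(
        n_sites=257, cluster_proportions=(0.105, 0.175, 0.128, 0.591), seed=11
    ))


def run_classify_filter_cluster(dataset, seed=0):
    """Library-level classify -> filter -> cluster on an in-memory dataset."""
    kept, _ = at.remove_nonref_control(dataset.site_records, dataset.rna_counts)
    patterns = at.classify_patterns(
        kept, dataset.rna_counts, dataset.protein_counts,
        dataset.rna_expr, dataset.protein_expr,
    )
    filtered, _ = at.apply_filters(
        kept, dataset.rna_counts, dataset.protein_counts, at.FilterConfig()
    )
    keys = {r.site.key for r in filtered}
    labelled, fit = at.assign_clusters(
        [p for p in patterns if p.site.key in keys], seed=seed
    )
    return kept, patterns, labelled, fit
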