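# Methods

## Scope and model

`allelotrace` analyses one patient: a tumor tissue and a matched non-tumor
control tissue, profiled by WES (one run per tissue), RNA-Seq (two
replicates per tissue) and label-free proteomics (two MS replicates per
tissue, searched against a variant-aware protein database so that wild-type
and mutant peptides are distinguishable at mutation sites).  The unit of
analysis is the *tumor-mutated allele*: the alternate allele of a non-silent
somatic point mutation.  The package quantifies how far each such allele
travels along the central dogma and what that implies for per-patient driver
nomination.

### Allelic fraction

At every level the allelic fraction is
`AF = alt / (ref + alt + other)` — mutant observations over all observations
at the locus.  `other` (reads supporting a third allele) is included in the
denominator and is zero at the protein level.  A zero denominator makes the
AF *undefined*; undefined AFs propagate as "uncovered" and never collapse to
0, because 0 is a claim about allele absence while uncovered claims nothing.
Concretely: a missing row in a count table means uncovered; a present row
with `alt_count = 0` means covered with the mutant absent.

### Site hygiene and filters

Sites whose control tissue shows the alternate allele in RNA (≥ 2 combined
control reads, the same presence rule as classification) are removed before
any analysis — their "mutant" allele is not tumor-specific.  Control-
uncovered sites are kept.  For cluster analysis, sites must additionally
pass `DP ≥ dp_min` (default 8) in tumor WES and combined tumor RNA and
`SC ≥ sc_min` (default 3) in combined tumor MS.  Thresholds apply to tumor
evidence only; replicates are summed before thresholding.

### Expression-pattern classification

RNA status per site: `GENE_NOT_EXPRESSED` when the gene's combined tumor
abundance is exactly 0; `SITE_NOT_COVERED` when the gene is expressed but no
allele passes the presence rule at the site; otherwise `WT_ONLY` / `BOTH` /
`MUT_ONLY` by which alleles pass.  The presence rule defaults to ≥ 2
supporting reads per allele — a guard against sequencing error at
depth-limited sites; a genotype-likelihood model is deliberately not used
because the classification must work at arbitrary (including low) site
depths and the rule should be transparent and monotone.  Protein status is
analogous with a one-spectral-count presence rule (mutant peptides already
pass their own identification FDR upstream), and a site only counts as a
tumor mutated-amino-acid identification if the mutant peptide is absent
from the control tissue.

### Cluster assignment

The four classes are logical categories plus one magnitude split:
translated sites (`Cluster_TL`) and transcribed-but-untranslated sites
(`Cluster_nTL`) are fixed by rule; only the untranscribed remainder is split
by magnitude of DNA AF into `Cluster_nTCM` / `Cluster_nTCS` with a
two-component 1-D Gaussian mixture fitted by EM.  Making the rules primary
and the mixture secondary keeps cluster identity interpretable and
reproducible; the mixture is only asked the one question it can answer
(where the moderate/small AF boundary lies in this patient).

EM details: k-means++ seeding on the data (seeded RNG) refined by ten Lloyd
iterations; unequal variances by default (an equal-variance option exists);
convergence at log-likelihood improvement < 1e-8, at most 500 iterations;
variance floor 1e-4 (flagged `degenerate` when it engages, e.g. identical
inputs).  Assignment is by maximum posterior responsibility, ties toward the
lower-mean component.  The fitted parameters are dumped to a JSON sidecar so
a run can be audited.

### ASE testing

For each level pair (DNA–RNA, RNA–protein, DNA–protein) with coverage on
both sides, the 2×2 table of (WT, mutant) counts is tested with a two-sided
Fisher exact test.  Each level pair forms one Benjamini–Hochberg family;
FDR < 0.05 is called significant.  The all-zero table is flagged untestable
rather than assigned a p-value.

### DPRE

`FC = log2(Exp_cancer / Exp_cirrhosis)` with sentinels: +10 when the control
abundance is 0, −10 when the tumor abundance is 0, undefined when both are
(the sentinel magnitude is configurable).  `NormFC = (FC − median) / IQR`
with type-7 (linear-interpolation) quantiles, computed per platform — per MS
replicate for protein, once for the replicate-combined RNA.  The IQR
denominator follows from the definition of the upper and lower quantiles;
normalization makes the two platforms' FC scales commensurable, so
`DPRE = NormFC_protein − NormFC_RNA` isolates translational and
post-translational change.  Eligibility requires the RNA FC sign to agree
between the two RNA replicates (zeros agree with anything); genes failing
this, or lacking a protein record, are excluded with a logged reason.
Group comparisons (genes with somatic mutations vs germline variants vs
neither; somatic takes precedence) use the two-sided two-sample KS test and
a Pearson χ² without continuity correction on (DPRE ≤ 0, DPRE > 0) — the
groups number in the thousands, so the correction would only bias.

### Driver prioritization

Criterion 1 (mutant allele at the protein level, tumor-specific) is a hard
gate.  Criterion 2 ("comparable" AFs across levels — a term the underlying
strategy leaves informal) is operationalized as: all three AFs defined, no
significant ASE for the site at the chosen FDR, and min AF ≥ 0.1 (the floor
sits below the 0.22–0.57 AF band observed for genes that pass).  Criterion 3
is membership in user-supplied known-driver or disease-pathway lists
(pathway lists replace proprietary network analysis).  Criteria 2 and 3
affect rank, not candidacy, so translated-but-unlisted genes remain visible.
Candidates sort by criteria met, then protein AF, then gene symbol and
position — a deterministic total order.

## The synthetic generator

`GeneratorConfig` defaults encode the study conditions: 5,000 non-silent
sites in 3,800 genes, WES mean depth 110×, tumor purity 0.8 with 60% clonal
sites (clonal AF = purity/2 = 0.4; subclonal AF uniform in 0.03–0.15), 8.5%
of mutated genes unexpressed, an overall not-transcribed rate of 0.34, a
0.5 probability of translation loss given transcription, and a −0.3 log2
protein-FC shift for somatically mutated genes (−0.05 for germline-variant
genes, giving the graded somatic ≥ germline ≥ none ordering of DPRE
distributions; with residual protein noise of 0.5 log2 per tissue this
yields a ~9–10 percentage-point gap in the share of genes with DPRE ≤ 0,
matching the observed patient-scale gap).

Mechanics worth knowing:

* **RNA dropout comes from the depth model.**  Site depth is Poisson with
  rate ∝ gene abundance × an exponential per-site capture efficiency
  (`p_site_uncovered_scale` widens it), so uncovered sites concentrate in
  weakly expressed genes rather than being an arbitrary flag.
* **The 0.34 not-transcribed rate is calibrated to the *observed* scale.**
  A transcribed subclonal allele at AF 0.03–0.05 can produce fewer than two
  mutant reads and read as wild-type-only; the generator computes that
  detectability loss exactly from the drawn depths (binomial tail) and
  adjusts the per-site elimination probability so the observed
  wild-type-only share matches the configured rate.  The generative
  transcribed fraction then also satisfies the total-probability identity
  `1 − p_not_transcribed − p_silent − uncovered share` to within a few
  percent.
* **Cross-level AF decay.**  The protein allele share is the DNA AF times
  log-normal noise (0.35 log2), and spectral counts are Poisson around
  abundance × allele share, so AF correlations decay DNA → RNA → protein.
* **Planted drivers.**  Five single-site, expressed genes receive generous,
  balanced evidence at every level (AF 0.4 throughout) and membership in
  the driver list; decoy list entries are ordinary genes.  Planted drivers
  are the positive control for the prioritization recall property.
* **Proportions mode.**  With `cluster_proportions` set, exact cluster
  memberships (largest-remainder rounding: 0.105/0.175/0.128/0.591 at
  n = 257 gives 27/45/33/152) are planted with clamped generous depths and
  deterministic allele counts, and the two untranscribed groups' AFs are
  drawn uniformly inside the moderate (0.13–0.53) and small (0.03–0.11)
  bands with a 7.5% inner margin.  The margin keeps the groups well
  separated so the EM split is exact; without it, draws hugging the shared
  band edge can be flipped by finite-depth rounding.

### What the generator does not emulate

Reads and spectra are not simulated (counts are drawn directly); there is no
mapping bias, GC or library-complexity structure, no copy-number variation
or purity gradient (AF structure is purely clonal/subclonal), no correlated
multi-site haplotypes, no peptide-level attribution ambiguity, and
replicate noise is independent log-normal.  Passing tests therefore
demonstrate that the statistical machinery recovers known signal under the
stated generative model — not that the model captures every failure mode of
real WES/RNA-Seq/MS data.

## Numerical and design choices

* Quantiles are type 7 (numpy default) everywhere quantiles appear.
* Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  checks them against exhaustive hypergeometric enumeration (all tables
  with margins ≤ 30) using an independent log-gamma implementation.
* BH q-values come from `statsmodels.stats.multitest`; an independent
  step-up recursion is the test oracle.
* The EM mixture is implemented in-package (log-sum-exp E-step, monotone
  log-likelihood asserted in tests); `sklearn.mixture.GaussianMixture`
  serves as an independent cross-check on well-separated data, never as the
  implementation.
* All pipeline randomness flows from the single `seed` in `PipelineConfig`
  (only the EM initialization consumes it); outputs use fixed column orders
  and `%.6g`/`%.10g` float formatting, so identical config + seed gives
  byte-identical outputs, manifest included.
* Degenerate inputs: empty pattern lists summarize to zero counts with
  percentages flagged undefined; a single untranscribed site cannot be
  split and is labelled moderate with a warning; a constant fold-change
  distribution (IQR = 0) is an error rather than a silent division.

## Problem sizes used by the tests

The default synthetic tumor (5,000 sites, ~18,800 genes, two replicates per
level) runs through the whole pipeline in a few seconds; the acceptance
suite adds an exhaustive Fisher check (~246k tables, a few minutes), 10,000
null simulations for test calibration, and a 20-seed EM recovery study at
n = 200.  These sizes were chosen to give stable statistics while keeping a
full run comfortably interactive.

## Known limitations

Single patient by design — no cohort-level recurrence statistics; no
copy-number or purity correction of allelic fractions; no phasing of
multiple mutations in one gene (per-site analysis, with a most-expressed
rollup for reporting); spectral counts are assumed pre-attributed to sites
(a peptide spanning two mutation sites is upstream's problem); the
"comparable AF" operationalization and the AF floor are package choices
where the underlying strategy is informal.
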