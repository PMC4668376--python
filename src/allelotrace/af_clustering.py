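"""Expression-based clustering of filtered somatic sites.

The four classes are rule-defined on the transcription/translation statuses:

* ``Cluster_TL``   — mutant allele present at the protein level;
* ``Cluster_nTL``  — mutant transcribed but not translated;
* ``Cluster_nTCM`` / ``Cluster_nTCS`` — mutant not transcribed, split into
  moderate- versus small-AF groups by a two-component 1-D Gaussian mixture
  fitted to the sites' DNA allelic fractions by expectation-maximization.

The EM fit is written here (quantile-seeded k-means++ initialization,
variance floor, monotone log-likelihood); assignment is by maximum posterior
responsibility with ties broken toward the lower-mean component.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .expression_classify import SitePattern
from .io_formats import CLUSTER_LABELS

__all__ = ["MixtureFit", "em_fit_1d", "assign_clusters", "cluster_af_summary"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    responsibilities: np.ndarray  # (n, k)
    seed: int
    converged: bool
    degenerate: bool
    loglik_trace: np.ndarray

    def log_density(self, x) -> np.ndarray:
        """Per-component weighted log density at new points, shape (n, k)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.means[None, :]) / self.sds[None, :]
        return (
            np.log(self.weights)[None, :]
            - np.log(self.sds)[None, :]
            - 0.5 * (_LOG_2PI + z * z)
        )

    def responsibility(self, x) -> np.ndarray:
        """Posterior component probabilities at new points, shape (n, k)."""
        log_d = self.log_density(x)
        log_norm = np.logaddexp.reduce(log_d, axis=1, keepdims=True)
        return np.exp(log_d - log_norm)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "weights": self.weights.tolist(),
                "loglik": self.loglik,
                "seed": self.seed,
                "converged": self.converged,
                "degenerate": self.degenerate,
                "n_iter": int(self.loglik_trace.size),
            },
            indent=2,
            sort_keys=True,
        )


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding followed by a few Lloyd iterations (1-D)."""
    n = x.size
    centers = [x[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(n)])
        else:
            centers.append(x[rng.choice(n, p=d2 / total)])
    means = np.sort(np.asarray(centers, dtype=float))
    for _ in range(10):
        assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        for j in range(k):
            members = x[assign == j]
            if members.size:
                means[j] = members.mean()
    return np.sort(means)


def em_fit_1d(
    values,
    k: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    equal_variance: bool = False,
    var_floor: float = 1e-4,
) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by expectation-maximization.

    Convergence is declared when the log-likelihood improves by less than
    ``tol``; variances are floored at ``var_floor`` (flagged ``degenerate``
    when the floor engages).  ``equal_variance=True`` ties the component
    variances (mclust model "E"; default is the unequal-variance model "V").
    Components are reported sorted by ascending mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")

    rng = np.random.default_rng(seed)
    means = _kmeanspp_init(x, k, rng)
    var = np.full(k, max(x.var(), var_floor))
    weights = np.full(k, 1.0 / k)
    degenerate = False
    converged = False
    trace = []
    prev_ll = -np.inf
    resp = np.full((n, k), 1.0 / k)

    for _ in range(max_iter):
        # E-step
        z = (x[:, None] - means[None, :]) / np.sqrt(var)[None, :]
        log_comp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(var)[None, :]
            - 0.5 * (_LOG_2PI + z * z)
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M-step
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if equal_variance:
            var = np.full(k, float((var * nk).sum() / n))
        floored = var < var_floor
        if floored.any():
            degenerate = True
            var = np.maximum(var, var_floor)

    order = np.argsort(means)
    return MixtureFit(
        k=k,
        means=means[order],
        sds=np.sqrt(var[order]),
        weights=weights[order],
        loglik=trace[-1],
        responsibilities=resp[:, order],
        seed=seed,
        converged=converged,
        degenerate=degenerate,
        loglik_trace=np.asarray(trace),
    )


def assign_clusters(
    patterns: Iterable[SitePattern],
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    equal_variance: bool = False,
) -> tuple:
    """Label every filtered site with one of the four expression clusters.

    Rules take precedence: mutant-translated sites are ``Cluster_TL``;
    transcribed-but-untranslated sites (including sites whose protein evidence
    covers only the wild-type allele) are ``Cluster_nTL``.  The remaining
    untranscribed sites are split by a k=2 EM on their DNA AF: the higher-mean
    component is ``Cluster_nTCM`` (moderate AF), the lower ``Cluster_nTCS``
    (small AF).  Returns ``(labelled patterns, MixtureFit or None)``.
    """
    patterns = list(patterns)
    labelled: list = [None] * len(patterns)
    untx_idx = []
    for i, p in enumerate(patterns):
        if p.mutant_translated:
            labelled[i] = replace(p, cluster="Cluster_TL")
        elif p.mutant_transcribed:
            labelled[i] = replace(p, cluster="Cluster_nTL")
        else:
            untx_idx.append(i)

    fit = None
    if len(untx_idx) == 0:
        pass
    elif len(untx_idx) < 2:
        warnings.warn(
            "fewer than 2 untranscribed sites: all labelled Cluster_nTCM",
            stacklevel=2,
        )
        for i in untx_idx:
            labelled[i] = replace(patterns[i], cluster="Cluster_nTCM")
    else:
        afs = []
        for i in untx_idx:
            if patterns[i].af_dna is None:
                raise ValueError(
                    f"site {patterns[i].site.chrom}:{patterns[i].site.pos} has "
                    "no DNA allelic fraction; cannot split untranscribed sites"
                )
            afs.append(patterns[i].af_dna)
        fit = em_fit_1d(
            afs, k=2, seed=seed, tol=tol, max_iter=max_iter,
            equal_variance=equal_variance,
        )
        # argmax returns the first (lower-mean) component on ties
        comp = np.argmax(fit.responsibilities, axis=1)
        for i, c in zip(untx_idx, comp):
            label = "Cluster_nTCM" if c == 1 else "Cluster_nTCS"
            labelled[i] = replace(patterns[i], cluster=label)

    return labelled, fit


def cluster_af_summary(patterns: Iterable[SitePattern]) -> pd.DataFrame:
    """Five-number AF summary per cluster per level (boxplot statistics).

    Uncovered AFs are excluded from the statistics; their counts are reported
    in ``n_uncovered``.  Empty cluster x level combinations carry NaN stats.
    """
    patterns = list(patterns)
    rows = []
    for label in CLUSTER_LABELS:
        members = [p for p in patterns if p.cluster == label]
        for level, attr in (("DNA", "af_dna"), ("RNA", "af_rna"), ("PROTEIN", "af_protein")):
            values = np.array(
                [getattr(p, attr) for p in members if getattr(p, attr) is not None]
            )
            n_unc = sum(getattr(p, attr) is None for p in members)
            if values.size:
                stats = dict(
                    min=values.min(),
                    q1=np.quantile(values, 0.25),
                    median=np.quantile(values, 0.5),
                    q3=np.quantile(values, 0.75),
                    max=values.max(),
                )
            else:
                stats = dict(min=np.nan, q1=np.nan, median=np.nan, q3=np.nan, max=np.nan)
            rows.append(dict(
                cluster=label, level=level, n=len(values), n_uncovered=n_unc, **stats
            ))
    return pd.DataFrame(rows)
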