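"""Gene-gene co-essentiality from guide-level depletion profiles.

Two genes are co-essential when knocking either out produces correlated
fitness effects across tumors.  Because each gene is targeted by many guides
of variable quality, a gene-gene correlation is summarized as the mean
Pearson correlation over all (guide-of-A, guide-of-B) pairs, each correlation
taken across tumors.  Significance is empirical: the same number of guide-pair
correlations is repeatedly resampled from the pool of non-targeting-control
(NTC) guide pairs, and the empirical FDR is the fraction of resampled means
that meet or exceed the observed mean.

``pearson_test`` provides the classical Pearson r with a two-sided p-value
from the t-distribution with n-2 degrees of freedom, as used for
dependency-profile correlations across large cell-line panels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import GuideLibrary

__all__ = [
    "CorrelationStat",
    "CoessentialityRecord",
    "guide_pair_correlations",
    "gene_gene_correlation",
    "ntc_pair_pool",
    "empirical_fdr",
    "coessentiality_matrix",
    "pearson_test",
    "depletion_vs_ntc",
]


@dataclass(frozen=True)
class CorrelationStat:
    """Pearson correlation with its t-statistic and two-sided p-value (n-2 df)."""

    r: float
    t: float
    p_value: float
    n: int
    perfect: bool = False


@dataclass
class CoessentialityRecord:
    """Mean guide-pair correlation for one unordered gene pair, with empirical FDR."""

    gene_a: str
    gene_b: str
    mean_r: float
    n_pairs: int
    pair_correlations: np.ndarray | None = None
    empirical_fdr: float | None = None
    iterations: int | None = None

    def __post_init__(self) -> None:
        if self.gene_b < self.gene_a:  # canonical order: record symmetric in (a, b)
            self.gene_a, self.gene_b = self.gene_b, self.gene_a


def _profiles(dep: pd.DataFrame, guides: list[str]) -> tuple[np.ndarray, list[str]]:
    """Extract guide rows, dropping zero-variance profiles with a warning."""
    sub = dep.loc[guides].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(guides, keep) if not k]
        warnings.warn(f"dropping zero-variance guide profiles: {dropped}")
    return sub[keep], [g for g, k in zip(guides, keep) if k]


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of a and every row of b (across columns)."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def guide_pair_correlations(
    dep: pd.DataFrame,
    library: GuideLibrary,
    gene_a: str,
    gene_b: str,
) -> np.ndarray:
    """One Pearson r across tumors per (guide-of-A, guide-of-B) pair.

    Self-pairs are excluded when ``gene_a == gene_b``.  Guides with zero
    variance across tumors are dropped (their Pearson r is undefined).
    """
    if dep.shape[1] < 3:
        raise ValueError("need at least 3 tumors for guide-pair correlations")
    a, _ = _profiles(dep, library.guides_for(gene_a))
    if gene_a == gene_b:
        r = _pairwise_r(a, a)
        iu = np.triu_indices(a.shape[0], k=1)
        return r[iu]
    b, _ = _profiles(dep, library.guides_for(gene_b))
    return _pairwise_r(a, b).ravel()


def gene_gene_correlation(
    dep: pd.DataFrame,
    library: GuideLibrary,
    gene_a: str,
    gene_b: str,
) -> CoessentialityRecord:
    """Gene-gene co-essentiality: the mean over all guide-pair correlations."""
    rs = guide_pair_correlations(dep, library, gene_a, gene_b)
    if rs.size == 0:
        raise ValueError(f"no usable guide pairs for ({gene_a}, {gene_b})")
    return CoessentialityRecord(
        gene_a=gene_a,
        gene_b=gene_b,
        mean_r=float(rs.mean()),
        n_pairs=int(rs.size),
        pair_correlations=rs,
    )


def ntc_pair_pool(dep: pd.DataFrame, library: GuideLibrary) -> np.ndarray:
    """Pearson r for every unordered pair of non-targeting guides (the null pool)."""
    if library.ntc_count() < 2:
        raise ValueError("need at least 2 non-targeting guides")
    ntc, _ = _profiles(dep, library.ntc_guides())
    r = _pairwise_r(ntc, ntc)
    iu = np.triu_indices(ntc.shape[0], k=1)
    return r[iu]


def _mc_means_without_replacement(
    pool: np.ndarray, k: int, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of `iterations` without-replacement samples of size k from pool.

    Each permutation of the pool yields floor(N/k) disjoint blocks, each a
    valid uniform without-replacement sample; blocks from one permutation are
    negatively dependent, which keeps the FDR estimator unbiased and only
    reduces its Monte-Carlo variance.
    """
    n = pool.size
    per = n // k
    means: list[np.ndarray] = []
    got = 0
    while got < iterations:
        perm = rng.permutation(pool)
        blocks = perm[: per * k].reshape(per, k)
        means.append(blocks.mean(axis=1))
        got += per
    return np.concatenate(means)[:iterations]


def _mc_means_with_replacement(
    pool: np.ndarray, k: int, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    means = np.empty(iterations)
    chunk = max(1, int(5e7 // max(k, 1)))
    for start in range(0, iterations, chunk):
        m = min(chunk, iterations - start)
        idx = rng.integers(0, pool.size, size=(m, k))
        means[start : start + m] = pool[idx].mean(axis=1)
    return means


def empirical_fdr(
    observed: CoessentialityRecord | float,
    pool: np.ndarray,
    n_pairs: int | None = None,
    iterations: int = 10_000,
    sampling: str = "without",
    seed: int | np.random.Generator | None = 0,
    two_sided: bool = False,
    add_one: bool = False,
) -> float:
    """Empirical FDR of an observed mean guide-pair correlation.

    Repeatedly draws ``n_pairs`` correlations from the NTC pair pool, averages
    them, and returns the fraction of iterations in which the resampled mean
    meets or exceeds the observed mean (ties count as exceedances, which can
    only inflate the FDR).  ``sampling`` is ``'without'`` (default) or
    ``'with'`` replacement per iteration, or ``'exhaustive'`` to enumerate all
    C(pool, n_pairs) subsets exactly (small pools only).  ``two_sided``
    compares absolute means for negative-correlation queries; ``add_one``
    applies the (x+1)/(iterations+1) permutation-test correction.
    """
    if isinstance(observed, CoessentialityRecord):
        mean_r = observed.mean_r
        k = observed.n_pairs
    else:
        mean_r = float(observed)
        if n_pairs is None:
            raise ValueError("n_pairs is required when observed is a scalar")
        k = int(n_pairs)
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty NTC pair pool")
    if k < 1:
        raise ValueError("n_pairs must be at least 1")

    if sampling == "exhaustive":
        subsets = np.array(list(itertools.combinations(pool, k)))
        sample_means = subsets.mean(axis=1)
        iterations = sample_means.size
    else:
        if iterations < 1:
            raise ValueError("iterations must be at least 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if sampling == "without":
            if k > pool.size:
                raise ValueError(
                    f"n_pairs={k} exceeds NTC pool size {pool.size}; use sampling='with'"
                )
            sample_means = _mc_means_without_replacement(pool, k, iterations, rng)
        elif sampling == "with":
            sample_means = _mc_means_with_replacement(pool, k, iterations, rng)
        else:
            raise ValueError(f"unknown sampling mode {sampling!r}")

    if two_sided:
        exceed = int(np.sum(np.abs(sample_means) >= abs(mean_r)))
    else:
        exceed = int(np.sum(sample_means >= mean_r))
    if add_one:
        return (exceed + 1) / (iterations + 1)
    return exceed / iterations


def coessentiality_matrix(
    dep: pd.DataFrame,
    library: GuideLibrary,
    genes: list[str] | None = None,
    iterations: int = 10_000,
    seed: int = 0,
    sampling: str = "without",
    two_sided: bool = False,
    add_one: bool = False,
) -> list[CoessentialityRecord]:
    """Co-essentiality records with empirical FDR for every unordered gene pair."""
    genes = list(genes) if genes is not None else library.genes()
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    pool = ntc_pair_pool(dep, library)
    rng = np.random.default_rng(seed)
    records = []
    for gene_a, gene_b in itertools.combinations(genes, 2):
        rec = gene_gene_correlation(dep, library, gene_a, gene_b)
        rec.empirical_fdr = empirical_fdr(
            rec, pool, iterations=iterations, sampling=sampling, seed=rng,
            two_sided=two_sided, add_one=add_one,
        )
        rec.iterations = iterations
        records.append(rec)
    return records


def records_to_frame(records: list[CoessentialityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in records],
            "gene_b": [r.gene_b for r in records],
            "mean_r": [r.mean_r for r in records],
            "n_pairs": [r.n_pairs for r in records],
            "empirical_fdr": [r.empirical_fdr for r in records],
            "iterations": [r.iterations for r in records],
        }
    )


def pearson_test(x, y) -> CorrelationStat:
    """Pearson r with two-sided p from the t-distribution (n-2 df).

    r = sum((x - x_mean)(y - y_mean)) / ((n-1) * s_x * s_y) with s the sample
    standard deviations, then t = r*sqrt(n-2)/sqrt(1-r^2) and
    p = 2*P(T_{n-2} > |t|).  |r| = 1 is reported with p = 0 and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("constant vector has undefined correlation")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationStat(r=r, t=float("inf") if r > 0 else float("-inf"),
                               p_value=0.0, n=n, perfect=True)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationStat(r=r, t=float(t), p_value=float(p), n=n)


@dataclass(frozen=True)
class DepletionVsNTC:
    """Per-tumor gene depletion relative to non-targeting controls."""

    gene: str
    tumor: str
    mean_difference: float
    p_value: float
    n_gene: int
    n_ntc: int


def depletion_vs_ntc(
    dep: pd.DataFrame,
    library: GuideLibrary,
    gene: str,
    tumor: str,
) -> DepletionVsNTC:
    """Gene-vs-NTC depletion query within one tumor.

    Returns the difference between the mean fold change of the gene's guides
    and the NTC mean, with a two-sided Wilcoxon rank-sum p-value comparing
    the two guide groups (exact at small group sizes).
    """
    if library.ntc_count() < 2:
        raise ValueError("need at least 2 non-targeting guides")
    g = dep.loc[library.guides_for(gene), tumor].to_numpy(dtype=float)
    ntc = dep.loc[library.ntc_guides(), tumor].to_numpy(dtype=float)
    stat = stats.mannwhitneyu(g, ntc, alternative="two-sided")
    return DepletionVsNTC(
        gene=gene,
        tumor=tumor,
        mean_difference=float(g.mean() - ntc.mean()),
        p_value=float(stat.pvalue),
        n_gene=g.size,
        n_ntc=ntc.size,
    )
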