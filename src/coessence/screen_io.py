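"""Guide libraries, guide counting, and depletion-matrix preprocessing.

The preprocessing chain for a pooled in-vivo CRISPR screen:

1. ``count_guides`` maps reads to library protospacers by exact 20-mer match
   (imperfect or ambiguous matches are discarded), one column per sample.
2. ``quantile_normalize`` forces all sample columns onto a common empirical
   distribution (the row-wise mean of the column-sorted values).
3. ``depletion_fold_change`` converts counts to log2 fold change of each
   guide between the baseline (initial cell pool) and each tumor, on a
   counts-per-million scale with a pseudocount.
4. ``per_gene_quantile_normalize`` quantile-normalizes each gene's guide
   fold-change submatrix across tumors, absorbing per-tumor engraftment
   bottleneck variance; non-targeting controls are pooled as one pseudo-gene.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

NTC_GENE = "NTC"
GUIDE_LEN = 20

__all__ = [
    "GuideLibrary",
    "CountMatrix",
    "load_guide_library",
    "count_guides",
    "quantile_normalize",
    "depletion_fold_change",
    "normalized_depletion",
    "per_gene_quantile_normalize",
    "NTC_GENE",
]


@dataclass(frozen=True)
class GuideLibrary:
    """Guide identities, target-gene assignments and protospacer sequences.

    ``records`` has columns guide_id, gene, sequence; non-targeting controls
    carry the sentinel gene ``NTC``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"guide_id", "gene", "sequence"}
        if not required.issubset(df.columns):
            raise ValueError(f"library must have columns {sorted(required)}")
        dup_ids = df["guide_id"][df["guide_id"].duplicated()]
        if len(dup_ids):
            raise ValueError(f"duplicate guide_id: {dup_ids.iloc[0]!r}")
        dup_seq = df["sequence"][df["sequence"].duplicated()]
        if len(dup_seq):
            raise ValueError(f"duplicate guide sequence: {dup_seq.iloc[0]!r}")
        bad = df["sequence"][~df["sequence"].str.fullmatch(f"[ACGT]{{{GUIDE_LEN}}}")]
        if len(bad):
            raise ValueError(f"non-ACGT or wrong-length sequence: {bad.iloc[0]!r}")

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.records["guide_id"])

    def ntc_mask(self) -> np.ndarray:
        return (self.records["gene"] == NTC_GENE).to_numpy()

    def ntc_guides(self) -> list[str]:
        return self.records.loc[self.ntc_mask(), "guide_id"].tolist()

    def ntc_count(self) -> int:
        return int(self.ntc_mask().sum())

    def genes(self) -> list[str]:
        g = self.records.loc[~self.ntc_mask(), "gene"].unique()
        return list(g)

    def guides_for(self, gene: str) -> list[str]:
        if gene == NTC_GENE:
            return self.ntc_guides()
        out = self.records.loc[self.records["gene"] == gene, "guide_id"].tolist()
        if not out:
            raise KeyError(f"gene {gene!r} not in library")
        return out


@dataclass
class CountMatrix:
    """Guides x samples integer counts with exactly one baseline sample flagged."""

    counts: pd.DataFrame
    baseline: str

    def __post_init__(self) -> None:
        if self.baseline not in self.counts.columns:
            raise ValueError(f"baseline sample {self.baseline!r} not among columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def tumor_samples(self) -> list[str]:
        return [c for c in self.counts.columns if c != self.baseline]

    def to_tsv(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        self.counts.rename_axis("guide_id").to_csv(path, sep="\t")
        if manifest_path is not None:
            import json

            Path(manifest_path).write_text(
                json.dumps({"baseline": self.baseline, "samples": list(self.counts.columns)}, indent=1)
            )

    @classmethod
    def from_tsv(cls, path: str | Path, manifest_path: str | Path) -> "CountMatrix":
        import json

        counts = pd.read_csv(path, sep="\t", index_col=0)
        manifest = json.loads(Path(manifest_path).read_text())
        return cls(counts=counts, baseline=manifest["baseline"])


def load_guide_library(path: str | Path) -> GuideLibrary:
    """Read a guide library TSV (columns guide_id, gene, sequence).

    Non-targeting rows are marked by an empty gene field or the literal
    ``NTC``; both normalize to the ``NTC`` sentinel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"guide_id", "gene", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"library file {path} lacks columns {sorted(missing)}")
    df = df.copy()
    df["gene"] = df["gene"].str.strip().replace("", NTC_GENE)
    df["sequence"] = df["sequence"].str.upper()
    return GuideLibrary(records=df.reset_index(drop=True))


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_guides(
    fastq_path: str | Path,
    library: GuideLibrary,
    locate: int | str = "scan",
) -> tuple[pd.Series, dict]:
    """Count exact, unique protospacer matches per guide in one FASTQ sample.

    ``locate`` is either an integer fixed offset (the protospacer occupies
    read positions [k, k+20)) or ``"scan"``, which searches every 20-mer of
    the read against the library.  A read contributes one count to a guide
    only if exactly one library sequence matches; reads with zero matches
    (including any imperfect match) or matches to two or more distinct
    guides are discarded.  Returns (counts indexed by guide_id, tally dict
    with total/matched/discarded).
    """
    if len(library.records) == 0:
        raise ValueError("empty guide library")
    seq_to_guide = dict(zip(library.records["sequence"], library.records["guide_id"]))
    counts = pd.Series(0, index=library.guide_ids, dtype=int)
    total = matched = 0
    with _open_maybe_gzip(fastq_path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            total += 1
            read = str(rec.seq).upper()
            if isinstance(locate, int):
                window = read[locate : locate + GUIDE_LEN]
                hit = seq_to_guide.get(window)
                hits = {hit} if hit is not None else set()
            elif locate == "scan":
                hits = {
                    seq_to_guide[read[i : i + GUIDE_LEN]]
                    for i in range(len(read) - GUIDE_LEN + 1)
                    if read[i : i + GUIDE_LEN] in seq_to_guide
                }
            else:
                raise ValueError(f"unknown locate strategy {locate!r}")
            if len(hits) == 1:
                counts[hits.pop()] += 1
                matched += 1
    return counts, {"total": total, "matched": matched, "discarded": total - matched}


def quantile_normalize(matrix: pd.DataFrame, tie_rule: str = "average") -> pd.DataFrame:
    """Quantile-normalize columns onto the mean-of-sorted reference distribution.

    After the operation every column's sorted values equal the row-wise mean
    of the column-wise sorted input (exactly so for tie-free columns), and
    within-column rank order is preserved.  ``tie_rule='average'`` assigns a
    tied run the mean of the reference values its ranks span; ``'ordinal'``
    breaks ties by input order.
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix, dtype=float))
    X = df.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    if np.isnan(X).any():
        raise ValueError("NaN values are not allowed")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        if tie_rule == "average":
            assigned = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
        elif tie_rule != "ordinal":
            raise ValueError(f"unknown tie_rule {tie_rule!r}")
        out[:, j] = assigned
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def depletion_fold_change(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-guide log2 fold change of each tumor against the baseline pool.

    Counts are first scaled to counts per million within each sample (so pool
    and tumor sequencing depths are comparable), then
    ``log2((cpm_tumor + pc) / (cpm_baseline + pc))``.  The pseudocount keeps
    fully depleted guides finite.  Returns a guides x tumors DataFrame.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    cpm = counts.counts.astype(float)
    totals = cpm.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    cpm = cpm / totals * 1e6
    base = cpm[counts.baseline]
    tumors = counts.tumor_samples
    dep = np.log2(cpm[tumors].add(pseudocount).div(base + pseudocount, axis=0))
    return dep


def normalized_depletion(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Standard preprocessing for co-essentiality: quantile-normalize raw counts
    across all samples, then per-guide log2 fold change of each tumor vs the
    baseline pool.  (Per-gene normalization is a separate, downstream step used
    for per-tumor gene-vs-NTC queries.)"""
    qn = quantile_normalize(counts.counts)
    return depletion_fold_change(CountMatrix(counts=qn, baseline=counts.baseline), pseudocount)


def per_gene_quantile_normalize(
    dep: pd.DataFrame,
    library: GuideLibrary,
    axis: str = "tumors",
    tie_rule: str = "average",
) -> pd.DataFrame:
    """Quantile-normalize each gene's guide fold-change submatrix across tumors.

    Applied per gene independently (NTC guides pooled as one pseudo-gene), so
    a tumor in which a gene's guides were systematically shifted by an
    engraftment bottleneck is forced onto the gene's common fold-change
    distribution.  ``axis='tumors'`` normalizes across tumor columns (the
    default); ``axis='guides'`` normalizes the transposed submatrix.  Genes
    with a single guide are passed through unchanged with a warning.
    """
    if axis not in ("tumors", "guides"):
        raise ValueError("axis must be 'tumors' or 'guides'")
    out = dep.copy()
    groups = [NTC_GENE] + library.genes() if library.ntc_count() else library.genes()
    for gene in groups:
        guides = [g for g in library.guides_for(gene) if g in dep.index]
        if len(guides) < 2:
            warnings.warn(f"gene {gene!r} has fewer than 2 guides; passed through unchanged")
            continue
        sub = dep.loc[guides]
        if axis == "tumors":
            out.loc[guides] = quantile_normalize(sub, tie_rule=tie_rule)
        else:
            out.loc[guides] = quantile_normalize(sub.T, tie_rule=tie_rule).T
    return out
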