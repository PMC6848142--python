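"""Differential proximity-interactome filter.

Given bait-prey tables from proximity labeling / AP-MS across wild-type and
knockout cell lines — spectral counts plus an externally computed interaction
probability score per (bait, prey, line, condition) — identify the preys whose
bait proximity is modulated by the knockout.  A prey is a candidate when, in
at least ``min_lines`` cell lines and with a consistent direction, the
probability score changes by more than ``prob_delta_min`` between WT and KO
and the (pseudocounted) spectral-count ratio exceeds ``fc_min`` (gained) or
falls below ``1/fc_min`` (lost).  KO subclone replicates are averaged within
a cell line before the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CandidateSet", "collapse_by_gene", "modulated_interactors"]

_REQUIRED = ["bait", "prey_gene", "cell_line", "condition", "spectral_count", "probability"]


@dataclass
class CandidateSet:
    """Preys passing the modulated-interactor filter, with per-line evidence.

    ``evidence`` is a per (prey, line) table of probability deltas (KO - WT)
    and pseudocounted KO/WT spectral-count fold changes; ``members`` maps each
    passing prey to its direction ('gained' or 'lost' in KO).
    """

    members: dict[str, str]
    evidence: pd.DataFrame
    thresholds: dict

    @property
    def preys(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, prey: str) -> bool:
        return prey in self.members


def collapse_by_gene(psm_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse peptide/PSM-level rows to one record per gene.

    Spectral counts are summed per (bait, prey gene, cell line, condition,
    replicate); gene symbols are upper-cased before collapsing so mixed-case
    rows merge.  Probability scores, when present, are taken as the maximum
    over collapsed rows (they are per bait-prey scores repeated across
    peptides).  Rows lacking a gene name are dropped; returns (table,
    number of dropped rows).
    """
    df = psm_table.copy()
    if "prey_gene" not in df.columns:
        raise ValueError("table lacks a prey_gene column")
    missing = df["prey_gene"].isna() | (df["prey_gene"].astype(str).str.strip() == "")
    dropped = int(missing.sum())
    df = df.loc[~missing].copy()
    df["prey_gene"] = df["prey_gene"].astype(str).str.upper()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    keys = ["bait", "prey_gene", "cell_line", "condition", "replicate"]
    agg = {"spectral_count": "sum"}
    if "probability" in df.columns:
        agg["probability"] = "max"
    out = df.groupby(keys, as_index=False).agg(agg)
    return out, dropped


def _per_line_evidence(records: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    """KO-vs-WT probability delta and count fold change per (prey, line)."""
    df = records.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    # Average KO subclone replicates (and any WT replicates) within a line.
    per_cond = (
        df.groupby(["prey_gene", "cell_line", "condition"], as_index=False)
        .agg(spectral_count=("spectral_count", "mean"), probability=("probability", "mean"))
    )
    wide = per_cond.pivot(index=["prey_gene", "cell_line"], columns="condition")
    for cond in ("WT", "KO"):
        if ("probability", cond) not in wide.columns:
            raise ValueError(f"missing {cond} records")
    ev = pd.DataFrame(index=wide.index)
    ev["prob_delta"] = wide[("probability", "KO")] - wide[("probability", "WT")]
    ev["fold_change"] = (wide[("spectral_count", "KO")] + pseudocount) / (
        wide[("spectral_count", "WT")] + pseudocount
    )
    ev["wt_missing"] = wide[("spectral_count", "WT")].isna()
    ev["ko_missing"] = wide[("spectral_count", "KO")].isna()
    # A prey seen in only one condition is scored through the pseudocount.
    ev["fold_change"] = (
        wide[("spectral_count", "KO")].fillna(0.0) + pseudocount
    ) / (wide[("spectral_count", "WT")].fillna(0.0) + pseudocount)
    ev["prob_delta"] = (
        wide[("probability", "KO")].fillna(0.0) - wide[("probability", "WT")].fillna(0.0)
    )
    return ev.reset_index()


def modulated_interactors(
    records: pd.DataFrame,
    prob_delta_min: float = 0.25,
    fc_min: float = 1.5,
    min_lines: int = 2,
    pseudocount: float = 0.5,
) -> CandidateSet:
    """Preys whose bait proximity differs reproducibly between WT and KO.

    Per cell line a prey supports 'gained' when the KO-WT probability delta
    exceeds ``prob_delta_min`` AND the pseudocounted KO/WT spectral-count
    ratio exceeds ``fc_min``; it supports 'lost' under the mirrored
    conditions (delta < -prob_delta_min, ratio < 1/fc_min).  A prey is a
    candidate when at least ``min_lines`` lines support the same direction;
    preys with conflicting directions across their supporting lines are
    excluded.
    """
    missing = set(_REQUIRED) - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    if ((records["probability"] < 0) | (records["probability"] > 1)).any():
        raise ValueError("probability scores must lie in [0, 1]")
    ev = _per_line_evidence(records, pseudocount)
    ev["gained"] = (ev["prob_delta"] > prob_delta_min) & (ev["fold_change"] > fc_min)
    ev["lost"] = (ev["prob_delta"] < -prob_delta_min) & (ev["fold_change"] < 1.0 / fc_min)

    members: dict[str, str] = {}
    for prey, sub in ev.groupby("prey_gene", sort=True):
        n_gained = int(sub["gained"].sum())
        n_lost = int(sub["lost"].sum())
        if n_gained >= min_lines and n_lost == 0:
            members[str(prey)] = "gained"
        elif n_lost >= min_lines and n_gained == 0:
            members[str(prey)] = "lost"
    return CandidateSet(
        members=members,
        evidence=ev,
        thresholds={
            "prob_delta_min": prob_delta_min,
            "fc_min": fc_min,
            "min_lines": min_lines,
            "pseudocount": pseudocount,
        },
    )
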