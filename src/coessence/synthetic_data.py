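"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, each seeded and deterministic:

* ``simulate_screen`` — a pooled in-vivo CRISPR tumorigenesis screen: a guide
  library (targeting guides plus non-targeting controls) with log-normal
  baseline representation, a per-tumor engraftment bottleneck (multinomial
  draw of a limited number of cells), per-guide exponential growth scaled by
  gene fitness effects, an optional shared latent effect that plants
  co-essential gene pairs, and multinomial sequencing to a fixed depth.
* ``simulate_isotherm`` — a 16-point two-fold MST titration with additive
  Gaussian noise around the mass-action binding curve for a known Kd.
* ``simulate_interactome`` — WT/KO bait-prey tables (spectral counts plus
  externally-computed probability scores) across cell lines with a known set
  of modulated preys.

The defaults mirror the emulated study: 500 non-targeting guides plus ~500
guides over 6 genes read out in 14 tumors and a baseline pool, 20 nM labeled
target in the binding assay, and three cell lines with duplicate KO subclones
in the interactome tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binding
from .screen_io import NTC_GENE, CountMatrix, GuideLibrary

__all__ = [
    "ScreenSimConfig",
    "ScreenTruth",
    "simulate_screen",
    "simulate_isotherm",
    "simulate_interactome",
    "default_screen_config",
]

_BASES = np.array(list("ACGT"))


@dataclass
class ScreenSimConfig:
    """Configuration of one simulated pooled screen.

    ``gene_effects`` maps gene name to a mean log2 fitness effect per tumor
    doubling-equivalent (negative = depleted in tumors).  ``coessential_pairs``
    plants correlated fitness: each (gene_a, gene_b, latent_sd) adds one shared
    N(0, latent_sd) draw per tumor to both genes' effects.  ``count_dispersion``
    adds Gamma-Poisson overdispersion at the sequencing step (0 = pure
    multinomial, column sums exactly equal the requested depth).
    ``bottleneck_cells`` is the number of injected cells that seed each tumor.
    """

    n_target_genes: int = 6
    guides_per_gene: int = 83
    n_ntc: int = 500
    n_tumors: int = 14
    baseline_depth: int = 1_000_000
    tumor_depth: int = 1_000_000
    bottleneck_cells: int = 10_000
    gene_effects: dict[str, float] = field(default_factory=dict)
    coessential_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    count_dispersion: float = 0.0
    guide_noise_sd: float = 0.1
    baseline_lognormal_sd: float = 0.5
    gene_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_target_genes, self.n_tumors, self.baseline_depth,
               self.tumor_depth, self.bottleneck_cells) <= 0:
            raise ValueError("all counts and depths must be positive")
        if self.guides_per_gene < 2:
            raise ValueError("guides_per_gene must be >= 2 (pair correlations need >= 2 guides)")
        if self.n_ntc < 2:
            raise ValueError("n_ntc must be >= 2")
        if self.count_dispersion < 0 or self.guide_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if self.gene_names is None:
            self.gene_names = [f"GENE{i + 1:02d}" for i in range(self.n_target_genes)]
        if len(self.gene_names) != self.n_target_genes:
            raise ValueError("gene_names length must equal n_target_genes")
        known = set(self.gene_names)
        for g in self.gene_effects:
            if g not in known:
                raise ValueError(f"gene_effects names unknown gene {g!r}")
        for a, b, sd in self.coessential_pairs:
            if a not in known or b not in known:
                raise ValueError(f"coessential pair ({a}, {b}) names a gene not in the library")
            if sd < 0:
                raise ValueError("latent_sd must be non-negative")


@dataclass
class ScreenTruth:
    """Ground truth emitted alongside a simulated screen."""

    realized_effects: pd.DataFrame  # genes x tumors, realized log2 effect
    coessential_pairs: list[tuple[str, str, float]]
    baseline_abundance: pd.Series  # per-guide relative abundance


def _random_sequences(n: int, rng: np.random.Generator, length: int = 20) -> list[str]:
    """Distinct random 20-mers (resampled on collision)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _build_library(config: ScreenSimConfig, rng: np.random.Generator) -> GuideLibrary:
    rows = []
    for gene in config.gene_names:
        for j in range(config.guides_per_gene):
            rows.append((f"{gene}_sg{j + 1:03d}", gene))
    for j in range(config.n_ntc):
        rows.append((f"NTC_sg{j + 1:03d}", NTC_GENE))
    seqs = _random_sequences(len(rows), rng)
    df = pd.DataFrame(rows, columns=["guide_id", "gene"])
    df["sequence"] = seqs
    return GuideLibrary(records=df)


def simulate_screen(config: ScreenSimConfig) -> tuple[GuideLibrary, CountMatrix, ScreenTruth]:
    """Simulate one pooled screen: baseline pool plus per-tumor counts.

    Mechanism per tumor: (i) a multinomial engraftment bottleneck of
    ``bottleneck_cells`` cells drawn from the baseline guide abundances,
    (ii) per-guide growth by ``2**(gene effect + shared latent effect +
    guide-level noise)`` (zero for non-targeting guides), (iii) multinomial
    sequencing to ``tumor_depth`` reads, optionally overdispersed by
    per-guide Gamma weights with variance ``count_dispersion``.

    Returns (library, counts, truth); the count matrix's first column is the
    baseline pool.
    """
    rng = np.random.default_rng(config.seed)
    library = _build_library(config, rng)
    n_guides = len(library.records)
    genes = library.records["gene"].to_numpy()

    # Baseline representation: uneven library, log-normal.
    abundance = rng.lognormal(mean=0.0, sigma=config.baseline_lognormal_sd, size=n_guides)
    p_base = abundance / abundance.sum()
    baseline_counts = rng.multinomial(config.baseline_depth, p_base)

    # Realized per-gene per-tumor effects = fixed effect + shared latent draws.
    effects = np.zeros((config.n_target_genes, config.n_tumors))
    for i, gene in enumerate(config.gene_names):
        effects[i, :] += config.gene_effects.get(gene, 0.0)
    for a, b, sd in config.coessential_pairs:
        z = rng.normal(0.0, sd, size=config.n_tumors)
        effects[config.gene_names.index(a), :] += z
        effects[config.gene_names.index(b), :] += z

    gene_index = {g: i for i, g in enumerate(config.gene_names)}
    columns = {"baseline": baseline_counts}
    for t in range(config.n_tumors):
        cells = rng.multinomial(config.bottleneck_cells, p_base).astype(float)
        guide_effect = np.array(
            [effects[gene_index[g], t] if g != NTC_GENE else 0.0 for g in genes]
        )
        if config.guide_noise_sd > 0:
            guide_effect = guide_effect + rng.normal(0.0, config.guide_noise_sd, size=n_guides)
        weights = cells * np.exp2(guide_effect)
        if config.count_dispersion > 0:
            shape = 1.0 / config.count_dispersion
            weights = weights * rng.gamma(shape, scale=1.0 / shape, size=n_guides)
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("all guides lost in bottleneck; increase bottleneck_cells")
        columns[f"tumor{t + 1:02d}"] = rng.multinomial(config.tumor_depth, weights / total)

    counts = pd.DataFrame(columns, index=library.guide_ids)
    truth = ScreenTruth(
        realized_effects=pd.DataFrame(
            effects, index=config.gene_names,
            columns=[f"tumor{t + 1:02d}" for t in range(config.n_tumors)],
        ),
        coessential_pairs=list(config.coessential_pairs),
        baseline_abundance=pd.Series(p_base, index=library.guide_ids),
    )
    return library, CountMatrix(counts=counts, baseline="baseline"), truth


def default_screen_config(**overrides) -> ScreenSimConfig:
    """The emulated study geometry: 6 genes x 83 guides + 500 NTC, 14 tumors."""
    return ScreenSimConfig(**overrides)


def simulate_isotherm(
    kd_nM: float,
    a0_nM: float = 20.0,
    top_ligand_nM: float = 5000.0,
    n_points: int = 16,
    fold: float = 2.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> binding.TitrationSeries:
    """Synthetic MST titration around a known Kd (``inf`` for a non-binder).

    Ligand concentrations are ``top_ligand_nM / fold**i`` for i = 0..n-1
    (final assay concentrations); the response is
    ``baseline + amplitude * fraction_bound / a0 + N(0, noise_sd)``.
    """
    if not (kd_nM > 0):
        raise ValueError("kd_nM must be positive (inf for a non-binder)")
    if n_points < 4:
        raise ValueError("need at least 4 titration points")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    rng = np.random.default_rng(seed)
    t0 = top_ligand_nM / fold ** np.arange(n_points)
    response = baseline + amplitude * binding.fraction_bound(a0_nM, t0, kd_nM) / a0_nM
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=n_points)
    return binding.TitrationSeries(T0_values=t0, responses=response, n_points=n_points, fold=fold)


def simulate_interactome(
    n_preys: int = 50,
    n_lines: int = 3,
    modulated_preys: list[str] | int = 5,
    prob_delta: float = 0.3,
    fc: float = 2.0,
    base_counts: float = 30.0,
    n_ko_replicates: int = 2,
    prob_noise_sd: float = 0.02,
    bait: str = "KRAS",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """WT/KO bait-prey tables with a planted set of modulated preys.

    Each prey gets, per cell line, one WT record and ``n_ko_replicates`` KO
    subclone records carrying a spectral count (Poisson around
    ``base_counts``, scaled by ``fc`` in KO for modulated preys) and a
    probability score (WT baseline U(0.2, 0.6); modulated preys shifted by
    ``prob_delta`` in KO, everything jittered by N(0, prob_noise_sd) — kept
    small relative to the filter margin so planted deltas hold in every line — and
    clipped to [0, 1]).  Returns (long-format table, list of modulated preys).
    """
    rng = np.random.default_rng(seed)
    preys = [f"PREY{i + 1:03d}" for i in range(n_preys)]
    if isinstance(modulated_preys, int):
        if modulated_preys > n_preys:
            raise ValueError("more modulated preys than preys")
        modulated = preys[:modulated_preys]
    else:
        unknown = set(modulated_preys) - set(preys)
        if unknown:
            raise ValueError(f"modulated preys not in prey set: {sorted(unknown)}")
        modulated = list(modulated_preys)
    mod_set = set(modulated)

    rows = []
    for line_i in range(n_lines):
        line = f"LINE{line_i + 1}"
        for prey in preys:
            wt_prob = rng.uniform(0.2, 0.6)
            wt_count = rng.poisson(base_counts)
            rows.append((bait, prey, line, "WT", 1,
                         int(wt_count),
                         float(np.clip(wt_prob + rng.normal(0, prob_noise_sd), 0, 1))))
            ko_prob = wt_prob + (prob_delta if prey in mod_set else 0.0)
            ko_mu = base_counts * (fc if prey in mod_set else 1.0)
            for rep in range(n_ko_replicates):
                rows.append((bait, prey, line, "KO", rep + 1,
                             int(rng.poisson(ko_mu)),
                             float(np.clip(ko_prob + rng.normal(0, prob_noise_sd), 0, 1))))
    table = pd.DataFrame(
        rows,
        columns=["bait", "prey_gene", "cell_line", "condition", "replicate",
                 "spectral_count", "probability"],
    )
    return table, modulated
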