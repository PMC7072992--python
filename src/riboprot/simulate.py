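"""Synthetic data with the structure the analysis modules assume.

Three generators, all pure functions of (configuration, seed):

* :func:`simulate_counts` — negative-binomial gene × sample read counts for
  XX/XY gonads across developmental stages, with a configurable set of
  planted sexually dimorphic genes and optional sex-reversed (SSR) samples,
  plus the generating truth for parameter-recovery tests.
* :func:`simulate_additive_distances` — a random binary tree and its exact
  patristic distance matrix, the oracle input for neighbor-joining.
* :func:`simulate_catalog` — an RP-style gene catalog whose names exercise
  the paralog suffix grammar.

The count model is NB(mean μ, variance μ + φμ²) with dispersion φ. Gene
means follow RPKM-scale baselines: μ = b_g · s_t · f_sex · L_g · N_s / 1e9
for gene baseline b_g (log-normal across genes), stage multiplier s_t, sex
fold f_sex, gene length L_g (bp) and library size N_s. Planted dimorphic
genes carry their fold in the stated direction at every stage; all other
genes have no sex effect, so the XY/XX ratio of an un-planted gene is 1 in
expectation at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .catalog import RPCatalog, RPGene
from .expression import CountsMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_additive_distances",
    "simulate_catalog",
    "default_planted",
]

#: Default stage multipliers: gonadal RP expression peaks around the onset
#: of differentiation (5–30 dah) and falls several-fold by 90–180 dah.
DEFAULT_STAGE_EFFECTS = {5: 1.5, 30: 1.6, 90: 0.45, 180: 0.45}


def default_planted(n_genes: int = 92) -> list[tuple[int, str, float]]:
    """Eleven planted dimorphic genes (nine XY-high, two XX-high) at fold 4,
    the configuration of the real data's dimorphic set."""
    idx = np.linspace(0, n_genes - 1, 11).astype(int)
    return [
        (int(i), "XY_high" if k < 9 else "XX_high", 4.0) for k, i in enumerate(idx)
    ]


@dataclass
class SimConfig:
    """Parameters of the gonadal count simulation.

    ``planted_dimorphic`` lists (gene index, direction, fold) with fold ≥ 1;
    direction is "XY_high" or "XX_high". ``baseline_scale`` multiplies every
    mean (0 gives all-zero counts). ``ssr_mode`` controls whether the SSR
    (sex-reversed XX) samples generated at the last stage draw from
    XY-direction means ("follows_XY", the biological expectation) or stay at
    XX means ("follows_XX", a negative control); None disables SSR samples.
    """

    n_genes: int = 92
    stages: Sequence[int] = (5, 30, 90, 180)
    replicates_per_group: int = 3
    # median ≈ 190 RPKM, mean ≈ 330 RPKM: keeps the simulated gene set at a
    # modest share (~15%) of each library, so RPKM normalization is free of
    # composition bias from the planted sex effects
    baseline_log2_mean: float = 7.6
    baseline_log2_sd: float = 1.5
    baseline_scale: float = 1.0
    stage_effects: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_EFFECTS)
    )
    planted_dimorphic: Sequence[tuple[int, str, float]] = field(
        default_factory=default_planted
    )
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (20_000_000, 40_000_000)
    gene_length_range_bp: tuple[int, int] = (900, 8000)
    ssr_mode: Optional[str] = "follows_XY"
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for i, direction, fold in self.planted_dimorphic:
            if fold < 1:
                raise ValueError(f"planted fold must be >= 1, got {fold}")
            if direction not in ("XY_high", "XX_high"):
                raise ValueError(f"unknown direction {direction!r}")
            if not 0 <= i < self.n_genes:
                raise ValueError(f"planted gene index {i} out of range")
        if self.ssr_mode not in (None, "follows_XY", "follows_XX"):
            raise ValueError(f"unknown ssr_mode {self.ssr_mode!r}")


@dataclass
class SimTruth:
    """Generating parameters behind one simulated dataset."""

    planted: list[tuple[str, str, float]]  # (gene, direction, fold)
    true_means: pd.DataFrame  # gene × group expected RPKM
    gene_baseline_rpkm: pd.Series

    @property
    def planted_genes(self) -> set[str]:
        return {g for g, _, _ in self.planted}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion·mean²."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _sex_fold(direction: str, fold: float, genotype: str) -> float:
    """Multiplier applied to one genotype so the XY/XX mean ratio equals
    fold (XY_high) or 1/fold (XX_high)."""
    if genotype == "XY":
        return fold if direction == "XY_high" else 1.0
    return fold if direction == "XX_high" else 1.0


def simulate_counts(
    cfg: SimConfig,
) -> tuple[CountsMatrix, pd.DataFrame, pd.Series, SimTruth]:
    """Simulate gonadal read counts.

    Returns (counts, sample metadata, gene lengths in bp, truth). Sample ids
    are ``<genotype>_<stage>dah_r<k>``; metadata has columns ``stage`` and
    ``genotype`` (XX, XY and, if enabled, SSR at the last stage).
    Deterministic for a given config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:03d}" for i in range(cfg.n_genes)]
    lengths = pd.Series(
        rng.integers(*cfg.gene_length_range_bp, size=cfg.n_genes), index=genes,
        name="gene_length_bp",
    )
    baseline = cfg.baseline_scale * np.exp2(
        rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=cfg.n_genes)
    )
    planted = {i: (d, f) for i, d, f in cfg.planted_dimorphic}

    groups: list[tuple[int, str]] = [
        (s, g) for s in cfg.stages for g in ("XX", "XY")
    ]
    if cfg.ssr_mode is not None:
        groups.append((max(cfg.stages), "SSR"))

    columns, col_means, meta_rows = [], [], []
    true_means: dict[str, np.ndarray] = {}
    for stage, genotype in groups:
        s_t = cfg.stage_effects.get(stage, 1.0)
        # SSR fish are genotypically XX; in follows_XY mode their planted
        # genes express at XY-direction means (phenotype, not genotype)
        effective = {"SSR": "XY" if cfg.ssr_mode == "follows_XY" else "XX"}.get(
            genotype, genotype
        )
        fold_vec = np.ones(cfg.n_genes)
        for i, (d, f) in planted.items():
            fold_vec[i] = _sex_fold(d, f, effective)
        rpkm_mean = baseline * s_t * fold_vec
        true_means[f"{genotype}_{stage}dah"] = rpkm_mean
        for k in range(cfg.replicates_per_group):
            sid = f"{genotype}_{stage}dah_r{k + 1}"
            n_lib = int(rng.integers(*cfg.library_size_range))
            mu = rpkm_mean * lengths.to_numpy() * n_lib / 1e9
            columns.append((sid, n_lib))
            col_means.append(mu)
            meta_rows.append({"sample_id": sid, "stage": stage, "genotype": genotype})

    counts = np.column_stack(
        [_nb_draw(rng, mu, cfg.nb_dispersion) for mu in col_means]
    )
    lib = pd.Series({sid: n for sid, n in columns}, name="library_size")
    # library size is total mapped reads; keep it at least the RP-gene sum
    lib = pd.concat([lib, pd.Series(counts.sum(axis=0), index=lib.index)], axis=1).max(axis=1)
    cm = CountsMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=[sid for sid, _ in columns]),
        library_sizes=lib,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = SimTruth(
        planted=[(genes[i], d, f) for i, d, f in cfg.planted_dimorphic],
        true_means=pd.DataFrame(true_means, index=genes),
        gene_baseline_rpkm=pd.Series(baseline, index=genes),
    )
    return cm, meta, lengths, truth


def simulate_additive_distances(
    n_leaves: int,
    branch_length_range: tuple[float, float] = (0.05, 1.0),
    seed: int = 0,
) -> tuple[TreeNode, DistanceMatrix]:
    """Random binary tree plus its exactly additive patristic distances.

    Leaves are named L1..Ln. The matrix of leaf-to-leaf path lengths is
    additive by construction, so neighbor-joining must reconstruct the
    generating topology from it.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    lo, hi = branch_length_range

    subtrees = [TreeNode(name=f"L{i + 1}") for i in range(n_leaves)]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        parent = TreeNode()
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent.extend([a, b])
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(parent)
    root = TreeNode()
    for s in subtrees:
        s.length = float(rng.uniform(lo, hi))
        root.append(s)

    dm_raw = root.tip_tip_distances()
    order = [f"L{i + 1}" for i in range(n_leaves)]
    dm = DistanceMatrix(
        np.array([[dm_raw[a, b] for b in order] for a in order]), order
    )
    return root, dm


def simulate_catalog(
    n_families: int,
    duplication_profile: Sequence[frozenset | set] | None = None,
    seed: int = 0,
    species_label: str = "synthetic",
) -> RPCatalog:
    """Random RP-style catalog whose names exercise the suffix grammar.

    ``duplication_profile`` gives, for the first families, which WGD eras
    the family retained duplicates from, as subsets of {"2R", "3R"}:
    {"2R","3R"} → four members base-1a/-1b/-2a/-2b, {"2R"} → base-1/base-2,
    {"3R"} → basea/baseb, {} → singleton. Remaining families are singletons.
    Every seventh singleton base gets a trailing uppercase "A" (a canonical
    protein name, not a duplicate index). Linkage groups are drawn uniformly
    from the tilapia set of 22.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    profile = list(duplication_profile or [])
    if len(profile) > n_families:
        raise ValueError("profile longer than n_families")
    rng = np.random.default_rng(seed)
    lgs = [f"LG{i}" for i in range(1, 24) if i != 21]  # LG21 merged into LG16

    genes: list[RPGene] = []
    for fam in range(n_families):
        subunit = "RPS" if fam % 2 == 0 else "RPL"
        base = f"{subunit}{fam + 50}"
        events = set(profile[fam]) if fam < len(profile) else set()
        if not events and fam % 7 == 3:
            base += "A"
        if events == {"2R", "3R"}:
            members = [f"{base}-1a", f"{base}-1b", f"{base}-2a", f"{base}-2b"]
        elif events == {"2R"}:
            members = [f"{base}-1", f"{base}-2"]
        elif events == {"3R"}:
            members = [f"{base}a", f"{base}b"]
        else:
            members = [base]
        for name in members:
            length = int(rng.integers(900, 8001))
            genes.append(
                RPGene(
                    name=name,
                    accession_label=f"LOC{rng.integers(100000000, 110000000)}",
                    linkage_group=str(rng.choice(lgs)),
                    exon_count=int(rng.integers(3, 11)),
                    gene_length_bp=length,
                    protein_length_aa=max(25, length // 30),
                )
            )
    return RPCatalog(genes=genes, species_label=species_label)
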