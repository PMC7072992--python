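"""Gonadal expression analysis: RPKM, ratio bins, dimorphism, sex reversal.

The analysis takes gene-level read counts for XX and XY gonads sampled at
four developmental stages (5, 30, 90, 180 days after hatching), normalizes
to RPKM (reads per kilobase of transcript per million mapped reads),

    RPKM = counts * 1e9 / (gene_length_bp * library_size),

and classifies each gene at each stage by its XY/XX ratio of group-mean
RPKM into three bins: XX-biased (ratio < 0.5), unbiased (0.5–2, closed
interval), XY-biased (ratio > 2). A gene is called sexually dimorphic when
it falls in the same biased bin at every examined stage. For secondary
sex-reversed (SSR) fish — genotypic XX masculinized by aromatase-inhibitor
feeding — a dimorphic call is concordant when the SSR/XX ratio follows the
phenotypic (XY) direction rather than the genotype.

No count-based significance test is applied: the binning itself is the
differential-expression criterion, by design. A small pseudocount (default
0.1 RPKM) keeps ratios finite for silent genes; at typical RP expression
levels (hundreds to thousands of RPKM) it is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountsMatrix",
    "DimorphismCall",
    "STAGES",
    "BINS",
    "rpkm",
    "group_samples",
    "group_stats",
    "count_above",
    "ratio_classify",
    "bin_counts",
    "call_dimorphic",
    "ssr_concordance",
]

#: Developmental stages examined, in days after hatching (dah).
STAGES = (5, 30, 90, 180)

#: Ratio bins, in (XX_biased, unbiased, XY_biased) order.
BINS = ("XX_biased", "unbiased", "XY_biased")

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class CountsMatrix:
    """Gene × sample read counts with per-sample library sizes.

    ``library_sizes`` are total mapped reads per sample and must be at least
    the per-sample count sum (the genes here are a subset of the library).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise ValueError(f"samples without library size: {missing}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        short = self.library_sizes < self.counts.sum(axis=0)
        if short.any():
            raise ValueError(
                f"library size smaller than column count sum for "
                f"{self.library_sizes.index[short].tolist()}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DimorphismCall:
    """A gene biased in the same direction at every examined stage."""

    gene: str
    direction: str  # "XY_high" or "XX_high"
    stages_supporting: tuple[int, ...]
    ssr_concordant: Optional[bool] = None


def rpkm(counts: CountsMatrix, gene_lengths_bp: pd.Series) -> pd.DataFrame:
    """RPKM-normalize a counts matrix: counts·1e9 / (length_bp · library size)."""
    lengths = pd.Series(gene_lengths_bp).reindex(counts.genes)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene length for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    c = counts.counts.to_numpy(dtype=float)
    values = c * 1e9 / (lengths.to_numpy(dtype=float)[:, None]
                        * counts.library_sizes.to_numpy(dtype=float)[None, :])
    return pd.DataFrame(values, index=counts.genes, columns=counts.samples)


def group_samples(
    meta: pd.DataFrame,
    stage: int | None = None,
    genotype: str | None = None,
    tissue: str | None = None,
) -> list[str]:
    """Sample ids matching a (stage, genotype) or tissue selection."""
    mask = pd.Series(True, index=meta.index)
    if stage is not None:
        mask &= meta["stage"] == stage
    if genotype is not None:
        mask &= meta["genotype"] == genotype
    if tissue is not None:
        mask &= meta["tissue"] == tissue
    return list(meta.index[mask])


def _group_means(expr: pd.DataFrame, samples: Sequence[str]) -> pd.Series:
    if len(samples) == 0:
        raise ValueError("empty sample group")
    return expr[list(samples)].mean(axis=1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def group_stats(expr: pd.DataFrame, samples: Sequence[str]) -> tuple[int, int]:
    """(total, average) RPKM over all genes for one sample group.

    Replicates are averaged per gene first; total is the sum of those gene
    means and average = total / n_genes. Both are rounded half-up to whole
    RPKM, the precision at which such summaries are reported.
    """
    means = _group_means(expr, samples)
    total = float(means.sum())
    return _round_half_up(total), _round_half_up(total / len(means))


def count_above(expr: pd.DataFrame, samples: Sequence[str], threshold: float) -> int:
    """Number of genes whose group-mean RPKM exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return int((_group_means(expr, samples) > threshold).sum())


def ratio_classify(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    stage: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene XY/XX ratio and bin at one stage.

    ratio = (mean XY RPKM + pseudocount) / (mean XX RPKM + pseudocount);
    bins: < 0.5 XX_biased, [0.5, 2] unbiased (closed interval), > 2 XY_biased.
    Returns a DataFrame indexed by gene with columns ``ratio`` and ``bin``.
    """
    xx = group_samples(meta, stage=stage, genotype="XX")
    xy = group_samples(meta, stage=stage, genotype="XY")
    if not xx or not xy:
        raise ValueError(f"stage {stage}: need both XX and XY samples")
    ratio = (_group_means(expr, xy) + pseudocount) / (_group_means(expr, xx) + pseudocount)
    bins = pd.Series(
        np.select([ratio < 0.5, ratio > 2.0], ["XX_biased", "XY_biased"], "unbiased"),
        index=ratio.index,
    )
    return pd.DataFrame({"ratio": ratio, "bin": bins})


def bin_counts(classification: pd.DataFrame) -> tuple[int, int, int]:
    """(n_XX_biased, n_unbiased, n_XY_biased); the three sum to n_genes."""
    vc = classification["bin"].value_counts()
    return tuple(int(vc.get(b, 0)) for b in BINS)


def call_dimorphic(
    classifications: Mapping[int, pd.DataFrame]
) -> list[DimorphismCall]:
    """Genes in the same biased bin at every stage of ``classifications``.

    XY_high requires XY_biased at all stages, XX_high requires XX_biased at
    all stages; any unbiased or opposite-bin stage disqualifies the gene.
    """
    if not classifications:
        raise ValueError("no stage classifications given")
    stages = tuple(sorted(classifications))
    bins = pd.DataFrame({s: classifications[s]["bin"] for s in stages})
    if bins.isna().any().any():
        raise ValueError("stages classify different gene sets")
    calls = []
    for gene, row in bins.iterrows():
        if (row == "XY_biased").all():
            calls.append(DimorphismCall(gene, "XY_high", stages))
        elif (row == "XX_biased").all():
            calls.append(DimorphismCall(gene, "XX_high", stages))
    return calls


def ssr_concordance(
    calls: Iterable[DimorphismCall],
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    stage: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DimorphismCall]:
    """Check whether dimorphic genes follow phenotype in sex-reversed fish.

    For each call, the ratio (SSR mean + pc) / (control XX mean + pc) is
    computed at ``stage`` (default: the only stage with SSR samples). An
    XY_high call is concordant when that ratio > 2 — the genotypically XX
    but phenotypically male gonad expresses the gene at male levels — and an
    XX_high call when the ratio < 0.5. Without SSR samples the calls are
    returned with ``ssr_concordant`` left unset.
    """
    calls = list(calls)
    ssr_meta = meta[meta["genotype"] == "SSR"]
    if ssr_meta.empty:
        return calls
    if stage is None:
        ssr_stages = sorted(set(ssr_meta["stage"]))
        if len(ssr_stages) > 1:
            raise ValueError(f"SSR samples at several stages {ssr_stages}; pass stage=")
        stage = ssr_stages[0]
    ssr = group_samples(meta, stage=stage, genotype="SSR")
    xx = group_samples(meta, stage=stage, genotype="XX")
    if not xx:
        raise ValueError(f"stage {stage}: no control XX samples")
    ratio = (_group_means(expr, ssr) + pseudocount) / (_group_means(expr, xx) + pseudocount)
    out = []
    for call in calls:
        r = float(ratio.loc[call.gene])
        ok = r > 2.0 if call.direction == "XY_high" else r < 0.5
        out.append(DimorphismCall(call.gene, call.direction, call.stages_supporting, ok))
    return out
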