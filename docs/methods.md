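# Methods

## The catalog and its name grammar

The catalog container stores the printed gene table verbatim: gene length is
the transcription-unit length in bp as published and is treated as an opaque
value (whether it includes UTRs is not derivable from the table; no
coordinate arithmetic is done on it). Summaries are rounded at the printed
precision — kb to 2 decimals, mean exon count to 1 decimal — so that
reported values can be compared digit-for-digit with the published ones.

Paralog families are derived purely from the name grammar
`base[-digit][a|b]`: a `-1/-2` index marks a duplicate pair retained from
the ancient vertebrate WGDs (2R), a trailing lowercase `a/b` the
teleost-specific WGD (3R). Only lowercase `a/b` is consumed, so canonical
protein names ending in uppercase letters (RPSA, RPS27A, RPL13A, …) remain
distinct bases automatically, with no whitelist to maintain. The grammar
accepts any name (an unsuffixed name is its own singleton family), so no
gene can be dropped by parsing.

One caveat the tests encode: the published prose calls RPL41b the smallest
gene (~0.91 kb) while the table itself prints 911 bp for RPL41a and 1905 bp
for RPL41b. The package ships the table as printed, so the argmin is
RPL41a; the minimum value (0.91 kb) is unchanged.

## Neighbor-joining and bootstrap

NJ uses the Studier–Keppler criterion Q(i,j) = (n−2)d(i,j) − r(i) − r(j)
with the standard limb-length formulas; ties in Q are broken at the first
row-major minimum, making the algorithm deterministic for a fixed input
ordering. Negative limb estimates (possible on non-additive inputs) are
clamped to zero with the deficit moved to the sibling limb, preserving the
pair's path length. The result is an unrooted tree stored with a basal
trifurcation. On exactly additive matrices the reconstruction is exact:
every input distance is reproduced as a leaf-to-leaf path within 1e-9
(tested), and the generating topology is recovered for random 5–10-leaf
trees. An independent NJ implementation (scikit-bio's) is used as a
cross-check oracle in the test suite, never as the implementation.

Distances default to the p-distance (proportion of differing sites), a
deliberate simplification: the distance model behind the published trees is
not specified, and for the highly conserved RP sequences involved the
p-distance is nearly linear in divergence. The distance function is
pluggable wherever a matrix is accepted.

Bootstrap supports resample alignment columns with replacement, rebuild the
tree, and score each internal edge of the full-data tree by the percentage
of replicates containing the same bipartition. Bipartitions are compared as
unordered pairs of tip-name sets, so the score is independent of rooting
and leaf order. Supports are reproducible given a seed.

## Duplication-timing verdicts

`classify_duplication` takes the two hypothesized descendant sets of a
duplication (the focal species' copy plus its presumed orthologs, per set)
and requires each to be monophyletic in the unrooted sense — equal to one
side of some edge. The verdict then depends only on the lineage tags of the
two sets and their context:

* **2R** — both sets contain tetrapod and teleost leaves (the split
  predates the fish–tetrapod divergence);
* **4R** — both sets are pure salmonid;
* **lineage-specific** — both sets carry the same single sub-teleost tag
  (e.g. percomorph only);
* **3R** — both sets are teleost-only and at least one tetrapod or pre-3R
  fish (gar, coelacanth) leaf lies outside both, representing the
  un-duplicated state;
* **unresolved** — anything else, notably paraphyletic duplicate sets.

Lineage tags are supplied per leaf by the caller rather than inferred from
taxonomy: the species panels used in this kind of analysis are small,
fixed, and hand-curated anyway. `unresolved` is a deliberate refusal to
guess — paraphyletic situations genuinely occur (the RPL22/RPS27 families)
and are settled by synteny, not topology. `synteny_support` counts shared
neighbor gene names within a ±window of the focal gene in two species'
blocks (orientation agreement reported separately); the verdict upgrade is
left to the analyst as a documented workflow, not automated.

The reported support of a call is the minimum bootstrap of the two
clade-defining edges, or unknown (None) when the tree carries no supports —
absence of supports never changes a verdict.

## Expression analysis

RPKM = c·10⁹/(L·N) with gene length L in bp and library size N = total
mapped reads. Replicates are averaged per gene *before* any ratio or total
is formed (group-mean convention); published group summaries are rounded
half-up to whole RPKM, and the consistency of that convention is checked
against the published per-stage table (printed average = printed total / 92
after rounding, all eight groups).

The XY/XX ratio uses a pseudocount (default 0.1 RPKM) in numerator and
denominator to keep ratios finite for silent genes; at RP expression levels
(hundreds to thousands of RPKM) it is negligible. Bin boundaries follow the
published wording "0.5–2" as a *closed* unbiased interval: a ratio of
exactly 2.0 or 0.5 is unbiased. No count-based significance test is layered
on top — the bins themselves are the differential-expression criterion this
analysis defines, and adding one would change what is being reproduced.

A dimorphism call requires the same biased bin at every examined stage; the
SSR concordance rule mirrors the binning: an XY-high call is concordant
when (SSR + pc)/(control XX + pc) > 2, an XX-high call when < 0.5. This
mirrored-ratio rule is this package's operational definition of a "reversed
expression profile" in sex-reversed fish; no quantitative criterion for it
is published.

## The count simulator

Counts are negative binomial with variance μ + φμ² (dispersion φ = 0.1 by
default, a standard bulk RNA-seq value; the published analysis reports RPKM
point values and states no noise model). Gene baselines are log-normal
(log2 mean 7.6, sd 1.5 → median ≈ 190, mean ≈ 330 RPKM) and gene lengths
uniform on 0.9–8 kb, matching the catalog's range. Stage multipliers
(default 1.5, 1.6, 0.45, 0.45 at 5/30/90/180 dah) reproduce the observed
rise-then-fall of gonadal RP expression. Planted dimorphic genes — default
eleven at fold 4, nine XY-high and two XX-high, the configuration of the
real dimorphic set — have their fold applied to one genotype's mean at
every stage; un-planted genes have expected XY/XX ratio 1 at every stage.
SSR samples are generated at the last stage and draw planted genes from
XY-direction means (`follows_XY`) or XX means (`follows_XX`, a negative
control). All generators are pure functions of (config, seed).

Two deliberate departures from the real data, and why:

* The baseline is scaled so the simulated gene set occupies a modest share
  (~15%) of each library. The library-size floor (N is at least the
  realized count sum) otherwise degenerates into total-count normalization,
  and the planted effects then bias N itself — a composition artifact that
  deflated planted folds by ~12% in an earlier parameterization. Absolute
  RPKM magnitudes are therefore a few-fold lower than the deposited data's
  peak stages; every downstream statistic used here is ratio- or
  rank-based, so this affects nothing but the printed scale.
* Stage multipliers are sex-independent: the real data show a strong global
  XX/XY divergence at 90–180 dah (nearly all genes XY-biased), which is a
  property of those libraries, not of individual genes. Planting it would
  make the cross-stage caller's truth ill-defined. Consequently the
  simulator validates the caller's operating characteristics on planted
  per-gene effects; it does not reproduce the published per-stage bin
  counts (32/50/10 etc.), which depend on the deposited libraries and are
  documented as desk-non-reproducible.

With the default conditions (92 genes, 11 planted at fold 4, φ = 0.1,
3 replicates/group) the caller's sensitivity is ≥ 10/11 with specificity
≥ 95% and full SSR concordance; sensitivity decays monotonically toward
fold 2 (where the planted ratio sits on the bin boundary), which the tests
check across a fold grid.

## ΔΔCt

ΔCt = Ct(target) − Ct(reference) per replicate; ΔΔCt subtracts the
calibrator group's *mean* ΔCt (Livak convention; per-replicate vs mean
calibration is not standardized, and the mean keeps the calibrator's
group-level R at exactly 1). The group-level R is 2 raised to the negative
group-mean ΔΔCt, so log2 R = −ΔΔCt exactly and R is shift-invariant in Ct;
replicate spread is reported as mean ± SD of per-replicate R values (whose
arithmetic mean exceeds the group-level R slightly, by Jensen's
inequality — both are reported, neither is rescaled). ANOVA/post-hoc
significance lettering is out of scope.

## Problem sizes and determinism

The test suite and acceptance script run on small problems throughout: NJ
recovery uses 200 random 5–10-leaf trees, bootstrap examples use ≤ 1000
replicates on ≤ 8 taxa, and caller validation uses ten simulations of the
default 92 × 27 design — sizes chosen because every property checked
(exactness on additive inputs, planted-truth recovery, closed-form
identities) is already fully expressed at this scale. All stochastic steps
take explicit seeds; hypothesis-based property tests are derandomized.

## Known limitations

* Duplicate dating trusts the supplied lineage tags and hypothesized
  paralog sets; it does not detect mislabeled leaves.
* The synteny scorer compares gene name sets in fixed windows; it does not
  align blocks or handle inversions beyond the orientation tally.
* The simulator plants stage-constant fold effects; stage-varying effects
  (a gene dimorphic only late) are not modeled, and real library
  composition effects are deliberately excluded (above).
* Tissue-panel analysis is limited to group summaries over a tissue
  metadata column; no tissue-specificity index is computed.
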