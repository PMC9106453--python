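# Methods

## The sponge model and the triple filter

A ceRNA (sponge) interaction is modelled at the level of steady-state
expression: when a circRNA that carries binding sites for a miRNA rises,
it titrates the miRNA away from its mRNA targets, so the *free* miRNA
signal falls and the target mRNA rises.  Across samples this yields a
characteristic sign pattern — corr(circ, mRNA) > 0, corr(miR, circ) < 0,
corr(miR, mRNA) < 0 — which, combined with predicted binding on both the
circRNA and the mRNA, defines the five-way triple filter in
`cerna.infer_triples`.  Correlations are computed across all samples
pooled: the severity gradient is what generates the co-variation, so
pooling is the intended use; per-group correlation is available but off by
default.  The filter uses `p ≤ p_max` for correlation significance and the
DE caller uses strict `P < p_thresh`, matching the conventions of each
step's community.

Kinetic titration (mass-action occupancy, site competition) is *not*
modelled anywhere; the package works entirely on the correlation
signature that titration leaves in expression data.

## Differential expression

Features are log2 intensities (pre-normalised chipset convention; no
normalisation is applied).  Effect size is the difference of group means
(log2 fold change) and significance is Welch's unequal-variance two-sample
t test — chosen because chipset group variances are rarely equal and the
test needs no distributional pooling; a moderated-variance (limma-style)
test is deliberately out of scope.  A feature is called up (down) when
log2FC > log2(2.0) (< −log2(2.0)) **and** raw P < 0.05.  BH q values are
reported for convenience but do not drive calls.  Zero-variance features
with equal means get p = 1; p = 0 underflow is clamped only for −log10
display in the volcano table, never for inference.

## Duplex scoring

`targets.duplex_align` is a Gotoh local alignment of the miRNA (5'→3')
against the reverse of a target window (antiparallel pairing geometry).
Scoring defaults are miRanda-like: +5 Watson–Crick, +2 G:U wobble, −3
mismatch, affine gaps (−9 open, −4 extend, a length-L gap costing
open + (L−1)·extend), and substitution columns pairing miRNA positions 2–8
multiplied by 2 (the seed weight; gap columns are never weighted).  All
state transitions are allowed, so a gap in one strand may directly follow
a gap in the other at opening cost.  Ties are broken toward the leftmost
target start, then the shorter alignment, with a fixed H > X > Y traceback
preference — reproducibility over arbitrariness.

Seed scanning (`find_seed_matches`) requires exact Watson–Crick pairing of
miRNA positions 2–7 with no G:U, then classifies 7mer-m8 (position 8
paired), 7mer-A1 (target A opposite position 1) and 8mer (both).
Candidate windows extend ±25 nt around each seed hit; overlapping sites of
one (miRNA, target) pair are merged keeping the best score.  The reportable
score threshold defaults to 70 — exactly the score of a bare 7mer-m8 seed
duplex (7 WC columns × 5 × 2) — so every canonical strong seed site is kept
and most chance 6mers are not.

True hybridisation ΔG is replaced by a linear pseudo-energy,
`energy = −0.25 × score` (≈ −17.5 for a bare seed site), because only the
*ranking* by energy is used downstream; a nearest-neighbour thermodynamic
model is a non-goal.  circRNAs are treated as linear sequences:
back-splice-junction-spanning sites are not detected — a known limitation.

## ceRNA pair scoring and selection

The pair score `|shared| · r(circ,mRNA) · mean(|r(miR,circ)|·|r(miR,mRNA)|)`
is repo-defined: it is linear in the number of shared miRNAs, bounded by
the correlation legs, and vanishes when any leg is null.  Shared-miRNA
enrichment is the exact hypergeometric upper tail of the overlap between
the circRNA's and the mRNA's bound-miRNA sets in the assayed miRNA
universe.  Pairs are ranked by (score desc, enrichment p asc, then ids)
and the top 200 kept by default.  Pair "energy" is the sum of per-site
pseudo-energies over both legs — exposed, but not used for ranking.

## Synthetic data

`simulate` draws every feature i.i.d. Normal(baseline 8.0, sd 0.5) on the
log2 scale; each planted axis adds `delta × severity_rank` to its circRNA
and mRNA means and subtracts it from its miRNA mean (rank 0–3 for
control → severe).  Defaults are the study conditions: 4 groups × 4
samples, 20 axes among 120 circRNAs / 40 miRNAs / 120 mRNAs, delta = 1.0
log2-units per rank.  The linear-in-rank effect is the simplest model that
reproduces a monotone DE-count trend across severity contrasts; Gaussian
i.i.d. noise is the simplest model supporting the correlation-sign filter.
The generator does **not** emulate probe-level chemistry, batch effects,
count noise or dropout, so green tests certify the *inference logic*, not
robustness to those artefacts.

Axis sequences carry two exact 7mer-m8 seed complements per target,
placed ≥ 60 nt apart so each stays a distinct locus after window merging
(two sites closer than an alignment window would be reported as one).
Non-axis sequences are uniform random — chance seed matches occur at the
natural background rate.  RNG streams are split per layer from one seed
(`SeedSequence.spawn`), so outputs are byte-identical for a fixed seed.

Immune mixtures are `signature · fractions + N(0, sd)` per gene over a
block-marker signature (each cell type has an exclusive high-expression
marker block), with the NK fraction declining 0.05 per severity rank from
0.25 — emulating the clinical observation that circulating NK share falls
with injury severity.

## Deconvolution

Non-negative least squares on the gene intersection (≥ 10 genes enforced),
then renormalisation to the simplex: absolute abundances are not
identifiable from relative expression without a scale anchor.  NNLS is the
standard transparent surrogate for ν-SVR-based signature tools; the result
carries a method tag.  Scale invariance in the bulk profile is exact.

## Calibrated recovery configuration

`CeRNAConfig.planted_recovery()` is the frozen calibration for recovering
planted axes from simulated data: correlation cutoffs at the defaults
(|r| ≥ 0.3, p ≤ 0.05), target prediction at a 7mer-m8 minimum seed class,
and ≥ 2 predicted sites per (miRNA, target) leg.  The two-site requirement
matches the generator's two planted sites per axis and suppresses
single-site chance seed matches in random sequence, which would otherwise
create triples whose correlation legs are genuinely (but coincidentally)
satisfied by parallel axes.  It was fixed once from a 20-seed Monte-Carlo
under the default conditions and is not adjusted per dataset.

## Problem sizes

Monte-Carlo checks run at the scale the analysis targets: 20 seeds for
axis recovery and trend statistics, 100 seeds for null DE calibration,
200 random pairs for the alignment oracle, 10 random instances for the
triple-filter oracle, and 20 × 50 noisy mixtures for deconvolution error —
sizes at which the reported rates have small enough Monte-Carlo error to
be meaningful while the whole suite stays quick to re-run.

## Known limitations

- Correlation filtering cannot distinguish direct sponging from shared
  upstream drivers; binding-site support narrows but does not remove this.
- The miRNA layer measures *free* miRNA as a proxy for sequestration;
  total-miRNA assays would weaken the negative-correlation signature.
- The DE test assumes approximate normality of log2 intensities within
  groups; paired or moderated designs are unsupported.
- The enrichment background defaults to the union of collection genes;
  platform-restricted backgrounds must be supplied explicitly.
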