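# Methods

## The melt model

A melt curve is modelled as a mixture of independent two-state duplex
species. Species *i* with melting temperature `Tm_i` and width `w_i`
contributes helicity

    theta_i(T) = 1 / (1 + exp((T - Tm_i) / w_i)),

and the dye signal is the helicity-weighted blend of two linear baselines,

    F(T) = upper(T) * H(T) + lower(T) * (1 - H(T)) + eps,
    H(T) = sum_i  w_i_frac * theta_i(T),

with `eps ~ N(0, fluor_sd)` i.i.d. per acquisition. The model is linear in
the species, so a mixture curve is exactly the weighted sum of its
single-species curves. This is the minimal model that reproduces the
qualitative behaviour HRM genotyping exploits: the G·C-pairing allele
melts above the A·T-pairing allele, heteroduplexes melt earlier, and
heterozygote transitions are flatter. Nearest-neighbour thermodynamics,
PCR kinetics and dye photochemistry are deliberately out of scope.

Genotype composition follows from random re-annealing after denaturation:
homozygotes are a single homoduplex (weight 1); heterozygotes are a
uniform 2×2 mixture — both homoduplexes plus the two single-mismatch
heteroduplexes at 0.25 each. Both heteroduplexes share one Tm by default
(`het_split_c = 0`): distinguishing G·T from A·C stability is below the
resolution this model targets. The denature/rapid-cool step that forms
heteroduplexes on the instrument is represented only by its outcome (the
four-species mixture), not kinetically.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `tm_gc_hom_c` | 85.0 °C | Tm of the G·C-allele homoduplex; mid-grid, since absolute Tms are assay-specific and not part of the validated quantities |
| `delta_tm_hom_c` | per assay: 0.50 / 0.59 / 0.72 °C | homozygote Tm separation for RET / PAX2 / ALDH1A2 |
| `het_penalty_c` | 1.0 °C | extra destabilization of each heteroduplex below the A·T homoduplex |
| `width_hom_c` | 0.35 °C | homoduplex transition width (90–10 span ≈ 1.54 °C) |
| `width_het_c` | 0.525 °C (1.5×) | heteroduplex width; produces the flatter het transition and the difference-plot asymmetry |
| baselines | upper 100 − 0.3·(T−65), lower 5 − 0.02·(T−65) | arbitrary signal units; instrument gain is not specified anywhere |
| `fluor_sd` | 0.25 units | acquisition noise on a ~89-unit transition |
| `tm_jitter_sd_c` | 0.025 °C | rigid per-well Tm shift (salt/volume); all species in a well move together |
| `baseline_jitter` | 0.02 | relative per-well gain variation |
| grid | 65–95 °C, 50/°C (1501 pts) | instrument-style high-resolution ramp |

The noise defaults were fixed once so that triplicate Tm SDs sit near the
≤ 0.06 °C ceiling reported for the real assays: the 95th percentile of the
SD of three draws from N(0, 0.025 °C) is ≈ 0.043 °C, leaving room for the
Tm-estimation noise contributed by `fluor_sd`.

The inverse-length utility `tm_shift_for_length` (ΔTm ∝ 1/length) captures
the design rule that shorter amplicons discriminate better. It is *not*
applied to the packaged assays: the measured separations (0.50 °C for the
95 bp amplicon vs 0.72 °C for the 124 bp one) show that sequence context
dominates pure size scaling.

## Analysis chain

**Normalization.** Straight lines are fitted by least squares to the
signal inside a pre-melt and a post-melt window; the normalized value is
`100·(F − lower_fit)/(upper_fit − lower_fit)`. Windows are placed
automatically at [Tm̂−7, Tm̂−5] and [Tm̂+3, Tm̂+5] around a coarse Tm̂.
The coarse peak uses a lightly smoothed derivative (half-width 12 points):
window placement only needs ~1 °C accuracy, but an unsmoothed argmax can
land on an acquisition-noise spike at the grid edge, where one-sided
differences double the noise.

**Tm estimation.** `−dF/dT` via a quadratic Savitzky–Golay
smoothing-derivative filter, half-width 25 points (0.5 °C at the default
grid; boundary points use the filter's one-sided polynomial fits). The Tm
is the global maximum, refined by parabolic interpolation through the
peak and its two neighbours; exact ties resolve toward the lower
temperature. Tm is always estimated on *unshifted* data. Against a
brute-force oracle (argmax of the closed-form signal derivative on a
0.001 °C grid) the estimator agrees within 0.02 °C at zero noise.

**Temperature shifting** translates curves along the temperature axis so
they cross a 5 % fluorescence level together (last downward crossing, for
robustness to pre-melt noise). Values are never altered; the applied shift
is recorded.

**Difference plots** subtract a reference curve pointwise after linear
resampling onto the reference grid; overhanging ends are dropped.

**Where shifting is *not* used.** Auto-grouping and the difference
amplitudes that feed genotype calls operate on normalized, *unshifted*
curves. In this melt model the two homozygote classes are exact rigid
translations of each other (identical widths), so aligning curves at any
fluorescence level makes them pointwise identical and would erase the
homozygote distinction entirely — and would also symmetrize the
heterozygote's deviation from the two homozygote references. Real
instrument curves carry small sequence-dependent shape differences that
survive shifting; two-state synthetic curves do not, so the transition
position must remain part of the distance. `temperature_shift` is provided
for shape-only visual comparison, mirroring instrument software.

## Calling

Calling is reference-assisted, as HRM genotyping is actually practised: a
standardization run of labelled (sequenced) samples — by default 3 samples
per genotype in triplicate — yields per-genotype mean profiles, mean Tms
and the expected homozygote ΔTm.

Unknown cohorts are auto-grouped by average-linkage agglomerative
clustering on the RMS pointwise distance between normalized curves, cut at
3× the median within-triplicate RMS distance (adaptive: scales with
whatever noise the plate shows; requires replicate structure, otherwise an
explicit threshold must be given). Cluster ids are assigned by first
occurrence, so grouping is deterministic given input order, and calls are
invariant to curve order because samples are processed sorted by id.

Cluster labelling: clusters whose mean 90–10 transition width exceeds
1.25× the reference homozygote width *and* whose difference amplitude
against the major-allele homozygote reference exceeds 5 % are
heterozygotes. The remaining (narrow) clusters are homozygotes: with two
of them, the higher mean Tm takes the G·C-pairing allele (an
ambiguous-labelling error is raised if they sit closer than 0.2 °C);
with any other count each cluster maps to the nearest reference
homozygote Tm. More than three clusters raises an error prompting
threshold review.

Triplicate QC: a sample is called only if its replicate Tm range is at
most 0.2 °C (≈ 3× the maximum replicate SD the technique is expected to
show) and all replicates fall in one cluster; otherwise the call is
*inconclusive* with the reason recorded. Inconclusive calls count as
errors in concordance — a blinded assay that refuses to answer has not
identified the sample.

## Evaluation

`blinded_validation` chains the full experiment: standardization
simulation (its own derived seed) → references → independent cohort
simulation → seeded id shuffle (blinding) → calling → unblinding →
concordance. Group Tm statistics and the ΔTm estimate are computed from
the *called* groups, as a blinded observer would form them, so miscalls
contaminate ΔTm; that is the honest replication of the procedure. The
default 25-sample panel is 13/8/4 (major-hom/het/minor-hom) — the true
panel composition of such validation cohorts is unknowable from reported
summaries, and the fraction is exposed as configuration.

The replicate-precision study measures homozygote triplicates (both
classes, alternating). Tm reproducibility is a homozygote-class property:
heterozygote mixtures have a broad derivative ridge whose two near-equal
maxima (homoduplex pair vs heteroduplex) let acquisition noise flip the
global argmax by ~1 °C in a few percent of wells — a Tm the assay never
uses, since heterozygotes are called by shape.

## Numerical choices and edge cases

* Derivatives require a uniform temperature grid (checked to 1e-6
  relative); the grid spacing is taken as the mean spacing.
* Parabolic peak refinement is skipped at grid boundaries and clamped to
  ±1 grid step; non-concave neighbourhoods keep the grid argmax.
* Level crossings (shift level, transition widths) are linearly
  interpolated; the *last* downward crossing defines the shift level and
  the 10 % edge, the *first* downward crossing the 90 % edge.
* Normalization raises a degenerate-baseline error when the fitted upper
  baseline does not exceed the lower one everywhere (e.g. pure-baseline
  input with no transition between the windows). Renormalization with the
  same windows is exactly idempotent only for flat baselines — a ratio of
  affine fits is not affine — and agrees to ~1e-3 otherwise.
* Logistic tails of species with unequal widths cross far above all Tms
  (at the 1e-4-helicity level), so "the het curve lies between the
  all-heteroduplex and all-G:C envelopes" holds to ~5e-3 signal units
  rather than exactly.
* Curve CSV serialization: temperatures at 3 decimals, fluorescence at 4.
* VCF output holds one site per assay with GT only; CHROM/POS are
  configuration values and the packaged files carry explicit placeholders
  rather than fabricated coordinates.

## Problem sizes used by the test and acceptance runs

Unit tests use reduced Monte-Carlo sizes chosen for a fast default suite
(e.g. 20 seeds for cluster purity, 60 seeds for het-call reliability,
300 triplicates for precision spot-checks). The acceptance suite and
`scripts/acceptance.py` run the full study design: 25-sample triplicate
cohorts per assay, 1000 homozygote triplicates per assay for replicate
precision, and 500 samples per noise level for the monotone-degradation
property.

## What passing on synthetic data does and does not show

The generator emulates the study design — grid, triplicates, cohort
sizes, the three assays' configured separations, replicate jitter at the
reported precision — but real HRM data adds PCR efficiency differences,
non-specific products, salt and template-quantity effects, plate-position
gradients, and sequence-dependent multi-domain melting, none of which are
modelled. Passing validation here demonstrates that the *analysis
pipeline* is correct and recovers its generative parameters at realistic
noise; it does not re-demonstrate the wet-lab performance of the assays.
Known further limitations: a second segregating site inside an amplicon
is not handled, pooled-DNA fraction estimation and unknown-variant
scanning are out of scope, and calling requires references (no
reference-free small-amplicon genotyping).
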