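# Methods

This note documents the models, parameter choices, numerical decisions and
limitations of the `tocky` package.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing model

Raw fluorescence values are used exactly as stored by the instrument — no
compensation, no logicle/arcsinh display transform.  The pipeline's own
log10(x + 1) step is the only transform applied before normalization, and it
is used identically for experimental and simulated data so that their angles
are commensurable.  Negative raw values (possible after acquisition-time
compensation) are floored at 0 on input, with the count recorded per sample,
so the log step stays defined without discarding cells.

Normalization is anchored on a single gated Timer-negative control shared by
all samples of an experiment, which is what makes normalized values and
angles comparable across samples.  Per channel:

* **Reference location** — the maximum of the control's log values by
  default (`quantile = 1.0`), configurable to a lower quantile (e.g. 0.995)
  when controls contain outliers.  The default reproduces the literal
  per-channel maximum; no automatic quantile is imposed because the right
  discount depends on how the control was gated.
* **Scale** — the scaled median absolute deviation (constant 1.4826, the
  value that makes the MAD of a normal sample estimate its SD).  The
  constant is configurable (`mad_constant = 1.0` gives the raw MAD); the
  scaled form is the prevailing convention and only changes angles through
  the *ratio* of the two channel scales.
* **Clamping** — normalized values below 0 are clamped to 0 and the channel
  deemed negative for that cell.  This is a deliberate modelling choice, not
  a numerical nicety: the New (0°) and Arrested (90°) loci are defined as
  exact singleton angles, which are attainable only if sub-threshold
  channels map to exactly 0.  Without clamping both anchors would be
  measure-zero and the five-locus scheme would degenerate to three occupied
  bins.  Degenerate controls (MAD = 0, or fewer than 10 events) are
  rejected rather than silently producing infinite normalized values.

The trigonometric transform sets I = √(Bnorm² + Rnorm²) and
θ = arccos(Bnorm/I)·180/π for Timer-positive cells; single-positive cells
are assigned exactly 0° or 90° (bypassing arccos round-off), other angles
are clipped into [0, 90].  Timer-negative cells carry angle NaN — they have
no direction, and every downstream consumer treats them through the
`timer_positive` flag, never through a sentinel angle.

## Locus scheme

The first locus is the single angle 0° and the last the single angle 90°;
the open interval between them is divided into k − 2 equal-width bins, open
at the left edge and closed at the right, with 90° always reserved for
Arrested.  The k = 5 inclusivity convention — NP-t (0°, 30°], Persistent
(30°, 60°], PA-t (60°, 90°) — is inherited by every other k so that
refining or coarsening the interior preserves counts exactly (merging the
three k = 5 interior bins reproduces the k = 3 interior count, a property
the tests sweep).  k = 3 is equivalent to classical quadrant analysis.
An `epsilon` tolerance (default 0, exact comparison) can widen the anchors
for data whose single-positive cells were not produced by the package's own
clamping.  Zero-count loci are always reported, never dropped: downstream
statistics must see sparse bins to handle them.

Percentages use one of two stated denominators: the parent population
(default — the natural choice in vivo, where composition shifts matter) or
the Timer-positive subset (useful when total Timer expression varies).

## Statistics

* **Global chi-square** — cells are pooled across the samples of each group
  into one 2×k contingency table (for two groups and five loci this gives
  df = 4); loci empty in both groups are dropped with a log entry and the
  df reduced.  No continuity correction (df > 1 in the primary use).
  Pooling rather than averaging per-sample tables treats cells as the unit;
  the locus-wise tests below treat samples as the unit, and the two views
  are complementary.
* **Locus-wise Mann-Whitney** — two-sided; exact enumeration whenever both
  groups have ≤ 8 samples and no ties (small mouse groups of 3–6 need the
  exact null), otherwise the normal approximation with continuity and tie
  correction.  An all-identical pooled sample yields p = 1.  Loci with
  fewer than 2 samples in a group are flagged untestable and excluded from
  the adjustment rather than polluting it.
* **Parametric route** — percentages are variance-stabilized by
  arcsin(√(p/100)) or the shifted logit ln((p + c)/(100 − p + c)) with
  c = 0.001 (the shift keeps the bounds finite).  Per locus, a Shapiro-Wilk
  test gates the parametric path; it is run on the *group-mean-centred*
  residuals of both groups pooled, because pooling uncentred values would
  flag a genuine group difference as non-normality.  Where normality is not
  rejected (p > 0.05) a Welch t-test is used — unequal variances are the
  safer default when group sizes differ; where it is rejected, the locus
  falls back to Mann-Whitney with a recorded flag instead of aborting.
* **Adjustment** — Benjamini-Hochberg step-up by default across the k loci,
  Holm and Bonferroni available; significance is declared at adjusted
  p < 0.05.

A structural consequence worth knowing: with 4 samples per group the
smallest exact two-sided Mann-Whitney p is 2/70 ≈ 0.0286, so after BH
across five loci a shift must touch at least three loci for any of them to
clear 0.05 (0.0286·5/3 ≈ 0.048).  With two affected loci the best
attainable adjusted p is ≈ 0.071 regardless of effect size.  This is a
property of exact rank tests at N = 4, not of the implementation.

## Maturation kinetics model

The linear chain X →(d) C →(kb) B →(ki) M →(kr) R →(s) with defaults
d = 0.3, kb = 8.7, ki = 0.78, kr = 0.14, s = 0.048 (all /h).  M is the
intermediate maturation form between blue and red (renamed from the
conventional I to avoid collision with Timer Intensity).  Under constant
transcription the steady states are d·X/k_out per species (e.g. R* = 625 at
X = 100) and the B/R ratio converges to s/ki ≈ 0.0615; under the transient
spike X(t) = cspike·exp(−kdecay·(t − tpeak)²) on [ton, toff]
(cspike = 10, tpeak = 2.5 h, ton = 0.5 h, toff = 6 h, kdecay = 1.8 /h²)
cells traverse the full 0°–90° range as blue decays at ≈ ki ≫ s.

Two input modes are kept because the parameter set is over-specified: the
spike formula uses X(t) directly (`x_mode="direct"`, the default), while
kdeg = 0.28 /h ("degradation of X") has no home in that formula.  In
`x_mode="ode"` X becomes a state with production by the spike and
first-order loss at kdeg.  The mode used is recorded in trajectory
metadata; both are tested.

Numerics: LSODA with rtol 1e-10 / atol 1e-12 (the chain's rates span two
orders of magnitude; dt is the *output* grid only), integrated piecewise
across the input discontinuities at ton and toff.  Round-off negatives
above −1e-8 are clipped to 0.  The test oracle is the matrix exponential of
the augmented linear system — an independent solution path.

Population synthesis draws each cell's time uniformly over the requested
window and applies **one** log-uniform scale factor in [10, 100] to both
channels.  One shared factor (rather than two independent ones) preserves
the cell's B/R ratio — i.e. its maturation state and angle — while
modelling expression-level heterogeneity, which is the quantity the
downstream analysis is supposed to recover.  The log-uniform family spreads
cells evenly across the decade of scales.  Simulated populations are
post-processed by the identical preprocessing code path used for real data,
with a synthetic autofluorescence population as the negative control.

## Synthetic data generator

The generator inverts the pipeline's own preprocessing map (target angle
and intensity → normalized channels → log fluorescence → raw), rather than
simulating chemistry; mechanistic populations come from the kinetics
module.  Two constructions make the inversion recoverable:

* negative-control log fluorescence is a normal *truncated at a hard upper
  bound* (mean + 3 sd per channel by default), so the pipeline's
  re-estimated threshold (the control's sample maximum) converges to the
  generator's anchor at O(1/n) instead of the slow Gumbel drift of an
  unbounded maximum;
* the "off" channel of a single-positive cell is drawn from the negative
  cloud clipped half an sd below the bound, so it always clamps to 0 and
  the 0°/90° anchors survive the round trip exactly.

Residual recovery error is dominated by sampling noise in the control's
per-channel scaled MAD (relative error ≈ 1.17/√n), which tilts the
channel-scale ratio and biases mid-range angles by roughly
0.5·(Δmad/mad) radians at worst.  `generate_experiment` therefore defaults
to a 20,000-event shared control — gated Timer-negative populations are
typically abundant in real acquisitions — keeping that bias well under a
degree; per-sample autofluorescent event counts remain whatever the
population spec says.  Replicate variability is modelled as Dirichlet
jitter on component proportions (concentration parameter exposed; off by
default).

What the generator does *not* emulate: photon-counting noise, spillover/
compensation artefacts, instrument drift between samples, or doublets.
Passing recovery tests therefore demonstrate correctness of the transform
and binning logic under distributional heterogeneity, not robustness to
instrument-level artefacts.

## Spike-in power framework

Hybrid samples draw round(fraction·n_total) angles (round half away from
zero, with replacement — pools may be smaller than n_total) from the spike
pool and the rest from the background pool.  Per condition and replicate,
one hybrid and one pure-background sample of equal size are binned and
compared by the global chi-square, and `n_rep_samples` (default 6) replicate
samples per side feed the locus-wise Mann-Whitney machinery with BH
adjustment.  The reported quantity is the mean of −log10(p) over
replicates; under the null p is uniform, so the calibration floor is
1/ln 10 ≈ 0.4343.  Conditions where any chi-square expected count falls
below 5 are flagged (`sparse_bins`) — the classical reliability rule — and
untestable conditions are recorded as missing, not zero.

The default pools are synthetic stand-ins for empirical ones: a high-angle
background (truncated normal at 72° ± 10°) and a mid-angle spike
(40° ± 10°), both with the same 15% mass at exactly 90° and none at 0°.
Giving both pools identical anchor mass is what isolates the binning
question: the 3-locus (quadrant) scheme sees only anchor counts and is
nearly blind to the interior shift, while k ≥ 4 resolves it — the
locus-count sensitivity jump the framework is designed to exhibit.
Replicate counts default to 50 per condition (1,000 for the null
calibration in the tests, where the target tolerance is tighter).

## Problem sizes used in the validation suite

Oracle comparisons run on 0–168 h grids (constant model) and 0–48 h at
0.1 h (transient); the null type-I simulation uses 500 replicates of 6 + 6
samples across 5 loci; spike-in calibration uses 1,000 replicates at
n_total = 10,000 and the sensitivity scans 60 replicates; the end-to-end
recovery experiment uses 2 groups × 4 samples × 5,000 cells with a
20,000-event control.  These sizes were chosen so each check's Monte-Carlo
error is comfortably below the tolerance it asserts.

## Known limitations

* FCS support is read-only and covers list-mode FCS 3.0/3.1 with float,
  double or uniform-width integer data; spillover matrices and display
  transforms in the file are ignored by design (the pipeline assumes
  compensation happened upstream, and applies none).
* The equal-width interior binning is fixed by construction; data-driven
  boundary placement is intentionally out of scope — the point of the
  scheme is that boundaries are biologically anchored, not fitted.
* The chi-square pools cells within groups and therefore ignores
  between-sample overdispersion; use the locus-wise tests when replicate
  variability matters.
* Rate constants of the kinetics model are fixed inputs; the package does
  not fit them to data.
* Timer-negative cells carry no angle; analyses needing a full-population
  angular statistic must choose a denominator explicitly.
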