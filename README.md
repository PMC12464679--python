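# tocky

Quantitative analysis of **fluorescent-Timer flow cytometry data**.

Fluorescent Timer (FT) proteins shift irreversibly from blue to red emission
as they mature (Fast-FT: ~4 h blue-to-red half-life), so a cell's position in
Timer-Blue vs Timer-Red fluorescence space encodes the recent history of
transcription of the reporter gene.  In the Tocky
(Timer-of-Cell-Kinetics-and-Activity) framework this two-channel readout is
reduced to two interpretable per-cell coordinates — Timer Angle and Timer
Intensity — and the angle axis is discretized into biologically anchored
categories ("loci") that support ordinary proportion statistics.  The package
is written for immunologists and cytometrists working with Timer reporter
systems (e.g. Nr4a3 or Foxp3 reporters in T cells), and for methodologists
who want a fully synthetic, ground-truth-controlled test bed for angular
binning schemes.

## The method

Given per-cell raw fluorescence (B, R) and a gated Timer-negative control:

1. **Log transform**: B_log = log10(B + 1), likewise R_log.
2. **Normalization / thresholding** (per channel, against the control):

       B_norm = max(0, (B_log − max(B_log,neg)) / MAD(B_log,neg))

   with the scaled MAD (constant 1.4826) of the log-transformed negative
   control, and the reference location configurable as a quantile of the
   control (default 1.0 = the literal maximum).  Cells at or below the
   threshold clamp to exactly 0; a cell with both channels at 0 is
   Timer-negative.
3. **Trigonometric transformation** to polar coordinates:

       I = sqrt(B_norm² + R_norm²),   θ = arccos(B_norm / I) · 180/π

   θ = 0° is pure blue (new transcription), 90° pure red (arrested
   transcription), and sustained transcription accumulates near 45°.
4. **Locus categorization** (k = 3..7, default 5): θ = 0° (New) and θ = 90°
   (Arrested) are singleton anchors; the open interval between them is cut
   into k − 2 equal-width, left-open/right-closed bins.  For k = 5:
   NP-t (0°, 30°], Persistent (30°, 60°], PA-t (60°, 90°).  Occupancies are
   reported as percentages of the parent population or of Timer⁺ cells.
5. **Statistics**: global Pearson chi-square on the pooled 2×k count table;
   locus-wise two-sided Mann-Whitney tests (exact for small untied groups);
   or Shapiro-Wilk-gated Welch t-tests on arcsine-square-root- or
   logit-transformed percentages — all with Benjamini-Hochberg (or
   Holm/Bonferroni) adjustment across loci.

Two validation tools accompany the pipeline: an ODE simulator of Timer
maturation (X → C → B → M → R, rates d = 0.3, kb = 8.7, ki = 0.78,
kr = 0.14, s = 0.048 /h) under constant or transient (windowed-Gaussian
spike) transcription, and a spike-in power framework that mixes a known
fraction of cells from a "spike" angle pool into a background pool and maps
detection sensitivity across locus counts, spike fractions and cell numbers.
A synthetic-data generator with exact per-cell ground truth makes every
stage testable without any external dataset.

## Worked example

A synthetic two-group experiment (4 samples per group, 5,000 cells each, half
Timer⁺) in which the treated group shifts weight from recently activated
(≈18°) towards waning (≈72°) transcription:

```python
from tocky.synthetic import PopulationSpec, TimerComponent, generate_experiment
from tocky.preprocess import preprocess_experiment
from tocky.locus import LocusScheme, locus_table, locus_dynamics, percent_matrix
from tocky.stats import wilcoxon_locuswise

spec_ctrl = PopulationSpec(n_neg=2500, components=(
    TimerComponent(n=875,  angle_mean=18.0, angle_sd=5.0, label="recent"),
    TimerComponent(n=1000, angle_mean=45.0, angle_sd=5.0, label="persistent"),
    TimerComponent(n=625,  angle_mean=72.0, angle_sd=5.0, label="waning")))
spec_trt = PopulationSpec(n_neg=2500, components=(
    TimerComponent(n=375,  angle_mean=18.0, angle_sd=5.0, label="recent"),
    TimerComponent(n=750,  angle_mean=45.0, angle_sd=5.0, label="persistent"),
    TimerComponent(n=1375, angle_mean=72.0, angle_sd=5.0, label="waning")))
exp, truth = generate_experiment({"control": spec_ctrl, "treated": spec_trt},
                                 n_samples=4, seed=20, dirichlet_conc=3000)

transformed = preprocess_experiment(exp)
tables = [locus_table(ts, LocusScheme(k=5), denominator="parent")
          for ts in transformed]
print(locus_dynamics(tables).to_string(index=False))
print(wilcoxon_locuswise(percent_matrix(tables, "control"),
                         percent_matrix(tables, "treated")).summary())
```

which prints:

```
  group      locus  mean_percent  sd_percent  n_samples
control        New         0.000    0.000000          4
control       NP-t        17.445    0.525706          4
control Persistent        20.270    0.724707          4
control       PA-t        12.285    0.492714          4
control   Arrested         0.010    0.020000          4
treated        New         0.005    0.010000          4
treated       NP-t         7.055    0.458221          4
treated Persistent        15.270    0.303535          4
treated       PA-t        27.675    0.535506          4
treated   Arrested         0.010    0.020000          4
wilcoxon comparison (adjust=BH, alpha=0.05)
     locus   method  statistic        p                 note  p_adjusted  significant
       New wilcoxon        6.0 0.453255 normal approximation    0.566568        False
      NP-t wilcoxon       16.0 0.028571                exact    0.047619         True
Persistent wilcoxon       16.0 0.028571                exact    0.047619         True
      PA-t wilcoxon        0.0 0.028571                exact    0.047619         True
  Arrested wilcoxon        8.0 1.000000 normal approximation    1.000000        False
```

The three loci the generator actually shifted (NP-t and Persistent down,
PA-t up) — and only those — come out significant after BH adjustment, at the
smallest p attainable by an exact two-sided Mann-Whitney test with four
samples per group (2/70 ≈ 0.029).  The mean percentages are the quantities a
locus-dynamics plot displays, with SD across the four replicate cultures.

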