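# Methods

## The measurement being modelled

An ECIS well holds one or ten 250-µm gold working electrodes (single- and
ten-electrode 8-well arrays; each well has a 0.8 cm² bottom). The instrument
reports series-equivalent resistance `R = Re(Z)` and capacitance
`C = −1/(ω·Im Z)` per well and frequency. Three acquisition modes matter
here: multi-frequency time series (attachment is read from capacitance at
64 kHz, migration from resistance at 4 kHz), 25-point frequency scans from
31.25 Hz to 100 kHz (morphology fitting), and rapid time collection — one
4 kHz sample per second for 2048 s (micromotion). The electric fence applies
3 sinusoidal pulses per 5 min at 40 kHz (200 ms on / 200 ms off; 1 mA on
single-electrode wells, 6 mA on ten-electrode wells), which at the ~2000 Ω /
~300 Ω cell-free 40 kHz well resistances corresponds to roughly 2 V — enough
to keep cells off the electrode without harming the coating.

## Forward model

The bare interface is a constant phase element in series with a solution/
constriction resistance: specific impedance `Zn = A·(jω)^(−n)` (Ω·cm²),
whole-well `Z = Zn/area + R_sol`. Defaults: `n = 0.9`; `A` chosen so the
cell-free 64 kHz series capacitance of a single electrode is 3.3 nF;
`R_sol` chosen per array so the cell-free 40 kHz well resistance equals the
nominal 2000 Ω (one electrode) or 300 Ω (ten electrodes). These three
interface parameters are never trusted in analysis: they are recalibrated
from the measured cell-free scan before any covered-scan fit.

A confluent layer of disc-shaped cells (radius `rc`, membrane capacitance
`Cm`, junctional resistance `Rb`, substrate gap `h`) transforms `Zn` into
`Zc` via the classic disc-cell solution (see README for the closed form).
The membranes are purely capacitive — `Zm = 2/(jωCm)` for the apical+basal
pair — because `Rb`, `h` and `Cm` are the three parameters this assay
reports; adding a membrane conductance would not be identifiable from a
25-point scan. The constraint parameter `α = rc·√(ρ/h)` (Ω^½·cm) and `h`
(nm) are interchangeable given medium resistivity `ρ` (default 54 Ω·cm,
typical culture medium) and `rc`; the conversion is
`h [nm] = 0.1·ρ·rc[µm]²/α²`.

The Bessel ratio `(γrc/2)·I0(γrc)/I1(γrc)` is evaluated with exponentially
scaled modified Bessel functions (the scaling cancels in the ratio), which
keeps it finite and accurate for `|γrc|` up to ~10³; below 10⁻⁶ a two-term
series supplies the `γrc → 0` limit of 1, which is what collapses `Zc` to
`Zn` when `Rb = α = 0`. Partial coverage mixes specific admittances
area-weighted: `Y = (1−c)/Zn + c/Zc` — covered and free patches are simply
in parallel.

## Inverse fit

`fit_cell_params` proceeds in two stages. The cell-free scan first
calibrates `(A, n, R_sol)` by least squares on `[log|Z|, phase]`. The
covered scan is then fit for `(Rb, α, Cm)` with the same objective,
multi-start from a seeded Latin-hypercube spread in log-parameter space
inside the bounds box (defaults: `Rb ∈ [10⁻⁴, 100] Ω·cm²`,
`α ∈ [0.05, 50] Ω^½·cm`, `Cm ∈ [0.1, 10] µF/cm²`). Log-magnitude plus phase
with equal weight treats all frequencies on comparable scales; ties across
starts break by lowest residual then lowest start index, so results are
reproducible given the seed. `rc` and `ρ` are inputs, not fit parameters —
the scan cannot separate them from `α` — and are exposed as configuration
because the instrument software may fix `rc` per condition. One caution for
users comparing across gain settings: rescaling all impedances by `c` maps
the exactly fitting parameters to `(c·Rb, √c·α, Cm/c)`; estimates are only
comparable after consistent calibration, and the suite pins this
equivariance.

## Kinetics

Baseline and plateau of a trace are means of its first and last `k = 5`
samples — the assay does not prescribe an estimator, and trimmed means of
the flat ends are the simplest robust choice. Threshold and midpoint
crossings are linearly interpolated between samples; at 5–10 min sampling a
nearest-sample rule would bias `T50` by several minutes. The attachment
regression uses all samples whose capacitance lies inside the threshold
band; the migration regression uses the samples between 10 % and 90 % of the
excursion (the central-window fractions are configurable — whether the
original analysis used the full rise or a central window is not stated). A
trace still rising in its last `k` samples yields an "unsaturated" warning
and the slope over the available window.

Stage segmentation fits a *continuous* piecewise-linear function with four
segments, breakpoints restricted to sample times, minimising total squared
error. Continuity couples the segments, so the textbook dynamic program for
independent segments does not apply; instead the search enumerates all
admissible breakpoint triples exactly for traces up to 120 samples and, for
longer traces, enumerates a coarse grid (~40 candidates) and refines each
breakpoint by coordinate descent at full resolution. On signals whose
stages differ visibly in slope — the regime in which a stage decomposition
is meaningful at all — the refined optimum coincides with exhaustive search,
which the suite verifies on 40-sample traces with the hierarchical path
forced.

## Var32

The 2048-point series is split into 64 segments of 32; each segment is
divided by *its own* mean (the scale-invariant reading of normalisation;
whole-series normalisation is available behind a flag), and population
variances (divisor 32) are averaged. The sample-variance alternative would
differ by a fixed 32/31 ≈ 1.032 factor — well inside the spread of the
statistic — but the divisor is stated here so results are comparable.

## Synthetic-data generator

The generator's defaults *are* the study conditions of the published
single-electrode-array experiment; they are calibrated once, from printed
values, and are not tuning knobs.

* **Attachment.** Capacitance maps linearly from the cell-free level
  (3.3 nF) to the confluent level (1.0 nF) as coverage grows; the decline is
  a lagged ramp whose central slope is exactly the profile's published rate
  (collagen 6.9381, control 1.1917, PLL 0.7438, PDL 0.2116 nF/h). A 0.25 h
  settling time precedes the decline everywhere; poly-lysines add the
  observed ~1 h spreading lag. One unit tension in the source data is
  resolved rather than propagated: the printed regression thresholds carry a
  µF symbol while the slopes are nF/h and attachment T50s are fractions of
  an hour — mutually consistent only if the thresholds are read in nF
  (falling from 3 to 1.5 *nF* at 6.9381 nF/h takes 0.216 h, matching the
  printed collagen attachment T50 of 0.2227 h almost exactly; the µF reading
  would take ~216 h). Thresholds are therefore numbers in the trace's own
  unit, nF here.
* **Migration.** Wound closure is a uniform inward radial front on the
  250-µm disc: coverage `c(t) = 1 − (1 − min(1, vt/r_e))²`, the simplest
  geometry consistent with cells migrating inward from the perimeter. The
  front speed is set from the published T50 (`v = (1−√½)·r_e/T50`), and in
  fast mode the resistance is an affine map of coverage whose plateau is
  set so the 10–90 % regression slope equals the published `S_r`. Model
  mode instead evaluates the forward model along the coverage path;
  because that map is nonlinear in coverage, its value-midpoint T50 lands
  2.7–10.4 samples later than fast mode's with default profiles — both
  modes cross their own halfway levels at the same coverage time, which is
  the invariant the suite asserts.
* **Stages.** A separate four-segment piecewise-linear resistance trace
  (1-min sampling) carries the published collagen stage durations
  0.19 / 1.68 / 4.74 h. These durations are *not* compatible with the
  attachment-slope calibration on a single trace (1.68 h of spreading at
  6.9381 nF/h exceeds any plausible capacitance swing — the figures come
  from different experiments), hence the two distinct trace families.
  Non-collagen stage durations and per-stage slopes are unpublished;
  defaults preserve the collagen-fastest/PDL-slowest ordering.
* **Micromotion.** Resistance is the baseline times `exp(X)` with `X` a
  stationary Ornstein–Uhlenbeck process (mean-reversion timescale 30 s):
  uncorrelated noise of the required Var32 magnitude (~3.5–4×10⁻⁷) would be
  implausibly white for a biological signal, and the OU sd can be calibrated
  in closed form — the expected mean-removed per-segment variance of an OU
  process with lag-1 correlation `r` is `σ²(1 − S/L²)` with
  `S = L + 2Σ(L−k)r^k` — so seed-averaged Var32 lands on the published
  per-substrate levels (control 3.54×10⁻⁷, collagen 3.89×10⁻⁷, PDL
  4.02×10⁻⁷; the PLL level is unpublished and defaults below control, the
  published ordering).
* **Scans.** Forward-model impedance with multiplicative noise on `|Z|` and
  optional additive phase jitter. Morphology defaults per substrate use the
  published `h` (control 49.1535, PLL 31.9073, PDL 51.4027, collagen
  60.7134 nm) and cell radii (collagen 11.72, PDL 13.39 µm; 11 µm
  otherwise); `Rb` was published only for control (1.7267 Ω·cm², described
  as similar across substrates) and is shared; `Cm` was never published and
  the 1 µF/cm² default is an assumption typical of epithelial layers.
* Noise is multiplicative Gaussian (instrument noise scales with signal),
  default sd 1 %. Every stream is keyed by (seed, stream kind, substrate,
  well index) through a `SeedSequence`, so runs are bit-reproducible and
  wells are independent.

What the generator does **not** emulate: proliferation, cell-to-cell
heterogeneity, drift and temperature artefacts, fence-pulse
electrochemistry, or frequency-dependent instrument error. Passing tests
therefore demonstrate that the analysis chain recovers known inputs under
idealised instrument statistics, not that it is robust to every failure
mode of real recordings.

## Numerical and reporting choices

* Electrolyte constants behind the zeta calculator default to 10 mM NaCl at
  25 °C (η = 8.9×10⁻⁴ Pa·s, λ = 0.1265 S/m, εᵣ = 78.5) — instruments rarely
  print what they assume; override when yours differs. The
  Helmholtz–Smoluchowski grouping `ζ = (ηλ/ε₀εᵣ)(ΔE/ΔP)` is the only
  dimensionally consistent one producing volts.
* Summaries report mean ± SEM (sd/√n, ddof = 1) per substrate; significance
  testing is deliberately out of scope.
* Report files use 6-significant-digit formatting for diffability; CSV
  dialects write 9 significant digits so round trips are lossless at
  instrument resolution.
* Degenerate inputs fail loudly and specifically: traces that never cross a
  required threshold name the missing threshold; flat traces have no
  baseline/plateau excursion; empty or malformed CSVs name the file and
  offending column or row.

## Problem sizes

Default desk-scale conditions: 24 h attachment and 12.5 h migration records
at 5-min sampling (289/151 samples), 1-min stage traces (~580 samples),
2048-point micromotion series, 25-point scans, four wells per substrate.
The acceptance script averages 20 noisy fit seeds, 20 ordering seeds and 25
micromotion seeds; the whole recomputation takes a few seconds on one CPU.
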