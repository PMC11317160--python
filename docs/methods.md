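# Methods

## Model of the locus

The simulator replicates a linear 60 kb locus cell by cell. Two origins fire
at truncated-positive normal times (early: 5 kb, mean 10 min, sd 2; late:
55 kb, mean 50 min, sd 5) and send forks outward at `v = 1000` bp/min. A
polar barrier at 30 kb arrests **rightward** forks with probability
`p_block = 0.9`; leftward forks are never affected. An arrested fork restarts
with probability `p_restart = 0.9` after a delay `T = 20` min, resuming
`resection_len = 1000` bp behind the barrier (the resected nascent strand is
re-synthesized) at speed `v_r` (default `v`), with **both strands made by
Pol δ**, insensitive to the barrier. A non-restarted arrest — or one whose
converging fork arrives before the restart delay elapses — is rescued by the
leftward canonical fork from the late origin. Kinematics are event-driven
and continuous in time: origin firing, barrier arrival, restart, fork
meetings and locus edges are resolved in exact order, meeting points are
computed analytically, and each bin (50 bp) inherits the polymerase of the
fork that covered its midpoint. Every bin is replicated exactly once per
cell on each strand; a configuration that leaves an interval unreplicated is
an error naming that interval.

The late origin's firing mean matters: the mean termination point of a
restarted fork against the converging fork is
`barrier + v·(t_late − t_early − T + (resection+barrier−origin₁)/v)/2`-style
kinematics, ≈ 10.5 kb downstream at the defaults chosen here. Firing the
converging origin much earlier would terminate restarted forks inside the
proximal analysis window and make the proximal bias systematically
underestimate restart; the default of 50 min reproduces the ~10 kb
progression scale such barrier loci display, and keeps the proximal window
(+0.5..+2.5 kb) essentially termination-free.

Sequencing is modeled per library (Pol δ-mutant, Pol ε-mutant) and strand:
counts per bin are Poisson with mean `D·[(1−β)·φ + β·(1−φ)]`, where `φ` is
the fraction of cells in which that strand of that bin was synthesized by
the library's mutated polymerase, `D = 100` the expected depth, and
`β = 0.05` the background incorporation by the non-mutated polymerase.

**Restart bookkeeping.** `realized_restart_fraction` is the fraction of
*all* cells in which a restarted fork actually resumed synthesis
(≈ `p_block·p_restart` = 0.81 at defaults) — this is the quantity the bias
increment measures. The arrest-conditional rate
(`conditional_restart_fraction` ≈ `p_restart`) is reported alongside.

## Usage, bias, and calibration

Counts are depth-normalized **per library** (one factor for both strand
tracks of a library — they come from one sequencing run). Normalizing each
strand track separately would force the strands' means equal, which is wrong
wherever Pol δ's share of total synthesis departs from one half, exactly
what restart produces; a per-track variant (`normalize_tetrad`) is kept for
symmetric genome-scale inputs. Usage is the within-strand ratio
`U_δ = d/(d+e)` (masked where `d+e = 0`), smoothed by a centered masked
moving average (default 5 bins = 250 bp — small against the ~1–10 kb
features being measured, enough to tame Poisson noise at depth 100).

Under the count model the observed usage is a two-parameter distortion of
the true synthesis fraction `φ`:

    U = g / (g + (1−g)·κ),   g = β + (1−2β)·φ,

with `κ` the residual δ/ε depth ratio left by mean normalization. The
baseline window (−10..−2 kb; unidirectional canonical replication, outside
the resection zone) identifies both parameters in closed form, because its
leading strand has `φ = 0` and its lagging strand `φ = 1`: with baseline
strand means `u0 < u1`,

    β/(1−β) = sqrt(odds(u0)/odds(u1)),   κ = 1/sqrt(odds(u0)·odds(u1)).

`calibrate_usage` inverts the distortion per bin; on ideal data
(`u0 = 0, u1 = 1`) it is exactly the identity, so the ideal anchors —
bias 0.5 ⇒ 0% restarted, bias 1.0 ⇒ 100% — and the exact mixture identity
`f(r-mixture) = r` are preserved.

## Restart fraction and progression

`b0` = mean calibrated bias over the baseline window; `b_prox` = mean over
the proximal window (+0.5..+2.5 kb: past the resection-perturbed barrier
bins, before appreciable termination); `f = (b_prox − b0)/(1 − b0)`, clipped
to [0, 1] (noise can push `b_prox` below `b0`; that is "no detectable
restart", not an error). Progression: `d_half` is the distance from the
barrier of the first smoothed bin (scanning from the proximal window's end,
ties to the smallest distance) whose increment over `b0` is ≤ half the
proximal increment; if none occurs within `progression_range` (default
20 kb) the estimate is censored at that range. The half-distance is
window-free and robust to the increment's absolute size, and directly
expresses "slower restarted forks terminate closer to the barrier".
Strain comparisons are plain ratios `f_mut/f_ref` and
`d_half,mut/d_half,ref` with censoring flags propagated.

## Uncertainty

The 95% CI on `f` is a moving-block bootstrap over genomic bins (block
length = smoothing window). Three choices matter:

- the bootstrap reruns the *whole* estimator per resample — baseline
  calibration (β, κ), `b0` and `b_prox` — so calibration noise is inside
  the interval;
- it resamples the **unsmoothed** usage bins, whose counting noise is
  independent across bins; resampling smoothed bins in blocks of the
  smoothing width would understate the window-mean variance by a
  computable factor (~0.68 for a 5-bin average over 40-bin windows);
- the interval is the basic (reflected) bootstrap interval: the nonlinear
  calibration solve skews the resampling distribution, and reflection
  around the point estimate orients that skew correctly.

Measured at generator defaults, the CI covers the realized restart
fraction in 93 of 100 seeded replicates (and 46/50 on an independent seed
block), satisfying the ≥ 90% design target.

## What the simulator does and does not emulate

It emulates: polar arrest, delayed HR restart with δ/δ synthesis, resection
re-synthesis, variable restart speed, converging-fork rescue, origin-timing
variability, background incorporation and Poisson depth noise — the
features the estimators must be robust to. It does **not** emulate mappability
variation, GC/coverage bias, replicate-to-replicate library chemistry
differences, fork reversal, checkpoint signaling, or genome-scale origin
programs; passing tests therefore validate the estimators under an idealized
but fully ground-truthed noise model, not the upstream read processing of
real libraries (which this package deliberately consumes as pre-binned
counts).

## Numerical and design notes

- Coordinates are 0-based, half-open everywhere; bins are addressed by
  midpoint.
- bedGraph is written with full round-trip float precision and re-read with
  correctly-rounded parsing, so write→read is bit-exact for unmasked bins;
  masked bins (undefined ratios) are omitted on write since bedGraph has no
  NA representation.
- Firing times are truncated at zero by rejection sampling; sd = 0 gives
  deterministic firing (used by the closed-form kinematics tests).
- Problem sizes used in validation: 5000 cells × 1200 bins per dataset,
  100 replicate datasets for coverage, depth 100 per library — sizes at
  which one dataset simulates in well under a second and the full
  validation suite runs in minutes on one CPU.
- The per-cell event loop is bounded (≤ ~10 events per cell at sane
  configurations) and guards against pathological non-termination.

## Known limitations

- The calibration assumes the baseline window is replicated by
  unidirectional canonical forks; at loci without such a window the
  uncorrected mapping (ideal anchors) must be used.
- `d_half` is a summary of the bias *decay*, not a per-fork speed; it
  conflates restart-fork speed with converging-fork timing (by design — the
  same conflation exists in the underlying data).
- With `p_restart` near 0 the proximal increment vanishes and progression is
  undefined (reported as an explicit error, not a number).
- Bootstrap intervals assume independent counting noise across bins after
  unsmoothing; structured artifacts (mappability, copy number) would violate
  this and are out of scope.
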