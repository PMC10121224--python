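# Methods

## Setting and scope

The pipeline analyzes well-level summary intensities from a two-channel
organoid qHTS campaign in 1536-well format (32 × 48). Three cell-line
contexts appear on the plates: a wild-type line carrying a GFP rod-reporter
(WT, the positive control), the GFP-reporter disease line (RD16), and a
reporter-negative parental line used as the autofluorescence counter-screen.
Each well is either DMSO vehicle or one compound at one nominal molar
concentration. The pipeline's job is to turn those reads into a ranked hit
list with toxic and autofluorescent false positives removed. Image-level
analysis, liquid-handling bookkeeping, and instrument-native file formats
are out of scope; inputs are plain CSV plate/layout tables.

Concentrations are treated as nominal source-series values supplied by the
layout (1:3 serial dilutions from a 10 mM DMSO stock in the presets: seven
points for a primary screen, eleven points in triplicate for a confirmatory
screen). No dilution arithmetic is applied, because final in-well
concentrations are not derivable from the assay description; all potencies
are therefore on the nominal scale, and only ratios of potencies enter the
triage decision.

## Plate QC masking

Localized artifact groups (dispenser misfires, evaporation patches) are
masked automatically: each well's intensity is compared, per channel, with
the median and MAD of its `window × window` spatial neighborhood restricted
to unmasked wells of the same (cell line, treatment) group, excluding the
well itself. The MAD is scaled by 1.4826 and floored at 1e-9 so constant
neighborhoods yield z = 0 rather than a division blow-up. Wells with
|z| > `z_threshold` that form 4-connected clusters of at least `min_cluster`
wells are masked (defaults 5, 5.0, 3). Isolated outliers are deliberately
left to the curve fit's residuals. The neighborhood is restricted to the
same cell line as well as the same treatment because control groups of
different lines sit at order-of-magnitude different baselines and would
poison each other's statistics. Masking is idempotent: previously masked
wells are reported as MANUAL and excluded from all statistics. This rule is
a documented, reproducible surrogate for what screeners usually do by eye;
no spatial detrending (B-scores) is applied, so sub-threshold gradients flow
through to normalization by design.

## Normalization

Per plate, over unmasked DMSO wells only, arithmetic control means are
computed per cell line and channel (a trimmed-mean option exists, off by
default). Plates without WT wells (typically counter-screen plates) borrow
the WT GFP mean from the first plate of the same replicate index that has
WT controls. The three percent scores are then computed per unmasked
compound well exactly as the formulas in the README; disease-assay wells
yield efficacy (GFP) and toxicity (DAPI), counter-screen wells yield
fluorescence, joined on (compound, concentration, replicate). Scores are
**not** clipped to [0, 100]: the "0 to 100%" range describes the anchor
calibration, and noise or super-WT rescue legitimately exceeds it; clipping
would bias the fits. Replicate plates are normalized independently and kept
as separate observations, preserving the error structure for fitting.
Degenerate windows (WT mean not above the disease/parental mean) and empty
control groups raise errors naming the plate and group.

## Dose–response model and fitting

The four-parameter logistic in log10 concentration (README) is fit per
compound and score type to all unmasked observations (replicates as
individual residuals), by bounded nonlinear least squares in
(A0, A∞, log10 AC50, n). Default bounds: A0, A∞ ∈ [−100, 200];
log10 AC50 within the tested range widened by two decades; n ∈ (0.01, 10].
At least four distinct concentrations are required; otherwise the fit is
skipped and classified INCONCLUSIVE.

The start heuristic sets A0/A∞ from the mean scores at the two lowest/two
highest concentrations, log AC50 from the interpolated half-rise crossing
(midpoint of the tested log-range if no crossing), and n = 1. Multistart
(default 5) runs this guess, one candidate from a coarse profiled lattice
over (log AC50, n) — at each lattice node the model is linear in (A0, A∞),
so the box-constrained linear solution is closed-form — and deterministic
seeded jitters of both. Each start first tries unbounded Levenberg–
Marquardt (cheap) and falls back to the bounded trust-region solver when LM
leaves the box; restarts stop early when two starts agree in SSE to 0.1% or
the fit is numerically perfect, and the winner gets a final tight polish.
The lowest-SSE converged solution is returned; r² values within 1e-12 of
zero are clamped to exactly 0 to keep serialized output stable against
floating-point cancellation noise.

Short series whose AC50 sits near the bottom of the tested range leave A0
nearly unidentifiable, and the free fit can run A0 to a bound while barely
lowering the SSE — wrongly failing the baseline criterion for genuinely
active compounds. The pipeline therefore lets a zero-baseline (A0 = 0) fit
compete against the free fit by small-sample AIC whenever the free baseline
drifts beyond 10 percent-points (fixed-bottom fitting on percent-normalized
data is standard practice). This selection is on in the pipeline defaults
and off in the bare `fit_hill`, which remains the exact least-squares
minimizer.

## Curve classification

The four behavior requirements for a well-behaved activation curve are made
operational with configurable thresholds: |A0| ≤ 20 (baseline near zero),
A∞ − A0 ≥ 20 (meaningful rise), log AC50 inside the tested range
(inflection), |A(C_max) − A∞| ≤ 10 (plateau), r² ≥ 0.7 (fit quality), plus
a data criterion (≥ 4 distinct concentrations, converged). All pass →
ACTIVE_FULL; only plateau and/or above-range inflection failing →
ACTIVE_PARTIAL; amplitude below threshold (including flat and falling
curves) → INACTIVE; anything else → INCONCLUSIVE, with failed tags
recorded. The numeric thresholds are this package's operationalization of
qualitative criteria and are logged with every run. Falling efficacy curves
are INACTIVE for triage because the screen seeks GFP increase, but their
fits are retained in the output.

## Hit triage

A hit needs an active efficacy class, fitted A∞ ≥ 30 (percent of the
WT-minus-disease window; half the anchor scale), and both selectivity
ratios ≥ 10 (a "permissive" preset of 3 exists; "≫ 1" has no published
number, and 10 is the conventional selectivity-index margin). A
counter-curve (toxicity or fluorescence) contributes +∞ — treated as
passing — when it is absent, unconverged, flat, or poorly fit; but a
credible liability curve counts even when incomplete: only MONOTONE,
FIT_QUALITY, and DATA failures disqualify it, because a below-range
liability AC50 or a missing plateau is evidence of *more* liability, not
less. Toxicity is checked before autofluorescence, mirroring a funnel that
first drops toxic compounds and then artifact false positives. Hits are
ranked by fitted efficacy amplitude (descending), potency (ascending AC50),
then compound id.

## Synthetic campaign generator

The generator emulates the statistical structure the analysis assumes, with
defaults fixed as the package's study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `wt_gfp_mean` | 1000 a.u. | WT GFP baseline |
| `rd16_gfp_fraction` | 0.4 | disease GFP deficit (≈60% fewer reporter-positive cells) |
| `rd16_viability_fraction` | 0.5 | disease viability deficit (≈50% lower) |
| `parental_gfp_mean` | 50 a.u. | reporter-negative background |
| `noise_cv` | 0.10 | per-well multiplicative lognormal CV, both channels |
| `gradient_amplitude` | 0.05 | additive separable row+column gradient, fraction of channel baseline |
| `edge_amplitude` | 0.05 | additive signal loss on edge rows/columns |
| `n_compounds` | 600 | campaign size |
| class mix | 0.60 / 0.12 / 0.10 / 0.08 / 0.05 / 0.05 | inactive / efficacious / toxic / autofluorescent / eff+toxic / eff+autofluorescent |

Compound mechanisms are unit-amplitude rising Hill curves with AC50 drawn
log-uniformly over the central 80% of the tested log-range (so active
inflections are observable), Hill slopes in [0.8, 3], saturating rescue
fractions in [0.5, 1], kill fractions in [0.5, 1], and autofluorescence
adding 0.3–1.0 of the WT-minus-parental window. Toxicity couples channels:
a killed fraction removes DAPI signal and reporter GFP proportionally —
which is exactly what makes the DAPI counter-metric necessary.
Autofluorescence adds identically to disease-assay and counter-screen GFP,
the artifact the parental retest exists to remove. Control wells are
scattered pseudo-randomly across each plate so spatial artifacts average
out of control means the way interleaved DMSO fields do on real plates.
Everything is drawn from one seeded generator, so a seed + config pair is
bit-reproducible.

What the generator does **not** emulate: image-level structure, well-to-well
carryover, liquid-handling failures beyond the additive artifacts above,
compound aggregation/solubility behavior, or inter-plate batch drift.
Passing funnel tests therefore demonstrate that the analysis recovers truth
under its own statistical assumptions, not that those assumptions exhaust
real screening data.

The analytic expectation oracle (`truth_to_expected_calls`) applies the
triage logic to the *apparent* noiseless efficacy curve computed in closed
form at the tested concentrations. Two confounds make this necessary:
autofluorescence masquerades as rescue in the disease assay (such compounds
are expected AUTOFLUORESCENT calls, caught by the counter-screen, not
expected inactives), and toxicity inside the tested range depresses the top
of the efficacy curve, so a compound can satisfy the nominal AC50-ratio
inequality while producing bell-shaped data no rising model should fit —
such compounds are expected non-hits (TOXIC).

## Numerical and reproducibility choices

Fit seeds derive deterministically from a base seed and the compound/score
identity (CRC32 mix, kept below 2^31). Pipeline CSVs are serialized at nine
significant digits: full float repr would expose ULP-level noise from
allocation-dependent summation order and break the byte-identical rerun
contract. The run log records a SHA-256 hash of the canonical YAML config.
AC50 precision under the default noise deserves a caveat: with 10% CV
intensity noise and the 0.4/0.5 disease windows, the information limit on
log10 AC50 for a free four-parameter fit on an 11-point triplicate design
is roughly 0.1 dex (the exact-MLE with a fixed baseline reaches a 90th
percentile error near 0.17 dex); single-replicate 7-point primary-screen
fits are correspondingly coarser, which is why triage decisions use
order-of-magnitude selectivity margins rather than exact potencies.

## Problem sizes used in the tests

The default suite runs a full 600-compound simulated campaign for funnel
fidelity, a 200-compound Monte-Carlo for noisy parameter recovery, a
60-curve optimizer-versus-grid battery (grid steps 0.01 in log AC50, 0.1 in
slope, with the linear parameters profiled in closed form), and a
40-compound campaign executed twice for byte-identity. These sizes keep the
statistical checks meaningful while the whole suite completes in a few
minutes on one CPU.

## Known limitations

* The QC rule is a surrogate for visual inspection; its thresholds are not
  calibrated against any instrument's artifact statistics. With dense true
  actives at scattered positions it can occasionally mask genuine
  saturating wells that happen to cluster spatially.
* Fluorescence scores on counter-screen plates depend on a borrowed WT
  control mean from a sibling plate, so cross-plate gain differences leak
  into the fluorescence scale (not into efficacy or toxicity).
* The curve classifier is a four-criterion operationalization, not a
  reproduction of any published multi-class curve taxonomy.
* Triage treats each compound independently; no structure-activity or
  scaffold grouping is attempted.
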