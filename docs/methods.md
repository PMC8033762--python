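# Methods

This note records the models, rules, numerical choices and limitations
behind `cardiotrial`, in the order the pipeline runs them.

## Cell models and integration

A cell model is a deterministic ODE system `rhs(t, y, factors) -> dy/dt`
whose named ionic currents are multiplied by per-current factors in [0, 1]
(`ChannelScaling`; missing entries mean 1, composition is the element-wise
product). Models never receive a stimulus current: every action potential
is spontaneous. The engine integrates with LSODA at rtol 1e-7 and
per-state-class absolute tolerances (1e-6 for potentials in mV, 1e-9 for
gates, 1e-4 for concentrations in nM); the models this pipeline targets are
stiff, and no canonical solver or tolerance is prescribed for them, so
these are our choices, validated by the grid-refinement and
reference-period tests. Output is sampled on a uniform grid, default
`output_dt` = 1 ms — fine enough that halving it moves APD₉₀ and CTD₉₀ by
< 0.5% (interpolation-limited, not solver-limited). A solver step-size
collapse raises `IntegrationFailure` carrying the last valid time; the
batch drivers record it per cell rather than aborting.

Externally everything is seconds / mV / nM; a plugin whose native units
differ is expected to convert inside its adapter.

### The fixture oscillator

The in-repo test bed is a two-current relaxation oscillator of the
FitzHugh–Nagumo class, mapped to membrane millivolts: a cubic fast variable
(the regenerative depolarizing current, registered as `I_CaL`), a linear
recovery variable (the repolarizing current, `I_Kr`), a fixed background
leak anchoring the resting potential, and a first-order Ca²⁺ follower
relaxing toward a sigmoid of vm (τ = 120 ms). Parameters are frozen in
`FixtureParams` and chosen so the limit cycle resembles an hSC-CM:
~35 bpm, MDP ≈ −75 mV, peak ≈ +28 mV, APD₉₀ ≈ 650 ms, cytosolic Ca²⁺
cycling between ~22 and ~239 nM. Its value as a fixture is that every
claim about it has an independent oracle: fixed points come from
root-solving the nullclines (`resting_point`), the period from a separate
high-order explicit integration at rtol 1e-10 with event detection. Scaling
`I_CaL` to 0 removes all inward drive and the cell settles to a
sub-threshold rest point (≈ −55 mV, quiescence); reducing `I_Kr` prolongs
the AP monotonically; blocking both fully ends all activity. A
`fixture-quiescent` variant (drive removed) converges to its algebraic
fixed point and exercises the steady-state diagnostics.

### Steady state

`run_to_steady_state` free-runs 800 s from the model's published initial
state and returns the final state plus a convergence diagnostic (relative
change of cycle length and CTD₉₀ between the last two complete cycles).
The diagnostic is reported, never asserted: whether a fixed pre-run length
suffices is an empirical question, and callers can inspect it. For the
fixture the 800 s cycle-length change is < 0.5%.

## Drug model

Pore block only: blocked fraction b([D]) = 1 − 1/(1 + ([D]/IC₅₀)^{n_H}),
conductance factor 1 − b, one (IC₅₀, n_H) pair per channel per
characterization, channels restricted to the seven-channel screening panel
(I_Na, I_Kr, I_CaL, I_NaL, I_Ks, I_to, I_K1). Concentrations are µM
throughout. State-dependent/kinetic binding and temperature corrections are
out of scope. A characterization applied to a model lacking one of its
channels (e.g. the late Na⁺ current, which most models omit) skips that
effect with a logged warning instead of raising, so one characterization
table serves models with different current inventories.

`fit_two_point_hill` reconstructs (IC₅₀, n_H) exactly through two
(concentration, blocked-fraction) anchors via the log-odds closed form —
n_H = ln(r₂/r₁)/ln(c₂/c₁), IC₅₀ = c₁/r₁^{1/n_H} with r = b/(1−b). This is
how the shipped example table was built from published per-concentration
block percentages; those entries are labeled as reconstructions in their
provenance column, and printed percentages are treated as rounded to
integer percent (tests assert after like rounding).

## Biomarkers

Cycle detection finds peaks on a lightly smoothed copy of the signal
(Savitzky–Golay, quadratic, 11 ms — a quadratic local fit preserves smooth
extrema; peak indices are then refined to the raw-sample maximum and all
values are read from raw samples, because the smoother undershoots at
slope kinks). AP peaks must exceed 0 mV with 20 mV prominence —
deliberately the same vocabulary as the classifier's residual-activity
rule, so "not an AP" means the same thing in both places. CaT peaks use a
prominence of 25% of the signal range.

Per cycle: the upstroke time is the maximum dV/dt between the pre-upstroke
minimum and the peak (parabolic sub-sample refinement); APD_x runs from the
upstroke to the x% repolarization level between the peak and that cycle's
MDP, linearly interpolated at the crossing; AP_Tri =
(APD₄₀−APD₃₀)/(APD₈₀−APD₇₀); APA = peak − MDP; rate = 60 / mean cycle
length. Measuring APDs from the dV/dt-max upstroke rather than a fixed
voltage threshold keeps the definition meaningful for very triangular APs.

CTD₉₀ is measured per transient from the CaT upstroke to 90% decay toward
that transient's own pre-upstroke diastolic level, then averaged (mean,
the simplest reading of "computed on the last eight") over exactly the
last eight complete transients. A transient truncated by the end of the
recording is not complete and is dropped from the tail before counting;
fewer than eight measurable transients yields a missing value with a
reason, never an extrapolation. The decay reference is per-transient by
design — the alternative global-minimum baseline, which differs under
baseline drift, is available as `ctd_baseline="global"`.

Quiescent traces are valid input everywhere: empty cycle sets, biomarkers
missing with reason "no spontaneous activity".

## Rhythm classification

In-silico abnormality calls are usually made by eye; this package fixes
them as explicit rules, all thresholds in `RhythmConfig`:

* **RF** — over the last 15 s: vm > −40 mV throughout and maximum upstroke
  velocity < 0.2 V/s ("stable" is defined by the velocity bound alone, no
  variance criterion). Assessed only when no AP peaks remain in the window.
* **Q / RESAC** — no AP peaks in the window; RESAC when residual peaks
  (prominence ≥ 2 mV) lie in (−40, 0) mV; Q when the mean vm < −40 mV or
  all residual peaks sit below −40 mV. The two are mutually exclusive and
  neither is counted as pro-arrhythmic. When the rules disagree (both
  conditions approached by a drifting trace) the disjunction is resolved
  toward RESAC first, then Q, then RF, with an explicit fallback note in
  the evidence.
* **IRR** — any consecutive cycle pair, on APs or CaTs, with
  |CL_{k+1} − CL_k| / min(CL_k, CL_{k+1}) > 1.5. The relative reading is
  the only one for which a 150% threshold is meaningful.
* **VT** — mean spontaneous rate above 2 Hz.
* **EAD** — within a cycle's post-peak, pre-minimum segment and above the
  diastolic band: a bump on the smoothed signal with prominence ≥ 2 mV
  (vm) or ≥ 5% of the transient amplitude (cai), lasting ≥ 10 ms, rising
  faster than 10 mV/s, and not reaching the AP/CaT range (that would be a
  new beat).
* **DAD** — in the diastolic interval (entered where the signal first
  returns to within 10% of its baseline after the peak — a hump can
  precede the post-peak minimum): excursions ≥ 2 mV above the local MDP
  (vm) or ≥ 10% of the diastolic level (cai) that do not reach 0 mV.
* **NORMAL** — none of the above; exclusive of everything.

Cessation and RF are judged on the last 15 s; irregularity, rate and
afterdepolarizations on all complete cycles of the trace.

Smoothing is Savitzky–Golay throughout: 11 ms for AP-peak detection, 35 ms
for bump/residual detection, 51 ms (cubic) for the RF velocity estimate —
at 1 mV noise the velocity estimator's noise floor is ~10 mV/s, well under
the 200 mV/s rule. Bump detection additionally floors its amplitude
threshold at 10× the noise level surviving the smoother (robust MAD of the
smoothing residual times the filter's white-noise gain): the extreme
spurious prominence over a long recording is ~2√(2 ln m) ≈ 7–8 sigma, so a
10-sigma floor suppresses false afterdepolarizations while leaving the
configured thresholds in charge on clean signals. The EAD/DAD thresholds
themselves are this package's own calibration on the synthetic suite —
there are no canonical printed values for visually-assessed events — and
the calibration result is: exact per-label precision/recall on the
noiseless suite, and per-label F1 = 1.0 at σ_vm = 1 mV / σ_cai = 2 nM
across the seeds the tests run.

## Trial protocol

Per model: one 800 s pre-run, cached per (model, base scaling, t_pre).
The control arm and every concentration arm then run the same 200 s window
from that cached state; CTD₉₀ uses the last eight transients in both arms,
so ΔCTD₉₀% is like-for-like and an identity drug (empty characterization)
reproduces the control computation bit-for-bit — ΔCTD₉₀ is exactly 0, not
approximately. (Measuring the baseline at the end of the pre-run instead
would introduce a window mismatch; the control-continuation design is the
one under which the identity property is exact.) The baseline models are
used as published — no re-tuning per drug.

Sensitivity maps run 36 cells (two currents × six block levels each) from
the cached steady state, 500 s per cell by default, 200 s for plugins
flagged `slow` (heavy spatially-detailed models); categories follow the
conventional four-color scheme: SPONTANEOUS (NORMAL), CESSATION (pure
Q/RESAC), TRANSIENT_IRR_TO_CESSATION (IRR that has died into Q/RESAC by
run end — only that combination), ARRHYTHMIC otherwise, annotated with the
event composite (EDR/ER shorthands for EAD+DAD+RF / EAD+RF). Mixed labels
with persistent events categorize as ARRHYTHMIC, since the transient
category is defined by ending in cessation.

## Synthetic traces

The generator builds waveform trains from piecewise-analytic templates
rather than ODE output, so every biomarker has a closed-form truth
independent of any solver: a raised-cosine upstroke (max slope exactly at
its midpoint), a piecewise-linear repolarization whose knots are the
APD₃₀/₄₀/₇₀/₈₀/₉₀ crossings, an exponential diastole; the CaT analogously
with its 90%-decay knot at CTD₉₀. Cycle onsets snap to the sampling grid so
sampled extrema coincide with analytic ones; biomarkers recovered from
noiseless traces agree with the template values to ≤ dt/2. Defaults (35
bpm, APD₉₀ 390 ms, CTD₉₀ 550 ms, MDP −75 mV, APA 102 mV, diastolic Ca²⁺
18 nM, amplitude 159 nM) sit near published baselines for spontaneously
beating hSC-CM models so the traces look right; they are generator
defaults, not assertions.

Abnormalities are injected by program, each constructed to satisfy its
classification rule: EAD = a 15 mV, σ = 12 ms Gaussian bump at the 60%
repolarization point (narrow enough to genuinely reverse the local decay);
DAD = a 5 mV mid-diastolic hump; RF = repolarization clipped at a
supra-−40 mV plateau from onset (the CaT held elevated from its decay on);
IRR = one cycle lengthened by a 2.8× multiplier; VT = a 150 bpm rate
override with time-compressed templates; Q = silence from onset; RESAC =
the train re-scaled to peak at −20 mV. Gaussian noise is added last; the
seed fully determines the output.

What passing on synthetic data does and does not show: the suite proves
the measurement and classification logic against known truth, including
under additive white noise, but real recordings differ — fluorescence dye
kinetics, baseline drift, well averaging, biological beat-to-beat
variability and non-white noise are all outside the generator. Results on
real in vitro traces depend on those factors and are not certified by
these tests. The in vitro summary-table emulator likewise produces a
schema-correct, monotone dose-effect table for exercising the comparison
report, not a model of any assay.

## Comparison report

Trials join the in vitro table on (drug, characterization, concentration)
with a configurable relative concentration tolerance (default 1%);
unmatched keys are listed in an appendix, never dropped. Per row and model:
ΔCTD₉₀% on both sides where measurable, a sign-concordance flag
(prolongation vs shortening), and an event-concordance flag (event/no
event and cessation/no cessation both agree). Summary statistics —
sign-concordance fraction, the fraction of rows where the simulated |Δ| is
smaller than the measured one (simulated changes are typically the smaller
ones), event concordance — are recomputed row-wise on demand.

## Problem sizes in the test suite

The default test run uses reduced study conditions chosen as this
package's own test design: a 60 s steady-state pre-run, 25–30 s assessment
windows and 60 s sensitivity cells for most fixture work, with the full
800 s pre-run exercised once (its convergence diagnostic is asserted) and
the full protocol durations shown in the README example. The fixture
oscillator converges to its limit cycle within a few beats, so the reduced
pre-runs sit on the same attractor; the identity, monotonicity and
cardinality properties under test are duration-independent.

## Known limitations

* The three published hSC-CM model parameterizations are not bundled;
  they attach through the plugin contract, and the pipeline's behavior
  with them is exercised here only via the fixture oscillator.
* The classifier's EAD/DAD thresholds are calibrated on the synthetic
  suite, not on expert-labeled model traces.
* The fixture's "currents" are phenomenological; its sensitivity map
  validates the machinery, not any physiological claim.
* Hill parameters reconstructed from two printed, integer-rounded
  percentages inherit that rounding error; the shipped table is for
  examples and tests, not pharmacological reference.
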