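# Methods

## Scope and assumptions

`apblock` predicts single-cell action potential changes under the
*conductance block* assumption: a compound at free concentration *C*
reduces each screened channel's maximal conductance by the factor

    f(C) = 1 / (1 + (C / IC50)^n),

and nothing else.  No state-dependent or voltage-dependent binding, no
change to channel kinetics once bound, no agonism (factors are capped at
1), no accumulation or binding kinetics — the steady-state level of block
is applied instantaneously, and the paced model is then run until its own
(slower) adaptation completes.  Only the six screenable currents IKr,
ICaL, INa, IKs, IK1 and Ito can be blocked.  Channels without a supplied
IC50 are explicitly left at factor 1.0; a non-positive IC50 is a
construction error, not a silent no-block, so "not measured" (omit the
channel) and "bad data" stay distinguishable.

Potency convention: pIC50 = −log10(IC50 in molar), IC50[µM] =
10^(6 − pIC50).  The Hill coefficient defaults to 1 (one compound molecule
fully blocking one channel); user-supplied values are accepted in (0, 10]
— steeper curves than 10 are treated as data errors.  Already-fitted
IC50s are the input contract; fitting Hill curves to raw inhibition data
is out of scope, and extrapolated IC50s are handled identically to
observed ones.

## The demonstration cell model

`sixcurrent_demo` is a nine-state Hodgkin–Huxley-style cell: membrane
voltage V plus eight gates.  Currents (conductances in mS/µF, Cm = 1):

    INa  = g_Na · m³ h · (V − E_Na)         g_Na  = 8.0    E_Na = +65 mV
    ICaL = g_CaL · d f · (V − E_Ca)         g_CaL = 0.12   E_Ca = +60 mV
    IKr  = g_Kr · xr · (V − E_K)            g_Kr  = 0.04   E_K  = −88 mV
    IKs  = g_Ks · xs² · (V − E_K)           g_Ks  = 0.03
    IK1  = g_K1 · k1∞(V) · (V − E_K)        g_K1  = 0.30
    Ito  = g_to · r s · (V − E_K)           g_to  = 0.08

Every gate g relaxes as dg/dt = (g∞(V) − g)/τ_g with sigmoidal steady
state g∞(V) = 1/(1 + exp(∓(V − V½)/k)); k1∞ is instantaneous.  Time
constants: τ_m 0.12 ms, τ_h 0.25–8 ms (voltage-dependent, fast
inactivation when depolarized, slower recovery at rest), τ_d 2 ms, τ_f
220 ms, τ_xr 140 ms, τ_xs 250 ms, τ_r 3 ms, τ_s 25 ms.  Nernst potentials
are fixed: there are no intracellular concentration dynamics.  That keeps
the state space small and steady-state pacing fast (the drug-free model
converges in ~4 paces), at the cost of realism — no calcium transient, no
rate-dependent ion accumulation, no electrogenic pumps/exchangers.

The constants were tuned once to meet the stated morphology targets at
1 Hz with the default stimulus and are frozen by regression tests:
resting potential −88.0 mV, peak +30.6 mV, APD90 242.3 ms, APD50
217.4 ms, dV/dt_max 163 mV/ms.  Qualitative pharmacology was part of the
tuning targets and is property-tested: 50% IKr block prolongs APD90
(242 → 337 ms), 50% ICaL block shortens it (→ 186 ms), 50% INa block
slows the upstroke (163 → 102 mV/ms).  Above roughly 75–80% IKr block the
model transitions abruptly from prolongation (APD90 ≈ 450 ms) to
repolarisation failure: a depolarized plateau with small oscillations.
It does not exhibit APD alternans at 1 Hz — the failure route is direct —
so alternans detection is exercised on synthetic traces.

`sixcurrent_demo_totalito` is the identical model flagged as carrying a
single *total* Ito conductance; an Ito block factor is applied to that
total conductance, covering the aliasing rule needed for literature
models that do not separate Ito,fast.

Default stimulus: square pulse, 2 ms, offset 10 ms into the pace,
amplitude 30 µA/µF ≈ 1.5× the measured excitation threshold (20.4 µA/µF),
the standard practice when a source model does not state its stimulus.

## Numerics

- **Solver**: scipy's variable-order BDF with adaptive steps; defaults
  abs_tol 1e-6, rel_tol 1e-8 (both configurable).  The rel < abs pairing
  is unusual but kept as the documented default.  Each pace is integrated
  piecewise — [0, stim_on], [stim_on, stim_off], [stim_off, period] — so
  the solver never steps across the stimulus discontinuity.
- **Output**: dense-output interpolation onto a uniform 0.1 ms grid, both
  pace endpoints included (10001 samples at 1 Hz); solver-internal steps
  are never exposed.  Exported/plotted traces are down-sampled to 1 ms;
  biomarkers always use the full grid.
- **Steady state**: after each pace, the Euclidean norm of the change in
  the raw state vector (mixed units, no per-variable weighting) at the
  pace boundary; converged when < 1e-6.  Pace limit: min(1800 paces,
  5 simulated minutes), configurable.
- **Oracle**: a fixed-step classic RK4 integrator at dt = 0.001 ms is an
  independent accuracy check; on the demo model's steady-state pace the
  two paths agree to 0.03 mV pointwise and < 0.01 ms in APD90 (test
  bounds: 0.5 mV, 1 ms).
- The demo-model right-hand side and the RK4 loop are numba-jitted, with
  a pure-Python fallback if numba is unavailable.

## Biomarkers and abnormality rules

APD_p runs from the instant of maximum upstroke velocity to the first
subsequent downward crossing of peak − (p/100)·(peak − rest), linearly
interpolated between bracketing samples; the max forward-difference slope
lives on a grid interval and the APD clock starts at that interval's
right edge, which makes square-pulse and linear-ramp closed forms exact to
one grid step.  An APD whose crossing never occurs is *absent*, never 0.
Rest is the voltage at trace start (pre-stimulus); measuring APD from the
upstroke rather than stimulus onset is the standard electrophysiology
convention.

Abnormality rules (the portal-style triggers are not published; these are
documented, configurable stand-ins):

- DEPOLARISATION_FAILURE: peak voltage below 0 mV.
- REPOLARISATION_FAILURE: an AP fired but APD90 is absent, **or** the
  membrane is still above −60 mV at the end of the pace.  The second
  trigger is needed because a depolarized plateau with oscillations can
  produce a nominal APD90 crossing tens of ms after the upstroke without
  any genuine recovery.  A failed-repolarisation pace reports APD90/APD50
  as absent and is excluded from ΔAPD90% (message instead of number).
- ALTERNANS: |APD90(last) − APD90(previous)| > 1 ms between the final two
  paces (an unconverged period-2 rhythm shows up exactly there).

## Study pipeline

The control (0 µM, always prepended to the requested grid) paces from the
model's default quiescent state; every test concentration warm-starts
from the control's converged state — an optimization only, verified to
change converged APD90 by < 1 ms versus a cold start.  ΔAPD90% is always
relative to the same-study control.  Concentration grids are log10-spaced
by default (sweeps span decades), linear on request, endpoints exact.  A
solver failure at one concentration is recorded in that row and the rest
of the sweep still runs.  Exports are deterministic given the result:
`summary.csv` (one row per concentration: factors, biomarkers, ΔAPD90%,
convergence, messages; absent values are empty cells), one trace CSV per
concentration, `metadata.json` echoing all inputs.

## What a green test establishes

The synthetic demonstration model emulates the *shape* of the problem —
six independently blockable stiff currents producing a realistic AP
morphology with the textbook pharmacology directions — not any particular
species or published cell model.  Green pipeline tests therefore
establish correctness of the machinery (dose–response algebra, block
application, steady-state pacing, biomarker extraction, reporting), and
the direction and monotonicity of predicted effects, but the magnitudes
of ΔAPD90% are properties of the demo model only and carry no clinical
calibration.  Known limitations: no calcium subsystem, no rate-dependent
drug binding (IC50s are rate-independent by construction), no late
sodium current, single cell only (no tissue, conduction or ECG-level
quantities), no uncertainty propagation from IC50 variability.
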