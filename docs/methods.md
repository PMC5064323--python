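# Methods

## Model

`cascadenet` implements a one-dimensional feedforward firing-rate network of
the early visual pathway with two cascaded adaptation mechanisms: adaptation
of the retinal transduction, and short-term synaptic depression (STD) at the
thalamocortical (LGN → V1) synapses.  Each of the three layers — retina,
LGN, V1 — has `N` neurons whose receptive-field centers `x_k, x_j, x_i` tile
the interval `[-L, L)` on a uniform, cell-centered grid
`x_k = -L + (k + 1/2)·(2L/N)`.  Periodic boundary conditions apply to all
three layers, to the couplings between them, and to the stimulus: every
distance is the minimum-image distance on a ring of circumference `2L`,
`d(a, b) = min(|a−b|, 2L−|a−b|)`.

The fixated dot produces an optical-strength profile on the retina,

    O_k = A · exp( − d(x_k, x_c)² / (2 σ_O²) ),

centered on the current gaze-relative stimulus position `x_c`.  The retinal
cell converts it to a firing rate through a multiplicative adaptation
factor `r_k ∈ (0, 1]`:

    R_k = r_k · O_k,
    dr_k/dt = (1 − r_k)/τ_r − f_r · r_k · O_k · κ.

LGN and V1 neurons are described by membrane potential and a sigmoidal
rate function:

    τ_m dV_j/dt = −V_j + g Σ_k W_jk R_k,          R_j = F(V_j),
    τ_m dV_i/dt = −V_i + g Σ_j W_ij S_j R_j,      R_i = F(V_i),
    F(V) = α / (1 + exp(−β (V − θ))),

and the thalamocortical synaptic strength `S_j ∈ (0, 1]` follows the
standard rate formulation of short-term depression,

    dS_j/dt = (1 − S_j)/τ_S − f_S · S_j · R_j · κ.

`κ = 10⁻³` is a unit conversion, not a parameter: rates are expressed in
Hz (per second) while all time constants and the integration step are in
milliseconds, so a rate entering a per-millisecond depletion term is scaled
by `ms/s`.  The same conversion is applied to the optical strength in the
retinal-adaptation equation, treating `A` as Hz-like.

The feedforward weights are Gaussian tuning curves of the circular distance
between receptive-field centers,

    W_jk ∝ exp(−d(x_j, x_k)²/(2σ1²)),   W_ij ∝ exp(−d(x_i, x_j)²/(2σ2²)),

with every row normalized to the total weight `w_sum`, so that the summed
synaptic weight received by a neuron — and therefore the entire dynamics of
the network-averaged rate — is independent of the grid resolution `N`.  In
practice the sustaining times computed at `N = 200` and `N = 1000` agree to
better than 0.01 ms, which is why the test suite runs at reduced `N`.

### Parameters

| name | default | units | meaning |
|---|---|---|---|
| `g` | 1.8 | — | feedforward gain |
| `tau_m` | 30 | ms | membrane time constant (LGN, V1) |
| `alpha` | 200 | Hz | rate-function saturation |
| `beta` | 1 | 1/potential | rate-function slope |
| `theta` | 6 | potential | rate-function threshold |
| `tau_S` | 200 | ms | STD recovery time constant |
| `tau_r` | 200 | ms | retinal-adaptation recovery time constant |
| `f_S`, `f_r` | 0.75 | — | depression/utilization fractions |
| `A` | 60 | Hz-like | stimulus peak optical strength |
| `sigma1`, `sigma2` | 1.5 | position | tuning widths of the two projections |
| `N` | 1000 | — | neurons per layer |
| `L` | 10 | position | half-width of the ring domain |
| `sigma_O` | 1.5 | position | stimulus width (implementation-owned; set to `sigma1`) |
| `w_sum` | 0.8 | — | summed feedforward weight per neuron (implementation-owned) |
| `dt` | 0.1 | ms | integration step (implementation-owned) |

The first twelve rows are the published constants of the model family this
package implements.  `sigma_O`, `w_sum` and `dt` close the gaps the printed
constants leave open.  `w_sum = 0.8` places the network in the regime that
exhibits the model's characteristic behaviour: baseline LGN/V1 activity in
the sensitive range of the sigmoid, a strong evoked transient, STD settling
slow enough (effective time constant of order 100 ms at baseline rates) that
the fixation-onset history matters over the 100–300 ms interval range, and
depression fast enough during the transient to cut the response short.  At
substantially larger coupling the network saturates (no evoked transient);
at substantially smaller coupling responses fall below a measurable size.

## Protocol and simulation

A trial starts in darkness: the state is initialized at rest
(`V = 0, S = 1, r = 1`) and relaxes for `settle_ms` (default 500 ms) with
zero drive.  At `t = 0` the fixation stimulus appears; microsaccades are
instantaneous displacements of the stimulus center by their signed
magnitude `M` at their onset times, accumulated and wrapped on the ring.
Note that the quiescent state is not exactly `S = 1`: the sigmoid has a
small positive rate at rest (`F(0) ≈ 0.5 Hz`), so the dark fixed point
carries `S ≈ 0.93`, with `r = 1` exactly.

The fixation-microsaccade interval TI is measured from the *onset* of
fixation, and this matters: the interval dependence of the response arises
precisely because the adaptation state (mostly `S`) is still settling
toward its fixation steady state when the microsaccade occurs.  A protocol
that pre-settled the fixation before the event would, by construction, show
no TI dependence at all.

Integration uses fixed-step explicit Euler (`dt = 0.1` ms) for the membrane
potentials and the exponential-Euler update for `S` and `r` (their
equations are linear in the state for a frozen rate, so the step
`S ← S∞ + (S − S∞)·exp(−b·dt)` is exact over one step).  This preserves
`S, r ∈ (0, 1]` exactly and remains stable during strong transients.
Halving `dt` changes the population-rate trace by well under 1 % in sup
norm (asserted in the suite).  The circulant weight matrices are applied by
FFT circular convolution; a test asserts the FFT path equals the dense
matrix product.

The model output is the network-averaged V1 rate `⟨R_i⟩`.  The **baseline**
is the mean of `⟨R_i⟩` over the final 100 ms of the trace: trials extend
2000 ms (= 10 τ_S) past the last event, and since the post-event steady
state is a ring translation of the pre-event one, this equals the fixation
steady state.

## Response timescales

For each microsaccade, `metrics.measure` extracts:

* **RT (responsive time)** — event onset to the peak of `⟨R_i⟩` within the
  window ending at the next event (or trace end); ties broken earliest;
* **ST (sustaining time)** — peak to the first crossing of the half-high
  level `baseline + (peak − baseline)/2`, located by linear interpolation
  between samples.

A peak must exceed baseline by 0.1 % of `α` to count (`NoPeakError`
otherwise); a trace that never returns to half-high raises `NoDecayError`.
Both timescales are invariant under affine rescaling of the trace and under
refinement of the time grid (property-tested).

## Sweeps and behavioral predictions

The default sweeps probe `M ∈ {1.4, 1.8, 2.2, 2.6, 3.0}` at `TI = 150` ms
and `TI ∈ {100, 150, 200, 250, 300}` ms at `M = 2.2`, with STD enabled and
disabled ("absence of STD" = `S` pinned at 1 with no dynamics).  The grid
ranges bracket the reference condition (`M = 2.2`, `TI = 150` ms) and are
restricted to the window in which ST cleanly measures the
microsaccade-evoked transient: below `TI ≈ 100` ms the response overlaps
the fixation-onset transient, and below `M ≈ σ_O` the displaced stimulus
barely clears its own adapted footprint; in both cases the onset tail
contaminates the half-high measurement.  The caps (`M = 3`, `TI = 300` ms)
delimit the small-magnitude/small-interval region in which the trends are
informative — beyond them the ST curves flatten as the adaptation state
saturates.

The headline result is a sign dichotomy.  With STD, ST falls monotonically
with M (a larger displacement recruits fresher synapses, drives a larger
LGN transient, and depletes `S` faster, cutting the response short) and
rises with TI (a later microsaccade meets more-depressed synapses whose
further depletion is slower).  Without STD both trends reverse, driven by
retinal adaptation alone.

Two behavioral predictions follow from the premise that microsaccades
counteract visual fading, so the sustaining time of the evoked response
sets the time for which the current fixation remains visible — i.e. the
interval to the next microsaccade reflects ST up to a positive monotone
(affine) calibration `TI_pred = u + v·ST`, `v > 0`.  All asserted
sign/shape claims are invariant to `(u, v)`; the default is the identity.

* magnitude → interval: `(TI)_n` vs `M_n` inherits ST(M) — exponentially
  decreasing with STD, increasing without;
* interval → interval: `(TI)_{n+1}` vs `(TI)_n` inherits ST(TI) — slightly
  positive linear relation with STD, decreasing (exponential fit) without.

`build_predictions` refuses to construct a prediction from a sweep whose ST
column is not monotone beyond a small tolerance (0.1 ms), reporting the
violating cells.

Exponential fits (`y = a·exp(−b·x) + c`) use least squares initialized from
the data: offset near the extremum of `y`, amplitude from the range, and
decay rate from a log-linear regression of `y − c` — nonlinear exponential
fits are sensitive to their starting point, so the initialization is part
of the documented procedure.  Noiseless generative data are recovered to
better than 1e-6 (asserted).

## Synthetic microsaccade event tables

The behavioral analysis operates on event tables (subject, trial, onset
time in ms, magnitude).  Because no suitable public recordings ship with
the package, `generate_synthetic_events` produces tables with exactly the
statistical structure the predictions describe, emulating five subjects
with 10 020 ms fixation trials:

* magnitudes i.i.d. lognormal (mean 2.0, sd 0.7 in the model's position
  units, clipped to [0.3, 6]);
* mean interval after a magnitude-M event: `μ(M) = a·exp(−b·M) + c` with
  defaults `a = 600` ms, `b = 0.5`, `c = 100` ms, giving a realistic
  microsaccade rate of roughly 2–4 events/s;
* realized intervals `TI_n = μ(M_n)·exp(η_n)` with `η` a stationary AR(1)
  process (lag-1 correlation `ρ = 0.3`, stationary sd 0.3): multiplicative
  lognormal noise with positive serial coupling between consecutive
  intervals.

This is the simplest generative process exhibiting both predicted
structures at once; its lag-1 regression slope has a closed form in the
lognormal moments, which the suite checks against the fitted slope.  What
the generator does **not** emulate: drift/tremor between events, binocular
or directional structure, magnitude–magnitude serial correlation,
refractory effects at very short intervals, and subject heterogeneity
(all subjects share one parameter set).  Passing the analysis-stage tests
therefore validates the estimator pipeline and its statistical power at
realistic sample sizes — not the realism of any particular recording.

The analysis (`pair_events`, `estimate_relations`) pairs events strictly
within trials, fits the exponential (magnitude → interval) and linear
(interval → interval) relations on the raw pooled pairs, and reports
equal-count binned means (default 8 bins) alongside for display.  A
per-subject mode (bin per subject, then fit) is provided; pooling is the
default.  Relations are unit-covariant in the magnitude: tables may carry
magnitudes in any consistent unit.

## Numerical and design choices

* **STD ablation**: "absence of STD" clamps `S ≡ 1`; the drive then equals
  the STD-enabled drive with `S` replaced by 1 (asserted).
* **Peak search**: global maximum per inter-event window, earliest tie wins.
* **Half-high crossing**: linear interpolation between samples (not nearest
  sample); ST is then accurate to well under one step.
* **Degenerate inputs**: flat traces raise `NoPeakError` rather than
  returning 0; non-finite states abort with the offending time step;
  trials with < 2 events are skipped and counted, never silently dropped.
* **Problem sizes**: the test suite simulates at `N = 200` (and `N = 64`
  for dynamical checks); the acceptance script runs the default
  `N = 1000`.  The row-normalized coupling makes these agree to ≪ 0.1 ms.

## Limitations

* The model is one-dimensional and purely feedforward: no inhibitory
  reticular neurons, no recurrent intracortical connections, no
  corticothalamic feedback, no spike-timing-dependent plasticity, no
  spiking — in keeping with the minimal model family it implements.
* Microsaccades are instantaneous displacements; drift and tremor between
  events are not modeled, and magnitude is a scalar (no 2-D direction).
* The absolute scale of ST (tens of ms) is far below behavioral
  inter-microsaccade intervals (hundreds of ms); only the signs and shapes
  of the relations, which are calibration-invariant, are scientifically
  asserted.  No quantitative agreement with any published curve is claimed.
* The equations above are the package's reconstruction of the model family
  from its printed constants and described mechanisms; `w_sum`, `σ_O` and
  the unit convention `κ` are its own, documented choices.
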