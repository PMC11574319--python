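# Methods

This note documents the models, estimators, numerical choices and defaults
behind the package, and what the synthetic test bed does and does not
establish about real recordings.

## Trace model and units

Time in seconds, voltage in mV, current in pA, temperature in °C;
conductance in nS, capacitance in pF (so nS/pF = 1/ms and mV/pA = GΩ).
Sweeps are uniformly sampled (20 kHz default), immutable after
construction, and carry their protocol in a JSON sidecar rather than
inferring it from the trace. All analysis windows are half-open [t0, t1);
sample indices are 0-based. On-disk format: two-column CSV
(`time_s,value`, 12 significant digits, LF endings) plus the sidecar;
families are directories with a `manifest.json`. This layout is an
artifact decision made for transparency and diff-ability; vendor
acquisition formats are out of scope.

## Conductance-model neuron

Single compartment:

C dV/dt = −[g_l(V−E_l) + g_kir·k∞(V)(V−E_K) + g_na·m³h(V−E_Na)
           + g_kv·n⁴(V−E_K)] + I_inj

* **Leak**: ohmic, E_l = −70 mV.
* **Inward rectifier (Kir)**: instantaneous Boltzmann activation
  k∞(V) = 1/(1+exp((V−V½)/k)), V½ = −80 mV, k = 20 mV, E_K = −90 mV. The
  conductance deactivates with depolarization, which is what makes the
  measured input resistance rise from the hyperpolarized to the
  depolarized conditioning level. The slope factor is deliberately shallow
  so the total steady-state I–V stays monotone (no bistability) over the
  subthreshold range.
* **Nav / Kv**: classic squid-style rate functions evaluated at V − 10 mV,
  which places the spike threshold near −45 mV; m³h and n⁴ gating.
* **Temperature**: all rate constants ×q10_rates^((T−T_ref)/10), all
  maximal conductances ×q10_cond^((T−T_ref)/10), T_ref = 23 °C. Defaults
  q10_rates = 3.0 and q10_cond = 1.4 are standard biophysical ranges.

Default parameters (an artifact choice, not measured values): C = 100 pF,
g_l = 4.7 nS, g_kir = 25 nS, g_na = 3.6 µS, g_kv = 360 nS, E_Na = +60 mV.
They were chosen once so that the resting potential before holding current
is ≈ −85 mV, the input resistance at −75 mV is ≈ 90 MΩ (τ ≈ 9 ms), and the
cell fires overshooting action potentials under a current ramp — the
qualitative phenotype of a striatal medium spiny neuron. With these
defaults the temperature effects run in the physiologically observed
directions: input resistance and membrane time constant fall, rheobase and
maximum firing rate rise, and Kv activation accelerates from 23 °C to
34 °C.

**Integration.** Current clamp: fixed-step classical RK4 at dt = 0.01 ms
(numba-compiled), decimated to the 20 kHz output rate; a non-finite state
aborts with the offending step index. Voltage clamp is ideal (V equals the
command instantly), so each gating ODE is linear with constant
coefficients within a segment; the RK4 update then reduces to the exact
geometric recurrence x_{k+1} = x∞ + (x_k − x∞)·φ(−(α+β)h) with φ the
degree-4 Taylor polynomial of exp, which the simulator evaluates in closed
form — numerically identical to looping the integrator, but O(1) per
sample.

**Holding current.** Solved by bisection on the injected DC current; the
resting potential for each candidate current comes from a root solve of
the steady-state current balance on the monotone subthreshold branch
([−120, −48] mV), converging well inside the 0.5 mV tolerance. A test
confirms the integrated cell actually rests at the target.

## EPSP / noise generator

Baseline 0 mV, Poisson-timed EPSPs (inter-event gaps by inversion of
uniforms, so event counts are bit-reproducible given the seed) with a
unit-peak double-exponential kernel (τ_rise = 1 ms, τ_decay = 10 ms,
amplitude 0.5 mV, 5 Hz), plus i.i.d. Gaussian noise (σ = 0.1 mV default).

## Thermostat model

Two lumped nodes (heater block C_h = 80 J/K, bath C_b = 40 J/K) with an
effectiveness-based heat exchanger: the perfusate (heat-capacity rate
C_q = ρc·Q, ρc = 4.186 J/(ml·K)) enters at ambient, leaves the block at
T_amb + ε(T_h − T_amb) with ε = 1 − exp(−k_ex/C_q), k_ex = 0.18 W/K, and
delivers C_q(T_out − T_b) to the bath. Losses to ambient: 0.3 W/K
(heater), 0.05 W/K (bath). Heating power 25 W when the relay is closed;
the relay closes at setpoint − hysteresis and opens at the setpoint
(hysteresis 0.3 °C — off-the-shelf thermostat controllers do not publish
their dead-band, so this is a plausible default). Explicit Euler at
dt = 0.1 s, logged every 10 s; a per-step temperature change above 5 °C
raises a stability error.

Two consequences built into the physics, both verified by tests: at a
fixed setpoint, steady-state bath temperature decreases with flow over the
working range (ε falls faster than C_q rises), so the setpoint required
for a 33 °C bath rises with flow; and since the steady heat loss
(k_ha + εC_q)(T_set − T_amb) rises with flow and setpoint, so does the
heating duty ratio. Defaults put the high-flow (6.5 ml/min) setpoint near
57 °C with ~6 min equilibration — the same regime as a bench system whose
heater sits near 60 °C and reaches temperature in ~10 min.

## Analysis choices

* **Input resistance**: steady-state window = last 20% of the probe,
  baseline = equal length immediately pre-probe; robust to the exact probe
  length and independent of the conditioning mechanism. Conditioning is
  realized as DC offsets (±100 pA default) because the experimental
  procedure for establishing the three potentials is not standardized.
  Spikes inside a window raise a contamination error rather than silently
  corrupting the estimate.
* **Double-exponential fit**: 8 multi-starts on a log-spaced slow-τ grid
  (0.2–50 ms), bounds τ ∈ (0.05, 500) ms, trust-region least squares;
  lowest RSS wins, ties broken toward the smaller slow τ. The fit segment
  starts 2 samples after pulse offset to skip the stimulus edge. If the
  optimizer parks essentially all amplitude in the fast slot (|A_s| <
  10⁻⁴|A_f|), the data is effectively single-exponential and the dominant
  component is relabelled as the reported slow one.
* **Spike onset**: second derivative by central differences with a 5-point
  smoother (applied to d²V/dt² only), maximized over the 2 ms before the
  dV/dt-threshold crossing — a literal "inflection point" rule. Rheobase
  varies by <2% as the threshold spans 10–30 mV/ms on synthetic spikes.
* **Leak model**: "weighted average" is read as driving-force weighting
  (weights ∝ |V − V_hold|, i.e. 5:10:15), which coincides with a
  least-squares slope anchored at the holding potential; an unweighted
  mean is available as a config switch. The template is a *time series*
  (not just a scalar conductance) so the 150 Hz low-pass is applied to the
  leak current model itself, as a zero-phase (forward-backward)
  second-order Butterworth — zero phase so subtraction introduces no lag
  into the τ estimates. Both ĝ and the template use baseline-subtracted
  currents, which makes the template zero before the step and the
  subtraction independent of the holding current. ĝ uses the steady-state
  window; the template uses the whole trace.
* **Kv τ**: first sample at or above (1−1/e)·I_max, no interpolation by
  default (sub-sample interpolation available behind a flag), reported for
  −10…+10 mV where the current is reliably outward. A command with no
  outward current is recorded as missing, not fatal.
* **Noise floor**: the smoothing filter is a pure feed-forward 10-sample
  moving average (unit feedback) — a general rational transfer function is
  not reconstructible from a length alone, and the moving average
  reproduces the closed-form residual variance σ²(N−1)/N exactly. Warm-up
  (first N−1 residual samples) is discarded rather than padded, which
  makes the constant-trace case exact. The default span is the first 10 s
  of contiguous valid residual, on the voltage channel.
* **Thermal statistics**: population (not sample) sd — these are
  descriptive statistics of a fixed logged window, by default 5 min
  starting 20 min after activation (ramp-up plus equilibration).
  Look-up bisection: setpoint bounds [target, target+60 °C], 0.05 °C
  tolerance, ≤40 iterations, steady state from the last 25% of a 1 h
  simulated run.
* **Statistics**: two-sided p throughout; no multiple-testing correction
  (per-test reporting), a Holm option can be layered by the caller. The
  Mann-Whitney exact path enumerates all C(n₁+n₂, n₁) labelings up to
  n₁+n₂ = 16 and defines the two-sided p as the probability of a U at
  least as far from n₁n₂/2 as observed (the enumeration distribution is
  symmetric about that center, so this equals the usual doubled tail);
  above 16 it uses the tie-corrected normal approximation with continuity
  correction. The per-property n in the comparison table is carried
  explicitly because individual measurements can drop out cell by cell.
* **Type-I calibration**: the null study draws paired measurements from a
  shared cell-level random effect plus independent measurement noise —
  two statistically identical conditions — because the neuron model itself
  is deterministic given its parameters (identical parameters would give
  literally identical values and a degenerate test). 1000 replicates of
  n = 15 pairs give a rejection rate statistically compatible with the
  nominal 5%.

## What the synthetic test bed does and does not show

The generators emulate the *structure* of the real data — protocols,
sampling, the direction and rough magnitude of temperature effects, relay
cycling and flow-dependent heater–bath differentials — but they are not
fitted to any measured recordings: the neuron's parameter values, the ramp
slope/duration, the thermostat's capacities and coefficients, and the
hysteresis width are artifact choices. Passing tests therefore establish
that the *estimators* are correct (exact on closed-form cases, within
stated tolerances on simulated ones) and that the modelled physics
reproduces the qualitative phenomenology; they do not validate the
simulators as quantitative models of any particular rig or cell, and
quantities like a measured bath sd of 0.2 °C or a rheobase of 264 pA are
properties of specific hardware and cells that the defaults do not attempt
to reproduce. Real-data features deliberately absent: electrode/access
resistance and capacitance artifacts, line noise and EMI physics (noise is
injected statistically), channel noise, multicompartment morphology, and
Peltier cooling mode.

## Problem sizes

Defaults used by the test suite and the acceptance script: 20 passive
cells for recovery checks; a 15-cell cohort (10% log-normal parameter CV)
measured at 23 and 34 °C; 1 h simulated thermostat runs at 0.1 s steps;
10 s noise spans at 20 kHz; 1000 calibration replicates. The whole
acceptance run completes in well under a minute on one CPU.
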