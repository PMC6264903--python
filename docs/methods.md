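# Methods

## Model

`gfnet` simulates a two-layer rate-coded neural network that learns to
transform the eye-centred (retinotopic) location of a visual target into a
head-centred representation, the transformation attributed to the primate
dorsal visual pathway (parietal areas 7a, LIP, PO/V6A).

**Input layer.** Each input neuron j is a retinotopic visual neuron with a
Gaussian tuning curve over the retinal target location r (preferred
location α_j, width σ) whose response is multiplicatively gain-modulated by
eye position e.  Two gain forms are implemented:

* peaked: `exp(−(e − β_j)² / 2ρ²)` — a Gaussian of eye position (found in
  area PO/V6A);
* sigmoid: `1 / (1 + exp(κ_j (e − β_j)))` — a saturating monotonic gain
  (the dominant form in 7a/LIP); κ_j > 0 gives gain > 0.5 for e < β_j.

The population tiles the preference space evenly.  The standard geometry is
201 retinal preferences × 61 eye-position preferences at 1° spacing, i.e.
12,261 peaked neurons or 24,522 sigmoid neurons (both gain signs at every
grid point).  The retinal-preference span is [−100°, 100°]: the nominal
visual space is ±90°, but the 201-point count is load-bearing (it fixes the
connectivity fraction's afferent count), and the extra margin only adds
effectively silent neurons.  Mixed populations convert each grid neuron to
sigmoid independently with probability p (the sigmoid modulation rate), the
gain sign then ±1 equiprobably.

**Output layer.** N = 900 competing neurons, each receiving afferents from
its own random subset (fraction ϕ) of the input layer.  Per neuron i:

* activation: τ_h dh_i/dt = −h_i + Σ_j w_ij v_j^I, with τ_h = 100 ms;
* firing rate: v_i = 1 / (1 + exp(−2φ(h_i − p_π − θ))), where p_π is the
  π-th percentile of the current activation distribution — an implicit
  model of lateral inhibition that keeps roughly (100 − π)% of the
  population strongly active;
* memory trace: τ_q dq_i/dt = −q_i + v_i, with τ_q = 400 ms.

**Plasticity.** Every rule factorises as dw_ij/dt = g_i · v_j^I with a
per-output-neuron postsynaptic factor g_i:

| rule                     | g_i                              | defaults |
|--------------------------|----------------------------------|----------|
| standard_trace           | ϱ q_i(t)                         | ϱ = 0.05 |
| hebbian                  | ϱ y_i(t)                         | ϱ = 0.05 |
| delayed_trace_antihebb   | α(β q_i(t−ΔT) − y_i(t))          | ΔT = 50 ms, β = 2.2 |
| delayed_rate_antihebb    | α(β y_i(t−ΔT) − y_i(t))          | ΔT = 500 ms, β = 2.4 |
| current_trace_antihebb   | α(β q_i(t) − y_i(t))             | β = 2.2 |
| delayed_trace_only       | α q_i(t−ΔT)                      | ΔT = 30 ms |

After every update each neuron's weight vector is clipped at zero
(synapses stay excitatory, consistent with Dale's law; how negative
anti-Hebbian excursions should be handled is not published, and a
signed-weight variant is available via ``Model.clip_negative``) and
renormalised to unit Euclidean norm.  The learning rates ϱ, α are per
second; the published tables give no α for the modified rules, so α = ϱ =
0.05 is assumed.

**Numerics.** All ODEs are integrated with Forward Euler at Δt = τ_h/10 =
10 ms.  The neural equations use milliseconds; the weight equation is
stepped in seconds (ϱ = 0.05 with a 10 ms step adds 5·10⁻⁴ per unit
pre/post activity), which is the only reading under which learning unfolds
over epochs rather than within a few steps.  The competition percentile is
evaluated on the post-update activation vector of the current step, before
the rates (the ordering is not specified in the published account; this
choice is deterministic and self-consistent).  Exponents in the rate function are
clamped at |x| ≤ 700.  Initial conditions are h = q = 0 with delay buffers
prefilled with zeros.  ΔT values are integer multiples of Δt, so delayed
reads index a ring buffer exactly.  The per-step weight work (drive, Euler
update, clip, renormalise over all stored synapses) is fused into a single
numba kernel whose output is bit-compatible with the plain numpy reference
path (asserted in the test suite).

## Protocols

**Training.** One epoch presents M = 8 head-centred target locations
(−63° … 63°, 18° apart) in order.  While a target is fixed, the eyes make
P = 15 fixations of 300 ms at eye positions drawn uniformly from
[−24°, 24°], joined by constant-velocity 400°/s saccades (~40 s of
simulated time per epoch).  Trace learning then binds input patterns that
share a head-centred location across eye positions, because gaze changes
much faster than the head-centred scene.  Trajectories are stored as exact
piecewise-linear breakpoints; sampling at 1 kHz and interpolating linearly
(the published procedure) is mathematically identical on such segments.  Each
period starts at a freshly drawn eye position; learning is active
continuously, including during saccades.  Dynamic state carries over
between epochs.

**Testing.** Learning disabled.  For each of E = 4 eye positions (−18°,
−6°, 6°, 18°) the target steps through T = 80 head-centred locations
(−79° … 79°, 2° apart), dwelling 330 ms; the instantaneous rates at the
end of each dwell form the E × T response matrix per neuron.  State is
reset at the start of each eye-position sweep and evolves continuously
within a sweep (330 ms ≫ τ_h, so carry-over is small; resets between
sweeps avoid sweep-order artefacts).  Because inputs are constant within a
dwell, the synaptic drive is computed once per dwell.

**Hebbian control.** 200 random (eye position, retinal location) patterns
presented 100 ms each with τ_h = 30 ms (no trace effect); pattern duration
is not published and is chosen ≥ 3τ_h so activations settle.

## Reference-frame analysis

Head-centredness Π is the mean Pearson correlation between full response
rows across all C(E,2) eye-position pairs.  Eye-centredness Ω is the same
average over windowed subvectors chosen so all windows span a common range
of retinal locations.  With targets t_j = t_1 + Δh(j−1) and eyes
e_i = e_1 + Δe(i−1), the exact retinal intersection gives first columns
f_i = (Δe/Δh)(i−1) + 1 and length V = T − (Δe/Δh)(E−1) (these satisfy the
alignment identities t_{f_i} − e_i = t_1 − e_1, t_{l_i} − e_i = t_T − e_E,
asserted at runtime).  The published closed forms instead give
V = T − (Δe/Δh)(E+1) — 2(Δe/Δh) columns short of the intersection, the
result of a sign error in the derivation — with the same f_i.  Both are
implemented (`variant='constraint'` / `'printed'`).

A neuron is head-centred if Π > 0 and Π > Ω, eye-centred if Ω > 0 and
Ω > Π, otherwise unclassified.  Zero-variance or non-responding
(within-window range < ε = 0.01; rates never reach exactly zero)
subvectors are dropped from pair averages; a metric with no valid pair is
undefined, and an undefined metric makes its comparisons fail.  Two
presence-filter readings are implemented: `'any'` excludes a neuron only
when no eye position shows an in-window response, `'all'` excludes it when
any eye position lacks one.

**Default pipeline choice.**  The defaults `variant='printed'`,
`presence='all'` were fixed by running the full-scale peaked standard-trace
experiment once and comparing all four (window × presence) combinations
with the published population statistics; only this combination reproduces
them (e.g. trained head-centred fraction 68% vs 87% under the
constraint-consistent/permissive alternative), and it also matches the
published account of a neuron being excluded because it lacked a response
at one of the four eye positions.  Population summaries report the head-centred fraction of
the whole output population, the mean Π among head-centred neurons
(undefined when none exist), and the mean Ω over all analysed neurons.

## Structure tools

The covariance between two input neurons over the stimulus grid
(r ∈ [−90°, 90°], e ∈ [−30°, 30°], 1° steps by default) predicts the weight
structure a purely Hebbian competitive learner would converge to.  Every
response factorises into a retinal profile times an eye gain, so the grid
covariance is computed from separable 1-D sums; a brute-force double loop
is the test oracle.  Peaked-gain covariance is localised in both preference
dimensions; sigmoid-gain covariance is localised in retinal preference but
elongated along eye preference — the structure that drives eye-centred
self-organisation.

The prewired construction assigns each output neuron one of nine
head-centred locations (−68° … 68°, balanced 100 neurons each) and sets
each sampled synapse to an elevated weight (10) when the presynaptic
neuron responds above half gain, at some eye position, to a target at the
assigned location — for κ > 0 this is h − β ≤ α ≤ h + W/2, mirrored for
κ < 0, with W = 60° the eye-position dimension size — and to a depressed
weight (1) otherwise, followed by unit-norm renormalisation.  Boundary
inclusion is taken as written (closed intervals); connectivity is sampled
at ϕ = 8.16% (exactly 2001 afferents per neuron).

## Reduced scales and what the tests show

Full-scale experiments (900 outputs, 1° grids, 20 epochs) run in minutes
and are used by `scripts/acceptance.py` for the untrained, trained-peaked,
prewired and mixed-population statistics.  The test suite uses smaller
problem sizes chosen as the smallest at which each phenomenon manifests:

* the `make_fixture` configuration (21 × 10 preference grid, 50 outputs,
  2 epochs) exercises all plumbing in seconds but is below the scale at
  which trace-driven self-organisation appears — the preference grids must
  be at least about half the tuning width (≤ 3°-spacing at σ = ρ = 6°) for
  neighbouring input patterns to overlap enough to be bound;
* directional self-organisation tests use 2° grids with 100–200 outputs
  and 5–20 epochs;
* the modified-rule comparisons keep the full 1° sigmoid population (the
  anti-Hebbian rescue is weak on coarsened grids) with 200 outputs.

Synthetic response matrices used in analysis tests are constructed directly
from closed-form eye-centred / head-centred response functions; they
emulate the geometry of real test responses but not competition noise, so
those tests validate the metrics, not the simulation.

## Known limitations

* The prewired model reproduces the published phenomenon qualitatively — a
  large head-centred subpopulation that collapses within one epoch of
  standard-trace plasticity and vanishes by epoch 5, against zero
  head-centred neurons for random weights — but the untrained head-centred
  fraction is ~35-45% rather than ~77%: with |κ| = 0.0625 the gain is
  shallow enough that the elevated-pool drive retains a partial eye-centred
  component (receptive fields shift by ~25% of the eye displacement), and
  steeper gains that sharpen the prewired model (|κ| ≥ 0.125) break the
  published untrained sigmoid eye-centredness of 0.88, which |κ| = 0.0625
  reproduces exactly.  The two published numbers appear mutually
  inconsistent under any single κ in this implementation.
* The modified learning rules reproduce the published effects
  directionally but weakly: with pure sigmoid inputs the anti-Hebbian
  rules produce a nonzero head-centred set (of order 10 neurons at full
  scale) where the standard rule and the delayed-trace-only rule produce
  none, but the published relative ordering of the rule variants and the
  large head-centred population for the delayed-trace-only rule on a
  50:50 mixed population do not emerge.  The learning rate α of these
  rules is not published (α = ϱ = 0.05 is assumed) and the outcome is
  sensitive to the α/β balance; neither clipping nor allowing signed
  weights changes the picture.
* Gain fields are peaked or sigmoidal only (no purely planar gain); no
  explicit inhibitory interneurons; no spiking dynamics; fixed-step
  Forward Euler only.
* The percentile convention, initial conditions, presentation duration of
  the Hebbian control, and test-time state handling are not published and
  follow the documented choices above.
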