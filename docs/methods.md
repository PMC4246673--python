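# Methods

## Model

`masskf` models each cortical region as a mesoscopic circuit of three
neural populations — pyramidal cells (p), excitatory spiny stellate
interneurons (e) and inhibitory interneurons (i) — plus an external
firing-rate input u.  Every synaptic pathway m→n is a second-order linear
stage driven by the presynaptic firing rate φ_m:

    dv_mn/dt = z_mn
    dz_mn/dt = (α_mn/τ_mn) φ_m − (2/τ_mn) z_mn − (1/τ_mn²) v_mn

whose impulse response is the classical alpha-function kernel
(t/τ)·e^(−t/τ).  v_mn is the post-synaptic potential (PSP, mV), α_mn a
lumped connectivity gain (synaptic gain × fibre count × peak rate,
treated as one dimensionless number) and τ_mn the synaptic time constant.
A population's membrane potential is the sum of its incoming PSPs, and
its output rate is the error-function sigmoid

    g(v) = ½ (erf((v − v0)/(√2 ς)) + 1),

the Gaussian CDF with threshold v0 = 6 mV and slope ς = 3 mV (the spread
of firing thresholds across the population).  A region contains five
pathways (u→p, e→p, p→i, i→p, p→e).  Regions couple through delayed
pyramidal-to-pyramidal pathways with the same second-order form,
time constant τ_d = 30.3 ms and gain α_jk; the four-region network is a
bidirectional ring.  Each inter-region pathway occupies exactly one
(v, z) pair, so the augmented state — all (v, z) pairs plus all gains,
which have trivial dynamics α̇ = 0 — has dimension 3(N+K): 15 for one
region (N=5), 84 for the ring (N=20, K=8).

The drift factorizes as dξ/dt = Aξ + (Bξ)∘g(Cξ) + D(u)ξ with A the
linear synaptic relaxation, B routing α/τ into the matching z rows, the
rows of C the population adjacency vectors γ_j (summing incoming PSP
positions), and D(u) = u·D1 for the input-driven pathways.  The matrices
are assembled mechanically from the per-connection equation above; a
per-connection loop implementation serves as the oracle in the tests.
Time stepping is forward Euler at δ = 1 ms.

Fixed constants: τ = 10 ms for all excitatory synapses, 20 ms for
inhibitory-to-pyramidal, u ~ N(220, 5.74).  Background (alpha-rhythm)
gains: α_up = 3.2, α_ep = 1755, α_pi = 548.4, α_ip = −3712.5,
α_pe = 2197; ring gains 76/63/44/70 by target region.  At these values
the deterministic system sits on a limit cycle near 10 Hz; PSPs swing
10–30 mV.

## Forward simulator

The simulator is the package's synthetic-data generator and defines the
benchmark conditions.  Per step it draws an input sample, takes an Euler
step, adds process noise, and pins the gain entries to a piecewise-linear
true-gain schedule (gains are scenario inputs, not dynamics).  The state
starts at the noise-free fixed point of the scheduled initial gains.

* **Process noise** enters only the z entries of input-driven synapses
  (the unmodeled afferent drive), with a default standard deviation of
  10 mV/s per step.  This is an order-of-magnitude choice — large enough
  to act as a genuine driving term alongside the input noise (whose
  per-step effect on z_up is δ·(α_up/τ)·σ_u ≈ 0.8 mV/s), small enough
  that the ECoG stays in the physiological tens-of-mV regime.  Reducing it
  to the input-noise scale was checked and *hurts* inversion accuracy
  (the extra drive acts as persistent excitation), so it is not a
  benchmark-friendly choice.
* **Measurement**: the single-region channel reads the pyramidal
  membrane potential (sum of its incoming PSPs); the four-region montage
  is differential, channel j = region j minus its ring successor
  (j mod 4 + 1), entries ±1 on PSP positions.  The montage matrix has
  rank 3 for four regions: the common mode of the four pyramidal
  potentials is invisible, which matters for inversion (below).  White
  Gaussian measurement noise, σ = 1 mV.
* **Seizure scenario** (100 s): region 1's input and excitatory gains
  ramp linearly from the background values to the epileptogenic plateau
  (α_up 8.1, α_ep 4387, α_pi 1370.9, α_pe 5483.7) over 30–40 s, hold to
  60 s, and ramp back by 70 s; its inhibitory gain stays at −3712.5.
  Ring gains are fixed for the whole run at 1.6 into region 1 and 162.5
  elsewhere, so the discharge spreads around the ring.  The ramp timing
  is the package's choice (the transition times are not constrained
  beyond "mid-run").

What the generator does *not* emulate: real ECoG artifacts, electrode
drift, volume conduction beyond the ±1 montage, model mismatch (the
inversion model is the generator model), or parameter stochasticity.
Passing benchmarks therefore demonstrate internal consistency of the
inversion under known model structure, not clinical readiness.

## Inversion: constrained Kalman filter

The filter estimates the augmented state (PSPs, derivatives, gains)
jointly from the ECoG alone.  The input realization is unknown to it; it
predicts with the constant mean drive and absorbs the input variance in
the process covariance.  Two variants share everything except the prior
mean:

* **analytic** — the expectation of the sigmoid of a Gaussian membrane
  potential has the closed form E[g(V)] = ½(erf((μ−v0)/√(2(ς²+σ²)))+1)
  for V ~ N(μ, σ²) with σ² = γPγᵀ, so the prior mean propagates through
  the nonlinearity exactly, up to the factorization
  E[(Bξ)∘g(Cξ)] ≈ (Bξ̂)∘E[g(Cξ̂)] which neglects the gain–potential
  cross-covariance and tightens as estimates converge.
* **ukf** — the standard unscented prior mean (weighted sigma-point
  mean).  In the tests and benchmarks the analytic variant is at least
  as accurate, most visibly for the input, p→i and i→p gains.

The prior covariance is the weighted scatter of Euler-propagated sigma
points about the prior mean, plus Q.  The update is the standard linear
Kalman step in Joseph-stabilized form, followed by symmetrization.

Numerical and design choices that were genuinely open:

* **Sigma-point set.** Scaled symmetric 2n+1 set.  The scaling is
  parametrized by the per-axis *spread* (distance of the off-center
  points in posterior standard deviations), default 2.32, independent of
  the state dimension — so the sigmoid is sampled equally locally at
  n = 15 and n = 84.  The classic κ = 3−n and small-α scalings give
  large negative center weights that turn the recentred scatter
  indefinite here and are not usable.
* **Bound constraints (clipping).** Gains live in physiological boxes
  (α_up ∈ [0, 300]; α_ep, α_pi, α_pe ∈ [0, 2·10⁴]; α_ip ∈ [−4·10⁴, 0];
  ring gains ∈ [0, 5000]).  Every prior and posterior gain mean is
  clamped elementwise; covariances are untouched.  Sigma-point gain
  coordinates are limited by *pairwise-symmetric truncation*: each ±
  pair is pulled toward the mean by a common factor so both points stay
  feasible.  Naive per-coordinate clamping makes the point set
  asymmetric whenever a gain mean sits near a bound relative to its
  spread (α_up = 3.2 in [0, 300] is the extreme case) and the asymmetry
  poisons the gain–state cross-covariances; with symmetric truncation a
  filter started at the true gains stays there instead of walking away.
* **Initialization.** Gains start at a weak-coupling guess: 10% of the
  physiologically active bound per intra-region pathway, 2% for
  inter-region pathways (long-range coupling is weaker than local), with
  the correct sign; states start at zero; the initial gain standard
  deviation is 5% of the bound width (2% for the ring network).
  Starting weak keeps every population on the responsive part of the
  sigmoid.  The obvious alternative — bound midpoints with the matching
  fixed point — saturates the excitatory chain (g′ ≈ 0 everywhere), the
  innovation information about the gains vanishes, and the filter
  freezes at the guess; it is not usable.
* **Parameter-drift inflation.** A strictly static parameter model
  (zero process noise on the gains) converges only from near-truth
  starts.  The filter therefore adds per-step variance
  (r_t·|α̂|)² to each gain, with r_t = 3·10⁻³ annealed exponentially
  (e-folding 25 s) to a floor of 10⁻⁴ — annealed parameter noise in the
  dual-estimation tradition, scaled by the parameter magnitude so the
  added uncertainty stays small relative to each gain.  Tracking mode
  (used for the seizure demonstration) raises the floor to 10⁻³ so the
  estimates can follow ramps.
* **Assumed noise.** R = (1 mV)²·I (the true measurement noise).
  Q is diagonal: (7 mV/s)² on input-synapse derivatives for the single
  region (10 for the ring network), (0.02 mV/s)² on other derivatives,
  (10⁻³ mV)² on PSP rows, zero on gains.
* **Degenerate covariances.** Cholesky with escalating diagonal jitter,
  10⁻¹² to 10⁻⁶ of the mean diagonal, before declaring the covariance
  indefinite.

The inner loop has two interchangeable implementations: a plain-numpy
reference and a numba-compiled path (default when numba is importable).
They agree to floating-point round-off per step; over long horizons the
chaotic limit-cycle dynamics amplify round-off, so trajectories are
compared on short horizons in the tests.

## Benchmarks and their scale

The benchmark harness replicates the validation protocol at desk scale:
10 independent 60 s single-region recordings (seeds base…base+9) for the
single-region comparisons and 5 independent 100 s four-region recordings
for the ring network — reduced from 50 realizations to keep a full run
in minutes on one core; the asserted quantities are means and worst
cases that are stable at this replication.  Accuracy is scored as
terminal percent bias per gain, 100·|α̂−α|/|α| at the final sample, and
as the RMS PSP tracking error over the final second.  Ring pathways are
split into a forward class (j → j+1 around the ring) and a backward
class for reporting; this directional convention is the package's own.

## Known limitations

* Residual single-region error concentrates on a DC-exchange manifold
  between the input pathway and the e→p pathway: both contribute
  low-frequency drive to the measured pyramidal potential, and only the
  sigmoid curvature separates them.  Terminal α_up biases of 5–20% per
  trial remain, and since v̄_up = α_up·τ·u_m ≈ 7 mV, they map directly
  onto v_up/v_ep tracking offsets of up to ~1 mV.
* The four-region differential montage is common-mode blind (rank 3).
  With the true gains pinned, the state decomposition within each region
  still drifts by 1–3 mV DC (measurement noise rectified through the
  sigmoid along weakly observed directions); with free gains,
  region-common gain errors of tens of percent persist, far above the
  single-region level.  An absolute-referenced channel halves these
  errors in a diagnostic run, which locates the problem in observability
  rather than in the filter machinery.
* The filter is a filter, not a smoother: early-time state estimates are
  not revisited.
* Euler at 1 ms is the model definition here, not an approximation to be
  refined; halving the step changes the limit cycle slightly.
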