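# Methods

## The kinetic scheme

`calyxstp` models a presynaptic terminal as a fixed population of `N_total`
identical release sites at which synaptic vesicles (SVs) dock and mature
through two sequential, reversible priming steps before fusing:

```
          k1(Ca)            k2(Ca)
    ES  <------->  LS  <--------->  TS ──(AP, p_fusion)──> ERS
          b1                b2
    ERS ──b4──> ES          LS ──(AP, κ)──> TSL ──b3──> LS
```

* **ES** — empty sites available for docking; **LS** — loosely docked SVs;
  **TS** — tightly docked, fusion-competent SVs; **TSL** — a labile tight
  state populated from LS immediately after each action potential (AP) with
  fraction `kappa_TSL`, decaying back to LS with rate `b3 = 1/tau_TSL`;
  **ERS** — refractory sites left behind by fusion, recovering to ES with
  rate `b4`.  Site conservation `ES+LS+TS+TSL+ERS = N_total` holds exactly.
* The forward priming rates rise linearly with the "effective" intracellular
  calcium, `k_i(Ca) = k_i,rest + sigma_i (Ca − Ca_rest)`, clamped at zero
  (rates are physical; below-rest calcium cannot make them negative).
* Replenishment draws on an unlimited reserve pool; only the sites are
  conserved.

Quantal content per stimulus is `m_j = p_fusion,j (TS + TSL)` with the
subpools evaluated immediately before the stimulus.  `m_j` are expected
values (real numbers); stochastic sampling lives only in the synthetic-data
generator.

### The effective calcium transient

Calcium is not modelled spatially.  Each AP adds a phenomenological transient
on top of `Ca_rest`: a large, fast local component (default 30 µM, τ 0.25 ms)
plus a smaller global component (454 nM) decaying bi-exponentially (60 ms /
230 ms, 85%/15%).  The local component carries ≈16% of the time integral.
Per-AP transients superpose linearly by default (`summation="additive"`;
linear buffering regime).  A `"reset"` mode that keeps only the most recent
AP's transient — the literal single-stimulus reading of the decay law — is
provided for comparison; nothing downstream depends on it.

### Influx facilitation/depression and the per-stimulus fusion probability

AP-evoked calcium influx facilitates and depresses during trains.  Two
scalars carry this: y is kicked toward a ceiling (`y += y_inc (y_max − y)`)
and z toward a floor (`z −= z_dec (z − z_min)`) at each AP, and both relax
exponentially back to 1 between APs (τ_y, τ_z).  The transient amplitude of
AP *j* is scaled by the post-kick product `y_j z_j`.  The exact update law is
this package's construction, parameterised entirely by the six published
constants; the qualitative form (increment-toward-ceiling,
decrement-toward-floor, relaxation to 1) is the standard scalar
facilitation/depression dynamic.

The fusion probability tracks the same influx scales:
`p_fusion,j = p_fusion · (y_j z_j)^n`, evaluated with the **pre-kick**
(relaxed) values so that the first AP of a resting train fuses with exactly
the resting `p_fusion`.  The exponent `n = 4` expresses the steep, roughly
fourth-power dependence of AP-triggered release on presynaptic calcium
influx at this synapse.  This coupling is load-bearing: with a strictly
constant `p_fusion` the scheme cannot facilitate at 200 Hz — tight-state
depletion (a fraction `p_fusion` per AP) always outweighs the labile-state
gain at the published `kappa_TSL = 0.1` — whereas with `n = 4` the control
parameter set yields a 200 Hz paired-pulse ratio of ≈1.04, preconditioning
suppresses the initial response while boosting apparent facilitation, and
the 10 Hz steady-state depression (≈0.37) lands on the observed ≈0.39.
Setting `p_fusion_cooperativity=0` recovers the constant-probability
variant.

### Numerical integration

Between stimuli the five-state ODE is integrated with an adaptive 8th-order
explicit scheme (DOP853, rtol 1e-8; tolerances configurable).  The calcium
transient is carried analytically as per-component exponential amplitudes,
so the right-hand side is exact in the transient and integration restarts
cleanly at each AP discontinuity.  Event order at an AP: (1) fusion from the
pre-AP state, (2) LS→TSL transfer of `κ·LS`, (3) influx kick, whose scale
applies to the current AP's transient.  States are clipped to zero within a
1e-6·N_total tolerance; larger negativity raises an error with the time
stamp.  Halving the tolerance changes quantal contents by <1e-4 relative.
Trajectories, when requested, are sampled at ≥1 kHz.

Equilibrium occupancies are closed-form (detailed balance along the chain:
`LS/ES = k1/b1`, `TS/LS = k2/b2`, TSL = ERS = 0), with vanishing backward
rates handled as limits.  The half-maximal tight-state calcium is found by
`brentq` on the closed form over [ca_ref, 10 µM] to 0.01 nM.

## Constrained NTF decomposition

Trial-averaged quantal-content trains from a cohort form a tensor
`X[stimulus, synapse, layer]` modelled as
`X ≈ Σ_c A[synapse, c] · B[c, layer, stimulus]`: per-synapse component
amplitudes shared across layers, per-layer base functions (BFs) shared
across synapses and normalized to unit cumulative sum.  Updates are
multiplicative least squares (Lee–Seung) adapted to this shared-BF
structure; amplitudes are initialized by per-synapse non-negative least
squares.

**Identifiability required one design decision beyond the obvious
constraints.**  With a free-form BF_TS the problem has a flat direction:
shrink every M_TS, raise BF_TS's first entry to keep the first response fit,
and let the delayed component absorb the rest — iterates drift along this
valley without changing the residual, so the recovered M_TS scale would
depend on the iteration budget.  Stage 1 therefore constrains BF_TS to the
one-parameter family `p (1−p)^(j−1)` (normalized): the exact release
schedule of a pre-existing, non-replenished pool fusing with probability `p`
per stimulus.  The projection is applied every iteration with
amplitude-mass compensation, ties BF_TS's first entry across all layers
exactly (the tied value is the cohort estimate of the initial fusion
probability), and couples the scale of M_TS to the shape of BF_TS, which
removes the flat direction.  On synthetic cohorts the recovered
m1-vs-M_TS slope then sits within a few percent of the generator's
p_fusion, stable from 200 to 1000 iterations.

BF_LS and BF_RS are free-form but their first entries are initialized at
(and capped to) very small values: release on the first stimulus is
attributed to pre-existing tightly docked vesicles.

Stage 2 (three components) freezes BF_TS, seeds both delayed BFs from the
stage-1 combined LS∪RS base function, and resolves the inherently
non-unique LS/RS split by pulling the cohort-mean M_LS a fixed fraction
(default 0.3, the middle of the 0.25–0.35 range) toward an external target
`FRP − mean M_TS` each cycle.  The shift rescales every synapse's M_LS
proportionally and compensates M_RS per synapse (clipped at zero); because
all BFs have unit cumulative sum this preserves each synapse's total
reconstructed quanta exactly.  The shift is applied *between* the amplitude
and base-function updates — applied after both, the next amplitude update
pulls the mean back and the iteration settles off target; with the adopted
ordering the mean converges onto the target.  The goodness-of-fit history
(SSE relative to the total sum of squares) is recorded per iteration; the
constraint projections can produce small upticks, so descent is monotone
only up to these projections.

## Pool and probability estimators

* Quantal contents from eEPSC peaks: `m = peak / q*` with `q* = −6.6 pA`
  (effective quantal size in 1 mM kynurenate; inward currents negative).
* **FRP′** (apparent fast-releasing pool) per high-frequency train (50, 100,
  200 Hz): straight line through the last 10 of 40 cumulative-release points
  versus stimulus index, intercept at index 0.  The window is exposed as a
  parameter; the last quarter of the train is the standard
  steady-state segment.  Trains that do not depress are rejected.
* **FRP**: regress `1/FRP′` on the inter-stimulus interval and invert the
  intercept at ISI = 0.  At cohort level a single line is fitted through the
  pooled per-synapse scatter (the way such plots are drawn), which is also
  markedly less biased than averaging per-synapse extrapolations: on the
  default synthetic cohort the pooled estimate lands within ~3% of the true
  resting LS+TS, per-synapse averaging ~14% above it (the 50 Hz trains of
  weakly depressing synapses deplete too little to extrapolate reliably).
* **p_fusion**: slope of the regression through the origin of per-synapse
  mean m1 on M_TS, `Σ m1·M_TS / Σ M_TS²`.
* **f_TS** = mean M_TS / (mean M_TS + mean M_LS); with M_LS pinned to
  `FRP − M_TS` this equals M_TS/FRP.
* Compound probabilities: `F = f_TS · p_fusion`,
  `p_r = F · occupancy` with the resting site occupancy defaulting to the
  model's closed-form `1 − ES/N_total ≈ 0.75`.
* STP metrics: PPR = m2/m1 (5 ms ISI ↔ 200 Hz, 10 ms ↔ 100 Hz), 10 Hz
  depression m5/m1, facilitation m_max/m1 (max over m2…m40), steady-state
  depression m_ss/m1 with m_ss = mean(m36…m40) for measured/synthetic trains
  and m40 for deterministic simulations.
* ΔC_m → SV count: 80 aF per vesicle.

## Synthetic cohort

The generator emulates the full experimental design: 40-stimulus trains at
5–200 Hz plus 100/200 Hz trains preconditioned with 2 or 4 stimuli at 10 Hz
(the 10 Hz rhythm continues into the main train, gap 100 ms — the gap is not
printed anywhere and is this package's choice), three repetitions per
protocol, trial-averaged.

Heterogeneity enters through `N_total` (log-normal, CV 0.35) and `k2_rest`
(log-normal, CV 0.4); `p_fusion` is uniform across synapses.  This mirrors
the headline finding that cohort heterogeneity is a priming-equilibrium
phenomenon, and makes the decomposition test honest: the generator's f_TS
spread (≈0.28–0.59) and the ≈5–6-fold span of initial quantal contents
(mean ≈175 SVs) match the recorded cohort's anchors (range ~10-fold, mean
≈184 SVs).  The log-normal choice itself is a stand-in — the across-synapse
distribution is not known beyond its range.

Noise is multiplicative log-normal per response (unit mean, CV 0.1 —
amplitude measurement error), optionally preceded by binomial resampling of
the fusion count.  All randomness flows through one `numpy` `default_rng`
seed recorded in the output.

What passing tests on this cohort do **not** show: real recordings add
correlated run-down/run-up, stimulation artefacts, postsynaptic receptor
nonlinearities and missing trials, none of which are emulated; parameter
recovery here demonstrates correctness of the estimators under the model's
own assumptions, not robustness to those effects.

## Problem sizes and runtimes

The default test suite and the acceptance script simulate one 50-synapse
cohort (500 train simulations, ≈40 s), a handful of single-condition trains
and recovery protocols (seconds), and run both NTF stages (200 + 100
iterations, <5 s).  These sizes reproduce the study's cohort scale exactly;
nothing is scaled down.

## Known limitations

* The per-AP influx update law and the `p_fusion` cooperativity exponent are
  reconstructions constrained by the published parameter names, bounds and
  qualitative behaviour, not printed equations.
* The geometric BF_TS constraint slightly misfits high-frequency layers
  where the fusion probability facilitates within the train; the recovered
  initial-BF_TS entry (≈0.17 on synthetic cohorts) is therefore a
  conservative estimate of p_fusion, and the regression slope — not the BF
  entry — is the estimator of record.
* Preconditioned layers share the same per-synapse amplitudes as regular
  layers although part of the tight pool is consumed before the main train;
  this is a property of the shared-amplitude tensor model itself.
* The FRP back-extrapolation inherits the classical biases of cumulative
  train methods (facilitation inflates, incomplete depletion deflates); the
  ISI-extrapolation compensates the latter only to first order.
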