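# Methods

## Scope and shape

`probfab` is a statistical emulation, not a circuit simulator: every block
of the physical fabric (noise source, amplifier chain, comparator, encoder,
chaos map) is replaced by its probability model, with a seeded pseudo-random
generator standing in for physical noise. Transistor-level behaviour,
amplifier bandwidth, switching rates and wall-clock timing are out of scope;
"cost" always means abstract computational steps.

## Noise model (`circuit_rng`)

The comparator input is modelled as an untruncated Gaussian with mean at the
post-amplifier operating point and standard deviation
`σ = gain_total · sqrt(kT/C)`. The supply rails are kept only as metadata:
for any realistic gain the Gaussian mass beyond the rails is far below
machine precision, so truncating would change nothing while forcing an
arbitrary renormalisation convention. Digital read-out is `1` iff the
sample strictly exceeds the threshold; equality (measure zero) emits `0`
so the rule is deterministic.

Defaults, chosen once as a representative operating point:

| parameter     | default | unit | why |
|---------------|---------|------|-----|
| temperature   | 300     | K    | room temperature |
| capacitance   | 500e-15 | F    | typical on-fabric capacitor; gives ≈ 91 μV RMS |
| gain_total    | 2500    | —    | two-OTA chain; amplifies 91 μV to ≈ 0.23 V so a 0.1–1.4 V select sweep spans p ≈ 1 → 0.19 |
| mean_level    | 1.2     | V    | mid-rail operating point |
| rails         | 0 / 2.4 | V    | symmetric around the operating point |

The amplifier gains and operating point are free configuration parameters
of the device; only their product and the mean enter the statistics.

`supply_to_noise_sigmas` uses the *unamplified* RMS: it quantifies why
amplification is needed (a 100 mV supply is ~1000σ above the raw noise).

## Chaos source (`chaos_rng`)

The published chaos circuit realises a tunable unimodal map; its exact
algebraic form is not reproduced in the available description, so the map
family is pluggable (`register_map`). The default is the logistic map
`x ← c·x(1−x)`: at `c = 4` it is chaotic on [0, 1] with the closed-form
arcsine invariant density, which lets the long-run statistics be tested
exactly (KS distance of a 10⁵-step orbit to Beta(½, ½) below 0.01; bit
balance at the median threshold ½). Bit extraction thresholds the held
value; multi-bit extraction per sample is deliberately not modelled.
Float64 iteration of the fully chaotic map follows a pseudo-orbit, not the
true orbit; shadowing makes its distributional statistics reliable at the
lengths used here (≤ 10⁵ iterates from interior starting points).

## Variate generation (`variate_gen`)

The encoder path actually simulates every bit: banks of `width` Bernoulli
bits are drawn and priority-encoded; in `chain` mode extra banks are
clocked for overflowed draws, so the accumulated index is *exactly*
geometric by memorylessness. `saturate` mode reproduces a fixed-width
read-out and reports its total-variation bias bound `(1−p)^width`.
Encoder width defaults to 32, the size of one physical trial array.

For exponential use the per-trial success probability is
`p = 1 − exp(−a·Δt)`, which makes the quantized CDF coincide with the
exponential CDF at every grid point `k·Δt`; the analytic KS distance to
`Exponential(a)` is then the first-cell mass `p` itself (`ks_bound`), and
the mean is exactly `Δt/p = (1/a)(1 + aΔt/2 + …)` — a known `+aΔt/2`
relative bias of the quantized read-out. The default `quantized` mode
returns `K·Δt` as the hardware would. `dequantized` mode subtracts a
uniform sub-quantum offset, `(K−U)·Δt`, which interpolates the staircase
CDF onto the continuous exponential (residual sup-distance `O((aΔt)²)`)
and removes the half-quantum mean bias; it is an idealisation of the
read-out, labelled as such, and is the right mode when comparing means
against the continuous-time law.

The simulator-facing hardware backend picks one quantum per draw set,
`Δt = q / max(a_i)` with `q = 0.01` by default, emulating a single shared
clock; `q` bounds the relative quantization error uniformly across
reactions. Overflow (chained) events are counted and logged.

The software baseline is the Lehmer/Park–Miller minimal-standard
generator, multiplier 16807, modulus 2³¹−1 (the canonical constants),
composed with `E = −ln(U)/a`. User seeds are spread over the full state
space through `numpy.random.SeedSequence` before forming the LCG state:
consecutive small raw seeds would otherwise start the recurrence at tiny
states whose first uniform is ~10⁻⁵, visibly inflating the first waiting
time of every run. The recurrence itself is untouched.

The chaos backend builds 32-bit binary-fraction uniforms from thresholded
orbit bits and inverse-transforms them. Successive logistic bits are
weakly dependent, so this source is documented as probabilistic rather
than ideal — it emulates the temperature-invariant alternative, and its
sample means are correct to within the tested 5%.

## Simulator (`gillespie`)

First-reaction stepping with the minimum-τ rule; ties (measure zero)
break to the lowest reaction index for determinism. The direct method
(one total exponential, proportional channel choice) is implemented only
as a cross-validation oracle and never shares code with the
first-reaction path. Mass-action propensities cover orders 0–2
(`c`, `c·X_A`, `c·X_A·X_B`, `c·X_A(X_A−1)/2`); higher orders are rejected
at construction — no general recipe for arbitrary dynamical systems is
attempted. Extinction (all propensities zero) halts the run cleanly; an
event that would land beyond `t_end` is discarded, so recorded times
never exceed the horizon. Trajectories are reproducible bit-for-bit from
`(network, config)`.

The deterministic limit integrates `ẋ = Σ ν_μ a_μ(x)` with fixed-step
classical RK4 (default substep 10⁻³, global error ≪ 10⁻⁶ for the decay
benchmark) using the same stochastic rate constants on continuous counts —
exact for linear networks, the standard mean-field reading for bimolecular
ones (no volume conversion is applied). Negative excursions abort with a
step-size error rather than being clipped.

## Cost model (`cost_model`)

Per-operation defaults (load 1, FP multiply 5, FP divide 32, ln 136,
uniform draw 88, compare 1, add 1, hardware Bernoulli-array clock 1,
priority-encode 1) give 261 steps per software exponential and 2 per
hardware one. The six-stage loop breakdown is kept in exact rationals so
per-unit divisions never round. The headline projection composes the two
figures as they are naturally quoted — the generator ratio at two
significant figures (130) times the waiting-time share truncated to whole
percent (0.98 for every r at δ = 2, where the share ranges over
0.983–0.987) — yielding 127; `exact_speedup` reports the unrounded
Amdahl ratio (e.g. 47.25X at r = 10, δ = 2) alongside, since the headline
composition is a quotation convention, not a bound.

## Randomness evaluation (`randomness_eval`)

Block entropies use the plug-in estimator on overlapping n-blocks with a
`5·2ⁿ` minimum-sample guard; an undersampled request raises rather than
returning a biased number. Classification (random / probabilistic /
deterministic) looks at H₁ against a 0.05-bit tolerance. The test battery
is a two-test subset of the standard suite — monobit frequency and runs,
with the standard statistic and erfc p-values — scored as suites are: the
proportion of m equal subsequences passing at the 1% level, pass mark
> 0.93. The full 16-test battery is out of scope.

## Synthetic study conditions

Fixture networks define the test conditions: decay (A→∅, c = 1, X₀ = 100),
birth–death (b = 10, c = 1; stationary law Poisson(10)), the classic
three-reaction predator–prey set, and seeded random mass-action networks
for invariant checks. Bernoulli estimation emulates the measured protocol:
2500 captures at each of 13 select voltages spanning 0.1–1.4 V, compared
against exact 95% binomial acceptance regions (the Wald interval's
coverage collapses at the near-degenerate upper thresholds, where
n·p·(1−p) ≲ 1). These generated inputs exercise the exact
distributional claims; they do not model device non-idealities (temperature
drift, amplifier saturation, comparator metastability, correlated sampling),
so passing tests validate the probability model, not a physical chip.

Problem sizes used by the test suite and acceptance script — 10⁵-draw
distributional checks, 1000-run trajectory ensembles, 120–150-run
system-size scans — were chosen so each statistical check has clear power
at its stated significance level.

## Numerical and statistical choices

- Stationarity of the birth–death process is checked on independent runs
  sampled at t = 8 (eight relaxation times), giving i.i.d. draws for a
  valid chi-square; time-weighted occupancy of one long run would violate
  the test's independence assumption.
- Mean-equivalence between software and hardware trajectory ensembles is
  tested with the dequantized hardware mode, because the quantized
  read-out's `+q/2` relative mean bias is real and detectable at 2×1000
  runs; the quantized mean `Δt/p` is asserted exactly in its own test.
- Distributional agreement of the quantized path with the continuous
  exponential is asserted analytically (`ks_bound < 0.01` at `a·Δt = 0.01`)
  plus empirically on the smoothed read-out; an empirical KS on the
  quantized draws at n = 10⁵ sits so close to its deterministic floor
  (0.00995) that sampling noise makes the comparison uninformative.
- Chi-square goodness-of-fit bins are pooled so every expected count is
  ≥ 5; geometric tails are pooled at the 99.99th percentile.

## Known limitations

- The chaos-backend uniforms inherit short-range correlations from the
  logistic orbit; do not use that backend where ideal randomness matters.
- The ODE limit uses stochastic constants directly on continuous counts;
  for bimolecular networks it is the mean-field approximation, not the
  exact first-moment equation.
- Saturate-mode encoder output is deliberately biased (bounded by
  `(1−p)^width`); chain mode is the default for exactness.
- The step-cost model counts abstract steps only; it makes no energy or
  wall-clock claims.
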