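# probfab

Software emulation of a probabilistic analog circuit fabric for stochastic
simulation: tunable thermal-noise Bernoulli bit generators, a chaotic-map
alternative source, priority-encoder exponential variate generation, a
first-reaction Gillespie simulator for mass-action reaction networks with
pluggable random-number backends, a computational step-cost model, and an
entropy/randomness validation suite.

## Who this is for

Researchers studying probabilistic/neuromorphic hardware for stochastic
computation, and anyone who wants a faithful, seeded software model of how
analog Bernoulli trial circuits turn into exponential waiting times and
drive the stochastic simulation of chemical and biological systems —
without access to the physical device.

## The model

**Bernoulli bits from thermal noise.** Johnson noise trapped on a capacitor
has RMS voltage `U_T = sqrt(kT/C)` (about 100 μV at 500 fF and room
temperature — roughly 1000σ below even a 100 mV supply, hence the amplifier
chain). The amplified noise, modelled as a Gaussian with standard deviation
`σ = A_total · U_T` around the operating point, is compared against a
"Probability Select" voltage `V`; the output is 1 with probability
`p = P(X > V)`, the Gaussian upper-tail mass. Sweeping `V` tunes `p`
continuously, and the mapping is inverted exactly by `calibrate_threshold`.

**Exponential variates from a priority encoder.** `N` parallel Bernoulli
units feed a priority encoder that reads out the index `K` of the first
success, which is geometric:

    Pr(K = k) = (1 − p)^(k−1) · p

With a time quantum `Δt` and `p = 1 − exp(−a·Δt)`, the read-out `K·Δt` is a
quantized `Exponential(a)` waiting time whose CDF agrees with the
exponential at every grid point. The software baseline is the classical
chain: a Park–Miller minimal-standard generator produces a uniform `U` and
`E = −ln(U)/a` maps it to an exponential.

**Stochastic simulation.** The first-reaction method: per event, each
reaction `i` draws `τ_i ~ Exponential(a_i)` from its backend, where `a_i`
is the mass-action propensity at the current counts; the smallest τ fires
and the state updates. The governing forms `P0(τ) = exp(−Σ a_i τ)` and
`P(τ, μ) = a_μ · P0(τ)` are exposed directly, along with the mean-field ODE
limit `ẋ = Σ_μ ν_μ a_μ(x)` to which trajectories converge at large copy
numbers.

**Why bother.** Counting computational steps, one software exponential
costs 261 steps (88 uniform + 136 ln + 5 multiply + 32 divide) against 2
for the encoder path, and waiting-time generation takes ≥ 98% of every
loop iteration at δ = 2 functional units — a projected ~127X trajectory
speed-up (130 × 0.98).

## Worked example

Step accounting for a 10-reaction network with 2 functional units:

```
$ probfab cost --reactions 10 --delta 2
iteration breakdown (r=10, delta=2, software)
  (1) initialize           1.0000
  (2) propensities        25.0000
  (3) waiting_times     2610.0000
  (4) find_minimum         4.5000
  (5) update               4.5000
  (6) loop                 1.0000
  total 2646.0000
  waiting-time share 98.6395%
  generator fold 130X, projected 127X, exact 47.25X
```

Generating the waiting times (step 3) takes 2610 of 2646 steps — 98.6% of
the iteration. Replacing it with the 2-step encoder path gives the 127X
projected fold (the exact ratio for this particular r, δ is 47X because
the other steps then dominate).

Simulate exponential decay (A → ∅, c = 1, 100 copies) on the emulated
hardware backend and inspect the trajectory:

```
$ probfab simulate --fixture decay --t-end 1.0 --seed 3 --backend hardware --out traj.tsv
wrote 71 records (70 events) to traj.tsv
$ head -3 traj.tsv
time	A	reaction
0	100	
0.0021	99	decay
```

70 events by t = 1 leaves 30 copies, consistent with the expected mean
100·e⁻¹ ≈ 36.8. Finally, draw 100 000 bits at p = 0.9 and score them:

```
$ probfab rng sample --dist bernoulli --p 0.9 --n 100000 --seed 7 --out bits.txt
$ probfab rng test --in bits.txt --tests monobit,entropy --blocks 50 --max-n 2
{
 "monobit": {"proportion_score": 0.0, "passed": false, ...},
 "entropy": {"h_n": [0.4658, 0.4659], "classification": "probabilistic"}
}
```

The biased source fails the fair-coin frequency test, as it must, and its
per-symbol entropy matches the binary entropy of 0.9
(−0.9·log₂0.9 − 0.1·log₂0.1 ≈ 0.469 bits): a *probabilistic* source —
genuinely stochastic, deliberately biased — rather than a *random* one.

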