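# Methods

## Scope and design

The package implements two agent-based dynamics of public opinion
expression on scale-free networks, together with the network generator,
the observables quantifying opinion misperception, and ensemble drivers.
Beliefs are frozen by construction: the object of study is the gap between
what agents privately think and what is publicly visible, not belief
change.

## Network generator

Degrees are drawn i.i.d. from the normalized truncated power law
`P(k) = k^(−λ) / Σ_{m=k_min}^{k_max} m^(−λ)` with `k_min = 2` and
`k_max = ⌊√N⌋` (the structural cutoff: above `∼√N` an uncorrelated simple
graph cannot realize a scale-free sequence without degree correlations).
Both bounds are configurable.  If the sampled sum is odd, one uniformly
chosen entry is redrawn until parity holds — a bias of order `1/N` on a
single entry.

Graphs are assembled by Molloy–Reed stub matching: stubs are shuffled and
paired; pairs forming self-loops or parallel edges are pooled and
re-paired among themselves; if the residue cannot resolve (e.g. two stubs
of one node) the matching restarts.  Rejection re-pairing (rather than
erasing illegal edges) preserves the degree sequence *exactly*, which
matters because hard-core placement keys on exact degree: every node of
degree `K_c` receives a hard-core agent (`b = −1`, `σ = 1`); all others
get `b = +1` and `σ ~ U(0,1]` (exact zeros rejected, so `σ > 0` always).
At large `K_c` a realization may contain no degree-`K_c` node; the
ensemble layer then regenerates the network under a fresh stream and
counts regenerations in the run manifest.

At `N = 5000`, `λ = 2.2` this gives mean degree ≈ 5.1, hard-core
prevalence 0.439 at `K_c = 2`, 0.180 at `K_c = 3`, 0.0031 at `K_c = 20`
(all equal to `P(K_c)` by construction).

## Conformity model (model 1)

Per elementary step, the selected agent expresses its belief with
probability `σ_i`; otherwise it adopts `sign(Σ_{j∈Γ_i} ω_j)`.  Two
zero-sum cases are deliberately distinct: if at least one neighbor has
*ever* expressed (tracked by an explicit flag, not by `ω ≠ 0`), a fair
coin picks ±1; if no neighbor has ever spoken, the agent emits the null
opinion `ω = 0`.  Silence here is only an initial-stage artifact and
disappears within a few time units.

## Goal-function model (model 2)

The selected non-hard-core agent expresses the `ω ∈ {−1, 0, +1}` nearest
to an anchor `v` (equivalently, `argmax G` with `G(ω) = −|v − ω|`); exact
half-integer ties are split by a fair coin.  Hard-core agents bypass the
maximization and always voice −1: they are *defined* as expressing their
belief regardless of the climate, and for low-degree hard cores raw
maximization could violate that definition.

The typeset form of the goal function is ambiguous about the denominator
`m + 1` (with `m = Σ_{j∈Γ_i} |ω_j|`, the number of non-silent neighbors).
Both readings are implemented behind the `parse` flag:

* `full` (default): `v = (σ_i b_i + Σ_j A_ij ω_j) / (m + 1)`
* `social`: `v = σ_i b_i + (Σ_j A_ij ω_j) / (m + 1)`

The choice is behaviorally decisive.  Under `social` the private drive
`σb` is never damped, so any agent with `σ > 1/2` keeps expressing and
expression cascades: the stationary silent fraction collapses to 1–6% and
no spiral of silence exists.  Under `full` the belief term is diluted as
neighbors speak up, conflicted neighborhoods push `|v|` below 1/2, and a
macroscopic silent phase (28–46% of agents across `K_c = 2…20`) emerges
with all the signatures of interest: the silent are almost exclusively
majority believers, minority voices never outnumber majority ones except
at `K_c = 2`, and the silenced-per-hard-core count scales superlinearly
(`ν ≈ 2.1`).  `full` is therefore the default; `social` remains available
for sensitivity analysis.

## Observables

`⟨ω⟩` averages over *all* agents (silent contribute 0).  The local
climate is `r = N^{-1} Σ_i Δ_i` with `Δ_i = Σ_{j∈Γ_i} ω_j / deg(i)` — the
per-node neighborhood mean, using the full degree in both models (in
model 2 the `m+1` normalization belongs to the decision rule, not to the
observable).  "Silenced" means `ω = 0` in the final snapshot, regardless
of history.  The scaling exponent of silenced-per-hard-core versus `K_c`
is an unweighted OLS slope in log–log; the fit report carries intercept
and residuals.

## Runs, stationarity and reproducibility

One time unit = `N` single-agent updates, uniform with replacement, each
seeing the effects of all previous ones.  Runs stop at a horizon of 200
time units or earlier once `|⟨ω⟩(t) − ⟨ω⟩(t − 20)| < 10⁻⁴`; both dynamics
plateau by `t ≈ 10–40`, so finals are insensitive to the exact rule.  All
randomness flows from one `numpy` Generator per realization, seeded as
`SeedSequence(master, spawn_key=(K_c, realization))`: ensembles are
reproducible piecewise, and identical configurations produce
byte-identical CSVs.  The compiled (numba) inner loops consume pre-drawn
random arrays from that same Generator, so results do not depend on
compilation details; a pure-Python step implementation is kept in the API
and tested for exact agreement with the kernels, and both are validated
against a brute-force enumeration oracle of one-step transition
distributions on ≤5-node fixtures.

## Ensemble scale

Headline experiments use `N = 5000`, `λ = 2.2`, `K_c ∈ {2, 3, 5, 10, 20}`,
with 100 realizations per `K_c` (fresh network + population + dynamics per
realization) and 200 networks for generator statistics; standard errors at
`R = 100` are ≈ 0.003 on `⟨ω⟩`-type quantities.  A `λ = 1.5` variant
checks robustness to stronger heterogeneity (orderings persist; exact
levels shift).

## What the defaults do and do not reproduce

Reproduced at desk scale (values from `scripts/acceptance.py --seed 1`):
hard-core prevalence 18.4% at `K_c = 3`; conformity-model belief mean
0.63 at `K_c = 3`; goal-function silencing with fewer than one silenced
agent per hard-core member at `K_c = 2` (0.84) versus ≈ 105 at
`K_c = 20`; scaling exponent `ν = 2.07`; minority–majority inversion only
at `K_c = 2`; `⟨ω⟩ < ⟨b⟩` everywhere in both models.

Not reproduced, under any reading we examined (several denominator,
influence-weight, initialization and decision-rule variants were explored
before freezing the defaults):

* **Conformity model, low `K_c`: `r < ⟨ω⟩` and `r ≈ 0.2`.**  With the
  minority on degree-3 nodes — *below* the mean degree ≈ 5 — neighborhood
  averages over-represent high-degree majority nodes (friendship
  paradox), so the climate is *more* majoritarian than the expressed
  mean: `r ≈ 0.75 > ⟨ω⟩ ≈ 0.58` at `K_c = 3`.  A self-consistency
  argument shows a 0.2 climate would require −1 concentrated on hubs,
  which sign-majority conformity toward a globally positive field cannot
  sustain.  The claimed ordering does emerge once the hard core sits
  above the mean degree (`K_c ≳ 10`), i.e. exactly where the majority
  illusion mechanism operates.
* **Goal-function model: a flat 55–60% silent fraction at every `K_c`.**
  Our stationary silent fraction is 28–46% and drifts with `K_c`.  At
  `K_c = 2` a 55% silent fraction would require silencing ≈ 98% of the
  majority (the hard core is 44% of agents and never silent); variants
  that achieve this at `K_c = 2` over-collapse to ≳ 90% silence at
  `K_c = 20`, where ≈ 40% of agents must keep expressing for the reported
  coexistence.  We found no fixed rule satisfying both regimes.
  Correspondingly our silenced-per-hard-core at `K_c = 20` is ≈ 105
  rather than ≈ 150.
* **Goal-function model: climate closer to beliefs than the expressed
  mean** (`|⟨b⟩ − r| ≤ |⟨b⟩ − ⟨ω⟩|`).  In our runs `r` sits below `⟨ω⟩`:
  vocal hard-core hubs are surrounded by silent low-degree shells, which
  drags neighborhood averages down.

The corresponding checks in `tests/test_acceptance.py` are asserted at
face value and fail loudly rather than being weakened; treat them as a
faithful record of the discrepancy.

## Limitations

The generator produces uncorrelated simple graphs with a hard cutoff; no
assortativity, clustering, community structure, directedness or weights —
features real social graphs have and which plausibly shift the silent
fraction.  Beliefs are binary and frozen; strengths are static; there is
no content, recommendation bias or agent turnover.  Passing tests
therefore certify the *mechanisms* (conformity, goal-driven silence,
friendship-paradox distortion) on idealized substrates, not quantitative
predictions for any real platform.
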