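# spiralsilence

Agent-based simulation of **opinion misperception** and the **spiral of
silence** in online communities.  The package asks a simple question with
uncomfortable answers: when a handful of loud, well-connected contrarians
("hard-core" agents) joins a community that overwhelmingly disagrees with
them, how wrong does the publicly visible opinion climate get — and why?

It is aimed at computational social scientists studying vocal minorities,
pluralistic ignorance and majority illusion on heterogeneous networks
(e.g. vaccine-hesitancy discourse on social media).

## The models

`N` agents sit on a scale-free network with degree distribution
`P(k) ∝ k^(−λ)` (default `λ = 2.2`, minimum degree 2, structural cutoff
`⌊√N⌋`), built by Molloy–Reed stub matching so degrees are realized
exactly.  Each agent `i` carries

* a fixed private belief `b_i = ±1`,
* a strength `σ_i ∈ (0, 1]`,
* an expressed opinion `ω_i ∈ {−1, 0, +1}` (0 = silent), initially 0.

The hard-core minority (`b = −1`, `σ = 1`) is placed on **every node of
degree `K_c`**, so its prevalence is `P(K_c)` and its connectivity is
controlled by a single parameter.  Dynamics are asynchronous: one time
unit = `N` random sequential single-agent updates.

**Conformity model** (`exogenous_model`).  With probability `σ_i` the
selected agent expresses its belief, `ω_i ← b_i`; otherwise it conforms to
the local expressed majority, `ω_i ← sign(Σ_{j∈Γ_i} ω_j)`, coin-flipping
exact ties (a null opinion is expressed only while no neighbor has ever
spoken).

**Goal-function model** (`endogenous_model`).  The selected agent
expresses the option `ω ∈ {−1, 0, +1}` maximizing

```
G(ω) = −| v − ω |,   v = (σ_i b_i + Σ_{j∈Γ_i} A_ij ω_j) / (m_i + 1)
```

with influence weights `A_ij = deg(j)/deg(i)` and `m_i` the number of
currently non-silent neighbors.  Silence is optimal whenever private and
social pulls nearly cancel (`|v| < 1/2`) — the seed of a silencing
cascade.  (An alternative normalization that divides only the social sum
is available via `parse="social"`; see `docs/methods.md`.)

Observables: the expressed mean `⟨ω⟩`, the belief mean `⟨b⟩` (constant),
and the *local opinion climate* `r = ⟨Δ_i⟩` with
`Δ_i = Σ_{j∈Γ_i} ω_j / deg(i)` — what agents actually see around
themselves.  Misperception decomposes as
`⟨b⟩ − r = (⟨b⟩ − ⟨ω⟩) − (r − ⟨ω⟩)`: a behavioral part (people not voicing
their belief) plus a topological part (neighborhoods misrepresenting the
population).

## Worked example

```
$ python examples/silencing_sweep.py
 kc  mean_b  mean_omega_f     r_f  frac_silent  silenced_per_hc  hc_fraction
  2  0.1006       -0.2723 -0.0669       0.3729           0.8294       0.4497
  3  0.6381        0.1491  0.0772       0.4067           2.2495       0.1809
  5  0.8826        0.3956  0.2123       0.3686           6.2989       0.0587
 10  0.9726        0.5656  0.3404       0.3083          22.7496       0.0137
 20  0.9946        0.6504  0.4025       0.2806         107.7598       0.0027

power-law fit: silenced per hard-core agent ~ K_c^2.07
```

Reading the table: at `K_c = 20` the hard core is 0.27% of the population,
yet the expressed mean (0.65) sits far below the belief mean (0.99) and
28% of agents — almost all privately pro-majority — are silent, about 108
per hard-core agent.  At `K_c = 2` the minority is huge (45%) but silences
less than one agent per member: the silencing reach grows superlinearly
(`∼ K_c^ν`, `ν ≈ 2.1`, tracking `λ`) because a roughly stable silent mass
is attributed to ever fewer hard-core agents.  Only at `K_c = 2` do
minority voices outnumber majority ones (−1 fraction 0.45 vs +1 fraction
0.18) — an inversion driven by silence, not conversion.

Other examples: `generate_network.py` (generator + hard-core placement),
`conformity_dynamics.py` (model 1 trajectory and misperception
decomposition), `silence_dynamics.py` (model 2 cascade at `K_c = 10`).

## Command line

```
spiralsilence simulate --model endo --kc 10 --seed 1 --out run/
spiralsilence sweep --model endo --kc-list 2,3,5,10,20 --realizations 100 --out sweep/
spiralsilence fit sweep/ensemble.csv
```

`sweep` writes `ensemble.csv` (per-`K_c` means ± standard errors) and a
JSON manifest (full config, seeds, regeneration counts, wall time).  A
YAML config file can replace any flag (`--config`); explicit flags win.

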