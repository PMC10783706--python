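"""Ensemble sweep over the hard-core degree K_c and the silencing scaling law.

Runs a reduced ensemble (R=10 per K_c; the headline experiments use 100+)
of the goal-function model, prints the per-K_c table, and fits the
power law silenced-per-HC ~ K_c^nu.  The exponent tracks the degree
exponent lambda: the silent fraction varies slowly with K_c while the
hard-core count falls as K_c^-lambda.
"""

from spiralsilence import ModelConfig, fit_silencing_scaling, sweep_kc

cfg = ModelConfig(model="endogenous", n=5000, lambda_exp=2.2,
                  kc_list=(2, 3, 5, 10, 20), realizations=10, seed=7)
table = sweep_kc(cfg)
cols = ["kc", "mean_b", "mean_omega_f", "r_f", "frac_silent", "silenced_per_hc", "hc_fraction"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))

nu, meta = fit_silencing_scaling(table)
print(f"\npower-law fit: silenced per hard-core agent ~ K_c^{nu:.2f}")
print("A handful of degree-20 hard-core agents silences ~100 agents each —")
print("two orders of magnitude beyond their direct neighborhoods — while at")
print("K_c=2 the large minority silences less than one agent per member.")
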