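#!/usr/bin/env python
"""Stochastic (SSA) vs deterministic model consistency.

Runs a 200-seed ensemble of hybrid runs (exact SSA below 50 000 cells,
deterministic continuation above) at an inflated escape rate and compares
the pooled producer fraction with the closed form.  Writes
results/stochastic_consistency.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from escapewatch.popmodel import ModelParams, producer_fraction
from escapewatch.stochastic import hybrid_run

OUT = Path("results")
OUT.mkdir(exist_ok=True)

params = ModelParams(0.3, 1e-3)
G, N_SEEDS = 20.0, 200

P, T = [], []
for seed in range(N_SEEDS):
    tr = hybrid_run(params, 1000, switch_threshold=50_000, g_max=G, seed=seed)
    P.append(tr.producers[-1])
    T.append(tr.producers[-1] + tr.nonproducers[-1])
P, T = np.array(P), np.array(T)
f_hat = P.sum() / T.sum()
det = producer_fraction(params, G)
se = ((P - f_hat * T) / T.mean()).std(ddof=1) / np.sqrt(N_SEEDS)

df = pd.DataFrame(
    [
        {
            "generations": G,
            "n_seeds": N_SEEDS,
            "pooled_producer_fraction": f_hat,
            "deterministic_fraction": det,
            "mc_se": se,
            "z": (f_hat - det) / se,
        }
    ]
)
df.to_csv(OUT / "stochastic_consistency.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print(
    f"\nPooled stochastic producer fraction {f_hat:.4f} vs deterministic "
    f"{det:.4f} at g={G:.0f}: |z| = {abs((f_hat-det)/se):.2f} Monte-Carlo s.e."
)
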