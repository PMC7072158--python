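"""Group statistics for a mutant-panel %PM experiment.

Simulates per-cell %PM values for a wild-type construct and two mutants
(one membrane-displaced, one indistinguishable from wild type), normalizes
to the wild-type mean, reports mean ± SEM per group, and runs a one-way
ANOVA with Welch comparisons against the wild-type reference at the
caption-style threshold p < 0.01.
"""

import numpy as np
import pandas as pd

import pmbind as pb

rng = np.random.default_rng(0)
raw = {
    "WT": rng.normal(62.0, 5.0, 12),
    "K84/85A": rng.normal(30.0, 5.0, 12),   # loop mutant, displaced
    "K55A-like": rng.normal(61.0, 5.0, 12), # localizes like wild type
}
wt = list(raw["WT"])
table = pd.DataFrame([
    {"group": g, "value": v}
    for g, vals in raw.items()
    for v in pb.normalize_to_reference(vals, wt)
])

print(pb.summarize(table).to_string(index=False, float_format="%.1f"))

res = pb.anova_oneway(table, alpha=0.01, reference="WT")
print(f"\none-way ANOVA: F = {res.F:.1f}, p = {res.p:.2e}")
for g, p in res.pairwise_p.items():
    star = "*" if res.significant[g] else "n.s."
    print(f"  {g:>10} vs WT: p = {p:.2e}  {star}")
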