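"""Type-I-error calibration of the covariate-adjusted burden test.

Simulates ancestry-confounded null cohorts (case status and carrier status
both depend on the subpopulation but are conditionally independent) and
measures the rejection rate of the Firth penalized-LRT burden test at
alpha = 0.05, adjusted for sex and five genotype PCs, next to the
unadjusted test, which should be visibly anti-conservative.

Writes results/null_calibration.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from recburden.firth import firth_fit, firth_inference
from recburden.simulate import simulate_null_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_REPLICATES = 200
ALPHA = 0.05

rng = np.random.default_rng(123)
rej_adj = rej_raw = done = 0
for _ in range(N_REPLICATES):
    samples, carrier = simulate_null_cohort(rng)
    if carrier.all() or not carrier.any():
        continue
    y = (samples["group"] == "case").to_numpy(float)
    base = [np.ones(len(samples)), carrier.astype(float)]
    covs = [(samples["sex"] == "male").to_numpy(float)] + [
        samples[f"PC{k}"].to_numpy() for k in range(1, 6)]
    for with_cov in (True, False):
        X = np.column_stack(base + (covs if with_cov else []))
        fit = firth_fit(X, y)
        p, *_ = firth_inference(fit, X, y, 1)
        if with_cov:
            rej_adj += p < ALPHA
        else:
            rej_raw += p < ALPHA
    done += 1

df = pd.DataFrame([
    {"test": "adjusted_sex_pc1_5", "replicates": done,
     "rejection_rate": rej_adj / done},
    {"test": "unadjusted", "replicates": done,
     "rejection_rate": rej_raw / done},
])
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "null_calibration.tsv", sep="\t", index=False)

print(f"{done} null cohorts at alpha = {ALPHA}:")
print(f"  adjusted type-I error:   {rej_adj / done:.3f} (target band 0.02-0.10)")
print(f"  unadjusted type-I error: {rej_raw / done:.3f} (confounded, inflated)")
print(f"wrote {RESULTS / 'null_calibration.tsv'}")
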