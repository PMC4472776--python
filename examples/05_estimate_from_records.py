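"""Round trip: patient-day records -> estimated daily transition matrices.

Generates synthetic longitudinal records from the calibrated matrices,
then re-estimates the matrices with the count-ratio estimator and
reports how close the estimate is to the generating truth.
"""

import numpy as np
import pandas as pd

from crbsim import estimate_matrices, generate_records, preprocess_records
from crbsim.datasets import load_reference_matrices

n = 20_000
frames = []
for arm, seed in (("CHG", 1), ("nonCHG", 2)):
    df = generate_records(load_reference_matrices(arm), n=n, seed=seed)
    df["patient_id"] += 0 if arm == "CHG" else n
    frames.append(df)
records = preprocess_records(pd.concat(frames, ignore_index=True))
print(f"{len(records):,} patient-day records for {2 * n:,} patients")

for arm in ("CHG", "nonCHG"):
    truth = load_reference_matrices(arm)
    est = estimate_matrices(records, arm)
    err = np.abs(est.P[:29, :2, :] - truth.P[:29, :2, :]).max()
    print(f"{arm:7s}: max |p_ij(t) error| over days 1-29, states 1-2 = {err:.4f}")

print("\nWell-occupied rows (states 1-2) are recovered to binomial noise,")
print("about 1/sqrt(row count).  The rare CRBSI rows see a handful of")
print("patients per day, so their estimates are individually noisy and")
print("lean on the nearest-earlier-day fallback - exactly the situation")
print("the validation report and fallback logging flag on real data.")
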