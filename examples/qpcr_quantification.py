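"""Quantify a small RT-qPCR validation experiment from a tidy Cq table.

Builds a synthetic Cq table for two reference assays and one target over
four samples (plus 10-fold dilution series per assay), then runs the full
workflow: standard-curve fit with efficiency QC, geNorm reference
stability (M), per-sample normalisation factor, and fold changes relative
to the lowest normalised sample, log2-transformed.
"""

import itertools

import numpy as np
import pandas as pd

from isomirkit.qpcr import analyze_cq_table

rng = np.random.default_rng(4)
samples = [f"pig{i}" for i in range(1, 5)]
quantities = {
    "let7a": dict(zip(samples, [1.0, 1.8, 0.6, 1.1])),
    "mir25": dict(zip(samples, [2.1, 3.6, 1.3, 2.2])),  # ~proportional to let7a
    "mir126": dict(zip(samples, [0.4, 0.9, 1.9, 3.8])),  # the target
}
rows = []
for assay, per_sample in quantities.items():
    slope = -1.0 / np.log10(2.0)  # 100% efficiency
    for d in 10.0 ** -np.arange(4):
        rows.append({"sample": "pool", "assay": assay, "replicate": 1,
                     "Cq": 28.0 + slope * np.log10(d), "dilution": d})
    for s, rep in itertools.product(samples, (1, 2)):
        cq = 28.0 + slope * np.log10(per_sample[s]) + rng.normal(0, 0.05)
        rows.append({"sample": s, "assay": assay, "replicate": rep,
                     "Cq": cq, "dilution": None})

curves, genorm, expression = analyze_cq_table(
    pd.DataFrame(rows), references=["let7a", "mir25"]
)
print("standard curves:")
print(curves.to_string(index=False))
print("\ngeNorm stability M (retain M < 1.5):")
print(genorm.m_values.round(4).to_string())
print("\nnormalisation factor per sample:")
print(genorm.nf.round(4).to_string())
print("\ntarget expression relative to the lowest normalised sample:")
print(expression.groupby("sample")[["fc", "log2_fc"]].mean().round(3))
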