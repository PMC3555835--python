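"""Hypergeometric over/under-representation of functional categories.

Builds a toy category map (GMT-style) over a 500-gene universe, samples a
target set in which one pathway is strongly over-drawn, and tests every
category in both tails with Benjamini-Hochberg correction per tail.
"""

import numpy as np

from isomirkit.enrichment import enrich

rng = np.random.default_rng(0)
universe = [f"gene{i}" for i in range(500)]
categories = {"renal_cell_carcinoma": ("planted signal", frozenset(universe[:40]))}
for i in range(8):
    members = rng.choice(universe, size=40, replace=False)
    categories[f"pathway_{i}"] = ("background", frozenset(members))

# 25 of 40 planted genes among 60 targets: strong over-representation
targets = universe[:25] + list(rng.choice(universe[40:], size=35, replace=False))
table = enrich(targets, categories, universe=universe)
cols = ["category", "K", "n", "k", "p_over", "q_over", "significant"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nlowest q ranks first; 'significant' flags q < 0.05 in either tail")
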