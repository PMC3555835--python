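"""Discover planted novel miRNA hairpins among unannotated tags.

Runs a zero-noise simulation, takes the tags that failed annotation,
keeps those mapping uniquely outside annotated features (19-23 nt,
CN > 2), clusters them by genomic overlap, extracts each cluster's
reference locus +- 50 nt and folds it.  Planted hairpins pass the
stem-loop screen (>= 16 pairs from the mature to the opposite arm);
decoy loci planted without hairpin context fail it.
"""

from isomirkit.pipeline import run_simulation
from isomirkit.simulate import SimulationConfig

config = SimulationConfig(
    seed=11, n_mirnas=12, n_novel=3, n_decoys=2, genome_length=11000,
    library_depths={k: 1500 for k in ("IB", "WB", "LD", "LW", "PT", "ME", "VT")},
).zero_noise()
bundle, reference, truth = run_simulation(config)

print(bundle.candidates.to_string(index=False))
passed = [c for c in bundle.novel_clusters if c.validated]
print(f"\n{len(passed)} of {len(bundle.novel_clusters)} candidate clusters "
      f"fold into a mature-bearing hairpin arm")
cl = passed[0]
s, e = cl.mature_span
print(f"\n{cl.cluster_id} precursor (mature span marked):")
print(cl.precursor)
print(cl.fold.structure)
print(" " * s + "^" * (e - s))
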