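"""Group fold changes from the bundled seven-library kidney count tables.

Normalises each miRNA's per-library counts to counts per thousand, averages
within breed groups (EU: Iberian + Wild Boar; EA: Landrace + Large White +
Pietrain; AS: Meishan + Vietnamese) and prints the signed fold change for
each pairwise contrast.  A positive value means the first group is higher;
|FC| > 1.5 (or absence from exactly one group) flags differential expression.
"""

from isomirkit import datasets
from isomirkit.expression import abundance_share, compare_groups

counts = datasets.abundant_counts()[list(datasets.LIBRARY_TOTALS)]
comparisons = compare_groups(
    counts, datasets.library_totals(), datasets.group_map()
)

show = ["Hsa-miR-200b-3p", "Ssc-miR-126", "Ssc-miR-99a", "Hsa-miR-200c-3p",
        "Bta-miR-193b"]
print(comparisons.loc[show, ["EU_vs_EA", "EU_vs_AS", "EA_vs_AS", "EU_vs_AS_de"]])

total = datasets.grand_total()
print(f"\ngrand total reads: {total}")
for mirna in ("Hsa-miR-200b-3p", "Ssc-miR-125b"):
    cn = int(counts.loc[mirna].sum())
    print(f"{mirna}: CN {cn} = {abundance_share(cn, total)}% of all reads")
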