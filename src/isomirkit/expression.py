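"""Counts-per-thousand normalisation and breed-group differential expression.

Raw cluster counts are normalised per library to counts per thousand
(cpt = raw / library_total x 1000, the library total being all
length-filtered reads), averaged within breed groups with equal library
weights, and compared between groups by a signed fold change: +a/b when
group a is higher, -b/a otherwise, so |FC| >= 1 and FC(a,b) = -FC(b,a).
A miRNA is called differentially expressed when |FC| exceeds 1.5
(strictly) or when it is expressed in exactly one of the two groups (zero
raw counts in every library of the other).  No p-value is attached: with
one pooled library per breed the ratio itself is the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass(frozen=True)
class GroupComparison:
    mirna_id: str
    group_a: str
    group_b: str
    fc: float | None  # signed fold change; None when an absence flag is set
    absent_in_a: bool
    absent_in_b: bool

    @property
    def de(self) -> bool:
        return call_de(self)


def normalize_cpt(raw: float, library_total: int) -> float:
    """Counts per thousand: raw / library_total x 1000."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return raw / library_total * 1000.0


def cpt_matrix(counts: pd.DataFrame, library_totals: dict[str, int]) -> pd.DataFrame:
    """Normalise a miRNA x library count matrix to counts per thousand."""
    libs = list(counts.columns)
    missing = [lib for lib in libs if lib not in library_totals]
    if missing:
        raise ValueError(f"no library total for {missing}")
    return counts.astype(float).div(
        pd.Series({lib: library_totals[lib] for lib in libs})
    ) * 1000.0


def group_means(cpt: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Unweighted arithmetic mean of member libraries' cpt, per group."""
    groups = sorted(set(group_map.values()))
    out = {}
    for g in groups:
        libs = [lib for lib in cpt.columns if group_map.get(lib) == g]
        if not libs:
            raise ValueError(f"group {g} has no libraries")
        out[g] = cpt[libs].mean(axis=1)
    return pd.DataFrame(out)


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed ratio of two positive group means (sign marks the higher group)."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("signed_fold_change requires positive means")
    return mean_a / mean_b if mean_a >= mean_b else -mean_b / mean_a


def compare(
    mirna_id: str,
    group_a: str,
    group_b: str,
    mean_a: float,
    mean_b: float,
    present_a: bool,
    present_b: bool,
) -> GroupComparison | None:
    """Build one group comparison; None when the miRNA is absent from both."""
    if not present_a and not present_b:
        return None
    if present_a != present_b:
        return GroupComparison(
            mirna_id, group_a, group_b, None,
            absent_in_a=not present_a, absent_in_b=not present_b,
        )
    return GroupComparison(
        mirna_id, group_a, group_b, signed_fold_change(mean_a, mean_b),
        absent_in_a=False, absent_in_b=False,
    )


def call_de(comparison: GroupComparison, fc_threshold: float = 1.5) -> bool:
    """DE iff |FC| strictly exceeds the threshold or exactly one group is absent."""
    if comparison.absent_in_a != comparison.absent_in_b:
        return True
    return comparison.fc is not None and abs(comparison.fc) > fc_threshold


def abundance_share(cluster_cn: int, grand_total: int) -> float:
    """Percentage share of total reads, to 2 decimal places."""
    if grand_total <= 0:
        raise ValueError("grand total must be positive")
    return round(100.0 * cluster_cn / grand_total, 2)


def compare_groups(
    counts: pd.DataFrame,
    library_totals: dict[str, int],
    group_map: dict[str, str],
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """All pairwise group comparisons for a miRNA x library count matrix.

    Group order follows sorted group names reversed to the conventional
    EU, EA, AS ordering when those labels are present.  "Absent" means
    zero raw counts in every library of the group.
    """
    cpt = cpt_matrix(counts, library_totals)
    means = group_means(cpt, group_map)
    groups = list(means.columns)
    if set(groups) == {"EU", "EA", "AS"}:
        groups = ["EU", "EA", "AS"]
    present = {}
    for g in groups:
        libs = [lib for lib in counts.columns if group_map.get(lib) == g]
        present[g] = counts[libs].sum(axis=1) > 0
    rows = []
    for mirna in counts.index:
        row: dict = {"mirna_id": mirna}
        for ga, gb in combinations(groups, 2):
            comp = compare(
                mirna, ga, gb,
                means.at[mirna, ga], means.at[mirna, gb],
                bool(present[ga][mirna]), bool(present[gb][mirna]),
            )
            col = f"{ga}_vs_{gb}"
            if comp is None:
                row[col] = None
                row[f"{col}_de"] = False
            else:
                row[col] = None if comp.fc is None else round(comp.fc, 2)
                row[f"{col}_de"] = call_de(comp, fc_threshold)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna_id")
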