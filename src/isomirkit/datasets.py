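"""Bundled example data: a seven-library porcine kidney small-RNA survey.

Pre-counted summaries from a pooled 454 run over kidney small-RNA
libraries of six porcine breeds plus the European Wild Boar: per-library
totals of length-filtered reads, the breed-group design (EU: European
origin, EA: European commercial, AS: Asian origin), and per-breed counts
for the most abundant miRNA clusters (CN > 350).  These tables let the
expression stage be exercised on real numbers without raw reads, which
were never deposited for this survey.
"""

from __future__ import annotations

import pandas as pd

#: Total length-filtered read counts per library.
LIBRARY_TOTALS: dict[str, int] = {
    "IB": 4022,
    "WB": 18391,
    "LD": 13704,
    "LW": 23815,
    "PT": 20215,
    "ME": 17407,
    "VT": 17751,
}

#: Breed-group membership of each library.
GROUP_MAP: dict[str, str] = {
    "IB": "EU",
    "WB": "EU",
    "LD": "EA",
    "LW": "EA",
    "PT": "EA",
    "ME": "AS",
    "VT": "AS",
}

_LIBS = ["IB", "WB", "LD", "LW", "PT", "ME", "VT"]

# miRNA: (total CN, isomiR count, per-library counts IB..VT)
_ABUNDANT = {
    "Hsa-miR-200b-3p": (27097, 123, [239, 4924, 4298, 5163, 3683, 6987, 1803]),
    "Ssc-miR-125b": (8809, 51, [567, 1245, 933, 2170, 2322, 798, 774]),
    "Ssc-miR-23b": (5412, 59, [116, 992, 638, 935, 1090, 673, 968]),
    "Ssc-miR-126": (5274, 49, [158, 928, 419, 1308, 1186, 660, 615]),
    "Ssc-miR-23a": (5156, 51, [123, 828, 535, 801, 1015, 598, 1256]),
    "Ssc-miR-192": (3863, 41, [89, 723, 194, 1105, 810, 484, 458]),
    "Ssc-miR-99a": (3781, 32, [339, 615, 375, 884, 888, 234, 446]),
    "Hsa-miR-200c-3p": (3478, 32, [42, 367, 309, 1076, 762, 631, 291]),
    "Ssc-miR-10b": (2846, 31, [69, 589, 271, 504, 519, 561, 333]),
    "Ssc-miR-126*": (2796, 26, [60, 440, 387, 503, 599, 418, 389]),
    "Ssc-miR-30d": (1977, 31, [82, 223, 142, 757, 434, 238, 101]),
    "Ssc-miR-125a": (1369, 29, [103, 192, 194, 308, 288, 173, 111]),
    "Ssc-miR-10a": (1317, 19, [43, 287, 176, 219, 188, 284, 120]),
    "Ssc-miR-365-3p": (986, 16, [10, 168, 173, 225, 246, 100, 64]),
    "Ssc-miR-92a": (797, 17, [12, 96, 105, 217, 125, 145, 97]),
    "Ssc-miR-204": (748, 14, [10, 61, 271, 173, 133, 58, 42]),
    "Ssc-miR-378": (743, 20, [67, 127, 52, 179, 148, 103, 67]),
    "Ssc-miR-26a": (598, 17, [3, 94, 76, 159, 134, 91, 41]),
    "Bta-miR-200a": (485, 9, [18, 87, 99, 95, 58, 101, 27]),
    "Bta-miR-193b": (473, 26, [69, 73, 83, 102, 78, 36, 32]),
    "Ssc-miR-30e-5p": (461, 14, [27, 57, 43, 134, 93, 56, 51]),
    "Ssc-miR-100": (405, 6, [20, 55, 72, 92, 83, 39, 44]),
    "Ssc-miR-99b": (350, 8, [15, 43, 47, 102, 73, 28, 42]),
}


def library_totals() -> dict[str, int]:
    """Per-library totals of length-filtered reads (copy)."""
    return dict(LIBRARY_TOTALS)


def group_map() -> dict[str, str]:
    """Library -> breed-group assignment (copy)."""
    return dict(GROUP_MAP)


def grand_total() -> int:
    """Total reads over all seven libraries."""
    return sum(LIBRARY_TOTALS.values())


def abundant_counts() -> pd.DataFrame:
    """Most-abundant miRNA clusters (CN > 350): per-library raw counts.

    Indexed by miRNA id; columns are the seven libraries plus ``CN``
    (summed copy number) and ``isomirs`` (distinct sequence variants in
    the cluster).
    """
    rows = {
        mirna: dict(zip(_LIBS, libs), CN=cn, isomirs=iso)
        for mirna, (cn, iso, libs) in _ABUNDANT.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[[*_LIBS, "CN", "isomirs"]]
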