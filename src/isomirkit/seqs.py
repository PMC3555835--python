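"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet, U should be mapped to T first)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_all(needle: str, haystack: str) -> list[int]:
    """All start positions of exact occurrences of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
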