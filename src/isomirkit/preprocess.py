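"""Read preprocessing: demultiplexing, adapter trimming, tag collapsing.

Pooled small-RNA runs carry a 5-nt multiplex identifier (MID) at the 5'
end of every read and a 3' sequencing adapter after the insert.  Reads
are assigned to the unique library whose MID is an exact prefix, the
insert is cut at the first exact occurrence of the adapter, and inserts
are collapsed into unique tags with per-library counts.  Tags are then
filtered on insert length (15-29 nt inclusive) and total copy number
(CN >= 3), the standard desk filters for 454-era miRNA surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

VALID_GROUPS = ("EU", "EA", "AS")
_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: barcode, adapter and breed-group membership."""

    library_id: str
    breed: str
    group: str
    mid: str
    adapter3: str

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        if len(self.mid) != 5:
            raise ValueError("MID must be a five nucleotide sequence tag")


@dataclass
class UniqueTag:
    """A distinct insert sequence with per-library counts."""

    sequence: str
    per_library_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        """Total copy number (CN) across libraries."""
        return sum(self.per_library_counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique_mids(specs: list[LibrarySpec]) -> None:
    mids = [s.mid for s in specs]
    if len(set(mids)) != len(mids):
        raise ValueError("library MIDs must be distinct")


def canonicalize(seq: str) -> str:
    """Uppercase, 5'->3', U->T."""
    return seq.upper().replace("U", "T")


def demultiplex_and_trim(
    reads, specs: list[LibrarySpec]
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Assign reads to libraries by exact MID prefix and trim the 3' adapter.

    Parameters
    ----------
    reads
        Iterable of (read_id, sequence) pairs, or plain sequences.
    specs
        Library specifications; MIDs must be distinct.

    Returns
    -------
    (inserts, discard_log)
        ``inserts`` maps library_id to the list of insert sequences.
        ``discard_log`` is a DataFrame with columns read_id, sequence,
        reason; unassignable reads are logged, never silently dropped.
    """
    _check_unique_mids(specs)
    by_mid = {s.mid: s for s in specs}
    inserts: dict[str, list[str]] = {s.library_id: [] for s in specs}
    discards: list[tuple[str, str, str]] = []
    for i, read in enumerate(reads):
        if isinstance(read, tuple):
            rid, seq = read
        else:
            rid, seq = f"read_{i}", read
        seq = canonicalize(str(seq))
        spec = by_mid.get(seq[:5])
        if spec is None:
            discards.append((rid, seq, "no_mid"))
            continue
        rest = seq[5:]
        cut = rest.find(spec.adapter3)
        insert = rest[:cut] if cut >= 0 else rest
        if not insert:
            discards.append((rid, seq, "empty_insert"))
            continue
        inserts[spec.library_id].append(insert)
    log = pd.DataFrame(discards, columns=["read_id", "sequence", "reason"])
    return inserts, log


def collapse_reads(
    inserts: dict[str, list[str]]
) -> tuple[list[UniqueTag], pd.DataFrame]:
    """Collapse per-library insert lists into unique tags with exact counts.

    Sequences are canonicalized (U->T, uppercase) before collapsing;
    inserts containing characters outside ACGT(U) are discarded with a
    logged reason.
    """
    counts: dict[str, dict[str, int]] = {}
    discards: list[tuple[str, str, str]] = []
    for lib, seqs in inserts.items():
        for seq in seqs:
            seq = canonicalize(seq)
            if not set(seq) <= _ALPHABET:
                discards.append((lib, seq, "non_nucleotide"))
                continue
            counts.setdefault(seq, {})
            counts[seq][lib] = counts[seq].get(lib, 0) + 1
    tags = [
        UniqueTag(sequence=seq, per_library_counts=dict(libcounts))
        for seq, libcounts in sorted(counts.items())
    ]
    log = pd.DataFrame(discards, columns=["library_id", "sequence", "reason"])
    return tags, log


def filter_tags(
    tags: list[UniqueTag],
    min_len: int = 15,
    max_len: int = 29,
    min_cn: int = 3,
) -> tuple[list[UniqueTag], pd.DataFrame]:
    """Keep tags with min_len <= length <= max_len and CN >= min_cn.

    Boundaries are inclusive.  Returns the kept tags and a removal log
    with one row per removed tag and the reason (length / count).
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept: list[UniqueTag] = []
    removed: list[tuple[str, int, int, str]] = []
    for tag in tags:
        if not (min_len <= len(tag) <= max_len):
            removed.append((tag.sequence, len(tag), tag.total_count, "length"))
        elif tag.total_count < min_cn:
            removed.append((tag.sequence, len(tag), tag.total_count, "count"))
        else:
            kept.append(tag)
    log = pd.DataFrame(removed, columns=["sequence", "length", "CN", "reason"])
    return kept, log


def library_totals(tags: list[UniqueTag], specs: list[LibrarySpec]) -> dict[str, int]:
    """Per-library total counts over the given tags (normalization denominators)."""
    totals = {s.library_id: 0 for s in specs}
    for tag in tags:
        for lib, c in tag.per_library_counts.items():
            totals[lib] = totals.get(lib, 0) + c
    return totals


# ---------------------------------------------------------------------------
# file I/O


def read_reads(path: str | Path):
    """Yield (id, sequence) from a FASTA or FASTQ file (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq)


def read_library_table(path: str | Path) -> list[LibrarySpec]:
    """Load a library table TSV: library_id, breed, group, mid, adapter3."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    specs = [
        LibrarySpec(
            library_id=r.library_id,
            breed=r.breed,
            group=r.group,
            mid=r.mid,
            adapter3=r.adapter3,
        )
        for r in df.itertuples()
    ]
    _check_unique_mids(specs)
    return specs


def tags_to_frame(tags: list[UniqueTag], specs: list[LibrarySpec]) -> pd.DataFrame:
    """Tag table with one column per library plus length and CN."""
    libs = [s.library_id for s in specs]
    rows = [
        {
            "sequence": t.sequence,
            "length": len(t),
            **{lib: t.per_library_counts.get(lib, 0) for lib in libs},
            "CN": t.total_count,
        }
        for t in tags
    ]
    cols = ["sequence", "length", *libs, "CN"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_tags(df: pd.DataFrame) -> list[UniqueTag]:
    libs = [c for c in df.columns if c not in {"sequence", "length", "CN"}]
    return [
        UniqueTag(
            sequence=r["sequence"],
            per_library_counts={
                lib: int(r[lib])
                for lib in libs
                if pd.notna(r[lib]) and int(r[lib]) > 0
            },
        )
        for _, r in df.iterrows()
    ]
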