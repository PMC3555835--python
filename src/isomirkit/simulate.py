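"""Synthetic data generator for the small-RNA profiling pipeline.

Builds a miniature study that mirrors the structure of a pooled
454-style multiplexed small-RNA run over seven porcine kidney libraries:

* a random background genome with planted miRNA hairpin loci (the mature
  sequence in one arm, a near-reverse-complement in the other, joined by a
  short terminal loop);
* a mature miRNA reference (FASTA with species-prefixed ids) covering the
  annotated loci only, plus planted *novel* hairpins and non-hairpin
  *decoy* loci that are absent from the reference and annotation mask;
* multiplexed reads: 5-nt library MID + isomiR insert + 3' adapter, with
  per-library depths, breed-group structure and configurable
  group-specific expression effects;
* ground-truth tables (expected and emitted counts, insert multisets,
  loci) against which every downstream stage can be checked.

IsomiRs are drawn from an explicit end-variability model: independent 5'
and 3' truncation or *templated* extension (extension bases are read from
the precursor flanks, so simulated variants stay genome-mappable) and an
optional single internal substitution.  3' variability can be set higher
than 5', matching what small-RNA surveys observe.

The opposite hairpin arm is not an exact reverse complement: three
interior positions are converted to G.U wobble partners, so each mature
sequence maps to exactly one genomic site while the stem still pairs
fully.  All randomness derives from a single integer seed through fixed
offsets, so a given (seed, config) pair is byte-reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import LibrarySpec
from .seqs import find_all, revcomp

_BASES = np.array(list("ACGT"))
LOOP_LEN = 6
MIN_GAP = 100  # background nucleotides between planted loci
CHROM = "chr1"

#: 3' adapter appended to every simulated read (fixed plumbing sequence).
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

#: Seven-library design: (id, breed, group, MID).  Depths below follow the
#: per-library totals of the kidney survey this package emulates.
DEFAULT_LIBRARY_TABLE = (
    ("IB", "Iberian", "EU", "ACACG"),
    ("WB", "Wild Boar", "EU", "CGTAC"),
    ("LD", "Landrace", "EA", "GATCG"),
    ("LW", "Large White", "EA", "TCAGT"),
    ("PT", "Pietrain", "EA", "AGTGA"),
    ("ME", "Meishan", "AS", "CTGCT"),
    ("VT", "Vietnamese", "AS", "GACTA"),
)

DEFAULT_DEPTHS = {
    "IB": 4022,
    "WB": 18391,
    "LD": 13704,
    "LW": 23815,
    "PT": 20215,
    "ME": 17407,
    "VT": 17751,
}


def default_libraries(adapter3: str = DEFAULT_ADAPTER3) -> list[LibrarySpec]:
    return [
        LibrarySpec(library_id=i, breed=b, group=g, mid=m, adapter3=adapter3)
        for i, b, g, m in DEFAULT_LIBRARY_TABLE
    ]


@dataclass
class IsomirModel:
    """End-variability model for isomiR draws.

    p_shift5 / p_shift3 are the per-read probabilities that the 5' / 3'
    end is shifted at all; a shifted end is truncated or template-extended
    (equiprobably) by 1..max_shift nucleotides.  p_internal_edit is the
    probability of a single internal substitution.
    """

    p_shift5: float = 0.10
    p_shift3: float = 0.30
    p_internal_edit: float = 0.02
    max_shift: int = 2

    def __post_init__(self) -> None:
        for p in (self.p_shift5, self.p_shift3, self.p_internal_edit):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.max_shift <= 4:
            raise ValueError("max_shift must be within the annotation tolerance (<=4)")


@dataclass
class SimulationConfig:
    seed: int = 1
    n_mirnas: int = 30
    n_novel: int = 5
    n_decoys: int = 3
    genome_length: int = 20000
    libraries: list[LibrarySpec] = field(default_factory=default_libraries)
    library_depths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    isomir_model: IsomirModel = field(default_factory=IsomirModel)
    #: miRNA id -> group -> multiplicative expression effect
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mids = [s.mid for s in self.libraries]
        if len(set(mids)) != len(mids):
            raise ValueError("library MIDs must be distinct")
        for spec in self.libraries:
            if spec.library_id not in self.library_depths:
                raise ValueError(f"no depth configured for library {spec.library_id}")
            if self.library_depths[spec.library_id] <= 0:
                raise ValueError("library depths must be positive")

    def zero_noise(self) -> "SimulationConfig":
        """Copy of this config with the isomiR model switched off."""
        return replace(
            self,
            isomir_model=IsomirModel(0.0, 0.0, 0.0, self.isomir_model.max_shift),
        )


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    mature: dict[str, str]  # id -> mature sequence (annotated + novel + decoy)
    loci: dict[str, Locus]  # id -> mature genomic span
    hairpin_spans: dict[str, tuple[int, int]]  # id -> hairpin interval (annot+novel)
    novel_ids: list[str]
    decoy_ids: list[str]
    base_weights: dict[str, float]
    expected_counts: pd.DataFrame | None = None  # entity x library, E[count]
    emitted_counts: pd.DataFrame | None = None  # entity x library, realised
    insert_truth: Counter | None = None  # (library, insert) -> count

    @property
    def annotated_ids(self) -> list[str]:
        skip = set(self.novel_ids) | set(self.decoy_ids)
        return [m for m in self.mature if m not in skip]


@dataclass
class Reference:
    genome: dict[str, str]
    mature: dict[str, str]  # annotated reference only
    mask: list[tuple[str, int, int]]  # BED-like 0-based half-open


class GenomeSizingError(ValueError):
    pass


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _draw_mature(rng: np.random.Generator) -> str:
    """A 19-23 nt mature with >=3 interior wobble-capable (G/T) positions."""
    while True:
        length = int(rng.integers(19, 24))
        seq = _random_seq(rng, length)
        if sum(1 for p in range(3, length - 3) if seq[p] in "GT") >= 3:
            return seq


def _build_hairpin(
    rng: np.random.Generator, mature: str
) -> tuple[str, int]:
    """Hairpin sequence and the mature's offset within it.

    The opposite arm is the reverse complement with three interior
    positions switched to their G.U wobble partner, breaking exact
    self-complementarity (unique genome mapping) while keeping the stem
    fully paired under wobble-aware folding.
    """
    L = len(mature)
    opp = list(revcomp(mature))
    wobble_sites = [p for p in range(3, L - 3) if mature[p] in "GT"]
    rng.shuffle(wobble_sites)
    for p in wobble_sites[:3]:
        opp[L - 1 - p] = "T" if mature[p] == "G" else "G"
    loop = _random_seq(rng, LOOP_LEN)
    if rng.random() < 0.5:  # mature on the 5' arm
        return mature + loop + "".join(opp), 0
    return "".join(opp) + loop + mature, L + LOOP_LEN


def generate_reference(
    config: SimulationConfig,
) -> tuple[Reference, GroundTruth]:
    """Plant annotated hairpins, novel hairpins and decoy loci in a genome.

    Deterministic for a fixed (seed, config).  Raises
    :class:`GenomeSizingError` when the loci cannot be placed without
    overlap.  Every planted mature (and decoy) occurs exactly once across
    both genome strands; the assembly is re-drawn from a derived seed in
    the rare case a background collision occurs.
    """
    for attempt in range(20):
        ref_truth = _try_generate(config, attempt)
        if ref_truth is not None:
            return ref_truth
    raise RuntimeError("could not assemble a collision-free genome in 20 attempts")


def _try_generate(config: SimulationConfig, attempt: int):
    base = config.seed + 1_000_003 * attempt
    rng_seq = np.random.default_rng(base + 1)
    rng_place = np.random.default_rng(base + 2)
    rng_weights = np.random.default_rng(config.seed + 3)  # weights don't re-draw

    ids = [f"ssc-miR-sim-{i + 1}" for i in range(config.n_mirnas)]
    novel_ids = [f"novel-{i + 1}" for i in range(config.n_novel)]
    decoy_ids = [f"decoy-{i + 1}" for i in range(config.n_decoys)]

    mature: dict[str, str] = {}
    for name in ids + novel_ids:
        seq = _draw_mature(rng_seq)
        while seq in mature.values():
            seq = _draw_mature(rng_seq)
        mature[name] = seq
    for name in decoy_ids:
        seq = _random_seq(rng_seq, int(rng_seq.integers(19, 24)))
        while seq in mature.values():
            seq = _random_seq(rng_seq, int(rng_seq.integers(19, 24)))
        mature[name] = seq

    # build the planted segments (hairpins for miRNAs/novels, bare decoys)
    segments: list[tuple[str, str, int]] = []  # (name, plus-strand segment, mature offset)
    strands: dict[str, str] = {}
    for name in ids + novel_ids:
        hairpin, off = _build_hairpin(rng_seq, mature[name])
        strand = "+" if rng_place.random() < 0.5 else "-"
        strands[name] = strand
        if strand == "+":
            segments.append((name, hairpin, off))
        else:
            # insert the reverse complement; the mature then lies on '-'
            plus = revcomp(hairpin)
            off_plus = len(hairpin) - off - len(mature[name])
            segments.append((name, plus, off_plus))
    for name in decoy_ids:
        strand = "+" if rng_place.random() < 0.5 else "-"
        strands[name] = strand
        seg = mature[name] if strand == "+" else revcomp(mature[name])
        segments.append((name, seg, 0))

    total_seg = sum(len(seg) for _, seg, _ in segments)
    n_gaps = len(segments) + 1
    slack = config.genome_length - total_seg - MIN_GAP * n_gaps
    if segments and slack < 0:
        raise GenomeSizingError(
            f"genome_length={config.genome_length} too small to place "
            f"{len(segments)} loci without overlap"
        )

    order = list(range(len(segments)))
    rng_place.shuffle(order)
    extra = (
        rng_place.multinomial(slack, [1 / n_gaps] * n_gaps)
        if segments
        else np.array([config.genome_length])
    )
    parts: list[str] = []
    pos = 0
    seg_start: dict[str, int] = {}
    for gi, si in enumerate(order):
        gap = MIN_GAP + int(extra[gi]) if segments else int(extra[gi])
        parts.append(_random_seq(rng_seq, gap))
        pos += gap
        name, seg, off = segments[si]
        seg_start[name] = pos
        parts.append(seg)
        pos += len(seg)
    last_gap = (MIN_GAP + int(extra[-1])) if segments else int(extra[-1])
    parts.append(_random_seq(rng_seq, last_gap))
    genome = "".join(parts)
    assert len(genome) == config.genome_length

    # verify unique mapping of every planted sequence across both strands
    rc_genome = revcomp(genome)
    for name, seq in mature.items():
        if len(find_all(seq, genome)) + len(find_all(seq, rc_genome)) != 1:
            return None  # background collision: re-draw

    loci: dict[str, Locus] = {}
    hairpin_spans: dict[str, tuple[int, int]] = {}
    mask: list[tuple[str, int, int]] = []
    for si in range(len(segments)):
        name, seg, off = segments[si]
        start = seg_start[name]
        L = len(mature[name])
        loci[name] = Locus(CHROM, start + off, start + off + L, strands[name])
        if name not in decoy_ids:
            hairpin_spans[name] = (start, start + len(seg))
            if name in set(ids):
                mask.append((CHROM, start, start + len(seg)))
    mask.sort(key=lambda iv: iv[1])

    weights = {}
    for name in ids + novel_ids + decoy_ids:
        w = float(np.clip(rng_weights.lognormal(mean=0.0, sigma=1.0), 0.35, 40.0))
        weights[name] = w

    reference = Reference(
        genome={CHROM: genome},
        mature={name: mature[name] for name in ids},
        mask=mask,
    )
    truth = GroundTruth(
        mature=mature,
        loci=loci,
        hairpin_spans=hairpin_spans,
        novel_ids=novel_ids,
        decoy_ids=decoy_ids,
        base_weights=weights,
    )
    return reference, truth


# ---------------------------------------------------------------------------
# isomiR draws


def simulate_isomirs(
    mature: str,
    context: tuple[str, str],
    model: IsomirModel,
    n_draws: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw isomiR sequences for one mature miRNA.

    ``context`` is the (upstream, downstream) genomic template adjacent to
    the mature, each at least ``max_shift`` nucleotides long; templated
    extensions read from it.  The unshifted mature is the modal draw
    whenever shift probabilities are below 0.5.
    """
    if len(mature) < 2 * model.max_shift:
        raise ValueError("mature too short for the configured max_shift")
    up, down = context
    if model.max_shift and (len(up) < model.max_shift or len(down) < model.max_shift):
        raise ValueError("context flanks shorter than max_shift")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    for _ in range(n_draws):
        seq = mature
        if model.p_shift5 and rng.random() < model.p_shift5:
            size = int(rng.integers(1, model.max_shift + 1))
            if rng.random() < 0.5:
                seq = up[len(up) - size :] + seq  # templated 5' extension
            else:
                seq = seq[size:]  # 5' truncation
        if model.p_shift3 and rng.random() < model.p_shift3:
            size = int(rng.integers(1, model.max_shift + 1))
            if rng.random() < 0.5:
                seq = seq + down[:size]
            else:
                seq = seq[: len(seq) - size]
        if model.p_internal_edit and rng.random() < model.p_internal_edit:
            pos = int(rng.integers(0, len(seq)))
            alt = [b for b in "ACGT" if b != seq[pos]]
            seq = seq[:pos] + alt[int(rng.integers(0, 3))] + seq[pos + 1 :]
        out.append(seq)
    return out


def _mature_context(
    truth: GroundTruth, reference: Reference, name: str, window: int = 10
) -> tuple[str, str]:
    """Strand-oriented (upstream, downstream) template around a mature locus."""
    loc = truth.loci[name]
    genome = reference.genome[loc.chrom]
    left = genome[max(0, loc.start - window) : loc.start]
    right = genome[loc.end : loc.end + window]
    if loc.strand == "+":
        return left, right
    return revcomp(right), revcomp(left)


# ---------------------------------------------------------------------------
# library simulation


def simulate_libraries(
    reference: Reference,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Emit pooled multiplexed reads and fill in the ground-truth counts.

    Each read is ``MID + isomiR insert + 3' adapter``.  Per-library read
    totals equal the configured depths exactly; the returned truth carries
    expected counts (depth x relative weight), the realised multinomial
    counts, and the exact insert multiset per library.
    """
    rng = np.random.default_rng(config.seed + 4)
    entities = truth.annotated_ids + truth.novel_ids + truth.decoy_ids
    libs = [s.library_id for s in config.libraries]
    expected = pd.DataFrame(0.0, index=entities, columns=libs)
    emitted = pd.DataFrame(0, index=entities, columns=libs)
    insert_truth: Counter = Counter()
    reads: list[tuple[str, str]] = []

    for spec in config.libraries:
        depth = config.library_depths[spec.library_id]
        w = np.array(
            [
                truth.base_weights[m]
                * config.effect_table.get(m, {}).get(spec.group, 1.0)
                for m in entities
            ]
        )
        p = w / w.sum()
        counts = rng.multinomial(depth, p)
        expected[spec.library_id] = depth * p
        emitted[spec.library_id] = counts
        lib_reads: list[str] = []
        for m, c in zip(entities, counts):
            if c == 0:
                continue
            ctx = _mature_context(truth, reference, m)
            for insert in simulate_isomirs(
                truth.mature[m], ctx, config.isomir_model, int(c), rng
            ):
                insert_truth[(spec.library_id, insert)] += 1
                lib_reads.append(spec.mid + insert + spec.adapter3)
        rng.shuffle(lib_reads)
        reads.extend(
            (f"{spec.library_id}_{i:06d}", seq) for i, seq in enumerate(lib_reads)
        )

    truth.expected_counts = expected
    truth.emitted_counts = emitted
    truth.insert_truth = insert_truth
    return reads, truth


def simulate_run(
    config: SimulationConfig,
) -> tuple[Reference, GroundTruth, list[tuple[str, str]]]:
    """Convenience wrapper: reference + truth + pooled reads in one call."""
    reference, truth = generate_reference(config)
    reads, truth = simulate_libraries(reference, truth, config)
    return reference, truth, reads


# ---------------------------------------------------------------------------
# writers (all plain text)


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_mask_bed(mask: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in mask:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_mask_bed(path: str | Path) -> list[tuple[str, int, int]]:
    mask = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, start, end, *_ = line.split("\t")
                mask.append((chrom, int(start), int(end)))
    return mask


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Reference, GroundTruth]:
    """Run the simulator and write genome/reference/mask/reads/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, truth, reads = simulate_run(config)
    write_fasta(reference.genome, out / "genome.fa")
    write_fasta(reference.mature, out / "mature.fa")
    write_mask_bed(reference.mask, out / "mask.bed")
    write_fasta(reads, out / "reads.fa")
    lib_rows = [
        {
            "library_id": s.library_id,
            "breed": s.breed,
            "group": s.group,
            "mid": s.mid,
            "adapter3": s.adapter3,
        }
        for s in config.libraries
    ]
    pd.DataFrame(lib_rows).to_csv(out / "libraries.tsv", sep="\t", index=False)
    truth.emitted_counts.rename_axis("entity").to_csv(out / "truth_counts.tsv", sep="\t")
    loci_rows = [
        {
            "entity": name,
            "chrom": loc.chrom,
            "start": loc.start,
            "end": loc.end,
            "strand": loc.strand,
            "kind": (
                "novel"
                if name in truth.novel_ids
                else "decoy" if name in truth.decoy_ids else "annotated"
            ),
        }
        for name, loc in truth.loci.items()
    ]
    pd.DataFrame(loci_rows).to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    return reference, truth
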