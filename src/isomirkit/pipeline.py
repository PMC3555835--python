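"""End-to-end orchestration: simulate/preprocess -> annotate -> discover -> express.

``run_reads`` drives the full pipeline over an in-memory read set and
returns a report bundle of paper-shaped tables: a per-library sequencing
summary (total counts, unique sequences, annotated counts split by
porcine vs orthologous reference, unannotated counts), the most-abundant
profile above a CN cutoff, the novel-candidate table with fold verdicts,
and the pairwise group-comparison table.  ``run_simulation`` wires the
synthetic-data generator in front of it.  Every read entering the
pipeline lands in exactly one bucket (annotated / unannotated /
discarded-with-reason), which the bundle's accounting table records.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, discovery, expression, preprocess
from .annotate import MatureReference
from .preprocess import LibrarySpec
from .simulate import SimulationConfig, simulate_run

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, with the survey's standard thresholds."""

    min_len: int = 15
    max_len: int = 29
    min_tag_cn: int = 3
    tolerance: int = 4  # terminal variant nucleotides allowed by the matcher
    allow_internal_mismatch: int = 0
    min_cluster_cn: int = 3  # miRNA-level CN filter
    novel_min_len: int = 19
    novel_max_len: int = 23
    novel_min_cn_exclusive: int = 2  # novel candidates need CN > 2
    flank: int = 50
    min_arm_pairs: int = 16
    allow_gu: bool = True
    fc_threshold: float = 1.5
    abundant_cn_cutoff: int = 350
    genorm_m_threshold: float = 1.5
    alpha: float = 0.05
    seed: int = 1

    def validate(self) -> None:
        if self.min_len > self.max_len or self.novel_min_len > self.novel_max_len:
            raise ValueError("length windows must be non-empty")
        for name in ("min_tag_cn", "tolerance", "min_cluster_cn", "flank",
                     "min_arm_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold below 1 would flag everything")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg


@dataclass
class ReportBundle:
    library_summary: pd.DataFrame
    profile: pd.DataFrame
    abundant: pd.DataFrame
    candidates: pd.DataFrame
    comparisons: pd.DataFrame
    accounting: pd.DataFrame
    clusters: list = field(repr=False, default_factory=list)
    novel_clusters: list = field(repr=False, default_factory=list)
    unannotated: list = field(repr=False, default_factory=list)
    tags: list = field(repr=False, default_factory=list)
    library_totals: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.library_summary.to_csv(out / "library_summary.tsv", sep="\t", index=False)
        self.profile.to_csv(out / "profile.tsv", sep="\t", index=False)
        self.abundant.to_csv(out / "abundant.tsv", sep="\t", index=False)
        self.candidates.to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
        self.comparisons.to_csv(out / "comparisons.tsv", sep="\t")
        self.accounting.to_csv(out / "accounting.tsv", sep="\t", index=False)


def run_reads(
    reads,
    specs: list[LibrarySpec],
    references: list[MatureReference],
    genome: dict[str, str] | None = None,
    mask: list[tuple[str, int, int]] | None = None,
    config: RunConfig | None = None,
) -> ReportBundle:
    """Run preprocess -> annotate -> discover -> express over raw reads."""
    cfg = config or RunConfig()
    cfg.validate()
    reads = list(reads)

    inserts, discard_log = preprocess.demultiplex_and_trim(reads, specs)
    tags, collapse_log = preprocess.collapse_reads(inserts)
    filtered, removal_log = preprocess.filter_tags(
        tags, cfg.min_len, cfg.max_len, cfg.min_tag_cn
    )
    # normalisation denominator: all reads surviving the length filter
    length_ok = [
        t for t in tags if cfg.min_len <= len(t) <= cfg.max_len
    ]
    lib_totals = preprocess.library_totals(length_ok, specs)

    clusters, unannotated = annotate.assign_tags(
        filtered, references, cfg.tolerance, cfg.allow_internal_mismatch
    )
    grand_total = sum(lib_totals.values())
    profile = annotate.build_profile(
        clusters, cfg.min_cluster_cn, grand_total,
        library_ids=[s.library_id for s in specs],
    )
    abundant = profile[profile["CN"] > cfg.abundant_cn_cutoff].reset_index(drop=True)

    if genome is not None:
        novel = discovery.discover(
            unannotated, genome, mask or [],
            cfg.novel_min_len, cfg.novel_max_len, cfg.novel_min_cn_exclusive,
            cfg.flank, cfg.min_arm_pairs, cfg.allow_gu,
        )
    else:
        novel = []
    candidates = discovery.candidates_to_frame(novel)

    libs = [s.library_id for s in specs]
    counts = profile.set_index("mirna_id")[libs]
    group_map = {s.library_id: s.group for s in specs}
    comparisons = (
        expression.compare_groups(counts, lib_totals, group_map, cfg.fc_threshold)
        if len(counts)
        else pd.DataFrame()
    )

    lib_rows = []
    for s in specs:
        lib = s.library_id
        total = lib_totals.get(lib, 0)
        uniq = sum(1 for t in length_ok if t.per_library_counts.get(lib, 0) > 0)
        ann = {"ssc": 0, "other": 0}
        for c in clusters:
            species = "ssc" if c.mirna_id.lower().startswith("ssc") else "other"
            ann[species] += c.per_library_totals().get(lib, 0)
        unann = sum(t.per_library_counts.get(lib, 0) for t in unannotated)
        lib_rows.append(
            {
                "library_id": lib,
                "breed": s.breed,
                "group": s.group,
                "total_counts": total,
                "unique_sequences": uniq,
                "annotated_porcine": ann["ssc"],
                "annotated_ortholog": ann["other"],
                "unannotated": unann,
            }
        )
    library_summary = pd.DataFrame(lib_rows)

    n_assigned = sum(len(v) for v in inserts.values())
    accounting = pd.DataFrame(
        [
            {"bucket": "input_reads", "count": len(reads)},
            {"bucket": "assigned", "count": n_assigned},
            {"bucket": "discarded_demux", "count": len(discard_log)},
            {"bucket": "discarded_non_nucleotide", "count": len(collapse_log)},
            {"bucket": "removed_by_tag_filter",
             "count": int(removal_log["CN"].sum()) if len(removal_log) else 0},
            {"bucket": "annotated",
             "count": sum(c.cluster_cn for c in clusters)},
            {"bucket": "unannotated",
             "count": sum(t.total_count for t in unannotated)},
        ]
    )
    for name, n in (("demultiplex", len(discard_log)),
                    ("tag filter", len(removal_log))):
        logger.info("%s removed %d records", name, n)

    return ReportBundle(
        library_summary=library_summary,
        profile=profile,
        abundant=abundant,
        candidates=candidates,
        comparisons=comparisons,
        accounting=accounting,
        clusters=clusters,
        novel_clusters=novel,
        unannotated=unannotated,
        tags=filtered,
        library_totals=lib_totals,
    )


def run_simulation(
    sim_config: SimulationConfig, config: RunConfig | None = None
):
    """Simulate a run and push it through the pipeline.

    Returns (bundle, reference, truth); the simulator's mature reference
    is used as the annotation database and its mask as the novel filter.
    """
    reference, truth, reads = simulate_run(sim_config)
    refs = [
        MatureReference(mid, seq) for mid, seq in sorted(reference.mature.items())
    ]
    bundle = run_reads(
        reads,
        sim_config.libraries,
        refs,
        genome=reference.genome,
        mask=reference.mask,
        config=config,
    )
    return bundle, reference, truth


def run_counts(
    counts: pd.DataFrame,
    library_totals: dict[str, int],
    group_map: dict[str, str],
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Tables-only entry point: group comparisons from a pre-counted matrix."""
    return expression.compare_groups(counts, library_totals, group_map, fc_threshold)
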