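"""Filtering of translated-search hit tables and abundance profiling.

Hits are filtered with strict thresholds (bit score > 50 and percent
identity > 90 by default, the standard stringency for mapping short reads
to a nonredundant protein set), reduced to one best hit per read, and
summarised as reads-per-million (RPM) or length-normalised
reads-per-kilobase-per-million (RPKM).  The lineage-level RPKM ratio of a
focal single-copy marker to a reference marker (e.g. rbcL of a
heterotrophic lineage vs amoA of ammonia-oxidising archaea) estimates the
relative abundance of the two populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io_core import AlignmentHit, _as_text_stream
from .orthology import select_best_per_query


@dataclass(frozen=True)
class FilterPolicy:
    """Strict (>) thresholds on bit score and percent identity, plus the
    best-hit-per-read rule.

    ``best_hit_after_filter`` keeps the default order: thresholds first,
    then best-hit selection among survivors (a read whose top raw hit fails
    the thresholds can still be counted through its next passing hit).
    """

    min_bitscore: float = 50.0
    min_pident: float = 90.0
    best_hit_only: bool = True
    best_hit_after_filter: bool = True


@dataclass(frozen=True)
class MarkerReference:
    marker_id: str
    lineage_label: str
    gene_length_bp: int

    def __post_init__(self):
        if self.gene_length_bp <= 0:
            raise ValueError("gene_length_bp must be positive")


def read_marker_references(source) -> list[MarkerReference]:
    frame = pd.read_csv(_as_text_stream(source), sep="\t")
    return [MarkerReference(str(r.marker_id), str(r.lineage), int(r.length_bp))
            for r in frame.itertuples(index=False)]


@dataclass
class AbundanceProfile:
    label: str
    read_count: int
    library_size: int

    @property
    def rpm(self) -> float:
        return 1e6 * self.read_count / self.library_size


def filter_hits(hits: list[AlignmentHit], policy: FilterPolicy = FilterPolicy()
                ) -> list[AlignmentHit]:
    """Apply the threshold and best-hit rules; idempotent."""
    def passes(h: AlignmentHit) -> bool:
        return h.bitscore > policy.min_bitscore and h.pident > policy.min_pident

    if policy.best_hit_only and not policy.best_hit_after_filter:
        best = select_best_per_query(hits)
        return [h for h in best.values() if passes(h)]
    surviving = [h for h in hits if passes(h)]
    if policy.best_hit_only:
        best = select_best_per_query(surviving)
        return list(best.values())
    return surviving


def profile_rpm(filtered: list[AlignmentHit], library_size: int,
                target_subjects: set[str], label: str = "target") -> AbundanceProfile:
    """RPM of reads whose (filtered) hit subject belongs to the target set."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    count = sum(1 for h in filtered if h.subject_id in target_subjects)
    return AbundanceProfile(label=label, read_count=count, library_size=library_size)


def profile_rpkm(read_counts: dict[str, int], markers: list[MarkerReference],
                 library_size: int) -> tuple[dict[str, float], dict[str, float]]:
    """Per-marker and lineage-summed RPKM.

    rpkm = 1e9 * reads / (gene_length_bp * library_size).  A count for a
    marker absent from the reference list is an error.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    by_id = {m.marker_id: m for m in markers}
    unknown = set(read_counts) - set(by_id)
    if unknown:
        raise ValueError(f"counts for unknown markers: {sorted(unknown)}")
    per_marker: dict[str, float] = {}
    per_lineage: dict[str, float] = {}
    for m in markers:
        count = read_counts.get(m.marker_id, 0)
        rpkm = 1e9 * count / (m.gene_length_bp * library_size)
        per_marker[m.marker_id] = rpkm
        per_lineage[m.lineage_label] = per_lineage.get(m.lineage_label, 0.0) + rpkm
    return per_marker, per_lineage


def marker_ratio(focal_rpkm: float, reference_rpkm: float) -> float | None:
    """100 * focal / reference; None (with a warning) when the reference is
    zero, including the 0/0 case."""
    if focal_rpkm < 0 or reference_rpkm < 0:
        raise ValueError("RPKM values must be nonnegative")
    if reference_rpkm == 0:
        warnings.warn("reference RPKM is zero; ratio undefined")
        return None
    return 100.0 * focal_rpkm / reference_rpkm


def marker_read_counts(filtered: list[AlignmentHit],
                       markers: list[MarkerReference]) -> dict[str, int]:
    """Tabulate filtered reads per marker (subjects not in the marker list
    are ignored)."""
    ids = {m.marker_id for m in markers}
    counts: dict[str, int] = {m: 0 for m in ids}
    for h in filtered:
        if h.subject_id in ids:
            counts[h.subject_id] += 1
    return counts


def lineage_ratio_profile(hits: list[AlignmentHit], markers: list[MarkerReference],
                          library_size: int, focal_lineage: str,
                          reference_lineage: str,
                          policy: FilterPolicy = FilterPolicy()) -> dict:
    """The full chain: filter -> count per marker -> RPKM -> lineage ratio."""
    filtered = filter_hits(hits, policy)
    counts = marker_read_counts(filtered, markers)
    per_marker, per_lineage = profile_rpkm(counts, markers, library_size)
    ratio = marker_ratio(per_lineage.get(focal_lineage, 0.0),
                         per_lineage.get(reference_lineage, 0.0))
    return {
        "per_marker_rpkm": per_marker,
        "per_lineage_rpkm": per_lineage,
        "ratio_pct": ratio,
        "n_filtered_reads": len(filtered),
    }
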