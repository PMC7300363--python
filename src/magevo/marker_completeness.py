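"""Single-copy-marker completeness estimation and genome-size extrapolation.

A marker set is curated from complete reference genomes (markers present in
at least ``min_genomes`` of them); a draft genome's completeness is the
fraction of those markers it carries, contamination is the fraction found
in extra copies, and the complete genome size is extrapolated from the bin
size by removing the contaminant fraction and scaling by completeness:

    size_complete = bin_size * (100 - contamination) / completeness

Contamination here is defined from the same marker set as completeness
(extra-copy fraction), giving one coherent estimator rather than mixing in
a lineage-specific collocated-marker workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io_core import SequenceRecord, _as_text_stream


@dataclass(frozen=True)
class MarkerSet:
    """Curated single-copy markers with their curation provenance."""

    marker_ids: tuple[str, ...]
    n_reference_genomes: int = 0
    min_genomes: int = 0

    def __post_init__(self):
        if not self.marker_ids:
            raise ValueError("marker set must be nonempty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class CompletenessEstimate:
    genome_id: str
    completeness_pct: float
    contamination_pct: float
    n_markers_found: int
    n_extra_copies: int


class MarkerHitTable:
    """(marker_id, genome_id) -> copy_count; absent pairs mean zero copies."""

    def __init__(self, rows: Iterable[tuple[str, str, int]]):
        self._counts: dict[tuple[str, str], int] = {}
        self.marker_order: list[str] = []
        self.genomes: set[str] = set()
        for marker_id, genome_id, copies in rows:
            copies = int(copies)
            if copies < 0:
                raise ValueError(f"negative copy count for ({marker_id}, {genome_id})")
            key = (marker_id, genome_id)
            if key in self._counts:
                raise ValueError(f"duplicate (marker, genome) pair {key}")
            self._counts[key] = copies
            if marker_id not in self.marker_order:
                self.marker_order.append(marker_id)
            self.genomes.add(genome_id)

    def copies(self, marker_id: str, genome_id: str) -> int:
        return self._counts.get((marker_id, genome_id), 0)

    @classmethod
    def from_tsv(cls, source) -> "MarkerHitTable":
        frame = pd.read_csv(_as_text_stream(source), sep="\t")
        required = {"marker_id", "genome_id", "copy_count"}
        if not required.issubset(frame.columns):
            raise ValueError(f"marker hit TSV needs columns {sorted(required)}")
        return cls(frame[["marker_id", "genome_id", "copy_count"]].itertuples(index=False))

    def to_tsv(self, handle) -> None:
        handle.write("marker_id\tgenome_id\tcopy_count\n")
        for (marker, genome), copies in sorted(self._counts.items()):
            handle.write(f"{marker}\t{genome}\t{copies}\n")


def marker_hits_from_records(records: Iterable[SequenceRecord], genome_id: str,
                             marker_field: int = 1) -> MarkerHitTable:
    """Tabulate marker copies from synthetic records whose IDs encode the
    marker as a ``|``-separated field (``none`` marks non-marker records)."""
    counts: dict[str, int] = {}
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) <= marker_field:
            continue
        marker = parts[marker_field]
        if marker == "none":
            continue
        counts[marker] = counts.get(marker, 0) + 1
    return MarkerHitTable((m, genome_id, c) for m, c in counts.items())


def curate_marker_set(hits: MarkerHitTable, reference_genomes: list[str],
                      min_genomes: int) -> MarkerSet:
    """Keep candidate markers present (copy >= 1) in at least ``min_genomes``
    of the reference genomes, in stable input order."""
    if min_genomes > len(reference_genomes):
        raise ValueError(
            f"min_genomes={min_genomes} exceeds the {len(reference_genomes)} reference genomes")
    kept = []
    for marker in hits.marker_order:
        n_present = sum(1 for g in reference_genomes if hits.copies(marker, g) >= 1)
        if n_present >= min_genomes:
            kept.append(marker)
    return MarkerSet(tuple(kept), n_reference_genomes=len(reference_genomes),
                     min_genomes=min_genomes)


def estimate_completeness(hits: MarkerHitTable, genome_id: str,
                          markers: MarkerSet) -> CompletenessEstimate:
    """Completeness = % of set markers present; contamination = % extra copies.

    A marker in several copies still counts once toward completeness
    (single-copy convention); each copy beyond the first counts toward
    contamination.
    """
    n_found = 0
    n_extra = 0
    for marker in markers.marker_ids:
        copies = hits.copies(marker, genome_id)
        if copies >= 1:
            n_found += 1
            n_extra += copies - 1
    n = len(markers)
    return CompletenessEstimate(
        genome_id=genome_id,
        completeness_pct=100.0 * n_found / n,
        contamination_pct=100.0 * n_extra / n,
        n_markers_found=n_found,
        n_extra_copies=n_extra,
    )


def extrapolate_genome_size(bin_size_kbp: float, completeness_pct: float,
                            contamination_pct: float) -> float:
    """Extrapolate the complete genome size from a bin's size and its
    completeness/contamination percentages (full precision; round only at
    reporting time)."""
    if bin_size_kbp <= 0:
        raise ValueError("bin_size_kbp must be positive")
    if completeness_pct <= 0 or completeness_pct > 100:
        raise ValueError("completeness_pct must be in (0, 100]")
    if not 0 <= contamination_pct < 100:
        raise ValueError("contamination_pct must be in [0, 100)")
    return bin_size_kbp * (100.0 - contamination_pct) / completeness_pct


def completeness_report(rows: Iterable[tuple[str, float, float, float]]) -> pd.DataFrame:
    """Assemble a report mirroring a MAG statistics table.

    ``rows`` are (genome_id, bin_size_kbp, completeness_pct,
    contamination_pct); completeness is reported to one decimal and
    extrapolated sizes to the nearest kbp.
    """
    out = []
    for genome_id, bin_size, comp, contam in rows:
        size = extrapolate_genome_size(bin_size, comp, contam)
        out.append({
            "genome_id": genome_id,
            "bin_size_kbp": bin_size,
            "completeness_pct": round(comp, 1),
            "contamination_pct": round(contam, 2),
            "extrapolated_size_kbp": int(round(size)),
        })
    return pd.DataFrame(out)
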