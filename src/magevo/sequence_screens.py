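"""Alignment-based sequence screens: conserved-residue checks against a
reference position list, and short-motif scans with an ``X`` wildcard.

Typical uses are checking whether a candidate RuBisCO large subunit retains
the catalytic residues defined on a curated alignment, or scanning
PQQ-dependent dehydrogenases for the DYD / DXD lanthanide-binding motif.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_core import SequenceRecord


@dataclass(frozen=True)
class ResidueSpec:
    """(alignment column, allowed residues) pairs; columns are 1-based
    positions in the alignment, not ungapped reference coordinates."""

    positions: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self):
        cols = [c for c, _ in self.positions]
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate alignment columns in spec")
        if any(c < 1 for c in cols):
            raise ValueError("alignment columns are 1-based")
        if any(not allowed for _, allowed in self.positions):
            raise ValueError("each position needs a nonempty allowed set")

    @classmethod
    def from_pairs(cls, pairs) -> "ResidueSpec":
        return cls(tuple((int(c), frozenset(s.upper() for s in allowed))
                         for c, allowed in pairs))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ResidueReport:
    query_id: str
    n_conserved: int
    mismatches: tuple[tuple[int, str, str], ...]  # (column, found, expected)
    gaps: tuple[int, ...]


def conserved_residue_check(alignment: list[SequenceRecord], spec: ResidueSpec,
                            query_id: str) -> ResidueReport:
    """Check the query row of an alignment at each spec column.

    A gap at a spec column counts as non-conserved and is reported
    separately from a substitution.  conserved + mismatches + gaps always
    equals the spec size.
    """
    lengths = {len(r) for r in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    (aln_len,) = lengths
    by_id = {r.id: r for r in alignment}
    if query_id not in by_id:
        raise ValueError(f"query {query_id!r} not in the alignment")
    query = by_id[query_id].residues
    n_conserved = 0
    mismatches = []
    gaps = []
    for column, allowed in spec.positions:
        if column > aln_len:
            raise ValueError(f"spec column {column} beyond alignment length {aln_len}")
        found = query[column - 1].upper()
        if found == "-":
            gaps.append(column)
        elif found in allowed:
            n_conserved += 1
        else:
            mismatches.append((column, found, "".join(sorted(allowed))))
    return ResidueReport(query_id, n_conserved, tuple(mismatches), tuple(gaps))


def reference_to_alignment_columns(aligned_reference: str,
                                   reference_positions: list[int]) -> list[int]:
    """Convert 1-based ungapped reference coordinates into 1-based
    alignment columns using the reference's aligned (gapped) row."""
    mapping = {}
    residue_index = 0
    for col, char in enumerate(aligned_reference, start=1):
        if char != "-":
            residue_index += 1
            mapping[residue_index] = col
    out = []
    for pos in reference_positions:
        if pos not in mapping:
            raise ValueError(f"reference position {pos} beyond the ungapped reference")
        out.append(mapping[pos])
    return out


def motif_scan(sequence: SequenceRecord | str, pattern: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions where ``pattern``
    matches; ``X`` matches any residue."""
    if not pattern:
        raise ValueError("pattern must be nonempty")
    residues = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    residues = residues.upper()
    pattern = pattern.upper()
    hits = []
    for start in range(len(residues) - len(pattern) + 1):
        window = residues[start:start + len(pattern)]
        if all(p == "X" or p == w for p, w in zip(pattern, window)):
            hits.append(start + 1)
    return hits
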