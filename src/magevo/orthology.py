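"""Best hits, reciprocal best hits, ortholog-group clustering, AAI/ANI
summaries, and greedy nonredundant protein sets.

Ortholog groups are the connected components of the undirected
reciprocal-best-hit (RBH) graph over a declared genome universe — a
deliberate simplification of spectral RBH-graph partitioners, chosen
because it is a fully defined, testable procedure.  The same best-hit
machinery applied to nucleotide ORF hit tables yields the ANI summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align

from .io_core import AlignmentHit, BinaryContentMatrix, SequenceRecord


def _hit_rank(hit: AlignmentHit) -> tuple:
    """Sort key implementing the fixed tie rule: max bitscore, then max
    pident, then lexicographically smallest subject id."""
    return (-hit.bitscore, -hit.pident, hit.subject_id)


def select_best_per_query(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    """One best hit per query under the bitscore -> pident -> subject-id
    tie rule; input order never matters."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def best_hits(hits: list[AlignmentHit], source_proteins: set[str],
              target_proteins: set[str]) -> tuple[dict[str, AlignmentHit], int]:
    """Best hit per source-genome query against the target genome.

    Rows whose query is not in ``source_proteins`` or whose subject is not
    in ``target_proteins`` are ignored; the count of ignored rows is
    returned alongside the map.
    """
    relevant = [h for h in hits
                if h.query_id in source_proteins and h.subject_id in target_proteins]
    return select_best_per_query(relevant), len(hits) - len(relevant)


def reciprocal_best_hits(ab: dict[str, AlignmentHit],
                         ba: dict[str, AlignmentHit]) -> set[tuple[str, str]]:
    """Pairs (a, b) with best(a) = b and best(b) = a."""
    pairs = set()
    for a, hit in ab.items():
        b = hit.subject_id
        back = ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.add((a, b))
    return pairs


@dataclass
class OrthologGroups:
    """Partition of the protein universe into ortholog groups.

    ``groups`` maps og_id -> set of (genome_id, protein_id); og_ids are the
    lexicographically smallest member's protein id, so they are stable
    under input reordering.
    """

    groups: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def membership(self) -> dict[str, str]:
        return {protein: og for og, members in self.groups.items()
                for _genome, protein in members}

    def to_matrix(self, genome_ids: list[str]) -> BinaryContentMatrix:
        og_ids = sorted(self.groups)
        cells = np.zeros((len(genome_ids), len(og_ids)), dtype=np.int8)
        gi = {g: i for i, g in enumerate(genome_ids)}
        for j, og in enumerate(og_ids):
            for genome, _protein in self.groups[og]:
                if genome in gi:
                    cells[gi[genome], j] = 1
        return BinaryContentMatrix.from_arrays(genome_ids, og_ids, cells)

    def write_tsv(self, handle) -> None:
        handle.write("og_id\tgenome_id\tprotein_id\n")
        for og in sorted(self.groups):
            for genome, protein in sorted(self.groups[og]):
                handle.write(f"{og}\t{genome}\t{protein}\n")


def cluster_ogs(rbh_sets: dict[tuple[str, str], set[tuple[str, str]]],
                proteins: dict[str, list[str]]) -> OrthologGroups:
    """Connected components of the RBH graph over the genome universe.

    ``rbh_sets`` maps (genomeA, genomeB) -> RBH pairs (proteinA, proteinB);
    ``proteins`` maps genome -> all protein ids, so proteins without any
    RBH edge become singleton groups.
    """
    graph = nx.Graph()
    owner: dict[str, str] = {}
    for genome, ids in proteins.items():
        for pid in ids:
            if pid in owner and owner[pid] != genome:
                raise ValueError(f"protein id {pid!r} appears in two genomes")
            owner[pid] = genome
            graph.add_node(pid)
    for (ga, gb), pairs in rbh_sets.items():
        for a, b in pairs:
            graph.add_edge(a, b)
    groups: dict[str, set[tuple[str, str]]] = {}
    for component in nx.connected_components(graph):
        og_id = min(component)
        groups[og_id] = {(owner[p], p) for p in component}
    return OrthologGroups(groups)


def compute_aai(ab: dict[str, AlignmentHit], ba: dict[str, AlignmentHit]
                ) -> tuple[float | None, float | None, float | None]:
    """Average amino-acid identity between two proteomes.

    Returns (two_way, a_to_b, b_to_a): the symmetric AAI is the unweighted
    mean percent identity over the union of both directions' best hits;
    the one-way means are reported alongside for transparency.  With no
    best hits at all the values are None (with a warning).
    """
    pidents_ab = [h.pident for h in ab.values()]
    pidents_ba = [h.pident for h in ba.values()]
    both = pidents_ab + pidents_ba
    if not both:
        warnings.warn("no best hits between the two proteomes; AAI undefined")
        return None, None, None
    two_way = float(np.mean(both))
    one_ab = float(np.mean(pidents_ab)) if pidents_ab else None
    one_ba = float(np.mean(pidents_ba)) if pidents_ba else None
    return two_way, one_ab, one_ba


# ---------------------------------------------------------------------------
# Greedy nonredundant set (CD-HIT-style)
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -10
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity over the shorter sequence, in [0, 1]."""
    alignment = _aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def nonredundant_set(proteins: list[SequenceRecord],
                     identity_threshold: float = 0.9
                     ) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest first (ties broken by id); each joins
    the first existing cluster whose representative reaches the identity
    threshold (computed over the shorter sequence), else founds a new
    cluster.  Returns the representatives and a member -> representative
    map.
    """
    if not proteins:
        raise ValueError("empty input")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(proteins, key=lambda r: (-len(r), r.id))
    representatives: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for rec in ordered:
        for rep in representatives:
            if pairwise_identity(rec.residues, rep.residues) >= identity_threshold:
                membership[rec.id] = rep.id
                break
        else:
            representatives.append(rec)
            membership[rec.id] = rec.id
    return representatives, membership
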