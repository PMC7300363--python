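"""Seeded generators with known ground truth.

The generators emulate the statistical structure the downstream analyses
assume: gene content evolving by gain/loss on a clock-like tree, protein
families diverging by point substitution, MAG-style incompleteness and
contamination, and translated read-mapping hit tables with controlled
identity, bit-score and abundance structure.  Every generator is a pure
function of its inputs and a seed, and records its latent variables in a
:class:`SyntheticTruth` so recovery tests have an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .io_core import (
    AlignmentHit,
    AnnotatedTree,
    BinaryContentMatrix,
    SequenceRecord,
    TreeNode,
    format_fasta,
    write_hits,
)

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

#: affine surrogate for a bit score; only its monotonicity in alignment
#: length and identity matters for filter tests.
BITSCORE_SLOPE = 0.5
BITSCORE_OFFSET = 10.0


def surrogate_bitscore(aln_length: int, pident: float) -> float:
    return BITSCORE_SLOPE * aln_length * pident / 100.0 + BITSCORE_OFFSET


@dataclass
class GainLossRates:
    """Gain (0->1) and loss (1->0) rates per unit branch length."""

    q01: float
    q10: float

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class SyntheticTruth:
    """Latent variables of a simulation, keyed by node/branch/read IDs.

    ``true_branch_events`` maps a child-node label to (gains, losses)
    summed over OGs; ``events_per_og`` keeps the per-OG counts needed for
    parity checks.
    """

    true_node_states: dict[str, np.ndarray] = field(default_factory=dict)
    true_branch_events: dict[str, tuple[int, int]] = field(default_factory=dict)
    events_per_og: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    true_genome_size_kbp: dict[str, float] = field(default_factory=dict)
    true_read_origin: dict[str, str] = field(default_factory=dict)

    def write_tsv(self, handle) -> None:
        """Long-format (entity, attribute, value) dump."""
        for label, (g, l) in sorted(self.true_branch_events.items()):
            handle.write(f"{label}\tgains\t{g}\n{label}\tlosses\t{l}\n")
        for genome, size in sorted(self.true_genome_size_kbp.items()):
            handle.write(f"{genome}\tcomplete_size_kbp\t{size:.3f}\n")
        for read, origin in sorted(self.true_read_origin.items()):
            handle.write(f"{read}\tsource_protein\t{origin}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> AnnotatedTree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    The root splits immediately into two lineages; while k lineages exist
    the next speciation arrives after Exp(k*birth_rate).  After the n-th
    lineage appears the tree is cut one further Exp(n*birth_rate) interval
    later, so the expected root-to-tip depth is sum_{k=2..n} 1/(k*birth_rate).
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    root = TreeNode("")
    birth_time = {id(root): 0.0}
    active = [root.add_child(TreeNode("")), root.add_child(TreeNode(""))]
    for child in active:
        birth_time[id(child)] = 0.0
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth_time[id(node)]
        for _ in range(2):
            child = node.add_child(TreeNode(""))
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.length = t - birth_time[id(node)]

    # deterministic left-to-right tip labels before tree validation
    counter = [0]

    def label_tips(node: TreeNode) -> None:
        if not node.children:
            counter[0] += 1
            node.label = f"t{counter[0]}"
        for child in node.children:
            label_tips(child)

    label_tips(root)
    return AnnotatedTree(root)


# ---------------------------------------------------------------------------
# Gene content
# ---------------------------------------------------------------------------

def _evolve_branch(states: np.ndarray, t: float, rates: GainLossRates,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evolve a vector of 0/1 states along one branch of length ``t``.

    Exact stochastic simulation: per OG, exponential waiting times with the
    state-dependent rate until the branch is exhausted.  Returns the child
    states and per-OG gain/loss counts.
    """
    s = states.copy()
    n = s.size
    remaining = np.full(n, float(t))
    gains = np.zeros(n, dtype=np.int64)
    losses = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    while alive.any():
        rate = np.where(s == 0, rates.q01, rates.q10).astype(float)
        wait = np.full(n, np.inf)
        positive = rate > 0
        # one draw per OG per round keeps the stream reproducible
        draws = rng.exponential(1.0, size=n)
        wait[positive] = draws[positive] / rate[positive]
        flip = alive & (wait <= remaining)
        if not flip.any():
            break
        remaining[flip] -= wait[flip]
        gained = flip & (s == 0)
        lost = flip & (s == 1)
        gains[gained] += 1
        losses[lost] += 1
        s[flip] ^= 1
        alive = flip  # only flipped OGs can flip again
    return s, gains, losses


def simulate_gene_content(tree: AnnotatedTree, n_ogs: int, rates: GainLossRates,
                          root_prior_p1: float, seed: int
                          ) -> tuple[BinaryContentMatrix, SyntheticTruth]:
    """Simulate presence/absence of ``n_ogs`` gene families down ``tree``.

    Each family's root state is Bernoulli(``root_prior_p1``) and evolves
    along every branch as a two-state continuous-time Markov chain with
    the given gain/loss rates.  All latent node states and per-branch event
    counts are recorded in the returned :class:`SyntheticTruth`.
    """
    if not 0.0 <= root_prior_p1 <= 1.0:
        raise ValueError("root_prior_p1 must lie in [0, 1]")
    if rates.q01 + rates.q10 <= 0 and n_ogs > 0:
        # degenerate but allowed: nothing ever changes
        pass
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    states: dict[int, np.ndarray] = {}
    root_states = (rng.random(n_ogs) < root_prior_p1).astype(np.int8)
    states[id(tree.root)] = root_states
    truth.true_node_states[tree.root.label] = root_states
    for node in tree.preorder():
        if node.parent is None:
            continue
        child_states, gains, losses = _evolve_branch(
            states[id(node.parent)], node.length, rates, rng)
        states[id(node)] = child_states
        truth.true_node_states[node.label] = child_states
        truth.true_branch_events[node.label] = (int(gains.sum()), int(losses.sum()))
        truth.events_per_og[node.label] = (gains, losses)
    tips = tree.tips()
    cells = np.vstack([states[id(t)] for t in tips])
    og_ids = [f"OG{i:05d}" for i in range(n_ogs)]
    matrix = BinaryContentMatrix.from_arrays([t.label for t in tips], og_ids, cells)
    return matrix, truth


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def evolve_family_sequences(tree: AnnotatedTree, content: BinaryContentMatrix,
                            mean_length_aa: int, sub_rate: float, seed: int
                            ) -> dict[str, list[SequenceRecord]]:
    """Evolve one protein per OG down the tree; emit per-taxon proteomes.

    Root sequences are i.i.d. uniform over the 20 amino acids with
    geometric lengths (mean ``mean_length_aa``, floored at 50).  Down each
    branch a Poisson(sub_rate * length * branch_length) number of positions
    mutate to a uniformly chosen different residue.  A taxon's FASTA holds
    exactly the OGs present (state 1) in ``content`` at that tip; record
    IDs are ``{taxon}|{og}`` so the truth is recoverable from the ID.
    """
    missing = set(content.taxon_ids) - {t.label for t in tree.tips()}
    if missing:
        raise ValueError(f"content taxa not on the tree: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    og_ids = content.og_ids
    n_ogs = len(og_ids)
    lengths = np.maximum(50, rng.geometric(1.0 / max(mean_length_aa, 1), size=n_ogs))

    def mutate(seq: np.ndarray, t: float) -> np.ndarray:
        n_sub = rng.poisson(sub_rate * t * seq.size)
        if n_sub == 0:
            return seq
        out = seq.copy()
        pos = rng.integers(seq.size, size=n_sub)
        shift = rng.integers(1, 20, size=n_sub)
        out[pos] = (out[pos] + shift) % 20
        return out

    # evolve every OG at every node; content only gates emission
    seqs: dict[int, list[np.ndarray]] = {
        id(tree.root): [rng.integers(20, size=L) for L in lengths]
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        seqs[id(node)] = [mutate(s, node.length) for s in seqs[id(node.parent)]]

    proteomes: dict[str, list[SequenceRecord]] = {}
    frame = content.frame
    for tip in tree.tips():
        if tip.label not in frame.index:
            continue
        records = []
        present = frame.loc[tip.label].to_numpy().nonzero()[0]
        for j in present:
            residues = AA[seqs[id(tip)][j]].tobytes().decode()
            records.append(SequenceRecord(id=f"{tip.label}|{og_ids[j]}", residues=residues))
        proteomes[tip.label] = records
    return proteomes


# ---------------------------------------------------------------------------
# MAG degradation
# ---------------------------------------------------------------------------

def degrade_to_mag(records: list[SequenceRecord], target_completeness_pct: float,
                   contaminant: list[SequenceRecord] | None,
                   contamination_pct: float, seed: int,
                   genome_id: str = "genome",
                   truth: SyntheticTruth | None = None
                   ) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Subsample a genome's records to a target completeness and inject
    contaminant records.

    Retains exactly ``round(n * pct/100)`` records chosen uniformly without
    replacement, then appends ``floor(retained * contamination_pct/100)``
    contaminant records.  The complete genome size (3 bp per residue) is
    recorded in the truth.
    """
    if not 0 < target_completeness_pct <= 100:
        raise ValueError("target_completeness_pct must be in (0, 100]")
    if not 0 <= contamination_pct < 100:
        raise ValueError("contamination_pct must be in [0, 100)")
    if contamination_pct > 0 and not contaminant:
        raise ValueError("contamination requested but no contaminant source given")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else SyntheticTruth()
    truth.true_genome_size_kbp[genome_id] = 3 * sum(len(r) for r in records) / 1000.0

    n_keep = int(round(len(records) * target_completeness_pct / 100.0))
    keep_idx = sorted(rng.choice(len(records), size=n_keep, replace=False))
    kept = [records[i] for i in keep_idx]
    n_contam = int(math.floor(n_keep * contamination_pct / 100.0))
    if n_contam > 0:
        if n_contam > len(contaminant):
            raise ValueError("contaminant source too small")
        contam_idx = sorted(rng.choice(len(contaminant), size=n_contam, replace=False))
        kept = kept + [contaminant[i] for i in contam_idx]
    return kept, truth


# ---------------------------------------------------------------------------
# Read-mapping hit tables
# ---------------------------------------------------------------------------

def simulate_read_hits(reference: list[tuple[SequenceRecord, str]],
                       lineage_abundances: dict[str, float],
                       n_reads: int, identity_mean_sd: tuple[float, float],
                       seed: int, read_length_aa: int = 100,
                       truth: SyntheticTruth | None = None
                       ) -> tuple[list[AlignmentHit], SyntheticTruth]:
    """Emit ``n_reads`` best-hit candidate rows against a labelled reference.

    Each read's source protein is drawn with probability proportional to
    abundance(lineage) x protein length (length-proportional sampling, as
    for shotgun reads over genes).  ``pident`` is Normal(mean, sd) truncated
    to [0, 100]; the bit score follows the documented affine surrogate in
    alignment length and identity.
    """
    weights = np.array(
        [lineage_abundances.get(lin, 0.0) * len(rec) for rec, lin in reference], float)
    if weights.sum() <= 0:
        raise ValueError("abundances must not all be zero")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else SyntheticTruth()
    p = weights / weights.sum()
    mean, sd = identity_mean_sd
    choices = rng.choice(len(reference), size=n_reads, p=p)
    pidents = np.clip(rng.normal(mean, sd, size=n_reads), 0.0, 100.0)
    hits = []
    for i, (ref_i, pid) in enumerate(zip(choices, pidents)):
        rec, _lineage = reference[ref_i]
        aln = min(len(rec), read_length_aa)
        read_id = f"read{i:06d}"
        hits.append(AlignmentHit(
            query_id=read_id, subject_id=rec.id, pident=round(float(pid), 2),
            aln_length=aln, mismatches=int(round(aln * (1 - pid / 100.0))),
            gapopen=0, qstart=1, qend=aln, sstart=1, send=aln,
            evalue=1e-10, bitscore=round(surrogate_bitscore(aln, float(pid)), 1)))
        truth.true_read_origin[read_id] = rec.id
    return hits, truth


# ---------------------------------------------------------------------------
# Synthetic cross-proteome hit tables (the pipeline never runs an aligner)
# ---------------------------------------------------------------------------

def all_vs_all_hits(proteomes: dict[str, list[SequenceRecord]],
                    min_pident: float = 30.0) -> list[AlignmentHit]:
    """Synthetic stand-in for an aligner's all-vs-all protein search.

    For every cross-genome protein pair, percent identity is derived from
    the edlib global (Needleman-Wunsch) edit distance over the longer
    sequence; pairs below ``min_pident`` are not reported, mimicking an
    aligner's score floor.  Bit scores use the affine surrogate.
    """
    hits: list[AlignmentHit] = []
    genomes = sorted(proteomes)
    for ga in genomes:
        for gb in genomes:
            if ga == gb:
                continue
            for a in proteomes[ga]:
                for b in proteomes[gb]:
                    aln = max(len(a), len(b))
                    dist = edlib.align(a.residues, b.residues, mode="NW")["editDistance"]
                    pident = 100.0 * (1 - dist / aln)
                    if pident < min_pident:
                        continue
                    hits.append(AlignmentHit(
                        query_id=a.id, subject_id=b.id, pident=round(pident, 2),
                        aln_length=aln, mismatches=dist, gapopen=0,
                        qstart=1, qend=len(a), sstart=1, send=len(b),
                        evalue=1e-10,
                        bitscore=round(surrogate_bitscore(aln, pident), 1)))
    return hits


# ---------------------------------------------------------------------------
# Fixture materialisation
# ---------------------------------------------------------------------------

def make_fixtures(outdir: str | Path, seed: int, n_tips: int = 8, n_ogs: int = 60,
                  rates: GainLossRates | None = None, root_prior_p1: float = 0.6,
                  mean_length_aa: int = 120, sub_rate: float = 0.05,
                  n_reads: int = 5000) -> dict[str, Path]:
    """Materialise a complete seeded demo dataset under ``outdir``.

    Writes a Yule tree, a simulated content matrix, per-taxon proteomes,
    an all-vs-all hit table, a read-mapping hit table with marker
    references, and the truth file.  Returns a name -> path manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rates = rates or GainLossRates(0.3, 0.9)
    rng = np.random.default_rng(seed)
    s_tree, s_content, s_seq, s_reads = rng.integers(2**31, size=4)

    tree = simulate_yule_tree(n_tips, 1.0, int(s_tree))
    content, truth = simulate_gene_content(tree, n_ogs, rates, root_prior_p1, int(s_content))
    proteomes = evolve_family_sequences(tree, content, mean_length_aa, sub_rate, int(s_seq))

    paths: dict[str, Path] = {}
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(tree.to_newick() + "\n")
    paths["content"] = outdir / "content.tsv"
    with open(paths["content"], "w") as fh:
        content.to_tsv(fh)
    proteome_dir = outdir / "proteomes"
    proteome_dir.mkdir(exist_ok=True)
    for taxon, records in proteomes.items():
        path = proteome_dir / f"{taxon}.faa"
        path.write_text(format_fasta(records))
        paths[f"proteome:{taxon}"] = path
    paths["hits"] = outdir / "allvall_hits.tsv"
    with open(paths["hits"], "w") as fh:
        write_hits(all_vs_all_hits(proteomes), fh)

    # single-copy marker references for abundance profiling: one focal
    # (rbcL-like) and one reference (amoA-like) lineage marker
    markers = [
        (SequenceRecord(id="focal_rbcL", residues="M" * 450), "FOCAL"),
        (SequenceRecord(id="ref_amoA", residues="M" * 250), "REF"),
    ]
    read_hits, truth = simulate_read_hits(
        markers, {"FOCAL": 0.014, "REF": 1.0}, n_reads, (95.0, 2.0),
        int(s_reads), truth=truth)
    paths["read_hits"] = outdir / "read_hits.tsv"
    with open(paths["read_hits"], "w") as fh:
        write_hits(read_hits, fh)
    paths["marker_refs"] = outdir / "marker_refs.tsv"
    with open(paths["marker_refs"], "w") as fh:
        fh.write("marker_id\tlineage\tlength_bp\n")
        for rec, lineage in markers:
            fh.write(f"{rec.id}\t{lineage}\t{3 * len(rec)}\n")
    paths["library_sizes"] = outdir / "library_sizes.tsv"
    paths["library_sizes"].write_text(f"sample_id\ttotal_reads\ndemo\t{n_reads}\n")
    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        truth.write_tsv(fh)
    return paths
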