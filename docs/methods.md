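# Methods

This note documents the models, estimators and numerical choices behind
each module, what the synthetic-data generator does and does not emulate,
and the known limitations. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Marker-based completeness and size extrapolation

A candidate marker is admitted to the working set if it is present
(copy ≥ 1) in at least `min_genomes` of the declared complete reference
genomes; with 23 thaumarchaeal references and `min_genomes = 22` this
yields the 113-marker working set used throughout. For a draft genome,

* completeness = 100 × (markers found) / |set|,
* contamination = 100 × Σ max(copies − 1, 0) / |set|,

so a duplicated marker counts once toward completeness and once per extra
copy toward contamination. Both estimates come from the *same* marker
set — one coherent estimator, rather than mixing a lineage-specific
collocated-marker workflow into the contamination column. The complete
genome size is extrapolated as

    size = bin_size × (100 − contamination) / completeness

i.e. the contaminant fraction is removed first and the remainder scaled up
by completeness. Internal values keep full precision; completeness is
reported to one decimal and sizes to the nearest kbp only at reporting
time.

Sampling error: with 113 markers in a ~1,000-gene genome, the retained
marker count after uniform subsampling is hypergeometric with a standard
deviation of roughly 4 percentage points at 75% completeness. Individual
estimates therefore scatter by several points around the target even when
the estimator is exactly unbiased; the recovery tests accordingly check
the mean signed and mean absolute error over 100 replicates (each ≤ 5
points) and the mean relative size error (≤ 10%), not each replicate in
isolation.

## Gene-content evolution model and ancestral reconstruction

Each ortholog group evolves independently as a two-state CTMC with gain
rate q01 and loss rate q10 per unit branch length (binary Mk model, "all
rates different" by default; an equal-rates restriction is available via
`equal_rates=True` / `--er` because popular implementations default to
it). The transition matrix is analytic: with q = q01 + q10,
P01(t) = (q01/q)(1 − e^{−qt}) and symmetrically for P10.

* **Likelihood** — Felsenstein pruning, vectorised across OGs, with
  per-node rescaling of partials (divide by the per-OG maximum,
  accumulate the log) so hundreds of tips do not underflow.
* **Root prior** — stationary distribution π1 = q01/(q01+q10) by default;
  a flat (0.5, 0.5) prior by flag, since published analyses often do not
  state which was used.
* **Rate fitting** — one (q01, q10) pair shared across all OGs,
  maximised by a 9×9 log-space grid over [10⁻³, 10¹] followed by
  Nelder–Mead refinement in log-rate space (function tolerance 1e-8);
  rates are clipped to [10⁻⁶, 100]. A matrix in which no OG shows both
  states yields a boundary fit with an explicit warning.
* **Marginals** — standard up–down pass: outside probabilities propagate
  the root prior down the tree, the per-node marginal is the normalised
  product of inside and outside terms. Tip marginals reproduce the
  observations exactly. Both the likelihood and the marginals are tested
  against brute-force enumeration over all internal state assignments
  (and the likelihood additionally cross-checked by hand against an
  independent pruning computation), to 1e-9/1e-10.
* **Calling and counting** — presence is called where marginal P(1)
  exceeds a threshold (default 0.5; a value exactly at the threshold
  calls absent — a documented tie rule). A branch whose parent calls 0
  and child calls 1 contributes one gain per OG, and symmetrically one
  loss. Reports are keyed by child-node label, which subsumes both
  "per-node" and "per-branch" readings.

**Ultrametricization.** Penalised-likelihood dating is a substantial
separate method; since reconstruction correctness is what matters here
(and the simulator produces clock-like trees anyway), trees are dated
deterministically by mean path lengths: each node's age is the mean path
length to its descendant tips, children older than their parent are
clamped to the parent's age, and branch lengths are rewritten as age
differences. The procedure is a fixed point on already-ultrametric trees.

**Known limitation — deep-branch event attribution.** Counting events
from called states is accurate where reconstruction is confident, but on
long, deep branches the marginal calls at both endpoints tend toward the
consensus state, so adjacent deep branches can trade event mass: one
undercounts while its neighbour overcounts, even though tree-wide totals
remain accurate to a few percent at low event rates (rate × branch length
≤ 0.1). Recovery tests therefore hold the ±15% band on tree-wide gain
and loss totals and on the median per-branch relative error (over
branches carrying ≥ 30 true events), not on every individual deep branch.
Multiple hits on one branch are invisible to any state-based count, which
is why the low-rate regime is the meaningful one.

## Orthology, AAI and nonredundant sets

Best hits take the maximal bit score, with ties broken by higher percent
identity and then lexicographically smallest subject id, so aligner
output order never matters. Ortholog groups are connected components of
the undirected RBH graph over the declared genome universe; singleton
proteins form singleton groups, and group ids are the lexicographically
smallest member, making the partition deterministic. This deliberately
replaces spectral partitioning of the RBH graph with a fully defined,
testable procedure adequate for synthetic data.

AAI is the unweighted mean percent identity over the union of both
directions' best hits — symmetric by construction; one-way means are
reported alongside because published values do not always state the
direction handling. The same operation on nucleotide ORF hit tables
yields an ANI summary (window-based ANI calculators are out of scope).

The nonredundant set uses greedy incremental clustering: sequences sorted
longest-first (ties by id); each joins the first cluster whose
representative reaches the identity threshold (default 0.9), computed
over the shorter sequence from a global alignment with unit
match/mismatch scores and affine gaps (open 10, extend 1); otherwise it
founds a cluster. Representative re-clustering is a fixed point.

## Abundance profiling

Filters are strict: bit score > 50 AND identity > 90 (the pident column
as reported by the aligner). Best-hit selection runs *after*
thresholding by default — a read whose top raw hit fails the filter can
still be counted through its next passing hit; the opposite order is
available behind a flag since published descriptions leave it
unspecified, and a test pins the difference. Library size is an explicit
input (total reads attempted), never inferred from surviving rows, so RPM
reflects sequencing depth. RPKM = 1e9 × reads / (gene length in bp ×
library size), summed per lineage across reference variants; the lineage
ratio is 100 × focal/reference RPKM, with 0-denominator cases reported
as missing rather than raised.

## Synthetic-data generator

The generator defines the study conditions for all recovery tests:

* **Trees** — pure-birth (Yule) trees, ultrametric by construction: the
  root splits immediately, each of k lineages splits at rate kλ, and the
  tree is cut one further inter-speciation interval after the n-th
  lineage appears, giving E[depth] = Σ_{k=2..n} 1/(kλ). One parameter
  suffices for recovery tests; birth–death trees are not needed.
* **Gene content** — exact stochastic simulation of the gain/loss CTMC
  per branch (state-dependent exponential waiting times), recording every
  latent node state and per-branch event count. Endpoint states and event
  counts satisfy the parity invariant (even events ⇒ equal endpoints) by
  construction, and tip frequencies match the closed-form transition
  probabilities (tested at 3 binomial SE on 20,000 OGs).
* **Sequences** — one uniform-random root protein per OG (geometric
  lengths, mean 120 aa, floored at 50 to avoid degenerate alignments),
  evolved by Poisson point substitutions; no indels, so within-family
  members stay alignable and equal-length.
* **MAG degradation** — uniform record subsampling to an exact retained
  count, with contamination modelled as whole-record injection from a
  donor genome (mirroring how binning contamination arises from foreign
  contigs).
* **Read hits** — reads drawn with probability ∝ lineage abundance ×
  protein length (length-proportional, as for shotgun reads over genes);
  identity Normal(mean, sd) truncated to [0, 100]; bit score from the
  affine surrogate 0.5 × aln_length × pident/100 + 10, documented and
  used only for its monotonicity — it is not calibrated to any scoring
  matrix.
* **Cross-proteome hit tables** — the pipeline consumes alignments as
  tabular input, so a synthetic stand-in computes percent identity from
  edlib global edit distances and emits BLAST-tabular rows above a floor.

What the generator does **not** emulate: sequencing error and read-level
nucleotide simulation, six-frame translation artifacts, indel evolution,
horizontal transfer (content changes are independent per branch), rate
variation across OGs, and compositional biases. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to every property of real ocean metagenomes.

## Problem sizes and seeds

Recovery studies use 128 tips × 4,000 OGs for rate fitting, 64 tips ×
5,000 OGs for gain/loss counting, 100 replicates for completeness
recovery, 50,000 reads per planted ratio for the abundance chain, and
200 random ≤ 6-tip instances for the enumeration cross-checks — sizes at
which the Monte-Carlo tolerances quoted above are meaningful while the
whole suite stays fast. All stochastic steps take explicit integer seeds;
the statistical assertions (3-SE bands) are run at fixed seeds and noted
as such, so they are deterministic in practice while remaining honest
Monte-Carlo checks.
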