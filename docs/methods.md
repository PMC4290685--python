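# Methods

## Patch definitions

Solvent-accessible surface areas (ASA) in the bound complex and the unbound
protein, and the relative accessibility, are inputs; the package never
computes them from coordinates.

* **Interface residue** — ASA loss upon complex formation ≥ 1.0 Å²
  (inclusive: a loss of exactly 1.0 Å² qualifies).
* **Surface residue** — unbound relative accessibility strictly > 5%.
* **Interface patch** — all interface residues of a protein.  No connectivity
  is imposed: a discontiguous binding site stays one patch.
* **Non-interface patch** — grown from a uniformly random non-interface
  surface residue by repeatedly adding the closest eligible surface residue
  in contact with the current patch, until it size-matches the interface
  patch; stalled growth restarts from a fresh seed (at most 100 restarts
  before a sampling error).  Contiguity is imposed here (and only here)
  because a scattered negative set would be trivially distinguishable by
  graph connectivity alone rather than by its attributes.
* **Centered surface patch** — a surface residue plus its k = 5 nearest
  surface residues.  "Nearest" is the minimum heavy-atom distance, the same
  metric as the contact criterion; ties break on (chain, resnum, icode).
  Neighbour candidates are restricted to surface residues so the patch stays
  on the surface rather than tunnelling through the core.

## Graphs and kernel

Two residues are in contact when their closest heavy-atom pair is within
r_a + r_b + 0.5 Å (strict inequality).  Van der Waals radii come from a
built-in element table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; 1.70 Å
fallback), overridable via the YAML config.  Patch graphs are induced on the
patch's residues; contacts to outside residues are ignored.

Contact edges carry no length, so the shortest-path transform uses **unit
edge weights**: the weight of a shortest-path edge is the hop count between
its endpoints (Floyd–Warshall; identical to BFS on an unweighted graph, and
verified against one in the tests).  Node pairs in different components get
**no edge** — the Brownian-bridge kernel has no sensible value at infinite
distance, and omitting unreachable pairs is the standard shortest-path-kernel
convention.  Consequently a graph with no edges at all has kernel 0 against
everything (logged as a warning).

Kernel parameters, exposed as `KernelParams`:

| parameter | meaning | default | origin |
|---|---|---|---|
| `gamma` | Gaussian width, 1/(2δ²), on normalized attributes | 72 | calibrated on protein–DNA interface patches; accuracy varies only ~3 points over 32–128 |
| `c` | Brownian-bridge cutoff, hop-count units | 2 | same calibration; accuracy changes < 1% for c in 1–5 |

`gamma` is exposed directly rather than δ because the calibrated quantity is
1/(2δ²).  An undirected edge has no canonical orientation, so the double sum
enumerates **both orientations of every edge in both graphs**.  This makes
K(G1, G2) = K(G2, G1) exact by construction; the uniform ×4 factor relative
to an unordered enumeration is harmless because the classifier only ever
compares K values against each other (and the voting comparison is between
equal-node-count graphs).  The kernel is computed from a precomputed
node-pair Gaussian matrix with an O(|E1|·|E2|) vectorized sum — no
approximation; a naive quadruple loop is kept in the test suite as an oracle.

## Normalization

Attributes are min–max scaled per attribute over the **pooled residues of the
training set**, not per protein: the kernel compares residues across
proteins, and per-protein scaling would make identical residues in different
proteins look different.  Negative-valued attributes (electrostatic
potential, PSSM log-odds) get no special transform — min–max covers them.
A constant attribute maps to 0; unseen values clip into [0, 1].  Application
is idempotent (a normalized protein passes through unchanged), and graph
construction refuses attributes outside [0, 1] so an unnormalized protein
cannot silently enter the kernel.  Inside cross-validation the normalizer is
refit on each fold's training proteins only.

When the structural-conservation column is absent from a feature table (no
structural neighbours exist for that protein), the reader flags PSSM-only
mode; the 20 PSSM columns can then be selected as the kernel's feature subset
(`FEATURE_GROUPS["pssm"]`, CLI `--feature-set pssm`), which retains most of
the discriminative signal.

## Voting and evaluation

One vote per training protein, granted when K(query, interface patch) is
**strictly** greater than K(query, non-interface patch); an exact kernel tie
grants no vote.  The query is labeled interface when v > |T|/2 — strict, so
with an even training count an exact half is non-interface.  Patch ranking is
by votes, ties broken lexicographically on the center residue key so top-k
lists are reproducible.  For residue-level scores each surface residue
inherits the vote count of the patch *centered* on it (the only construction
that yields exactly one score per surface residue); its ground truth is its
own interface status.

ROC curves place one point per integer vote threshold t (predict interface
iff v > t) from |T| down to 0, closing the curve at (1, 1); the trapezoid AUC
over that grid equals the Mann–Whitney rank statistic of the scores,
mid-ranking ties (asserted against an independent rank-based computation).
P_random for a protein is N/N_all over all centered surface patches, where N
counts patches with at least as many interface residues as the top-1 patch
(inclusive, so P_random ≥ 1/N_all).  Top-k prediction takes the union of the
top-k patches' residues; coverage = TP/N_int, accuracy = TP/N_pr.

Leave-one-out cross-validation is at **protein level**: the held-out
protein's own patch pair is excluded from its training set, and the
normalizer is refit per fold.  The sampled non-interface patch of each
protein is seeded from a CRC32 hash of (run seed, protein id), so every
evaluation is deterministic given its seed *and* invariant to the order
proteins are listed in.

## Synthetic data

The generator produces the inputs the predictor consumes, with a single
class-difficulty dial, and makes no claim of physical realism:

* **Geometry** — a self-avoiding random walk with 3.8 Å steps (the Cα
  virtual-bond length) and a 3.0 Å clash floor, with each step biased toward
  the running centroid (bias weight 0.8).  The bias collapses the chain into
  a globule with many non-consecutive contacts, which keeps the surface
  contact graph well connected — an extended coil would fragment once the
  interface cluster is removed and contiguous non-interface patches of
  interface size would not exist.  One carbon-like atom per residue by
  default (`atoms_per_residue` adds 1.5 Å satellite atoms for contact-rule
  stress tests).
* **Labels** — a contact-contiguous cluster of ⌈0.2·n⌉ residues is the
  interface.  Of the 26 attributes, 8 (chosen once per dataset) are
  informative: interface residues draw them from mean 0.4 + `separation`,
  everything else from mean 0.4, all with Gaussian noise (sd 0.15 by
  default) and clipped to [0, 1].  This mimics real feature tables, where a
  few attributes (PSSM, electrostatics) carry most of the signal and the
  rest are near-uninformative.
* **Accessibility** — interface residues lose ≥ 1.5 Å² of ASA, non-interface
  residues less than 0.5 Å²; 10% of non-interface residues are buried
  (rel_acc < 5%), all others exposed, so ≥ 90% of residues are surface and
  the interface is entirely on the surface.

Default conditions: 20 proteins × 60 residues, separation 1.0, noise
sd 0.15.  At these settings leave-one-out patch classification is expected
at its ceiling (the informative attributes differ by ~7σ between classes),
and at separation 0 it collapses to coin-flipping; the acceptance script
computes both, plus the residue-level AUC and ranked-patch statistics, at
exactly these sizes.  What passing these checks shows is that the kernel,
voting and evaluation machinery are correct and well calibrated — not that
the method attains any particular accuracy on real protein–DNA complexes,
whose feature distributions are far less clean.

## Numerical and design notes

* Floyd–Warshall is run on the dense hop-count adjacency via
  `scipy.sparse.csgraph`; patch graphs are small (≤ a few dozen nodes), so
  no sparse machinery is needed.
* With γ = 72, node-kernel values underflow to 0 below ‖x−y‖² ≈ 10⁻²·⁵ of
  separation; this is harmless since only comparisons of K matter.
* Altloc records resolve to the highest-occupancy conformer (first-listed on
  ties); hydrogens, deuteriums, waters and non-amino-acid hetero groups are
  dropped on reading.
* PSSM columns follow the standard PSI-BLAST order
  (A R N D C Q E G H I L K M F P S T W Y V).
* Empty insertion codes are written as `-` in feature tables so every TSV
  cell is non-empty.

## Limitations

* Shortest-path distances are hop counts, not physical Å path lengths; two
  patches with the same topology but different geometric extent compare as
  identical up to their labels.
* The voting score is an integer in 0..|T| and is not a calibrated
  probability.
* The interface patch may be disconnected, in which case its shortest-path
  graph simply has no edges between components; extremely fragmented
  interfaces lose cross-fragment information.
* Feature quality is inherited entirely from the supplied table; the package
  performs no structure-based feature computation.
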