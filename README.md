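# patchkernel

Graph-kernel prediction of DNA-binding sites on protein structures.

## The problem

Many proteins bind DNA through a localized surface patch, and knowing which
residues form that patch is central to understanding transcription, repair and
genome organisation.  Most structure-based predictors flatten the physico-
chemical properties of a surface patch into a feature *vector*, which discards
how those properties are arranged in space — yet the spatial arrangement of,
say, a conserved positive ridge is exactly what makes a patch a binding site.

`patchkernel` keeps the geometry.  A surface patch is encoded as a **labeled
residue-contact graph**: one node per residue carrying a 26-dimensional
attribute vector (relative solvent accessibility, electrostatic potential,
sequence entropy, surface curvature, pocket size, structural conservation, and
the 20 PSSM log-odds columns), with an edge between residues whose closest
heavy atoms approach within the sum of their van der Waals radii plus 0.5 Å.
Patches are compared with a **shortest-path graph kernel** and classified by a
size-matched **voting strategy**.

## The method

Each contact graph G is first transformed into its shortest-path graph S:
same nodes, one edge per connected node pair, weighted by the hop-count
distance in G (Floyd–Warshall).  Two patches are compared by summing an edge
kernel over all pairs of shortest-path edges,

    K(G1, G2) = Σ_{e1 ∈ E1} Σ_{e2 ∈ E2} k_edge(e1, e2)
    k_edge(e1, e2) = k_node(v1, v2) · k_weight(e1, e2) · k_node(w1, w2)

with a Gaussian node kernel `k_node(v, w) = exp(−γ‖labels(v) − labels(w)‖²)`
(γ = 72 by default) and a Brownian-bridge weight kernel
`k_weight = max(0, c − |w1 − w2|)` (c = 2), so edges score highly when both
endpoints carry similar attributes *and* the edges have similar lengths.

Raw kernel values grow with graph size, so a query patch G is never compared
across differently sized training patches.  Instead each training protein
contributes a size-matched pair — its *interface patch* (all residues losing
≥ 1 Å² of solvent-accessible surface area upon DNA binding) and a contiguous
random *non-interface patch* of the same residue count — and votes for
"interface" whenever `K(G, G_int) > K(G, G_non-int)`.  G is predicted to be an
interface patch when v > |T|/2.  For whole-protein prediction, every surface
residue (relative accessibility > 5%) seeds a 6-residue *centered patch*
(itself plus its 5 nearest surface neighbours); ranking patches by votes
localizes the binding site, and per-residue scores yield an ROC.

Feature computation (NACCESS, Delphi, PSI-BLAST, …) is out of scope: features
arrive as a TSV table and are min–max normalized to [0, 1] over the training
set.  A bundled generator emits fully synthetic proteins — compact
self-avoiding backbone walks with a contiguous interface cluster and a
tunable attribute separation between classes — so the entire pipeline is
testable without external data.

## Worked example

```sh
patchkernel synth --n-proteins 8 --n-res 50 --separation 1.0 --seed 7 --out-dir demo/
patchkernel evaluate --dataset-dir demo/ --mode loocv --seed 17 --out metrics.json
```

prints

```
{
  "accuracy": 1.0,
  "mode": "loocv",
  "sensitivity": 1.0,
  "specificity": 1.0
}
```

— under leave-one-protein-out cross-validation all 8 interface and all 8
non-interface patches are classified correctly (at full attribute separation
the two classes are essentially disjoint, so the voting ceiling is expected).
Scoring one protein's surface against the other proteins as training set:

```sh
patchkernel predict --query-pdb demo/synth000.pdb --query-features demo/synth000.tsv \
    --train-dir demo/ --seed 17 --out preds.tsv
head -4 preds.tsv
```

```
center	votes	total	label	rank
A1	8	8	interface	1
A2	8	8	interface	2
A3	8	8	interface	3
```

Each row is one centered surface patch: `votes` of the 8 training proteins
found it more similar to their interface patch than to their non-interface
patch; patches are ranked so the top rows point at the predicted binding
site.  `patchkernel patches`, `patchkernel graph` and `patchkernel kernel`
expose the intermediate objects (patch lists, shortest-path graphs as JSON,
and single kernel values); all commands accept `--gamma/--c` or a YAML
`--config` with a radius-table override.

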