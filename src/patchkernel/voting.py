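"""Size-matched voting classification of patches.

The raw graph-kernel value grows with graph size, so comparing K(G, G_x) and
K(G, G_y) across differently sized G_x, G_y is meaningless.  The voting
strategy sidesteps this: every training protein contributes one
interface/non-interface patch pair of identical node count, the query is
compared against both members of each pair, and each pair votes for whichever
member is more similar.  The query is predicted to be an interface patch when
it collects strictly more than half of the possible votes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import PatchKernelError
from .graphs import ShortestPathGraph
from .kernel import KernelParams, graph_kernel
from .patches import INTERFACE, NON_INTERFACE, Patch


@dataclass(frozen=True)
class TrainingPair:
    """One training protein's size-matched interface/non-interface graphs."""

    protein_id: str
    interface_graph: ShortestPathGraph
    noninterface_graph: ShortestPathGraph

    def __post_init__(self) -> None:
        if self.interface_graph.n_nodes != self.noninterface_graph.n_nodes:
            raise ValueError(
                f"{self.protein_id}: training pair graphs are not size-matched "
                f"({self.interface_graph.n_nodes} vs "
                f"{self.noninterface_graph.n_nodes} nodes)"
            )


@dataclass(frozen=True)
class VoteResult:
    """Votes for "query is an interface patch" out of ``total`` training pairs."""

    votes: int
    total: int
    label: str
    per_pair: tuple[tuple[str, float, float], ...]  # (protein_id, K_int, K_non)


def vote(query_graph: ShortestPathGraph,
         training_pairs: Sequence[TrainingPair],
         params: KernelParams = KernelParams()) -> VoteResult:
    """Compare the query with every training pair; one vote per pair where
    K(query, interface) strictly exceeds K(query, non-interface)."""
    if not training_pairs:
        raise PatchKernelError("voting requires at least one training pair")
    per_pair = []
    votes = 0
    for pair in training_pairs:
        k_int = graph_kernel(query_graph, pair.interface_graph, params)
        k_non = graph_kernel(query_graph, pair.noninterface_graph, params)
        if k_int > k_non:
            votes += 1
        per_pair.append((pair.protein_id, k_int, k_non))
    total = len(training_pairs)
    label = INTERFACE if votes * 2 > total else NON_INTERFACE
    return VoteResult(votes=votes, total=total, label=label,
                      per_pair=tuple(per_pair))


def classify_at_threshold(vote_result: VoteResult, threshold: float) -> str:
    """Interface iff votes strictly exceed ``threshold`` (default rule uses
    threshold = total/2)."""
    if not 0 <= threshold <= vote_result.total:
        raise PatchKernelError(
            f"threshold {threshold} outside [0, {vote_result.total}]"
        )
    return INTERFACE if vote_result.votes > threshold else NON_INTERFACE


def rank_patches(patch_graphs: Sequence[tuple[Patch, ShortestPathGraph]],
                 training_pairs: Sequence[TrainingPair],
                 params: KernelParams = KernelParams(),
                 ) -> list[tuple[Patch, int]]:
    """Vote every patch and sort by votes, descending; ties break on the
    center residue key (then the residue-key tuple) so ranking is
    deterministic and independent of input order."""
    scored = []
    for patch, graph in patch_graphs:
        result = vote(graph, training_pairs, params)
        scored.append((patch, result.votes))
    scored.sort(key=lambda pv: (-pv[1],
                                pv[0].center if pv[0].center is not None else (),
                                pv[0].residue_keys))
    return scored
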