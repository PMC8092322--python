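"""Anticodon-switch detection by closest-nonequal-neighbor analysis.

A tRNA gene whose nearest distinct neighbor in the pool decodes a different
amino acid is a candidate anticodon switch: its body still belongs to the
neighbor's family while its anticodon delivers another amino acid.  Pairwise
similarity is exact global edit distance (unit costs), a deterministic and
parameter-free replacement for heuristic read-aligner matching.  Per-family
neighbor-joining trees under a Jukes-Cantor model, with column-resampling
bootstrap, support phylogenetic inspection of candidate events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .genetics import GeneticCode, STANDARD_CODE, TRNAGene, locate_anticodon


class NoNeighborError(ValueError):
    """Every pool sequence is identical to the query."""


@dataclass(frozen=True)
class SwitchEvent:
    """A gene paired with its closest nonequal neighbor.

    ``switched`` is true when the gene's decoded amino acid differs from the
    neighbor's: the gene sits inside another amino acid's sequence family.
    The header-annotated amino acid is carried alongside the decoded one so
    header/sequence disagreements stay visible.
    """

    gene_id: str
    neighbor_id: str
    distance: int
    annotated_aa: Optional[str]
    decoded_aa: str
    neighbor_aa: str
    switched: bool


def edit_distance(a: str, b: str, band: Optional[int] = None) -> int:
    """Global (Needleman-Wunsch) edit distance with unit costs.

    ``band`` caps the explored diagonal band (edlib's k); distances above the
    band are reported as band + 1, which preserves nearest-neighbor ordering
    whenever the true nearest distance is within the band.
    """
    if not a:
        return len(b)
    if not b:
        return len(a)
    k = -1 if band is None else band
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    d = res["editDistance"]
    return band + 1 if d == -1 else d


def closest_nonequal_neighbor(
    gene: TRNAGene,
    pool: Sequence[TRNAGene],
    code: GeneticCode = STANDARD_CODE,
    band: Optional[int] = None,
) -> SwitchEvent:
    """Find the pool member nearest to ``gene`` among those with a different
    sequence, and compare decoded amino acids.

    Identical duplicate gene copies are excluded ("nonequal" at the sequence
    level).  Distance ties are broken by lexicographically smallest gene_id.
    """
    best: Optional[tuple[int, str, TRNAGene]] = None
    for other in pool:
        if other.sequence == gene.sequence:
            continue
        d = edit_distance(gene.sequence, other.sequence, band=band)
        key = (d, other.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (d, other.gene_id, other)
    if best is None:
        raise NoNeighborError(f"{gene.gene_id}: no nonequal sequence in pool")
    d, _, neighbor = best
    my_aa = locate_anticodon(gene, code).decoded_aa
    nb_aa = locate_anticodon(neighbor, code).decoded_aa
    return SwitchEvent(
        gene_id=gene.gene_id,
        neighbor_id=neighbor.gene_id,
        distance=d,
        annotated_aa=gene.annotated_isotype,
        decoded_aa=my_aa,
        neighbor_aa=nb_aa,
        switched=my_aa != nb_aa,
    )


def count_switches(
    pool: Sequence[TRNAGene],
    code: GeneticCode = STANDARD_CODE,
    band: Optional[int] = None,
) -> tuple[int, list[SwitchEvent]]:
    """One SwitchEvent per pool gene; returns (number switched, events)."""
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 genes")
    events = [
        closest_nonequal_neighbor(g, pool, code=code, band=band) for g in pool
    ]
    return sum(e.switched for e in events), events


def deduplicated_switch_pairs(events: Iterable[SwitchEvent]) -> set[frozenset]:
    """Unordered (gene, neighbor) pairs among switched events."""
    return {
        frozenset((e.gene_id, e.neighbor_id)) for e in events if e.switched
    }


# --- distances and trees -----------------------------------------------------

JC_SATURATION_CAP = 5.0


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned sequences."""
    if len(a) != len(b):
        raise ValueError("p-distance needs aligned equal-length sequences")
    if not a:
        return 0.0
    return sum(x != y for x, y in zip(a, b)) / len(a)


def jc_distance(p: float, cap: float = JC_SATURATION_CAP) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); saturates at ``cap``.

    p >= 0.75 lies outside the model's domain (more differences than the
    stationary expectation) and is reported as the cap.
    """
    if p < 0:
        raise ValueError("p must be nonnegative")
    if p >= 0.75:
        return cap
    d = -0.75 * math.log1p(-4.0 * p / 3.0)
    return min(d, cap)


def jc_distance_matrix(
    ids: Sequence[str], seqs: Sequence[str], cap: float = JC_SATURATION_CAP
) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(p_distance(seqs[i], seqs[j]), cap)
    return DistanceMatrix(d, list(ids))


def nj_tree(matrix: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted tree with nonnegative branches.

    Negative branch-length estimates (possible on non-additive inputs) are
    clamped to zero when ``clamp_negative`` is set.
    """
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(matrix, neg_as_zero=clamp_negative)


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Nontrivial bipartitions of ``taxa``, each as its smaller/canonical side."""
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    ids: Sequence[str],
    aligned_seqs: Sequence[str],
    n_replicates: int = 100,
    seed: int = 0,
    cap: float = JC_SATURATION_CAP,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for NJ bipartitions.

    Columns are resampled with replacement ``n_replicates`` times; support
    for each bipartition of the full-alignment NJ tree is the fraction of
    replicate trees containing it.  Deterministic under ``seed``.
    """
    if n_replicates == 0:
        return {}
    taxa = frozenset(ids)
    ref_tree = nj_tree(jc_distance_matrix(ids, aligned_seqs, cap))
    ref_bip = _bipartitions(ref_tree, taxa)
    counts = {b: 0 for b in ref_bip}
    rng = np.random.default_rng(seed)
    length = len(aligned_seqs[0])
    for _ in range(n_replicates):
        pick = rng.integers(0, length, size=length)
        rep = ["".join(s[p] for p in pick) for s in aligned_seqs]
        rep_tree = nj_tree(jc_distance_matrix(ids, rep, cap))
        for b in _bipartitions(rep_tree, taxa):
            if b in counts:
                counts[b] += 1
    return {b: c / n_replicates for b, c in counts.items()}
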