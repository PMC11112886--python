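"""Self-contained distance-tree construction with bootstrap supports.

Classical neighbor joining (Saitou-Nei agglomeration with the Q
criterion) plus a nonparametric bootstrap over alignment columns, so the
tree-based discrimination method runs without external phylogenetics
tools. Externally inferred ML trees remain first-class inputs elsewhere;
this module only guarantees *a* supported tree.

Supports are bipartition frequencies: each internal edge of the tree
built from the full alignment is scored by the percentage of replicate
trees (columns resampled with replacement, matrix and NJ rebuilt) that
contain the same unrooted split. Everything is deterministic given the
seed. Replicates whose K2P matrix saturates fall back to raw differences
for that replicate; the count of such fallbacks is recorded on the
returned tree (``bootstrap_fallbacks``).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix, matrix_from_codes
from .errors import AlignmentError, SaturationError
from .io_model import LabeledAlignment, SupportTree
from .treedisc import bipartitions


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0
    model: str = "K2P"

    def __post_init__(self):
        if self.replicates < 1:
            raise AlignmentError("replicates must be >= 1")


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Unrooted NJ tree (supports absent) from a finite distance matrix.

    Negative branch lengths are clamped to 0 with the remainder shifted to
    the sibling edge, preserving the pair's summed length. Ties in the Q
    criterion break on the first (row-major) minimal pair, so the result
    is deterministic.
    """
    D = np.array(dm.values, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise AlignmentError("neighbor joining needs >= 3 samples")
    if not np.isfinite(D).all():
        i, j = np.argwhere(~np.isfinite(D))[0]
        raise AlignmentError(
            f"non-finite distance between {dm.sample_ids[i]!r} and {dm.sample_ids[j]!r}"
        )
    taxa = dendropy.TaxonNamespace(list(dm.sample_ids))
    nodes = [
        dendropy.Node(taxon=taxa.get_taxon(sid)) for sid in dm.sample_ids
    ]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = li
        nodes[aj].edge.length = lj
        # distances from the new node to every other active node
        new_d = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D[ai, :] = new_d
        D[:, ai] = new_d
        D[ai, ai] = 0.0
        nodes[ai] = parent
        active.pop(j)
    # final three-point resolution
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = dendropy.Node()
    for k, lk in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = lk
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    for nd in tree:
        nd.support = None
    return SupportTree(tree)


def _resampled_matrix(
    codes: np.ndarray,
    sample_ids: list[str],
    weights: np.ndarray,
    model: str,
) -> tuple[DistanceMatrix, bool]:
    """Weighted-column distance matrix; K2P saturation falls back to raw."""
    try:
        return matrix_from_codes(codes, sample_ids, model, weights=weights), False
    except SaturationError:
        if model == "K2P":
            return (
                matrix_from_codes(codes, sample_ids, "raw_differences", weights=weights),
                True,
            )
        raise


def bootstrap_tree(aln: LabeledAlignment, cfg: BootstrapConfig) -> SupportTree:
    """NJ tree from the full alignment with bootstrap supports.

    Column patterns are compressed to unique site patterns once, so each
    replicate only reweights patterns (a multinomial draw) instead of
    materialising a resampled alignment.
    """
    codes = aln.codes
    L = codes.shape[1]
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    base, base_fell_back = _resampled_matrix(
        patterns, aln.sample_ids, counts.astype(float), cfg.model
    )
    tree = neighbor_joining(base)
    edge_splits = bipartitions(tree)
    freq = dict.fromkeys(edge_splits, 0)
    rng = np.random.default_rng(cfg.seed)
    probs = counts / L
    n_fallback = 0
    for _ in range(cfg.replicates):
        w = rng.multinomial(L, probs).astype(float)
        rep_dm, fell_back = _resampled_matrix(patterns, aln.sample_ids, w, cfg.model)
        n_fallback += int(fell_back)
        rep_splits = bipartitions(neighbor_joining(rep_dm))
        for key in freq:
            if key in rep_splits:
                freq[key] += 1
    ref = min(aln.sample_ids)
    leaves = frozenset(aln.sample_ids)
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        key = side if ref not in side else leaves - side
        nd.support = 100.0 * freq[key] / cfg.replicates
    tree.bootstrap_fallbacks = n_fallback + int(base_fell_back)
    tree.bootstrap_seed = cfg.seed
    tree.bootstrap_replicates = cfg.replicates
    return tree
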