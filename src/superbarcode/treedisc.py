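"""Tree-based species discrimination and two-tree conflict statistics.

The discrimination criterion: after contracting every internal edge whose
bootstrap support is below a threshold (default 50) to a polytomy, a
species with multiple sampled individuals is successfully identified iff
some edge of the tree separates exactly its individuals from every other
leaf. The support reported for a success is the support of that edge.

Monophyly is bipartition-based, so verdicts are stable under rerooting;
when an outgroup is supplied its leaves are pruned before the scan so the
criterion reads "split from all other ingroup leaves".

Cytonuclear (or any two-tree) conflict is summarised as bipartition
statistics: shared bipartitions, Robinson-Foulds distance on the
support-collapsed trees, and the list of well-supported (>= threshold)
bipartitions of one tree that are incompatible with well-supported
bipartitions of the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import TreeError
from .io_model import SampleRecord, SupportTree
from .seqstats import round_half_up

SUPPORT_THRESHOLD = 50.0


# ---------------------------------------------------------------------------
# bipartition machinery
# ---------------------------------------------------------------------------

def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _canonical(side: frozenset, all_leaves: frozenset, ref: str) -> frozenset:
    """Encode a split by the side NOT containing the reference leaf."""
    return all_leaves - side if ref in side else side


def bipartitions(
    tree: SupportTree, include_trivial: bool = False
) -> dict[frozenset, float | None]:
    """Canonical nontrivial splits of an (unrooted) tree with their supports.

    Keys are the split side not containing the lexicographically smallest
    leaf. With ``include_trivial`` pendant (single-leaf) splits are kept too.
    """
    leaves = frozenset(tree.leaf_labels())
    ref = min(leaves)
    out: dict[frozenset, float | None] = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = _leafset(nd)
        if not include_trivial and (len(side) < 2 or len(side) > len(leaves) - 2):
            continue
        if len(side) < 1 or len(side) > len(leaves) - 1:
            continue
        key = _canonical(side, leaves, ref)
        sup = getattr(nd, "support", None)
        if key in out:
            if sup is not None and (out[key] is None or sup > out[key]):
                out[key] = sup
        else:
            out[key] = sup
    return out


def _compatible(a: frozenset, b: frozenset, leaves: frozenset) -> bool:
    """Two splits are compatible iff one of the four intersections is empty."""
    return (
        not (a & b)
        or not (a - b)
        or not (b - a)
        or not (leaves - a - b)
    )


# ---------------------------------------------------------------------------
# support collapse
# ---------------------------------------------------------------------------

def collapse_low_support(
    tree: SupportTree, threshold: float = SUPPORT_THRESHOLD
) -> SupportTree:
    """Contract every internal edge with support below the threshold.

    Missing supports count as below threshold (a warning is emitted once).
    Edges with support >= threshold are untouched. Returns a new tree.
    """
    out = tree.clone()
    targets = []
    saw_missing = False
    for nd in out.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        sup = getattr(nd, "support", None)
        if sup is None:
            saw_missing = True
            targets.append(nd)
        elif sup < threshold:
            targets.append(nd)
    if saw_missing:
        warnings.warn("internal edges without support treated as below threshold")
    for nd in targets:
        nd.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# monophyly and resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyVerdict:
    species: str
    monophyletic: bool
    support: float | None  # present only for successes
    n_individuals: int


def monophyly_test(
    tree: SupportTree,
    samples: list[SampleRecord],
    outgroup: list[str] | None = None,
    support_threshold: float = SUPPORT_THRESHOLD,
    collapse: bool = True,
) -> list[MonophylyVerdict]:
    """Per-species discrimination verdicts for multi-individual species.

    The tree's leaf set must contain every study sample; extra leaves are
    allowed (they count as "other" unless listed in ``outgroup``, in which
    case they are pruned first).
    """
    by_species: dict[str, list[str]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s.sample_id)
    leaves = set(tree.leaf_labels())
    missing = sorted(i for ids in by_species.values() for i in ids if i not in leaves)
    if missing:
        raise TreeError(f"samples missing from tree: {', '.join(missing)}")
    work = collapse_low_support(tree, support_threshold) if collapse else tree.clone()
    if outgroup:
        keep = [lf for lf in work.leaf_labels() if lf not in set(outgroup)]
        if len(keep) < 2:
            raise TreeError("pruning the outgroup leaves fewer than 2 leaves")
        work.tree.retain_taxa_with_labels(keep)
    # exact side -> support of the clade-adjacent edge; when the tree is
    # rooted both root-child edges appear with their own supports, so a
    # species clade reports its own edge rather than its complement's
    side_support: dict[frozenset, float | None] = {}
    for nd in work.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side_support.setdefault(_leafset(nd), getattr(nd, "support", None))
    all_leaves = frozenset(work.leaf_labels())
    verdicts = []
    for sp in sorted(by_species):
        ids = by_species[sp]
        if len(ids) < 2:
            continue
        want = frozenset(ids)
        if want in side_support:
            verdicts.append(MonophylyVerdict(sp, True, side_support[want], len(ids)))
        elif (all_leaves - want) in side_support:
            verdicts.append(
                MonophylyVerdict(sp, True, side_support[all_leaves - want], len(ids))
            )
        else:
            verdicts.append(MonophylyVerdict(sp, False, None, len(ids)))
    return verdicts


def resolution(verdicts: list[MonophylyVerdict]) -> float:
    """Percentage of successfully discriminated species, half-up to 2 dp."""
    if not verdicts:
        raise TreeError("no verdicts to summarise")
    return round_half_up(100.0 * sum(v.monophyletic for v in verdicts) / len(verdicts))


def compare_datasets(
    verdicts_a: list[MonophylyVerdict], verdicts_b: list[MonophylyVerdict]
) -> tuple[list[str], list[str], list[tuple[str, float | None, float | None]]]:
    """Species gained/lost by dataset A relative to dataset B.

    ``gained``: monophyletic in A but not B; ``lost``: the converse;
    ``support_shift``: (species, support_a, support_b) for shared successes.
    """
    a = {v.species: v for v in verdicts_a}
    b = {v.species: v for v in verdicts_b}
    if set(a) != set(b):
        diff = sorted(set(a).symmetric_difference(b))
        raise TreeError(f"species universes differ: {', '.join(diff)}")
    gained = sorted(sp for sp in a if a[sp].monophyletic and not b[sp].monophyletic)
    lost = sorted(sp for sp in a if b[sp].monophyletic and not a[sp].monophyletic)
    shift = [
        (sp, a[sp].support, b[sp].support)
        for sp in sorted(a)
        if a[sp].monophyletic and b[sp].monophyletic
    ]
    return gained, lost, shift


SUPPORT_BINS = ("=100", "[90,100)", "[65,90)", "<65")


def support_summary(
    verdicts: list[MonophylyVerdict],
) -> tuple[dict[str, int], list[float]]:
    """Histogram of supports among successes: bins =100, [90,100), [65,90), <65."""
    sups = sorted(
        (v.support for v in verdicts if v.monophyletic and v.support is not None),
        reverse=True,
    )
    hist = dict.fromkeys(SUPPORT_BINS, 0)
    for s in sups:
        if s == 100:
            hist["=100"] += 1
        elif s >= 90:
            hist["[90,100)"] += 1
        elif s >= 65:
            hist["[65,90)"] += 1
        else:
            hist["<65"] += 1
    return hist, sups


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def _dominant_section_clades(
    tree: SupportTree, samples: list[SampleRecord]
) -> dict[str, frozenset]:
    """Per section, the maximal section-pure clade holding the most members.

    A clade here is a bipartition side (unrooted semantics); "pure" means
    every leaf in it belongs to the section. Sections whose members are
    fully scattered still get their largest pure clade (possibly one leaf).
    """
    leaves = frozenset(tree.leaf_labels())
    section_of = {s.sample_id: s.section for s in samples if s.sample_id in leaves}
    sides: list[frozenset] = [frozenset([lf]) for lf in leaves]
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = _leafset(nd)
        sides.append(side)
        sides.append(leaves - side)
    best: dict[str, frozenset] = {}
    for side in sides:
        secs = {section_of.get(lf) for lf in side}
        if len(secs) != 1:
            continue
        (sec,) = secs
        if sec is None:
            continue
        if sec not in best or len(side) > len(best[sec]) or (
            len(side) == len(best[sec]) and sorted(side) < sorted(best[sec])
        ):
            best[sec] = side
    return best


def select_representatives(
    tree: SupportTree, samples: list[SampleRecord]
) -> dict[str, str]:
    """One representative sample per species.

    Rules, in order: (1) singleton species and monophyletic species keep a
    sample as-is; (2) among candidates, samples of "own" provenance are
    preferred over downloaded ones; (3) individuals placed outside their
    section's dominant clade (strays) are excluded. Ties break on
    lexicographic sample id. A species whose every individual is a stray is
    flagged (warning) and keeps its first sample by id.
    """
    leaves = set(tree.leaf_labels())
    missing = sorted(s.sample_id for s in samples if s.sample_id not in leaves)
    if missing:
        raise TreeError(f"samples missing from tree: {', '.join(missing)}")
    dominant = _dominant_section_clades(tree, samples)
    by_species: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)
    chosen: dict[str, str] = {}
    for sp in sorted(by_species):
        recs = sorted(by_species[sp], key=lambda r: r.sample_id)
        if len(recs) == 1:
            chosen[sp] = recs[0].sample_id
            continue
        in_section = [
            r
            for r in recs
            if not r.section or r.sample_id in dominant.get(r.section, frozenset())
        ]
        if not in_section:
            warnings.warn(
                f"species {sp!r}: every individual is a stray from its section; "
                "keeping the first by id"
            )
            in_section = recs
        own = [r for r in in_section if r.provenance == "own"]
        pool = own or in_section
        chosen[sp] = min(r.sample_id for r in pool)
    return chosen


# ---------------------------------------------------------------------------
# two-tree comparison
# ---------------------------------------------------------------------------

@dataclass
class TreeComparison:
    level: str
    shared_bipartitions: int
    conflicting_bipartitions: list[tuple[tuple[str, ...], float | None, float | None]]
    rf_distance: int
    pruned: list[str]  # leaves/groups excluded from the comparison


def _relabel_to_level(
    tree: SupportTree, samples: list[SampleRecord], level: str
) -> tuple[SupportTree, set[str], set[str]]:
    """Collapse monophyletic groups to single leaves named after the group.

    Returns (tree over group names, retained groups, excluded groups).
    Groups not monophyletic in the tree are excluded (pruned) rather than
    forced into a placement.
    """
    key = {"species": lambda s: s.species, "section": lambda s: s.section}[level]
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(key(s), []).append(s.sample_id)
    work = tree.clone()
    leaves = set(work.leaf_labels())
    splits = None
    retained, excluded = set(), set()
    keep_leaf: dict[str, str] = {}
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    splits = bipartitions(work, include_trivial=True)
    for g, ids in groups.items():
        ids_in = [i for i in ids if i in leaves]
        if not ids_in or not g:
            excluded.add(g or "<unlabeled>")
            continue
        if len(ids_in) == 1 or _canonical(frozenset(ids_in), all_leaves, ref) in splits:
            retained.add(g)
            keep_leaf[g] = min(ids_in)
        else:
            excluded.add(g)
    work.tree.retain_taxa_with_labels(sorted(keep_leaf.values()))
    # fresh taxa: clone(depth=1) shares Taxon objects with the source tree,
    # so relabeling in place would corrupt the caller's tree
    import dendropy

    rep_to_group = {rep: g for g, rep in keep_leaf.items()}
    ns = dendropy.TaxonNamespace()
    for lf in work.tree.leaf_node_iter():
        lf.taxon = ns.new_taxon(rep_to_group[lf.taxon.label])
    work.tree.taxon_namespace = ns
    return work, retained, excluded


def compare_trees(
    tree_a: SupportTree,
    tree_b: SupportTree,
    at: str = "sample",
    samples: list[SampleRecord] | None = None,
    support_threshold: float = SUPPORT_THRESHOLD,
) -> TreeComparison:
    """Bipartition conflict statistics between two trees.

    At ``sample`` level leaves are compared as-is; at ``species`` or
    ``section`` level multi-member groups are collapsed to one leaf where
    monophyletic in *both* trees and excluded (reported) otherwise.
    Conflicts are pairs of incompatible bipartitions each supported at
    >= ``support_threshold`` in its own tree; the RF distance is computed on
    the support-collapsed trees.
    """
    pruned: list[str] = []
    a, b = tree_a, tree_b
    if at != "sample":
        if samples is None:
            raise TreeError(f"comparison at {at!r} level needs sample records")
        a, keep_a, excl_a = _relabel_to_level(tree_a, samples, at)
        b, keep_b, excl_b = _relabel_to_level(tree_b, samples, at)
        shared_groups = keep_a & keep_b
        pruned.extend(sorted((keep_a | keep_b | excl_a | excl_b) - shared_groups))
        a.tree.retain_taxa_with_labels(sorted(shared_groups))
        b.tree.retain_taxa_with_labels(sorted(shared_groups))
        a, b = SupportTree(a.tree), SupportTree(b.tree)
    else:
        la, lb = set(a.leaf_labels()), set(b.leaf_labels())
        shared = la & lb
        pruned.extend(sorted(la.symmetric_difference(lb)))
        if shared != la or shared != lb:
            a, b = a.clone(), b.clone()
            a.tree.retain_taxa_with_labels(sorted(shared))
            b.tree.retain_taxa_with_labels(sorted(shared))
    if len(a.leaf_labels()) < 4:
        raise TreeError("fewer than 4 shared leaves; comparison undefined")

    leaves = frozenset(a.leaf_labels())
    splits_a = bipartitions(a)
    splits_b = bipartitions(b)
    shared_splits = len(set(splits_a) & set(splits_b))

    strong_a = {k: v for k, v in splits_a.items() if v is not None and v >= support_threshold}
    strong_b = {k: v for k, v in splits_b.items() if v is not None and v >= support_threshold}
    conflicts = []
    for ka, va in sorted(strong_a.items(), key=lambda kv: sorted(kv[0])):
        for kb, vb in sorted(strong_b.items(), key=lambda kv: sorted(kv[0])):
            if not _compatible(ka, kb, leaves):
                # describe the conflict by the smaller side of A's split
                desc = min(
                    (tuple(sorted(ka)), tuple(sorted(leaves - ka))),
                    key=lambda s: (len(s), s),
                )
                conflicts.append((desc, va, vb))

    ca = collapse_low_support(a, support_threshold)
    cb = collapse_low_support(b, support_threshold)
    sa, sb = set(bipartitions(ca)), set(bipartitions(cb))
    rf = len(sa - sb) + len(sb - sa)
    return TreeComparison(
        level=at,
        shared_bipartitions=shared_splits,
        conflicting_bipartitions=conflicts,
        rf_distance=rf,
        pruned=pruned,
    )
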