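"""Shared fixtures and independent brute-force oracles.

The oracle functions re-derive each statistic with plain Python loops and
no shared code with the implementation, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from superbarcode import LabeledAlignment, SampleRecord


def make_aln(
    rows: list[str],
    species: list[str] | None = None,
    ids: list[str] | None = None,
    sections: list[str] | None = None,
    provenance: list[str] | None = None,
    name: str = "toy",
) -> LabeledAlignment:
    n = len(rows)
    species = species or [f"sp{i}" for i in range(n)]
    ids = ids or [f"s{i}" for i in range(n)]
    sections = sections or [""] * n
    provenance = provenance or ["own"] * n
    samples = [
        SampleRecord(i, sp, sec, prov)
        for i, sp, sec, prov in zip(ids, species, sections, provenance)
    ]
    return LabeledAlignment(
        name=name, samples=samples, matrix=np.array([list(r) for r in rows])
    )


def random_aln(rng, n_rows: int, n_cols: int, gap_frac: float = 0.05) -> LabeledAlignment:
    """Random alignment over ACGT with sprinkled gaps and Ns."""
    chars = np.array(list("ACGT"))
    mat = chars[rng.integers(0, 4, size=(n_rows, n_cols))]
    mask = rng.random((n_rows, n_cols)) < gap_frac
    mat[mask] = np.where(rng.random(mask.sum()) < 0.5, "-", "N")
    rows = ["".join(r) for r in mat]
    return make_aln(rows)


def related_aln(
    rng, n_rows: int, n_cols: int, mut: float = 0.08, gap_frac: float = 0.0,
    species: list[str] | None = None,
) -> LabeledAlignment:
    """Rows mutated from one ancestral sequence; divergence stays far from
    K2P saturation so corrected distances are defined for every pair."""
    chars = np.array(list("ACGT"))
    base = chars[rng.integers(0, 4, size=n_cols)]
    mat = np.tile(base, (n_rows, 1))
    for i in range(n_rows):
        hit = rng.random(n_cols) < mut
        mat[i, hit] = chars[rng.integers(0, 4, size=int(hit.sum()))]
    if gap_frac:
        mask = rng.random((n_rows, n_cols)) < gap_frac
        mat[mask] = np.where(rng.random(mask.sum()) < 0.5, "-", "N")
    return make_aln(["".join(r) for r in mat], species=species)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

BASES = set("ACGT")
PURINES = set("AG")


def oracle_site_classes(rows: list[str]) -> tuple[int, int]:
    n_var = n_pi = 0
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c in BASES:
                counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pi += 1
    return n_var, n_pi


def oracle_haplotypes(rows: list[str]) -> int:
    keep = [
        i for i in range(len(rows[0])) if all(r[i] in BASES for r in rows)
    ]
    if not keep:
        return 1
    return len({"".join(r[i] for i in keep) for r in rows})


def oracle_k2p(a: str, b: str) -> float:
    comp = ts = tv = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            comp += 1
            if x != y:
                if (x in PURINES) == (y in PURINES):
                    ts += 1
                else:
                    tv += 1
    p, q = ts / comp, tv / comp
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def oracle_raw_diff(a: str, b: str) -> int:
    return sum(
        1 for x, y in zip(a, b) if x in BASES and y in BASES and x != y
    )


def oracle_pi(rows: list[str]) -> float:
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            comp = diff = 0
            for x, y in zip(rows[i], rows[j]):
                if x in BASES and y in BASES:
                    comp += 1
                    diff += x != y
            if comp:
                vals.append(diff / comp)
    return sum(vals) / len(vals)


def oracle_gap_verdicts(dist: dict[tuple[str, str], float], species_of: dict[str, str]):
    """Barcoding-gap verdict per multi-individual species by exhaustive scan."""
    by_sp: dict[str, list[str]] = {}
    for sid, sp in species_of.items():
        by_sp.setdefault(sp, []).append(sid)

    def d(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    out = {}
    for sp, ids in by_sp.items():
        if len(ids) < 2:
            continue
        intra = max(d(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :])
        inter = min(
            d(a, b) for a in ids for b in species_of if species_of[b] != sp
        )
        out[sp] = inter > intra
    return out


def random_additive_tree(rng, n_taxa: int):
    """Random binary tree with positive branch lengths.

    Returns (labels, patristic distance matrix, set of nontrivial splits in
    canonical encoding), for NJ consistency checks.
    """
    import dendropy

    from superbarcode import SupportTree
    from superbarcode.treedisc import bipartitions

    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [dendropy.Node(taxon=dendropy.Taxon(label=l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        p = dendropy.Node()
        p.add_child(a)
        p.add_child(b)
        a.edge.length = float(rng.uniform(0.05, 1.0))
        b.edge.length = float(rng.uniform(0.05, 1.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [p]
    ns = dendropy.TaxonNamespace([nd.taxon for nd in nodes[0].leaf_iter()])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(n_taxa):
            if x != y:
                D[x, y] = pdm.patristic_distance(
                    ns.get_taxon(labels[x]), ns.get_taxon(labels[y])
                )
    splits = set(bipartitions(SupportTree(tree)))
    return labels, D, splits


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
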