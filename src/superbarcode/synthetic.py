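"""Synthetic study generator: labeled alignments, trees, and ground truth.

Emulates the sampling design of a genus-level super-barcoding study — by
default 55 species / 83 samples with 21 multi-individual (2-4) species
grouped into 13 sections — together with the two failure modes that break
barcodes in practice:

* **chloroplast capture**: a hybridization event replaces one sample's
  plastid haplotype with a near-copy of another species' haplotype, so the
  recipient species loses its barcoding gap and monophyly on plastid
  markers while nuclear markers are untouched;
* **ILS-style haplotype sharing**: a pair of species shares an identical
  haplotype, planting a zero-distance species pair.

Sequences evolve along a pure-birth (Yule) species tree under a two-rate
(transition/transversion) substitution model — the same model family the
K2P distance estimator assumes, so estimator consistency is directly
testable. Branch lengths are in expected substitutions per site:
between-species divergence ~ tree path length x ``interspecific_scale``,
within-species divergence ~ ``intraspecific_scale``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import AlignmentError
from .io_model import (
    LabeledAlignment,
    SampleRecord,
    SupportTree,
    write_alignment,
    write_sample_map,
    write_tree,
)


@dataclass(frozen=True)
class CaptureEvent:
    donor_species: str
    recipient_sample: str
    markers: tuple[str, ...]  # marker names whose haplotype is captured


@dataclass(frozen=True)
class IlsPair:
    species_a: str
    species_b: str
    fraction: float = 0.5  # fraction of b's individuals carrying a's haplotype
    markers: tuple[str, ...] | None = None  # None = all markers


def _default_individuals() -> list[int]:
    # 21 multi-individual species (16 x 2 + 3 x 3 + 2 x 4 = 49 samples)
    # plus 34 singletons: 83 samples of 55 species.
    return [2] * 16 + [3] * 3 + [4] * 2 + [1] * 34


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of one synthetic study; defaults mirror the emulated design."""

    n_species: int = 55
    individuals_per_species: tuple[int, ...] = field(
        default_factory=lambda: tuple(_default_individuals())
    )
    marker_names: tuple[str, ...] = ("plastome", "nrdna", "its")
    marker_lengths: tuple[int, ...] = (20000, 4000, 700)
    marker_kinds: tuple[str, ...] = ("plastid", "nuclear", "nuclear")
    marker_rate_multipliers: tuple[float, ...] = (1.0, 1.0, 3.0)
    interspecific_scale: float = 0.05  # expected subs/site per unit tree path
    intraspecific_scale: float = 0.002  # expected pairwise divergence within species
    ts_tv_ratio: float = 1.5  # P/Q rate-class ratio (kappa / 2)
    gc: float = 0.5  # equilibrium G+C fraction
    n_sections: int = 13
    capture_events: tuple[CaptureEvent, ...] = ()
    ils_pairs: tuple[IlsPair, ...] = ()
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.marker_lengths)

    def __post_init__(self):
        if self.n_species < 2:
            raise AlignmentError("need >= 2 species")
        if len(self.individuals_per_species) != self.n_species:
            raise AlignmentError(
                f"individuals_per_species has {len(self.individuals_per_species)} entries "
                f"for {self.n_species} species"
            )
        if not (
            len(self.marker_names)
            == len(self.marker_lengths)
            == len(self.marker_kinds)
            == len(self.marker_rate_multipliers)
        ):
            raise AlignmentError("marker_* tuples must have equal lengths")
        if self.intraspecific_scale >= self.interspecific_scale:
            warnings.warn(
                "intraspecific_scale >= interspecific_scale: outside the default "
                "regime, species may be indistinguishable"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    species_tree: SupportTree
    gene_trees: dict[str, SupportTree]
    haplotype_origin: dict[tuple[str, str], str]  # (marker, sample_id) -> species
    expected_plastid_failures: set[str]
    expected_nuclear_failures: set[str]


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int, seed: int, min_wait: float = 0.01, min_divergence: float = 0.2
) -> SupportTree:
    """Pure-birth (Yule) tree scaled to unit root depth, deterministic per seed.

    ``min_wait`` floors every inter-event waiting time and
    ``min_divergence`` guarantees the youngest split sits at least that
    fraction of the total depth before the present. Together they make the
    configured inter/intra scale ratio a *realized* divergence ratio for
    every species pair: species that are effectively indistinguishable are
    planted explicitly through the ILS/capture knobs, never produced as a
    side effect of vanishing branch lengths.
    """
    if n_species < 2:
        raise AlignmentError("need >= 2 species")
    if not (0 <= min_divergence < 1):
        raise AlignmentError("min_divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += max(rng.exponential(1.0 / len(active)), min_wait)
        k = int(rng.integers(len(active)))
        node, birth = active.pop(k)
        node.edge.length = t - birth
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.extend([(a, t), (b, t)])
    T = t + max(rng.exponential(1.0 / n_species), min_wait)
    if t > 0:
        T = max(T, t / (1.0 - min_divergence))
    width = len(str(n_species))
    taxa = dendropy.TaxonNamespace()
    for node, birth in active:
        node.edge.length = T - birth
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    # name leaves in traversal order and rescale to unit depth
    idx = 0
    for lf in tree.leaf_node_iter():
        idx += 1
        lf.taxon = taxa.new_taxon(f"sp{idx:0{width}d}")
    for nd in tree:
        if nd.edge.length is not None:
            nd.edge.length /= T
        nd.support = None
    tree.is_rooted = True
    return SupportTree(tree)


def assign_sections(tree: SupportTree, n_sections: int) -> dict[str, str]:
    """Species -> section labels by cutting the tree at its earliest splits.

    The n_sections - 1 shallowest internal nodes (the root included) are
    removed conceptually; each remaining maximal subtree is one section, so
    sections are clades by construction.
    """
    t = tree.tree
    internal = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
    depth: dict[int, float] = {}
    for nd in t.preorder_node_iter():
        parent = nd.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (nd.edge.length or 0.0)
        depth[id(nd)] = d
    # the k shallowest internal nodes are ancestor-closed (contain the root);
    # removing them leaves k + 1 subtrees = sections
    n_cut = min(max(n_sections, 1), len(internal) + 1) - 1
    cut = {
        id(nd)
        for nd in sorted(internal, key=lambda nd: (depth[id(nd)], id(nd)))[:n_cut]
    }
    # section roots: nodes whose parent is in the cut set but are not cut themselves
    roots = []
    for nd in t.preorder_node_iter():
        parent = nd.parent_node
        if id(nd) in cut:
            continue
        if parent is None or id(parent) in cut:
            roots.append(nd)
    width = len(str(len(roots)))
    mapping: dict[str, str] = {}
    for i, r in enumerate(sorted(roots, key=lambda nd: min(lf.taxon.label for lf in nd.leaf_iter()))):
        for lf in r.leaf_iter():
            mapping[lf.taxon.label] = f"sect{i + 1:0{width}d}"
    return mapping


def scenario_samples(cfg: ScenarioConfig, tree: SupportTree) -> list[SampleRecord]:
    """Sample records for a scenario: per-species individual counts spread
    deterministically (seeded permutation) over the species of the tree."""
    species = sorted(tree.leaf_labels())
    rng = np.random.default_rng([cfg.seed, 777])
    counts = np.array(cfg.individuals_per_species)[rng.permutation(cfg.n_species)]
    sections = assign_sections(tree, cfg.n_sections)
    records = []
    for sp, k in zip(species, counts):
        for j in range(int(k)):
            records.append(
                SampleRecord(
                    sample_id=f"{sp}_{j + 1}",
                    species=sp,
                    section=sections.get(sp, ""),
                    provenance="own",
                )
            )
    return records


# ---------------------------------------------------------------------------
# sequence evolution (two-rate ts/tv model, K2P-matched)
# ---------------------------------------------------------------------------

def _k2p_probs(d: float, ts_tv_ratio: float) -> tuple[float, float]:
    """(p_transition, p_each_transversion) after expected distance d."""
    beta = 1.0 / (2.0 * (ts_tv_ratio + 1.0))
    alpha = ts_tv_ratio / (ts_tv_ratio + 1.0)
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv_each)


def _evolve_seq(parent: np.ndarray, d: float, ts_tv_ratio: float, rng) -> np.ndarray:
    """One branch of length d (expected subs/site) under the two-rate model."""
    if d <= 0:
        return parent.copy()
    p_ts, p_tv = _k2p_probs(d, ts_tv_ratio)
    u = rng.random(parent.shape[0])
    child = parent.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    child[ts_mask] = parent[ts_mask] ^ 2  # A<->G, C<->T
    child[tv1_mask] = parent[tv1_mask] ^ 1
    child[tv2_mask] = parent[tv2_mask] ^ 3
    return child


_BASES = np.array(list("ACGT"), dtype="U1")


def evolve_marker(
    species_tree: SupportTree, cfg: ScenarioConfig, marker_index: int
) -> LabeledAlignment:
    """Simulate one marker's alignment for every sample of the scenario."""
    if not (0 <= marker_index < cfg.n_markers):
        raise AlignmentError(f"marker_index {marker_index} out of range")
    L = cfg.marker_lengths[marker_index]
    scale = cfg.interspecific_scale * cfg.marker_rate_multipliers[marker_index]
    rng = np.random.default_rng([cfg.seed, marker_index])
    freqs = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    root_seq = rng.choice(4, size=L, p=freqs).astype(np.int8)
    seqs: dict[int, np.ndarray] = {id(species_tree.tree.seed_node): root_seq}
    species_seq: dict[str, np.ndarray] = {}
    for nd in species_tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        d = (nd.edge.length or 0.0) * scale
        seqs[id(nd)] = _evolve_seq(seqs[id(nd.parent_node)], d, cfg.ts_tv_ratio, rng)
        if nd.is_leaf():
            species_seq[nd.taxon.label] = seqs[id(nd)]
    records = scenario_samples(cfg, species_tree)
    half_intra = cfg.intraspecific_scale / 2.0 * cfg.marker_rate_multipliers[marker_index]
    rows = []
    for rec in records:
        rows.append(
            _evolve_seq(species_seq[rec.species], half_intra, cfg.ts_tv_ratio, rng)
        )
    matrix = _BASES[np.vstack(rows)]
    return LabeledAlignment(
        name=cfg.marker_names[marker_index], samples=records, matrix=matrix
    )


# ---------------------------------------------------------------------------
# planted failure modes
# ---------------------------------------------------------------------------

def _copy_alignments(alignments: list[LabeledAlignment]) -> list[LabeledAlignment]:
    return [
        LabeledAlignment(a.name, list(a.samples), a.matrix.copy(), list(a.blocks))
        for a in alignments
    ]


def _donor_row(aln: LabeledAlignment, species: str) -> int:
    candidates = sorted(
        i for i, s in enumerate(aln.samples) if s.species == species
    )
    if not candidates:
        raise AlignmentError(f"donor species {species!r} not in alignment {aln.name!r}")
    return candidates[0]


def apply_capture(
    alignments: list[LabeledAlignment], cfg: ScenarioConfig
) -> list[LabeledAlignment]:
    """Plant the configured chloroplast-capture events.

    For each event the recipient sample's rows on the captured markers are
    replaced by a near-copy (intraspecific-scale perturbation) of the donor
    species' first haplotype. Deterministic per (seed, event, marker) and
    idempotent: re-running replaces the row with the same bytes.
    """
    out = _copy_alignments(alignments)
    by_name = {a.name: a for a in out}
    from .io_model import _CODE

    for ev_idx, ev in enumerate(cfg.capture_events):
        for marker in ev.markers:
            if marker not in by_name:
                raise AlignmentError(f"capture event names unknown marker {marker!r}")
            aln = by_name[marker]
            try:
                r = aln.sample_ids.index(ev.recipient_sample)
            except ValueError:
                raise AlignmentError(
                    f"capture recipient {ev.recipient_sample!r} not in {marker!r}"
                ) from None
            rec = aln.samples[r]
            n_conspecific = sum(s.species == rec.species for s in aln.samples)
            if n_conspecific < 2:
                warnings.warn(
                    f"capture recipient {ev.recipient_sample!r} belongs to singleton "
                    f"species {rec.species!r}; discrimination tests will not see it"
                )
            donor = _donor_row(aln, ev.donor_species)
            donor_codes = _CODE[
                np.ascontiguousarray(aln.matrix[donor]).view(np.uint32).astype(np.uint8)
            ]
            m_idx = list(cfg.marker_names).index(marker)
            rng = np.random.default_rng([cfg.seed, 10_000 + ev_idx, m_idx])
            captured = _evolve_seq(
                donor_codes, cfg.intraspecific_scale / 2.0, cfg.ts_tv_ratio, rng
            )
            aln.matrix[r] = _BASES[captured]
            if hasattr(aln, "_codes"):
                del aln._codes
    return out


def apply_ils(
    alignments: list[LabeledAlignment], cfg: ScenarioConfig
) -> list[LabeledAlignment]:
    """Plant ILS-style identical haplotype sharing.

    For each pair (a, b, fraction) the first ceil(fraction * n_b)
    individuals of species b (by sample id) receive an exact copy of
    species a's first haplotype on the designated markers, guaranteeing a
    zero-distance species pair.
    """
    out = _copy_alignments(alignments)
    by_name = {a.name: a for a in out}
    for pair in cfg.ils_pairs:
        markers = pair.markers or tuple(by_name)
        for marker in markers:
            if marker not in by_name:
                raise AlignmentError(f"ILS pair names unknown marker {marker!r}")
            aln = by_name[marker]
            donor = _donor_row(aln, pair.species_a)
            b_rows = sorted(
                (s.sample_id, i)
                for i, s in enumerate(aln.samples)
                if s.species == pair.species_b
            )
            if not b_rows:
                raise AlignmentError(f"ILS species {pair.species_b!r} not in {marker!r}")
            k = max(1, int(np.ceil(pair.fraction * len(b_rows))))
            for _, i in b_rows[:k]:
                aln.matrix[i] = aln.matrix[donor]
            if hasattr(aln, "_codes"):
                del aln._codes
    return out


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def build_ground_truth(
    cfg: ScenarioConfig, tree: SupportTree, records: list[SampleRecord]
) -> GroundTruth:
    origin = {
        (m, r.sample_id): r.species for m in cfg.marker_names for r in records
    }
    counts: dict[str, int] = {}
    for r in records:
        counts[r.species] = counts.get(r.species, 0) + 1
    multi = {sp for sp, n in counts.items() if n >= 2}
    plastid = {m for m, k in zip(cfg.marker_names, cfg.marker_kinds) if k == "plastid"}
    fail_p: set[str] = set()
    fail_n: set[str] = set()
    by_id = {r.sample_id: r for r in records}
    for ev in cfg.capture_events:
        sp = by_id[ev.recipient_sample].species
        for m in ev.markers:
            origin[(m, ev.recipient_sample)] = ev.donor_species
            (fail_p if m in plastid else fail_n).add(sp)
    for pair in cfg.ils_pairs:
        markers = pair.markers or cfg.marker_names
        b_ids = sorted(r.sample_id for r in records if r.species == pair.species_b)
        k = max(1, int(np.ceil(pair.fraction * len(b_ids)))) if b_ids else 0
        for m in markers:
            for sid in b_ids[:k]:
                origin[(m, sid)] = pair.species_a
            if pair.species_b in multi:
                (fail_p if m in plastid else fail_n).add(pair.species_b)
    return GroundTruth(
        species_tree=tree,
        gene_trees={m: tree for m in cfg.marker_names},
        haplotype_origin=origin,
        expected_plastid_failures=fail_p,
        expected_nuclear_failures=fail_n,
    )


def load_scenario_config(path) -> ScenarioConfig:
    """Read a ScenarioConfig from a flat TOML file.

    Scalar keys mirror the dataclass fields; ``capture_events`` and
    ``ils_pairs`` are arrays of tables.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    events = tuple(
        CaptureEvent(
            donor_species=e["donor_species"],
            recipient_sample=e["recipient_sample"],
            markers=tuple(e["markers"]),
        )
        for e in raw.pop("capture_events", [])
    )
    pairs = tuple(
        IlsPair(
            species_a=p["species_a"],
            species_b=p["species_b"],
            fraction=p.get("fraction", 0.5),
            markers=tuple(p["markers"]) if "markers" in p else None,
        )
        for p in raw.pop("ils_pairs", [])
    )
    for key in (
        "individuals_per_species",
        "marker_names",
        "marker_lengths",
        "marker_kinds",
        "marker_rate_multipliers",
    ):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ScenarioConfig(capture_events=events, ils_pairs=pairs, **raw)


def emit_scenario(
    cfg: ScenarioConfig, out_dir: str | None = None
) -> tuple[dict[str, LabeledAlignment], list[SampleRecord], GroundTruth]:
    """Generate the full scenario; optionally write it to disk.

    Writes one aligned FASTA per marker, ``map.tsv``, the species tree as
    newick and the ground truth as TSV/JSON when ``out_dir`` is given.
    """
    tree = simulate_species_tree(cfg.n_species, cfg.seed)
    alignments = [evolve_marker(tree, cfg, i) for i in range(cfg.n_markers)]
    alignments = apply_ils(alignments, cfg)
    alignments = apply_capture(alignments, cfg)
    records = alignments[0].samples
    truth = build_ground_truth(cfg, tree, records)
    by_name = {a.name: a for a in alignments}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for a in alignments:
            write_alignment(a, os.path.join(out_dir, f"{a.name}.fasta"))
        write_sample_map(records, os.path.join(out_dir, "map.tsv"))
        write_tree(truth.species_tree, os.path.join(out_dir, "species_tree.nwk"))
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(
                {
                    "expected_plastid_failures": sorted(truth.expected_plastid_failures),
                    "expected_nuclear_failures": sorted(truth.expected_nuclear_failures),
                    "haplotype_origin": {
                        f"{m}:{s}": sp
                        for (m, s), sp in sorted(truth.haplotype_origin.items())
                        if sp != next(r.species for r in records if r.sample_id == s)
                    },
                },
                fh,
                indent=1,
            )
    return by_name, records, truth
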