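"""Pairwise distances and distance-based species discrimination.

Implements the Kimura 2-parameter (K2P) corrected distance and raw
difference counts over a labeled alignment, the per-species barcoding-gap
test (a species with multiple individuals is successfully identified when
its minimum interspecific distance strictly exceeds its maximum
intraspecific distance), and three dataset-level summary statistics used
to compare barcoding datasets:

``zero_k2p``
    number of multi-individual species whose minimum interspecific K2P
    distance is exactly zero (they necessarily fail the gap test);
``zero_k2p_all_pairs``
    number of unordered species pairs — over *all* species, singletons
    included — whose minimum between-species K2P distance is zero;
``AMID``
    the average (and range) of each multi-individual species' minimum
    interspecific raw difference count, a measure of how much
    interspecific variation a dataset offers.

Distances use pairwise deletion by default: each pair of rows is compared
over the columns where both carry an unambiguous base (A/C/G/T). IUPAC
ambiguity codes are excluded entirely; there is no fractional matching.
K2P saturation (a non-positive logarithm argument) raises
:class:`~superbarcode.errors.SaturationError` naming the offending pair
rather than clamping to infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import AlignmentError, SaturationError
from .io_model import DiscriminationReport, LabeledAlignment, SampleRecord
from .seqstats import round_half_up

_MODELS = ("K2P", "raw_differences")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix over samples, tagged with its model."""

    sample_ids: list[str]
    values: np.ndarray
    model: str  # "K2P" | "raw_differences"
    deletion: str = "pairwise"  # "pairwise" | "complete"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise AlignmentError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.model not in _MODELS:
            raise AlignmentError(f"unknown model {self.model!r}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise AlignmentError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style export."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.sample_ids)}\n")
            for i, sid in enumerate(self.sample_ids):
                row = "\t".join(f"{self.values[i, j]:.8g}" for j in range(i))
                fh.write(f"{sid}\t{row}\n" if row else f"{sid}\n")


# ---------------------------------------------------------------------------
# pair counting (shared by K2P, raw differences and nucleotide diversity)
# ---------------------------------------------------------------------------

def pair_counts(
    codes: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair (comparable, transition, transversion) counts via one-hot products.

    ``codes`` is the int8-encoded alignment (n x L, -1 for gap/ambiguity);
    optional ``weights`` are non-negative per-column multiplicities (used by
    the bootstrap). Returns three (n, n) float arrays.
    """
    onehot = [(codes == b) for b in range(4)]
    if weights is None:
        left = [x.astype(np.float64) for x in onehot]
    else:
        w = np.asarray(weights, dtype=np.float64)
        left = [x * w for x in onehot]
    right = [x.astype(np.float64).T for x in onehot]
    a, c, g, t = left
    at, ct, gt, tt = right
    comparable = (a + c + g + t) @ (at + ct + gt + tt)
    ts = a @ gt + g @ at + c @ tt + t @ ct
    matches = a @ at + c @ ct + g @ gt + t @ tt
    tv = comparable - matches - ts
    return comparable, ts, tv


def _k2p_from_counts(comparable: float, ts: float, tv: float) -> float:
    if comparable <= 0:
        raise SaturationError("no comparable columns between the sequences")
    p = ts / comparable
    q = tv / comparable
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(
            f"K2P distance undefined (saturation: P={p:.4g}, Q={q:.4g})"
        )
    return -0.5 * np.log(a1) - 0.25 * np.log(a2)


def _encode(seq) -> np.ndarray:
    from .io_model import _CODE, _normalize_seq

    if isinstance(seq, str):
        arr = _normalize_seq(seq, "<seq>")
    else:
        arr = np.asarray(seq, dtype="U1")
    return _CODE[np.ascontiguousarray(arr).view(np.uint32).astype(np.uint8)]


def k2p_distance(seq_a, seq_b) -> float:
    """K2P distance between two aligned rows (strings or char arrays).

    With P and Q the transition (A<->G, C<->T) and transversion proportions
    over columns where both rows are unambiguous:
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    ca, cb = _encode(seq_a), _encode(seq_b)
    if ca.shape != cb.shape:
        raise AlignmentError("sequences must come from one alignment (equal length)")
    both = (ca >= 0) & (cb >= 0)
    comparable = int(both.sum())
    if comparable == 0:
        raise SaturationError("no comparable columns between the sequences")
    diff = both & (ca != cb)
    ts = int((diff & ((ca ^ cb) == 2)).sum())  # A<->G, C<->T differ by XOR 2
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(comparable, ts, tv)


def raw_differences(seq_a, seq_b) -> int:
    """Number of differing comparable columns between two aligned rows."""
    ca, cb = _encode(seq_a), _encode(seq_b)
    both = (ca >= 0) & (cb >= 0)
    return int((both & (ca != cb)).sum())


def matrix_from_codes(
    codes: np.ndarray,
    sample_ids: list[str],
    model: str = "K2P",
    deletion: str = "pairwise",
    weights: np.ndarray | None = None,
) -> DistanceMatrix:
    """Distance matrix from an int8-encoded alignment (bootstrap entry point)."""
    if model not in _MODELS:
        raise AlignmentError(f"unknown model {model!r}")
    if deletion not in ("pairwise", "complete"):
        raise AlignmentError(f"unknown deletion mode {deletion!r}")
    n = codes.shape[0]
    if n < 2:
        raise AlignmentError("distance matrix needs >= 2 sequences")
    if deletion == "complete":
        keep = (codes >= 0).all(axis=0)
        codes = codes[:, keep]
        if weights is not None:
            weights = np.asarray(weights)[keep]
    comparable, ts, tv = pair_counts(codes, weights)
    off = ~np.eye(n, dtype=bool)
    if (comparable[off] <= 0).any():
        i, j = np.argwhere(off & (comparable <= 0))[0]
        raise SaturationError(
            f"no comparable columns between {sample_ids[i]!r} and {sample_ids[j]!r}",
            pair=(sample_ids[i], sample_ids[j]),
        )
    if model == "raw_differences":
        values = ts + tv
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(list(sample_ids), values, model, deletion)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ts / comparable
        q = tv / comparable
        a1 = 1.0 - 2.0 * p - q
        a2 = 1.0 - 2.0 * q
        bad = off & ((a1 <= 0) | (a2 <= 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SaturationError(
                f"K2P saturation between {sample_ids[i]!r} and {sample_ids[j]!r} "
                f"(P={p[i, j]:.4g}, Q={q[i, j]:.4g})",
                pair=(sample_ids[i], sample_ids[j]),
            )
        values = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(sample_ids), values, model, deletion)


def distance_matrix(
    aln: LabeledAlignment, model: str = "K2P", deletion: str = "pairwise"
) -> DistanceMatrix:
    """Pairwise K2P or raw-difference matrix over all samples of an alignment."""
    return matrix_from_codes(aln.codes, aln.sample_ids, model, deletion)


# ---------------------------------------------------------------------------
# species-level discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesDistanceSummary:
    """Barcoding-gap verdict for one multi-individual species."""

    species: str
    n_individuals: int
    max_intra: float
    min_inter: float
    nearest_other: str
    has_gap: bool


def _species_blocks(dm: DistanceMatrix, samples: list[SampleRecord]) -> dict[str, np.ndarray]:
    by_id = {s.sample_id: s for s in samples}
    missing = [i for i in dm.sample_ids if i not in by_id]
    if missing:
        raise AlignmentError(f"samples not in map: {', '.join(missing)}")
    species = np.array([by_id[i].species for i in dm.sample_ids])
    return {sp: np.flatnonzero(species == sp) for sp in dict.fromkeys(species)}


def barcoding_gaps(
    dm: DistanceMatrix, samples: list[SampleRecord]
) -> list[SpeciesDistanceSummary]:
    """Gap verdict per multi-individual species.

    Singleton species are never evaluated but do participate as potential
    nearest neighbors. A tie (min_inter == max_intra) is a failure: the gap
    must be strict.
    """
    blocks = _species_blocks(dm, samples)
    by_id = {s.sample_id: s for s in samples}
    species_order = np.array([by_id[i].species for i in dm.sample_ids])
    out: list[SpeciesDistanceSummary] = []
    for sp in sorted(blocks):
        idx = blocks[sp]
        if len(idx) < 2:
            continue
        intra = dm.values[np.ix_(idx, idx)]
        max_intra = float(intra.max())
        other = np.setdiff1d(np.arange(len(dm.sample_ids)), idx)
        inter = dm.values[np.ix_(idx, other)]
        k = int(np.argmin(inter))
        min_inter = float(inter.flat[k])
        nearest = str(species_order[other[k % len(other)]])
        out.append(
            SpeciesDistanceSummary(
                species=sp,
                n_individuals=len(idx),
                max_intra=max_intra,
                min_inter=min_inter,
                nearest_other=nearest,
                has_gap=min_inter > max_intra,
            )
        )
    if not out:
        warnings.warn("no species with >= 2 individuals; nothing to evaluate")
    return out


def zero_k2p_stats(dm: DistanceMatrix, samples: list[SampleRecord]) -> tuple[int, int]:
    """(zero_k2p, zero_k2p_all_pairs) over a K2P matrix.

    ``zero_k2p``: multi-individual species whose minimum interspecific
    distance is exactly 0. ``zero_k2p_all_pairs``: unordered species pairs
    (all species, singletons included) whose minimum between-species
    distance is 0.
    """
    if dm.model != "K2P":
        raise AlignmentError("zero-K2P statistics are defined on a K2P matrix")
    blocks = _species_blocks(dm, samples)
    zero_multi = 0
    for sp, idx in blocks.items():
        if len(idx) < 2:
            continue
        other = np.setdiff1d(np.arange(len(dm.sample_ids)), idx)
        if dm.values[np.ix_(idx, other)].min() == 0.0:
            zero_multi += 1
    names = sorted(blocks)
    zero_pairs = 0
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if dm.values[np.ix_(blocks[a], blocks[b])].min() == 0.0:
                zero_pairs += 1
    return zero_multi, zero_pairs


def amid(dm_raw: DistanceMatrix, samples: list[SampleRecord]) -> tuple[float, float, float]:
    """Average (and range) of minimum interspecific differences.

    For each multi-individual species take its minimum interspecific raw
    difference count; return (mean, min, max) over those species.
    """
    if dm_raw.model != "raw_differences":
        raise AlignmentError("AMID is defined on a raw-differences matrix")
    blocks = _species_blocks(dm_raw, samples)
    minima = []
    for sp, idx in blocks.items():
        if len(idx) < 2:
            continue
        other = np.setdiff1d(np.arange(len(dm_raw.sample_ids)), idx)
        minima.append(float(dm_raw.values[np.ix_(idx, other)].min()))
    if not minima:
        raise AlignmentError("AMID needs at least one multi-individual species")
    return float(np.mean(minima)), float(min(minima)), float(max(minima))


def evaluate_distance(
    aln: LabeledAlignment, deletion: str = "pairwise"
) -> DiscriminationReport:
    """Full distance-based report for one dataset.

    Builds the K2P matrix for the gap test and zero-distance statistics and
    the raw-difference matrix for AMID.
    """
    dm_k2p = distance_matrix(aln, "K2P", deletion)
    dm_raw = distance_matrix(aln, "raw_differences", deletion)
    gaps = barcoding_gaps(dm_k2p, aln.samples)
    z_multi, z_pairs = zero_k2p_stats(dm_k2p, aln.samples)
    rows = pd.DataFrame(
        [
            {
                "species": g.species,
                "n_individuals": g.n_individuals,
                "success": g.has_gap,
                "support": np.nan,
                "max_intra": g.max_intra,
                "min_inter": g.min_inter,
                "nearest_other": g.nearest_other,
            }
            for g in gaps
        ],
        columns=[
            "species",
            "n_individuals",
            "success",
            "support",
            "max_intra",
            "min_inter",
            "nearest_other",
        ],
    )
    summary: dict = {
        "n_assessed": len(gaps),
        "n_success": int(sum(g.has_gap for g in gaps)),
        "zero_k2p": z_multi,
        "zero_k2p_all_pairs": z_pairs,
    }
    summary["resolution_pct"] = (
        round_half_up(100.0 * summary["n_success"] / summary["n_assessed"])
        if gaps
        else float("nan")
    )
    try:
        mean, lo, hi = amid(dm_raw, aln.samples)
        summary.update(amid_mean=mean, amid_min=lo, amid_max=hi)
    except AlignmentError:
        summary.update(amid_mean=float("nan"), amid_min=float("nan"), amid_max=float("nan"))
    return DiscriminationReport(dataset=aln.name, method="distance", rows=rows, summary=summary)


def resolution_vs_zero_k2p(reports) -> tuple[float, float, float]:
    """OLS of resolution percentage on the zero-K2P species count.

    ``reports`` is a sequence of DiscriminationReports (distance method) or
    (resolution_pct, zero_k2p) pairs. Returns (slope, Pearson r, two-sided p).
    """
    pts = []
    for r in reports:
        if isinstance(r, DiscriminationReport):
            pts.append((float(r.summary["zero_k2p"]), float(r.summary["resolution_pct"])))
        else:
            res, zk = r
            pts.append((float(zk), float(res)))
    if len(pts) < 3:
        raise AlignmentError("regression needs >= 3 datasets")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise AlignmentError("zero variance in the zero-K2P predictor")
    if np.ptp(y) == 0:
        return 0.0, 0.0, 1.0
    fit = _sps.linregress(x, y)
    return float(fit.slope), float(fit.rvalue), float(fit.pvalue)
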