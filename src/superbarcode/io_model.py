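"""Shared data model and readers/writers.

The pipeline consumes species-labeled multiple sequence alignments. A
:class:`LabeledAlignment` couples an aligned character matrix (rows =
samples) with a :class:`SampleRecord` per row giving the species (and
optionally taxonomic section and provenance) of each sample. Trees with
bootstrap supports are wrapped in :class:`SupportTree` around a dendropy
tree, and per-dataset discrimination results live in
:class:`DiscriminationReport`.

Conventions
-----------
* Sequences are uppercase-normalized on input; ``U`` becomes ``T`` and the
  gap dialects ``.`` / ``?`` become ``-``. IUPAC ambiguity codes are kept
  verbatim in the matrix; downstream statistics decide their treatment.
* Columns are 0-based half-open internally; user-facing TSV output is
  1-based inclusive.
* Newick support labels in either the ``)87:`` or ``)0.87:`` dialect are
  accepted; if every support in a tree is <= 1 they are rescaled to the
  0-100 scale.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, TreeError

# int8 encoding used by every numeric routine: unambiguous bases 0-3,
# anything else (gap or IUPAC ambiguity) is -1 and excluded from
# comparable columns.
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i

GAP = "-"
AMBIGUITY_CODES = set("RYSWKMBDHVN")
VALID_CHARS = set("ACGT-") | AMBIGUITY_CODES


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual: id, species label, optional section/provenance."""

    sample_id: str
    species: str
    section: str = ""
    provenance: str = "own"  # "own" | "downloaded"

    def __post_init__(self):
        if not self.sample_id:
            raise AlignmentError("sample_id must be non-empty")
        if not self.species:
            raise AlignmentError(f"sample {self.sample_id!r}: species must be non-empty")
        if self.provenance not in ("own", "downloaded"):
            raise AlignmentError(
                f"sample {self.sample_id!r}: provenance must be 'own' or 'downloaded', "
                f"got {self.provenance!r}"
            )


@dataclass
class LabeledAlignment:
    """Aligned sequences keyed by sample id, each mapped to a species.

    ``matrix`` is an (n_samples, length) array of single characters over
    {A,C,G,T, IUPAC ambiguity codes, '-'}. ``blocks`` records the column
    provenance of concatenated members as (name, start, end) half-open
    intervals.
    """

    name: str
    samples: list[SampleRecord]
    matrix: np.ndarray
    blocks: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.samples) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.samples)} sample records but {self.matrix.shape[0]} rows"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {', '.join(dupes)}")
        if not self.blocks:
            self.blocks = [(self.name, 0, self.matrix.shape[1])]

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.samples]

    @property
    def codes(self) -> np.ndarray:
        """int8 view: A,C,G,T -> 0..3, gap/ambiguity -> -1 (cached)."""
        cached = getattr(self, "_codes", None)
        if cached is None or cached.shape != self.matrix.shape:
            cp = np.ascontiguousarray(self.matrix).view(np.uint32).reshape(self.matrix.shape)
            cached = _CODE[cp.astype(np.uint8)]
            self._codes = cached
        return cached

    def row(self, sample_id: str) -> np.ndarray:
        return self.matrix[self.sample_ids.index(sample_id)]

    def region(self, start: int, end: int, name: str | None = None) -> "LabeledAlignment":
        """Column slice [start, end) as a new alignment."""
        if not (0 <= start <= end <= self.length):
            raise AlignmentError(f"region [{start}, {end}) outside alignment of length {self.length}")
        return LabeledAlignment(
            name=name or f"{self.name}[{start}:{end}]",
            samples=list(self.samples),
            matrix=self.matrix[:, start:end].copy(),
        )

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[s.species] = counts.get(s.species, 0) + 1
        return counts

    def multi_individual_species(self) -> list[str]:
        return sorted(sp for sp, n in self.species_counts().items() if n >= 2)


def _normalize_seq(seq: str, sample_id: str) -> np.ndarray:
    s = seq.upper().replace("U", "T").replace(".", "-").replace("?", "-")
    arr = np.array(list(s), dtype="U1")
    bad = sorted(set(arr.tolist()) - VALID_CHARS)
    if bad:
        raise AlignmentError(
            f"sample {sample_id!r}: invalid characters {', '.join(map(repr, bad))}"
        )
    return arr


# ---------------------------------------------------------------------------
# sample maps
# ---------------------------------------------------------------------------

def read_sample_map(path) -> dict[str, SampleRecord]:
    """TSV with header sample_id/species[/section/provenance] -> ordered dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "species"}
    if not required.issubset(df.columns):
        raise AlignmentError(
            f"sample map {path} must contain columns sample_id and species, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise AlignmentError(f"duplicate sample_id in map: {', '.join(dupes)}")
    records: dict[str, SampleRecord] = {}
    for _, r in df.iterrows():
        records[r["sample_id"]] = SampleRecord(
            sample_id=r["sample_id"],
            species=r["species"],
            section=r.get("section", ""),
            provenance=r.get("provenance", "own") or "own",
        )
    return records


def write_sample_map(records, path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "species": r.species,
            "section": r.section,
            "provenance": r.provenance,
        }
        for r in (records.values() if isinstance(records, dict) else records)
    ]
    pd.DataFrame(rows, columns=["sample_id", "species", "section", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignment(path, map_path, name: str | None = None) -> LabeledAlignment:
    """Read an aligned FASTA plus its sample map into a LabeledAlignment.

    Every FASTA record id must resolve to exactly one map row; rows must all
    have equal length.
    """
    records = read_sample_map(map_path)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise AlignmentError(f"duplicate FASTA record id {rec.id!r}")
        ids.append(rec.id)
        rows.append(_normalize_seq(str(rec.seq), rec.id))
    if not rows:
        raise AlignmentError(f"no FASTA records in {path}")
    unmapped = [i for i in ids if i not in records]
    if unmapped:
        raise AlignmentError(f"unmapped sample {', '.join(unmapped)}")
    length = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != length:
            raise AlignmentError(
                f"ragged alignment: row {sid!r} has length {len(row)}, expected {length}"
            )
    import os

    aln_name = name or os.path.splitext(os.path.basename(str(path)))[0]
    return LabeledAlignment(
        name=aln_name,
        samples=[records[i] for i in ids],
        matrix=np.vstack(rows),
    )


def write_alignment(aln: LabeledAlignment, path) -> None:
    with open(path, "w") as fh:
        for rec, row in zip(aln.samples, aln.matrix):
            fh.write(f">{rec.sample_id}\n{''.join(row)}\n")


def concatenate(alignments: list[LabeledAlignment], name: str) -> LabeledAlignment:
    """Column-wise concatenation of alignments over one shared sample set.

    Rows are taken in the first alignment's sample order; block boundaries
    of every member are retained (shifted).
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    first = alignments[0]
    ref_ids = first.sample_ids
    ref_set = set(ref_ids)
    for aln in alignments[1:]:
        other = set(aln.sample_ids)
        if other != ref_set:
            diff = sorted(ref_set.symmetric_difference(other))
            raise AlignmentError(
                f"sample sets differ between {first.name!r} and {aln.name!r}: "
                f"{', '.join(diff)}"
            )
    pieces = [first.matrix]
    blocks = list(first.blocks)
    offset = first.length
    for aln in alignments[1:]:
        order = [aln.sample_ids.index(i) for i in ref_ids]
        pieces.append(aln.matrix[order])
        blocks.extend((n, s + offset, e + offset) for n, s, e in aln.blocks)
        offset += aln.length
    return LabeledAlignment(
        name=name,
        samples=list(first.samples),
        matrix=np.hstack(pieces),
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class SupportTree:
    """A (usually unrooted) tree whose internal nodes may carry supports.

    Supports live on ``node.support`` as floats on the 0-100 scale (or
    ``None`` when absent). Leaf labels are sample ids and must be unique.
    """

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("tree has duplicate leaf labels")
        for nd in self.tree:
            if not hasattr(nd, "support"):
                nd.support = None

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "SupportTree":
        t = self.tree.clone(depth=1)
        for src, dst in zip(self.tree, t):
            dst.support = getattr(src, "support", None)
        return SupportTree(t)

    def to_newick(self) -> str:
        t = self.tree.clone(depth=1)
        for src, dst in zip(self.tree, t):
            if not dst.is_leaf():
                sup = getattr(src, "support", None)
                dst.label = None if sup is None else f"{sup:g}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()

    @staticmethod
    def from_newick(newick: str) -> "SupportTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except (dendropy.utility.error.DataParseError, ValueError) as exc:
            raise TreeError(f"malformed newick: {exc}") from None
        supports = []
        for nd in tree:
            nd.support = None
            if nd.is_leaf() or nd.parent_node is None:
                continue
            if nd.label is not None:
                try:
                    nd.support = float(nd.label)
                    supports.append(nd.support)
                except ValueError:
                    warnings.warn(f"non-numeric internal node label {nd.label!r} ignored")
        # ")0.87:" dialect: proportions rescaled to the 0-100 scale
        if supports and max(supports) <= 1.0:
            for nd in tree:
                if nd.support is not None:
                    nd.support *= 100.0
        return SupportTree(tree)


def read_tree(path) -> SupportTree:
    with open(path) as fh:
        return SupportTree.from_newick(fh.read())


def write_tree(tree: SupportTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# discrimination reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "species",
    "n_individuals",
    "success",
    "support",
    "max_intra",
    "min_inter",
    "nearest_other",
]


@dataclass
class DiscriminationReport:
    """Per-species success/failure plus dataset-level summary statistics.

    ``rows`` is a DataFrame with columns species, n_individuals, success,
    support, max_intra, min_inter, nearest_other (unused cells NaN/empty);
    ``summary`` holds dataset-level statistics such as resolution_pct,
    zero_k2p, zero_k2p_all_pairs, amid_mean, amid_min, amid_max.
    """

    dataset: str
    method: str  # "tree" | "distance"
    rows: pd.DataFrame
    summary: dict

    def __post_init__(self):
        df = pd.DataFrame(self.rows, columns=_REPORT_COLUMNS)
        df["species"] = df["species"].astype(str)
        df["n_individuals"] = df["n_individuals"].astype(int) if len(df) else df["n_individuals"]
        df["success"] = df["success"].astype(bool) if len(df) else df["success"]
        self.rows = df.reset_index(drop=True)

    def __eq__(self, other):
        if not isinstance(other, DiscriminationReport):
            return NotImplemented
        if self.dataset != other.dataset or self.method != other.method:
            return False
        if set(self.summary) != set(other.summary):
            return False
        for k, v in self.summary.items():
            w = other.summary[k]
            if isinstance(v, float) and isinstance(w, float):
                if not (v == w or (np.isnan(v) and np.isnan(w))):
                    return False
            elif v != w:
                return False
        a, b = self.rows.fillna(""), other.rows.fillna("")
        return a.shape == b.shape and bool((a.astype(str) == b.astype(str)).all().all())


def write_report(report: DiscriminationReport, path) -> None:
    """One TSV row per species plus a key/value summary block; lossless."""
    buf = io.StringIO()
    buf.write(f"#dataset\t{report.dataset}\n")
    buf.write(f"#method\t{report.method}\n")
    for k in sorted(report.summary):
        buf.write(f"#summary\t{k}\t{report.summary[k]!r}\n")
    df = report.rows.copy()
    for col in ("support", "max_intra", "min_inter"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df["nearest_other"] = df["nearest_other"].fillna("")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_report(path) -> DiscriminationReport:
    dataset = method = ""
    summary: dict = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#dataset\t"):
                dataset = line.rstrip("\n").split("\t", 1)[1]
            elif line.startswith("#method\t"):
                method = line.rstrip("\n").split("\t", 1)[1]
            elif line.startswith("#summary\t"):
                _, k, v = line.rstrip("\n").split("\t", 2)
                summary[k] = eval(v, {"__builtins__": {}}, {"nan": float("nan")})
            else:
                body.append(line)
    df = pd.read_csv(
        io.StringIO("".join(body)),
        sep="\t",
        dtype={"species": str, "nearest_other": str},
        keep_default_na=False,
    )
    if len(df):
        for col in ("support", "max_intra", "min_inter"):
            df[col] = df[col].map(lambda v: np.nan if v == "" else float(v))
        df["success"] = df["success"].map(
            lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else v == "True"
        )
    else:
        df = pd.DataFrame(columns=_REPORT_COLUMNS)
    return DiscriminationReport(dataset=dataset, method=method, rows=df, summary=summary)
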