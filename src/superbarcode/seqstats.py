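"""Alignment feature statistics.

Per-dataset summaries in the style of a barcoding feature-comparison
table: aligned length, variable sites, parsimony-informative (PI) sites,
haplotype count, and GC content.

Site-classification conventions (documented, DnaSP-default-like):

* Columns are classified on unambiguous bases (A/C/G/T) only. A column is
  *variable* when >= 2 distinct unambiguous bases occur among its rows;
  *parsimony-informative* when >= 2 distinct unambiguous bases each occur
  in >= 2 rows. A column whose variation involves only gaps or ambiguity
  codes is not variable.
* Haplotypes are counted after excluding every column that contains any
  gap or ambiguity code in any row (site-exclusion convention), then
  counting distinct row strings.
* GC content is (#G + #C) / (#A + #C + #G + #T); gaps and ambiguity codes
  enter neither numerator nor denominator.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .io_model import LabeledAlignment


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (table formatting; Python's round is half-even)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class AlignmentFeatures:
    """One feature-table row for a dataset."""

    name: str
    n_samples: int
    aligned_length: int
    n_variable: int
    pct_variable: float
    n_pi: int
    pct_pi: float
    n_haplotypes: int
    gc_content: float


def _base_counts(aln: LabeledAlignment) -> np.ndarray:
    """(4, L) counts of A,C,G,T per column, ignoring gaps/ambiguities."""
    codes = aln.codes
    return np.stack([(codes == b).sum(axis=0) for b in range(4)])


def site_classes(aln: LabeledAlignment) -> tuple[int, int]:
    """Count (variable, parsimony-informative) columns.

    Raises for alignments with fewer than two rows, where the statistics
    are undefined.
    """
    if aln.n_samples < 2:
        raise AlignmentError("site classification needs >= 2 sequences")
    counts = _base_counts(aln)
    n_states = (counts > 0).sum(axis=0)
    n_variable = int((n_states >= 2).sum())
    n_pi = int((((counts >= 2).sum(axis=0)) >= 2).sum())
    return n_variable, n_pi


def haplotype_count(aln: LabeledAlignment) -> int:
    """Distinct row strings after masking columns with any gap/ambiguity.

    When every column is masked the alignment carries no comparable signal
    and 1 is returned with a warning.
    """
    if aln.n_samples < 1:
        raise AlignmentError("empty alignment")
    clean = (aln.codes >= 0).all(axis=0)
    if not clean.any():
        warnings.warn(
            f"{aln.name}: every column contains a gap or ambiguity; haplotype count "
            "defaults to 1"
        )
        return 1
    masked = aln.codes[:, clean]
    return len({row.tobytes() for row in masked})


def gc_content(aln: LabeledAlignment, region: tuple[int, int] | None = None) -> float:
    """GC fraction over unambiguous bases, optionally restricted to [start, end)."""
    codes = aln.codes
    if region is not None:
        start, end = region
        if not (0 <= start <= end <= aln.length):
            raise AlignmentError(f"region {region} outside alignment of length {aln.length}")
        codes = codes[:, start:end]
    n_acgt = int((codes >= 0).sum())
    if n_acgt == 0:
        raise AlignmentError(f"{aln.name}: no unambiguous bases in requested region")
    n_gc = int(((codes == 1) | (codes == 2)).sum())
    return n_gc / n_acgt


def alignment_features(aln: LabeledAlignment) -> AlignmentFeatures:
    n_var, n_pi = site_classes(aln)
    return AlignmentFeatures(
        name=aln.name,
        n_samples=aln.n_samples,
        aligned_length=aln.length,
        n_variable=n_var,
        pct_variable=round_half_up(100.0 * n_var / aln.length),
        n_pi=n_pi,
        pct_pi=round_half_up(100.0 * n_pi / aln.length),
        n_haplotypes=haplotype_count(aln),
        gc_content=gc_content(aln),
    )


def features_table(alns: list[LabeledAlignment]) -> pd.DataFrame:
    """Feature-comparison table: one row per dataset."""
    if not alns:
        raise AlignmentError("no alignments given")
    return pd.DataFrame([vars(alignment_features(a)) for a in alns])
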