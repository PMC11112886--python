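"""Sliding-window nucleotide diversity and hypervariable-region calling.

Nucleotide diversity (pi) is the average over all unordered sample pairs
of (pairwise differences / pairwise comparable sites), comparing only
columns where both rows carry an unambiguous base. The per-pair
denominator makes the statistic robust in gap-rich spacer regions; pairs
with zero comparable sites are skipped.

A sliding-window profile (default 600 bp windows, 100 bp step) is scanned
against an annotation track of named regions; a region is called a
hypervariable hotspot when its peak window pi exceeds ``pi_threshold``
(default 0.020) and its aligned length exceeds ``length_threshold``
(default 600 bp). The peak ("crest") of a region is the maximum pi among
full-length windows whose midpoint falls inside the region; partial
terminal windows are flagged and excluded from peaks by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import pair_counts
from .errors import AlignmentError
from .io_model import LabeledAlignment


@dataclass(frozen=True)
class Window:
    start: int  # 0-based, half-open
    end: int
    pi: float
    partial: bool = False

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class WindowProfile:
    window_length: int
    step: int
    windows: list[Window]
    alignment_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        # user-facing coordinates are 1-based inclusive
        return pd.DataFrame(
            [
                {
                    "start": w.start + 1,
                    "end": w.end,
                    "midpoint": w.midpoint + 0.5,
                    "pi": w.pi,
                    "partial": w.partial,
                }
                for w in self.windows
            ]
        )


@dataclass(frozen=True)
class Hotspot:
    region_name: str
    start: int
    end: int
    peak_pi: float
    aligned_length: int


def _pi_from_counts(comparable: np.ndarray, diffs: np.ndarray) -> float:
    n = comparable.shape[0]
    iu = np.triu_indices(n, k=1)
    comp = comparable[iu]
    dif = diffs[iu]
    ok = comp > 0
    if not ok.any():
        raise AlignmentError("every sample pair has zero comparable sites")
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} sample pair(s) with no comparable sites skipped")
    return float(np.mean(dif[ok] / comp[ok]))


def nucleotide_diversity(
    aln: LabeledAlignment, interval: tuple[int, int] | None = None
) -> float:
    """Average per-site pairwise difference (pi) over an alignment or slice."""
    if aln.n_samples < 2:
        raise AlignmentError("nucleotide diversity needs >= 2 sequences")
    codes = aln.codes
    if interval is not None:
        start, end = interval
        if not (0 <= start <= end <= aln.length):
            raise AlignmentError(f"interval {interval} outside alignment of length {aln.length}")
        codes = codes[:, start:end]
    comparable, ts, tv = pair_counts(codes)
    return _pi_from_counts(comparable, ts + tv)


def sliding_window(
    aln: LabeledAlignment, window: int = 600, step: int = 100
) -> WindowProfile:
    """Window-wise pi at starts 0, step, 2*step, ... while start < length.

    The terminal windows that run past the end are retained, truncated and
    flagged as partial. A window longer than the alignment degenerates to a
    single whole-alignment window (with a warning). Windows where every
    pair lacks comparable sites get pi = NaN and are flagged partial.
    """
    if not (window >= step >= 1):
        raise AlignmentError(f"need window >= step >= 1, got window={window}, step={step}")
    if aln.n_samples < 2:
        raise AlignmentError("sliding window needs >= 2 sequences")
    if window > aln.length:
        warnings.warn(
            f"window ({window}) exceeds alignment length ({aln.length}); "
            "using a single whole-alignment window"
        )
        try:
            pi = nucleotide_diversity(aln)
            win = Window(0, aln.length, pi, partial=True)
        except AlignmentError:
            win = Window(0, aln.length, float("nan"), partial=True)
        return WindowProfile(window, step, [win], aln.name)
    codes = aln.codes
    windows: list[Window] = []
    for start in range(0, aln.length, step):
        end = min(start + window, aln.length)
        comparable, ts, tv = pair_counts(codes[:, start:end])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pi = _pi_from_counts(comparable, ts + tv)
            partial = end - start < window
        except AlignmentError:
            pi, partial = float("nan"), True
        windows.append(Window(start, end, pi, partial))
    return WindowProfile(window, step, windows, aln.name)


def call_hotspots(
    profile: WindowProfile,
    annotations: list[tuple[str, int, int]],
    pi_threshold: float = 0.020,
    length_threshold: int = 600,
) -> list[Hotspot]:
    """Hypervariable regions among annotated intervals, ordered by peak pi.

    ``annotations`` are (name, start, end) half-open column intervals and
    must not overlap. A region qualifies iff its peak full-window pi
    strictly exceeds ``pi_threshold`` and end - start strictly exceeds
    ``length_threshold``.
    """
    ordered = sorted(annotations, key=lambda a: a[1])
    for (n1, s1, e1), (n2, s2, e2) in zip(ordered, ordered[1:]):
        if e1 > s2:
            raise AlignmentError(f"annotations {n1!r} and {n2!r} overlap")
    out: list[Hotspot] = []
    for name, start, end in annotations:
        peaks = [
            w.pi
            for w in profile.windows
            if not w.partial and start <= w.midpoint < end and np.isfinite(w.pi)
        ]
        if not peaks:
            continue
        peak = max(peaks)
        if peak > pi_threshold and (end - start) > length_threshold:
            out.append(Hotspot(name, start, end, peak, end - start))
    return sorted(out, key=lambda h: (-h.peak_pi, h.region_name))
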