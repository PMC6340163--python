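"""RR-series editing and the two-event RR-increment pattern matrix.

Works on annotated RR-interval series — either recorded Holter
normal-to-normal series (at the typical 8 ms R-peak resolution of a
128 Hz ECG) or series produced by the lattice model (1 step, or 7 ms
after scaling).

Editing follows the standard normal-to-normal protocol: short runs of
non-normal beats (artifacts, ectopy) are substituted beat-by-beat with
the median of the last seven preceding normal intervals; longer runs
are deleted outright, and the junction is logged so that increment
pairs are never formed across a deletion.

The pattern matrix P(ΔRR_i, ΔRR_j) is the joint probability of two
*consecutive* RR increments, binned on both axes with bins centred on
zero.  Accelerations are negative increments, decelerations positive;
a healthy denervated rhythm concentrates all mass at (0, 0), while
re-entry and missed-beat episodes show up as off-origin peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedRRSeries",
    "EditLog",
    "PatternMatrix",
    "clean_rr",
    "increments",
    "pattern_matrix",
    "pattern_matrix_from_rr",
    "read_rr_csv",
    "write_rr_csv",
]

NORMAL = "normal"


@dataclass
class AnnotatedRRSeries:
    """RR intervals in ms with per-beat annotations.

    ``labels[i]`` is ``"normal"`` for a verified normal-to-normal
    interval and anything else for artifacts/ectopy.  ``resolution`` is
    the quantisation of the intervals in ms (8 ms for 128 Hz Holter
    recordings).
    """

    rr: np.ndarray
    labels: np.ndarray
    resolution: float = 8.0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.rr.ndim != 1 or self.rr.shape != self.labels.shape:
            raise ValueError("rr and labels must be 1-D and the same length")
        if (self.rr <= 0).any():
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return self.rr.size


@dataclass
class EditLog:
    """Record of substitutions and deletions applied by :func:`clean_rr`.

    ``patches`` are (input_start, run_length, substituted_value);
    ``deletions`` are (input_start, run_length); ``junctions`` are the
    positions *in the cleaned output* where a deletion removed beats —
    increment pairs must not be formed across them.
    """

    patches: list[tuple[int, int, float]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    junctions: list[int] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.patches and not self.deletions


def clean_rr(series: AnnotatedRRSeries, max_patch: int = 5,
             target_len: int = 20000) -> tuple[np.ndarray, EditLog]:
    """Edit an annotated RR series to a normal-to-normal series.

    Runs of non-normal beats strictly shorter than ``max_patch`` are
    replaced beat-by-beat with the median of the last seven normal
    intervals preceding the run; runs of length ``max_patch`` or more —
    or runs with fewer than seven normal beats before them — are
    deleted and the junction logged.  The output is truncated to
    ``target_len`` beats from the start.  Applied to its own (all
    normal) output the edit is the identity.
    """
    if max_patch < 1:
        raise ValueError("max_patch must be at least 1")
    out: list[float] = []
    log = EditLog()
    normals_seen: list[float] = []
    rr, labels = series.rr, series.labels
    n = rr.size
    i = 0
    while i < n:
        if labels[i] == NORMAL:
            out.append(float(rr[i]))
            normals_seen.append(float(rr[i]))
            i += 1
            continue
        j = i
        while j < n and labels[j] != NORMAL:
            j += 1
        run_len = j - i
        if run_len < max_patch and len(normals_seen) >= 7:
            value = float(np.median(normals_seen[-7:]))
            out.extend([value] * run_len)
            log.patches.append((i, run_len, value))
        else:
            log.deletions.append((i, run_len))
            log.junctions.append(len(out))
        i = j
    cleaned = np.asarray(out[:target_len], dtype=float)
    log.junctions = [p for p in log.junctions if 0 < p < cleaned.size]
    return cleaned, log


def increments(rr: np.ndarray) -> np.ndarray:
    """First differences δRR_k = RR_k − RR_{k−1}."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two RR intervals to form increments")
    return np.diff(rr)


@dataclass
class PatternMatrix:
    """Joint probability of two consecutive RR increments.

    ``P[i, j]`` is the probability of observing an increment in the bin
    centred at ``centers[i]`` followed by one in the bin centred at
    ``centers[j]``.  Bins are half-open ``[c − w/2, c + w/2)`` with
    width ``w = bin_width``; the support is auto-sized to the data and
    symmetric about zero.
    """

    bin_width: float
    centers: np.ndarray
    P: np.ndarray

    def prob(self, di: float, dj: float) -> float:
        """Probability of the bin pair containing (di, dj)."""
        w = self.bin_width
        ci = int(np.floor(di / w + 0.5))
        cj = int(np.floor(dj / w + 0.5))
        half = (self.P.shape[0] - 1) // 2
        if abs(ci) > half or abs(cj) > half:
            return 0.0
        return float(self.P[ci + half, cj + half])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.centers, columns=self.centers)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="dRR_i\\dRR_j")


def _matrix_from_pairs(a: np.ndarray, b: np.ndarray,
                       bin_width: float) -> PatternMatrix:
    ka = np.floor(a / bin_width + 0.5).astype(int)
    kb = np.floor(b / bin_width + 0.5).astype(int)
    half = int(max(np.abs(ka).max(), np.abs(kb).max())) if ka.size else 0
    size = 2 * half + 1
    P = np.zeros((size, size))
    np.add.at(P, (ka + half, kb + half), 1.0)
    P /= ka.size
    centers = (np.arange(size) - half) * bin_width
    return PatternMatrix(bin_width=bin_width, centers=centers, P=P)


def pattern_matrix(drr: np.ndarray, bin_width: float = 8.0) -> PatternMatrix:
    """Pattern matrix of consecutive (overlapping) increment pairs."""
    drr = np.asarray(drr, dtype=float)
    if drr.size < 2:
        raise ValueError("need at least two increments to form a pair")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return _matrix_from_pairs(drr[:-1], drr[1:], bin_width)


def pattern_matrix_from_rr(rr: np.ndarray, bin_width: float = 8.0,
                           junctions=()) -> PatternMatrix:
    """Pattern matrix straight from an RR series, honouring junctions.

    ``junctions`` (positions where beats were deleted, from the
    :class:`EditLog`) split the series into segments; increments and
    pairs are formed within segments only, never across a deletion.
    """
    rr = np.asarray(rr, dtype=float)
    bounds = [0, *sorted(set(junctions)), rr.size]
    a_parts, b_parts = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo >= 3:  # need >= 2 increments for a pair
            drr = np.diff(rr[lo:hi])
            a_parts.append(drr[:-1])
            b_parts.append(drr[1:])
    if not a_parts:
        raise ValueError("no segment long enough to form an increment pair")
    return _matrix_from_pairs(np.concatenate(a_parts), np.concatenate(b_parts),
                              bin_width)


def read_rr_csv(path, resolution: float = 8.0) -> AnnotatedRRSeries:
    """Read an RR series from CSV (rr_ms,label) or bare one-per-line text."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    if "," in first:
        df = pd.read_csv(path, header=0 if "rr" in first.lower() else None,
                         names=["rr_ms", "label"])
        return AnnotatedRRSeries(df["rr_ms"].to_numpy(float),
                                 df["label"].astype(str).to_numpy(object),
                                 resolution)
    rr = np.loadtxt(path, ndmin=1)
    return AnnotatedRRSeries(rr, np.full(rr.size, NORMAL, dtype=object),
                             resolution)


def write_rr_csv(series: AnnotatedRRSeries, path) -> None:
    pd.DataFrame({"rr_ms": series.rr, "label": series.labels}).to_csv(
        path, index=False)
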