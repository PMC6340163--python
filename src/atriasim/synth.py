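"""Synthetic annotated RR-series fixtures.

Generates reproducible RR series that emulate edited Holter
normal-to-normal tachograms: intervals quantised to the recording
resolution (8 ms by default), a controlled increment structure
(bounded random walk of the interval around its base value), and
planted runs of non-normal beats for exercising the editing protocol.
These fixtures reproduce the *format and increment statistics* of real
recordings, not their physiology — they carry no autonomic modulation,
circadian trend, or respiratory rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrv import NORMAL, AnnotatedRRSeries

__all__ = ["FixtureSpec", "gen_synthetic_rr"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic annotated RR series.

    ``noise_quanta`` bounds the per-beat increment (in resolution
    units): each beat the interval moves by a uniform integer in
    [−noise_quanta, noise_quanta] quanta, reflected so the interval
    stays within ``±max_dev_ms`` of ``base_ms``.  ``artifacts`` plants
    runs of non-normal beats as (start_index, run_length) pairs; the
    artifact intervals are set to half the local value (short ectopic
    coupling) and labelled ``"artifact"``.
    """

    length: int = 2000
    base_ms: float = 800.0
    resolution_ms: float = 8.0
    noise_quanta: int = 1
    max_dev_ms: float = 80.0
    artifacts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be at least 2")
        if self.base_ms <= 0 or self.resolution_ms <= 0:
            raise ValueError("base_ms and resolution_ms must be positive")
        if self.noise_quanta < 0 or self.max_dev_ms < 0:
            raise ValueError("noise_quanta and max_dev_ms must be non-negative")
        for start, run in self.artifacts:
            if start < 0 or run < 1 or start + run > self.length:
                raise ValueError(f"artifact run {(start, run)} outside series")


def gen_synthetic_rr(spec: FixtureSpec, seed: int | None = None) -> AnnotatedRRSeries:
    """Generate the series described by ``spec``; deterministic per seed."""
    rng = np.random.default_rng(seed)
    q = spec.resolution_ms
    max_dev = int(spec.max_dev_ms / q)
    steps = rng.integers(-spec.noise_quanta, spec.noise_quanta + 1,
                         size=spec.length)
    dev = np.empty(spec.length, dtype=np.int64)
    level = 0
    for k in range(spec.length):  # reflecting bounded walk, in quanta
        level += int(steps[k])
        level = max(-max_dev, min(max_dev, level))
        dev[k] = level
    rr = spec.base_ms + q * dev.astype(float)
    labels = np.full(spec.length, NORMAL, dtype=object)
    for start, run in spec.artifacts:
        rr[start:start + run] = np.maximum(q, np.round(rr[start:start + run]
                                                       / 2.0 / q) * q)
        labels[start:start + run] = "artifact"
    return AnnotatedRRSeries(rr=rr, labels=labels, resolution=q)
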