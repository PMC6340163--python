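"""Limit-state classification of simulated rhythms and parameter sweeps.

After an initial transient, every run settles into a limit state read
off its RR series (in steps) relative to the nominal pacemaker period
``T_SAN = f + r0 + a``:

* **normal** — sinus rhythm: the RR span stays within a quarter of
  ``T_SAN`` (the 200 ms / 800 ms variability bound of a healthy human
  rhythm) and the mean RR tracks ``T_SAN``;
* **san_arrhythmia** — SAN–atrial re-entry: a wave circulating around
  the node doubles the beats, producing RR intervals well below
  ``T_SAN``;
* **lost_normal** — sinus rhythm with missed beats: some pacemaker
  excitations die out before reaching the AVN, so occasional RR
  intervals are well above ``T_SAN``;
* **lost_arrhythmia** — both doubled and missed beats (re-entry with
  losses, or fibrillation-like self-organised wandering waves);
* **dead** — almost no conducted beats: no AVN events, or a mean RR
  more than three pacemaker periods (over two thirds of excitations
  lost).

The module also provides the two standard experiments over the tissue
parameters: the phase-diagram sweep over transversal connection density
``p_H = p_L`` and refusal probability, and the wavefront-velocity
metric based on first-front arrival times.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cells import CellTimers, RefusePolicy
from .engine import SimConfig, SimResult, run

__all__ = [
    "RhythmLabel",
    "ClassifierThresholds",
    "StateTable",
    "VelocityResult",
    "classify",
    "classify_run",
    "phase_sweep",
    "velocity_metric",
]

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


class RhythmLabel(str, enum.Enum):
    NORMAL = "normal"
    SAN_ARRHYTHMIA = "san_arrhythmia"
    LOST_NORMAL = "lost_normal"
    LOST_ARRHYTHMIA = "lost_arrhythmia"
    DEAD = "dead"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds, all expressed relative to ``T_SAN``.

    ``normal_span_frac`` is the healthy-variability bound
    (200 ms / 800 ms = 0.25); ``dead_mean_mult`` the dead-state multiple
    of the pacemaker period; RR intervals below ``short_beat_frac·T_SAN``
    mark doubled (re-entrant) beats and above ``missed_beat_frac·T_SAN``
    missed beats; ``mean_tol`` is the relative tolerance for the mean RR
    to track ``T_SAN`` in the normal rule.
    """

    normal_span_frac: float = 0.25
    dead_mean_mult: float = 3.0
    short_beat_frac: float = 0.75
    missed_beat_frac: float = 1.25
    mean_tol: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.short_beat_frac < 1.0 < self.missed_beat_frac
                < self.dead_mean_mult):
            raise ValueError(
                "need 0 < short_beat_frac < 1 < missed_beat_frac < dead_mean_mult"
            )
        if self.normal_span_frac <= 0 or self.mean_tol < 0:
            raise ValueError("normal_span_frac must be positive, mean_tol >= 0")


def classify(rr: np.ndarray, t_san: float,
             thr: ClassifierThresholds | None = None) -> RhythmLabel:
    """Classify an RR series (transient already removed) into a limit state.

    Decision cascade: (1) empty series or mean RR above
    ``dead_mean_mult·T_SAN`` → dead; (2) span below
    ``normal_span_frac·T_SAN`` with mean RR within ``mean_tol`` of
    ``T_SAN`` → normal; otherwise (3) the presence of short
    (< ``short_beat_frac·T_SAN``) and/or long
    (> ``missed_beat_frac·T_SAN``) beats decides between re-entry,
    missed beats, or both.  The cascade is scale-invariant: rescaling
    ``rr`` and ``t_san`` together leaves the label unchanged.
    """
    if t_san <= 0:
        raise ValueError("t_san must be positive")
    if thr is None:
        thr = ClassifierThresholds()
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        return RhythmLabel.DEAD
    mean = rr.mean()
    if mean > thr.dead_mean_mult * t_san:
        return RhythmLabel.DEAD
    span = rr.max() - rr.min()
    if span < thr.normal_span_frac * t_san and abs(mean / t_san - 1.0) <= thr.mean_tol:
        return RhythmLabel.NORMAL
    has_short = bool((rr < thr.short_beat_frac * t_san).any())
    has_missed = bool((rr > thr.missed_beat_frac * t_san).any())
    if has_short and has_missed:
        return RhythmLabel.LOST_ARRHYTHMIA
    if has_short:
        return RhythmLabel.SAN_ARRHYTHMIA
    if has_missed:
        return RhythmLabel.LOST_NORMAL
    logger.info("wide-but-bounded RR series fell through to normal")
    return RhythmLabel.NORMAL


def classify_run(result: SimResult,
                 thr: ClassifierThresholds | None = None) -> RhythmLabel:
    """Classify a simulation result, discarding the configured transient."""
    return classify(result.rr_after_transient, result.config.t_san, thr)


@dataclass
class StateTable:
    """Limit-state statistics over a (p_H = p_L, p_refuse) grid.

    ``table`` is long-format: one row per (p_HL, p_refuse, label) with
    the observed probability over ``n`` realizations.
    """

    table: pd.DataFrame
    reps: int
    seeds: np.ndarray

    def probabilities(self, p_hl: float, p_refuse: float) -> pd.Series:
        sub = self.table[(self.table.p_HL == p_hl)
                         & (self.table.p_refuse == p_refuse)]
        return sub.set_index("label")["probability"]

    def most_probable(self) -> pd.DataFrame:
        """Matrix of the modal label per grid cell (rows p_refuse, cols p_HL)."""
        idx = self.table.groupby(["p_refuse", "p_HL"])["probability"].idxmax()
        modal = self.table.loc[idx]
        return modal.pivot(index="p_refuse", columns="p_HL", values="label")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _with_params(base: SimConfig, p_hl: float, p_refuse: float,
                 seed: int) -> SimConfig:
    spec = replace(base.spec, p_H=p_hl, p_L=p_hl)
    refuse = replace(base.refuse, p_refuse=p_refuse)
    return replace(base, spec=spec, refuse=refuse, seed=seed)


def phase_sweep(
    p_hl_values,
    p_refuse_values,
    reps: int,
    base: SimConfig | None = None,
    seed: int | None = None,
    thr: ClassifierThresholds | None = None,
) -> StateTable:
    """Monte-Carlo phase diagram over connection density and refusal.

    For every grid cell, ``reps`` independent seeded tissues are built
    and simulated, their limit states classified, and label frequencies
    tabulated.  Per-cell probabilities sum to one.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if base is None:
        base = SimConfig()
    master = np.random.default_rng(seed)
    p_hl_values = list(p_hl_values)
    p_refuse_values = list(p_refuse_values)
    seeds = master.integers(0, _MAX_SEED,
                            size=(len(p_hl_values), len(p_refuse_values), reps))
    rows = []
    labels = [lab.value for lab in RhythmLabel]
    for i, p_hl in enumerate(p_hl_values):
        for j, p_ref in enumerate(p_refuse_values):
            counts = dict.fromkeys(labels, 0)
            for s in seeds[i, j]:
                result = run(_with_params(base, p_hl, p_ref, int(s)))
                counts[classify_run(result, thr).value] += 1
            for lab in labels:
                rows.append({"p_HL": p_hl, "p_refuse": p_ref, "label": lab,
                             "probability": counts[lab] / reps, "n": reps})
    return StateTable(table=pd.DataFrame(rows), reps=reps, seeds=seeds)


@dataclass
class VelocityResult:
    """Mean first-front delay t_avn_first − t_bottom_first, in steps."""

    mean_delay: float
    delays: np.ndarray
    n_excluded: int  # realizations with no AVN event


def velocity_metric(config: SimConfig, reps: int,
                    seed: int | None = None) -> VelocityResult:
    """Mean signed first-front delay over ``reps`` realizations.

    The columns are always fully connected, so the first wavefront
    reaches the bottom border as fast as the dynamics allow; the extra
    steps it then needs to assemble an AVN excitation measure the
    effective slowing by sparse transversal coupling and refusals.
    Realizations with no AVN event are excluded and counted.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    master = np.random.default_rng(seed)
    seeds = master.integers(0, _MAX_SEED, size=reps)
    delays = []
    excluded = 0
    for s in seeds:
        result = run(replace(config, seed=int(s)))
        d = result.front_delay
        if d is None:
            excluded += 1
        else:
            delays.append(d)
    delays = np.asarray(delays, dtype=float)
    mean = float(delays.mean()) if delays.size else float("nan")
    return VelocityResult(mean_delay=mean, delays=delays, n_excluded=excluded)
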