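"""Single-cell timed-automaton semantics.

A cardiac cell is modelled as a three-state oscillator timed automaton.
The states follow the physiological phases of the membrane action
potential: ``F`` (firing — rapid depolarisation), ``R`` (refractory —
plateau and repolarisation) and ``A`` (activity/rest — diastolic
interval).  A single integer clock ``x`` counts the steps spent in the
current state; each state has a guard (``f``, ``r``, ``a``) after which
the cyclic transition F→R→A→F fires and the clock resets.

Step semantics are *increment-then-check*: every global step the clock
advances by one (unless a neighbour interaction halves it), and the
guard of the current state is then evaluated against the new clock
value.  A state with an integer guard θ therefore lasts exactly θ
steps, and an isolated cell fires with period ``f + r + a``.

Two stochastic ingredients perturb the deterministic cycle:

* the refractory guard of each cell is drawn once at tissue build time
  as ``r = r0 + r_noise·ξ`` with ξ ~ U[0, 1], modelling cell-to-cell
  variability of the action-potential duration;
* the A→F *fire* transition may be refused with probability
  ``p_refuse`` — a per-step Bernoulli trial re-tested every step while
  the guard holds — modelling fatigue/dysfunction of the tissue.

Neighbour interactions modify the cycle: a refractory cell whose count
of firing in-neighbours exceeds ``N_R`` has its clock halved (floor),
prolonging the refractory stay; a resting cell with more than ``N_F``
firing in-neighbours is forced to fire (still subject to refusal).
Forced firing takes precedence over the halving, which takes precedence
over the intrinsic guard transition, which takes precedence over the
plain time pass.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "CellPhase",
    "CellTimers",
    "InteractionThresholds",
    "RefusePolicy",
    "draw_refractory",
    "intrinsic_step",
    "interact_step",
    "cell_step",
    "cycle_period",
]


class CellPhase(enum.IntEnum):
    """Automaton state: firing, refractory, or activity (rest)."""

    F = 0
    R = 1
    A = 2


@dataclass(frozen=True)
class CellTimers:
    """Guard thresholds of the three automaton states, in steps.

    ``f`` and ``a`` are integers; the refractory guard is drawn per cell
    as ``r = r0 + r_noise·ξ`` and may be fractional.  The clock test is
    ``x >= r``, so the effective refractory length is ``ceil(r)`` steps.
    """

    f: float
    r0: float
    a: float
    r_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.f <= 0 or self.r0 <= 0 or self.a <= 0:
            raise ValueError("guards f, r0, a must be positive")
        if self.r_noise < 0:
            raise ValueError("r_noise must be non-negative")


@dataclass(frozen=True)
class InteractionThresholds:
    """Neighbour-count thresholds for interaction transitions.

    A transition is effective only when the number of firing
    in-neighbours *strictly exceeds* the threshold: more than ``N_R``
    firing neighbours halve a refractory cell's clock; more than
    ``N_F`` force a resting cell to fire.
    """

    N_R: int = 3
    N_F: int = 0

    def __post_init__(self) -> None:
        if self.N_R < 0 or self.N_F < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class RefusePolicy:
    """Probability of refusing an enabled fire transition, per role.

    ``applies_to`` names the tissue roles subject to refusal; by default
    every cell (SAN, atrial and AVN alike) is dysfunctional with the
    same probability.
    """

    p_refuse: float = 0.0
    applies_to: frozenset[str] = frozenset({"SAN", "ATRIAL", "AVN"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_refuse <= 1.0:
            raise ValueError("p_refuse must be in [0, 1]")


def draw_refractory(r0: float, r_noise: float, xi: float) -> float:
    """Draw a refractory guard ``r = r0 + r_noise·xi``.

    Parameters
    ----------
    r0
        Base refractory length, steps; must be positive.
    r_noise
        Maximal uniform spread of the refractory length, steps.
    xi
        Uniform deviate in [0, 1].
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if r_noise < 0:
        raise ValueError("r_noise must be non-negative")
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return r0 + r_noise * xi


def cycle_period(timers: CellTimers) -> float:
    """Nominal firing-to-firing interval of an isolated cell: f + r0 + a.

    Exact for a cell with ``r_noise == 0`` under the increment-then-check
    step semantics; for noisy cells it is the lower bound of the period.
    """
    return timers.f + timers.r0 + timers.a


def intrinsic_step(
    phase: CellPhase,
    x: int,
    timers: CellTimers,
    r: float | None = None,
    refuse_draw: float = 1.0,
    p_refuse: float = 0.0,
) -> tuple[CellPhase, int]:
    """Advance one step of the intrinsic (interaction-free) cell cycle.

    The clock increments by one; if the guard of the current state is
    then met, the cyclic transition fires with a clock reset — except
    A→F, which is refused (the cell stays in A with its clock growing
    past ``a``) when ``refuse_draw < p_refuse``.  Refusal is re-tested
    on every subsequent step while the guard holds.

    ``r`` is the cell's drawn refractory guard; defaults to ``r0``.
    """
    if r is None:
        r = timers.r0
    x_new = x + 1
    if phase is CellPhase.F:
        if x_new >= timers.f:
            return CellPhase.R, 0
    elif phase is CellPhase.R:
        if x_new >= r:
            return CellPhase.A, 0
    else:  # A
        if x_new >= timers.a and refuse_draw >= p_refuse:
            return CellPhase.F, 0
    return phase, x_new


def interact_step(
    phase: CellPhase,
    x: int,
    n_firing: int,
    thresholds: InteractionThresholds,
    timers: CellTimers | None = None,
    r: float | None = None,
    refuse_draw: float = 1.0,
    p_refuse: float = 0.0,
) -> tuple[CellPhase, int, bool]:
    """Advance one step including neighbour-interaction transitions.

    Precedence within the step: forced firing (rest cell, more than
    ``N_F`` firing neighbours) > clock halving (refractory cell, more
    than ``N_R``) > intrinsic guard transition > time pass.  The halving
    replaces this step's clock increment and suppresses the intrinsic
    guard check; forced firing is subject to the same refusal test as
    intrinsic firing.  Returns ``(phase, clock, fired)``.
    """
    if n_firing < 0:
        raise ValueError("n_firing must be non-negative")
    if phase is CellPhase.A and n_firing > thresholds.N_F:
        if refuse_draw >= p_refuse:
            return CellPhase.F, 0, True
        return CellPhase.A, x + 1, False
    if phase is CellPhase.R and n_firing > thresholds.N_R:
        return CellPhase.R, x // 2, False
    if timers is None:
        # no interaction applies and no timers given: plain time pass
        return phase, x + 1, False
    new_phase, new_x = intrinsic_step(phase, x, timers, r, refuse_draw, p_refuse)
    return new_phase, new_x, new_phase is CellPhase.F and phase is CellPhase.A


def cell_step(
    phase: CellPhase,
    x: int,
    n_firing: int,
    thresholds: InteractionThresholds,
    timers: CellTimers,
    r: float,
    refuse_draw: float,
    p_refuse: float,
) -> tuple[CellPhase, int]:
    """Full per-cell update rule — the scalar reference semantics.

    This is the per-cell map the lattice engine applies synchronously to
    every cell; kept as a plain scalar function so the vectorised engine
    can be checked against it state-for-state.
    """
    new_phase, new_x, _ = interact_step(
        phase, x, n_firing, thresholds, timers, r, refuse_draw, p_refuse
    )
    return new_phase, new_x
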