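"""Synchronous lattice dynamics, AVN event detection and RR extraction.

The whole tissue is updated in lock-step: each global step the firing
pattern is snapshotted, every cell counts its firing in-neighbours, and
the per-cell automaton rule (see :mod:`atriasim.cells`) is applied to
all cells simultaneously.  The update is fully vectorised — the
firing-neighbour count is one sparse matrix–vector product — but is
state-for-state identical to applying the scalar cell rule in row-major
order, with one uniform refusal deviate consumed per cell per step.

A heartbeat is an AVN excitation event: the step at which the number of
simultaneously firing AVN cells first reaches ``avn_k`` (edge-triggered;
the detector re-arms only after the count drops below the threshold, so
one wavefront registers one beat).  The RR series is the sequence of
step distances between consecutive events.

The refusal probability may itself drift in time as a bounded random
walk — each step, with probability ``p_walk``, ``p_refuse`` moves by
±ε, moves outside [0, z] being rejected — emulating slow fluctuations
of tissue fatigue in a living heart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cells import CellPhase, CellTimers, InteractionThresholds, RefusePolicy
from .tissue import (
    ROLE_AVN,
    ROLE_NAMES,
    ROLE_SAN,
    LatticeSpec,
    NodeRegions,
    Tissue,
    build_lattice,
)

__all__ = [
    "DEFAULT_SAN_TIMERS",
    "DEFAULT_ATRIAL_TIMERS",
    "SimConfig",
    "WalkSpec",
    "SimResult",
    "TissueState",
    "initial_state",
    "step_tissue",
    "detect_avn_event",
    "walk_refuse",
    "run",
    "scale_rr",
]

_F = int(CellPhase.F)
_R = int(CellPhase.R)
_A = int(CellPhase.A)

#: Default pacemaker guards: T_SAN = 5 + 70 + 40 = 115 steps (~805 ms at
#: 7 ms per step, a plausible resting sinus interval).
DEFAULT_SAN_TIMERS = CellTimers(f=5, r0=70, a=40, r_noise=0)

#: Default working-myocardium guards: refractory 50–60 steps (r_noise=10
#: gives a 20% uniform spread of the action-potential duration) and an
#: activity guard of 10·T_SAN so atrial cells never self-fire in a
#: normally driven tissue.
DEFAULT_ATRIAL_TIMERS = CellTimers(f=5, r0=50, a=1150, r_noise=10)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one tissue simulation."""

    spec: LatticeSpec = field(default_factory=LatticeSpec)
    regions: NodeRegions = field(default_factory=NodeRegions)
    san_timers: CellTimers = DEFAULT_SAN_TIMERS
    atrial_timers: CellTimers = DEFAULT_ATRIAL_TIMERS
    avn_timers: CellTimers | None = None
    thresholds: InteractionThresholds = field(default_factory=InteractionThresholds)
    refuse: RefusePolicy = field(default_factory=RefusePolicy)
    total_steps: int = 6000
    transient_beats: int = 10
    seed: int | None = None
    initial_phase: str = "rest"  # "rest" | "random_san_clock"

    def __post_init__(self) -> None:
        if self.total_steps <= 0:
            raise ValueError("total_steps must be positive")
        if self.transient_beats < 0:
            raise ValueError("transient_beats must be non-negative")
        if self.initial_phase not in ("rest", "random_san_clock"):
            raise ValueError("initial_phase must be 'rest' or 'random_san_clock'")

    @property
    def t_san(self) -> float:
        """Nominal pacemaker period f + r0 + a."""
        t = self.san_timers
        return t.f + t.r0 + t.a


@dataclass(frozen=True)
class WalkSpec:
    """Bounded ±ε random walk of the refusal probability on [0, z]."""

    p_walk: float = 0.001
    eps: float = 0.05
    z: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_walk <= 1.0:
            raise ValueError("p_walk must be in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if not 0.0 < self.z <= 1.0:
            raise ValueError("z must be in (0, 1]")


@dataclass
class SimResult:
    """Outcome of one run: beat times, RR series, front timings."""

    avn_event_times: np.ndarray          # step indices of AVN excitations
    rr: np.ndarray                       # inter-event step counts
    t_bottom_first: int | None           # first step a bottom-row cell fires
    t_avn_first: int | None              # first AVN event step
    p_refuse_trace: np.ndarray | None    # per-step p_refuse (walk runs only)
    seed: int | None
    config: SimConfig

    @property
    def rr_after_transient(self) -> np.ndarray:
        return self.rr[self.config.transient_beats:]

    @property
    def front_delay(self) -> int | None:
        """Signed step difference t_avn_first − t_bottom_first.

        The first wavefront descends the always-connected columns at the
        maximal possible speed, so this difference measures how much the
        actual lateral organisation slows the front on its way to the
        AVN: larger delay, slower effective propagation.
        """
        if self.t_avn_first is None or self.t_bottom_first is None:
            return None
        return self.t_avn_first - self.t_bottom_first


@dataclass
class TissueState:
    """Mutable per-cell dynamical state of the lattice."""

    phase: np.ndarray  # (n,) int8, CellPhase values
    clock: np.ndarray  # (n,) int64


def initial_state(tissue: Tissue, policy: str = "rest",
                  rng: np.random.Generator | None = None) -> TissueState:
    """All cells at rest (A, x=0); optionally randomise SAN clocks.

    With the default policy the SAN fires first in unison after
    ``a_SAN`` steps.  ``random_san_clock`` draws each SAN clock
    uniformly in [0, a) to exercise pacemaker self-organisation.
    """
    n = tissue.n_cells
    phase = np.full(n, _A, dtype=np.int8)
    clock = np.zeros(n, dtype=np.int64)
    if policy == "random_san_clock":
        if rng is None:
            raise ValueError("random_san_clock policy needs an rng")
        san = np.flatnonzero(tissue.roles == ROLE_SAN)
        clock[san] = rng.integers(0, int(tissue.a[san].min()), size=san.size)
    return TissueState(phase=phase, clock=clock)


def _refusable_mask(tissue: Tissue, policy: RefusePolicy) -> np.ndarray:
    mask = np.zeros(tissue.n_cells, dtype=bool)
    for role, name in ROLE_NAMES.items():
        if name in policy.applies_to:
            mask |= tissue.roles == role
    return mask


def step_tissue(
    state: TissueState,
    tissue: Tissue,
    thresholds: InteractionThresholds,
    p_refuse: float,
    refusable: np.ndarray,
    rng: np.random.Generator,
) -> TissueState:
    """One synchronous global update; returns the committed next state.

    Phases are snapshotted, firing in-neighbours counted from the
    snapshot, and the per-cell rule applied everywhere at once with the
    precedence forced firing > clock halving > intrinsic guard > time
    pass.  One uniform deviate is drawn per cell (row-major) for the
    refusal test, keeping runs reproducible bit-for-bit.
    """
    phase, x = state.phase, state.clock
    firing = (phase == _F).astype(np.float32)
    nf = tissue.adjacency @ firing

    u = rng.random(x.size)
    refuse = refusable & (u < p_refuse)

    is_f = phase == _F
    is_r = phase == _R
    is_a = phase == _A
    inc = x + 1

    halve = is_r & (nf > thresholds.N_R)
    attempt = is_a & ((nf > thresholds.N_F) | (inc >= tissue.a))
    fire = attempt & ~refuse
    to_r = is_f & (inc >= tissue.f)
    to_a = is_r & ~halve & (inc >= tissue.r)

    new_phase = phase.copy()
    new_x = inc
    new_x[halve] = x[halve] >> 1
    new_phase[to_r] = _R
    new_x[to_r] = 0
    new_phase[to_a] = _A
    new_x[to_a] = 0
    new_phase[fire] = _F
    new_x[fire] = 0
    return TissueState(phase=new_phase, clock=new_x)


def detect_avn_event(count: int, armed: bool, k: int) -> tuple[bool, bool]:
    """Edge-triggered AVN beat detector.

    An event is registered the first step the simultaneous AVN firing
    count reaches ``k`` while armed; the detector then stays disarmed
    until the count drops below ``k``, so a single sustained wavefront
    cannot register twice.  Returns ``(event, armed_next)``.
    """
    if armed and count >= k:
        return True, False
    if count < k:
        return False, True
    return False, armed


def walk_refuse(p: float, walk: WalkSpec, zeta: float, sign: int) -> float:
    """One step of the bounded random walk of ``p_refuse``.

    With probability ``p_walk`` (tested via ``zeta``) the value moves by
    ``sign·eps``; a move that would leave [0, z] is rejected and the
    value stays put (no clamping).
    """
    if zeta < walk.p_walk:
        cand = p + sign * walk.eps
        # tolerate float round-off at the interval ends
        if -1e-12 <= cand <= walk.z + 1e-12:
            return float(min(max(cand, 0.0), walk.z))
    return p


def run(config: SimConfig, walk: WalkSpec | None = None,
        tissue: Tissue | None = None) -> SimResult:
    """Simulate a tissue for ``total_steps`` and extract the rhythm.

    Builds the lattice (unless one is supplied), iterates the
    synchronous update, records AVN excitation events and derives the
    RR series.  When ``walk`` is given, ``p_refuse`` performs its
    random walk, updated before each tissue step, starting from the
    configured value; the per-step trace is returned.  Fully
    reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    build_rng, run_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    if tissue is None:
        tissue = build_lattice(
            config.spec, config.regions, config.san_timers,
            config.atrial_timers, seed=config.seed,
            avn_timers=config.avn_timers, rng=build_rng,
        )
    state = initial_state(tissue, config.initial_phase, run_rng)
    refusable = _refusable_mask(tissue, config.refuse)
    avn_cells = np.flatnonzero(tissue.roles == ROLE_AVN)
    bottom_row = np.arange(tissue.n_cells - tissue.spec.L, tissue.n_cells)
    k = config.regions.avn_k

    p_refuse = config.refuse.p_refuse
    if walk is not None:
        p_refuse = min(p_refuse, walk.z)
        trace = np.empty(config.total_steps)
    else:
        trace = None

    events: list[int] = []
    armed = True
    t_bottom_first: int | None = None
    t_avn_first: int | None = None

    for t in range(config.total_steps):
        if walk is not None:
            zeta = run_rng.random()
            sign = 1 if run_rng.random() < 0.5 else -1
            p_refuse = walk_refuse(p_refuse, walk, zeta, sign)
            trace[t] = p_refuse
        state = step_tissue(state, tissue, config.thresholds,
                            p_refuse, refusable, run_rng)
        if t_bottom_first is None and (state.phase[bottom_row] == _F).any():
            t_bottom_first = t
        count = int((state.phase[avn_cells] == _F).sum())
        event, armed = detect_avn_event(count, armed, k)
        if event:
            events.append(t)
            if t_avn_first is None:
                t_avn_first = t

    times = np.asarray(events, dtype=np.int64)
    rr = np.diff(times) if times.size >= 2 else np.empty(0, dtype=np.int64)
    return SimResult(
        avn_event_times=times, rr=rr,
        t_bottom_first=t_bottom_first, t_avn_first=t_avn_first,
        p_refuse_trace=trace, seed=config.seed, config=config,
    )


def scale_rr(rr: np.ndarray, factor: float = 7.0) -> np.ndarray:
    """Convert an RR series from steps to milliseconds (default 7 ms/step)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return np.asarray(rr, dtype=float) * factor
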