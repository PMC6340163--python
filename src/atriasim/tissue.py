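"""Stochastic lattice network of the right atrium.

Cells sit on the vertices of a regular ``L × L`` square lattice.  Each
pair of vertical neighbours (N/S) is linked independently with
probability ``p_V`` (1 by default — columns are always fully
conducting), horizontal neighbours (E/W) with ``p_H``, and the four
diagonal neighbours (NE/NW/SE/SW) with ``p_L``.  Lowering ``p_H`` and
``p_L`` emulates the loss of transversal intercellular coupling caused
by collagen deposition (fibrosis).  The expected neighbour count of an
interior cell is ``2(p_V + p_H) + 4 p_L``.

Two rectangular regions are special:

* the **SAN** (sinoatrial node), an elongated block of self-exciting
  pacemaker cells in the left-upper part of the lattice.  SAN cells
  cannot read signals from outside — there are no edges into the SAN —
  and only a random half of the SAN cells bordering the atrium (the
  *exit* cells) carry one-way SAN→atrium pathways;
* the **AVN** (atrioventricular node), a small block centred on the
  bottom boundary.  AVN cells behave as ordinary atrial automata; the
  node differs only in event counting — an AVN excitation is registered
  when at least ``avn_k`` of its cells fire simultaneously.

Every cell's refractory guard is drawn once at build time as
``r = r0 + r_noise·ξ``, ξ ~ U[0, 1], with per-role parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .cells import CellTimers

__all__ = [
    "ROLE_SAN",
    "ROLE_ATRIAL",
    "ROLE_AVN",
    "ROLE_NAMES",
    "LatticeSpec",
    "NodeRegions",
    "Tissue",
    "build_lattice",
    "mean_degree",
    "empirical_degree",
]

ROLE_SAN = 0
ROLE_ATRIAL = 1
ROLE_AVN = 2
ROLE_NAMES = {ROLE_SAN: "SAN", ROLE_ATRIAL: "ATRIAL", ROLE_AVN: "AVN"}

# unordered neighbour offsets by direction class, (drow, dcol)
_V_OFFSETS = [(1, 0)]
_H_OFFSETS = [(0, 1)]
_L_OFFSETS = [(1, 1), (1, -1)]


class ConfigurationError(ValueError):
    """Invalid lattice/region geometry or parameters."""


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice size and connection probabilities by direction class."""

    L: int = 100
    p_V: float = 1.0
    p_H: float = 0.5
    p_L: float = 0.5

    def __post_init__(self) -> None:
        if self.L < 10:
            raise ConfigurationError("lattice size L must be at least 10")
        for name in ("p_V", "p_H", "p_L"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class NodeRegions:
    """Geometry of the SAN and AVN regions, half-open (row, col) ranges.

    Defaults place an elongated 20 × 4 SAN in the left-upper part of a
    100 × 100 lattice and an eight-cell (2 × 4) AVN centred on the
    bottom boundary, with an AVN excitation registered when ``avn_k``
    of the eight cells fire at once.
    """

    san_rows: tuple[int, int] = (10, 30)
    san_cols: tuple[int, int] = (2, 6)
    avn_rows: tuple[int, int] | None = None  # default: bottom two rows
    avn_cols: tuple[int, int] | None = None  # default: centred, 4 wide
    san_exit_fraction: float = 0.5
    san_conn_prob: float = 1.0
    avn_k: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.san_exit_fraction <= 1.0:
            raise ConfigurationError("san_exit_fraction must be in (0, 1]")
        if not 0.0 <= self.san_conn_prob <= 1.0:
            raise ConfigurationError("san_conn_prob outside [0, 1]")
        if self.avn_k < 1:
            raise ConfigurationError("avn_k must be at least 1")

    def resolve(self, L: int) -> tuple[tuple[int, int], tuple[int, int],
                                       tuple[int, int], tuple[int, int]]:
        """Concrete (rows, cols) ranges for both regions on an L-lattice."""
        avn_rows = self.avn_rows if self.avn_rows is not None else (L - 2, L)
        avn_cols = (self.avn_cols if self.avn_cols is not None
                    else (L // 2 - 2, L // 2 + 2))
        for name, (lo, hi), bound in (
            ("san_rows", self.san_rows, L), ("san_cols", self.san_cols, L),
            ("avn_rows", avn_rows, L), ("avn_cols", avn_cols, L),
        ):
            if not (0 <= lo < hi <= bound):
                raise ConfigurationError(f"{name}={lo, hi} degenerate or outside lattice")
        if (self.san_rows[1] > avn_rows[0] and avn_rows[1] > self.san_rows[0]
                and self.san_cols[1] > avn_cols[0] and avn_cols[1] > self.san_cols[0]):
            raise ConfigurationError("SAN and AVN rectangles overlap")
        n_avn = (avn_rows[1] - avn_rows[0]) * (avn_cols[1] - avn_cols[0])
        if self.avn_k > n_avn:
            raise ConfigurationError("avn_k exceeds AVN cell count")
        return self.san_rows, self.san_cols, avn_rows, avn_cols


@dataclass
class Tissue:
    """A built lattice: roles, directed adjacency, per-cell timers.

    ``adjacency`` is a sparse boolean matrix with ``adjacency[i, j]``
    true when cell *j* is an in-neighbour of cell *i* (edge j→i); the
    firing-neighbour count of every cell is then a single sparse
    matrix–vector product.  Within the atrium edges are symmetric;
    SAN→atrium pathways are strictly one-way.
    """

    spec: LatticeSpec
    regions: NodeRegions
    roles: np.ndarray                 # (L²,) int8
    adjacency: sp.csr_matrix          # (L², L²) float32, in-neighbour incidence
    f: np.ndarray                     # (L²,) float64 firing guards
    r: np.ndarray                     # (L²,) float64 drawn refractory guards
    a: np.ndarray                     # (L²,) float64 activity guards
    exit_mask: np.ndarray             # (L²,) bool, SAN cells allowed to transmit
    seed: int | None = None
    role_timers: dict[str, CellTimers] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.spec.L ** 2

    def flat(self, row: int, col: int) -> int:
        return row * self.spec.L + col

    def in_neighbors(self, i: int) -> np.ndarray:
        """Flat indices of the in-neighbour set O(i)."""
        return self.adjacency.indices[
            self.adjacency.indptr[i]:self.adjacency.indptr[i + 1]
        ]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        coo = self.adjacency.tocoo()
        doc = {
            "spec": {"L": self.spec.L, "p_V": self.spec.p_V,
                     "p_H": self.spec.p_H, "p_L": self.spec.p_L},
            "regions": {
                "san_rows": list(self.regions.san_rows),
                "san_cols": list(self.regions.san_cols),
                "avn_rows": list(self.regions.avn_rows) if self.regions.avn_rows else None,
                "avn_cols": list(self.regions.avn_cols) if self.regions.avn_cols else None,
                "san_exit_fraction": self.regions.san_exit_fraction,
                "san_conn_prob": self.regions.san_conn_prob,
                "avn_k": self.regions.avn_k,
            },
            "roles": self.roles.tolist(),
            "edges": [coo.col.tolist(), coo.row.tolist()],  # j -> i
            "f": self.f.tolist(),
            "r": self.r.tolist(),
            "a": self.a.tolist(),
            "exit_mask": np.flatnonzero(self.exit_mask).tolist(),
            "seed": self.seed,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Tissue":
        doc = json.loads(text)
        spec = LatticeSpec(**doc["spec"])
        reg = doc["regions"]
        regions = NodeRegions(
            san_rows=tuple(reg["san_rows"]), san_cols=tuple(reg["san_cols"]),
            avn_rows=tuple(reg["avn_rows"]) if reg["avn_rows"] else None,
            avn_cols=tuple(reg["avn_cols"]) if reg["avn_cols"] else None,
            san_exit_fraction=reg["san_exit_fraction"],
            san_conn_prob=reg["san_conn_prob"], avn_k=reg["avn_k"],
        )
        n = spec.L ** 2
        src, dst = doc["edges"]
        adjacency = sp.csr_matrix(
            (np.ones(len(src), dtype=np.float32), (np.asarray(dst), np.asarray(src))),
            shape=(n, n),
        )
        exit_mask = np.zeros(n, dtype=bool)
        exit_mask[doc["exit_mask"]] = True
        return cls(
            spec=spec, regions=regions,
            roles=np.asarray(doc["roles"], dtype=np.int8),
            adjacency=adjacency,
            f=np.asarray(doc["f"], dtype=float),
            r=np.asarray(doc["r"], dtype=float),
            a=np.asarray(doc["a"], dtype=float),
            exit_mask=exit_mask, seed=doc["seed"],
        )


def mean_degree(spec: LatticeSpec) -> float:
    """Expected neighbour count of an interior cell: 2(p_V + p_H) + 4 p_L."""
    return 2.0 * (spec.p_V + spec.p_H) + 4.0 * spec.p_L


def _pair_indices(L: int, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of all in-lattice unordered pairs at offset (dr, dc)."""
    rows = np.arange(max(0, -dr), min(L, L - dr))
    cols = np.arange(max(0, -dc), min(L, L - dc))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    i = (rr * L + cc).ravel()
    j = ((rr + dr) * L + (cc + dc)).ravel()
    return i, j


def build_lattice(
    spec: LatticeSpec,
    regions: NodeRegions,
    san_timers: CellTimers,
    atrial_timers: CellTimers,
    seed: int | None = None,
    avn_timers: CellTimers | None = None,
    rng: np.random.Generator | None = None,
) -> Tissue:
    """Build the stochastic lattice tissue; deterministic for a fixed seed.

    Each unordered atrial neighbour pair is linked independently with
    the probability of its direction class; SAN-internal links use the
    common ``san_conn_prob``; SAN→atrium edges run one-way from a
    random ``san_exit_fraction`` subset of the SAN cells bordering the
    atrium, and no edge enters the SAN.  Boundary cells simply lack the
    missing neighbours (open boundaries).  AVN cells take atrial timers
    unless ``avn_timers`` is given.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = spec.L
    n = L * L
    san_rows, san_cols, avn_rows, avn_cols = regions.resolve(L)

    roles = np.full((L, L), ROLE_ATRIAL, dtype=np.int8)
    roles[san_rows[0]:san_rows[1], san_cols[0]:san_cols[1]] = ROLE_SAN
    roles[avn_rows[0]:avn_rows[1], avn_cols[0]:avn_cols[1]] = ROLE_AVN
    roles = roles.ravel()

    if avn_timers is None:
        avn_timers = atrial_timers
    by_role = {ROLE_SAN: san_timers, ROLE_ATRIAL: atrial_timers, ROLE_AVN: avn_timers}

    # per-cell guards; refractory drawn with one uniform deviate per cell
    # (row-major order) so builds are reproducible
    xi = rng.random(n)
    f = np.empty(n)
    r = np.empty(n)
    a = np.empty(n)
    for role, t in by_role.items():
        m = roles == role
        f[m] = t.f
        a[m] = t.a
        r[m] = t.r0 + t.r_noise * xi[m]

    # exit mask: SAN cells with at least one non-SAN 8-neighbour
    san_grid = (roles == ROLE_SAN).reshape(L, L)
    border = np.zeros((L, L), dtype=bool)
    padded = np.pad(san_grid, 1, constant_values=True)  # outside counts as SAN
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            border |= ~padded[1 + dr:L + 1 + dr, 1 + dc:L + 1 + dc]
    bordering = np.flatnonzero(san_grid & border)
    n_exit = int(np.floor(regions.san_exit_fraction * bordering.size + 0.5))
    exit_cells = rng.permutation(bordering)[:n_exit]
    exit_mask = np.zeros(n, dtype=bool)
    exit_mask[exit_cells] = True

    # edges, one Bernoulli draw per unordered neighbour pair, class order V,H,L
    src_list: list[np.ndarray] = []
    dst_list: list[np.ndarray] = []
    class_offsets = [(spec.p_V, _V_OFFSETS), (spec.p_H, _H_OFFSETS), (spec.p_L, _L_OFFSETS)]
    is_san = roles == ROLE_SAN
    for p_class, offsets in class_offsets:
        for dr, dc in offsets:
            i, j = _pair_indices(L, dr, dc)
            san_i, san_j = is_san[i], is_san[j]
            prob = np.where(san_i & san_j, regions.san_conn_prob, p_class)
            u = rng.random(i.size)
            keep = u < prob
            both_non_san = keep & ~san_i & ~san_j
            both_san = keep & san_i & san_j
            # symmetric links within the atrium and within the SAN
            for m in (both_non_san, both_san):
                src_list += [i[m], j[m]]
                dst_list += [j[m], i[m]]
            # one-way SAN -> atrium pathways from exit cells only
            m = keep & san_i & ~san_j & exit_mask[i]
            src_list.append(i[m])
            dst_list.append(j[m])
            m = keep & san_j & ~san_i & exit_mask[j]
            src_list.append(j[m])
            dst_list.append(i[m])

    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    adjacency = sp.csr_matrix(
        (np.ones(src.size, dtype=np.float32), (dst, src)), shape=(n, n)
    )

    return Tissue(
        spec=spec, regions=regions, roles=roles, adjacency=adjacency,
        f=f, r=r, a=a, exit_mask=exit_mask, seed=seed,
        role_timers={"SAN": san_timers, "ATRIAL": atrial_timers, "AVN": avn_timers},
    )


def empirical_degree(tissue: Tissue) -> float:
    """Mean in-degree of interior atrial cells away from both nodes.

    Averages |O(J)| over atrial cells that are not on the lattice
    boundary and whose full 8-neighbourhood is atrial, so the estimate
    is not biased by the SAN's one-way pathways or region borders.
    """
    L = tissue.spec.L
    atrial = (tissue.roles == ROLE_ATRIAL).reshape(L, L)
    ok = np.zeros((L, L), dtype=bool)
    ok[1:-1, 1:-1] = True
    padded = np.pad(atrial, 1, constant_values=False)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            ok &= padded[1 + dr:L + 1 + dr, 1 + dc:L + 1 + dc]
    cells = np.flatnonzero(ok.ravel())
    if cells.size == 0:
        raise ConfigurationError("no interior atrial cells away from the nodes")
    indeg = np.asarray(tissue.adjacency.sum(axis=1)).ravel()
    return float(indeg[cells].mean())
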