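"""Structured-document configuration for simulations.

A configuration is a flat YAML mapping with optional sections
(``lattice``, ``regions``, ``timers``, ``thresholds``, ``refuse``,
``run``, ``walk``, ``classifier``).  Missing sections and keys take
the package defaults; unknown keys and out-of-range values are
rejected with a descriptive error.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .cells import CellTimers, InteractionThresholds, RefusePolicy
from .engine import (
    DEFAULT_ATRIAL_TIMERS,
    DEFAULT_SAN_TIMERS,
    SimConfig,
    WalkSpec,
)
from .rhythm import ClassifierThresholds
from .tissue import ConfigurationError, LatticeSpec, NodeRegions

__all__ = ["ParsedConfig", "parse_config", "parse_config_file", "config_to_dict"]


@dataclass
class ParsedConfig:
    sim: SimConfig
    walk: WalkSpec | None
    classifier: ClassifierThresholds


def _section(doc: dict, name: str, allowed: set[str]) -> dict:
    sec = doc.pop(name, {}) or {}
    if not isinstance(sec, dict):
        raise ConfigurationError(f"section '{name}' must be a mapping")
    unknown = set(sec) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{name}': {', '.join(sorted(unknown))}")
    return sec


def _timers(sec: dict, default: CellTimers) -> CellTimers:
    return CellTimers(
        f=sec.get("f", default.f), r0=sec.get("r0", default.r0),
        a=sec.get("a", default.a), r_noise=sec.get("r_noise", default.r_noise),
    )


def parse_config(document: dict | None) -> ParsedConfig:
    """Validate a configuration mapping, filling defaults.

    Raises :class:`~atriasim.tissue.ConfigurationError` on unknown keys
    and propagates range errors from the underlying dataclasses.
    """
    doc = dict(document or {})
    try:
        lat = _section(doc, "lattice", {"L", "p_V", "p_H", "p_L"})
        reg = _section(doc, "regions", {
            "san_rows", "san_cols", "avn_rows", "avn_cols",
            "san_exit_fraction", "san_conn_prob", "avn_k"})
        tim = _section(doc, "timers", {"san", "atrial", "avn"})
        thr = _section(doc, "thresholds", {"N_R", "N_F"})
        ref = _section(doc, "refuse", {"p_refuse", "applies_to"})
        run_sec = _section(doc, "run", {
            "total_steps", "transient_beats", "seed", "initial_phase"})
        walk_sec = _section(doc, "walk", {"p_walk", "eps", "z"})
        cls = _section(doc, "classifier", {
            "normal_span_frac", "dead_mean_mult", "short_beat_frac",
            "missed_beat_frac", "mean_tol"})
        if doc:
            raise ConfigurationError(
                f"unknown section(s): {', '.join(sorted(doc))}")

        spec = LatticeSpec(**lat)
        regions = NodeRegions(**{
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in reg.items()})
        san_t = _timers(tim.get("san", {}) or {}, DEFAULT_SAN_TIMERS)
        atr_t = _timers(tim.get("atrial", {}) or {}, DEFAULT_ATRIAL_TIMERS)
        avn_t = _timers(tim["avn"], atr_t) if tim.get("avn") else None
        refuse = RefusePolicy(
            p_refuse=ref.get("p_refuse", 0.0),
            applies_to=frozenset(ref.get("applies_to",
                                         ("SAN", "ATRIAL", "AVN"))),
        )
        sim = SimConfig(
            spec=spec, regions=regions, san_timers=san_t,
            atrial_timers=atr_t, avn_timers=avn_t,
            thresholds=InteractionThresholds(**thr), refuse=refuse, **run_sec,
        )
        walk = WalkSpec(**walk_sec) if walk_sec else None
        classifier = ClassifierThresholds(**cls)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(str(exc)) from exc
    return ParsedConfig(sim=sim, walk=walk, classifier=classifier)


def parse_config_file(path) -> ParsedConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))


def config_to_dict(sim: SimConfig, walk: WalkSpec | None = None) -> dict:
    """Round-trippable plain-dict snapshot of an effective configuration."""
    doc = {
        "lattice": {"L": sim.spec.L, "p_V": sim.spec.p_V,
                    "p_H": sim.spec.p_H, "p_L": sim.spec.p_L},
        "regions": {
            "san_rows": list(sim.regions.san_rows),
            "san_cols": list(sim.regions.san_cols),
            "avn_rows": list(sim.regions.avn_rows) if sim.regions.avn_rows else None,
            "avn_cols": list(sim.regions.avn_cols) if sim.regions.avn_cols else None,
            "san_exit_fraction": sim.regions.san_exit_fraction,
            "san_conn_prob": sim.regions.san_conn_prob,
            "avn_k": sim.regions.avn_k,
        },
        "timers": {
            name: {"f": t.f, "r0": t.r0, "a": t.a, "r_noise": t.r_noise}
            for name, t in (("san", sim.san_timers), ("atrial", sim.atrial_timers),
                            *((("avn", sim.avn_timers),) if sim.avn_timers else ()))
        },
        "thresholds": {"N_R": sim.thresholds.N_R, "N_F": sim.thresholds.N_F},
        "refuse": {"p_refuse": sim.refuse.p_refuse,
                   "applies_to": sorted(sim.refuse.applies_to)},
        "run": {"total_steps": sim.total_steps,
                "transient_beats": sim.transient_beats,
                "seed": sim.seed, "initial_phase": sim.initial_phase},
    }
    if walk is not None:
        doc["walk"] = {"p_walk": walk.p_walk, "eps": walk.eps, "z": walk.z}
    return doc
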