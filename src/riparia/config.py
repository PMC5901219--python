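"""Run configuration: one YAML file validated against module preconditions.

The resolved configuration (plus the seed) is embedded in every output
table's metadata header, so results are reproducible from any file they
produced.  All randomness flows from the single top-level ``seed`` through
named substreams (``flow``, ``cohort``, ``community``, ``fixture``), so
each subsystem is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibrate import PlotSite
from .flow import FlowRegime, SegmentedRegime, make_drifting_regime
from .species import SpeciesParams

__all__ = ["RunConfig", "ConfigError", "load_config", "substream"]

_SUBSTREAMS = {"flow": 0, "cohort": 1, "community": 2, "fixture": 3}


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` itemizes every problem found."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_SUBSTREAMS[name],)))


@dataclass
class RunConfig:
    """Validated configuration for the command-line workflows."""

    seed: int
    output_dir: Path
    flow: FlowRegime | SegmentedRegime | None
    species: SpeciesParams | None
    plots: list = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    def section(self, name: str, default=None):
        return self.raw.get(name, {} if default is None else default)

    def meta(self) -> dict:
        """Fully resolved config for embedding into output headers.

        The output directory is omitted so re-runs into different
        directories stay byte-identical.
        """
        raw = {k: v for k, v in self.raw.items() if k != "output_dir"}
        return {"config": raw, "seed": int(self.seed)}

    def require(self, *attrs) -> None:
        missing = [a for a in attrs if getattr(self, a) in (None, [])]
        if missing:
            raise ConfigError([f"config section {a!r} is required for this "
                               "subcommand" for a in missing])


def _build_flow(section, errors):
    if not section:
        return None
    if "segments" in section:
        try:
            segs = tuple(
                (s["t_start"], s["t_end"],
                 FlowRegime(mu=s["mu"], sigma=s["sigma"],
                            tau_h=s.get("tau_h", 0.0)))
                for s in section["segments"])
            return SegmentedRegime(segs)
        except (KeyError, TypeError, ValueError) as e:
            errors.append(f"flow.segments: {e}")
            return None
    missing = [k for k in ("mu", "sigma") if k not in section]
    if missing:
        errors.append(f"flow: missing key(s) {missing}")
        return None
    try:
        base = FlowRegime(mu=section["mu"], sigma=section["sigma"],
                          tau_h=section.get("tau_h", 0.0))
    except ValueError as e:
        errors.append(f"flow: {e}")
        return None
    drift = section.get("drift")
    if drift:
        try:
            return make_drifting_regime(
                base, mean_amplitude=drift["mean_amplitude"],
                sd_amplitude=drift.get("sd_amplitude", 0.0),
                period=drift["period"], horizon=drift["horizon"],
                n_segments=drift.get("n_segments", 60))
        except (KeyError, ValueError) as e:
            errors.append(f"flow.drift: {e}")
            return None
    return base


def _build_species(section, errors):
    if not section:
        return None
    required = ("lam", "a_f", "A", "B", "C", "D")
    missing = [k for k in required if k not in section]
    if missing:
        errors.append(f"species: missing key(s) {missing}")
        return None
    try:
        return SpeciesParams(**section)
    except (TypeError, ValueError) as e:
        errors.append(f"species: {e}")
        return None


def _build_plots(section, errors):
    plots = []
    for i, p in enumerate(section or []):
        try:
            plots.append(PlotSite(id=str(p["id"]), x=float(p.get("x", 0.0)),
                                  altitude=float(p["altitude"]),
                                  eta=(float(p["eta"]) if "eta" in p
                                       else None)))
        except (KeyError, TypeError, ValueError) as e:
            errors.append(f"plots[{i}]: {e}")
    return plots


def load_config(path, seed: int | None = None,
                output_dir=None) -> RunConfig:
    """Load and validate a YAML config; CLI flags override config keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    errors: list[str] = []
    flow = _build_flow(raw.get("flow", {}), errors)
    species = _build_species(raw.get("species", {}), errors)
    plots = _build_plots(raw.get("plots", []), errors)
    if seed is not None:
        raw = {**raw, "seed": int(seed)}
    if output_dir is not None:
        raw = {**raw, "output_dir": str(output_dir)}
    cfg_seed = raw.get("seed", 0)
    if not isinstance(cfg_seed, int):
        errors.append(f"seed must be an integer, got {cfg_seed!r}")
        cfg_seed = 0
    if errors:
        raise ConfigError(errors)
    return RunConfig(seed=cfg_seed,
                     output_dir=Path(raw.get("output_dir", "riparia-out")),
                     flow=flow, species=species, plots=plots, raw=raw)
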