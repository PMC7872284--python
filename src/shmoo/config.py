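"""YAML run-configuration loading for the command-line interface.

A config file holds up to four sections, each mapping directly onto the
corresponding parameter dataclass (unknown keys are rejected):

    mechanics:   MechanicsParams   (P, rho_w, mu0, lambda_A, k_s)
    polarity:    PolarityParams    (D, k_D, k_X, k_R, k_I, A_CWI, rho_0, c_A)
    rates:       StochasticRates   (beta1..3, k_act, k_inact, A_on, A_off,
                                    D_mem, A_CWI)
    run:         free-form run settings consumed by the CLI subcommands
                 (n_nodes, t_end, Ns, Nphi, dt_mech, seeds, ...)

All quantities are in μm / s / MPa; densities are molecules/μm² (stochastic)
or units of rho_0 (continuum).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .continuum import ContinuumConfig
from .coupling import CouplingConfig
from .polarity import PolarityParams
from .stochastic import StochasticRates
from .wall_mechanics import MechanicsParams

__all__ = ["load_config", "dump_config", "RunConfig"]


@dataclasses.dataclass
class RunConfig:
    mechanics: MechanicsParams
    polarity: PolarityParams
    rates: StochasticRates
    run: dict
    explicit: frozenset = frozenset()   # sections present in the config file

    def continuum(self, **overrides) -> ContinuumConfig:
        allowed = {f.name for f in dataclasses.fields(ContinuumConfig)}
        extra = {k: v for k, v in self.run.items() if k in allowed}
        extra.update(overrides)
        return ContinuumConfig(mechanics=self.mechanics, polarity=self.polarity,
                               **extra)

    def coupling(self, **overrides) -> CouplingConfig:
        """Coupled-run config; sections absent from the file keep the
        CouplingConfig defaults (feedback on, stochastic-scale k_s)."""
        allowed = {f.name for f in dataclasses.fields(CouplingConfig)}
        extra = {k: v for k, v in self.run.items() if k in allowed}
        extra.update(overrides)
        if "mechanics" in self.explicit:
            extra.setdefault("mechanics", self.mechanics)
        if "rates" in self.explicit:
            extra.setdefault("rates", self.rates)
        return CouplingConfig(**extra)


def _build(cls, section: dict | None, name: str):
    section = section or {}
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return cls(**section)


def load_config(path=None) -> RunConfig:
    """Load a YAML config; a missing path gives all defaults."""
    doc = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        mechanics=_build(MechanicsParams, doc.get("mechanics"), "mechanics"),
        polarity=_build(PolarityParams, doc.get("polarity"), "polarity"),
        rates=_build(StochasticRates, doc.get("rates"), "rates"),
        run=dict(doc.get("run") or {}),
        explicit=frozenset(doc.keys()),
    )


def dump_config(cfg: RunConfig, path):
    doc = {
        "mechanics": dataclasses.asdict(cfg.mechanics),
        "polarity": dataclasses.asdict(cfg.polarity),
        "rates": dataclasses.asdict(cfg.rates),
        "run": cfg.run,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
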