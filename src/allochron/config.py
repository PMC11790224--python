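"""Simulation configuration, validation, and scenario presets.

Defaults correspond to the standard parameterisation of the model:
K=100 patches of N=500 individuals, a T=100-night season, encounter rate
eta=25, profile narrowness a=50, divergent selection c=1 toward habitat
optima 0 (corn) and 1 (rice), regulation cost s_r=0.05, migration m=0.01,
L=20 timing loci, and mutation rate mu=1e-5.  Corn-rich patches (the first
K/2) have f_k=0.8, rice-rich patches 0.2.  Sympatric runs start all
patches at tau0=0.5; secondary-contact runs start the two clusters locally
adapted at tau0=0.1 / 0.9 with gene flow restored at ``contact_generation``.

Full-scale runs (the defaults above, thousands of generations) are
expensive; the ``*-mini`` presets are scaled-down counterparts (K=10,
N=100, a few hundred generations) that preserve each scenario's parameter
deltas and qualitative behaviour at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = ["SimulationConfig", "load_config", "get_preset", "PRESETS", "ConfigError"]


class ConfigError(ValueError):
    """Raised on invalid configuration; message lists every violation."""


@dataclass
class SimulationConfig:
    # metapopulation
    K: int = 100
    N: int = 500
    m: float = 0.01
    f_corn_rich: float = 0.8
    f_rice_rich: float = 0.2
    scenario: str = "sympatry"  # or "secondary_contact"
    contact_generation: int = 250
    # mating
    T: int = 100
    eta: float = 25.0
    a: float = 50.0
    system: str = "baseline"  # baseline | scramble | monogamy
    # selection
    c: float = 1.0
    tau_corn_opt: float = 0.0
    tau_rice_opt: float = 1.0
    s_r: float = 0.05
    # genetics
    L: int = 20
    mu: float = 1.0e-5
    sex_specific_expression: bool = False
    # founders: juvenile timing per cluster (corn-rich first)
    tau0_corn: float = 0.5
    tau0_rice: float = 0.5
    # run control
    generations: int = 1000
    census_interval: int = 25
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        errors = []
        if self.K < 2 or self.K % 2:
            errors.append(f"K must be an even integer >= 2, got {self.K}")
        if self.N < 2 or self.N % 2:
            errors.append(f"N must be an even integer >= 2, got {self.N}")
        if not 0.0 <= self.m <= 1.0:
            errors.append(f"m must lie in [0, 1], got {self.m}")
        for name in ("f_corn_rich", "f_rice_rich", "tau_corn_opt", "tau_rice_opt",
                     "tau0_corn", "tau0_rice"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1], got {v}")
        if self.scenario not in ("sympatry", "secondary_contact"):
            errors.append(f"scenario must be sympatry or secondary_contact, got {self.scenario!r}")
        if self.T < 0:
            errors.append(f"T must be >= 0, got {self.T}")
        if self.eta < 0:
            errors.append(f"eta must be >= 0, got {self.eta}")
        if self.a < 0:
            errors.append(f"a must be >= 0, got {self.a}")
        if self.system not in ("baseline", "scramble", "monogamy"):
            errors.append(f"unknown mating system {self.system!r}")
        if self.c < 0:
            errors.append(f"c must be >= 0, got {self.c}")
        if not 0.0 <= self.s_r < 1.0:
            errors.append(f"s_r must lie in [0, 1), got {self.s_r}")
        if self.L < 1:
            errors.append(f"L must be >= 1, got {self.L}")
        if not 0.0 <= self.mu < 1.0 / 3.0:
            errors.append(f"mu must satisfy 0 <= mu < 1/3, got {self.mu}")
        if self.generations < 0:
            errors.append(f"generations must be >= 0, got {self.generations}")
        if self.census_interval < 1:
            errors.append(f"census_interval must be >= 1, got {self.census_interval}")
        if self.contact_generation < 0:
            errors.append(f"contact_generation must be >= 0, got {self.contact_generation}")
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
        return self


_FIELDS = {f.name for f in fields(SimulationConfig)}


def load_config(path) -> SimulationConfig:
    """Load a YAML config file; unspecified fields take the defaults above.

    Unknown keys and out-of-range values raise :class:`ConfigError` listing
    every violation.  An empty file yields the full default configuration.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ConfigError("unknown configuration keys: " + ", ".join(unknown))
    return SimulationConfig(**data).validate()


def _preset(**kw) -> SimulationConfig:
    return replace(SimulationConfig(), **kw)


#: Named scenario presets.  The fig1*/fig2* full-scale presets carry each
#: scenario's parameter deltas against the defaults; the *-mini variants
#: shrink K, N, and the generation count to desk scale.
PRESETS: dict[str, SimulationConfig] = {
    # secondary contact, high initial divergence, baseline mating system:
    # allochronic variation collapses under sexual selection for earliness
    "fig1a": _preset(system="baseline", scenario="secondary_contact",
                     tau0_corn=0.1, tau0_rice=0.9, generations=2000),
    # scramble competition, low initial divergence: divergence builds slowly
    "fig1b": _preset(system="scramble", scenario="secondary_contact",
                     tau0_corn=0.4, tau0_rice=0.6, generations=2000),
    # monogamy, low initial divergence: rapid, pronounced diversification
    "fig1c": _preset(system="monogamy", scenario="secondary_contact",
                     tau0_corn=0.4, tau0_rice=0.6, generations=2000),
    # sex-specific expression enabled: maintenance after secondary contact
    "fig2a": _preset(system="baseline", scenario="secondary_contact",
                     tau0_corn=0.1, tau0_rice=0.9, generations=2000,
                     sex_specific_expression=True),
    # sex-specific expression, sympatric emergence from tau0=0.5
    "fig2b": _preset(system="baseline", scenario="sympatry",
                     tau0_corn=0.5, tau0_rice=0.5, generations=5000,
                     sex_specific_expression=True),
    # grid template (c and m are swept by the grid driver)
    "fig3": _preset(system="baseline", scenario="secondary_contact",
                    tau0_corn=0.1, tau0_rice=0.9, generations=10000,
                    sex_specific_expression=True),
}

# Scaled-down presets shrink the metapopulation and the horizon; the
# mutation rate is scaled up to preserve the population-level mutational
# input per locus per generation (K*N*mu = 0.5, as at full scale), the
# standard rescaling for forward simulations — without it a mini
# population is mutation-limited and shows no evolutionary change at all.
_MINI = dict(K=10, N=100, mu=5.0e-4, contact_generation=100, generations=400,
             census_interval=25)
PRESETS.update({
    "fig1a-mini": replace(PRESETS["fig1a"], **_MINI),
    "fig1b-mini": replace(PRESETS["fig1b"], **_MINI),
    # the mini monogamy run starts from the same high initial divergence as
    # fig1a-mini so the mating-system contrast (collapse vs. retention) is
    # visible within a few hundred generations
    "fig1c-mini": replace(PRESETS["fig1c"], tau0_corn=0.1, tau0_rice=0.9, **_MINI),
    "fig2a-mini": replace(PRESETS["fig2a"], **_MINI),
    "fig2b-mini": replace(PRESETS["fig2b"], K=10, N=100, mu=5.0e-4,
                          generations=1000, census_interval=25),
    # grid template at desk scale; the grid driver sweeps c and m
    "fig3-mini": replace(PRESETS["fig3"], K=4, N=50, mu=2.5e-3,
                         contact_generation=50, generations=250,
                         census_interval=50),
})


def get_preset(name: str, **overrides) -> SimulationConfig:
    """Fetch a named preset, optionally overriding fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(base, **overrides).validate()
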