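"""Habitat settlement, soft viability selection, migration, and the
generation loop over the metapopulation.

Each patch k offers corn and rice habitat in local proportions f_k and
1 - f_k.  Females settle into one habitat at random (probability equal to
the local proportions) at the start of the mating season and oviposit
there.  Juvenile survival to adulthood is soft: exactly N offspring are
recruited per patch by a viability-weighted lottery with replacement,

    S_k(tau, ell) = (1 - s_r)**(ell / 2L)
                    * (f_k / F_k)       * exp(-c (tau - tau*_corn)**2)   [corn]
    S_k(tau, ell) = (1 - s_r)**(ell / 2L)
                    * ((1-f_k)/(1-F_k)) * exp(-c (tau - tau*_rice)**2)   [rice]

where F_k is the realised fraction of females that settled in corn, c the
strength of divergent ecological selection, tau*_corn/tau*_rice the habitat
optima for juvenile timing, and s_r the survival cost of carrying ell
sex-specifically regulated timing alleles (out of 2L).  The f/F competition
ratios make expected recruitment per habitat track the habitat proportions
regardless of settlement noise.

Generations are discrete and non-overlapping; the per-generation order is
migrate -> settle -> mate (T-night season) -> assign sires -> regulate.
Before secondary contact, the K patches form two isolated clusters of K/2
patches (corn-rich and rice-rich) with separate migrant pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .activity import ActivityParams
from .genetics import (
    REG_FEMALE,
    REG_MALE,
    REG_NONE,
    Genome,
    GeneticsParams,
    mutate_sign_arrays,
)
from .individual import CORN, FEMALE, MALE, RICE, Individual, new_adult
from .mating import MatingRecord, SeasonParams, assign_sire, run_season

__all__ = [
    "SelectionParams",
    "Patch",
    "MetaPopulation",
    "settle",
    "viability",
    "regulate",
    "migrate",
    "step_generation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Viability-selection parameters.

    c : strength of divergent ecological selection on juvenile timing (>= 0).
    tau_corn_opt, tau_rice_opt : optimal juvenile timing in each habitat.
    s_r : survival cost of fully sex-specific regulation (0 <= s_r < 1).
    """

    c: float = 1.0
    tau_corn_opt: float = 0.0
    tau_rice_opt: float = 1.0
    s_r: float = 0.05

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be >= 0")
        for name in ("tau_corn_opt", "tau_rice_opt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.s_r < 1.0:
            raise ValueError("s_r must lie in [0, 1)")


@dataclass
class Patch:
    """One deme: its corn-habitat fraction and current adult roster."""

    index: int
    f_corn: float
    adults: list = field(default_factory=list)


@dataclass
class MetaPopulation:
    """K patches linked by migration at rate m.

    Under the ``secondary_contact`` scenario the first K/2 patches
    (corn-rich) and the last K/2 (rice-rich) exchange no migrants until
    ``contact_generation``.
    """

    patches: list
    m: float = 0.01
    scenario: str = "sympatry"
    contact_generation: int = 250

    @property
    def K(self) -> int:
        return len(self.patches)

    def all_adults(self):
        for p in self.patches:
            yield from p.adults


def settle(females, f_k: float, rng: np.random.Generator) -> float:
    """Assign each female a habitat (corn with probability f_k); in place.

    Returns the realised corn fraction F_k among these females (binomially
    distributed around f_k).
    """
    n = len(females)
    if n == 0:
        return 0.0
    corn = rng.random(n) < f_k
    for ind, c in zip(females, corn):
        ind.habitat = CORN if c else RICE
    return float(corn.sum()) / n


def viability(tau_juv, ell, habitat, f_k: float, F_k: float,
              params: SelectionParams, L: int = 20):
    """Juvenile survival weight S_k(tau, ell); vectorised over offspring.

    The caller must only evaluate habitats that contain mothers, which
    guarantees F_k > 0 for corn and F_k < 1 for rice.
    """
    tau_juv = np.asarray(tau_juv, dtype=float)
    ell = np.asarray(ell, dtype=float)
    habitat = np.asarray(habitat)
    if np.any((tau_juv < 0) | (tau_juv > 1)) or np.any(ell < 0):
        raise ValueError("tau_juv must lie in [0,1] and ell must be >= 0")
    cost = (1.0 - params.s_r) ** (ell / (2.0 * L))
    is_corn = habitat == CORN
    ratio = np.where(is_corn,
                     f_k / F_k if np.any(is_corn) else 1.0,
                     (1.0 - f_k) / (1.0 - F_k) if np.any(~is_corn) else 1.0)
    opt = np.where(is_corn, params.tau_corn_opt, params.tau_rice_opt)
    s = cost * ratio * np.exp(-params.c * (tau_juv - opt) ** 2)
    return s if s.ndim else float(s)


def _stack_genomes(genomes):
    return (
        np.stack([g.default_sign for g in genomes]),
        np.stack([g.regulation for g in genomes]),
        np.stack([g.regulated_sign for g in genomes]),
        np.stack([g.neutral for g in genomes]),
    )


def regulate(patch: Patch, matings: list, selection: SelectionParams,
             genetics: GeneticsParams, rng: np.random.Generator,
             n_target: int, f_realized: float,
             exact_sex_balance: bool = False) -> list:
    """Soft density regulation: recruit exactly ``n_target`` adults.

    Offspring are generated by repeatedly drawing a mated female uniformly,
    forming one Mendelian offspring with her clutch's sire, and accepting
    it with probability viability / S_bound (rejection sampling; S_bound is
    the larger habitat competition ratio, as the cost and Gaussian factors
    never exceed one).  With no mated females the patch is left empty this
    generation (to be refilled by migration).

    Offspring sex is a fair coin (equal frequencies in expectation), so
    patch sex ratios fluctuate by order sqrt(N) around balance.  These
    fluctuations matter: whenever females are locally in excess, males —
    who return to the market every night — can accumulate extra clutches,
    and the earliest-active males claim them, which is the engine of
    directional sexual selection under the baseline system.
    ``exact_sex_balance=True`` instead recruits exactly half of each sex,
    removing sex-ratio noise (and with it most sexual selection); useful
    as a control.

    Offspring creation is batched over numpy arrays for speed; each
    accepted offspring is statistically identical to a single
    ``make_offspring`` draw followed by the acceptance test.
    """
    records = [r for r in matings if r.sire is not None]
    if not records:
        logger.warning("patch %d: no mated females; left empty this generation",
                       patch.index)
        return []
    n_m = len(records)
    hab = np.array([r.female.habitat for r in records])
    m_def, m_reg, m_rsg, m_neu = _stack_genomes([r.female.genome for r in records])
    f_def, f_reg, f_rsg, f_neu = _stack_genomes([r.sire.genome for r in records])
    L = genetics.L
    f_k, F_k = patch.f_corn, f_realized
    ratios = []
    if np.any(hab == CORN):
        ratios.append(f_k / F_k)
    if np.any(hab == RICE):
        ratios.append((1.0 - f_k) / (1.0 - F_k))
    s_bound = max(ratios)

    batches = []  # accepted (def, reg, rsg, neu) array blocks
    n_accepted = 0
    rows_l = np.arange(L)
    rows_n = np.arange(m_neu.shape[1])
    attempts = 0
    while n_accepted < n_target:
        b = 2 * (n_target - n_accepted) + 16
        attempts += b
        if attempts > 10000 * n_target:
            raise RuntimeError(f"patch {patch.index}: rejection sampler stalled")
        midx = rng.integers(0, n_m, size=b)
        cm = rng.integers(0, 2, size=(b, L))
        cf = rng.integers(0, 2, size=(b, L))
        sel_m = (midx[:, None], rows_l[None, :], cm)
        sel_f = (midx[:, None], rows_l[None, :], cf)
        c_def = np.stack([m_def[sel_m], f_def[sel_f]], axis=2)
        c_reg = np.stack([m_reg[sel_m], f_reg[sel_f]], axis=2)
        c_rsg = np.stack([m_rsg[sel_m], f_rsg[sel_f]], axis=2)
        nm = rng.integers(0, 2, size=(b, rows_n.size))
        nf = rng.integers(0, 2, size=(b, rows_n.size))
        c_neu = np.stack([m_neu[midx[:, None], rows_n[None, :], nm],
                          f_neu[midx[:, None], rows_n[None, :], nf]], axis=2)
        mutate_sign_arrays(c_def, c_reg, c_rsg, genetics.mu,
                           genetics.regulatory_enabled, rng)
        if genetics.mu > 0.0:
            flip = rng.random(c_neu.shape) < genetics.mu
            if flip.any():
                c_neu[flip] ^= 1
        tau_juv = (2 * L + c_def.sum(axis=(1, 2), dtype=np.int64)) / (4.0 * L)
        ell = np.count_nonzero(c_reg != REG_NONE, axis=(1, 2))
        s = viability(tau_juv, ell, hab[midx], f_k, F_k, selection, L)
        accept = np.flatnonzero(rng.random(b) < s / s_bound)[: n_target - n_accepted]
        if accept.size:
            batches.append((c_def[accept], c_reg[accept], c_rsg[accept], c_neu[accept]))
            n_accepted += accept.size
    a_def, a_reg, a_rsg, a_neu = (np.concatenate(parts) for parts in zip(*batches))
    if exact_sex_balance:
        sexes = rng.permutation(np.repeat([FEMALE, MALE], (n_target + 1) // 2)[:n_target])
    else:
        sexes = rng.integers(0, 2, size=n_target)
    # expressed phenotypes, vectorised over the whole cohort
    tau_juv = (2 * L + a_def.sum(axis=(1, 2), dtype=np.int64)) / (4.0 * L)
    eff_f = np.where(a_reg == REG_FEMALE, a_rsg, a_def)
    eff_m = np.where(a_reg == REG_MALE, a_rsg, a_def)
    tau_female = (2 * L + eff_f.sum(axis=(1, 2), dtype=np.int64)) / (4.0 * L)
    tau_male = (2 * L + eff_m.sum(axis=(1, 2), dtype=np.int64)) / (4.0 * L)
    ell = np.count_nonzero(a_reg != REG_NONE, axis=(1, 2))
    return [
        Individual(
            sex=int(sx),
            genome=Genome(a_def[i], a_reg[i], a_rsg[i], a_neu[i]),
            tau_juv=float(tau_juv[i]),
            tau_adult=float(tau_female[i] if sx == FEMALE else tau_male[i]),
            ell=int(ell[i]),
            patch=patch.index,
        )
        for i, sx in enumerate(sexes)
    ]


def migrate(metapop: MetaPopulation, generation: int,
            rng: np.random.Generator) -> MetaPopulation:
    """Disperse a fraction m of adults through the migrant pool(s); in place.

    Each adult emigrates independently with probability m and is reassigned
    uniformly over accessible patches (possibly its natal patch).  Before
    secondary contact, the two K/2-patch clusters keep separate pools.
    """
    K = metapop.K
    split = (metapop.scenario == "secondary_contact"
             and generation < metapop.contact_generation)
    half = K // 2
    pools = {0: [], 1: []} if split else {0: []}
    for patch in metapop.patches:
        n = len(patch.adults)
        if n == 0 or metapop.m == 0.0:
            continue
        stay_mask = rng.random(n) >= metapop.m
        movers = [a for a, stay in zip(patch.adults, stay_mask) if not stay]
        patch.adults = [a for a, stay in zip(patch.adults, stay_mask) if stay]
        key = (patch.index >= half) if split else 0
        pools[int(key)].extend(movers)
    for key, pool in pools.items():
        if not pool:
            continue
        lo, hi = (half * key, half * key + half) if split else (0, K)
        dest = rng.integers(lo, hi, size=len(pool))
        for ind, d in zip(pool, dest):
            ind.patch = int(d)
            metapop.patches[int(d)].adults.append(ind)
    return metapop


def step_generation(metapop: MetaPopulation, generation: int,
                    season: SeasonParams, activity: ActivityParams,
                    selection: SelectionParams, genetics: GeneticsParams,
                    rng: np.random.Generator, n_per_patch: int) -> list:
    """Advance the metapopulation by one generation (in place).

    Order: migration, female habitat settlement, the T-night mating season
    in every patch, sire assignment, and soft density regulation back to
    ``n_per_patch`` adults per patch.  Returns the season's MatingRecords
    (sires set) across all patches, for census statistics.
    """
    migrate(metapop, generation, rng)
    all_records: list[MatingRecord] = []
    for patch in metapop.patches:
        females = [i for i in patch.adults if i.sex == FEMALE]
        f_realized = settle(females, patch.f_corn, rng)
        records = run_season(patch.adults, season, activity, rng)
        for rec in records:
            assign_sire(rec, season.system, rng)
        patch.adults = regulate(patch, records, selection, genetics, rng,
                                n_per_patch, f_realized)
        all_records.extend(records)
    return all_records
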