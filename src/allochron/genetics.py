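"""Diploid genetics of circadian timing and neutral marker loci.

Timing is encoded by L diploid, bi-allelic loci with free recombination.
Alleles act additively with equal effect sizes +/- delta, delta = 1/(4L),
around a baseline of 0.5, so the phenotype tau spans exactly [0, 1]
(all-minus genomes express 0, all-plus genomes express 1).

Each timing allele carries, besides its default effect sign, a
cis-regulatory state: expression may be reversed in adults of one sex
(female- or male-limited regulation), while juveniles and the other sex
express the default sign.  Three mutation types shape this architecture:

1. switch-on  — an unregulated allele acquires female- or male-limited
   regulation; the regulated sex then expresses the reversed sign;
2. switch-off — a regulated allele loses its regulation;
3. default-reversal — the default (juvenile) sign of a regulated allele
   flips without altering what the regulated sex expresses.

Ordinary allelic-state mutations flip the allele wholesale (default sign
and, for regulated alleles, the regulated sign with it) at rate mu per
allele per generation.  When regulatory evolution is enabled, the
regulatory mutation types add a further 2*mu, bringing the total per-allele
event rate to 3*mu in every regulatory state.

A separate panel of 20 neutral diploid bi-allelic loci (alleles 0/1,
mutating at rate mu) tracks genome-wide differentiation; founders are fixed
for allele 0, so any later differentiation reflects accumulated isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "REG_NONE",
    "REG_FEMALE",
    "REG_MALE",
    "JUVENILE",
    "FEMALE_ADULT",
    "MALE_ADULT",
    "N_NEUTRAL_LOCI",
    "TimingAllele",
    "Genome",
    "GeneticsParams",
    "express",
    "count_regulated",
    "mutate",
    "make_offspring",
    "founder_genome",
    "random_genome",
]

logger = logging.getLogger(__name__)

# regulatory states of a timing allele
REG_NONE, REG_FEMALE, REG_MALE = 0, 1, 2

# expression contexts
JUVENILE, FEMALE_ADULT, MALE_ADULT = "juvenile", "female_adult", "male_adult"
_CONTEXT_TO_REG = {JUVENILE: -1, FEMALE_ADULT: REG_FEMALE, MALE_ADULT: REG_MALE}

N_NEUTRAL_LOCI = 20


class TimingAllele(NamedTuple):
    """View of one timing allele: default effect sign and regulatory state."""

    default_sign: int
    regulation: int
    regulated_sign: int


@dataclass
class GeneticsParams:
    """Mutation/architecture parameters.

    L : number of diploid timing loci (effect size delta = 1/(4L)).
    mu : per-allele per-generation rate of allelic-state mutations.
    regulatory_enabled : whether the sex-specific regulatory machinery can
        evolve (adds 2*mu of regulatory events per timing allele).
    """

    L: int = 20
    mu: float = 1.0e-5
    regulatory_enabled: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 <= self.mu < 1.0 / 3.0):
            raise ValueError("mu must satisfy 0 <= mu < 1/3")

    @property
    def delta(self) -> float:
        return 1.0 / (4.0 * self.L)


@dataclass
class Genome:
    """Diploid genotype: (L, 2) timing-allele arrays plus a neutral panel.

    ``default_sign`` and ``regulated_sign`` hold +/-1; ``regulation`` holds
    REG_NONE/REG_FEMALE/REG_MALE; ``neutral`` holds 0/1 alleles with shape
    (N_NEUTRAL_LOCI, 2).  Invariant: unregulated alleles keep
    regulated_sign == default_sign.
    """

    default_sign: np.ndarray
    regulation: np.ndarray
    regulated_sign: np.ndarray
    neutral: np.ndarray

    @property
    def L(self) -> int:
        return self.default_sign.shape[0]

    def allele(self, locus: int, copy: int) -> TimingAllele:
        return TimingAllele(
            int(self.default_sign[locus, copy]),
            int(self.regulation[locus, copy]),
            int(self.regulated_sign[locus, copy]),
        )

    def copy(self) -> "Genome":
        return Genome(
            self.default_sign.copy(),
            self.regulation.copy(),
            self.regulated_sign.copy(),
            self.neutral.copy(),
        )


def express(genome: Genome, context: str) -> float:
    """Expressed timing phenotype tau in the given context.

    tau = 0.5 + sum over the 2L alleles of (effective sign) * delta with
    delta = 1/(4L).  The effective sign of an allele is its regulated sign
    in adults of the sex its regulation targets, and its default sign
    otherwise (juveniles always express defaults).
    """
    reg_ctx = _CONTEXT_TO_REG[context]
    if reg_ctx < 0:
        eff = genome.default_sign
    else:
        eff = np.where(genome.regulation == reg_ctx, genome.regulated_sign, genome.default_sign)
    # single correctly-rounded division keeps achievable phenotypes exact
    L = genome.L
    return (2 * L + int(eff.sum())) / (4.0 * L)


def count_regulated(genome: Genome) -> int:
    """Number ell of timing alleles under sex-specific regulation (0..2L)."""
    return int(np.count_nonzero(genome.regulation != REG_NONE))


def mutate_sign_arrays(default_sign: np.ndarray, regulation: np.ndarray,
                       regulated_sign: np.ndarray, mu: float,
                       regulatory_enabled: bool, rng: np.random.Generator) -> int:
    """Mutate timing-allele arrays in place; returns the number of events.

    Works on arrays of any leading shape (one genome's (L, 2) slots or a
    batch (B, L, 2)).  Every allele draws one uniform; the [0, total_rate)
    interval is partitioned into equal-mu slices whose meaning depends on
    the allele's regulatory state, keeping the total event rate at 3*mu
    (regulation enabled) or mu (disabled) in every state.
    """
    if mu == 0.0:
        return 0
    u = rng.random(default_sign.shape)
    total = 3.0 * mu if regulatory_enabled else mu
    hit = u < total
    if not hit.any():
        return 0
    n_events = int(hit.sum())
    # slice 0: allelic-state flip (all regulatory states)
    flip = u < mu
    if flip.any():
        default_sign[flip] *= -1
        # regulated alleles flip wholesale; unregulated keep signs mirrored
        regulated_sign[flip] *= -1
    if regulatory_enabled:
        regulated = regulation != REG_NONE
        # slices 1 and 2 for unregulated alleles: switch on female / male regulation
        on_f = (~regulated) & (u >= mu) & (u < 2.0 * mu)
        on_m = (~regulated) & (u >= 2.0 * mu) & (u < 3.0 * mu)
        if on_f.any():
            regulation[on_f] = REG_FEMALE
            regulated_sign[on_f] = -default_sign[on_f]
        if on_m.any():
            regulation[on_m] = REG_MALE
            regulated_sign[on_m] = -default_sign[on_m]
        # slices 1 and 2 for regulated alleles: switch off / reverse default
        off = regulated & (u >= mu) & (u < 2.0 * mu)
        rev = regulated & (u >= 2.0 * mu) & (u < 3.0 * mu)
        if off.any():
            regulation[off] = REG_NONE
            regulated_sign[off] = default_sign[off]
        if rev.any():
            # default (juvenile) expression reverses; adult pattern untouched
            default_sign[rev] *= -1
    return n_events


def _apply_timing_mutations(genome: Genome, mu: float, regulatory_enabled: bool,
                            rng: np.random.Generator) -> int:
    return mutate_sign_arrays(genome.default_sign, genome.regulation,
                              genome.regulated_sign, mu, regulatory_enabled, rng)


def mutate(genome: Genome, mu: float, regulatory_enabled: bool,
           rng: np.random.Generator, return_events: bool = False):
    """Return a mutated copy of ``genome``.

    Timing alleles: allelic-state flips at rate mu, plus (when enabled)
    regulatory events at 2*mu partitioned as described in the module
    docstring.  Neutral alleles flip 0<->1 at rate mu.
    """
    out = genome.copy()
    n_events = _apply_timing_mutations(out, mu, regulatory_enabled, rng)
    if mu > 0.0:
        flip_n = rng.random(out.neutral.shape) < mu
        if flip_n.any():
            out.neutral[flip_n] ^= 1
    if return_events:
        return out, n_events
    return out


def make_offspring(mother, father, rng: np.random.Generator,
                   params: GeneticsParams | None = None) -> Genome:
    """Mendelian offspring genome: one allele per locus from each parent.

    ``mother``/``father`` may be Genome objects or individuals exposing a
    ``genome`` attribute (and a ``sex`` attribute, in which case opposite
    sexes are enforced).  Loci recombine freely.  Mutation is applied when
    ``params`` is given.
    """
    gm = getattr(mother, "genome", mother)
    gf = getattr(father, "genome", father)
    sm, sf = getattr(mother, "sex", None), getattr(father, "sex", None)
    if sm is not None and sf is not None and sm == sf:
        raise ValueError("parents must be of opposite sex")
    L = gm.L
    mi = rng.integers(0, 2, size=L)
    fi = rng.integers(0, 2, size=L)
    rows = np.arange(L)
    child = Genome(
        default_sign=np.stack([gm.default_sign[rows, mi], gf.default_sign[rows, fi]], axis=1),
        regulation=np.stack([gm.regulation[rows, mi], gf.regulation[rows, fi]], axis=1),
        regulated_sign=np.stack([gm.regulated_sign[rows, mi], gf.regulated_sign[rows, fi]], axis=1),
        neutral=_inherit_neutral(gm.neutral, gf.neutral, rng),
    )
    if params is not None:
        _apply_timing_mutations(child, params.mu, params.regulatory_enabled, rng)
        if params.mu > 0.0:
            flip = rng.random(child.neutral.shape) < params.mu
            if flip.any():
                child.neutral[flip] ^= 1
    return child


def _inherit_neutral(nm: np.ndarray, nf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = nm.shape[0]
    rows = np.arange(n)
    return np.stack(
        [nm[rows, rng.integers(0, 2, size=n)], nf[rows, rng.integers(0, 2, size=n)]],
        axis=1,
    ).astype(np.int8)


def founder_genome(tau0: float, L: int = 20) -> Genome:
    """Deterministic founder genome expressing juvenile timing ``tau0``.

    Places n_plus = round(2L * tau0) plus-alleles (the rest minus) in a
    homozygous locus-by-locus layout from the first locus, with at most one
    heterozygous locus when n_plus is odd; no allele is regulated, and the
    neutral panel is fixed for allele 0.  If ``tau0`` is not expressible as
    0.5 + (n_plus - n_minus)/(4L), the nearest achievable value is used and
    a warning logged.
    """
    if not 0.0 <= tau0 <= 1.0:
        raise ValueError("tau0 must lie in [0, 1]")
    n_plus = int(round(2 * L * tau0))
    achieved = 0.5 + (2 * n_plus - 2 * L) / (4.0 * L)
    if abs(achieved - tau0) > 1e-12:
        logger.warning(
            "tau0=%g not achievable with L=%d; using nearest value %g", tau0, L, achieved
        )
    sign = -np.ones((L, 2), dtype=np.int8)
    flat = sign.reshape(-1)  # row-major: locus-by-locus, homozygous first
    flat[:n_plus] = 1
    return Genome(
        default_sign=sign,
        regulation=np.zeros((L, 2), dtype=np.int8),
        regulated_sign=sign.copy(),
        neutral=np.zeros((N_NEUTRAL_LOCI, 2), dtype=np.int8),
    )


def random_genome(rng: np.random.Generator, L: int = 20, p_plus: float = 0.5) -> Genome:
    """Unregulated genome with i.i.d. +/- alleles (plus with prob. p_plus).

    Convenience generator for toy populations with standing timing
    variance (tau has mean ~0.5 and SD sqrt(2L p(1-p))/(2L) at p=1/2).
    """
    sign = np.where(rng.random((L, 2)) < p_plus, 1, -1).astype(np.int8)
    return Genome(
        default_sign=sign,
        regulation=np.zeros((L, 2), dtype=np.int8),
        regulated_sign=sign.copy(),
        neutral=np.zeros((N_NEUTRAL_LOCI, 2), dtype=np.int8),
    )
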