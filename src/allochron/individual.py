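"""Individual moths: sex, genome, and cached expressed phenotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetics import (
    FEMALE_ADULT,
    JUVENILE,
    MALE_ADULT,
    Genome,
    count_regulated,
    express,
)

__all__ = ["FEMALE", "MALE", "CORN", "RICE", "UNSET", "Individual", "new_adult"]

FEMALE, MALE = 0, 1
# habitat labels; habitat is set for females at settlement, UNSET otherwise
CORN, RICE, UNSET = 0, 1, -1


@dataclass(slots=True, eq=False)  # identity semantics: each moth is unique
class Individual:
    """One adult moth.

    Expressed phenotypes are computed once at the adult transition and
    cached: ``tau_juv`` is the juvenile (default-sign) timing used for
    viability selection, ``tau_adult`` the sex-specific adult timing
    governing mate encounters, and ``ell`` the number of sex-specifically
    regulated timing alleles (which sets the regulation survival cost).
    """

    sex: int
    genome: Genome
    tau_juv: float
    tau_adult: float
    ell: int
    patch: int = 0
    habitat: int = UNSET
    mate_ids: list = field(default_factory=list)


def new_adult(sex: int, genome: Genome, patch: int = 0) -> Individual:
    """Build an adult, expressing juvenile and sex-specific adult timing."""
    tau_juv = express(genome, JUVENILE)
    tau_adult = express(genome, FEMALE_ADULT if sex == FEMALE else MALE_ADULT)
    return Individual(
        sex=sex,
        genome=genome,
        tau_juv=tau_juv,
        tau_adult=tau_adult,
        ell=count_regulated(genome),
        patch=patch,
    )
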