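"""Small synthetic populations for experiments and tests.

These builders produce toy patches with controlled timing variance —
useful for probing the mating market in isolation from the full life
cycle.  They are not part of the simulation itself.
"""

from __future__ import annotations

import numpy as np

from .genetics import founder_genome, random_genome
from .individual import FEMALE, MALE, Individual, new_adult

__all__ = ["spread_adults", "toy_patch"]


def spread_adults(n: int, sex: int, rng: np.random.Generator,
                  tau_range: tuple[float, float] = (0.1, 0.9), L: int = 20) -> list:
    """``n`` adults of one sex with juvenile timings evenly spread over
    ``tau_range`` (snapped to the nearest achievable genotypic value) and
    shuffled ordering."""
    taus = np.linspace(tau_range[0], tau_range[1], n)
    adults = [new_adult(sex, founder_genome(float(t), L)) for t in taus]
    rng.shuffle(adults)
    return adults


def toy_patch(n_females: int, n_males: int, rng: np.random.Generator,
              tau_range: tuple[float, float] = (0.1, 0.9)) -> list:
    """A mixed-sex toy roster with standing timing variance in both sexes."""
    return (spread_adults(n_females, FEMALE, rng, tau_range)
            + spread_adults(n_males, MALE, rng, tau_range))
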