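"""The nightly mating market over a T-night season, under three mating systems.

baseline (*S. frugiperda*-like, first-male precedence)
    Encounters are processed in chronological order within each night; a
    mating happens iff both partners are still available at that moment.
    Mating occupies the rest of the night for both partners (neither can
    mate twice in one night).  A mated female leaves the market for the
    whole season; males return the next night.  Because late males find the
    pool of receptive females depleted by earlier rivals, this system
    generates directional sexual selection for early male activity.

scramble
    Mating takes negligible time: a female mates with *every* male she
    encounters during her night, the males remaining available throughout.
    She then leaves the market; one of her partners (uniformly chosen)
    sires the whole clutch.

monogamy
    As baseline, but a mated male also leaves the market for the rest of
    the season: available males and females deplete in pairs, so the
    operational sex ratio stays constant and sexual selection on timing is
    suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import betaincinv

from .activity import ActivityParams, pair_encounter_matrix
from .individual import FEMALE, MALE, Individual

__all__ = [
    "SYSTEMS",
    "SeasonParams",
    "EncounterEvent",
    "MatingRecord",
    "simulate_night",
    "run_season",
    "assign_sire",
]

SYSTEMS = ("baseline", "scramble", "monogamy")


@dataclass(frozen=True)
class SeasonParams:
    """Mating-season parameters: number of nights T and the mating system."""

    T: int = 100
    system: str = "baseline"

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown mating system {self.system!r}; expected one of {SYSTEMS}")


class EncounterEvent(NamedTuple):
    """A time-stamped female-male encounter within one night."""

    night: int
    time: float
    female: "Individual"
    male: "Individual"


@dataclass
class MatingRecord:
    """Realised matings of one female over the season.

    Under baseline and monogamy ``partners`` holds exactly one male; under
    scramble it holds every male mated during the female's single active
    night (with multiplicity).  ``sire`` is set by :func:`assign_sire`.
    """

    female: Individual
    partners: list = field(default_factory=list)
    sire: Individual | None = None
    night_mated: int = 0


def _sample_events(lam_sub: np.ndarray, tau_f: np.ndarray, tau_m: np.ndarray,
                   a: float, rng: np.random.Generator):
    """Draw each pair's *first* nightly encounter, sorted by time.

    Per pair, the number of encounters is Poisson(lambda) with i.i.d.
    beta-distributed times; but under baseline and monogamy a mating
    blocks both partners for the rest of the night, so an encounter later
    than a pair's first one can never change the outcome (if the first was
    skipped, the blocking partner is still blocked).  It therefore
    suffices to sample, for pairs with k >= 1 encounters, the minimum of k
    beta variates — via the beta quantile of the minimum of k uniforms —
    which cuts the event list from O(sum k) to one entry per meeting pair.

    Returns (rows, cols, times) time-sorted; rows/cols index into the
    current female/male subsets.
    """
    counts = rng.poisson(lam_sub)
    rows, cols = np.nonzero(counts)
    if rows.size == 0:
        return rows, cols, np.empty(0)
    return _order_first_encounters(counts, rows, cols, tau_f, tau_m, a, rng)


def _resolve_night(counts, rows, cols, tau_f, tau_m, n_f, n_m, a, rng):
    """Matings of one night given the pair-encounter counts.

    Chronological order only matters among pairs connected through shared
    individuals, so the bipartite encounter graph is split into connected
    components: single-pair components mate unconditionally, and
    first-encounter times are sampled only inside larger components, where
    the sequential first-available rule is applied.  Returns the mated
    (rows, cols).
    """
    if rows.size == 1:
        return rows, cols
    n = rows.size
    if n > 2000:
        # dense market: almost surely one giant component; order it whole
        r, c, _ = _order_first_encounters(counts, rows, cols, tau_f, tau_m,
                                          a, rng, order_only=True)
        picked = _chronological_matings(r, c, n_f, n_m)
        return r[picked], c[picked]
    adj = coo_matrix((np.ones(n, dtype=np.int8), (rows, n_f + cols)),
                     shape=(n_f + n_m, n_f + n_m))
    ncomp, labels = connected_components(adj, directed=False)
    edge_comp = labels[rows]
    edges_per_comp = np.bincount(edge_comp, minlength=ncomp)
    single = edges_per_comp[edge_comp] == 1
    out_r = [rows[single]]
    out_c = [cols[single]]
    # contested components resolved independently (they share no individual);
    # within a timing-monomorphic component the quantile transform is skipped
    if not single.all():
        comp_sorted = edge_comp[~single]
        order = np.argsort(comp_sorted, kind="stable")
        cr, cc = rows[~single][order], cols[~single][order]
        bounds = np.flatnonzero(np.r_[True, np.diff(comp_sorted[order]) != 0, True])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            er, ec, _ = _order_first_encounters(counts, cr[lo:hi], cc[lo:hi],
                                                tau_f, tau_m, a, rng, order_only=True)
            picked = _chronological_matings(er, ec, n_f, n_m)
            out_r.append(er[picked])
            out_c.append(ec[picked])
    return np.concatenate(out_r), np.concatenate(out_c)


def _order_first_encounters(counts, rows, cols, tau_f, tau_m, a, rng,
                            order_only: bool = False):
    """Min-of-k beta first-encounter times for meeting pairs, time-sorted.

    With ``order_only`` and all pairs sharing one encounter-time
    distribution (a timing-monomorphic market), the beta quantile map is
    strictly increasing and common to all pairs, so the quantile levels
    themselves give the exact chronological order and the transform is
    skipped.
    """
    k = counts[rows, cols].astype(float)
    u_min = 1.0 - (1.0 - rng.random(rows.size)) ** (1.0 / k)
    tau_bar = (tau_f[rows] + tau_m[cols]) / 2.0
    if order_only and np.ptp(tau_bar) == 0.0:
        times = u_min
    else:
        times = betaincinv(1.0 + a * tau_bar, 1.0 + a * (1.0 - tau_bar), u_min)
    order = np.argsort(times, kind="stable")
    return rows[order], cols[order], times[order]


def _chronological_matings(rows: np.ndarray, cols: np.ndarray, n_f: int, n_m: int):
    """First-available sequential matching over time-ordered encounters.

    Both participants of an event mate iff neither has mated yet tonight;
    skipped events can never become valid later, so scanning forward over
    the sorted events is exact.  Returns indices into the event arrays.
    """
    f_free = np.ones(n_f, dtype=bool)
    m_free = np.ones(n_m, dtype=bool)
    picked = []
    i, n = 0, rows.size
    while i < n:
        valid = f_free[rows[i:]] & m_free[cols[i:]]
        j = int(np.argmax(valid))
        if not valid[j]:
            break
        i += j
        picked.append(i)
        f_free[rows[i]] = False
        m_free[cols[i]] = False
        i += 1
    return picked


def simulate_night(females: Sequence[Individual], males: Sequence[Individual],
                   system: str, activity: ActivityParams, rng: np.random.Generator,
                   night: int = 1):
    """Simulate one night among currently available adults.

    Returns a list of ``EncounterEvent`` records, one per realised mating
    (a scramble female appears once per partner).  Availability across
    nights is the caller's concern (see :func:`run_season`).
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown mating system {system!r}")
    if not females or not males:
        return []
    tau_f = np.array([f.tau_adult for f in females])
    tau_m = np.array([m.tau_adult for m in males])
    lam = pair_encounter_matrix(tau_f, tau_m, activity)
    return _night_matings(lam, tau_f, tau_m, females, males, system, activity.a, rng, night)


def _night_matings(lam, tau_f, tau_m, females, males, system, a, rng, night):
    if system == "scramble":
        counts = rng.poisson(lam)
        rows, cols = np.nonzero(counts)
        out = []
        for r, c in zip(rows, cols):
            out.extend(
                EncounterEvent(night, np.nan, females[r], males[c])
                for _ in range(int(counts[r, c]))
            )
        return out
    rows, cols, times = _sample_events(lam, tau_f, tau_m, a, rng)
    picked = _chronological_matings(rows, cols, len(females), len(males))
    return [EncounterEvent(night, float(times[i]), females[rows[i]], males[cols[i]]) for i in picked]


def run_season(adults: Sequence[Individual], params: SeasonParams,
               activity: ActivityParams, rng: np.random.Generator) -> list[MatingRecord]:
    """Run the full T-night season for one patch.

    Returns one :class:`MatingRecord` per mated female (sire unset).
    Females leave the market permanently after mating in every system;
    males only do so under monogamy.
    """
    females = [i for i in adults if i.sex == FEMALE]
    males = [i for i in adults if i.sex == MALE]
    if not females or not males:
        return []
    tau_f = np.array([f.tau_adult for f in females])
    tau_m = np.array([m.tau_adult for m in males])
    lam = pair_encounter_matrix(tau_f, tau_m, activity)
    f_avail = np.ones(len(females), dtype=bool)
    m_avail = np.ones(len(males), dtype=bool)
    records: list[MatingRecord] = []

    for night in range(1, params.T + 1):
        f_idx = np.flatnonzero(f_avail)
        m_idx = np.flatnonzero(m_avail)
        if f_idx.size == 0 or m_idx.size == 0:
            break
        sub = lam[np.ix_(f_idx, m_idx)]
        if not sub.any():
            break  # remaining pairs can never meet; rates are season-constant

        if params.system == "scramble":
            counts = rng.poisson(sub)
            row_tot = counts.sum(axis=1)
            for r in np.flatnonzero(row_tot):
                fg = int(f_idx[r])
                partners = [males[int(m_idx[c])] for c in np.repeat(
                    np.arange(m_idx.size), counts[r])]
                rec = MatingRecord(female=females[fg], partners=partners, night_mated=night)
                females[fg].mate_ids.extend(id(p) for p in partners)
                records.append(rec)
                f_avail[fg] = False
        else:
            counts = rng.poisson(sub)
            rows, cols = np.nonzero(counts)
            if rows.size == 0:
                continue
            rows, cols = _resolve_night(counts, rows, cols, tau_f[f_idx],
                                        tau_m[m_idx], f_idx.size, m_idx.size,
                                        activity.a, rng)
            picked = range(rows.size)
            for i in picked:
                fg, mg = int(f_idx[rows[i]]), int(m_idx[cols[i]])
                rec = MatingRecord(female=females[fg], partners=[males[mg]],
                                   night_mated=night)
                females[fg].mate_ids.append(id(males[mg]))
                records.append(rec)
                f_avail[fg] = False
                if params.system == "monogamy":
                    m_avail[mg] = False
    return records


def assign_sire(record: MatingRecord, system: str, rng: np.random.Generator) -> MatingRecord:
    """Set the sire of a female's clutch.

    Single-partner records (baseline/monogamy, or a one-partner scramble
    night) use that male; multi-partner scramble records draw the sire
    uniformly — every mate has an equal chance of fathering the clutch.
    """
    if not record.partners:
        raise ValueError("cannot assign a sire to a record with no partners")
    if len(record.partners) == 1:
        record.sire = record.partners[0]
    else:
        record.sire = record.partners[int(rng.integers(len(record.partners)))]
    return record
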