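"""The nightly mating market and the three mating systems."""

import numpy as np
import pytest

from allochron.activity import ActivityParams, pair_encounter_matrix
from allochron.genetics import founder_genome
from allochron.individual import FEMALE, MALE, new_adult
from allochron.mating import (
    MatingRecord,
    SeasonParams,
    assign_sire,
    run_season,
    simulate_night,
)


def adults(taus_f, taus_m):
    fem = [new_adult(FEMALE, founder_genome(t)) for t in taus_f]
    mal = [new_adult(MALE, founder_genome(t)) for t in taus_m]
    return fem, mal


DENSE = ActivityParams(a=50.0, eta=25.0)


class TestSimulateNight:
    def test_empty_market(self, rng):
        assert simulate_night([], [], "baseline", DENSE, rng) == []

    def test_single_pair_mates_with_poisson_zero_class_rate(self, rng):
        # P(mating) = P(at least one encounter) = 1 - exp(-eta)
        eta = 0.5
        params = ActivityParams(a=50.0, eta=eta)
        n = 4000
        mated = 0
        for _ in range(n):
            f, m = adults([0.5], [0.5])
            mated += bool(simulate_night(f, m, "baseline", params, rng))
        p = 1.0 - np.exp(-eta)
        se = np.sqrt(n * p * (1 - p))
        assert abs(mated - n * p) < 3 * se

    def test_identical_pair_with_dense_encounters_always_mates(self, rng):
        for _ in range(50):
            f, m = adults([0.5], [0.5])
            assert len(simulate_night(f, m, "baseline", DENSE, rng)) == 1

    def test_baseline_one_female_mates_exactly_one_of_two_males(self, rng):
        for _ in range(50):
            f, m = adults([0.5], [0.5, 0.5])
            matings = simulate_night(f, m, "baseline", DENSE, rng)
            assert len(matings) == 1

    def test_scramble_female_mates_every_encountered_male(self, rng):
        # with eta=25 the female all but surely meets both males
        f, m = adults([0.5], [0.5, 0.5])
        matings = simulate_night(f, m, "scramble", DENSE, rng)
        assert {id(e.male) for e in matings} == {id(x) for x in m}

    def test_baseline_nobody_mates_twice_in_a_night(self, rng):
        f, m = adults([0.3, 0.5, 0.7] * 4, [0.3, 0.5, 0.7] * 4)
        matings = simulate_night(f, m, "baseline", DENSE, rng)
        females = [id(e.female) for e in matings]
        males = [id(e.male) for e in matings]
        assert len(females) == len(set(females))
        assert len(males) == len(set(males))

    def test_unknown_system_rejected(self, rng):
        f, m = adults([0.5], [0.5])
        with pytest.raises(ValueError):
            simulate_night(f, m, "polygyny", DENSE, rng)


class TestAgainstBruteForce:
    """The production path samples only each pair's first nightly encounter;
    the oracle simulates every encounter event and processes them in time
    order.  Pair-mating frequencies must agree."""

    @staticmethod
    def brute_force_night(fem, mal, system, params, rng):
        tau_f = np.array([f.tau_adult for f in fem])
        tau_m = np.array([m.tau_adult for m in mal])
        lam = pair_encounter_matrix(tau_f, tau_m, params)
        events = []
        for i in range(len(fem)):
            for j in range(len(mal)):
                for _ in range(rng.poisson(lam[i, j])):
                    tb = (tau_f[i] + tau_m[j]) / 2.0
                    t = rng.beta(1 + params.a * tb, 1 + params.a * (1 - tb))
                    events.append((t, i, j))
        events.sort()
        f_free = [True] * len(fem)
        m_free = [True] * len(mal)
        out = []
        for _, i, j in events:
            if f_free[i] and m_free[j]:
                out.append((i, j))
                f_free[i] = False
                m_free[j] = False
        return out

    def test_pair_mating_frequencies_match(self, rng):
        taus_f, taus_m = [0.35, 0.5], [0.4, 0.5, 0.65]
        params = ActivityParams(a=50.0, eta=3.0)
        n = 3000
        counts_fast = np.zeros((2, 3))
        counts_slow = np.zeros((2, 3))
        for _ in range(n):
            fem, mal = adults(taus_f, taus_m)
            fi = {id(x): k for k, x in enumerate(fem)}
            mi = {id(x): k for k, x in enumerate(mal)}
            for e in simulate_night(fem, mal, "baseline", params, rng):
                counts_fast[fi[id(e.female)], mi[id(e.male)]] += 1
            for i, j in self.brute_force_night(fem, mal, "baseline", params, rng):
                counts_slow[i, j] += 1
        # total-variation distance between pair-frequency tables
        tv = 0.5 * np.abs(counts_fast / n - counts_slow / n).sum()
        assert tv < 0.05


class TestRunSeason:
    def test_zero_nights_no_matings(self, rng):
        f, m = adults([0.5], [0.5])
        assert run_season(f + m, SeasonParams(T=0), DENSE, rng) == []

    def test_single_sex_roster_empty_result(self, rng):
        f, _ = adults([0.5, 0.5], [])
        assert run_season(f, SeasonParams(T=10), DENSE, rng) == []

    def test_monogamy_two_females_one_male_single_mating(self, rng):
        for _ in range(20):
            f, m = adults([0.5, 0.5], [0.5])
            recs = run_season(f + m, SeasonParams(T=10, system="monogamy"), DENSE, rng)
            assert len(recs) == 1

    def test_baseline_male_remates_across_nights(self, rng):
        for _ in range(20):
            f, m = adults([0.5, 0.5], [0.5])
            recs = run_season(f + m, SeasonParams(T=5, system="baseline"), DENSE, rng)
            assert len(recs) == 2
            assert sorted(r.night_mated for r in recs) == [1, 2]

    def test_each_female_mates_at_most_once_per_season(self, rng):
        f, m = adults(np.linspace(0.2, 0.8, 10), np.linspace(0.2, 0.8, 10))
        for system in ("baseline", "scramble", "monogamy"):
            recs = run_season(f + m, SeasonParams(T=20, system=system), DENSE, rng)
            ids = [id(r.female) for r in recs]
            assert len(ids) == len(set(ids))
            for r in f:
                r.mate_ids.clear()

    def test_monogamy_males_sire_at_most_once(self, rng):
        f, m = adults(np.linspace(0.2, 0.8, 10), np.linspace(0.2, 0.8, 10))
        recs = run_season(f + m, SeasonParams(T=20, system="monogamy"), DENSE, rng)
        partner_ids = [id(p) for r in recs for p in r.partners]
        assert len(partner_ids) == len(set(partner_ids))

    def test_monogamy_available_sex_difference_constant(self, rng):
        # males and females leave the market in pairs
        f, m = adults([0.4, 0.5, 0.6, 0.5], [0.5, 0.5])
        recs = run_season(f + m, SeasonParams(T=30, system="monogamy"), DENSE, rng)
        assert len(recs) == 2  # both males consumed, two females left over

    def test_scramble_records_allow_multiple_partners(self, rng):
        f, m = adults([0.5], [0.5, 0.5, 0.5])
        recs = run_season(f + m, SeasonParams(T=1, system="scramble"), DENSE, rng)
        assert len(recs) == 1
        assert len(recs[0].partners) >= 2  # virtually surely meets >1 male at eta=25


class TestAssignSire:
    def test_single_partner_is_sire(self, rng):
        f, m = adults([0.5], [0.5])
        rec = MatingRecord(female=f[0], partners=[m[0]])
        assert assign_sire(rec, "baseline", rng).sire is m[0]

    def test_no_partner_is_error(self, rng):
        f, _ = adults([0.5], [])
        with pytest.raises(ValueError):
            assign_sire(MatingRecord(female=f[0]), "scramble", rng)

    def test_scramble_sire_uniform_over_partners(self, rng):
        f, m = adults([0.5], [0.2, 0.4, 0.6, 0.8])
        n = 10_000
        hits = np.zeros(4)
        for _ in range(n):
            rec = MatingRecord(female=f[0], partners=list(m))
            sire = assign_sire(rec, "scramble", rng).sire
            hits[m.index(sire)] += 1
        se = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(hits - n / 4) < 3 * se)
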