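"""Settlement, viability selection, density regulation, migration."""

import dataclasses

import numpy as np
import pytest

from allochron.activity import ActivityParams
from allochron.config import SimulationConfig
from allochron.genetics import GeneticsParams, founder_genome
from allochron.individual import CORN, FEMALE, MALE, RICE, new_adult
from allochron.lifecycle import (
    MetaPopulation,
    Patch,
    SelectionParams,
    migrate,
    regulate,
    settle,
    step_generation,
    viability,
)
from allochron.mating import MatingRecord, SeasonParams
from allochron.run import initialize_metapopulation


def females(n, tau=0.5):
    return [new_adult(FEMALE, founder_genome(tau)) for _ in range(n)]


class TestSettle:
    def test_all_corn_when_f_is_one(self, rng):
        fem = females(10)
        assert settle(fem, 1.0, rng) == 1.0
        assert all(f.habitat == CORN for f in fem)

    def test_all_rice_when_f_is_zero(self, rng):
        fem = females(10)
        assert settle(fem, 0.0, rng) == 0.0
        assert all(f.habitat == RICE for f in fem)

    def test_realized_fraction_binomial(self, rng):
        n, f_k, reps = 250, 0.8, 10_000
        fem = females(n)
        vals = np.array([settle(fem, f_k, rng) for _ in range(reps)])
        se_mean = np.sqrt(f_k * (1 - f_k) / n / reps)
        assert abs(vals.mean() - f_k) < 3 * se_mean
        assert vals.var() == pytest.approx(f_k * (1 - f_k) / n, rel=0.1)


class TestViability:
    def test_optimal_unregulated_resident_has_unit_survival(self):
        p = SelectionParams(c=1.0, s_r=0.05)
        assert viability(0.0, 0, CORN, 0.8, 0.8, p) == pytest.approx(1.0)

    def test_no_selection_when_c_zero(self):
        p = SelectionParams(c=0.0, s_r=0.05)
        vals = [viability(t, 0, RICE, 0.5, 0.5, p) for t in (0.0, 0.4, 1.0)]
        assert np.ptp(vals) == 0.0

    def test_scalar_formula(self):
        # (1-0.05)^(40/40) * 1 * exp(-1*(0.5-0)^2)
        p = SelectionParams(c=1.0, tau_corn_opt=0.0, s_r=0.05)
        expect = 0.95 * np.exp(-0.25)
        assert viability(0.5, 40, CORN, 0.8, 0.8, p, L=20) == pytest.approx(expect)

    def test_competition_ratio_scales_survival(self):
        p = SelectionParams(c=0.0)
        assert viability(0.5, 0, CORN, 0.8, 0.4, p) == pytest.approx(2.0)
        assert viability(0.5, 0, RICE, 0.8, 0.4, p) == pytest.approx(0.2 / 0.6)

    def test_domain_errors(self):
        p = SelectionParams()
        with pytest.raises(ValueError):
            viability(1.5, 0, CORN, 0.8, 0.8, p)


def mated_record(tau_mother, tau_father, habitat):
    mother = new_adult(FEMALE, founder_genome(tau_mother))
    father = new_adult(MALE, founder_genome(tau_father))
    mother.habitat = habitat
    return MatingRecord(female=mother, partners=[father], sire=father)


NEUTRAL_GENETICS = GeneticsParams(L=20, mu=0.0, regulatory_enabled=False)


class TestRegulate:
    def test_single_pair_neutral_fills_patch(self, rng):
        patch = Patch(0, 0.8)
        recs = [mated_record(0.5, 0.5, CORN)]
        sel = SelectionParams(c=0.0, s_r=0.0)
        roster = regulate(patch, recs, sel, NEUTRAL_GENETICS, rng, 100, 1.0)
        assert len(roster) == 100
        assert all(ind.tau_juv == 0.5 for ind in roster)  # parents homozygous-identical

    def test_roster_size_is_exactly_n(self, rng):
        patch = Patch(0, 0.5)
        recs = [mated_record(0.1, 0.9, CORN), mated_record(0.9, 0.1, RICE)]
        sel = SelectionParams(c=2.0)
        roster = regulate(patch, recs, sel, NEUTRAL_GENETICS, rng, 251, 0.5)
        assert len(roster) == 251

    def test_no_mated_females_leaves_patch_empty(self, rng, caplog):
        import logging

        patch = Patch(3, 0.5)
        with caplog.at_level(logging.WARNING):
            roster = regulate(patch, [], SelectionParams(), NEUTRAL_GENETICS, rng, 100, 0.5)
        assert roster == []
        assert any("no mated females" in r.message for r in caplog.records)

    def test_maternal_share_follows_viability_ratio(self, rng):
        # two corn mothers whose offspring viabilities differ by e^{-ln 2}=1/2
        c = np.log(2.0) / (0.5**2 - 0.25**2)
        sel = SelectionParams(c=c, tau_corn_opt=0.0, s_r=0.0)
        patch = Patch(0, 0.8)
        recs = [mated_record(0.25, 0.25, CORN), mated_record(0.5, 0.5, CORN)]
        n = 6000
        roster = regulate(patch, recs, sel, NEUTRAL_GENETICS, rng, n, 1.0)
        share = np.mean([ind.tau_juv == 0.25 for ind in roster])
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(share - 2 / 3) < 3.5 * se

    def test_rejection_sampler_matches_enumerated_lottery(self, rng):
        # five mothers with distinct genotypes; compare maternal frequencies
        # against the explicit normalised-weight lottery
        taus = [0.1, 0.3, 0.5, 0.7, 0.9]
        sel = SelectionParams(c=1.5, tau_corn_opt=0.0, s_r=0.0)
        patch = Patch(0, 0.8)
        recs = [mated_record(t, t, CORN) for t in taus]
        n = 100_000
        roster = regulate(patch, recs, sel, NEUTRAL_GENETICS, rng, n, 1.0)
        got = np.array([np.mean([ind.tau_juv == t for ind in roster]) for t in taus])
        w = np.exp(-1.5 * np.array(taus) ** 2)
        expect = w / w.sum()
        assert 0.5 * np.abs(got - expect).sum() < 0.02  # total variation

    def test_soft_selection_habitat_shares_track_f_k(self, rng):
        # expected corn-habitat offspring share equals f_k regardless of the
        # realized settlement fraction F_k: the f/F weights cancel settlement
        # noise.  Corn and rice mothers are tagged by distinct timings.
        f_k = 0.7
        sel = SelectionParams(c=0.0, s_r=0.0)
        for n_corn in (2, 5, 8):  # deliberately skewed realisations
            F_k = n_corn / 10
            recs = [mated_record(0.4, 0.4, CORN) for _ in range(n_corn)]
            recs += [mated_record(0.6, 0.6, RICE) for _ in range(10 - n_corn)]
            n = 20_000
            roster = regulate(Patch(0, f_k), recs, sel, NEUTRAL_GENETICS, rng, n, F_k)
            corn_share = np.mean([ind.tau_juv == 0.4 for ind in roster])
            se = np.sqrt(f_k * (1 - f_k) / n)
            assert abs(corn_share - f_k) < 4 * se


class TestMigrate:
    def metapop(self, K=4, N=20, m=0.5, scenario="sympatry", contact=100):
        cfg = SimulationConfig(K=K, N=N, m=m, scenario=scenario,
                               contact_generation=contact, generations=0)
        mp = initialize_metapopulation(cfg)
        return mp

    def test_zero_rate_identity(self, rng):
        mp = self.metapop(m=0.0)
        before = [list(p.adults) for p in mp.patches]
        migrate(mp, 1, rng)
        assert all(p.adults == b for p, b in zip(mp.patches, before))

    def test_count_conserved_no_duplicates(self, rng):
        mp = self.metapop(m=0.5)
        all_ids = {id(a) for p in mp.patches for a in p.adults}
        migrate(mp, 1, rng)
        after = [id(a) for p in mp.patches for a in p.adults]
        assert len(after) == len(all_ids)
        assert set(after) == all_ids

    def test_full_migration_spreads_over_patches(self, rng):
        # m=1, K=2: expected half of each source in each destination
        reps, moved = 200, []
        for _ in range(reps):
            mp = self.metapop(K=2, N=50, m=1.0)
            src = [id(a) for a in mp.patches[0].adults]
            migrate(mp, 1, rng)
            moved.append(sum(id(a) in src for a in mp.patches[0].adults))
        mean = np.mean(moved)
        se = np.sqrt(50 * 0.25 / reps)
        assert abs(mean - 25.0) < 3 * se

    def test_clusters_isolated_before_contact(self, rng):
        mp = self.metapop(K=6, m=1.0, scenario="secondary_contact", contact=50)
        first = {id(a) for p in mp.patches[:3] for a in p.adults}
        migrate(mp, 10, rng)
        assert {id(a) for p in mp.patches[:3] for a in p.adults} == first

    def test_clusters_mix_after_contact(self, rng):
        mp = self.metapop(K=6, m=1.0, scenario="secondary_contact", contact=50)
        first = {id(a) for p in mp.patches[:3] for a in p.adults}
        migrate(mp, 50, rng)
        crossed = {id(a) for p in mp.patches[3:] for a in p.adults} & first
        assert crossed  # virtually sure at m=1

    def test_patch_attribute_updated(self, rng):
        mp = self.metapop(m=1.0)
        migrate(mp, 1, rng)
        for p in mp.patches:
            assert all(a.patch == p.index for a in p.adults)


class TestStepGeneration:
    def test_population_size_conserved(self, rng):
        cfg = SimulationConfig(K=4, N=20, generations=0, T=20)
        mp = initialize_metapopulation(cfg)
        for gen in range(1, 4):
            step_generation(mp, gen, SeasonParams(T=20), ActivityParams(),
                            SelectionParams(), GeneticsParams(), rng, 20)
            assert sum(len(p.adults) for p in mp.patches) == 80

    def test_monomorphic_neutral_population_is_stationary(self, rng):
        cfg = SimulationConfig(K=2, N=30, m=0.0, generations=0)
        mp = initialize_metapopulation(cfg)
        step_generation(mp, 1, SeasonParams(T=10), ActivityParams(),
                        SelectionParams(c=0.0, s_r=0.0),
                        GeneticsParams(mu=0.0), rng, 30)
        taus = [a.tau_juv for p in mp.patches for a in p.adults]
        assert set(taus) == {0.5}

    def test_mating_records_have_sires(self, rng):
        cfg = SimulationConfig(K=2, N=20, generations=0)
        mp = initialize_metapopulation(cfg)
        recs = step_generation(mp, 1, SeasonParams(T=10), ActivityParams(),
                               SelectionParams(), GeneticsParams(), rng, 20)
        assert recs
        assert all(r.sire is not None for r in recs)
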