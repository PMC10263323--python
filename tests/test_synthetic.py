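import numpy as np
import pytest

from isoweb import (
    SimulationTruth,
    classify_nodes,
    gen_biomass,
    gen_foodweb,
    gen_mixing_dataset,
    ilr_inv,
    table1_fixture,
    trout_diet_sources,
    trout_summary,
)
from isoweb.errors import FeasibilityError, ValidationError


class TestGenMixingDataset:
    def test_noise_free_limit_hits_mixture_point(self, zero_tdf, three_sources):
        exact = [
            type(s)(s.name, s.zone, s.mean_d13C, 0.0, s.mean_d15N, 0.0, s.n)
            for s in three_sources
        ]
        truth = SimulationTruth(true_p=[0.5, 0.3, 0.2], tdf=zero_tdf,
                                xi=(1e-12, 1e-12), sigma_re=0.0, n_consumers=5, seed=1)
        consumers, _ = gen_mixing_dataset(truth, exact)
        mix_c = sum(p * s.mean_d13C for p, s in zip(truth.true_p, exact))
        mix_n = sum(p * s.mean_d15N for p, s in zip(truth.true_p, exact))
        for c in consumers:
            assert c.d13C == pytest.approx(mix_c, abs=1e-4)
            assert c.d15N == pytest.approx(mix_n, abs=1e-4)

    def test_large_sample_mean_matches_mixture_within_3se(self, zero_tdf, three_sources):
        truth = SimulationTruth(true_p=[0.6, 0.3, 0.1], tdf=zero_tdf,
                                xi=(1.0, 1.0), sigma_re=0.0, n_consumers=10_000, seed=2)
        consumers, _ = gen_mixing_dataset(truth, three_sources)
        p = np.asarray(truth.true_p)
        mix_c = sum(pi * s.mean_d13C for pi, s in zip(p, three_sources))
        sd_c = np.sqrt(sum(pi**2 * s.sd_d13C**2 for pi, s in zip(p, three_sources)))
        obs = np.mean([c.d13C for c in consumers])
        assert abs(obs - mix_c) < 3 * sd_c / np.sqrt(10_000)

    def test_same_seed_identical_different_seed_not(self, zero_tdf, three_sources):
        truth = lambda s: SimulationTruth(true_p=[0.5, 0.3, 0.2], tdf=zero_tdf,
                                          n_consumers=5, seed=s)
        a, _ = gen_mixing_dataset(truth(7), three_sources)
        b, _ = gen_mixing_dataset(truth(7), three_sources)
        c, _ = gen_mixing_dataset(truth(8), three_sources)
        assert [(m.d13C, m.d15N) for m in a] == [(m.d13C, m.d15N) for m in b]
        assert [(m.d13C, m.d15N) for m in a] != [(m.d13C, m.d15N) for m in c]

    def test_simplex_mismatch_rejected(self, zero_tdf, three_sources):
        truth = SimulationTruth(true_p=[0.5, 0.5], tdf=zero_tdf, seed=1)
        with pytest.raises(ValidationError):
            gen_mixing_dataset(truth, three_sources)

    def test_provenance_records_truth(self, zero_tdf, three_sources):
        truth = SimulationTruth(true_p=[0.5, 0.3, 0.2], tdf=zero_tdf,
                                n_consumers=3, seed=42)
        _, prov = gen_mixing_dataset(truth, three_sources)
        assert prov["seed"] == 42 and prov["true_p"] == [0.5, 0.3, 0.2]

    def test_random_effect_spreads_consumer_diets(self, zero_tdf, three_sources):
        truth = SimulationTruth(true_p=[0.5, 0.3, 0.2], tdf=zero_tdf,
                                sigma_re=1.0, n_consumers=200, seed=3)
        consumers, _ = gen_mixing_dataset(truth, three_sources)
        spread = np.std([c.d13C for c in consumers])
        truth0 = SimulationTruth(true_p=[0.5, 0.3, 0.2], tdf=zero_tdf,
                                 sigma_re=0.0, n_consumers=200, seed=3)
        consumers0, _ = gen_mixing_dataset(truth0, three_sources)
        assert spread > np.std([c.d13C for c in consumers0])


class TestGenFoodweb:
    def test_minimal_two_node_web(self):
        web = gen_foodweb(1, 1, 0, 0, seed=1)
        assert web.adjacency.sum() == 1
        assert classify_nodes(web) == {"basal1": "basal", "herb1": "herbivore"}

    def test_zero_consumers_link_free(self):
        web = gen_foodweb(4, 0, 0, 0, seed=1)
        assert web.adjacency.sum() == 0

    def test_classification_recovers_generating_categories(self):
        for seed in range(5):
            web = gen_foodweb(5, 5, 3, 1, connectance_target=0.06, seed=seed)
            cats = classify_nodes(web)
            gen = {n: web.node_attrs[n]["guild"] for n in web.node_names}
            assert cats == gen

    def test_realized_connectance_in_band(self):
        for seed in range(5):
            web = gen_foodweb(5, 5, 3, 1, connectance_target=0.06, seed=seed)
            C = web.adjacency.sum() / web.n_nodes**2
            assert 0.048 <= C <= 0.072

    def test_infeasible_target_rejected(self):
        with pytest.raises(FeasibilityError):
            gen_foodweb(2, 2, 0, 0, connectance_target=0.9, seed=1)

    def test_consumers_without_basal_rejected(self):
        with pytest.raises(FeasibilityError):
            gen_foodweb(0, 2, 0, 0, seed=1)

    def test_output_passes_invariants_and_zones_cycle(self):
        web = gen_foodweb(3, 3, 1, 1, seed=9)
        assert set(np.unique(web.adjacency)) <= {0, 1}
        zones = {web.node_attrs[n]["zone"] for n in web.node_names}
        assert zones == {"littoral", "pelagic"}


class TestFixture:
    def test_group_counts_per_lake(self):
        assert len(table1_fixture("El Sol")) == 14
        assert len(table1_fixture("La Luna")) == 6

    def test_gastropod_values(self):
        physa = {s.name: s for s in table1_fixture("El Sol")}["Physa sp."]
        assert (physa.mean_d13C, physa.sd_d13C) == (-11.94, 0.14)
        assert (physa.mean_d15N, physa.sd_d15N) == (2.8, 0.57)

    def test_fishless_lake_macroalgae(self):
        malg = {s.name: s for s in table1_fixture("La Luna")}["Macroalgae"]
        assert (malg.mean_d13C, malg.sd_d13C) == (-16.8, 1.01)
        assert (malg.mean_d15N, malg.sd_d15N) == (-7.5, 0.64)

    def test_trout_row(self):
        t = trout_summary()
        assert (t.mean_d13C, t.sd_d13C, t.mean_d15N, t.sd_d15N) == (-15.3, 1.54, 6.63, 0.37)

    def test_six_candidate_diet_sources(self):
        srcs = trout_diet_sources()
        assert len(srcs) == 6
        assert {s.zone for s in srcs} <= {"littoral", "pelagic", "profundal"}

    def test_unknown_lake_rejected(self):
        with pytest.raises(ValidationError):
            table1_fixture("Atlantis")


def test_gen_biomass_positive_and_seeded():
    names = ["a", "b", "c"]
    b1 = gen_biomass(names, seed=5)
    b2 = gen_biomass(names, seed=5)
    assert all(r.biomass > 0 for r in b1)
    assert [r.biomass for r in b1] == [r.biomass for r in b2]
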