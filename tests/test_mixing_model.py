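import numpy as np
import pytest

from isoweb import (
    DietPosterior,
    MixingModelSpec,
    SourceSummary,
    TDFSpec,
    compare,
    fit,
    gelman_rubin,
    geweke,
    ilr,
    ilr_inv,
    uniform_prior,
)
from isoweb.errors import ComparisonError, InsufficientDataError, ValidationError
from .conftest import make_consumer

FAST = dict(chains=2, iterations=3000, burn=1500, thin=3)


class TestILR:
    def test_round_trip_to_1e10(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(2, 9)))
            assert np.abs(ilr_inv(ilr(p)) - p).max() < 1e-10

    def test_inverse_lands_on_simplex(self, rng):
        z = rng.normal(0, 3, (20, 4))
        p = ilr_inv(z)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p > 0).all()

    def test_norm_matches_skbio_oracle(self, rng):
        """Any orthonormal ILR basis preserves the clr norm; cross-check ours
        against scikit-bio's implementation."""
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            ours = np.linalg.norm(ilr(p))
            theirs = np.linalg.norm(skbio_comp.ilr(p))
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_uniform_composition_maps_to_origin(self):
        assert np.abs(ilr(np.full(6, 1 / 6))).max() < 1e-12


class TestFit:
    def test_two_source_symmetry(self, zero_tdf):
        srcs = [SourceSummary("A", "pelagic", -10, 0.5, 0, 0.5, 5),
                SourceSummary("B", "pelagic", -20, 0.5, 0, 0.5, 5)]
        spec = MixingModelSpec(srcs, zero_tdf, uniform_prior(["A", "B"]))
        post = fit(spec, [make_consumer("c", -15.0, 0.0)], seed=5, **FAST)
        assert post.p_mean == pytest.approx([0.5, 0.5], abs=0.08)

    def test_source_relabeling_invariance(self, zero_tdf):
        srcs = [SourceSummary("A", "pelagic", -10, 0.5, 0, 0.5, 5),
                SourceSummary("B", "pelagic", -20, 0.5, 3, 0.5, 5)]
        cons = [make_consumer("c", -13.0, 1.0)]
        post1 = fit(MixingModelSpec(srcs, zero_tdf, uniform_prior(["A", "B"])),
                    cons, seed=5, **FAST)
        post2 = fit(MixingModelSpec(srcs[::-1], zero_tdf, uniform_prior(["B", "A"])),
                    cons, seed=6, **FAST)
        assert post1.p_mean[0] == pytest.approx(post2.p_mean[1], abs=0.08)

    def test_single_source_degenerate_without_sampling(self, zero_tdf):
        srcs = [SourceSummary("only", "pelagic", -10, 0.5, 0, 0.5, 5)]
        prior = uniform_prior(["only", "pad"])  # build a 1-source prior by hand
        prior.source_names, prior.alpha = ["only"], np.array([1.0])
        spec = MixingModelSpec(srcs, zero_tdf, prior)
        post = fit(spec, [make_consumer("c", -10.0, 0.0)], seed=1, **FAST)
        assert (post.draws["p"] == 1.0).all()
        assert post.settings.get("degenerate")

    def test_consumer_at_source_gets_full_mass_when_errors_small(self, zero_tdf):
        srcs = [SourceSummary("A", "pelagic", -10, 0.05, 0, 0.05, 5),
                SourceSummary("B", "pelagic", -20, 0.05, 10, 0.05, 5)]
        spec = MixingModelSpec(srcs, zero_tdf, uniform_prior(["A", "B"]),
                               random_effect="none")
        post = fit(spec, [make_consumer("c", -10.0, 0.0)], seed=2, **FAST)
        assert post.p_mean[0] > 0.9

    def test_draws_satisfy_simplex_constraint(self, zero_tdf, three_sources):
        spec = MixingModelSpec(three_sources, zero_tdf, uniform_prior(["A", "B", "C"]))
        post = fit(spec, [make_consumer("c", -15.0, 5.0)], seed=3, **FAST)
        assert np.abs(post.draws["p"].sum(axis=-1) - 1).max() < 1e-9
        assert np.abs(post.draws["p_consumer"].sum(axis=-1) - 1).max() < 1e-9
        assert (post.draws["xi"] > 0).all()

    def test_seed_required_and_reproducible(self, zero_tdf, three_sources):
        spec = MixingModelSpec(three_sources, zero_tdf, uniform_prior(["A", "B", "C"]))
        cons = [make_consumer("c", -15.0, 5.0)]
        with pytest.raises(ValueError, match="seed"):
            fit(spec, cons, **FAST)
        p1 = fit(spec, cons, seed=9, **FAST).draws["p"]
        p2 = fit(spec, cons, seed=9, **FAST).draws["p"]
        assert (p1 == p2).all()

    def test_burn_must_be_less_than_iterations(self, zero_tdf, three_sources):
        spec = MixingModelSpec(three_sources, zero_tdf, uniform_prior(["A", "B", "C"]))
        with pytest.raises(ValidationError):
            fit(spec, [make_consumer("c", -15, 5)], chains=2,
                iterations=100, burn=100, seed=1)

    def test_prior_source_mismatch_rejected(self, zero_tdf, three_sources):
        with pytest.raises(ValidationError):
            MixingModelSpec(three_sources, zero_tdf, uniform_prior(["X", "Y", "Z"]))


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        x = rng.standard_normal(1000)
        assert gelman_rubin(np.stack([x, x])) <= 1.01

    def test_iid_chains_below_105(self, rng):
        chains = rng.standard_normal((3, 1000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 10])
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            gelman_rubin(rng.standard_normal((1, 100)))

    def test_matches_arviz_oracle(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 500)) + rng.normal(0, 0.1, (4, 1))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values[0])
        assert ours == pytest.approx(theirs, abs=0.01)


class TestGeweke:
    def test_constant_chain_zero(self):
        assert geweke(np.full(500, 3.14)) == 0.0

    def test_iid_chain_usually_passes(self, rng):
        zs = [geweke(rng.standard_normal(2000)) for _ in range(40)]
        assert np.mean(np.abs(zs) < 1.96) >= 0.9

    def test_linear_drift_detected(self, rng):
        n = 4000
        x = np.linspace(0, 3, n) + rng.standard_normal(n)  # 3-sigma drift
        assert abs(geweke(x)) > 1.96

    def test_overlapping_windows_rejected(self, rng):
        with pytest.raises(ValidationError):
            geweke(rng.standard_normal(100), first_frac=0.6, last_frac=0.6)


class TestCompare:
    def _two_fits(self, zero_tdf, identical=True):
        srcs = [SourceSummary("A", "pelagic", -10, 0.5, 0, 0.5, 5),
                SourceSummary("B", "pelagic", -20, 0.5, 5, 0.5, 5)]
        cons = [make_consumer(f"c{i}", -15 + i, 2.0) for i in range(4)]
        spec1 = MixingModelSpec(srcs, zero_tdf, uniform_prior(["A", "B"]), name="m1")
        tdf2 = zero_tdf if identical else TDFSpec("shift", 15.0, 0.1, -8.0, 0.1)
        spec2 = MixingModelSpec(srcs, tdf2, uniform_prior(["A", "B"]), name="m2")
        post1 = fit(spec1, cons, seed=4, **FAST)
        post2 = fit(spec2, cons, seed=4, **FAST)
        return post1, post2

    def test_identical_models_split_weight(self, zero_tdf):
        post1, post2 = self._two_fits(zero_tdf, identical=True)
        table = compare([post1, post2], method="loo")
        assert table["dLOOic"].tolist() == [0.0, 0.0]
        assert table["weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_grossly_wrong_tdf_ranked_last(self, zero_tdf):
        post1, post2 = self._two_fits(zero_tdf, identical=False)
        table = compare([post1, post2], method="loo")
        assert table.iloc[0]["model"] == "m1"
        assert table.iloc[0]["weight"] > 0.5

    def test_weights_normalized_for_waic_too(self, zero_tdf):
        post1, post2 = self._two_fits(zero_tdf, identical=False)
        table = compare([post1, post2], method="waic")
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert set(table.columns) >= {"WAIC", "se_WAIC", "dWAIC", "se_dWAIC", "weight"}

    def test_mismatched_consumers_rejected(self, zero_tdf):
        post1, post2 = self._two_fits(zero_tdf)
        post2.consumer_ids = post2.consumer_ids[:-1]
        with pytest.raises(ComparisonError):
            compare([post1, post2])
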