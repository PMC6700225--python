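"""ABC fitting: distance metric, target construction, normalization, and a
small end-to-end recovery smoke test."""

import numpy as np
import pytest

from golgisim.engine import GlycanProfile, exact_profile
from golgisim.fitting import (
    PriorSpec,
    TargetNotComplexError,
    abc_smc,
    make_target_profile,
    normalize_rates_to_wt_time,
    posterior_total_fold,
    profile_distance,
    rate_change_report,
)
from golgisim.glycans import Antenna, GlycanState

A = Antenna

BI = GlycanState(man=3, armA=A.SIA, armB=A.SIA, fuc=1)
MAN5 = GlycanState(man=5)
MAN8 = GlycanState(man=8)


class TestProfileDistance:
    def test_identity_is_zero(self):
        p = GlycanProfile(abundance={BI.code(): 0.6, MAN5.code(): 0.4})
        assert profile_distance(p, p) == 0.0

    def test_disjoint_supports_is_two(self):
        p = GlycanProfile(abundance={BI.code(): 1.0})
        q = GlycanProfile(abundance={MAN5.code(): 1.0})
        assert profile_distance(p, q) == pytest.approx(2.0)

    def test_hand_computed_value(self):
        p = GlycanProfile(abundance={BI.code(): 0.6, MAN5.code(): 0.4})
        q = GlycanProfile(abundance={BI.code(): 0.5, MAN5.code(): 0.5})
        assert profile_distance(p, q) == pytest.approx(0.2)

    def test_symmetry(self):
        p = GlycanProfile(abundance={BI.code(): 0.7, MAN8.code(): 0.3})
        q = GlycanProfile(abundance={MAN5.code(): 0.2, BI.code(): 0.8})
        assert profile_distance(p, q) == pytest.approx(profile_distance(q, p))


class TestMakeTargetProfile:
    def wt(self, oligo):
        return GlycanProfile(
            abundance={MAN5.code(): oligo * 0.6, MAN8.code(): oligo * 0.4, BI.code(): 1 - oligo}
        )

    def test_target_gets_complement_of_oligomannose(self):
        target_state = GlycanState(man=3, armA=A.SIA, armB=A.GAL, fuc=1)
        t = make_target_profile(target_state, self.wt(0.3))
        assert t.get(target_state.code()) == pytest.approx(0.7)
        assert t.get(MAN5.code()) == pytest.approx(0.18)
        assert sum(t.abundance.values()) == pytest.approx(1.0)

    def test_zero_oligomannose_gives_full_abundance(self):
        wt = GlycanProfile(abundance={BI.code(): 1.0})
        t = make_target_profile(GlycanState(man=3, armA=A.SIA, armB=A.GAL, fuc=1), wt)
        assert sum(t.abundance.values()) == pytest.approx(1.0)
        assert max(t.abundance.values()) == pytest.approx(1.0)

    def test_rejects_non_complex_target(self):
        with pytest.raises(TargetNotComplexError):
            make_target_profile(MAN5, self.wt(0.3))


class TestTimeNormalization:
    def test_identity_when_scale_one(self, reference_config):
        priors = PriorSpec(reference=reference_config, mode="fixed")
        theta = np.zeros(len(priors.param_names()))
        assert np.allclose(normalize_rates_to_wt_time(theta, priors), theta)

    def test_profile_invariant_under_normalization(self, reference_config):
        priors = PriorSpec(reference=reference_config, mode="fixed")
        rng = np.random.Generator(np.random.Philox(key=[1, 2]))
        theta = priors.sample(rng)
        theta[priors.param_names().index("log_time_scale")] = np.log(2.0)
        normalized = normalize_rates_to_wt_time(theta, priors)
        p1 = exact_profile(priors.to_config(theta))
        p2 = exact_profile(priors.to_config(normalized))
        assert profile_distance(p1, p2) <= 1e-9
        t_idx = priors.param_names().index("log_time_scale")
        assert normalized[t_idx] == 0.0

    def test_round_trip(self, reference_config):
        priors = PriorSpec(reference=reference_config, mode="variable")
        rng = np.random.Generator(np.random.Philox(key=[3, 4]))
        theta = priors.sample(rng)
        once = normalize_rates_to_wt_time(theta, priors)
        twice = normalize_rates_to_wt_time(once, priors)
        assert np.allclose(once, twice)


class TestPriors:
    def test_draws_yield_valid_configs(self, reference_config):
        for mode in ("fixed", "variable"):
            priors = PriorSpec(reference=reference_config, mode=mode)
            rng = np.random.Generator(np.random.Philox(key=[5, 6]))
            for _ in range(20):
                cfg = priors.to_config(priors.sample(rng))
                assert cfg.n_cisternae == reference_config.n_cisternae

    def test_degenerate_prior_rejected(self, reference_config):
        with pytest.raises(ValueError):
            PriorSpec(reference=reference_config, mode="fixed", sigma_rate=0.0)

    def test_unknown_mode_rejected(self, reference_config):
        with pytest.raises(ValueError):
            PriorSpec(reference=reference_config, mode="both")


@pytest.fixture(scope="module")
def self_fit_result(reference_config, reference_exact):
    """Short self-fit: the target is the reference's own exact profile."""
    return abc_smc(
        reference_exact,
        PriorSpec(reference=reference_config, mode="fixed"),
        n_particles=40,
        max_generations=5,
        seed=13,
    )


class TestAbcSmoke:
    @pytest.fixture
    def result(self, self_fit_result):
        return self_fit_result

    def test_tolerances_non_increasing(self, result):
        assert all(b <= a + 1e-12 for a, b in zip(result.tolerances, result.tolerances[1:]))

    def test_distances_within_final_tolerance(self, result):
        assert np.all(result.distances <= result.final_tolerance() + 1e-12)

    def test_particle_count(self, result):
        assert len(result.particles) == 40

    def test_fixed_mode_preserves_cisternal_fractions(self, result, reference_config):
        cfg = result.particle_config(result.best_particle())
        for e, ref_row in reference_config.rates.items():
            ref_row = np.array(ref_row)
            row = np.array(cfg.rates[e])
            assert np.allclose(row / row.sum(), ref_row / ref_row.sum(), atol=1e-12)

    def test_rate_change_report_shape(self, result, reference_config):
        report = rate_change_report(result, reference_config)
        assert set(report["enzyme"]) == set(reference_config.rates)
        assert "pct_change_total" in report.columns

    def test_echoed_reference_reports_small_changes(self, reference_config, reference_exact):
        """Self-fit posterior folds stay within the recovery bound of 1."""
        res = abc_smc(
            reference_exact,
            PriorSpec(reference=reference_config, mode="fixed"),
            n_particles=40,
            max_generations=6,
            seed=14,
        )
        fold = posterior_total_fold(res, "ManI", reference_config)
        assert 0.5 <= fold <= 2.0
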