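"""Monte Carlo fluctuation-protocol simulation against exact oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from clonefluct import (
    AssayProtocol,
    SwitchingModel,
    expand_clone,
    expected_resistant_fraction,
    fluctuation_experiment,
    predicted_cv,
    predicted_cv_grid,
    suspension_assay,
)
from clonefluct.simulate import Founder

from oracles import (
    lineage_resistant_prob,
    survival_cv_exact,
    survival_cv_moments_large,
)


class TestExpandClone:
    def test_no_switching_doubles_founder_state(self):
        m = SwitchingModel(k_on=0.0, k_off=0.0)
        s = expand_clone(m, G=1, founder="resistant", rng=0)
        assert (s.n_sensitive, s.n_resistant) == (0, 2)
        assert s.total == 2

    def test_symmetric_chain_equilibrates_in_one_step(self):
        m = SwitchingModel(k_on=0.5, k_off=0.5)
        assert expected_resistant_fraction(m, 2, Founder.SENSITIVE) == pytest.approx(0.5)

    def test_lineage_recursion_three_generations(self):
        # m1 = 0.3, m2 = 0.4815, m3 = 0.5913 from a sensitive founder
        m = SwitchingModel(k_on=0.3, k_off=0.095)
        assert expected_resistant_fraction(m, 3, Founder.SENSITIVE) == pytest.approx(
            lineage_resistant_prob(0.3, 0.095, 3, 0.0), rel=1e-12
        )
        assert expected_resistant_fraction(m, 3, Founder.SENSITIVE) == pytest.approx(
            0.5913, abs=5e-5
        )

    def test_empirical_mean_matches_recursion(self):
        m = SwitchingModel(k_on=0.3, k_off=0.095)
        rng = np.random.default_rng(7)
        fracs = [
            expand_clone(m, 5, "sensitive", rng).resistant_fraction for _ in range(3000)
        ]
        expected = expected_resistant_fraction(m, 5, Founder.SENSITIVE)
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 4 * se

    def test_total_cells_deterministic_doubling(self):
        m = SwitchingModel(k_on=0.1, k_off=0.1)
        assert expand_clone(m, 10, "sensitive", rng=1).total == 2**10

    def test_exact_mode_guards_large_G(self):
        m = SwitchingModel(k_on=0.1, k_off=0.1)
        with pytest.raises(ValueError, match="aggregate"):
            expand_clone(m, 30, "sensitive", rng=0, mode="exact")


class TestSuspensionAssay:
    def test_pure_resistant_expectation(self):
        # expected survival e^(gamma*24) = 2^(24/100) ~ 1.181
        m = SwitchingModel(k_on=0.1, k_off=0.1, T_d_susp=100.0)
        rng = np.random.default_rng(3)
        vals = [suspension_assay(m, (0, 5000), 24.0, rng) for _ in range(400)]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - 2 ** (24 / 100)) < 4 * se

    def test_pure_sensitive_all_dead(self):
        m = SwitchingModel(k_on=0.1, k_off=0.1)
        assert suspension_assay(m, (1000, 0), 24.0, rng=0) == 0.0

    def test_mixture_reproduces_mean_survival(self):
        """(60,000 S, 190,000 R) at T_d = 100 h gives ~0.9 mean survival."""
        m = SwitchingModel(k_on=0.1, k_off=0.1, T_d_susp=100.0)
        rng = np.random.default_rng(5)
        vals = [suspension_assay(m, (60_000, 190_000), 24.0, rng) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(0.76 * 2 ** (24 / 100), abs=0.005)
        assert np.mean(vals) == pytest.approx(0.90, abs=0.01)

    def test_exponential_sensitive_death_mode(self):
        from clonefluct import SensitiveDeath

        m = SwitchingModel(
            k_on=0.0, k_off=0.0, T_d_susp=float("inf"),
            sensitive_death=SensitiveDeath.EXPONENTIAL, delta=math.log(2) / 24,
        )
        rng = np.random.default_rng(11)
        vals = [suspension_assay(m, (10_000, 0), 24.0, rng) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)


class TestFluctuationExperiment:
    def test_homogeneous_no_switching_zero_cv(self):
        m = SwitchingModel(k_on=0.0, k_off=0.0, T_d_susp=float("inf"))
        proto = AssayProtocol(N0=1000, G=12, n_clones=20)
        res = fluctuation_experiment(m, proto, seed=1, founder="resistant")
        assert res.cv() == 0.0
        assert np.all(res.survival == res.survival[0])

    def test_reproducible_given_seed(self, default_model, default_protocol):
        a = fluctuation_experiment(default_model, default_protocol, seed=42)
        b = fluctuation_experiment(default_model, default_protocol, seed=42)
        np.testing.assert_array_equal(a.survival, b.survival)
        assert a.run_record() == b.run_record()

    def test_table_schema_round_trip(self, default_model, tmp_path):
        from clonefluct import read_table, write_table

        proto = AssayProtocol(N0=1000, G=12, n_clones=15)
        res = fluctuation_experiment(default_model, proto, seed=3)
        tbl = res.to_table(passage="P1")
        assert list(tbl.columns) == [
            "clone_id", "passage", "n_plated", "n_live", "survival_fraction",
        ]
        path = tmp_path / "t.csv"
        write_table(tbl, path)
        back = read_table(path)
        np.testing.assert_allclose(back["survival_fraction"], tbl["survival_fraction"])

    def test_exact_mode_rejects_overplating(self, default_model):
        proto = AssayProtocol(N0=100, G=4, n_clones=5)  # 2^4 = 16 < 100
        with pytest.raises(ValueError, match="aggregate"):
            fluctuation_experiment(default_model, proto, seed=0, mode="exact")

    def test_mean_survival_conserves_survival_law(self, default_model):
        """Mean per-clone survival converges to f_eq * e^(gamma*T)."""
        proto = AssayProtocol(n_clones=4000, N0=10_000, G=16)
        res = fluctuation_experiment(default_model, proto, seed=9)
        expected = default_model.f_eq * math.exp(default_model.gamma * 24.0)
        se = res.survival.std(ddof=1) / math.sqrt(proto.n_clones)
        assert abs(res.survival.mean() - expected) < 4 * se

    def test_exact_and_aggregate_agree_in_distribution(self, default_model, small_protocol):
        """KS two-sample test between per-cell and count-propagation modes
        at alpha = 0.01 over 20 seeds; at most one rejection is compatible
        with identical distributions (>= 2 has null probability < 2 %)."""
        rejections = 0
        for seed in range(20):
            a = fluctuation_experiment(
                default_model, small_protocol, seed=seed, mode="exact"
            ).survival
            b = fluctuation_experiment(
                default_model, small_protocol, seed=seed + 1000, mode="aggregate"
            ).survival
            rejections += stats.ks_2samp(a, b).pvalue < 0.01
        assert rejections <= 1

    def test_founder_effect_decays_with_expansion(self, default_model):
        # lineage autocorrelation (1-k_on-k_off)^G: negligible at G=20
        lam = default_model.relaxation_eigenvalue
        assert 0.55 < lam < 0.65
        assert lam**20 < 1e-4
        proto = AssayProtocol(n_clones=4000, N0=10_000, G=20)
        res = fluctuation_experiment(default_model, proto, seed=13)
        r = np.corrcoef(res.founders.astype(float), res.survival)[0, 1]
        assert abs(r) < 3.5 / math.sqrt(proto.n_clones)


class TestPredictedCV:
    def test_homogeneous_model_zero(self):
        m = SwitchingModel(k_on=0.0, k_off=0.0, T_d_susp=float("inf"))
        proto = AssayProtocol(N0=1000, G=10, n_clones=10)
        cv, err = predicted_cv(m, proto, n_reps=5, seed=0, founder="resistant")
        assert cv == 0.0 and err == 0.0

    def test_matches_enumeration_oracle_small_instance(self):
        """MC predicted CV within 3 MC standard errors of the exact
        enumeration oracle on a desk-size instance (G=4, N0=16)."""
        m = SwitchingModel(k_on=0.3, k_off=0.095, T_d_susp=50.0)
        proto = AssayProtocol(T=24.0, N0=16, G=4, n_clones=2000)
        cv_mc, se = predicted_cv(m, proto, n_reps=60, seed=17)
        _, cv_exact = survival_cv_exact(0.3, 0.095, G=4, n0=16, T=24.0, T_d=50.0)
        assert abs(cv_mc - cv_exact) < 3 * se

    def test_oracle_agreement_with_whole_clone_plating(self):
        # G=2 instance, every cell plated: switching noise + assay noise only
        m = SwitchingModel(k_on=0.25, k_off=0.1, T_d_susp=40.0)
        proto = AssayProtocol(T=24.0, N0=4, G=2, n_clones=3000)
        cv_mc, se = predicted_cv(m, proto, n_reps=50, seed=23)
        _, cv_exact = survival_cv_exact(0.25, 0.1, G=2, n0=4, T=24.0, T_d=40.0)
        assert abs(cv_mc - cv_exact) < 3 * se

    def test_cv_nonincreasing_in_plated_cells(self, default_model):
        """Plating more cells shrinks the sampling-noise term."""
        cvs = []
        for n0 in (1000, 10_000, 100_000):
            proto = AssayProtocol(N0=n0, G=20, n_clones=60)
            cv, _ = predicted_cv(default_model, proto, n_reps=80, seed=31)
            cvs.append(cv)
        assert cvs[0] > cvs[1] > cvs[2]

    def test_study_protocol_cv_below_001_across_doubling_times(self):
        """The central model prediction: under the stated protocol the
        two-state model cannot generate interclonal CV anywhere near the
        observed 0.25-0.3 for any biologically relevant doubling time."""
        df = predicted_cv_grid([38, 100, 200], n_reps=60, seed=5)
        assert (df["cv"] < 0.01).all()

    def test_oracles_agree_with_each_other(self):
        # pmf enumeration and moment recursion are independent derivations
        m1, c1 = survival_cv_exact(0.3, 0.095, G=4, n0=16, T=24.0, T_d=50.0)
        m2, c2 = survival_cv_moments_large(0.3, 0.095, 4, 16, 24.0, 50.0, 0.3 / 0.395)
        assert m1 == pytest.approx(m2, rel=1e-10)
        assert c1 == pytest.approx(c2, rel=1e-10)

    @pytest.mark.parametrize("T_d", [38.0, 100.0, 200.0])
    def test_matches_moment_recursion_at_protocol_scale(self, T_d):
        """At the full protocol (G=20, N0=250,000, 60 clones) the MC
        prediction matches the exact moment-recursion CV within MC error
        plus the small-sample bias of the 60-clone sample CV."""
        m = SwitchingModel.from_survival_balance(T_d_susp=T_d)
        proto = AssayProtocol()
        cv_mc, se = predicted_cv(m, proto, n_reps=200, seed=41)
        _, cv_exact = survival_cv_moments_large(
            m.k_on, m.k_off, proto.G, proto.N0, proto.T, T_d, m.f_eq
        )
        # E[sample CV] ~ population CV * (1 - 1/(4n)) at n = 60
        assert abs(cv_mc - cv_exact) < 3 * se + cv_exact / (4 * proto.n_clones) * 2

    def test_deterministic_given_seed(self, default_model, default_protocol):
        a = predicted_cv(default_model, default_protocol, n_reps=10, seed=2)
        b = predicted_cv(default_model, default_protocol, n_reps=10, seed=2)
        assert a == b
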