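import numpy as np
import pytest
from scipy import integrate, special, stats

from cmgipd import (
    METHOD_NAMES,
    PriorSpec,
    ShrinkageState,
    baseline_prior_logpdf,
    expected_prior_shrinkage,
    hyperprior_logpdf,
    method_spec,
    prior_precision_cmg,
    prior_precision_nmg,
    tuning_function,
)
from cmgipd.data_model import DesignMatrices
from cmgipd.priors import g_log_density


def make_design(columns_by_study):
    """Minimal design carrying only interaction columns, one per study."""
    cols = [np.atleast_2d(np.asarray(c, dtype=float).T).T for c in columns_by_study]
    Xem = np.vstack(cols)
    n_i = np.array([c.shape[0] for c in cols])
    offs = np.concatenate([[0], np.cumsum(n_i)])
    rows = [np.arange(offs[i], offs[i + 1]) for i in range(len(cols))]
    return DesignMatrices(
        W=Xem,
        column_names=[],
        Xc=Xem,
        Xem=Xem,
        t=np.ones(Xem.shape[0]),
        moderator_indices=tuple(range(Xem.shape[1])),
        study_rows=rows,
        n_i=n_i,
        include_main_effects=False,
    )


class TestRegistry:
    def test_twenty_methods(self):
        assert len(METHOD_NAMES) == 20

    @pytest.mark.parametrize("name", METHOD_NAMES)
    def test_name_roundtrip(self, name):
        assert method_spec(name).name == name

    def test_unknown_method(self):
        with pytest.raises(KeyError, match="unknown method"):
            method_spec("LASSO")

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PriorSpec("nmg", g_rule="HG", a=2)  # needs a > 2
        with pytest.raises(ValueError):
            PriorSpec("cmg", shrink="S1", tuning="sqrt")
        with pytest.raises(ValueError):
            PriorSpec("cmg", shrink="S1", tuning="n", b_fixed=3.0)


class TestTuningFunction:
    @pytest.mark.parametrize(
        "form, n, p, expected",
        [
            ("n", 100, 0.5, 50.0),
            ("pow", 100, 1.0, 100.0),
            ("pow", 100, 0.0, 1.0),
            ("log", 100, 1.0, np.log(100.0)),
            ("n", 100, 1.0 / 100, 1.0),
        ],
    )
    def test_values(self, form, n, p, expected):
        assert tuning_function(form, n, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "form, n, p",
        [("n", 100, 0.001), ("n", 100, 1.5), ("pow", 100, -0.1),
         ("log", 100, 0.005), ("log", 100, 1.0 / 100)],
    )
    def test_domain_errors(self, form, n, p):
        with pytest.raises(ValueError):
            tuning_function(form, n, p)

    def test_bounded_by_study_size(self):
        rng = np.random.default_rng(0)
        n = 120
        for form in ("n", "pow"):
            lo = 1.0 / n if form == "n" else 0.0
            p = rng.uniform(lo, 1.0, size=50)
            assert np.all(tuning_function(form, n, p) <= n + 1e-9)


class TestPriorPrecision:
    def test_single_study_hand_sum(self):
        des = make_design([[1.0, 1.0, 0.0, 0.0]])
        assert prior_precision_nmg(0, des, [1.0], 2.0) == pytest.approx(1.0)

    def test_two_studies_hand_sum(self):
        # (2,0) in study 1 (sigma^2=4), (0,3) in study 2 (sigma^2=1)
        des = make_design([[2.0, 0.0], [0.0, 3.0]])
        assert prior_precision_nmg(0, des, [4.0, 1.0], 1.0) == pytest.approx(10.0)

    def test_flat_limit(self):
        des = make_design([[1.0, 1.0]])
        assert prior_precision_nmg(0, des, [1.0], 1e12) == pytest.approx(0.0, abs=1e-10)

    def test_cmg_hand_sum(self):
        # f(n) = 2: two unit entries with sigma^2 = 1 -> 1/2 + 1/2 = 1
        des = make_design([[1.0, 1.0]])
        spec = method_spec("CMG-S2-n")
        p = np.array([1.0])  # f = n * p = 2
        assert prior_precision_cmg(0, des, [1.0], 1.0, p, spec) == pytest.approx(1.0)

    def test_cuip_total_sample_size(self):
        des = make_design([[1.0, 1.0, 1.0, 1.0]])
        spec = method_spec("CUIP")
        assert prior_precision_cmg(0, des, [1.0], 1.0, None, spec) == pytest.approx(1.0)

    def test_cmg_with_unit_tuning_reduces_to_nmg(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            cols = [rng.normal(size=rng.integers(2, 9)) for _ in range(3)]
            des = make_design([c[:, None] for c in cols])
            s2 = rng.uniform(0.5, 4.0, size=3)
            g = rng.uniform(0.1, 10.0)
            spec = method_spec("CMG-S1-pow")
            p = np.zeros(3)  # power form with p_i = 0 gives f = 1 exactly
            assert prior_precision_cmg(0, des, s2, g, p, spec) == pytest.approx(
                prior_precision_nmg(0, des, s2, g), rel=1e-12
            )

    def test_zero_interaction_column_errors(self):
        des = make_design([[0.0, 0.0]])
        with pytest.raises(ValueError, match="zero"):
            prior_precision_nmg(0, des, [1.0], 1.0)


class TestHyperpriorLogpdf:
    def test_s2_closed_form(self):
        spec = method_spec("CMG-S2-pow")
        st = ShrinkageState(g=np.array([1.0]), p=np.array([0.5]))
        lp = hyperprior_logpdf(spec, st, N=100, n_i=np.array([100]))
        assert lp == pytest.approx(-2 * np.log(2.0))

    def test_hg4_matches_s2(self):
        g = np.linspace(0.05, 25.0, 40)
        hg4 = g_log_density(method_spec("HG4"), g)
        s2 = g_log_density(method_spec("CMG-S2-n"), g)
        np.testing.assert_allclose(hg4, s2, rtol=1e-12)

    def test_zs_mode_at_n_over_three(self):
        # IG(1/2, N/2) with N = 100 has its mode at (N/2)/(3/2) = 100/3
        spec = method_spec("ZS")
        g = np.linspace(1.0, 200.0, 20001)
        lp = g_log_density(spec, g, N=100)
        assert g[np.argmax(lp)] == pytest.approx(100.0 / 3.0, abs=0.05)

    def test_out_of_support_is_minus_inf(self):
        spec = method_spec("CMG-S1-n")
        st = ShrinkageState(
            g=np.array([1.0]), b=np.array([2.5]), p=np.array([0.5])
        )
        assert hyperprior_logpdf(spec, st, N=10, n_i=np.array([10])) == -np.inf
        st2 = ShrinkageState(
            g=np.array([1.0]), b=np.array([1.0]), p=np.array([0.001])
        )
        assert hyperprior_logpdf(spec, st2, N=10, n_i=np.array([10])) == -np.inf

    @pytest.mark.parametrize(
        "spec, kwargs",
        [
            (method_spec("CMG-S2-n"), {}),
            (method_spec("CMG-S1-n", b_fixed=1.3), {}),
            (method_spec("CMG-S3-n", b_fixed=0.7), {}),
            (method_spec("HG3"), {}),
            (method_spec("HG4"), {}),
            (method_spec("HGN3"), {"N": 50}),
            (method_spec("ZS"), {"N": 100}),
            (method_spec("CZS"), {}),
        ],
        ids=["S2", "S1", "S3", "HG3", "HG4", "HGN3", "ZS", "CZS"],
    )
    def test_density_integrates_to_one(self, spec, kwargs):
        # substitute g = w/(1-w) to integrate over (0, 1)
        def integrand(w):
            g = w / (1.0 - w)
            return np.exp(g_log_density(spec, g, **kwargs)) / (1.0 - w) ** 2

        mass, _ = integrate.quad(integrand, 1e-12, 1 - 1e-12, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_jacobian_of_shrinkage_transform(self):
        # sampling w ~ Beta(2, b) and mapping g = w/(1-w) must reproduce
        # the g-scale density (KS on the closed-form CDF) and the logpdf
        # must equal the Beta pdf times |dw/dg|
        b = 1.3
        spec = method_spec("CMG-S1-n", b_fixed=b)
        rng = np.random.default_rng(12)
        w = rng.beta(2.0, b, size=100_000)
        g = w / (1.0 - w)
        ks = stats.kstest(g, lambda x: special.betainc(2.0, b, x / (1.0 + x)))
        assert ks.pvalue > 0.01
        gg = np.array([0.1, 0.7, 3.0, 20.0])
        expected = stats.beta.logpdf(gg / (1 + gg), 2.0, b) - 2 * np.log1p(gg)
        np.testing.assert_allclose(g_log_density(spec, gg), expected, rtol=1e-10)

    def test_hg3_has_more_mass_near_full_retention(self):
        # P(g/(1+g) > 0.9) is larger for a = 3 than a = 4
        def tail(spec):
            def integrand(w):
                g = w / (1.0 - w)
                return np.exp(g_log_density(spec, g)) / (1.0 - w) ** 2

            val, _ = integrate.quad(integrand, 0.9, 1 - 1e-12)
            return val

        assert tail(method_spec("HG3")) > tail(method_spec("HG4"))


class TestExpectedShrinkage:
    def test_uip_and_cuip_are_deterministic(self):
        est, se = expected_prior_shrinkage(method_spec("UIP"), 100, seed=0, N=625)
        assert est == pytest.approx(625 / 626) and se == 0.0
        est, se = expected_prior_shrinkage(method_spec("CUIP"), 100, seed=0)
        assert est == pytest.approx(0.5) and se == 0.0

    def test_hg4_is_uniform_shrinkage(self):
        est, se = expected_prior_shrinkage(method_spec("HG4"), 200_000, seed=1)
        assert est == pytest.approx(0.5, abs=4 * se)

    def test_unsupported_family_errors(self):
        with pytest.raises(ValueError, match="NMG/CMG"):
            expected_prior_shrinkage(method_spec("HS"), 100, seed=0)


class TestBaselineLogpdf:
    def test_flat_is_constant(self):
        assert baseline_prior_logpdf(method_spec("Flat"), [0.0, 5.0, -3.0]) == 0.0

    def test_horseshoe_unit_scales(self):
        st = ShrinkageState(lambda_hs=np.array([1.0]), tau_hs=1.0)
        lp = baseline_prior_logpdf(method_spec("HS"), [0.0], st)
        assert lp == pytest.approx(stats.norm.logpdf(0.0))

    def test_ssvs_slab_sd(self):
        # included component with h_k = 100, eta = 1 has SD 10
        st = ShrinkageState(indicators=np.array([1]), eta=1.0)
        lp = baseline_prior_logpdf(method_spec("SSVS"), [0.0], st)
        assert lp == pytest.approx(stats.norm.logpdf(0.0, scale=10.0))

    def test_g_family_rejected(self):
        with pytest.raises(ValueError, match="not a baseline"):
            baseline_prior_logpdf(method_spec("ZS"), [0.0], ShrinkageState())
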