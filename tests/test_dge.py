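import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import polygamma

from cdscreen import dge, synthetic
from cdscreen.preprocess import collapse_probes
from conftest import make_study


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.5, 1.0, 5.0, 50.0])
    def test_inverse_identity(self, x):
        y = float(polygamma(1, x))
        assert dge.trigamma_inverse(y) == pytest.approx(x, abs=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dge.trigamma_inverse(0.0)


class TestFitPrior:
    def test_parameter_recovery(self):
        """Variances from the scaled-F model recover (d0, s0^2)."""
        rng = np.random.default_rng(42)
        d0, s0_sq, d_g = 4.0, 1.0, 6
        s2 = s0_sq * stats.f.rvs(d_g, d0, size=50_000, random_state=rng)
        prior = dge.fit_prior(s2, df=d_g)
        assert 3.5 <= prior.d0 <= 4.5
        assert 0.9 <= prior.s0_sq <= 1.1

    def test_identical_variances_take_infinite_d0_branch(self):
        prior = dge.fit_prior(np.full(100, 2.5), df=4)
        assert math.isinf(prior.d0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            dge.fit_prior(np.zeros(100), df=4)

    def test_matches_limma_style_moment_equations(self):
        """Fitted parameters satisfy the moment equations they were solved from."""
        rng = np.random.default_rng(7)
        s2 = stats.f.rvs(4, 8, size=20_000, random_state=rng)
        prior = dge.fit_prior(s2, df=4)
        e = np.log(s2) - polygamma(0, 2.0) + math.log(2.0)
        # variance moment: var(e) - trigamma(d_g/2) = trigamma(d0/2)
        assert float(polygamma(1, prior.d0 / 2)) == pytest.approx(
            float(np.var(e, ddof=1)) - float(polygamma(1, 2.0)), rel=1e-6
        )
        # mean moment: log s0^2 = mean(e) + digamma(d0/2) - log(d0/2)
        assert math.log(prior.s0_sq) == pytest.approx(
            float(e.mean())
            + float(polygamma(0, prior.d0 / 2))
            - math.log(prior.d0 / 2),
            abs=1e-10,
        )


def direct_moderated_oracle(ctrl, case, d0, s0_sq):
    """Plain-loop evaluation of the moderated-t formulas, per gene."""
    out = []
    n1, n2 = ctrl.shape[1], case.shape[1]
    d_g = n1 + n2 - 2
    for x, y in zip(ctrl, case):
        m1, m2 = sum(x) / n1, sum(y) / n2
        ss = sum((v - m1) ** 2 for v in x) + sum((v - m2) ** 2 for v in y)
        s2 = ss / d_g
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        t = (m2 - m1) / math.sqrt(s2_post * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df=d0 + d_g)
        out.append((t, p))
    return out


def bh_oracle(p):
    """Step-up formula: adj_(i) = min_{j>=i} m p_(j) / j, clipped to 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, m * p[i] / (pos + 1))
        adj[i] = min(1.0, running)
    return adj


class TestModeratedT:
    def test_matches_direct_formula_oracle(self, rng):
        ctrl = rng.normal(8, 1, size=(20, 3))
        case = rng.normal(8, 1, size=(20, 3))
        study = make_study(np.hstack([ctrl, case]), 3, 3)
        prior = dge.EBayesPrior(d0=3.0, s0_sq=0.7)
        table = dge.moderated_t(study, prior=prior)
        expected = direct_moderated_oracle(ctrl, case, 3.0, 0.7)
        for (t_exp, p_exp), t_got, p_got in zip(
            expected, table["t"], table["p"]
        ):
            assert t_got == pytest.approx(t_exp, abs=1e-10)
            assert p_got == pytest.approx(p_exp, abs=1e-10)

    def test_tiny_d0_approaches_ordinary_t(self, rng):
        vals = rng.normal(5, 1, size=(30, 10))
        study = make_study(vals, 5, 5)
        plain = dge.ordinary_t(study)
        tiny = dge.moderated_t(study, prior=dge.EBayesPrior(d0=1e-12, s0_sq=1.0))
        assert np.allclose(tiny["t"], plain["t"], atol=1e-8)
        assert np.allclose(tiny["p"], plain["p"], atol=1e-8)

    def test_ordinary_t_matches_scipy(self, rng):
        vals = rng.normal(5, 1, size=(15, 9))
        study = make_study(vals, 4, 5)
        plain = dge.ordinary_t(study)
        t_ref, p_ref = stats.ttest_ind(vals[:, 4:].T, vals[:, :4].T)
        assert np.allclose(plain["t"], t_ref, atol=1e-10)
        assert np.allclose(plain["p"], p_ref, atol=1e-10)

    def test_infinite_d0_full_shrinkage(self, rng):
        vals = rng.normal(size=(10, 8))
        study = make_study(vals, 4, 4)
        prior = dge.EBayesPrior(d0=math.inf, s0_sq=0.5)
        table = dge.moderated_t(study, prior=prior)
        assert np.allclose(table["s2_post"], 0.5)

    def test_posterior_variance_between_prior_and_sample(self, rng):
        vals = rng.normal(size=(50, 12))
        study = make_study(vals, 6, 6)
        prior = dge.EBayesPrior(d0=4.0, s0_sq=1.0)
        table = dge.moderated_t(study, prior=prior)
        lo = np.minimum(table["s2"], prior.s0_sq)
        hi = np.maximum(table["s2"], prior.s0_sq)
        inner = table["s2"] != prior.s0_sq
        assert (table.loc[inner, "s2_post"] > lo[inner]).all()
        assert (table.loc[inner, "s2_post"] < hi[inner]).all()

    def test_zero_variance_sentinel(self):
        vals = np.array([[1, 1, 1, 2, 2, 2], [3, 3, 3, 3, 3, 3]], dtype=float)
        study = make_study(vals, 3, 3)
        table = dge.ordinary_t(study)
        assert table["t"].iloc[0] == np.inf and table["p"].iloc[0] == 0.0
        assert np.isnan(table["t"].iloc[1]) and table["p"].iloc[1] == 1.0

    def test_monotone_in_log_fc_at_fixed_variance(self):
        """|t| grows with |log_fc| when the variance is held fixed."""
        base = np.array([[0, 0, 0, 1, 1, 1], [0, 0, 0, 2, 2, 2]], dtype=float)
        jitter = np.tile([-0.1, 0.0, 0.1], (2, 2))
        study = make_study(base + jitter, 3, 3)
        table = dge.moderated_t(study, prior=dge.EBayesPrior(d0=2.0, s0_sq=0.1))
        assert abs(table["t"].iloc[1]) > abs(table["t"].iloc[0])

    def test_group_too_small_rejected(self, rng):
        vals = rng.normal(size=(5, 4))
        study = make_study(vals, 1, 3)
        with pytest.raises(ValueError, match="control"):
            dge.moderated_t(study, prior=dge.EBayesPrior(d0=1.0, s0_sq=1.0))


class TestBhAdjust:
    def test_hand_worked_example(self):
        assert np.allclose(dge.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert np.allclose(dge.bh_adjust([1.0, 1.0]), [1.0, 1.0])
        assert np.allclose(dge.bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dge.bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_never_decreases(self, p):
        adj = dge.bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.integers(0, 10**6))
    def test_permutation_equivariant(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        adj = dge.bh_adjust(p)
        adj_perm = dge.bh_adjust([p[i] for i in perm])
        assert np.allclose(adj_perm, adj[perm], atol=1e-12)


class TestSelectDegs:
    def test_alpha_zero_selects_nothing(self, small_study):
        table = dge.moderated_t(small_study)
        assert dge.select_degs(table, alpha=0.0) == {}

    def test_signs_follow_log_fc(self, small_study):
        table = dge.moderated_t(small_study)
        degs = dge.select_degs(table, alpha=0.05)
        for gene, sign in degs.items():
            fc = table.loc[gene, "log_fc"]
            assert (sign == "up") == (fc > 0)

    def test_planted_recovery_and_fdr(self):
        """Recall >= 0.95 and empirical FDR <= 0.10 on planted-DEG studies."""
        recalls, fdrs = [], []
        for seed in range(20):
            spec = synthetic.StudySpec(
                n_genes=1000, n_control=10, n_case=10, deg_fraction=0.1,
                effect_size=2.0, noise_sd=0.5, n_probes_per_gene=(1.0,),
                unmapped_probe_fraction=0.0, seed=seed,
            )
            study, ann, truth = synthetic.simulate_study(spec)
            gene_study, _ = collapse_probes(study, ann)
            table = dge.moderated_t(gene_study)
            selected = set(dge.select_degs(table, alpha=0.05))
            planted = set(truth.deg_signs)
            recalls.append(len(selected & planted) / len(planted))
            fdrs.append(len(selected - planted) / max(1, len(selected)))
        assert np.mean(recalls) >= 0.95
        assert np.mean(fdrs) <= 0.10
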