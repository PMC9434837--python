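import numpy as np
import pandas as pd
import pytest

from citepipe import thresholding as th


def _draw_mixture(rng, n, pi, mu, sigma):
    comp = rng.random(n) < pi[1]
    return np.where(comp, rng.normal(mu[1], sigma[1], n), rng.normal(mu[0], sigma[0], n))


class TestFitMixture:
    def test_recovers_known_mixture(self):
        # 5,000 draws from 0.6 N(0,1) + 0.4 N(4,1)
        rng = np.random.default_rng(42)
        x = _draw_mixture(rng, 5000, (0.6, 0.4), (0.0, 4.0), (1.0, 1.0))
        fit = th.fit_mixture_1d(x, seed=0)
        assert fit.converged
        assert fit.mu[0] == pytest.approx(0.0, abs=0.1)
        assert fit.mu[1] == pytest.approx(4.0, abs=0.1)
        assert fit.pi[0] == pytest.approx(0.6, abs=0.03)
        assert fit.pi[1] == pytest.approx(0.4, abs=0.03)

    def test_all_identical_values_degenerate(self):
        fit = th.fit_mixture_1d(np.full(100, 3.5))
        assert not fit.converged

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="50"):
            th.fit_mixture_1d(np.arange(10.0))

    def test_components_ordered(self):
        rng = np.random.default_rng(3)
        x = _draw_mixture(rng, 2000, (0.3, 0.7), (5.0, -2.0)[::-1], (1.0, 0.5)[::-1])
        fit = th.fit_mixture_1d(x, seed=0)
        assert fit.mu[0] <= fit.mu[1]
        assert fit.pi.sum() == pytest.approx(1.0)
        assert (fit.sigma > 0).all()

    def test_em_at_least_as_good_as_grid_search_oracle(self):
        # brute-force ML oracle on a (mu1, mu2) grid with sigma and pi fixed
        # at their true values; EM's free optimum must match or beat it
        rng = np.random.default_rng(7)
        x = _draw_mixture(rng, 2000, (0.5, 0.5), (0.0, 5.0), (1.0, 1.0))
        grid1 = np.arange(-0.5, 0.5, 0.01)
        grid2 = np.arange(4.5, 5.5, 0.01)
        best_ll = -np.inf
        pi = np.array([0.5, 0.5])
        sigma = np.array([1.0, 1.0])
        for m1 in grid1:
            for m2 in grid2:
                ll = th.mixture_loglik(x, pi, np.array([m1, m2]), sigma)
                if ll > best_ll:
                    best_ll, best_mu = ll, (m1, m2)
        fit = th.fit_mixture_1d(x, seed=0)
        assert fit.loglik >= best_ll - 1e-4
        assert fit.mu[0] == pytest.approx(best_mu[0], abs=0.05)
        assert fit.mu[1] == pytest.approx(best_mu[1], abs=0.05)


class TestGaussianIntersection:
    def _fit(self, pi, mu, sigma):
        return th.MixtureFit(
            pi=np.asarray(pi, float), mu=np.asarray(mu, float),
            sigma=np.asarray(sigma, float), loglik=0.0, converged=True,
            n_iter=1, n_obs=100,
        )

    def test_symmetric_case_is_midpoint(self):
        fit = self._fit((0.5, 0.5), (0.0, 4.0), (1.0, 1.0))
        assert th.gaussian_intersection(fit) == pytest.approx(2.0, abs=1e-12)

    def test_unequal_weights_closed_form(self):
        # pi1 e^{-x^2/2} = pi2 e^{-(x-4)^2/2}  ->  x = 2 + ln(9)/4
        fit = self._fit((0.9, 0.1), (0.0, 4.0), (1.0, 1.0))
        assert th.gaussian_intersection(fit) == pytest.approx(
            2.0 + np.log(9.0) / 4.0, abs=1e-6
        )

    def test_unequal_sigma_matches_sign_change_oracle(self):
        fit = self._fit((0.5, 0.5), (0.0, 4.0), (1.0, 2.0))
        got = th.gaussian_intersection(fit)
        assert 0.0 < got < 4.0

        def f(x):
            return 0.5 * np.exp(-0.5 * x**2) / 1.0 - \
                0.5 * np.exp(-0.5 * ((x - 4.0) / 2.0) ** 2) / 2.0

        # coarse scan for the sign change, then a 1e-6-step local grid
        xs = np.arange(0.0, 4.0, 1e-3)
        signs = np.sign(f(xs))
        (changes,) = np.nonzero(np.diff(signs) != 0)
        assert len(changes) >= 1
        lo = xs[changes[0]]
        fine = np.arange(lo - 1e-3, lo + 2e-3, 1e-6)
        fsigns = np.sign(f(fine))
        (fchanges,) = np.nonzero(np.diff(fsigns) != 0)
        root = fine[fchanges[0]]
        assert got == pytest.approx(root, abs=2e-6)

    def test_invariant_under_label_swap(self):
        fit_a = self._fit((0.7, 0.3), (0.0, 3.0), (1.0, 1.5))
        fit_b = self._fit((0.3, 0.7), (3.0, 0.0), (1.5, 1.0))
        assert th.gaussian_intersection(fit_a) == pytest.approx(
            th.gaussian_intersection(fit_b), abs=1e-12
        )

    def test_nonconverged_raises(self):
        fit = self._fit((0.5, 0.5), (0.0, 4.0), (1.0, 1.0))
        fit.converged = False
        with pytest.raises(ValueError, match="negative_population"):
            th.gaussian_intersection(fit)


class TestNegativePopulation:
    def test_quantile_bounded_by_max(self, rng):
        vals = rng.uniform(0, 1.0, 500)
        thr = th.threshold_from_negative_population(vals, quantile=0.99)
        assert thr <= 1.0

    def test_standard_normal_quantile(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(100_000)
        thr = th.threshold_from_negative_population(vals, quantile=0.99)
        assert thr == pytest.approx(2.326, abs=0.05)

    def test_quantile_one_is_max(self, rng):
        vals = rng.normal(size=200)
        thr = th.threshold_from_negative_population(vals, quantile=1.0)
        assert thr == vals.max()

    def test_too_few_negatives(self):
        with pytest.raises(ValueError, match="50"):
            th.threshold_from_negative_population(np.arange(20.0))


class TestApplyThresholds:
    def _clr(self, values):
        arr = np.atleast_2d(np.asarray(values, float))
        return pd.DataFrame(
            arr, index=[f"c{i}" for i in range(arr.shape[0])],
            columns=[f"m{j}" for j in range(arr.shape[1])],
        )

    def test_value_at_threshold_unchanged(self):
        out = th.apply_thresholds(self._clr([[2.0]]), {"m0": 2.0})
        assert out.iloc[0, 0] == 2.0

    def test_below_threshold_zeroed(self):
        out = th.apply_thresholds(self._clr([[1.0], [3.0]]), {"m0": 2.0})
        assert list(out["m0"]) == [0.0, 3.0]

    def test_all_below_gives_zero_column(self):
        out = th.apply_thresholds(self._clr([[0.1], [0.5], [1.9]]), {"m0": 2.0})
        assert (out["m0"] == 0).all()

    def test_missing_threshold_names_marker(self):
        with pytest.raises(KeyError, match="m0"):
            th.apply_thresholds(self._clr([[1.0]]), {})

    def test_true_negative_leakage_on_synthetic(self, small_cohort):
        # fraction of true-negative (type, marker) cells left nonzero <= 5%
        from citepipe.qc import clr_normalize

        adt, rna, tags, cells, truth = small_cohort
        singlets = truth.cells.index[~truth.cells["is_doublet"]]
        clr = clr_normalize(adt.subset_cells(singlets))
        fitted = th.fit_thresholds(clr, seed=0)
        zeroed = th.apply_thresholds(clr, fitted)
        leak_num = leak_den = 0
        true_type = truth.cells.loc[singlets, "true_type"]
        for t, pos in truth.positive_markers.items():
            neg_markers = [m for m in clr.columns if m not in pos]
            in_type = (true_type == t).to_numpy()
            vals = zeroed.loc[in_type, neg_markers].to_numpy()
            leak_num += (vals > 0).sum()
            leak_den += vals.size
        assert leak_num / leak_den <= 0.05

    def test_sensitivity_specificity_on_synthetic(self, small_cohort):
        # signal/background means >= 3 CLR units apart in the default cohort:
        # per-marker sensitivity >= 90%, specificity >= 95%
        from citepipe.qc import clr_normalize

        adt, rna, tags, cells, truth = small_cohort
        singlets = truth.cells.index[~truth.cells["is_doublet"]]
        clr = clr_normalize(adt.subset_cells(singlets))
        fitted = th.fit_thresholds(clr, seed=0)
        zeroed = th.apply_thresholds(clr, fitted)
        true_type = truth.cells.loc[singlets, "true_type"]
        for marker in ["CD3", "CD4", "CD19", "CD14", "CD56"]:
            pos_types = [t for t, pos in truth.positive_markers.items() if marker in pos]
            is_pos = true_type.isin(pos_types).to_numpy()
            nonzero = (zeroed[marker] > 0).to_numpy()
            assert nonzero[is_pos].mean() >= 0.90, marker
            assert (~nonzero[~is_pos]).mean() >= 0.95, marker


class TestExcludeMarker:
    def test_exclude_one_of_forty(self):
        markers = [f"ab{i}" for i in range(40)]
        out = th.exclude_marker(markers, "ab7")
        assert len(out) == 39 and "ab7" not in out

    def test_exclude_none(self):
        markers = [f"ab{i}" for i in range(40)]
        assert len(th.exclude_marker(markers, [])) == 40

    def test_unknown_marker_noop(self):
        markers = ["a", "b"]
        assert th.exclude_marker(markers, "zzz") == ["a", "b"]


class TestFitThresholds:
    def test_unimodal_marker_routed_to_negative_population(self, rng):
        clr = pd.DataFrame({
            "flat": rng.normal(0, 1, 3000),
            "bimodal": np.concatenate([rng.normal(0, 1, 1500), rng.normal(6, 1, 1500)]),
        })
        fitted = {t.marker: t for t in th.fit_thresholds(clr, seed=0)}
        assert fitted["flat"].method == "negative_population"
        assert fitted["bimodal"].method == "mixture"
        assert 1.0 < fitted["bimodal"].threshold < 5.0

    def test_declared_negative_population_used(self, rng):
        clr = pd.DataFrame({"m": np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])})
        neg = rng.normal(0, 1, 1000)
        fitted = th.fit_thresholds(clr, negative_populations={"m": neg}, seed=0)
        assert fitted[0].method == "negative_population"
        assert fitted[0].threshold == pytest.approx(np.quantile(neg, 0.99))

    def test_manual_override(self, rng):
        clr = pd.DataFrame({"m": rng.normal(0, 1, 100)})
        fitted = th.fit_thresholds(clr, manual={"m": 1.23}, seed=0)
        assert fitted[0].method == "manual"
        assert fitted[0].threshold == 1.23

    def test_mixture_threshold_between_means(self, rng):
        clr = pd.DataFrame({"m": np.concatenate([rng.normal(0, 1, 2000), rng.normal(5, 1, 1000)])})
        (fit,) = th.fit_thresholds(clr, seed=0)
        assert fit.method == "mixture" and fit.converged
        assert fit.mu1 <= fit.threshold <= fit.mu2
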