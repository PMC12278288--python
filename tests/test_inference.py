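import itertools

import numpy as np
import pytest
from scipy import stats as sps

from themeclust.errors import DegenerateInputError, ValidationError
from themeclust.inference import (
    contribution_table,
    kruskal_wallis,
    robust_r2,
    shapiro_wilk,
)


class TestShapiroWilk:
    def test_skewed_sample_rejected(self):
        y = np.random.default_rng(0).lognormal(0, 1.5, 168)
        assert shapiro_wilk(y).p_value < 0.05

    def test_normal_sample_type_i_rate(self):
        """Rejection rate at alpha=0.05 over 1000 normal samples stays
        within 3 binomial SDs of the nominal level."""
        rng = np.random.default_rng(1)
        rejections = sum(
            shapiro_wilk(rng.normal(size=168)).p_value < 0.05 for _ in range(1000)
        )
        rate = rejections / 1000
        sd = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < 3 * sd

    def test_validation(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            shapiro_wilk([3.0, 3.0, 3.0])


def _exact_mid_p(y, g):
    """Exact permutation mid-p: half-weight on the observed atom, the
    appropriate target for a continuous approximation to a discrete test."""
    h_obs, _ = kruskal_wallis(y, g)
    hs = np.array([
        kruskal_wallis(y, list(p))[0] for p in set(itertools.permutations(tuple(g)))
    ])
    return h_obs, (np.mean(hs >= h_obs - 1e-12) + np.mean(hs > h_obs + 1e-12)) / 2


class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1..9, group mean ranks 2/5/8: H = (12/90)*3*(9+0+9) = 7.2
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9], [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_identical_values_h_zero_p_one(self):
        assert kruskal_wallis([4.0] * 6, [0, 0, 1, 1, 2, 2]) == (0.0, 1.0)

    def test_rank_invariance_under_exp(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        g = rng.integers(0, 3, 30)
        h1, _ = kruskal_wallis(y, g)
        h2, _ = kruskal_wallis(np.exp(y), g)
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.integers(0, 5, 45).astype(float)
            g = rng.integers(0, 3, 45)
            if len(np.unique(g)) < 2 or np.ptp(y) == 0:
                continue
            h, p = kruskal_wallis(y, g)
            h_ref, p_ref = sps.kruskal(*[y[g == k] for k in np.unique(g)])
            assert h == pytest.approx(h_ref, rel=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-9)

    @pytest.mark.parametrize("sizes", [(2, 2, 2), (3, 2, 2), (3, 3, 1), (4, 3)])
    def test_small_sample_p_tracks_exact_enumeration(self, sizes):
        """For total n <= 7 the chi-square p must track the exact
        permutation p; the 0.15 band is the scale of the chi-square
        approximation error at these sizes."""
        rng = np.random.default_rng(sum(sizes))
        g = np.repeat(np.arange(len(sizes)), sizes)
        for _ in range(4):
            y = rng.normal(size=len(g)) + g * rng.uniform(0, 2)
            h_obs, p_mid = _exact_mid_p(y, g)
            _, p_chi = kruskal_wallis(y, g)
            assert abs(p_chi - p_mid) < 0.15

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1.0, 2.0], [0, 0])


class TestRobustR2:
    def test_perfect_fit_is_one(self):
        assert robust_r2([1.0, 1, 2, 2, 5, 5], [0, 0, 1, 1, 2, 2]) == pytest.approx(1.0)

    def test_null_response_near_zero(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=168)
        g = np.repeat([0, 1, 2], 56)
        assert robust_r2(y, g) < 0.1

    def test_matches_ols_on_clean_gaussian(self):
        rng = np.random.default_rng(5)
        g = np.repeat([0, 1, 2], 56)
        y = np.array([0.0, 3.0, 6.0])[g] + rng.normal(0, 1, 168)
        mu = np.array([y[g == k].mean() for k in range(3)])
        ols = 1 - ((y - mu[g]) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert robust_r2(y, g) == pytest.approx(ols, abs=0.05)

    def test_stable_under_gross_contamination(self):
        rng = np.random.default_rng(6)
        g = np.repeat([0, 1, 2], 56)
        y = np.array([0.0, 3.0, 6.0])[g] + rng.normal(0, 1, 168)
        clean = robust_r2(y, g)
        yc = y.copy()
        idx = rng.choice(168, 8, replace=False)  # ~5% gross outliers
        yc[idx] += rng.choice([-1.0, 1.0], 8) * 50
        contaminated = robust_r2(yc, g)
        mu = np.array([yc[g == k].mean() for k in range(3)])
        ols_c = 1 - ((yc - mu[g]) ** 2).sum() / ((yc - yc.mean()) ** 2).sum()
        assert abs(contaminated - clean) < 0.1
        assert abs(ols_c - clean) > abs(contaminated - clean)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            robust_r2([2.0, 2.0, 2.0, 2.0], [0, 0, 1, 1])
        with pytest.raises(ValidationError):
            robust_r2([1.0, 2.0], [0, 0])


class TestContributionTable:
    def test_planted_signal_ranks_first_noise_nonsignificant(self):
        import pandas as pd

        from themeclust.data_io import IndicatorTable, ThemeSpec

        rng = np.random.default_rng(7)
        n = 168
        g = np.repeat([1, 2, 3], 56)
        signal = g * 10.0 + rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        table = IndicatorTable(
            values=pd.DataFrame(
                {"signal": signal, "noise": noise},
                index=pd.Index([f"c{i}" for i in range(n)], name="country"),
            ),
            themes=(ThemeSpec("T", ("signal", "noise")),),
        )
        assignments = {"T": {f"c{i}": int(g[i]) for i in range(n)}}
        rows = contribution_table(table, assignments)
        assert rows[0].variable == "signal"
        assert rows[0].robust_r2 > 0.9
        noise_row = next(r for r in rows if r.variable == "noise")
        assert noise_row.p_value > 0.05
        assert noise_row.robust_r2 < 0.1

    def test_duplicate_columns_identical_statistics(self):
        import pandas as pd

        from themeclust.data_io import IndicatorTable, ThemeSpec

        rng = np.random.default_rng(8)
        n = 60
        g = np.repeat([1, 2, 3], 20)
        x = g * 2.0 + rng.normal(0, 1, n)
        table = IndicatorTable(
            values=pd.DataFrame(
                {"x1": x, "x2": x},
                index=pd.Index([f"c{i}" for i in range(n)], name="country"),
            ),
            themes=(ThemeSpec("T", ("x1", "x2")),),
        )
        assignments = {"T": {f"c{i}": int(g[i]) for i in range(n)}}
        r1, r2 = contribution_table(table, assignments)
        assert r1.robust_r2 == pytest.approx(r2.robust_r2)
        assert r1.h_stat == pytest.approx(r2.h_stat)

    def test_robust_r2_rank_order_tracks_planted_separation(self):
        """Variables with stronger between-tier separation must earn higher
        robust R^2: Spearman correlation of the two rankings >= 0.9."""
        import pandas as pd

        from themeclust.data_io import IndicatorTable, ThemeSpec

        rng = np.random.default_rng(10)
        n = 168
        g = np.repeat([1, 2, 3], 56)
        separations = np.linspace(0.5, 6.0, 8)
        cols = {
            f"v{j}": g * sep + rng.normal(0, 1, n)
            for j, sep in enumerate(separations)
        }
        table = IndicatorTable(
            values=pd.DataFrame(cols, index=pd.Index([f"c{i}" for i in range(n)], name="country")),
            themes=(ThemeSpec("T", tuple(cols)),),
        )
        assignments = {"T": {f"c{i}": int(g[i]) for i in range(n)}}
        rows = contribution_table(table, assignments)
        r2_by_var = {r.variable: r.robust_r2 for r in rows}
        rho = sps.spearmanr(
            separations, [r2_by_var[f"v{j}"] for j in range(len(separations))]
        ).statistic
        assert rho >= 0.9

    def test_bh_column_monotone_and_bounded(self):
        import pandas as pd

        from themeclust.data_io import IndicatorTable, ThemeSpec

        rng = np.random.default_rng(9)
        n = 90
        g = np.repeat([1, 2, 3], 30)
        cols = {f"v{j}": g * (j % 3) + rng.normal(0, 1, n) for j in range(6)}
        table = IndicatorTable(
            values=pd.DataFrame(cols, index=pd.Index([f"c{i}" for i in range(n)], name="country")),
            themes=(ThemeSpec("T", tuple(cols)),),
        )
        assignments = {"T": {f"c{i}": int(g[i]) for i in range(n)}}
        rows = contribution_table(table, assignments, bh=True)
        from statsmodels.stats.multitest import multipletests

        ref = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        np.testing.assert_allclose([r.p_bh for r in rows], ref, rtol=1e-12)
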