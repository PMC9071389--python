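"""Half-life pipeline: filter/mask rules, exponential fitting vs brute-force
oracles, normalization factors, replicate merging, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bricdecay.bricseq import (
    HalfLifeConfig,
    compute_half_lives,
    counts_matrix,
    DecayFit,
    estimate_norm_factors,
    filter_genes,
    fit_decay,
    mask_timepoints,
    merge_replicates,
    _cpm,
)
from bricdecay.simdata import SimConfig, simulate_bric_counts, simulate_truth
from conftest import TIMES, TCOLS, make_tidy_counts

LN2 = np.log(2.0)


def _matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=TCOLS)
    df.index.name = "gene_id"
    return df


def exact_exp(a: float, halflife: float, times=TIMES) -> np.ndarray:
    return a * 2.0 ** (-np.asarray(times) / halflife)


# ---------------------------------------------------------------------------
# hand-worked twelve-gene fixture; library columns are padded to exactly
# 2.5e6 reads so that cpm == 0.4 * count and every rule outcome is checkable
# by hand
# ---------------------------------------------------------------------------

FIXTURE_REP1 = {
    "g_lowsum":   [1, 1, 1, 1, 1, 1, 3],                       # total 9
    "g_lowearly": [10, 4, 10, 10, 10, 10, 10],                 # cpm(t1)=1.6
    "g_boundary": [5, 5, 5, 5, 5, 5, 5],                       # cpm 2.0 flat
    "g_exact":    [131072, 65536, 32768, 8192, 512, 32, 2],    # t1/2 = 1 h
    "g_suffix":   [1000, 500, 250, 1, 400, 200, 100],          # cpm(t4)=0.4
    "g_rebound":  [50, 40, 30, 20, 10, 2, 30],                 # 30/2 = 15x
    "g_toofew":   [5, 5, 25, 5, 5, 5, 5],                      # rebound at t2
    "g_capneg":   [10, 11, 12, 13, 14, 15, 16],                # rising, b<0
    "g_extra1":   [800, 700, 600, 500, 400, 300, 200],
    "g_extra2":   [100, 90, 80, 70, 60, 50, 40],
    "g_extra3":   [60, 50, 40, 30, 20, 10, 5],
}

FIXTURE_REP2 = dict(
    FIXTURE_REP1,
    g_exact=[65536, 16384, 4096, 256, 1, 1, 1],                # t1/2 = 0.5 h
    g_suffix=[5, 5, 25, 5, 5, 5, 5],                           # fails in rep 2
)


def _with_ballast(rows: dict) -> dict:
    rows = dict(rows)
    arr = np.array(list(rows.values()), dtype=float)
    ballast = 2_500_000 - arr.sum(axis=0)
    assert (ballast > 0).all()
    rows["g_ballast"] = ballast.tolist()
    return rows


@pytest.fixture(scope="module")
def fixture_counts() -> pd.DataFrame:
    r1 = make_tidy_counts(_with_ballast(FIXTURE_REP1), replicate=1)
    r2 = make_tidy_counts(_with_ballast(FIXTURE_REP2), replicate=2)
    return pd.concat([r1, r2], ignore_index=True)


class TestFilterRules:
    def test_fixture_filter_outcomes(self, fixture_counts):
        mat, times = counts_matrix(fixture_counts, "S2", 1)
        flt = filter_genes(mat, times)
        assert not flt.loc["g_lowsum", "kept"]
        assert flt.loc["g_lowsum", "reason"] == "low_total"
        assert not flt.loc["g_lowearly", "kept"]
        assert flt.loc["g_lowearly", "reason"] == "low_early_cpm"
        # boundary gene: total 35 >= 10 and cpm exactly 2.0 (strict "below")
        assert flt.loc["g_boundary", "kept"]
        kept = flt[flt["kept"]].index
        assert set(kept) == set(flt.index) - {"g_lowsum", "g_lowearly"}

    def test_missing_early_timepoint_rejected(self, fixture_counts):
        mat, times = counts_matrix(fixture_counts, "S2", 1)
        with pytest.raises(ValueError):
            filter_genes(mat.drop(columns=["t1"]), times[times != 1.0])


@pytest.fixture(scope="module")
def fixture_masks(fixture_counts):
    mat, times = counts_matrix(fixture_counts, "S2", 1)
    flt = filter_genes(mat, times)
    cpm_kept = _cpm(mat).loc[flt[flt["kept"]].index]
    return mask_timepoints(cpm_kept)


class TestMaskRules:

    def test_low_cpm_masks_suffix(self, fixture_masks):
        valid, reason = fixture_masks
        assert valid.loc["g_suffix"].tolist() == [True] * 3 + [False] * 4
        assert reason.loc["g_suffix"] == "low_cpm_tail"

    def test_rebound_masks_late_points(self, fixture_masks):
        valid, reason = fixture_masks
        assert valid.loc["g_rebound"].tolist() == [True] * 6 + [False]
        assert reason.loc["g_rebound"] == "rebound_tail"

    def test_all_points_valid_when_no_rule_fires(self, fixture_masks):
        valid, reason = fixture_masks
        assert valid.loc["g_exact"].all()
        assert reason.loc["g_exact"] == ""

    def test_early_rebound_leaves_too_few_points(self, fixture_masks):
        valid, reason = fixture_masks
        assert valid.loc["g_toofew"].sum() == 2
        assert reason.loc["g_toofew"] == "too_few_points"

    @pytest.mark.parametrize(
        "series,n_valid",
        [
            ([5, 4, 3, 0.4, 2, 1, 1], 3),      # low-cpm suffix
            ([5, 4, 3, 2, 1, 0.9, 3.0], 6),    # 3.0/0.9 > 3 rebound
            ([5, 4, 3, 2, 1, 0.9, 0.5], 7),    # monotone, all >= 0.5
        ],
    )
    def test_documented_mask_examples(self, series, n_valid):
        cpm = pd.DataFrame([series], index=["g"], columns=TCOLS)
        valid, _ = mask_timepoints(cpm)
        assert valid.loc["g"].sum() == n_valid
        assert valid.loc["g"].tolist() == [True] * n_valid + [False] * (7 - n_valid)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=7, max_size=7),
        st.floats(1.5, 5.0),
    )
    def test_masked_points_always_form_a_suffix(self, series, ratio):
        cpm = pd.DataFrame([series], index=["g"], columns=TCOLS)
        valid, _ = mask_timepoints(cpm, HalfLifeConfig(rebound_ratio=ratio))
        v = valid.loc["g"].tolist()
        assert v == sorted(v, reverse=True)  # True...True False...False


class TestFitDecay:
    def test_noiseless_series_recovers_half_life_exactly(self):
        fit = fit_decay(exact_exp(100.0, 4.0), TIMES)
        assert fit.status == "fitted"
        assert fit.half_life_h == pytest.approx(4.0, abs=1e-6)
        assert fit.half_life_h == pytest.approx(LN2 / fit.b, rel=1e-12)

    def test_constant_series_is_capped_at_16(self):
        fit = fit_decay([50.0] * 7, TIMES)
        assert fit.status == "capped16"
        assert fit.half_life_h == 16.0

    def test_too_few_points_fail(self):
        fit = fit_decay([10.0, 5.0], TIMES[:2])
        assert fit.status == "failed"

    def test_matches_grid_search_sse_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            hl = rng.uniform(0.5, 12.0)
            y = exact_exp(100.0, hl) * rng.lognormal(0, 0.2, size=7)
            fit = fit_decay(y, TIMES)
            a_grid = np.linspace(0.2 * y.max(), 2.0 * y.max(), 400)
            b_grid = np.linspace(-0.5, 3.0, 1200)
            pred = a_grid[None, :, None] * np.exp(
                -b_grid[:, None, None] * TIMES[None, None, :]
            )
            sse = ((pred - y[None, None, :]) ** 2).sum(axis=2)
            i, j = np.unravel_index(sse.argmin(), sse.shape)
            assert fit.rss <= sse[i, j] + 1e-9 * sse[i, j]
            assert abs(fit.b - b_grid[i]) < 2 * (b_grid[1] - b_grid[0])

    def test_at_least_as_good_as_scipy_curve_fit(self):
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(8)
        for _ in range(5):
            y = exact_exp(50.0, rng.uniform(1, 10)) * rng.lognormal(0, 0.15, 7)
            fit = fit_decay(y, TIMES)
            popt, _ = curve_fit(
                lambda t, a, b: a * np.exp(-b * t), TIMES, y,
                p0=[y[0], 0.2], maxfev=10_000,
            )
            sse_scipy = ((popt[0] * np.exp(-popt[1] * TIMES) - y) ** 2).sum()
            assert fit.rss <= sse_scipy * (1 + 1e-8)


class TestNormFactors:
    def _perfect_matrix(self, n=200, seed=0, distortion=None):
        rng = np.random.default_rng(seed)
        hl = np.exp(np.log(4) + 0.6 * rng.standard_normal(n)).clip(0.5, 40)
        a = np.exp(5 + rng.standard_normal(n))
        Y = a[:, None] * 2.0 ** (-np.outer(1 / hl, TIMES))
        if distortion is not None:
            Y = Y * np.asarray(distortion)
        mat = pd.DataFrame(Y, columns=TCOLS,
                           index=[f"g{i}" for i in range(n)])
        mask = pd.DataFrame(True, index=mat.index, columns=mat.columns)
        return mat, mask

    def test_perfect_exponentials_give_unit_factors_in_one_pass(self):
        mat, mask = self._perfect_matrix()
        nf = estimate_norm_factors(mat, mask, TIMES)
        assert np.abs(nf.factors - 1).max() < 1e-6
        assert nf.n_iterations == 1

    def test_injected_distortion_recovered_up_to_exponential_factor(self):
        d = np.array([1, 1, 1, 0.7, 1, 1.3, 1.0])
        mat, mask = self._perfect_matrix(distortion=d)
        nf = estimate_norm_factors(mat, mask, TIMES)
        # the product f*d can differ from 1 only by c*exp(k*t): the
        # exponential direction is unidentifiable from the data
        resid = np.log(nf.factors * d)
        slope, intercept = np.polyfit(TIMES, resid, 1)
        tilt_free = np.exp(resid - slope * TIMES - intercept)
        assert np.abs(tilt_free - 1).max() < 0.02

    def test_exponential_distortion_absorbed_into_rates(self):
        d = np.exp(0.05 * TIMES)
        mat, mask = self._perfect_matrix(distortion=d)
        nf = estimate_norm_factors(mat, mask, TIMES)
        assert np.abs(nf.factors - 1).max() < 1e-6

    def test_rerun_on_corrected_data_is_idempotent(self):
        d = np.array([1, 1, 1, 0.7, 1, 1.3, 1.0])
        mat, mask = self._perfect_matrix(distortion=d)
        nf = estimate_norm_factors(mat, mask, TIMES)
        corrected = mat * nf.factors
        nf2 = estimate_norm_factors(corrected, mask, TIMES)
        assert np.abs(nf2.factors - 1).max() < 5e-3

    def test_too_few_complete_genes_rejected(self):
        mat, mask = self._perfect_matrix(n=20)
        with pytest.raises(ValueError, match="all time points"):
            estimate_norm_factors(mat, mask, TIMES)


class TestMergeReplicates:
    def _fit(self, hl, status="fitted"):
        return DecayFit(1.0, LN2 / hl if hl else np.nan, hl, status, 7, 0.0)

    def test_arithmetic_mean_of_two_replicates(self):
        merged, status = merge_replicates([self._fit(4.0), self._fit(6.0)])
        assert merged == 5.0 and status == "merged"

    def test_capped_value_participates_in_mean(self):
        merged, status = merge_replicates(
            [self._fit(16.0, "capped16"), self._fit(12.0)]
        )
        assert merged == 14.0 and status == "merged"

    def test_single_usable_replicate_is_flagged(self):
        failed = DecayFit(np.nan, np.nan, np.nan, "failed", 2, np.nan)
        merged, status = merge_replicates([failed, self._fit(8.0)])
        assert merged == 8.0 and status == "single_replicate"

    def test_no_usable_replicate_gives_absent(self):
        failed = DecayFit(np.nan, np.nan, np.nan, "failed", 2, np.nan)
        merged, status = merge_replicates([failed, failed])
        assert status is None


@pytest.fixture(scope="module")
def result(fixture_counts):
    table, report = compute_half_lives(fixture_counts, HalfLifeConfig(norm_mode="off"))
    return table.set_index("gene_id"), report


class TestFixturePipeline:
    """End-to-end hand-worked outcomes on the twelve-gene fixture."""

    def test_filtered_genes_absent(self, result):
        table, _ = result
        assert "g_lowsum" not in table.index
        assert "g_lowearly" not in table.index
        assert "g_toofew" not in table.index  # failed in both replicates

    def test_exact_exponentials_merge_to_hand_computed_mean(self, result):
        table, _ = result
        row = table.loc["g_exact"]
        assert row["half_life_rep1"] == pytest.approx(1.0, abs=1e-6)
        assert row["half_life_rep2"] == pytest.approx(0.5, abs=1e-6)
        assert row["half_life_h"] == pytest.approx(0.75, abs=1e-6)
        assert row["status"] == "merged"

    def test_flat_and_rising_genes_cap_at_16(self, result):
        table, _ = result
        assert table.loc["g_boundary", "half_life_h"] == 16.0
        assert table.loc["g_boundary", "status_rep1"] == "capped16"
        assert table.loc["g_capneg", "half_life_h"] == 16.0

    def test_suffix_masked_gene_fits_on_three_points(self, result):
        table, _ = result
        row = table.loc["g_suffix"]
        assert row["n_points_rep1"] == 3
        assert row["half_life_rep1"] == pytest.approx(1.0, abs=1e-6)
        assert row["status_rep2"] == "failed"
        assert row["status"] == "single_replicate"
        assert row["half_life_h"] == pytest.approx(1.0, abs=1e-6)

    def test_report_counts_are_consistent(self, result):
        _, report = result
        stage = report["conditions"]["S2"]["1"]
        assert stage["genes_in"] == 12
        assert stage["kept_after_filter"] == 10
        assert (
            stage["fitted"] + stage["capped16"] + stage["failed"]
            == stage["kept_after_filter"]
        )
        assert stage["failed"] == stage["too_few_points"] == 1


class TestPipelineProperties:
    def test_noiseless_recovery_matches_truth(self, small_config, small_truth,
                                              small_counts):
        table, _ = compute_half_lives(small_counts)
        est = table.set_index("gene_id")["half_life_h"]
        truth = small_truth.set_index("gene_id")["true_halflife_h"].clip(upper=16.0)
        err = (est - truth.loc[est.index]).abs()
        assert err.max() < 1e-4

    def test_scale_invariance(self, small_counts):
        table1, _ = compute_half_lives(small_counts)
        scaled = small_counts.copy()
        scaled[TCOLS] = scaled[TCOLS] * 7.3
        table2, _ = compute_half_lives(scaled)
        m1 = table1.set_index("gene_id")["half_life_h"]
        m2 = table2.set_index("gene_id")["half_life_h"]
        assert np.allclose(m1.to_numpy(), m2.loc[m1.index].to_numpy(), atol=1e-8)

    def test_empty_input_gives_empty_table(self):
        empty = pd.DataFrame(
            columns=["gene_id", "condition", "replicate"] + TCOLS
        )
        table, _ = compute_half_lives(empty)
        assert table.empty
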