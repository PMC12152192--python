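import math

import numpy as np
import pandas as pd
import pytest

from ibmscreen.enrichment_stats import (
    ImputationError,
    LFQMatrix,
    classify_hits,
    impute_lower_tail,
    prepare,
    run_enrichment,
    t_test_two_sample,
)

SAMPLES = ["A1", "A2", "A3", "B1", "B2", "B3"]
GROUPS = {s: s[0] for s in SAMPLES}


def matrix_from(rows: dict, log_transformed=False) -> LFQMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=SAMPLES, dtype=float)
    return LFQMatrix(intensities=df, groups=GROUPS, log_transformed=log_transformed)


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t, independent of the implementation."""
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (sum(a) / na - sum(b) / nb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


class TestLFQMatrix:
    def test_rejects_nonpositive_raw_intensities(self):
        with pytest.raises(ValueError, match="positive"):
            matrix_from({"P1": [1, 2, 3, 4, 5, 0]})

    def test_rejects_single_sample_group(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"], columns=["A1", "A2", "B1"])
        with pytest.raises(ValueError, match="at least 2"):
            LFQMatrix(intensities=df, groups={"A1": "A", "A2": "A", "B1": "B"})


class TestPrepare:
    def test_one_sided_presence_retained_under_any_group(self):
        m = matrix_from({"P1": [4, 8, 16, np.nan, np.nan, np.nan]})
        out = prepare(m, min_valid=2, mode="any_group")
        assert list(out.intensities.index) == ["P1"]
        assert out.intensities.loc["P1", "A2"] == 3.0  # log2(8)

    def test_sparse_protein_dropped(self):
        m = matrix_from({"P1": [4, np.nan, np.nan, 8, np.nan, np.nan]})
        assert prepare(m, min_valid=2).intensities.empty

    def test_each_group_mode_is_stricter(self):
        m = matrix_from({"P1": [4, 8, 16, 4, np.nan, np.nan]})
        assert not prepare(m, min_valid=2, mode="any_group").intensities.empty
        assert prepare(m, min_valid=2, mode="each_group").intensities.empty

    def test_filter_matches_brute_force_on_planted_matrix(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(3, 1, size=(50, 6))
        mask = rng.random((50, 6)) < 0.4
        values[mask] = np.nan
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(50)], columns=SAMPLES)
        m = LFQMatrix(intensities=df, groups=GROUPS)
        kept = set(prepare(m, min_valid=2).intensities.index)
        expected = {
            f"P{i}"
            for i in range(50)
            if (~mask[i, :3]).sum() >= 2 or (~mask[i, 3:]).sum() >= 2
        }
        assert kept == expected


class TestImputeLowerTail:
    def test_complete_matrix_unchanged(self):
        m = matrix_from({"P1": [1, 2, 3, 4, 5, 6]}, log_transformed=True)
        out, mask = impute_lower_tail(m, seed=0)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)
        assert not mask.any().any()

    def test_present_cells_untouched_and_seed_reproducible(self):
        rng = np.random.default_rng(2)
        values = rng.normal(25, 1, size=(30, 6))
        values[rng.random((30, 6)) < 0.3] = np.nan
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(30)], columns=SAMPLES)
        m = LFQMatrix(intensities=df, groups=GROUPS, log_transformed=True)
        out1, mask = impute_lower_tail(m, seed=42)
        out2, _ = impute_lower_tail(m, seed=42)
        pd.testing.assert_frame_equal(out1.intensities, out2.intensities)
        present = ~df.isna().to_numpy()
        assert (out1.intensities.to_numpy()[present] == df.to_numpy()[present]).all()
        assert not out1.intensities.isna().any().any()
        assert mask.equals(df.isna())

    def test_constant_present_values_raise(self):
        m = matrix_from({"P1": [5, 5, 5, 5, np.nan, 5]}, log_transformed=True)
        with pytest.raises(ImputationError, match="constant"):
            impute_lower_tail(m, seed=0)

    def test_column_scope_uses_per_sample_distributions(self):
        df = pd.DataFrame(
            {
                "A1": [10.0, 10.5, np.nan, 9.5],
                "A2": [10.0, 10.4, 9.6, 10.2],
                "A3": [30.0, 30.5, np.nan, 29.5],
                "B1": [10.0, 9.9, 10.1, 10.3],
                "B2": [10.2, 9.8, 10.0, 10.1],
                "B3": [9.9, 10.0, 10.2, 10.4],
            },
            index=[f"P{i}" for i in range(4)],
        )
        m = LFQMatrix(intensities=df, groups=GROUPS, log_transformed=True)
        out, _ = impute_lower_tail(m, downshift=1.8, width=0.3, scope="column", seed=1)
        # imputed A3 cell comes from the A3 column's distribution (around 30)
        assert out.intensities.loc["P2", "A3"] > 20
        assert out.intensities.loc["P2", "A1"] < 20

    def test_calibration_against_downshifted_normal(self):
        # large matrix: empirical imputed mean/sd match mu - d*sigma and w*sigma
        rng = np.random.default_rng(7)
        values = rng.normal(25, 2, size=(2000, 6))
        miss = rng.random((2000, 6)) < 0.3
        present = values[~miss]
        mu, sigma = present.mean(), present.std(ddof=1)
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(2000)], columns=SAMPLES)
        df[pd.DataFrame(miss, index=df.index, columns=df.columns)] = np.nan
        m = LFQMatrix(intensities=df, groups=GROUPS, log_transformed=True)
        out, mask = impute_lower_tail(m, downshift=1.8, width=0.3, seed=3)
        imputed = out.intensities.to_numpy()[mask.to_numpy()]
        se = 0.3 * sigma / math.sqrt(imputed.size)
        assert imputed.size > 3000
        assert abs(imputed.mean() - (mu - 1.8 * sigma)) < 3 * se
        assert abs(imputed.std(ddof=1) - 0.3 * sigma) / (0.3 * sigma) < 0.05


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        m = matrix_from({"P1": [1, 2, 3, 1, 2, 3]}, log_transformed=True)
        row = t_test_two_sample(m).loc["P1"]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_textbook_example_against_closed_form(self):
        m = matrix_from({"P1": [1, 2, 3, 4, 5, 6]}, log_transformed=True)
        row = t_test_two_sample(m).loc["P1"]
        t_expected, df_expected = pooled_t_oracle([1, 2, 3], [4, 5, 6])
        assert row["t"] == pytest.approx(t_expected)
        assert row["t"] == pytest.approx(-3.6742, abs=1e-4)
        assert row["p"] == pytest.approx(0.02131, abs=1e-5)
        assert row["df"] == df_expected == 4
        assert row["difference"] == pytest.approx(-3.0)

    def test_random_matrices_match_closed_form(self):
        rng = np.random.default_rng(11)
        values = rng.normal(20, 2, size=(40, 6))
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(40)], columns=SAMPLES)
        m = LFQMatrix(intensities=df, groups=GROUPS, log_transformed=True)
        rows = t_test_two_sample(m)
        for i in range(40):
            t_expected, _ = pooled_t_oracle(list(values[i, :3]), list(values[i, 3:]))
            assert rows.iloc[i]["t"] == pytest.approx(t_expected)

    def test_swapping_groups_flips_sign_keeps_p(self):
        m = matrix_from({"P1": [1, 2, 3, 4, 5, 7]}, log_transformed=True)
        ab = t_test_two_sample(m, group_order=("A", "B")).loc["P1"]
        ba = t_test_two_sample(m, group_order=("B", "A")).loc["P1"]
        assert ab["t"] == pytest.approx(-ba["t"])
        assert ab["difference"] == pytest.approx(-ba["difference"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_missing_values_rejected(self):
        m = matrix_from({"P1": [1, 2, 3, 4, 5, np.nan]}, log_transformed=True)
        with pytest.raises(ValueError, match="missing"):
            t_test_two_sample(m)


class TestClassifyHits:
    def base_rows(self, p, difference):
        return pd.DataFrame(
            {"difference": [difference], "t": [1.0], "p": [p],
             "neg_log10_p": [-math.log10(p)]},
            index=pd.Index(["P1"], name="protein"),
        )

    def test_textbook_p_is_below_cutoff(self):
        rows = self.base_rows(0.02131, 3.0)
        assert not classify_hits(rows)["significant"].iloc[0]

    def test_strong_positive_enrichment_is_a_hit(self):
        assert classify_hits(self.base_rows(0.001, 1.0))["significant"].iloc[0]

    def test_negative_difference_blocked_when_required(self):
        rows = self.base_rows(0.001, -1.0)
        assert not classify_hits(rows)["significant"].iloc[0]
        assert classify_hits(rows, require_positive_difference=False)[
            "significant"
        ].iloc[0]

    def test_output_sorted_by_p_with_fdr_column(self):
        rows = pd.DataFrame(
            {"difference": [1, 1, 1], "t": [1, 2, 3], "p": [0.5, 0.001, 0.04],
             "neg_log10_p": [-math.log10(p) for p in (0.5, 0.001, 0.04)]},
            index=pd.Index(["P1", "P2", "P3"], name="protein"),
        )
        out = classify_hits(rows)
        assert list(out.index) == ["P2", "P3", "P1"]
        assert "bh_fdr" in out.columns
        assert (out["bh_fdr"] >= out["p"]).all()


class TestRunEnrichment:
    def test_pipeline_recovers_planted_enrichment(self):
        from ibmscreen.synthetic_data import gen_lfq

        planted = gen_lfq(n_proteins=60, n_enriched=6, seed=21)
        result = run_enrichment(planted.matrix, preset="pulldown", seed=22)
        hits = set(result.hits)
        assert len(hits & planted.enriched) >= 5
        assert result.manifest["downshift"] == 1.8
        assert result.manifest["min_valid"] == 2

    def test_ip_preset_parameters(self):
        from ibmscreen.synthetic_data import gen_lfq

        planted = gen_lfq(n_proteins=40, n_enriched=4, seed=31)
        result = run_enrichment(planted.matrix, preset="ip", seed=32)
        assert result.manifest["downshift"] == 2.0
        assert result.manifest["min_valid"] == 3
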