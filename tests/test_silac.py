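"""Site-table IO, normalization, significance testing, and the filter cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphoflux import silac
from phosphoflux.errors import ConfigurationError, EmptyInputError, SchemaError
from phosphoflux.synthetic import SilacSimConfig, generate_silac_table


def one_sample_t_oracle(values, mu0=0.0):
    """Textbook one-sample t: statistic from first principles, p from the
    t CDF.  Independent of scipy.stats.ttest_1samp."""
    x = np.asarray(values, float)
    n = x.size
    mean = x.sum() / n
    var = ((x - mean) ** 2).sum() / (n - 1)
    t = (mean - mu0) / np.sqrt(var / n)
    return 2.0 * (1.0 - stats.t.cdf(abs(t), df=n - 1))


class TestIO:
    def test_round_trip(self, toy_six_site_table, tmp_path):
        path = tmp_path / "sites.tsv"
        silac.write_site_table(toy_six_site_table, path)
        back = silac.read_site_table(path)
        pd.testing.assert_frame_equal(
            back, toy_six_site_table, check_dtype=False, check_exact=False
        )

    def test_generator_contract(self, tmp_path):
        table = generate_silac_table(SilacSimConfig(n_sites=50, missing_rate=0.0, seed=4))
        path = tmp_path / "gen.tsv"
        silac.write_site_table(table, path)
        back = silac.read_site_table(path)
        assert len(back) == 50
        assert (back[silac.ratio_columns(back)].notna().sum(axis=1) == 4).all()

    def test_missing_required_column(self, toy_six_site_table, tmp_path):
        path = tmp_path / "bad.tsv"
        toy_six_site_table.drop(columns=["window"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="window"):
            silac.read_site_table(path)

    def test_missing_ratio_columns(self, toy_six_site_table, tmp_path):
        path = tmp_path / "bad.tsv"
        cols = silac.ratio_columns(toy_six_site_table)
        toy_six_site_table.drop(columns=cols).to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="log2_ratio"):
            silac.read_site_table(path)

    def test_non_numeric_ratio_reports_row(self, toy_six_site_table, tmp_path):
        path = tmp_path / "bad.tsv"
        bad = toy_six_site_table.copy()
        bad["log2_ratio_rep1"] = bad["log2_ratio_rep1"].astype(object)
        bad.loc[2, "log2_ratio_rep1"] = "oops"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="row 2"):
            silac.read_site_table(path)

    def test_column_map_renames(self, toy_six_site_table, tmp_path):
        path = tmp_path / "alien.tsv"
        toy_six_site_table.rename(columns={"protein_id": "Accession"}).to_csv(
            path, sep="\t", index=False
        )
        back = silac.read_site_table(path, column_map={"Accession": "protein_id"})
        assert list(back["protein_id"]) == list(toy_six_site_table["protein_id"])


class TestNormalization:
    def test_median_shift(self):
        table = pd.DataFrame(
            {
                "protein_id": list("abc"),
                "position": [1, 2, 3],
                "residue": "S",
                "window": "A" * 15,
                "log2_ratio_rep1": [0.0, 1.0, 2.0],
            }
        )
        centered = silac.median_center(table)
        assert list(centered["log2_ratio_rep1"]) == [-1.0, 0.0, 1.0]

    def test_idempotent(self, toy_six_site_table):
        once = silac.median_center(toy_six_site_table)
        twice = silac.median_center(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_removes_mixing_shift(self):
        table = generate_silac_table(
            SilacSimConfig(n_sites=301, frac_spiked=0.0, mixing_shift=0.5, missing_rate=0.0, seed=1)
        )
        centered = silac.median_center(table)
        for col in silac.ratio_columns(centered):
            assert centered[col].median() == 0.0  # odd count: exactly zero

    def test_pooled_mode(self):
        table = generate_silac_table(SilacSimConfig(n_sites=100, mixing_shift=1.0, seed=2))
        centered = silac.median_center(table, per_replicate=False)
        pooled = centered[silac.ratio_columns(centered)].to_numpy().ravel()
        assert abs(np.nanmedian(pooled)) < 1e-12

    def test_all_missing_raises(self):
        table = pd.DataFrame(
            {
                "protein_id": ["a"],
                "position": [1],
                "residue": "S",
                "window": "A" * 15,
                "log2_ratio_rep1": [np.nan],
            }
        )
        with pytest.raises(EmptyInputError):
            silac.median_center(table)

    def test_protein_abundance_subtraction(self, toy_six_site_table):
        table = toy_six_site_table.copy()
        table["protein_log2_ratio"] = [0.5, np.nan, 0.0, 0.2, np.nan, 2.0]
        out = silac.correct_protein_abundance(table)
        assert list(out.loc[0, silac.ratio_columns(out)]) == pytest.approx([1.0, 1.1, 0.9, 1.0])
        # missing protein ratio: unchanged, flagged uncorrected
        assert list(out.loc[1, silac.ratio_columns(out)]) == pytest.approx([2.5, -0.5, 1.5, 0.5])
        assert list(out["abundance_corrected"]) == [True, False, True, True, False, True]
        # protein ratio equal to every replicate ratio -> all zeros
        assert (out.loc[5, silac.ratio_columns(out)] == 0.0).all()


class TestFoldChangeTest:
    def test_matches_textbook_oracle(self):
        values = [1.1, 0.9, 1.0, 1.2]
        p = silac.fold_change_test(values)
        assert p == pytest.approx(one_sample_t_oracle(values), abs=1e-10)

    def test_two_values_against_oracle(self):
        values = [0.1, -0.1]
        p = silac.fold_change_test(values)
        assert p == pytest.approx(one_sample_t_oracle(values), abs=1e-10)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(silac.fold_change_test([1.0, 1.0, 1.0, 1.0]))

    def test_single_replicate_is_undefined(self):
        assert np.isnan(silac.fold_change_test([1.0, np.nan, np.nan, np.nan]))

    def test_welch_vs_reference_matches_scipy(self):
        x, ref = [1.2, 0.8, 1.1], [0.0, 0.2, -0.1, 0.1]
        p = silac.fold_change_test(x, mode="welch_vs_reference", reference=ref)
        expected = stats.ttest_ind(x, ref, equal_var=False).pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_rowwise(self, rng):
        values = rng.normal(0, 1, size=(40, 4))
        values[rng.random((40, 4)) < 0.2] = np.nan
        table = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(40)],
                "position": range(40),
                "residue": "S",
                "window": "A" * 15,
            }
        )
        for j in range(4):
            table[f"log2_ratio_rep{j + 1}"] = values[:, j]
        out = silac.add_pvalues(table)
        for i in range(40):
            expected = silac.fold_change_test(values[i])
            got = out.loc[i, "p_value"]
            assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(
                expected, abs=1e-12
            )

    def test_deposited_pvalues_used_verbatim(self, toy_six_site_table):
        table = toy_six_site_table.copy()
        table["p_value"] = [0.5] * 6
        out = silac.add_pvalues(table)
        assert (out["p_value"] == 0.5).all()


class TestCascade:
    def test_toy_counts(self, toy_six_site_table):
        result = silac.apply_cascade(toy_six_site_table, ["cdk1_minimal"])
        counts = result.counts["cdk1_minimal"]
        assert (counts["motif_sites"], counts["fold_sites"], counts["sig_sites"]) == (3, 2, 1)

    def test_tier_tables_reproduce_counts(self, toy_six_site_table):
        result = silac.apply_cascade(toy_six_site_table, ["cdk1_minimal"])
        for tier in ("motif", "fold", "sig"):
            table = result.tier_tables[("cdk1_minimal", tier)]
            assert len(table) == result.counts["cdk1_minimal"][f"{tier}_sites"]

    def test_vacuous_thresholds(self, toy_six_site_table):
        result = silac.apply_cascade(
            toy_six_site_table, ["cdk1_minimal"], fold_threshold=-np.inf, p_threshold=1.0
        )
        counts = result.counts["cdk1_minimal"]
        # the zero-variance site has undefined p and never reaches the p tier
        assert counts["fold_sites"] == counts["motif_sites"]
        assert counts["sig_sites"] == 3

    def test_monotone_in_thresholds(self, rng):
        table = generate_silac_table(SilacSimConfig(n_sites=300, seed=9))
        prev = None
        for fold in (-np.inf, 0.0, 0.5, 1.0, 2.0):
            counts = silac.apply_cascade(table, ["cdk1_minimal"], fold_threshold=fold).counts[
                "cdk1_minimal"
            ]
            if prev is not None:
                assert counts["fold_sites"] <= prev["fold_sites"]
                assert counts["sig_sites"] <= prev["sig_sites"]
            assert counts["sig_sites"] <= counts["fold_sites"] <= counts["motif_sites"]
            prev = counts
        p_prev = None
        for p in (1.0, 0.5, 0.1, 0.01):
            counts = silac.apply_cascade(table, ["cdk1_minimal"], p_threshold=p).counts[
                "cdk1_minimal"
            ]
            if p_prev is not None:
                assert counts["sig_sites"] <= p_prev["sig_sites"]
            p_prev = counts

    def test_empty_rules_rejected(self, toy_six_site_table):
        with pytest.raises(ConfigurationError):
            silac.apply_cascade(toy_six_site_table, [])

    def test_duplicate_sites_collapse(self, toy_six_site_table):
        doubled = pd.concat([toy_six_site_table, toy_six_site_table], ignore_index=True)
        result = silac.apply_cascade(doubled, ["cdk1_minimal"])
        counts = result.counts["cdk1_minimal"]
        assert (counts["motif_sites"], counts["fold_sites"], counts["sig_sites"]) == (3, 2, 1)

    def test_mitotic_list_intersection(self, toy_six_site_table):
        result = silac.apply_cascade(
            toy_six_site_table, ["cdk1_minimal"], mitotic_list=["P1"]
        )
        counts = result.counts["cdk1_minimal"]
        assert counts["mitotic_fold_sites"] == 1
        assert counts["mitotic_sig_sites"] == 1
        assert counts["mitotic_fold_proteins"] == 1

    def test_report_contains_counts(self, toy_six_site_table, tmp_path):
        import yaml

        result = silac.apply_cascade(toy_six_site_table, ["cdk1_minimal"])
        path = tmp_path / "report.yaml"
        silac.write_cascade_report(result, path)
        report = yaml.safe_load(path.read_text())
        tiers = report["motifs"]["cdk1_minimal"]
        assert (tiers["motif_sites"], tiers["fold_sites"], tiers["sig_sites"]) == (3, 2, 1)

    def test_empty_table_report(self, toy_six_site_table, tmp_path):
        empty = toy_six_site_table.iloc[0:0]
        result = silac.apply_cascade(empty, ["cdk1_minimal"])
        assert result.counts["cdk1_minimal"]["motif_sites"] == 0
        silac.write_cascade_report(result, tmp_path / "empty.yaml")
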