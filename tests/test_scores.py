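"""Score construction: weights parsing, variant filtering, allele
alignment, the weighted-sum score, standardization and validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bwvar import dataio
from bwvar.scores import (
    align_dosages,
    compute_score,
    filter_variants,
    read_weights,
    standardize,
    validate_score,
)


def _write(tmp_path, df):
    p = tmp_path / "weights.tsv"
    df.to_csv(p, sep="\t", index=False)
    return p


class TestReadWeights:
    def test_well_formed_table_round_trips(self, tmp_path, toy_weights):
        table = read_weights(_write(tmp_path, toy_weights))
        assert len(table) == 5
        assert list(table["snp_id"]) == list(toy_weights["snp_id"])

    def test_duplicate_snp_id_rejected(self, tmp_path, toy_weights):
        dup = pd.concat([toy_weights, toy_weights.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            read_weights(_write(tmp_path, dup))

    def test_missing_column_named(self, tmp_path, toy_weights):
        with pytest.raises(ValueError, match="imputation_r2"):
            read_weights(_write(tmp_path, toy_weights.drop(columns=["imputation_r2"])))

    def test_identical_alleles_rejected(self, tmp_path, toy_weights):
        bad = toy_weights.copy()
        bad.loc[2, "other_allele"] = bad.loc[2, "effect_allele"]
        with pytest.raises(ValueError, match="rs3"):
            read_weights(_write(tmp_path, bad))

    def test_empty_file_gives_empty_table(self, tmp_path, caplog):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            table = read_weights(p)
        assert table.empty
        assert "empty" in caplog.text


class TestFilterVariants:
    def test_zero_thresholds_retain_everything(self, toy_weights):
        kept, report = filter_variants(toy_weights, 0.0, 0.0)
        assert len(kept) == 5 and report.empty

    def test_joint_maf_info_filter_on_toy_table(self, toy_weights):
        # MAF (0.0005, 0.002, 0.3, 0.4, 0.0009), info (0.9, 0.3, 0.9, 0.5, 0.9)
        # at thresholds (0.001, 0.4): only rs3 and rs4 pass both predicates
        kept, report = filter_variants(toy_weights, 0.001, 0.4)
        assert list(kept["snp_id"]) == ["rs3", "rs4"]
        assert len(report) == 3

    def test_boundary_is_strict(self, toy_weights):
        row = toy_weights.iloc[[0]].copy()
        row["effect_allele_freq"] = 0.999  # MAF exactly 0.001
        kept, report = filter_variants(row, 0.001, 0.0)
        assert kept.empty
        assert "MAF" in report["reason"].iloc[0]

    def test_ambiguous_snps_warn_or_drop(self, toy_weights):
        amb = toy_weights.copy()
        amb.loc[2, ["effect_allele", "other_allele"]] = ["A", "T"]
        kept, _ = filter_variants(amb, 0.0, 0.0)
        assert "rs3" in set(kept["snp_id"])  # retained with warning
        kept2, report2 = filter_variants(amb, 0.0, 0.0, drop_ambiguous=True)
        assert "rs3" not in set(kept2["snp_id"])
        assert "ambiguous" in report2["reason"].iloc[0]


class TestAlignDosages:
    def _vcf_data(self, toy_weights, dosages, flip=()):
        ref = [(w.effect_allele if w.snp_id in flip else w.other_allele)
               for w in toy_weights.itertuples()]
        alt = [(w.other_allele if w.snp_id in flip else w.effect_allele)
               for w in toy_weights.itertuples()]
        return dataio.VcfData(sample_ids=["s1"], snp_ids=list(toy_weights["snp_id"]),
                              ref=ref, alt=alt, dosages=np.asarray(dosages))

    def test_identity_orientation_unchanged(self, toy_weights):
        vd = self._vcf_data(toy_weights, [[1.4, 0, 2, 1, 0.5]])
        out = align_dosages(vd, toy_weights)
        assert out[0, 0] == pytest.approx(1.4)

    def test_flipped_snp_complemented(self, toy_weights):
        vd = self._vcf_data(toy_weights, [[2, 0.5, 0, 1, 1]], flip={"rs1", "rs2"})
        out = align_dosages(vd, toy_weights)
        assert out[0, 0] == pytest.approx(0.0)   # 2 - 2
        assert out[0, 1] == pytest.approx(1.5)   # 2 - 0.5

    def test_allele_mismatch_names_snp(self, toy_weights):
        vd = self._vcf_data(toy_weights, [[1, 1, 1, 1, 1]])
        vd.alt[3] = "G"
        with pytest.raises(ValueError, match="rs4"):
            align_dosages(vd, toy_weights)

    def test_absent_snp_errors_unless_allowed(self, toy_weights):
        vd = self._vcf_data(toy_weights.iloc[:4], [[1, 1, 1, 1]])
        with pytest.raises(KeyError, match="rs5"):
            align_dosages(vd, toy_weights)
        out = align_dosages(vd, toy_weights, allow_missing=True)
        assert out[0, 4] == pytest.approx(2 * 0.0009)  # 2f imputation


class TestComputeScore:
    def test_hand_sum(self, toy_weights):
        w3 = toy_weights.iloc[:3].copy()
        w3["weight_maternal_adj"] = [0.02, -0.01, 0.03]
        got = compute_score(np.array([[1.0, 2.0, 0.0]]), w3, "weight_maternal_adj")
        assert got[0] == pytest.approx(0.02 * 1 - 0.01 * 2 + 0.03 * 0)

    def test_null_and_unit_cases(self, toy_weights):
        w = toy_weights.copy()
        w["weight_fetal_adj"] = 0.0
        assert compute_score(np.ones((4, 5)), w, "weight_fetal_adj") == pytest.approx([0.0] * 4)
        w1 = toy_weights.iloc[[0]].copy()
        w1["weight_fetal_adj"] = 1.0
        assert compute_score(np.array([[2.0]]), w1, "weight_fetal_adj")[0] == 2.0

    def test_missing_dosage_imputed_as_2f(self, toy_weights):
        w1 = toy_weights.iloc[[2]].copy()  # f = 0.3
        w1["weight_fetal_adj"] = 1.0
        got = compute_score(np.array([[np.nan]]), w1, "weight_fetal_adj")
        assert got[0] == pytest.approx(0.6)

    def test_all_weights_missing_rejected(self, toy_weights):
        w = toy_weights.copy()
        w["weight_fetal_adj"] = np.nan
        with pytest.raises(ValueError, match="weight_fetal_adj"):
            compute_score(np.ones((2, 5)), w, "weight_fetal_adj")

    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_linearity_in_weights(self, w1, w2):
        base = pd.DataFrame({
            "effect_allele_freq": [0.5] * 5,
            "wa": w1, "wb": w2, "wsum": np.add(w1, w2),
        })
        d = np.arange(10.0).reshape(2, 5)
        total = compute_score(d, base, "wa") + compute_score(d, base, "wb")
        assert compute_score(d, base, "wsum") == pytest.approx(total, abs=1e-9)


class TestStandardize:
    def test_hand_case(self):
        assert standardize([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40))
    def test_centering_and_unit_sd(self, xs):
        x = np.asarray(xs)
        if np.std(x, ddof=1) < 1e-8:
            return
        z = standardize(x)
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([2.0, 2.0, 2.0])


class TestValidateScore:
    def test_perfect_fit(self):
        z = standardize(np.arange(10.0))
        res = validate_score(z, z)
        assert res["slope"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_slope_equals_cov_over_var(self, rng):
        x = standardize(rng.normal(size=200))
        y = 3570 + 80 * x + rng.normal(0, 400, size=200)
        res = validate_score(x, y)
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res["slope"] == pytest.approx(expected, rel=1e-10)

    def test_null_association(self, rng):
        x = standardize(rng.normal(size=5000))
        y = rng.normal(3570, 444, size=5000)
        res = validate_score(x, y)
        assert abs(res["slope"]) < 3 * 444 / np.sqrt(5000)
        assert res["p"] > 1e-4

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            validate_score(np.zeros(5), np.arange(5.0))


class TestOrientationInvariance:
    def test_flipping_vcf_alleles_leaves_scores_unchanged(self, tmp_path, genotype_cohort):
        from bwvar.scores import standardize as stdz

        cohort = genotype_cohort
        flip = set(cohort.weights["snp_id"].iloc[::2])
        p_fwd, p_flp = tmp_path / "fwd.vcf", tmp_path / "flp.vcf"
        dataio.write_vcf(cohort.genotypes, cohort.weights, p_fwd)
        dataio.write_vcf(cohort.genotypes, cohort.weights, p_flp, flip_snps=flip)
        for path in (p_fwd, p_flp):
            vd = dataio.read_vcf(path)
            aligned = align_dosages(vd, cohort.weights)
        fwd = align_dosages(dataio.read_vcf(p_fwd), cohort.weights)
        flp = align_dosages(dataio.read_vcf(p_flp), cohort.weights)
        np.testing.assert_allclose(fwd, flp)
        s_fwd = stdz(compute_score(fwd, cohort.weights, "weight_fetal_adj"))
        s_flp = stdz(compute_score(flp, cohort.weights, "weight_fetal_adj"))
        np.testing.assert_allclose(s_fwd, s_flp, atol=1e-12)
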