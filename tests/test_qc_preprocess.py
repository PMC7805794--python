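import numpy as np
import pandas as pd
import pytest

from dnamclocks.core_io import BetaMatrix, SampleSheet
from dnamclocks.qc_preprocess import (detection_p_filter, filter_bisulphite_conversion,
                                      genotype_concordance, pca_outliers, predict_sex,
                                      quantile_normalize, remove_blacklist_probes,
                                      run_qc_pipeline)
from dnamclocks.synthetic_data import SimulationConfig, inject_defects, simulate_cohort


def _sheet(ids, **cols):
    base = dict(sample_id=ids, age=[50.0] * len(ids), sex=["unknown"] * len(ids),
                donor_id=ids, region=["ctx"] * len(ids), batch=["b"] * len(ids))
    base.update(cols)
    return SampleSheet(pd.DataFrame(base))


class TestConversionFilter:
    def test_strict_boundary(self):
        sheet = _sheet(["a", "b", "c"], bisulphite_conversion_pct=[81.0, 80.0, 79.9])
        res = filter_bisulphite_conversion(sheet)
        assert res.kept == ["a", "b"]  # exactly 80 is kept, <80 excluded
        assert res.excluded == ["c"]

    def test_all_passing_is_identity(self):
        sheet = _sheet(["a", "b"], bisulphite_conversion_pct=[95.0, 88.0])
        assert filter_bisulphite_conversion(sheet).excluded == []

    def test_missing_metric_names_samples(self):
        sheet = _sheet(["a", "b"], bisulphite_conversion_pct=[95.0, np.nan])
        with pytest.raises(ValueError, match="b"):
            filter_bisulphite_conversion(sheet)


class TestDetectionPFilter:
    @staticmethod
    def _fixture(n_probes=100, n_samples=10):
        sites = [f"cg{i:03d}" for i in range(n_probes)]
        ids = [f"s{j}" for j in range(n_samples)]
        betas = BetaMatrix(pd.DataFrame(0.5, index=sites, columns=ids))
        detp = pd.DataFrame(0.001, index=sites, columns=ids)
        return betas, detp

    def test_sample_failing_two_percent_removed(self):
        betas, detp = self._fixture()
        detp.iloc[0:2, 0] = 0.5  # 2/100 probes fail in s0: 2% > 1%
        out, rep = detection_p_filter(betas, detp)
        assert rep["samples_removed"] == ["s0"]
        assert out.n_samples == 9

    def test_all_confident_is_identity(self):
        betas, detp = self._fixture()
        detp[:] = 0.01
        out, rep = detection_p_filter(betas, detp)
        assert out.n_sites == 100 and out.n_samples == 10
        assert rep["samples_removed"] == [] and rep["probes_removed"] == []

    def test_probe_failing_after_sample_removal(self):
        betas, detp = self._fixture()
        detp.iloc[5, 0:2] = 0.5  # cg005 fails in 2/10 samples: 20% > 1%
        out, rep = detection_p_filter(betas, detp)
        assert rep["probes_removed"] == ["cg005"]
        assert rep["samples_removed"] == []  # 1/100 probes = 1%, not > 1%

    def test_idempotent(self, qc_cohort):
        out1, _ = detection_p_filter(qc_cohort.betas, qc_cohort.detection_p)
        out2, _ = detection_p_filter(out1, qc_cohort.detection_p)
        pd.testing.assert_frame_equal(out1.data, out2.data)

    def test_shape_mismatch_is_error(self):
        betas, detp = self._fixture()
        with pytest.raises(ValueError, match="cover"):
            detection_p_filter(betas, detp.iloc[:50])


class TestPredictSex:
    def test_clean_cohort_no_mismatches(self, qc_cohort):
        rep = predict_sex(qc_cohort.betas, qc_cohort.annotation, qc_cohort.samples)
        assert rep.n_mismatches == 0
        assert rep.confident
        truth = qc_cohort.samples.data.set_index("sample_id")["sex"]
        pred = rep.predictions.set_index("sample_id")["predicted_sex"]
        assert (pred == truth.reindex(pred.index)).all()

    def test_single_swapped_label_flagged(self, defect_cohort):
        rep = predict_sex(defect_cohort.betas, defect_cohort.annotation,
                          defect_cohort.samples)
        flagged = rep.predictions.query("mismatch")["sample_id"].tolist()
        assert flagged == defect_cohort.defect_labels["sex_swap"]

    def test_degenerate_identical_samples_undetermined(self):
        sites = [f"cgX{i:02d}" for i in range(25)] + [f"cgY{i:02d}" for i in range(6)]
        betas = BetaMatrix(pd.DataFrame(0.5, index=sites, columns=["a", "b", "c", "d"]))
        ann = pd.DataFrame({"chromosome": ["X"] * 25 + ["Y"] * 6}, index=sites)
        rep = predict_sex(betas, ann)
        assert set(rep.predictions["predicted_sex"]) == {"undetermined"}
        assert not rep.confident

    def test_too_few_sex_probes_is_error(self):
        sites = [f"cgX{i}" for i in range(5)]
        betas = BetaMatrix(pd.DataFrame(0.5, index=sites, columns=["a", "b", "c", "d"]))
        ann = pd.DataFrame({"chromosome": ["X"] * 5}, index=sites)
        with pytest.raises(ValueError, match="probes"):
            predict_sex(betas, ann)


class TestGenotypeConcordance:
    def test_identical_snp_profiles_are_same_individual(self):
        vals = np.tile(np.array([0.0, 0.5, 1.0, 0.5, 0.0, 1.0, 0.5, 0.0, 1.0, 0.5]),
                       (2, 1)).T
        betas = BetaMatrix(pd.DataFrame(vals * 0.96 + 0.02,
                                        index=[f"rs{i}" for i in range(10)],
                                        columns=["a", "b"]))
        sheet = _sheet(["a", "b"], donor_id=["d1", "d1"])
        rep = genotype_concordance(betas, sheet)
        assert rep.pairs.iloc[0]["r"] == pytest.approx(1.0)
        assert rep.mismatches == [] and rep.duplications == []

    def test_simulated_cohort_separates_pairs(self, qc_cohort):
        snp = qc_cohort.betas.select_sites(
            qc_cohort.annotation.index[qc_cohort.annotation["is_snp"]])
        rep = genotype_concordance(snp, qc_cohort.samples)
        same = rep.pairs[rep.pairs["same_donor"]]
        diff = rep.pairs[~rep.pairs["same_donor"]]
        # >= 95% of pairs on the right side of the threshold
        ok = (same["r"] > 0.9).sum() + (diff["r"] < 0.9).sum()
        assert ok / len(rep.pairs) >= 0.95
        assert rep.mismatches == []

    def test_shuffled_genotypes_flagged_as_mismatch(self, defect_cohort):
        snp = defect_cohort.betas.select_sites(
            defect_cohort.annotation.index[defect_cohort.annotation["is_snp"]])
        rep = genotype_concordance(snp, defect_cohort.samples)
        bad = defect_cohort.defect_labels["genotype_mismatch"][0]
        assert any(bad in pair for pair in rep.mismatches)

    def test_too_few_probes_is_error(self):
        betas = BetaMatrix(pd.DataFrame(0.5, index=["rs1"], columns=["a", "b"]))
        with pytest.raises(ValueError, match="SNP probes"):
            genotype_concordance(betas, _sheet(["a", "b"]))


class TestPCAOutliers:
    def test_constructed_outlier_flagged_exactly(self):
        r = np.random.default_rng(1)
        sites = [f"cg{i:03d}" for i in range(300)]
        ids = [f"s{j}" for j in range(51)]
        vals = np.clip(0.5 + r.normal(0, 0.02, (300, 51)), 0, 1)
        vals[:200, 50] = np.clip(vals[:200, 50] + 0.2, 0, 1)  # 10 SD on 200 probes
        betas = BetaMatrix(pd.DataFrame(vals, index=sites, columns=ids))
        assert pca_outliers(betas) == ["s50"]

    def test_homogeneous_cohort_low_false_positive_rate(self):
        flagged = total = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals = np.clip(0.5 + r.normal(0, 0.02, (200, 60)), 0, 1)
            betas = BetaMatrix(pd.DataFrame(
                vals, index=[f"cg{i}" for i in range(200)],
                columns=[f"s{j}" for j in range(60)]))
            flagged += len(pca_outliers(betas))
            total += 60
        assert flagged / total <= 0.03  # ~1% expected at 3 SD, allow slack

    def test_too_few_samples_is_error(self):
        betas = BetaMatrix(pd.DataFrame(0.5, index=["cg1", "cg2"], columns=["a", "b", "c"]))
        with pytest.raises(ValueError, match="samples"):
            pca_outliers(betas, n_pc=3)


class TestBlacklist:
    def test_removes_intersection_only(self, qc_cohort):
        targets = qc_cohort.betas.site_ids[:2]
        out, n = remove_blacklist_probes(qc_cohort.betas, set(targets) | {"cg_not_there"})
        assert n == 2
        assert out.n_sites == qc_cohort.betas.n_sites - 2

    def test_empty_blacklist_is_identity(self, qc_cohort):
        out, n = remove_blacklist_probes(qc_cohort.betas, [])
        assert n == 0 and out.n_sites == qc_cohort.betas.n_sites

    def test_full_blacklist_warns(self, qc_cohort):
        with pytest.warns(UserWarning, match="every probe"):
            out, _ = remove_blacklist_probes(qc_cohort.betas, qc_cohort.betas.site_ids)
        assert out.n_sites == 0

    def test_idempotent(self, qc_cohort):
        bl = qc_cohort.betas.site_ids[:5]
        once, _ = remove_blacklist_probes(qc_cohort.betas, bl)
        twice, n2 = remove_blacklist_probes(once, bl)
        assert n2 == 0
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestQuantileNormalize:
    @staticmethod
    def _intensities(rng, n_probes=60, n_samples=5):
        sites = [f"cg{i:02d}" for i in range(n_probes)]
        ids = [f"s{j}" for j in range(n_samples)]
        meth = pd.DataFrame(rng.gamma(4, 500, (n_probes, n_samples)), index=sites, columns=ids)
        unmeth = pd.DataFrame(rng.gamma(4, 500, (n_probes, n_samples)), index=sites, columns=ids)
        ptype = pd.Series(["I"] * (n_probes // 2) + ["II"] * (n_probes - n_probes // 2),
                          index=sites)
        return meth, unmeth, ptype

    def test_identical_samples_unchanged(self, rng):
        meth, unmeth, ptype = self._intensities(rng, n_samples=1)
        meth = pd.concat([meth, meth.rename(columns={"s0": "s1"})], axis=1)
        unmeth = pd.concat([unmeth, unmeth.rename(columns={"s0": "s1"})], axis=1)
        out = quantile_normalize(meth, unmeth, ptype)
        expected = meth.to_numpy() / (meth.to_numpy() + unmeth.to_numpy() + 100.0)
        assert out.data.to_numpy() == pytest.approx(expected)

    def test_within_type_m_distributions_identical_multisets(self, rng):
        from dnamclocks.qc_preprocess import quantile_normalize_intensities
        meth, _, ptype = self._intensities(rng)
        norm = quantile_normalize_intensities(meth, ptype)
        for t in ("I", "II"):
            idx = ptype[ptype == t].index
            block = norm.loc[idx].to_numpy()
            ref = np.sort(block[:, 0])
            for j in range(1, block.shape[1]):
                assert np.sort(block[:, j]) == pytest.approx(ref)

    def test_rank_invariance_under_monotone_transform(self, rng):
        from dnamclocks.qc_preprocess import quantile_normalize_intensities
        meth, _, ptype = self._intensities(rng)
        norm1 = quantile_normalize_intensities(meth, ptype)
        meth2 = meth.copy()
        meth2["s0"] = meth2["s0"] * 2.0  # monotone, rank-preserving
        norm2 = quantile_normalize_intensities(meth2, ptype)
        for t in ("I", "II"):
            idx = ptype[ptype == t].index
            for col in meth.columns:
                # each sample keeps its own input ranks, before and after
                for norm, src in ((norm1, meth), (norm2, meth2)):
                    a = src.loc[idx, col].to_numpy()
                    b = norm.loc[idx, col].to_numpy()
                    assert np.array_equal(np.argsort(a, kind="stable"),
                                          np.argsort(b, kind="stable"))

    def test_negative_intensity_rejected(self, rng):
        meth, unmeth, ptype = self._intensities(rng)
        meth.iloc[0, 0] = -5.0
        with pytest.raises(ValueError, match="non-negative"):
            quantile_normalize(meth, unmeth, ptype)


class TestPipeline:
    def test_clean_cohort_loses_nothing_but_blacklist(self, qc_cohort):
        bl = qc_cohort.betas.site_ids[:3]
        res = run_qc_pipeline(qc_cohort.betas, qc_cohort.samples,
                              detp=qc_cohort.detection_p,
                              annotation=qc_cohort.annotation, blacklist=bl)
        assert res.betas.n_samples == qc_cohort.betas.n_samples
        assert res.betas.n_sites == qc_cohort.betas.n_sites - 3
        assert res.steps["conversion"].excluded == []
        assert res.steps["sex_check"].n_mismatches == 0
        assert res.steps["pca_outliers"] == []

    def test_defects_detected_end_to_end(self, defect_cohort):
        labels = defect_cohort.defect_labels
        res = run_qc_pipeline(defect_cohort.betas, defect_cohort.samples,
                              detp=defect_cohort.detection_p,
                              annotation=defect_cohort.annotation)
        assert res.steps["conversion"].excluded == labels["low_conversion"]
        flagged = res.steps["sex_check"].predictions.query("mismatch")["sample_id"]
        assert flagged.tolist() == labels["sex_swap"]
        assert any(labels["genotype_mismatch"][0] in p
                   for p in res.steps["genotype"].mismatches)
        assert res.steps["detection_p"]["samples_removed"] == labels["bad_sample_detp"]
        assert res.steps["pca_outliers"] == labels["pca_outlier"]
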