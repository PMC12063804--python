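"""Tests of the evaluation suite: CCC, stability, power, discrimination,
image quality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctharmony.evaluation import (
    ConstantInputError,
    PairingError,
    ccc,
    discrimination_report,
    image_quality,
    paired_power,
    reproducibility_report,
    stability_report,
)
from ctharmony.synthetic import feature_names, simulate_feature_table
from ctharmony.types import SimDesign


def _paired_table(n_groups=3, n_scans=10, n_features=4, seed=0, shifts=None):
    """Long-format table with per-scan latent shared across groups."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(0, 3, size=(n_scans, n_features))
    rows = []
    for g in range(1, n_groups + 1):
        shift = 0.0 if shifts is None else shifts.get(g, 0.0)
        noise = rng.normal(0, 0.3, size=(n_scans, n_features))
        for s in range(n_scans):
            rows.append([g, s, 1] + list(latent[s] + shift + noise[s]))
    cols = ["group", "scan", "roi"] + feature_names(n_features)
    return pd.DataFrame(rows, columns=cols)


class TestCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert ccc(x, x) == pytest.approx(1.0)

    def test_perfect_reversed_concordance(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ccc(x, -x) == pytest.approx(-1.0)

    def test_toy_value(self):
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(0.5714, abs=5e-5)

    def test_symmetry_and_pearson_bound(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            assert ccc(x, y) == ccc(y, x)
            assert abs(ccc(x, y)) <= abs(stats.pearsonr(x, y).statistic) + 1e-12

    def test_equality_with_pearson_iff_moments_match(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.5, size=50)
        y = (y - y.mean()) / y.std() * x.std() + x.mean()  # match moments
        assert ccc(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_constant_input_signalled(self):
        with pytest.raises(ConstantInputError):
            ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestReproducibility:
    def test_self_comparison_is_perfect(self):
        table = _paired_table()
        rep = reproducibility_report(table, reference_group=1)
        assert rep.average_ccc == pytest.approx(1.0, abs=0.05)

    def test_reference_duplicated_as_other_group_gives_ccc_one(self):
        table = _paired_table(n_groups=1)
        dup = table.copy()
        dup["group"] = 2
        both = pd.concat([table, dup], ignore_index=True)
        rep = reproducibility_report(both, reference_group=1)
        assert rep.average_ccc == pytest.approx(1.0)
        assert rep.fraction_reproducible == 1.0

    def test_constant_feature_excluded(self):
        table = _paired_table()
        table["f000"] = 7.0
        rep = reproducibility_report(table, reference_group=1)
        assert "f000" in rep.excluded_features
        assert "f000" not in set(rep.records["feature"])

    def test_matches_brute_force_loop(self):
        table = _paired_table(n_groups=4, n_scans=8, n_features=3, seed=5)
        rep = reproducibility_report(table, reference_group=1)
        feats = feature_names(3)
        expected = []
        for g in (2, 3, 4):
            for f in feats:
                ref = table[(table.group == 1)].sort_values("scan")[f].to_numpy()
                oth = table[(table.group == g)].sort_values("scan")[f].to_numpy()
                expected.append(ccc(ref, oth))
        assert rep.average_ccc == pytest.approx(float(np.mean(expected)), abs=1e-12)

    def test_misaligned_scans_rejected(self):
        table = _paired_table()
        table.loc[(table.group == 2) & (table.scan == 0), "scan"] = 99
        with pytest.raises(PairingError):
            reproducibility_report(table, reference_group=1)

    def test_baseline_attached_when_harmonized_given(self):
        table = _paired_table(shifts={2: 5.0, 3: 5.0})
        harmonized = _paired_table()
        rep = reproducibility_report(table, harmonized, reference_group=1)
        assert rep.baseline is not None
        assert rep.average_ccc >= rep.baseline.average_ccc


class TestStability:
    def test_identical_groups_fully_stable(self):
        table = _paired_table(seed=1)
        base = table[table.group == 1].copy()
        pieces = []
        for g in (1, 2, 3):
            p = base.copy()
            p["group"] = g
            pieces.append(p)
        rep = stability_report(pd.concat(pieces, ignore_index=True), reference_group=1)
        assert (rep.per_roi["percent_stable"] == 100.0).all()
        assert (rep.records["test"] == "all-zero").all()

    def test_bonferroni_arithmetic(self):
        # raw p = 0.02 with 7 comparisons -> adjusted 0.14 -> stable
        assert min(1.0, 7 * 0.02) == pytest.approx(0.14)
        table = _paired_table(n_groups=2, n_scans=30, seed=2)
        rep = stability_report(table, reference_group=1, n_comparisons=7)
        assert (rep.records["p_adjusted"] >= rep.records["p_raw"]).all()
        assert (rep.records["p_adjusted"] <= 1.0).all()

    def test_large_shift_detected_as_unstable(self):
        table = _paired_table(n_groups=8, n_scans=30, n_features=4, seed=3)
        pooled_sd = table[table.group == 1]["f000"].std()
        table.loc[table.group == 2, "f000"] += 3.0 * pooled_sd
        rep = stability_report(table, reference_group=7)
        stable_f0 = (
            rep.records[(rep.records.feature == "f000") & (rep.records.group == 2)][
                "p_adjusted"
            ]
            > 0.05
        ).all()
        assert not stable_f0


class TestPairedPower:
    def test_reference_scenario(self):
        assert paired_power(0.5, 0.05, 30) == pytest.approx(0.754, abs=5e-4)

    def test_null_effect_gives_type_one_rate(self):
        assert paired_power(0.0, 0.05, 20) == pytest.approx(0.05, abs=1e-9)

    def test_large_sample_saturates(self):
        assert paired_power(0.5, 0.05, 1000) >= 0.999

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.power import TTestPower

        for d, n in ((0.3, 25), (0.5, 30), (0.8, 12)):
            expected = TTestPower().power(effect_size=d, nobs=n, alpha=0.05)
            assert paired_power(d, 0.05, n) == pytest.approx(expected, abs=1e-6)


class TestDiscrimination:
    @staticmethod
    def _class_table(n_per_class=25, n_features=6, sep=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for roi in (1, 2, 3, 4):
            centers = rng.normal(0, sep, size=n_features)
            for s in range(n_per_class):
                rows.append([1, s, roi] + list(centers + rng.normal(size=n_features)))
        return pd.DataFrame(rows, columns=["group", "scan", "roi"] + feature_names(n_features))

    def test_separable_classes_reach_perfect_auc(self):
        table = self._class_table(sep=5.0, seed=1)
        rep = discrimination_report(table, seed=0)
        assert all(v == pytest.approx(1.0) for v in rep.per_class_auc.values())
        assert rep.macro_auc == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self):
        table = self._class_table(n_per_class=100, sep=3.0, seed=2)
        rng = np.random.default_rng(7)
        table["roi"] = rng.permutation(table["roi"].to_numpy())
        rep = discrimination_report(table, seed=0)
        assert 0.40 <= rep.macro_auc <= 0.60

    def test_duplicated_feature_column_filtered(self):
        table = self._class_table(seed=3)
        table["f005"] = table["f000"]  # exact duplicate
        rep = discrimination_report(table, seed=0)
        assert ("f000" in rep.retained_features) != ("f005" in rep.retained_features) or (
            "f005" in rep.dropped_features
        )
        assert "f005" in rep.dropped_features

    def test_too_few_samples_per_class_rejected(self):
        table = self._class_table(n_per_class=2)
        with pytest.raises(ValueError):
            discrimination_report(table, seed=0)


class TestImageQuality:
    def test_identity_pair(self):
        imgs = [np.random.default_rng(0).random((16, 16))]
        rep = image_quality(imgs, imgs, data_range=1.0)
        assert rep.nmse == 0.0
        assert rep.ssim == pytest.approx(1.0)
        assert rep.psnr == pytest.approx(100.0)  # cap

    def test_uniform_error_gives_20db(self):
        t = [np.random.default_rng(1).random((32, 32))]
        g = [t[0] + 0.1]
        rep = image_quality(g, t, data_range=1.0)
        assert rep.psnr == pytest.approx(20.0, abs=1e-9)
        assert rep.nmse == pytest.approx(0.01 * t[0].size / (t[0] ** 2).sum())

    def test_reports_three_metrics(self):
        t = [np.random.default_rng(2).random((16, 16)) for _ in range(3)]
        g = [x + 0.05 for x in t]
        rep = image_quality(g, t, data_range=1.0)
        assert set(rep.per_image.columns) == {"nmse", "psnr", "ssim"}
        assert rep.nmse >= 0 and -1 <= rep.ssim <= 1 and np.isfinite(rep.psnr)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            image_quality([np.zeros((4, 4))], [np.zeros((5, 5))])
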