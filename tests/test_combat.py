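"""Tests of reference-batch ComBat against brute-force oracles and
simulation recovery."""

import numpy as np
import pandas as pd
import pytest

from ctharmony import combat
from ctharmony.combat import (
    DesignMatrixError,
    ReferenceComBat,
    StratumError,
    UnknownBatchError,
    harmonize_per_roi,
)
from ctharmony.synthetic import simulate_feature_table
from ctharmony.types import SimDesign

FEATS = lambda t: [c for c in t.columns if c.startswith("f")]


def _sim(gamma, delta, n=200, n_features=10, seed=0, n_rois=1, **kw):
    d = SimDesign(
        n_features=n_features,
        batch_ids=[1, 2],
        n_per_batch=n,
        gamma=np.asarray(gamma, float),
        delta=np.asarray(delta, float),
        noise_sd=1.0,
        n_rois=n_rois,
        seed=seed,
        **kw,
    )
    return simulate_feature_table(d)


def _location_scale_oracle(table, reference=1):
    """Independent non-EB oracle: per-feature standardized batch moments."""
    feats = FEATS(table)
    Y = table[feats].to_numpy(float)
    batches = table["group"].to_numpy()
    ref = batches == reference
    alpha = Y[ref].mean(axis=0)
    var = Y[ref].var(axis=0, ddof=1)
    Z = (Y - alpha) / np.sqrt(var)
    out = {}
    for b in np.unique(batches):
        rows = batches == b
        out[b] = (Z[rows].mean(axis=0), Z[rows].var(axis=0, ddof=1))
    harmonized = np.empty_like(Y)
    for b in np.unique(batches):
        rows = batches == b
        g, v = out[b]
        if b == reference:
            g, v = np.zeros_like(g), np.ones_like(v)
        harmonized[rows] = ((Z[rows] - g) / np.sqrt(v)) * np.sqrt(var) + alpha
    return out, harmonized


class TestNonEB:
    def test_matches_brute_force_moment_oracle(self):
        table = _sim([0.0, 3.0], [1.0, 2.0], n=4, n_features=3, seed=1)
        model = combat.fit(table, reference_batch=1, eb=False)
        oracle, harmonized = _location_scale_oracle(table, reference=1)
        g2, v2 = oracle[2]
        assert np.allclose(model.gamma_star_.loc[2].to_numpy(), g2, atol=1e-6)
        assert np.allclose(model.delta_star_.loc[2].to_numpy(), np.sqrt(v2), atol=1e-6)
        out = model.transform(table)
        assert np.allclose(out[FEATS(table)].to_numpy(), harmonized, atol=1e-6)

    def test_non_eb_equals_oracle_on_random_instances(self, rng):
        for seed in range(3):
            table = _sim(
                rng.normal(0, 2, 2), np.exp(rng.normal(0, 0.3, 2)), n=8, n_features=5, seed=seed
            )
            model = combat.fit(table, reference_batch=1, eb=False)
            _, harmonized = _location_scale_oracle(table, reference=1)
            assert np.allclose(model.transform(table)[FEATS(table)].to_numpy(), harmonized, 1e-6)


class TestContracts:
    def test_single_reference_batch_is_identity(self):
        d = SimDesign(n_features=4, batch_ids=[7], n_per_batch=6, seed=0)
        table = simulate_feature_table(d)
        model = combat.fit(table, reference_batch=7)
        out = model.transform(table)
        assert np.allclose(out[FEATS(table)], table[FEATS(table)], atol=1e-9)

    def test_reference_rows_unchanged(self):
        table = _sim([0.0, 2.0], [1.0, 1.5], seed=2)
        out = combat.fit(table, reference_batch=1).transform(table)
        ref = table.group == 1
        assert np.allclose(
            out[ref][FEATS(table)].to_numpy(), table[ref][FEATS(table)].to_numpy(), atol=1e-6
        )

    def test_unseen_batch_label_rejected(self):
        table = _sim([0.0, 2.0], [1.0, 1.5])
        model = combat.fit(table, reference_batch=1)
        bad = table.copy()
        bad.loc[bad.index[:5], "group"] = 99
        with pytest.raises(UnknownBatchError):
            model.transform(bad)

    def test_constant_feature_passes_through_with_warning(self):
        table = _sim([0.0, 2.0], [1.0, 1.0], n=20, n_features=3, seed=3)
        table["f000"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            model = combat.fit(table, reference_batch=1)
        out = model.transform(table)
        assert (out["f000"] == 5.0).all()
        assert "f000" in model.constant_features_

    def test_singular_covariate_design_rejected(self):
        table = _sim([0.0, 2.0], [1.0, 1.0], n=10, n_features=3, seed=4)
        table["x"] = (table["group"] == 2).astype(float)  # confounded with batch
        with pytest.raises(DesignMatrixError):
            combat.fit(table, covariates=["x"], reference_batch=1)

    def test_no_nans_and_positive_delta(self):
        table = _sim([0.0, 2.0], [1.0, 0.3], seed=5)
        model = combat.fit(table, reference_batch=1)
        assert (model.delta_star_.to_numpy() > 0).all()
        assert not model.transform(table).isna().any().any()

    def test_json_roundtrip(self):
        table = _sim([0.0, 2.0], [1.0, 1.5], n=20, seed=6)
        model = combat.fit(table, reference_batch=1)
        clone = ReferenceComBat.from_json(model.to_json())
        assert np.allclose(
            clone.transform(table)[FEATS(table)], model.transform(table)[FEATS(table)]
        )


class TestEBRecovery:
    def test_recovers_injected_batch_effects_within_10pct(self):
        table = _sim([0.0, 2.0], [1.0, 1.5], n=200, n_features=30, seed=7)
        model = combat.fit(table, reference_batch=1)
        assert model.gamma_star_.loc[2].mean() == pytest.approx(2.0, rel=0.10)
        assert model.delta_star_.loc[2].mean() == pytest.approx(1.5, rel=0.10)

    def test_additive_effect_gap_reduced_90pct(self):
        table = _sim([0.0, 3.0], [1.0, 1.0], n=200, n_features=10, seed=8)
        out = combat.fit(table, reference_batch=1).transform(table)
        feats = FEATS(table)
        before = (table[table.group == 2][feats].mean() - table[table.group == 1][feats].mean()).abs()
        after = (out[out.group == 2][feats].mean() - out[out.group == 1][feats].mean()).abs()
        assert ((before - after) / before >= 0.90).all()

    def test_near_idempotence(self):
        table = _sim([0.0, 2.0], [1.0, 1.5], n=200, n_features=10, seed=9)
        once = combat.fit(table, reference_batch=1).transform(table)
        twice = combat.fit(once, reference_batch=1).transform(once)
        feats = FEATS(table)
        shift = (twice[feats].mean() - once[feats].mean()).abs()
        assert (shift <= 1e-2 * table[feats].std()).all()

    def test_batch_means_move_toward_reference(self):
        table = simulate_feature_table(
            SimDesign(
                n_features=8,
                batch_ids=[1, 2, 3],
                n_per_batch=100,
                gamma=np.array([0.0, 4.0, -3.0]),
                delta=np.array([1.0, 1.3, 0.8]),
                seed=10,
            )
        )
        out = combat.fit(table, reference_batch=1).transform(table)
        feats = FEATS(table)
        ref_mean = table[table.group == 1][feats].mean()
        for b in (2, 3):
            before = (table[table.group == b][feats].mean() - ref_mean).abs()
            after = (out[out.group == b][feats].mean() - ref_mean).abs()
            assert (after < before).all()

    def test_covariate_protection(self):
        # binary covariate with beta = 5 alongside batch effects
        n = 100
        rng = np.random.default_rng(11)
        x = np.tile([0.0, 1.0], n // 2)
        d = SimDesign(
            n_features=6,
            batch_ids=[1, 2],
            n_per_batch=n,
            beta=np.full(6, 5.0)[None, :] * np.ones((1, 1)),
            covariates=x[:, None],
            gamma=np.array([0.0, 3.0]),
            delta=np.array([1.0, 1.5]),
            seed=12,
        )
        table = simulate_feature_table(d)
        table["x"] = np.tile(x, 2)
        model = combat.fit(table, covariates=["x"], reference_batch=1)
        out = model.transform(table)
        feats = FEATS(table)
        diff = out[out.x == 1][feats].mean() - out[out.x == 0][feats].mean()
        assert (diff >= 0.80 * 5.0).all()


class TestPerROI:
    def test_equals_manual_loop(self):
        table = _sim([0.0, 2.0], [1.0, 1.3], n=30, n_features=5, n_rois=4, seed=13)
        auto = harmonize_per_roi(table, reference_batch=1, batch_key="group")
        manual = []
        for roi, sub in table.groupby("roi", sort=False):
            piece = combat.fit(sub, reference_batch=1).transform(sub)
            piece.attrs = {}
            manual.append(piece)
        manual = pd.concat(manual).loc[table.index]
        assert np.allclose(auto[FEATS(table)], manual[FEATS(table)])

    def test_per_roi_effects_reduced_per_stratum(self):
        rng = np.random.default_rng(14)
        gamma = rng.normal(0, 3, size=(3, 2, 6))  # distinct per roi
        table = _sim(gamma, 1.0, n=100, n_features=6, n_rois=3, seed=15)
        out = harmonize_per_roi(table, reference_batch=1, batch_key="group")
        feats = FEATS(table)
        for roi in (1, 2, 3):
            t = table[table.roi == roi]
            o = out[out.roi == roi]
            before = (t[t.group == 2][feats].mean() - t[t.group == 1][feats].mean()).abs()
            after = (o[o.group == 2][feats].mean() - o[o.group == 1][feats].mean()).abs()
            big = before > 0.5  # reliably estimable gaps
            assert ((before[big] - after[big]) / before[big] >= 0.90).all()

    def test_single_roi_equals_plain_fit_transform(self):
        table = _sim([0.0, 2.0], [1.0, 1.3], n=30, n_features=5, seed=16)
        auto = harmonize_per_roi(table, reference_batch=1, batch_key="group")
        plain = combat.fit(table, reference_batch=1).transform(table)
        assert np.allclose(auto[FEATS(table)], plain[FEATS(table)])

    def test_stratum_with_single_batch_rejected(self):
        table = _sim([0.0, 2.0], [1.0, 1.3], n=10, n_features=3, n_rois=2, seed=17)
        broken = table[~((table.roi == 2) & (table.group == 2))]
        with pytest.raises(StratumError, match="2"):
            harmonize_per_roi(broken, reference_batch=1, batch_key="group")
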