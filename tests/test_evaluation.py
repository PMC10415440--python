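"""ROI statistics, regression, Bland-Altman and ANOVA post hoc checks."""

import numpy as np
import pytest

import wfsep as w
from wfsep.evaluation import agreement_report


def _pdff(values, mask=None):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return w.PdffMap(values=values, mask=mask)


class TestRoiStats:
    def test_constant_region(self):
        pdff = _pdff(np.full((4, 4), 0.25))
        roi = w.Roi("RHL", 0, np.ones((4, 4), bool))
        mean, std = w.roi_stats(pdff, roi)
        assert mean == pytest.approx(0.25)
        assert std == 0.0

    def test_two_pixel_sample_std(self):
        vals = np.zeros((2, 2))
        vals[0, 0], vals[0, 1] = 0.1, 0.3
        sel = np.zeros((2, 2), bool)
        sel[0, :] = True
        mean, std = w.roi_stats(_pdff(vals), w.Roi("LHL", 0, sel))
        assert mean == pytest.approx(0.2)
        assert std == pytest.approx(np.sqrt(((0.1 - 0.2) ** 2 + (0.3 - 0.2) ** 2) / 1))

    def test_roi_outside_mask_raises(self):
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        sel = np.zeros((4, 4), bool)
        sel[3, 3] = True
        with pytest.raises(w.ValidationError):
            w.roi_stats(_pdff(np.zeros((4, 4)), mask), w.Roi("r", 0, sel))


class TestLsRegression:
    def test_identity_line(self):
        x = np.array([0.05, 0.10, 0.20, 0.30])
        slope, intercept, r2 = w.ls_regression(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_exact_affine_relation(self):
        x = np.array([1.0, 2.0, 3.0])
        slope, intercept, r2 = w.ls_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 0.4, 20)
        y = 0.9 * x + 0.01 + rng.normal(0, 0.01, 20)
        slope, intercept, r2 = w.ls_regression(x, y)
        # closed-form normal equations computed independently
        xm, ym = x.mean(), y.mean()
        sxx = ((x - xm) ** 2).sum()
        sxy = ((x - xm) * (y - ym)).sum()
        syy = ((y - ym) ** 2).sum()
        assert slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert intercept == pytest.approx(ym - (sxy / sxx) * xm, abs=1e-10)
        assert r2 == pytest.approx(sxy**2 / (sxx * syy), abs=1e-10)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 15)
        y = rng.uniform(0, 1, 15)
        perm = rng.permutation(15)
        assert w.ls_regression(x, y) == pytest.approx(w.ls_regression(x[perm], y[perm]))

    def test_zero_variance_x_rejected(self):
        with pytest.raises(w.ValidationError):
            w.ls_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestBlandAltman:
    def test_identity_agreement(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert w.bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset_zero_spread(self):
        x = np.array([0.1, 0.2, 0.3])
        bias, lo, hi = w.bland_altman(x, x + 0.5)
        assert bias == pytest.approx(0.5)
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(0.5)

    def test_unit_spread_hand_computation(self):
        # differences (-1, 0, 1): bias 0, sample STD 1, LoA = +/-1.96
        x = np.zeros(3)
        y = np.array([-1.0, 0.0, 1.0])
        bias, lo, hi = w.bland_altman(x, y)
        assert bias == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_length_mismatch_rejected(self):
        with pytest.raises(w.ValidationError):
            w.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


class TestAnovaPosthocStd:
    def test_identical_groups_not_significant(self):
        g = {"a": [0.01, 0.02, 0.03, 0.02], "b": [0.01, 0.02, 0.03, 0.02]}
        _, pairs = w.anova_posthoc_std(g)
        assert all(not sig for *_, sig in pairs)

    def test_large_effect_detected(self):
        rng = np.random.default_rng(3)
        g = {
            "ref": rng.normal(0.01, 0.001, 20),
            "blurred": rng.normal(0.05, 0.001, 20),
        }
        anova_p, pairs = w.anova_posthoc_std(g, alpha=0.05)
        assert anova_p < 0.05
        assert pairs[0][3] is True

    def test_matches_independent_tukey_implementation(self):
        """Cross-check pairwise p-values against statsmodels Tukey HSD."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        g = {
            "gc": rng.normal(0.020, 0.004, 12),
            "mdwf": rng.normal(0.022, 0.004, 12),
            "unet": rng.normal(0.030, 0.004, 12),
        }
        _, pairs = w.anova_posthoc_std(g)
        endog = np.concatenate(list(g.values()))
        labels = sum(([k] * len(v) for k, v in g.items()), [])
        sm = pairwise_tukeyhsd(endog, labels, alpha=0.05)
        sm_p = {tuple(sorted((a, b))): p for (a, b), p in zip(
            [(r[0], r[1]) for r in sm.summary().data[1:]], sm.pvalues)}
        for a, b, p, _ in pairs:
            assert p == pytest.approx(sm_p[tuple(sorted((a, b)))], abs=1e-6)

    def test_degenerate_groups_return_p_one(self):
        g = {"a": [0.01, 0.01], "b": [0.01, 0.01]}
        anova_p, pairs = w.anova_posthoc_std(g)
        assert anova_p == 1.0
        assert pairs[0][2] == 1.0 and pairs[0][3] is False


class TestMaeMap:
    def _maps(self, delta_fieldmap=0.0):
        shape = (6, 6)
        rng = np.random.default_rng(0)
        water = rng.uniform(0.2, 1, shape).astype(complex)
        fat = rng.uniform(0, 0.5, shape).astype(complex)
        return w.ParameterMaps(
            water=water,
            fat=fat,
            r2star_per_s=rng.uniform(0, 150, shape),
            fieldmap_hz=rng.uniform(-300, 300, shape) + delta_fieldmap,
            mask=np.ones(shape, bool),
        )

    def test_identical_maps_zero_error(self):
        maps = self._maps()
        assert all(v == 0.0 for v in w.mae_map(maps, maps).values())

    def test_fieldmap_channel_isolation(self):
        ref = self._maps()
        pred = self._maps(delta_fieldmap=10.0)
        err = w.mae_map(pred, ref)
        assert err["fieldmap_hz"] == pytest.approx(10.0)
        assert err["water"] == 0 and err["fat"] == 0 and err["r2star_per_s"] == 0
        assert err["pdff"] == 0

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(5)
        a, b = self._maps(), self._maps(delta_fieldmap=rng.uniform(1, 5))
        b.water += rng.uniform(0, 0.1, b.shape)
        err = w.mae_map(b, a)
        acc = 0.0
        for r in range(6):
            for c in range(6):
                acc += abs(abs(b.water[r, c]) - abs(a.water[r, c]))
        assert err["water"] == pytest.approx(acc / 36, abs=1e-10)

    def test_empty_mask_rejected(self):
        maps = self._maps()
        with pytest.raises(w.ValidationError):
            w.mae_map(maps, maps, mask=np.zeros(maps.shape, bool))


class TestRoiSerialization:
    def test_rle_json_round_trip(self):
        rng = np.random.default_rng(11)
        mask = rng.random((12, 10)) > 0.6
        mask[0, 0] = True  # ensure non-empty
        roi = w.Roi("RHL", 3, mask)
        restored = w.Roi.from_json_dict(roi.to_json_dict())
        assert restored.label == "RHL" and restored.slice_index == 3
        assert np.array_equal(restored.pixel_mask, mask)

    def test_missing_field_raises_schema_error(self):
        with pytest.raises(w.ValidationError):
            w.Roi.from_json_dict({"label": "x", "slice_index": 0})


def test_agreement_report_invariants():
    rng = np.random.default_rng(13)
    ref = [(m, s) for m, s in zip(rng.uniform(0.03, 0.3, 10), rng.uniform(0.005, 0.02, 10))]
    test = [(m + rng.normal(0, 0.01), s + rng.normal(0, 0.002)) for m, s in ref]
    rep = agreement_report(ref, test, "graphcut", "network")
    assert rep.loa_low <= rep.bias <= rep.loa_high
    assert 0.0 <= rep.r_squared <= 1.0
    d = rep.to_dict()
    assert set(d["roi_means"]) == {"graphcut", "network"}
    assert len(d["anova"]["posthoc"]) == 1
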