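"""Label normalisation, loss, schedule, and training behaviour."""

import numpy as np
import pytest

import wfsep as w
from wfsep.training import (
    TrainingDivergedError,
    labels_to_maps,
    normalize_echoes,
    pdff_from_outputs,
)


@pytest.fixture()
def tiny_setup(acq3, spectrum):
    cfg = w.NetworkConfig(
        input_size=16, n_echoes=3, encoder_filters=(2, 3, 4, 5), bottleneck_filters=10
    )
    tcfg = w.TrainConfig(epochs=2, batch_size=4, initial_lr=1e-3, seed=0)
    phantom = w.PhantomConfig(image_size=16, n_regions=2, noise_snr=None)
    samples = w.build_dataset(12, acq3, spectrum, tcfg, phantom_template=phantom, seed=5)
    return cfg, tcfg, samples


class TestMakeLabels:
    def test_normalisation_constants(self, small_maps):
        maps = small_maps
        maps.r2star_per_s[maps.mask] = 200.0
        maps.fieldmap_hz[maps.mask] = -400.0
        labels = w.make_labels(maps, w.TrainConfig())
        assert np.allclose(labels.values[2][labels.mask], 1.0)
        assert np.allclose(labels.values[3][labels.mask], -1.0)

    def test_out_of_range_r2star_clipped(self, small_maps):
        maps = small_maps
        maps.r2star_per_s[maps.mask] = 250.0
        labels = w.make_labels(maps, w.TrainConfig())
        assert labels.values[2].max() == 1.0

    def test_round_trip_inverts_for_in_range_values(self, small_maps):
        cfg = w.TrainConfig()
        labels = w.make_labels(small_maps, cfg)
        restored = labels_to_maps(labels, cfg)
        m = labels.mask
        assert np.allclose(np.abs(restored.water[m]), np.abs(small_maps.water[m]), atol=1e-12)
        assert np.allclose(np.abs(restored.fat[m]), np.abs(small_maps.fat[m]), atol=1e-12)
        assert np.allclose(restored.r2star_per_s[m], small_maps.r2star_per_s[m], atol=1e-12)
        assert np.allclose(restored.fieldmap_hz[m], small_maps.fieldmap_hz[m], atol=1e-12)

    def test_absolute_fieldmap_option(self, small_maps):
        cfg = w.TrainConfig(signed_fieldmap=False)
        labels = w.make_labels(small_maps, cfg)
        assert np.all(labels.values[3] >= 0)


class TestMaeLoss:
    def test_zero_when_equal(self):
        y = np.random.default_rng(0).uniform(0, 1, (4, 8, 8))
        mask = np.ones((8, 8), bool)
        assert w.mae_loss(y, y, mask) == 0.0

    def test_constant_offset_full_mask(self):
        y = np.random.default_rng(1).uniform(0, 1, (4, 8, 8))
        assert w.mae_loss(y + 0.1, y, np.ones((8, 8), bool)) == pytest.approx(0.1, abs=1e-9)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, (4, 5, 5))
        y = rng.uniform(0, 1, (4, 5, 5))
        mask = rng.random((5, 5)) > 0.3
        acc = sum(
            abs(p[c, i, j] - y[c, i, j])
            for c in range(4)
            for i in range(5)
            for j in range(5)
            if mask[i, j]
        )
        assert w.mae_loss(p, y, mask) == pytest.approx(acc / (mask.sum() * 4), abs=1e-10)

    def test_empty_mask_rejected(self):
        with pytest.raises(w.ValidationError):
            w.mae_loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.zeros((4, 4), bool))


class TestSchedule:
    def test_cosine_closed_form(self):
        cfg = w.TrainConfig(epochs=120, initial_lr=5e-4)
        for e in range(0, 120, 13):
            expected = 5e-4 * 0.5 * (1 + np.cos(np.pi * e / 120))
            assert w.cosine_lr(e, cfg) == pytest.approx(expected, abs=1e-9)
        assert w.cosine_lr(0, cfg) == pytest.approx(5e-4)


class TestDatasetAndSplit:
    def test_phantom_level_split_has_no_leakage(self, tiny_setup):
        _, tcfg, samples = tiny_setup
        train_s, val_s = w.split_dataset(samples, 0.25, seed=3)
        assert {s.phantom_id for s in train_s}.isdisjoint({s.phantom_id for s in val_s})
        assert len(train_s) + len(val_s) == len(samples)

    def test_dataset_masks_nonempty_and_inputs_scaled(self, tiny_setup):
        _, _, samples = tiny_setup
        for s in samples:
            assert s.mask.any()
            assert np.abs(s.input).max() < 20.0


class TestTrain:
    def test_seeded_determinism_first_epoch(self, tiny_setup):
        cfg, tcfg, samples = tiny_setup
        losses = []
        for _ in range(2):
            net = w.build_mdwf_net(cfg, seed=1)
            hist = w.train(net, samples, tcfg)
            losses.append(hist.train_mae[0])
        assert losses[0] == losses[1]

    def test_history_and_lr_schedule_recorded(self, tiny_setup):
        cfg, tcfg, samples = tiny_setup
        net = w.build_unet(
            w.NetworkConfig(
                input_size=16, n_echoes=3, encoder_filters=(2, 3, 4, 5),
                bottleneck_filters=10, variant="unet",
            ),
            seed=2,
        )
        hist = w.train(net, samples, tcfg)
        assert len(hist.train_mae) == tcfg.epochs == len(hist.val_mae)
        assert hist.learning_rates[0] == pytest.approx(tcfg.initial_lr)

    def test_divergence_detected(self, tiny_setup):
        cfg, tcfg, samples = tiny_setup
        net = w.build_mdwf_net(cfg, seed=1)
        for p in net.parameters():
            p.data = p.data * np.inf
        with pytest.raises(TrainingDivergedError):
            w.train(net, samples, tcfg)


class TestPredictMaps:
    def test_zero_input_produces_finite_outputs(self, tiny_setup, acq3):
        cfg, tcfg, _ = tiny_setup
        net = w.build_mdwf_net(cfg, seed=0)
        echoes = w.EchoSeries(
            data=np.zeros((3, 16, 16), complex),
            echo_times_s=tuple(acq3.echo_times_s),
            acquisition=acq3,
        )
        maps, pdff = w.predict_maps(net, echoes, tcfg)
        assert np.isfinite(pdff.values).all()
        assert np.isfinite(maps.r2star_per_s).all()

    def test_echo_count_mismatch_rejected(self, tiny_setup, spectrum):
        cfg, tcfg, _ = tiny_setup
        net = w.build_mdwf_net(cfg, seed=0)
        acq6 = w.AcquisitionParams.from_ms(1.29, 2.1, 6)
        maps = w.generate_phantom(w.PhantomConfig(image_size=16, seed=1, noise_snr=None))
        echoes = w.simulate_signal(maps, acq6, spectrum)
        with pytest.raises(w.ValidationError):
            w.predict_maps(net, echoes, tcfg)

    def test_denormalisation_scales(self, tiny_setup, acq3, spectrum):
        cfg, tcfg, _ = tiny_setup
        net = w.build_mdwf_net(cfg, seed=0)
        maps = w.generate_phantom(w.PhantomConfig(image_size=16, seed=2, noise_snr=None))
        echoes = w.simulate_signal(maps, acq3, spectrum)
        pred, _ = w.predict_maps(net, echoes, tcfg)
        assert pred.r2star_per_s.max() <= tcfg.r2star_norm_per_s + 1e-6
        assert np.abs(pred.fieldmap_hz).max() <= tcfg.fieldmap_norm_hz * 5  # linear head


def test_single_slice_overfit_drives_loss_down(acq3, spectrum):
    """Either variant can overfit one slice to a small residual quickly."""
    import wfsep.tensor as T
    from wfsep.tensor import Tensor

    phantom = w.PhantomConfig(image_size=32, n_regions=2, noise_snr=None)
    tcfg = w.TrainConfig(epochs=1, batch_size=1, initial_lr=3e-3, seed=0)
    sample = w.build_dataset(1, acq3, spectrum, tcfg, phantom_template=phantom, seed=9)[0]
    x = sample.input[None]
    y = sample.labels[None]
    m = sample.mask[None]
    cfg = w.NetworkConfig(
        input_size=32, n_echoes=3, encoder_filters=(4, 8, 16, 32), bottleneck_filters=64
    )
    for build in (w.build_mdwf_net, w.build_unet):
        net = build(cfg, seed=0)
        opt = T.Adam(net.parameters(), lr=3e-3)
        first = None
        for _ in range(300):
            wf, r2, fm = net.forward_tensors(Tensor(x))
            loss = T.masked_mae(T.concat([wf, r2, fm], axis=1), y, m)
            if first is None:
                first = loss.item()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert loss.item() < 0.05
        assert loss.item() < 0.2 * first


def test_pdff_from_outputs_uses_ratio_convention():
    wf = np.zeros((1, 2, 4, 4), np.float32)
    wf[0, 0] = 3.0
    wf[0, 1] = 1.0
    out = w.NetworkOutputs(
        waterfat=wf,
        r2star_norm=np.zeros((1, 1, 4, 4), np.float32),
        fieldmap_norm=np.zeros((1, 1, 4, 4), np.float32),
    )
    pdff = pdff_from_outputs(out, np.ones((4, 4), bool))
    assert np.allclose(pdff.values, 0.25)
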