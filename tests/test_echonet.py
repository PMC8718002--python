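"""Echo synthesis, spectrograms, chunking, splits, the CNN and evaluation."""

import numpy as np
import pytest
from scipy.stats import beta

from floralecho import sonar, synthdata
from floralecho.config import SimConfig, SpectrogramConfig
from floralecho.echonet import (
    EchoCNN,
    EchoRenderer,
    Hyper,
    build_chunks,
    chunk_interval,
    chunk_random,
    clopper_pearson,
    evaluate,
    highpass_call,
    make_echo,
    spectrogram,
    spectrogram_shape,
    split_by_flower,
    train,
)
from floralecho.echonet.train import _dataset

from conftest import chunks_for


@pytest.fixture(scope="module")
def call():
    return synthdata.synthesize_call()


@pytest.fixture(scope="module")
def filtered_call(call):
    return highpass_call(call, 500_000.0)


class TestMakeEcho:
    def test_unit_impulse_returns_filtered_call(self, filtered_call):
        ir = np.zeros(16)
        ir[0] = 1.0
        echo = make_echo(ir, filtered_call, length=1024)
        assert np.allclose(echo[: filtered_call.size], filtered_call)
        assert np.allclose(echo[filtered_call.size :], 0.0)

    def test_linearity(self, filtered_call):
        ir = np.zeros(64)
        ir[0] = 0.5
        half = make_echo(ir, filtered_call, length=1024)
        ir[0] = 1.0
        full = make_echo(ir, filtered_call, length=1024)
        assert np.allclose(half, 0.5 * full)

    def test_two_path_ir_imprints_notch_comb(self, filtered_call):
        # FFT product oracle: echo spectrum = call spectrum x IR transfer
        ir = np.zeros(256)
        ir[0], ir[50] = 1.0, 0.9
        n = 2048
        echo = make_echo(ir, filtered_call, length=n)
        echo_spec = np.abs(np.fft.rfft(echo, n))
        ref = np.abs(np.fft.rfft(filtered_call, n) * np.fft.rfft(ir, n))
        assert np.allclose(echo_spec, ref, atol=1e-8 * ref.max())

    def test_empty_ir_rejected(self, filtered_call):
        with pytest.raises(ValueError):
            make_echo(np.array([]), filtered_call)


class TestSpectrogram:
    def test_frame_count_formula(self):
        cfg = SpectrogramConfig()
        for n in (256, 1024, 1280, 2048):
            spec = spectrogram(np.random.default_rng(0).normal(size=n), cfg)
            assert spec.shape == (129, (n - 256) // 26 + 1)
            assert spec.shape == spectrogram_shape(n, cfg)

    def test_tone_concentrates_in_one_row(self):
        fs = 500_000.0
        t = np.arange(2048) / fs
        spec = spectrogram(np.sin(2 * np.pi * 68_000.0 * t))
        row = np.argmax(spec.sum(axis=1))
        expected = int(round(68_000.0 / (fs / 256)))
        assert abs(row - expected) <= 1

    def test_silence_maps_to_zeros(self):
        assert np.all(spectrogram(np.zeros(1024)) == 0.0)

    def test_values_normalized_to_unit_interval(self):
        spec = spectrogram(np.random.default_rng(1).normal(size=1024))
        assert spec.min() == 0.0 and spec.max() == 1.0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100))


def _dummy_scans(n_az=101, n_el=101, ir_len=64):
    scans = {}
    for plane, n in (("azimuth", n_az), ("elevation", n_el)):
        irs = np.zeros((n, ir_len))
        irs[:, 0] = 1.0
        scans[plane] = sonar.ImpulseResponseScan(
            "f1", plane, np.linspace(-90, 90, n), irs, 500_000.0
        )
    return scans


class TestChunking:
    def test_random_chunk_counts(self):
        scans = _dummy_scans()
        rng = np.random.default_rng(0)
        assert len(chunk_random(scans, "sp", 10, rng)) == 20  # floor(202/10)
        assert len(chunk_random(scans, "sp", 1, rng)) == 202
        assert len(chunk_random(scans, "sp", 3, rng)) == 67

    def test_random_chunks_partition_without_replacement(self):
        scans = _dummy_scans()
        chunks = chunk_random(scans, "sp", 7, np.random.default_rng(1))
        seen = [ref for c in chunks for ref in c.ir_refs]
        assert len(seen) == len(set(seen))
        assert all(c.flower_id == "f1" and c.k == 7 for c in chunks)

    def test_random_chunks_deterministic_per_seed(self):
        scans = _dummy_scans()
        a = chunk_random(scans, "sp", 5, np.random.default_rng(3))
        b = chunk_random(scans, "sp", 5, np.random.default_rng(3))
        assert a == b

    def test_interval_chunks_are_arithmetic_progressions(self):
        scans = _dummy_scans()
        chunks = chunk_interval(scans, "sp", 5, np.random.default_rng(2))
        assert len(chunks) == 202 // 5
        for c in chunks:
            planes = {p for p, _ in c.ir_refs}
            assert len(planes) == 1  # stays within one plane's angular order
            idx = [i for _, i in c.ir_refs]
            diffs = set(np.diff(idx))
            assert len(diffs) == 1
            n = diffs.pop()
            assert 2 <= n <= 8
            assert max(idx) < 101  # no wrap-around

    def test_interval_k10_always_satisfiable(self):
        # worst case n=8 spans 73 of the 101 angles
        scans = _dummy_scans()
        chunks = chunk_interval(scans, "sp", 10, np.random.default_rng(4))
        assert len(chunks) == 20

    def test_interval_impossible_on_tiny_scan(self):
        scans = _dummy_scans(n_az=5, n_el=5)
        with pytest.raises(ValueError):
            chunk_interval(scans, "sp", 10, np.random.default_rng(0))

    def test_interval_chunks_less_angularly_diverse_than_random(self):
        # mirrors the sampling-scheme rationale: echoes in angular succession
        # are mutually redundant compared to a random draw over the sphere
        scans = _dummy_scans()
        angles = {p: scans[p].angles for p in scans}

        def mean_pairwise(chunks):
            vals = []
            for c in chunks:
                a = np.array([angles[p][i] for p, i in c.ir_refs])
                diff = np.abs(a[:, None] - a[None, :])
                vals.append(diff[np.triu_indices(len(a), 1)].mean())
            return np.mean(vals)

        rng = np.random.default_rng(5)
        rand = mean_pairwise(chunk_random(scans, "sp", 5, rng))
        intv = mean_pairwise(chunk_interval(scans, "sp", 5, rng))
        assert intv < rand


class TestSplit:
    def _ids(self, n=14, n_species=4):
        return {
            f"S{j}": [f"S{j}_{i:02d}" for i in range(n)] for j in range(n_species)
        }

    def test_default_split_leaves_two_unused(self):
        split = split_by_flower(self._ids(), seed=0)
        for sp in self._ids():
            used = (
                set(split.train[sp]) | set(split.val[sp]) | set(split.test[sp])
            )
            assert len(split.train[sp]) == 8
            assert len(split.val[sp]) == 2
            assert len(split.test[sp]) == 2
            assert len(used) == 12  # 2 of 14 unused

    @pytest.mark.parametrize("seed", [0, 1, 7, 1234])
    def test_disjoint_and_all_species_present(self, seed):
        split = split_by_flower(self._ids(), seed=seed)
        split.assert_disjoint()
        for part in ("train", "val", "test"):
            assert set(getattr(split, part)) == set(self._ids())

    def test_leftover_to_train_option(self):
        split = split_by_flower(self._ids(), seed=0, use_leftover_in_train=True)
        assert all(len(v) == 10 for v in split.train.values())

    def test_too_few_flowers_rejected(self):
        with pytest.raises(ValueError, match="split needs"):
            split_by_flower({"S0": ["a", "b", "c"]}, counts=(8, 2, 2), seed=0)


class TestModel:
    def test_output_is_probability_vector(self):
        m = EchoCNN((32, 20), 3, n_classes=12, seed=0)
        x = np.random.default_rng(0).random((4, 3, 32, 20))
        probs = m.predict_proba(x)
        assert probs.shape == (4, 12)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_branch_parameter_count_independent_of_k(self):
        m1 = EchoCNN((32, 20), 1, seed=0)
        m10 = EchoCNN((32, 20), 10, seed=0)
        assert m1.n_branch_params == m10.n_branch_params

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            EchoCNN((32, 20), 4)

    def test_wrong_input_shape_rejected(self):
        m = EchoCNN((32, 20), 3)
        with pytest.raises(ValueError):
            m.predict_proba(np.zeros((2, 3, 31, 20)))

    def test_untrained_model_is_at_chance_on_balanced_data(self):
        m = EchoCNN((32, 20), 1, n_classes=12, seed=1)
        rng = np.random.default_rng(2)
        x = rng.random((240, 1, 32, 20))
        y = np.repeat(np.arange(12), 20)
        acc = np.mean(m.predict_proba(x).argmax(axis=1) == y)
        assert abs(acc - 1 / 12) < 0.08

    def test_gradients_match_finite_differences(self):
        m = EchoCNN((17, 17), 1, n_classes=3, branch_channels=4,
                    trunk_channels=8, dense_sizes=(16, 8), seed=3,
                    dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.random((4, 1, 17, 17)) - 0.5
        y = np.array([0, 1, 2, 0])
        _, grads, _ = m.loss_and_grads(x, y)
        for name, g in grads.items():
            p = m.params[name]
            idx = tuple(np.unravel_index(np.argmax(np.abs(g)), p.shape))
            eps = 1e-6
            p[idx] += eps
            l1, _, _ = m.loss_and_grads(x, y)
            p[idx] -= 2 * eps
            l2, _, _ = m.loss_and_grads(x, y)
            p[idx] += eps
            num = (l1 - l2) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-10)

    def test_save_load_round_trip(self, tmp_path):
        m = EchoCNN((32, 20), 3, n_classes=5, seed=0)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = EchoCNN.load(path)
        x = np.random.default_rng(3).random((2, 3, 32, 20))
        assert np.allclose(m.predict_proba(x), m2.predict_proba(x))


class TestTraining:
    def test_loss_decreases_and_seed_reproducible(self, toy_dataset):
        ds = toy_dataset
        train_chunks = chunks_for(ds, "train", 1, "random")[:60]
        val_chunks = chunks_for(ds, "val", 1, "random")[:15]
        hyper = Hyper(epochs=5, learning_rate=1e-3, patience=10, seed=0)
        reports = []
        for _ in range(2):
            model = EchoCNN(ds["renderer"].shape, 1, n_classes=3, seed=0)
            reports.append(
                train(model, train_chunks, val_chunks, ds["renderer"],
                      ds["class_order"], hyper)
            )
        a, b = reports
        assert a.train_loss == b.train_loss  # same seed, same trajectory
        assert a.train_loss[-1] < a.train_loss[0]

    def test_early_stopping_restores_best_weights(self, toy_dataset):
        ds = toy_dataset
        train_chunks = chunks_for(ds, "train", 1, "random")[:40]
        val_chunks = chunks_for(ds, "val", 1, "random")[:10]
        model = EchoCNN(ds["renderer"].shape, 1, n_classes=3, seed=0)
        hyper = Hyper(epochs=40, learning_rate=3e-3, patience=2, seed=0)
        report = train(model, train_chunks, val_chunks, ds["renderer"],
                       ds["class_order"], hyper)
        if report.early_stopped:
            assert report.epochs_run < 40
            best = int(np.argmin(report.val_loss))
            assert report.epochs_run - 1 - best >= 2


class TestEvaluation:
    def test_clopper_pearson_matches_beta_quantiles(self):
        lo, hi = clopper_pearson(73, 100)
        assert lo == pytest.approx(beta.ppf(0.025, 73, 28), abs=1e-12)
        assert hi == pytest.approx(beta.ppf(0.975, 74, 27), abs=1e-12)
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_ci_width_halves_with_quadruple_n(self):
        lo1, hi1 = clopper_pearson(73, 100)
        lo4, hi4 = clopper_pearson(292, 400)
        assert (hi4 - lo4) / (hi1 - lo1) == pytest.approx(0.5, abs=0.1)

    def test_perfect_classifier_gives_identity_confusion(self, toy_dataset):
        ds = toy_dataset
        chunks = chunks_for(ds, "test", 3, "random")
        x, y = _dataset(chunks, ds["renderer"], ds["class_order"])

        class Oracle:
            def predict_proba(self, xb, batch_size=64):
                labels = [
                    y[next(j for j in range(len(x)) if np.array_equal(x[j], row))]
                    for row in xb
                ]
                return np.eye(len(ds["class_order"]))[labels]

        report = evaluate(Oracle(), chunks, ds["renderer"], ds["class_order"],
                          {s: "bat" for s in ds["class_order"]})
        assert report.test_accuracy == 1.0
        assert np.all(report.confusion == np.diag(np.bincount(y, minlength=3)))
        assert report.per_syndrome["bat"]["accuracy"] == 1.0
        assert report.confusion.sum(axis=1).tolist() == np.bincount(y).tolist()


class TestSyndromeOrdering:
    """Lower within-species morphological variance makes species easier to
    classify early in training; with syndrome-specific variability this makes
    bat-pollinated species the easier classes (a statistical property)."""

    def _run(self, seed):
        from conftest import make_separable_species

        cfg = SimConfig(seed=seed, n_angles=15)
        truth = synthdata.GroundTruthAcoustics()
        templates = make_separable_species(
            scales=(0.5, 1.0, 2.0, 4.0),
            cv=(0.03, 0.15, 0.03, 0.15),
            syndromes=("bat", "other", "bat", "other"),
        )
        flowers = synthdata.sample_flowers(templates, 6, seed + 1)
        scans = {
            f.flower_id: synthdata.simulate_flower_scans(f, truth, cfg)
            for f in flowers
        }
        sbf = {f.flower_id: f.species_id for f in flowers}
        by_sp: dict = {}
        for f in flowers:
            by_sp.setdefault(f.species_id, []).append(f.flower_id)
        split = split_by_flower(by_sp, counts=(4, 1, 1), seed=seed)
        rend = EchoRenderer(scans, synthdata.synthesize_call(),
                            cfg.sample_rate, echo_len=1536)
        chunks = {
            p: build_chunks(scans, sbf, split.ids(p), 1, "random", seed + 10 + i)
            for i, p in enumerate(("train", "val", "test"))
        }
        co = sorted(by_sp)
        model = EchoCNN(rend.shape, 1, n_classes=4, seed=seed)
        rep = train(model, chunks["train"], chunks["val"], rend, co,
                    Hyper(epochs=8, learning_rate=1e-3, patience=10, seed=seed))
        return evaluate(model, chunks["test"], rend, co,
                        {t.species_id: t.syndrome for t in templates}, report=rep)

    def test_bat_species_easier_early_in_training(self):
        bat, other = [], []
        for seed in (1, 3):
            rep = self._run(seed)
            bat.append(rep.per_syndrome["bat"]["accuracy"])
            other.append(rep.per_syndrome["other"]["accuracy"])
        assert np.mean(bat) > np.mean(other)
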