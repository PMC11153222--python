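"""Architecture table, construction, and the training protocol."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from ictus.io import Recording, SeizureAnnotation
from ictus.model import (
    TrainConfig,
    build_model,
    count_convolutions,
    default_architecture,
    extract_training_segments,
    load_model,
    loso_folds,
    predict_epoch,
    save_model,
    shape_trace,
    train,
)


def test_default_architecture_census():
    spec = default_architecture()
    assert spec.n_levels == 29
    assert spec.count("conv") == 3
    assert spec.count("inception") == 9
    assert spec.count("maxpool") == 5
    assert spec.count("avgpool") == 1
    assert spec.count("dropout") == 1
    dropout = next(l for l in spec.layers if l.kind == "dropout")
    assert dropout.rate == 0.4 and dropout.level == 28
    fc = next(l for l in spec.layers if l.kind == "fc")
    assert fc.channels == 2
    assert spec.layers[-1].kind == "softmax"
    level1 = next(l for l in spec.layers if l.level == 1)
    assert level1.kind == "conv" and level1.kernel == (5, 3)
    assert level1.stride == (1, 1) and level1.channels == 64


def test_count_convolutions():
    spec = default_architecture()
    assert count_convolutions(spec) == (3, 54)
    no_inception = type(spec)(
        layers=tuple(l for l in spec.layers if l.kind != "inception"),
        input_shape=spec.input_shape,
    )
    assert count_convolutions(no_inception) == (3, 0)


def test_shape_trace_endpoints():
    trace = shape_trace(default_architecture())
    by_level = {l.level: (i, o) for l, i, o in trace if l.level is not None}
    assert by_level[1] == ((120, 344, 1), (116, 342, 64))
    assert by_level[27] == ((7, 7, 1024), (1, 1, 1024))
    assert by_level[29] == ((1, 1, 1024), (1, 1, 2))
    # ceil-mode pooling is forced at level 4: (112 - 3)/2 + 1 = 55.5 -> 56
    assert by_level[4] == ((112, 112, 64), (56, 56, 64))


def test_shape_trace_rejects_inconsistent_spec():
    spec = default_architecture()
    bad = type(spec)(layers=spec.layers, input_shape=(4, 4, 1))
    with pytest.raises(ValueError, match="level"):
        shape_trace(bad)


def test_inception_branch_sums_match_output_widths():
    spec = default_architecture()
    widths = [l.inception for l in spec.layers if l.kind == "inception"]
    assert [i.out_channels for i in widths] == [256, 480, 512, 512, 512, 528, 832, 832, 1024]
    for i in widths:
        assert i.b1 + i.b2[1] + i.b3[1] + i.b4 == i.out_channels


def test_build_forward_softmax_and_determinism():
    spec = default_architecture(width=1 / 8)
    a = build_model(spec, seed=3)
    b = build_model(spec, seed=3)
    c = build_model(spec, seed=4)
    x = np.random.default_rng(0).normal(size=(4, 120, 344)).astype(np.float32)
    pa, pb, pc = a.predict_proba(x), b.predict_proba(x), c.predict_proba(x)
    assert pa.shape == (4, 2)
    assert np.allclose(pa.sum(axis=1), 1.0, atol=1e-6)
    assert np.array_equal(pa, pb)  # same seed, bitwise identical
    assert not np.array_equal(pa, pc)  # different seed


def test_full_width_forward():
    model = build_model(default_architecture(), seed=0)
    x = np.random.default_rng(1).normal(size=(120, 344)).astype(np.float32)
    probs = model.predict_proba(x)
    assert probs.shape == (2,)
    assert probs.sum() == pytest.approx(1.0, abs=1e-6)


def test_predict_shape_mismatch():
    model = build_model(default_architecture(width=1 / 32), seed=0)
    with pytest.raises(ValueError, match="shape"):
        model.predict_proba(np.zeros((100, 344), dtype=np.float32))


def _rec_of_duration(duration_s: float) -> Recording:
    n = int(duration_s * 256)
    return Recording(np.zeros((1, n)), fs=256.0, channel_labels=("c0",))


def test_extract_training_segments():
    rec = _rec_of_duration(3600)
    assert extract_training_segments(rec, SeizureAnnotation(((700.0, 750.0),))) == [(100.0, 1000.0)]
    # clipped at the recording start
    assert extract_training_segments(rec, SeizureAnnotation(((300.0, 350.0),))) == [(0.0, 600.0)]
    # two onsets 100 s apart merge into one span (interval-union oracle)
    two = extract_training_segments(rec, SeizureAnnotation(((700.0, 750.0), (800.0, 850.0))))
    assert two == [(100.0, 1100.0)]


def test_loso_folds_partition():
    data = {f"s{i}": i for i in range(16)}
    folds = loso_folds(data)
    assert len(folds) == 16
    tests = [t for _, t in folds]
    assert sorted(tests) == sorted(data)
    for train_subjects, test_subject in folds:
        assert test_subject not in train_subjects
        assert len(train_subjects) == 15
    with pytest.raises(ValueError):
        loso_folds({"only": 1})


def _separable_epochs(n: int, offset_db: float, seed: int):
    """Two classes differing by a planted band-power offset in rows 40-60."""
    rng = np.random.default_rng(seed)
    x = rng.normal(-100.0, 1.0, size=(n, 120, 344)).astype(np.float32)
    y = np.arange(n) % 2
    x[y == 1, 40:60, :] += offset_db
    return x, y


def test_training_protocol_separable_toy():
    """A linearly separable planted offset is learned to 100% train accuracy
    within 30 epochs; the 20% stratified hold-out split is honored and
    validation accuracy is recorded every 50 iterations."""
    x, y = _separable_epochs(100, offset_db=20.0, seed=0)
    model = build_model(default_architecture(width=1 / 32), seed=1)
    cfg = TrainConfig(epochs=30, batch_size=4, seed=2, val_frequency=50,
                      early_stop_train_acc=100.0)
    train(model, x, y, cfg)
    h = model.history
    assert h["n_train"] == 80 and h["n_val"] == 20  # 80/20 split
    assert 50 in h["val_iteration"]  # periodic validation
    assert h["val_acc"][-1] == 100.0
    # training stopped once an epoch reached 100% accuracy, within 30 epochs
    n_epochs_run = len(h["train_acc"]) // 20
    assert n_epochs_run <= 30
    assert np.mean(h["train_acc"][-20:]) == 100.0
    # a held-out floor-only epoch is classified seizure-free
    floor_only = np.random.default_rng(9).normal(-100.0, 1.0, size=(120, 344)).astype(np.float32)
    label, p_active = predict_epoch(model, floor_only)
    assert label == "seizure-free" and p_active < 0.5
    planted = floor_only.copy()
    planted[40:60, :] += 20.0
    label, p_active = predict_epoch(model, planted)
    assert label == "seizure-active" and p_active > 0.5


def test_training_determinism():
    x, y = _separable_epochs(24, offset_db=10.0, seed=3)
    cfg = TrainConfig(epochs=2, batch_size=8, seed=7)
    runs = []
    for _ in range(2):
        model = build_model(default_architecture(width=1 / 32), seed=5)
        train(model, x, y, cfg)
        runs.append(model.history["loss"])
    assert runs[0] == runs[1]  # bitwise-identical loss history


def test_training_rejects_single_class():
    x = np.zeros((10, 120, 344), dtype=np.float32)
    y = np.zeros(10, dtype=np.int64)
    model = build_model(default_architecture(width=1 / 32), seed=0)
    with pytest.raises(ValueError, match="both classes"):
        train(model, x, y, TrainConfig(epochs=1))


def test_accuracy_nondecreasing_in_snr():
    """Planted-offset recovery: mean test accuracy rises with SNR (5 seeds)."""
    offsets = [0.0, 2.0, 6.0]
    means = []
    for offset in offsets:
        accs = []
        for seed in range(5):
            x_tr, y_tr = _separable_epochs(36, offset, seed=100 + seed)
            x_te, y_te = _separable_epochs(18, offset, seed=200 + seed)
            model = build_model(default_architecture(width=1 / 32), seed=seed)
            train(model, x_tr, y_tr, TrainConfig(epochs=2, batch_size=12, seed=seed))
            pred = model.predict_proba(x_te).argmax(axis=1)
            accs.append(float(np.mean(pred == y_te)))
        means.append(np.mean(accs))
    rho, _ = spearmanr(offsets, means)
    assert rho > 0


def test_checkpoint_round_trip(tmp_path):
    x, y = _separable_epochs(24, offset_db=15.0, seed=4)
    model = build_model(default_architecture(width=1 / 32), seed=2)
    train(model, x, y, TrainConfig(epochs=1, batch_size=8, seed=3))
    path = save_model(model, tmp_path / "m.npz")
    back = load_model(path)
    assert back.mean_offset == model.mean_offset
    probe = np.random.default_rng(0).normal(-100, 5, size=(3, 120, 344)).astype(np.float32)
    assert np.array_equal(back.predict_proba(probe), model.predict_proba(probe))
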