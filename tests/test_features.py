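"""Sliding windows and STFT spectrogram features."""

from __future__ import annotations

import numpy as np
import pytest

from ictus.features import (
    SEIZURE_ACTIVE,
    SEIZURE_FREE,
    SpectrogramEpoch,
    StftParams,
    WindowConfig,
    epoch_from_segment,
    frame_power,
    label_window,
    load_epochs,
    recording_to_epochs,
    rhythm_band,
    save_epochs,
    sliding_windows,
    stack_channels,
    stft_channel,
)
from ictus.io import Recording, SeizureAnnotation

FS = 256.0


def _rec(n_samples: int, n_ch: int = 6, seed: int = 0) -> Recording:
    rng = np.random.default_rng(seed)
    return Recording(
        rng.normal(size=(n_ch, n_samples)),
        fs=FS,
        channel_labels=tuple(f"c{i}" for i in range(n_ch)),
    )


def test_window_geometry_defaults():
    cfg = WindowConfig()
    assert cfg.window_samples == 345  # 1.35 s at 256 Hz
    assert cfg.hop_samples == 345 - 256  # 1-s overlap


def test_sliding_window_counts():
    cfg = WindowConfig()
    segs = sliding_windows(_rec(2560), cfg)  # 10-s recording
    # brute-force enumeration of valid offsets
    expected = len([o for o in range(0, 2560 - 345 + 1, 89)])
    assert expected == 25
    assert len(segs) == expected
    assert all(s.samples.shape == (6, 345) for s in segs)
    assert segs[1].start_s == pytest.approx(89 / FS)
    assert sliding_windows(_rec(256), cfg) == []  # 1-s recording: zero windows


def test_stft_params_defaults():
    p = StftParams()
    assert np.allclose(p.window, [0.08, 0.08])  # 2-sample symmetric Hamming
    assert p.fs / p.nfft == 2.0  # 2 Hz bin spacing
    assert len(p.band_bin_indices) == 20  # [20, 60) half-open at 2 Hz
    assert p.band_bin_freqs[0] == 20.0 and p.band_bin_freqs[-1] == 58.0
    with pytest.raises(ValueError, match="zero"):
        StftParams(band=(59.0, 59.5))


def test_frame_count_identity_brute_force():
    p = StftParams()
    for n in range(2, 501):
        brute = len([u for u in range(0, n) if u + p.win_len <= n])  # hop = 1
        assert p.n_frames(n) == brute
    assert p.n_frames(345) == 344


def test_stft_channel_shape_and_floor():
    p = StftParams()
    m = stft_channel(np.zeros(345), p)
    assert m.shape == (20, 344)
    assert np.all(m == p.floor_db)  # silent window hits the configured floor


def test_sinusoid_peaks_at_its_bin_against_dft_oracle():
    p = StftParams()
    t = np.arange(345) / FS
    x = np.sin(2 * np.pi * 40.0 * t)
    m = stft_channel(x, p)
    assert p.band_bin_freqs[int(m.mean(axis=1).argmax())] == 40.0
    # independent brute-force windowed DFT of a few frames
    w = p.window
    norm = p.nfft * np.sum(w**2)
    for u in (0, 100, 343):
        for k in p.band_bin_indices[:5]:
            acc = sum(
                x[u + t_] * w[t_] * np.exp(-2j * np.pi * k * t_ / p.nfft)
                for t_ in range(p.win_len)
            )
            expected_db = 10 * np.log10(max(abs(acc) ** 2 / norm, 10 ** (p.floor_db / 10)))
            row = np.where(p.band_bin_indices == k)[0][0]
            assert m[row, u] == pytest.approx(expected_db, abs=1e-8)


def test_parseval_power_identity():
    """Two-sided bin power sums to the windowed signal's mean power (white noise)."""
    p = StftParams()
    rng = np.random.default_rng(42)
    ratios = []
    for _ in range(100):
        x = rng.normal(size=345)
        pw = frame_power(x, p, two_sided=True)
        per_frame = pw.sum(axis=1)  # mean power of each windowed frame / sum(w^2)
        frames = np.lib.stride_tricks.sliding_window_view(x, p.win_len)[:: p.hop] * p.window
        direct = (frames**2).sum(axis=1) / np.sum(p.window**2)
        assert np.allclose(per_frame * np.sum(p.window**2), direct * np.sum(p.window**2), rtol=1e-9)
        ratios.append(pw.sum() * np.sum(p.window**2) / (frames**2).sum())
    assert abs(np.mean(ratios) - 1.0) < 0.1


def test_shift_covariance():
    p = StftParams()
    rng = np.random.default_rng(7)
    x = rng.normal(size=500)
    k = 5
    a = stft_channel(x[:345], p)
    b = stft_channel(x[k : k + 345], p)
    # delaying the input by k*hop shifts the columns by k
    assert np.allclose(a[:, k:], b[:, : 344 - k], atol=1e-9)


def test_log_power_scaling_monotonicity():
    p = StftParams()
    rng = np.random.default_rng(8)
    x = rng.normal(size=345)
    a = stft_channel(x, p)
    b = stft_channel(10.0 * x, p)
    above = a > p.floor_db + 20
    assert np.allclose(b[above] - a[above], 20.0, atol=1e-9)


def test_stack_channels():
    rng = np.random.default_rng(1)
    mats = [rng.normal(size=(20, 344)) for _ in range(6)]
    ep = stack_channels(mats, start_s=0.0)
    assert ep.values.shape == (120, 344)
    assert ep.values.size == 41_280
    assert np.array_equal(ep.values[40:60], mats[2])  # block 2 is channel 2
    with pytest.raises(ValueError, match="shapes differ"):
        stack_channels(mats[:5] + [rng.normal(size=(19, 344))], start_s=0.0)
    with pytest.raises(ValueError, match="6"):
        stack_channels(mats[:5], start_s=0.0)


@pytest.mark.parametrize(
    "name,edges",
    [
        ("delta", (1.0, 4.0)),
        ("theta", (4.0, 8.0)),
        ("alpha", (8.0, 12.0)),
        ("beta", (12.0, 30.0)),
        ("gamma", (30.0, 60.0)),
        ("selected", (20.0, 60.0)),
    ],
)
def test_rhythm_bands(name, edges):
    assert rhythm_band(name) == edges


def test_rhythm_band_unknown():
    with pytest.raises(ValueError):
        rhythm_band("mu")


def test_band_height_scales_epoch():
    p = StftParams(band=rhythm_band("gamma"))
    assert len(p.band_bin_indices) == 15  # [30, 60) at 2 Hz
    m = stft_channel(np.random.default_rng(0).normal(size=345), p)
    assert m.shape == (15, 344)


def test_label_window_overlap_rule():
    ann = SeizureAnnotation(((361.0, 413.0),))
    # overlap 0.35 s < half of 1.35 s -> seizure-free
    assert label_window((360.0, 361.35), ann) == SEIZURE_FREE
    # fully inside
    assert label_window((370.0, 371.35), ann) == SEIZURE_ACTIVE
    # empty annotation
    assert label_window((370.0, 371.35), SeizureAnnotation()) == SEIZURE_FREE
    # exactly half the window overlaps -> active (>= rule)
    assert label_window((360.325, 361.675), ann) == SEIZURE_ACTIVE


def test_recording_to_epochs_matches_per_window(small_recording):
    rec, ann = small_recording
    wcfg, p = WindowConfig(), StftParams()
    epochs, labels, starts = recording_to_epochs(rec, wcfg, p, ann=ann)
    assert epochs.shape[1:] == (120, 344)
    assert len(epochs) == (rec.n_samples - 345) // 89 + 1
    segs = sliding_windows(rec, wcfg)
    for k in (0, 37, len(segs) - 1):
        direct = epoch_from_segment(segs[k], p).values
        assert np.allclose(epochs[k], direct, atol=1e-4)
        assert starts[k] == pytest.approx(segs[k].start_s)
    # labels agree with the overlap rule
    for k in range(0, len(segs), 17):
        expect = label_window((starts[k], starts[k] + wcfg.window_s), ann)
        assert labels[k] == (1 if expect == SEIZURE_ACTIVE else 0)


def test_epochs_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    epochs = rng.normal(size=(4, 120, 344)).astype(np.float32)
    labels = np.array([0, 1, 0, 1], dtype=np.int8)
    starts = np.arange(4) * 0.348
    p = save_epochs(tmp_path / "e.h5", epochs, labels, starts, StftParams())
    e2, l2, s2 = load_epochs(p)
    assert np.array_equal(e2, epochs) and np.array_equal(l2, labels)
    assert np.allclose(s2, starts)
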