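"""Generator: fingerprints, disease effect, events, balancing, round trips."""

import numpy as np
import pytest
from scipy.signal import periodogram

from eegleak.classifiers import band_power_features
from eegleak.preprocessing import segment_timeseries
from eegleak.synthetic_cohort import (
    BAND_RANGES,
    CohortConfig,
    EventPackingError,
    InvalidConfigError,
    balance_nonevent,
    generate_cohort,
    inject_events,
    read_edf,
    read_npz,
    write_edf,
    write_npz,
)


def theta_power(signal, fs):
    """Periodogram estimate of theta-band power, averaged over channels."""
    freqs, psd = periodogram(signal, fs=fs, axis=1)
    lo, hi = BAND_RANGES["theta"]
    mask = (freqs >= lo) & (freqs < hi)
    df = freqs[1] - freqs[0]
    return (psd[:, mask].sum(axis=1) * df).mean()


@pytest.mark.parametrize(
    "bad",
    [
        dict(duration=-1.0),
        dict(fs=0.0),
        dict(n_subjects_per_group=0),
        dict(noise_level=-0.1),
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(InvalidConfigError):
        generate_cohort(CohortConfig(**bad))


def test_reproducibility_bit_identical():
    config = CohortConfig(n_subjects_per_group=2, duration=10.0, seed=9)
    a = generate_cohort(config)
    b = generate_cohort(config)
    for ra, rb in zip(a, b):
        assert ra.subject_id == rb.subject_id
        assert np.array_equal(ra.signal, rb.signal)


def test_groups_balanced_and_profiles_fixed(small_cohort):
    _, recs = small_cohort
    groups = [r.group_label for r in recs]
    assert sum(groups) == len(groups) // 2
    ids = [r.subject_id for r in recs]
    assert len(set(ids)) == len(ids)
    for r in recs:
        assert r.profile.subject_id == r.subject_id


def test_zero_variation_subjects_identical_up_to_phase():
    """With no fingerprint, no disease and no noise, subjects differ only by
    oscillator phase: their per-channel power spectra coincide."""
    config = CohortConfig(
        n_subjects_per_group=2,
        duration=20.0,
        fingerprint_strength=0.0,
        disease_effect=0.0,
        noise_level=0.0,
        seed=3,
    )
    recs = generate_cohort(config)
    _, ref = periodogram(recs[0].signal, fs=config.fs, axis=1)
    for rec in recs[1:]:
        _, psd = periodogram(rec.signal, fs=config.fs, axis=1)
        assert np.allclose(psd, ref, atol=1e-8 * ref.max())


def test_fingerprint_within_subject_similarity(small_cohort):
    """Within-subject band-power correlations exceed between-subject ones."""
    config, recs = small_cohort
    feats, owners = [], []
    for rec in recs:
        segs = segment_timeseries(rec, 2.0)
        f = band_power_features(segs.X, config.fs)
        feats.append(f)
        owners.append(np.full(len(f), rec.subject_id, dtype=object))
    feats = np.concatenate(feats)
    owners = np.concatenate(owners)
    corr = np.corrcoef(feats)
    same = np.equal.outer(owners, owners)
    off_diag = ~np.eye(len(owners), dtype=bool)
    within = corr[same & off_diag].mean()
    between = corr[~same].mean()
    assert within > between


def test_no_fingerprint_subject_id_at_chance():
    """Nearest-centroid subject identification: above chance only when
    fingerprints exist."""

    def identification_accuracy(strength, seed):
        config = CohortConfig(
            n_subjects_per_group=5,
            duration=60.0,
            fingerprint_strength=strength,
            seed=seed,
        )
        recs = generate_cohort(config)
        train_f, test_f, test_owner, centroids = [], [], [], {}
        for rec in recs:
            segs = segment_timeseries(rec, 2.0)
            f = band_power_features(segs.X, config.fs)
            half = len(f) // 2
            centroids[rec.subject_id] = f[:half].mean(axis=0)
            test_f.append(f[half:])
            test_owner.append(np.full(len(f) - half, rec.subject_id, dtype=object))
        test_f = np.concatenate(test_f)
        test_owner = np.concatenate(test_owner)
        names = list(centroids)
        cents = np.stack([centroids[n] for n in names])
        d = ((test_f[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        pred = np.array(names, dtype=object)[d.argmin(axis=1)]
        return float(np.mean(pred == test_owner)), len(names)

    acc_fp, n_subj = identification_accuracy(1.0, seed=5)
    acc_null, _ = identification_accuracy(0.0, seed=5)
    chance = 1.0 / n_subj
    # binomial 3-sigma band around chance for the null generator
    n_test = 150  # 10 subjects x 15 held-out segments
    band = 3 * np.sqrt(chance * (1 - chance) / n_test)
    assert acc_fp > chance + band
    assert abs(acc_null - chance) < max(3 * band, 0.12)


def test_disease_effect_recovered_by_periodogram():
    """Group difference in theta band power estimates disease_effect."""
    d = 0.3
    config = CohortConfig(
        n_subjects_per_group=50,
        n_channels=4,
        duration=30.0,
        fingerprint_strength=0.3,
        disease_effect=d,
        noise_level=1.0,
        seed=11,
    )
    recs = generate_cohort(config)
    g0 = [theta_power(r.signal, config.fs) for r in recs if r.group_label == 0]
    g1 = [theta_power(r.signal, config.fs) for r in recs if r.group_label == 1]
    diff = np.mean(g1) - np.mean(g0)
    se = np.sqrt(np.var(g0) / len(g0) + np.var(g1) / len(g1))
    assert abs(diff - d) < 3 * se


class TestInjectEvents:
    def _recording(self, duration=60.0, seed=0):
        config = CohortConfig(
            n_subjects_per_group=1, n_channels=3, duration=duration, seed=seed
        )
        return generate_cohort(config)[0]

    def test_zero_events_is_identity(self):
        rec = self._recording()
        out = inject_events(rec, 0, 5.0, 2.0, seed=1)
        assert out is rec

    def test_three_disjoint_events_bookkeeping(self):
        rec = self._recording()
        out = inject_events(rec, 3, 5.0, 2.0, seed=1)
        assert len(out.event_intervals) == 3
        total = sum(e - s for s, e in out.event_intervals)
        assert total == pytest.approx(15.0)
        intervals = sorted(out.event_intervals)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2  # disjoint

    def test_strong_events_raise_within_event_variance(self):
        rec = self._recording()
        out = inject_events(rec, 3, 5.0, 20.0, seed=2)
        fs = out.fs
        in_mask = np.zeros(out.n_samples, dtype=bool)
        for s, e in out.event_intervals:
            in_mask[int(s * fs) : int(e * fs)] = True
        within = out.signal[:, in_mask].var()
        outside = out.signal[:, ~in_mask].var()
        assert within > outside

    def test_infeasible_packing_raises(self):
        rec = self._recording(duration=10.0)
        with pytest.raises(EventPackingError, match="s"):
            inject_events(rec, 3, 5.0, 1.0, seed=1)


class TestBalanceNonevent:
    def _rec_with_events(self, intervals, duration=60.0):
        config = CohortConfig(
            n_subjects_per_group=1, n_channels=2, duration=duration, seed=4
        )
        rec = generate_cohort(config)[0]
        rec.event_intervals = list(intervals)
        return rec

    def test_pool_from_recording_start(self):
        rec = self._rec_with_events([(30.0, 40.0)])
        pools = balance_nonevent(rec)
        assert pools.total_samples("event") == pools.total_samples("nonevent")
        assert pools.nonevent[0][0] == 0.0  # starts at t=0

    def test_zero_events_warns_empty(self):
        rec = self._rec_with_events([])
        with pytest.warns(UserWarning, match="no events"):
            pools = balance_nonevent(rec)
        assert pools.event == [] and pools.nonevent == []

    def test_event_at_origin_skipped(self):
        rec = self._rec_with_events([(0.0, 10.0)])
        pools = balance_nonevent(rec)
        # non-event pool must start after the event span and not intersect it
        for start, end, _ in pools.nonevent:
            assert start >= 10.0
            for es, ee in rec.event_intervals:
                assert end <= es or start >= ee

    def test_more_event_than_nonevent_time_errors(self):
        rec = self._rec_with_events([(0.0, 40.0)], duration=60.0)
        with pytest.raises(ValueError, match="non-event"):
            balance_nonevent(rec)


class TestInterchange:
    def test_npz_round_trip(self, tmp_path, small_cohort):
        _, recs = small_cohort
        subset = recs[:2]
        write_npz(subset, tmp_path)
        back = read_npz(tmp_path)
        assert len(back) == 2
        by_id = {r.subject_id: r for r in back}
        for rec in subset:
            got = by_id[rec.subject_id]
            assert np.allclose(got.signal, rec.signal)
            assert got.group_label == rec.group_label
            assert got.fs == rec.fs

    def test_edf_round_trip_via_mne(self, tmp_path, small_cohort):
        _, recs = small_cohort
        rec = recs[0]
        path = tmp_path / "subject.edf"
        write_edf(rec, path)
        back = read_edf(path, subject_id=rec.subject_id)
        # MNE reports EEG in volts; our units are microvolt-scale
        got = back.signal * 1e6
        n = got.shape[1]
        span = rec.signal.max() - rec.signal.min()
        # 16-bit quantization: errors bounded by ~1 LSB of the phys range
        assert got.shape[0] == rec.n_channels
        assert np.max(np.abs(got - rec.signal[:, :n])) < 2 * span / 65535
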