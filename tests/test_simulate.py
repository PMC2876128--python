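import numpy as np
import pytest

from crpcna import (
    ArrayDesignConfig,
    SequenceSimConfig,
    add_noise,
    simulate_array_design,
    simulate_sequences,
)


def test_sequence_benchmark_cardinalities():
    cfg = SequenceSimConfig(seed=0, n_sequences=10)
    by_snr = simulate_sequences(cfg)
    assert set(by_snr) == {2.0, 1.3, 1.0}
    for snr, datasets in by_snr.items():
        assert len(datasets) == 10
        for ds in datasets:
            (series,) = ds.observations
            assert series.T == 300
            assert len(ds.truth) == 4
            assert sorted(r.end_index - r.start_index for r in ds.truth) == [5, 10, 20, 40]
            # 75 aberrant points in total
            labels = ds.truth_labels()[series.chromosome]
            assert int(np.sum(labels != 2)) == 75


def test_sequence_regions_are_separated():
    cfg = SequenceSimConfig(seed=3, n_sequences=20)
    for ds in simulate_sequences(cfg)[2.0]:
        regions = sorted((r.start_index, r.end_index) for r in ds.truth)
        for (_, e1), (s2, _) in zip(regions, regions[1:]):
            assert s2 - e1 >= cfg.min_gap


def test_sequence_noise_level_follows_snr():
    # SNR = 0.4 / sigma, so snr 2 -> sigma 0.2
    cfg = SequenceSimConfig(seed=1, n_sequences=50)
    datasets = simulate_sequences(cfg)[2.0]
    resid = []
    for ds in datasets:
        (series,) = ds.observations
        labels = ds.truth_labels()[series.chromosome]
        clean = np.where(labels != 2, 0.4, 0.0)
        resid.append(series.value - clean)
    sd = float(np.std(np.concatenate(resid)))
    assert sd == pytest.approx(0.2, rel=0.02)


def test_sequence_determinism():
    a = simulate_sequences(SequenceSimConfig(seed=5, n_sequences=3))
    b = simulate_sequences(SequenceSimConfig(seed=5, n_sequences=3))
    for snr in a:
        for da, db in zip(a[snr], b[snr]):
            np.testing.assert_array_equal(da.observations[0].value, db.observations[0].value)
            assert da.truth == db.truth
    c = simulate_sequences(SequenceSimConfig(seed=6, n_sequences=3))
    assert not np.array_equal(
        a[2.0][0].observations[0].value, c[2.0][0].observations[0].value
    )


def test_array_design_cardinalities():
    samples = simulate_array_design(ArrayDesignConfig(seed=0, markers_per_chromosome=150))
    assert len(samples) == 18  # 2 kinds x 3 SNR levels x 3 references
    for ds in samples:
        assert len(ds.observations) == 22
        assert len(ds.truth) == 22
        lens = [r.end_index - r.start_index for r in ds.truth]
        assert all(4 <= L <= 100 for L in lens)
        assert {r.chromosome for r in ds.truth} == {f"chr{i}" for i in range(1, 23)}


def test_array_design_kinds_and_means():
    samples = simulate_array_design(ArrayDesignConfig(seed=2, markers_per_chromosome=200))
    dels = [s for s in samples if s.provenance["copy_number"] == 1]
    amps = [s for s in samples if s.provenance["copy_number"] == 3]
    assert len(dels) == len(amps) == 9
    ds = next(s for s in dels if s.provenance["snr"] == 5.0)
    labels = ds.truth_labels()
    ab, norm = [], []
    for series in ds.observations:
        mask = labels[series.chromosome] != 2
        ab.append(series.value[mask])
        norm.append(series.value[~mask])
    ab, norm = np.concatenate(ab), np.concatenate(norm)
    sigma = ds.provenance["sigma"]
    assert np.mean(ab) - np.mean(norm) == pytest.approx(
        -0.45, abs=3 * sigma / np.sqrt(len(ab))
    )
    assert np.mean(norm) == pytest.approx(0.0, abs=3 * sigma / np.sqrt(len(norm)))


def test_array_design_shares_geometry_across_samples():
    samples = simulate_array_design(ArrayDesignConfig(seed=4, markers_per_chromosome=120))
    first = [(r.chromosome, r.start_index, r.end_index) for r in samples[0].truth]
    for ds in samples[1:]:
        assert [(r.chromosome, r.start_index, r.end_index) for r in ds.truth] == first
        for s0, s in zip(samples[0].observations, ds.observations):
            np.testing.assert_array_equal(s0.pos_bp, s.pos_bp)


def test_add_noise_statistics_and_determinism():
    clean = np.zeros(100_000)
    noisy = add_noise(clean, snr=2.0, seed=9, signal=0.4)
    assert float(np.std(noisy - clean)) == pytest.approx(0.2, rel=0.02)
    np.testing.assert_array_equal(noisy, add_noise(clean, snr=2.0, seed=9, signal=0.4))
    # infinite SNR leaves the data untouched
    np.testing.assert_allclose(add_noise(clean, snr=np.inf, seed=1), clean)
    with pytest.raises(ValueError):
        add_noise(clean, snr=0.0, seed=1)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SequenceSimConfig(length=50)  # regions + gaps do not fit
    with pytest.raises(ValueError):
        ArrayDesignConfig(markers_per_chromosome=50)  # longest region cannot fit
    with pytest.raises(ValueError):
        SequenceSimConfig(snr_levels=(2.0, 0.0))
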