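import numpy as np
import pandas as pd
import pytest

from crpcna.features import (
    IntensityTable,
    log2_ratio_series,
    normalize_to_common_mean,
    select_best_fit_references,
)


def make_table(values: dict[str, np.ndarray], n=None, chrom="chr1") -> IntensityTable:
    n = n if n is not None else len(next(iter(values.values())))
    markers = pd.DataFrame(
        {
            "marker": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(n) * 10_000 + 1,
        }
    )
    return IntensityTable(markers=markers, values=pd.DataFrame(values))


def test_normalization_scales_each_sample_to_the_target():
    rng = np.random.default_rng(0)
    table = make_table(
        {
            "test": rng.uniform(500, 4000, size=200),
            "refA": rng.uniform(100, 900, size=200),
        }
    )
    out = normalize_to_common_mean(table, target_mean=1000.0)
    means = out.values.mean(axis=0)
    assert means["test"] == pytest.approx(1000.0, rel=1e-6)
    assert means["refA"] == pytest.approx(1000.0, rel=1e-6)
    # already at target -> identity
    again = normalize_to_common_mean(out, target_mean=1000.0)
    np.testing.assert_allclose(again.values.to_numpy(), out.values.to_numpy())
    # linear: a sample at mean 2000 is exactly halved
    doubled = make_table({"s": np.full(10, 2000.0)})
    np.testing.assert_allclose(
        normalize_to_common_mean(doubled, 1000.0).values["s"], 1000.0
    )


def test_best_fit_prefers_flat_log_ratio_tracks():
    rng = np.random.default_rng(1)
    test = rng.uniform(800, 1200, size=300)
    table = make_table(
        {
            "test": test,
            "identical": test.copy(),
            "scaled": 2.0 * test,  # constant log-ratio: also score 0
            "noisy": test * rng.lognormal(0, 0.3, size=300),
        }
    )
    sel = select_best_fit_references(table, "test", m_refs=2)
    assert set(sel.reference_names) == {"identical", "scaled"}
    assert sel.fit_score["identical"] == pytest.approx(0.0, abs=1e-12)
    # the scale-blindness of the criterion is why samples are mean-normalized first
    assert sel.fit_score["scaled"] == pytest.approx(0.0, abs=1e-12)
    sel_all = select_best_fit_references(table, "test", m_refs=3)
    assert len(sel_all.reference_names) == 3
    with pytest.raises(ValueError):
        select_best_fit_references(table, "test", m_refs=4)


def test_log2_ratio_values():
    base = np.full(50, 1000.0)
    test = base.copy()
    test[10] = 2000.0     # one doubled marker -> log2 ratio exactly 1
    test[20] = 1500.0     # 1.5x -> log2(1.5)
    table = make_table({"test": test, "r1": base.copy(), "r2": base.copy()})
    sel = select_best_fit_references(table, "test", m_refs=2)
    (series,) = log2_ratio_series(table, "test", sel)
    assert series.value[0] == pytest.approx(0.0, abs=1e-12)
    assert series.value[10] == pytest.approx(1.0, abs=1e-12)
    assert series.value[20] == pytest.approx(np.log2(1.5), abs=1e-12)


def test_duplicate_reference_does_not_change_the_ratio():
    rng = np.random.default_rng(3)
    base = rng.uniform(900, 1100, size=80)
    test = base * rng.lognormal(0, 0.05, size=80)
    t1 = make_table({"test": test, "r1": base.copy(), "r2": base.copy()})
    (a,) = log2_ratio_series(t1, "test", select_best_fit_references(t1, "test", 1))
    (b,) = log2_ratio_series(t1, "test", select_best_fit_references(t1, "test", 2))
    np.testing.assert_allclose(a.value, b.value, atol=1e-12)


def test_copy_number_ordering_survives_extraction():
    # intensities built as copy * base / 2 with multiplicative noise
    rng = np.random.default_rng(4)
    n = 900
    base = rng.uniform(800, 1200, size=n)
    copies = np.full(n, 2)
    copies[100:200] = 1
    copies[500:650] = 3
    test = copies * base / 2 * rng.lognormal(0, 0.1, size=n)
    table = make_table({"test": test, "r1": base.copy(), "r2": base * 1.1})
    table = normalize_to_common_mean(table)
    sel = select_best_fit_references(table, "test", m_refs=2)
    (series,) = log2_ratio_series(table, "test", sel)
    means = {c: float(np.mean(series.value[copies == c])) for c in (1, 2, 3)}
    assert means[1] < means[2] < means[3]


def test_zero_reference_mean_names_the_marker():
    vals = {"test": np.full(5, 100.0), "r1": np.array([1.0, 1.0, 0.0, 1.0, 1.0])}
    table = IntensityTable(
        markers=pd.DataFrame(
            {"marker": list("abcde"), "chrom": "chr1", "pos": range(1, 6)}
        ),
        values=pd.DataFrame(vals),
    )
    from crpcna.features import BestFitSelection

    sel = BestFitSelection(test_sample="test", reference_names=("r1",), fit_score={"r1": 0.0})
    with pytest.raises(ValueError, match="'c'"):
        log2_ratio_series(table, "test", sel)


def test_table_validation():
    with pytest.raises(ValueError, match="non-negative"):
        make_table({"s": np.array([1.0, -2.0, 3.0])})
    with pytest.raises(ValueError, match="duplicate"):
        IntensityTable(
            markers=pd.DataFrame(
                {"marker": ["a", "a"], "chrom": "chr1", "pos": [1, 2]}
            ),
            values=pd.DataFrame({"s": [1.0, 2.0]}),
        )
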