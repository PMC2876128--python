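"""Log2-ratio feature extraction from normalized SNP intensity tables.

Given a marker x sample table of normalized total intensities, the
test sample's log2-ratio track is computed against the average of its
*m* best-fitting reference samples — references are assumed to carry
two copies almost everywhere, so a good reference makes the log-ratio
track flat.  The fit score of a candidate reference is the standard
deviation over markers of log2(test / reference): it is blind to a
constant scale offset (a reference at exactly twice the test scores 0
too), which is why samples are first normalized to a common autosomal
mean intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ProbeSeries

__all__ = [
    "IntensityTable",
    "BestFitSelection",
    "normalize_to_common_mean",
    "select_best_fit_references",
    "log2_ratio_series",
]

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class IntensityTable:
    """Normalized intensities: marker annotation plus a marker x sample matrix."""

    markers: pd.DataFrame        # columns: marker, chrom, pos
    values: pd.DataFrame         # index aligned with markers, one column per sample

    def __post_init__(self) -> None:
        need = {"marker", "chrom", "pos"}
        if not need.issubset(self.markers.columns):
            raise ValueError(f"marker table needs columns {sorted(need)}")
        if len(self.markers) != len(self.values):
            raise ValueError("marker table and value matrix differ in length")
        if self.markers["marker"].duplicated().any():
            dup = self.markers.loc[self.markers["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        key = self.markers[["chrom", "pos"]]
        if not key.equals(key.sort_values(["chrom", "pos"]).reset_index(drop=True)):
            raise ValueError("markers must be sorted by (chrom, pos)")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def autosomal_mask(self) -> np.ndarray:
        return self.markers["chrom"].astype(str).isin(_AUTOSOMES).to_numpy()


@dataclass(frozen=True)
class BestFitSelection:
    test_sample: str
    reference_names: tuple[str, ...]
    fit_score: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.reference_names) < 1:
            raise ValueError("at least one reference must be selected")
        if len(set(self.reference_names)) != len(self.reference_names):
            raise ValueError("selected references must be distinct")
        if self.test_sample in self.reference_names:
            raise ValueError("test sample cannot be its own reference")


def normalize_to_common_mean(table: IntensityTable, target_mean: float = 1000.0) -> IntensityTable:
    """Linearly rescale each sample so its autosomal mean intensity equals the target."""
    if target_mean <= 0:
        raise ValueError("target mean must be positive")
    mask = table.autosomal_mask()
    if not mask.any():
        raise ValueError("no autosomal markers to normalize against")
    means = table.values.loc[mask].mean(axis=0)
    zero = means[means <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has non-positive autosomal mean")
    scaled = table.values * (target_mean / means)
    return IntensityTable(markers=table.markers, values=scaled)


def select_best_fit_references(
    table: IntensityTable, test_sample: str, m_refs: int = 3
) -> BestFitSelection:
    """Pick the m references whose log-ratio track against the test is flattest.

    Score = sd over markers of log2(test / reference); smaller is
    better (flatter track under the two-copy assumption).  Returns the
    selected names in ascending score order.
    """
    if test_sample not in table.samples:
        raise ValueError(f"unknown test sample {test_sample!r}")
    candidates = [s for s in table.samples if s != test_sample]
    if m_refs < 1 or m_refs > len(candidates):
        raise ValueError(
            f"m_refs={m_refs} but only {len(candidates)} candidate references exist"
        )
    test = table.values[test_sample].to_numpy(dtype=float)
    scores: dict[str, float] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name in candidates:
            ref = table.values[name].to_numpy(dtype=float)
            lr = np.log2(test / ref)
            lr = lr[np.isfinite(lr)]
            scores[name] = float(np.std(lr)) if lr.size else float("inf")
    chosen = tuple(sorted(candidates, key=lambda s: (scores[s], s))[:m_refs])
    return BestFitSelection(test_sample=test_sample, reference_names=chosen, fit_score=scores)


def log2_ratio_series(
    table: IntensityTable, test_sample: str, selection: BestFitSelection
) -> list[ProbeSeries]:
    """Per-chromosome log2(test / mean-of-selected-references) tracks."""
    if selection.test_sample != test_sample:
        raise ValueError("selection was made for a different test sample")
    test = table.values[test_sample].to_numpy(dtype=float)
    refs = table.values[list(selection.reference_names)].to_numpy(dtype=float)
    ref_mean = refs.mean(axis=1)
    bad = np.flatnonzero(ref_mean <= 0)
    if bad.size:
        marker = table.markers["marker"].iloc[int(bad[0])]
        raise ValueError(f"reference mean is non-positive at marker {marker!r}")
    values = np.log2(test / ref_mean)
    out = []
    df = table.markers.assign(log2ratio=values)
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out.append(
            ProbeSeries(
                chromosome=str(chrom),
                ids=sub["marker"].to_numpy(dtype=object),
                pos_bp=sub["pos"].to_numpy(dtype=np.int64),
                value=sub["log2ratio"].to_numpy(dtype=float),
            )
        )
    return out
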