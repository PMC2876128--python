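"""Seven-metric evaluation of copy-number calls against ground truth.

Detection is scored as a binary aberrant / normal problem at two
granularities:

* marker level: per-SNP confusion counts give snp-recall
  ``sr = TP / (TP + FN)`` and snp-precision ``sp = TP / (TP + FP)``;
* region level: a truth region counts *detected* if at least one of
  its markers is predicted aberrant, giving region-recall ``rr``; a
  predicted region counts *true* if at least one of its markers falls
  inside some truth region, giving region-precision ``rp``.

The hybrid metrics multiply the two levels, ``hr = sr * rr`` and
``hp = sp * rp``, and the overall f-score is their harmonic mean.
Copy-number values are ignored for detection: any state other than the
normal one counts as aberrant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyCounts",
    "MetricsReport",
    "regions_from_labels",
    "contingency",
    "contingency_from_labels",
    "compute_metrics",
    "evaluate_labels",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Marker- and region-level confusion counts."""

    snp_tp: int
    snp_fp: int
    snp_fn: int
    snp_tn: int
    region_detected: int
    region_missed: int
    pred_region_true: int
    pred_region_false: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"count {name} must be non-negative, got {v}")

    @property
    def n_markers(self) -> int:
        return self.snp_tp + self.snp_fp + self.snp_fn + self.snp_tn

    @property
    def n_truth_regions(self) -> int:
        return self.region_detected + self.region_missed


@dataclass(frozen=True)
class MetricsReport:
    sr: float
    sp: float
    rr: float
    rp: float
    hr: float
    hp: float
    f: float
    counts: ContingencyCounts | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("sr", "sp", "rr", "rp", "hr", "hp", "f")}


def regions_from_labels(aberrant: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of aberrant markers as half-open index intervals."""
    aberrant = np.asarray(aberrant, dtype=bool)
    if aberrant.size == 0:
        return []
    padded = np.concatenate([[False], aberrant, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, ends)]


def _check_disjoint(regions: list[tuple[int, int]], what: str) -> None:
    prev_end = -1
    for a, b in sorted(regions):
        if b <= a:
            raise ValueError(f"{what} region ({a}, {b}) is empty or inverted")
        if a < prev_end:
            raise ValueError(f"{what} regions overlap at index {a}")
        prev_end = b


def contingency(
    truth_regions: list[tuple[int, int]],
    predicted_regions: list[tuple[int, int]],
    n_markers: int,
) -> ContingencyCounts:
    """Confusion counts from aberrant regions over a shared marker universe.

    Regions are half-open marker-index intervals; each call set must be
    internally non-overlapping.
    """
    _check_disjoint(truth_regions, "truth")
    _check_disjoint(predicted_regions, "predicted")
    truth = np.zeros(n_markers, dtype=bool)
    for a, b in truth_regions:
        if b > n_markers:
            raise ValueError(f"truth region ({a}, {b}) exceeds the marker universe")
        truth[a:b] = True
    pred = np.zeros(n_markers, dtype=bool)
    for a, b in predicted_regions:
        if b > n_markers:
            raise ValueError(f"predicted region ({a}, {b}) exceeds the marker universe")
        pred[a:b] = True

    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    tn = int(np.sum(~truth & ~pred))

    detected = sum(bool(pred[a:b].any()) for a, b in truth_regions)
    pred_true = sum(bool(truth[a:b].any()) for a, b in predicted_regions)
    return ContingencyCounts(
        snp_tp=tp,
        snp_fp=fp,
        snp_fn=fn,
        snp_tn=tn,
        region_detected=detected,
        region_missed=len(truth_regions) - detected,
        pred_region_true=pred_true,
        pred_region_false=len(predicted_regions) - pred_true,
    )


def contingency_from_labels(
    truth_states,
    predicted_states,
    normal_state: int = 2,
) -> ContingencyCounts:
    """Confusion counts from per-marker copy-number arrays.

    A marker is aberrant when its state differs from ``normal_state``;
    regions are the maximal aberrant runs of each array.
    """
    truth_states = np.asarray(truth_states)
    predicted_states = np.asarray(predicted_states)
    if truth_states.shape != predicted_states.shape:
        raise ValueError("truth and prediction must cover the same markers")
    truth_ab = truth_states != normal_state
    pred_ab = predicted_states != normal_state
    return contingency(
        regions_from_labels(truth_ab),
        regions_from_labels(pred_ab),
        len(truth_states),
    )


def _ratio(num: int, den: int, errors: int) -> float:
    # Degenerate empty denominators: a vacuously perfect call set (no
    # errors of the relevant kind) scores 1, anything else 0.
    if den > 0:
        return num / den
    return 1.0 if errors == 0 else 0.0


def compute_metrics(counts: ContingencyCounts) -> MetricsReport:
    """The seven detection metrics from a contingency table.

    ``hr = sr * rr``, ``hp = sp * rp``, ``f = 2 hp hr / (hp + hr)``.
    """
    sr = _ratio(counts.snp_tp, counts.snp_tp + counts.snp_fn, counts.snp_fp)
    sp = _ratio(counts.snp_tp, counts.snp_tp + counts.snp_fp, counts.snp_fn)
    rr = _ratio(
        counts.region_detected,
        counts.region_detected + counts.region_missed,
        counts.pred_region_false,
    )
    rp = _ratio(
        counts.pred_region_true,
        counts.pred_region_true + counts.pred_region_false,
        counts.region_missed,
    )
    hr = sr * rr
    hp = sp * rp
    f = 2.0 * hp * hr / (hp + hr) if hp + hr > 0 else 0.0
    return MetricsReport(sr=sr, sp=sp, rr=rr, rp=rp, hr=hr, hp=hp, f=f, counts=counts)


def evaluate_labels(truth_states, predicted_states, normal_state: int = 2) -> MetricsReport:
    """Convenience: contingency + metrics from per-marker state arrays."""
    return compute_metrics(
        contingency_from_labels(truth_states, predicted_states, normal_state)
    )
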