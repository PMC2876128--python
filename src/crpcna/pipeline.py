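"""End-to-end detection over a multi-chromosome sample."""

from __future__ import annotations

import numpy as np

from .inference import segments_from_path, viterbi_decode
from .model import CrpModel, DecodeResult, ProbeSeries

__all__ = ["detect_sample", "apply_probability_filter", "call_posterior"]


def apply_probability_filter(
    result: DecodeResult,
    series: ProbeSeries,
    model: CrpModel,
    min_probability: float,
) -> DecodeResult:
    """Reassign low-confidence aberrant segments to the normal state.

    An aberrant segment whose mean posterior (of its assigned state)
    falls below ``min_probability`` is relabelled normal; segments are
    then rebuilt from the filtered path.  Posteriors and path
    probability are left as computed — the filter is a reporting
    threshold, not a model change.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError("min_probability must lie in [0, 1]")
    if min_probability == 0.0:
        return result
    normal = model.states.normal
    path = result.path.copy()
    for seg in result.segments:
        if seg.state != normal and seg.mean_probability < min_probability:
            path[seg.start_index : seg.end_index] = normal
    segments = segments_from_path(path, series, result.posteriors, model)
    return DecodeResult(
        path=path,
        delta_final=result.delta_final,
        log_Z=result.log_Z,
        path_probability=result.path_probability,
        posteriors=result.posteriors,
        segments=tuple(segments),
    )


def detect_sample(
    series_list: list[ProbeSeries],
    model: CrpModel,
    min_probability: float = 0.0,
) -> dict[str, DecodeResult]:
    """Decode each chromosome independently (no cross-chromosome transitions)."""
    out: dict[str, DecodeResult] = {}
    for series in series_list:
        result = viterbi_decode(series, model)
        out[series.chromosome] = apply_probability_filter(
            result, series, model, min_probability
        )
    return out


def call_posterior(result: DecodeResult, model: CrpModel) -> np.ndarray:
    """Posterior probability of each marker's called state."""
    idx = {s: i for i, s in enumerate(model.states.labels)}
    cols = np.array([idx[s] for s in result.path])
    return result.posteriors[np.arange(len(cols)), cols]
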