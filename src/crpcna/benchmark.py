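"""Self-contained benchmark runs: simulate, detect, evaluate.

These drive the package's own validation: the genome-wide array design
(one aberrant region per autosome, deletion and amplification samples
at several SNR levels) and the 300-point sequence design.  Emission
parameters are fitted per sample from the simulator's known region
labels — the same information a user would have from known monosomy /
trisomy regions — with the package defaults as fallback for states the
sample does not contain.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .inference import fit_emission_params, viterbi_decode
from .metrics import MetricsReport, evaluate_labels
from .model import CrpModel, default_model
from .simulate import (
    ArrayDesignConfig,
    SequenceSimConfig,
    SimulatedDataset,
    simulate_array_design,
    simulate_sequences,
)

__all__ = [
    "evaluate_dataset",
    "run_array_benchmark",
    "run_sequence_benchmark",
]


def _fit_model_for(dataset: SimulatedDataset, base: CrpModel) -> CrpModel:
    labels = dataset.truth_labels(normal_state=base.states.normal)
    values = np.concatenate([s.value for s in dataset.observations])
    lab = np.concatenate([labels[s.chromosome] for s in dataset.observations])
    emission = fit_emission_params(values, lab, base.states, base.emission)
    return replace(base, emission=emission)


def evaluate_dataset(
    dataset: SimulatedDataset,
    model: CrpModel | None = None,
    fit_from_truth: bool = True,
    m: int = 4,
) -> MetricsReport:
    """Decode one simulated sample and score it against its truth."""
    base = model if model is not None else default_model(m=m)
    used = _fit_model_for(dataset, base) if fit_from_truth else base
    labels = dataset.truth_labels(normal_state=used.states.normal)
    truth, pred = [], []
    for series in dataset.observations:
        truth.append(labels[series.chromosome])
        pred.append(viterbi_decode(series, used).path)
    return evaluate_labels(
        np.concatenate(truth), np.concatenate(pred), used.states.normal
    )


def run_array_benchmark(
    seeds,
    markers_per_chromosome: int = 500,
    snr_levels: tuple[float, ...] = (5.0, 2.0, 1.25),
    m: int = 4,
) -> dict[float, list[float]]:
    """Per-SNR f-scores of the detector over replicate array designs.

    Each seed draws a fresh region geometry and noise; every one of the
    design's samples at the requested SNR levels is decoded with
    per-sample fitted emissions.  Returns {snr: [f per sample per seed]}.
    """
    out: dict[float, list[float]] = {snr: [] for snr in snr_levels}
    for seed in seeds:
        cfg = ArrayDesignConfig(
            seed=int(seed),
            markers_per_chromosome=markers_per_chromosome,
            snr_levels=tuple(snr_levels),
        )
        for dataset in simulate_array_design(cfg):
            report = evaluate_dataset(dataset, m=m)
            out[dataset.provenance["snr"]].append(report.f)
    return out


def run_sequence_benchmark(
    seed: int,
    n_sequences: int = 100,
    snr_levels: tuple[float, ...] = (2.0, 1.3, 1.0),
    m: int = 4,
) -> dict[float, list[float]]:
    """Per-SNR f-scores on the 300-point sequence design.

    Decoding uses a 3-state model with the design's known means
    (0 normal, 0.4 gain, -0.4 for the unused loss state) and the known
    noise sigma — the generating parameters, as the design specifies
    them, not values tuned to the data.
    """
    cfg = SequenceSimConfig(seed=seed, n_sequences=n_sequences, snr_levels=tuple(snr_levels))
    out: dict[float, list[float]] = {}
    for snr, datasets in simulate_sequences(cfg).items():
        sigma = cfg.aberrant_mean / snr
        model = default_model(
            m=m,
            states=(1, 2, 3),
            means={1: -cfg.aberrant_mean, 2: 0.0, 3: cfg.aberrant_mean},
            sds=sigma,
        )
        scores = []
        for dataset in datasets:
            scores.append(evaluate_dataset(dataset, model=model, fit_from_truth=False).f)
        out[snr] = scores
    return out
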