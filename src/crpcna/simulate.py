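"""Synthetic log2-ratio validation data with known aberration regions.

Two generators mirror the two standard benchmark designs for SNP-array
copy-number callers, both expressed directly at the log2-ratio level:

* :func:`simulate_sequences` — per noise level, 100 independent
  sequences of 300 points carrying four gain regions of 5, 10, 20 and
  40 markers with mean shift 0.4; Gaussian noise with sigma = 0.4/SNR
  on every point, SNR ladder {2, 1.3, 1}.
* :func:`simulate_array_design` — a genome-wide 500K-style design: one
  aberrant region per autosome (22 total), lengths uniform in
  [4, 100] markers, one-copy deletion and three-copy amplification
  samples for each of three reference samples at SNR levels
  {5, 2, 1.25}, 18 samples in all.  Deletions sit at the empirical
  monosomy mean -0.45 and amplifications at the trisomy mean 0.38;
  sigma = |aberrant mean| / SNR on every probe of the sample.

All randomness flows from one integer seed through per-sample child
seeds, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ProbeSeries

__all__ = [
    "SequenceSimConfig",
    "ArrayDesignConfig",
    "TruthRegion",
    "SimulatedDataset",
    "simulate_sequences",
    "simulate_array_design",
    "add_noise",
    "DELETION_MEAN",
    "AMPLIFICATION_MEAN",
]

# Empirical one-copy / three-copy log2-ratio means on SNP arrays.
DELETION_MEAN = -0.45
AMPLIFICATION_MEAN = 0.38


@dataclass(frozen=True)
class SequenceSimConfig:
    n_sequences: int = 100
    length: int = 300
    region_lengths: tuple[int, ...] = (5, 10, 20, 40)
    aberrant_mean: float = 0.4
    normal_mean: float = 0.0
    snr_levels: tuple[float, ...] = (2.0, 1.3, 1.0)
    min_gap: int = 5
    marker_spacing_bp: int = 10_000
    aberrant_copy: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be at least 1")
        if any(s <= 0 for s in self.snr_levels):
            raise ValueError("SNR levels must be positive")
        need = sum(self.region_lengths) + self.min_gap * (len(self.region_lengths) - 1)
        if need > self.length:
            raise ValueError(
                f"regions plus gaps need {need} markers but sequences have {self.length}"
            )


@dataclass(frozen=True)
class ArrayDesignConfig:
    n_autosomes: int = 22
    region_length_range: tuple[int, int] = (4, 100)
    markers_per_chromosome: int = 500
    snr_levels: tuple[float, ...] = (5.0, 2.0, 1.25)
    reference_sample_names: tuple[str, ...] = ("NA10851", "NA12812", "NA18605")
    deletion_copy: int = 1
    amplification_copy: int = 3
    deletion_mean: float = DELETION_MEAN
    amplification_mean: float = AMPLIFICATION_MEAN
    min_spacing_bp: int = 2_000
    max_spacing_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.region_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid region length range")
        if hi > self.markers_per_chromosome:
            raise ValueError(
                "longest region does not fit on a chromosome of "
                f"{self.markers_per_chromosome} markers"
            )
        if any(s <= 0 for s in self.snr_levels):
            raise ValueError("SNR levels must be positive")


@dataclass(frozen=True)
class TruthRegion:
    chromosome: str
    start_index: int
    end_index: int          # half-open marker indices
    start_bp: int
    end_bp: int             # half-open bp
    copy_number: int


@dataclass(frozen=True)
class SimulatedDataset:
    """Observations plus ground truth for one simulated sample."""

    name: str
    observations: tuple[ProbeSeries, ...]
    truth: tuple[TruthRegion, ...]
    provenance: dict = field(default_factory=dict)

    def series(self, chromosome: str) -> ProbeSeries:
        for s in self.observations:
            if s.chromosome == chromosome:
                return s
        raise KeyError(chromosome)

    def truth_labels(self, normal_state: int = 2) -> dict[str, np.ndarray]:
        """Per-chromosome per-marker true copy-number arrays."""
        out = {s.chromosome: np.full(s.T, normal_state) for s in self.observations}
        for r in self.truth:
            out[r.chromosome][r.start_index : r.end_index] = r.copy_number
        return out


def _child_seed(rng_or_seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(rng_or_seed), spawn_key=tuple(key)))


def add_noise(clean, snr: float, seed: int, signal: float = 0.4) -> np.ndarray:
    """Add N(0, sigma) noise with sigma = signal / snr to every value."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = np.asarray(clean, dtype=float)
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, abs(signal) / snr, size=clean.shape)


def _place_regions(
    rng: np.random.Generator, length: int, region_lengths: tuple[int, ...], min_gap: int
) -> list[tuple[int, int]]:
    """Place non-overlapping regions in random order with >= min_gap spacing."""
    order = rng.permutation(len(region_lengths))
    lens = [region_lengths[i] for i in order]
    n = len(lens)
    free = length - sum(lens) - min_gap * (n - 1)
    # split the leftover markers over n+1 gaps (ends may touch the regions)
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    extras = np.diff(np.concatenate([[0], cuts, [free]]))
    regions = []
    pos = int(extras[0])
    for i, L in enumerate(lens):
        regions.append((pos, pos + L))
        pos += L + (min_gap + int(extras[i + 1]) if i < n - 1 else 0)
    return regions


def simulate_sequences(config: SequenceSimConfig) -> dict[float, list[SimulatedDataset]]:
    """The sequence benchmark: per SNR level, n independent noisy sequences.

    Returns a dict mapping each SNR level to a list of single-sequence
    datasets.  Region geometry is redrawn per sequence; noise
    sigma = aberrant_mean / SNR applies to every point.
    """
    out: dict[float, list[SimulatedDataset]] = {}
    positions = np.arange(config.length, dtype=np.int64) * config.marker_spacing_bp + 1_000
    for snr_i, snr in enumerate(config.snr_levels):
        sigma = config.aberrant_mean / snr
        datasets = []
        for i in range(config.n_sequences):
            rng = _child_seed(config.seed, snr_i, i)
            regions = _place_regions(rng, config.length, config.region_lengths, config.min_gap)
            clean = np.full(config.length, config.normal_mean)
            for a, b in regions:
                clean[a:b] = config.aberrant_mean
            values = clean + rng.normal(0.0, sigma, size=config.length)
            chrom = f"seq{i:03d}"
            series = ProbeSeries(
                chromosome=chrom,
                ids=np.array([f"{chrom}_m{t:04d}" for t in range(config.length)], dtype=object),
                pos_bp=positions,
                value=values,
            )
            truth = tuple(
                TruthRegion(
                    chromosome=chrom,
                    start_index=a,
                    end_index=b,
                    start_bp=int(positions[a]),
                    end_bp=int(positions[b - 1]) + 1,
                    copy_number=config.aberrant_copy,
                )
                for a, b in sorted(regions)
            )
            datasets.append(
                SimulatedDataset(
                    name=f"snr{snr:g}_{chrom}",
                    observations=(series,),
                    truth=truth,
                    provenance={"snr": snr, "sigma": sigma, "seed": config.seed, "index": i},
                )
            )
        out[snr] = datasets
    return out


def simulate_array_design(config: ArrayDesignConfig) -> list[SimulatedDataset]:
    """The genome-wide benchmark: 2 x |SNR levels| x |references| samples.

    One shared marker map and one shared set of aberrant regions (one
    region per autosome, length uniform over the configured range) are
    drawn first, as on a fixed array design; each sample then gets its
    own noise realisation.  Deletion samples place the one-copy mean in
    every region, amplification samples the three-copy mean; all other
    markers sit at 0.  Noise sigma = |aberrant mean| / SNR on every
    probe of the sample.
    """
    design_rng = _child_seed(config.seed, 0)
    lo, hi = config.region_length_range
    n_mark = config.markers_per_chromosome

    chroms = [f"chr{i}" for i in range(1, config.n_autosomes + 1)]
    positions: dict[str, np.ndarray] = {}
    regions: dict[str, tuple[int, int]] = {}
    for chrom in chroms:
        gaps = design_rng.integers(config.min_spacing_bp, config.max_spacing_bp, size=n_mark)
        positions[chrom] = np.cumsum(gaps).astype(np.int64)
        L = int(design_rng.integers(lo, hi + 1))
        start = int(design_rng.integers(0, n_mark - L + 1))
        regions[chrom] = (start, start + L)

    samples: list[SimulatedDataset] = []
    sample_index = 0
    for ref in config.reference_sample_names:
        for snr in config.snr_levels:
            for kind, copy, mean in (
                ("del", config.deletion_copy, config.deletion_mean),
                ("amp", config.amplification_copy, config.amplification_mean),
            ):
                sigma = abs(mean) / snr
                noise_rng = _child_seed(config.seed, 1, sample_index)
                series_list = []
                truth = []
                for chrom in chroms:
                    a, b = regions[chrom]
                    clean = np.zeros(n_mark)
                    clean[a:b] = mean
                    values = clean + noise_rng.normal(0.0, sigma, size=n_mark)
                    pos = positions[chrom]
                    series_list.append(
                        ProbeSeries(
                            chromosome=chrom,
                            ids=np.array(
                                [f"{chrom}_m{t:04d}" for t in range(n_mark)], dtype=object
                            ),
                            pos_bp=pos,
                            value=values,
                        )
                    )
                    truth.append(
                        TruthRegion(
                            chromosome=chrom,
                            start_index=a,
                            end_index=b,
                            start_bp=int(pos[a]),
                            end_bp=int(pos[b - 1]) + 1,
                            copy_number=copy,
                        )
                    )
                samples.append(
                    SimulatedDataset(
                        name=f"{ref}_snr{snr:g}_{kind}",
                        observations=tuple(series_list),
                        truth=tuple(truth),
                        provenance={
                            "reference": ref,
                            "snr": snr,
                            "sigma": sigma,
                            "aberrant_mean": mean,
                            "copy_number": copy,
                            "seed": config.seed,
                            "sample_index": sample_index,
                        },
                    )
                )
                sample_index += 1
    return samples
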