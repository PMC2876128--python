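"""Domain types for the conditional random pattern (CRP) copy-number model.

The model labels each SNP marker of an ordered log2-ratio track with an
integer copy number.  Its components are:

* a :class:`StateSpace` of candidate copy numbers (default ``{0,1,2,3,4}``),
* Gaussian :class:`EmissionParams` giving the log2-ratio distribution of
  each copy number,
* distance-dependent :class:`TransitionParams` based on Haldane's map
  function, and
* a :class:`PatternSet` of candidate aberration run patterns used by the
  local-evidence function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "EmissionParams",
    "TransitionParams",
    "PatternSet",
    "ProbeSeries",
    "CrpModel",
    "DecodeResult",
    "Segment",
    "DEFAULT_MEANS_5STATE",
    "DEFAULT_SD_5STATE",
    "MEANS_3STATE",
    "SDS_3STATE",
    "default_model",
    "three_state_model",
]

# Default 5-state emission means (log2-ratio units).  The one- and
# three-copy values -0.45 / 0.38 are empirical SNP-array means for
# monosomy / trisomy; array compression pulls them well below the naive
# log2(1/2) = -1 and log2(3/2) = 0.585.  The zero- and four-copy means
# are extrapolations beyond the calibrated range and should be refit
# from known regions whenever such regions exist.
DEFAULT_MEANS_5STATE = {0: -2.0, 1: -0.45, 2: 0.0, 3: 0.38, 4: 0.8}
DEFAULT_SD_5STATE = 0.25

# Three-state (loss / normal / gain) configuration used for array-CGH
# style tracks.
MEANS_3STATE = {1: -0.27, 2: 0.0, 3: 0.27}
SDS_3STATE = {1: 0.1, 2: 0.1, 3: 0.1}


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of candidate integer copy numbers."""

    labels: tuple[int, ...] = (0, 1, 2, 3, 4)
    normal: int = 2

    def __post_init__(self) -> None:
        labels = tuple(int(c) for c in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("state space needs at least two copy numbers")
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ValueError("copy numbers must be strictly increasing")
        if self.normal not in labels:
            raise ValueError(f"normal state {self.normal} not in {labels}")

    @property
    def K(self) -> int:
        return len(self.labels)

    def index(self, state: int) -> int:
        try:
            return self.labels.index(state)
        except ValueError:
            raise ValueError(f"unknown copy-number state {state!r}; states are {self.labels}") from None

    def preference_order(self) -> np.ndarray:
        """State indices sorted by closeness to the normal copy number.

        Used to break Viterbi ties toward the normal state deterministically.
        """
        return np.array(
            sorted(range(self.K), key=lambda i: (abs(self.labels[i] - self.normal), self.labels[i]))
        )


@dataclass(frozen=True)
class EmissionParams:
    """Per-state Gaussian parameters for log2-ratio observations."""

    mean: dict[int, float]
    sd: dict[int, float]

    def __post_init__(self) -> None:
        if set(self.mean) != set(self.sd):
            raise ValueError("mean and sd must cover the same states")
        for s, sd in self.sd.items():
            if not np.isfinite(sd) or sd <= 0:
                raise ValueError(f"sd for state {s} must be positive, got {sd}")
        states = sorted(self.mean)
        mus = [self.mean[s] for s in states]
        if any(b < a for a, b in zip(mus, mus[1:])):
            warnings.warn(
                "emission means are not non-decreasing in copy number: "
                f"{dict(zip(states, mus))}",
                UserWarning,
                stacklevel=2,
            )

    def states(self) -> list[int]:
        return sorted(self.mean)

    def arrays(self, states: StateSpace) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) aligned with ``states.labels``."""
        try:
            mu = np.array([self.mean[s] for s in states.labels], dtype=float)
            sd = np.array([self.sd[s] for s in states.labels], dtype=float)
        except KeyError as e:
            raise ValueError(f"no emission parameters for state {e.args[0]}") from None
        return mu, sd


@dataclass(frozen=True)
class TransitionParams:
    """Haldane map-function transition model.

    theta(d) = 0.5 * (1 - exp(-2 * rho * d)) with d in megabases and
    rho in Morgans per megabase; theta is clamped to
    [theta_floor, 0.5).  The probability of staying is 1 - theta; the
    change mass theta is split uniformly over the K - 1 other states.
    """

    morgans_per_mb: float = 0.01
    theta_floor: float = 1e-10
    max_theta: float = 0.5

    def __post_init__(self) -> None:
        if self.morgans_per_mb <= 0:
            raise ValueError("morgans_per_mb must be positive")
        if not 0 < self.theta_floor < 0.5:
            raise ValueError("theta_floor must lie in (0, 0.5)")
        if self.max_theta != 0.5:
            raise ValueError("max_theta is fixed at 0.5")


@dataclass(frozen=True)
class PatternSet:
    """Candidate aberration run patterns around a center locus.

    For minimum run length ``m`` the window holds the 2m-1 offsets
    -(m-1)..+(m-1); each pattern is a contiguous run of at least m
    offsets containing the center (offset 0).  There are m(m+1)/2 such
    patterns; for m=4 these are the ten classic seven-locus patterns.
    """

    m: int
    patterns: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        object.__setattr__(self, "m", int(self.m))
        expected = self.m * (self.m + 1) // 2
        if len(self.patterns) != expected:
            raise ValueError(f"expected {expected} patterns for m={self.m}, got {len(self.patterns)}")
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("patterns must be pairwise distinct")
        half = self.m - 1
        for p in self.patterns:
            if 0 not in p:
                raise ValueError(f"pattern {p} does not contain the center offset 0")
            if len(p) < self.m:
                raise ValueError(f"pattern {p} shorter than m={self.m}")
            if list(p) != list(range(p[0], p[-1] + 1)):
                raise ValueError(f"pattern {p} is not a contiguous run")
            if p[0] < -half or p[-1] > half:
                raise ValueError(f"pattern {p} exceeds the window [-{half}, {half}]")

    @property
    def window(self) -> tuple[int, ...]:
        half = self.m - 1
        return tuple(range(-half, half + 1))

    def runs(self) -> list[tuple[int, int]]:
        """(first_offset, last_offset) per pattern."""
        return [(p[0], p[-1]) for p in self.patterns]


@dataclass(frozen=True)
class ProbeSeries:
    """One chromosome's ordered markers with log2-ratio values."""

    chromosome: str
    ids: np.ndarray
    pos_bp: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        pos = np.asarray(self.pos_bp, dtype=np.int64)
        val = np.asarray(self.value, dtype=float)
        if not (len(ids) == len(pos) == len(val)):
            raise ValueError("ids, pos_bp and value must have equal length")
        if len(val) < 1:
            raise ValueError("a probe series needs at least one marker")
        if np.any(np.diff(pos) <= 0):
            bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
            raise ValueError(
                f"positions must be strictly increasing within chromosome "
                f"{self.chromosome}; violation at marker index {bad}"
            )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "pos_bp", pos)
        object.__setattr__(self, "value", val)

    @property
    def T(self) -> int:
        return len(self.value)

    def distances_mb(self) -> np.ndarray:
        """Inter-marker distances d_t in megabases (length T-1)."""
        return np.diff(self.pos_bp) / 1e6

    def require_finite(self) -> None:
        bad = ~np.isfinite(self.value)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-finite log2-ratio at marker {self.ids[i]!r} "
                f"(chromosome {self.chromosome}, index {i})"
            )


@dataclass(frozen=True)
class CrpModel:
    """Fully specified CRP model: states, emissions, transitions, patterns."""

    states: StateSpace
    emission: EmissionParams
    transition: TransitionParams
    patterns: PatternSet

    def __post_init__(self) -> None:
        # forces a KeyError -> ValueError if a state lacks parameters
        self.emission.arrays(self.states)


@dataclass(frozen=True)
class Segment:
    """Maximal run of constant inferred copy number."""

    chromosome: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    state: int
    n_markers: int
    mean_probability: float
    short: bool = False

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("segment must contain at least one marker")
        if self.n_markers != self.end_index - self.start_index:
            raise ValueError("n_markers inconsistent with index range")


@dataclass(frozen=True)
class DecodeResult:
    """Viterbi decoding output for one probe series."""

    path: np.ndarray                 # copy number per marker
    delta_final: float               # max_y delta_T(y), log scale
    log_Z: float                     # log partition function
    path_probability: float          # exp(delta_final - log_Z)
    posteriors: np.ndarray           # (T, K) per-locus state probabilities
    segments: tuple[Segment, ...] = field(default_factory=tuple)


def default_model(
    m: int = 4,
    means: dict[int, float] | None = None,
    sds: dict[int, float] | float | None = None,
    morgans_per_mb: float = 0.01,
    states: tuple[int, ...] = (0, 1, 2, 3, 4),
    normal: int = 2,
) -> CrpModel:
    """Build a CRP model with 5-state SNP-array defaults."""
    from .patterns import enumerate_patterns

    mean = dict(DEFAULT_MEANS_5STATE) if means is None else dict(means)
    mean = {s: mean[s] for s in states}
    if sds is None:
        sd = {s: DEFAULT_SD_5STATE for s in states}
    elif isinstance(sds, dict):
        sd = {s: sds[s] for s in states}
    else:
        sd = {s: float(sds) for s in states}
    return CrpModel(
        states=StateSpace(labels=states, normal=normal),
        emission=EmissionParams(mean=mean, sd=sd),
        transition=TransitionParams(morgans_per_mb=morgans_per_mb),
        patterns=enumerate_patterns(m),
    )


def three_state_model(
    m: int = 4,
    means: dict[int, float] | None = None,
    sds: dict[int, float] | None = None,
    morgans_per_mb: float = 0.01,
) -> CrpModel:
    """Loss / normal / gain model with array-CGH style defaults."""
    from .patterns import enumerate_patterns

    mean = dict(MEANS_3STATE) if means is None else dict(means)
    sd = dict(SDS_3STATE) if sds is None else dict(sds)
    return CrpModel(
        states=StateSpace(labels=(1, 2, 3), normal=2),
        emission=EmissionParams(mean=mean, sd=sd),
        transition=TransitionParams(morgans_per_mb=morgans_per_mb),
        patterns=enumerate_patterns(m),
    )
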