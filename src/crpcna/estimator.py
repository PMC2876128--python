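"""Scikit-learn-style front end to the CRP copy-number model.

:class:`CRPDetector` wraps the model as an estimator: ``fit`` learns
Gaussian emission parameters from markers with known copy numbers
(e.g. monosomy/trisomy chromosomes), ``predict`` runs exact Viterbi
decoding over an ordered log2-ratio track, and ``predict_proba``
returns forward-backward posterior marginals.  It composes with
``sklearn.base.clone`` and ``get_params``/``set_params``; note that
samples along the track are *not* i.i.d. (the whole sequence is one
decoding problem), so cross-validation utilities that shuffle rows do
not apply.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator

from .inference import fit_emission_params, viterbi_decode
from .model import (
    DEFAULT_MEANS_5STATE,
    DEFAULT_SD_5STATE,
    CrpModel,
    DecodeResult,
    EmissionParams,
    ProbeSeries,
    StateSpace,
    TransitionParams,
)
from .patterns import enumerate_patterns

__all__ = ["CRPDetector"]


class CRPDetector(BaseEstimator):
    """Copy-number aberration caller for ordered log2-ratio tracks.

    Parameters
    ----------
    states : tuple of int
        Candidate copy numbers, strictly increasing.
    means, sds : dict, sequence, scalar or None
        Emission Gaussian parameters per state.  ``None`` uses the
        5-state SNP-array defaults (means only defined for states
        within {0..4}); a scalar ``sds`` is shared by all states.
    m : int
        Minimum believable aberration run length in markers; the local
        evidence window spans 2m-1 markers and m(m+1)/2 run patterns.
    morgans_per_mb : float
        Genetic-map rate used by the Haldane transition model
        (default 0.01 Morgan/Mb, the 1 cM/Mb genome average).
    normal_state : int
        The copy number regarded as non-aberrant (ties in decoding are
        broken toward it).
    default_spacing_bp : int
        Marker spacing assumed when ``predict`` is given no positions.

    Attributes
    ----------
    emission_ : EmissionParams
        Emission parameters in effect after ``fit``.
    model_ : CrpModel
        The assembled model used for decoding.
    classes_ : ndarray
        The copy-number states, as sklearn convention.
    """

    def __init__(
        self,
        states: tuple[int, ...] = (0, 1, 2, 3, 4),
        means=None,
        sds=None,
        m: int = 4,
        morgans_per_mb: float = 0.01,
        theta_floor: float = 1e-10,
        normal_state: int = 2,
        default_spacing_bp: int = 10_000,
    ):
        self.states = states
        self.means = means
        self.sds = sds
        self.m = m
        self.morgans_per_mb = morgans_per_mb
        self.theta_floor = theta_floor
        self.normal_state = normal_state
        self.default_spacing_bp = default_spacing_bp

    # ------------------------------------------------------------------
    def _base_emission(self) -> EmissionParams:
        states = tuple(self.states)
        if self.means is None:
            mean = {s: DEFAULT_MEANS_5STATE[s] for s in states}
        elif isinstance(self.means, dict):
            mean = {s: float(self.means[s]) for s in states}
        else:
            mean = dict(zip(states, (float(v) for v in self.means)))
        if self.sds is None:
            sd = {s: DEFAULT_SD_5STATE for s in states}
        elif isinstance(self.sds, dict):
            sd = {s: float(self.sds[s]) for s in states}
        elif isinstance(self.sds, numbers.Number):
            sd = {s: float(self.sds) for s in states}
        else:
            sd = dict(zip(states, (float(v) for v in self.sds)))
        return EmissionParams(mean=mean, sd=sd)

    def _assemble(self, emission: EmissionParams) -> CrpModel:
        return CrpModel(
            states=StateSpace(labels=tuple(self.states), normal=self.normal_state),
            emission=emission,
            transition=TransitionParams(
                morgans_per_mb=self.morgans_per_mb, theta_floor=self.theta_floor
            ),
            patterns=enumerate_patterns(self.m),
        )

    @staticmethod
    def _as_values(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1-D log2-ratio track (or a (T, 1) column)")
        return X

    def _series(self, X, pos_bp=None, chromosome: str = "chr") -> ProbeSeries:
        values = self._as_values(X)
        if pos_bp is None:
            pos_bp = np.arange(len(values), dtype=np.int64) * self.default_spacing_bp + 1_000
        ids = np.array([f"{chromosome}_m{i}" for i in range(len(values))], dtype=object)
        return ProbeSeries(chromosome=chromosome, ids=ids, pos_bp=pos_bp, value=values)

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Learn emission parameters from labelled markers.

        X is a 1-D array of log2-ratios (or a (T, 1) column); y gives
        each marker's known copy number.  States absent from y keep
        their configured (or default) parameters.  With ``y=None`` the
        configured parameters are used unchanged.
        """
        base = self._base_emission()
        space = StateSpace(labels=tuple(self.states), normal=self.normal_state)
        if y is None:
            self.emission_ = base
        else:
            values = self._as_values(X)
            y = np.asarray(y)
            self.emission_ = fit_emission_params(values, y, space, base)
        self.model_ = self._assemble(self.emission_)
        self.classes_ = np.array(space.labels)
        self.n_features_in_ = 1
        return self

    def _check_fitted(self) -> CrpModel:
        if not hasattr(self, "model_"):
            # unfitted use with explicit parameters is fine: assemble on the fly
            return self._assemble(self._base_emission())
        return self.model_

    def decode(self, series: ProbeSeries) -> DecodeResult:
        """Full decoding of one chromosome: path, segments, posteriors."""
        return viterbi_decode(series, self._check_fitted())

    def predict(self, X, pos_bp=None) -> np.ndarray:
        """Viterbi copy-number path for a log2-ratio track."""
        return self.decode(self._series(X, pos_bp)).path

    def predict_proba(self, X, pos_bp=None) -> np.ndarray:
        """(T, K) per-marker posterior over copy-number states."""
        return self.decode(self._series(X, pos_bp)).posteriors

    def score(self, X, y, pos_bp=None) -> float:
        """Mean per-marker accuracy of the decoded path against y."""
        pred = self.predict(X, pos_bp)
        return float(np.mean(pred == np.asarray(y)))
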