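"""Correlation-maximizing spatial filters with temporal and L2 regularization.

Given per-trial channel features x_n (band power at a latency) and a
continuous per-trial behavioral response y_n (reaction time), the estimator
finds the weighting w over channels whose projection w'x_n maximally
Pearson-correlates with y across trials.  Maximizing

    r(w) = (w' X y) / (sqrt(w' R w * N) * ||y||),      R = X X' / N,

has the closed-form solution w ∝ R^{-1} X y; with an L2 (ridge) prior on w
the solution becomes w ∝ (R + λ I)^{-1} X y.  Temporal regularization
augments X with the Δt consecutive latency samples of a short window and
replicates y once per sample (the Kronecker construction 1 ⊗ y), which both
pools the covariance estimate over Δt-fold more samples and ties the fit to
the whole window.

Channels and response are mean-centered before solving, as Pearson
correlation presumes; the covariance is normalized by the augmented column
count N·Δt.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .spectral import BandPowerDataset
from .windows import Window, window_samples

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedCorrelationError",
    "ResponseVector",
    "TrialMatrix",
    "AugmentedDesign",
    "SpatialFilter",
    "build_augmented",
    "solve_weights",
    "objective",
    "default_lambda_grid",
]


class UndefinedCorrelationError(ValueError):
    """A correlation was requested for a zero-variance projection or response."""


@dataclass
class ResponseVector:
    """Per-trial continuous behavioral measurements (reaction time, ms)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def centered(self) -> np.ndarray:
        return self.values - self.values.mean()


@dataclass
class TrialMatrix:
    """Channel-by-trial feature matrix at one latency."""

    values: np.ndarray
    latency_ms: float
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trial matrix must be 2-D (channels x trials)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial matrix must be finite")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 trials")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.values.shape[1])


@dataclass
class AugmentedDesign:
    """Window-augmented design: centered data matrix (D x N·Δt), the
    replicated centered response, and the pooled covariance estimate."""

    values: np.ndarray
    response: np.ndarray
    delta_t: int
    covariance: np.ndarray
    cross: np.ndarray
    n_trials: int
    window: Window | None = None
    band: str = ""
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d, m = self.values.shape
        if self.response.shape != (m,):
            raise ValueError("response length must equal N * delta_t")
        if m != self.n_trials * self.delta_t:
            raise ValueError("augmented column count must be N * delta_t")
        if self.covariance.shape != (d, d):
            raise ValueError("covariance must be D x D")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def response_norm(self) -> float:
        return float(np.linalg.norm(self.response))


@dataclass
class SpatialFilter:
    """Fitted spatial weighting with its regularization and training window.

    ``weights`` are reported at unit L2 norm (the objective is scale-free);
    ``achieved_r`` is the training value of the correlation objective.
    """

    weights: np.ndarray
    lam: float
    tau: Window | None
    band: str
    achieved_r: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if not -1.0 - 1e-9 <= self.achieved_r <= 1.0 + 1e-9:
            raise ValueError("achieved_r must lie in [-1, 1]")

    def to_json(self) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "lambda": self.lam,
            "tau": None if self.tau is None else [self.tau.start_ms, self.tau.stop_ms],
            "band": self.band,
            "achieved_r": self.achieved_r,
            "ch_names": list(self.ch_names),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SpatialFilter":
        payload = json.loads(text)
        tau = payload["tau"]
        return cls(
            np.asarray(payload["weights"]),
            payload["lambda"],
            None if tau is None else Window(*tau),
            payload["band"],
            payload["achieved_r"],
            payload["ch_names"],
        )


def build_augmented(
    band_data: BandPowerDataset, window: Window, response: ResponseVector
) -> AugmentedDesign:
    """Construct the augmented design for one training window.

    Columns are the per-latency trial matrices of every sample in the
    window, concatenated sample-block by sample-block; the response is
    replicated once per sample (1 ⊗ y).  Channels and response are centered
    over the augmented columns, and the covariance is normalized by N·Δt.
    """
    if len(response) != band_data.n_trials:
        raise ValueError("response length must equal the trial count")
    idx = window_samples(window, band_data.latencies_ms)
    delta_t = len(idx)
    slab = band_data.values[:, idx, :]  # (D, delta_t, N)
    d, _, n = slab.shape
    x = slab.reshape(d, delta_t * n)  # sample-major blocks [X^t, X^{t+1}, ...]
    x = x - x.mean(axis=1, keepdims=True)
    y = np.tile(response.values, delta_t)
    y = y - y.mean()
    m = delta_t * n
    cov = (x @ x.T) / m
    cross = x @ y
    return AugmentedDesign(
        values=x,
        response=y,
        delta_t=delta_t,
        covariance=cov,
        cross=cross,
        n_trials=n,
        window=window,
        band=band_data.band.name,
        ch_names=list(band_data.ch_names),
    )


def objective(weights: np.ndarray, design: AugmentedDesign) -> float:
    """Pearson correlation between the projected design and the response."""
    w = np.asarray(weights, dtype=float).ravel()
    m = design.values.shape[1]
    proj_norm_sq = float(w @ (design.covariance @ w)) * m
    y_norm = design.response_norm
    if y_norm == 0:
        raise UndefinedCorrelationError("response has zero variance")
    # relative tolerance against the total data scale: catches projections that
    # are zero up to rounding without flagging genuinely small variances
    tol = float(np.trace(design.covariance)) * m * float(w @ w) * 1e-15
    if proj_norm_sq <= tol:
        raise UndefinedCorrelationError("projection has zero variance")
    r = float(w @ design.cross) / (np.sqrt(proj_norm_sq) * y_norm)
    return float(np.clip(r, -1.0, 1.0))


def solve_weights(design: AugmentedDesign, lam: float = 0.0) -> SpatialFilter:
    """Closed-form ridge solution w = (R + λI)^{-1} X̃ ỹ via a linear solve.

    Uses a symmetric positive-definite (Cholesky) factorization; at λ = 0
    with a singular covariance the solve falls back to the pseudoinverse
    with a logged warning.  The reported weights are unit-norm and
    ``achieved_r`` is the training objective at the solution.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    d = design.n_channels
    a = design.covariance + lam * np.eye(d)
    b = design.cross
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
        w = linalg.cho_solve((c, low), b, check_finite=False)
    except linalg.LinAlgError:
        msg = "covariance + lambda*I singular; using pseudoinverse solution"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        logger.warning(msg)
        w = np.linalg.pinv(a) @ b
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    r = objective(w, design)
    return SpatialFilter(
        weights=w,
        lam=float(lam),
        tau=design.window,
        band=design.band,
        achieved_r=r,
        ch_names=list(design.ch_names),
    )


def default_lambda_grid(design: AugmentedDesign, n: int = 5) -> np.ndarray:
    """Logarithmic λ grid scaled by the mean covariance eigenvalue."""
    scale = float(np.trace(design.covariance)) / design.n_channels
    if scale <= 0:
        scale = 1.0
    return scale * np.logspace(-4, 0, n)
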