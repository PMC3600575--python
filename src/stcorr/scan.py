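"""Sliding-window search for the optimal training window τ.

For every window of the grid the held-out performance of the fitted spatial
filter is the cross-validated correlation r_cv: trials are partitioned into
k folds; per fold the filter is trained on the remaining folds (with the
ridge λ selected on an inner split of the training folds only), the held-out
trials are projected (component amplitude averaged across the window
samples), and the pooled held-out (z, y) pairs across folds give one Pearson
correlation.  Significance per window comes from a permutation null: the
response is shuffled across trials and the full cross-validation — including
λ selection — is rerun per permutation; the add-one p-value is
(1 + #{null ≥ observed}) / (1 + n_perm).  Benjamini–Hochberg step-up
controls the FDR across the window grid, and τ is the significant window
whose r_cv is the largest local maximum along the significant offsets.

The permutation engine is vectorized over permutations: for a fixed fold
partition the covariance factorization per (fold, λ) is shared, and the
cross-covariances of all permuted responses are computed as one matrix
product.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.stats.multitest import multipletests

from .estimator import ResponseVector, UndefinedCorrelationError
from .spectral import BandPowerDataset
from .windows import Window, WindowSpec, window_grid, window_samples

__all__ = [
    "Split",
    "NullDistribution",
    "ScanResult",
    "split_train_test",
    "cv_correlation",
    "permutation_null",
    "permutation_pvalue",
    "fdr_select",
    "select_tau",
    "scan_windows",
    "window_grid",
    "WindowSpec",
]


# ---------------------------------------------------------------------------
# train/test split


@dataclass
class Split:
    """One side of a trial partition."""

    data: BandPowerDataset
    response: ResponseVector
    indices: np.ndarray


def split_train_test(
    dataset: BandPowerDataset,
    response: ResponseVector,
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[Split, Split]:
    """Random disjoint trial partition, reproducible under ``seed``."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = dataset.n_trials
    if len(response) != n:
        raise ValueError("response length must equal the trial count")
    n_train = int(round(fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError(f"too few trials ({n}) for a {fraction:.0%} split")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (
        Split(dataset.subset_trials(tr), ResponseVector(response.values[tr]), tr),
        Split(dataset.subset_trials(te), ResponseVector(response.values[te]), te),
    )


# ---------------------------------------------------------------------------
# pooled cross-validation engine (vectorized over response columns)


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < 2 * k:
        raise ValueError(f"{n} trials cannot give {k} folds of >= 2 trials")
    return np.array_split(rng.permutation(n), k)


def _design_stats(slab: np.ndarray, tbar: np.ndarray, y_mat: np.ndarray, idx: np.ndarray):
    """Centered covariance and cross-covariances of the augmented design on a
    trial subset, for every response column at once.

    Uses the identity X̃ Ỹc = Δt · T̄ Yc (each latency block of the augmented
    matrix multiplies the same replicated response block), where T̄ is the
    window-averaged trial matrix.
    """
    d, dt, _ = slab.shape
    x = slab[:, :, idx].reshape(d, dt * len(idx))
    mu = x.mean(axis=1)
    xc = x - mu[:, None]
    cov = (xc @ xc.T) / x.shape[1]
    yc = y_mat[idx] - y_mat[idx].mean(axis=0, keepdims=True)
    cross = dt * ((tbar[:, idx] - mu[:, None]) @ yc)
    return cov, cross, mu


def _ridge_solve(cov: np.ndarray, rhs: np.ndarray, lam: float) -> np.ndarray:
    a = cov + lam * np.eye(cov.shape[0])
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
        return linalg.cho_solve((c, low), rhs, check_finite=False)
    except linalg.LinAlgError:
        return np.linalg.pinv(a) @ rhs


def _train_scale(cov: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Training-set scale of each projection column: sqrt(w' R w).

    A low-noise, training-derived normalization that makes held-out
    projections comparable across folds without touching the held-out draws.
    """
    q = np.einsum("dp,dp->p", w, cov @ w)
    return np.sqrt(np.maximum(q, 0.0))


def _unit_columns(w: np.ndarray) -> np.ndarray:
    """Normalize filter columns to unit L2 norm (correlation is scale-free;
    a deterministic per-fold scale keeps pooled projections comparable without
    injecting data-estimated scaling noise)."""
    norms = np.linalg.norm(w, axis=0)
    return w / np.where(norms > 0, norms, 1.0)


def _masked_corr(z: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of (n, P) arrays over masked rows."""
    cnt = mask.sum(axis=0)
    ok = cnt >= 3
    r = np.full(z.shape[1], np.nan)
    if not ok.any():
        return r
    w = mask.astype(float)
    zm = (z * w).sum(axis=0) / np.maximum(cnt, 1)
    ym = (y * w).sum(axis=0) / np.maximum(cnt, 1)
    zc = (z - zm) * w
    yc = (y - ym) * w
    zn = np.linalg.norm(zc, axis=0)
    yn = np.linalg.norm(yc, axis=0)
    good = ok & (zn > 0) & (yn > 0)
    r[good] = (zc * yc).sum(axis=0)[good] / (zn[good] * yn[good])
    return np.clip(r, -1.0, 1.0)


def _select_lambda_inner(
    slab: np.ndarray,
    tbar: np.ndarray,
    y_mat: np.ndarray,
    tr: np.ndarray,
    lambda_grid: np.ndarray,
    inner_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """λ index per response column maximizing the pooled inner-CV correlation."""
    n_lam = len(lambda_grid)
    p = y_mat.shape[1]
    z_in = np.empty((n_lam, len(tr), p))
    for loc in _fold_indices(len(tr), inner_folds, rng):
        iva_loc = np.sort(loc)
        itr = np.delete(tr, iva_loc)
        iva = tr[iva_loc]
        cov, cross, mu = _design_stats(slab, tbar, y_mat, itr)
        tv = tbar[:, iva] - mu[:, None]
        for li, lam in enumerate(lambda_grid):
            w = _unit_columns(_ridge_solve(cov, cross, lam))
            sd_tr = _train_scale(cov, w)
            z_in[li][iva_loc] = (tv.T @ w) / np.where(sd_tr > 0, sd_tr, 1.0)
    y_tr = y_mat[tr]
    full = np.ones((len(tr), p), dtype=bool)
    r = np.stack([_masked_corr(z_in[li], y_tr, full) for li in range(n_lam)])
    r = np.where(np.isnan(r), -np.inf, r)
    return np.argmax(r, axis=0)  # ties resolve to the smallest λ


def _pooled_cv_engine(
    slab: np.ndarray,
    y_mat: np.ndarray,
    lambda_grid: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
    inner_folds: int = 3,
    fixed_lam_idx: np.ndarray | None = None,
):
    """Pooled k-fold CV correlation for every response column.

    Returns (r_cv, lam_idx_mode, lam_idx_folds).  ``fixed_lam_idx`` skips the
    inner selection and applies the given λ index per column in every fold.
    """
    d, dt, n = slab.shape
    p = y_mat.shape[1]
    tbar = slab.mean(axis=1)
    scale = float(np.std(tbar)) + 1e-300
    folds = _fold_indices(n, k_folds, rng)
    z_cv = np.zeros((n, p))
    valid = np.zeros((n, p), dtype=bool)
    lam_idx_folds = np.empty((k_folds, p), dtype=int)
    n_skipped = 0
    for f, va_unsorted in enumerate(folds):
        va = np.sort(va_unsorted)
        tr = np.sort(np.concatenate([folds[g] for g in range(k_folds) if g != f]))
        if fixed_lam_idx is not None:
            lam_f = np.broadcast_to(np.asarray(fixed_lam_idx, dtype=int), (p,))
        else:
            lam_f = _select_lambda_inner(slab, tbar, y_mat, tr, lambda_grid, inner_folds, rng)
        lam_idx_folds[f] = lam_f
        cov, cross, mu = _design_stats(slab, tbar, y_mat, tr)
        tv = tbar[:, va] - mu[:, None]
        fold_sd = np.zeros(p)
        for li in np.unique(lam_f):
            cols = np.flatnonzero(lam_f == li)
            # the solution scale is arbitrary and varies across folds: use a
            # unit-norm filter and rescale the projection by its *training*
            # spread, a low-noise estimate that leaves the held-out draws
            # untouched
            w = _unit_columns(_ridge_solve(cov, cross[:, cols], lambda_grid[li]))
            sd_tr = _train_scale(cov, w)
            fold_sd[cols] = sd_tr
            z_cv[np.ix_(va, cols)] = (tv.T @ w) / np.where(sd_tr > 0, sd_tr, 1.0)
        fold_ok = fold_sd > 1e-12 * scale
        n_skipped += int(np.sum(~fold_ok[:1]))  # count for the observed column only
        valid[np.ix_(va, np.flatnonzero(fold_ok))] = True
    if n_skipped:
        warnings.warn(
            f"{n_skipped} fold(s) with degenerate projection variance were skipped",
            RuntimeWarning,
            stacklevel=3,
        )
    if not valid[:, 0].any():
        raise UndefinedCorrelationError("all folds degenerate: no held-out variance")
    r = _masked_corr(z_cv, y_mat, valid)
    counts = (lam_idx_folds[:, :, None] == np.arange(len(lambda_grid))).sum(axis=0)
    lam_mode = np.argmax(counts, axis=1)  # ties resolve to the smallest λ
    return r, lam_mode, lam_idx_folds


def _window_slab(dataset: BandPowerDataset, window: Window) -> np.ndarray:
    idx = window_samples(window, dataset.latencies_ms)
    return dataset.values[:, idx, :]


def _lambda_grid_for(slab: np.ndarray, lambda_grid) -> np.ndarray:
    """Absolute grid; default is logarithmic, scaled by the mean eigenvalue of
    the full-training-set window covariance."""
    if lambda_grid is not None:
        grid = np.sort(np.asarray(lambda_grid, dtype=float))
        if np.any(grid < 0):
            raise ValueError("lambda grid must be nonnegative")
        return grid
    d, dt, n = slab.shape
    x = slab.reshape(d, dt * n)
    xc = x - x.mean(axis=1, keepdims=True)
    scale = float(np.einsum("ij,ij->", xc, xc)) / (dt * n) / d
    if scale <= 0:
        scale = 1.0
    return scale * np.logspace(-5, -1, 5)


def cv_correlation(
    train: BandPowerDataset,
    response: ResponseVector,
    window: Window,
    lambda_grid=None,
    k_folds: int = 5,
    seed: int = 0,
    inner_folds: int = 3,
) -> tuple[float, float]:
    """Cross-validated correlation at one window; returns (r_cv, λ chosen).

    The reported λ is the per-fold choice occurring most often (ties toward
    the smaller value).
    """
    if len(response) != train.n_trials:
        raise ValueError("response length must equal the trial count")
    slab = _window_slab(train, window)
    grid = _lambda_grid_for(slab, lambda_grid)
    rng = np.random.default_rng(seed)
    r, lam_mode, _ = _pooled_cv_engine(
        slab, response.values[:, None], grid, k_folds, rng, inner_folds
    )
    return float(r[0]), float(grid[lam_mode[0]])


# ---------------------------------------------------------------------------
# permutation null and FDR


@dataclass
class NullDistribution:
    """Permutation distribution of r_cv at one window."""

    values: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_perm:
            raise ValueError("null value count must match the configured n_perm")


def _window_stats(
    train: BandPowerDataset,
    response: ResponseVector,
    window: Window,
    n_perm: int,
    seed: int,
    k_folds: int = 5,
    lambda_grid=None,
    inner_folds: int = 3,
    reselect_lambda: bool = True,
):
    """Observed r_cv, chosen λ, and the permutation null in one engine pass."""
    slab = _window_slab(train, window)
    grid = _lambda_grid_for(slab, lambda_grid)
    rng_perm = np.random.default_rng([seed, 1])
    y = response.values
    y_mat = np.empty((len(y), n_perm + 1))
    y_mat[:, 0] = y
    for j in range(n_perm):
        y_mat[:, j + 1] = y[rng_perm.permutation(len(y))]
    if reselect_lambda:
        r, lam_mode, _ = _pooled_cv_engine(
            slab, y_mat, grid, k_folds, np.random.default_rng(seed), inner_folds
        )
        lam_chosen = float(grid[lam_mode[0]])
    else:
        # select λ on the observed response only, then freeze it for the null
        r0, lam0 = cv_correlation(
            train, response, window, grid, k_folds, seed, inner_folds
        )
        lam_idx = int(np.argmin(np.abs(grid - lam0)))
        r, _, _ = _pooled_cv_engine(
            slab,
            y_mat,
            grid,
            k_folds,
            np.random.default_rng(seed),
            inner_folds,
            fixed_lam_idx=np.full(n_perm + 1, lam_idx),
        )
        lam_chosen = lam0
    null = NullDistribution(r[1:], n_perm, seed)
    p = permutation_pvalue(float(r[0]), null)
    return float(r[0]), lam_chosen, null, p


def permutation_null(
    train: BandPowerDataset,
    response: ResponseVector,
    window: Window,
    n_perm: int = 1000,
    seed: int = 0,
    k_folds: int = 5,
    lambda_grid=None,
    inner_folds: int = 3,
    reselect_lambda: bool = True,
) -> NullDistribution:
    """Null distribution of r_cv under random reassignment of the response.

    Each permutation shuffles the response across trials and reruns the full
    cross-validation (λ selection included unless ``reselect_lambda`` is
    False, in which case the observed data's λ is frozen).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _, _, null, _ = _window_stats(
        train, response, window, n_perm, seed, k_folds, lambda_grid, inner_folds, reselect_lambda
    )
    return null


def permutation_pvalue(observed: float, null: NullDistribution) -> float:
    """Add-one permutation p-value: (1 + #{null ≥ observed}) / (1 + n_perm)."""
    nulls = null.values[np.isfinite(null.values)]
    return float((1 + np.sum(nulls >= observed)) / (1 + null.n_perm))


def fdr_select(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# scan assembly and τ selection


@dataclass
class ScanResult:
    """Per-window scan outcome plus the selected τ."""

    windows: list[Window]
    r_cv: np.ndarray
    lam: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    selected: Window | None
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start_ms": [w.start_ms for w in self.windows],
                "window_end_ms": [w.stop_ms for w in self.windows],
                "r_cv": self.r_cv,
                "lambda": self.lam,
                "p": self.p_values,
                "significant": self.significant.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_summary_json(self, path) -> None:
        summary = {
            "selected_tau_ms": None
            if self.selected is None
            else [self.selected.start_ms, self.selected.stop_ms],
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": {k: str(v) for k, v in self.config.items()},
        }
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a sequence; plateaus credit their earliest
    index; endpoints count when not exceeded by their single neighbor."""
    n = len(values)
    if n == 0:
        return np.zeros(0, dtype=int)
    if n == 1:
        return np.array([0])
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok:
            out.append(i)  # plateau ties break toward the earliest window
        i = j + 1
    return np.asarray(out, dtype=int)


def select_tau(scan: ScanResult) -> Window | None:
    """τ = the FDR-significant window whose r_cv is the largest among the
    local maxima taken along the significant offsets; None when no window is
    significant."""
    sig = np.flatnonzero(scan.significant)
    if sig.size == 0:
        return None
    r_sig = scan.r_cv[sig]
    cand = _local_maxima(r_sig)
    best = cand[np.argmax(r_sig[cand])]
    return scan.windows[sig[best]]


def scan_windows(
    train: BandPowerDataset,
    response: ResponseVector,
    spec: WindowSpec,
    lambda_grid=None,
    k_folds: int = 5,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    inner_folds: int = 3,
    reselect_lambda: bool = True,
) -> ScanResult:
    """Full sliding-window scan: per-window r_cv, permutation p, FDR mask, τ.

    Reproducible bit-for-bit for a given (seed, configuration); each window
    draws its fold partition and permutations from an independently spawned
    child seed.
    """
    wins = window_grid(spec)
    r_cv = np.empty(len(wins))
    lam = np.empty(len(wins))
    p = np.empty(len(wins))
    root = np.random.SeedSequence([int(seed), 2026])
    children = root.spawn(len(wins))
    for i, win in enumerate(wins):
        wseed = int(children[i].generate_state(1)[0])
        r_cv[i], lam[i], _, p[i] = _window_stats(
            train,
            response,
            win,
            n_perm,
            wseed,
            k_folds,
            lambda_grid,
            inner_folds,
            reselect_lambda,
        )
    sig = fdr_select(p, q)
    config = {
        "epoch_ms": [spec.epoch_start_ms, spec.epoch_stop_ms],
        "duration_ms": spec.duration_ms,
        "step_ms": spec.step_ms,
        "k_folds": k_folds,
        "inner_folds": inner_folds,
        "n_perm": n_perm,
        "q": q,
        "reselect_lambda": reselect_lambda,
        "lambda_grid": None if lambda_grid is None else list(np.asarray(lambda_grid, float)),
        "band": train.band.name,
    }
    result = ScanResult(wins, r_cv, lam, p, sig, None, seed, config)
    result.selected = select_tau(result)
    return result
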