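"""Lagged ridge encoding models (temporal receptive fields).

Per electrode, the model predicts the response at frame ``t`` from the
stimulus feature(s) at delays tau:

    yhat(t) = sum_f sum_tau  w(f, tau) * S(f, t - tau)

The weight matrix ``w`` is fit by ridge regression on a random 80%
chunk-partition of the frames, with the ridge strength chosen by inner
cross-validation. Performance is the Pearson correlation between yhat
and the response on the held-out 20%. Significance uses a permutation
null built by shuffling chunks of the *training* response — destroying
the stimulus–response correspondence while preserving the response
autocorrelation — refitting, and re-scoring on the held-out frames;
the p-value is the fraction of null correlations at or above the true
one, floored at 1/n_perm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seegenc.core import EnvelopeSeries, HighGammaSeries

DEFAULT_DELAY_MIN = 0.0
DEFAULT_DELAY_MAX = 0.6
DEFAULT_N_DELAYS = 60
DEFAULT_TRAIN_FRAC = 0.8
DEFAULT_CHUNK_SEC = 5.0
DEFAULT_N_PERM = 100
DEFAULT_INNER_FOLDS = 5
# spanned 8 decades wide; rescaled to the design's eigenvalue magnitude at fit
DEFAULT_ALPHA_GRID = np.logspace(-2, 6, 9)


@dataclass
class LaggedDesign:
    """Delayed stimulus matrix S(f, t − tau).

    ``matrix`` has one row per frame and one column per (feature, delay)
    pair, delays fastest-varying. Rows where ``t − tau`` falls before the
    recording start are zero-padded (causal).
    """

    matrix: np.ndarray
    delays: np.ndarray
    features: list[str]
    fs: float

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_delays(self) -> int:
        return self.delays.size


@dataclass
class TRFModel:
    """Fitted ridge weights plus everything needed to reproduce the fit."""

    weights: np.ndarray          # (n_features, n_delays)
    alpha: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    alpha_grid: np.ndarray
    col_mean: np.ndarray         # training means used for centering
    y_mean: float

    @property
    def kernel(self) -> np.ndarray:
        """Weights for the first (here: only) feature, indexed by delay."""
        return self.weights[0]

    def predict(self, design: LaggedDesign,
                idx: np.ndarray | None = None) -> np.ndarray:
        x = design.matrix if idx is None else design.matrix[idx]
        return (x - self.col_mean) @ self.weights.ravel() + self.y_mean


@dataclass
class ElectrodeScore:
    """Held-out correlation, permutation null, and p-value for one electrode."""

    r: float
    null_r: np.ndarray
    p: float
    channel: str = ""
    device: str = ""
    alpha: float = np.nan
    model: TRFModel | None = field(default=None, repr=False)


def make_lagged_design(env: EnvelopeSeries,
                       delay_min: float = DEFAULT_DELAY_MIN,
                       delay_max: float = DEFAULT_DELAY_MAX,
                       n_delays: int = DEFAULT_N_DELAYS) -> LaggedDesign:
    """Build the delayed stimulus matrix from an envelope.

    The delay grid is ``n_delays`` points from ``delay_min`` (inclusive)
    toward ``delay_max`` (exclusive) — with the defaults, {0.00, 0.01,
    …, 0.59} s on the 100 Hz grid.
    """
    if n_delays > len(env):
        raise ValueError(f"n_delays={n_delays} exceeds frame count {len(env)}")
    delays = delay_min + np.arange(n_delays) * (delay_max - delay_min) / n_delays
    lags = np.round(delays * env.fs).astype(int)
    n = len(env)
    matrix = np.zeros((n, n_delays))
    for j, lag in enumerate(lags):
        if lag == 0:
            matrix[:, j] = env.values
        elif lag < n:
            matrix[lag:, j] = env.values[: n - lag]
    return LaggedDesign(matrix=matrix, delays=delays,
                        features=["envelope"], fs=env.fs)


def chunk_slices(n_frames: int, chunk_len: int) -> list[slice]:
    """Contiguous chunks of ``chunk_len`` frames; the remainder forms a
    final short chunk."""
    starts = list(range(0, n_frames, chunk_len))
    return [slice(s, min(s + chunk_len, n_frames)) for s in starts]


def split_train_test(n_frames: int, train_frac: float = DEFAULT_TRAIN_FRAC,
                     chunk_sec: float = DEFAULT_CHUNK_SEC, fs: float = 100.0,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random chunk-wise train/test partition of the frame axis.

    Frames are grouped into contiguous ``chunk_sec`` chunks, and whole
    chunks are assigned at random to train (fraction ``train_frac``) or
    test. Chunk-level assignment limits leakage through the response
    autocorrelation that per-frame sampling would allow.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    chunk_len = max(1, int(round(chunk_sec * fs)))
    chunks = chunk_slices(n_frames, chunk_len)
    if len(chunks) < 2:
        raise ValueError("need at least 2 chunks; shorten chunk_sec or add data")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chunks))
    n_train = int(round(train_frac * len(chunks)))
    n_train = min(max(n_train, 1), len(chunks) - 1)
    train_chunks = order[:n_train]
    train_idx = np.sort(np.concatenate([np.arange(chunks[i].start, chunks[i].stop)
                                        for i in train_chunks]))
    mask = np.ones(n_frames, dtype=bool)
    mask[train_idx] = False
    return train_idx, np.flatnonzero(mask)


class RidgeWorkspace:
    """Cached SVD of a centered training design.

    Ridge solves for many responses or many alphas against the same
    design and training set reduce to cheap matrix–vector products:
    ``w(alpha) = V diag(s / (s^2 + alpha)) U^T y_c``. Used to make the
    100-permutation null and per-channel fits affordable.
    """

    def __init__(self, design: LaggedDesign, train_idx: np.ndarray):
        self.design = design
        self.train_idx = np.asarray(train_idx)
        x = design.matrix[self.train_idx]
        self.col_mean = x.mean(axis=0)
        xc = x - self.col_mean
        self.u, self.s, self.vt = np.linalg.svd(xc, full_matrices=False)
        self.col_var = xc.var(axis=0)
        # alpha scale comparable to the Gram eigenvalues n * var
        self.alpha_scale = max(float(self.col_var.mean()) * len(self.train_idx),
                               np.finfo(float).tiny)

    def solve(self, y_train: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
        """Ridge weights and training intercept for one response vector."""
        y_mean = float(y_train.mean())
        uty = self.u.T @ (y_train - y_mean)
        if alpha == 0.0:
            if self.s[-1] < 1e-10 * self.s[0]:
                raise np.linalg.LinAlgError(
                    "design is singular with alpha=0; use alpha > 0")
            shrink = 1.0 / self.s
        else:
            shrink = self.s / (self.s ** 2 + alpha)
        return self.vt.T @ (shrink * uty), y_mean


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance series in correlation; returning r=0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


def _select_alpha(design: LaggedDesign, response: np.ndarray,
                  train_idx: np.ndarray, alpha_grid: np.ndarray,
                  inner_folds: int) -> float:
    """Inner cross-validation: best mean held-out correlation over the grid.

    Folds are contiguous blocks of the training frames; the outer split
    is already chunk-wise, so block folds keep leakage low at a fraction
    of the cost of re-chunking.
    """
    folds = np.array_split(np.arange(train_idx.size), inner_folds)
    scores = np.zeros((len(alpha_grid), inner_folds))
    for k, fold in enumerate(folds):
        if fold.size == 0:
            continue
        mask = np.ones(train_idx.size, dtype=bool)
        mask[fold] = False
        ws = RidgeWorkspace(design, train_idx[mask])
        x_val = design.matrix[train_idx[fold]]
        y_val = response[train_idx[fold]]
        y_tr = response[train_idx[mask]]
        for i, a in enumerate(alpha_grid):
            w, y_mean = ws.solve(y_tr, a * ws.alpha_scale)
            pred = (x_val - ws.col_mean) @ w + y_mean
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scores[i, k] = _pearson(pred, y_val)
    return float(alpha_grid[int(np.argmax(scores.mean(axis=1)))])


def ridge_fit(design: LaggedDesign, response: np.ndarray,
              train_idx: np.ndarray, test_idx: np.ndarray,
              alpha_grid: np.ndarray | None = None,
              alpha: float | None = None,
              inner_folds: int = DEFAULT_INNER_FOLDS,
              workspace: RidgeWorkspace | None = None) -> TRFModel:
    """Fit ridge weights on the training frames.

    ``alpha`` fixes the penalty outright (already on the absolute scale);
    otherwise it is chosen from ``alpha_grid`` (relative units, rescaled
    by the design's eigenvalue magnitude) by inner cross-validation.
    """
    response = np.asarray(response, dtype=np.float64).ravel()
    if response.size != design.n_frames:
        raise ValueError("response length must equal design frame count")
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    ws = workspace or RidgeWorkspace(design, train_idx)
    if alpha is None:
        rel = _select_alpha(design, response, train_idx, np.asarray(alpha_grid),
                            inner_folds)
        alpha = rel * ws.alpha_scale
    w, y_mean = ws.solve(response[train_idx], float(alpha))
    n_feat = len(design.features)
    return TRFModel(weights=w.reshape(n_feat, design.n_delays),
                    alpha=float(alpha), train_idx=np.asarray(train_idx),
                    test_idx=np.asarray(test_idx),
                    alpha_grid=np.asarray(alpha_grid),
                    col_mean=ws.col_mean, y_mean=y_mean)


def score(model: TRFModel, design: LaggedDesign, response: np.ndarray) -> float:
    """Pearson correlation between prediction and response on held-out frames."""
    if model.test_idx.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(design, model.test_idx)
    return _pearson(pred, np.asarray(response, dtype=np.float64)[model.test_idx])


def _shuffle_training_response(response: np.ndarray, train_idx: np.ndarray,
                               chunk_len: int, rng: np.random.Generator) -> np.ndarray:
    """Chunk-shuffle the response over the training frames only.

    The training frames (in temporal order) are cut into contiguous
    runs of ``chunk_len`` and the runs are permuted, preserving the
    multiset of training response values and their local autocorrelation.
    """
    y = response.copy()
    segments = [response[train_idx[sl]] for sl in
                chunk_slices(train_idx.size, chunk_len)]
    order = rng.permutation(len(segments))
    y[train_idx] = np.concatenate([segments[i] for i in order])
    return y


def permutation_test(design: LaggedDesign, response: np.ndarray,
                     train_idx: np.ndarray, test_idx: np.ndarray,
                     n_perm: int = DEFAULT_N_PERM,
                     chunk_sec: float = DEFAULT_CHUNK_SEC,
                     alpha_policy: str = "reuse",
                     alpha_grid: np.ndarray | None = None,
                     seed: int = 0,
                     true_model: TRFModel | None = None,
                     workspace: RidgeWorkspace | None = None) -> ElectrodeScore:
    """Chunk-shuffle permutation test of the held-out correlation.

    For each of ``n_perm`` shuffles the training response is chunk-
    shuffled, a null model is fit on the same split, and its held-out
    correlation recorded. ``p`` is the fraction of null correlations at
    or above the true one (ties count as exceedance), floored at
    ``1/n_perm``.

    ``alpha_policy='reuse'`` refits nulls at the true model's penalty;
    ``'per_shuffle'`` re-selects the penalty for every shuffle.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alpha_policy not in ("reuse", "per_shuffle"):
        raise ValueError("alpha_policy must be 'reuse' or 'per_shuffle'")
    response = np.asarray(response, dtype=np.float64).ravel()
    ws = workspace or RidgeWorkspace(design, train_idx)
    if true_model is None:
        true_model = ridge_fit(design, response, train_idx, test_idx,
                               alpha_grid=alpha_grid, workspace=ws)
    true_r = score(true_model, design, response)
    chunk_len = max(1, int(round(chunk_sec * design.fs)))
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        y_null = _shuffle_training_response(response, train_idx, chunk_len, rng)
        if alpha_policy == "reuse":
            null_model = ridge_fit(design, y_null, train_idx, test_idx,
                                   alpha=true_model.alpha, workspace=ws)
        else:
            null_model = ridge_fit(design, y_null, train_idx, test_idx,
                                   alpha_grid=alpha_grid, workspace=ws)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            null_r[i] = score(null_model, design, y_null)
    p = max(float(np.mean(null_r >= true_r)), 1.0 / n_perm)
    return ElectrodeScore(r=true_r, null_r=null_r, p=p,
                          alpha=true_model.alpha, model=true_model)


def fit_all_electrodes(hg: HighGammaSeries, env: EnvelopeSeries,
                       delay_min: float = DEFAULT_DELAY_MIN,
                       delay_max: float = DEFAULT_DELAY_MAX,
                       n_delays: int = DEFAULT_N_DELAYS,
                       train_frac: float = DEFAULT_TRAIN_FRAC,
                       chunk_sec: float = DEFAULT_CHUNK_SEC,
                       n_perm: int = DEFAULT_N_PERM,
                       alpha_grid: np.ndarray | None = None,
                       alpha_policy: str = "reuse",
                       seed: int = 0,
                       sig_level: float = 0.05) -> tuple[pd.DataFrame, list[ElectrodeScore]]:
    """Fit, score, and permutation-test the model for every electrode.

    All channels share one train/test split and one design factorization.
    Returns a per-electrode table (``channel, device, r, p, alpha,
    significant``) and the full score objects (null distributions and
    fitted weights included).
    """
    if hg.n_frames != len(env):
        raise ValueError(
            f"frame mismatch: high-gamma has {hg.n_frames}, envelope {len(env)}")
    design = make_lagged_design(env, delay_min, delay_max, n_delays)
    train_idx, test_idx = split_train_test(hg.n_frames, train_frac, chunk_sec,
                                           fs=hg.fs, seed=seed)
    ws = RidgeWorkspace(design, train_idx)
    scores: list[ElectrodeScore] = []
    for c in range(hg.n_channels):
        es = permutation_test(design, hg.data[c], train_idx, test_idx,
                              n_perm=n_perm, chunk_sec=chunk_sec,
                              alpha_policy=alpha_policy, alpha_grid=alpha_grid,
                              seed=seed + 1 + c, workspace=ws)
        es.channel = hg.channel_labels[c]
        es.device = hg.device_labels[c]
        scores.append(es)
    table = pd.DataFrame({
        "channel": [s.channel for s in scores],
        "device": [s.device for s in scores],
        "r": [s.r for s in scores],
        "p": [s.p for s in scores],
        "alpha": [s.alpha for s in scores],
        "significant": [s.p < sig_level for s in scores],
    })
    return table, scores
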