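"""ZOOPS EM motif discovery for promoter elements.

Zero-or-one-occurrence-per-sequence expectation maximization: each window
either contains one motif occurrence at an unknown offset or none.  The
E-step computes, per window, a posterior over motif start offsets plus the
no-site option against a 0-order background; the M-step re-estimates the
base-frequency matrix (pseudocount 0.25 per cell) and the site prior.  The
likelihood is monotone non-decreasing per iteration; the best of several
seeded restarts is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import BASES

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class MotifModel:
    """Fitted promoter-element model."""

    width: int
    freq: np.ndarray                      # (4, width), rows A,C,G,T; columns sum to 1
    offsets: np.ndarray                   # best-hit offset per window, -1 when no hit
    hit: np.ndarray                       # posterior(site) >= 0.5 per window
    fraction_with_hit: float
    gamma: float                          # fitted per-window site prior
    ll_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def freq_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=list(BASES),
                            columns=[f"pos{i+1}" for i in range(self.width)])


def encode_windows(windows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode variable-length windows, padded with 4."""
    lens = np.array([len(w) for w in windows])
    X = np.full((len(windows), int(lens.max())), 4, dtype=np.int8)
    for i, w in enumerate(windows):
        X[i, :len(w)] = [_BASE_IDX[b] for b in w.upper()]
    return X, lens


class ZoopsEM(BaseEstimator):
    """ZOOPS EM estimator for one ungapped motif.

    Parameters follow the fit-shaped estimator convention: construct with
    hyperparameters, ``fit(windows)`` learns the model and stores it as
    ``model_``.
    """

    def __init__(self, width: int = 6, n_restarts: int = 20, max_iter: int = 500,
                 tol: float = 1e-6, pseudocount: float = 0.25, seed: int = 0,
                 hit_threshold: float = 0.5):
        self.width = width
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.pseudocount = pseudocount
        self.seed = seed
        self.hit_threshold = hit_threshold

    # -- internals ---------------------------------------------------------

    def _run(self, X: np.ndarray, lens: np.ndarray, log_bg: np.ndarray,
             f0: np.ndarray, gamma0: float) -> tuple[float, np.ndarray, float, list[float],
                                                     np.ndarray, np.ndarray]:
        w = self.width
        N, Lmax = X.shape
        J = Lmax - w + 1
        n_off = lens - w + 1                       # valid offsets per window
        valid = np.arange(J)[None, :] < n_off[:, None]
        # per-window constant: log background probability of the full window
        log_bg_ext = np.append(log_bg, 0.0)
        const = log_bg_ext[X].sum(axis=1)

        f = f0.copy()
        gamma = gamma0
        ll_trace: list[float] = []
        prev_ll = -np.inf
        post = np.zeros((N, J))
        for _ in range(self.max_iter):
            with np.errstate(divide="ignore"):
                lr = np.log(f) - log_bg[:, None]   # (4, w) log likelihood-ratio
            lr_ext = np.vstack([lr, np.zeros((1, w))])
            S = np.zeros((N, J))
            for k in range(w):
                S += lr_ext[X[:, k:k + J], k]
            S[~valid] = -np.inf
            with np.errstate(over="ignore"):
                es = np.exp(S)
            site_mass = (gamma / np.maximum(n_off, 1))[:, None] * es
            denom = (1.0 - gamma) + site_mass.sum(axis=1)
            post = site_mass / denom[:, None]
            p_site = post.sum(axis=1)
            ll = float(np.sum(np.log(denom) + const))
            ll_trace.append(ll)
            if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            # M-step
            counts = np.zeros((4, w))
            for k in range(w):
                xk = X[:, k:k + J]
                for b in range(4):
                    counts[b, k] = post[xk == b].sum()
            f = (counts + self.pseudocount) / (counts.sum(axis=0) + 4 * self.pseudocount)
            gamma = float(np.clip(p_site.mean(), 1e-6, 1.0 - 1e-6))
        offsets = np.where(post.max(axis=1) > 0, post.argmax(axis=1), 0)
        return ll_trace[-1], f, gamma, ll_trace, post.sum(axis=1), offsets

    # -- public API --------------------------------------------------------

    def fit(self, windows: list[str]) -> "ZoopsEM":
        if len(windows) < 10:
            raise ValueError("need at least 10 windows")
        if any(len(w) < self.width for w in windows):
            windows = [w for w in windows if len(w) >= self.width]
            if len(windows) < 10:
                raise ValueError("too few windows at least as wide as the motif")
        X, lens = encode_windows(windows)
        base_counts = np.bincount(X[X < 4].ravel(), minlength=4).astype(float)
        degenerate = int((base_counts > 0).sum()) <= 1
        bg = (base_counts + 1.0) / (base_counts.sum() + 4.0)
        log_bg = np.log(bg)

        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(max(1, self.n_restarts)):
            i = int(rng.integers(len(windows)))
            j = int(rng.integers(lens[i] - self.width + 1))
            f0 = np.full((4, self.width), 0.125)
            for k in range(self.width):
                f0[X[i, j + k], k] = 0.625
            res = self._run(X, lens, log_bg, f0, gamma0=0.5)
            if best is None or res[0] > best[0]:
                best = res
        ll, f, gamma, trace, p_site, offsets = best
        hit = p_site >= self.hit_threshold
        self.model_ = MotifModel(
            width=self.width, freq=f,
            offsets=np.where(hit, offsets, -1),
            hit=hit, fraction_with_hit=float(hit.mean()),
            gamma=gamma, ll_trace=trace, degenerate=degenerate)
        return self

    def fit_model(self, windows: list[str]) -> MotifModel:
        return self.fit(windows).model_


def em_motif_search(windows: list[str], width: int = 6, n_restarts: int = 20,
                    seed: int = 0, **kwargs) -> MotifModel:
    """Functional wrapper over :class:`ZoopsEM`."""
    return ZoopsEM(width=width, n_restarts=n_restarts, seed=seed, **kwargs).fit_model(windows)


def consensus_string(model: MotifModel | np.ndarray, threshold: float = 0.5) -> str:
    """Render each motif position as its argmax base when that base's
    frequency reaches ``threshold``, else 'n'."""
    freq = model.freq if isinstance(model, MotifModel) else np.asarray(model)
    out = []
    for i in range(freq.shape[1]):
        b = int(freq[:, i].argmax())
        out.append(BASES[b] if freq[b, i] >= threshold else "n")
    return "".join(out)
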