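"""Non-negative matrix factorization under the generalized Kullback-Leibler
divergence, with multiplicative updates and a multi-restart initialization.

The factorization V ~ WH (all entries non-negative, V of size F x T, W of
F x K, H of K x T) is fitted by minimizing the generalized KL divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

with the classical multiplicative update rules

    W <- W * ((V / WH) H^T) / (1 H^T)
    H <- H * (W^T (V / WH)) / (W^T 1)

which never increase the divergence and preserve non-negativity. Zeros are
absorbing: a zero row of H or zero column of W stays zero, so a small epsilon
floor is applied inside divisions to avoid 0/0 without materially moving the
fixed points.

Initialization follows a multi-restart protocol: several random non-negative
(W, H) pairs are drawn, the pair with the smallest Euclidean (Frobenius)
distance ||V - WH|| is kept, and that pair is then refined with the KL
updates for up to ``max_iter`` iterations.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np

EPS = 1e-12
DEFAULT_N_RESTARTS = 10
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-6


@dataclass
class NmfModel:
    """Fitted factorization: basis W (F x K), activations H (K x T)."""

    W: np.ndarray
    H: np.ndarray
    divergence_trace: np.ndarray
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return self.W.shape[1]


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH).

    Uses the convention 0 * log(0/x) = 0. Returns +inf when (WH)_ij = 0 at a
    position where V_ij > 0.
    """
    V = np.asarray(V, dtype=np.float64)
    R = np.asarray(W, dtype=np.float64) @ np.asarray(H, dtype=np.float64)
    return float(_KlTracker(V)(R))


def update_W(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """One multiplicative basis update; KL-non-increasing."""
    R = W @ H
    numer = (V / np.maximum(R, EPS)) @ H.T
    denom = np.maximum(H.sum(axis=1)[None, :], EPS)
    return W * numer / denom


def update_H(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """One multiplicative activation update; KL-non-increasing."""
    R = W @ H
    numer = W.T @ (V / np.maximum(R, EPS))
    denom = np.maximum(W.sum(axis=0)[:, None], EPS)
    return H * numer / denom


def _random_factors(
    rng: np.random.Generator, F: int, K: int, T: int, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    # entries in (0, 1] scaled to V's mean; scale-matched init speeds convergence
    W = (1.0 - rng.random((F, K))) * scale
    H = 1.0 - rng.random((K, T))
    return W, H


class _KlTracker:
    """Evaluates D(V || R) cheaply for a fixed V by caching its log terms."""

    def __init__(self, V: np.ndarray) -> None:
        self._V_sum = float(V.sum())
        self._idx = np.flatnonzero(V)
        Vp = V.ravel()[self._idx]
        self._Vp = Vp
        self._VlogV = float(Vp @ np.log(Vp))

    def __call__(self, R: np.ndarray) -> float:
        Rp = R.ravel()[self._idx]
        if np.any(Rp == 0):
            return float("inf")
        return self._VlogV - float(self._Vp @ np.log(Rp)) - self._V_sum + float(R.sum())


def _fit_kl(
    V: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    max_iter: int,
    tol: float,
    update_basis: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating multiplicative updates with a shared-product inner loop.

    Mathematically identical to iterating :func:`update_H` (and, when
    ``update_basis``, :func:`update_W`), but each W @ H product is computed
    once and reused by the following step and the divergence trace.
    """
    kl = _KlTracker(V)
    R = W @ H
    trace = [kl(R)]
    Q = np.empty_like(R)
    for _ in range(max_iter):
        np.divide(V, np.maximum(R, EPS, out=R), out=Q)
        H *= (W.T @ Q) / np.maximum(W.sum(axis=0)[:, None], EPS)
        if update_basis:
            R = np.matmul(W, H, out=R)
            np.divide(V, np.maximum(R, EPS, out=R), out=Q)
            W *= (Q @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
        R = np.matmul(W, H, out=R)
        trace.append(kl(R))
        prev, cur = trace[-2], trace[-1]
        if np.isfinite(prev) and abs(prev - cur) <= tol * max(abs(prev), EPS):
            break
    return W, H, np.asarray(trace, dtype=np.float64)


def nmf_decompose(
    V: np.ndarray,
    K: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
    dtype: np.dtype | type = np.float64,
) -> NmfModel:
    """Full KL-NMF of ``V`` at rank ``K`` with multi-restart initialization.

    ``n_restarts`` random (W, H) pairs are drawn from a seeded generator and
    the pair minimizing the Frobenius distance ||V - WH|| is refined by
    alternating multiplicative updates, stopping early when the relative KL
    change between iterations drops below ``tol``. Deterministic given
    ``seed``. Large pooled factorizations may pass ``dtype=np.float32`` to
    halve memory traffic; the divergence trace is always reported in double
    precision.
    """
    V = np.asarray(V, dtype=dtype)
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    if K < 1:
        raise ValueError("K must be >= 1")
    F, T = V.shape
    if K > min(F, T):
        warnings.warn(
            f"rank K={K} exceeds min(F, T)={min(F, T)}; the factorization is "
            "over-complete",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    scale = max(float(V.mean()), EPS)
    best: tuple[np.ndarray, np.ndarray] | None = None
    best_dist = np.inf
    for _ in range(max(n_restarts, 1)):
        W0, H0 = _random_factors(rng, F, K, T, scale)
        W0 = W0.astype(dtype)
        H0 = H0.astype(dtype)
        dist = float(np.linalg.norm(V - W0 @ H0))
        if dist < best_dist:
            best_dist = dist
            best = (W0, H0)
    W, H = best
    W, H, trace = _fit_kl(V, W, H, max_iter, tol, update_basis=True)
    return NmfModel(
        W=W,
        H=H,
        divergence_trace=trace,
        seed=seed,
        config={
            "K": K,
            "n_restarts": n_restarts,
            "max_iter": max_iter,
            "tol": tol,
            "mode": "full",
        },
    )


def infer_activations(
    V: np.ndarray,
    W_fixed: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
    return_model: bool = False,
    dtype: np.dtype | type = np.float64,
) -> np.ndarray | NmfModel:
    """Infer activations H for ``V`` against a fixed basis ``W_fixed``.

    H is initialized randomly (seeded) and refined with the activation update
    only; the basis is untouched. Because the KL activation update decouples
    across columns of V, inference over concatenated spectrograms equals
    per-column inference.
    """
    V = np.asarray(V, dtype=dtype)
    W_fixed = np.asarray(W_fixed, dtype=dtype)
    if V.shape[0] != W_fixed.shape[0]:
        raise ValueError("W_fixed row count must match V")
    dead = (W_fixed.sum(axis=1) <= 0) & (V.max(axis=1) > 0)
    if np.any(dead):
        warnings.warn(
            "basis has all-zero rows where V is positive; divergence is "
            "infinite there",
            stacklevel=2,
        )
    K, T = W_fixed.shape[1], V.shape[1]
    rng = np.random.default_rng(seed)
    scale = max(float(V.mean()), EPS) / max(float(W_fixed.mean()) * K, EPS)
    H = ((1.0 - rng.random((K, T))) * scale).astype(dtype)
    _, H, trace = _fit_kl(V, W_fixed.copy(), H, max_iter, tol, update_basis=False)
    if return_model:
        return NmfModel(
            W=W_fixed,
            H=H,
            divergence_trace=trace,
            seed=seed,
            config={"max_iter": max_iter, "tol": tol, "mode": "activations"},
        )
    return H


def save_model(model: NmfModel, path: str | Path) -> None:
    """Serialize a model to a zip archive of .npy arrays + JSON metadata."""
    path = Path(path)
    meta = {
        "seed": model.seed,
        "config": model.config,
        "shapes": {"W": list(model.W.shape), "H": list(model.H.shape)},
    }
    with zipfile.ZipFile(path, "w") as zf:
        for name, arr in (
            ("W", model.W),
            ("H", model.H),
            ("divergence_trace", model.divergence_trace),
        ):
            buf = BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2))


def load_model(path: str | Path) -> NmfModel:
    """Load a model saved by :func:`save_model`."""
    with zipfile.ZipFile(Path(path)) as zf:
        arrays = {
            name: np.load(BytesIO(zf.read(f"{name}.npy")))
            for name in ("W", "H", "divergence_trace")
        }
        meta = json.loads(zf.read("meta.json"))
    return NmfModel(
        W=arrays["W"],
        H=arrays["H"],
        divergence_trace=arrays["divergence_trace"],
        seed=meta.get("seed"),
        config=meta.get("config", {}),
    )
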