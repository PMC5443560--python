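"""Alternating-least-squares non-negative matrix factorization.

Approximates a non-negative genes × voxels matrix *A* (m × n) as the
product *W H* of a non-negative basis matrix *W* (m × s, "signature
expression profiles") and weight matrix *H* (s × n), for a small
subspace size *s*. Each ALS iteration performs four steps:

1. holding W fixed, solve the least-squares problem
   (WᵀW) H = Wᵀ A for H;
2. set negative elements of H to 0;
3. holding H fixed, solve (H Hᵀ) Wᵀ = H Aᵀ for W;
4. set negative elements of W to 0.

The normal-equation systems can become singular after clamping, so the
solves use a minimum-norm least-squares solution rather than direct
inversion. The default stopping rule is a fixed cap of 1000 iterations;
an optional tolerance on the change in relative reconstruction error
can stop earlier. ALS is non-convex, so ``als_nmf`` runs several
independently initialized restarts and keeps the best fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

DEFAULT_MAX_ITER = 1000
DEFAULT_RESTARTS = 10

#: scale of the positive noise used to revive an all-zero factor row/column
_RESEED_SCALE = 1e-3


@dataclass
class FactorizationResult:
    """Outcome of one best-of-restarts ALS-NMF decomposition."""

    W: np.ndarray
    H: np.ndarray
    s: int
    iterations_run: int
    relative_error: float
    seed: int | None
    restarts_used: int
    error_history: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factors must be non-negative")
        if not np.isfinite(self.relative_error) or self.relative_error < 0:
            raise ValueError("relative_error must be finite and non-negative")


def reconstruction_error(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Relative Frobenius reconstruction error ‖A − WH‖_F / ‖A‖_F."""
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape[0] != A.shape[0] or H.shape[1] != A.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: A {A.shape}, W {W.shape}, H {H.shape}"
        )
    norm_a = np.linalg.norm(A)
    if norm_a == 0:
        raise ValueError("A is all-zero; relative error undefined")
    return float(np.linalg.norm(A - W @ H) / norm_a)


def _revive_zero_rows(X: np.ndarray, rng: np.random.Generator, scale: float) -> int:
    """Re-seed all-zero rows of X with small positive noise; return count."""
    dead = ~X.any(axis=1)
    n_dead = int(dead.sum())
    if n_dead:
        X[dead] = rng.uniform(0, scale, size=(n_dead, X.shape[1]))
    return n_dead


def _als_single(
    A: np.ndarray,
    s: int,
    max_iter: int,
    tol: float,
    seed: int,
    assert_nonneg: bool = False,
) -> tuple[np.ndarray, np.ndarray, int, float, np.ndarray, bool]:
    """One ALS run from one random initialization.

    Returns (W, H, iterations, relative_error, error_history, degenerate).
    A run is marked degenerate when a factor row/column collapses to
    zero a second time after having been revived once.
    """
    rng = np.random.default_rng(seed)
    m, n = A.shape
    norm_a = np.linalg.norm(A)
    scale = float(A.mean())
    W = rng.uniform(0.0, 1.0, size=(m, s)) * (scale if scale > 0 else 1.0)
    H = np.zeros((s, n))
    revive_scale = _RESEED_SCALE * (scale if scale > 0 else 1.0)
    revived_h = revived_w = 0
    degenerate = False
    history = []
    prev_err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        H = np.linalg.lstsq(W, A, rcond=None)[0]
        np.clip(H, 0, None, out=H)
        if _revive_zero_rows(H, rng, revive_scale):
            revived_h += 1
            if revived_h > 1:
                degenerate = True
                break
        W = np.linalg.lstsq(H.T, A.T, rcond=None)[0].T
        np.clip(W, 0, None, out=W)
        if _revive_zero_rows(W.T, rng, revive_scale):
            revived_w += 1
            if revived_w > 1:
                degenerate = True
                break
        if assert_nonneg:
            assert (W >= 0).all() and (H >= 0).all()
        err = float(np.linalg.norm(A - W @ H) / norm_a)
        history.append(err)
        if tol > 0 and abs(prev_err - err) < tol:
            break
        prev_err = err
    if not history:
        degenerate = True
        history = [np.inf]
    return W, H, it, history[-1], np.asarray(history), degenerate


def als_nmf(
    A: np.ndarray,
    s: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = 0.0,
    seed: int | None = None,
    restarts: int = DEFAULT_RESTARTS,
    assert_nonneg: bool = False,
) -> FactorizationResult:
    """Best-of-restarts ALS-NMF of a non-negative matrix.

    Parameters
    ----------
    A
        Non-negative m × n matrix (genes × voxels).
    s
        Subspace size (number of signature profiles), 1 ≤ s ≤ min(m, n).
    max_iter
        Iteration cap per restart (default 1000).
    tol
        Early-stop threshold on the absolute change in relative
        reconstruction error between iterations; 0 (default) disables
        early stopping and runs exactly ``max_iter`` iterations.
    seed
        Master seed. Restart initializations are seeded deterministically
        from it, so identical ``(A, s, seed, restarts)`` give bit-identical
        results.
    restarts
        Number of independent random initializations; the restart with
        the lowest relative error is returned.
    assert_nonneg
        Assert factor non-negativity after every iteration (test builds).

    Raises
    ------
    ValueError
        If A has negative entries, s is out of range, or every restart
        degenerates (collapses a factor to zero twice).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be 2-D")
    if (A < 0).any():
        raise ValueError("A must be non-negative")
    m, n = A.shape
    if not (1 <= s <= min(m, n)):
        raise ValueError(f"s must satisfy 1 <= s <= min(m, n) = {min(m, n)}, got {s}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    master = np.random.default_rng(seed)
    restart_seeds = master.integers(0, 2**31 - 1, size=restarts)
    best = None
    for rs in restart_seeds:
        W, H, iters, err, history, degenerate = _als_single(
            A, s, max_iter, tol, int(rs), assert_nonneg=assert_nonneg
        )
        if degenerate:
            continue
        if best is None or err < best[3]:
            best = (W, H, iters, err, history)
    if best is None:
        raise ValueError(f"all {restarts} restarts degenerated (zero factor)")
    W, H, iters, err, history = best
    return FactorizationResult(
        W=W,
        H=H,
        s=s,
        iterations_run=iters,
        relative_error=err,
        seed=seed,
        restarts_used=restarts,
        error_history=history,
    )


# ----------------------------------------------------------------------
# factor comparison (recovery tests, cross-run matching)
# ----------------------------------------------------------------------

def match_columns_cosine(W: np.ndarray, W_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column matching between two bases, scored by cosine similarity.

    Non-negative factorizations are identifiable only up to column
    permutation and positive rescaling; cosine similarity is invariant
    to the rescaling and the Hungarian assignment finds the best
    permutation. Returns ``(perm, cosines)`` where ``W[:, perm[j]]``
    matches ``W_ref[:, j]``.
    """
    W = np.asarray(W, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    if W.shape != W_ref.shape:
        raise ValueError(f"shape mismatch: {W.shape} vs {W_ref.shape}")

    def _unit(X):
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        return X / norms

    C = _unit(W_ref).T @ _unit(W)  # C[j, k] = cos(ref_j, W_k)
    ref_idx, w_idx = linear_sum_assignment(-C)
    perm = np.empty(W.shape[1], dtype=int)
    perm[ref_idx] = w_idx
    return perm, C[ref_idx, w_idx]
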