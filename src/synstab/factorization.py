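"""Non-negative factorization of an activation matrix into synergies and
commands, the reconstruction-similarity index L, and dimension selection.

The activation matrix M (muscles x time) is modelled as

    M = W C + E,     W >= 0 (m x n, unit-norm columns),  C >= 0 (n x t),

with n < m.  W's columns are the muscle synergies spanning the synergy
space; the rows of C are the time-dependent neural commands driving them.
The factorization uses the classic Lee-Seung multiplicative updates for the
squared Frobenius objective, restarted from several random initializations,
and keeps the restart with the best similarity

    L = 100 * (1 - (1/m) * sum_i  mean_j E_ij^2 / mean_j M'_ij^2),

where M' = W C.  L weighs each muscle's residual against that muscle's
reconstructed power, so a single poorly reconstructed muscle drags L down
even if its amplitude is small.  The synergy-space dimension n is the
smallest one whose best-of-restarts L exceeds a threshold (75 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ActivationMatrix

__all__ = [
    "FactorizationConfig",
    "SynergyDecomposition",
    "DimensionSelection",
    "DegenerateSynergyError",
    "nmf",
    "normalize_synergies",
    "similarity_L",
    "select_dimension",
]

_EPS = 1e-12


class DegenerateSynergyError(ValueError):
    """A synergy column collapsed to zero and cannot be unit-normalized."""


@dataclass(frozen=True)
class FactorizationConfig:
    """Settings for the multiplicative-update NMF.

    restarts
        Number of random initializations; the best-L fit is kept.  NMF is
        non-convex, so restarts guard against poor local minima.
    max_iter
        Iteration cap per restart.
    tol
        Stop when the relative change of the residual norm between
        iterations falls below this.
    seed
        Base seed; each restart draws from an independent stream spawned
        from it, so results are reproducible bit-for-bit.
    """

    restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0


@dataclass(frozen=True)
class SynergyDecomposition:
    """One trial's factorization M ~ W C.

    W has unit-norm non-negative columns (the synergies); C carries the
    matching non-negative command rows; L is the reconstruction similarity
    in (0, 100].
    """

    W: np.ndarray
    C: np.ndarray
    L: float
    n: int
    restarts_used: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if W.ndim != 2 or C.ndim != 2 or W.shape[1] != C.shape[0]:
            raise ValueError("W (m x n) and C (n x t) shapes are inconsistent")
        if np.any(W < 0) or np.any(C < 0):
            raise ValueError("W and C must be non-negative")
        norms = np.linalg.norm(W, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("columns of W must have unit Euclidean norm")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "C", C)

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass(frozen=True)
class DimensionSelection:
    """Result of scanning candidate dimensions n = 1 .. m-1."""

    n: int
    L_curve: dict[int, float] = field(default_factory=dict)
    reached_threshold: bool = True
    threshold: float = 75.0


def _as_matrix(M: ActivationMatrix | np.ndarray) -> np.ndarray:
    if isinstance(M, ActivationMatrix):
        return M.values
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-D matrix")
    return M


def normalize_synergies(
    W: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each synergy column of W to unit norm, compensating in C.

    The corresponding command row is multiplied by the inverse factor so the
    product W C is unchanged.

    Raises
    ------
    DegenerateSynergyError
        If some column of W is identically zero.
    """
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms <= 0):
        raise DegenerateSynergyError("all-zero synergy column cannot be normalized")
    return W / norms, C * norms[:, None]


def similarity_L(
    M: ActivationMatrix | np.ndarray, W: np.ndarray, C: np.ndarray
) -> float:
    """Reconstruction similarity L between M and M' = W C.

    Per muscle, the mean squared residual is divided by the mean squared
    reconstructed value; L = 100 * (1 - average of those ratios).  L = 100
    only when M = W C exactly.

    Raises
    ------
    ValueError
        If a muscle row of the reconstruction is identically zero (the
        per-muscle ratio is then undefined).
    """
    M = _as_matrix(M)
    recon = np.asarray(W, dtype=float) @ np.asarray(C, dtype=float)
    if M.shape != recon.shape:
        raise ValueError("M and W C have inconsistent shapes")
    recon_power = np.mean(recon**2, axis=1)
    if np.any(recon_power <= 0):
        raise ValueError("a muscle row of the reconstruction is identically zero")
    err_power = np.mean((M - recon) ** 2, axis=1)
    return float(100.0 * (1.0 - np.mean(err_power / recon_power)))


def _multiplicative_updates(
    M: np.ndarray, W: np.ndarray, C: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lee-Seung updates for ||M - WC||_F^2; residual never increases."""
    prev = np.linalg.norm(M - W @ C)
    for _ in range(max_iter):
        C *= (W.T @ M) / np.maximum(W.T @ W @ C, _EPS)
        W *= (M @ C.T) / np.maximum(W @ C @ C.T, _EPS)
        resid = np.linalg.norm(M - W @ C)
        if prev > 0 and (prev - resid) / prev < tol:
            break
        prev = resid
    return W, C


def nmf(
    M: ActivationMatrix | np.ndarray,
    n: int,
    cfg: FactorizationConfig | None = None,
) -> SynergyDecomposition:
    """Factorize M into n synergies with multiplicative-update NMF.

    Runs ``cfg.restarts`` random initializations (uniform in (0, 1]) and
    keeps the restart with the highest similarity L.  The returned W is
    column-normalized to unit norm with C rescaled accordingly.
    Deterministic given ``cfg.seed``.

    Raises
    ------
    ValueError
        If M has a negative entry or n is not in [1, m).
    """
    cfg = cfg or FactorizationConfig()
    M = _as_matrix(M)
    if np.any(M < 0):
        raise ValueError("M must be non-negative")
    m = M.shape[0]
    if not 1 <= n < m:
        raise ValueError(f"dimension n={n} must satisfy 1 <= n < m={m}")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    root = np.random.SeedSequence(cfg.seed)
    for child in root.spawn(cfg.restarts):
        rng = np.random.default_rng(child)
        # uniform in (0, 1]: strictly positive init keeps updates well-defined
        W0 = 1.0 - rng.random((m, n))
        C0 = 1.0 - rng.random((n, M.shape[1]))
        W, C = _multiplicative_updates(M, W0, C0, cfg.max_iter, cfg.tol)
        try:
            L = similarity_L(M, W, C)
        except ValueError:
            continue
        if best is None or L > best[0]:
            best = (L, W, C)
    if best is None:
        raise DegenerateSynergyError("every restart produced a degenerate fit")
    L, W, C = best
    W, C = normalize_synergies(np.maximum(W, 0), np.maximum(C, 0))
    return SynergyDecomposition(
        W=W, C=C, L=L, n=n, restarts_used=cfg.restarts, seed=cfg.seed
    )


def select_dimension(
    M: ActivationMatrix | np.ndarray,
    threshold: float = 75.0,
    cfg: FactorizationConfig | None = None,
    scan_all: bool = False,
) -> DimensionSelection:
    """Smallest dimension n in 1..m-1 whose best-of-restarts L exceeds threshold.

    Returns the selected n together with the L-versus-n curve.  If no
    candidate reaches the threshold, n = m - 1 is reported with
    ``reached_threshold=False``.  With ``scan_all=True`` the full curve up
    to m - 1 is computed even after the threshold is met.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must lie strictly between 0 and 100")
    M = _as_matrix(M)
    m = M.shape[0]
    curve: dict[int, float] = {}
    selected: int | None = None
    for n in range(1, m):
        curve[n] = nmf(M, n, cfg).L
        if selected is None and curve[n] > threshold:
            selected = n
            if not scan_all:
                break
    if selected is None:
        return DimensionSelection(
            n=m - 1, L_curve=curve, reached_threshold=False, threshold=threshold
        )
    return DimensionSelection(
        n=selected, L_curve=curve, reached_threshold=True, threshold=threshold
    )
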