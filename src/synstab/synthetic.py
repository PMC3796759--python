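"""Synthetic EMG-like trial cohorts with known ground truth.

Trials are generated from the forward model M = W C + E: a true synergy
matrix W* with controlled pairwise column angles (hence controlled SCI), true
burst-like command profiles C*, per-trial perturbations of W* and C* whose
scales (sigma_W, sigma_C) set the cross-trial stability of synergies and
commands, and additive observation noise.  Two participant profiles bracket
the behaviors of interest:

* ``skilled`` -- small sigma_W (stable synergy space, high SSI), large
  sigma_C (variable commands, low SSI_c), small pair angle (small synergy
  space, high SCI);
* ``unskilled`` -- the opposite on all three axes.

Everything is deterministic given (seed, trial index), so cohorts can be
regenerated bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .factorization import normalize_synergies
from .preprocess import ActivationMatrix

__all__ = [
    "SyntheticGroundTruth",
    "SyntheticParticipant",
    "PROFILES",
    "make_synergy_space",
    "make_commands",
    "make_trial",
    "make_participant",
]

# Profile parameters: cross-trial synergy perturbation, command perturbation,
# inter-synergy angle (degrees), observation noise.  Chosen so the skilled /
# unskilled contrast in SSI, SSI_c and SCI is visible through the full
# NMF pipeline at the default trial geometry (m=6, t=160, p=5, n=2).
PROFILES: dict[str, dict[str, float]] = {
    "skilled": {"sigma_W": 0.05, "sigma_C": 0.30, "pair_angle": 40.0, "noise_sd": 0.02},
    "unskilled": {"sigma_W": 0.35, "sigma_C": 0.05, "pair_angle": 80.0, "noise_sd": 0.02},
}


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True factors and perturbation scales behind a generated cohort."""

    W_star: np.ndarray
    C_star: np.ndarray
    sigma_W: float = 0.0
    sigma_C: float = 0.0
    noise_sd: float = 0.0
    pair_angle: float = 60.0
    seed: int = 0

    @property
    def m(self) -> int:
        return self.W_star.shape[0]

    @property
    def n(self) -> int:
        return self.W_star.shape[1]

    @property
    def t(self) -> int:
        return self.C_star.shape[1]


def make_synergy_space(
    m: int, n: int, pair_angle: float = 60.0, seed: int = 0
) -> np.ndarray:
    """Non-negative unit columns with all pairwise angles equal to pair_angle.

    Columns are built as ``w_i = a*s + b*e_i`` where s is a shared random
    non-negative unit direction, the e_i are disjoint-support unit directions
    orthogonal to s and each other, ``a = sqrt(cos(angle))`` and
    ``a^2 + b^2 = 1``.  Then ``w_i . w_j = a^2 = cos(angle)`` exactly for
    every pair, so for n = 2 the SCI of the result is cos(pair_angle).
    Coordinates are randomly assigned per seed.

    Raises
    ------
    ValueError
        If the angle is outside [0, 90] degrees or cannot be realized in the
        non-negative orthant of R^m (needs m >= n+1 for angles below 90,
        m >= n at 90 degrees).
    """
    if n < 1 or m < n:
        raise ValueError("need m >= n >= 1")
    if not 0.0 <= pair_angle <= 90.0:
        raise ValueError("pair_angle must lie in [0, 90] degrees")
    cos_t = float(np.cos(np.deg2rad(pair_angle)))
    if cos_t < 1e-12:
        cos_t = 0.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coords = rng.permutation(m)

    if n == 1:
        w = np.zeros(m)
        w[coords] = rng.uniform(0.2, 1.0, size=m)
        return (w / np.linalg.norm(w))[:, None]

    a = np.sqrt(cos_t)
    b = np.sqrt(1.0 - cos_t)
    if cos_t == 1.0:
        # zero angle: all columns identical
        shared = np.zeros(m)
        shared[coords] = rng.uniform(0.2, 1.0, size=m)
        shared /= np.linalg.norm(shared)
        return np.tile(shared[:, None], (1, n))
    if cos_t > 0 and m < n + 1:
        raise ValueError(
            f"pair angle {pair_angle} deg infeasible for n={n} in the "
            f"non-negative orthant of R^{m}: need m >= n + 1"
        )
    private = coords[:n]
    shared_coords = coords[n:]
    shared = np.zeros(m)
    if cos_t > 0:
        shared[shared_coords] = rng.uniform(0.2, 1.0, size=len(shared_coords))
        shared /= np.linalg.norm(shared)
    W = np.zeros((m, n))
    for i in range(n):
        e = np.zeros(m)
        e[private[i]] = 1.0
        W[:, i] = a * shared + b * e
    return W


def make_commands(n: int, t: int, seed: int = 0) -> np.ndarray:
    """Burst-like non-negative command profiles, one Gaussian bump per synergy.

    Bump centers are staggered across the window so different synergies peak
    at different times, as posture-response bursts do; center jitter, width
    and amplitude are drawn per seed.  Every row has a strictly positive
    maximum.
    """
    if n < 1 or t < 8:
        raise ValueError("need n >= 1 and t >= 8")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    j = np.arange(t)
    C = np.empty((n, t))
    # stagger nominal centers over the middle 60% of the window
    centers = np.linspace(0.2, 0.8, n) * t
    for i in range(n):
        center = centers[i] + rng.uniform(-0.05, 0.05) * t
        width = rng.uniform(0.06, 0.12) * t
        amp = rng.uniform(0.6, 1.0)
        C[i] = amp * np.exp(-((j - center) ** 2) / (2.0 * width**2))
    return C


def _perturb_columns(
    X: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian perturbation truncated at zero."""
    if sigma <= 0:
        return X.copy()
    return np.clip(X + rng.normal(0.0, sigma, size=X.shape), 0.0, None)


def make_trial(
    gt: SyntheticGroundTruth, trial_index: int
) -> ActivationMatrix:
    """Generate one trial: M = clip0(perturb(W*) perturb(C*) + noise).

    The perturbed W is re-normalized to unit columns before the product, so
    sigma_W moves the trial's synergy *directions* (what SSI measures) rather
    than overall amplitude.  Randomness is seeded by (gt.seed, trial_index).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(gt.seed, spawn_key=(int(trial_index),))
    )
    W = _perturb_columns(gt.W_star, gt.sigma_W, rng)
    W, _ = normalize_synergies(W, np.zeros((gt.n, 1)))
    C = _perturb_columns(gt.C_star, gt.sigma_C, rng)
    M = W @ C
    if gt.noise_sd > 0:
        M = M + rng.normal(0.0, gt.noise_sd, size=M.shape)
    return ActivationMatrix(values=np.clip(M, 0.0, None), rate=1000.0)


@dataclass(frozen=True)
class SyntheticParticipant:
    """A generated cohort of p trials plus its ground truth."""

    trials: list[ActivationMatrix]
    ground_truth: SyntheticGroundTruth
    profile: str | None = None
    scores: list[int] = field(default_factory=list)


def make_participant(
    profile: str,
    p: int = 5,
    m: int = 6,
    n: int = 2,
    t: int = 160,
    seed: int = 0,
    overrides: dict[str, float] | None = None,
) -> SyntheticParticipant:
    """Generate a p-trial cohort under a named skill profile.

    ``skilled`` participants keep a stable, small synergy space with variable
    commands; ``unskilled`` participants wander over a large synergy space
    with stereotyped commands.  Individual profile parameters can be
    overridden via ``overrides``.

    Raises
    ------
    ValueError
        For an unknown profile label or p < 2.
    """
    if profile not in PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
        )
    if p < 2:
        raise ValueError("need at least 2 trials")
    params = dict(PROFILES[profile])
    if overrides:
        params.update(overrides)
    gt = SyntheticGroundTruth(
        W_star=make_synergy_space(m, n, params["pair_angle"], seed=seed),
        C_star=make_commands(n, t, seed=seed),
        sigma_W=params["sigma_W"],
        sigma_C=params["sigma_C"],
        noise_sd=params["noise_sd"],
        pair_angle=params["pair_angle"],
        seed=seed,
    )
    trials = [make_trial(gt, k) for k in range(p)]
    return SyntheticParticipant(trials=trials, ground_truth=gt, profile=profile)
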