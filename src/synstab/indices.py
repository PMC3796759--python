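"""Cross-trial synergy indices: SSI, SSI_c and SCI.

Given p per-trial decompositions of the same behavior by one participant,
these indices quantify how the participant uses the synergy space:

* **SSI** (synergy stability index) -- mean over synergies of the mean
  pairwise Pearson correlation of matched synergy vectors across trials.
  SSI = 1 means the same synergy space is reused in every trial.
* **SSI_c** -- the same statistic over the neural-command time courses.
* **SCI** (synergy coordination index) -- mean pairwise inner product of the
  unit synergy vectors of one trial; SCI = 1 for identical columns (a
  one-directional, tightly coordinated space), SCI = 0 for mutually
  orthogonal columns (the largest non-negative space).

NMF is invariant to a column permutation of W (with the matching row
permutation of C), so before computing SSI the trials are aligned:
synergies of each trial are re-sorted to maximize their summed correlation
with the first trial's synergies, which is exactly the permutation that
maximizes SSI.  n is small (typically 2 or 3), so exhaustive search over
all n! orderings is used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .factorization import SynergyDecomposition

__all__ = [
    "SynergyEnsemble",
    "pearson",
    "match_synergies",
    "compute_ssi",
    "compute_ssic",
    "compute_sci",
    "ensemble_sci",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Computed as sum((x - xbar)(y - ybar)) / (m * S_x * S_y) with population
    standard deviations S (denominator m), which coincides with the usual
    sample formula.

    Raises
    ------
    ValueError
        If the vectors differ in length, are shorter than 2, or either is
        constant (zero variance).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.mean(dx**2))
    sy = np.sqrt(np.mean(dy**2))
    if sx == 0 or sy == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.mean(dx * dy) / (sx * sy))


@dataclass
class SynergyEnsemble:
    """The p per-trial decompositions of one participant, plus alignment.

    ``permutations[j]`` is the column order applied to trial j's W (and the
    row order applied to its C) so that synergy i means the same thing in
    every trial.  Indices are filled in by :func:`match_synergies` /
    ``compute_*`` and cached on the instance.
    """

    decompositions: list[SynergyDecomposition]
    permutations: list[tuple[int, ...]] | None = None
    ssi: float | None = None
    ssi_c: float | None = None
    sci_per_trial: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.decompositions:
            raise ValueError("ensemble must contain at least one decomposition")
        m0, n0 = self.decompositions[0].W.shape
        for d in self.decompositions:
            if d.W.shape != (m0, n0):
                raise ValueError("all decompositions must share m and n")

    @property
    def p(self) -> int:
        return len(self.decompositions)

    @property
    def n(self) -> int:
        return self.decompositions[0].W.shape[1]

    def matched_W(self) -> list[np.ndarray]:
        """Per-trial W with alignment permutations applied."""
        perms = self.permutations or [tuple(range(self.n))] * self.p
        return [d.W[:, perm] for d, perm in zip(self.decompositions, perms)]

    def matched_C(self) -> list[np.ndarray]:
        """Per-trial C with the same row permutations applied."""
        perms = self.permutations or [tuple(range(self.n))] * self.p
        return [d.C[perm, :] for d, perm in zip(self.decompositions, perms)]

    @property
    def sci_mean(self) -> float | None:
        if not self.sci_per_trial:
            return None
        return float(np.mean(self.sci_per_trial))


def _pairwise_mean_r(vectors: list[np.ndarray]) -> float:
    """Mean Pearson r over all unordered pairs of a list of vectors."""
    pairs = list(itertools.combinations(range(len(vectors)), 2))
    return float(np.mean([pearson(vectors[l], vectors[q]) for l, q in pairs]))


def match_synergies(ensemble: SynergyEnsemble) -> list[tuple[int, ...]]:
    """Align synergy ordering across trials ("re-sorting").

    The first trial is the reference.  For every other trial the column
    permutation maximizing the summed correlation
    ``sum_i r(W_ref^(i), W_j^(perm(i)))`` is found by exhaustive search over
    all n! orderings; ties go to the lexicographically smallest permutation.
    The permutations are stored on the ensemble and returned.
    """
    n = ensemble.n
    identity = tuple(range(n))
    perms: list[tuple[int, ...]] = [identity]
    ref = ensemble.decompositions[0].W
    for d in ensemble.decompositions[1:]:
        best_perm, best_score = identity, -np.inf
        for perm in itertools.permutations(range(n)):
            score = sum(
                pearson(ref[:, i], d.W[:, perm[i]]) for i in range(n)
            )
            if score > best_score:
                best_perm, best_score = perm, score
        perms.append(best_perm)
    ensemble.permutations = perms
    return perms


def _check_matched(ensemble: SynergyEnsemble) -> None:
    if ensemble.p < 2:
        raise ValueError("need at least 2 trials")
    if ensemble.permutations is None:
        match_synergies(ensemble)


def _warn_if_outside_unit(value: float, name: str) -> None:
    if not -1e-9 <= value <= 1 + 1e-9:
        warnings.warn(
            f"{name}={value:.4f} lies outside [0, 1]; the nominal range "
            "presumes matched non-negative synergies",
            stacklevel=3,
        )


def compute_ssi(ensemble: SynergyEnsemble) -> float:
    """Synergy stability index over a matched ensemble.

    For each synergy index i, the Pearson correlations of the matched
    synergy vectors over all unordered trial pairs are averaged; SSI is the
    mean over the n synergies.  Matching is performed first if it has not
    been already.
    """
    _check_matched(ensemble)
    Ws = ensemble.matched_W()
    ssi = float(
        np.mean(
            [_pairwise_mean_r([W[:, i] for W in Ws]) for i in range(ensemble.n)]
        )
    )
    _warn_if_outside_unit(ssi, "SSI")
    ensemble.ssi = ssi
    return ssi


def compute_ssic(ensemble: SynergyEnsemble) -> float:
    """Command stability index: the SSI statistic over neural-command rows."""
    _check_matched(ensemble)
    Cs = ensemble.matched_C()
    ssic = float(
        np.mean(
            [_pairwise_mean_r([C[i, :] for C in Cs]) for i in range(ensemble.n)]
        )
    )
    _warn_if_outside_unit(ssic, "SSI_c")
    ensemble.ssi_c = ssic
    return ssic


def compute_sci(W: np.ndarray) -> float:
    """Synergy coordination index of one unit-column synergy matrix.

    Mean inner product over unordered column pairs,
    ``2/(n(n-1)) * sum_{i<j} W^(i) . W^(j)``: 1 for identical columns, 0 for
    mutually orthogonal ones.

    Raises
    ------
    ValueError
        If n < 2, columns are not unit-norm, or entries are negative.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("SCI requires at least 2 synergy columns")
    if np.any(W < 0):
        raise ValueError("SCI requires non-negative synergy columns")
    if not np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-6):
        raise ValueError("SCI requires unit-norm synergy columns")
    gram = W.T @ W
    n = W.shape[1]
    upper = gram[np.triu_indices(n, k=1)]
    return float(np.mean(upper))


def ensemble_sci(ensemble: SynergyEnsemble) -> list[float]:
    """Per-trial SCI, cached on the ensemble (mean via ``sci_mean``)."""
    scis = [compute_sci(d.W) for d in ensemble.decompositions]
    ensemble.sci_per_trial = scis
    return scis
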