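"""End-to-end orchestration: preprocess -> per-trial NMF -> matching ->
indices, plus trial filtering by balance score and the downstream
least-squares trends (index vs. score across participants, index vs.
session across training days).

Balance scores are observer-assigned integers on the scale
{+2, +1, -1, -2} (from a clean hands-on-hips response down to stepping off
the platform); synergies are computed only on trials of one response
quality (score +1 by default) so that differences in response *strategy* do
not masquerade as differences in synergy stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .factorization import FactorizationConfig, SynergyDecomposition, nmf
from .indices import SynergyEnsemble, compute_ssi, compute_ssic, ensemble_sci, match_synergies
from .preprocess import (
    ActivationMatrix,
    EMGRecording,
    extract_window,
    lowpass,
    normalize_emg,
    rectify,
)

__all__ = [
    "PipelineConfig",
    "ParticipantReport",
    "TrendResult",
    "InsufficientTrialsError",
    "filter_trials",
    "preprocess_trials",
    "run_participant",
    "correlate_index_with_scores",
    "track_sessions",
]

INDEX_NAMES = ("ssi", "ssi_c", "sci")


class InsufficientTrialsError(ValueError):
    """Fewer than two trials qualify for analysis."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis chain in one place.

    ``n`` may be a fixed dimension or ``"auto"``, in which case the common
    dimension for a participant is the smallest n whose per-trial L exceeds
    ``threshold`` in every analyzed trial.
    """

    threshold: float = 75.0
    latency_ms: float = 40.0
    window_ms: float = 160.0
    cutoff_hz: float = 32.0
    filter_order: int = 4
    norm_mode: str = "max"
    restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0
    n: int | str = "auto"
    target_score: int = 1
    max_trials: int = 5


@dataclass(frozen=True)
class ParticipantReport:
    """Per-participant analysis summary (one session)."""

    participant: str
    n: int
    L_per_trial: tuple[float, ...]
    ssi: float
    ssi_c: float
    sci_per_trial: tuple[float, ...]
    sci_mean: float
    sci_sd: float
    n_trials: int
    n_available: int | None = None
    score_mean: float | None = None
    score_min: int | None = None
    score_max: int | None = None
    session: float | None = None
    reached_threshold: bool = True

    def to_dict(self) -> dict:
        return {
            "participant": self.participant,
            "n": self.n,
            "L_per_trial": list(self.L_per_trial),
            "ssi": self.ssi,
            "ssi_c": self.ssi_c,
            "sci_per_trial": list(self.sci_per_trial),
            "sci_mean": self.sci_mean,
            "sci_sd": self.sci_sd,
            "n_trials": self.n_trials,
            "n_available": self.n_available,
            "score_mean": self.score_mean,
            "score_min": self.score_min,
            "score_max": self.score_max,
            "session": self.session,
            "reached_threshold": self.reached_threshold,
        }


@dataclass(frozen=True)
class TrendResult:
    """Least-squares line and Pearson r of an index against a covariate."""

    slope: float
    intercept: float
    r: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("correlation coefficient outside [-1, 1]")


def filter_trials(
    trials_with_scores: Sequence[tuple[object, int]],
    target_score: int = 1,
    count: int = 5,
) -> tuple[list, list[int], int]:
    """Keep the first ``count`` trials whose score equals ``target_score``.

    Returns ``(trials, scores, n_available)`` where ``n_available`` is how
    many qualifying trials existed before truncation.

    Raises
    ------
    InsufficientTrialsError
        If fewer than 2 trials carry the target score.
    """
    valid = {-2, -1, 1, 2}
    for _, score in trials_with_scores:
        if score not in valid:
            raise ValueError(f"score {score} not on the {sorted(valid)} scale")
    kept = [(t, s) for t, s in trials_with_scores if s == target_score]
    if len(kept) < 2:
        raise InsufficientTrialsError(
            f"only {len(kept)} trial(s) with score {target_score:+d}; need >= 2"
        )
    n_available = len(kept)
    if n_available < count:
        warnings.warn(
            f"only {n_available} qualifying trials available; requested {count}",
            stacklevel=2,
        )
    kept = kept[:count]
    return [t for t, _ in kept], [s for _, s in kept], n_available


def preprocess_trials(
    recordings: Sequence[EMGRecording], cfg: PipelineConfig
) -> list[ActivationMatrix]:
    """Rectify, low-pass, normalize across the trial set, and window.

    The filtered envelope is clipped at zero: zero-phase filtering of a
    rectified signal can ring slightly negative, and the activation matrix
    must be non-negative.
    """
    processed = []
    for r in recordings:
        env = lowpass(rectify(r), cfg.cutoff_hz, cfg.filter_order)
        processed.append(replace(env, samples=np.clip(env.samples, 0.0, None)))
    processed = normalize_emg(processed, mode=cfg.norm_mode)
    return [extract_window(r, cfg.latency_ms, cfg.window_ms) for r in processed]


def _trial_seed(base: int, trial_index: int) -> int:
    """Deterministic per-trial seed derived from the top-level seed."""
    ss = np.random.SeedSequence(base, spawn_key=(trial_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _decompose_all(
    matrices: Sequence[ActivationMatrix], n: int, cfg: PipelineConfig
) -> list[SynergyDecomposition]:
    return [
        nmf(
            M,
            n,
            FactorizationConfig(
                restarts=cfg.restarts,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                seed=_trial_seed(cfg.seed, k),
            ),
        )
        for k, M in enumerate(matrices)
    ]


def _select_common_dimension(
    matrices: Sequence[ActivationMatrix], cfg: PipelineConfig
) -> tuple[int, list[SynergyDecomposition], bool]:
    """Smallest n whose L exceeds the threshold in *every* trial."""
    m = matrices[0].m
    last: list[SynergyDecomposition] | None = None
    for n in range(1, m):
        decomps = _decompose_all(matrices, n, cfg)
        last = decomps
        if min(d.L for d in decomps) > cfg.threshold:
            return n, decomps, True
    assert last is not None
    return m - 1, last, False


def run_participant(
    trials: Sequence[EMGRecording | ActivationMatrix],
    cfg: PipelineConfig | None = None,
    participant: str = "P1",
    scores: Sequence[int] | None = None,
    n_available: int | None = None,
    session: float | None = None,
) -> ParticipantReport:
    """Full single-participant analysis.

    Raw recordings are preprocessed (already-windowed activation matrices
    are used as-is); a common dimension is chosen; each trial is decomposed
    by NMF; synergies are matched across trials; SSI, SSI_c and per-trial
    SCI are computed.

    Raises
    ------
    InsufficientTrialsError
        With fewer than 2 trials.
    """
    cfg = cfg or PipelineConfig()
    if len(trials) < 2:
        raise InsufficientTrialsError("need at least 2 trials for the indices")

    if isinstance(trials[0], EMGRecording):
        matrices = preprocess_trials(trials, cfg)  # type: ignore[arg-type]
    else:
        matrices = list(trials)  # type: ignore[assignment]

    if cfg.n == "auto":
        n, decomps, reached = _select_common_dimension(matrices, cfg)
    else:
        n = int(cfg.n)
        decomps = _decompose_all(matrices, n, cfg)
        reached = all(d.L > cfg.threshold for d in decomps)

    ensemble = SynergyEnsemble(decompositions=decomps)
    match_synergies(ensemble)
    ssi = compute_ssi(ensemble)
    ssi_c = compute_ssic(ensemble)
    if n >= 2:
        scis = ensemble_sci(ensemble)
    else:
        scis = []

    score_arr = np.asarray(scores) if scores is not None else None
    return ParticipantReport(
        participant=participant,
        n=n,
        L_per_trial=tuple(d.L for d in decomps),
        ssi=ssi,
        ssi_c=ssi_c,
        sci_per_trial=tuple(scis),
        sci_mean=float(np.mean(scis)) if scis else float("nan"),
        sci_sd=float(np.std(scis)) if scis else float("nan"),
        n_trials=len(matrices),
        n_available=n_available,
        score_mean=float(score_arr.mean()) if score_arr is not None else None,
        score_min=int(score_arr.min()) if score_arr is not None else None,
        score_max=int(score_arr.max()) if score_arr is not None else None,
        session=session,
        reached_threshold=reached,
    )


def _index_value(report: ParticipantReport, index: str) -> float:
    if index == "ssi":
        return report.ssi
    if index == "ssi_c":
        return report.ssi_c
    if index == "sci":
        return report.sci_mean
    raise KeyError(index)


def _trend(x: np.ndarray, y: np.ndarray) -> TrendResult:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant covariate or index: trend undefined")
    fit = stats.linregress(x, y)
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue))


def correlate_index_with_scores(
    reports: Sequence[ParticipantReport],
) -> dict[str, TrendResult]:
    """Least-squares line and Pearson r of each index against mean score.

    Requires at least 3 participants with scores attached.
    """
    scored = [r for r in reports if r.score_mean is not None]
    if len(scored) < 3:
        raise ValueError("need >= 3 participants with scores")
    x = np.array([r.score_mean for r in scored])
    return {
        idx: _trend(x, np.array([_index_value(r, idx) for r in scored]))
        for idx in INDEX_NAMES
    }


def track_sessions(
    session_reports: Sequence[ParticipantReport],
) -> dict[str, TrendResult]:
    """Per-index least-squares trend across training sessions.

    Each report must carry a numeric ``session`` label; reports from
    multiple participants are pooled.  Requires at least 2 distinct
    sessions.
    """
    labelled = [r for r in session_reports if r.session is not None]
    if len({r.session for r in labelled}) < 2:
        raise ValueError("need reports from >= 2 distinct sessions")
    x = np.array([r.session for r in labelled])
    return {
        idx: _trend(x, np.array([_index_value(r, idx) for r in labelled]))
        for idx in INDEX_NAMES
    }
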