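"""Clinical workflow simulation: Full and Manually Initiated matching chains.

Two review workflows wrap the matcher. The *Full* workflow runs the
automated match first; if the reviewer rejects it, a semi-automated match
(user-placed search window) is tried; if that too is rejected, the user
falls back to a manual match in the guidance vendor's review software. The
*Manually Initiated* workflow skips the automated step. The outcome is the
first approved match, or the manual fallback, which is never rejected.

The manual fallback cannot be re-implemented (it is a human operating a
GUI); it is modelled as the gold-standard displacement plus seeded per-axis
normal noise whose scale is calibrated to published manual-matching error
spreads. Reviewer behaviour is either stochastic (per-method Bernoulli
rejection probabilities) or deterministic (reject on a low correlation
score or an edge peak), with review times drawn from a per-method
triangular distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .grids import Displacement3D
from .phantom import CohortDataset
from .registration import MatchResult, RegistrationConfig, extract_template, match

__all__ = [
    "ObserverModel",
    "ClaritySurrogate",
    "MethodAttempt",
    "WorkflowOutcome",
    "WorkflowError",
    "decide",
    "run_full_workflow",
    "run_manually_initiated_workflow",
    "simulate_cohort_workflows",
]

# per-method review-time triangles (min, mode, max) in seconds; the semi and
# manual entries follow published workflow-time rows, the automated entry is
# a configuration default
DEFAULT_TIME_MODEL = {
    "automated": (15.0, 40.0, 120.0),
    "semi_automated": (15.0, 43.0, 136.0),
    "clarity_surrogate": (16.0, 152.0, 308.0),
}


class WorkflowError(RuntimeError):
    pass


@dataclass
class ObserverModel:
    """A simulated reviewer: rejection behaviour plus a review-time model."""

    observer_id: str = "obs"
    p_reject_auto: float = 0.0
    p_reject_semi: float = 0.0
    decision_mode: str = "threshold"  # "bernoulli" or "threshold"
    score_threshold: float = 0.4
    time_model: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TIME_MODEL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_reject_auto, self.p_reject_semi):
            if not 0.0 <= p <= 1.0:
                raise WorkflowError("rejection probabilities must lie in [0, 1]")
        if self.decision_mode not in ("bernoulli", "threshold"):
            raise WorkflowError(f"unknown decision mode {self.decision_mode!r}")
        self._rng = np.random.default_rng(self.seed)

    def fresh(self) -> "ObserverModel":
        """A copy with its random stream reset to the configured seed."""
        return dataclasses.replace(self)


@dataclass
class ClaritySurrogate:
    """Manual-match stand-in: gold standard plus seeded per-axis noise."""

    sd_mm: Tuple[float, float, float] = (2.1, 2.1, 1.8)
    match_time_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd_mm) < 0):
            raise WorkflowError("surrogate error SDs must be non-negative")

    def match_for(self, gold: Displacement3D, key: Sequence[int] = ()) -> MatchResult:
        """A deterministic surrogate match for one fraction (shared by observers)."""
        rng = np.random.default_rng([int(self.seed), *map(int, key)])
        noisy = gold.as_array() + rng.normal(0.0, 1.0, 3) * np.asarray(self.sd_mm)
        return MatchResult(
            displacement=Displacement3D.from_array(noisy),
            peak_score=np.nan,
            method="clarity_surrogate",
            time_s=self.match_time_s,
        )


@dataclass
class MethodAttempt:
    method: str
    result: MatchResult
    decision: str  # "accept" or "reject"
    review_time_s: float


@dataclass
class WorkflowOutcome:
    final: Displacement3D
    source_method: str
    attempts: List[MethodAttempt]
    total_time_s: float


def decide(observer: ObserverModel, attempt: MatchResult) -> Tuple[str, float]:
    """One review decision plus the time it took.

    Bernoulli mode rejects with the method-specific probability; threshold
    mode rejects deterministically on a low peak score or an edge peak.
    """
    method = attempt.method
    if observer.decision_mode == "bernoulli":
        p = observer.p_reject_auto if method == "automated" else observer.p_reject_semi
        reject = bool(observer._rng.random() < p)
    else:
        reject = bool(
            attempt.peak_score < observer.score_threshold
            or "edge_peak" in attempt.flags
        )
    lo, mode, hi = observer.time_model.get(method, (0.0, 0.0, 0.0))
    t = float(observer._rng.triangular(lo, mode, hi)) if hi > lo else float(mode)
    return ("reject" if reject else "accept"), t


DecisionSource = Union[ObserverModel, Sequence[Tuple[bool, float]]]


def _next_decision(
    decisions: DecisionSource, attempt: MatchResult, cursor: List[int]
) -> Tuple[str, float]:
    if isinstance(decisions, ObserverModel):
        return decide(decisions, attempt)
    i = cursor[0]
    if i >= len(decisions):
        raise WorkflowError(
            f"decision list exhausted before reviewing {attempt.method} match"
        )
    cursor[0] += 1
    accept, t = decisions[i]
    return ("accept" if accept else "reject"), float(t)


def _run_stages(
    stages: Sequence[Tuple[str, Callable[[], MatchResult]]],
    clarity_provider: Callable[[], MatchResult],
    decisions: DecisionSource,
) -> WorkflowOutcome:
    attempts: List[MethodAttempt] = []
    total = 0.0
    cursor = [0]
    for name, provider in stages:
        try:
            result = provider()
        except Exception as exc:  # noqa: BLE001 - stage name must be reported
            raise WorkflowError(f"{name} match stage failed: {exc}") from exc
        decision, review_t = _next_decision(decisions, result, cursor)
        attempt_t = result.time_s + review_t
        attempts.append(MethodAttempt(name, result, decision, review_t))
        total += attempt_t
        if decision == "accept":
            return WorkflowOutcome(result.displacement, name, attempts, total)
    try:
        clarity = clarity_provider()
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(f"clarity_surrogate match stage failed: {exc}") from exc
    attempts.append(MethodAttempt("clarity_surrogate", clarity, "accept", 0.0))
    total += clarity.time_s
    return WorkflowOutcome(clarity.displacement, "clarity_surrogate", attempts, total)


def run_full_workflow(
    auto: Union[MatchResult, Callable[[], MatchResult]],
    semi_provider: Callable[[], MatchResult],
    clarity_provider: Callable[[], MatchResult],
    decisions: DecisionSource,
) -> WorkflowOutcome:
    """Automated → semi-automated → manual fallback; first accept wins."""
    auto_provider = auto if callable(auto) else (lambda: auto)
    return _run_stages(
        [("automated", auto_provider), ("semi_automated", semi_provider)],
        clarity_provider,
        decisions,
    )


def run_manually_initiated_workflow(
    semi_provider: Callable[[], MatchResult],
    clarity_provider: Callable[[], MatchResult],
    decisions: DecisionSource,
) -> WorkflowOutcome:
    """Semi-automated → manual fallback; first accept wins."""
    return _run_stages(
        [("semi_automated", semi_provider)], clarity_provider, decisions
    )


def simulate_cohort_workflows(
    cohort: CohortDataset,
    config: RegistrationConfig,
    observers: Sequence[ObserverModel],
    clarity: ClaritySurrogate,
    mode: str = "full",
    golds: Optional[Dict[Tuple[int, int], Displacement3D]] = None,
    split: Optional[str] = None,
    deterministic_times: bool = True,
) -> pd.DataFrame:
    """Replay a workflow over a cohort for several simulated observers.

    The automated and semi-automated matches and the manual surrogate are
    computed once per fraction and shared across observers (matching a
    review process where algorithmic results are observer-independent);
    only the accept/reject decisions and review times vary per observer.
    The semi-automated search window is placed at the gold-standard
    prostate position, modelling a user who locates the prostate correctly
    to within the window margin. ``golds`` defaults to the phantom truth.
    """
    if mode not in ("full", "manual_init"):
        raise WorkflowError(f"unknown workflow mode {mode!r}")
    obs = [o.fresh() for o in observers]
    rows = []
    for patient, fraction in cohort.pairs(split):
        key = (patient.patient_id, fraction.fraction_id)
        gold = (
            golds[key] if golds is not None else fraction.true_shift
        )
        ref = patient.bundle.reference
        rpv = patient.bundle.rpv_mask

        template = extract_template(ref, rpv)
        lo_mm = template.world_offset_mm + gold.as_array()
        hi_mm = (
            template.world_offset_mm
            + (np.asarray(template.shape) - 1) * ref.spacing_mm
            + gold.as_array()
        )
        auto_result = match(ref, rpv, fraction.guide, config, mode="automated",
                            keep_correlation=False)
        semi_result = match(
            ref, rpv, fraction.guide, config, mode="semi",
            window_box_mm=(lo_mm, hi_mm), keep_correlation=False,
        )
        clarity_result = clarity.match_for(gold, key)
        if deterministic_times:
            # wall-clock match times are hardware noise; keep only the seeded
            # review-time model so outcome tables reproduce byte-for-byte
            auto_result.time_s = 0.0
            semi_result.time_s = 0.0

        for o in obs:
            if mode == "full":
                outcome = run_full_workflow(
                    auto_result, lambda: semi_result, lambda: clarity_result, o
                )
            else:
                outcome = run_manually_initiated_workflow(
                    lambda: semi_result, lambda: clarity_result, o
                )
            d = outcome.final.as_array()
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "fraction": fraction.fraction_id,
                    "observer_id": o.observer_id,
                    "workflow": mode,
                    "source_method": outcome.source_method,
                    "dx_lr_mm": d[0],
                    "dy_ap_mm": d[1],
                    "dz_si_mm": d[2],
                    "total_time_s": outcome.total_time_s,
                    "n_attempts": len(outcome.attempts),
                }
            )
    return pd.DataFrame(rows)
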