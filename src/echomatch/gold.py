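"""Landmark-based gold-standard matching with multi-observer consensus.

Prostatic calcifications visible in both the reference and guide scans act
as endogenous fiducial markers. A landmark match is the mean displacement
over up to five such landmark pairs; the gold standard is the mean of three
observers' landmark matches, with a repeat round (up to two) requested
whenever any two observers disagree by more than 5 mm on any axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np

from .grids import Displacement3D

__all__ = [
    "LandmarkPair",
    "ObserverMatch",
    "GoldStandard",
    "GoldStandardError",
    "landmark_match",
    "simulate_observer_landmarks",
    "consensus",
    "interobserver_difference",
]

MAX_LANDMARKS = 5


class GoldStandardError(ValueError):
    pass


@dataclass(frozen=True)
class LandmarkPair:
    """One landmark seen in both scans: id plus mm positions in each."""

    id: int
    ref_mm: Tuple[float, float, float]
    guide_mm: Tuple[float, float, float]

    def shift(self) -> np.ndarray:
        return np.asarray(self.guide_mm, dtype=float) - np.asarray(
            self.ref_mm, dtype=float
        )


@dataclass(frozen=True)
class ObserverMatch:
    observer_id: str
    displacement: Displacement3D
    n_landmarks: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_landmarks <= MAX_LANDMARKS:
            raise GoldStandardError(
                f"n_landmarks must lie in 1..{MAX_LANDMARKS}, got {self.n_landmarks}"
            )


@dataclass
class GoldStandard:
    displacement: Displacement3D
    n_rounds: int
    converged: bool
    per_observer: List[List[ObserverMatch]] = field(default_factory=list)


def landmark_match(pairs: Sequence[LandmarkPair]) -> Displacement3D:
    """Mean landmark shift over 1..5 pairs."""
    if len(pairs) == 0:
        raise GoldStandardError("landmark match requires at least one landmark pair")
    if len(pairs) > MAX_LANDMARKS:
        raise GoldStandardError(
            f"at most {MAX_LANDMARKS} landmark pairs are used, got {len(pairs)}"
        )
    shifts = np.stack([p.shift() for p in pairs])
    return Displacement3D.from_array(shifts.mean(axis=0))


def simulate_observer_landmarks(
    true_pairs: Sequence[LandmarkPair], noise_sd_mm, seed: int
) -> List[LandmarkPair]:
    """Perturb guide-side landmark positions with independent normal noise.

    Reference-side landmarks are contour-time annotations and stay fixed;
    localization uncertainty enters on the guide scan only. Deterministic
    per seed.
    """
    sd = np.broadcast_to(np.asarray(noise_sd_mm, dtype=float), (3,))
    if np.any(sd < 0):
        raise GoldStandardError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for p in true_pairs:
        noisy = np.asarray(p.guide_mm, dtype=float) + rng.normal(0.0, 1.0, 3) * sd
        out.append(LandmarkPair(p.id, tuple(p.ref_mm), tuple(noisy)))
    return out


def interobserver_difference(matches: Sequence[ObserverMatch]) -> float:
    """Max over observer pairs and axes of the absolute displacement difference."""
    arr = np.stack([m.displacement.as_array() for m in matches])
    return float(np.max(arr.max(axis=0) - arr.min(axis=0)))


def consensus(
    first_round: Sequence[ObserverMatch],
    threshold_mm: float = 5.0,
    max_repeats: int = 2,
    repeat_provider: Callable[[int], Sequence[ObserverMatch]] = None,
) -> GoldStandard:
    """Multi-observer consensus with the 5 mm repeat rule.

    If the interobserver difference of a round exceeds ``threshold_mm``,
    a fresh round is requested from ``repeat_provider(round_number)``, up
    to ``max_repeats`` times (3 rounds total). The gold standard is the
    mean of the final round; ``converged`` records whether that round met
    the threshold.
    """
    if len(first_round) < 2:
        raise GoldStandardError("consensus requires at least two observers")
    rounds: List[List[ObserverMatch]] = [list(first_round)]
    while (
        interobserver_difference(rounds[-1]) > threshold_mm
        and len(rounds) <= max_repeats
    ):
        if repeat_provider is None:
            raise GoldStandardError(
                "interobserver difference exceeds threshold but no repeat "
                "provider was supplied"
            )
        nxt = list(repeat_provider(len(rounds) + 1))
        if len(nxt) < 2:
            raise GoldStandardError("repeat round has fewer than two observers")
        rounds.append(nxt)
    final = rounds[-1]
    mean = np.stack([m.displacement.as_array() for m in final]).mean(axis=0)
    return GoldStandard(
        displacement=Displacement3D.from_array(mean),
        n_rounds=len(rounds),
        converged=interobserver_difference(final) <= threshold_mm,
        per_observer=rounds,
    )
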