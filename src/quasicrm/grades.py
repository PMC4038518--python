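"""Toxicity-grade severity scale and equivalent-toxicity (ET) score arithmetic.

Phase I oncology trials grade adverse events on the CTC ordinal scale.  The
designs in this package pool the grades into four categories — 0–1 (none or
minimal), 2 (moderate), 3 (severe), 4 (life threatening) — and map each
category to a numeric severity weight, the *equivalent toxicity score*.  With
the conventional weights a grade-3 event scores 1 (the classical DLT), grade 2
scores 0.5 and grade 4 scores 1.5, so a grade-4 event carries one and a half
times the evidential weight of a DLT rather than being treated identically.

Scores are normalised by the maximum attainable score ``s_max`` so that each
patient contributes a fractional event in [0, 1] to the quasi-Bernoulli
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "GRADE_LABELS",
    "DEFAULT_WEIGHTS",
    "ETScale",
    "ToxicityProfile",
    "TargetScore",
    "mean_et_score",
    "target_from_profile",
    "score_2dp",
]

#: The four pooled grade categories, in severity order.
GRADE_LABELS: tuple[str, ...] = ("0-1", "2", "3", "4")

#: Conventional severity weights: grade 3 defines one DLT-equivalent.
DEFAULT_WEIGHTS: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)


@dataclass(frozen=True)
class ETScale:
    """Severity weights for the grade categories plus the normalisation maximum.

    Parameters
    ----------
    weights
        Non-decreasing severity weights aligned to :data:`GRADE_LABELS`;
        ``weights[0]`` must be 0 (no toxicity scores nothing).
    s_max
        Normalisation maximum.  Normalised scores are ``weight / s_max`` and
        must lie in [0, 1], so ``s_max >= max(weights)``.  Defaults to the
        most severe modelled grade's weight.
    """

    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    s_max: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if self.s_max is None:
            object.__setattr__(self, "s_max", max(w))
        if w[0] != 0.0:
            raise ValueError("weights[0] must be 0 (no-toxicity category)")
        if any(b < a for a, b in zip(w, w[1:])):
            raise ValueError("weights must be non-decreasing in grade severity")
        if not (self.s_max > 0 and self.s_max >= max(w)):
            raise ValueError("s_max must be positive and >= max(weights)")

    @property
    def n_grades(self) -> int:
        return len(self.weights)

    def score(self, grade: int) -> float:
        """ET score of a single grade-category index (0-based)."""
        return self.weights[grade]

    def normalized(self, et_score: float | np.ndarray) -> float | np.ndarray:
        """Map an ET score to the fractional-event scale [0, 1]."""
        return np.asarray(et_score, dtype=float) / self.s_max if np.ndim(et_score) else float(et_score) / self.s_max


def _check_probs(probs: Sequence[float], scale: ETScale, *, tol: float = 1e-9,
                 require_normalized: bool = True) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (scale.n_grades,):
        raise ValueError(
            f"expected {scale.n_grades} grade-category probabilities, got shape {p.shape}"
        )
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValueError("grade probabilities must lie in [0, 1]")
    if require_normalized and abs(p.sum() - 1.0) > tol:
        raise ValueError(f"grade probabilities must sum to 1 (got {p.sum():.6g})")
    return p


@dataclass(frozen=True)
class ToxicityProfile:
    """Elicited grade mix *at the MTD*, used to derive the target ET score.

    The profile answers "what mix of toxicity grades would clinicians accept
    at the dose they call the MTD?"; its mean ET score is the target the
    design aims for.
    """

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = _check_probs(self.probs, ETScale())
        object.__setattr__(self, "probs", tuple(p))


class TargetScore(NamedTuple):
    """Target ET score and its normalised (fractional-event) counterpart."""

    et: float
    normalized: float


def mean_et_score(dist, scale: ETScale = ETScale()) -> float:
    """Mean ET score of a grade distribution: ``sum_g p_g * w_g``.

    ``dist`` may be a :class:`~quasicrm.scenarios.GradeDistribution`, a
    :class:`ToxicityProfile`, or a bare probability sequence.  Linear in the
    probabilities and bounded by ``max(weights)``.
    """
    probs = getattr(dist, "probs", dist)
    strict = getattr(dist, "is_normalized", None)
    p = _check_probs(probs, scale, require_normalized=strict is None or strict)
    return float(p @ np.asarray(scale.weights))


def target_from_profile(profile: ToxicityProfile | Sequence[float],
                        scale: ETScale = ETScale()) -> TargetScore:
    """Derive the target ET score from the elicited MTD toxicity profile.

    Returns both the target on the ET-score scale and divided by ``s_max``
    (the value compared against model-based toxicity probabilities).
    """
    if not isinstance(profile, ToxicityProfile):
        profile = ToxicityProfile(tuple(float(x) for x in profile))
    et = mean_et_score(profile, scale)
    return TargetScore(et=et, normalized=et / scale.s_max)


def score_2dp(x: float) -> float:
    """Round an ET score to 2 decimals with round-half-even on the exact value.

    Scores built from grade probabilities printed to 2 decimals and weights
    printed to 1 decimal lie exactly on a 0.005 grid, so exact halfway cases
    (0.115, 0.475, 0.705, ...) occur routinely.  Binary floating point breaks
    these ties erratically; this helper reconstructs the exact decimal on the
    0.005 grid before applying banker's rounding.
    """
    exact = Decimal(round(x * 200)).scaleb(0) / Decimal(200)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
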