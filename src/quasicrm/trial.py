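"""Sequential trial conduct: accrual, model update, dose assignment, stopping.

The algorithm mirrors standard CRM practice.  The trial starts at a chosen
dose (the lowest, by default); after each cohort the ensemble posterior is
refitted to all accumulated data, the trial stops if the lowest dose is
estimated too toxic (``Pr(pi_1 > theta* | D) > stop_cutoff`` under the
selected model), and otherwise the next cohort receives the dose whose
estimated toxicity is closest to the target, with escalation limited to one
level per step (de-escalation unrestricted).  After the maximum sample size
the MTD is the closest-to-target dose among those actually tried, computed
from the full data.  Everything is deterministic given the random seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import DEFAULT_QUAD_ORDER, TrialData
from .grades import ETScale
from .model import ModelEnsemble, RobustQuasiCRM, RobustQuasiCRMResults
from .scenarios import Scenario

__all__ = ["DesignConfig", "TrialResult", "recommend_dose", "check_stop", "run_trial"]


@dataclass(frozen=True)
class DesignConfig:
    """Everything that defines one dose-finding design.

    Parameters
    ----------
    ensemble
        Candidate skeleton models (K = 1 gives the plain Quasi-CRM).
    target_et
        Target ET score theta on the severity-weight scale; the normalised
        target theta* = theta / s_max is the decision threshold.
    scale
        Grade-to-score map; defaults to weights (0, 0.5, 1, 1.5), s_max 1.5.
    max_n, cohort_size, start_dose
        Accrual plan; defaults 20 / 1 / lowest dose.
    stop_cutoff
        Safety cutoff: stop when Pr(pi_1 > theta* | D) exceeds it (0.90).
    escalation_restricted
        Never escalate by more than one level per step (on by default).
    use_bma
        Decide doses from the model-averaged curve instead of the selected
        model's curve (comparison studies; selection is the published rule).
    stop_under
        Evaluate the stopping probability under the ``"selected"`` model
        (default) or the posterior ``"bma"`` mixture.
    """

    ensemble: ModelEnsemble
    target_et: float = 0.47
    scale: ETScale = field(default_factory=ETScale)
    max_n: int = 20
    cohort_size: int = 1
    start_dose: int = 1
    stop_cutoff: float = 0.90
    escalation_restricted: bool = True
    quad_order: int = DEFAULT_QUAD_ORDER
    use_bma: bool = False
    stop_under: str = "selected"
    label: str = ""

    def __post_init__(self) -> None:
        J = self.ensemble.n_doses
        if not 0.0 < self.target_et <= self.scale.s_max:
            raise ValueError("target_et must lie in (0, s_max]")
        if not 1 <= self.start_dose <= J:
            raise ValueError("start_dose out of range")
        if not self.max_n >= self.cohort_size >= 1:
            raise ValueError("need max_n >= cohort_size >= 1")
        if not 0.5 < self.stop_cutoff <= 1.0:
            raise ValueError("stop_cutoff must lie in (0.5, 1]")
        if self.stop_under not in ("selected", "bma"):
            raise ValueError("stop_under must be 'selected' or 'bma'")

    @property
    def target_norm(self) -> float:
        """theta* = theta / s_max, on the fractional-event scale."""
        return self.target_et / self.scale.s_max

    @property
    def n_doses(self) -> int:
        return self.ensemble.n_doses

    def with_label(self, label: str) -> "DesignConfig":
        return replace(self, label=label)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated (or conducted) trial."""

    data: TrialData
    selected_dose: int | None      #: recommended MTD, or None if stopped for safety
    stopped: bool
    trace: tuple[dict, ...]        #: one entry per model update
    label: str = ""

    @property
    def n_patients(self) -> int:
        return self.data.n

    def n_per_dose(self) -> np.ndarray:
        return self.data.counts()

    def trace_frame(self) -> pd.DataFrame:
        """Decision trace as a tidy frame (exportable to CSV)."""
        rows = []
        for t in self.trace:
            row = dict(t)
            row["pi_hat"] = ",".join(f"{x:.6f}" for x in row["pi_hat"])
            rows.append(row)
        return pd.DataFrame(rows)


def recommend_dose(post_probs: Sequence[float], target_norm: float,
                   current_dose: int | None, config: DesignConfig | None = None,
                   *, escalation_restricted: bool = True) -> int:
    """Closest-to-target dose with the no-skip escalation restriction.

    Candidate is ``argmin_j |pi_j - theta*|`` with ties (to numerical
    tolerance) broken to the lower dose; if escalation is restricted the
    result is capped at ``current_dose + 1``.
    """
    if config is not None:
        escalation_restricted = config.escalation_restricted
    pi = np.asarray(post_probs, dtype=float)
    dist = np.abs(pi - target_norm)
    candidate = int(np.flatnonzero(dist <= dist.min() + 1e-12)[0]) + 1
    if escalation_restricted and current_dose is not None and candidate > current_dose + 1:
        candidate = current_dose + 1
    return candidate


def _stop_probability(results: RobustQuasiCRMResults, config: DesignConfig) -> float:
    if config.stop_under == "bma":
        probs = [s.prob_overdose_d1 for s in results.per_model]
        return float(np.dot(results.post_model_probs, probs))
    return results.prob_overdose


def check_stop(results: RobustQuasiCRMResults, config: DesignConfig) -> bool:
    """True iff the lowest dose is estimated too toxic to continue."""
    if config.stop_cutoff >= 1.0:
        return False
    return _stop_probability(results, config) > config.stop_cutoff


def run_trial(scenario: Scenario, config: DesignConfig,
              rng: int | np.random.Generator | None = None,
              uniforms: np.ndarray | None = None) -> TrialResult:
    """Simulate one trial against ``scenario`` truth.

    Grades are drawn by inverse CDF from one uniform per patient, pre-drawn up
    front; passing the same ``uniforms`` to different designs yields
    common-random-number comparisons (a patient's latent outcome at a given
    dose does not depend on the design that assigned it).
    """
    if scenario.n_doses != config.n_doses:
        raise ValueError("scenario and design disagree on the number of doses")
    if uniforms is None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        uniforms = gen.random(config.max_n)
    if len(uniforms) < config.max_n:
        raise ValueError("need one uniform draw per potential patient")

    cum = scenario.cumulative_sampling_probs()      # (J, G)
    overdose_mode = "all" if config.stop_under == "bma" else "selected"
    data = TrialData(config.n_doses, config.scale)
    dose = config.start_dose
    trace: list[dict] = []
    stopped = False
    results = None

    while data.n < config.max_n:
        take = min(config.cohort_size, config.max_n - data.n)
        for _ in range(take):
            u = uniforms[data.n]
            grade = int(min(np.searchsorted(cum[dose - 1], u, side="right"),
                            cum.shape[1] - 1))
            data.add(dose, grade)
        results = RobustQuasiCRM(data, config.ensemble, config.target_norm,
                                 config.quad_order).fit(compute_overdose=overdose_mode)
        entry = {
            "n": data.n,
            "dose": dose,
            "selected_model": results.selected_model,
            "pi_hat": tuple(results.bma_pi if config.use_bma else results.pi_hat),
            "prob_overdose_d1": _stop_probability(results, config),
        }
        if check_stop(results, config):
            stopped = True
            entry["next_dose"] = None
            trace.append(entry)
            break
        if data.n < config.max_n:
            dose = results.recommend_dose(
                dose, escalation_restricted=config.escalation_restricted,
                use_bma=config.use_bma)
        entry["next_dose"] = dose if data.n < config.max_n else None
        trace.append(entry)

    if stopped:
        selected = None
    else:
        tried = np.flatnonzero(data.counts() > 0) + 1
        selected = results.recommend_dose(
            None, escalation_restricted=False, allowed=tried,
            use_bma=config.use_bma)
        trace[-1]["next_dose"] = None
    return TrialResult(data=data, selected_dose=selected, stopped=stopped,
                       trace=tuple(trace), label=config.label)
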