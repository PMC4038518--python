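"""Robust Quasi-CRM model: Bayesian model selection across parallel skeletons.

``RobustQuasiCRM`` is the statsmodels-style model object: it binds accumulated
trial data to an ensemble of candidate skeleton models and a normalised target
score; ``fit()`` returns a :class:`RobustQuasiCRMResults` carrying per-model
posterior summaries, posterior model probabilities

    P(M_k | D) = L(D | M_k) P(M_k) / sum_l L(D | M_l) P(M_l),

Bayes factors ``B_kl = L(D | M_k) / L(D | M_l)``, the highest-posterior model
(the decision statistic of the robust design), and the Bayesian-model-average
curve (a secondary estimator).  With a single skeleton the pipeline is
operationally the plain Quasi-CRM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    DEFAULT_PRIOR_SD,
    DEFAULT_QUAD_ORDER,
    PosteriorSummary,
    SkeletonModel,
    TrialData,
    _fit_arrays,
    _overdose_log_numerator,
    _overdose_threshold,
)

__all__ = [
    "ModelEnsemble",
    "RobustQuasiCRM",
    "RobustQuasiCRMResults",
    "posterior_model_probs",
    "bayes_factor",
    "select_model",
    "bma_estimate",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ModelEnsemble:
    """K parallel skeleton models with prior model probabilities.

    Models must share the number of doses.  Prior weights default to uniform
    1/K; explicit weights are renormalised to sum to 1, so only their ratios
    matter.
    """

    models: tuple[SkeletonModel, ...]

    def __post_init__(self) -> None:
        models = tuple(self.models)
        if not models:
            raise ValueError("ensemble needs at least one model")
        J = models[0].n_doses
        if any(m.n_doses != J for m in models):
            raise ValueError("all skeletons must share the number of doses")
        object.__setattr__(self, "models", models)

    @classmethod
    def from_skeletons(cls, skeletons: Sequence[Sequence[float]],
                       prior_weights: Sequence[float] | None = None,
                       prior_sd: float = DEFAULT_PRIOR_SD) -> "ModelEnsemble":
        if prior_weights is None:
            prior_weights = [None] * len(skeletons)
        models = tuple(
            SkeletonModel(tuple(s), prior_weight=w, prior_sd=prior_sd)
            for s, w in zip(skeletons, prior_weights)
        )
        return cls(models)

    @property
    def K(self) -> int:
        return len(self.models)

    @property
    def n_doses(self) -> int:
        return self.models[0].n_doses

    def prior_weights(self) -> np.ndarray:
        """Normalised prior model probabilities (uniform where unspecified)."""
        raw = np.array([
            1.0 if m.prior_weight is None else float(m.prior_weight)
            for m in self.models
        ])
        if raw.sum() <= 0:
            raise ValueError("prior model weights must have positive mass")
        return raw / raw.sum()

    def skeleton_matrix(self) -> np.ndarray:
        return np.array([m.skeleton for m in self.models])

    def prior_sds(self) -> np.ndarray:
        return np.array([m.prior_sd for m in self.models])


class RobustQuasiCRM:
    """Quasi-CRM with model selection, bound to one dataset.

    Parameters
    ----------
    data
        Accumulated trial data (may be empty).
    ensemble
        Candidate skeleton models; a single-model ensemble gives the plain
        Quasi-CRM.
    target_norm
        Normalised target score theta* = theta / s_max, needed for the
        overdose probability and dose recommendation.
    quad_order
        Per-segment Gauss–Legendre order for the posterior integrals.
    """

    def __init__(self, data: TrialData, ensemble: ModelEnsemble,
                 target_norm: float | None = None, quad_order: int = DEFAULT_QUAD_ORDER):
        if ensemble.n_doses != data.n_doses:
            raise ValueError("ensemble and data disagree on the number of doses")
        if target_norm is not None and not 0.0 < target_norm <= 1.0:
            raise ValueError("target_norm must lie in (0, 1]")
        self.data = data
        self.ensemble = ensemble
        self.target_norm = target_norm
        self.quad_order = int(quad_order)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, ensemble: ModelEnsemble,
                       scale=None, **kwargs) -> "RobustQuasiCRM":
        """Build from a frame with ``dose`` and either ``grade`` or ``y`` columns."""
        from .grades import ETScale

        scale = scale or ETScale()
        data = TrialData(ensemble.n_doses, scale)
        for _, row in frame.iterrows():
            if "grade" in frame.columns and not pd.isna(row["grade"]):
                data.add(int(row["dose"]), int(row["grade"]))
            else:
                data.add_score(int(row["dose"]), float(row["y"]))
        return cls(data, ensemble, **kwargs)

    def fit(self, compute_overdose: str = "selected") -> "RobustQuasiCRMResults":
        """Integrate every model's posterior and select the highest-posterior one.

        ``compute_overdose`` is one of ``"selected"`` (default: only the
        winning model's ``Pr(pi_1 > theta* | D)`` is integrated, the quantity
        the stopping rule consumes), ``"all"`` or ``"none"``.
        """
        if compute_overdose not in ("selected", "all", "none"):
            raise ValueError("compute_overdose must be 'selected', 'all' or 'none'")
        ens = self.ensemble
        log_skel = np.log(ens.skeleton_matrix())
        n_j, Y_j = self.data.counts(), self.data.score_sums()
        log_marg, alpha_mean, pi_hat = _fit_arrays(
            log_skel, ens.prior_sds(), n_j, Y_j, self.quad_order)
        if not np.all(np.isfinite(log_marg)):
            raise FloatingPointError("non-finite marginal likelihood")

        prior_w = ens.prior_weights()
        log_post = np.log(prior_w) + log_marg
        post = np.exp(log_post - log_post.max())
        post /= post.sum()
        selected = int(np.flatnonzero(post >= post.max() - _TIE_TOL)[0])

        overdose = [None] * ens.K
        if self.target_norm is not None and compute_overdose != "none":
            which = range(ens.K) if compute_overdose == "all" else [selected]
            for k in which:
                if self.target_norm >= 1.0:   # pi can never exceed 1
                    overdose[k] = 0.0
                    continue
                alpha0 = _overdose_threshold(ens.models[k].skeleton[0], self.target_norm)
                log_num = _overdose_log_numerator(
                    log_skel[k], n_j, Y_j, ens.models[k].prior_sd, alpha0)
                overdose[k] = float(np.clip(math.exp(log_num - log_marg[k]), 0.0, 1.0))

        per_model = tuple(
            PosteriorSummary(
                log_marginal=float(log_marg[k]),
                post_mean_alpha=float(alpha_mean[k]),
                post_probs=tuple(pi_hat[k]),
                prob_overdose_d1=overdose[k],
            )
            for k in range(ens.K)
        )
        return RobustQuasiCRMResults(self, per_model, tuple(post), selected)


@dataclass(frozen=True)
class RobustQuasiCRMResults:
    """Fitted ensemble posterior; the Results half of the Model/Results pair."""

    model: RobustQuasiCRM
    per_model: tuple[PosteriorSummary, ...]
    post_model_probs: tuple[float, ...]
    selected_index: int                     #: 0-based index of the winning model

    # -- model choice -------------------------------------------------------
    @property
    def selected_model(self) -> int:
        """1-based number of the highest-posterior model (ties to the lowest)."""
        return self.selected_index + 1

    @property
    def selected_posterior(self) -> PosteriorSummary:
        return self.per_model[self.selected_index]

    # -- toxicity estimates -------------------------------------------------
    @property
    def pi_hat(self) -> np.ndarray:
        """Posterior-mean toxicity curve of the selected model (decision statistic)."""
        return np.asarray(self.selected_posterior.post_probs)

    @property
    def bma_pi(self) -> np.ndarray:
        """Bayesian-model-average curve: sum_k P(M_k|D) pi_hat^(k)."""
        w = np.asarray(self.post_model_probs)
        mat = np.array([s.post_probs for s in self.per_model])
        return w @ mat

    @property
    def prob_overdose(self) -> float:
        """Pr(pi_1 > theta* | D) under the selected model."""
        p = self.selected_posterior.prob_overdose_d1
        if p is None:
            raise ValueError("overdose probability was not computed "
                             "(no target_norm or compute_overdose='none')")
        return p

    def bayes_factor(self, k: int, l: int) -> float:
        """B_kl = L(D|M_k) / L(D|M_l); model numbers are 1-based."""
        lm = [s.log_marginal for s in self.per_model]
        return math.exp(lm[k - 1] - lm[l - 1])

    def bayes_factors_vs_ref(self, ref: int = 1) -> np.ndarray:
        return np.array([self.bayes_factor(k, ref) for k in range(1, len(self.per_model) + 1)])

    # -- dose decision ------------------------------------------------------
    def recommend_dose(self, current_dose: int | None = None, *,
                       escalation_restricted: bool = True,
                       allowed: Sequence[int] | None = None,
                       use_bma: bool = False) -> int:
        """Dose with estimated toxicity closest to the target (1-based).

        Ties (within numerical tolerance) go to the lower dose.  With
        ``escalation_restricted`` the result never exceeds
        ``current_dose + 1``; de-escalation is unrestricted.  ``allowed``
        optionally limits the candidates (e.g. to doses already tried for the
        final selection).  ``use_bma`` switches the decision statistic from
        the selected model's curve to the model average.
        """
        if self.model.target_norm is None:
            raise ValueError("recommend_dose requires a target_norm")
        pi = self.bma_pi if use_bma else self.pi_hat
        dist = np.abs(pi - self.model.target_norm)
        if allowed is not None:
            mask = np.full(dist.shape, np.inf)
            idx = np.asarray(allowed, dtype=int) - 1
            mask[idx] = 0.0
            dist = dist + mask
        candidate = int(np.flatnonzero(dist <= dist.min() + _TIE_TOL)[0]) + 1
        if (escalation_restricted and current_dose is not None
                and candidate > current_dose + 1):
            candidate = current_dose + 1
        return candidate

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of model weights and the selected toxicity curve."""
        lines = [
            "Robust Quasi-CRM fit",
            f"  patients: {self.model.data.n}    models: {len(self.per_model)}"
            f"    selected: M{self.selected_model}",
        ]
        if self.model.target_norm is not None:
            lines.append(f"  normalised target theta*: {self.model.target_norm:.4f}")
        lines.append("")
        head = "  model  prior_w  post_prob  log_marginal"
        lines.append(head)
        prior_w = self.model.ensemble.prior_weights()
        for k, s in enumerate(self.per_model):
            mark = "*" if k == self.selected_index else " "
            lines.append(
                f"  M{k + 1}{mark}    {prior_w[k]:.3f}    {self.post_model_probs[k]:.4f}"
                f"     {s.log_marginal:.4f}"
            )
        lines.append("")
        lines.append("  dose   pi_hat (selected)   pi_hat (BMA)")
        bma = self.bma_pi
        for j, (a, b) in enumerate(zip(self.pi_hat, bma), start=1):
            lines.append(f"  {j:>4}   {a:.4f}              {b:.4f}")
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": np.arange(1, len(self.per_model) + 1),
            "prior_weight": self.model.ensemble.prior_weights(),
            "post_model_prob": self.post_model_probs,
            "log_marginal": [s.log_marginal for s in self.per_model],
            "selected": [k == self.selected_index for k in range(len(self.per_model))],
        })

    def plot_curves(self, ax=None):
        """Plot per-model posterior toxicity curves against the target."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        doses = np.arange(1, self.model.ensemble.n_doses + 1)
        for k, s in enumerate(self.per_model):
            style = "-" if k == self.selected_index else "--"
            ax.plot(doses, s.post_probs, style, label=f"M{k + 1}"
                    + (" (selected)" if k == self.selected_index else ""))
        if self.model.target_norm is not None:
            ax.axhline(self.model.target_norm, color="k", lw=0.8, ls=":")
        ax.set_xlabel("dose level")
        ax.set_ylabel("posterior mean toxicity probability")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Functional surface over the Model/Results objects


def posterior_model_probs(ensemble: ModelEnsemble, data: TrialData,
                          quad_order: int = DEFAULT_QUAD_ORDER) -> np.ndarray:
    """P(M_k | D) for every model; proportional to prior weight times marginal."""
    res = RobustQuasiCRM(data, ensemble, quad_order=quad_order).fit(compute_overdose="none")
    return np.asarray(res.post_model_probs)


def bayes_factor(ensemble: ModelEnsemble, data: TrialData, k: int, l: int,
                 quad_order: int = DEFAULT_QUAD_ORDER) -> float:
    """B_kl = L(D|M_k) / L(D|M_l) (model numbers 1-based)."""
    res = RobustQuasiCRM(data, ensemble, quad_order=quad_order).fit(compute_overdose="none")
    return res.bayes_factor(k, l)


def select_model(ensemble: ModelEnsemble, data: TrialData,
                 quad_order: int = DEFAULT_QUAD_ORDER) -> int:
    """1-based number of the highest-posterior model (ties to the lowest)."""
    res = RobustQuasiCRM(data, ensemble, quad_order=quad_order).fit(compute_overdose="none")
    return res.selected_model


def bma_estimate(ensemble: ModelEnsemble, data: TrialData,
                 quad_order: int = DEFAULT_QUAD_ORDER) -> np.ndarray:
    """Model-averaged toxicity curve (secondary estimator; selection is the default)."""
    res = RobustQuasiCRM(data, ensemble, quad_order=quad_order).fit(compute_overdose="none")
    return res.bma_pi
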