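"""Monte-Carlo operating characteristics of dose-finding designs.

Replicates many independent trials against a scenario truth and aggregates
the frequentist summaries used to judge a design: the distribution of the
recommended MTD over doses (plus an explicit early-stop category), the mean
number of patients treated at each dose, and the mean number treated above
the scenario's true MTD (the overdosing burden).  A common-random-number mode
reuses each replicate's latent patient outcomes across designs so that design
contrasts are not blurred by sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import DEFAULT_PRIOR_SD
from .grades import ETScale
from .model import ModelEnsemble
from .scenarios import Scenario, true_mtd
from .trial import DesignConfig, run_trial

__all__ = [
    "DEFAULT_SKELETONS",
    "OperatingCharacteristics",
    "simulate_oc",
    "compare_designs",
    "table2_designs",
    "format_table2",
    "oc_frame",
]

#: Three prior opinions on the dose-toxicity curve, for six doses: a
#: moderate-start fast-rising skeleton, a shallow low-ceiling skeleton, and an
#: evenly spread one.  These are reconstructions satisfying the published
#: prose description (the original numeric values are not recoverable) and
#: can be overridden in any design config.
DEFAULT_SKELETONS: tuple[tuple[float, ...], ...] = (
    (0.11, 0.25, 0.40, 0.55, 0.70, 0.85),
    (0.01, 0.03, 0.07, 0.12, 0.16, 0.20),
    (0.20, 0.35, 0.50, 0.65, 0.80, 0.95),
)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregate of ``n_reps`` simulated trials for one design."""

    label: str
    selection: tuple[float, ...]       #: P(select dose j) over doses, sums with stop_rate to 1
    stop_rate: float                   #: P(early safety stop — no dose selected)
    mean_patients: tuple[float, ...]   #: mean patients treated at each dose
    mean_patients_above_mtd: float     #: mean patients treated above the true MTD
    true_mtd: int
    n_reps: int
    seed: int | None

    @property
    def n_doses(self) -> int:
        return len(self.selection)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose": np.arange(1, self.n_doses + 1),
            "selection_prob": self.selection,
            "mean_patients": self.mean_patients,
        })


def _replicate_uniforms(seed: int | None, n_reps: int, max_n: int) -> np.ndarray:
    """One uniform stream per replicate, spawned from a master seed so results
    are invariant to evaluation order."""
    children = np.random.SeedSequence(seed).spawn(n_reps)
    return np.stack([np.random.default_rng(s).random(max_n) for s in children])


def _aggregate(results, scenario: Scenario, config: DesignConfig,
               label: str, seed) -> OperatingCharacteristics:
    J = config.n_doses
    n_reps = len(results)
    sel = np.zeros(J)
    stops = 0
    patients = np.zeros(J)
    for r in results:
        if r.stopped:
            stops += 1
        else:
            sel[r.selected_dose - 1] += 1
        patients += r.n_per_dose()
    mtd = true_mtd(scenario, config.scale, config.target_et)
    mean_patients = patients / n_reps
    return OperatingCharacteristics(
        label=label or config.label,
        selection=tuple(sel / n_reps),
        stop_rate=stops / n_reps,
        mean_patients=tuple(mean_patients),
        mean_patients_above_mtd=float(mean_patients[mtd:].sum()),
        true_mtd=mtd,
        n_reps=n_reps,
        seed=seed,
    )


def simulate_oc(scenario: Scenario, config: DesignConfig, n_reps: int,
                seed: int | None = None,
                uniforms: np.ndarray | None = None) -> OperatingCharacteristics:
    """Operating characteristics of one design over ``n_reps`` seeded trials."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if uniforms is None:
        uniforms = _replicate_uniforms(seed, n_reps, config.max_n)
    results = [run_trial(scenario, config, uniforms=u) for u in uniforms]
    return _aggregate(results, scenario, config, config.label, seed)


def compare_designs(scenario: Scenario, configs: Sequence[DesignConfig],
                    n_reps: int, seed: int | None = None,
                    common_random_numbers: bool = True,
                    ) -> list[OperatingCharacteristics]:
    """Simulate several designs against one truth.

    With ``common_random_numbers`` every design sees the same per-replicate
    latent outcome stream, so identical designs give identical rows and
    contrasts between designs are sharpened.
    """
    max_n = max(c.max_n for c in configs)
    out = []
    for i, config in enumerate(configs):
        u = _replicate_uniforms(seed if common_random_numbers else
                                (None if seed is None else seed + i),
                                n_reps, max_n)
        out.append(simulate_oc(scenario, config, n_reps,
                               seed=seed, uniforms=u[:, :config.max_n]))
    return out


def table2_designs(skeletons: Sequence[Sequence[float]] = DEFAULT_SKELETONS,
                   prior_sd: float = DEFAULT_PRIOR_SD,
                   **config_kwargs) -> list[DesignConfig]:
    """The four benchmark designs: the K-skeleton robust design plus each
    single-skeleton Quasi-CRM, sharing all other settings."""
    robust = DesignConfig(
        ensemble=ModelEnsemble.from_skeletons(skeletons, prior_sd=prior_sd),
        label="Robust Quasi-CRM", **config_kwargs)
    singles = [
        DesignConfig(
            ensemble=ModelEnsemble.from_skeletons([sk], prior_sd=prior_sd),
            label=f"Quasi-CRM {i}", **config_kwargs)
        for i, sk in enumerate(skeletons, start=1)
    ]
    return singles + [robust]


def oc_frame(blocks: dict[str, tuple[Scenario, Sequence[OperatingCharacteristics]]],
             scale: ETScale = ETScale()) -> pd.DataFrame:
    """Tidy long-format table over scenarios and designs (round-trips via CSV)."""
    rows = []
    for scen_label, (scenario, ocs) in blocks.items():
        et = scenario.et_scores(scale)
        for oc in ocs:
            for j in range(oc.n_doses):
                rows.append({
                    "scenario": scen_label,
                    "design": oc.label,
                    "dose": j + 1,
                    "mean_et": et[j],
                    "is_true_mtd": j + 1 == oc.true_mtd,
                    "selection_prob": oc.selection[j],
                    "mean_patients": oc.mean_patients[j],
                    "stop_rate": oc.stop_rate,
                    "mean_patients_above_mtd": oc.mean_patients_above_mtd,
                    "n_reps": oc.n_reps,
                })
    return pd.DataFrame(rows)


def format_table2(blocks: dict[str, tuple[Scenario, Sequence[OperatingCharacteristics]]],
                  scale: ETScale = ETScale()) -> str:
    """Markdown report mirroring the benchmark layout: per scenario, the ET
    score row, then each design's selection and mean-patient rows with the
    patients-above-MTD column."""
    lines = []
    header_doses = None
    for scen_label, (scenario, ocs) in blocks.items():
        J = scenario.n_doses
        if header_doses != J:
            cols = " | ".join(str(j) for j in range(1, J + 1))
            lines.append(f"| Design | {cols} | patients>MTD |")
            lines.append("|" + "---|" * (J + 2))
            header_doses = J
        lines.append(f"| **Scenario {scen_label}** |" + " |" * (J + 1))
        et = scenario.printed_et_scores(scale)
        lines.append("| (ET score) | " + " | ".join(f"{x:.2f}" for x in et) + " | |")
        for oc in ocs:
            sel = " | ".join(f"{x:.3f}" for x in oc.selection)
            pts = " | ".join(f"{x:.3f}" for x in oc.mean_patients)
            lines.append(f"| {oc.label} | {sel} | |")
            lines.append(f"| # patients | {pts} | {oc.mean_patients_above_mtd:.3f} |")
    return "\n".join(lines) + "\n" if lines else "| Design |\n"
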