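"""Simulation-truth scenarios: per-dose grade distributions and their ET scores.

A *scenario* is the ground truth a simulated trial samples from: for each dose
level, a probability vector over the four pooled grade categories.  Eight
scenarios (A–H) covering six dose levels ship as packaged presets, together
with the severity-weight arithmetic needed to locate each scenario's true MTD
(the dose whose mean ET score is closest to the target).

Two preset accessors exist because the published label sets disagree for
scenarios C–F: :func:`table1_scenario` returns a stored row group verbatim,
while :func:`table2_scenario` returns the truth used by the published
operating-characteristics presets, applying the documented relabelling
``{C↔E, D↔F}`` (the relabelled groups are the ones whose computed ET rows
match the printed per-scenario score rows).  A, B, G and H agree under both.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .grades import GRADE_LABELS, ETScale, _check_probs, mean_et_score

__all__ = [
    "GradeDistribution",
    "Scenario",
    "true_mtd",
    "sample_grade",
    "random_scenario",
    "table1_scenario",
    "table2_scenario",
    "TABLE2_TRUTH_GROUP",
    "SCENARIO_NAMES",
    "load_scenarios",
    "dump_scenarios",
    "scenario_summary",
]

SCENARIO_NAMES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Table-2 preset label -> stored row group providing its simulation truth.
#: The relabelled pairs are documented in docs/methods.md.
TABLE2_TRUTH_GROUP: dict[str, str] = {
    "A": "A", "B": "B", "C": "E", "D": "F", "E": "C", "F": "D", "G": "G", "H": "H",
}


@dataclass(frozen=True)
class GradeDistribution:
    """Probability vector over the four pooled grade categories at one dose.

    ``strict=False`` admits vectors whose entries do not sum to 1, which two
    packaged preset columns require (stored verbatim as published).  Sampling
    always uses the proportionally renormalised probabilities.
    """

    probs: tuple[float, ...]
    strict: bool = True

    def __post_init__(self) -> None:
        p = _check_probs(self.probs, ETScale(), require_normalized=self.strict)
        if p.sum() <= 0:
            raise ValueError("grade probabilities must have positive mass")
        object.__setattr__(self, "probs", tuple(p))

    @property
    def is_normalized(self) -> bool:
        return abs(sum(self.probs) - 1.0) <= 1e-9

    def sampling_probs(self) -> np.ndarray:
        p = np.asarray(self.probs)
        return p / p.sum()


@dataclass(frozen=True)
class Scenario:
    """Ordered per-dose grade distributions defining one simulation truth."""

    name: str
    doses: tuple[GradeDistribution, ...]

    def __post_init__(self) -> None:
        if len(self.doses) < 2:
            raise ValueError("a scenario needs at least two dose levels")
        object.__setattr__(self, "doses", tuple(self.doses))

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def et_scores(self, scale: ETScale = ETScale()) -> np.ndarray:
        """Per-dose mean ET scores under ``scale`` (verbatim probabilities)."""
        return np.array([mean_et_score(d, scale) for d in self.doses])

    def printed_et_scores(self, scale: ETScale = ETScale()) -> list[float]:
        """Per-dose mean ET scores rounded to 2 decimals in exact decimal
        arithmetic (round-half-even), matching tabulated presentation."""
        out = []
        for d in self.doses:
            s = sum(
                Decimal(repr(float(p))) * Decimal(repr(float(w)))
                for p, w in zip(d.probs, scale.weights)
            )
            out.append(float(s.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)))
        return out

    def cumulative_sampling_probs(self) -> np.ndarray:
        """(J, G) row-wise cumulative renormalised probabilities, for
        inverse-CDF grade sampling with one uniform per patient."""
        p = np.stack([d.sampling_probs() for d in self.doses])
        return np.cumsum(p, axis=1)


def true_mtd(scenario: Scenario, scale: ETScale, target_et: float) -> int:
    """Dose (1-based) whose mean ET score is closest to the target.

    Ties go to the lower dose for safety.  Invariant to rescaling the weights
    and the target by a common positive factor.
    """
    dist = np.abs(scenario.et_scores(scale) - target_et)
    return int(np.argmin(dist)) + 1  # argmin takes the first (lowest) minimiser


def sample_grade(dist: GradeDistribution, rng: np.random.Generator) -> int:
    """Draw one grade-category index (0-based) from ``dist``, renormalised."""
    u = rng.random()
    cum = np.cumsum(dist.sampling_probs())
    return int(min(np.searchsorted(cum, u, side="right"), len(cum) - 1))


def random_scenario(J: int, rng: np.random.Generator,
                    scale: ETScale = ETScale()) -> Scenario:
    """Random scenario with strictly increasing mean ET score across doses.

    A property-test generator: draws Dirichlet grade mixes per dose and sorts
    them by mean ET score, re-drawing on ties.  Not a model of any real agent.
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    for _ in range(100):
        probs = rng.dirichlet(np.ones(len(scale.weights)), size=J)
        scores = probs @ np.asarray(scale.weights)
        order = np.argsort(scores, kind="stable")
        if np.all(np.diff(scores[order]) > 1e-6):
            doses = tuple(GradeDistribution(tuple(probs[i])) for i in order)
            return Scenario(name="random", doses=doses)
    raise RuntimeError("failed to draw a scenario with distinct dose scores")


# ---------------------------------------------------------------------------
# Packaged presets and plain-text (YAML) round-tripping

def _as_scenario(name: str, table: dict, strict: bool = True) -> Scenario:
    rows = [table[g] for g in GRADE_LABELS]
    cols = np.asarray(rows, dtype=float).T
    doses = []
    for j, col in enumerate(cols):
        strict_col = strict and abs(col.sum() - 1.0) <= 1e-9
        doses.append(GradeDistribution(tuple(col), strict=strict_col))
    return Scenario(name=name, doses=tuple(doses))


def load_scenarios(source) -> dict[str, Scenario]:
    """Load scenarios from a YAML file path, file object, or string.

    Format: one mapping per scenario; keys are the grade labels ``0-1, 2, 3,
    4``; values are per-dose probability lists (columns = doses).
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" in text or ":" in text.splitlines()[0]:
            raw = yaml.safe_load(io.StringIO(text))
        else:
            with open(text) as fh:
                raw = yaml.safe_load(fh)
    out = {}
    for name, table in raw.items():
        missing = [g for g in GRADE_LABELS if g not in table]
        if missing:
            raise ValueError(f"scenario {name!r}: missing grade rows {missing}")
        out[str(name)] = _as_scenario(str(name), table)
    return out


def dump_scenarios(scenarios: dict[str, Scenario] | Sequence[Scenario], path=None) -> str:
    """Serialise scenarios to the YAML table format (round-trips exactly)."""
    if not isinstance(scenarios, dict):
        scenarios = {s.name: s for s in scenarios}
    doc = {}
    for name, sc in scenarios.items():
        mat = np.array([d.probs for d in sc.doses]).T
        doc[name] = {g: [float(x) for x in row] for g, row in zip(GRADE_LABELS, mat)}
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _packaged_scenarios() -> dict[str, Scenario]:
    text = resources.files("quasicrm.presets").joinpath("table1_scenarios.yaml").read_text()
    return load_scenarios(text)


def table1_scenario(name: str) -> Scenario:
    """Stored row group ``name`` (A–H), probabilities verbatim."""
    table = _packaged_scenarios()
    if name not in table:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(table)}")
    return table[name]


def table2_scenario(name: str) -> Scenario:
    """Simulation truth for operating-characteristics preset ``name`` (A–H).

    Applies the documented C↔E / D↔F relabelling, returning the row group
    whose computed ET scores match the preset's published score row.
    """
    if name not in TABLE2_TRUTH_GROUP:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(TABLE2_TRUTH_GROUP)}")
    group = TABLE2_TRUTH_GROUP[name]
    sc = table1_scenario(group)
    return Scenario(name=name, doses=sc.doses)


def scenario_summary(scenario: Scenario, scale: ETScale = ETScale()) -> pd.DataFrame:
    """Tidy per-dose summary: grade probabilities, mean ET, normalised ET."""
    rows = []
    for j, d in enumerate(scenario.doses, start=1):
        et = mean_et_score(d, scale)
        row = {"dose": j}
        row.update({f"p_grade_{g}": p for g, p in zip(GRADE_LABELS, d.probs)})
        row["mean_et"] = et
        row["mean_et_normalized"] = et / scale.s_max
        rows.append(row)
    return pd.DataFrame(rows)
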