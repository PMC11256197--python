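"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator is the inverse of the analysis model. Each mouse carries one
latent radiation tolerance per assay, z = dose + eps with
eps ~ Logistic(0, b); the maximal grade it reaches is the highest grade g
whose TD50 its latent exceeds. This guarantees

* P(max grade >= g) = 1 / (1 + exp(-(dose - TD50_g)/b)) exactly — the
  logistic dose-response the pipeline fits — and
* grade nesting by construction (a responder at a severe grade responds at
  every milder grade), the structure implied by reducing longitudinal
  scores to a maximum.

Longitudinal trajectories are qualitative stand-ins constrained by the
published timing facts (acute onset around day 12, peak around days 14-17,
dose-dependent time at score; stepwise irreversible fibrosis progression)
whose one hard contract is that the trajectory maximum equals the assigned
maximal grade exactly. Alanine QA readings are drawn near 97% of the
planned dose with a few percent spread, optionally contaminated with gross
errors to exercise the 15% exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import datasets
from .toxicity import ToxicityRecord

__all__ = ["GeneratorConfig", "SyntheticCohort", "simulate_max_grades",
           "simulate_trajectories", "simulate_alanine", "simulate_exclusion_flags",
           "simulate_cohort"]

ACUTE_DAYS = tuple(range(8, 29))  # daily scoring, days 8-28
FIBROSIS_WEEKS = tuple(range(9, 31, 2))  # biweekly scoring, weeks 9-29


def _default_design() -> list[tuple[str, float, int]]:
    return [
        (arm, dose, n_skin)
        for arm, groups in datasets.COHORT_DESIGN.items()
        for dose, n_skin, _ in groups
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the reference experiment: the per-arm dose-group
    design (140 analyzed mice), the grade-wise acute and fibrosis TD50s,
    a shared logistic scale b = 3 Gy, acute onset ~ Normal(12, 1) days
    truncated to [9, 14] with peak damage reached within days 14-17, and
    alanine readings at 97.4% (SD 2.4%) of plan.
    """

    design: list[tuple[str, float, int]] = field(default_factory=_default_design)
    acute_td50s: dict[str, dict[float, float]] = field(
        default_factory=lambda: {a: dict(g) for a, g in datasets.TD50_ACUTE_SOBP.items()}
    )
    fibrosis_td50s: dict[str, dict[float, float]] = field(
        default_factory=lambda: {a: dict(g) for a, g in datasets.TD50_FIBROSIS_SOBP.items()}
    )
    slope_b: float = 3.0
    onset_day_mean: float = 12.0
    onset_day_sd: float = 1.0
    onset_day_bounds: tuple[float, float] = (9.0, 14.0)
    peak_window: tuple[int, int] = (14, 17)
    alanine_mean_rel: float = datasets.ALANINE_MEAN_REL
    alanine_sd_rel: float = datasets.ALANINE_SD_REL
    alanine_contamination_rate: float = 0.0
    #: dose-dependent Bernoulli probability of a necrosis exclusion before a
    #: fibrotic score is reached: logistic in dose with (td50, scale); the
    #: default rate of 0 keeps group counts equal to the design.
    necrosis_td50: float | None = None
    necrosis_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be > 0")
        if not 0.0 <= self.alanine_contamination_rate <= 1.0:
            raise ValueError("contamination rate must be in [0, 1]")
        for name, td50s in (("acute", self.acute_td50s), ("fibrosis", self.fibrosis_td50s)):
            for arm, mapping in td50s.items():
                grades = sorted(mapping)
                vals = [mapping[g] for g in grades]
                if any(b <= a for a, b in zip(vals, vals[1:])):
                    raise ValueError(
                        f"{name} TD50s for {arm} must be strictly increasing in grade"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acute_td50s"] = {a: {f"{g:g}": v for g, v in m.items()} for a, m in self.acute_td50s.items()}
        d["fibrosis_td50s"] = {a: {f"{g:g}": v for g, v in m.items()} for a, m in self.fibrosis_td50s.items()}
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort: toxicity records, alanine readings, and the truth."""

    records: list[ToxicityRecord]
    alanine: pd.DataFrame  # mouse_id, arm, planned_dose, measured_rel_dose
    truth: GeneratorConfig
    flags: list[tuple[str, str, str]] = field(default_factory=list)  # (mouse_id, rule, stage)

    def acute_records(self) -> list[ToxicityRecord]:
        return [r for r in self.records if r.assay == "acute"]

    def fibrosis_records(self) -> list[ToxicityRecord]:
        return [r for r in self.records if r.assay == "fibrosis"]


def _mouse_table(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for arm, dose, n in config.design:
        for _ in range(int(n)):
            rows.append((f"M{i:04d}", arm, float(dose)))
            i += 1
    return pd.DataFrame(rows, columns=["mouse_id", "arm", "dose"])


def _assign_max(dose: np.ndarray, eps: np.ndarray, td50s: dict[float, float]) -> np.ndarray:
    """Highest grade whose TD50 the latent tolerance z = dose + eps reaches."""
    z = dose + eps
    out = np.zeros_like(dose)
    for g in sorted(td50s):  # increasing TD50 with grade
        out = np.where(z >= td50s[g], g, out)
    return out


def simulate_max_grades(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-mouse maximal acute and fibrosis grades from the latent model.

    Returns a frame with columns mouse_id, arm, dose, acute_max,
    fibrosis_max. Acute and fibrosis latents are independent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mice = _mouse_table(config)
    dose = mice["dose"].to_numpy()
    out = mice.copy()
    for col, td50s in (("acute_max", config.acute_td50s), ("fibrosis_max", config.fibrosis_td50s)):
        eps = rng.logistic(0.0, config.slope_b, size=len(mice))
        vals = np.empty(len(mice))
        for arm in ("CONV", "FLASH"):
            m = (mice["arm"] == arm).to_numpy()
            vals[m] = _assign_max(dose[m], eps[m], td50s[arm])
        out[col] = vals
    return out


def _acute_trajectory(max_g: float, dose: float, rng: np.random.Generator,
                      config: GeneratorConfig) -> tuple[tuple[float, float], ...]:
    days = ACUTE_DAYS
    if max_g == 0:
        return tuple((float(d), 0.0) for d in days)
    lo, hi = config.onset_day_bounds
    onset = rng.normal(config.onset_day_mean, config.onset_day_sd)
    onset = int(round(min(max(onset, lo), hi)))
    n_steps = int(round((max_g - 1.5) / 0.5))  # days from first score to max
    # dose-dependent time spent at the maximal score
    plateau = max(1, int(round(dose / 10.0)))
    onset = min(onset, days[-1] - n_steps)  # the max must be reached in-window
    grades = []
    for d in days:
        if d < onset:
            g = 0.0
        elif d <= onset + n_steps:  # rise in 0.5 steps
            g = 1.5 + 0.5 * (d - onset)
        elif d <= onset + n_steps + plateau:  # hold at max
            g = max_g
        else:  # decline in 0.5 steps; below 1.5 means healed
            g = max_g - 0.5 * (d - (onset + n_steps + plateau))
            g = g if g >= 1.5 else 0.0
        grades.append((float(d), float(g)))
    return tuple(grades)


def _fibrosis_trajectory(max_g: float, rng: np.random.Generator) -> tuple[tuple[float, float], ...]:
    weeks = FIBROSIS_WEEKS
    if max_g == 0:
        return tuple((float(w), 0.0) for w in weeks)
    n_steps = int(max_g) - 2  # visits from grade 2 up to max (one grade per visit)
    onset = float(rng.choice([13, 15, 17]))
    onset = min(onset, weeks[-1] - 2 * n_steps)  # reach the max in-window
    grades = []
    for w in weeks:
        if w < onset:
            g = 0.0
        else:
            g = min(2.0 + (w - onset) // 2, max_g)  # irreversible progression
        grades.append((float(w), float(g)))
    return tuple(grades)


def simulate_trajectories(
    max_grades: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[ToxicityRecord]:
    """Expand assigned maximal grades into longitudinal score records.

    Produces one acute and one fibrosis record per mouse. The maximum over
    each trajectory equals the assigned maximal grade exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    records: list[ToxicityRecord] = []
    for row in max_grades.itertuples(index=False):
        records.append(
            ToxicityRecord(
                mouse_id=row.mouse_id, arm=row.arm, dose=row.dose, assay="acute",
                observations=_acute_trajectory(row.acute_max, row.dose, rng, config),
            )
        )
        records.append(
            ToxicityRecord(
                mouse_id=row.mouse_id, arm=row.arm, dose=row.dose, assay="fibrosis",
                observations=_fibrosis_trajectory(row.fibrosis_max, rng),
            )
        )
    return records


def simulate_alanine(
    mice: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw alanine QA readings relative to the planned dose.

    Readings are Normal(mean_rel, sd_rel) per mouse; with probability
    ``alanine_contamination_rate`` a reading is replaced by a gross error
    uniform in [0.5, 0.84], which fails the 15% deviation rule.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(mice)
    rel = rng.normal(config.alanine_mean_rel, config.alanine_sd_rel, size=n)
    if config.alanine_contamination_rate > 0:
        bad = rng.random(n) < config.alanine_contamination_rate
        rel = np.where(bad, rng.uniform(0.5, 0.84, size=n), rel)
    out = mice[["mouse_id", "arm", "dose"]].copy()
    out = out.rename(columns={"dose": "planned_dose"})
    out["measured_rel_dose"] = rel
    return out


def simulate_exclusion_flags(
    mice: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[tuple[str, str, str]]:
    """Draw necrosis exclusion flags (stage pre_fibrosis), logistic in dose.

    Models mice whose leg becomes necrotic before a fibrotic score can be
    reached. Disabled (no flags) unless ``necrosis_td50`` is set.
    """
    if config.necrosis_td50 is None:
        return []
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    dose = mice["dose"].to_numpy()
    p = 1.0 / (1.0 + np.exp(-(dose - config.necrosis_td50) / config.necrosis_scale))
    hit = rng.random(len(mice)) < p
    return [
        (mid, "necrosis", "pre_fibrosis")
        for mid, h in zip(mice["mouse_id"], hit) if h
    ]


def simulate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort: max grades, trajectories, and alanine QA.

    Identical (config, seed) pairs give bit-identical cohorts.
    """
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    maxg = simulate_max_grades(config, rng)
    records = simulate_trajectories(maxg, config, rng)
    alanine = simulate_alanine(maxg, config, rng)
    flags = simulate_exclusion_flags(maxg, config, rng)
    return SyntheticCohort(records=records, alanine=alanine, truth=config, flags=flags)
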