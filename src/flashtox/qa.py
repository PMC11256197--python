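"""Dosimetric QA corrections and predefined exclusion filtering.

Alanine pellets read against a Co-60 calibration need a beam-quality
correction kQ in the proton SOBP; the corrected reading relative to the
planned dose is a gross-error catch: a mouse whose delivered dose deviates
by more than 15% from plan is excluded. Further predefined exclusion rules
(weight loss, off-target damage, technical error) apply before the acute
analysis; necrotic development before a fibrotic score adds exclusions
before the late analysis, so the fibrosis analysis set is always a subset
of the acute one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import datasets
from .toxicity import ToxicityRecord

__all__ = ["AlanineRecord", "ExclusionEntry", "ExclusionLog", "correct_alanine",
           "apply_exclusions", "EXCLUSION_RULES", "STAGES"]

EXCLUSION_RULES = ("weight_loss", "off_target", "necrosis", "alanine_deviation", "technical")
STAGES = ("pre_acute", "pre_fibrosis")

#: Rule precedence when several rules hit the same mouse at one stage.
_RULE_ORDER = ("technical", "weight_loss", "off_target", "necrosis", "alanine_deviation")


@dataclass(frozen=True)
class AlanineRecord:
    """One corrected alanine reading: raw x kQ relative to the planned dose."""

    mouse_id: str
    raw_dose: float  # Gy, Co-60-referenced readout
    kq: float
    planned_dose: float  # Gy
    corrected_rel: float

    def __post_init__(self) -> None:
        if self.kq <= 0:
            raise ValueError("kq must be > 0")
        if self.planned_dose <= 0:
            raise ValueError("planned_dose must be > 0")


@dataclass(frozen=True)
class ExclusionEntry:
    mouse_id: str
    rule: str
    stage: str

    def __post_init__(self) -> None:
        if self.rule not in EXCLUSION_RULES:
            raise ValueError(f"unknown exclusion rule {self.rule!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown exclusion stage {self.stage!r}")


@dataclass
class ExclusionLog:
    """Per-stage record of excluded mice; at most one primary rule per mouse/stage."""

    entries: list[ExclusionEntry] = field(default_factory=list)

    def excluded_ids(self, stage: str | None = None) -> set[str]:
        return {e.mouse_id for e in self.entries if stage is None or e.stage == stage}

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {s: {} for s in STAGES}
        for e in self.entries:
            out[e.stage][e.rule] = out[e.stage].get(e.rule, 0) + 1
        return out

    def to_dicts(self) -> list[dict]:
        return [{"mouse_id": e.mouse_id, "rule": e.rule, "stage": e.stage} for e in self.entries]


def correct_alanine(
    raw_dose: float,
    kq: float = datasets.ALANINE_KQ,
    planned_dose: float = 1.0,
    mouse_id: str = "",
) -> AlanineRecord:
    """Apply the beam-quality correction and normalize to the planned dose."""
    if raw_dose < 0:
        raise ValueError("raw_dose must be >= 0")
    if planned_dose <= 0:
        raise ValueError("planned_dose must be > 0")
    return AlanineRecord(
        mouse_id=mouse_id, raw_dose=raw_dose, kq=kq, planned_dose=planned_dose,
        corrected_rel=raw_dose * kq / planned_dose,
    )


def apply_exclusions(
    records: Iterable[ToxicityRecord],
    alanine: Mapping[str, float] | Sequence[AlanineRecord] | None = None,
    flags: Iterable[tuple[str, str, str]] = (),
    threshold_rel: float = datasets.ALANINE_EXCLUSION_THRESHOLD,
    stage: str = "pre_acute",
) -> tuple[list[ToxicityRecord], ExclusionLog]:
    """Drop mice failing the predefined exclusion criteria at one stage.

    ``alanine`` maps mouse_id to the corrected relative dose (or is a list
    of :class:`AlanineRecord`); a mouse is excluded on the alanine rule iff
    |corrected_rel - 1| > threshold_rel (strict — a deviation of exactly
    15% is retained). ``flags`` are externally supplied (mouse_id, rule,
    stage) triples; only those matching ``stage`` apply. A missing alanine
    record is a warning, not an exclusion. Idempotent: re-filtering a
    filtered set excludes nothing new.

    At stage ``pre_fibrosis`` the alanine rule is not re-applied (those
    mice are already gone); only the stage's flags (necrosis) act.
    """
    if threshold_rel <= 0:
        raise ValueError("threshold_rel must be > 0")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    records = list(records)
    mouse_ids = {r.mouse_id for r in records}

    rel: dict[str, float] = {}
    if alanine is not None:
        if isinstance(alanine, Mapping):
            rel = dict(alanine)
        else:
            rel = {a.mouse_id: a.corrected_rel for a in alanine}

    # collect candidate rules per mouse, then keep the highest-precedence one
    candidates: dict[str, list[str]] = {}
    for mid, rule, flag_stage in flags:
        if flag_stage != stage or mid not in mouse_ids:
            continue
        candidates.setdefault(mid, []).append(rule)
    if stage == "pre_acute":
        for mid in sorted(mouse_ids):
            if mid not in rel:
                if alanine is not None:
                    warnings.warn(f"no alanine record for mouse {mid}; retained", stacklevel=2)
                continue
            # strict inequality at the boundary, robust to float representation
            if abs(rel[mid] - 1.0) > threshold_rel + 1e-12:
                candidates.setdefault(mid, []).append("alanine_deviation")

    log = ExclusionLog()
    for mid in sorted(candidates):
        rule = min(candidates[mid], key=_RULE_ORDER.index)
        log.entries.append(ExclusionEntry(mouse_id=mid, rule=rule, stage=stage))

    dropped = log.excluded_ids()
    kept = [r for r in records if r.mouse_id not in dropped]
    return kept, log
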