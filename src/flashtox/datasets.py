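"""Reference design and dose-response values for a murine SOBP FLASH experiment.

The constants here describe a preclinical hindleg-irradiation experiment that
compared ultra-high dose-rate (FLASH, ~60 Gy/s field rate) with conventional
dose-rate (CONV, ~0.35 Gy/s) proton delivery inside a spread-out Bragg peak,
scoring acute skin toxicity (grades 1.5-3.5) and late fibrosis (grades 2-4).
They serve two purposes:

* default study conditions for :mod:`flashtox.simulate` (cohort design,
  per-grade TD50s, timing of toxicity onset, alanine QA statistics), and
* reference TD50 tables for dose-modifying-factor (DMF) arithmetic and
  cross-study TD50 comparisons.

All doses are in Gy.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Cohort design: (dose Gy, n skin-toxicity assay, n fibrosis assay) per arm.
# Totals: FLASH 73/72, CONV 67/65 mice (140 skin / 137 fibrosis analyzed,
# out of 145 allocated; see EXCLUSION_COUNTS below).
# --------------------------------------------------------------------------

COHORT_DESIGN: dict[str, list[tuple[float, int, int]]] = {
    "FLASH": [
        (30.4, 7, 7),
        (35.5, 7, 7),
        (40.5, 8, 8),
        (43.1, 8, 8),
        (45.6, 8, 8),
        (48.1, 8, 8),
        (50.7, 8, 8),
        (55.7, 7, 7),
        (60.8, 7, 7),
        (65.9, 5, 4),
    ],
    "CONV": [
        (19.9, 7, 7),
        (24.9, 8, 8),
        (29.8, 8, 8),
        (32.3, 7, 7),
        (34.8, 8, 8),
        (37.3, 8, 8),
        (39.8, 8, 6),
        (44.8, 8, 8),
        (49.7, 5, 5),
    ],
}

#: Mice allocated across the four consecutive experiments.
N_ALLOCATED = 145

#: Exclusions applied before the acute analysis (stage "pre_acute") and the
#: additional exclusions before the fibrosis analysis (stage "pre_fibrosis").
EXCLUSION_COUNTS = {
    "pre_acute": {"technical": 1, "off_target": 2, "alanine_deviation": 2},
    "pre_fibrosis": {"necrosis": 3},
}

# --------------------------------------------------------------------------
# Reference TD50 estimates (Gy) by toxicity grade.
#
# "sobp" rows are from the SOBP experiment itself; "entrance" rows are the
# companion entrance-plateau experiment used for the cross-study comparison
# of acute skin response.
# --------------------------------------------------------------------------

ACUTE_GRADES = (1.5, 2.0, 2.5, 3.0, 3.5)
FIBROSIS_GRADES = (2.0, 3.0, 4.0)

TD50_ACUTE_SOBP: dict[str, dict[float, float]] = {
    "CONV": {1.5: 27.1, 2.0: 28.0, 2.5: 31.4, 3.0: 34.1, 3.5: 38.4},
    "FLASH": {1.5: 38.4, 2.0: 40.7, 2.5: 44.0, 3.0: 46.6, 3.5: 51.8},
}

TD50_ACUTE_ENTRANCE: dict[str, dict[float, float]] = {
    "CONV": {1.5: 24.7, 2.0: 28.1, 2.5: 30.0, 3.0: 32.4, 3.5: 34.8},
    "FLASH": {1.5: 39.1, 2.0: 40.9, 2.5: 43.2, 3.0: 47.4, 3.5: 52.2},
}

TD50_FIBROSIS_SOBP: dict[str, dict[float, float]] = {
    "CONV": {2.0: 43.6, 3.0: 47.5, 4.0: 49.0},
    "FLASH": {2.0: 51.1, 3.0: 55.9, 4.0: 57.7},
}

# --------------------------------------------------------------------------
# Delivery and dosimetry constants.
# --------------------------------------------------------------------------

#: PBS spot grid: 5 x 7 spots, 6 mm spacing, rim spots 40% heavier.
FIELD_ROWS = 5
FIELD_COLS = 7
SPOT_SPACING_MM = 6.0
RIM_FACTOR = 1.4

#: Lateral Gaussian spot spread at the SOBP treatment depth (mm).
SPOT_SIGMA_MM = 8.0

#: Field dose rates (Gy/s): FLASH single-paint target and CONV repainted target.
FLASH_FIELD_DOSE_RATE = 60.0
CONV_FIELD_DOSE_RATE = 0.35

#: CONV repainting: 144-360 repaints depending on dose, 4.4 ms mean pauses.
CONV_REPAINT_DOSE_RANGE = (19.9, 49.7)
CONV_REPAINT_RANGE = (144, 360)
CONV_MEAN_PAUSE_S = 0.0044

#: Alanine beam-quality correction (Co-60-referenced readout in the proton SOBP).
ALANINE_KQ = 1.032
ALANINE_KQ_UNC = 0.021

#: Relative-dose deviation beyond which a mouse is excluded as a gross error.
ALANINE_EXCLUSION_THRESHOLD = 0.15

#: Observed alanine dose relative to plan: ~97.1% (SD 2.1%) CONV,
#: ~97.7% (SD 2.7%) FLASH; a single pooled default is used by the generator.
ALANINE_MEAN_REL = 0.974
ALANINE_SD_REL = 0.024


def cohort_totals() -> dict[str, dict[str, int]]:
    """Per-arm totals of the analyzed cohort, by assay."""
    return {
        arm: {
            "skin": sum(n_skin for _, n_skin, _ in groups),
            "fibrosis": sum(n_fib for _, _, n_fib in groups),
        }
        for arm, groups in COHORT_DESIGN.items()
    }
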