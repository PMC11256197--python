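"""Graded-toxicity dose-response analysis: TD50s and dose-modifying factors.

The pipeline follows the standard preclinical normal-tissue workflow:

1. Longitudinal toxicity scores per mouse are reduced to the maximal grade
   reached over the assay window.
2. For each grade of interest, each mouse becomes a binomial observation —
   did it ever reach that grade — aggregated into responder counts per
   (arm, dose) group. Responder sets are nested across grades by
   construction.
3. A two-parameter logistic dose-response P(d) = 1 / (1 + exp(-(d - TD50)/b))
   is fitted per arm and grade by binomial maximum likelihood (a GLM with
   logit link in the (beta0, beta1) parameterization; TD50 = -beta0/beta1,
   b = 1/beta1).
4. The FLASH tissue-sparing effect is the dose-modifying factor
   DMF = TD50_FLASH / TD50_CONV per grade, with a 95% CI; grade-wise DMFs
   are summarized by their mean and (min, max) range.

TD50 confidence intervals use the delta method on -beta0/beta1 by default,
with a profile-likelihood alternative; DMF CIs use the delta method on the
log ratio (arms independent) or a seeded parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import ACUTE_GRADES, FIBROSIS_GRADES

__all__ = [
    "ToxicityRecord",
    "ResponderTable",
    "DoseResponseFit",
    "DMFEstimate",
    "InsufficientDataError",
    "NotEstimableError",
    "max_grade",
    "to_responders",
    "fit_logistic",
    "fit_from_td50",
    "dmf",
    "mean_dmf",
    "td50_ratio_across_studies",
    "build_report",
]

_GRADE_SETS = {"acute": ACUTE_GRADES, "fibrosis": FIBROSIS_GRADES}

_Z95 = 1.959963984540054


class InsufficientDataError(ValueError):
    """Fewer than two dose levels (or no informative groups) for a fit."""


class NotEstimableError(RuntimeError):
    """A downstream quantity could not be estimated (e.g. non-converged fit)."""


@dataclass
class ToxicityRecord:
    """Longitudinal graded scores for one mouse in one assay.

    ``observations`` holds (time, grade) pairs — time in days for the acute
    skin assay (window days 8-28), weeks for the fibrosis leg-extension
    assay (window weeks 9-30). Grade 0 means no observable damage.
    """

    mouse_id: str
    arm: str  # "CONV" | "FLASH"
    dose: float  # planned dose, Gy
    assay: str  # "acute" | "fibrosis"
    observations: tuple[tuple[float, float], ...]
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("CONV", "FLASH"):
            raise ValueError(f"arm must be CONV or FLASH, got {self.arm!r}")
        if self.assay not in _GRADE_SETS:
            raise ValueError(f"assay must be acute or fibrosis, got {self.assay!r}")
        allowed = set(_GRADE_SETS[self.assay]) | {0.0}
        for _, g in self.observations:
            if float(g) not in allowed:
                raise ValueError(f"grade {g} not valid for {self.assay} assay")


@dataclass
class ResponderTable:
    """Per-(arm, dose) binomial responder counts at one grade."""

    assay: str
    grade: float
    table: pd.DataFrame  # columns: arm, dose, n, responders

    def for_arm(self, arm: str) -> pd.DataFrame:
        return self.table[self.table["arm"] == arm].reset_index(drop=True)


@dataclass
class DoseResponseFit:
    """A fitted two-parameter logistic dose-response curve.

    ``slope`` is the logistic scale parameter b (Gy); smaller b means a
    steeper curve. ``cov`` is the covariance of (td50, slope); it is None
    for fits constructed directly from a reference TD50.
    """

    arm: str
    grade: float
    td50: float
    slope: float
    cov: np.ndarray | None = None
    td50_ci95: tuple[float, float] | None = None
    n_total: int = 0
    converged: bool = True
    ci_method: str = "delta"

    @property
    def td50_se(self) -> float | None:
        if self.cov is None:
            return None
        return float(np.sqrt(self.cov[0, 0]))

    def predict(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return 1.0 / (1.0 + np.exp(-(d - self.td50) / self.slope))

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "grade": self.grade,
            "td50": self.td50,
            "slope": self.slope,
            "td50_se": self.td50_se,
            "td50_ci95": list(self.td50_ci95) if self.td50_ci95 else None,
            "n_total": self.n_total,
            "converged": self.converged,
            "ci_method": self.ci_method,
        }


@dataclass
class DMFEstimate:
    """Dose-modifying factor: TD50_FLASH / TD50_CONV at one grade."""

    grade: float
    td50_conv: float
    td50_flash: float
    dmf: float
    ci95: tuple[float, float] | None = None
    method: str = "delta_log_ratio"
    estimable: bool = True

    def to_dict(self) -> dict:
        return {
            "grade": self.grade,
            "td50_conv": self.td50_conv,
            "td50_flash": self.td50_flash,
            "dmf": self.dmf,
            "ci95": list(self.ci95) if self.ci95 else None,
            "method": self.method,
            "estimable": self.estimable,
        }


# --------------------------------------------------------------------------
# Score reduction and binomial conversion
# --------------------------------------------------------------------------


def max_grade(record: ToxicityRecord) -> float:
    """Maximal grade reached over the assay window (0 if never graded)."""
    if not record.observations:
        raise ValueError(f"mouse {record.mouse_id}: no observations")
    return float(max(g for _, g in record.observations))


def to_responders(records: Iterable[ToxicityRecord], grade: float) -> ResponderTable:
    """Convert per-mouse score histories to binomial responder counts.

    A mouse is a responder at ``grade`` iff its maximal grade reached at
    least ``grade`` at least once. Excluded records are dropped (a count is
    emitted as a warning when any are).
    """
    records = list(records)
    if not records:
        raise ValueError("no records given")
    assays = {r.assay for r in records}
    if len(assays) != 1:
        raise ValueError(f"records mix assays: {sorted(assays)}")
    assay = assays.pop()
    if float(grade) not in _GRADE_SETS[assay]:
        raise ValueError(f"grade {grade} is not a scored {assay} grade")

    kept = [r for r in records if not r.excluded]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} excluded record(s)", stacklevel=2)

    rows: dict[tuple[str, float], list[int]] = {}
    for r in kept:
        key = (r.arm, r.dose)
        n, resp = rows.setdefault(key, [0, 0])
        rows[key][0] = n + 1
        rows[key][1] = resp + (1 if max_grade(r) >= grade else 0)
    table = pd.DataFrame(
        [(arm, dose, n, resp) for (arm, dose), (n, resp) in sorted(rows.items())],
        columns=["arm", "dose", "n", "responders"],
    )
    return ResponderTable(assay=assay, grade=float(grade), table=table)


# --------------------------------------------------------------------------
# Logistic dose-response fit
# --------------------------------------------------------------------------


def _neg_loglik(beta: np.ndarray, dose: np.ndarray, n: np.ndarray, resp: np.ndarray) -> float:
    eta = beta[0] + beta[1] * dose
    # log(1+e^eta) computed stably
    log1pexp = np.logaddexp(0.0, eta)
    return float(-(resp * eta - n * log1pexp).sum())


def fit_logistic(
    table: ResponderTable,
    arm: str,
    ci: str = "delta",
) -> DoseResponseFit:
    """Binomial ML fit of the two-parameter logistic dose-response curve.

    Fits in the (beta0, beta1) GLM parameterization and transforms to
    (TD50, b) = (-beta0/beta1, 1/beta1); the covariance is propagated with
    the delta method. ``ci`` selects the TD50 interval construction:
    ``"delta"`` (Wald on -beta0/beta1) or ``"profile"`` (likelihood ratio).

    Complete separation is reported via ``converged=False`` rather than an
    exception; fewer than two dose levels raises
    :class:`InsufficientDataError`.
    """
    import statsmodels.api as sm

    sub = table.for_arm(arm)
    if sub["dose"].nunique() < 2:
        raise InsufficientDataError(f"{arm}: need >= 2 dose levels, got {sub['dose'].nunique()}")
    dose = sub["dose"].to_numpy(float)
    n = sub["n"].to_numpy(float)
    resp = sub["responders"].to_numpy(float)
    n_total = int(n.sum())

    if resp.sum() == 0 or (n - resp).sum() == 0:
        # no information about the curve location inside the dose range
        return DoseResponseFit(
            arm=arm, grade=table.grade, td50=np.nan, slope=np.nan,
            n_total=n_total, converged=False, ci_method=ci,
        )

    # complete separation: every group all-or-none, with the all-none doses
    # strictly below the all-responder doses; the MLE slope is infinitely
    # steep and the likelihood has no interior maximum
    partial = (resp > 0) & (resp < n)
    if not partial.any():
        d_zero = dose[resp == 0]
        d_full = dose[resp == n]
        if d_zero.size and d_full.size and d_zero.max() < d_full.min():
            return DoseResponseFit(
                arm=arm, grade=table.grade,
                td50=float((d_zero.max() + d_full.min()) / 2.0), slope=0.0,
                n_total=n_total, converged=False, ci_method=ci,
            )

    X = np.column_stack([np.ones_like(dose), dose])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(np.column_stack([resp, n - resp]), X,
                     family=sm.families.Binomial()).fit(maxiter=200)
    b0, b1 = res.params
    cov_beta = np.asarray(res.cov_params())

    separated = (
        not np.all(np.isfinite(res.bse))
        or abs(b1) > 1e4
        or np.sqrt(cov_beta[1, 1]) > 1e4
    )
    if separated or b1 <= 0:
        return DoseResponseFit(
            arm=arm, grade=table.grade, td50=float(-b0 / b1) if b1 != 0 else np.nan,
            slope=np.inf if b1 <= 0 else float(1.0 / b1),
            n_total=n_total, converged=False, ci_method=ci,
        )

    td50 = float(-b0 / b1)
    slope = float(1.0 / b1)
    # delta method: (td50, b) = g(beta); J = dg/dbeta
    J = np.array([[-1.0 / b1, b0 / b1**2], [0.0, -1.0 / b1**2]])
    cov = J @ cov_beta @ J.T

    if ci == "delta":
        se = float(np.sqrt(cov[0, 0]))
        ci95 = (td50 - _Z95 * se, td50 + _Z95 * se)
    elif ci == "profile":
        ci95 = _profile_ci_td50(dose, n, resp, td50, slope)
    else:
        raise ValueError(f"unknown ci method {ci!r}")

    return DoseResponseFit(
        arm=arm, grade=table.grade, td50=td50, slope=slope, cov=cov,
        td50_ci95=ci95, n_total=n_total, converged=True, ci_method=ci,
    )


def _profile_ci_td50(
    dose: np.ndarray, n: np.ndarray, resp: np.ndarray, td50_hat: float, b_hat: float
) -> tuple[float, float]:
    """95% profile-likelihood interval for TD50 (slope profiled out)."""
    crit = stats.chi2.ppf(0.95, df=1)

    def nll_at(td50: float) -> float:
        def f(logb: float) -> float:
            b = np.exp(logb)
            return _neg_loglik(np.array([-td50 / b, 1.0 / b]), dose, n, resp)

        r = optimize.minimize_scalar(f, bracket=(np.log(b_hat) - 1, np.log(b_hat) + 1))
        return float(r.fun)

    nll_hat = nll_at(td50_hat)

    def deviance(td50: float) -> float:
        return 2.0 * (nll_at(td50) - nll_hat) - crit

    span = max(5.0 * b_hat, 0.5 * td50_hat)
    lo = _bracketed_root(deviance, td50_hat, td50_hat - span, increasing=False)
    hi = _bracketed_root(deviance, td50_hat, td50_hat + span, increasing=True)
    return (lo, hi)


def _bracketed_root(f, x_inner: float, x_outer: float, increasing: bool) -> float:
    """Root of f between x_inner (f<0) and x_outer, expanding if needed."""
    step = x_outer - x_inner
    for _ in range(30):
        if f(x_outer) > 0:
            return float(optimize.brentq(f, min(x_inner, x_outer), max(x_inner, x_outer)))
        x_outer += step
    return float("inf") if increasing else float("-inf")


def fit_from_td50(td50: float, arm: str = "", grade: float = 0.0, slope: float = np.nan) -> DoseResponseFit:
    """Wrap a reference TD50 value (e.g. a published table entry) as a fit.

    No covariance is attached, so downstream DMFs carry point estimates only.
    """
    return DoseResponseFit(arm=arm, grade=float(grade), td50=float(td50), slope=slope)


# --------------------------------------------------------------------------
# Dose-modifying factor
# --------------------------------------------------------------------------


def dmf(
    fit_conv: DoseResponseFit,
    fit_flash: DoseResponseFit,
    method: str = "delta_log_ratio",
    responder_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> DMFEstimate:
    """Dose-modifying factor TD50_FLASH / TD50_CONV with a 95% CI.

    ``method``:

    * ``"delta_log_ratio"`` — Wald interval on log(TD50_FLASH) - log(TD50_CONV),
      treating the arms as independent (default);
    * ``"bootstrap"`` — seeded parametric bootstrap, resampling binomial
      responders at the fitted probabilities (requires ``responder_tables``,
      the per-arm (conv, flash) dataframes used for the fits);
    * ``"none"`` — point estimate only (used with reference TD50s).

    A non-converged input yields an estimate flagged ``estimable=False``.
    """
    grade = fit_conv.grade or fit_flash.grade
    if not (fit_conv.converged and fit_flash.converged) or not np.isfinite(
        fit_conv.td50 * fit_flash.td50
    ):
        return DMFEstimate(
            grade=grade, td50_conv=fit_conv.td50, td50_flash=fit_flash.td50,
            dmf=np.nan, ci95=None, method=method, estimable=False,
        )

    ratio = fit_flash.td50 / fit_conv.td50
    ci: tuple[float, float] | None = None
    if method == "delta_log_ratio" and fit_conv.cov is not None and fit_flash.cov is not None:
        var_log = (
            fit_conv.cov[0, 0] / fit_conv.td50**2 + fit_flash.cov[0, 0] / fit_flash.td50**2
        )
        se = float(np.sqrt(var_log))
        ci = (ratio * np.exp(-_Z95 * se), ratio * np.exp(_Z95 * se))
    elif method == "bootstrap":
        if responder_tables is None:
            raise ValueError("bootstrap DMF CI requires the per-arm responder tables")
        ci = _bootstrap_dmf_ci(fit_conv, fit_flash, responder_tables, n_boot, seed)
    elif method == "none" or fit_conv.cov is None or fit_flash.cov is None:
        ci = None
    else:
        raise ValueError(f"unknown DMF CI method {method!r}")

    return DMFEstimate(
        grade=grade, td50_conv=fit_conv.td50, td50_flash=fit_flash.td50,
        dmf=float(ratio), ci95=ci, method=method,
    )


def _bootstrap_dmf_ci(fit_conv, fit_flash, tables, n_boot, seed) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    ratios = []
    parts = []
    for f, tab in zip((fit_conv, fit_flash), tables):
        dose = tab["dose"].to_numpy(float)
        n = tab["n"].to_numpy(int)
        parts.append((f, dose, n, f.predict(dose)))
    for _ in range(n_boot):
        td50s = []
        for f, dose, n, p in parts:
            resp = rng.binomial(n, p)
            boot = ResponderTable(
                assay="acute" if f.grade in ACUTE_GRADES else "fibrosis",
                grade=f.grade,
                table=pd.DataFrame({"arm": f.arm or "X", "dose": dose, "n": n, "responders": resp}),
            )
            try:
                bf = fit_logistic(boot, f.arm or "X")
            except InsufficientDataError:
                bf = None
            td50s.append(bf.td50 if bf is not None and bf.converged else np.nan)
        ratios.append(td50s[1] / td50s[0])
    ratios = np.asarray(ratios)
    ratios = ratios[np.isfinite(ratios)]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return (float(lo), float(hi))


def mean_dmf(estimates: Sequence[DMFEstimate]) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean and (min, max) range of grade-wise DMF values.

    The range is the spread across grades, not a sampling interval.
    """
    vals = [e.dmf for e in estimates if e.estimable and np.isfinite(e.dmf)]
    if not vals:
        raise ValueError("no estimable DMF values")
    return float(np.mean(vals)), (float(min(vals)), float(max(vals)))


def td50_ratio_across_studies(
    td50s_a: Mapping[float, float], td50s_b: Mapping[float, float]
) -> tuple[float, tuple[float, float]]:
    """Mean and range of per-grade TD50 ratios a/b between two studies.

    Both inputs are grade -> TD50 mappings over the same grade set.
    """
    if set(td50s_a) != set(td50s_b):
        raise ValueError(f"grade sets differ: {sorted(td50s_a)} vs {sorted(td50s_b)}")
    if not td50s_a:
        raise ValueError("empty TD50 mapping")
    ratios = [td50s_a[g] / td50s_b[g] for g in sorted(td50s_a)]
    return float(np.mean(ratios)), (float(min(ratios)), float(max(ratios)))


# --------------------------------------------------------------------------
# Assembled report
# --------------------------------------------------------------------------


def build_report(
    records: Iterable[ToxicityRecord],
    grades: Mapping[str, Sequence[float]] | None = None,
    ci: str = "delta",
    dmf_method: str = "delta_log_ratio",
    seed: int | None = None,
    dose_lattice: np.ndarray | None = None,
    exclusion_log: list[dict] | None = None,
) -> dict:
    """Fit every (assay, grade, arm), compute DMFs and summaries.

    Returns a JSON-serializable dict with blocks ``fits``, ``dmf``,
    ``mean_dmf``, ``exclusions`` and ``curves`` (fitted P(d) sampled on a
    dose lattice for plotting). A grade whose fit fails in one arm is
    flagged not-estimable without aborting the other grades.
    """
    records = list(records)
    if grades is None:
        grades = {"acute": ACUTE_GRADES, "fibrosis": FIBROSIS_GRADES}
    if dose_lattice is None:
        doses = [r.dose for r in records if not r.excluded]
        lo, hi = (min(doses), max(doses)) if doses else (0.0, 70.0)
        dose_lattice = np.linspace(max(lo - 10, 0.0), hi + 10, 101)

    report: dict = {
        "fits": {},
        "dmf": {},
        "mean_dmf": {},
        "exclusions": exclusion_log or [],
        "curves": {"dose_Gy": [float(d) for d in dose_lattice]},
    }
    for assay, grade_list in grades.items():
        assay_records = [r for r in records if r.assay == assay]
        if not assay_records:
            continue
        report["fits"][assay] = {}
        report["dmf"][assay] = {}
        report["curves"][assay] = {}
        dmfs = []
        for g in grade_list:
            key = f"{g:g}"
            table = to_responders(assay_records, g)
            block: dict = {}
            curves: dict = {}
            fits: dict[str, DoseResponseFit] = {}
            for arm in ("CONV", "FLASH"):
                try:
                    f = fit_logistic(table, arm, ci=ci)
                except InsufficientDataError as err:
                    f = DoseResponseFit(arm=arm, grade=g, td50=np.nan, slope=np.nan,
                                        converged=False)
                    block.setdefault("errors", []).append(str(err))
                fits[arm] = f
                block[arm] = _jsonable(f.to_dict())
                if f.converged:
                    curves[arm] = [float(p) for p in f.predict(dose_lattice)]
                grp = table.for_arm(arm)
                block[arm]["observed"] = {
                    "dose": [float(d) for d in grp["dose"]],
                    "n": [int(v) for v in grp["n"]],
                    "responders": [int(v) for v in grp["responders"]],
                }
            est = dmf(
                fits["CONV"], fits["FLASH"], method=dmf_method,
                responder_tables=(table.for_arm("CONV"), table.for_arm("FLASH")),
                seed=seed,
            )
            if est.estimable:
                dmfs.append(est)
            block["dmf"] = _jsonable(est.to_dict())
            report["fits"][assay][key] = block
            report["dmf"][assay][key] = _jsonable(est.to_dict())
            report["curves"][assay][key] = curves
        if dmfs:
            m, rng_ = mean_dmf(dmfs)
            report["mean_dmf"][assay] = {"mean": m, "range": list(rng_), "n_grades": len(dmfs)}
        else:
            report["mean_dmf"][assay] = {"mean": None, "range": None, "n_grades": 0}
    return report


def _jsonable(obj):
    """Recursively convert numpy scalars / NaN to JSON-safe python values."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
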