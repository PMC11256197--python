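import numpy as np
import pandas as pd
import pytest

from flashtox import build_field_plan, schedule_conv, schedule_flash
from flashtox.toxicity import ResponderTable


@pytest.fixture(scope="session")
def plan():
    """The standard 5x7 field: 6 mm spacing, rim factor 1.4, sigma 8 mm."""
    return build_field_plan(5, 7, 6.0, 1.4, 8.0)


@pytest.fixture(scope="session")
def flash_schedule(plan):
    return schedule_flash(plan, prescribed_dose=60.0, field_dose_rate=60.0)


@pytest.fixture(scope="session")
def conv_schedule(plan):
    return schedule_conv(plan, prescribed_dose=30.0, field_dose_rate=0.35,
                         n_repaints=200, mean_pause=0.0044)


def make_responder_table(doses, n, responders, arm="CONV", grade=1.5, assay="acute"):
    return ResponderTable(
        assay=assay,
        grade=grade,
        table=pd.DataFrame(
            {"arm": arm, "dose": doses, "n": n, "responders": responders}
        ),
    )


def grid_search_mle(dose, n, resp, td50_range=(5.0, 80.0), b_range=(0.05, 20.0), rounds=5):
    """Independent brute-force binomial MLE of (td50, b) by iterated grid refinement.

    Evaluates the binomial log-likelihood of the two-parameter logistic
    directly on successively finer 81x81 grids; no gradient-based fitting.
    """
    dose = np.asarray(dose, float)
    n = np.asarray(n, float)
    resp = np.asarray(resp, float)

    def loglik(td50, b):
        with np.errstate(over="ignore"):  # exp overflow saturates to p = 0/1, then clipped
            p = 1.0 / (1.0 + np.exp(-(dose[None, None, :] - td50[..., None]) / b[..., None]))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return (resp * np.log(p) + (n - resp) * np.log1p(-p)).sum(axis=-1)

    t_lo, t_hi = td50_range
    b_lo, b_hi = b_range
    for _ in range(rounds):
        ts = np.linspace(t_lo, t_hi, 81)
        bs = np.linspace(b_lo, b_hi, 81)
        T, B = np.meshgrid(ts, bs, indexing="ij")
        ll = loglik(T, B)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        dt = ts[1] - ts[0]
        db = bs[1] - bs[0]
        t_lo, t_hi = ts[i] - 2 * dt, ts[i] + 2 * dt
        b_lo, b_hi = max(bs[j] - 2 * db, 1e-6), bs[j] + 2 * db
    return float(ts[i]), float(bs[j])
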