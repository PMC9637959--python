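"""Model-skill metrics for measured vs simulated series, with the qualitative
classification bands conventional in crop-model evaluation.

All second moments are population (1/n) moments so the perfect-agreement
identities (RMSE 0, NSE 1, d 1, CCC 1, r 1) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EvaluationReport:
    """Skill metrics for one observed/simulated pair of series."""

    n: int
    rmse: float
    nrmse: float
    pearson_r: float
    nse: float
    willmott_d: float
    lin_ccc: float
    undefined: dict = field(default_factory=dict)


def compute_metrics(observed, simulated) -> EvaluationReport:
    """RMSE, NRMSE (mean-normalised), Pearson r, Nash-Sutcliffe efficiency,
    Willmott's index of agreement d and Lin's concordance correlation.

    With constant observations r, NSE, d and CCC are undefined; they are
    reported as NaN with a reason in ``undefined`` and RMSE is still computed.
    """
    o = np.asarray(observed, float)
    s = np.asarray(simulated, float)
    if o.shape != s.shape or o.ndim != 1:
        raise ValueError("observed and simulated must be equal-length 1-D")
    n = len(o)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    sq_err = float(((s - o) ** 2).sum())
    rmse = float(np.sqrt(sq_err / n))
    obar, sbar = float(o.mean()), float(s.mean())
    nrmse = rmse / obar if obar != 0 else float("nan")
    undefined = {}
    ss_obs = float(((o - obar) ** 2).sum())
    if ss_obs == 0:
        undefined = {m: "observed series is constant"
                     for m in ("pearson_r", "nse", "lin_ccc")}
        r = nse = ccc = float("nan")
    else:
        nse = 1.0 - sq_err / ss_obs
        var_o = ss_obs / n
        var_s = float(((s - sbar) ** 2).mean())
        cov = float(((o - obar) * (s - sbar)).mean())
        ccc = 2 * cov / (var_o + var_s + (obar - sbar) ** 2)
        r = cov / np.sqrt(var_o * var_s) if var_s > 0 else float("nan")
        if var_s == 0:
            undefined["pearson_r"] = "simulated series is constant"
    denom_d = float(((np.abs(s - obar) + np.abs(o - obar)) ** 2).sum())
    d = 1.0 - sq_err / denom_d if denom_d > 0 else 1.0
    return EvaluationReport(n=n, rmse=rmse, nrmse=nrmse, pearson_r=float(r),
                            nse=float(nse), willmott_d=float(d),
                            lin_ccc=float(ccc), undefined=undefined)


#: variable -> RMSE threshold for a "good" flag (units of the variable)
RMSE_GOOD_THRESHOLDS = {
    "flowering_days": 5.0,   # days to 50% flowering
    "yield_t_ha": 0.5,       # seed yield
    "biomass_t_ha": 1.5,     # aboveground biomass
}


def _band(value: float, bounds: tuple[float, float, float]) -> str:
    """unsatisfactory <= b0 < satisfactory <= b1 < good <= b2 < very good."""
    b0, b1, b2 = bounds
    if np.isnan(value):
        return "undefined"
    if value <= b0:
        return "unsatisfactory"
    if value <= b1:
        return "satisfactory"
    if value <= b2:
        return "good"
    return "very good"


def classify_performance(report: EvaluationReport,
                         variable: str | None = None) -> dict:
    """Qualitative labels per metric.

    d: unsatisfactory <= 0.75 < satisfactory <= 0.85 < good <= 0.95 < very
    good; NSE: unsatisfactory <= 0.5 < satisfactory <= 0.65 < good <= 0.75 <
    very good.  RMSE gains a good/not-good flag when ``variable`` names one of
    the thresholded quantities (days to flowering, yield, biomass).
    """
    labels = {
        "willmott_d": _band(report.willmott_d, (0.75, 0.85, 0.95)),
        "nse": _band(report.nse, (0.5, 0.65, 0.75)),
    }
    threshold = RMSE_GOOD_THRESHOLDS.get(variable or "")
    if threshold is not None:
        labels["rmse"] = "good" if report.rmse <= threshold else "not good"
    return labels
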