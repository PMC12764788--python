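"""Common-gradient (parallel / coincident) biomarker screen.

For each physical quantity y the cohort supplies observations y_ij with
tumour fraction c_ij for supplier group i.  Two linear models with a
common gradient beta are compared:

    parallel:    y_ij = alpha_i + beta c_ij + eps_ij
    coincident:  y_ij = alpha   + beta c_ij + eps_ij

The parallel model is preferred when a nested F-test rejects equal
intercepts at the 5% level.  The gradient's two-sided t-test p-value and
the adjusted R-squared of the chosen model drive the biomarker call: a
quantity is a biomarker when the gradient is significant (p < 0.05) and
tumour fraction accounts for a large share of its variance
(adjusted R^2 >= 0.5); significant-but-weak when 0.2 <= adj R^2 < 0.5;
none-suitable otherwise.

Adjusted R-squared convention: 1 - (1 - R^2)(n - 1)/(n - 1 - p) with p
the number of fitted coefficients beyond one grand intercept (parallel:
p = 3, coincident: p = 1), i.e. the convention of R's summary.lm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .profiles import GROUPS

MODEL_KINDS = ("parallel", "coincident")
CLASSIFICATIONS = ("biomarker", "significant-but-weak", "none-suitable")

#: Decision thresholds of the biomarker call (config-exposed).
ALPHA_LEVEL = 0.05
R2_BIOMARKER = 0.5
R2_WEAK = 0.2


class DegenerateDesignError(ValueError):
    """Rank-deficient design (e.g. all tumour fractions equal)."""


@dataclass
class ObservationTable:
    """(group, c, y) rows for one physical quantity across the cohort."""

    group: np.ndarray        # labels from GROUPS
    c: np.ndarray            # tumour fraction, percent
    y: np.ndarray
    quantity_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        self.c = np.asarray(self.c, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.group.size == self.c.size == self.y.size):
            raise ValueError("group, c and y must have equal length")
        if np.any((self.c < 0) | (self.c > 100)):
            raise ValueError("tumour fractions must lie in [0, 100]")
        unknown = set(self.group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")

    @property
    def n(self) -> int:
        return int(self.y.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group, "c": self.c, "y": self.y})


@dataclass
class ModelFit:
    """One common-gradient OLS fit."""

    model_kind: str
    intercepts: Dict[str, float]   # per group (parallel) or {"all": alpha}
    beta: float
    beta_se: float
    beta_p_value: float
    adjusted_r2: float
    rss: float
    residuals: np.ndarray
    n: int

    @property
    def n_coefficients(self) -> int:
        return 4 if self.model_kind == "parallel" else 2


def fit_common_gradient(table: ObservationTable, kind: str) -> ModelFit:
    """OLS fit of the parallel or coincident common-gradient model."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    df = table.to_frame()
    n = table.n
    n_par = 4 if kind == "parallel" else 2
    if n < n_par + 2:
        raise ValueError(f"need at least {n_par + 2} rows for the {kind} model")
    if np.ptp(table.c) == 0:
        raise DegenerateDesignError("all tumour fractions equal; slope unidentifiable")
    if kind == "parallel" and len(set(table.group)) < 2:
        raise DegenerateDesignError("parallel model needs >= 2 non-empty groups")

    formula = "y ~ C(group) + c" if kind == "parallel" else "y ~ c"
    res = smf.ols(formula, data=df).fit()
    params = res.params
    if kind == "parallel":
        base = params["Intercept"]
        intercepts = {}
        present = [g for g in GROUPS if g in set(table.group)]
        for g in present:
            key = f"C(group)[T.{g}]"
            intercepts[g] = float(base + params.get(key, 0.0))
    else:
        intercepts = {"all": float(params["Intercept"])}
    return ModelFit(
        model_kind=kind,
        intercepts=intercepts,
        beta=float(params["c"]),
        beta_se=float(res.bse["c"]),
        beta_p_value=float(res.pvalues["c"]),
        adjusted_r2=float(res.rsquared_adj),
        rss=float(res.ssr),
        residuals=np.asarray(res.resid),
        n=n,
    )


def compare_models(fit_parallel: ModelFit, fit_coincident: ModelFit):
    """Nested F-test of equal intercepts; returns (chosen_kind, F, p).

    F = [(RSS_c - RSS_p)/2] / [RSS_p/(n - 4)] against F(2, n - 4);
    parallel is chosen when the test rejects at the 5% level.
    """
    if fit_parallel.model_kind != "parallel" or fit_coincident.model_kind != "coincident":
        raise ValueError("arguments must be (parallel fit, coincident fit)")
    if fit_parallel.n != fit_coincident.n:
        raise ValueError("fits come from different tables")
    n = fit_parallel.n
    num = max(fit_coincident.rss - fit_parallel.rss, 0.0) / 2.0
    den = fit_parallel.rss / (n - 4)
    if den == 0.0:
        f_stat = np.inf if num > 0 else 0.0
    else:
        f_stat = num / den
    p = float(sps.f.sf(f_stat, 2, n - 4)) if np.isfinite(f_stat) else 0.0
    chosen = "parallel" if p < ALPHA_LEVEL else "coincident"
    return chosen, float(f_stat), p


def percent_change(fit: ModelFit, group_sizes: Optional[Dict[str, int]] = None) -> float:
    """Percent change of y over the full 0-100% tumour-fraction range.

    100 * (beta * 100) / y(c=0), with y(0) the coincident intercept or
    the group-size-weighted mean of the parallel intercepts.
    """
    if fit.model_kind == "coincident":
        y0 = fit.intercepts["all"]
    else:
        if group_sizes:
            w = np.array([group_sizes.get(g, 0) for g in fit.intercepts], dtype=float)
        else:
            w = np.ones(len(fit.intercepts))
        y0 = float(np.average(list(fit.intercepts.values()), weights=w))
    if y0 == 0.0:
        raise ZeroDivisionError("intercept at c=0 is zero; percent change undefined")
    return 100.0 * (fit.beta * 100.0) / y0


def classify(beta_p_value: float, adjusted_r2: float,
             alpha: float = ALPHA_LEVEL, r2_biomarker: float = R2_BIOMARKER,
             r2_weak: float = R2_WEAK) -> str:
    """Biomarker call from the chosen model's p-value and adjusted R^2."""
    if beta_p_value < alpha and adjusted_r2 >= r2_biomarker:
        return "biomarker"
    if beta_p_value < alpha and r2_weak <= adjusted_r2 < r2_biomarker:
        return "significant-but-weak"
    return "none-suitable"


@dataclass
class QuantityScreen:
    """Full screen outcome for one quantity (one report row)."""

    quantity: str
    units: str
    model: str
    gradient: float
    p_value: float
    adjusted_r2: float
    percent_change_0_100: float
    classification: str
    f_statistic: float
    f_p_value: float
    fit_parallel: ModelFit = field(repr=False, default=None)
    fit_coincident: ModelFit = field(repr=False, default=None)


def screen_quantity(table: ObservationTable,
                    alpha: float = ALPHA_LEVEL,
                    r2_biomarker: float = R2_BIOMARKER,
                    r2_weak: float = R2_WEAK) -> QuantityScreen:
    """Fit both models, choose one, and classify the quantity."""
    fit_p = fit_common_gradient(table, "parallel")
    fit_c = fit_common_gradient(table, "coincident")
    chosen, f_stat, f_p = compare_models(fit_p, fit_c)
    fit = fit_p if chosen == "parallel" else fit_c
    sizes = {g: int(np.sum(table.group == g)) for g in set(table.group)}
    return QuantityScreen(
        quantity=table.quantity_name,
        units=table.units,
        model=chosen,
        gradient=fit.beta,
        p_value=fit.beta_p_value,
        adjusted_r2=fit.adjusted_r2,
        percent_change_0_100=percent_change(fit, sizes),
        classification=classify(fit.beta_p_value, fit.adjusted_r2,
                                alpha, r2_biomarker, r2_weak),
        f_statistic=f_stat,
        f_p_value=f_p,
        fit_parallel=fit_p,
        fit_coincident=fit_c,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; the screen applies no correction
    by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def report_frame(screens: Sequence[QuantityScreen],
                 bh_correction: bool = False) -> pd.DataFrame:
    """Assemble the per-quantity screen report (the study-summary twin)."""
    df = pd.DataFrame([{
        "quantity": s.quantity,
        "units": s.units,
        "model": s.model,
        "gradient": s.gradient,
        "p_value": s.p_value,
        "adjusted_R2": s.adjusted_r2,
        "percent_change_0_100": s.percent_change_0_100,
        "classification": s.classification,
    } for s in screens])
    if bh_correction:
        df["p_value_bh"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
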