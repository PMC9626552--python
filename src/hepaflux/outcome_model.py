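"""Time-integrated biomarkers and the multivariate outcome model.

The predictive analysis condenses each liver's longitudinal mitochondrial
biomarkers (P-L control efficiency, cytochrome c control efficiency, LEAK
respiration, ...) into trapezoidal areas under the curve over a perfusion
window — by default the first 6 h of NMP, with the end-of-cold-storage biopsy
assigned t = 0 — and regresses a continuous early-graft-function score
(L-GrAFT; MEAF or an EAD flag can be substituted) on those AUC terms.

Model selection is bidirectional stepwise AIC from the intercept-only model,
with the marginality (hierarchy) rule: a product interaction may enter only
while both parents are in the model, and a parent may not leave while its
interaction is in. The selected model is refit by ordinary least squares and
reported with Type II sums of squares (each term tested against the model
containing every term that does not contain it), per-term F and p, raw and
standardized coefficients (beta = b·sd(x)/sd(y)), 95% confidence intervals,
r², adjusted r² and the overall F test. Partial residual diagnostics are
provided for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DesignError, UndefinedValueError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiomarkerSeries:
    """Longitudinal observations of one biomarker for one liver."""

    liver_id: str
    parameter: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise UndefinedValueError("times and values must be matching 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise UndefinedValueError("observation times must be strictly increasing")

    def auc(self, window: tuple[float, float] = (0.0, 6.0)) -> float:
        return time_auc(self.times, self.values, window)


def time_auc(
    times: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float] = (0.0, 6.0),
    time_average: bool = False,
) -> float:
    """Trapezoidal AUC of (times, values) clipped to ``window``.

    Observation times inside the window enter as-is; values at the window
    edges are linearly interpolated from the neighbouring observations, and
    the integral is never extrapolated beyond the first/last observation.
    Fewer than two observations inside the window give NaN (the row is then
    excluded downstream). With ``time_average`` the integral is divided by the
    integrated duration, turning value·hours into a mean level.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise UndefinedValueError("times and values must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise UndefinedValueError("observation times must be strictly increasing")
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise UndefinedValueError("window must have t1 > t0")

    inside = (t >= t0) & (t <= t1)
    if inside.sum() < 2:
        return float("nan")

    lo = max(t0, float(t[0]))
    hi = min(t1, float(t[-1]))
    grid = np.unique(np.concatenate([[lo, hi], t[(t > lo) & (t < hi)]]))
    vals = np.interp(grid, t, v)
    area = float(np.trapezoid(vals, grid))
    if time_average:
        area /= hi - lo
    return area


def cohort_aucs(
    biomarkers: pd.DataFrame,
    parameters: list[str] | None = None,
    window: tuple[float, float] = (0.0, 6.0),
    time_average: bool = False,
) -> pd.DataFrame:
    """Per-liver AUC of each biomarker from a tidy long table.

    ``biomarkers`` has columns liver_id, time_h, parameter, value. Output is
    one row per liver with ``<parameter>_auc`` columns; NaN where the window
    holds fewer than two observations.
    """
    required = {"liver_id", "time_h", "parameter", "value"}
    missing = required - set(biomarkers.columns)
    if missing:
        raise UndefinedValueError(f"biomarker table missing columns {sorted(missing)}")
    parameters = parameters or sorted(biomarkers["parameter"].unique())
    rows: dict[str, dict[str, float]] = {}
    for (liver, param), g in biomarkers.groupby(["liver_id", "parameter"], sort=True):
        if param not in parameters:
            continue
        g = g.sort_values("time_h")
        rows.setdefault(liver, {})[f"{param}_auc"] = time_auc(
            g["time_h"].to_numpy(), g["value"].to_numpy(), window,
            time_average=time_average,
        )
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "liver_id"
    cols = [f"{p}_auc" for p in parameters]
    return out.reindex(columns=cols).reset_index()


def interaction_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def _parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


def _contains(term: str, other: str) -> bool:
    """True when ``term`` is an interaction containing main effect ``other``."""
    return other in _parents(term)


def assemble_design(
    cohort: pd.DataFrame,
    predictors: list[str],
    interactions: list[tuple[str, str]] | None = None,
    outcome: str | None = None,
) -> pd.DataFrame:
    """Model table: main effects plus requested pairwise product interactions.

    Complete cases only; the number of dropped rows is logged. Interaction
    columns are the elementwise products of their parents and named "a:b".
    """
    missing = [p for p in predictors if p not in cohort.columns]
    if missing:
        raise DesignError(f"predictors not in cohort table: {missing}")
    cols = list(predictors)
    if outcome is not None:
        if outcome not in cohort.columns:
            raise DesignError(f"outcome column {outcome!r} not in cohort table")
        cols = cols + [outcome]
    table = cohort[cols].copy()
    for a, b in interactions or []:
        if a not in predictors or b not in predictors:
            raise DesignError(f"interaction ({a}, {b}) needs both parents in predictors")
        table[interaction_name(a, b)] = table[a] * table[b]

    n_before = len(table)
    table = table.dropna()
    dropped = n_before - len(table)
    if dropped:
        logger.info("assemble_design: excluded %d incomplete rows of %d", dropped, n_before)

    for col in table.columns:
        if outcome is not None and col == outcome:
            continue
        if float(np.std(table[col].to_numpy())) == 0.0:
            raise DesignError(f"zero-variance predictor {col!r}")
    return table.reset_index(drop=True)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DesignError("singular (collinear) design")
    r = y - X @ beta
    return float(r @ r)


def _design_matrix(table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    n = len(table)
    cols = [np.ones(n)]
    cols.extend(table[t].to_numpy(dtype=float) for t in terms)
    return np.column_stack(cols)


RSS_FLOOR_FRACTION = 1e-10


def aic_ls(rss: float, n: int, n_params: int, rss_floor: float = 0.0) -> float:
    """Least-squares AIC on the profile-likelihood scale: n·log(RSS/n) + 2p,
    with p counting the regression coefficients including the intercept.

    ``rss_floor`` guards the numerically-perfect-fit regime: once RSS is at
    rounding level, log-RSS differences between nested perfect fits are float
    noise, so all of them are scored at the floor and the 2p penalty selects
    the smallest such model.
    """
    rss = max(rss, rss_floor, 1e-300)
    return n * float(np.log(rss / n)) + 2.0 * n_params


def hierarchy_ok(terms: set[str]) -> bool:
    return all(p in terms for t in terms for p in _parents(t))


def stepwise_aic(
    model_table: pd.DataFrame,
    outcome: str,
    scope: list[str] | None = None,
) -> list[str]:
    """Bidirectional stepwise AIC selection from the intercept-only model.

    At each step every single admissible add or drop move is scored and the
    one with the lowest AIC taken; the search stops when no move improves on
    the current AIC. Admissibility enforces marginality: an interaction may be
    added only when both parents are in, a main effect may not be dropped
    while one of its interactions remains. AIC ties break lexicographically on
    the term name (deterministic selection).
    """
    if outcome not in model_table.columns:
        raise DesignError(f"outcome column {outcome!r} not in model table")
    scope = list(scope) if scope is not None else [
        c for c in model_table.columns if c != outcome
    ]
    y = model_table[outcome].to_numpy(dtype=float)
    n = len(model_table)
    if n <= len(scope) + 1:
        raise DesignError(
            f"n = {n} rows cannot support {len(scope)} candidate terms"
        )

    tss = float(np.sum((y - y.mean()) ** 2))
    floor = RSS_FLOOR_FRACTION * tss

    current: list[str] = []
    current_aic = aic_ls(_rss(_design_matrix(model_table, current), y), n, 1, floor)
    while True:
        moves: list[tuple[float, str, str]] = []  # (aic, kind, term)
        in_set = set(current)
        for term in scope:
            if term in in_set:
                continue
            if not all(p in in_set for p in _parents(term)):
                continue
            cand = current + [term]
            rss = _rss(_design_matrix(model_table, cand), y)
            moves.append((aic_ls(rss, n, len(cand) + 1, floor), "add", term))
        for term in current:
            if any(_contains(t, term) for t in in_set if t != term):
                continue
            cand = [t for t in current if t != term]
            rss = _rss(_design_matrix(model_table, cand), y)
            moves.append((aic_ls(rss, n, len(cand) + 1, floor), "drop", term))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2], m[1]))
        best_aic, kind, term = moves[0]
        if best_aic >= current_aic - 1e-10:
            break
        if kind == "add":
            current = current + [term]
        else:
            current = [t for t in current if t != term]
        current_aic = best_aic
    # report in scope order for stable downstream tables
    return [t for t in scope if t in current]


@dataclass
class OutcomeModelFit:
    """Fitted outcome regression with its Type II ANOVA table.

    ``terms`` has one row per model term: raw coefficient b with its 95% CI,
    standardized beta, Type II sum of squares, F and p. Residual df equals
    n - (number of terms + 1).
    """

    terms: pd.DataFrame
    intercept: float
    r2: float
    adj_r2: float
    f_statistic: float
    f_df: tuple[int, int]
    f_pvalue: float
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    model_table: pd.DataFrame
    outcome: str
    rss: float

    @property
    def term_names(self) -> list[str]:
        return list(self.terms["term"])

    def coefficient(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise DesignError(f"term {term!r} not in fitted model")
        return float(row["b"].iloc[0])


def type2_ss(model_table: pd.DataFrame, terms: list[str], outcome: str) -> dict[str, float]:
    """Type II sum of squares per term by explicit nested refits.

    SS(term) = RSS(model with every term not containing it) - RSS(that model
    plus the term). For terms contained in no other term this reduces to
    RSS(full without term) - RSS(full).
    """
    y = model_table[outcome].to_numpy(dtype=float)
    ss: dict[str, float] = {}
    for term in terms:
        comparison = [t for t in terms if t != term and not _contains(t, term)]
        rss_without = _rss(_design_matrix(model_table, comparison), y)
        rss_with = _rss(_design_matrix(model_table, comparison + [term]), y)
        ss[term] = rss_without - rss_with
    return ss


def fit_and_anova(
    model_table: pd.DataFrame, terms: list[str], outcome: str
) -> OutcomeModelFit:
    """Least-squares fit of ``outcome`` on ``terms`` with Type II ANOVA."""
    for t in terms:
        if t not in model_table.columns:
            raise DesignError(f"term {t!r} not in model table")
    y = model_table[outcome].to_numpy(dtype=float)
    n = len(model_table)
    df_resid = n - (len(terms) + 1)
    if df_resid < 1:
        raise DesignError(f"residual df {df_resid} < 1 for n={n}, {len(terms)} terms")

    X = pd.DataFrame(
        {t: model_table[t].to_numpy(dtype=float) for t in terms}
    )
    X.insert(0, "Intercept", 1.0)
    ols = sm.OLS(y, X)
    res = ols.fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("singular (collinear) design")

    conf = res.conf_int(alpha=0.05)
    sd_y = float(np.std(y, ddof=1))
    ss2 = type2_ss(model_table, terms, outcome)
    rss = float(res.ssr)
    sigma2 = rss / df_resid

    rows = []
    for t in terms:
        b = float(res.params[t])
        sd_x = float(np.std(model_table[t].to_numpy(dtype=float), ddof=1))
        f_stat = ss2[t] / sigma2
        rows.append(
            {
                "term": t,
                "b": b,
                "ci_low": float(conf.loc[t, 0]),
                "ci_high": float(conf.loc[t, 1]),
                "beta": b * sd_x / sd_y if sd_y > 0 else np.nan,
                "ss2": ss2[t],
                "F": f_stat,
                "p": float(scipy.stats.f.sf(f_stat, 1, df_resid)),
            }
        )
    terms_df = pd.DataFrame(
        rows, columns=["term", "b", "ci_low", "ci_high", "beta", "ss2", "F", "p"]
    )

    if terms:
        f_statistic = float(res.fvalue)
        f_pvalue = float(res.f_pvalue)
    else:
        f_statistic, f_pvalue = np.nan, np.nan
    return OutcomeModelFit(
        terms=terms_df,
        intercept=float(res.params["Intercept"]),
        r2=float(res.rsquared) if terms else 0.0,
        adj_r2=float(res.rsquared_adj) if terms else 0.0,
        f_statistic=f_statistic,
        f_df=(len(terms), df_resid),
        f_pvalue=f_pvalue,
        n=n,
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        model_table=model_table.reset_index(drop=True),
        outcome=outcome,
        rss=rss,
    )


def partial_residuals(fit: OutcomeModelFit, term: str) -> np.ndarray:
    """Component-plus-residual values for one term: e + b_term · x_term.

    Regressing the returned values on x_term recovers exactly b_term, which is
    what makes the partial residual plot read as 'the effect of this term with
    the others held fixed'.
    """
    b = fit.coefficient(term)
    x = fit.model_table[term].to_numpy(dtype=float)
    return fit.residuals + b * x


def build_cohort_table(
    biomarkers: pd.DataFrame,
    outcomes: pd.DataFrame,
    parameters: list[str],
    window: tuple[float, float] = (0.0, 6.0),
    time_average: bool = False,
) -> pd.DataFrame:
    """Join per-liver biomarker AUCs with the outcome table on liver_id."""
    aucs = cohort_aucs(biomarkers, parameters, window, time_average=time_average)
    if "liver_id" not in outcomes.columns:
        raise DesignError("outcomes table needs a liver_id column")
    if outcomes["liver_id"].duplicated().any():
        raise DesignError("duplicated liver_id in outcomes table")
    return aucs.merge(outcomes, on="liver_id", how="inner")
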