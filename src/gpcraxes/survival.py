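"""Axis survival screening.

Patients in a cohort are stratified at the median expression of single
genes (high = strictly above the median, ties to low) or jointly for a
receptor-partner axis (both-high vs both-low, mixed patients excluded).
Group contrasts use the two-group log-rank test and univariate Cox
proportional-hazards regression with the low group as reference, so
HR > 1 means higher hazard in the high-expression group.

An axis passes the screen when its combined stratification at least
doubles (or halves) the hazard ratio of *both* single-gene
stratifications, its log-rank p is below 0.05 and below both individual
p values; q-values are BH-adjusted over tested axes within the cohort.
A combinatorial predictor (per-patient weighted sum of high/low
indicators, weighted by the univariate Cox coefficients) gives a
second-round model whose coefficient beta_c is regressed on the
individual coefficients across selected models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from gpcraxes.diffexp import adjust_pvalues
from gpcraxes.errors import DegenerateInputError, SchemaError

logger = logging.getLogger(__name__)

LOGRANK_ALPHA = 0.05
FDR_CUT = 0.1
HR_FOLD = 2.0


@dataclass
class SurvivalDataset:
    """Per-patient follow-up and expression for one cohort.

    ``expression`` is a gene x patient DataFrame aligned to ``time`` and
    ``event`` (1 = death observed, 0 = censored).
    """

    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame
    cohort: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if (self.time <= 0).any():
            raise SchemaError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise SchemaError("event indicator must be 0/1")
        if self.expression.shape[1] != len(self.time):
            raise SchemaError("expression columns must align with patients")


@dataclass
class CoxResult:
    beta: float
    hr: float
    p: float
    missing: bool = False
    diagnostic: str = ""


@dataclass
class AxisScreenRecord:
    receptor: str
    partner: str
    partner_kind: str
    hr_axis: float
    hr_r: float
    hr_p: float
    logrank_p_axis: float
    logrank_p_r: float
    logrank_p_p: float
    passes_filter: bool
    missing: bool = False


@dataclass
class CombinatorialCoxResult:
    beta_r: float
    beta_p: float
    hr_r: float
    hr_p: float
    predictor: np.ndarray
    beta_c: float
    hr_c: float
    logrank_p_c: float
    selected: bool
    missing: bool = False


def median_stratify(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Label patients 'high' (strictly above the median) or 'low'
    (at or below: ties go to low).  Raises on constant vectors."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise DegenerateInputError("need >=4 patients to stratify")
    if not np.isfinite(values).all():
        raise SchemaError("expression values must be finite")
    if np.ptp(values) == 0:
        raise DegenerateInputError("constant expression vector cannot be stratified")
    med = np.median(values)
    return np.where(values > med, "high", "low")


def combined_stratify(
    values_r: np.ndarray | Sequence[float], values_p: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Joint two-gene stratification: 'high' when both values exceed
    their medians, 'low' when both are at or below, 'excluded' for
    mixed patients (dropped from the comparison)."""
    labels_r = median_stratify(values_r)
    labels_p = median_stratify(values_p)
    out = np.full(len(labels_r), "excluded", dtype=object)
    out[(labels_r == "high") & (labels_p == "high")] = "high"
    out[(labels_r == "low") & (labels_p == "low")] = "low"
    return out.astype(str)


def km_logrank(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Two-group log-rank test plus Kaplan-Meier curve tables.

    Returns (statistic, p, km_tables); each KM table carries time,
    at-risk count, observed events and the survival estimate.
    """
    groups = np.asarray(groups)
    keep = groups != "excluded"
    time, event, groups = time[keep], event[keep], groups[keep]
    names = sorted(set(groups))
    if len(names) != 2 or any((groups == g).sum() == 0 for g in names):
        raise DegenerateInputError(f"log-rank needs exactly two non-empty groups, got {names}")
    a, b = names
    res = logrank_test(
        time[groups == a], time[groups == b], event[groups == a], event[groups == b]
    )
    tables = {}
    for g in names:
        kmf = KaplanMeierFitter()
        kmf.fit(time[groups == g], event[groups == g], label=g)
        tab = kmf.event_table.copy()
        tab["survival"] = kmf.survival_function_[g].reindex(tab.index).to_numpy()
        tables[g] = tab.reset_index().rename(
            columns={"event_at": "time", "at_risk": "n_at_risk", "observed": "n_events"}
        )[["time", "n_at_risk", "n_events", "survival"]]
    return float(res.test_statistic), float(res.p_value), tables


def _logrank_p(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> float:
    """Two-group log-rank p without building KM curve tables (screen path)."""
    groups = np.asarray(groups)
    keep = groups != "excluded"
    time, event, groups = time[keep], event[keep], groups[keep]
    names = sorted(set(groups))
    if len(names) != 2:
        raise DegenerateInputError(f"log-rank needs exactly two non-empty groups, got {names}")
    a, b = names
    res = logrank_test(
        time[groups == a], time[groups == b], event[groups == a], event[groups == b]
    )
    return float(res.p_value)


def cox_score_test(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Cox partial-likelihood score test at beta = 0 for a binary
    high/low covariate (Breslow ties).  For two groups this is the
    log-rank computation, so the two tests agree exactly in the absence
    of ties and asymptotically otherwise."""
    from scipy import stats

    groups = np.asarray(groups)
    keep = groups != "excluded"
    time, event, x = time[keep], event[keep], (groups[keep] == "high").astype(float)
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    U = 0.0
    I = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = int(((time == t) & (event == 1)).sum())
        n = at_risk.sum()
        n1 = x[at_risk].sum()
        d1 = x[(time == t) & (event == 1)].sum()
        p = n1 / n
        U += d1 - d * p
        if n > 1:
            I += d * p * (1 - p) * (n - d) / (n - 1)
    if I == 0:
        raise DegenerateInputError("score test information is zero")
    stat = U * U / I
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cox_univariate(
    time: np.ndarray, event: np.ndarray, covariate: np.ndarray | Sequence[float]
) -> CoxResult:
    """Univariate unadjusted Cox PH fit (Efron ties, lifelines backend).

    The covariate may be a binary high/low indicator (0 = low reference)
    or a continuous value.  Non-convergence or separation yields a
    result flagged missing with a diagnostic instead of raising.
    """
    covariate = np.asarray(covariate, dtype=float)
    if np.ptp(covariate) == 0:
        raise DegenerateInputError("constant covariate")
    if event.sum() == 0:
        raise DegenerateInputError("no observed events")
    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    cph = CoxPHFitter()
    try:
        import warnings

        from lifelines.exceptions import ConvergenceWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        return CoxResult(np.nan, np.nan, np.nan, missing=True, diagnostic=str(exc))
    beta = float(cph.params_["x"])
    return CoxResult(beta=beta, hr=float(np.exp(beta)), p=float(cph.summary.loc["x", "p"]))


def _groups_to_indicator(groups: np.ndarray) -> np.ndarray:
    return (np.asarray(groups) == "high").astype(float)


def _single_gene_result(
    dataset: SurvivalDataset, gene: str
) -> tuple[CoxResult, float, np.ndarray] | None:
    """(cox, logrank_p, groups) for a median stratification, or None if
    the gene is absent or degenerate."""
    if gene not in dataset.expression.index:
        return None
    try:
        groups = median_stratify(dataset.expression.loc[gene].to_numpy())
        p = _logrank_p(dataset.time, dataset.event, groups)
        cox = cox_univariate(dataset.time, dataset.event, _groups_to_indicator(groups))
    except DegenerateInputError:
        return None
    if cox.missing:
        return None
    return cox, p, groups


def axis_screen(
    dataset: SurvivalDataset,
    axes: Sequence[tuple[str, str, str]],
    fdr_cut: float = FDR_CUT,
    alpha: float = LOGRANK_ALPHA,
    hr_fold: float = HR_FOLD,
) -> pd.DataFrame:
    """Screen receptor-partner axes for combined survival association.

    For each axis the receptor and partner are median-stratified
    individually and jointly (both-high vs both-low); an axis passes
    when the combined HR differs from both individual HRs by more than
    ``hr_fold`` in either direction, the combined log-rank p is below
    ``alpha`` and below both individual p values.  Single-gene results
    are cached across axes; q is BH over combined log-rank p values.
    """
    cache: dict[str, tuple[CoxResult, float, np.ndarray] | None] = {}

    def single(gene: str):
        if gene not in cache:
            cache[gene] = _single_gene_result(dataset, gene)
        return cache[gene]

    records = []
    for receptor, partner, kind in axes:
        rec = {
            "receptor": receptor,
            "partner": partner,
            "partner_kind": kind,
            "hr_axis": np.nan,
            "hr_r": np.nan,
            "hr_p": np.nan,
            "logrank_p_axis": np.nan,
            "logrank_p_r": np.nan,
            "logrank_p_p": np.nan,
            "n_high": 0,
            "n_low": 0,
            "passes_filter": False,
            "missing": True,
        }
        res_r, res_p = single(receptor), single(partner)
        if res_r is None or res_p is None:
            records.append(rec)
            continue
        cox_r, p_r, _ = res_r
        cox_p, p_p, _ = res_p
        rec.update(hr_r=cox_r.hr, hr_p=cox_p.hr, logrank_p_r=p_r, logrank_p_p=p_p)
        try:
            groups = combined_stratify(
                dataset.expression.loc[receptor].to_numpy(),
                dataset.expression.loc[partner].to_numpy(),
            )
            if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
                raise DegenerateInputError("empty combined group")
            p_axis = _logrank_p(dataset.time, dataset.event, groups)
            keep = groups != "excluded"
            cox_axis = cox_univariate(
                dataset.time[keep], dataset.event[keep], _groups_to_indicator(groups[keep])
            )
        except DegenerateInputError as exc:
            logger.debug("axis (%s, %s) untestable: %s", receptor, partner, exc)
            records.append(rec)
            continue
        if cox_axis.missing:
            records.append(rec)
            continue
        ratio_r = cox_axis.hr / cox_r.hr
        ratio_p = cox_axis.hr / cox_p.hr
        passes = (
            (ratio_r < 1 / hr_fold or ratio_r > hr_fold)
            and (ratio_p < 1 / hr_fold or ratio_p > hr_fold)
            and p_axis < min(p_r, p_p)
            and p_axis < alpha
        )
        rec.update(
            hr_axis=cox_axis.hr,
            logrank_p_axis=p_axis,
            n_high=int((groups == "high").sum()),
            n_low=int((groups == "low").sum()),
            passes_filter=bool(passes),
            missing=False,
        )
        records.append(rec)
    out = pd.DataFrame(records)
    out["q"] = adjust_pvalues(out["logrank_p_axis"].to_numpy())
    out["significant"] = out["passes_filter"] & (out["q"] < fdr_cut)
    return out


def combinatorial_cox(
    dataset: SurvivalDataset,
    axis: tuple[str, str, str],
    beta_r: float | None = None,
    beta_p: float | None = None,
    mode: str = "indicator",
    alpha: float = LOGRANK_ALPHA,
    hr_fold: float = HR_FOLD,
) -> CombinatorialCoxResult:
    """Second-round combinatorial Cox model for one axis.

    The per-patient predictor is beta_r * receptor_i + beta_p * partner_i
    where the component values are the binary high/low indicators
    (``mode='indicator'``, default) or standardized continuous
    expression (``mode='continuous'``); the betas default to the
    univariate Cox coefficients fit on this dataset.  Patients are then
    re-stratified at the predictor's median and beta_c / hr_c /
    logrank_p_c computed.  The model is selected when hr_c differs at
    least ``hr_fold``-fold (in either direction) from both individual
    HRs, with logrank_p_c below ``alpha`` and both individual p values.
    """
    receptor, partner, _ = axis
    res_r = _single_gene_result(dataset, receptor)
    res_p = _single_gene_result(dataset, partner)
    if res_r is None or res_p is None:
        return CombinatorialCoxResult(
            np.nan, np.nan, np.nan, np.nan, np.empty(0), np.nan, np.nan, np.nan, False, missing=True
        )
    cox_r, p_r, groups_r = res_r
    cox_p, p_p, groups_p = res_p
    if beta_r is None:
        beta_r = cox_r.beta
    if beta_p is None:
        beta_p = cox_p.beta

    if mode == "indicator":
        x_r = _groups_to_indicator(groups_r)
        x_p = _groups_to_indicator(groups_p)
    elif mode == "continuous":
        er = dataset.expression.loc[receptor].to_numpy(dtype=float)
        ep = dataset.expression.loc[partner].to_numpy(dtype=float)
        x_r = (er - er.mean()) / er.std()
        x_p = (ep - ep.mean()) / ep.std()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    predictor = beta_r * x_r + beta_p * x_p
    if np.ptp(predictor) == 0:
        return CombinatorialCoxResult(
            beta_r, beta_p, cox_r.hr, cox_p.hr, predictor, np.nan, np.nan, np.nan, False, missing=True
        )
    groups_c = median_stratify(predictor)
    p_c = _logrank_p(dataset.time, dataset.event, groups_c)
    cox_c = cox_univariate(dataset.time, dataset.event, _groups_to_indicator(groups_c))
    if cox_c.missing:
        return CombinatorialCoxResult(
            beta_r, beta_p, cox_r.hr, cox_p.hr, predictor, np.nan, np.nan, np.nan, False, missing=True
        )
    ratio_r = cox_c.hr / cox_r.hr
    ratio_p = cox_c.hr / cox_p.hr
    selected = (
        (ratio_r >= hr_fold or ratio_r <= 1 / hr_fold)
        and (ratio_p >= hr_fold or ratio_p <= 1 / hr_fold)
        and p_c < alpha
        and p_c < min(p_r, p_p)
    )
    return CombinatorialCoxResult(
        beta_r=beta_r,
        beta_p=beta_p,
        hr_r=cox_r.hr,
        hr_p=cox_p.hr,
        predictor=predictor,
        beta_c=cox_c.beta,
        hr_c=cox_c.hr,
        logrank_p_c=p_c,
        selected=bool(selected),
    )


def coefficient_regression(results: Sequence[CombinatorialCoxResult]) -> dict:
    """OLS of beta_c on (beta_r, beta_partner) over selected models.

    Returns intercept, the two slopes, R-squared and residual sd.  Needs
    at least three selected models and a full-rank design.
    """
    import statsmodels.api as sm

    rows = [(r.beta_c, r.beta_r, r.beta_p) for r in results if r.selected and not r.missing]
    if len(rows) < 3:
        raise DegenerateInputError(f"need >=3 selected models, got {len(rows)}")
    y = np.array([r[0] for r in rows])
    X = sm.add_constant(np.array([[r[1], r[2]] for r in rows]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("rank-deficient design in coefficient regression")
    fit = sm.OLS(y, X).fit()
    return {
        "intercept": float(fit.params[0]),
        "slope_beta_r": float(fit.params[1]),
        "slope_beta_p": float(fit.params[2]),
        "r_squared": float(fit.rsquared),
        "residual_sd": float(np.sqrt(fit.mse_resid)) if len(rows) > 3 else 0.0,
        "n_models": len(rows),
    }


def load_survival_dataset(
    clinical: pd.DataFrame, expression: pd.DataFrame, cohort: str | None = None
) -> SurvivalDataset:
    """Assemble a dataset from a clinical table (patient, time, event,
    cohort) and a gene x patient expression matrix, intersecting on
    patients present in both."""
    if cohort is not None:
        clinical = clinical[clinical["cohort"] == cohort]
    patients = [p for p in clinical["patient"] if p in expression.columns]
    clin = clinical.set_index("patient").loc[patients]
    return SurvivalDataset(
        time=clin["time"].to_numpy(dtype=float),
        event=clin["event"].to_numpy(dtype=int),
        expression=expression[patients],
        cohort=cohort or "",
    )
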