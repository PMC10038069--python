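"""Survival modeling and evaluation: Cox fits, nomogram point scaling, the
integrated immune-CSC-TB profile score, and the evaluation battery
(Harrell's C, calibration, IPCW time-dependent ROC, decision curves).

Kaplan-Meier estimation, the log-rank test and the Efron-ties Cox partial
likelihood are delegated to lifelines; the nomogram construction, the
two-factor integrated score and the evaluation metrics are implemented here.

Conventions: time in months, event = 1 for observed death/relapse, risk
scores ordered so larger means higher hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

NOMOGRAM_HORIZONS = (12.0, 24.0, 36.0)  # months


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float  # NaN when S never reaches 0.5

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Product-limit estimator with Greenwood confidence band.

    The median is the smallest observed time with S(t) <= 0.5, NaN if the
    curve never crosses it.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    median = float(kmf.median_survival_time_)
    return KMEstimate(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        ci_low=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_high=ci.iloc[:, 1].to_numpy(dtype=float),
        median=median if np.isfinite(median) else float("nan"),
    )


def logrank_test(groups: Sequence, records: pd.DataFrame) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, two-sided p)."""
    groups = np.asarray(groups)
    if len(groups) != len(records):
        raise ValueError("group labels and records must align")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxFit:
    factors: tuple
    coefficients: pd.Series  # log-hazard per factor
    standard_errors: pd.Series
    covariance: pd.DataFrame
    baseline_times: np.ndarray  # event-time grid (Breslow, at covariate means)
    baseline_survival: np.ndarray
    covariate_means: pd.Series
    summary: pd.DataFrame  # HR with 95% CI per factor

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[list(self.factors)].to_numpy(dtype=float) @ self.coefficients.to_numpy()

    def baseline_survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.baseline_survival[idx])

    def predict_survival(self, X: pd.DataFrame, t: float) -> np.ndarray:
        """S(t | x) = S0(t)^exp(lp(x) - lp(mean)) with the Breslow baseline."""
        lp = self.linear_predictor(X)
        lp_bar = float(self.covariate_means @ self.coefficients)
        return self.baseline_survival_at(t) ** np.exp(lp - lp_bar)


def cox_fit(X: pd.DataFrame, records: pd.DataFrame, factors: Sequence[str]) -> CoxFit:
    """Multivariate Cox fit (Efron ties, Breslow baseline).

    Raises on constant covariates (no information), on exactly collinear
    factor pairs (naming the pair), and passes lifelines' convergence errors
    through with advice to penalize when the likelihood is monotone.
    """
    factors = tuple(factors)
    if X[list(factors)].isna().any().any():
        raise ValueError("missing feature values are not allowed in cox_fit")
    for f in factors:
        if X[f].nunique() <= 1:
            raise ValueError(f"covariate {f!r} is constant; no information to fit")
    mat = X[list(factors)].to_numpy(dtype=float)
    if len(factors) > 1:
        corr = np.corrcoef(mat, rowvar=False)
        for i in range(len(factors)):
            for j in range(i + 1, len(factors)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear factors: {factors[i]!r} and {factors[j]!r}"
                    )
    if int(records["event"].sum()) < len(factors):
        raise ValueError("fewer events than factors; the fit is unidentified")

    df = X[list(factors)].copy()
    df["time"] = records["time"].to_numpy()
    df["event"] = records["event"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(
            "Cox fit failed to converge; with separated/monotone likelihoods "
            "consider a penalized fit (CoxPHFitter(penalizer=...))"
        ) from exc

    coefs = cph.params_
    se = cph.standard_errors_
    summary = pd.DataFrame(
        {
            "coef": coefs,
            "HR": np.exp(coefs),
            "HR_low": np.exp(coefs - 1.96 * se),
            "HR_high": np.exp(coefs + 1.96 * se),
            "p": cph.summary["p"],
        }
    )
    base = cph.baseline_survival_
    return CoxFit(
        factors=factors,
        coefficients=coefs,
        standard_errors=se,
        covariance=cph.variance_matrix_,
        baseline_times=base.index.to_numpy(dtype=float),
        baseline_survival=base.iloc[:, 0].to_numpy(dtype=float),
        covariate_means=df[list(factors)].mean(),
        summary=summary,
    )


def univariate_cox(X: pd.DataFrame, records: pd.DataFrame, factors: Sequence[str]) -> pd.DataFrame:
    """One single-factor Cox fit per factor; rows of HR with 95% CI."""
    rows = []
    for f in factors:
        fit = cox_fit(X, records, [f])
        rows.append(fit.summary.loc[f])
    return pd.DataFrame(rows, index=list(factors))


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NomogramModel:
    """Point-scale rescaling of a Cox model.

    Each factor contributes ``100 * |beta_j| * |x - ref_j| / D`` points,
    where ref_j is the risk-minimizing end of the factor's observed range
    and D = max_k |beta_k| * range_k, so the most influential factor spans
    0-100 points.  Total points are an exact affine image of the linear
    predictor, inverted for the survival lookup at each horizon.
    """

    factors: tuple
    coefficients: Mapping[str, float]
    references: Mapping[str, float]  # risk-minimizing range end per factor
    scale: float  # D above
    coxfit: CoxFit
    horizons: tuple = NOMOGRAM_HORIZONS

    def factor_points(self, factor: str, value) -> np.ndarray:
        beta = self.coefficients[factor]
        return 100.0 * beta * (np.asarray(value, dtype=float) - self.references[factor]) / self.scale

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        pts = np.zeros(len(X))
        for f in self.factors:
            pts = pts + self.factor_points(f, X[f].to_numpy())
        return pts

    def lp_from_points(self, points) -> np.ndarray:
        lp_ref = sum(self.coefficients[f] * self.references[f] for f in self.factors)
        return lp_ref + self.scale * np.asarray(points, dtype=float) / 100.0

    def points_from_lp(self, lp) -> np.ndarray:
        lp_ref = sum(self.coefficients[f] * self.references[f] for f in self.factors)
        return 100.0 * (np.asarray(lp, dtype=float) - lp_ref) / self.scale

    def survival_from_points(self, points, horizon: float) -> np.ndarray:
        lp = self.lp_from_points(points)
        lp_bar = float(self.coxfit.covariate_means @ self.coxfit.coefficients)
        return self.coxfit.baseline_survival_at(horizon) ** np.exp(lp - lp_bar)


def build_nomogram(
    coxfit: CoxFit,
    factor_ranges: Mapping[str, tuple[float, float]],
    horizons: Sequence[float] = NOMOGRAM_HORIZONS,
) -> NomogramModel:
    """Rescale a fitted Cox model onto the 0-100 point axes."""
    refs, spans = {}, {}
    for f in coxfit.factors:
        lo, hi = factor_ranges[f]
        if hi <= lo:
            raise ValueError(f"factor {f!r} has zero range; no axis can be drawn")
        beta = float(coxfit.coefficients[f])
        refs[f] = lo if beta >= 0 else hi  # risk-increasing direction gains points
        spans[f] = abs(beta) * (hi - lo)
    scale = max(spans.values())
    if scale == 0:
        # every coefficient is exactly zero: flat axes, unit scale avoids 0/0
        scale = 1.0
    return NomogramModel(
        factors=coxfit.factors,
        coefficients={f: float(coxfit.coefficients[f]) for f in coxfit.factors},
        references=refs,
        scale=scale,
        coxfit=coxfit,
        horizons=tuple(horizons),
    )


INTEGRATED_FACTORS = ("cd8_cd133_index", "cd8_tb_index")


def integrated_profile_score(nomogram: NomogramModel, patients: pd.DataFrame) -> np.ndarray:
    """Integrated immune-CSC-TB profile: sum of the CD8/CD133 and CD8/TB
    point contributions from a two-factor nomogram.

    Higher points always mean higher modeled hazard (the fitted sign is
    folded into the point direction); callers report the direction via the
    nomogram's coefficient signs.
    """
    if set(nomogram.factors) != set(INTEGRATED_FACTORS):
        raise ValueError(
            "integrated profile requires a nomogram restricted to the "
            f"{INTEGRATED_FACTORS} factors"
        )
    return nomogram.total_points(patients)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def concordance_index(
    scores, time, event, with_ci: bool = True
) -> tuple[float, tuple[float, float] | None]:
    """Harrell's C over usable pairs; higher score must mean higher risk.

    A pair is usable when the earlier time is an event; score ties count
    one half.  The confidence interval is a normal approximation on the
    concordance proportion.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    conc = 0.0
    n_pairs = 0
    for i in np.flatnonzero(e == 1):
        later = t > t[i]
        n_pairs += int(later.sum())
        conc += np.sum(s[i] > s[later]) + 0.5 * np.sum(s[i] == s[later])
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all times tied or no events)")
    c = conc / n_pairs
    if not with_ci:
        return float(c), None
    se = np.sqrt(max(c * (1 - c), 1e-12) / n_pairs)
    return float(c), (float(max(c - 1.96 * se, 0.0)), float(min(c + 1.96 * se, 1.0)))


def calibration_curve(
    predict_survival: Callable[[pd.DataFrame], np.ndarray],
    X: pd.DataFrame,
    records: pd.DataFrame,
    horizon: float,
    n_groups: int = 10,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Predicted-vs-observed survival at ``horizon`` by predicted quantile.

    Groups are deciles (or fewer when predictions tie) of predicted
    survival; observed survival is the within-group Kaplan-Meier value with
    its Greenwood band.
    """
    if horizon > records["time"].max():
        raise ValueError("horizon lies beyond the last observed time")
    pred = np.asarray(predict_survival(X), dtype=float)
    if np.unique(pred).size < 2:
        grp = np.zeros(len(pred), dtype=int)  # constant predictions: one group
    else:
        grp = pd.qcut(pred, q=n_groups, labels=False, duplicates="drop")
    rows = []
    for g in np.unique(grp):
        m = grp == g
        if m.sum() < min_group_size:
            continue
        km = km_estimate(records.loc[m])
        lo_idx = np.searchsorted(km.times, horizon, side="right") - 1
        rows.append(
            {
                "group": int(g),
                "n": int(m.sum()),
                "predicted": float(pred[m].mean()),
                "observed": km.at(horizon),
                "observed_low": float(km.ci_low[lo_idx]) if lo_idx >= 0 else 1.0,
                "observed_high": float(km.ci_high[lo_idx]) if lo_idx >= 0 else 1.0,
            }
        )
    return pd.DataFrame(rows)


def _censoring_km(records: pd.DataFrame) -> KMEstimate:
    """KM of the censoring distribution (events and censorings swapped)."""
    flipped = records.assign(event=1 - records["event"])
    return km_estimate(flipped)


def time_dependent_roc(
    scores, records: pd.DataFrame, horizon: float
) -> tuple[float, pd.DataFrame]:
    """Cumulative/dynamic AUC(t) with IPCW weights.

    Cases are subjects with an observed event by ``horizon``; controls are
    those still at risk beyond it.  Weights are 1/G(t_i) for cases and
    1/G(horizon) for controls, with G the Kaplan-Meier estimate of the
    censoring survival.  Without censoring this reduces exactly to the
    empirical AUC of the binary outcome (event by horizon).
    """
    s = np.asarray(scores, dtype=float)
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if not cases.any() or not controls.any():
        raise ValueError("need both events by the horizon and survivors beyond it")
    G = _censoring_km(records)
    g_tau = G.at(horizon)
    if g_tau <= 0:
        raise ValueError("censoring survival reaches 0 at the horizon; AUC undefined")
    # G evaluated just before each case's event time
    w_case = np.array([1.0 / max(G.at(ti - 1e-9), 1e-12) for ti in t[cases]])
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_tau)

    sc, scc = s[cases], s[controls]
    diff = sc[:, None] - scc[None, :]
    wij = w_case[:, None] * w_ctrl[None, :]
    auc = float(np.sum(wij * ((diff > 0) + 0.5 * (diff == 0))) / np.sum(wij))

    thresholds = np.unique(s)[::-1]
    sens = [np.sum(w_case * (sc >= th)) / np.sum(w_case) for th in thresholds]
    fpr = [np.sum(w_ctrl * (scc >= th)) / np.sum(w_ctrl) for th in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "fpr": fpr})
    return auc, roc


def decision_curve(
    risk, records: pd.DataFrame, horizon: float, thresholds
) -> pd.DataFrame:
    """Survival-adapted decision-curve analysis.

    ``risk`` is the model's predicted event probability by ``horizon``
    (1 - S(horizon)).  Within each treated stratum (risk >= p) the event
    probability is estimated by Kaplan-Meier so censoring is respected:
    NB(p) = TP/n - FP/n * p/(1-p).  Treat-all and treat-none reference
    curves are included.
    """
    r = np.asarray(risk, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    bad = (thr <= 0) | (thr >= 1)
    if bad.any():
        warnings.warn("thresholds at 0 or 1 are excluded from the decision curve")
        thr = thr[~bad]
    n = len(records)
    km_all = km_estimate(records)
    f_all = 1.0 - km_all.at(horizon)
    rows = []
    for p in thr:
        odds = p / (1 - p)
        treated = r >= p
        if treated.any():
            km_tr = km_estimate(records.loc[treated])
            f_tr = 1.0 - km_tr.at(horizon)
            frac = treated.mean()
            nb = frac * f_tr - frac * (1 - f_tr) * odds
        else:
            nb = 0.0
        rows.append(
            {
                "threshold": float(p),
                "net_benefit": float(nb),
                "treat_all": float(f_all - (1 - f_all) * odds),
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)
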