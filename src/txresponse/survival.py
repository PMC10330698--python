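"""Kaplan-Meier curves, log-rank tests, Cox proportional hazards, stratification.

Survival records are rows of ``(subject_id, time, event, covariates...)``
with time in months and ``event`` 1 for an observed event, 0 for censoring.
Kaplan-Meier estimation and log-rank testing are delegated to lifelines; the
Cox partial-likelihood fit is a Newton-Raphson maximizer written here so that
both Efron and Breslow tie corrections are available and the convergence
criterion is explicit.

Stratified analyses follow the "high: median and above, low: below median"
convention, including the 2x2 joint stratification by two features together
with a Cox interaction model on the two indicators and their product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .expression import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("time", "event")


class ConvergenceError(ValidationError):
    """Raised when the Cox fit cannot be completed (e.g. separation)."""


def read_survival(path) -> pd.DataFrame:
    """Read a survival CSV (subject_id, time, event, covariate columns)."""
    records = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"survival table missing columns: {missing}")
    _validate(records)
    return records


def _validate(records: pd.DataFrame) -> None:
    if (records["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    table: pd.DataFrame  # columns: time, at_risk, events, censored, survival
    median: float

    @property
    def event_times(self) -> np.ndarray:
        return self.table.loc[self.table["events"] > 0, "time"].to_numpy()

    def survival_at(self, t: float) -> float:
        prior = self.table[self.table["time"] <= t]
        return float(prior["survival"].iloc[-1]) if len(prior) else 1.0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def km_fit(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate; events precede censorings at ties."""
    _validate(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    et = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "time": et.index.to_numpy(dtype=float),
            "at_risk": et["at_risk"].to_numpy(dtype=int),
            "events": et["observed"].to_numpy(dtype=int),
            "censored": et["censored"].to_numpy(dtype=int),
            "survival": [float(surv.loc[t]) for t in et.index],
        }
    )
    return KMCurve(table=table, median=float(kmf.median_survival_time_))


def km_plot(curves: dict[str, KMCurve], path) -> None:
    """Minimal step-plot export of one or more KM curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.table["time"].to_numpy()])
        s = np.concatenate([[1.0], curve.table["survival"].to_numpy()])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def logrank_test(records: pd.DataFrame, groups) -> tuple[float, float]:
    """Unweighted log-rank test across k groups; returns (chi2, p)."""
    _validate(records)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    if records["event"].sum() == 0:
        raise ValidationError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards partial-likelihood fit."""

    summary: pd.DataFrame  # per covariate: beta, hr, se, z, p, ci_low, ci_high
    converged: bool
    n_iter: int
    n_events: int
    log_likelihood: float
    ties: str

    @property
    def beta(self) -> pd.Series:
        return self.summary["beta"]

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]

    def to_tsv(self, path) -> None:
        out = self.summary.copy()
        out.index.name = "term"
        out.to_csv(path, sep="\t")


def _cox_loglik(beta, times, events, x, ties):
    """Log partial likelihood with gradient and information matrix.

    Iterates distinct event times from largest to smallest, accumulating the
    risk-set sums S0 = sum exp(eta), S1 = sum exp(eta) x, S2 = sum exp(eta)
    x x'.  Efron's correction down-weights the tied deaths' own contribution
    by l/d at the l-th tied factor; Breslow uses the full risk set for every
    tied death.
    """
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="mergesort")
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[order[i]]
        # everyone with time == t enters the risk set
        block = []
        while i < n and times[order[i]] == t:
            k = order[i]
            s0 += w[k]
            s1 += w[k] * x[k]
            s2 += w[k] * np.outer(x[k], x[k])
            if events[k] == 1:
                block.append(k)
            i += 1
        d = len(block)
        if d == 0:
            continue
        xb = x[block]
        wb = w[block]
        ll += float(eta[block].sum())
        d0 = wb.sum()
        d1 = wb @ xb
        d2 = (wb[:, None] * xb).T @ xb
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            phi0 = s0 - frac * d0
            phi1 = s1 - frac * d1
            phi2 = s2 - frac * d2
            nu = phi1 / phi0
            ll -= np.log(phi0)
            grad -= nu
            info += phi2 / phi0 - np.outer(nu, nu)
        grad += xb.sum(axis=0)
    return ll, grad, info


def cox_fit(
    records: pd.DataFrame,
    covariate_names: list[str],
    ties: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-9,
) -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Converges when the maximal absolute score falls below ``tol`` (with
    step-halving whenever a full Newton step decreases the likelihood) or
    after ``max_iter`` iterations, in which case the fit is returned flagged
    unconverged.  Wald statistics, p values and 95% confidence intervals are
    reported per covariate.
    """
    _validate(records)
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be efron or breslow, got {ties!r}")
    missing = [c for c in covariate_names if c not in records.columns]
    if missing:
        raise ValidationError(f"missing covariates: {missing}")
    n_events = int(records["event"].sum())
    if n_events == 0:
        raise ValidationError("Cox fit needs at least one event")
    x_raw = records[list(covariate_names)].to_numpy(dtype=float)
    constant = [c for c, s in zip(covariate_names, x_raw.std(axis=0)) if s == 0]
    if constant:
        raise ValidationError(f"constant covariates: {constant}")
    center = x_raw.mean(axis=0)
    x = x_raw - center  # beta is shift-invariant; centering stabilizes exp()
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, times, events, x, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik(new_beta, times, events, x, ties)
        halvings = 0
        # only halve on a decrease beyond float noise in the summed likelihood
        noise = 1e-10 * max(1.0, abs(ll))
        while new_ll < ll - noise and halvings < 10:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, times, events, x, ties)
            halvings += 1
        stalled = new_ll <= ll + 1e-13
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if stalled:
            # likelihood is flat to machine precision: accept if the score is tiny
            converged = bool(np.max(np.abs(grad)) < 1e-6)
            break
        if np.max(np.abs(beta)) > 20:
            raise ConvergenceError(
                "coefficients diverged (|beta| > 20): likely complete separation; "
                "consider penalized regression"
            )
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged:
        logger.warning("Cox fit did not converge in %d iterations (max |score| = %.3g)",
                       max_iter, float(np.max(np.abs(grad))))
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": pvals,
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
        },
        index=list(covariate_names),
    )
    return CoxFit(
        summary=summary,
        converged=converged,
        n_iter=it,
        n_events=n_events,
        log_likelihood=float(ll),
        ties=ties,
    )


def median_stratify(values) -> np.ndarray:
    """Label each value 'high' (median and above) or 'low' (below median).

    For even n the median is the midpoint of the two central order
    statistics.  Degenerate all-identical input labels everything 'high'
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("median stratification needs >= 2 subjects")
    if np.ptp(values) == 0:
        logger.warning("all values identical: degenerate stratification (all 'high')")
        return np.full(values.size, "high", dtype=object)
    med = np.median(values)
    return np.where(values >= med, "high", "low").astype(object)


@dataclass
class JointStrataResult:
    """2x2 joint median stratification with log-rank and interaction Cox fit."""

    labels: pd.Series  # per subject, e.g. "high/high"
    n_groups: int
    logrank_statistic: float
    logrank_p: float
    interaction_fit: CoxFit | None


def joint_strata_analysis(
    records: pd.DataFrame,
    feature1,
    feature2,
    feature_names: tuple[str, str] = ("feature1", "feature2"),
) -> JointStrataResult:
    """Stratify by two features jointly and test their survival interaction.

    Both features are median-stratified; subjects fall into the four
    high/low combinations; a log-rank test is run across the non-empty
    groups; and a Cox model with the two high-indicators and their product
    reports main-effect and interaction hazard ratios.  The interaction fit
    is skipped (None) when an indicator is constant or the design is
    collinear (e.g. identical features collapse the 2x2 to two groups).
    """
    _validate(records)
    f1 = np.asarray(feature1, dtype=float)
    f2 = np.asarray(feature2, dtype=float)
    if f1.size != len(records) or f2.size != len(records):
        raise ValidationError("features must be defined for every record")
    s1 = median_stratify(f1)
    s2 = median_stratify(f2)
    labels = pd.Series([f"{a}/{b}" for a, b in zip(s1, s2)], index=records.index)
    observed = labels.unique()
    if len(observed) < 4:
        logger.warning("joint strata collapsed to %d groups: %s", len(observed),
                       sorted(observed))
    chi2, p = logrank_test(records, labels.to_numpy())
    x1 = (s1 == "high").astype(float)
    x2 = (s2 == "high").astype(float)
    design = records.copy()
    n1, n2 = feature_names
    design[f"{n1}_high"] = x1
    design[f"{n2}_high"] = x2
    design["interaction"] = x1 * x2
    terms = [f"{n1}_high", f"{n2}_high", "interaction"]
    mat = design[terms].to_numpy()
    fit: CoxFit | None = None
    if (mat.std(axis=0) == 0).any() or np.linalg.matrix_rank(mat - mat.mean(axis=0)) < 3:
        logger.warning("interaction fit skipped: constant or collinear indicators")
    else:
        try:
            fit = cox_fit(design, terms)
        except ConvergenceError as exc:
            logger.warning("interaction fit skipped: %s", exc)
    return JointStrataResult(
        labels=labels,
        n_groups=len(observed),
        logrank_statistic=chi2,
        logrank_p=p,
        interaction_fit=fit,
    )


def filter_pre_progression(records: pd.DataFrame, flag_column: str) -> pd.DataFrame:
    """Keep subjects whose biopsy preceded progression (truthy flag column).

    Progression-free-survival analyses of on-treatment biopsies should not
    condition on samples taken after the event being timed; the caller
    supplies the biopsy-before-progression flag per record.
    """
    if flag_column not in records.columns:
        raise ValidationError(f"missing flag column {flag_column!r}")
    return records[records[flag_column].astype(bool)].reset_index(drop=True)
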