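"""Expression-survival association screens.

Median-split Kaplan-Meier with a two-group log-rank test, univariate Cox
proportional-hazards regression (Newton iteration on the Breslow partial
likelihood for a single continuous covariate), and a screen over gene x
tumour-type pairs with Benjamini-Hochberg FDR adjustment across the whole
family.

Expression covariates are z-scored per tumour type by default so Cox
coefficients are log-hazards per standard deviation; raw scale by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxResult",
    "KMResult",
    "cox_newton",
    "cox_association",
    "km_median_split",
    "survival_screen",
]


@dataclass(frozen=True)
class CoxResult:
    coefficient: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool
    n_iterations: int


@dataclass(frozen=True)
class KMResult:
    """Two product-limit curves and the log-rank comparison."""

    high_curve: pd.DataFrame   # columns: time, survival
    low_curve: pd.DataFrame
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    evaluable: bool


def cox_newton(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Maximise the Breslow partial likelihood for one covariate by Newton.

    Iterates to a gradient magnitude below ``tol`` with step-halving when a
    step would decrease the partial log-likelihood. ``se`` is the inverse
    square root of the observed information; the p-value is a two-sided
    Wald test.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(x) == len(time) == len(event)):
        raise ValueError("x, time and event must have equal length")
    n_events = int(event.sum())
    if n_events == 0:
        return CoxResult(float("nan"), float("nan"), float("nan"),
                         len(x), 0, False, 0)

    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    # Unique event times (Breslow: all events at time t share one risk set).
    unique_times, start_idx = np.unique(time, return_index=True)

    def loglik_grad_hess(beta: float) -> tuple[float, float, float]:
        eta = beta * x
        w = np.exp(eta)
        # Reverse cumulative sums: risk set at time t = all with time >= t.
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((x * w)[::-1])[::-1]
        s2 = np.cumsum((x * x * w)[::-1])[::-1]
        ll = grad = hess = 0.0
        for t_idx, t in zip(start_idx, unique_times):
            at_t = event[time == t].astype(bool)
            d = int(at_t.sum())
            if d == 0:
                continue
            ev_x = x[time == t][at_t]
            m0, m1, m2 = s0[t_idx], s1[t_idx], s2[t_idx]
            ll += beta * ev_x.sum() - d * np.log(m0)
            mean = m1 / m0
            grad += ev_x.sum() - d * mean
            hess -= d * (m2 / m0 - mean * mean)
        return ll, grad, hess

    beta = 0.0
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if abs(grad) < tol:
            converged = True
            break
        if hess >= 0:
            break  # degenerate information; cannot proceed
        step = -grad / hess
        new_beta = beta + step
        new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        iterations = max_iter
    if abs(grad) < tol:
        converged = True
    if not converged or hess >= 0:
        return CoxResult(beta, float("nan"), float("nan"), len(x), n_events,
                         False, iterations)
    se = 1.0 / np.sqrt(-hess)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(float(beta), float(se), float(p), len(x), n_events,
                     True, iterations)


def _aligned(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    gene: str,
    tumour_type: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if gene not in expression.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    sub = survival[survival["tumour_type"] == tumour_type]
    ids = [s for s in sub["sample"] if s in expression.columns]
    sub = sub.set_index("sample").loc[ids]
    x = expression.loc[gene, ids].to_numpy(dtype=float)
    return x, sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=int)


def cox_association(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    gene: str,
    tumour_type: str,
    z_scale: bool = True,
    min_events: int = 10,
    tol: float = 1e-8,
) -> CoxResult:
    """Univariate Cox regression of survival on one gene's expression.

    With ``z_scale`` (default) the covariate is z-scored within the tumour
    type, so the coefficient is a log-hazard per expression SD.
    """
    x, time, event = _aligned(expression, survival, gene, tumour_type)
    if int(event.sum()) < min_events:
        return CoxResult(float("nan"), float("nan"), float("nan"),
                         len(x), int(event.sum()), False, 0)
    if z_scale:
        sd = x.std(ddof=0)
        if sd == 0:
            return CoxResult(float("nan"), float("nan"), float("nan"),
                             len(x), int(event.sum()), False, 0)
        x = (x - x.mean()) / sd
    return cox_newton(x, time, event, tol=tol)


def km_median_split(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    gene: str,
    tumour_type: str,
) -> KMResult:
    """Kaplan-Meier curves for expression > median vs <= median groups."""
    x, time, event = _aligned(expression, survival, gene, tumour_type)
    if int(event.sum()) < 2:
        raise ValueError("need at least 2 events for a median-split comparison")
    median = np.median(x)
    high = x > median
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("median split produced an empty group")

    def fit(mask: np.ndarray) -> pd.DataFrame:
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        return curve

    high_curve, low_curve = fit(high), fit(~high)
    if event.sum() == 0 or len(np.unique(time[event == 1])) == 0:
        return KMResult(high_curve, low_curve, int(high.sum()), int((~high).sum()),
                        float("nan"), float("nan"), False)
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    return KMResult(
        high_curve, low_curve, int(high.sum()), int((~high).sum()),
        float(lr.test_statistic), float(lr.p_value), True,
    )


def survival_screen(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    gene_set: list[str] | None = None,
    tumour_types: list[str] | None = None,
    z_scale: bool = True,
    min_events: int = 10,
    fdr: float = 0.05,
    include_logrank: bool = True,
) -> pd.DataFrame:
    """Cox association for every gene x tumour-type pair with BH-FDR.

    All evaluable (converged) pairs form a single Benjamini-Hochberg family;
    significant associations are those with ``fdr_p`` < ``fdr``. Direction
    ``worse_with_high`` corresponds to a positive Cox coefficient.
    """
    genes = list(gene_set) if gene_set is not None else list(expression.index)
    if tumour_types is None:
        tumour_types = sorted(survival["tumour_type"].unique())
    rows = []
    for ttype in tumour_types:
        for gene in genes:
            res = cox_association(expression, survival, gene, ttype,
                                  z_scale=z_scale, min_events=min_events)
            lr_chi2 = lr_p = float("nan")
            if include_logrank and res.converged:
                try:
                    km = km_median_split(expression, survival, gene, ttype)
                    lr_chi2, lr_p = km.logrank_chi2, km.logrank_p
                except ValueError:
                    pass
            rows.append({
                "gene": gene,
                "tumour_type": ttype,
                "cox_coefficient": res.coefficient,
                "se": res.se,
                "p": res.p,
                "n": res.n,
                "n_events": res.n_events,
                "converged": res.converged,
                "logrank_chi2": lr_chi2,
                "logrank_p": lr_p,
            })
    out = pd.DataFrame(rows)
    out["fdr_p"] = np.nan
    ok = out["converged"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = ok & (out["fdr_p"] < fdr)
    out["direction"] = np.where(
        out["cox_coefficient"] > 0, "worse_with_high", "better_with_high"
    )
    return out
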