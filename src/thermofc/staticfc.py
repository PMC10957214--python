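"""Static functional connectivity: Pearson matrices and edge-wise statistics.

For each cleaned acquisition an N x N Pearson correlation matrix is computed
over time.  Edge-wise condition contrasts use linear mixed models on
Fisher-transformed correlations with the animal as random intercept (fitted
by REML), a Wald test on the two-level condition fixed effect, a
Shapiro-Wilk check of residual normality, and Benjamini-Hochberg adjustment
over the family of testable edges (45 for 10 ROIs) at FDR 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import CleanSeries, CorrelationMatrix, InvalidInputError, RoiSet

__all__ = [
    "EdgeTestResult",
    "correlation_matrix",
    "fisher_transform",
    "inverse_fisher",
    "edge_observations",
    "edge_mixed_model",
    "benjamini_hochberg",
    "compare_conditions",
    "mean_condition_matrix",
]

logger = logging.getLogger(__name__)

FISHER_CLIP = 1.0 - 1e-7


def correlation_matrix(clean: CleanSeries) -> CorrelationMatrix:
    """Pearson correlation matrix of the ROI signals over time."""
    x = clean.signals
    if x.shape[1] < 3:
        raise InvalidInputError("need at least 3 frames for a correlation matrix")
    std = x.std(axis=1, ddof=1)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        names = [clean.roi.names[i] for i in dead]
        raise InvalidInputError(f"zero-variance ROI(s): {names}")
    values = np.corrcoef(x)
    # guard against numerical drift outside [-1, 1]
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(values=values, roi=clean.roi, n_frames=x.shape[1])


def fisher_transform(r):
    """Fisher z = atanh(r), with |r| clipped to 1 - 1e-7."""
    r = np.clip(np.asarray(r, dtype=float), -FISHER_CLIP, FISHER_CLIP)
    return np.arctanh(r)


def inverse_fisher(z):
    return np.tanh(np.asarray(z, dtype=float))


def edge_observations(matrices: list[CorrelationMatrix],
                      meta: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-edge observations across a cohort.

    ``meta`` must align row-wise with ``matrices`` and provide
    acquisition_id, animal_id, condition.  Output columns: roi_i, roi_j
    (i < j in canonical order), acquisition_id, animal_id, condition, r, z.
    """
    if len(matrices) != len(meta):
        raise InvalidInputError("metadata rows must align with matrices")
    rows = []
    for cm, (_, m) in zip(matrices, meta.iterrows()):
        names = cm.roi.names
        iu = np.triu_indices(cm.roi.n, k=1)
        for i, j in zip(*iu):
            r = cm.values[i, j]
            rows.append({
                "roi_i": names[i],
                "roi_j": names[j],
                "acquisition_id": m["acquisition_id"],
                "animal_id": m["animal_id"],
                "condition": m["condition"],
                "r": r,
                "z": float(fisher_transform(r)),
            })
    return pd.DataFrame(rows)


@dataclass
class EdgeTestResult:
    edge: tuple[str, str]
    condition_pair: tuple[str, str]
    estimate: float  # fixed-effect difference (cond_b - cond_a) on Fisher scale
    p_raw: float
    shapiro_p: float
    n_obs: int
    n_animals: int
    method: str  # "mixedlm" or "ols" (degenerate-variance fallback)
    status: str = "ok"  # or "untestable"
    p_adjusted: float = np.nan
    significant: bool = False


def _wald_df(n_obs: int, n_groups: int, n_fixed: int) -> int:
    """Residual degrees of freedom for the Wald t reference.

    The finite-sample reference t(N - g - (p - 1)) (observations minus
    animals minus non-intercept fixed effects) keeps the test close to its
    nominal level at cohort-scale designs, where the asymptotic normal
    reference is anticonservative.
    """
    return max(n_obs - n_groups - (n_fixed - 1), 1)


def _fit_condition_model(df: pd.DataFrame, value_col: str = "z",
                         reference: str = "t"):
    """REML random-intercept fit of value ~ condition, with OLS fallback.

    Returns (estimate, p_raw, residuals, method).  ``df`` must contain
    columns value_col, animal_id, and a 2-level categorical ``condition``
    whose second level's coefficient is tested.  ``reference`` selects the
    Wald reference distribution: "t" (default) or "normal".
    """
    data = df.copy()
    data["y"] = data[value_col]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm("y ~ C(condition)", data, groups=data["animal_id"])
            fit = model.fit(reml=True)
            coef_name = [n for n in fit.params.index if n.startswith("C(condition)")][0]
            singular = not np.isfinite(fit.bse[coef_name]) or fit.cov_re.iloc[0, 0] < 1e-10
            if not singular:
                resid = np.asarray(fit.resid)
                if reference == "t":
                    tstat = fit.params[coef_name] / fit.bse[coef_name]
                    dof = _wald_df(len(data), data["animal_id"].nunique(),
                                   len(fit.fe_params))
                    p = float(2 * stats.t.sf(abs(tstat), dof))
                else:
                    p = float(fit.pvalues[coef_name])
                return float(fit.params[coef_name]), p, resid, "mixedlm"
        except (np.linalg.LinAlgError, ValueError):
            pass
    logger.info("degenerate mixed-model fit; falling back to OLS")
    ols = smf.ols("y ~ C(condition)", data).fit()
    coef_name = [n for n in ols.params.index if n.startswith("C(condition)")][0]
    return (float(ols.params[coef_name]), float(ols.pvalues[coef_name]),
            np.asarray(ols.resid), "ols")


def edge_mixed_model(obs: pd.DataFrame, condition_pair: tuple[str, str]) -> EdgeTestResult:
    """Mixed-model condition contrast for one edge.

    ``obs`` holds the Fisher-scale observations of a single edge; rows whose
    condition is outside ``condition_pair`` are ignored.  The model is
    z ~ condition with a per-animal random intercept, fitted by REML; the
    reported p-value is the Wald test of the condition coefficient and the
    estimate is mean(cond_b) - mean(cond_a) adjusting for animal.
    """
    cond_a, cond_b = condition_pair
    edge = (obs["roi_i"].iloc[0], obs["roi_j"].iloc[0])
    df = obs.loc[obs["condition"].isin(condition_pair)].copy()
    df["condition"] = pd.Categorical(df["condition"], categories=[cond_a, cond_b])

    counts = df["condition"].value_counts()
    n_animals = df["animal_id"].nunique()
    enough = (
        n_animals >= 2
        and counts.get(cond_a, 0) >= 3
        and counts.get(cond_b, 0) >= 3
    )
    if not enough:
        logger.warning("edge %s untestable for %s: insufficient data", edge, condition_pair)
        return EdgeTestResult(edge, condition_pair, np.nan, np.nan, np.nan,
                              len(df), n_animals, "none", status="untestable")

    estimate, p_raw, resid, method = _fit_condition_model(df)
    if len(resid) >= 3 and np.ptp(resid) > 0:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    else:
        shapiro_p = np.nan
    return EdgeTestResult(edge, condition_pair, estimate, p_raw, shapiro_p,
                          len(df), n_animals, method)


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH adjustment; returns (adjusted p, reject mask at FDR q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    # canonical step-up rule: reject iff adjusted p <= q (equivalent to the
    # largest k with p_(k) <= k q / m)
    return adjusted, adjusted <= q


def compare_conditions(observations: pd.DataFrame, condition_pair: tuple[str, str],
                       roi: RoiSet | None = None, q: float = 0.05):
    """Edge-wise condition comparison across the full edge family.

    Fits the mixed model for every edge, applies BH over the family of
    testable edges, and returns (significance matrix (N x N bool), delta-z
    matrix of fixed-effect estimates, tidy result table).
    """
    roi = roi or RoiSet()
    results: list[EdgeTestResult] = []
    for (ri, rj), sub in observations.groupby(["roi_i", "roi_j"], sort=True):
        results.append(edge_mixed_model(sub, condition_pair))

    testable = [r for r in results if r.status == "ok"]
    if testable:
        adjusted, reject = benjamini_hochberg([r.p_raw for r in testable], q)
        for r, padj, rej in zip(testable, adjusted, reject):
            r.p_adjusted = float(padj)
            r.significant = bool(rej)

    n = roi.n
    sig = np.zeros((n, n), dtype=bool)
    delta = np.full((n, n), np.nan)
    np.fill_diagonal(delta, 0.0)
    for r in results:
        i, j = roi.index(r.edge[0]), roi.index(r.edge[1])
        if r.status == "ok":
            sig[i, j] = sig[j, i] = r.significant
            delta[i, j] = delta[j, i] = r.estimate

    table = pd.DataFrame([{
        "roi_i": r.edge[0], "roi_j": r.edge[1],
        "condition_a": r.condition_pair[0], "condition_b": r.condition_pair[1],
        "estimate": r.estimate, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
        "significant": r.significant, "shapiro_p": r.shapiro_p,
        "n_obs": r.n_obs, "n_animals": r.n_animals,
        "method": r.method, "status": r.status,
    } for r in results])
    return sig, delta, table


def mean_condition_matrix(matrices: list[CorrelationMatrix], meta: pd.DataFrame,
                          condition: str) -> np.ndarray:
    """Average Pearson matrix over the acquisitions of one condition."""
    sel = [m.values for m, (_, row) in zip(matrices, meta.iterrows())
           if row["condition"] == condition]
    if not sel:
        raise InvalidInputError(f"no acquisitions for condition {condition!r}")
    return np.mean(sel, axis=0)
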