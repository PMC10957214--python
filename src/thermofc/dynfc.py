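"""Dynamic functional connectivity via cofluctuation clustering.

The static Pearson matrix decomposes exactly into per-frame cofluctuation
matrices: with per-ROI z-scores z_i (sample-variance normalization),
C_ij(t) = z_i(t) z_j(t) and r_ij = sum_t C_ij(t) / (T - 1).  Each frame's
symmetric cofluctuation matrix is vectorized to its N(N+1)/2 = 55 upper-
triangle elements; frames from all acquisitions are concatenated, outlier
frames (mean z-scored L1 distance to all others > 3) are discarded, and the
remainder is clustered with L1-distance k-means (coordinate-wise-median
centroids, best of many random restarts).  The number of brain states is
selected with the Duda-Hart split criterion, and per-acquisition state
occurrence rates are compared across thermal conditions with animal-random-
intercept mixed models and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .core import CleanSeries, InvalidInputError, RoiSet, triu_indices
from .preprocess import zscore_rows
from .staticfc import _fit_condition_model, benjamini_hochberg

__all__ = [
    "CofluctuationSeries",
    "BrainStateModel",
    "zscore_series",
    "cofluctuation_series",
    "concatenate_cohort",
    "outlier_scores",
    "filter_outliers",
    "kmeans_l1",
    "duda_hart_k",
    "occurrence_rates",
    "animal_state_homogeneity",
    "compare_occurrence",
    "align_states",
]

logger = logging.getLogger(__name__)


@dataclass
class CofluctuationSeries:
    """Per-frame vectorized cofluctuation matrices with provenance."""

    values: np.ndarray  # (T, L) with L = N(N+1)/2
    frame_meta: pd.DataFrame  # acquisition_id, animal_id, condition, frame
    roi: RoiSet = field(default_factory=RoiSet)

    def __post_init__(self) -> None:
        n = self.roi.n
        expected = n * (n + 1) // 2
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise InvalidInputError(
                f"cofluctuation values must be (T, {expected}); got {self.values.shape}"
            )
        if len(self.frame_meta) != self.values.shape[0]:
            raise InvalidInputError("frame_meta must align with values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainStateModel:
    """Result of L1 k-means clustering of cofluctuation frames."""

    k: int
    centroids: np.ndarray  # (K, L)
    labels: np.ndarray  # (T',)
    total_within_l1: float
    restarts: int
    seed: int
    state_order: np.ndarray  # permutation: state_order[rank] = original state
    objective_history: list[float] = field(default_factory=list)


def zscore_series(clean: CleanSeries) -> np.ndarray:
    """Per-ROI z-score with sample (1/(T-1)) variance normalization."""
    return zscore_rows(clean.signals, ddof=1)


def cofluctuation_series(clean: CleanSeries) -> CofluctuationSeries:
    """Per-frame cofluctuation vectors C_ij(t) = z_i(t) z_j(t), i <= j."""
    z = zscore_series(clean)
    rows, cols = triu_indices(clean.roi.n, with_diagonal=True)
    values = (z[rows] * z[cols]).T  # (T, 55)
    meta = pd.DataFrame({
        "acquisition_id": clean.source_id,
        "animal_id": clean.animal_id,
        "condition": clean.condition,
        "frame": np.arange(z.shape[1]),
    })
    return CofluctuationSeries(values=values, frame_meta=meta, roi=clean.roi)


def concatenate_cohort(series: list[CofluctuationSeries]) -> CofluctuationSeries:
    """Stack per-acquisition cofluctuation series, preserving provenance."""
    if not series:
        raise InvalidInputError("no series to concatenate")
    roi = series[0].roi
    for s in series[1:]:
        if s.roi.names != roi.names:
            raise InvalidInputError("all series must share the same RoiSet")
    values = np.vstack([s.values for s in series])
    meta = pd.concat([s.frame_meta for s in series], ignore_index=True)
    return CofluctuationSeries(values=values, frame_meta=meta, roi=roi)


def outlier_scores(values: np.ndarray) -> np.ndarray:
    """z-scored mean L1 distance of each frame to all other frames.

    Computed per coordinate with sorted prefix sums in O(L T log T); the
    T x T distance matrix is never materialized.  For a sorted column s with
    prefix sums P, the summed distance of the element of rank r is
    s_r (2(r+1) - T) - 2 P_{r+1} + P_T.
    """
    x = np.asarray(values, dtype=float)
    t = x.shape[0]
    if t < 3:
        raise InvalidInputError("need at least 3 frames for outlier scoring")
    total = np.zeros(t)
    for c in range(x.shape[1]):
        col = x[:, c]
        order = np.argsort(col, kind="stable")
        s = col[order]
        prefix = np.concatenate([[0.0], np.cumsum(s)])
        ranks = np.arange(1, t + 1)
        contrib = s * (2 * ranks - t) - 2 * prefix[1:] + prefix[t]
        total[order] += contrib
    mean_dist = total / (t - 1)
    sd = mean_dist.std(ddof=1)
    if sd == 0:
        return np.zeros(t)
    return (mean_dist - mean_dist.mean()) / sd


def filter_outliers(cofl: CofluctuationSeries, z_threshold: float = 3.0
                    ) -> tuple[CofluctuationSeries, np.ndarray]:
    """Drop frames whose mean z-scored L1 distance exceeds the threshold."""
    scores = outlier_scores(cofl.values)
    keep = scores <= z_threshold
    filtered = CofluctuationSeries(
        values=cofl.values[keep],
        frame_meta=cofl.frame_meta.loc[keep].reset_index(drop=True),
        roi=cofl.roi,
    )
    return filtered, keep


def _lloyd_l1(x: np.ndarray, init: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One L1 k-means run: L1 assignment, coordinate-wise-median update."""
    centroids = init.copy()
    k = centroids.shape[0]
    labels = np.full(x.shape[0], -1, dtype=np.int64)
    history: list[float] = []
    for _ in range(max_iter):
        dist = cdist(x, centroids, metric="cityblock")
        new_labels = dist.argmin(axis=1)
        point_dist = dist[np.arange(x.shape[0]), new_labels]
        history.append(float(point_dist.sum()))
        for j in range(k):
            if not np.any(new_labels == j):
                # re-seed an empty cluster at the point farthest from its centroid
                far = int(point_dist.argmax())
                centroids[j] = x[far]
                new_labels[far] = j
                point_dist[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = np.median(x[labels == j], axis=0)
    dist = cdist(x, centroids, metric="cityblock")
    labels = dist.argmin(axis=1)
    objective = float(dist[np.arange(x.shape[0]), labels].sum())
    history.append(objective)
    return labels, centroids, objective, history


def kmeans_l1(x: np.ndarray, k: int, restarts: int = 500, max_iter: int = 300,
              seed: int = 0) -> BrainStateModel:
    """k-means with the L1 (cityblock) distance and median centroid updates.

    Each restart initializes centroids at ``k`` distinct data points chosen
    uniformly at random (per-restart RNG streams derived from ``seed``); the
    run minimizing the total within-cluster L1 distance is retained.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("x must be 2-D (frames x features)")
    if k > x.shape[0]:
        raise InvalidInputError(f"K={k} exceeds the number of frames {x.shape[0]}")
    if restarts < 1:
        raise InvalidInputError("restarts must be >= 1")

    streams = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for stream in streams:
        rng = np.random.default_rng(stream)
        init = x[rng.choice(x.shape[0], size=k, replace=False)]
        labels, centroids, objective, history = _lloyd_l1(x, init, max_iter)
        if best is None or objective < best[2]:
            best = (labels, centroids, objective, history)

    labels, centroids, objective, history = best
    pooled = np.bincount(labels, minlength=k).astype(float)
    norms = np.abs(centroids).sum(axis=1)
    # descending occurrence, ties broken by descending centroid L1 norm
    order = np.lexsort((-norms, -pooled))
    return BrainStateModel(
        k=k, centroids=centroids, labels=labels, total_within_l1=objective,
        restarts=restarts, seed=seed, state_order=order,
        objective_history=history,
    )


def duda_hart_critical(n: int, d: int, alpha: float = 0.05) -> float:
    """Critical Je(2)/Je(1) ratio below which a cluster should be split."""
    z = stats.norm.ppf(1 - alpha)
    return 1 - 2 / (np.pi * d) - z * np.sqrt(2 * (1 - 8 / (np.pi**2 * d)) / (n * d))


def duda_hart_k(x: np.ndarray, k_max: int = 10, alpha: float = 0.05,
                restarts: int = 20, max_iter: int = 300, seed: int = 0,
                min_cluster_factor: int = 2) -> tuple[int | None, pd.DataFrame]:
    """Select the number of clusters with the Duda-Hart split criterion.

    For each K in 1..k_max the data are clustered (L1 k-means) and every
    cluster is tentatively split in two (squared-error 2-means); the split
    is deemed significant when Je(2)/Je(1) falls below the critical value
    1 - 2/(pi d) - z_alpha sqrt(2 (1 - 8/(pi^2 d)) / (n d)).  The selected K
    is the smallest whose split count is zero and stays zero through k_max.
    Clusters smaller than ``min_cluster_factor * d`` frames are exempted
    from the test (counted in the report as ``n_exempt``).
    """
    from sklearn.cluster import KMeans

    x = np.asarray(x, dtype=float)
    if k_max < 1:
        raise InvalidInputError("k_max must be >= 1")
    d = x.shape[1]
    min_size = max(min_cluster_factor * d, 4)
    rows = []
    ss = np.random.SeedSequence(seed).spawn(k_max)
    for k, stream in zip(range(1, k_max + 1), ss):
        child = np.random.default_rng(stream)
        model = kmeans_l1(x, k, restarts=restarts, max_iter=max_iter,
                          seed=int(child.integers(2**31 - 1)))
        split_count = 0
        n_exempt = 0
        for j in range(k):
            members = x[model.labels == j]
            n = members.shape[0]
            if n < min_size:
                n_exempt += 1
                continue
            mean = members.mean(axis=0)
            je1 = float(((members - mean) ** 2).sum())
            if je1 <= 0:
                continue
            km2 = KMeans(n_clusters=2, n_init=5,
                         random_state=int(child.integers(2**31 - 1)))
            km2.fit(members)
            je2 = float(km2.inertia_)
            if je2 / je1 < duda_hart_critical(n, d, alpha):
                split_count += 1
        rows.append({"k": k, "split_count": split_count, "n_exempt": n_exempt})

    report = pd.DataFrame(rows)
    selected = None
    for k in range(1, k_max + 1):
        tail = report.loc[report["k"] >= k, "split_count"]
        if (tail == 0).all():
            selected = k
            break
    return selected, report


def occurrence_rates(model: BrainStateModel, frame_meta: pd.DataFrame,
                     manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-acquisition fraction of retained frames in each brain state.

    States are reported both under their internal index (``state``) and
    their occurrence rank (``state_rank``: 1 = most frequent overall).
    Rates sum to 1 within each acquisition.
    """
    if len(frame_meta) != len(model.labels):
        raise InvalidInputError("frame_meta must align with model labels")
    rank_of_state = np.empty(model.k, dtype=int)
    rank_of_state[model.state_order] = np.arange(1, model.k + 1)

    df = frame_meta.copy()
    df["state"] = model.labels
    rows = []
    for acq_id, sub in df.groupby("acquisition_id", sort=True):
        counts = np.bincount(sub["state"], minlength=model.k)
        rates = counts / counts.sum()
        for s in range(model.k):
            rows.append({
                "animal_id": sub["animal_id"].iloc[0],
                "condition": sub["condition"].iloc[0],
                "acquisition_id": acq_id,
                "state": s,
                "state_rank": int(rank_of_state[s]),
                "rate": rates[s],
            })
    table = pd.DataFrame(rows)
    if manifest is not None:
        known = set(manifest["acquisition_id"])
        unknown = set(table["acquisition_id"]) - known
        if unknown:
            raise InvalidInputError(f"labeled frames from acquisitions not in manifest: {sorted(unknown)}")
    return table


def animal_state_homogeneity(model: BrainStateModel, frame_meta: pd.DataFrame
                             ) -> tuple[pd.DataFrame, float, float]:
    """Each animal's share of each state's frames, plus a descriptive chi-square.

    Returns (composition table: animals x states, chi2 statistic, p-value).
    The chi-square tests independence of animal and state in the frame
    contingency table; it is reported as a diagnostic, not used for gating.
    """
    if frame_meta["animal_id"].nunique() < 2:
        raise InvalidInputError("homogeneity check needs at least 2 animals")
    counts = pd.crosstab(frame_meta["animal_id"], pd.Series(model.labels, name="state"))
    counts = counts.reindex(columns=range(model.k), fill_value=0)
    shares = counts / counts.sum(axis=0)
    chi2, p, _, _ = stats.chi2_contingency(counts.to_numpy() + 0.0)
    return shares, float(chi2), float(p)


def _omnibus_condition_test(df: pd.DataFrame) -> tuple[float, str]:
    """Wald test that all condition coefficients are zero (mixed model).

    The joint Wald statistic is referred to an F(q, N - g - q) distribution
    rather than chi-square(q), keeping the omnibus test near its nominal
    level at cohort-scale designs.
    """
    import statsmodels.formula.api as smf

    from .staticfc import _wald_df

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm("rate ~ C(condition)", df, groups=df["animal_id"]).fit(reml=True)
            names = [n for n in fit.params.index if n.startswith("C(condition)")]
            if names and np.all(np.isfinite([fit.bse[n] for n in names])):
                contrast = pd.DataFrame(
                    np.eye(len(fit.params))[[list(fit.params.index).index(n) for n in names]],
                    columns=fit.params.index,
                )
                wald = fit.wald_test(contrast.to_numpy(), scalar=True)
                q = len(names)
                dof = _wald_df(len(df), df["animal_id"].nunique(), len(fit.fe_params))
                p = float(stats.f.sf(float(wald.statistic) / q, q, dof))
                return p, "mixedlm"
        except (np.linalg.LinAlgError, ValueError):
            pass
        fit = smf.ols("rate ~ C(condition)", df).fit()
        names = [n for n in fit.params.index if n.startswith("C(condition)")]
        wald = fit.f_test(np.eye(len(fit.params))[[list(fit.params.index).index(n) for n in names]])
        return float(wald.pvalue), "ols"


def compare_occurrence(table: pd.DataFrame, q: float = 0.05,
                       omnibus_alpha: float = 0.05) -> pd.DataFrame:
    """Condition statistics on state occurrence rates.

    Per state: an animal-random-intercept mixed model with the multi-level
    condition fixed effect.  Omnibus p-values are BH-adjusted across the
    family of K states (each state is one hypothesis); pairwise condition
    contrasts are computed only for states whose adjusted omnibus p-value is
    below ``omnibus_alpha``, and their p-values are BH-adjusted at FDR ``q``
    within the state.  Returns a tidy table with one omnibus row per state
    plus pairwise rows; a significant omnibus row means the state's
    occurrence rate differs somewhere across conditions.
    """
    conditions = sorted(table["condition"].unique())
    omni_rows = []
    subs = {}
    for state, sub in table.groupby("state", sort=True):
        subs[state] = sub.copy()
        if len(conditions) < 2:
            omni_rows.append({"state": state, "kind": "omnibus", "condition_a": None,
                              "condition_b": None, "estimate": np.nan, "p_raw": np.nan,
                              "p_adjusted": np.nan, "significant": False,
                              "status": "untestable", "method": "none"})
            continue
        p_omni, method = _omnibus_condition_test(subs[state])
        omni_rows.append({"state": state, "kind": "omnibus", "condition_a": None,
                          "condition_b": None, "estimate": np.nan, "p_raw": p_omni,
                          "p_adjusted": np.nan, "significant": False,
                          "status": "ok", "method": method})

    testable = [r for r in omni_rows if r["status"] == "ok"]
    if testable:
        adjusted, reject = benjamini_hochberg([r["p_raw"] for r in testable],
                                              q=omnibus_alpha)
        for r, padj, rej in zip(testable, adjusted, reject):
            r["p_adjusted"] = float(padj)
            r["significant"] = bool(rej)

    rows = []
    for omni in omni_rows:
        rows.append(omni)
        if not omni["significant"]:
            continue
        sub = subs[omni["state"]]
        pair_rows = []
        for ia in range(len(conditions)):
            for ib in range(ia + 1, len(conditions)):
                ca, cb = conditions[ia], conditions[ib]
                pair = sub.loc[sub["condition"].isin([ca, cb])].copy()
                pair["condition"] = pd.Categorical(pair["condition"], categories=[ca, cb])
                est, p_raw, _, m = _fit_condition_model(pair, value_col="rate")
                pair_rows.append({"state": omni["state"], "kind": "pairwise",
                                  "condition_a": ca, "condition_b": cb,
                                  "estimate": est, "p_raw": p_raw,
                                  "p_adjusted": np.nan, "significant": False,
                                  "status": "ok", "method": m})
        adjusted, reject = benjamini_hochberg([r["p_raw"] for r in pair_rows], q)
        for r, padj, rej in zip(pair_rows, adjusted, reject):
            r["p_adjusted"] = float(padj)
            r["significant"] = bool(rej)
        rows.extend(pair_rows)
    return pd.DataFrame(rows)


def align_states(centroids: np.ndarray, references: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of centroids to reference patterns by correlation.

    Both inputs are (K, L) vectorized symmetric matrices.  Returns
    (assignment, correlations) where ``assignment[j]`` is the centroid index
    matched to reference j and ``correlations[j]`` the Pearson correlation
    of that pair.
    """
    centroids = np.asarray(centroids, dtype=float)
    references = np.asarray(references, dtype=float)
    k = references.shape[0]
    corr = np.empty((k, centroids.shape[0]))
    for i in range(k):
        for j in range(centroids.shape[0]):
            corr[i, j] = np.corrcoef(references[i], centroids[j])[0, 1]
    ref_idx, cen_idx = linear_sum_assignment(-corr)
    assignment = np.empty(k, dtype=int)
    correlations = np.empty(k)
    for r, c in zip(ref_idx, cen_idx):
        assignment[r] = c
        correlations[r] = corr[r, c]
    return assignment, correlations
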