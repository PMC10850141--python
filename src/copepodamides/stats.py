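"""Compositional statistics for copepodamide profiles.

Implements the multivariate workflow used to compare freshwater and marine
copepodamide compositions: Bray-Curtis dissimilarity between samples,
one-way PERMANOVA (distance-based pseudo-F with a label-permutation null),
PERMDISP (homogeneity of multivariate dispersion via principal-coordinates
embedding), non-metric multidimensional scaling (SMACOF majorisation with
Kruskal's monotone regression by pool-adjacent-violators), ANCOVA with
partial eta squared, and centroid confidence ellipses for ordination plots.

The permutation machinery is written here from first principles; only the
ordinary linear-model fit behind the ANCOVA and the Shapiro-Wilk normality
diagnostic come from statsmodels/scipy.

Distance matrices are square pandas DataFrames (index == columns == sample
ids) or plain symmetric ndarrays. Bray-Curtis does not satisfy the triangle
inequality in general; nothing here assumes it does.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "bray_curtis",
    "permanova",
    "permdisp",
    "nmds",
    "ancova",
    "centroid_ellipses",
    "pava",
    "pcoa",
    "PermutationTestResult",
    "OrdinationResult",
    "AncovaResult",
    "Ellipse",
]


# ---------------------------------------------------------------------------
# dissimilarity


def bray_curtis(matrix: pd.DataFrame | np.ndarray, normalise: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between rows.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk), in [0, 1].
    With ``normalise`` each row is first rescaled to relative abundance, so
    the comparison is compositional rather than driven by totals. A pair of
    all-zero rows has undefined distance: it is set to NaN with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(x.shape[0]))
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")

    zero_rows = x.sum(axis=1) == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero sample(s); distances between "
            "two all-zero samples are undefined (NaN)",
            stacklevel=2,
        )
    if normalise:
        totals = x.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(totals > 0, x / totals, x)

    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    summ = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(summ > 0, diff / summ, np.nan)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def _as_square(d) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(arr).any():
        raise ValueError("distance matrix contains NaN (undefined pairs)")
    return arr


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermutationTestResult:
    """A permutation test outcome (PERMANOVA pseudo-F or PERMDISP F)."""

    statistic: float
    df_between: int
    df_within: int
    p_value: float
    n_permutations: int
    method: str
    r_squared: float | None = None
    seed: int | None = None


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    return codes, len(uniques)


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_among, SS_within) from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        if n_g > 1:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss_total - ss_within, ss_within


def _distinct_label_permutations(codes: np.ndarray):
    """All distinct assignments of the multiset of labels to positions."""
    from sympy.utilities.iterables import multiset_permutations

    return multiset_permutations(list(codes))


def permanova(
    d: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F follows the distance-based sum-of-squares decomposition
    (equivalent to Gower-centring the squared-distance matrix):
    SS_total = sum d_ij^2 / n over all pairs, SS_within the analogous
    per-group sums, F = (SS_among/(a-1)) / (SS_within/(n-a)). The p-value
    comes from free permutation of group labels, with the observed statistic
    included in numerator and denominator: p = (#{F_perm >= F_obs} + 1) /
    (n_perm + 1), so p >= 1/(n_perm + 1).

    ``method="exact"`` enumerates all distinct label assignments instead
    (p = #{F >= F_obs} / #assignments); ``"auto"`` switches to exact when
    the enumeration is smaller than ``n_permutations``.
    """
    arr = _as_square(d)
    codes, n_groups = _group_codes(groups)
    n = arr.shape[0]
    if codes.size != n:
        raise ValueError("groups length must match distance matrix size")
    d2 = arr ** 2

    ss_among, ss_within = _permanova_ss(d2, codes, n_groups)
    ss_total = ss_among + ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0 or df_w <= 0:
        if ss_among <= 0:
            raise ValueError("all distances equal; pseudo-F undefined")
        f_obs = math.inf
    else:
        f_obs = (ss_among / df_b) / (ss_within / df_w)
    r2 = ss_among / ss_total if ss_total > 0 else float("nan")

    counts = np.bincount(codes, minlength=n_groups)
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(int(c))

    if method == "auto":
        method = "exact" if n_distinct <= n_permutations else "permutation"

    def f_of(perm_codes: np.ndarray) -> float:
        a, w = _permanova_ss(d2, perm_codes, n_groups)
        if w <= 0:
            return math.inf if a > 0 else -math.inf
        return (a / df_b) / (w / df_w)

    if method == "exact":
        stats = [f_of(np.asarray(p)) for p in _distinct_label_permutations(codes)]
        n_perm = len(stats)
        p = sum(s >= f_obs - 1e-12 for s in stats) / n_perm
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        n_perm = n_permutations
        count = 0
        perm = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            if f_of(perm) >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    return PermutationTestResult(
        statistic=f_obs, df_between=df_b, df_within=df_w, p_value=p,
        n_permutations=n_perm, method=method, r_squared=r2, seed=seed,
    )


# ---------------------------------------------------------------------------
# principal coordinates + PERMDISP


def pcoa(d: pd.DataFrame | np.ndarray, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates embedding of a distance matrix.

    Gower-centres -0.5 * d^2 and eigendecomposes. Negative eigenvalues
    (Bray-Curtis is not Euclidean-embeddable in general) are truncated at
    zero and the truncation logged via warning when substantial. Returns
    (coordinates n x k, eigenvalues).
    """
    arr = _as_square(d)
    n = arr.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (arr ** 2) @ j
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg = eigval < -1e-8
    if neg.any() and -eigval[neg].sum() > 0.05 * eigval[~neg].sum():
        warnings.warn(
            "substantial negative eigenvalues truncated at zero in PCoA",
            stacklevel=2,
        )
    eigval_trunc = np.clip(eigval, 0.0, None)
    coords = eigvec * np.sqrt(eigval_trunc)
    if k is not None:
        coords = coords[:, :k]
    return coords, eigval


def permdisp(
    d: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test of multivariate dispersion homogeneity.

    Samples are embedded by principal coordinates; each sample's Euclidean
    distance to its group centroid (the group mean in the embedding — means,
    not spatial medians) is the dispersion score; the ANOVA F on those
    scores is the statistic, with a label-permutation null on the scores.
    Groups of size 1 contribute a dispersion of 0 and are flagged.
    """
    codes, n_groups = _group_codes(groups)
    coords, _ = pcoa(d)
    n = coords.shape[0]

    singletons = [g for g in range(n_groups) if (codes == g).sum() == 1]
    if singletons:
        warnings.warn("group(s) of size 1: dispersion is trivially 0", stacklevel=2)

    z = np.empty(n)
    for g in range(n_groups):
        mask = codes == g
        centroid = coords[mask].mean(axis=0)
        z[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)

    df_b, df_w = n_groups - 1, n - n_groups

    def anova_f(values: np.ndarray, c: np.ndarray) -> float:
        grand = values.mean()
        ss_b = sum(
            (c == g).sum() * (values[c == g].mean() - grand) ** 2
            for g in range(n_groups)
        )
        ss_w = sum(
            ((values[c == g] - values[c == g].mean()) ** 2).sum()
            for g in range(n_groups)
        )
        if ss_w <= 0:
            return math.inf if ss_b > 0 else math.nan
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(z, codes)
    if math.isnan(f_obs):
        return PermutationTestResult(
            statistic=math.nan, df_between=df_b, df_within=df_w, p_value=1.0,
            n_permutations=0, method="degenerate", seed=seed,
        )

    rng = np.random.default_rng(seed)
    count = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_p = anova_f(z, perm)
        if not math.isnan(f_p) and f_p >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermutationTestResult(
        statistic=f_obs, df_between=df_b, df_within=df_w, p_value=p,
        n_permutations=n_permutations, method="permutation", seed=seed,
    )


# ---------------------------------------------------------------------------
# nMDS


def pava(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Isotonic (non-decreasing) least-squares fit by pool-adjacent-violators.

    Returns the fitted values; ties in the predictor should be pre-pooled by
    the caller (tied blocks averaged).
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # blocks as (value, weight) merged while out of order
    values: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for yi, wi in zip(y, w):
        values.append(yi)
        wts.append(wi)
        sizes.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            v = (values[-2] * wts[-2] + values[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            sizes[-2] += sizes[-1]
            values[-2] = v
            values.pop()
            wts.pop()
            sizes.pop()
    out = np.empty_like(y)
    pos = 0
    for v, s in zip(values, sizes):
        out[pos : pos + s] = v
        pos += s
    return out


def _monotone_fit(dissim: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Kruskal monotone regression of configuration distances on
    dissimilarities, with tied dissimilarity blocks averaged."""
    order = np.argsort(dissim, kind="stable")
    ds, cs = dissim[order], dist[order]
    # pool exact ties in the dissimilarities: average their distances
    uniq, inverse, counts = np.unique(ds, return_inverse=True, return_counts=True)
    pooled = np.bincount(inverse, weights=cs) / counts
    fitted_blocks = pava(pooled, counts.astype(float))
    fitted = fitted_blocks[inverse]
    out = np.empty_like(fitted)
    out[order] = fitted
    return out


@dataclass
class OrdinationResult:
    """nMDS result: coordinates, Kruskal stress-1 and convergence info."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_restarts: int
    best_restart: int
    seed: int | None = None
    stress_history: list[float] = field(default_factory=list)


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dist ** 2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((dist - dhat) ** 2).sum() / denom)


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling by SMACOF majorisation.

    Each iteration fits disparities by monotone regression of the current
    configuration distances on the dissimilarities (pool-adjacent-violators,
    tied blocks averaged) and then applies a Guttman transform. Quality is
    Kruskal's stress-1, sqrt(sum (d - dhat)^2 / sum d^2); it is invariant to
    rotation, translation and uniform scaling of the configuration. The
    first restart starts from the principal-coordinates embedding, further
    restarts from random configurations; the best final stress wins.
    """
    arr = _as_square(d)
    n = arr.shape[0]
    if n < k + 1:
        raise ValueError("need at least k + 1 samples")
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    iu = np.triu_indices(n, 1)
    dissim = arr[iu]
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, bool, int, list[float]] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = pcoa(arr, k)[0]
            if x.shape[1] < k:  # degenerate: pad with zeros
                x = np.column_stack([x, np.zeros((n, k - x.shape[1]))])
        else:
            x = rng.normal(scale=np.nanmax(dissim) or 1.0, size=(n, k))

        history: list[float] = []
        converged = False
        prev = math.inf
        prev_x = x
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dist_mat = np.sqrt((diff ** 2).sum(axis=2))
            dist = dist_mat[iu]
            dhat = _monotone_fit(dissim, dist)
            stress = _stress1(dist, dhat)
            if stress > prev + 1e-12:
                # the majorisation step reduces raw stress, not stress-1;
                # on the rare uptick keep the previous configuration
                x = prev_x
                converged = True
                break
            history.append(stress)
            if abs(prev - stress) < tol:
                converged = True
                break
            prev = stress
            prev_x = x
            # Guttman transform with weights 1
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio_u = np.where(dist > 0, dhat / dist, 0.0)
            b = np.zeros((n, n))
            b[iu] = -ratio_u
            b = b + b.T
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
        final = history[-1] if history else math.inf
        if best is None or final < best[0]:
            best = (final, x, converged, restart, history)

    stress, x, converged, restart, history = best
    coords = pd.DataFrame(x, index=ids, columns=[f"nmds{i+1}" for i in range(k)])
    return OrdinationResult(
        coordinates=coords, stress=stress, converged=converged,
        n_restarts=max(1, n_restarts), best_restart=restart, seed=seed,
        stress_history=history,
    )


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass(frozen=True)
class AncovaResult:
    """One-way ANCOVA with a single covariate.

    Partial eta squared per term is SS_term / (SS_term + SS_residual). The
    interaction p-value from a separate group x covariate model is the
    slope-homogeneity diagnostic; the Shapiro-Wilk test on residuals is the
    normality diagnostic.
    """

    group_f: float
    group_p: float
    group_partial_eta_sq: float
    covariate_f: float
    covariate_p: float
    covariate_partial_eta_sq: float
    df_group: tuple[int, int]
    df_covariate: tuple[int, int]
    interaction_p: float | None
    shapiro_statistic: float
    shapiro_p: float
    n: int
    covariate_dropped: bool = False


def ancova(response, group, covariate) -> AncovaResult:
    """ANCOVA of ``response`` on a categorical ``group`` controlling for a
    numeric ``covariate`` (type-II sums of squares).

    A constant covariate carries no information and is dropped with a
    warning (the model degrades to a one-way ANOVA).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    df = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "g": np.asarray(group),
            "x": np.asarray(covariate, dtype=float),
        }
    )
    if df.groupby("g").size().min() < 3:
        raise ValueError("need at least 3 observations per group")

    single_group = df["g"].nunique() == 1
    covariate_dropped = bool(np.ptp(df["x"].to_numpy()) == 0)
    if covariate_dropped:
        warnings.warn("constant covariate dropped from ANCOVA", stacklevel=2)
        formula = "y ~ 1" if single_group else "y ~ C(g)"
    elif single_group:
        # degenerates to simple linear regression on the covariate
        formula = "y ~ x"
    else:
        formula = "y ~ C(g) + x"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = int(table.loc["Residual", "df"])

    def term(name):
        if name not in table.index:
            return math.nan, math.nan, 0.0, 0
        row = table.loc[name]
        eta = float(row["sum_sq"] / (row["sum_sq"] + ss_resid))
        return float(row["F"]), float(row["PR(>F)"]), eta, int(row["df"])

    g_f, g_p, g_eta, g_df = term("C(g)")
    x_f, x_p, x_eta, x_df = term("x")

    interaction_p = None
    if not covariate_dropped and not single_group:
        inter_fit = smf.ols("y ~ C(g) * x", data=df).fit()
        inter_table = sm.stats.anova_lm(inter_fit, typ=2)
        interaction_p = float(inter_table.loc["C(g):x", "PR(>F)"])

    resid = fit.resid.to_numpy() if hasattr(fit.resid, "to_numpy") else np.asarray(fit.resid)
    if np.ptp(resid) == 0:
        sh_stat, sh_p = math.nan, math.nan
    else:
        sh_stat, sh_p = sps.shapiro(resid)

    return AncovaResult(
        group_f=g_f, group_p=g_p, group_partial_eta_sq=g_eta,
        covariate_f=x_f, covariate_p=x_p, covariate_partial_eta_sq=x_eta,
        df_group=(g_df, df_resid), df_covariate=(x_df, df_resid),
        interaction_p=interaction_p,
        shapiro_statistic=float(sh_stat), shapiro_p=float(sh_p),
        n=len(df), covariate_dropped=covariate_dropped,
    )


# ---------------------------------------------------------------------------
# centroid ellipses


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse of a group centroid in ordination space."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float
    level: float
    n: int

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


def centroid_ellipses(
    coords: pd.DataFrame | np.ndarray,
    groups: Sequence,
    level: float = 0.95,
) -> dict[str, Ellipse | tuple[float, float]]:
    """Per-group centroid with a confidence ellipse for the centroid.

    The ellipse derives from the standard-error covariance of the mean
    (sample covariance / n) scaled by the chi-square quantile at ``level``
    with 2 df. Groups with fewer than 3 samples get the bare centroid tuple,
    no ellipse.
    """
    from scipy import stats as sps

    x = coords.to_numpy(dtype=float) if isinstance(coords, pd.DataFrame) else np.asarray(coords, dtype=float)
    if x.shape[1] != 2:
        raise ValueError("centroid ellipses are defined for 2-D ordinations")
    labels = np.asarray(groups)
    out: dict[str, Ellipse | tuple[float, float]] = {}
    scale = sps.chi2.ppf(level, df=2)
    for g in pd.unique(labels):
        pts = x[labels == g]
        center = pts.mean(axis=0)
        if pts.shape[0] < 3:
            out[str(g)] = (float(center[0]), float(center[1]))
            continue
        cov = np.cov(pts, rowvar=False) / pts.shape[0]
        eigval, eigvec = np.linalg.eigh(cov)
        eigval = np.clip(eigval, 0.0, None)[::-1]
        eigvec = eigvec[:, ::-1]
        angle = math.degrees(math.atan2(eigvec[1, 0], eigvec[0, 0]))
        out[str(g)] = Ellipse(
            center=(float(center[0]), float(center[1])),
            semi_axes=(float(math.sqrt(scale * eigval[0])),
                       float(math.sqrt(scale * eigval[1]))),
            angle_deg=angle, level=level, n=int(pts.shape[0]),
        )
    return out
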