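"""The texture-dietary space: PCA of the extant framework and projection of
fossil unknowns.

The ordination is built from extant (framework) specimens only, on the
log-transformed texture parameters that passed the guild screen.  Fossils
are projected afterwards as unknown datum points using the stored centring,
scaling and loadings; projection never alters the model, so fossil data
play no role in structuring the space.

PCA is performed on the correlation matrix (each column standardised to
unit variance) because ISO texture parameters span orders of magnitude;
covariance-matrix mode is available via ``scale=False``.  Eigenvector sign
is arbitrary, so each axis is signed to make its largest-magnitude loading
positive — results are then reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OrdinationModel", "OrdinationScores", "CorrelationResult",
           "fit_framework_pca", "project_unknowns", "correlate_axes_with_diet",
           "compare_groups_along_axis", "ontogenetic_trend", "spearman",
           "guild_hulls"]


@dataclass(frozen=True)
class OrdinationModel:
    """Fitted framework PCA: everything needed to project new specimens."""

    parameters: tuple                # column names used
    means: np.ndarray                # per-parameter centring means
    scales: np.ndarray               # per-parameter divisors (1s in covariance mode)
    loadings: np.ndarray             # (n_params, n_axes), orthonormal columns
    eigenvalues: np.ndarray          # non-increasing
    percent_variance: np.ndarray
    training_scores: pd.DataFrame    # framework specimen scores (id index)
    scaled: bool = True
    flags: tuple = field(default_factory=tuple)

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class OrdinationScores:
    """Per-specimen PC scores with a framework/projected origin flag."""

    scores: pd.DataFrame             # index: specimen id; columns PC1..PCk + origin
    flags: tuple = field(default_factory=tuple)

    def axis(self, name: str) -> pd.Series:
        return self.scores[name]


@dataclass(frozen=True)
class CorrelationResult:
    axis: str
    category: str
    rs: float
    p: float
    n: int
    undefined: bool = False


def _axis_names(k):
    return [f"PC{i + 1}" for i in range(k)]


def fit_framework_pca(table: pd.DataFrame, scale: bool = True) -> OrdinationModel:
    """Fit the extant-framework PCA.

    ``table``: framework specimens × selected (already log-transformed)
    parameters, indexed by specimen id, no missing values.  Eigen-
    decomposition of the correlation matrix (or covariance with
    ``scale=False``).  Requires ≥ 2 parameters and ≥ 3 specimens; a
    constant column raises naming it; more parameters than specimens is
    allowed but flagged.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("PCA needs at least 2 parameters")
    if n < 3:
        raise ValueError("PCA needs at least 3 framework specimens")
    if not np.isfinite(X).all():
        raise ValueError("missing values in PCA input")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"constant parameter column {table.columns[j]!r}")
    scales = sds if scale else np.ones(p)
    Z = (X - means) / scales
    C = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    pct = 100.0 * evals / evals.sum()
    scores = Z @ evecs
    flags = ("more parameters than specimens",) if p > n else ()
    sc = pd.DataFrame(scores, index=table.index, columns=_axis_names(p))
    return OrdinationModel(parameters=tuple(table.columns), means=means,
                           scales=scales, loadings=evecs, eigenvalues=evals,
                           percent_variance=pct, training_scores=sc,
                           scaled=scale, flags=flags)


def framework_scores(model: OrdinationModel, guilds=None) -> OrdinationScores:
    """The stored training scores wrapped with origin = framework."""
    df = model.training_scores.copy()
    df["origin"] = "framework"
    if guilds is not None:
        df["guild"] = list(guilds)
    return OrdinationScores(scores=df)


def project_unknowns(model: OrdinationModel, samples: pd.DataFrame) -> OrdinationScores:
    """Project new specimens into a fitted texture-dietary space.

    Each sample is centred (and scaled, if the model was) by the *stored*
    training statistics and multiplied by the stored loadings; the model is
    never refitted.  Samples must provide every model parameter; scores
    beyond 3× the training score range are flagged, not rejected.
    """
    missing = [p for p in model.parameters if p not in samples.columns]
    if missing:
        raise ValueError(f"samples lack model parameter(s): {', '.join(missing)}")
    X = samples[list(model.parameters)].to_numpy(dtype=float)
    Z = (X - model.means) / model.scales
    scores = Z @ model.loadings
    df = pd.DataFrame(scores, index=samples.index, columns=_axis_names(model.n_axes))
    df["origin"] = "projected"
    flags = []
    train = model.training_scores.to_numpy()
    lim = 3.0 * np.abs(train).max(axis=0)
    out_of_range = (np.abs(scores) > lim).any(axis=1)
    for sid in df.index[out_of_range]:
        flags.append(f"{sid}: score beyond 3x training range")
    return OrdinationScores(scores=df, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Correlation / comparison statistics
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple:
    """Spearman rank correlation with average-rank ties.

    Two-sided P by exact permutation for n ≤ 9 and by the t approximation
    otherwise.  Returns ``(rs, p, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan"), n
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact: permute one rank vector over all n! orders
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
        all_rs = num / denom
        p = float(np.mean(np.abs(all_rs) >= abs(rs) - 1e-12))
        assert perms.shape[0] == factorial(n)
    else:
        t = rs * np.sqrt((n - 2) / max(1e-300, 1.0 - rs**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return rs, p, n


def correlate_axes_with_diet(scores: OrdinationScores,
                             diets: pd.DataFrame,
                             axes=("PC1", "PC2"),
                             bh: bool = False, fdr: float = 0.05):
    """Spearman correlations of framework PC scores with dietary categories.

    ``diets``: per-specimen dietary proportions aligned to the framework
    scores by index.  Every framework specimen must map to a composition.
    Categories constant across taxa are flagged undefined.  With
    ``bh=True`` a Benjamini–Hochberg flag across the whole family is
    appended to each result tuple.
    """
    fw = scores.scores[scores.scores["origin"] == "framework"]
    missing = fw.index.difference(diets.index)
    if len(missing):
        raise ValueError(f"no dietary composition for specimen(s): {list(missing)[:5]}")
    diets = diets.loc[fw.index]
    results = []
    for ax in axes:
        for cat in diets.columns:
            y = diets[cat].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                results.append(CorrelationResult(ax, cat, float("nan"),
                                                 float("nan"), len(y), undefined=True))
                continue
            rs, p, n = spearman(fw[ax].to_numpy(), y)
            results.append(CorrelationResult(ax, cat, rs, p, n))
    if bh:
        from .guilds import bh_adjust
        idx = [i for i, r in enumerate(results) if not r.undefined]
        flags, _ = bh_adjust([results[i].p for i in idx], fdr)
        return results, {i: bool(f) for i, f in zip(idx, flags)}
    return results


def compare_groups_along_axis(scores: OrdinationScores, group_a, group_b,
                              axis: str = "PC1"):
    """Two-sample pooled-variance t-test between specimen groups on one axis.

    df = nA + nB − 2.  Zero pooled variance returns ``(nan, df, nan)``.
    """
    a = scores.scores.loc[list(group_a), axis].to_numpy(dtype=float)
    b = scores.scores.loc[list(group_b), axis].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 specimens")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float("nan"), df, float("nan")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def ontogenetic_trend(jaw_lengths_cm, axis_scores, confidence: float = 0.95):
    """Size-related trend along an ordination axis.

    Spearman correlation of axis score against lower jaw length plus an
    ordinary least-squares line with a pointwise confidence band for
    plotting.  Returns a dict with rs, p, n, slope, intercept and the band
    (x sorted, fitted, lower, upper).  Jaw lengths must be positive; n ≥ 4.
    """
    x = np.asarray(jaw_lengths_cm, dtype=float)
    y = np.asarray(axis_scores, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if (x <= 0).any():
        raise ValueError("jaw lengths must be positive")
    rs, p, n = spearman(x, y)
    import statsmodels.api as sm
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    order = np.argsort(x)
    xs = x[order]
    pred = fit.get_prediction(sm.add_constant(xs))
    band = pred.conf_int(alpha=1 - confidence)
    return {
        "rs": rs, "p": p, "n": n,
        "slope": float(fit.params[1]), "intercept": float(fit.params[0]),
        "band_x": xs, "band_fit": pred.predicted_mean,
        "band_lower": band[:, 0], "band_upper": band[:, 1],
    }


def guild_hulls(scores: OrdinationScores, guilds, axes=("PC1", "PC2")) -> dict:
    """Convex hull vertices per guild over framework scores (descriptive)."""
    from scipy.spatial import ConvexHull
    fw = scores.scores[scores.scores["origin"] == "framework"]
    guilds = pd.Series(list(guilds), index=fw.index)
    hulls = {}
    for g in guilds.unique():
        pts = fw.loc[guilds == g, list(axes)].to_numpy(dtype=float)
        if len(pts) < 3:
            hulls[g] = pts
            continue
        hull = ConvexHull(pts)
        hulls[g] = pts[hull.vertices]
    return hulls
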