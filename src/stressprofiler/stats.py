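"""Statistical procedures for the stress-susceptibility pipeline.

Contingency statistics (Yates-corrected chi-square with the phi effect
size), tie-corrected Kruskal-Wallis with Dunn's Bonferroni post-hocs,
variance-partitioning two-way ANOVA (Type III, effect coding) with
Bonferroni t post-hocs, the split-plot three-way ANOVA used for the
four-gene amygdalar panel, a normality-gated two-group dispatcher
(Shapiro-Wilk + Levene deciding between Student t, Welch t and
Mann-Whitney), Pearson correlation, and the permutation-of-regressor-
residuals test used for covariate-adjusted candidate-gene association.

scipy.stats supplies the classical distributions and the elementary tests;
the composite procedures (Yates/phi conventions, rank machinery, Type III
partitioning, the split-plot decomposition, the permutation scheme) are
implemented here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiler import ContingencyTable2x2

__all__ = [
    "ChiSquareResult",
    "KruskalResult",
    "DunnResult",
    "AnovaTable",
    "PermAssocResult",
    "CompareReport",
    "yates_chi_square",
    "kruskal_wallis",
    "dunn_pairwise",
    "two_way_anova",
    "mixed_three_way_anova",
    "normality_gated_compare",
    "pearson_correlation",
    "permutation_regressor_residuals",
    "sex_stratified_association",
]


# ---------------------------------------------------------------------------
# Contingency statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChiSquareResult:
    """2x2 chi-square with Yates continuity correction and phi effect size.

    phi is computed from the UNCORRECTED statistic, sqrt(chi2 / N) — the
    convention that reproduces the printed effect sizes alongside
    continuity-corrected test statistics.
    """

    statistic_corrected: float
    statistic_uncorrected: float
    df: int
    p: float
    phi: float
    n: int


def yates_chi_square(table: ContingencyTable2x2 | np.ndarray) -> ChiSquareResult:
    """Yates continuity-corrected chi-square on a 2x2 table.

    Corrected statistic: sum over cells of (max(|O - E| - 0.5, 0))^2 / E,
    with the correction clamped at zero so identical-proportion tables give
    exactly 0.  p comes from the chi-square distribution with 1 df.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.to_array()
    else:
        obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal: expected counts undefined")
    expected = np.outer(row, col) / n
    dev = np.abs(obs - expected)
    stat_unc = float(((obs - expected) ** 2 / expected).sum())
    stat_cor = float((np.maximum(dev - 0.5, 0.0) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat_cor, 1))
    phi = float(np.sqrt(stat_unc / n))
    return ChiSquareResult(stat_cor, stat_unc, 1, p, phi, int(n))


# ---------------------------------------------------------------------------
# Rank-based multi-group tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float
    mean_ranks: tuple[float, ...]
    group_sizes: tuple[int, ...]
    tie_correction: float


def _pooled_midranks(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # midranks
    out = []
    i = 0
    for g in groups:
        out.append(ranks[i : i + g.size])
        i += g.size
    return pooled, out


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list[np.ndarray] | list[list[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with per-group mean ranks.

    H = [12/(N(N+1)) * sum n_i R_i^2 - 3(N+1)] / C with the tie correction
    C = 1 - sum(t^3 - t)/(N^3 - N).  All-identical input returns H = 0 with
    a warning (the correction denominator vanishes).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 1 for g in gs):
        raise ValueError("every group needs at least 1 value")
    pooled, rank_groups = _pooled_midranks(gs)
    n_total = pooled.size
    mean_ranks = tuple(float(r.mean()) for r in rank_groups)
    sizes = tuple(int(g.size) for g in gs)
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n_total**3 - n_total)
    if correction <= 0:
        warnings.warn("all values identical: H set to 0", RuntimeWarning)
        return KruskalResult(0.0, len(gs) - 1, 1.0, mean_ranks, sizes, 0.0)
    h_raw = (
        12.0 / (n_total * (n_total + 1))
        * sum(n * r**2 for n, r in zip(sizes, mean_ranks))
        - 3.0 * (n_total + 1)
    )
    h = h_raw / correction
    df = len(gs) - 1
    p = float(sps.chi2.sf(h, df))
    return KruskalResult(float(h), df, p, mean_ranks, sizes, float(correction))


@dataclass(frozen=True)
class DunnResult:
    pairs: tuple[tuple[int, int], ...]
    z: tuple[float, ...]
    p_raw: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    adjustment: str


def dunn_pairwise(
    groups: list[np.ndarray] | list[list[float]], adjustment: str = "bonferroni"
) -> DunnResult:
    """Dunn's pairwise z comparisons from pooled midranks, tie-corrected.

    z_ij = (R_i - R_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the tie
    term T = sum(t^3 - t)/(12(N-1)); two-sided normal p, Bonferroni
    adjusted over all pairs.
    """
    if adjustment != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    pooled, rank_groups = _pooled_midranks(gs)
    n_total = pooled.size
    tie = _tie_term(pooled) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie
    mean_ranks = [r.mean() for r in rank_groups]
    sizes = [g.size for g in gs]
    pairs, zs, ps = [], [], []
    m = len(gs) * (len(gs) - 1) // 2
    for i, j in itertools.combinations(range(len(gs)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        pairs.append((i, j))
        zs.append(float(z))
        ps.append(float(min(p, 1.0)))
    p_adj = [float(min(p * m, 1.0)) for p in ps]
    return DunnResult(tuple(pairs), tuple(zs), tuple(ps), tuple(p_adj), adjustment)


# ---------------------------------------------------------------------------
# ANOVA: Type III two-way and split-plot three-way
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Per-term SS/df/F/p plus the fraction of variance explained.

    variance_explained defaults to classical eta-squared, SS_term/SS_total;
    partial eta-squared (SS_term / (SS_term + SS_error)) is optional.
    """

    terms: pd.DataFrame  # index=term, columns=[ss, df, F, p, variance_explained]
    ss_total: float
    posthoc: pd.DataFrame | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]


def _effect_code(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effect) coding: levels sorted, last level = -1 row."""
    levels = sorted(pd.unique(labels.astype(str)))
    k = len(levels)
    idx = pd.Categorical(labels.astype(str), categories=levels).codes
    x = np.zeros((labels.size, k - 1))
    for j in range(k - 1):
        x[idx == j, j] = 1.0
    x[idx == k - 1, :] = -1.0
    return x, levels

def _ss_resid(y: np.ndarray, x: np.ndarray) -> float:
    """Residual SS of y on columns of x (least squares)."""
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return float(np.sum((y - fitted) ** 2))


def two_way_anova(
    values: np.ndarray | pd.Series,
    factor_a: pd.Series | np.ndarray,
    factor_b: pd.Series | np.ndarray,
    *,
    a_name: str = "A",
    b_name: str = "B",
    partial_eta: bool = False,
    posthoc: bool = True,
    posthoc_alpha: float = 0.05,
) -> AnovaTable:
    """Two-way crossed ANOVA with Type III sums of squares (effect coding).

    Designed for the 2x2 prenatal-stress x adult-trauma expression panels
    with unbalanced cells (n = 6-8).  Each Type III SS is the increase in
    residual SS when the term's columns are dropped from the full
    effect-coded model.  Post-hoc: all pairwise Welch t-tests between
    cells, flagged significant at the Bonferroni-corrected alpha
    (alpha / number of planned comparisons; 0.05/4 convention exposed via
    ``posthoc_alpha`` and the 4 within/between comparisons reported).
    """
    y = np.asarray(values, dtype=float)
    fa = pd.Series(factor_a).astype(str).reset_index(drop=True)
    fb = pd.Series(factor_b).astype(str).reset_index(drop=True)
    if y.size != fa.size or y.size != fb.size:
        raise ValueError("values and factors must have equal length")
    cells = fa + "|" + fb
    counts = cells.value_counts()
    la, lb = sorted(fa.unique()), sorted(fb.unique())
    if len(la) != 2 or len(lb) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    if len(counts) < 4 or counts.min() < 1:
        raise ValueError("empty design cell: interaction inestimable")

    xa, _ = _effect_code(fa)
    xb, _ = _effect_code(fb)
    xab = xa * xb
    ones = np.ones((y.size, 1))
    full = np.hstack([ones, xa, xb, xab])
    sse_full = _ss_resid(y, full)
    df_err = y.size - full.shape[1]
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = sse_full / df_err

    pieces = {a_name: xa, b_name: xb, f"{a_name}:{b_name}": xab}
    rows = {}
    for term, cols in pieces.items():
        reduced = np.hstack([ones] + [blk for name, blk in pieces.items() if name != term])
        ss = _ss_resid(y, reduced) - sse_full
        ss = max(ss, 0.0)
        df = cols.shape[1]
        f = (ss / df) / mse if mse > 0 else np.inf
        p = float(sps.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0
        rows[term] = dict(ss=ss, df=df, F=f, p=p)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows["residual"] = dict(ss=sse_full, df=df_err, F=np.nan, p=np.nan)

    tbl = pd.DataFrame(rows).T
    if partial_eta:
        ve = tbl["ss"] / (tbl["ss"] + sse_full)
        ve.loc["residual"] = np.nan
    else:
        ve = tbl["ss"] / ss_total if ss_total > 0 else tbl["ss"] * np.nan
    tbl["variance_explained"] = ve

    post = None
    if posthoc:
        cell_levels = sorted(cells.unique())
        recs = []
        n_pairs = len(cell_levels) * (len(cell_levels) - 1) // 2
        for c1, c2 in itertools.combinations(cell_levels, 2):
            y1, y2 = y[cells == c1], y[cells == c2]
            t, p = sps.ttest_ind(y1, y2)
            recs.append(
                dict(cell1=c1, cell2=c2, t=float(t), p=float(p),
                     significant=bool(p < posthoc_alpha / 4),
                     alpha_corrected=posthoc_alpha / 4)
            )
        post = pd.DataFrame(recs)
    return AnovaTable(terms=tbl, ss_total=ss_total, posthoc=post)


def mixed_three_way_anova(
    panel: pd.DataFrame,
    *,
    subject: str,
    between_a: str,
    between_b: str,
    within: str,
    value: str,
) -> AnovaTable:
    """Split-plot three-way ANOVA: 2x2 between-subject design, one
    repeated within-subject factor (the gene panel).

    Between-subject terms (A, B, A:B) are computed on the per-subject means
    (Type III, effect-coded) and tested against the subject-within-cell
    error; within terms (W and its interactions with A, B) are Type III
    drop-term SS on subject-centered data, tested against the
    subject-x-within residual.  No sphericity adjustment (the default for
    this design at n = 6-8 per cell).

    Subjects missing any within level are excluded with a warning.
    """
    df = panel[[subject, between_a, between_b, within, value]].dropna().copy()
    w_levels = sorted(df[within].astype(str).unique())
    g = len(w_levels)
    complete = df.groupby(subject)[within].nunique()
    bad = complete.index[complete < g]
    if len(bad):
        warnings.warn(
            f"{len(bad)} subject(s) missing a {within!r} level excluded", RuntimeWarning
        )
        df = df[~df[subject].isin(bad)]
    if df.empty:
        raise ValueError("no complete subjects")

    subj_info = (
        df.groupby(subject)
        .agg(mean=(value, "mean"), a=(between_a, "first"), b=(between_b, "first"))
        .reset_index()
    )
    n_subj = len(subj_info)
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    # --- between-subject stratum: Type III two-way on subject means,
    # SS scaled by g (each subject mean averages g observations)
    sm = subj_info["mean"].to_numpy()
    xa, _ = _effect_code(subj_info["a"])
    xb, _ = _effect_code(subj_info["b"])
    xab = xa * xb
    ones = np.ones((n_subj, 1))
    full_b = np.hstack([ones, xa, xb, xab])
    sse_b = _ss_resid(sm, full_b)  # subject-within-cell error on the mean scale
    ss_subj_err = g * sse_b
    df_subj_err = n_subj - full_b.shape[1]
    if df_subj_err <= 0:
        raise ValueError("no between-subject error degrees of freedom")
    ms_subj_err = ss_subj_err / df_subj_err

    between_terms = {}
    pieces_b = {between_a: xa, between_b: xb, f"{between_a}:{between_b}": xab}
    for term in pieces_b:
        reduced = np.hstack([ones] + [v for k, v in pieces_b.items() if k != term])
        ss = g * max(_ss_resid(sm, reduced) - sse_b, 0.0)
        dfree = pieces_b[term].shape[1]
        f = (ss / dfree) / ms_subj_err
        p = float(sps.f.sf(f, dfree, df_subj_err))
        between_terms[term] = dict(ss=ss, df=dfree, F=f, p=p)

    # --- within-subject stratum: Type III on subject-centered data
    subj_means = df.groupby(subject)[value].transform("mean").to_numpy()
    yc = y - subj_means
    xw, _ = _effect_code(df[within])
    xa_f, _ = _effect_code(df[between_a])
    xb_f, _ = _effect_code(df[between_b])
    wa = np.hstack([xw * xa_f[:, [j]] for j in range(xa_f.shape[1])])
    wb = np.hstack([xw * xb_f[:, [j]] for j in range(xb_f.shape[1])])
    wab = np.hstack(
        [xw * (xa_f[:, [i]] * xb_f[:, [j]])
         for i in range(xa_f.shape[1]) for j in range(xb_f.shape[1])]
    )
    pieces_w = {
        within: xw,
        f"{within}:{between_a}": wa,
        f"{within}:{between_b}": wb,
        f"{within}:{between_a}:{between_b}": wab,
    }
    full_w = np.hstack(list(pieces_w.values()))
    sse_w = _ss_resid(yc, full_w)
    df_w_err = (n_subj - 4) * (g - 1)
    if df_w_err <= 0:
        raise ValueError("no within-subject error degrees of freedom")
    ms_w_err = sse_w / df_w_err

    within_terms = {}
    for term in pieces_w:
        reduced_cols = [v for k, v in pieces_w.items() if k != term]
        ss = max(_ss_resid(yc, np.hstack(reduced_cols)) - sse_w, 0.0)
        dfree = pieces_w[term].shape[1]
        f = (ss / dfree) / ms_w_err
        p = float(sps.f.sf(f, dfree, df_w_err))
        within_terms[term] = dict(ss=ss, df=dfree, F=f, p=p)

    rows = {}
    rows.update(between_terms)
    rows["subject_error"] = dict(ss=ss_subj_err, df=df_subj_err, F=np.nan, p=np.nan)
    rows.update(within_terms)
    rows["residual"] = dict(ss=sse_w, df=df_w_err, F=np.nan, p=np.nan)
    tbl = pd.DataFrame(rows).T
    tbl["variance_explained"] = tbl["ss"] / ss_total if ss_total > 0 else np.nan
    return AnovaTable(terms=tbl, ss_total=ss_total)


# ---------------------------------------------------------------------------
# Normality-gated two-group dispatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompareReport:
    """Two-group comparison with the dispatch route recorded."""

    route: str  # "student_t" | "welch_t" | "mann_whitney"
    statistic: float
    p: float
    shapiro_p: tuple[float, float]
    levene_p: float
    n: tuple[int, int]
    mean_difference: float


def normality_gated_compare(
    x: np.ndarray | list[float], y: np.ndarray | list[float], alpha: float = 0.05
) -> CompareReport:
    """Shapiro-Wilk on each sample plus Levene; dispatch accordingly.

    Both samples normal and variances homogeneous -> Student's t; normal
    but heteroscedastic -> Welch's t; any normality failure ->
    Mann-Whitney U.  The report records the route taken for the audit log.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3 in each sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on near-constant input
        sw_x = float(sps.shapiro(x).pvalue) if np.ptp(x) > 0 else 0.0
        sw_y = float(sps.shapiro(y).pvalue) if np.ptp(y) > 0 else 0.0
        lev = float(sps.levene(x, y).pvalue) if (np.ptp(x) > 0 or np.ptp(y) > 0) else 1.0
    normal = sw_x > alpha and sw_y > alpha
    equal_var = lev > alpha
    if not normal:
        route = "mann_whitney"
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    elif equal_var:
        route = "student_t"
        res = sps.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        route = "welch_t"
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return CompareReport(
        route=route,
        statistic=stat,
        p=p,
        shapiro_p=(sw_x, sw_y),
        levene_p=lev,
        n=(int(x.size), int(y.size)),
        mean_difference=float(x.mean() - y.mean()),
    )


# ---------------------------------------------------------------------------
# Correlation and permutation association
# ---------------------------------------------------------------------------

def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with the two-sided t-based p; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


@dataclass(frozen=True)
class PermAssocResult:
    F_observed: float
    p_parametric: float
    p_permutation: float
    n_permutations: int
    n: int


def permutation_regressor_residuals(
    y,
    covariates,
    regressor,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermAssocResult:
    """Permutation-of-regressor-residuals F test for one regressor.

    The regressor of interest is regressed on the covariates; its residuals
    are permuted, added back to the covariate-explained part, and the
    partial F for the (permuted) regressor in ``y ~ covariates + regressor``
    is recomputed each time.  p_permutation uses the add-one estimator
    (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the smallest attainable p
    is 1/(n_perm + 1).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(regressor, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.size
    if g.size != n or x.shape[0] != n:
        raise ValueError("length mismatch between y, covariates and regressor")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if np.ptp(g) == 0:
        raise ValueError("constant regressor")
    xm = np.hstack([np.ones((n, 1)), x])
    if np.linalg.matrix_rank(xm) < xm.shape[1]:
        raise ValueError("collinear covariates")
    p_cov = xm.shape[1]
    df_err = n - p_cov - 1
    if df_err < 1:
        raise ValueError("not enough observations for the full model")

    # hat-matrix residual maker for the covariate space
    q, _ = np.linalg.qr(xm)
    def resid(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    ey = resid(y)
    eg = resid(g)
    sse_red = float(ey @ ey)

    def partial_f(eg_k: np.ndarray) -> float:
        denom = float(eg_k @ eg_k)
        if denom <= 0:
            return 0.0
        num = float(ey @ eg_k) ** 2 / denom
        sse_full = sse_red - num
        if sse_full <= 0:
            return np.inf
        return num / (sse_full / df_err)

    f_obs = partial_f(eg)
    p_param = float(sps.f.sf(f_obs, 1, df_err))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        eg_p = rng.permutation(eg)
        # permuted regressor = covariate fit + permuted residuals; its
        # covariate-space residual is resid(eg_p) (the fitted part vanishes)
        f_k = partial_f(resid(eg_p))
        if f_k >= f_obs:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return PermAssocResult(float(f_obs), p_param, float(p_perm), int(n_perm), int(n))


def sex_stratified_association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    strata: str = "sex",
    covariates: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stratum association between outcome and predictor.

    Without covariates each stratum gets a Pearson correlation; with
    covariates the permutation-of-regressor-residuals test is used.
    Strata with fewer than 3 usable rows are skipped with a warning.
    """
    cols = [outcome, predictor, strata] + (covariates or [])
    rows = []
    for level, sub in table[cols].dropna().groupby(strata):
        if len(sub) < 3:
            warnings.warn(f"stratum {level!r} has n < 3: skipped", RuntimeWarning)
            continue
        if covariates:
            res = permutation_regressor_residuals(
                sub[outcome], sub[covariates].to_numpy(), sub[predictor],
                n_perm=n_perm, seed=seed,
            )
            r, _, _ = pearson_correlation(sub[predictor], sub[outcome])
            rows.append(
                dict(stratum=level, n=res.n, r=r, F=res.F_observed,
                     p=res.p_permutation, method="perm_regressor_residuals")
            )
        else:
            r, p, n = pearson_correlation(sub[predictor], sub[outcome])
            rows.append(dict(stratum=level, n=n, r=r, F=np.nan, p=p,
                             method="pearson"))
    return pd.DataFrame(rows)
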