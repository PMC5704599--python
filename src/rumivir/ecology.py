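"""Alpha/beta diversity and permutation-based multivariate statistics.

Distance matrices are square pandas data frames over sample ids.  The
multi-factor PERMANOVA uses Gower-centered inner products with
sequential (Type-I) sums of squares and free permutation of rows; the
dispersion test embeds the distances by principal coordinates (negative
eigenvalues kept on "imaginary" axes whose squared distances subtract)
and measures member distances to the group spatial median.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from rumivir.errors import InputError

__all__ = [
    "alpha_anova",
    "bray_curtis",
    "chao1",
    "dispersion_test",
    "gower_center",
    "intra_group_contrast",
    "permanova",
    "rarefaction_curve",
    "rarefy",
    "shannon",
    "weighted_unifrac",
]


# ---------------------------------------------------------------------------
# alpha diversity


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate of one sample's count vector.

    Bias-corrected form ``S + F1(F1-1) / (2(F2+1))``; the classic form
    ``S + F1^2 / (2 F2)`` is used when ``bias_corrected`` is false (with
    a fallback to the corrected form when no doubletons exist).
    """
    c = np.asarray(counts)
    c = c[c > 0]
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity over nonzero proportions (default base 2)."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return 0.0
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def rarefy(counts: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample (column) to ``depth`` reads without replacement.

    Columns with fewer than ``depth`` total reads are skipped with a
    warning.  Column sums of the result equal ``depth`` exactly.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for col in counts.columns:
        vec = counts[col].to_numpy()
        total = int(vec.sum())
        if total < depth:
            warnings.warn(f"sample {col!r} has {total} < depth {depth}; skipped", stacklevel=2)
            continue
        out[col] = rng.multivariate_hypergeometric(vec.astype(np.int64), depth)
    return pd.DataFrame(out, index=counts.index)


def rarefaction_curve(
    counts: pd.DataFrame,
    depths,
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean Chao1/Shannon per sample at each subsampling depth."""
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        acc: dict[str, list] = {}
        for _ in range(reps):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = rarefy(counts, int(depth), seed=int(rng.integers(2**31)))
            for col in sub.columns:
                acc.setdefault(col, []).append(
                    (chao1(sub[col].to_numpy()), shannon(sub[col].to_numpy()))
                )
        for col, vals in acc.items():
            arr = np.array(vals)
            rows.append(
                {
                    "sample": col,
                    "depth": int(depth),
                    "chao1": arr[:, 0].mean(),
                    "shannon": arr[:, 1].mean(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances


def _check_square(D: pd.DataFrame) -> None:
    a = D.to_numpy(float)
    if a.shape[0] != a.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10) or not np.allclose(np.diag(a), 0, atol=1e-10):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    if (a < -1e-12).any():
        raise InputError("negative distances")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples of a feature x sample table."""
    x = table.to_numpy(float).T
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero samples are identical
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def _parse_tree(tree):
    from skbio import TreeNode

    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(io.StringIO(str(tree)))


def weighted_unifrac(
    table: pd.DataFrame, tree, normalized: bool = False
) -> pd.DataFrame:
    """Weighted UniFrac distances between samples.

    Raw form: ``sum_branches b * |p_A - p_B|`` where ``p`` is the
    fraction of a sample's reads descending from the branch.  The
    normalized form divides by ``sum_branches b * (p_A + p_B)``.
    """
    t = _parse_tree(tree)
    tips = {n.name for n in t.tips()}
    missing = set(table.index) - tips
    if missing:
        raise InputError(f"tree lacks tips for features: {sorted(missing)[:5]}")

    feat_pos = {f: i for i, f in enumerate(table.index)}
    branches = []  # (length, indicator over features)
    for node in t.postorder(include_self=False):
        b = node.length or 0.0
        idx = [feat_pos[tip.name] for tip in node.tips(include_self=True) if tip.name in feat_pos]
        if b > 0 and idx:
            branches.append((b, np.array(idx)))

    totals = table.sum(axis=0).to_numpy(float)
    props = table.to_numpy(float) / np.where(totals > 0, totals, 1.0)

    n = table.shape[1]
    # branch x sample matrix of descending proportions
    pb = np.array([props[idx].sum(axis=0) for _, idx in branches])
    lens = np.array([b for b, _ in branches])

    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(pb[:, i, None] - pb[:, i + 1 :])
        d[i, i + 1 :] = lens @ diff
        if normalized:
            denom = lens @ (pb[:, i, None] + pb[:, i + 1 :])
            with np.errstate(invalid="ignore", divide="ignore"):
                d[i, i + 1 :] = np.where(denom > 0, d[i, i + 1 :] / denom, 0.0)
    d = d + d.T
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


# ---------------------------------------------------------------------------
# PERMANOVA


def gower_center(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix ``G = -1/2 J D^2 J``."""
    a = D.to_numpy(float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (a**2) @ j


def _dummy(values) -> np.ndarray:
    levels = sorted(set(values))
    arr = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        arr[i, levels.index(v)] = 1.0
    return arr


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms, Residual, Total
    n_permutations: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"PermanovaResult(n_permutations={self.n_permutations})\n{self.table}"


def _sequential_stats(G: np.ndarray, hats: list[np.ndarray], dfs: list[int], df_resid: int):
    """Sequential SS and pseudo-F per term for one (permuted) G."""
    ss_total = np.trace(G)
    fitted = [float((h * G).sum()) for h in hats]  # tr(H G), H symmetric
    # fitted[0] is the intercept-only model (0 after Gower centering)
    ss_terms = [fitted[k + 1] - fitted[k] for k in range(len(hats) - 1)]
    ss_resid = ss_total - fitted[-1]
    if ss_resid <= 1e-12 * max(abs(ss_total), 1.0):
        ss_resid = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0
        f = np.array(
            [
                (ss / df) / ms_resid if ms_resid > 0 else np.inf
                for ss, df in zip(ss_terms, dfs)
            ]
        )
    return np.array(ss_terms), ss_resid, ss_total, f


def permanova(
    D: pd.DataFrame,
    design: pd.DataFrame,
    terms: tuple[str, ...] = ("steer", "period", "diet"),
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Multi-factor PERMANOVA with sequential sums of squares.

    ``design`` holds one categorical column per term, aligned to the
    sample ids of ``D``.  P-values use the plus-one rule
    ``(#\\{F_perm >= F_obs\\} + 1) / (n_perm + 1)`` under free row
    permutation; with ``exact=True`` all ``n!`` permutations are
    enumerated instead (the identity permutation plays the plus-one
    role).

    Raises
    ------
    InputError
        If a term contributes no degrees of freedom or the residual has
        none (confounded terms), naming the offending terms.
    """
    _check_square(D)
    ids = list(D.index)
    design = design.loc[ids]
    n = len(ids)
    G = gower_center(D)

    xs = [np.ones((n, 1))]
    dfs = []
    rank_prev = 1
    for t in terms:
        xs.append(_dummy(design[t].tolist()))
        x_cum = np.hstack(xs)
        rank = np.linalg.matrix_rank(x_cum)
        df_t = rank - rank_prev
        if df_t == 0:
            raise InputError(f"term {t!r} is confounded with earlier terms {terms}")
        dfs.append(df_t)
        rank_prev = rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise InputError(f"zero residual df: terms {terms} are confounded with samples")

    hats = []
    for k in range(len(terms) + 1):
        hats.append(_hat(np.hstack(xs[: k + 1])))

    ss_terms, ss_resid, ss_total, f_obs = _sequential_stats(G, hats, dfs, df_resid)

    if exact:
        if math.factorial(n) > 200_000:
            raise InputError("exact enumeration infeasible for this n")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            Gp = G[np.ix_(perm, perm)]
            _, _, _, f_p = _sequential_stats(Gp, hats, dfs, df_resid)
            count += f_p >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            _, _, _, f_p = _sequential_stats(Gp, hats, dfs, df_resid)
            count += f_p >= f_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_used = n_perm

    rows = []
    for k, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": dfs[k],
                "SS": ss_terms[k],
                "F": f_obs[k],
                "R2": ss_terms[k] / ss_total,
                "P": pvals[k],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "SS": ss_resid,
            "F": np.nan,
            "R2": ss_resid / ss_total,
            "P": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "F": np.nan, "R2": 1.0, "P": np.nan}
    )
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_used)


# ---------------------------------------------------------------------------
# dispersion homogeneity (betadisper-style)


def _pcoa_embed(D: pd.DataFrame, tol: float = 1e-8):
    """Eigen-embedding of a distance matrix.

    Returns ``(pos, neg)`` coordinate blocks; squared distances in the
    embedding are ``||dx_pos||^2 - ||dx_neg||^2``.
    """
    G = gower_center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.max(np.abs(vals)) if len(vals) else 1.0
    keep_pos = vals > tol * scale
    keep_neg = vals < -tol * scale
    pos = vecs[:, keep_pos] * np.sqrt(vals[keep_pos])
    neg = vecs[:, keep_neg] * np.sqrt(-vals[keep_neg])
    return pos, neg


def _spatial_median(x: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Weiszfeld iteration for the geometric (spatial) median."""
    if x.shape[0] == 0 or x.shape[1] == 0:
        return np.zeros(x.shape[1])
    m = x.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(x - m, axis=1)
        if (d < tol).any():
            # median coincides with a data point
            return x[d.argmin()].copy()
        w = 1.0 / d
        m_new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(m_new - m) < tol:
            return m_new
        m = m_new
    return m


@dataclass
class DispersionResult:
    distances: pd.Series  # per-sample distance to its group spatial median
    group_dispersions: pd.Series  # mean distance per group
    f_statistic: float
    p_value: float


def dispersion_test(D: pd.DataFrame, grouping: pd.Series) -> DispersionResult:
    """Homogeneity of multivariate dispersions.

    Embeds ``D`` by PCoA (negative eigenvalues on imaginary axes),
    computes each group's spatial median, and runs a one-way ANOVA on
    the member-to-median distances.
    """
    _check_square(D)
    grouping = grouping.loc[D.index]
    pos, neg = _pcoa_embed(D)

    dist = pd.Series(0.0, index=D.index)
    for g in sorted(set(grouping)):
        idx = np.where((grouping == g).to_numpy())[0]
        m_pos = _spatial_median(pos[idx]) if pos.size else np.zeros(0)
        m_neg = _spatial_median(neg[idx]) if neg.size else np.zeros(0)
        d2 = np.zeros(len(idx))
        if pos.size:
            d2 += ((pos[idx] - m_pos) ** 2).sum(axis=1)
        if neg.size:
            d2 -= ((neg[idx] - m_neg) ** 2).sum(axis=1)
        dist.iloc[idx] = np.sqrt(np.clip(d2, 0.0, None))

    groups = [dist[(grouping == g).to_numpy()].to_numpy() for g in sorted(set(grouping))]
    disp = pd.Series({g: v.mean() for g, v in zip(sorted(set(grouping)), groups)})
    if all(np.allclose(v, v.mean()) for v in groups) and len({round(v.mean(), 12) for v in groups}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat, p = scipy.stats.f_oneway(*groups)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
    return DispersionResult(dist, disp, float(f_stat), float(p))


# ---------------------------------------------------------------------------
# intra-group distance contrast and alpha-diversity ANOVA


def _within_group_distances(D: pd.DataFrame, grouping: pd.Series) -> np.ndarray:
    vals = []
    a = D.to_numpy(float)
    ids = list(D.index)
    for g in sorted(set(grouping)):
        idx = [i for i, s in enumerate(ids) if grouping[s] == g]
        for i, j in itertools.combinations(idx, 2):
            vals.append(a[i, j])
    return np.array(vals)


def intra_group_contrast(
    D: pd.DataFrame,
    grouping_a: pd.Series,
    grouping_b: pd.Series,
    pooled: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test of within-group distances between two groupings.

    Positive t when grouping_a's within-group distances exceed
    grouping_b's.  Welch's test by default; ``pooled=True`` uses the
    pooled-variance form.
    """
    _check_square(D)
    da = _within_group_distances(D, grouping_a.loc[D.index])
    db = _within_group_distances(D, grouping_b.loc[D.index])
    if da.size < 2 or db.size < 2:
        raise InputError("need at least two within-group distances per grouping")
    if np.var(da) == 0 and np.var(db) == 0:
        if np.isclose(da.mean(), db.mean()):
            return 0.0, 1.0
        return (np.inf if da.mean() > db.mean() else -np.inf), 0.0
    t, p = scipy.stats.ttest_ind(da, db, equal_var=pooled)
    return float(t), float(p)


def alpha_anova(
    metric: pd.Series,
    design: pd.DataFrame,
    terms: tuple[str, ...] = ("steer", "period", "diet"),
    pairwise_factor: str = "diet",
    adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main-effects ANOVA of an alpha-diversity metric plus pairwise tests.

    Fits ``metric ~ steer + period + diet`` (no interactions) and
    reports the sequential (Type-I) ANOVA table in the given term
    order, followed by unadjusted pairwise t-tests between levels of
    ``pairwise_factor`` (Holm adjustment with ``adjust='holm'``).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    design = design.loc[metric.index]
    data = design[list(terms)].astype(str).copy()
    data["y"] = metric.to_numpy(float)

    if np.allclose(data["y"].var(ddof=0), 0.0):
        table = pd.DataFrame(
            {"df": [np.nan] * len(terms), "sum_sq": 0.0, "F": 0.0, "PR(>F)": 1.0},
            index=list(terms),
        )
    else:
        formula = "y ~ " + " + ".join(f"C({t})" for t in terms)
        fit = smf.ols(formula, data=data).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        table.index = [
            t.replace("C(", "").replace(")", "") if t.startswith("C(") else t
            for t in table.index
        ]

    levels = sorted(set(data[pairwise_factor]))
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        y1 = data.loc[data[pairwise_factor] == g1, "y"]
        y2 = data.loc[data[pairwise_factor] == g2, "y"]
        if np.var(y1) == 0 and np.var(y2) == 0 and np.isclose(y1.mean(), y2.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_ind(y1, y2, equal_var=False)
        rows.append({"group1": g1, "group2": g2, "t": float(t), "P": float(p)})
    pairwise = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        pairwise["P_adj"] = multipletests(pairwise["P"], method="holm")[1]
    return table, pairwise
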