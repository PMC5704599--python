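"""Ecological driver models: collinearity prefilter, constrained
ordination (CAP/db-RDA) with permutation tests and backward selection,
variance inflation factors, PLSR responder screening and univariate
regression support.

CAP here is redundancy analysis on the principal-coordinate scores of a
dissimilarity matrix; axes with negative eigenvalues are discarded
before the constraint projection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from rumivir.ecology import _check_square, gower_center
from rumivir.errors import InputError

__all__ = [
    "CapFit",
    "PlsrScreen",
    "backward_select",
    "cap_fit",
    "cap_permutation_tests",
    "collinearity_prefilter",
    "plsr_screen",
    "univariate_screen",
    "vif",
]


def collinearity_prefilter(
    X: pd.DataFrame,
    r_threshold: float = 0.85,
    keep_priority: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy removal of highly correlated explanatory variables.

    Variables are visited in ``keep_priority`` order (unlisted columns
    follow in input order); a variable is kept unless its absolute
    Pearson correlation with an already-kept variable reaches
    ``r_threshold``.  Returns the reduced table and the full correlation
    matrix.
    """
    corr = X.corr(method="pearson")
    order = list(keep_priority or [])
    order += [c for c in X.columns if c not in order]
    unknown = set(order) - set(X.columns)
    if unknown:
        raise InputError(f"priority names not in table: {sorted(unknown)}")
    kept: list[str] = []
    for col in order:
        if all(abs(corr.at[col, k]) < r_threshold for k in kept):
            kept.append(col)
    kept_in_input_order = [c for c in X.columns if c in kept]
    return X[kept_in_input_order], corr


@dataclass
class CapFit:
    """A constrained analysis of principal coordinates."""

    axis_scores: pd.DataFrame  # retained PCoA axes (samples x axes)
    constrained_scores: pd.DataFrame
    constrained_inertia: float
    total_inertia: float
    terms: list[str] = field(default_factory=list)
    rank_constraints: int = 0

    @property
    def variation_explained(self) -> float:
        return self.constrained_inertia / self.total_inertia

    def f_statistic(self) -> float:
        n, q = self.axis_scores.shape[0], self.rank_constraints
        ss_res = self.total_inertia - self.constrained_inertia
        if ss_res <= 0:
            return np.inf
        return (self.constrained_inertia / q) / (ss_res / (n - q - 1))


def _pcoa_scores(D: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    G = gower_center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.max(np.abs(vals)) if len(vals) else 1.0
    keep = vals > tol * scale
    scores = vecs[:, keep] * np.sqrt(vals[keep])
    return pd.DataFrame(scores, index=D.index, columns=[f"PCo{i+1}" for i in range(keep.sum())])


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _find_dependent_columns(x: np.ndarray, names: list[str]) -> list[str]:
    dependent = []
    rank = 0
    cols: list[np.ndarray] = []
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [x[:, j]]) if cols else x[:, [j]]
        r = np.linalg.matrix_rank(trial)
        if r == rank:
            dependent.append(name)
        else:
            cols.append(x[:, j])
            rank = r
    return dependent


def cap_fit(D: pd.DataFrame, X: pd.DataFrame) -> CapFit:
    """Fit a CAP model: project PCoA scores onto the column space of X.

    Constrained inertia is the sum of squares of the fitted scores;
    ``variation_explained`` is its share of the total (non-negative
    eigenvalue) inertia.

    Raises
    ------
    InputError
        If X has linearly dependent columns (they are listed) or too
        few samples.
    """
    _check_square(D)
    X = X.loc[D.index]
    n = len(D)
    xc = _center(X.to_numpy(float))
    q = np.linalg.matrix_rank(xc)
    if q < xc.shape[1]:
        dep = _find_dependent_columns(xc, list(X.columns))
        raise InputError(f"rank-deficient explanatory table; dependent columns: {dep}")
    if n <= q + 1:
        raise InputError("need more samples than explanatory variables + 1")

    scores = _pcoa_scores(D)
    y = scores.to_numpy(float)
    hat = xc @ np.linalg.pinv(xc)
    fitted = hat @ y
    return CapFit(
        axis_scores=scores,
        constrained_scores=pd.DataFrame(fitted, index=D.index, columns=scores.columns),
        constrained_inertia=float((fitted**2).sum()),
        total_inertia=float((y**2).sum()),
        terms=list(X.columns),
        rank_constraints=int(q),
    )


def _cap_ss(y: np.ndarray, xc: np.ndarray) -> float:
    hat = xc @ np.linalg.pinv(xc)
    return float(((hat @ y) ** 2).sum())


def cap_permutation_tests(
    D: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    marginal: bool = True,
    exact: bool = False,
) -> pd.DataFrame:
    """Overall and marginal permutation tests for a CAP model.

    The overall F compares constrained to residual inertia; each
    marginal F measures the drop in constrained inertia when the term is
    removed, given all others.  Permutations shuffle the rows of X
    (plus-one P; ``exact=True`` enumerates all row orders for small n).
    """
    # rank deficiency is tolerated here (duplicated terms get marginal
    # F = 0); only cap_fit enforces full column rank
    _check_square(D)
    scores = _pcoa_scores(D)
    y = scores.to_numpy(float)
    xc = _center(X.loc[D.index].to_numpy(float))
    n = y.shape[0]
    q = int(np.linalg.matrix_rank(xc))
    if n <= q + 1:
        raise InputError("need more samples than explanatory variables + 1")
    ss_total = float((y**2).sum())

    def stats_for(x_rows: np.ndarray) -> np.ndarray:
        """[overall F, marginal F per term] for a given row order of X."""
        ss_full = _cap_ss(y, x_rows)
        ss_res = ss_total - ss_full
        ms_res = ss_res / (n - q - 1)
        overall = (ss_full / q) / ms_res if ms_res > 0 else np.inf
        out = [overall]
        if marginal:
            for j in range(x_rows.shape[1]):
                x_wo = np.delete(x_rows, j, axis=1)
                ss_wo = _cap_ss(y, x_wo) if x_wo.shape[1] else 0.0
                df_j = q - np.linalg.matrix_rank(x_wo) if x_wo.shape[1] else q
                df_j = max(df_j, 0)
                if df_j == 0:
                    out.append(0.0)
                else:
                    out.append(((ss_full - ss_wo) / df_j) / ms_res if ms_res > 0 else np.inf)
        return np.array(out)

    obs = stats_for(xc)
    if exact:
        if math.factorial(n) > 200_000:
            raise InputError("exact enumeration infeasible for this n")
        count = np.zeros_like(obs)
        total = 0
        for perm in itertools.permutations(range(n)):
            count += stats_for(xc[list(perm)]) >= obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros_like(obs)
        for _ in range(n_perm):
            count += stats_for(xc[rng.permutation(n)]) >= obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_used = n_perm

    rows = [{"term": "<overall>", "F": obs[0], "P": pvals[0]}]
    if marginal:
        for j, t in enumerate(X.columns):
            rows.append({"term": t, "F": obs[j + 1], "P": pvals[j + 1]})
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["n_permutations"] = n_used
    return out


def backward_select(
    D: pd.DataFrame,
    X: pd.DataFrame,
    alpha_drop: float = 0.10,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Backward stepwise selection on marginal CAP permutation P-values.

    Repeatedly drops the variable with the largest marginal P while that
    P exceeds ``alpha_drop`` (strict), stopping when one variable
    remains.  Returns the reduced table and an audit trace with one row
    per elimination round.
    """
    rng = np.random.default_rng(seed)
    current = X.copy()
    trace = []
    step = 0
    while current.shape[1] > 1:
        tests = cap_permutation_tests(
            D, current, n_perm=n_perm, seed=int(rng.integers(2**31)), marginal=True
        )
        margins = tests.drop(index="<overall>")
        worst = margins["P"].idxmax()
        worst_p = float(margins.loc[worst, "P"])
        trace.append(
            {
                "step": step,
                "candidate": worst,
                "P": worst_p,
                "dropped": worst_p > alpha_drop,
                "remaining": ",".join(current.columns),
            }
        )
        if worst_p <= alpha_drop:
            break
        current = current.drop(columns=[worst])
        step += 1
    return current, pd.DataFrame(trace)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: ``1 / (1 - R^2_j)`` per variable.

    Exactly collinear variables get ``inf``.
    """
    xc = _center(X.to_numpy(float))
    out = {}
    for j, name in enumerate(X.columns):
        others = np.delete(xc, j, axis=1)
        yj = xc[:, j]
        ss_tot = float(yj @ yj)
        if others.shape[1] == 0 or ss_tot == 0:
            out[name] = 1.0
            continue
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class PlsrScreen:
    """PLSR responder screen over a feature matrix."""

    x_scores: pd.DataFrame  # samples x components
    x_loadings: pd.DataFrame
    pct_variance_component1: pd.Series  # per response feature, 0-100
    responders: pd.Index
    cv_press: pd.Series | None = None  # leave-one-out PRESS per n_components


def plsr_screen(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_components: int = 2,
    var_explained_threshold: float = 30.0,
    cross_validate: bool = True,
    standardize: bool = True,
    seed: int | None = None,
) -> PlsrScreen:
    """Screen features whose abundances track the explanatory variables.

    Fits a PLS regression with X as predictors and the feature matrix
    (samples x features, e.g. normalized abundances transposed) as the
    multivariate response.  A feature is a responder when the
    one-component model explains more than ``var_explained_threshold``
    percent of its variance.  Leave-one-out PRESS per component count is
    reported for diagnostics when ``cross_validate``.
    """
    from sklearn.cross_decomposition import PLSRegression

    Xs = X.loc[Y.index]
    n = len(Y)
    if n <= n_components:
        raise InputError("need more samples than PLS components")
    xv = Xs.to_numpy(float)
    if standardize:
        sd = xv.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise InputError("constant explanatory variable cannot be standardized")
        xv = (xv - xv.mean(axis=0)) / sd
    yv = Y.to_numpy(float)

    pls1 = PLSRegression(n_components=1, scale=False).fit(xv, yv)
    fitted1 = pls1.predict(xv)
    yc = yv - yv.mean(axis=0)
    ss_tot = (yc**2).sum(axis=0)
    ss_res = ((yv - fitted1) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(ss_tot > 0, 100.0 * (1.0 - ss_res / ss_tot), 0.0)
    pct = pd.Series(np.clip(pct, 0.0, 100.0), index=Y.columns)

    pls = PLSRegression(n_components=n_components, scale=False).fit(xv, yv)
    scores = pd.DataFrame(
        pls.x_scores_, index=Y.index, columns=[f"comp{i+1}" for i in range(n_components)]
    )
    loadings = pd.DataFrame(
        pls.x_loadings_, index=Xs.columns, columns=scores.columns
    )

    press = None
    if cross_validate:
        press_vals = {}
        for k in range(1, n_components + 1):
            sse = 0.0
            for i in range(n):
                mask = np.arange(n) != i
                m = PLSRegression(n_components=k, scale=False).fit(xv[mask], yv[mask])
                sse += float(((yv[i] - m.predict(xv[i : i + 1])[0]) ** 2).sum())
            press_vals[k] = sse
        press = pd.Series(press_vals, name="press")

    responders = pct.index[pct > var_explained_threshold]
    return PlsrScreen(
        x_scores=scores,
        x_loadings=loadings,
        pct_variance_component1=pct,
        responders=responders,
        cv_press=press,
    )


def univariate_screen(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    responders=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (feature, variable) simple linear regression.

    Returns slope, t, two-sided P and a significance flag.  Constant
    responses yield slope 0 with P reported as NA (reason noted).
    """
    Xs = X.loc[Y.index]
    features = list(responders) if responders is not None else list(Y.columns)
    rows = []
    for f in features:
        y = Y[f].to_numpy(float)
        for v in Xs.columns:
            x = Xs[v].to_numpy(float)
            if np.var(y) == 0 or np.var(x) == 0:
                rows.append(
                    {
                        "feature": f,
                        "variable": v,
                        "slope": 0.0,
                        "t": np.nan,
                        "P": np.nan,
                        "significant": False,
                        "note": "constant response" if np.var(y) == 0 else "constant predictor",
                    }
                )
                continue
            res = scipy.stats.linregress(x, y)
            t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
            rows.append(
                {
                    "feature": f,
                    "variable": v,
                    "slope": res.slope,
                    "t": t,
                    "P": res.pvalue,
                    "significant": bool(res.pvalue < alpha),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
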