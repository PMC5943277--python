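"""Ecological indices and the regression battery.

Implements the downstream statistics of the inoculation study:

* yield response of each inoculated plot relative to matched controls,
* commonness (Levins niche breadth, 1 / sum of squared trial shares) of
  each indigenous OTU from control plots only,
* robustness (inoculated/control mean read abundance ratio) per trial,
* Bray-Curtis similarity and a two-factor crossed PERMANOVA with
  sequential sums of squares and free permutation of sample labels,
* Pearson correlation with an optional natural-log transform,
* multiple linear regression with bidirectional AIC-stepwise selection and
  standardized partial regression coefficients,
* binomial logistic regression with a Gaussian random intercept per block
  (marginal likelihood by Gauss-Hermite quadrature) and odds ratios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

__all__ = ["yield_response", "commonness", "robustness", "bray_curtis",
           "bray_curtis_matrix", "permanova", "correlate", "stepwise_lm",
           "logistic_glmm", "odds_ratio", "RegressionFit"]


# ---------------------------------------------------------------- indices

def yield_response(metadata: pd.DataFrame,
                   match_cols: Sequence[str] = ("trial", "p_level"),
                   yield_col: str = "yield_kg_ha") -> pd.DataFrame:
    """Relative yield change of each inoculated plot vs matched controls.

    response = (yield_inoculated - mean control yield) / mean control yield,
    with controls matched on ``match_cols`` (trial and P level by default).
    """
    meta = metadata.copy()
    ctrl = meta[~meta["inoculated"]]
    inoc = meta[meta["inoculated"]]
    if inoc.empty:
        raise ValueError("no inoculated plots in metadata")
    ctrl_mean = ctrl.groupby(list(match_cols))[yield_col].mean()
    rows = []
    for _, r in inoc.iterrows():
        key = tuple(r[c] for c in match_cols)
        key = key[0] if len(key) == 1 else key
        if key not in ctrl_mean.index:
            raise ValueError(f"no control plots matching {key!r}")
        cm = ctrl_mean.loc[key]
        if cm == 0:
            raise ZeroDivisionError(f"zero control mean yield for {key!r}")
        rows.append({"sample_id": r["sample_id"],
                     "trial": r["trial"],
                     "p_level": r["p_level"],
                     "response": (r[yield_col] - cm) / cm})
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class CommonnessResult:
    commonness: pd.Series          # otu -> 1 / sum P_ij^2, in [1, n_trials]
    shares: pd.DataFrame           # P_ij matrix, trials x OTUs, columns sum to 1
    excluded_rare: list
    excluded_zero: list


def _rare_filter(counts: pd.DataFrame, threshold: float) -> pd.Index:
    """OTUs whose mean relative abundance is below ``threshold``."""
    rel = counts.div(counts.sum(axis=1), axis=0)
    return counts.columns[rel.mean(axis=0) < threshold]


def commonness(table, metadata: pd.DataFrame, rare_filter: float = 0.002,
               exclude=()) -> CommonnessResult:
    """Levins niche breadth of each indigenous OTU across trials.

    Uses control plots only.  P_ij = (mean read number of OTU j in trial i)
    / (sum of OTU j's trial means); commonness_j = 1 / sum_i P_ij^2,
    ranging from 1 (single-trial specialist) to the number of trials
    (even generalist).  OTUs below the rare filter (default 0.2% mean
    relative abundance) and OTUs in ``exclude`` (the inoculum set, whose
    origin cannot be discriminated) are left out.
    """
    meta = metadata.set_index("sample_id")
    ctrl_samples = meta.index[~meta["inoculated"]]
    counts = table.counts.loc[table.counts.index.intersection(ctrl_samples)]
    trials = meta.loc[counts.index, "trial"]
    if trials.nunique() < 2:
        raise ValueError("commonness needs >= 2 trials")
    rare = set(_rare_filter(counts, rare_filter))
    drop = rare | set(exclude)
    kept = [c for c in counts.columns if c not in drop]
    trial_means = counts[kept].groupby(trials).mean()
    colsum = trial_means.sum(axis=0)
    zero = list(colsum.index[colsum == 0])
    trial_means = trial_means.drop(columns=zero)
    shares = trial_means.div(trial_means.sum(axis=0), axis=1)
    comm = 1.0 / (shares ** 2).sum(axis=0)
    return CommonnessResult(commonness=comm, shares=shares,
                            excluded_rare=sorted(rare & set(counts.columns)),
                            excluded_zero=zero)


@dataclass
class RobustnessResult:
    ratios: pd.DataFrame           # OTUs x trials; NaN where undefined
    undefined: list                # (otu, trial) with zero control mean


def robustness(table, metadata: pd.DataFrame, rare_filter: float = 0.002,
               exclude=()) -> RobustnessResult:
    """Inoculated/control mean read-abundance ratio per (OTU, trial).

    Ratios < 1 indicate displacement of the indigenous OTU by the
    introduced fungus.  Entries with a zero control mean are flagged
    undefined (NaN), never silently zero.  The same rare filter and
    inoculum-set exclusion as for commonness keep the OTU universe
    consistent.
    """
    meta = metadata.set_index("sample_id")
    counts = table.counts.loc[table.counts.index.intersection(meta.index)]
    ctrl_counts = counts.loc[~meta.loc[counts.index, "inoculated"]]
    drop = set(_rare_filter(ctrl_counts, rare_filter)) | set(exclude)
    kept = [c for c in counts.columns if c not in drop]
    trials = meta.loc[counts.index, "trial"]
    inoc = meta.loc[counts.index, "inoculated"]
    out = {}
    undefined = []
    for trial in sorted(trials.unique()):
        sel = trials == trial
        if inoc[sel].nunique() < 2:
            raise ValueError(f"trial {trial!r} lacks both treatments")
        mi = counts.loc[sel & inoc, kept].mean()
        mc = counts.loc[sel & ~inoc, kept].mean()
        ratio = mi / mc
        ratio[mc == 0] = np.nan
        undefined += [(o, trial) for o in kept if mc[o] == 0]
        out[trial] = ratio
    return RobustnessResult(ratios=pd.DataFrame(out), undefined=undefined)


# ---------------------------------------------- Bray-Curtis and PERMANOVA

def bray_curtis(x, y) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both samples are all-zero")
    return 1.0 - np.abs(x - y).sum() / denom


def bray_curtis_matrix(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity (1 - similarity) between samples."""
    counts = table.counts if hasattr(table, "counts") else table
    X = counts.to_numpy(dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - bray_curtis(X[i], X[j])
    return pd.DataFrame(D, index=counts.index, columns=counts.index)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _dummy(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype("category"), drop_first=True,
                          dtype=float).to_numpy()


def permanova(dist: pd.DataFrame, factors: pd.DataFrame,
              terms: Sequence[str] = ("trial", "inoculated", "trial:inoculated"),
              n_perm: int = 9999, seed: Optional[int] = None,
              exhaustive: bool = False) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Two-factor crossed design with interaction by default, partitioned
    with sequential (Type I) sums of squares in the order given by
    ``terms`` (``"a:b"`` denotes the interaction of columns ``a`` and
    ``b``).  Sample labels are permuted freely; the p-value for each term
    is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.  With
    ``exhaustive=True`` every permutation of the samples is enumerated and
    the p-value is the exact fraction ``#{F >= F_obs} / n!`` (identity
    included).  Deterministic under ``seed``.
    """
    samples = list(dist.index)
    if list(dist.columns) != samples:
        raise ValueError("distance matrix index/columns mismatch")
    D = dist.to_numpy(dtype=float)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    fac = factors.loc[samples]
    n = len(samples)

    def term_design(term):
        if ":" in term:
            a, b = term.split(":")
            combo = fac[a].astype(str) + "\x1f" + fac[b].astype(str)
            # interaction dummies = products of main-effect dummies
            da, db = _dummy(fac[a]), _dummy(fac[b])
            cols = [da[:, i] * db[:, j]
                    for i in range(da.shape[1]) for j in range(db.shape[1])]
            return np.column_stack(cols) if cols else np.empty((n, 0))
        if fac[term].nunique() < 2:
            raise ValueError(f"factor {term!r} has a single level")
        return _dummy(fac[term])

    designs = [term_design(t) for t in terms]
    dfs = [X.shape[1] for X in designs]
    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    X_cum = ones
    for X in designs:
        X_cum = np.hstack([X_cum, X])
        hats.append(_hat(X_cum))
    H_full = hats[-1]
    df_resid = n - int(round(np.trace(H_full)))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    R = np.eye(n) - H_full
    # tr(H @ G_perm) with G_perm = P G P^T equals tr(H_perm @ G); permute H.
    term_H = [hats[k + 1] - hats[k] for k in range(len(designs))]
    G = _gower_center(D)

    def f_stats(perm):
        Gp = G[np.ix_(perm, perm)]
        ss_resid = float((R * Gp.T).sum())
        out = []
        for H, df in zip(term_H, dfs):
            ss = float((H * Gp.T).sum())
            out.append((ss, (ss / df) / (ss_resid / df_resid)))
        return out, ss_resid

    ident = np.arange(n)
    obs, ss_resid = f_stats(ident)
    f_obs = np.array([f for _, f in obs])

    if exhaustive:
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            fp = np.array([f for _, f in f_stats(np.array(perm))[0]])
            count += fp >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            fp = np.array([f for _, f in f_stats(perm)[0]])
            count += fp >= f_obs - 1e-12
        pvals = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return pd.DataFrame({
        "df": dfs,
        "SS": [ss for ss, _ in obs],
        "pseudo_F": f_obs,
        "p": pvals,
        "n_perm": n_used,
    }, index=list(terms))


# ------------------------------------------------------------ regressions

def log_transform(x, pseudo_count: float = 0.5) -> np.ndarray:
    """Natural log; a pseudo-count is added when zeros are present."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log transform of negative values")
    if np.any(x == 0):
        x = x + pseudo_count
    return np.log(x)


def correlate(x, y, log_x: bool = False, log_y: bool = False):
    """Pearson correlation with optional log transforms; returns (R, p)."""
    x = log_transform(x) if log_x else np.asarray(x, dtype=float)
    y = log_transform(y) if log_y else np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def odds_ratio(coefficient: float) -> float:
    """Multiplicative change in odds per unit predictor: exp(coefficient)."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coefficient))


@dataclass
class RegressionFit:
    family: str
    terms: list
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    std_coefs: Optional[pd.Series] = None      # linear models
    odds_ratios: Optional[pd.Series] = None    # logistic models
    re_sd: Optional[float] = None              # mixed models
    converged: bool = True
    loglik: Optional[float] = None


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Greedily drop columns until the design has full column rank."""
    cols = list(X.columns)
    while cols:
        M = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in cols])
        if np.linalg.matrix_rank(M) == M.shape[1]:
            break
        import warnings
        warnings.warn(f"dropping collinear covariate {cols[-1]!r}")
        cols = cols[:-1]
    return X[cols]


def _stepwise(candidates, fit_aic, start=None):
    """Bidirectional stepwise AIC search; returns the selected term list.

    Starts from ``start`` (default: all candidates) and repeatedly applies
    the single add/drop move that lowers AIC most, until no move improves.
    """
    current = list(candidates) if start is None else list(start)
    best_aic = fit_aic(current)
    while True:
        moves = []
        for t in current:
            trial = [c for c in current if c != t]
            moves.append((fit_aic(trial), trial))
        for t in candidates:
            if t not in current:
                moves.append((fit_aic(current + [t]), current + [t]))
        if not moves:
            break
        aic_new, terms_new = min(moves, key=lambda m: m[0])
        if aic_new < best_aic - 1e-10:
            best_aic, current = aic_new, terms_new
        else:
            break
    return current, best_aic


def stepwise_lm(data: pd.DataFrame, response: str,
                candidates: Sequence[str], select: bool = True) -> RegressionFit:
    """OLS with bidirectional AIC-stepwise covariate selection.

    Reports coefficient estimates, standard errors, p-values and
    standardized partial regression coefficients (the slopes of the same
    model refit on z-scored response and predictors).
    """
    df = data.dropna(subset=[response, *candidates])
    if len(df) <= len(candidates) + 1:
        raise ValueError("too few observations for the full model")
    X_all = _drop_collinear(df[list(candidates)].astype(float))
    candidates = list(X_all.columns)
    y = df[response].astype(float)

    def fit(terms):
        X = sm.add_constant(X_all[terms], has_constant="add")
        return sm.OLS(y, X).fit()

    if select:
        terms, _ = _stepwise(candidates, lambda t: fit(t).aic)
    else:
        terms = candidates
    res = fit(terms)
    if terms:
        Xz = (X_all[terms] - X_all[terms].mean()) / X_all[terms].std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        std = sm.OLS(yz, sm.add_constant(Xz, has_constant="add")).fit()
        std_coefs = std.params.drop("const")
    else:
        std_coefs = pd.Series(dtype=float)
    return RegressionFit(
        family="gaussian", terms=list(terms), params=res.params,
        bse=res.bse, pvalues=res.pvalues, aic=float(res.aic),
        std_coefs=std_coefs, loglik=float(res.llf))


# ----------------------------------------------- binomial GLMM (quadrature)

def _glmm_nll(theta, y, m, X, gcodes, n_groups, nodes, weights, fix_re_sd):
    """Negative marginal log-likelihood, random intercept per group.

    The per-group integral over the Gaussian random effect is evaluated by
    adaptive Gauss-Hermite quadrature: nodes are centred at each group's
    conditional mode and scaled by the conditional curvature (found by a
    short Newton iteration on the concave joint log-density), which keeps
    the rule accurate even when the binomial likelihood is much narrower
    than the random-effect prior.  Binomial combinatorial constants are
    omitted (added back for AIC by the caller).
    """
    if fix_re_sd is None:
        beta, log_sd = theta[:-1], theta[-1]
        sd = math.exp(min(log_sd, 5.0))
    else:
        beta, sd = theta, fix_re_sd
    eta0 = X @ beta
    if sd < 1e-10:
        ll = float(np.sum(y * eta0 - m * np.logaddexp(0.0, eta0)))
        return -ll
    inv_var = 1.0 / (sd * sd)
    u = np.zeros(n_groups)
    # Newton iteration for the conditional modes, all groups at once
    for _ in range(100):
        eta = eta0 + u[gcodes]
        p = special.expit(eta)
        grad = np.bincount(gcodes, y - m * p, minlength=n_groups) - u * inv_var
        curv = np.bincount(gcodes, m * p * (1 - p), minlength=n_groups) + inv_var
        step = grad / curv
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(curv)          # conditional sd at the mode
    # h(u) per group at each shifted node
    uk = u[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta = eta0[:, None] + uk[gcodes]
    term = y[:, None] * eta - m[:, None] * np.logaddexp(0.0, eta)
    h = np.zeros((n_groups, len(nodes)))
    np.add.at(h, gcodes, term)
    h += (-0.5 * uk * uk * inv_var
          - 0.5 * math.log(2 * math.pi * sd * sd)
          + nodes[None, :] ** 2 + np.log(weights)[None, :])
    log_int = (special.logsumexp(h, axis=1)
               + 0.5 * math.log(2.0) + np.log(tau))
    return -float(np.sum(log_int))


def logistic_glmm(data: pd.DataFrame, successes: str, trials,
                  covariates: Sequence[str], group: str = "block",
                  select: bool = False, n_quad: int = 21,
                  fix_re_sd: Optional[float] = None) -> RegressionFit:
    """Binomial logistic regression with a Gaussian random intercept.

    Models per-plot (successes, failures) counts — e.g. inoculum-type reads
    out of the rarefaction depth — on covariates, with a random intercept
    for ``group`` integrated out of the likelihood by Gauss-Hermite
    quadrature and maximized by L-BFGS.  ``trials`` is a column name or an
    integer constant.  With ``select=True`` a bidirectional AIC-stepwise
    search over the covariates is run first.  ``fix_re_sd`` pins the
    random-effect standard deviation (0 reduces the model to a plain
    binomial GLM).  Odds ratios are exp(coefficients).
    """
    df = data.dropna(subset=[successes, *covariates, group]).reset_index(drop=True)
    y = df[successes].to_numpy(float)
    m = (np.full(len(df), float(trials)) if isinstance(trials, (int, float))
         else df[trials].to_numpy(float))
    if np.any(y > m) or np.any(y < 0):
        raise ValueError("successes must lie in [0, trials]")
    gcodes, _glevels = pd.factorize(df[group])
    n_groups = len(_glevels)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    X_all = _drop_collinear(df[list(covariates)].astype(float))
    covariates = list(X_all.columns)

    def fit(terms):
        X = np.column_stack([np.ones(len(df))] +
                            [X_all[t].to_numpy(float) for t in terms])
        # start from the fixed-effects GLM fit
        glm = sm.GLM(np.column_stack([y, m - y]), X,
                     family=sm.families.Binomial()).fit()
        beta0 = np.asarray(glm.params)
        if fix_re_sd is None:
            theta0 = np.append(beta0, math.log(0.5))
        else:
            theta0 = beta0
        res = optimize.minimize(
            _glmm_nll, theta0,
            args=(y, m, X, gcodes, n_groups, nodes, weights, fix_re_sd),
            method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-7, "maxiter": 1000})
        k = X.shape[1] + (1 if fix_re_sd is None else 0)
        # add back the binomial combinatorial constants for a true loglik
        const = float(np.sum(special.gammaln(m + 1) - special.gammaln(y + 1)
                             - special.gammaln(m - y + 1)))
        ll = -res.fun + const
        aic = 2 * k - 2 * ll
        return res, aic, ll, X, k

    if select:
        terms, _ = _stepwise(covariates, lambda t: fit(t)[1])
    else:
        terms = covariates
    res, aic, ll, X, k = fit(terms)
    names = ["const"] + list(terms)
    if fix_re_sd is None:
        beta = res.x[:-1]
        re_sd = float(math.exp(res.x[-1]))
    else:
        beta = res.x
        re_sd = float(fix_re_sd)
    # standard errors from the numerical Hessian of the profile in beta
    try:
        import statsmodels.tools.numdiff as nd
        hess = nd.approx_hess(
            res.x, _glmm_nll,
            args=(y, m, X, gcodes, n_groups, nodes, weights, fix_re_sd))
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:len(beta)], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    params = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    z = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    if not res.success:
        grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.nan
        import warnings
        warnings.warn(f"GLMM optimizer did not converge (|grad|={grad_norm:.3g})")
    return RegressionFit(
        family="binomial-glmm", terms=list(terms), params=params, bse=bse,
        pvalues=pvals, aic=float(aic),
        odds_ratios=np.exp(params.drop("const")),
        re_sd=re_sd, converged=bool(res.success), loglik=float(ll))
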