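"""Nested linear mixed models for cells-within-animals designs.

The measurement design has several cells (or slices) per animal, so cell
values are not independent: a random intercept per animal absorbs the
between-animal variance.  Repeated measurements within a cell (AP number,
injected current, blade, distance from electrode) are modelled through a
residual covariance structure chosen among

* ``diagonal``           — independent, heteroscedastic per within-level,
* ``compound_symmetry``  — shared correlation, homoscedastic,
* ``unstructured``       — full symmetric covariance (log-Cholesky),

selected by smaller-is-better information criteria (AIC by default) among
candidates that converged, with ties broken toward the simpler structure.

Estimation is restricted maximum likelihood with the profile computed by
this module (block-wise by animal); generic numerical optimization is
delegated to scipy.  Fixed-effect tests are Wald F statistics with
containment-style denominator degrees of freedom: effects constant within
animal are tested against the number of animals, within-cell effects
against the residual.  Estimated marginal means average predictions over
a balanced grid of the off-target factors.  No multiple-testing
correction is applied.

The module also carries the delta-delta-Ct genotype-calling arithmetic
used for qPCR genotyping of the transgenic colony.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor as _cho_factor, cho_solve as _cho_solve

from .exceptions import ConvergenceError

STRUCTURES = ("none", "diagonal", "compound_symmetry", "unstructured")
_COMPLEXITY = {s: i for i, s in enumerate(STRUCTURES)}


# ---------------------------------------------------------------------------
# model specification and design assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declares the model: response, fixed factors, nesting, covariance."""

    response: str
    fixed: Sequence[str]
    interactions: Sequence[tuple[str, str]] = ()
    random_group: str = "animal_id"
    subject: Optional[str] = None       # e.g. cell_id, for repeated measures
    within: Optional[str] = None        # repeated factor column
    covariance: str = "compound_symmetry"

    def __post_init__(self) -> None:
        fixed = list(self.fixed)
        for a, b in self.interactions:
            if a not in fixed or b not in fixed:
                raise ValueError("interactions must be among fixed factors")
        if self.within is not None and self.subject is None:
            raise ValueError("a repeated factor requires a subject column")
        if self.covariance not in STRUCTURES:
            raise ValueError(f"unknown covariance {self.covariance!r}")


def _levels(table: pd.DataFrame, col: str) -> list:
    return sorted(table[col].dropna().unique().tolist())


def _design_matrix(
    table: pd.DataFrame, spec: ModelSpec,
    levels: Optional[dict[str, list]] = None,
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Treatment-coded fixed-effects design matrix with named columns."""
    if levels is None:
        levels = {f: _levels(table, f) for f in spec.fixed}
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["Intercept"]
    dummies: dict[str, dict] = {}
    for f in spec.fixed:
        dummies[f] = {}
        for lev in levels[f][1:]:
            d = (table[f] == lev).to_numpy(dtype=float)
            cols.append(d)
            names.append(f"{f}[{lev}]")
            dummies[f][lev] = d
    for a, b in spec.interactions:
        for la, da in dummies[a].items():
            for lb, db in dummies[b].items():
                cols.append(da * db)
                names.append(f"{a}[{la}]:{b}[{lb}]")
    return np.column_stack(cols), names, levels


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _block_layout(table: pd.DataFrame, spec: ModelSpec):
    """Row indices grouped by animal, with per-row subject and level codes."""
    animals = table[spec.random_group].to_numpy()
    order = np.argsort(animals, kind="stable")
    blocks = []
    for _, idx in itertools.groupby(order, key=lambda i: animals[i]):
        blocks.append(np.fromiter(idx, dtype=int))
    return blocks


def _sigma_matrix(structure: str, theta: np.ndarray, k: int) -> np.ndarray:
    """Within-subject residual covariance Sigma(theta), k x k."""
    if structure in ("none",):
        return np.exp(2 * theta[0]) * np.eye(k)
    if structure == "diagonal":
        return np.diag(np.exp(2 * theta[:k]))
    if structure == "compound_symmetry":
        s_c2 = np.exp(2 * theta[0])
        s_e2 = np.exp(2 * theta[1])
        return s_c2 * np.ones((k, k)) + s_e2 * np.eye(k)
    if structure == "unstructured":
        L = np.zeros((k, k))
        tril = np.tril_indices(k)
        vals = theta[: len(tril[0])].copy()
        L[tril] = vals
        diag = np.arange(k)
        L[diag, diag] = np.exp(L[diag, diag])
        return L @ L.T
    raise ValueError(structure)


def _n_theta(structure: str, k: int) -> int:
    return {"none": 1, "diagonal": k, "compound_symmetry": 2,
            "unstructured": k * (k + 1) // 2}[structure]


def _reml_neg2ll(
    log_sa: float, theta: np.ndarray, structure: str,
    X: np.ndarray, y: np.ndarray, blocks, subj_codes, level_codes, k: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """-2 restricted log-likelihood plus GLS beta and its covariance."""
    p = X.shape[1]
    s_a2 = math.exp(2 * log_sa)
    sigma = _sigma_matrix(structure, theta, k)
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for rows in blocks:
        Xa = X[rows]
        ya = y[rows]
        n_a = len(rows)
        # residual covariance: block-diagonal over subjects within animal
        R = np.zeros((n_a, n_a))
        subs = subj_codes[rows]
        levs = level_codes[rows]
        for s in np.unique(subs):
            m = np.flatnonzero(subs == s)
            li = levs[m]
            R[np.ix_(m, m)] = sigma[np.ix_(li, li)]
        V = R + s_a2
        try:
            c, low = _cho_factor(V)
        except np.linalg.LinAlgError:
            return math.inf, np.full(p, np.nan), np.full((p, p), np.nan)
        logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
        vix = _cho_solve((c, low), Xa)
        viy = _cho_solve((c, low), ya)
        xtvx += Xa.T @ vix
        xtvy += Xa.T @ viy
        ytvy += float(ya @ viy)
    try:
        beta = np.linalg.solve(xtvx, xtvy)
        cov_beta = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return math.inf, np.full(p, np.nan), np.full((p, p), np.nan)
    rss = ytvy - float(xtvy @ beta)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0 or rss <= 0:
        return math.inf, beta, cov_beta
    n = len(y)
    neg2 = ((n - p) * math.log(2 * math.pi) + logdet + logdet_x + rss)
    return neg2, beta, cov_beta


def _fit_random_intercept(X: np.ndarray, y: np.ndarray, blocks):
    """Profiled REML for y = Xb + animal intercept + iid residual.

    With V = s_e^2 (I + rho J) per animal block, the Woodbury identity
    gives every REML quantity from per-block Gram matrices, and s_e^2 is
    profiled out analytically, leaving a one-dimensional search over the
    variance ratio rho.
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    grams = []
    for rows in blocks:
        Xa, ya = X[rows], y[rows]
        grams.append((Xa.T @ Xa, Xa.T @ ya, Xa.sum(axis=0),
                      float(ya.sum()), float(ya @ ya), len(rows)))

    def assemble(rho: float):
        A = np.zeros((p, p))
        b = np.zeros(p)
        yy = 0.0
        logdet_w = 0.0
        for xtx, xty, s, t, y2, n_a in grams:
            cfac = rho / (1.0 + n_a * rho)
            A += xtx - cfac * np.outer(s, s)
            b += xty - cfac * s * t
            yy += y2 - cfac * t * t
            logdet_w += math.log(1.0 + n_a * rho)
        return A, b, yy, logdet_w

    def neg2_profiled(log_rho: float) -> float:
        rho = math.exp(log_rho)
        A, b, yy, logdet_w = assemble(rho)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return math.inf
        rss = yy - float(b @ beta)
        if rss <= 0:
            return math.inf
        s_e2 = rss / (n - p)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return math.inf
        return ((n - p) * (math.log(2 * math.pi) + 1.0 + math.log(s_e2))
                + logdet_w + logdet_a)

    res = minimize_scalar(neg2_profiled, bounds=(-20.0, 10.0),
                          method="bounded",
                          options={"xatol": 1e-6})
    rho = math.exp(res.x)
    A, b, yy, _ = assemble(rho)
    beta = np.linalg.solve(A, b)
    rss = yy - float(b @ beta)
    s_e2 = rss / (n - p)
    cov_beta = s_e2 * np.linalg.inv(A)
    return (beta, cov_beta, math.sqrt(rho * s_e2), math.sqrt(s_e2),
            float(res.fun), bool(res.success))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FixedEffectTest:
    statistic: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class FitResult:
    spec: ModelSpec
    structure: str
    beta: np.ndarray
    names: list[str]
    cov_beta: np.ndarray
    variance_components: dict[str, float]
    neg2_reml: float
    aic: float
    bic: float
    converged: bool
    singular_random_effect: bool
    n_obs: int
    n_groups: int
    tests: dict[str, FixedEffectTest] = field(default_factory=dict)
    emmeans: Optional[pd.DataFrame] = None
    levels: dict[str, list] = field(default_factory=dict)
    df_method: str = "containment"

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def contrast(
        self, factor: str, level_hi: Optional[str] = None,
        level_lo: Optional[str] = None, alpha: float = 0.05,
    ) -> dict:
        """EMM difference level_hi - level_lo with a t interval."""
        em = self.emmeans_for(factor)
        levs = em[factor].tolist()
        if level_hi is None:
            level_hi = levs[1]
        if level_lo is None:
            level_lo = levs[0]
        lrow = {r[factor]: np.asarray(r["_lvec"])
                for _, r in em.iterrows()}
        lvec = lrow[level_hi] - lrow[level_lo]
        est = float(lvec @ self.beta)
        se = float(np.sqrt(lvec @ self.cov_beta @ lvec))
        df = self._df_for_factor(factor)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return {
            "estimate": est, "se": se, "df": df,
            "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
            "t": est / se if se > 0 else math.inf,
            "p": 2 * stats.t.sf(abs(est / se), df) if se > 0 else 0.0,
        }

    def _between_factors(self) -> set[str]:
        return set(self.spec.fixed) - {self.spec.within}

    def _df_for_factor(self, factor: str) -> float:
        p_between = 1 + sum(
            len(self.levels[f]) - 1 for f in self.spec.fixed
            if f != self.spec.within
        )
        if factor == self.spec.within:
            return max(1.0, self.n_obs - len(self.beta) - self.n_groups + 1)
        return max(1.0, self.n_groups - p_between)

    def emmeans_for(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means for one factor, balanced over others."""
        others = [f for f in self.spec.fixed if f != factor]
        rows = []
        df = self._df_for_factor(factor)
        tcrit = stats.t.ppf(0.975, df)
        for lev in self.levels[factor]:
            grid = list(itertools.product(
                *[self.levels[f] for f in others])) or [()]
            lvec = np.zeros(len(self.beta))
            for combo in grid:
                assignment = dict(zip(others, combo))
                assignment[factor] = lev
                lvec += self._row_vector(assignment)
            lvec /= len(grid)
            est = float(lvec @ self.beta)
            se = float(np.sqrt(lvec @ self.cov_beta @ lvec))
            rows.append({factor: lev, "emmean": est, "se": se, "df": df,
                         "ci_low": est - tcrit * se,
                         "ci_high": est + tcrit * se,
                         "_lvec": lvec.tolist()})
        return pd.DataFrame(rows)

    def _row_vector(self, assignment: dict) -> np.ndarray:
        v = np.zeros(len(self.beta))
        for j, name in enumerate(self.names):
            if name == "Intercept":
                v[j] = 1.0
                continue
            terms = name.split(":")
            val = 1.0
            for term in terms:
                f, lev = term[:-1].split("[")
                if str(assignment.get(f)) != lev:
                    val = 0.0
                    break
            v[j] = val
        return v


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_lmm(table: pd.DataFrame, spec: ModelSpec,
            compute_emmeans: bool = True) -> FitResult:
    """Fit the nested linear mixed model by REML.

    Requires at least two animals per level of the first fixed factor.
    A structured failure falls back to the next-simpler covariance; a
    random-effect variance estimated at (numerically) zero is flagged but
    the fit is kept.
    """
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X, names, levels = _design_matrix(table, spec)
    blocks = _block_layout(table, spec)

    if spec.within is not None:
        wlevels = _levels(table, spec.within)
        lmap = {lv: i for i, lv in enumerate(wlevels)}
        level_codes = table[spec.within].map(lmap).to_numpy(dtype=int)
        subj_vals = table[spec.subject].astype(str).to_numpy()
        _, subj_codes = np.unique(subj_vals, return_inverse=True)
        k = len(wlevels)
        structure = spec.covariance
    else:
        level_codes = np.zeros(len(y), dtype=int)
        subj_codes = np.arange(len(y))
        k = 1
        structure = "none"

    if structure == "none":
        beta, cov_beta, s_a, s_e, neg2, success = _fit_random_intercept(
            X, y, blocks)
        sd0 = float(np.std(y)) or 1.0
        fit = FitResult(
            spec=spec, structure=structure, beta=beta, names=names,
            cov_beta=cov_beta,
            variance_components={"animal_sd": s_a, "residual_sd": s_e},
            neg2_reml=neg2, aic=neg2 + 2 * 2,
            bic=neg2 + 2 * math.log(len(y) - X.shape[1]),
            converged=success and math.isfinite(neg2),
            singular_random_effect=s_a < 1e-6 * sd0,
            n_obs=len(y), n_groups=len(blocks), levels=levels,
        )
        fit.tests = _wald_tests(fit)
        if compute_emmeans and spec.fixed:
            fit.emmeans = fit.emmeans_for(spec.fixed[0])
        return fit

    sd0 = float(np.std(y)) or 1.0
    q = _n_theta(structure, k)
    if structure == "unstructured":
        theta0 = np.zeros(q)
        tril = np.tril_indices(k)
        theta0[np.flatnonzero(tril[0] == tril[1])] = math.log(sd0 * 0.8)
    else:
        theta0 = np.full(q, math.log(sd0 * 0.8))

    x0 = np.r_[math.log(sd0 * 0.5), theta0]

    def objective(x):
        return _reml_neg2ll(x[0], x[1:], structure, X, y, blocks,
                            subj_codes, level_codes, k)[0]

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6,
                 "maxiter": 300 * (1 + q)},
    )
    neg2, beta, cov_beta = _reml_neg2ll(
        res.x[0], res.x[1:], structure, X, y, blocks, subj_codes,
        level_codes, k,
    )
    converged = bool(res.success) and math.isfinite(neg2)
    s_a = math.exp(res.x[0])
    varcomp = {"animal_sd": s_a}
    if structure == "none":
        varcomp["residual_sd"] = math.exp(res.x[1])
    elif structure == "diagonal":
        for i in range(k):
            varcomp[f"level{i + 1}_sd"] = math.exp(res.x[1 + i])
    elif structure == "compound_symmetry":
        varcomp["cell_sd"] = math.exp(res.x[1])
        varcomp["residual_sd"] = math.exp(res.x[2])

    n_params_cov = 1 + q
    n, p = len(y), X.shape[1]
    fit = FitResult(
        spec=spec, structure=structure, beta=beta, names=names,
        cov_beta=cov_beta, variance_components=varcomp,
        neg2_reml=neg2, aic=neg2 + 2 * n_params_cov,
        bic=neg2 + n_params_cov * math.log(n - p),
        converged=converged,
        singular_random_effect=s_a < 1e-6 * sd0,
        n_obs=n, n_groups=len(blocks), levels=levels,
    )
    fit.tests = _wald_tests(fit)
    if compute_emmeans and spec.fixed:
        fit.emmeans = fit.emmeans_for(spec.fixed[0])
    return fit


def _wald_tests(fit: FitResult) -> dict[str, FixedEffectTest]:
    tests = {}
    terms: dict[str, list[int]] = {}
    for j, name in enumerate(fit.names):
        if name == "Intercept":
            continue
        base = ":".join(t[:-1].split("[")[0] for t in name.split(":"))
        terms.setdefault(base, []).append(j)
    for term, idx in terms.items():
        L = np.zeros((len(idx), len(fit.beta)))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        est = L @ fit.beta
        cov = L @ fit.cov_beta @ L.T
        try:
            f_stat = float(est @ np.linalg.solve(cov, est)) / len(idx)
        except np.linalg.LinAlgError:
            continue
        parts = term.split(":")
        within_involved = fit.spec.within in parts
        df_den = fit._df_for_factor(
            fit.spec.within if within_involved else parts[0]
        )
        p_val = float(stats.f.sf(f_stat, len(idx), df_den))
        tests[term] = FixedEffectTest(f_stat, len(idx), df_den, p_val)
    return tests


@dataclass
class CovarianceSelection:
    chosen: str
    fit: FitResult
    criteria: pd.DataFrame


def select_covariance(
    table: pd.DataFrame, spec: ModelSpec,
    candidates: Sequence[str] = ("compound_symmetry", "diagonal"),
    criterion: str = "aic",
) -> CovarianceSelection:
    """Fit each candidate structure and keep the best by information
    criterion (smaller is better); ties go to the simpler structure."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate structures")
    rows = []
    fits: dict[str, FitResult] = {}
    for cand in candidates:
        import dataclasses as _dc
        sub = _dc.replace(spec, covariance=cand)
        try:
            fit = fit_lmm(table, sub, compute_emmeans=False)
        except Exception as exc:  # structured failure of one candidate
            rows.append({"structure": cand, "aic": math.inf,
                         "bic": math.inf, "converged": False,
                         "error": str(exc)})
            continue
        fits[cand] = fit
        rows.append({"structure": cand, "aic": fit.aic, "bic": fit.bic,
                     "converged": fit.converged, "error": ""})
    crit_table = pd.DataFrame(rows)
    ok = crit_table[crit_table.converged]
    if ok.empty:
        raise ConvergenceError(
            "no candidate converged:\n" + crit_table.to_string()
        )
    key = criterion.lower()
    best_val = ok[key].min()
    tied = ok[np.isclose(ok[key], best_val, atol=1e-6)]
    chosen = min(tied.structure, key=lambda s: _COMPLEXITY[s])
    return CovarianceSelection(chosen=chosen, fit=fits[chosen],
                               criteria=crit_table.drop(columns=["error"]))


# ---------------------------------------------------------------------------
# qPCR genotyping and simple proportions
# ---------------------------------------------------------------------------

@dataclass
class DdctResult:
    ddct: Optional[float]
    relative_quantity: Optional[float]
    call: str                     # negative | hemizygous | homozygous


def ddct_genotype(
    ct_target: Optional[float], ct_norm: float,
    ct_target_ref: float, ct_norm_ref: float,
) -> DdctResult:
    """Delta-delta-Ct relative quantification against a homozygous
    reference sample.

    ddCt = (ct_target - ct_norm) - (ct_target_ref - ct_norm_ref);
    relative quantity = 2^(-ddCt).  The genotype call is the nearest of
    {0: negative, 0.5: hemizygous, 1: homozygous} on the relative
    quantity; an undetermined target with a detected normalizer is called
    negative outright.
    """
    for v, label in ((ct_norm, "ct_norm"), (ct_target_ref, "ct_target_ref"),
                     (ct_norm_ref, "ct_norm_ref")):
        if v is None or not math.isfinite(v):
            raise ValueError(f"{label} must be finite")
    if ct_target is None or not math.isfinite(ct_target):
        return DdctResult(ddct=None, relative_quantity=0.0, call="negative")
    ddct = (ct_target - ct_norm) - (ct_target_ref - ct_norm_ref)
    rq = 2.0 ** (-ddct)
    calls = {0.0: "negative", 0.5: "hemizygous", 1.0: "homozygous"}
    nearest = min(calls, key=lambda c: abs(rq - c))
    return DdctResult(ddct=float(ddct), relative_quantity=float(rq),
                      call=calls[nearest])


def fraction_percent(count: int, total: int, decimals: int = 0) -> float:
    """Percentage of ``count`` out of ``total`` at the stated precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
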