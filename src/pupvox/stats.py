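"""Inference layer: permutation-tested random-intercept models, per-seal
Mann–Whitney tests, Bonferroni control, and coefficient-of-variation
analysis.

The core model is a linear mixed model with two crossed random intercepts
(recording session and individual seal), condition and trial number as
fixed effects, fitted by REML/ML with the variance profile computed through
the Woodbury identity (the random-effects design has few levels, so each
likelihood evaluation is O(n q^2) for q = n_sessions + n_seals).  A
package-owned solver keeps permutation tests affordable: statsmodels'
MixedLM serves as an independent cross-check in the test suite, not as the
fitting path.

Permutation p-values: condition labels are permuted at the block level
within each session — calls within a block share a condition by design, so
blocks are the exchangeable units.  Variance components are estimated once
by REML under the condition-free null model (hence identical for observed
and permuted data), the data are whitened with that covariance, and the
statistic is the F ratio for the condition term in the whitened regression.
p = (1 + #{permuted >= observed}) / (1 + n_perm), so p is never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as spstats

from .audio import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "StatResult",
    "RandomInterceptFit",
    "fit_random_intercept_model",
    "permutation_p",
    "pairwise_condition_tests",
    "mann_whitney",
    "per_seal_intensity_tests",
    "coefficient_of_variation",
    "bonferroni_alpha",
]


def bonferroni_alpha(n_comparisons: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed-model analysis."""

    response: str
    fixed: tuple[str, ...] = ("condition", "trial_index")
    random: tuple[str, ...] = ("session_id", "seal_id")
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class StatResult:
    """One model or test outcome."""

    comparison: str
    response: str
    statistic: float
    p_perm: float
    pseudo_r2: float
    n: int
    alpha_adjusted: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_perm <= 1.0) and not math.isnan(self.p_perm):
            raise ValueError(f"p_perm must lie in (0, 1], got {self.p_perm}")

    @property
    def significant(self) -> bool:
        return self.p_perm < self.alpha_adjusted


@dataclass
class RandomInterceptFit:
    beta: pd.Series
    var_components: dict  # variance per random factor, plus "residual"
    fitted: np.ndarray
    pseudo_r2: float
    loglik: float
    lr_vs_null: float
    n: int
    converged: bool
    dropped: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Design matrices


def _condition_dummies(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded condition columns, reference = first condition
    present in the canonical (no_playback, low, high) order."""
    present = [c for c in CONDITIONS if c in set(df["condition"])]
    if len(present) < 2:
        return np.empty((len(df), 0)), []
    cols, names = [], []
    for c in present[1:]:
        cols.append((df["condition"] == c).to_numpy(float))
        names.append(f"condition[{c}]")
    return np.column_stack(cols), names


def _fixed_design(
    df: pd.DataFrame, fixed: Sequence[str], include_condition: bool = True
) -> tuple[np.ndarray, list[str]]:
    X = [np.ones(len(df))]
    names = ["intercept"]
    for term in fixed:
        if term == "condition":
            if include_condition:
                C, cnames = _condition_dummies(df)
                if C.shape[1]:
                    X.append(C)
                    names.extend(cnames)
        elif term in df.columns:
            X.append(df[term].to_numpy(float)[:, None])
            names.append(term)
        else:
            raise KeyError(f"fixed-effect column {term!r} not in table")
    return np.hstack([np.atleast_2d(a.T).T for a in X]), names


def _indicator(df: pd.DataFrame, col: str) -> np.ndarray:
    codes, _ = pd.factorize(df[col])
    Z = np.zeros((len(df), codes.max() + 1))
    Z[np.arange(len(df)), codes] = 1.0
    return Z


# ---------------------------------------------------------------------------
# REML/ML core (Woodbury-profiled likelihood)


def _profiled_loglik(
    log_gammas: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Zs: Sequence[np.ndarray],
    reml: bool,
) -> tuple[float, np.ndarray, float]:
    """Profiled (over beta, sigma^2) log-likelihood at variance ratios
    gamma = exp(log_gammas).  Returns (loglik, beta, sigma2)."""
    n, p = X.shape
    gammas = np.exp(log_gammas)
    Zw = np.hstack([Z * math.sqrt(g) for Z, g in zip(Zs, gammas)])
    q = Zw.shape[1]
    M = np.eye(q) + Zw.T @ Zw
    L = np.linalg.cholesky(M)

    def vinv(A: np.ndarray) -> np.ndarray:
        t = np.linalg.solve(L, Zw.T @ A)
        return A - Zw @ np.linalg.solve(L.T, t)

    XtViX = X.T @ vinv(X)
    XtViy = X.T @ vinv(y)
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    quad = float(r @ vinv(r))
    logdetV0 = 2.0 * float(np.sum(np.log(np.diag(L))))
    if quad <= 0 or not math.isfinite(quad):
        # saturated/degenerate fit: likelihood unbounded, treat as invalid
        return -1e12, beta, max(quad / max(n - p, 1), 1e-300)
    if reml:
        dof = n - p
        if dof <= 0:
            raise ValueError("REML requires more observations than fixed effects")
        sigma2 = quad / dof
        sign, logdetX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (
            dof * (math.log(2 * math.pi * sigma2) + 1.0) + logdetV0 + logdetX
        )
    else:
        sigma2 = quad / n
        ll = -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdetV0)
    return ll, beta, sigma2


_LOG_GAMMA_BOUNDS = (-23.0, 12.0)  # gamma in [1e-10, ~1.6e5]


def _fit_core(
    y: np.ndarray,
    X: np.ndarray,
    Zs: Sequence[np.ndarray],
    reml: bool,
) -> tuple[np.ndarray, float, np.ndarray, float, bool]:
    """Optimize the profiled likelihood over log variance ratios.

    Returns (gammas, loglik, beta, sigma2, converged)."""

    def neg(lg: np.ndarray) -> float:
        try:
            return -_profiled_loglik(lg, y, X, Zs, reml)[0]
        except (np.linalg.LinAlgError, ValueError):
            return 1e12

    x0 = np.full(len(Zs), -1.0)
    res = optimize.minimize(
        neg,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
    )
    lg = np.clip(res.x, *_LOG_GAMMA_BOUNDS)
    ll, beta, sigma2 = _profiled_loglik(lg, y, X, Zs, reml)
    return np.exp(lg), ll, beta, sigma2, bool(res.success)


def fit_random_intercept_model(
    table: pd.DataFrame, spec: ModelSpec
) -> RandomInterceptFit:
    """REML fit of the random-intercept model for `spec.response`.

    Variance components that collapse to (numerically) zero are reported as
    zero and logged as dropped — the profiled likelihood is continuous at
    the boundary, so this matches refitting without the component.  The
    pseudo-R² is the squared correlation between fitted (including BLUPs)
    and observed responses.  ``lr_vs_null`` is the ML likelihood-ratio
    statistic against the same model without the condition term.
    """
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    if len(df) == 0:
        raise ValueError("no non-missing responses to fit")
    X, names = _fixed_design(df, spec.fixed, include_condition=True)
    if len(df) <= X.shape[1] + 1:
        raise ValueError(
            f"too few observations ({len(df)}) for {X.shape[1]} fixed effects"
        )
    Zs = [_indicator(df, col) for col in spec.random]
    for col, Z in zip(spec.random, Zs):
        if Z.shape[1] < 2:
            logger.info("random factor %s has < 2 levels", col)

    gammas, ll, beta, sigma2, conv = _fit_core(y, X, Zs, reml=True)
    dropped = [
        col for col, g in zip(spec.random, gammas) if g <= 1e-8
    ]
    for col in dropped:
        logger.info("variance component %s collapsed to zero; dropped", col)

    # BLUP fitted values
    Zw = np.hstack([Z * math.sqrt(g) for Z, g in zip(Zs, gammas)])
    M = np.eye(Zw.shape[1]) + Zw.T @ Zw
    r = y - X @ beta
    u = Zw.T @ r - Zw.T @ (Zw @ np.linalg.solve(M, Zw.T @ r))
    fitted = X @ beta + Zw @ u
    if np.std(fitted) > 0 and np.std(y) > 0:
        pseudo_r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        pseudo_r2 = 0.0

    # ML likelihood ratio against the condition-free model
    _, ll_full_ml, _, _, _ = _fit_core(y, X, Zs, reml=False)
    X0, _ = _fixed_design(df, spec.fixed, include_condition=False)
    _, ll_null_ml, _, _, _ = _fit_core(y, X0, Zs, reml=False)
    lr = max(2.0 * (ll_full_ml - ll_null_ml), 0.0)

    var_components = {
        col: float(g * sigma2) if g > 1e-8 else 0.0
        for col, g in zip(spec.random, gammas)
    }
    var_components["residual"] = float(sigma2)
    return RandomInterceptFit(
        beta=pd.Series(beta, index=names),
        var_components=var_components,
        fitted=fitted,
        pseudo_r2=pseudo_r2,
        loglik=float(ll),
        lr_vs_null=float(lr),
        n=len(df),
        converged=conv,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Permutation inference


class _ConditionPermuter:
    """Pre-compiled permutation of condition labels at the exchangeability
    unit.

    With a ``block_index`` column, labels are permuted across the blocks of
    each session (calls keep their block, blocks swap conditions).  Without
    one (grouped tables such as per-cell CV rows), labels are permuted
    among the rows of each (session, seal) group.  Labels are integer codes
    indexing the canonical condition order."""

    def __init__(self, df: pd.DataFrame):
        cond_codes = np.array(
            [CONDITIONS.index(c) for c in df["condition"]], dtype=np.intp
        )
        self.codes = cond_codes
        self.groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        if "block_index" in df.columns:
            unit = pd.MultiIndex.from_arrays(
                [df["session_id"], df["block_index"]]
            )
            sess_key = df["session_id"].to_numpy()
        else:
            unit = pd.MultiIndex.from_arrays(
                [df["session_id"], df["seal_id"], np.arange(len(df))]
            )
            sess_key = (
                df["session_id"].astype(str) + "\x00" + df["seal_id"].astype(str)
            ).to_numpy()
        unit_codes, uniq = pd.factorize(unit)
        # per exchange group (session, or session x seal): the units it owns
        unit_cond = np.empty(len(uniq), dtype=np.intp)
        unit_group: dict = {}
        first = {}
        for row, u in enumerate(unit_codes):
            if u not in first:
                first[u] = row
                unit_cond[u] = cond_codes[row]
                unit_group.setdefault(sess_key[row], []).append(u)
        for units in unit_group.values():
            units = np.asarray(units, dtype=np.intp)
            self.groups.append((units, unit_cond[units].copy(), units.copy()))
        self.unit_codes = unit_codes
        self.unit_cond = unit_cond

    def permute(self, rng: np.random.Generator) -> np.ndarray:
        new_unit_cond = self.unit_cond.copy()
        for units, conds, _ in self.groups:
            new_unit_cond[units] = conds[rng.permutation(len(conds))]
        return new_unit_cond[self.unit_codes]


def _whitener(
    Zs: Sequence[np.ndarray], gammas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Matrices (U, d) such that whitening is A -> A - U @ (d * (U.T @ A))
    with V0^{-1/2} = I - U diag(d) U'."""
    Zw = np.hstack([Z * math.sqrt(g) for Z, g in zip(Zs, gammas)])
    U, svals, _ = np.linalg.svd(Zw, full_matrices=False)
    d = 1.0 - 1.0 / np.sqrt(1.0 + svals**2)
    return U, d


def _code_dummies(codes: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Treatment-coded columns from integer condition codes; reference is
    the first present code in canonical order."""
    return np.column_stack(
        [(codes == c).astype(float) for c in present[1:]]
    )


def permutation_p(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[float, float]:
    """Permutation p-value for the condition effect.

    Returns (p_perm, observed statistic).  See the module docstring for the
    exchangeability scheme and the fixed-covariance whitening."""
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    X0, _ = _fixed_design(df, spec.fixed, include_condition=False)
    Zs = [_indicator(df, col) for col in spec.random]
    gammas, _, _, _, _ = _fit_core(y, X0, Zs, reml=True)
    U, d = _whitener(Zs, gammas)

    def whiten(A: np.ndarray) -> np.ndarray:
        return A - U @ (d[:, None] * (U.T @ A)) if A.ndim == 2 else A - U @ (
            d * (U.T @ A)
        )

    yw = whiten(y)
    X0w = whiten(X0)
    Q0, _ = np.linalg.qr(X0w)
    r_y = yw - Q0 @ (Q0.T @ yw)
    rss0 = float(r_y @ r_y)
    n, p0 = X0w.shape

    permuter = _ConditionPermuter(df)
    present = np.array(
        sorted(np.unique(permuter.codes)), dtype=np.intp
    )

    def f_stat(codes: np.ndarray) -> float:
        C = _code_dummies(codes, present)
        Cw = whiten(C)
        r_C = Cw - Q0 @ (Q0.T @ Cw)
        Q1, R1 = np.linalg.qr(r_C)
        keep = np.abs(np.diag(R1)) > 1e-10 * max(1.0, np.abs(R1).max())
        Q1 = Q1[:, keep]
        df1 = Q1.shape[1]
        if df1 == 0:
            return 0.0
        proj = Q1.T @ r_y
        rss1 = rss0 - float(proj @ proj)
        df2 = n - p0 - df1
        if df2 <= 0 or rss1 <= 0:
            return float("inf")
        return ((rss0 - rss1) / df1) / (rss1 / df2)

    obs = f_stat(permuter.codes)
    rng = np.random.default_rng(spec.seed)
    count = 0
    for _ in range(spec.n_perm):
        if f_stat(permuter.permute(rng)) >= obs:
            count += 1
    p = (1 + count) / (1 + spec.n_perm)
    return p, obs


def _model_result(
    table: pd.DataFrame,
    spec: ModelSpec,
    comparison: str,
    alpha_adjusted: float,
) -> StatResult:
    fit = fit_random_intercept_model(table, spec)
    p, stat = permutation_p(table, spec)
    return StatResult(
        comparison=comparison,
        response=spec.response,
        statistic=stat,
        p_perm=p,
        pseudo_r2=fit.pseudo_r2,
        n=fit.n,
        alpha_adjusted=alpha_adjusted,
    )


def condition_main_test(
    table: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> StatResult:
    """Omnibus condition effect (all three levels)."""
    return _model_result(table, spec, "all_conditions", alpha)


def pairwise_condition_tests(
    table: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> list[StatResult]:
    """Model refit on each two-condition subset; Bonferroni alpha/3."""
    present = [c for c in CONDITIONS if c in set(table["condition"])]
    pairs = list(itertools.combinations(present, 2))
    adj = bonferroni_alpha(3, alpha)
    results = []
    for i, (a, b) in enumerate(pairs):
        sub = table[table["condition"].isin([a, b])]
        pair_spec = ModelSpec(
            response=spec.response,
            fixed=spec.fixed,
            random=spec.random,
            n_perm=spec.n_perm,
            seed=spec.seed + 1 + i,
        )
        results.append(_model_result(sub, pair_spec, f"{a}_vs_{b}", adj))
    return results


# ---------------------------------------------------------------------------
# Mann–Whitney


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when min(|x|, |y|) <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 12 and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def per_seal_intensity_tests(
    features: pd.DataFrame,
    measures: Sequence[str] = (
        "intensity_linear",
        "octave_slope_db_per_oct",
        "r14_db",
    ),
    alpha: float = 0.05,
) -> list[StatResult]:
    """Per-seal, per-condition-pair Mann–Whitney tests for each measure.

    The family-wise threshold is alpha / (n_seals * 3) per measure family
    (0.05/24 for the eight-seal design).  Seal/pair cells with an empty
    sample are skipped and logged."""
    seals = sorted(features["seal_id"].unique())
    adj = bonferroni_alpha(len(seals) * 3, alpha)
    results = []
    for seal in seals:
        sub = features[features["seal_id"] == seal]
        present = [c for c in CONDITIONS if c in set(sub["condition"])]
        for a, b in itertools.combinations(present, 2):
            for measure in measures:
                xa = sub.loc[sub["condition"] == a, measure].dropna().to_numpy()
                xb = sub.loc[sub["condition"] == b, measure].dropna().to_numpy()
                if len(xa) == 0 or len(xb) == 0:
                    logger.info(
                        "skipping %s %s vs %s on %s: empty cell",
                        seal, a, b, measure,
                    )
                    continue
                mw = mann_whitney(xa, xb)
                results.append(
                    StatResult(
                        comparison=f"{seal}:{a}_vs_{b}",
                        response=measure,
                        statistic=mw["U"],
                        p_perm=mw["p"],
                        pseudo_r2=float("nan"),
                        n=len(xa) + len(xb),
                        alpha_adjusted=adj,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# Coefficient of variation


def coefficient_of_variation(
    table: pd.DataFrame,
    response: str,
    spec: ModelSpec | None = None,
    min_group_size: int = 3,
) -> tuple[pd.DataFrame, StatResult | None]:
    """Dispersion analysis: CV = sample sd (n−1) / mean per
    (session, seal, condition) group, groups with fewer than
    `min_group_size` calls dropped (logged); the CV table is then analysed
    with the random-intercept model + permutation test (condition fixed
    effect only).  Returns (cv_table, model result or None when the model
    cannot be fitted)."""
    df = table.dropna(subset=[response])
    rows = []
    n_dropped = 0
    for (sess, seal, cond), grp in df.groupby(
        ["session_id", "seal_id", "condition"], sort=False
    ):
        vals = grp[response].to_numpy(float)
        if len(vals) < min_group_size:
            n_dropped += 1
            continue
        m = float(np.mean(vals))
        rows.append(
            {
                "session_id": sess,
                "seal_id": seal,
                "condition": cond,
                "cv": float(np.std(vals, ddof=1)) / m if m != 0 else float("nan"),
                "n_calls": len(vals),
            }
        )
    if n_dropped:
        logger.info("CV analysis dropped %d groups with < %d calls", n_dropped, min_group_size)
    cv_table = pd.DataFrame(
        rows, columns=["session_id", "seal_id", "condition", "cv", "n_calls"]
    )
    if len(cv_table) < 4 or cv_table["condition"].nunique() < 2:
        return cv_table, None
    spec = spec or ModelSpec(response="cv", fixed=("condition",), n_perm=1000)
    cv_spec = ModelSpec(
        response="cv",
        fixed=("condition",),
        random=spec.random,
        n_perm=spec.n_perm,
        seed=spec.seed,
    )
    result = _model_result(cv_table, cv_spec, "all_conditions", 0.05)
    return cv_table, result
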