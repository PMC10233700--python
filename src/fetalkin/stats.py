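"""Robust log-scale mixed-effects analysis of absolute movement time.

The model is a mixed-model ANOVA on ``log(AMT)`` with fixed factors for
maternal position, parity, oxygen condition, placental position, fetal
position, fetal sex, gestational-age group (categorical, per week),
joint distance class, extremity and side, interaction terms for
GA x extremity and GA x side, and two random intercepts: one per
subject and one per repeated scan of a subject in a given maternal
position.  Variance components are estimated by REML (via statsmodels
``MixedLM``).

Outliers are handled by robust reweighting: each row receives a Tukey
bisquare weight computed from its scaled marginal residual (tuning
constant c = 7.041, i.e. 99% asymptotic Gaussian efficiency; scale =
normalized MAD), the fixed effects are refit by weighted generalized
least squares holding the random-effect structure fixed, and the loop
repeats until the weights stabilize.

Fitted log-scale contrasts ``beta`` are retransformed to percent
effects ``(exp(beta) - 1) * 100`` with delta-method standard errors and
endpoint-retransformed Wald confidence intervals.  False discovery is
controlled per hypothesis family (one family per fixed effect or
interaction) by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BISQUARE_C_99",
    "ModelSpec",
    "FitResult",
    "log_transform",
    "bisquare_weights",
    "bisquare_tuning_constant",
    "fit_mixed",
    "robust_refit",
    "retransform_contrast",
    "build_contrasts",
    "fdr_adjust",
    "analyze",
]

#: Bisquare tuning constant giving 99% asymptotic efficiency at the
#: Gaussian model.
BISQUARE_C_99 = 7.041

_DEFAULT_FACTORS = (
    "maternal_position",
    "parity",
    "oxygen",
    "placental_position",
    "fetal_position",
    "fetal_sex",
    "ga_group",
    "distance_class",
    "extremity",
    "side",
)
_DEFAULT_INTERACTIONS = (("ga_group", "extremity"), ("ga_group", "side"))


@dataclass
class ModelSpec:
    """Model structure and fitting options."""

    fixed_factors: tuple[str, ...] = _DEFAULT_FACTORS
    interactions: tuple[tuple[str, str], ...] = _DEFAULT_INTERACTIONS
    response: str = "log_amt"
    subject_col: str = "subject_id"
    position_col: str = "maternal_position"
    robust: bool = True
    bisquare_efficiency: float = 0.99
    max_iterations: int = 50
    weight_tolerance: float = 1e-6
    alpha: float = 0.05
    #: What to do when the design matrix is rank deficient: ``"raise"``
    #: (default) or ``"drop"`` the aliased columns (their levels then
    #: merge with the reference — only sensible for small smoke runs).
    on_singular: str = "raise"
    #: Factors reported as pairwise contrast families; by default every
    #: fixed factor except those whose content is reported through
    #: interaction slices (ga_group, extremity, side).
    report_pairwise: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.bisquare_efficiency < 1.0:
            raise ValueError("bisquare efficiency must lie in (0.5, 1)")

    def pairwise_families(self) -> tuple[str, ...]:
        if self.report_pairwise is not None:
            return self.report_pairwise
        sliced = {f for pair in self.interactions for f in pair}
        return tuple(f for f in self.fixed_factors if f not in sliced)


# ---------------------------------------------------------------------------
# response transform
# ---------------------------------------------------------------------------


def log_transform(
    table: pd.DataFrame,
    zero_rule: str = "offset",
    offset_s: float | None = None,
    amt_col: str = "amt_s",
) -> pd.DataFrame:
    """Add the ``log_amt`` response column.

    ``log_amt = ln(amt)`` for positive AMT.  Zero AMT (a joint that
    never crossed the velocity threshold in an epoch) is handled by
    ``zero_rule``:

    * ``"offset"`` (default): substitute half a frame interval,
      ``ln(dt/2)`` (``dt`` from the ``dt_s`` column, or ``offset_s``),
      and flag the row in ``zero_substituted``;
    * ``"drop"``: remove the row.

    Negative AMT raises ``ValueError``.
    """
    amt = table[amt_col].to_numpy(float)
    if np.any(amt < 0):
        raise ValueError("negative AMT")
    out = table.copy()
    zero = amt == 0
    out["zero_substituted"] = zero
    if zero.any():
        if zero_rule == "drop":
            out = out.loc[~zero].reset_index(drop=True)
            amt = out[amt_col].to_numpy(float)
            zero = amt == 0
        elif zero_rule == "offset":
            if "dt_s" in out.columns:
                sub = out["dt_s"].to_numpy(float) / 2.0
            elif offset_s is not None:
                sub = np.full(len(out), float(offset_s))
            else:
                raise ValueError(
                    "zero AMT present but no dt_s column or offset_s given"
                )
            amt = np.where(zero, sub, amt)
        else:
            raise ValueError(f"unknown zero_rule {zero_rule!r}")
    out["log_amt"] = np.log(amt)
    out.attrs["log_transform"] = {"zero_rule": zero_rule, "n_zero": int(zero.sum())}
    return out


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclass
class _DesignInfo:
    columns: list[str]
    #: column -> {factor: level} constraints (empty for the intercept)
    col_terms: dict[str, dict[str, str]]
    #: family name -> list of columns
    family_cols: dict[str, list[str]]
    levels: dict[str, list[str]]
    #: column -> grouping level at which it varies
    #: ("subject" | "cell" | "row"); filled in by the fit
    col_grouping: dict[str, str] = field(default_factory=dict)
    #: grouping level -> denominator degrees of freedom (between-within)
    ddf: dict[str, float] = field(default_factory=dict)


def _col_pairwise(factor: str, level: str) -> str:
    return f"{factor}[{level}]"


def _build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, _DesignInfo]:
    missing = [f for f in spec.fixed_factors if f not in table.columns]
    if missing:
        raise KeyError(f"factors absent from table: {missing}")
    levels = {
        f: sorted(table[f].astype(str).unique(), key=lambda s: (len(s), s))
        if f == "ga_group"
        else sorted(table[f].astype(str).unique())
        for f in spec.fixed_factors
    }
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    col_terms: dict[str, dict[str, str]] = {"Intercept": {}}
    family_cols: dict[str, list[str]] = {}
    for f in spec.fixed_factors:
        vals = table[f].astype(str).to_numpy()
        family_cols[f] = []
        for lv in levels[f][1:]:  # first level is the reference
            name = _col_pairwise(f, lv)
            cols[name] = (vals == lv).astype(float)
            col_terms[name] = {f: lv}
            family_cols[f].append(name)
    for f1, f2 in spec.interactions:
        fam = f"{f1}:{f2}"
        family_cols[fam] = []
        v1 = table[f1].astype(str).to_numpy()
        v2 = table[f2].astype(str).to_numpy()
        for l1 in levels[f1][1:]:
            for l2 in levels[f2][1:]:
                name = f"{f1}[{l1}]:{f2}[{l2}]"
                cols[name] = ((v1 == l1) & (v2 == l2)).astype(float)
                col_terms[name] = {f1: l1, f2: l2}
                family_cols[fam].append(name)
    X = pd.DataFrame(cols, index=table.index)
    info = _DesignInfo(
        columns=list(X.columns),
        col_terms=col_terms,
        family_cols=family_cols,
        levels=levels,
    )
    return X, info


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    from scipy.linalg import qr

    arr = X.to_numpy()
    _, r, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    n_ok = int((diag > tol).sum())
    return [X.columns[piv[i]] for i in range(n_ok, arr.shape[1])]


def _encode(info: _DesignInfo, assignment: Mapping[str, str]) -> np.ndarray:
    """Design-row encoding restricted to the factors in ``assignment``.

    A column contributes iff every factor it involves is assigned; the
    value is 1 when all its level constraints match.  Differences of two
    encodings that assign the same factors are therefore valid contrast
    vectors: unassigned factors cancel.
    """
    vec = np.zeros(len(info.columns))
    for j, col in enumerate(info.columns):
        terms = info.col_terms[col]
        if not terms:
            continue  # intercept cancels in contrasts
        if set(terms) <= set(assignment):
            vec[j] = float(all(assignment[f] == lv for f, lv in terms.items()))
    return vec


# ---------------------------------------------------------------------------
# bisquare
# ---------------------------------------------------------------------------


def bisquare_weights(resid: np.ndarray, scale: float, c: float = BISQUARE_C_99) -> np.ndarray:
    """Tukey bisquare weights: ``(1 - u^2)^2`` for ``|u| < 1`` else 0,
    with ``u = r / (c * scale)``."""
    if scale <= 0:
        return np.ones_like(np.asarray(resid, float))
    u = np.asarray(resid, float) / (c * scale)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w


def bisquare_tuning_constant(efficiency: float) -> float:
    """Tuning constant c achieving a given asymptotic Gaussian efficiency.

    Solves ``(E psi')^2 / E psi^2 = efficiency`` under the standard
    normal, where ``psi(r) = r (1 - (r/c)^2)^2`` on ``|r| < c``.
    Reproduces the conventional c = 4.685 (95%) and c = 7.041 (99%).
    """
    if not 0.5 < efficiency < 1.0:
        raise ValueError("efficiency must lie in (0.5, 1)")

    def eff(c: float) -> float:
        psi2 = integrate.quad(
            lambda r: (r * (1 - (r / c) ** 2) ** 2) ** 2 * sps.norm.pdf(r), -c, c
        )[0]
        dpsi = integrate.quad(
            lambda r: (1 - (r / c) ** 2) * (1 - 5 * (r / c) ** 2) * sps.norm.pdf(r),
            -c,
            c,
        )[0]
        return dpsi**2 / psi2

    return float(optimize.brentq(lambda c: eff(c) - efficiency, 1.0, 40.0))


# ---------------------------------------------------------------------------
# mixed-model fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted model state: log-scale coefficients, their covariance,
    variance components, robust weights and the convergence trace."""

    params: pd.Series
    cov_params: pd.DataFrame
    var_subject: float
    var_scan_within_position: float
    var_residual: float
    weights: np.ndarray
    iterations: int
    converged: bool
    spec: ModelSpec
    info: _DesignInfo
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    subjects: np.ndarray = field(repr=False)
    cells: np.ndarray = field(repr=False)
    weight_trace: list[float] = field(default_factory=list)

    def _ddf_for(self, cols: list[str]) -> float:
        """Between-within denominator df: finest grouping among cols."""
        order = {"subject": 0, "cell": 1, "row": 2}
        finest = max(
            (self.info.col_grouping.get(c, "row") for c in cols),
            key=lambda g: order[g],
            default="row",
        )
        return self.info.ddf.get(finest, float(len(self.y) - len(self.params)))

    def contrast(
        self, assignment_a: Mapping[str, str], assignment_b: Mapping[str, str]
    ) -> tuple[float, float]:
        """Log-scale estimate and SE of ``a - b``."""
        est, se, _ = self.contrast_with_df(assignment_a, assignment_b)
        return est, se

    def contrast_with_df(
        self, assignment_a: Mapping[str, str], assignment_b: Mapping[str, str]
    ) -> tuple[float, float, float]:
        """Log-scale estimate, SE and denominator df of ``a - b``."""
        c = _encode(self.info, {k: str(v) for k, v in assignment_a.items()}) - _encode(
            self.info, {k: str(v) for k, v in assignment_b.items()}
        )
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        involved = [col for col, w in zip(self.info.columns, c) if w != 0.0]
        return est, se, self._ddf_for(involved)

    def family_pvalue(self, family: str) -> float:
        """Joint Wald F test that all columns of a family are zero."""
        cols = self.info.family_cols[family]
        if not cols:
            return float("nan")
        idx = [self.info.columns.index(c) for c in cols]
        b = self.params.to_numpy()[idx]
        V = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b)) / len(idx)
        return float(sps.f.sf(stat, len(idx), self._ddf_for(cols)))


def fit_mixed(table: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """REML fit of the two-random-intercept mixed model.

    ``table`` must carry the response column (see :func:`log_transform`)
    and all model factors.  Deterministic given data and spec.
    """
    spec = spec or ModelSpec()
    if spec.response not in table.columns:
        raise KeyError(
            f"response column {spec.response!r} missing; run log_transform first"
        )
    if table[spec.subject_col].nunique() < 2:
        raise ValueError("at least two subjects are required")
    # keep observed factors only (a factor with a single level is dropped
    # rather than producing an all-zero family)
    factors = tuple(
        f for f in spec.fixed_factors if table[f].astype(str).nunique() > 1
    )
    interactions = tuple(
        (f1, f2)
        for f1, f2 in spec.interactions
        if f1 in factors and f2 in factors
    )
    spec_eff = replace(spec, fixed_factors=factors, interactions=interactions)

    table = table.sort_values([spec.subject_col, spec.position_col], kind="stable")
    table = table.reset_index(drop=True)
    y = table[spec.response].to_numpy(float)
    X, info = _build_design(table, spec_eff)
    aliased = _aliased_columns(X)
    if aliased:
        if spec.on_singular == "drop":
            warnings.warn(f"dropping aliased design columns: {aliased}")
            X = X.drop(columns=aliased)
            info.columns = list(X.columns)
            for col in aliased:
                info.col_terms.pop(col, None)
            for fam in info.family_cols:
                info.family_cols[fam] = [
                    c for c in info.family_cols[fam] if c not in aliased
                ]
        else:
            raise ValueError(f"singular design; aliased columns: {aliased}")

    subjects = table[spec.subject_col].astype(str).to_numpy()
    cells = np.array(
        [f"{s}|{p}" for s, p in zip(subjects, table[spec.position_col].astype(str))]
    )

    # between-within denominator degrees of freedom: classify each
    # column by the finest grouping at which it varies, then apportion
    # the sample at each level
    def _constant_within(vals: np.ndarray, groups: np.ndarray) -> bool:
        df_ = pd.DataFrame({"g": groups, "v": vals})
        return bool((df_.groupby("g")["v"].nunique() == 1).all())

    for col in X.columns:
        v = X[col].to_numpy()
        if _constant_within(v, subjects):
            info.col_grouping[col] = "subject"
        elif _constant_within(v, cells):
            info.col_grouping[col] = "cell"
        else:
            info.col_grouping[col] = "row"
    n_subj = len(np.unique(subjects))
    n_cell = len(np.unique(cells))
    p_subj = sum(1 for g in info.col_grouping.values() if g == "subject")
    p_cell = sum(1 for g in info.col_grouping.values() if g in ("subject", "cell"))
    info.ddf = {
        "subject": max(float(n_subj - p_subj), 1.0),
        "cell": max(float(n_cell - p_cell), 1.0),
        "row": max(float(len(y) - X.shape[1]), 1.0),
    }

    mats, colnames = [], []
    for _, sub in pd.DataFrame({"g": subjects, "c": cells}).groupby("g", sort=True):
        d = pd.get_dummies(sub["c"])
        mats.append(d.to_numpy(float))
        colnames.append(list(d.columns))
    vcs = VCSpec(["scan_within_position"], [colnames], [mats])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=subjects, exog_re=np.ones((len(y), 1)), exog_vc=vcs)
        res = model.fit(reml=True)
        if not res.converged:
            # gradient methods stall when a variance component sits on
            # the zero boundary; derivative-free restart handles it
            res = model.fit(reml=True, method="powell", maxiter=5000)

    k = X.shape[1]
    params = pd.Series(np.asarray(res.fe_params), index=X.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=X.columns, columns=X.columns
    )
    return FitResult(
        params=params,
        cov_params=cov,
        var_subject=float(res.cov_re.iloc[0, 0]),
        var_scan_within_position=float(res.vcomp[0]),
        var_residual=float(res.scale),
        weights=np.ones(len(y)),
        iterations=0,
        converged=bool(res.converged),
        spec=spec_eff,
        info=info,
        X=X,
        y=y,
        subjects=subjects,
        cells=cells,
    )


def _weighted_gls(fit: FitResult, weights: np.ndarray):
    """Fixed-effect WGLS holding the variance components fixed.

    Per-subject marginal covariance
    ``V = var_subj * J + var_cell * Z Z' + var_resid * diag(1/w)``;
    rows with zero weight are excluded.
    """
    Xa = fit.X.to_numpy()
    p = Xa.shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    order = np.argsort(fit.subjects, kind="stable")
    boundaries = np.flatnonzero(
        np.r_[True, fit.subjects[order][1:] != fit.subjects[order][:-1]]
    )
    groups = np.split(order, boundaries[1:])
    for idx in groups:
        act = idx[weights[idx] > 1e-12]
        if len(act) == 0:
            continue
        Xs = Xa[act]
        ys = fit.y[act]
        cs = fit.cells[act]
        n = len(act)
        V = np.full((n, n), fit.var_subject)
        V += fit.var_scan_within_position * (cs[:, None] == cs[None, :])
        V[np.diag_indices(n)] += fit.var_residual / weights[act]
        sol = np.linalg.solve(V, np.column_stack([Xs, ys]))
        A += Xs.T @ sol[:, :p]
        bvec += Xs.T @ sol[:, p]
    cov = np.linalg.inv(A)
    beta = cov @ bvec
    return beta, cov


def robust_refit(fit: FitResult, spec: ModelSpec | None = None) -> FitResult:
    """Iterated bisquare reweighting of the mixed-model fit.

    Marginal residuals are scaled by the normalized MAD, converted to
    bisquare weights (c for the configured efficiency), and the fixed
    effects are refit by weighted GLS with the random-effect structure
    held fixed — repeated until the largest weight change falls below
    the tolerance.  If the loop hits the iteration cap the last iterate
    is returned with ``converged=False``.
    """
    spec = spec or fit.spec
    if not spec.robust:
        return replace(fit, weights=np.ones(len(fit.y)), iterations=0, converged=True)
    c = (
        BISQUARE_C_99
        if abs(spec.bisquare_efficiency - 0.99) < 1e-12
        else bisquare_tuning_constant(spec.bisquare_efficiency)
    )
    beta = fit.params.to_numpy().copy()
    cov = fit.cov_params.to_numpy().copy()
    w = np.ones(len(fit.y))
    trace: list[float] = []
    converged = False
    iterations = 0
    Xa = fit.X.to_numpy()
    for iterations in range(1, spec.max_iterations + 1):
        r = fit.y - Xa @ beta
        s = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        w_new = bisquare_weights(r, s, c)
        delta = float(np.max(np.abs(w_new - w)))
        trace.append(delta)
        w = w_new
        beta, cov = _weighted_gls(fit, w)
        if delta < spec.weight_tolerance:
            converged = True
            break
    return replace(
        fit,
        params=pd.Series(beta, index=fit.X.columns),
        cov_params=pd.DataFrame(cov, index=fit.X.columns, columns=fit.X.columns),
        weights=w,
        iterations=iterations,
        converged=converged,
        weight_trace=trace,
    )


# ---------------------------------------------------------------------------
# contrasts, retransformation, FDR
# ---------------------------------------------------------------------------


def retransform_contrast(
    beta: float, se_log: float, ci_log: tuple[float, float] | None = None
) -> tuple[float, float, tuple[float, float]]:
    """Log-scale contrast -> percent scale.

    ``estimate% = (exp(beta) - 1) * 100``; CI endpoints are
    retransformed the same way; the SE uses the delta method
    ``exp(beta) * se_log * 100``.
    """
    if not np.isfinite(beta):
        raise ValueError("non-finite contrast estimate")
    if ci_log is None:
        z = sps.norm.ppf(0.975)
        ci_log = (beta - z * se_log, beta + z * se_log)
    pct = (math.exp(beta) - 1.0) * 100.0
    se_pct = math.exp(beta) * se_log * 100.0
    return pct, se_pct, ((math.exp(ci_log[0]) - 1) * 100.0, (math.exp(ci_log[1]) - 1) * 100.0)


def build_contrasts(fit: FitResult, families: Sequence[tuple] | None = None) -> pd.DataFrame:
    """All reported contrasts, on log and percent scales.

    ``families`` is a sequence of ``("factor", "pairwise")`` or
    ``("f1:f2", "slices")`` entries; by default every pairwise factor
    family of the model spec plus per-week slices of each interaction.
    Pairwise labels order the two levels alphabetically (``a-b`` =
    effect of a relative to b); slice labels read ``week*[a-b]``.

    Inference is Wald-type on the log scale with between-within
    denominator degrees of freedom (t per contrast, F per family).
    """
    spec = fit.spec
    if families is None:
        families = [(f, "pairwise") for f in spec.pairwise_families()]
        families += [(f"{f1}:{f2}", "slices") for f1, f2 in spec.interactions]
    rows = []
    for fam, kind in families:
        if kind == "pairwise":
            if fam not in fit.info.levels:
                raise KeyError(f"unknown factor {fam!r}")
            levels = fit.info.levels[fam]
            fam_p = fit.family_pvalue(fam)
            for i, a in enumerate(levels):
                for b in levels[i + 1 :]:
                    est, se, df = fit.contrast_with_df({fam: a}, {fam: b})
                    rows.append((fam, f"{a}-{b}", fam_p, est, se, df))
        elif kind == "slices":
            f1, f2 = fam.split(":")
            if fam not in fit.info.family_cols:
                raise KeyError(f"unknown interaction {fam!r}")
            fam_p = fit.family_pvalue(fam)
            lv2 = fit.info.levels[f2]
            for wk in fit.info.levels[f1]:
                for i, a in enumerate(lv2):
                    for b in lv2[i + 1 :]:
                        est, se, df = fit.contrast_with_df(
                            {f1: wk, f2: a}, {f1: wk, f2: b}
                        )
                        rows.append((fam, f"{wk}*[{a}-{b}]", fam_p, est, se, df))
        else:
            raise ValueError(f"unknown family kind {kind!r}")
    out = []
    for fam, label, fam_p, est, se, df in rows:
        tstat = est / se if se > 0 else 0.0
        p = float(2 * sps.t.sf(abs(tstat), df)) if se > 0 else 1.0
        q = sps.t.ppf(0.975, df)
        pct, se_pct, (lo, hi) = retransform_contrast(est, se, (est - q * se, est + q * se))
        out.append(
            {
                "effect": fam,
                "contrast": label,
                "effect_p": fam_p,
                "est_log": est,
                "se_log": se,
                "estimate_pct": pct,
                "se_pct": se_pct,
                "ci_low_pct": lo,
                "ci_high_pct": hi,
                "p": p,
            }
        )
    return pd.DataFrame(out)


def fdr_adjust(contrast_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg within each effect family.

    Appends ``fdr`` plus raw/FDR significance flags at ``alpha``.
    """
    p = contrast_table["p"].to_numpy(float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    out = contrast_table.copy()
    out["fdr"] = np.nan
    for fam, idx in out.groupby("effect").groups.items():
        _, q, _, _ = multipletests(out.loc[idx, "p"], alpha=alpha, method="fdr_bh")
        out.loc[idx, "fdr"] = q
    out["significant_raw"] = out["p"] < alpha
    out["significant_fdr"] = out["fdr"] < alpha
    return out


def analyze(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    zero_rule: str = "offset",
) -> tuple[FitResult, pd.DataFrame]:
    """Full pipeline: log transform -> REML fit -> robust refit ->
    contrasts -> per-family FDR.  Returns (fit, contrast table)."""
    spec = spec or ModelSpec()
    modeling = (
        log_transform(table, zero_rule=zero_rule)
        if spec.response not in table.columns
        else table
    )
    fit = fit_mixed(modeling, spec)
    fit = robust_refit(fit)
    contrasts = fdr_adjust(build_contrasts(fit), alpha=spec.alpha)
    return fit, contrasts
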