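"""Inference layer: transformation selection, linear mixed models with
nested random intercepts, Tukey-adjusted pairwise contrasts, and
case-level Spearman correlations.

Degrees of freedom use a between-within approximation (recorded on every
contrast) rather than Kenward-Roger, which is not available in this
ecosystem.  Assumption checks operationalize the visual diagnostics:
residual normality via Shapiro-Wilk (subsampled to 5000) and
homoscedasticity via a test of |residual| on fitted values, both at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "Transformation",
    "apply_transformation",
    "ModelSpec",
    "ModelFit",
    "ContrastResult",
    "CorrelationResult",
    "fit_lmem",
    "fixed_effect_test",
    "posthoc_contrasts",
    "select_transformation",
    "case_level_correlations",
    "simulate_measurement_table",
]

DEFAULT_LAMBDA_GRID = tuple(np.arange(-2.0, 2.25, 0.25))


@dataclass
class Transformation:
    """One member of the candidate transformation set.

    ``tukey_ladder`` is the sign-preserving ladder of powers: ``x**lam``
    for ``lam > 0``, ``log(x)`` for ``lam == 0`` and ``-(x**lam)`` for
    ``lam < 0``.  Log-type transforms of data containing zeros add an
    offset of half the smallest positive value; the offset used is
    recorded on the instance.
    """

    name: str = "identity"
    lam: float | None = None
    offset_used: float = 0.0
    rescale_used: float = 1.0

    def __post_init__(self) -> None:
        valid = ("identity", "sqrt", "log", "arcsine_sqrt", "tukey_ladder")
        if self.name not in valid:
            raise ValueError(f"unknown transformation {self.name!r}")
        if self.name == "tukey_ladder" and self.lam is None:
            raise ValueError("tukey_ladder requires a lambda")

    @property
    def label(self) -> str:
        if self.name == "tukey_ladder":
            return f"tukey_ladder({self.lam:g})"
        return self.name

    def _offset_for(self, x: np.ndarray) -> float:
        if np.all(x > 0):
            return 0.0
        pos = x[x > 0]
        if len(pos) == 0:
            raise ValueError(
                f"{self.label}: no positive values; cannot derive a log offset"
            )
        return float(pos.min() / 2.0)

    def apply(self, values: Sequence[float]) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"{self.label}: non-finite input values")
        if self.name == "identity":
            return x.copy()
        if self.name == "sqrt":
            bad = x[x < 0]
            if len(bad):
                raise ValueError(
                    f"sqrt: negative values not allowed (e.g. {bad[:3]})"
                )
            return np.sqrt(x)
        if self.name == "arcsine_sqrt":
            if np.any(x < 0):
                raise ValueError("arcsine_sqrt: negative values not allowed")
            scale = 1.0
            if np.any(x > 1.0):
                if np.all(x <= 100.0):
                    scale = 100.0  # percent scale
                else:
                    bad = x[x > 100.0]
                    raise ValueError(
                        f"arcsine_sqrt: values above 100 (e.g. {bad[:3]})"
                    )
            self.rescale_used = scale
            return np.arcsin(np.sqrt(x / scale))
        # log and tukey_ladder
        lam = 0.0 if self.name == "log" else float(self.lam)
        if lam > 0:
            bad = x[x < 0]
            if len(bad):
                raise ValueError(
                    f"{self.label}: negative values not allowed (e.g. {bad[:3]})"
                )
            return np.power(x, lam)
        bad = x[x < 0]
        if len(bad):
            raise ValueError(
                f"{self.label}: negative values not allowed (e.g. {bad[:3]})"
            )
        offset = self._offset_for(x)
        self.offset_used = offset
        xs = x + offset
        if lam == 0:
            return np.log(xs)
        return -np.power(xs, lam)


def apply_transformation(
    values: Sequence[float], transformation: Transformation | str
) -> np.ndarray:
    """Elementwise transformation of an outcome vector."""
    if isinstance(transformation, str):
        transformation = Transformation(transformation)
    return transformation.apply(values)


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model recipe: outcome, fixed formula, random structure,
    transformation.

    ``random`` is ``"case"`` (random intercept per case) or
    ``"case_roi"`` (random intercepts for case and for ROI-within-case).
    """

    outcome: str
    fixed: str = "group"
    random: str = "case"
    transformation: Transformation = field(default_factory=Transformation)
    case_column: str = "case_id"
    roi_column: str = "roi_pair_id"
    group_column: str = "group"

    def __post_init__(self) -> None:
        if self.random not in ("case", "case_roi"):
            raise ValueError("random must be 'case' or 'case_roi'")


@dataclass
class ModelFit:
    """A fitted mixed model plus the bookkeeping downstream steps need."""

    spec: ModelSpec
    params: pd.Series
    cov_fe: np.ndarray
    design_info: object
    aic: float
    bic: float
    reml: bool
    converged: bool
    variance_components: dict[str, float]
    diagnostics: dict
    n_obs: int
    n_cases: int
    data: pd.DataFrame
    within_columns: list[str]
    result: object = None

    @property
    def k_fe(self) -> int:
        return len(self.params)

    @property
    def df_between(self) -> int:
        n_between = self.k_fe - len(self.within_columns)
        return max(self.n_cases - n_between, 1)

    @property
    def df_within(self) -> int:
        return max(self.n_obs - self.n_cases - len(self.within_columns), 1)


@dataclass
class ContrastResult:
    """One post-hoc comparison on the transformed scale."""

    comparison: str
    estimate: float
    se: float
    t: float
    df: float
    df_method: str
    p_adjusted: float
    p_unadjusted: float
    adjustment: str
    transformation: str


@dataclass
class CorrelationResult:
    """Spearman correlation of two case-level means within one group."""

    group: str
    var_x: str
    var_y: str
    rho: float | None
    p: float | None
    n_cases: int
    note: str = ""


def _model_columns(spec: ModelSpec) -> list[str]:
    cols = [spec.outcome, spec.case_column]
    if spec.random == "case_roi":
        cols.append(spec.roi_column)
    for name in ("group", "plaque_status", "age_years"):
        if name in spec.fixed:
            cols.append(name)
    return cols


def _residual_diagnostics(
    resid: np.ndarray, fitted: np.ndarray, max_n: int = 5000
) -> dict:
    rng = np.random.default_rng(0)
    r = np.asarray(resid, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if len(r) > max_n:
        idx = rng.choice(len(r), size=max_n, replace=False)
        r_sub = r[idx]
    else:
        r_sub = r
    if np.ptp(r_sub) == 0:
        return {
            "shapiro_w": np.nan, "shapiro_p": 0.0,
            "het_slope": np.nan, "het_p": 0.0, "degenerate": True,
        }
    sw = sps.shapiro(r_sub)
    if np.ptp(f) == 0:
        het_slope, het_p = 0.0, 1.0
    else:
        lr = sps.linregress(f, np.abs(r))
        het_slope, het_p = float(lr.slope), float(lr.pvalue)
    return {
        "shapiro_w": float(sw.statistic),
        "shapiro_p": float(sw.pvalue),
        "het_slope": het_slope,
        "het_p": het_p,
        "degenerate": False,
    }


def fit_lmem(
    measurements: pd.DataFrame, spec: ModelSpec, compute_ic: bool = True
) -> ModelFit:
    """REML fit of ``transformed(outcome) ~ fixed`` with the requested
    random-intercept structure.

    AIC/BIC come from an ML refit (REML likelihoods are not comparable
    across fixed-effect structures); pass ``compute_ic=False`` to skip the
    refit when information criteria are not needed.  Rows with missing
    values in any model column are dropped listwise.  A singular or
    non-converged fit is returned flagged (``converged=False``) rather
    than raised.
    """
    cols = [c for c in dict.fromkeys(_model_columns(spec))
            if c in measurements.columns]
    if spec.outcome not in measurements.columns:
        raise ValueError(
            f"outcome column {spec.outcome!r} not in measurement table "
            f"(have {sorted(measurements.columns)})"
        )
    data = measurements[cols].dropna().reset_index(drop=True).copy()
    n_cases = data[spec.case_column].nunique()
    if n_cases < 2:
        raise ValueError("at least 2 cases are required for a mixed model")
    y = np.asarray(data[spec.outcome], dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(
            f"outcome {spec.outcome!r} is constant; model is degenerate"
        )
    transformation = replace(spec.transformation)
    data["_y"] = transformation.apply(y)
    formula = f"_y ~ {spec.fixed}"
    vc_formula = None
    if spec.random == "case_roi":
        data["_roi"] = (
            data[spec.case_column].astype(str)
            + ":" + data[spec.roi_column].astype(str)
        )
        vc_formula = {"roi": "0 + C(_roi)"}
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data[spec.case_column],
            re_formula="1", vc_formula=vc_formula,
        )
        try:
            res = model.fit(reml=True)
            res_ml = model.fit(reml=False) if compute_ic else None
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise RuntimeError(f"mixed model failed to fit: {exc}") from exc
        converged = bool(res.converged) and (
            res_ml is None or bool(res_ml.converged)
        )

    k_params = model.k_fe + model.k_re2 + model.k_vc + 1  # + residual var
    if res_ml is not None:
        aic = float(-2.0 * res_ml.llf + 2.0 * k_params)
        bic = float(-2.0 * res_ml.llf + np.log(len(data)) * k_params)
    else:
        aic = bic = float("nan")

    cov = np.asarray(res.cov_params())[: model.k_fe, : model.k_fe]
    design_info = model.data.design_info

    # classify design columns as within-case (vary inside a case) or between
    exog = pd.DataFrame(model.exog, columns=design_info.column_names)
    exog[spec.case_column] = data[spec.case_column].values
    within_cols = [
        c for c in design_info.column_names
        if exog.groupby(spec.case_column)[c].nunique().max() > 1
    ]

    vcomp = {"case_intercept_var": float(res.cov_re.iloc[0, 0])}
    if vc_formula is not None:
        vcomp["roi_in_case_var"] = float(res.vcomp[0])
    vcomp["residual_var"] = float(res.scale)

    diagnostics = _residual_diagnostics(
        np.asarray(res.resid, dtype=float),
        np.asarray(res.fittedvalues, dtype=float),
    )
    spec_used = replace(spec, transformation=transformation)
    return ModelFit(
        spec=spec_used,
        params=res.fe_params,
        cov_fe=cov,
        design_info=design_info,
        aic=aic,
        bic=bic,
        reml=True,
        converged=converged,
        variance_components=vcomp,
        diagnostics=diagnostics,
        n_obs=len(data),
        n_cases=int(n_cases),
        data=data,
        within_columns=within_cols,
        result=res,
    )


def fixed_effect_test(fit: ModelFit, variable: str) -> dict:
    """Wald F test of all fixed-effect columns involving ``variable``,
    with between-within denominator degrees of freedom."""
    names = list(fit.design_info.column_names)
    idx = [i for i, n in enumerate(names) if variable in n]
    if not idx:
        raise ValueError(
            f"term {variable!r} not in the model (columns: {names})"
        )
    L = np.zeros((len(idx), len(names)))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    beta = np.asarray(fit.params, dtype=float)
    V = L @ fit.cov_fe @ L.T
    est = L @ beta
    stat = float(est @ np.linalg.solve(V, est))
    q = len(idx)
    within = any(names[i] in fit.within_columns for i in idx)
    df2 = fit.df_within if within else fit.df_between
    F = stat / q
    return {
        "variable": variable,
        "F": F,
        "df_num": q,
        "df_den": df2,
        "p": float(sps.f.sf(F, q, df2)),
        "df_method": "between_within",
    }


def _emm_rows(fit: ModelFit, grid: pd.DataFrame) -> np.ndarray:
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    return np.asarray(X)


def _levels(fit: ModelFit, column: str) -> list[str]:
    return list(pd.unique(fit.data[column]))


def posthoc_contrasts(fit: ModelFit, family: str) -> list[ContrastResult]:
    """Estimated-marginal-mean contrasts with Tukey (studentized-range)
    adjustment.

    ``family`` is ``"group_pairs"`` (all pairwise group differences,
    averaged over plaque status when present) or ``"plaque_within_group"``
    (the plaque minus no-plaque difference inside each group).
    """
    spec = fit.spec
    has_group = spec.group_column in fit.data.columns and (
        spec.group_column in spec.fixed
    )
    has_plaque = "plaque_status" in fit.data.columns and (
        "plaque_status" in spec.fixed
    )
    if family == "group_pairs" and not has_group:
        raise ValueError("model has no group term")
    if family == "plaque_within_group" and not has_plaque:
        raise ValueError("model has no plaque_status term")

    groups = _levels(fit, spec.group_column) if has_group else [None]
    plaques = _levels(fit, "plaque_status") if has_plaque else [None]
    # order plaque levels so the contrast reads plaque - no_plaque
    if has_plaque and "plaque" in plaques and "no_plaque" in plaques:
        plaques = ["plaque", "no_plaque"]

    def cell_row(g, p) -> np.ndarray:
        cells = {}
        if g is not None:
            cells[spec.group_column] = [g]
        if p is not None:
            cells["plaque_status"] = [p]
        if "age_years" in spec.fixed:
            cells["age_years"] = [float(fit.data["age_years"].mean())]
        return _emm_rows(fit, pd.DataFrame(cells))[0]

    contrasts: list[tuple[str, np.ndarray]] = []
    if family == "group_pairs":
        emm = {
            g: np.mean([cell_row(g, p) for p in plaques], axis=0)
            for g in groups
        }
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                contrasts.append((f"{a} - {b}", emm[a] - emm[b]))
        k_means = len(groups)
    else:
        for g in groups:
            lbl = "plaque - no_plaque" + (f" | {g}" if g is not None else "")
            contrasts.append(
                (lbl, cell_row(g, plaques[0]) - cell_row(g, plaques[1]))
            )
        k_means = len(groups) * len(plaques)
    k_means = max(k_means, 2)

    beta = np.asarray(fit.params, dtype=float)
    names = list(fit.design_info.column_names)
    results = []
    for label, L in contrasts:
        est = float(L @ beta)
        se = float(np.sqrt(L @ fit.cov_fe @ L))
        t = est / se if se > 0 else np.nan
        within = any(
            abs(L[i]) > 1e-12 and names[i] in fit.within_columns
            for i in range(len(names))
        )
        df = fit.df_within if within else fit.df_between
        p_un = float(2.0 * sps.t.sf(abs(t), df))
        p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0),
                                               k_means, df))
        results.append(
            ContrastResult(
                comparison=label,
                estimate=est,
                se=se,
                t=float(t),
                df=float(df),
                df_method="between_within",
                p_adjusted=min(max(p_adj, p_un), 1.0),
                p_unadjusted=p_un,
                adjustment=f"tukey(k={k_means})",
                transformation=fit.spec.transformation.label,
            )
        )
    return results


def default_candidates(
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> list[Transformation]:
    cands = [
        Transformation("identity"),
        Transformation("sqrt"),
        Transformation("log"),
        Transformation("arcsine_sqrt"),
    ]
    cands += [Transformation("tukey_ladder", lam=l) for l in lambda_grid]
    return cands


def select_transformation(
    measurements: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    candidates: Sequence[Transformation] | None = None,
) -> tuple[ModelFit, list[dict]]:
    """Pick the transformation under which the model meets its assumptions.

    The identity-scale model is fitted first and kept if its residuals
    pass both the normality and homoscedasticity checks.  Otherwise every
    candidate is fitted; among those passing, the one with the best
    Shapiro-Wilk statistic wins; if none passes, the best-normality
    candidate is returned.  The full trail of fits is returned alongside.
    """
    if candidates is None:
        candidates = default_candidates()
    trail: list[dict] = []

    def try_candidate(tr: Transformation):
        cspec = replace(spec, transformation=tr)
        entry = {"transformation": tr.label}
        try:
            fit = fit_lmem(measurements, cspec, compute_ic=False)
        except (ValueError, RuntimeError) as exc:
            entry.update(status="failed", reason=str(exc))
            trail.append(entry)
            return None
        d = fit.diagnostics
        entry.update(
            status="fitted",
            shapiro_w=d["shapiro_w"], shapiro_p=d["shapiro_p"],
            het_p=d["het_p"],
            passes=bool(d["shapiro_p"] > alpha and d["het_p"] > alpha),
            converged=fit.converged,
        )
        trail.append(entry)
        return fit

    def with_ic(fit: ModelFit) -> ModelFit:
        return fit_lmem(measurements,
                        replace(spec, transformation=fit.spec.transformation))

    ident = try_candidate(Transformation("identity"))
    if ident is not None and trail[-1]["passes"] and ident.converged:
        return with_ic(ident), trail

    fits: list[tuple[dict, ModelFit]] = []
    if ident is not None:
        fits.append((trail[0], ident))
    for tr in candidates:
        if tr.name == "identity":
            continue
        f = try_candidate(tr)
        if f is not None and f.converged:
            fits.append((trail[-1], f))
    if not fits:
        raise RuntimeError(
            "no candidate transformation produced a converged fit; "
            f"trail: {trail}"
        )
    passing = [(e, f) for e, f in fits if e.get("passes")]
    pool = passing if passing else fits
    best = max(pool, key=lambda ef: (ef[0]["shapiro_w"]
                                     if np.isfinite(ef[0]["shapiro_w"])
                                     else -np.inf))
    return with_ic(best[1]), trail


def case_level_correlations(
    measurements: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    group_column: str = "group",
    case_column: str = "case_id",
    min_cases: int = 3,
) -> list[CorrelationResult]:
    """Per-group Spearman correlations computed on one mean per case."""
    results = []
    for group, sub in measurements.groupby(group_column, sort=True):
        for var_x, var_y in pairs:
            means = (
                sub.groupby(case_column)[[var_x, var_y]].mean().dropna()
            )
            n = len(means)
            if n < min_cases:
                results.append(
                    CorrelationResult(
                        group=str(group), var_x=var_x, var_y=var_y,
                        rho=None, p=None, n_cases=n,
                        note=f"skipped: only {n} cases (< {min_cases})",
                    )
                )
                continue
            rho, p = sps.spearmanr(means[var_x], means[var_y])
            results.append(
                CorrelationResult(
                    group=str(group), var_x=var_x, var_y=var_y,
                    rho=float(rho), p=float(p), n_cases=n,
                )
            )
    return results


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def contrasts_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def simulate_measurement_table(
    group_sizes: Mapping[str, int],
    n_pairs_per_case: int = 4,
    case_sd: float = 1.0,
    roi_sd: float = 0.0,
    resid_sd: float = 1.0,
    group_effects: Mapping[str, float] | None = None,
    plaque_effect: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
    paired: bool = True,
) -> pd.DataFrame:
    """Fast tabular cohort simulator for calibration and power studies.

    Each case contributes ``n_pairs_per_case`` ROI pairs; with
    ``paired=True`` each pair yields a plaque and a no-plaque observation
    (``plaque_effect`` added to the former).  The outcome column is
    ``value``.
    """
    rng = np.random.default_rng(seed)
    group_effects = group_effects or {}
    rows = []
    case_idx = 0
    for group, n in group_sizes.items():
        for _ in range(n):
            case_idx += 1
            cid = f"C{case_idx:03d}"
            u_case = rng.normal(0.0, case_sd)
            mu = baseline + group_effects.get(group, 0.0) + u_case
            for p in range(n_pairs_per_case):
                u_roi = rng.normal(0.0, roi_sd) if roi_sd > 0 else 0.0
                statuses = ["plaque", "no_plaque"] if paired else ["random"]
                for status in statuses:
                    val = mu + u_roi + rng.normal(0.0, resid_sd)
                    if status == "plaque":
                        val += plaque_effect
                    rows.append(
                        {
                            "case_id": cid,
                            "group": group,
                            "roi_pair_id": f"{cid}_p{p:02d}",
                            "plaque_status": status,
                            "value": val,
                        }
                    )
    return pd.DataFrame(rows)
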