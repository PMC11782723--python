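"""Three-level mixed-effects group comparisons.

Observations (Level-1) are nested in children (Level-2) nested in
classrooms (Level-3).  Every model carries random intercepts for child
and classroom and is estimated by REML.  Between-group effects are
parameterized as a TD intercept with ASD and DD contrasts.  Fixed
effects are tested with Wald statistics t = B/SE; p-values use the
standard-normal reference (a documented choice — a Satterthwaite
approximation could be substituted).  Effect sizes follow the
d = 2·t/√df convention with df = n_obs − (number of fixed-effect
parameters).  Continuous predictors are mean-centered at the child
level before fitting.  Random-effect significance is assessed by
comparing REML deviances (−2·log-likelihood) of nested random
structures against χ²(1); the usual boundary caveat (this test is
conservative for a variance tested at zero) applies.

The REML fitting engine is :class:`statsmodels` MixedLM (classroom as
the grouping factor, child as a variance component); everything layered
on top — contrasts, Wald summaries, ICCs, effect sizes, deviance tests —
is assembled here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "ModelResult",
    "center_within_child",
    "fit_three_level",
    "cohens_d_from_t",
    "icc",
    "lrt_random_effect",
    "format_fixed_effects",
]

RANDOM_STRUCTURES = ("both", "child_only", "classroom_only")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, group contrasts, optional centered covariate."""

    outcome: str
    include_group: bool = True  # ASD & DD contrasts vs the TD reference
    covariate: str | None = None  # continuous predictor, centered within child
    alpha: float = 0.01
    reference_group: str = "TD"


@dataclass
class ModelResult:
    """Fixed effects, variance components and fit diagnostics."""

    spec: ModelSpec
    fixed: pd.DataFrame  # index: term; columns: B, SE, ci_low, ci_high, t, p, d
    var_child: float
    var_classroom: float
    var_residual: float
    icc_child: float
    icc_classroom: float
    deviance: float  # −2 · (restricted) log-likelihood
    n_obs: int
    n_children: int
    n_classrooms: int
    converged: bool
    boundary: bool  # a variance component estimated at (or near) zero
    random: str = "both"

    def term(self, name: str) -> pd.Series:
        return self.fixed.loc[name]

    def significant(self, name: str) -> bool:
        return bool(self.fixed.loc[name, "p"] < self.spec.alpha)

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "fixed": self.fixed.reset_index().to_dict("records"),
            "var_child": self.var_child,
            "var_classroom": self.var_classroom,
            "var_residual": self.var_residual,
            "icc_child": self.icc_child,
            "icc_classroom": self.icc_classroom,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
            "n_children": self.n_children,
            "n_classrooms": self.n_classrooms,
            "converged": self.converged,
            "boundary": self.boundary,
            "random": self.random,
        }


def center_within_child(values, child_ids) -> np.ndarray:
    """Subtract each child's own mean; per-child centered values sum to 0."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(child_ids)).astype(str)
    return (s - s.groupby(g.values).transform("mean")).to_numpy()


def cohens_d_from_t(t: float, df: float) -> float:
    """d = 2·t/√df (the EMA-style conversion for multilevel Wald t)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * t / np.sqrt(df)


def icc(var_child: float, var_classroom: float, var_residual: float) -> tuple[float, float]:
    """Share of total variance at the child and classroom levels."""
    comps = (var_child, var_classroom, var_residual)
    if any(v < 0 for v in comps):
        raise ValueError("variance components must be non-negative")
    total = sum(comps)
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_child / total, var_classroom / total


def lrt_random_effect(deviance_full: float, deviance_reduced: float) -> tuple[float, float]:
    """Deviance difference test for one random effect, χ²(1) reference."""
    chi2 = deviance_reduced - deviance_full
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(chi2), p


def _term_labels(spec: ModelSpec, null_model: bool) -> dict[str, str]:
    ref = spec.reference_group
    labels = {"Intercept": f"{ref} (intercept)" if not null_model else "(intercept)"}
    patt = f"C(group, Treatment('{ref}'))"
    for g in ("ASD", "DD"):
        labels[f"{patt}[T.{g}]"] = g
    if spec.covariate:
        labels[f"{spec.covariate}_c"] = spec.covariate
    return labels


def fit_three_level(
    spec: ModelSpec,
    table: pd.DataFrame,
    random: str = "both",
    child_col: str = "child_id",
    class_col: str = "classroom_id",
) -> ModelResult:
    """Fit a random-intercept model for one outcome by REML.

    Parameters
    ----------
    spec
        Outcome and fixed-effect structure.  With ``include_group`` the
        fixed part is a TD intercept plus ASD and DD contrasts; a
        covariate, if named, is mean-centered within child before entry.
    table
        Child × observation analysis table (one row per observation)
        with ``child_id``, ``classroom_id``, ``group`` and outcome
        columns.  Rows missing the outcome (or covariate) are dropped.
    random
        ``"both"`` (child + classroom intercepts; the default),
        ``"child_only"`` or ``"classroom_only"`` — the reduced
        structures used by the deviance tests.

    Notes
    -----
    Variance components estimated at zero are reported at the boundary
    with ``boundary=True`` rather than raised as errors.
    """
    if random not in RANDOM_STRUCTURES:
        raise ValueError(f"random must be one of {RANDOM_STRUCTURES}")
    df = table.copy()
    needed = [spec.outcome] + ([spec.covariate] if spec.covariate else [])
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if spec.covariate:
        df[f"{spec.covariate}_c"] = center_within_child(df[spec.covariate], df[child_col])

    n_children = df[child_col].nunique()
    n_classrooms = df[class_col].nunique()
    if n_classrooms < 2 and random != "child_only":
        raise ValueError("need >= 2 classrooms for a classroom random intercept")
    if n_children < 2:
        raise ValueError("need >= 2 children")
    if df[spec.outcome].nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} is degenerate")

    terms = []
    if spec.include_group:
        terms.append(f"C(group, Treatment('{spec.reference_group}'))")
    if spec.covariate:
        terms.append(f"{spec.covariate}_c")
    formula = f"{spec.outcome} ~ " + (" + ".join(terms) if terms else "1")

    if random == "both":
        md = smf.mixedlm(
            formula, df, groups=class_col, re_formula="1",
            vc_formula={"child": f"0 + C({child_col})"},
        )
    elif random == "classroom_only":
        md = smf.mixedlm(formula, df, groups=class_col, re_formula="1")
    else:  # child_only
        md = smf.mixedlm(formula, df, groups=child_col, re_formula="1")

    # REML surfaces with near-boundary variance components can defeat a
    # single optimizer; fit with several and keep the best restricted
    # likelihood.
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for methods in (["lbfgs"], ["powell"], ["cg"]):
            try:
                cand = md.fit(reml=True, method=methods)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf + 1e-10):
                res = cand
    if res is None:
        raise np.linalg.LinAlgError(
            f"REML fit failed for {spec.outcome!r} (random={random})"
        )

    var_classroom = var_child = 0.0
    if random == "both":
        var_classroom = float(res.cov_re.iloc[0, 0])
        var_child = float(res.vcomp[0])
    elif random == "classroom_only":
        var_classroom = float(res.cov_re.iloc[0, 0])
    else:
        var_child = float(res.cov_re.iloc[0, 0])
    var_residual = float(res.scale)
    icc_child, icc_classroom = icc(max(var_child, 0.0), max(var_classroom, 0.0), var_residual)

    fe = res.fe_params
    se = res.bse_fe
    n_obs = len(df)
    df_d = n_obs - len(fe)
    labels = _term_labels(spec, null_model=not terms)
    rows = {}
    for name in fe.index:
        b, s = float(fe[name]), float(se[name])
        t = b / s if s > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(t))) if np.isfinite(t) else np.nan
        label = labels.get(name, name)
        d = cohens_d_from_t(t, df_d) if (label != labels["Intercept"] and np.isfinite(t)) else np.nan
        rows[label] = {
            "B": b, "SE": s,
            "ci_low": b - 1.96 * s, "ci_high": b + 1.96 * s,
            "t": t, "p": p, "d": d,
        }
    fixed = pd.DataFrame.from_dict(rows, orient="index")
    fixed.index.name = "term"

    return ModelResult(
        spec=spec,
        fixed=fixed,
        var_child=var_child,
        var_classroom=var_classroom,
        var_residual=var_residual,
        icc_child=icc_child,
        icc_classroom=icc_classroom,
        deviance=float(-2.0 * res.llf),
        n_obs=n_obs,
        n_children=n_children,
        n_classrooms=n_classrooms,
        converged=bool(res.converged),
        boundary=bool(min(var_child, var_classroom) < 1e-8 and random == "both"),
        random=random,
    )


def format_fixed_effects(result: ModelResult, digits: int = 5) -> str:
    """Text table in the conventional 'Group B SE 95% CI t p d' layout."""
    lines = [f"Outcome: {result.spec.outcome}   (n_obs={result.n_obs}, "
             f"children={result.n_children}, classrooms={result.n_classrooms})",
             f"{'Group':<18}{'B':>12}{'SE':>12}{'95% CI':>26}{'t':>8}{'p':>9}{'d':>8}"]
    for term, r in result.fixed.iterrows():
        ci = f"{r.ci_low:.{digits}g} – {r.ci_high:.{digits}g}"
        d = f"{r.d:.2f}" if np.isfinite(r.d) else ""
        p = f"{r.p:.3f}" if r.p >= 0.001 else "<0.001"
        lines.append(
            f"{term:<18}{r.B:>12.{digits}g}{r.SE:>12.{digits}g}{ci:>26}{r.t:>8.2f}{p:>9}{d:>8}"
        )
    lines.append(
        f"Variance: child={result.var_child:.4g}  classroom={result.var_classroom:.4g}  "
        f"residual={result.var_residual:.4g}   ICC child={result.icc_child:.3f}  "
        f"classroom={result.icc_classroom:.3f}"
    )
    return "\n".join(lines)
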