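import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadtrack.models import (
    ModelSpec,
    center_within_child,
    cohens_d_from_t,
    fit_three_level,
    icc,
    lrt_random_effect,
)
from dyadtrack.simulate import simulate_analysis_table


def test_center_within_child_examples():
    out = center_within_child([2.0, 4.0], ["a", "a"])
    np.testing.assert_allclose(out, [-1.0, 1.0])
    np.testing.assert_allclose(center_within_child([7.0], ["solo"]), [0.0])


def test_center_within_child_sums_to_zero(rng):
    kids = np.repeat([f"k{i}" for i in range(3)], [4, 2, 5])
    vals = rng.normal(size=len(kids))
    centered = pd.Series(center_within_child(vals, kids)).groupby(kids).sum()
    np.testing.assert_allclose(centered, 0.0, atol=1e-12)


def test_cohens_d_examples():
    assert cohens_d_from_t(0.0, 50) == 0.0
    assert cohens_d_from_t(5.0, 100) == pytest.approx(1.0)
    assert np.sign(cohens_d_from_t(-2.2, 80)) == -1.0


def test_icc_examples():
    assert icc(1.0, 1.0, 2.0) == (pytest.approx(0.25), pytest.approx(0.25))
    assert icc(0.0, 1.0, 1.0)[0] == 0.0
    with pytest.raises(ValueError):
        icc(0.0, 0.0, 0.0)


def test_lrt_examples():
    chi2, p = lrt_random_effect(100.0, 100.0)
    assert chi2 == 0.0 and p == 1.0
    chi2, p = lrt_random_effect(100.0, 103.84)
    assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)
    assert p == pytest.approx(0.05, abs=1e-3)


def _table(seed=5, **kw):
    defaults = dict(
        effects={"intercept": 1.0, "ASD": 0.5, "DD": 0.2},
        sd_child=0.4, sd_classroom=0.3, sd_residual=0.6, seed=seed,
    )
    defaults.update(kw)
    return simulate_analysis_table(**defaults)


def test_balanced_single_classroom_matches_gls_closed_form(rng):
    """With a balanced design (equal observations per child) and only a
    child random intercept, GLS fixed effects reduce to plain group means."""
    rows = []
    means = {"TD": 1.0, "ASD": 1.6, "DD": 1.2}
    for g in ("TD", "ASD", "DD"):
        for i in range(6):
            u = rng.normal(0, 0.5)
            for o in range(3):
                rows.append({
                    "child_id": f"{g}{i}", "classroom_id": "C1", "group": g,
                    "y": means[g] + u + rng.normal(0, 0.3),
                })
    df = pd.DataFrame(rows)
    res = fit_three_level(ModelSpec("y"), df, random="child_only")
    grp = df.groupby("group")["y"].mean()
    assert res.fixed.loc["TD (intercept)", "B"] == pytest.approx(grp["TD"], abs=1e-6)
    assert res.fixed.loc["ASD", "B"] == pytest.approx(grp["ASD"] - grp["TD"], abs=1e-6)
    assert res.fixed.loc["DD", "B"] == pytest.approx(grp["DD"] - grp["TD"], abs=1e-6)


def test_three_level_fit_matches_lme4(tmp_path):
    """Independent oracle: lme4's REML fit of the identical model."""
    df = _table(seed=11)
    csv = tmp_path / "tb.csv"
    df.to_csv(csv, index=False)
    out = tmp_path / "ref.json"
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        d <- read.csv("{csv}")
        d$group <- relevel(factor(d$group), ref="TD")
        m <- lmer(y ~ group + (1|classroom_id) + (1|child_id), data=d, REML=TRUE)
        co <- summary(m)$coefficients
        vc <- as.data.frame(VarCorr(m))
        write_json(list(b=as.list(co[,1]), se=as.list(co[,2]),
                        vc=as.list(setNames(vc$vcov, vc$grp)),
                        dev=-2*as.numeric(logLik(m))),
                   "{out}", digits=12, auto_unbox=TRUE)
    """)
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    ref = json.loads(out.read_text())
    res = fit_three_level(ModelSpec("y"), df)
    ours = res.fixed["B"]
    assert ours["TD (intercept)"] == pytest.approx(ref["b"]["(Intercept)"], rel=1e-4)
    assert ours["ASD"] == pytest.approx(ref["b"]["groupASD"], rel=1e-4)
    assert ours["DD"] == pytest.approx(ref["b"]["groupDD"], rel=1e-4)
    assert res.fixed.loc["ASD", "SE"] == pytest.approx(ref["se"]["groupASD"], rel=1e-3)
    assert res.var_child == pytest.approx(ref["vc"]["child_id"], rel=1e-3)
    assert res.var_classroom == pytest.approx(ref["vc"]["classroom_id"], rel=1e-3)
    assert res.var_residual == pytest.approx(ref["vc"]["Residual"], rel=1e-3)
    assert res.deviance == pytest.approx(ref["dev"], abs=1e-3)


def test_fixed_effect_recovery_with_known_generator():
    df = _table(seed=21, n_classrooms=12, children_per_class={"ASD": 5, "DD": 5, "TD": 6})
    res = fit_three_level(ModelSpec("y"), df)
    for term, truth in (("ASD", 0.5), ("DD", 0.2), ("TD (intercept)", 1.0)):
        r = res.fixed.loc[term]
        assert abs(r.B - truth) < 3 * r.SE


def test_ci_is_b_plus_minus_196_se():
    res = fit_three_level(ModelSpec("y"), _table())
    for _, r in res.fixed.iterrows():
        assert r.ci_low == pytest.approx(r.B - 1.96 * r.SE)
        assert r.ci_high == pytest.approx(r.B + 1.96 * r.SE)


def test_icc_recovery_from_generative_variances():
    # generative: var_child=0.25, var_classroom=1.0, var_resid=0.75 → ICCs 0.125, 0.5
    df = _table(seed=33, n_classrooms=60, children_per_class={"ASD": 4, "DD": 4, "TD": 4},
                sd_child=0.5, sd_classroom=1.0, sd_residual=np.sqrt(0.75))
    res = fit_three_level(ModelSpec("y", include_group=False), df)
    assert res.icc_classroom == pytest.approx(0.5, abs=0.15)
    assert res.icc_child == pytest.approx(0.125, abs=0.08)


def test_strong_classroom_effect_detected_by_deviance_test():
    df = _table(seed=44, sd_classroom=1.5)
    full = fit_three_level(ModelSpec("y"), df)
    reduced = fit_three_level(ModelSpec("y"), df, random="child_only")
    chi2, p = lrt_random_effect(full.deviance, reduced.deviance)
    assert chi2 > 0 and p < 0.01


def test_null_classroom_effect_small_deviance_change():
    df = _table(seed=45, sd_classroom=0.0)
    full = fit_three_level(ModelSpec("y"), df)
    assert full.var_classroom < 0.1 * full.var_residual
    reduced = fit_three_level(ModelSpec("y"), df, random="child_only")
    chi2, _ = lrt_random_effect(full.deviance, reduced.deviance)
    assert chi2 < 3.84


def test_covariate_centered_before_fit(rng):
    df = _table(seed=55)
    # covariate = child-level constant + within-child noise; only the
    # within-child part should drive the slope after centering
    child_means = {c: rng.normal(0, 2) for c in df.child_id.unique()}
    df["cov"] = df.child_id.map(child_means) + rng.normal(0, 1, len(df))
    df["y"] = df["y"] + 0.3 * (df["cov"] - df.child_id.map(child_means))
    res = fit_three_level(ModelSpec("y", include_group=False, covariate="cov"), df)
    r = res.fixed.loc["cov"]
    assert abs(r.B - 0.3) < 3 * r.SE


def test_degenerate_inputs_raise():
    df = _table()
    with pytest.raises(ValueError):
        fit_three_level(ModelSpec("y"), df.assign(y=1.0))
    with pytest.raises(ValueError):
        fit_three_level(ModelSpec("y"), df[df.classroom_id == "C1"])
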