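"""Design matrices, OLS fits, interaction pruning, and genome-wide flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from facesym import (
    GenotypeMatrix,
    build_design,
    genomewide_flag,
    ols_fit,
    prune_interactions,
)


def _cov(n, rng, cohorts=("RS1", "RS2")):
    return pd.DataFrame(
        {
            "age": rng.uniform(45, 92, n),
            "sex": rng.choice(["female", "male"], n),
            "cohort": rng.choice(cohorts, n),
        },
        index=pd.Index([f"i{k}" for k in range(n)], name="individual_id"),
    )


def _hl(n, rng):
    return pd.Series(
        rng.beta(5, 3, n), index=[f"i{k}" for k in range(n)], name="hl"
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_reference_coded_genotype_indicators(rng):
    cov = _cov(3, rng)
    g = GenotypeMatrix(
        individual_ids=["i0", "i1", "i2"],
        locus_ids=["rsA"],
        calls=np.array([[0.0], [1.0], [2.0]]),
    )
    X = build_design(cov, _hl(3, rng), g)
    np.testing.assert_array_equal(X["rsA_1"], [0.0, 1.0, 0.0])
    np.testing.assert_array_equal(X["rsA_2"], [0.0, 0.0, 1.0])


def test_single_level_factors_dropped(rng):
    cov = _cov(30, rng)
    cov["sex"] = "female"
    with pytest.warns(UserWarning, match="sex has a single level"):
        X = build_design(cov, _hl(30, rng))
    assert "sex_male" not in X.columns

    g = GenotypeMatrix(
        individual_ids=list(cov.index),
        locus_ids=["rsB"],
        calls=np.zeros((30, 1)),
    )
    cov2 = _cov(30, rng)
    with pytest.warns(UserWarning, match="single observed genotype class"):
        X2 = build_design(cov2, _hl(30, rng), g)
    assert not any(c.startswith("rsB") for c in X2.columns)


def test_design_column_count_without_interactions(rng):
    n = 40
    cov = _cov(n, rng)
    calls = rng.integers(0, 3, (n, 3)).astype(float)
    # ensure all three classes observed per locus
    calls[:3, :] = [[0.0] * 3, [1.0] * 3, [2.0] * 3]
    g = GenotypeMatrix(
        individual_ids=list(cov.index),
        locus_ids=["s1", "s2", "s3"],
        calls=calls,
    )
    X = build_design(cov, _hl(n, rng), g)
    # const + sex + age + hl + cohort + 2 per SNP
    assert X.shape[1] == 5 + 2 * 3


def test_missing_fields_dropped_with_warning(rng):
    n = 20
    cov = _cov(n, rng)
    hl = _hl(n, rng)
    hl.iloc[4] = np.nan
    g = GenotypeMatrix(
        individual_ids=list(cov.index),
        locus_ids=["s1"],
        calls=np.array([[0.0], [1.0], [2.0]] * 6 + [[np.nan], [1.0]]),
    )
    with pytest.warns(UserWarning, match="dropped 2 individual"):
        X = build_design(cov, hl, g)
    assert len(X) == n - 2


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def test_ols_exact_line():
    X = pd.DataFrame({"const": np.ones(4), "x": [0.0, 1.0, 2.0, 3.0]})
    fit = ols_fit(X, 1.0 + 2.0 * X["x"].to_numpy())
    np.testing.assert_allclose(fit.estimates, [1.0, 2.0], atol=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_normal_equations_hand_computation():
    """x = [0,1,2], y = [1,2,4]: slope 3/2, intercept 5/6."""
    X = pd.DataFrame({"const": np.ones(3), "x": [0.0, 1.0, 2.0]})
    fit = ols_fit(X, np.array([1.0, 2.0, 4.0]))
    assert fit.coef("x") == pytest.approx(1.5, abs=1e-12)
    assert fit.coef("const") == pytest.approx(5.0 / 6.0, abs=1e-12)
    np.testing.assert_allclose(
        fit.t_values, fit.estimates / fit.standard_errors, atol=1e-10
    )


def test_ols_row_permutation_invariance(rng):
    n = 50
    X = pd.DataFrame(
        {"const": np.ones(n), "x": rng.normal(size=n), "z": rng.normal(size=n)},
        index=[f"i{k}" for k in range(n)],
    )
    y = pd.Series(rng.normal(size=n), index=X.index)
    fit1 = ols_fit(X, y)
    perm = rng.permutation(n)
    fit2 = ols_fit(X.iloc[perm], y.iloc[perm])
    np.testing.assert_allclose(fit2.estimates, fit1.estimates, atol=1e-12)
    np.testing.assert_allclose(fit2.p_values, fit1.p_values, atol=1e-12)


def test_ols_agrees_with_pseudoinverse_oracle(rng):
    """Estimates, SEs and p-values match a from-scratch pinv computation
    on 100 random designs."""
    for _ in range(100):
        n = int(rng.integers(12, 40))
        p = int(rng.integers(2, 6))
        Xv = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        X = pd.DataFrame(Xv, columns=[f"c{j}" for j in range(p)])
        fit = ols_fit(X, y)
        beta = np.linalg.pinv(Xv) @ y
        resid = y - Xv @ beta
        df = n - p
        s2 = resid @ resid / df
        cov = s2 * np.linalg.inv(Xv.T @ Xv)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        np.testing.assert_allclose(fit.estimates, beta, atol=1e-8)
        np.testing.assert_allclose(fit.standard_errors, se, atol=1e-8)
        np.testing.assert_allclose(fit.p_values, pvals, atol=1e-8)


def test_ols_rank_deficiency_names_terms(rng):
    n = 30
    x = rng.normal(size=n)
    X = pd.DataFrame({"const": np.ones(n), "x": x, "x2": 2 * x})
    with pytest.raises(ValueError, match="rank deficient"):
        ols_fit(X, rng.normal(size=n))


def test_ols_rejects_nonfinite_response(rng):
    X = pd.DataFrame({"const": np.ones(5), "x": np.arange(5.0)})
    y = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    with pytest.raises(ValueError, match="non-finite response"):
        ols_fit(X, y)


# ---------------------------------------------------------------------------
# interaction pruning
# ---------------------------------------------------------------------------

def test_alpha_one_retains_all_interactions(rng):
    n = 200
    cov = _cov(n, rng)
    hl = _hl(n, rng)
    y = pd.Series(rng.normal(size=n), index=cov.index)
    fit, removed = prune_interactions(cov, hl, response=y, alpha=1.0)
    assert removed == []
    assert {"sex_male:age", "sex_male:hl", "age:hl"} <= set(fit.term_names)


def test_null_interactions_removed_at_oracle_rate(rng):
    """On null data the stepwise procedure retains >=1 interaction at the
    same familywise rate as an independently coded implementation."""

    def oracle_stepwise(cov, hl, y, alpha=0.05):
        # independent route: numpy lstsq + t distribution, same rule
        base = {
            "const": np.ones(len(cov)),
            "sex_male": (cov["sex"] == "male").to_numpy(float),
            "age": cov["age"].to_numpy(),
            "hl": hl.to_numpy(),
            "cohort_RS2": (cov["cohort"] == "RS2").to_numpy(float),
        }
        inter = {
            "sex_male:age": base["sex_male"] * base["age"],
            "sex_male:hl": base["sex_male"] * base["hl"],
            "age:hl": base["age"] * base["hl"],
        }
        current = dict(inter)
        while current:
            cols = list(base.values()) + list(current.values())
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = len(y) - X.shape[1]
            s2 = resid @ resid / df
            se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
            pv = 2 * stats.t.sf(np.abs(beta / se), df)
            names = list(base) + list(current)
            cand = {nm: pv[names.index(nm)] for nm in current}
            worst = max(cand, key=cand.get)
            if cand[worst] <= alpha:
                break
            del current[worst]
        return len(current) > 0

    reps = 300
    ours = 0
    theirs = 0
    for r in range(reps):
        rng_r = np.random.default_rng(1000 + r)
        n = 150
        cov = _cov(n, rng_r)
        hl = _hl(n, rng_r)
        y = rng_r.normal(size=n)
        fit, removed = prune_interactions(
            cov, hl, response=pd.Series(y, index=cov.index), alpha=0.05
        )
        ours += len(removed) < 3
        rng_o = np.random.default_rng(50_000 + r)
        cov_o = _cov(n, rng_o)
        hl_o = _hl(n, rng_o)
        theirs += oracle_stepwise(cov_o, hl_o, rng_o.normal(size=n))
    p1, p2 = ours / reps, theirs / reps
    pooled_se = np.sqrt(p1 * (1 - p1) / reps + p2 * (1 - p2) / reps)
    assert abs(p1 - p2) <= 3 * pooled_se + 1e-9


def test_strong_interaction_retained(rng):
    """A planted sex x HL interaction ~10x its SE survives pruning."""
    kept = 0
    reps = 50
    for r in range(reps):
        rng_r = np.random.default_rng(200 + r)
        n = 400
        cov = _cov(n, rng_r)
        hl = _hl(n, rng_r)
        male = (cov["sex"] == "male").to_numpy(float)
        noise = rng_r.normal(0, 1.0, n)
        # the interaction coefficient's SE is ~0.6 here (collinearity with the
        # main effects included); 6.0 is ~10x that SE
        y = 1.0 + 6.0 * male * hl.to_numpy() + noise
        fit, removed = prune_interactions(
            cov, hl, response=pd.Series(y, index=cov.index), alpha=0.05
        )
        kept += "sex_male:hl" in fit.term_names
    assert kept >= int(0.96 * reps)


# ---------------------------------------------------------------------------
# genome-wide flag
# ---------------------------------------------------------------------------

def test_genomewide_flag_threshold():
    from facesym.association import ModelFit

    fit = ModelFit(
        term_names=["a", "b", "c"],
        estimates=np.ones(3),
        standard_errors=np.ones(3),
        t_values=np.ones(3),
        p_values=np.array([1e-9, 1e-7, 0.5]),
        n=100,
        residual_df=97,
        r_squared=0.1,
    )
    flags = genomewide_flag(fit)
    assert flags == {"a": True, "b": False, "c": False}
    flags5 = genomewide_flag(fit, threshold=1e-6)
    assert flags5["b"] is True
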