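"""Association models: OLS regressions and an ANOVA-style regression tree.

Two complementary analyses relate asymmetry scores to genotype data:

* a general linear model regressing FA (or TA) on sex, age, HL, cohort, and a
  small set of focal SNPs with reference-coded genotype indicators
  (``1 vs 0`` and ``2 vs 0``), with optional pairwise interactions among
  sex, age and HL that are pruned stepwise (largest non-significant p first);
* a CART regression tree over many SNPs: recursive binary partitioning of the
  response, where each split sends a subset of the genotype levels {0, 1, 2}
  left and is accepted only if the within-node sum-of-squares reduction is at
  least ``cp`` times the root sum of squares (ANOVA splitting rule).

Per-term p-values are reported unadjusted; a separate genome-wide flag marks
terms passing a multiplicity-guarding threshold (default P <= 1e-8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import GenotypeMatrix
from .heterozygosity import HLScores

__all__ = [
    "ModelFit",
    "TreeNode",
    "RegressionTree",
    "AnovaTreeRegressor",
    "build_design",
    "ols_fit",
    "prune_interactions",
    "anova_tree",
    "genomewide_flag",
]

#: Candidate pairwise interactions among the demographic/diversity terms.
INTERACTION_CANDIDATES = (("sex", "age"), ("sex", "hl"), ("age", "hl"))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _as_hl_series(hl) -> pd.Series | None:
    if hl is None:
        return None
    if isinstance(hl, HLScores):
        return hl.to_series()
    if isinstance(hl, pd.Series):
        return hl.astype(float)
    raise TypeError("hl must be HLScores, a pandas Series, or None")


def build_design(
    covariates: pd.DataFrame,
    hl=None,
    genotypes: GenotypeMatrix | pd.DataFrame | None = None,
    snp_subset=None,
    interactions=(),
) -> pd.DataFrame:
    """Design matrix with treatment coding, indexed by individual id.

    Columns: intercept; ``sex_male`` (female reference); ``age``; ``hl``;
    one indicator per non-reference cohort label; per SNP two indicators
    (genotype 1 vs 0 and 2 vs 0, reference being the lowest observed class);
    plus requested pairwise interaction columns among sex, age and HL.
    Individuals with any missing required field are dropped (count logged via
    a warning).  A SNP with a single observed genotype class contributes no
    columns (warning), as does a single-level sex or cohort factor.
    """
    df = covariates[["age", "sex", "cohort"]].copy()
    hl_series = _as_hl_series(hl)
    if hl_series is not None:
        df["hl"] = hl_series.reindex(df.index)
    gframe = None
    if genotypes is not None:
        gframe = (
            genotypes.to_frame()
            if isinstance(genotypes, GenotypeMatrix)
            else genotypes.astype(float)
        )
        if snp_subset is not None:
            gframe = gframe[list(snp_subset)]
        gframe = gframe.reindex(df.index)
        for snp in gframe.columns:
            df[f"__snp__{snp}"] = gframe[snp]

    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} individual(s) with missing model fields",
            stacklevel=2,
        )
    if df.empty:
        raise ValueError("no complete-case individuals left for the design matrix")

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0

    if df["sex"].nunique() > 1:
        X["sex_male"] = (df["sex"] == "male").astype(float)
    else:
        warnings.warn("sex has a single level; dropping the sex term", stacklevel=2)
    X["age"] = df["age"].astype(float)
    if hl_series is not None:
        X["hl"] = df["hl"].astype(float)

    cohort_levels = sorted(df["cohort"].unique())
    if len(cohort_levels) > 1:
        for level in cohort_levels[1:]:
            X[f"cohort_{level}"] = (df["cohort"] == level).astype(float)
    elif "cohort" in covariates.columns and len(cohort_levels) == 1:
        warnings.warn("cohort has a single level; dropping the cohort term", stacklevel=2)

    if gframe is not None:
        for snp in gframe.columns:
            g = df[f"__snp__{snp}"]
            observed = sorted(int(v) for v in g.unique())
            if len(observed) < 2:
                warnings.warn(
                    f"SNP {snp!r} has a single observed genotype class; "
                    "dropping its indicators",
                    stacklevel=2,
                )
                continue
            ref = 0 if 0 in observed else observed[0]
            if ref != 0:
                warnings.warn(
                    f"SNP {snp!r}: genotype 0 unobserved; using {ref} as reference",
                    stacklevel=2,
                )
            for level in observed:
                if level == ref:
                    continue
                X[f"{snp}_{level}"] = (g == level).astype(float)

    term_map = {"sex": "sex_male", "age": "age", "hl": "hl"}
    for pair in interactions:
        a, b = pair
        ca, cb = term_map[a], term_map[b]
        if ca not in X.columns or cb not in X.columns:
            warnings.warn(
                f"interaction {a}:{b} skipped (component term missing)", stacklevel=2
            )
            continue
        X[f"{ca}:{cb}"] = X[ca] * X[cb]
    return X


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Fitted linear-model artifact (coefficients, SEs, t and p values)."""

    term_names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    n: int
    residual_df: int
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "std_error": self.standard_errors,
                "t_value": self.t_values,
                "p_value": self.p_values,
            },
            index=pd.Index(self.term_names, name="term"),
        )

    def p(self, term: str) -> float:
        return float(self.p_values[self.term_names.index(term)])

    def coef(self, term: str) -> float:
        return float(self.estimates[self.term_names.index(term)])


def ols_fit(design: pd.DataFrame, response) -> ModelFit:
    """Ordinary least squares with residual-t two-sided p-values.

    The design must be full column rank; a rank deficiency raises an error
    naming the collinear terms (identified by pivoted QR).
    """
    X = design
    if isinstance(response, pd.Series):
        y = response.reindex(X.index).to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        if y.shape[0] != len(X):
            raise ValueError("response length does not match design rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than terms ({p})")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        _, _, piv = sla.qr(Xv, mode="economic", pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    res = sm.OLS(y, Xv).fit()
    return ModelFit(
        term_names=list(X.columns),
        estimates=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        t_values=np.asarray(res.tvalues, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        n=n,
        residual_df=int(res.df_resid),
        r_squared=float(res.rsquared),
    )


def prune_interactions(
    covariates: pd.DataFrame,
    hl,
    genotypes=None,
    response=None,
    snp_subset=None,
    alpha: float = 0.05,
    candidates=INTERACTION_CANDIDATES,
) -> tuple[ModelFit, list[tuple[str, float]]]:
    """Stepwise backward pruning of the sex/age/HL pairwise interactions.

    Starting from the full model with all candidate interactions, the
    interaction with the largest p-value above ``alpha`` is removed and the
    model refitted, until every remaining candidate is significant or none
    remain.  Base terms are always retained.  Returns the final fit and the
    removal log (term, p at removal).
    """
    if response is None:
        raise ValueError("a response vector is required")
    current = list(candidates)
    removed: list[tuple[str, float]] = []
    term_map = {"sex": "sex_male", "age": "age", "hl": "hl"}
    while True:
        X = build_design(
            covariates, hl, genotypes, snp_subset=snp_subset, interactions=current
        )
        fit = ols_fit(X, response)
        present = [
            (pair, f"{term_map[pair[0]]}:{term_map[pair[1]]}")
            for pair in current
            if f"{term_map[pair[0]]}:{term_map[pair[1]]}" in fit.term_names
        ]
        if not present:
            return fit, removed
        worst_pair, worst_term = max(present, key=lambda it: fit.p(it[1]))
        worst_p = fit.p(worst_term)
        if worst_p <= alpha:
            return fit, removed
        current.remove(worst_pair)
        removed.append((worst_term, worst_p))


def genomewide_flag(fit: ModelFit, threshold: float = 1e-8) -> dict[str, bool]:
    """Flag terms whose p-value passes the genome-wide threshold."""
    return {
        term: bool(p <= threshold)
        for term, p in zip(fit.term_names, fit.p_values)
    }


# ---------------------------------------------------------------------------
# ANOVA regression tree
# ---------------------------------------------------------------------------

def _sse(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    return float(((y - y.mean()) ** 2).sum())


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    mean_response: float
    ss: float
    split_locus: str | None = None
    left_levels: tuple[int, ...] | None = None  # genotype classes sent left
    improvement: float = 0.0
    left: int | None = None
    right: int | None = None
    n_missing_routed: int = 0
    majority_left: bool = True

    @property
    def is_leaf(self) -> bool:
        return self.split_locus is None


@dataclass
class RegressionTree:
    """CART tree over categorical genotype predictors (ANOVA splitting)."""

    nodes: dict[int, TreeNode]
    locus_ids: list[str]
    cp: float
    minsplit: int
    minbucket: int
    max_depth: int
    ss_root: float
    n: int

    @property
    def n_splits(self) -> int:
        return sum(1 for nd in self.nodes.values() if not nd.is_leaf)

    def predict(self, X) -> np.ndarray:
        Xv = _tree_matrix(X, self.locus_ids)
        out = np.empty(Xv.shape[0])
        for i in range(Xv.shape[0]):
            node = self.nodes[0]
            while not node.is_leaf:
                j = self.locus_ids.index(node.split_locus)
                g = Xv[i, j]
                if np.isnan(g):
                    go_left = node.majority_left
                else:
                    go_left = int(g) in node.left_levels
                node = self.nodes[node.left if go_left else node.right]
            out[i] = node.mean_response
        return out

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(nid: int, indent: int) -> None:
            nd = self.nodes[nid]
            pad = "  " * indent
            if nd.is_leaf:
                lines.append(
                    f"{pad}leaf: n={nd.n} mean={nd.mean_response:.6g} ss={nd.ss:.6g}"
                )
            else:
                levels = ",".join(str(v) for v in nd.left_levels)
                lines.append(
                    f"{pad}node: n={nd.n} mean={nd.mean_response:.6g} "
                    f"split={nd.split_locus} left_levels={{{levels}}} "
                    f"improvement={nd.improvement:.6g}"
                )
                walk(nd.left, indent + 1)
                walk(nd.right, indent + 1)

        walk(0, 0)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cp": self.cp,
            "minsplit": self.minsplit,
            "minbucket": self.minbucket,
            "max_depth": self.max_depth,
            "ss_root": self.ss_root,
            "n": self.n,
            "n_splits": self.n_splits,
            "nodes": [
                {
                    "node_id": nd.node_id,
                    "depth": nd.depth,
                    "n": nd.n,
                    "mean_response": nd.mean_response,
                    "ss": nd.ss,
                    "split_locus": nd.split_locus,
                    "left_levels": list(nd.left_levels) if nd.left_levels else None,
                    "improvement": nd.improvement,
                    "left": nd.left,
                    "right": nd.right,
                    "n_missing_routed": nd.n_missing_routed,
                }
                for nd in sorted(self.nodes.values(), key=lambda nd: nd.node_id)
            ],
        }


def _tree_matrix(X, locus_ids=None) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.calls if locus_ids is None else X.subset_loci(locus_ids).calls
    if isinstance(X, pd.DataFrame):
        return (X[locus_ids] if locus_ids is not None else X).to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _candidate_partitions(levels: np.ndarray) -> list[tuple[int, ...]]:
    """Non-redundant binary partitions of the observed genotype classes.

    Three observed classes admit three partitions ({0}, {1}, {2} vs the
    rest); two classes admit one.
    """
    levels = [int(v) for v in levels]
    if len(levels) >= 3:
        return [(lv,) for lv in levels]
    return [(levels[0],)]


class AnovaTreeRegressor(RegressorMixin, BaseEstimator):
    """Regression tree over 0/1/2-coded genotypes with ANOVA splitting.

    At every node each locus is scanned over all non-redundant binary
    partitions of its observed genotype classes; the (locus, partition)
    maximizing the sum-of-squares reduction is chosen and accepted only if
    the improvement is at least ``cp * SS_root`` and both children hold at
    least ``minbucket`` individuals (default ``round(minsplit / 3)``).
    Individuals missing the split locus follow the majority branch.  A
    root-only tree is a valid fit.  The tree is grown without
    cross-validation pruning; ``cp`` acts as the only complexity gate.

    Parameters
    ----------
    cp : float
        Complexity parameter; minimum relative improvement for a split.
    minsplit : int
        Minimum node size eligible for splitting.
    max_depth : int
        Maximum tree depth.
    minbucket : int or None
        Minimum child size; ``None`` means ``max(1, round(minsplit / 3))``.
    """

    def __init__(
        self,
        cp: float = 0.01,
        minsplit: int = 20,
        max_depth: int = 30,
        minbucket: int | None = None,
    ):
        self.cp = cp
        self.minsplit = minsplit
        self.max_depth = max_depth
        self.minbucket = minbucket

    def fit(self, X, y):
        if isinstance(X, GenotypeMatrix):
            locus_ids = list(X.locus_ids)
        elif isinstance(X, pd.DataFrame):
            locus_ids = [str(c) for c in X.columns]
        else:
            locus_ids = [f"locus{j}" for j in range(np.asarray(X).shape[1])]
        Xv = _tree_matrix(X)
        yv = np.asarray(y, dtype=float)
        if yv.shape[0] != Xv.shape[0]:
            raise ValueError("response length does not match genotype rows")
        if not np.all(np.isfinite(yv)):
            raise ValueError("non-finite response values")
        minbucket = (
            max(1, round(self.minsplit / 3))
            if self.minbucket is None
            else self.minbucket
        )
        ss_root = _sse(yv)
        nodes: dict[int, TreeNode] = {}
        counter = [0]

        def build(idx: np.ndarray, depth: int) -> int:
            nid = counter[0]
            counter[0] += 1
            ysub = yv[idx]
            node = TreeNode(
                node_id=nid,
                depth=depth,
                n=idx.size,
                mean_response=float(ysub.mean()),
                ss=_sse(ysub),
            )
            nodes[nid] = node
            # float-noise floor: a numerically constant node is a leaf
            ss_floor = 1e-20 * idx.size * (1.0 + node.mean_response**2)
            if idx.size < self.minsplit or depth >= self.max_depth or node.ss <= ss_floor:
                return nid
            best = None  # (improvement, j, partition, obs mask, left mask, majority_left)
            for j in range(Xv.shape[1]):
                g = Xv[idx, j]
                obs = ~np.isnan(g)
                n_miss = int((~obs).sum())
                gobs = g[obs]
                if gobs.size < 2:
                    continue
                levels = np.unique(gobs)
                if levels.size < 2:
                    continue
                yobs = ysub[obs]
                ss_sub = _sse(yobs)
                for part in _candidate_partitions(levels):
                    lmask = np.isin(gobs, part)
                    nl = int(lmask.sum())
                    nr = gobs.size - nl
                    if nl == 0 or nr == 0:
                        continue
                    majority_left = nl >= nr
                    nl_eff = nl + (n_miss if majority_left else 0)
                    nr_eff = nr + (0 if majority_left else n_miss)
                    if min(nl_eff, nr_eff) < minbucket:
                        continue
                    imp = ss_sub - _sse(yobs[lmask]) - _sse(yobs[~lmask])
                    if best is None or imp > best[0] + 1e-12:
                        best = (imp, j, part, obs, lmask, majority_left)
            if best is None or best[0] < self.cp * ss_root:
                return nid
            imp, j, part, obs, lmask, majority_left = best
            full_left = np.zeros(idx.size, dtype=bool)
            full_left[obs] = lmask
            full_left[~obs] = majority_left
            node.split_locus = locus_ids[j]
            node.left_levels = tuple(int(v) for v in part)
            node.improvement = float(imp)
            node.n_missing_routed = int((~obs).sum())
            node.majority_left = majority_left
            node.left = build(idx[full_left], depth + 1)
            node.right = build(idx[~full_left], depth + 1)
            return nid

        build(np.arange(yv.shape[0]), 0)
        self.tree_ = RegressionTree(
            nodes=nodes,
            locus_ids=locus_ids,
            cp=self.cp,
            minsplit=self.minsplit,
            minbucket=minbucket,
            max_depth=self.max_depth,
            ss_root=ss_root,
            n=yv.shape[0],
        )
        self.locus_ids_ = locus_ids
        self.n_features_in_ = Xv.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise AttributeError("AnovaTreeRegressor is not fitted yet")
        return self.tree_.predict(X)


def anova_tree(
    genotypes,
    response,
    cp: float = 0.01,
    minsplit: int = 20,
    max_depth: int = 30,
) -> RegressionTree:
    """Fit the ANOVA regression tree of a response on many SNP genotypes."""
    if isinstance(response, pd.Series) and isinstance(genotypes, GenotypeMatrix):
        response = response.reindex(genotypes.individual_ids).to_numpy(dtype=float)
    est = AnovaTreeRegressor(cp=cp, minsplit=minsplit, max_depth=max_depth)
    est.fit(genotypes, response)
    return est.tree_
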