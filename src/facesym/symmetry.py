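"""Object-symmetry decomposition of landmark shape variation.

The analysis quantifies how asymmetric each face is, and splits that asymmetry
into a population-level directional component and individual fluctuating
deviations:

1.  every configuration gets a mirrored, relabeled copy
    (:func:`reflect_relabel`);
2.  originals and reflections are superimposed jointly by generalized
    Procrustes analysis (GPA): centering, scaling to unit centroid size, and
    least-squares rotation to an iteratively refined consensus;
3.  individual *i*'s asymmetry vector is the difference between its aligned
    original and aligned reflection, ``a_i``.  Total asymmetry is
    ``TA_i = ||a_i||``, the directional asymmetry (DA) vector is the sample
    mean ``ā``, and fluctuating asymmetry is ``FA_i = ||a_i - ā||``.

Scores are Euclidean norms in the joint-GPA aligned coordinate space
(small-deviation Procrustes distances); no tangent-space projection is applied
beyond the superimposition itself, and no factor-½ halving of the
original-minus-reflection difference is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import (
    DEFAULT_SCHEME,
    LandmarkConfiguration,
    SymmetryScheme,
    stack_configurations,
)

__all__ = [
    "ProcrustesResult",
    "AsymmetryScores",
    "AsymmetryScorer",
    "reflect_relabel",
    "optimal_rotation",
    "generalized_procrustes",
    "asymmetry_scores",
]


def reflect_relabel(
    config: LandmarkConfiguration, scheme: SymmetryScheme = DEFAULT_SCHEME
) -> LandmarkConfiguration:
    """Mirrored copy of a configuration with left/right labels swapped.

    The reflection negates the scheme's reflection axis for every landmark;
    relabeling then restores the anatomical naming so that e.g. the mirrored
    right zygion is stored under the left zygion's row.  Midline landmarks
    keep their labels.  The operation is an involution.
    """
    scheme.validate_landmarks(config.n_landmarks)
    return LandmarkConfiguration(
        individual_id=config.individual_id,
        coordinates=scheme.reflect(config.coordinates),
        landmark_names=config.landmark_names,
    )


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` minimizing ``||source @ R - target||_F``.

    Both configurations must be centered.  Reflections are not permitted: the
    determinant of the returned matrix is +1 (handedness preserved), enforced
    by the usual sign correction on the smallest singular vector of the
    cross-covariance.  A degenerate source (rank < 2, i.e. collinear points)
    is flagged with a warning and the identity is returned.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3:
        raise ValueError("source and target must be matching (k, 3) matrices")
    if S.shape[0] < 3:
        raise ValueError("at least 3 landmarks required for a 3D rotation")
    if np.linalg.matrix_rank(S) < 2:
        warnings.warn(
            "degenerate (rank < 2) configuration; returning identity rotation",
            stacklevel=2,
        )
        return np.eye(3)
    H = S.T @ T
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    return (U * np.array([1.0, 1.0, d])) @ Vt


def _batch_rotations_to(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-configuration proper rotations aligning each A[m] onto C."""
    H = np.einsum("mki,kj->mij", A, C)
    U, _, Vt = np.linalg.svd(H)
    UVt = np.einsum("mij,mjk->mik", U, Vt)
    d = np.sign(np.linalg.det(UVt))
    d[d == 0] = 1.0
    U = U.copy()
    U[:, :, 2] *= d[:, None]
    return np.einsum("mij,mjk->mik", U, Vt)


@dataclass
class ProcrustesResult:
    """Outcome of a generalized Procrustes superimposition."""

    individual_ids: list[str]
    aligned: np.ndarray          # (m, k, 3), unit centroid size, consensus frame
    consensus: np.ndarray        # (k, 3) mean shape, unit centroid size
    centroid_sizes: np.ndarray   # (m,) sizes of the raw configurations
    iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    @property
    def mean_shape(self) -> np.ndarray:
        """Coordinate-wise mean of the aligned configurations."""
        return self.aligned.mean(axis=0)


def generalized_procrustes(
    configs,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Full generalized Procrustes analysis (translation, scale, rotation).

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the current consensus; the consensus is the
    renormalized mean of the aligned configurations.  Iteration stops when the
    root-mean-square change of the consensus falls below ``tol``.

    The recorded objective is the summed squared deviation of the aligned
    configurations from the (unit-size) consensus, which is non-increasing
    across iterations because both the rotation step and the consensus update
    are exact coordinate-descent minimizers.
    """
    ids, X = stack_configurations(configs)
    m, k, _ = X.shape
    if m < 2:
        raise ValueError("generalized Procrustes analysis needs >= 2 configurations")
    Xc = X - X.mean(axis=1, keepdims=True)
    cs = np.sqrt((Xc**2).sum(axis=(1, 2)))
    if np.any(cs <= 0):
        raise ValueError("configuration with zero centroid size")
    A = Xc / cs[:, None, None]

    C = A[0].copy()
    C /= np.sqrt((C**2).sum())
    converged = False
    iterations = 0
    history: list[float] = []
    for iterations in range(1, max_iter + 1):
        R = _batch_rotations_to(A, C)
        A = np.einsum("mki,mij->mkj", A, R)
        C_new = A.mean(axis=0)
        C_new /= np.sqrt((C_new**2).sum())
        history.append(float(((A - C_new) ** 2).sum()))
        change = np.sqrt(np.mean((C_new - C) ** 2))
        C = C_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last consensus "
            "change above tolerance)",
            stacklevel=2,
        )
    return ProcrustesResult(
        individual_ids=ids,
        aligned=A,
        consensus=C,
        centroid_sizes=cs,
        iterations=iterations,
        converged=converged,
        objective_history=history,
    )


@dataclass
class AsymmetryScores:
    """Per-individual asymmetry scores and the population DA vector.

    ``ta[i]`` is the norm of individual *i*'s asymmetry vector ``a_i`` (shape
    distance between aligned original and reflection), ``fa[i]`` the norm of
    its deviation from the sample mean asymmetry, and ``da_vector`` the
    flattened mean asymmetry field (directional asymmetry).
    """

    individual_ids: list[str]
    ta: np.ndarray
    fa: np.ndarray | None
    da_vector: np.ndarray
    da_magnitude: float
    asymmetry_vectors: np.ndarray  # (n, 3k) individual a_i in the aligned frame
    procrustes: ProcrustesResult

    def to_frame(self):
        import pandas as pd

        data = {"ta": self.ta}
        if self.fa is not None:
            data["fa"] = self.fa
        return pd.DataFrame(data, index=pd.Index(self.individual_ids, name="individual_id"))


def asymmetry_scores(
    configs,
    scheme: SymmetryScheme = DEFAULT_SCHEME,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_single: bool = False,
) -> AsymmetryScores:
    """Total, fluctuating, and directional asymmetry via object symmetry.

    Builds the reflected-relabeled copy of every configuration, runs one joint
    GPA over all ``2n`` configurations, and scores each individual from the
    difference between its aligned original and aligned reflection.

    With a single individual FA (a deviation from the population mean) is
    undefined; pass ``allow_single=True`` to still obtain TA and the (trivial)
    DA vector.
    """
    ids, X = stack_configurations(configs)
    n = X.shape[0]
    scheme.validate_landmarks(X.shape[1])
    if n < 2 and not allow_single:
        raise ValueError(
            "fluctuating asymmetry is undefined for a single individual; "
            "pass allow_single=True to compute TA only"
        )
    refl = scheme.reflect(X)
    # even for n == 1 the joint set (original + reflection) is a valid GPA input
    gpa = generalized_procrustes(np.concatenate([X, refl]), tol=tol, max_iter=max_iter)
    a = (gpa.aligned[:n] - gpa.aligned[n:]).reshape(n, -1)
    ta = np.linalg.norm(a, axis=1)
    if n == 1:
        da_vector = a[0].copy()
        return AsymmetryScores(
            individual_ids=ids,
            ta=ta,
            fa=None,
            da_vector=da_vector,
            da_magnitude=float(np.linalg.norm(da_vector)),
            asymmetry_vectors=a,
            procrustes=gpa,
        )
    da_vector = a.mean(axis=0)
    fa = np.linalg.norm(a - da_vector, axis=1)
    return AsymmetryScores(
        individual_ids=ids,
        ta=ta,
        fa=fa,
        da_vector=da_vector,
        da_magnitude=float(np.linalg.norm(da_vector)),
        asymmetry_vectors=a,
        procrustes=gpa,
    )


class AsymmetryScorer(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper around the object-symmetry scoring.

    Like manifold embedders, the transform is defined for the fitted cohort
    only (the joint GPA couples all individuals), so use
    :meth:`fit_transform`; fitted attributes expose the scores and the DA
    vector.

    Parameters
    ----------
    scheme
        The left/right pairing scheme.
    tol, max_iter
        GPA convergence controls.
    """

    def __init__(
        self,
        scheme: SymmetryScheme = DEFAULT_SCHEME,
        tol: float = 1e-10,
        max_iter: int = 100,
    ):
        self.scheme = scheme
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        scores = asymmetry_scores(
            X, self.scheme, tol=self.tol, max_iter=self.max_iter
        )
        self.scores_ = scores
        self.individual_ids_ = scores.individual_ids
        self.ta_ = scores.ta
        self.fa_ = scores.fa
        self.da_vector_ = scores.da_vector
        self.da_magnitude_ = scores.da_magnitude
        self.consensus_ = scores.procrustes.consensus
        self.n_iterations_ = scores.procrustes.iterations
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return np.column_stack([self.ta_, self.fa_])

    def transform(self, X):
        raise NotImplementedError(
            "asymmetry scores are defined jointly for the fitted cohort; "
            "use fit_transform"
        )
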