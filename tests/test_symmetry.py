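"""Object-symmetry decomposition: reflection, rotations, GPA, TA/FA scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from facesym import (
    LandmarkConfiguration,
    SymmetryScheme,
    asymmetry_scores,
    default_template,
    generalized_procrustes,
    optimal_rotation,
    reflect_relabel,
)
from facesym.landmarks import DEFAULT_SCHEME

TOY_SCHEME = SymmetryScheme(paired_indices=((0, 1),), midline_indices=(2,))


def _center_unit(X):
    Xc = X - X.mean(axis=0)
    return Xc / np.sqrt((Xc**2).sum())


# ---------------------------------------------------------------------------
# reflection-relabeling
# ---------------------------------------------------------------------------

def test_reflect_relabel_toy_hand_computation():
    """Pair coordinates are exchanged; the midline landmark gets x negated."""
    config = LandmarkConfiguration(
        "toy",
        np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        landmark_names=("left", "right", "mid"),
    )
    out = reflect_relabel(config, TOY_SCHEME)
    # mirrored right (-(-1)=1) lands under the left label and vice versa
    np.testing.assert_allclose(
        out.coordinates,
        [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
    )
    asym = LandmarkConfiguration(
        "toy2",
        np.array([[1.2, 0.1, 0.0], [-1.0, 0.0, 0.3], [0.05, 1.0, 0.0]]),
        landmark_names=("left", "right", "mid"),
    )
    out2 = reflect_relabel(asym, TOY_SCHEME)
    np.testing.assert_allclose(
        out2.coordinates,
        [[1.0, 0.0, 0.3], [-1.2, 0.1, 0.0], [-0.05, 1.0, 0.0]],
    )


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**32 - 1))
def test_reflect_relabel_is_involution(seed):
    coords = np.random.default_rng(seed).normal(size=(9, 3))
    config = LandmarkConfiguration("x", coords)
    twice = reflect_relabel(reflect_relabel(config))
    np.testing.assert_array_equal(twice.coordinates, coords)


def test_symmetric_configuration_maps_to_itself():
    """A symmetric face equals its reflection after optimal alignment."""
    T = default_template()
    config = LandmarkConfiguration("sym", T)
    refl = reflect_relabel(config)
    A = _center_unit(T)
    B = _center_unit(refl.coordinates)
    R = optimal_rotation(A, B)
    assert np.linalg.norm(A @ R - B) <= 1e-10


# ---------------------------------------------------------------------------
# optimal rotation
# ---------------------------------------------------------------------------

def test_optimal_rotation_identity_and_recovery(rng):
    S = rng.normal(size=(9, 3))
    S -= S.mean(axis=0)
    np.testing.assert_allclose(optimal_rotation(S, S), np.eye(3), atol=1e-12)
    R_true = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    R_hat = optimal_rotation(S, S @ R_true)
    np.testing.assert_allclose(R_hat, R_true, atol=1e-10)
    assert np.isclose(np.linalg.det(R_hat), 1.0)


def test_optimal_rotation_degenerate_returns_identity():
    S = np.array([[1.0, 0, 0], [-1.0, 0, 0], [2.0, 0, 0], [-2.0, 0, 0]])
    with pytest.warns(UserWarning, match="degenerate"):
        R = optimal_rotation(S, S)
    np.testing.assert_array_equal(R, np.eye(3))


def test_optimal_rotation_matches_random_search_oracle(rng):
    """Kabsch residual equals the best of a large random-rotation search."""
    S = rng.normal(size=(6, 3))
    S -= S.mean(axis=0)
    T = S @ Rotation.random(rng=np.random.default_rng(5)).as_matrix()
    T += 0.05 * rng.normal(size=T.shape)
    T -= T.mean(axis=0)
    R = optimal_rotation(S, T)
    res_impl = np.linalg.norm(S @ R - T)

    H = S.T @ T
    const = (S**2).sum() + (T**2).sum()

    def best_trace(mats):
        # ||S R - T||^2 = ||S||^2 + ||T||^2 - 2 tr(R^T H)
        traces = np.einsum("nij,ij->n", mats, H)
        k = int(np.argmax(traces))
        return mats[k], traces[k]

    search_rng = np.random.default_rng(9)
    incumbent, tr = best_trace(Rotation.random(200_000, rng=search_rng).as_matrix())
    # anneal: random local perturbations with shrinking angle
    for scale in (0.1, 0.02, 0.004, 8e-4, 1.6e-4, 3e-5):
        perturb = Rotation.from_rotvec(
            search_rng.normal(0.0, scale, (50_000, 3))
        ).as_matrix()
        cand, tr_new = best_trace(np.einsum("ij,njk->nik", incumbent, perturb))
        if tr_new > tr:
            incumbent, tr = cand, tr_new
    res_search = np.sqrt(const - 2 * tr)
    assert res_impl <= res_search + 1e-12
    assert res_search - res_impl <= 1e-4


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

def test_gpa_similarity_invariance(rng):
    """Inputs differing only by similarity transforms align perfectly."""
    base = default_template() + rng.normal(0, 2.0, (9, 3))
    configs = []
    for i in range(5):
        R = Rotation.random(rng=np.random.default_rng(i)).as_matrix()
        s = float(np.exp(rng.normal(0, 0.3)))
        t = rng.normal(0, 30, 3)
        configs.append(s * base @ R.T + t)
    res = generalized_procrustes(np.stack(configs))
    for i in range(5):
        for j in range(i):
            assert np.linalg.norm(res.aligned[i] - res.aligned[j]) <= 1e-8


def test_gpa_two_shape_closed_form_oracle(rng):
    """Joint GPA of two shapes reproduces the direct SVD superimposition."""
    X1 = default_template() + rng.normal(0, 3.0, (9, 3))
    X2 = default_template() + rng.normal(0, 3.0, (9, 3))
    res = generalized_procrustes(np.stack([X1, X2]))
    d_gpa = np.linalg.norm(res.aligned[0] - res.aligned[1])
    A, B = _center_unit(X1), _center_unit(X2)
    R = optimal_rotation(A, B)
    d_direct = np.linalg.norm(A @ R - B)
    assert abs(d_gpa - d_direct) <= 1e-8


def test_gpa_objective_monotone_and_invariants(rng):
    configs = default_template()[None] + rng.normal(0, 2.0, (8, 9, 3))
    res = generalized_procrustes(configs)
    hist = np.array(res.objective_history)
    assert np.all(np.diff(hist) <= 1e-12)
    # unit centroid size, centered, consensus = renormalized mean
    for A in res.aligned:
        assert abs(np.sqrt((A**2).sum()) - 1.0) <= 1e-10
        assert np.linalg.norm(A.mean(axis=0)) <= 1e-10
    mean = res.aligned.mean(axis=0)
    np.testing.assert_allclose(
        res.consensus, mean / np.sqrt((mean**2).sum()), atol=1e-10
    )


# ---------------------------------------------------------------------------
# asymmetry scores
# ---------------------------------------------------------------------------

def test_symmetric_faces_score_zero(rng):
    T = default_template()
    sym = [
        LandmarkConfiguration(f"s{i}", T * (1.0 + 0.05 * i)) for i in range(4)
    ]
    scores = asymmetry_scores(sym)
    assert np.all(scores.ta <= 1e-10)
    assert np.all(scores.fa <= 1e-10)


def test_identical_asymmetry_gives_zero_fa():
    """If every individual shares one asymmetry vector, FA vanishes and
    DA magnitude equals the common TA."""
    T = default_template()
    scheme = DEFAULT_SCHEME
    shift = np.zeros((9, 3))
    shift[7, 0] = 0.4  # lateral nose deviation shared by everyone
    a = scheme.antisymmetric_part(shift)
    configs = [LandmarkConfiguration(f"i{i}", T + a / 2) for i in range(5)]
    scores = asymmetry_scores(configs)
    assert np.all(scores.fa <= 1e-10)
    assert scores.da_magnitude == pytest.approx(scores.ta[0], abs=1e-10)
    assert scores.da_magnitude > 1e-4


def test_single_individual_requires_flag():
    T = default_template()
    shift = np.zeros((9, 3))
    shift[7, 0] = 0.2
    cfg = [LandmarkConfiguration("only", T + DEFAULT_SCHEME.antisymmetric_part(shift) / 2)]
    with pytest.raises(ValueError, match="single individual"):
        asymmetry_scores(cfg)
    scores = asymmetry_scores(cfg, allow_single=True)
    assert scores.fa is None
    assert scores.ta[0] > 0


def test_scores_invariant_to_similarity_transforms(rng):
    """Per-individual rotations/translations/scales change no score."""
    from facesym import SimulationParams, simulate_covariates, simulate_faces

    params = SimulationParams(n_individuals=40, n_loci=5, noise_sigma=0.0, seed=3)
    cov = simulate_covariates(params)
    plain, _ = simulate_faces(params, cov, apply_nuisance=False)
    moved, _ = simulate_faces(params, cov, apply_nuisance=True)
    s0 = asymmetry_scores(plain)
    s1 = asymmetry_scores(moved)
    np.testing.assert_allclose(s1.ta, s0.ta, rtol=1e-8)
    np.testing.assert_allclose(s1.fa, s0.fa, rtol=1e-8, atol=1e-14)


def test_reflection_consistency(rng):
    """Scoring the mirrored dataset preserves TA/FA and negates DA."""
    from facesym import SimulationParams, simulate_covariates, simulate_faces

    params = SimulationParams(n_individuals=30, n_loci=5, noise_sigma=0.0, seed=4)
    cov = simulate_covariates(params)
    configs, _ = simulate_faces(params, cov, apply_nuisance=False)
    mirrored = [reflect_relabel(c) for c in configs]
    s0 = asymmetry_scores(configs)
    s1 = asymmetry_scores(mirrored)
    np.testing.assert_allclose(s1.ta, s0.ta, rtol=1e-8)
    np.testing.assert_allclose(s1.fa, s0.fa, rtol=1e-8, atol=1e-14)
    # rotate run 1's frame onto run 0's before comparing DA fields
    R = optimal_rotation(s1.procrustes.consensus, s0.procrustes.consensus)
    da1 = s1.da_vector.reshape(-1, 3) @ R
    np.testing.assert_allclose(da1, -s0.da_vector.reshape(-1, 3), atol=1e-8)


def test_fa_deviations_average_to_zero(small_cohort):
    scores = asymmetry_scores(small_cohort.configs)
    dev = scores.asymmetry_vectors - scores.da_vector
    assert np.linalg.norm(dev.mean(axis=0)) <= 1e-12


def test_ta_matches_brute_force_rotation_search():
    """TA on a tiny two-individual dataset equals an independent Procrustes
    distance obtained by direct optimization over rotations."""
    base = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    rng = np.random.default_rng(2)
    configs = []
    for i in range(2):
        d = TOY_SCHEME.antisymmetric_part(rng.normal(0, 0.004, (3, 3)))
        configs.append(
            LandmarkConfiguration(f"t{i}", base + d / 2, landmark_names=("l", "r", "m"))
        )
    scores = asymmetry_scores(configs, TOY_SCHEME)

    for i, cfg in enumerate(configs):
        X = _center_unit(cfg.coordinates)
        Y = _center_unit(TOY_SCHEME.reflect(cfg.coordinates))

        def resid(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.linalg.norm(X @ R - Y)

        # multi-start local optimization over rotation vectors
        best = np.inf
        for s in range(20):
            x0 = np.random.default_rng(s).normal(0, 1.5, 3)
            out = minimize(resid, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000})
            best = min(best, out.fun)
        assert scores.ta[i] == pytest.approx(best, abs=1e-4)
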