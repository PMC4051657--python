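"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a large adult population cohort: biallelic SNP
genotypes under a tunable inbreeding coefficient, demographic covariates
(truncated-normal ages, sex, two cohort waves), and 3D facial landmark data
with planted directional asymmetry, per-individual fluctuating-asymmetry
scale, nuisance similarity transforms, and measurement noise.  An optional
effect of individual homozygosity (HL) — or of a designated SNP — on the FA
scale provides a recoverable ground truth for the association analysis.

Generative model for faces
--------------------------
For individual *i* with FA scale ``sigma_i``::

    a_i     = P_a(da_vector) + P_a(eps_i) * sigma_i        (asymmetry field)
    config  = template + P_s(delta_i) + a_i / 2            (then nuisance + noise)

where ``P_a``/``P_s`` are the antisymmetric/symmetric projectors of the
symmetry scheme, ``eps_i`` is standard Gaussian per coordinate, and
``delta_i`` a Gaussian symmetric shape deviation.  Because the asymmetry
field enters with a factor ½, the difference between the configuration and
its reflected-relabeled copy equals ``a_i`` exactly, so the downstream
object-symmetry pipeline can recover the planted values.  ``sigma_i`` is::

    sigma_i = fa_sigma0 + beta_hl * HL_i + beta_snp[g_i] + beta_male * male_i
              + beta_age * (age_i - age_mean)

Independent named random streams are used per stage, so e.g. disabling the
nuisance transforms does not change the drawn asymmetries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .heterozygosity import HLScores, allele_frequencies, hl_index
from .landmarks import (
    DEFAULT_SCHEME,
    LandmarkConfiguration,
    SymmetryScheme,
    default_template,
)

__all__ = [
    "SimulationParams",
    "FaceTruth",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_faces",
    "simulate_cohort",
]

_STREAMS = (
    "allele_freqs",
    "genotypes",
    "covariates",
    "faces_symmetric",
    "faces_asymmetric",
    "nuisance",
    "noise",
)


@dataclass
class SimulationParams:
    """Parameters of the synthetic cohort.

    Defaults mirror the target data structure: 3215 individuals aged 45–92
    (mean 59.5, SD 8.0), two cohort waves, and 102 biallelic SNPs.  Landmark
    units are millimetres on a template of centroid size ≈ 157 mm;
    ``fa_sigma0 = 0.1`` mm yields fluctuating-asymmetry scores of order
    2e-3 Procrustes units, and the default planted DA has norm equal to 5% of
    the FA scale (the "DA very small" regime).
    """

    n_individuals: int = 3215
    n_loci: int = 102
    allele_freqs: np.ndarray | None = None  # default: Uniform(0.1, 0.9) per locus
    inbreeding_f: float = 0.0
    age_mean: float = 59.5
    age_sd: float = 8.0
    age_range: tuple[float, float] = (45.0, 92.0)
    male_fraction: float = 0.45
    cohort_labels: tuple[str, ...] = ("RS1", "RS2")
    cohort_fractions: tuple[float, ...] = (2470 / 3215, 745 / 3215)
    template: np.ndarray | None = None
    scheme: SymmetryScheme = field(default_factory=SymmetryScheme)
    da_vector: np.ndarray | None = None  # (k, 3) field; default: nose x-shift
    fa_sigma0: float = 0.1
    beta_hl: float = 0.0
    beta_snp: dict | None = None  # {"locus": str, "shifts": (s0, s1, s2)}
    beta_male: float = 0.0
    beta_age: float = 0.0
    sym_sigma: float = 2.0
    noise_sigma: float = 0.01
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("n_individuals and n_loci must be positive")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        fr = np.asarray(self.cohort_fractions, dtype=float)
        if len(fr) != len(self.cohort_labels):
            raise ValueError("cohort_fractions must match cohort_labels")
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("cohort_fractions must be nonnegative and sum to 1")
        if self.allele_freqs is not None:
            p = np.asarray(self.allele_freqs, dtype=float)
            if p.shape != (self.n_loci,):
                raise ValueError("allele_freqs length must equal n_loci")
            if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
                raise ValueError("allele frequencies must be finite and in [0, 1]")
        if self.fa_sigma0 <= 0:
            raise ValueError("fa_sigma0 must be positive")
        # sigma must stay positive over the attainable HL range [0, 1]
        if self.fa_sigma0 + min(0.0, self.beta_hl) <= 0:
            raise ValueError("fa_sigma0 + beta_hl*HL must be positive for HL in [0,1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.noise_sigma < 0 or self.sym_sigma < 0:
            raise ValueError("noise_sigma and sym_sigma must be nonnegative")

    # -- derived quantities ----------------------------------------------
    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {
            name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)
        }

    def resolved_allele_freqs(self) -> np.ndarray:
        if self.allele_freqs is not None:
            return np.asarray(self.allele_freqs, dtype=float)
        rng = self.streams()["allele_freqs"]
        return rng.uniform(0.1, 0.9, self.n_loci)

    def resolved_template(self) -> np.ndarray:
        return (
            default_template()
            if self.template is None
            else np.asarray(self.template, dtype=float)
        )

    def resolved_da_vector(self) -> np.ndarray:
        """Planted DA field, projected onto the antisymmetric subspace."""
        if self.da_vector is None:
            da = np.zeros_like(self.resolved_template())
            # lateral (x) shift of the nose tip: norm = 5% of the FA scale
            da[7, 0] = 0.05 * self.fa_sigma0
        else:
            da = np.asarray(self.da_vector, dtype=float)
        return self.scheme.antisymmetric_part(da)


@dataclass
class FaceTruth:
    """Ground truth planted in a simulated landmark dataset."""

    asymmetry: np.ndarray   # (n, 3k) planted a_i, flattened
    sigma: np.ndarray       # (n,) per-individual FA scale
    da_applied: np.ndarray  # (3k,) antisymmetric planted DA field


def simulate_genotypes(params: SimulationParams) -> GenotypeMatrix:
    """Biallelic genotypes under the inbreeding-coefficient model.

    At a locus with ALT frequency ``p`` and inbreeding coefficient ``F``,
    genotype probabilities are ``P(0) = (1-p)^2 + p(1-p)F``,
    ``P(1) = 2p(1-p)(1-F)``, ``P(2) = p^2 + p(1-p)F``.  Loci are independent.
    """
    params.validate()
    p = params.resolved_allele_freqs()
    F = params.inbreeding_f
    p0 = (1.0 - p) ** 2 + p * (1.0 - p) * F
    p1 = 2.0 * p * (1.0 - p) * (1.0 - F)
    rng = params.streams()["genotypes"]
    u = rng.random((params.n_individuals, params.n_loci))
    calls = (u >= p0).astype(float) + (u >= p0 + p1).astype(float)
    ids = [f"id{i + 1:05d}" for i in range(params.n_individuals)]
    loci = [f"snp{j + 1:03d}" for j in range(params.n_loci)]
    return GenotypeMatrix(individual_ids=ids, locus_ids=loci, calls=calls)


def simulate_covariates(params: SimulationParams) -> pd.DataFrame:
    """Ages (truncated normal), sex (Bernoulli), and cohort labels."""
    params.validate()
    rng = params.streams()["covariates"]
    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    age = stats.truncnorm.rvs(
        a, b,
        loc=params.age_mean,
        scale=params.age_sd,
        size=params.n_individuals,
        random_state=rng,
    )
    sex = np.where(rng.random(params.n_individuals) < params.male_fraction, "male", "female")
    cohort = rng.choice(
        params.cohort_labels, size=params.n_individuals, p=params.cohort_fractions
    )
    ids = [f"id{i + 1:05d}" for i in range(params.n_individuals)]
    return pd.DataFrame(
        {"age": age, "sex": sex, "cohort": cohort},
        index=pd.Index(ids, name="individual_id"),
    )


def _fa_scales(params, covariates, hl, genotypes) -> np.ndarray:
    n = len(covariates)
    sigma = np.full(n, params.fa_sigma0)
    if params.beta_hl != 0.0:
        if hl is None:
            raise ValueError("hl scores are required when beta_hl != 0")
        hl_vals = hl.to_series().reindex(covariates.index).to_numpy() if isinstance(hl, HLScores) else np.asarray(hl, dtype=float)
        if np.any(~np.isfinite(hl_vals)):
            raise ValueError("HL must be defined for every individual when beta_hl != 0")
        sigma = sigma + params.beta_hl * hl_vals
    if params.beta_snp is not None:
        if genotypes is None:
            raise ValueError("genotypes are required when beta_snp is set")
        locus = params.beta_snp["locus"]
        shifts = np.asarray(params.beta_snp["shifts"], dtype=float)
        col = genotypes.locus_ids.index(locus)
        g = genotypes.calls[:, col]
        shift = np.where(np.isnan(g), 0.0, shifts[np.nan_to_num(g).astype(int)])
        sigma = sigma + shift
    if params.beta_male != 0.0:
        sigma = sigma + params.beta_male * (covariates["sex"].to_numpy() == "male")
    if params.beta_age != 0.0:
        sigma = sigma + params.beta_age * (
            covariates["age"].to_numpy() - params.age_mean
        )
    if np.any(sigma <= 0):
        raise ValueError("planted effects drive the FA scale non-positive")
    return sigma


def simulate_faces(
    params: SimulationParams,
    covariates: pd.DataFrame,
    hl: HLScores | np.ndarray | None = None,
    genotypes: GenotypeMatrix | None = None,
    apply_nuisance: bool = True,
) -> tuple[list[LandmarkConfiguration], FaceTruth]:
    """Landmark configurations with planted asymmetry and nuisance transforms.

    Returns the configurations together with the planted per-individual
    asymmetry vectors (the ground truth the scoring pipeline should recover).
    Set ``apply_nuisance=False`` to skip the random similarity transforms;
    thanks to independent random streams this does not change the drawn
    asymmetries or noise.
    """
    params.validate()
    scheme = params.scheme
    T = params.resolved_template()
    scheme.validate_landmarks(T.shape[0])
    if not scheme.is_symmetric(T, tol=1e-9):
        raise ValueError(
            "template is not symmetric under the scheme: paired landmarks must "
            "be mirror images and midline landmarks must lie on the reflection plane"
        )
    n = len(covariates)
    k = T.shape[0]
    sigma = _fa_scales(params, covariates, hl, genotypes)
    streams = params.streams()

    da = params.resolved_da_vector()
    eps = streams["faces_asymmetric"].normal(size=(n, k, 3))
    a = da[None, :, :] + scheme.antisymmetric_part(eps) * sigma[:, None, None]

    if params.sym_sigma > 0:
        delta = streams["faces_symmetric"].normal(0.0, params.sym_sigma, (n, k, 3))
        sym_dev = scheme.symmetric_part(delta)
    else:
        sym_dev = 0.0
    X = T[None, :, :] + sym_dev + a / 2.0

    if apply_nuisance:
        rng = streams["nuisance"]
        from scipy.spatial.transform import Rotation

        quat = rng.normal(size=(n, 4))
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        R = Rotation.from_quat(quat).as_matrix()  # uniform random rotations
        scale = np.exp(rng.normal(0.0, 0.15, n))
        trans = rng.normal(0.0, 50.0, (n, 3))
        X = scale[:, None, None] * np.einsum("nkj,nij->nki", X, R) + trans[:, None, :]

    if params.noise_sigma > 0:
        X = X + streams["noise"].normal(0.0, params.noise_sigma, X.shape)

    ids = list(covariates.index.astype(str))
    configs = [
        LandmarkConfiguration(individual_id=ids[i], coordinates=X[i])
        for i in range(n)
    ]
    truth = FaceTruth(
        asymmetry=a.reshape(n, -1), sigma=sigma, da_applied=da.ravel()
    )
    return configs, truth


@dataclass
class SimulatedCohort:
    """Bundle of all simulated data kinds plus the planted ground truth."""

    params: SimulationParams
    configs: list[LandmarkConfiguration]
    truth: FaceTruth
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    hl: HLScores


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Full cohort: genotypes → HL → covariates → faces (HL-dependent FA)."""
    genotypes = simulate_genotypes(params)
    covariates = simulate_covariates(params)
    diversity = allele_frequencies(genotypes)
    hl = hl_index(genotypes, diversity)
    configs, truth = simulate_faces(params, covariates, hl=hl, genotypes=genotypes)
    return SimulatedCohort(
        params=params,
        configs=configs,
        truth=truth,
        genotypes=genotypes,
        covariates=covariates,
        hl=hl,
    )
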