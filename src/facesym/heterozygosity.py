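"""Homozygosity by loci (HL) and per-locus expected heterozygosity.

HL weights each locus by its allelic variability rather than counting
homozygous loci uniformly::

    HL = sum(E_h) / (sum(E_h) + sum(E_j))

where ``E_h`` and ``E_j`` are the expected heterozygosities (``2 p (1 - p)``
for a biallelic locus with allele frequency ``p``) of the loci an individual
bears in homozygosis and heterozygosis, respectively.  HL is 0 when every
used locus is heterozygous and 1 when every used locus is homozygous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import GenotypeMatrix

__all__ = [
    "LocusDiversity",
    "HLScores",
    "HomozygosityByLoci",
    "allele_frequencies",
    "hl_index",
    "population_summary",
]


@dataclass
class LocusDiversity:
    """Per-locus ALT-allele frequency and expected heterozygosity."""

    locus_ids: list[str]
    alt_freq: np.ndarray
    expected_het: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alt_freq": self.alt_freq, "expected_het": self.expected_het},
            index=pd.Index(self.locus_ids, name="locus_id"),
        )


@dataclass
class HLScores:
    """Per-individual homozygosity-by-loci scores in [0, 1] (NaN if undefined)."""

    individual_ids: list[str]
    hl: np.ndarray
    n_loci_used: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.hl, index=pd.Index(self.individual_ids, name="individual_id"), name="hl"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hl": self.hl, "n_loci_used": self.n_loci_used},
            index=pd.Index(self.individual_ids, name="individual_id"),
        )


def _as_matrix(g) -> GenotypeMatrix:
    if isinstance(g, GenotypeMatrix):
        return g
    if isinstance(g, pd.DataFrame):
        return GenotypeMatrix.from_frame(g)
    raise TypeError("expected a GenotypeMatrix or DataFrame of calls")


def allele_frequencies(g, small_sample_correction: bool = False) -> LocusDiversity:
    """Plug-in allele frequencies and expected heterozygosity per locus.

    ``alt_freq = (sum of calls) / (2 * number of non-missing calls)`` and
    ``expected_het = 2 p (1 - p)``.  With ``small_sample_correction`` the
    unbiased ``2n/(2n - 1)`` factor is applied.  Loci with every call missing
    are excluded with a warning.
    """
    g = _as_matrix(g)
    calls = g.calls
    n_obs = (~np.isnan(calls)).sum(axis=0)
    empty = n_obs == 0
    if np.any(empty):
        dropped = [l for l, e in zip(g.locus_ids, empty) if e]
        warnings.warn(
            f"excluding {len(dropped)} locus/loci with all calls missing: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    keep = ~empty
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0)[keep] / (2.0 * n_obs[keep])
    e = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        two_n = 2.0 * n_obs[keep]
        e = e * two_n / np.maximum(two_n - 1.0, 1.0)
    return LocusDiversity(
        locus_ids=[l for l, k in zip(g.locus_ids, keep) if k],
        alt_freq=p,
        expected_het=e,
    )


def hl_index(g, div: LocusDiversity) -> HLScores:
    """Homozygosity by loci for every individual.

    Homozygous calls (0 or 2) contribute their locus's expected heterozygosity
    to numerator and denominator; heterozygous calls (1) to the denominator
    only; missing calls contribute nowhere.  An individual whose used loci
    give a zero denominator (all missing, or all monomorphic) has undefined HL
    (NaN) and triggers a warning.
    """
    g = _as_matrix(g)
    e_by_locus = dict(zip(div.locus_ids, div.expected_het))
    cols = [i for i, l in enumerate(g.locus_ids) if l in e_by_locus]
    if not cols:
        raise ValueError("no overlap between genotype loci and diversity loci")
    E = np.array([e_by_locus[g.locus_ids[i]] for i in cols])
    C = g.calls[:, cols]
    hom = ((C == 0.0) | (C == 2.0)).astype(float)
    het = (C == 1.0).astype(float)
    sum_eh = hom @ E
    sum_ej = het @ E
    denom = sum_eh + sum_ej
    n_used = (~np.isnan(C)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hl = np.where(denom > 0, sum_eh / np.where(denom > 0, denom, 1.0), np.nan)
    n_undef = int(np.sum(~np.isfinite(hl)))
    if n_undef:
        warnings.warn(
            f"HL undefined for {n_undef} individual(s) (no informative loci)",
            stacklevel=2,
        )
    return HLScores(
        individual_ids=list(g.individual_ids), hl=hl, n_loci_used=n_used
    )


_DECILES = tuple(range(10, 100, 10))


def population_summary(hl, groups=None) -> pd.DataFrame:
    """Per-group HL mean, standard error, and decile percentiles.

    ``groups`` maps individuals to labels (Series aligned by individual id, or
    an array in individual order); with ``None`` a single "all" group is used.
    Percentiles use linear interpolation between closest order statistics.
    Groups with no defined HL values are excluded with a warning.
    """
    if isinstance(hl, HLScores):
        s = hl.to_series()
    else:
        s = pd.Series(np.asarray(hl, dtype=float), name="hl")
    if groups is None:
        labels = pd.Series("all", index=s.index)
    elif isinstance(groups, pd.Series):
        labels = groups.reindex(s.index)
    else:
        labels = pd.Series(list(groups), index=s.index)
    rows = {}
    for label in labels.dropna().unique():
        vals = s[labels == label].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"group {label!r} has no HL values; excluded", stacklevel=2)
            continue
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        row = {"n": vals.size, "mean_hl": float(np.mean(vals)), "se_hl": se}
        pct = np.percentile(vals, _DECILES, method="linear")
        row.update({f"p{q}": float(v) for q, v in zip(_DECILES, pct)})
        rows[label] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


class HomozygosityByLoci(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer computing HL scores from genotype calls.

    ``fit`` estimates per-locus allele frequencies (hence expected
    heterozygosities) from the supplied cohort; ``transform`` scores any
    cohort genotyped at the same loci against those frequencies.  By default
    the frequencies come from the analyzed cohort itself (fit_transform).

    Parameters
    ----------
    small_sample_correction
        Apply the unbiased ``2n/(2n-1)`` factor to expected heterozygosity.
    """

    def __init__(self, small_sample_correction: bool = False):
        self.small_sample_correction = small_sample_correction

    def fit(self, X, y=None):
        g = _as_matrix(X)
        self.diversity_ = allele_frequencies(
            g, small_sample_correction=self.small_sample_correction
        )
        self.locus_ids_ = list(self.diversity_.locus_ids)
        return self

    def transform(self, X) -> np.ndarray:
        scores = self.score(X)
        return scores.hl[:, None]

    def score_table(self, X) -> pd.DataFrame:
        return self.score(X).to_frame()

    def score(self, X) -> HLScores:
        if not hasattr(self, "diversity_"):
            raise AttributeError("HomozygosityByLoci is not fitted yet")
        return hl_index(_as_matrix(X), self.diversity_)
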