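"""Genotype matrix container: individuals × biallelic loci, ALT-allele counts.

Calls are coded 0/1/2 (count of ALT alleles; 0 = hom-ref, 1 = het, 2 =
hom-alt) and stored as floats with NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray  # (n, L) float, values in {0, 1, 2, NaN}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, L = self.calls.shape
        if n != len(self.individual_ids) or L != len(self.locus_ids):
            raise ValueError("calls dimensions inconsistent with id lists")
        vals = self.calls[~np.isnan(self.calls)]
        if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("genotype calls must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls,
            index=pd.Index(self.individual_ids, name="individual_id"),
            columns=self.locus_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            individual_ids=[str(i) for i in df.index],
            locus_ids=[str(c) for c in df.columns],
            calls=df.to_numpy(dtype=float),
        )

    def subset_loci(self, loci) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in loci]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )
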