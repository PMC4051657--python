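"""Readers and writers for landmarks, genotypes, and covariates.

Formats
-------
* landmarks: long-format delimited table (``individual_id, landmark, x, y, z``;
  one row per landmark) or TPS records (``LM3=k`` followed by *k* coordinate
  triples and an ``ID=`` line);
* genotypes: individuals × loci table of 0/1/2/NA calls, or VCF v4.x with
  biallelic diploid records (parsed with cyvcf2);
* covariates: delimited table with ``individual_id, age, sex, cohort``.

All readers validate strictly; individuals with incomplete landmark sets are
excluded with a warning, while malformed values are hard errors.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .landmarks import DEFAULT_LANDMARK_NAMES, LandmarkConfiguration

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_genotypes",
    "write_genotypes",
    "read_covariates",
    "write_covariates",
]


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(
    path,
    format: str = "long",
    landmark_names: tuple[str, ...] = DEFAULT_LANDMARK_NAMES,
) -> list[LandmarkConfiguration]:
    """Read landmark configurations, validating the landmark set.

    Individuals missing one or more of the expected landmarks are excluded
    with a warning reporting the count.  Duplicate (individual, landmark)
    rows and unknown landmark names are hard errors.
    """
    if format == "long":
        return _read_landmarks_long(path, landmark_names)
    if format == "tps":
        return _read_landmarks_tps(path, landmark_names)
    raise ValueError(f"unknown landmark format {format!r} (expected 'long' or 'tps')")


def _read_landmarks_long(path, landmark_names) -> list[LandmarkConfiguration]:
    df = pd.read_csv(
        path,
        dtype={"individual_id": str, "landmark": str},
        float_precision="round_trip",
    )
    required = {"individual_id", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"landmark table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    unknown = sorted(set(df["landmark"]) - set(landmark_names))
    if unknown:
        raise ValueError(
            f"unknown landmark name(s) {unknown}; expected {list(landmark_names)}"
        )
    dup = df.duplicated(subset=["individual_id", "landmark"])
    if dup.any():
        bad = df.loc[dup, ["individual_id", "landmark"]].iloc[0]
        raise ValueError(
            f"duplicate landmark row for individual {bad['individual_id']!r}, "
            f"landmark {bad['landmark']!r}"
        )
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite or missing coordinate values in landmark table")
    configs: list[LandmarkConfiguration] = []
    n_excluded = 0
    for ind, sub in df.groupby("individual_id", sort=False):
        have = set(sub["landmark"])
        if have != set(landmark_names):
            n_excluded += 1
            continue
        ordered = sub.set_index("landmark").loc[list(landmark_names), ["x", "y", "z"]]
        configs.append(
            LandmarkConfiguration(
                individual_id=str(ind),
                coordinates=ordered.to_numpy(dtype=float),
                landmark_names=tuple(landmark_names),
            )
        )
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} individual(s) with incomplete landmark sets",
            stacklevel=3,
        )
    return configs


def _read_landmarks_tps(path, landmark_names) -> list[LandmarkConfiguration]:
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record = 0
    k_expected = len(landmark_names)
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM3="):
            raise ValueError(f"expected 'LM3=' record at line {i}, got {line!r}")
        k = int(line.split("=", 1)[1])
        if k != k_expected:
            raise ValueError(
                f"TPS record {record} has LM3={k}, expected {k_expected} landmarks"
            )
        rows = []
        for j in range(k):
            if i >= len(lines):
                raise ValueError(f"truncated TPS record {record}: missing coordinates")
            parts = lines[i].split()
            if len(parts) != 3:
                raise ValueError(
                    f"TPS record {record}, line {i + 1}: expected 3 coordinates"
                )
            rows.append([float(p) for p in parts])
            i += 1
        ind = f"tps{record:04d}"
        if i < len(lines) and lines[i].strip().upper().startswith("ID="):
            ind = lines[i].strip().split("=", 1)[1]
            i += 1
        configs.append(
            LandmarkConfiguration(
                individual_id=ind,
                coordinates=np.array(rows),
                landmark_names=tuple(landmark_names),
            )
        )
        record += 1
    return configs


def write_landmarks(configs, path, format: str = "long") -> None:
    configs = list(configs)
    if format == "long":
        rows = []
        for c in configs:
            for name, (x, y, z) in zip(c.landmark_names, c.coordinates):
                rows.append((c.individual_id, name, x, y, z))
        pd.DataFrame(rows, columns=["individual_id", "landmark", "x", "y", "z"]).to_csv(
            path, index=False, float_format="%.17g"
        )
        return
    if format == "tps":
        with open(path, "w") as fh:
            for c in configs:
                fh.write(f"LM3={c.n_landmarks}\n")
                for x, y, z in c.coordinates:
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
                fh.write(f"ID={c.individual_id}\n")
        return
    raise ValueError(f"unknown landmark format {format!r}")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "table") -> GenotypeMatrix:
    """Read a genotype matrix as ALT-allele counts (0/1/2, NaN missing).

    For VCF input, only biallelic SNP records with diploid genotypes are
    accepted; multi-allelic records are skipped with a warning, half calls and
    ``./.`` become missing, and a non-diploid genotype is a hard error naming
    the record.
    """
    if format == "table":
        return _read_genotypes_table(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'table' or 'vcf')")


_MISSING_TOKENS = {"", "na", "nan", "."}


def _read_genotypes_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str)
    calls = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            token = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
            if token.lower() in _MISSING_TOKENS:
                calls[i, j] = np.nan
            elif token in {"0", "1", "2"}:
                calls[i, j] = float(token)
            else:
                raise ValueError(
                    f"invalid genotype value {raw!r} at individual "
                    f"{df.index[i]!r}, locus {col!r} (expected 0, 1, 2 or NA)"
                )
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        locus_ids=[str(c) for c in df.columns],
        calls=calls,
    )


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        col = np.empty(len(samples), dtype=float)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype for sample {samples[i]!r} at record {name}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = np.nan
            else:
                col[i] = float(alleles[0] + alleles[1])
        locus_ids.append(name)
        columns.append(col)
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} multi-allelic record(s) in {path}", stacklevel=3
        )
    calls = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(individual_ids=samples, locus_ids=locus_ids, calls=calls)


def write_genotypes(g: GenotypeMatrix, path, format: str = "table") -> None:
    if format == "table":
        df = g.to_frame()
        # keep integer rendering for valid calls, NA for missing
        out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.to_csv(path)
        return
    if format == "vcf":
        _write_genotypes_vcf(g, path)
        return
    raise ValueError(f"unknown genotype format {format!r}")


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 writer for biallelic count-coded genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            gts = [
                _GT_STRINGS.get(c, "./.") if not np.isnan(c) else "./."
                for c in g.calls[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

_SEX_LEVELS = {"female", "male"}


def read_covariates(path) -> pd.DataFrame:
    """Covariate table indexed by individual id (columns: age, sex, cohort)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str, "cohort": str})
    required = {"individual_id", "age", "sex", "cohort"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"covariate table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if df["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in covariate table")
    df = df.set_index("individual_id")
    df["sex"] = df["sex"].str.strip().str.lower()
    bad_sex = sorted(set(df["sex"]) - _SEX_LEVELS)
    if bad_sex:
        raise ValueError(f"invalid sex value(s) {bad_sex}; expected female/male")
    age = pd.to_numeric(df["age"], errors="coerce")
    if not np.all(np.isfinite(age)) or np.any(age <= 0):
        raise ValueError("age must be finite and positive for every individual")
    df["age"] = age.astype(float)
    return df[["age", "sex", "cohort"]]


def write_covariates(df: pd.DataFrame, path) -> None:
    out = df.reset_index()
    if "individual_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "individual_id"})
    out.to_csv(path, index=False)
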