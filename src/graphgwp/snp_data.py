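"""SNP genotype and phenotype I/O, validation, MAF filtering and imputation.

Genotypes are allele dosages: counts 0/1/2 of a reference allele per
individual per marker. Two on-disk dialects are accepted:

* CSV/TSV with a header row; first column is the individual ID, remaining
  columns are marker dosages.
* PLINK ``.raw`` (space-delimited, columns ``FID IID PAT MAT SEX PHENOTYPE``
  followed by one dosage column per marker); the IID column becomes the
  individual ID.

Missing dosages are carried as NaN until :func:`impute_missing` runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "PhenotypeVector",
    "DataFormatError",
    "ValidationError",
    "load_genotypes",
    "write_genotypes",
    "load_phenotypes",
    "write_phenotypes",
    "minor_allele_frequencies",
    "filter_maf",
    "impute_missing",
    "align",
]

_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class DataFormatError(ValueError):
    """Malformed input file (header, delimiter, or cell contents)."""


class ValidationError(ValueError):
    """Structurally valid file violating a data contract (e.g. duplicate IDs)."""


@dataclass
class MarkerMatrix:
    """Individuals x markers allele-dosage matrix with string IDs.

    ``dosages`` entries are in {0, 1, 2} or NaN (missing, pre-imputation).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        n, p = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValidationError(
                f"{len(self.individual_ids)} individual IDs but {n} dosage rows"
            )
        if p != len(self.marker_ids):
            raise ValidationError(
                f"{len(self.marker_ids)} marker IDs but {p} dosage columns"
            )
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual IDs")
        if len(set(self.marker_ids)) != p:
            raise ValidationError("duplicate marker IDs")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(np.asarray(self.dosages, dtype=float)).any())

    def copy(self) -> "MarkerMatrix":
        return MarkerMatrix(
            list(self.individual_ids), list(self.marker_ids), self.dosages.copy()
        )


@dataclass
class PhenotypeVector:
    """Continuous trait values keyed by individual ID."""

    individual_ids: list[str]
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.individual_ids):
            raise ValidationError("phenotype values must align 1:1 with IDs")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicate individual IDs in phenotypes")
        if not np.all(np.isfinite(self.values)):
            bad = [self.individual_ids[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise ValidationError(f"non-finite phenotype values for IDs {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)


def _validate_dosages(
    values: np.ndarray,
    individual_ids: list[str],
    marker_ids: list[str],
) -> np.ndarray:
    """Check every non-missing entry is 0, 1 or 2; NaN marks missing."""
    arr = np.asarray(values, dtype=float)
    bad = np.isfinite(arr) & ~np.isin(arr, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataFormatError(
            f"non-dosage value {arr[i, j]!r} at individual {individual_ids[i]!r}, "
            f"marker {marker_ids[j]!r} (expected 0/1/2 or missing)"
        )
    return arr


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".raw":
        return "plink_raw"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def load_genotypes(
    path: str | Path,
    format: str = "infer",
    missing_code: str = "NA",
) -> MarkerMatrix:
    """Read a genotype matrix from CSV/TSV or PLINK ``.raw``.

    Row order of the file is preserved. Missing entries (``missing_code``)
    become NaN; any other non-0/1/2 cell raises :class:`DataFormatError`
    naming the offending individual and marker.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "infer":
        format = _infer_format(path)
    if format not in ("csv", "tsv", "plink_raw"):
        raise ValueError(f"unknown genotype format {format!r}")

    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=[missing_code], dtype=str)
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise DataFormatError(
                f"PLINK .raw header missing columns {missing_meta} in {path}"
            )
        ids = df["IID"].astype(str).tolist()
        marker_cols = [c for c in df.columns if c not in _PLINK_META_COLS]
        body = df[marker_cols]
    else:
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, na_values=[missing_code], dtype=str)
        if df.shape[1] < 2:
            raise DataFormatError(
                f"genotype file {path} needs an ID column plus >=1 marker column"
            )
        ids = df.iloc[:, 0].astype(str).tolist()
        marker_cols = list(df.columns[1:])
        body = df.iloc[:, 1:]

    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate individual IDs {dupes[:5]} in {path}")

    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric dosage cell in {path}: {exc}") from exc
    values = _validate_dosages(values, ids, [str(c) for c in marker_cols])
    return MarkerMatrix(ids, [str(c) for c in marker_cols], values)


def write_genotypes(
    m: MarkerMatrix,
    path: str | Path,
    format: str = "tsv",
    missing_code: str = "NA",
) -> Path:
    """Write a MarkerMatrix as CSV/TSV (round-trips with :func:`load_genotypes`).

    Dosages are written as integers where exact, so a 0/1/2 matrix
    round-trips bit-exactly through text.
    """
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    arr = np.asarray(m.dosages, dtype=float)
    with io.StringIO() as buf:
        buf.write("id" + sep + sep.join(m.marker_ids) + "\n")
        for i, ind in enumerate(m.individual_ids):
            cells = [
                missing_code
                if np.isnan(v)
                else (str(int(v)) if float(v).is_integer() else repr(v))
                for v in arr[i]
            ]
            buf.write(ind + sep + sep.join(cells) + "\n")
        path.write_text(buf.getvalue())
    return path


def load_phenotypes(path: str | Path, format: str = "infer") -> PhenotypeVector:
    """Read a two-column (ID, value) phenotype table with a header row."""
    path = Path(path)
    if format == "infer":
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise DataFormatError(f"phenotype file {path} needs (ID, value) columns")
    return PhenotypeVector(
        df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_phenotypes(p: PhenotypeVector, path: str | Path, format: str = "tsv") -> Path:
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    df = pd.DataFrame({"id": p.individual_ids, "value": p.values})
    df.to_csv(path, sep=sep, index=False)
    return path


def minor_allele_frequencies(m: MarkerMatrix) -> np.ndarray:
    """Per-marker MAF: min(p, 1-p), p = (sum of dosages) / (2 n)."""
    arr = np.asarray(m.dosages, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("impute missing dosages before computing MAF")
    p = arr.sum(axis=0) / (2.0 * m.n_individuals)
    return np.minimum(p, 1.0 - p)


def filter_maf(m: MarkerMatrix, threshold: float) -> MarkerMatrix:
    """Drop markers with minor allele frequency below ``threshold``.

    The input is left untouched; surviving columns keep their order.
    ``threshold > 0`` also removes monomorphic markers (MAF 0), which carry
    no distance or model information.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    maf = minor_allele_frequencies(m)
    keep = maf >= threshold
    return MarkerMatrix(
        list(m.individual_ids),
        [mk for mk, k in zip(m.marker_ids, keep) if k],
        m.dosages[:, keep].copy(),
    )


def impute_missing(
    m: MarkerMatrix, mode: str = "column_mean", seed: int = 0
) -> MarkerMatrix:
    """Replace missing dosages.

    ``column_mean`` (default, deterministic) inserts the column's observed
    mean dosage; ``genotype_frequency`` draws 0/1/2 from the column's
    observed genotype distribution using ``seed``.
    """
    if mode not in ("column_mean", "genotype_frequency"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    arr = np.asarray(m.dosages, dtype=float).copy()
    missing = np.isnan(arr)
    if not missing.any():
        return m.copy()
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        cols = [m.marker_ids[j] for j in np.flatnonzero(fully_missing)]
        raise ValidationError(f"markers with no observed genotypes: {cols[:10]}")

    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(missing.any(axis=0)):
        col = arr[:, j]
        obs = col[~np.isnan(col)]
        idx = np.flatnonzero(np.isnan(col))
        if mode == "column_mean":
            col[idx] = obs.mean()
        else:
            genotypes, counts = np.unique(obs, return_counts=True)
            col[idx] = rng.choice(genotypes, size=idx.size, p=counts / counts.sum())
    return MarkerMatrix(list(m.individual_ids), list(m.marker_ids), arr)


def align(m: MarkerMatrix, p: PhenotypeVector) -> tuple[MarkerMatrix, PhenotypeVector]:
    """Reorder the phenotype vector to the marker matrix's individual order.

    Every genotyped individual must have a phenotype; extra phenotyped
    individuals are dropped.
    """
    lookup = {i: k for k, i in enumerate(p.individual_ids)}
    missing = [i for i in m.individual_ids if i not in lookup]
    if missing:
        raise ValidationError(f"no phenotype for individuals {missing[:10]}")
    order = [lookup[i] for i in m.individual_ids]
    return m, PhenotypeVector(list(m.individual_ids), p.values[order])
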