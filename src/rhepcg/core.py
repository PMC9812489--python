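"""Domain types, genotype/phenotype standardization, and text-file I/O.

Genotypes are biallelic allele dosages in {0, 1, 2}, one row per
individual.  Standardization centers each marker column and scales it so
that the column sum of squares equals the number of individuals n
(divisor-n variance).  Under that convention the genomic relationship
matrix G = ZZ'/m has trace exactly n, which downstream moment estimators
rely on as an identity rather than an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawGenotypes",
    "StandardizedDesign",
    "VarianceComponents",
    "PredictionResult",
    "GenotypeFormatError",
    "DegenerateMarkerError",
    "load_genotypes",
    "load_phenotypes",
    "standardize",
]

#: Number of leading metadata columns (FID IID PAT MAT SEX PHENOTYPE) in a
#: PLINK ``.raw`` dosage export; genotype dosages start at column 7.
PLINK_RAW_META_COLS = 6


class GenotypeFormatError(ValueError):
    """A genotype file violates the dosage format contract."""


class DegenerateMarkerError(ValueError):
    """One or more marker columns are constant and cannot be scaled."""


@dataclass(frozen=True)
class RawGenotypes:
    """Unscaled allele-dosage matrix with identifiers.

    Attributes
    ----------
    matrix : ndarray of shape (n, m)
        Integer dosages in {0, 1, 2}; no missing values.
    ids : list of str
        Individual identifiers, length n.
    marker_names : list of str
        Marker identifiers, length m.
    """

    matrix: np.ndarray
    ids: list[str] = field(default_factory=list)
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2:
            raise GenotypeFormatError("genotype matrix must be 2-dimensional")
        n, m = mat.shape
        if n < 2 or m < 1:
            raise GenotypeFormatError(
                f"need at least 2 individuals and 1 marker, got {n}x{m}"
            )
        bad = ~np.isin(mat, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"dosage {mat[i, j]!r} at row {i + 1}, column {j + 1} "
                "is not in {0, 1, 2}"
            )
        object.__setattr__(self, "matrix", mat.astype(np.int8, copy=False))
        if not self.ids:
            object.__setattr__(self, "ids", [f"ind{i + 1}" for i in range(n)])
        if not self.marker_names:
            object.__setattr__(
                self, "marker_names", [f"m{j + 1}" for j in range(m)]
            )
        if len(self.ids) != n:
            raise GenotypeFormatError("ids length does not match row count")
        if len(self.marker_names) != m:
            raise GenotypeFormatError("marker_names length does not match columns")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class StandardizedDesign:
    """Centered/scaled genotype design with (optionally standardized) phenotype.

    ``Z`` holds marker columns with mean 0 and sum of squares n (divisor-n
    scaling) when built without a reference.  ``X`` is the intercept
    incidence vector of ones.  ``col_means``/``col_scales`` are the training
    statistics, reused to place candidate individuals on the training scale.
    ``y_mean``/``y_scale`` allow back-transformation of predictions to the
    raw phenotype scale.
    """

    Z: np.ndarray
    y: Optional[np.ndarray]
    X: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    y_mean: float = 0.0
    y_scale: float = 1.0

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass(frozen=True)
class VarianceComponents:
    """Additive and residual variance on the GRM (G = ZZ'/m) scale."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    method: str = "RHE"

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")

    @property
    def ratio(self) -> float:
        """Shrinkage ratio sigma_e2 / sigma_g2 (the ridge parameter source)."""
        return self.sigma_e2 / self.sigma_g2


@dataclass(frozen=True)
class PredictionResult:
    """Predicted genotypic values and their squared correlation with phenotypes."""

    predicted: np.ndarray
    r2: Optional[float] = None


# ---------------------------------------------------------------------------
# file I/O


def _parse_dosage_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    arr = df.to_numpy()
    flat = pd.to_numeric(pd.Series(arr.ravel()), errors="coerce")
    vals = flat.to_numpy(dtype=float).reshape(arr.shape)
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise GenotypeFormatError(
            f"{path}: non-numeric or missing dosage at row {i + 1}, column {j + 1}"
        )
    if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        i, j = np.argwhere(~np.isin(vals, (0.0, 1.0, 2.0)))[0]
        raise GenotypeFormatError(
            f"{path}: dosage {vals[i, j]} at row {i + 1}, column {j + 1} "
            "is not in {0, 1, 2}"
        )
    return vals.astype(np.int8)


def load_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    *,
    id_column: bool = False,
    header: bool = False,
    impute_missing: bool = False,
) -> RawGenotypes:
    """Load an allele-dosage matrix from delimited text.

    Parameters
    ----------
    path : str or Path
        File to read.
    dialect : {"tsv", "csv", "plink_raw"}
        ``tsv``/``csv`` are plain dosage tables (whitespace or comma
        delimited) with optional header row and optional leading ID column.
        ``plink_raw`` is the PLINK ``--recode A`` dialect: a header line and
        six metadata columns (FID IID PAT MAT SEX PHENOTYPE) before the
        dosages.
    id_column : bool
        For tsv/csv: the first column holds individual IDs.
    header : bool
        For tsv/csv: the first row holds marker names.
    impute_missing : bool
        Replace missing dosages by the rounded column mean instead of
        rejecting the file.  Off by default.

    Raises
    ------
    GenotypeFormatError
        On ragged rows, non-{0,1,2} entries, or missing values when
        ``impute_missing`` is off.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", header=0)
        if df.shape[1] <= PLINK_RAW_META_COLS:
            raise GenotypeFormatError(
                f"{path}: PLINK .raw needs >{PLINK_RAW_META_COLS} columns"
            )
        ids = df.iloc[:, 1].astype(str).tolist()  # IID column
        marker_names = list(df.columns[PLINK_RAW_META_COLS:])
        body = df.iloc[:, PLINK_RAW_META_COLS:]
    elif dialect in ("tsv", "csv"):
        sep = r"\s+" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str)
        ids = []
        if id_column:
            ids = df.iloc[:, 0].astype(str).tolist()
            df = df.iloc[:, 1:]
        marker_names = [str(c) for c in df.columns] if header else []
        body = df
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if impute_missing:
        num = body.apply(pd.to_numeric, errors="coerce")
        means = num.mean(axis=0)
        num = num.fillna(means.round())
        body = num
    mat = _parse_dosage_frame(body, str(path))
    return RawGenotypes(matrix=mat, ids=ids, marker_names=marker_names)


def load_phenotypes(
    path: str | Path, *, ids: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Load a phenotype vector from one- or two-column delimited text.

    Two-column files are interpreted as (ID, value); when ``ids`` is given
    the rows are cross-checked and reordered to match.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"[,\s]+", header=None, engine="python")
    if df.shape[1] == 1:
        return df.iloc[:, 0].astype(float).to_numpy()
    if df.shape[1] == 2:
        file_ids = df.iloc[:, 0].astype(str)
        vals = df.iloc[:, 1].astype(float)
        if ids is not None:
            lookup = dict(zip(file_ids, vals))
            missing = [i for i in ids if str(i) not in lookup]
            if missing:
                raise ValueError(
                    f"{path}: phenotypes missing for individuals {missing[:5]}"
                )
            return np.array([lookup[str(i)] for i in ids], dtype=float)
        return vals.to_numpy()
    raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")


# ---------------------------------------------------------------------------
# standardization


def standardize(
    raw: RawGenotypes | np.ndarray,
    y_raw: Optional[np.ndarray] = None,
    reference: Optional[StandardizedDesign] = None,
    *,
    standardize_phenotype: bool = True,
) -> StandardizedDesign:
    """Center and scale genotypes (and optionally the phenotype).

    Without a reference, column j becomes (x_ij - mean_j) / scale_j with
    scale_j = sqrt(mean squared deviation, divisor n), so each column has
    mean 0 and sum of squares exactly n.  With a reference (candidate-set
    standardization) the reference's training means/scales are applied
    unchanged: marker effects estimated on the training scale must be
    applied on that same scale.

    The phenotype, when given and ``standardize_phenotype`` is on, is
    centered and scaled to unit variance (divisor n-1); the raw mean/SD are
    retained on the design for back-transformation.
    """
    mat = raw.matrix if isinstance(raw, RawGenotypes) else np.asarray(raw)
    mat = mat.astype(np.float64)
    n = mat.shape[0]

    if reference is not None:
        col_means = reference.col_means
        col_scales = reference.col_scales
        if mat.shape[1] != col_means.shape[0]:
            raise ValueError(
                f"marker count {mat.shape[1]} does not match reference "
                f"{col_means.shape[0]}"
            )
    else:
        col_means = mat.mean(axis=0)
        col_scales = np.sqrt(((mat - col_means) ** 2).mean(axis=0))
        degenerate = col_scales <= 0.0
        if degenerate.any():
            names = (
                [raw.marker_names[j] for j in np.flatnonzero(degenerate)[:10]]
                if isinstance(raw, RawGenotypes)
                else np.flatnonzero(degenerate)[:10].tolist()
            )
            raise DegenerateMarkerError(
                f"constant marker column(s) cannot be standardized: {names}"
            )

    Z = (mat - col_means) / col_scales

    y = None
    y_mean, y_scale = 0.0, 1.0
    if y_raw is not None:
        y_raw = np.asarray(y_raw, dtype=float)
        if y_raw.shape[0] != n:
            raise ValueError(
                f"phenotype length {y_raw.shape[0]} does not match n={n}"
            )
        if standardize_phenotype:
            y_mean = float(y_raw.mean())
            y_scale = float(y_raw.std(ddof=1))
            if y_scale <= 0:
                raise ValueError("phenotype is constant; cannot standardize")
            y = (y_raw - y_mean) / y_scale
        else:
            y = y_raw.copy()

    return StandardizedDesign(
        Z=Z,
        y=y,
        X=np.ones(n),
        col_means=np.asarray(col_means, dtype=float),
        col_scales=np.asarray(col_scales, dtype=float),
        y_mean=y_mean,
        y_scale=y_scale,
    )
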