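"""Shared data model: feature matrices, masks, demographics validation.

Every harmonization method in this package consumes a :class:`FeatureMatrix`
(subjects x features) together with a validated demographic table carrying a
``SiteName`` label per subject.  This module owns the masking / network
vectorization plumbing that turns volumes, surfaces, square networks, or plain
tables into that matrix and back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SITE_COLUMN = "SiteName"
#: demographic columns that are never treated as covariates
PATH_COLUMNS = ("FileList", "FileListLH", "FileListRH")

SPACE_KINDS = ("volume", "surface", "network", "table")


class HarmonizationError(ValueError):
    """Raised on any contract violation (bad mask, bad demographics, ...)."""


@dataclass
class FeatureMatrix:
    """Subjects x features values after masking/vectorization.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_subjects, n_features)``; every entry finite.
    subject_ids
        Ordered subject identifiers, one per row.
    feature_index
        Per-feature provenance: flat voxel index, ``("L"|"R", vertex)`` pair,
        or ``(row, col)`` network cell; length equals ``n_features``.
    space_kind
        One of ``volume | surface | network | table`` (mutually exclusive).
    """

    values: np.ndarray
    subject_ids: list
    feature_index: list
    space_kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise HarmonizationError("feature matrix must be 2-D (subjects x features)")
        n, p = self.values.shape
        if n < 2:
            raise HarmonizationError(f"need at least 2 subjects, got {n}")
        if p < 1:
            raise HarmonizationError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise HarmonizationError("feature matrix contains non-finite values after masking")
        if len(self.subject_ids) != n:
            raise HarmonizationError("subject_ids length does not match row count")
        if len(self.feature_index) != p:
            raise HarmonizationError("feature_index length does not match feature count")
        if self.space_kind not in SPACE_KINDS:
            raise HarmonizationError(f"unknown space_kind {self.space_kind!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Same provenance, new values (e.g. after harmonization)."""
        return FeatureMatrix(values, list(self.subject_ids), list(self.feature_index), self.space_kind)


@dataclass
class MaskSpec:
    """Binary inclusion mask on the data grid.

    ``kind`` is one of ``volume`` (3-D binary array), ``surface_pair``
    (two binary vertex arrays, left then right hemisphere), ``network_upper_triangle``
    (side length ``n``; features are the strict upper triangle), or ``none``
    (include everything — permitted but discouraged).
    """

    kind: str
    grid: object = None  # ndarray, (ndarray, ndarray) pair, or int side length

    def __post_init__(self):
        if self.kind not in ("volume", "surface_pair", "network_upper_triangle", "none"):
            raise HarmonizationError(f"unknown mask kind {self.kind!r}")
        if self.kind in ("volume",):
            self.grid = _check_binary(np.asarray(self.grid))
        elif self.kind == "surface_pair":
            lh, rh = self.grid
            self.grid = (_check_binary(np.asarray(lh)), _check_binary(np.asarray(rh)))
        elif self.kind == "network_upper_triangle":
            self.grid = int(self.grid)
            if self.grid < 2:
                raise HarmonizationError("network mask needs side length >= 2")

    def n_selected(self) -> int:
        if self.kind == "volume":
            return int(self.grid.sum())
        if self.kind == "surface_pair":
            return int(self.grid[0].sum() + self.grid[1].sum())
        if self.kind == "network_upper_triangle":
            n = self.grid
            return n * (n - 1) // 2
        raise HarmonizationError("n_selected undefined for kind=none without data shape")


def _check_binary(arr: np.ndarray) -> np.ndarray:
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        bad = [v for v in vals if v not in (0, 1)][:5]
        raise HarmonizationError(
            f"masks must be binary, containing only 1s and 0s; found {bad}"
        )
    return arr.astype(bool)


@dataclass
class ValidatedDemographics:
    """Demographic table after validation.

    ``site`` holds one label per subject; ``site_order`` fixes first-appearance
    order so dummy/one-hot coding is deterministic across runs.
    """

    table: pd.DataFrame
    site: pd.Series = field(init=False)
    site_order: list = field(init=False)
    covariate_types: dict = field(init=False)

    def __post_init__(self):
        self.site = self.table[SITE_COLUMN].astype(str)
        self.site_order = list(dict.fromkeys(self.site))
        self.covariate_types = _type_covariates(self.table)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def covariate_columns(self) -> list:
        return list(self.covariate_types)

    def site_sizes(self) -> dict:
        counts = self.site.value_counts()
        return {s: int(counts[s]) for s in self.site_order}

    def site_codes(self) -> np.ndarray:
        """Integer site code per subject, in first-appearance order."""
        lookup = {s: i for i, s in enumerate(self.site_order)}
        return np.array([lookup[s] for s in self.site], dtype=int)

    def site_design(self) -> np.ndarray:
        """One-hot site indicator matrix, columns in first-appearance order."""
        codes = self.site_codes()
        design = np.zeros((len(codes), len(self.site_order)))
        design[np.arange(len(codes)), codes] = 1.0
        return design

    def covariate_design(self, adjust_vars: Sequence[str] | None = None) -> tuple[np.ndarray, list]:
        """Numeric design for the requested covariates.

        Continuous columns enter as-is; categorical columns are dummy-coded
        dropping the first level (first-appearance order).  Returns the design
        and the generated column names.
        """
        if adjust_vars is None:
            adjust_vars = self.covariate_columns
        unknown = [v for v in adjust_vars if v not in self.covariate_types]
        if unknown:
            raise HarmonizationError(f"unknown covariate column(s): {unknown}")
        cols, names = [], []
        for var in adjust_vars:
            col = self.table[var]
            if self.covariate_types[var] == "continuous":
                cols.append(pd.to_numeric(col).to_numpy(dtype=float))
                names.append(var)
            else:
                levels = list(dict.fromkeys(col.astype(str)))
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                    names.append(f"{var}[{lev}]")
        if not cols:
            return np.empty((self.n_subjects, 0)), []
        return np.column_stack(cols), names


def _type_covariates(table: pd.DataFrame) -> dict:
    """Numeric-parseable for every subject -> continuous, else categorical."""
    out = {}
    for col in table.columns:
        if col == SITE_COLUMN or col in PATH_COLUMNS:
            continue
        series = table[col]
        if series.isna().any():
            raise HarmonizationError(
                f"covariate column {col!r} has missing values; imputation is not supported"
            )
        try:
            pd.to_numeric(series)
            out[col] = "continuous"
        except (ValueError, TypeError):
            out[col] = "categorical"
    return out


def validate_demographics(table: pd.DataFrame, n_loaded_subjects: int) -> ValidatedDemographics:
    """Check a parsed demographic table against the loaded data.

    Requires the mandatory ``SiteName`` column, a row per loaded subject,
    at least two distinct sites, and at least two subjects per site.
    """
    if SITE_COLUMN not in table.columns:
        raise HarmonizationError(f'missing required column "{SITE_COLUMN}"')
    if len(table) != n_loaded_subjects:
        raise HarmonizationError(
            f"demographic table has {len(table)} rows but {n_loaded_subjects} subjects were loaded"
        )
    site = table[SITE_COLUMN].astype(str)
    if site.isna().any():
        raise HarmonizationError("SiteName column has missing entries")
    counts = site.value_counts()
    if len(counts) < 2:
        raise HarmonizationError("harmonization requires at least 2 distinct sites")
    small = sorted(counts[counts < 2].index)
    if small:
        raise HarmonizationError(f"every site needs >= 2 subjects; too small: {small}")
    return ValidatedDemographics(table.reset_index(drop=True))


def apply_mask(stack: Sequence[np.ndarray], mask: MaskSpec,
               subject_ids: Sequence | None = None) -> FeatureMatrix:
    """Mask a stack of per-subject arrays into a subjects x features matrix.

    Feature order is a fixed row-major (last axis fastest) traversal of the
    stored array, so outputs are reproducible across machines.  ``kind=none``
    includes every cell but emits a warning: harmonizing unmasked grids drags
    in uninformative zero cells.
    """
    arrays = [np.asarray(a, dtype=float) for a in stack]
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise HarmonizationError(
                f"subject {i} has shape {a.shape}, expected {shape}; the mask must match the size of the input data"
            )
    if mask.kind == "none":
        warnings.warn(
            "no mask supplied: including every cell is permitted but not recommended",
            UserWarning, stacklevel=2,
        )
        flat = np.ones(shape, dtype=bool)
        space = "volume" if len(shape) == 3 else "table"
        idx = list(np.flatnonzero(flat.ravel(order="C")))
        values = np.stack([a.ravel(order="C") for a in arrays])
    elif mask.kind == "volume":
        if mask.grid.shape != shape:
            raise HarmonizationError(
                f"mask shape {mask.grid.shape} does not match data shape {shape}"
            )
        sel = mask.grid.ravel(order="C")
        if not sel.any():
            raise HarmonizationError("mask selects zero cells")
        idx = list(np.flatnonzero(sel))
        values = np.stack([a.ravel(order="C")[sel] for a in arrays])
        space = "volume"
    else:
        raise HarmonizationError(f"apply_mask does not handle mask kind {mask.kind!r} directly")
    if subject_ids is None:
        subject_ids = list(range(len(arrays)))
    return FeatureMatrix(values, list(subject_ids), idx, space)


def unmask(matrix: FeatureMatrix, mask: MaskSpec, shape: tuple, fill: float = 0.0) -> list[np.ndarray]:
    """Inverse of :func:`apply_mask`: scatter features back onto the grid.

    Cells outside the mask get ``fill`` (default 0).  The round trip
    ``apply_mask(unmask(M)) == M`` is exact.
    """
    if mask.kind == "volume":
        sel = mask.grid.ravel(order="C")
    elif mask.kind == "none":
        sel = np.ones(int(np.prod(shape)), dtype=bool)
    else:
        raise HarmonizationError(f"unmask does not handle mask kind {mask.kind!r}")
    m = int(sel.sum())
    if matrix.n_features != m:
        raise HarmonizationError(
            f"matrix has {matrix.n_features} features but mask selects {m} cells"
        )
    out = []
    for row in matrix.values:
        flat = np.full(sel.shape, fill, dtype=float)
        flat[sel] = row
        out.append(flat.reshape(shape))
    return out


def vectorize_network(square: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, row-major (i<j, i then j)."""
    square = np.asarray(square, dtype=float)
    if square.ndim != 2 or square.shape[0] != square.shape[1]:
        raise HarmonizationError(f"network matrix must be square, got shape {square.shape}")
    if not np.all(np.isfinite(square)):
        raise HarmonizationError("network matrix contains non-finite values")
    iu = np.triu_indices(square.shape[0], k=1)
    return square[iu]


def rebuild_network(vector: np.ndarray, n: int, output: str = "upper") -> np.ndarray:
    """Rebuild an n x n matrix from a strict-upper-triangle vector.

    ``output="upper"`` (default) leaves the diagonal and lower triangle at 0 —
    the output network consists solely of the harmonized upper-triangular
    portion.  ``output="symmetric"`` mirrors the triangle for downstream tools
    that expect symmetry.
    """
    vector = np.asarray(vector, dtype=float)
    expect = n * (n - 1) // 2
    if vector.shape != (expect,):
        raise HarmonizationError(
            f"vector length {vector.size} does not match n(n-1)/2 = {expect} for n={n}"
        )
    if output not in ("upper", "symmetric"):
        raise HarmonizationError(f"unknown network output mode {output!r}")
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mat[iu] = vector
    if output == "symmetric":
        mat = mat + mat.T
    return mat


def network_feature_index(n: int) -> list:
    iu = np.triu_indices(n, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))
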