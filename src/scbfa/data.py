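"""Core matrix containers.

The canonical in-memory layout is cells x features everywhere; readers are
responsible for transposing 10x-style (features x cells) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValidationError(f"duplicate {what} id: {x!r}")
            seen.add(x)


@dataclass
class CountMatrix:
    """Nonnegative integer cells x features count matrix (raw observations O).

    Parameters
    ----------
    values
        Dense ``(n_cells, n_features)`` array of nonnegative integers.
    cell_ids, feature_ids
        Unique string identifiers for rows and columns.
    feature_is_mito
        Optional boolean mask flagging mitochondrial features; defaults to
        all-False when omitted.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    feature_is_mito: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d array")
        n, g = self.values.shape
        if n < 1 or g < 1:
            raise ValidationError("need at least one cell and one feature")
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.feature_ids) != g:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {g} columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.feature_ids, "feature")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative count at cell {self.cell_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=0, rtol=0):
                bad = np.argwhere(self.values != rounded)[0]
                i, j = bad
                raise ValidationError(
                    f"non-integer value {self.values[i, j]!r} at cell "
                    f"{self.cell_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
            self.values = rounded.astype(np.int64)
        if self.feature_is_mito is None:
            self.feature_is_mito = np.zeros(g, dtype=bool)
        else:
            self.feature_is_mito = np.asarray(self.feature_is_mito, dtype=bool)
            if self.feature_is_mito.shape != (g,):
                raise ValidationError("feature_is_mito length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def subset(self, cells=None, features=None) -> "CountMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        cells = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        features = (
            np.arange(self.n_features) if features is None else np.asarray(features)
        )
        return CountMatrix(
            values=self.values[np.ix_(cells, features)],
            cell_ids=self.cell_ids[cells],
            feature_ids=self.feature_ids[features],
            feature_is_mito=self.feature_is_mito[features],
        )


@dataclass
class DetectionMatrix:
    """Binary cells x features detection-pattern matrix B (B_ij = 1 iff O_ij >= 1)."""

    values: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d array")
        if not np.all(np.isin(self.values, (0, 1))):
            raise ValidationError("detection matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.feature_ids) != g:
            raise ValidationError("id/shape mismatch")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.feature_ids, "feature")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
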