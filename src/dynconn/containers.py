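"""Core in-memory containers shared across pipeline stages.

The pipeline's atomic input is a set of component time courses (one ICA
component per column, one repetition time (TR) per row).  Connectivity is
carried either as a full symmetric ``C x C`` matrix (:class:`ConnMatrix`,
static) or as a stack of windowed matrices (:class:`WindowStack`, dynamic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimecourseSet",
    "ConnMatrix",
    "WindowStack",
    "EdgeVarianceMatrix",
    "vec_upper",
    "unvec_upper",
]


def vec_upper(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (k=1) edge vector of a square matrix, row-major."""
    mat = np.asarray(mat)
    i, j = np.triu_indices(mat.shape[-1], k=1)
    return mat[..., i, j]


def unvec_upper(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vec_upper`: symmetric matrix with zero diagonal."""
    out = np.zeros((n, n), dtype=float)
    i, j = np.triu_indices(n, k=1)
    out[i, j] = vec
    out[j, i] = vec
    return out


@dataclass
class TimecourseSet:
    """One subject's component time courses.

    Parameters
    ----------
    subject_id : str
    data : ndarray, shape (T, C)
        One row per TR, one column per component. Arbitrary signal units.
    tr_seconds : float
        Repetition time in seconds.
    component_ids : list of str
        Column labels; defaults to ``IC01..ICxx``.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-course data must be 2-D (T x C)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-course data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.component_ids:
            self.component_ids = [
                f"IC{k + 1:02d}" for k in range(self.data.shape[1])
            ]
        if len(self.component_ids) != self.data.shape[1]:
            raise ValueError("component_ids length must match column count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "TimecourseSet":
        """Copy of this set with ``data`` replaced (same id, TR, components)."""
        return TimecourseSet(
            subject_id=self.subject_id,
            data=np.asarray(data, dtype=float),
            tr_seconds=self.tr_seconds,
            component_ids=list(self.component_ids),
        )


@dataclass
class ConnMatrix:
    """Symmetric component-by-component connectivity matrix.

    ``scale`` records whether values are raw Pearson r (diagonal 1) or
    Fisher z = atanh(r) (diagonal excluded from all edge statistics).
    """

    values: np.ndarray
    scale: str  # "pearson_r" | "fisher_z"
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if not self.component_ids:
            self.component_ids = [
                f"IC{k + 1:02d}" for k in range(self.values.shape[0])
            ]

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle edges as a flat vector (diagonal excluded)."""
        return vec_upper(self.values)


@dataclass
class WindowStack:
    """Stack of windowed Fisher-z connectivity matrices for one subject.

    ``windows`` has shape (W, C, C); ``onsets`` holds each window's start
    index into the conditioned time course (step-1 sliding by default).
    """

    windows: np.ndarray
    window_length_tr: int
    sigma_tr: float
    step_tr: int
    onsets: np.ndarray
    component_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.windows.ndim != 3 or self.windows.shape[1] != self.windows.shape[2]:
            raise ValueError("windows must have shape (W, C, C)")
        if self.onsets.shape[0] != self.windows.shape[0]:
            raise ValueError("onsets length must equal window count")
        if not self.component_ids:
            self.component_ids = [
                f"IC{k + 1:02d}" for k in range(self.windows.shape[1])
            ]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_components(self) -> int:
        return self.windows.shape[1]

    def edge_matrix(self) -> np.ndarray:
        """(W, E) matrix of upper-triangle edge vectors, one row per window."""
        return vec_upper(self.windows)


@dataclass
class EdgeVarianceMatrix:
    """Per-edge temporal variance of windowed connectivity (zero diagonal)."""

    values: np.ndarray
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("variance matrix must be non-negative")
        if not self.component_ids:
            self.component_ids = [
                f"IC{k + 1:02d}" for k in range(self.values.shape[0])
            ]

    def edge_vector(self) -> np.ndarray:
        return vec_upper(self.values)
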