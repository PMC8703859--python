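"""Diffusion gradient tables (b-values and gradient directions).

A gradient table pairs each acquired volume with its diffusion weighting:
the b-value in s/mm^2 and the unit gradient direction. The FSL text dialect
is used on disk: ``bval`` is one whitespace-separated line of b-values,
``bvec`` is three lines holding the x, y and z components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientTable", "make_gradient_table", "read_bval_bvec", "write_bval_bvec"]

# directions below this b-value are treated as unweighted (b0) acquisitions
B0_THRESHOLD = 50.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class GradientTable:
    """Acquisition geometry: per-volume b-values and unit directions.

    Parameters
    ----------
    bvals : ndarray, shape (n,)
        Diffusion weighting per volume, s/mm^2.
    bvecs : ndarray, shape (n, 3)
        Gradient directions; unit norm wherever ``bvals > 0``.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    _b0_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must have shape (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals length {bvals.shape[0]} != bvecs length {bvecs.shape[0]}"
            )
        if not (np.all(np.isfinite(bvals)) and np.all(np.isfinite(bvecs))):
            raise ValueError("gradient table contains non-finite entries")
        b0 = bvals <= B0_THRESHOLD
        if not b0.any():
            raise ValueError("gradient table needs at least one b=0 volume")
        norms = np.linalg.norm(bvecs[~b0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("every b>0 direction must have unit norm (tol 1e-6)")
        if _n_independent_directions(bvecs[~b0]) < 6:
            raise ValueError("insufficient directions for tensor fit")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "_b0_mask", b0)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of unweighted (b ~ 0) volumes."""
        return self._b0_mask

    @property
    def n_directions(self) -> int:
        return int((~self._b0_mask).sum())


def _n_independent_directions(dirs: np.ndarray) -> int:
    """Rank of the 6-column tensor design built from the directions.

    A unique tensor fit needs rank 6, which requires >= 6 suitably spread
    (non-collinear, non-coplanar) directions.
    """
    if dirs.shape[0] < 6:
        return dirs.shape[0]
    g = dirs
    design = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    return int(np.linalg.matrix_rank(design))


def make_gradient_table(n_dirs: int, b: float = 1000.0, n_b0: int = 1) -> GradientTable:
    """Build a deterministic single-shell table: ``n_b0`` b0s then ``n_dirs``
    directions laid out by the spherical Fibonacci spiral (approximately
    uniform on the sphere).

    Raises
    ------
    ValueError
        If ``n_dirs < 6`` ("insufficient directions for tensor fit").
    """
    if n_dirs < 6:
        raise ValueError("insufficient directions for tensor fit")
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    if n_dirs == 6:
        # the 6-point Fibonacci spiral is degenerate for the tensor design
        # (rank 5); use the classic icosahedral six-direction scheme instead
        dirs = np.array(
            [
                [1, 1, 0], [1, -1, 0],
                [1, 0, 1], [1, 0, -1],
                [0, 1, 1], [0, 1, -1],
            ],
            dtype=float,
        ) / np.sqrt(2.0)
    else:
        i = np.arange(n_dirs)
        z = 1.0 - 2.0 * (i + 0.5) / n_dirs
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
        phi = i * _GOLDEN_ANGLE
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read an FSL-dialect bval/bvec pair."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # FSL convention: rows are components
        bvecs = bvecs.T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_bval_bvec(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write an FSL-dialect bval (one line) / bvec (three lines) pair."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(_fmt(v) for v in gtab.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(_fmt(v) for v in gtab.bvecs[:, axis]) + "\n")


def _fmt(v: float) -> str:
    return f"{v:.10g}"
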