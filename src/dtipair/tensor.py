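"""Diffusion tensor fitting and scalar metric maps.

Per voxel, water diffusion is modelled by a symmetric 3x3 tensor D (mm^2/s)
entering the single-tensor signal equation

    S(b, g) = S0 * exp(-b * g^T D g)

so that ln(S/S0) is linear in the six unique tensor components. The fit here
is ordinary (unweighted) log-linear least squares; S0 is the mean of the b=0
volumes. From the sorted eigenvalues l1 >= l2 >= l3 six scalar metrics are
derived:

    MD     = (l1 + l2 + l3) / 3
    FA     = sqrt(3/2) * ||l - MD|| / ||l||            (0 isotropic, 1 linear)
    AD     = l1
    RD1    = l2,  RD2 = l3
    TSkew  = (1/3) * sum_i (l_i - MD)^3
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gradients import GradientTable

__all__ = [
    "DWIVolume",
    "DiffusionTensorField",
    "EigenSystem",
    "ScalarMaps",
    "METRIC_NAMES",
    "fit_tensor_loglinear",
    "eigendecompose",
    "md_of",
    "fa_of",
    "tskew_of",
    "compute_scalar_maps",
]

METRIC_NAMES = ("FA", "MD", "AD", "RD1", "RD2", "TSkew")

# unique-component storage order used throughout the package
COMPONENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# floor applied to the signal (relative to S0) before taking the log, so
# noise-dominated voxels cannot produce -inf
SIGNAL_FLOOR_REL = 1e-6


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition plus its gradient table."""

    signal: np.ndarray  # (x, y, z, n_volumes), arbitrary intensity units
    gtab: GradientTable
    voxel_size: np.ndarray | tuple = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got ndim={self.signal.ndim}")
        if self.signal.shape[3] != len(self.gtab):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but gradient table "
                f"has {len(self.gtab)} entries"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class DiffusionTensorField:
    """Six unique tensor components per voxel plus the fitted mask.

    ``components`` has shape (x, y, z, 6) in the order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz), units mm^2/s. Voxels outside ``mask``
    hold zeros.
    """

    components: np.ndarray
    mask: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Return the field as full symmetric 3x3 matrices, shape (x,y,z,3,3)."""
        c = self.components
        m = np.zeros(c.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m


@dataclass
class EigenSystem:
    """Sorted eigen-structure of a single diffusion tensor.

    ``eigenvalues`` descend (l1 >= l2 >= l3); ``eigenvectors`` columns are the
    matching unit eigenvectors (v1, v2, v3). Negative eigenvalues are kept
    (not clamped) and flagged via ``has_negative``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.eigenvalues < 0))


@dataclass
class ScalarMaps:
    """The six per-voxel scalar metric volumes plus the shared mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    n_negative_eigenvalue_voxels: int = 0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    """Rows b * (gx^2, 2 gx gy, 2 gx gz, gy^2, 2 gy gz, gz^2) for the b>0 volumes."""
    g = gtab.bvecs[~gtab.b0_mask]
    b = gtab.bvals[~gtab.b0_mask][:, None]
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            g[:, 1] ** 2,
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ]
    )


def fit_tensor_loglinear(dwi: DWIVolume, mask: np.ndarray | None = None) -> DiffusionTensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    S0 is the mean of the b=0 volumes; each masked voxel solves
    ``ln(S/S0) = -b g^T D g`` over the six unique components. Signals are
    floored at ``SIGNAL_FLOOR_REL * S0`` before the log.

    Raises
    ------
    ValueError
        If the gradient scheme cannot determine six components
        ("degenerate gradient scheme"), or the mask includes voxels with
        non-positive S0.
    """
    gtab = dwi.gtab
    design = _design_matrix(gtab)
    if design.shape[0] < 6 or np.linalg.matrix_rank(design) < 6:
        raise ValueError("degenerate gradient scheme")
    if mask is None:
        mask = np.ones(dwi.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.grid_shape:
        raise ValueError("mask shape does not match DWI grid")

    s0 = dwi.signal[..., gtab.b0_mask].mean(axis=-1)
    if np.any(s0[mask] <= 0):
        raise ValueError("mask contains voxels with non-positive b0 signal")

    sig = dwi.signal[..., ~gtab.b0_mask][mask]  # (n_vox, n_dirs)
    s0m = s0[mask][:, None]
    floored = np.maximum(sig, SIGNAL_FLOOR_REL * s0m)
    y = np.log(floored / s0m)  # (n_vox, n_dirs)

    # same design for every voxel: one pseudoinverse, applied to all voxels
    coefs = -(np.linalg.pinv(design) @ y.T).T  # (n_vox, 6)

    components = np.zeros(dwi.grid_shape + (6,), dtype=float)
    components[mask] = coefs
    return DiffusionTensorField(components=components, mask=mask)


def eigendecompose(components: np.ndarray) -> EigenSystem:
    """Eigen-structure of one tensor given its six unique components.

    Eigenvalues are sorted descending; eigenvectors are orthonormal. Negative
    eigenvalues are preserved (flagged on the returned object, not clamped).
    """
    c = np.asarray(components, dtype=float).ravel()
    if c.shape != (6,):
        raise ValueError("expected 6 unique tensor components")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite tensor components")
    m = np.array(
        [
            [c[0], c[1], c[2]],
            [c[1], c[3], c[4]],
            [c[2], c[4], c[5]],
        ]
    )
    vals, vecs = np.linalg.eigh(m)  # ascending
    order = np.argsort(vals)[::-1]
    return EigenSystem(eigenvalues=vals[order], eigenvectors=vecs[:, order])


def md_of(l1: float, l2: float, l3: float) -> float:
    """Mean diffusivity: arithmetic mean of the three eigenvalues."""
    return (l1 + l2 + l3) / 3.0


def fa_of(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy, sqrt(3/2) * ||l - MD|| / ||l||.

    Returns 0 when all eigenvalues are zero. In [0, 1] for non-negative
    eigenvalues.
    """
    lam = np.array([l1, l2, l3], dtype=float)
    norm2 = float(np.dot(lam, lam))
    if norm2 == 0.0:
        return 0.0
    md = lam.mean()
    dev = lam - md
    return float(np.sqrt(1.5 * np.dot(dev, dev) / norm2))


def tskew_of(l1: float, l2: float, l3: float) -> float:
    """Tensor skewness, the third moment of the eigenvalues about MD:
    (1/3) * sum_i (l_i - MD)^3, units (mm^2/s)^3."""
    lam = np.array([l1, l2, l3], dtype=float)
    dev = lam - lam.mean()
    return float(np.sum(dev**3) / 3.0)


def compute_scalar_maps(field: DiffusionTensorField) -> ScalarMaps:
    """Compute FA, MD, AD, RD1, RD2 and TSkew maps over the field's mask.

    Voxels outside the mask are zero. Negative eigenvalues are used as-is
    (FA may exceed 1 there); their voxel count is reported for QC.
    """
    mask = field.mask
    shape = field.components.shape[:-1]
    maps = {name: np.zeros(shape, dtype=float) for name in METRIC_NAMES}
    if not mask.any():
        warnings.warn("empty mask: scalar maps are all zero", stacklevel=2)
        return ScalarMaps(maps=maps, mask=mask)

    matrices = field.as_matrices()[mask]  # (n_vox, 3, 3)
    if not np.all(np.isfinite(matrices)):
        bad = np.argwhere(mask)[~np.all(np.isfinite(matrices.reshape(len(matrices), -1)), axis=1)]
        raise ValueError(f"non-finite tensor components at voxels {bad[:5].tolist()}")
    vals = np.linalg.eigvalsh(matrices)[:, ::-1]  # descending: l1 >= l2 >= l3

    l1, l2, l3 = vals[:, 0], vals[:, 1], vals[:, 2]
    md = vals.mean(axis=1)
    dev = vals - md[:, None]
    norm2 = np.einsum("ij,ij->i", vals, vals)
    fa = np.zeros_like(md)
    nz = norm2 > 0
    fa[nz] = np.sqrt(1.5 * np.einsum("ij,ij->i", dev, dev)[nz] / norm2[nz])
    tskew = (dev**3).sum(axis=1) / 3.0

    for name, arr in zip(METRIC_NAMES, (fa, md, l1, l2, l3, tskew)):
        maps[name][mask] = arr
    n_neg = int(np.count_nonzero((vals < 0).any(axis=1)))
    return ScalarMaps(maps=maps, mask=mask, n_negative_eigenvalue_voxels=n_neg)


def save_scalar_maps(maps: ScalarMaps, out_dir: str | Path, subject_id: str,
                     affine: np.ndarray | None = None) -> list[Path]:
    """Write one 3D NIfTI per metric, named ``<subject>_<metric>.nii.gz``."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    written = []
    for name in METRIC_NAMES:
        path = out_dir / f"{subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(maps[name].astype(np.float64), affine), path)
        written.append(path)
    return written
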