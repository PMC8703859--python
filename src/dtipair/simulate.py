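"""Synthetic diffusion-MRI cohorts with known ground truth.

Two generators back the test surface of the whole pipeline:

* :func:`simulate_subject_dwi` builds a DWI phantom voxel by voxel: each
  atlas region gets a ground-truth diffusion tensor (physiological
  white-matter eigenvalues, randomized principal direction), the noiseless
  signal follows the single-tensor equation S = S0 exp(-b g^T D g), and
  magnitude noise is Rician — sqrt((S + e1)^2 + e2^2) with Gaussian channel
  noise of scale ``noise_sigma``.

* :func:`simulate_feature_cohort` is the fast path: it emits per-subject
  regional feature matrices directly from a latent Gaussian model in which
  chosen region pairs share a latent component only in the case class, so
  the planted group difference lives exactly in the inter-region
  correlations the pipeline is built to detect. The generated matrices are
  pushed through the real pair-correlation stage.

Both are deterministic given (config, seed). Neither claims distributional
realism beyond the documented structure; they define controlled conditions,
not data facsimiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .correlation import (
    CohortMatrix,
    assemble_cohort,
    pair_correlation_matrix,
    pair_feature_names,
    pair_index,
    upper_triangle_vector,
)
from .gradients import GradientTable, write_bval_bvec
from .regional import FEATURE_COLUMNS, load_region_table
from .tensor import DWIVolume

__all__ = [
    "SimulationConfig",
    "LabelVolume",
    "make_label_volume",
    "simulate_subject_dwi",
    "simulate_feature_cohort",
    "rician_noise",
    "write_subject_dataset",
]

# physiological white-matter baseline eigenvalues, mm^2/s
BASE_EIGENVALUES = (1.7e-3, 0.4e-3, 0.3e-3)

#: default planted pairs (1-based JHU ids): anterior limb of internal
#: capsule L & uncinate fasciculus R; body of corpus callosum & tapetum L;
#: middle cerebellar peduncle & inferior cerebellar peduncle R
DEFAULT_AFFECTED_PAIRS = ((18, 45), (4, 48), (1, 11))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for both generators.

    ``effect_size`` is the relative eigenvalue perturbation for the DWI
    generator and the latent coupling strength for the feature generator
    (coupling correlation = effect_size / (1 + effect_size)). ``noise_sigma``
    defaults to s0/30, a mid-range magnitude-SNR regime.
    """

    n_per_class: int = 60
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 48
    affected_pairs: tuple[tuple[int, int], ...] = DEFAULT_AFFECTED_PAIRS
    effect_size: float = 1.5
    s0: float = 1000.0
    noise_sigma: float | None = None  # None -> s0 / 30
    profile_scale: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for l, m in self.affected_pairs:
            if not (1 <= l <= self.n_regions and 1 <= m <= self.n_regions and l != m):
                raise ValueError(f"invalid affected pair ({l}, {m})")

    @property
    def sigma(self) -> float:
        return self.s0 / 30.0 if self.noise_sigma is None else float(self.noise_sigma)


@dataclass(frozen=True)
class LabelVolume:
    """3D integer region labels; ids 1..n_regions, 0 = background."""

    labels: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int32)
        present = np.unique(labels)
        if present.min() < 0 or present.max() > self.n_regions:
            raise ValueError("label ids must lie in 0..n_regions")
        missing = set(range(1, self.n_regions + 1)) - set(int(v) for v in present)
        if missing:
            raise ValueError(f"regions with no voxels: {sorted(missing)[:5]}")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


def make_label_volume(grid_shape: tuple[int, int, int], n_regions: int = 48,
                      background_shell: int = 0) -> LabelVolume:
    """Deterministically partition a grid into ``n_regions`` contiguous blocks.

    Interior voxels (after stripping an optional background shell) are split
    into near-equal runs in C order, so every region is a contiguous slab.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    labels = np.zeros(grid_shape, dtype=np.int32)
    sl = tuple(
        slice(background_shell, s - background_shell) if s > 2 * background_shell else slice(None)
        for s in grid_shape
    )
    interior = labels[sl]
    n_vox = interior.size
    if n_vox < n_regions:
        raise ValueError(
            f"grid interior has {n_vox} voxels, fewer than {n_regions} regions"
        )
    flat = np.zeros(n_vox, dtype=np.int32)
    bounds = np.linspace(0, n_vox, n_regions + 1).astype(int)
    for rid in range(1, n_regions + 1):
        flat[bounds[rid - 1] : bounds[rid]] = rid
    labels[sl] = flat.reshape(interior.shape)
    return LabelVolume(labels=labels, n_regions=n_regions)


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI (Rician) noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    e1 = rng.normal(0.0, sigma, size=np.shape(signal))
    e2 = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.sqrt((signal + e1) ** 2 + e2**2)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix (sign-fixed)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _region_tensors(config: SimulationConfig, class_label: int, seed: int) -> np.ndarray:
    """Ground-truth 3x3 tensors per region id (index 0 unused).

    Directions depend only on the seed (shared across classes); the case
    class scales the eigenvalues of regions in affected pairs by
    (1 + effect_size).
    """
    affected = {r for pair in config.affected_pairs for r in pair}
    base = np.array(BASE_EIGENVALUES)
    tensors = np.zeros((config.n_regions + 1, 3, 3))
    root = np.random.SeedSequence([seed, 1009])
    for rid, child in zip(range(1, config.n_regions + 1), root.spawn(config.n_regions)):
        rng = np.random.default_rng(child)
        rot = _random_rotation(rng)
        evals = base.copy()
        if class_label == 1 and rid in affected:
            evals = evals * (1.0 + config.effect_size)
        tensors[rid] = rot @ np.diag(evals) @ rot.T
    return tensors


def simulate_subject_dwi(
    config: SimulationConfig,
    class_label: int,
    labels: LabelVolume,
    gtab: GradientTable,
    seed: int,
) -> tuple[DWIVolume, dict]:
    """Simulate one subject's 4D DWI volume on a labelled grid.

    Returns (volume, ground_truth) where the ground truth carries the
    per-region tensors, the class label and the noise scale. Background
    voxels (label 0) hold pure noise around zero signal.
    """
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    if labels.shape != tuple(config.grid_shape):
        raise ValueError("label volume does not match config grid_shape")
    tensors = _region_tensors(config, class_label, config.seed)

    b = gtab.bvals  # (n_vol,)
    g = gtab.bvecs  # (n_vol, 3)
    # quadratic form g^T D g for every (region, volume)
    quad = np.einsum("vi,rij,vj->rv", g, tensors, g)  # (n_regions+1, n_vol)
    decay = np.exp(-b[None, :] * quad)
    region_signal = config.s0 * decay
    region_signal[0] = 0.0  # background

    signal = region_signal[labels.labels]  # (x, y, z, n_vol)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2003, seed, class_label]))
    noisy = rician_noise(signal, config.sigma, rng)
    dwi = DWIVolume(signal=noisy, gtab=gtab)
    ground_truth = {
        "class_label": class_label,
        "noise_sigma": config.sigma,
        "s0": config.s0,
        "effect_size": config.effect_size,
        "affected_pairs": [list(p) for p in config.affected_pairs],
        "tensors": {str(r): tensors[r].tolist() for r in range(1, config.n_regions + 1)},
    }
    return dwi, ground_truth


def _subject_feature_matrix(
    config: SimulationConfig,
    class_label: int,
    profile: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One latent-model regional matrix (n_regions x 18).

    Row r = profile + e_r with unit Gaussian e_r; in the case class each
    affected pair mixes a shared latent w into both rows with weight
    a = effect_size / (1 + effect_size), giving within-pair correlation a
    on top of the profile-induced baseline.
    """
    n_stats = len(FEATURE_COLUMNS)
    noise = rng.normal(size=(config.n_regions, n_stats))
    if class_label == 1 and config.effect_size > 0:
        a = config.effect_size / (1.0 + config.effect_size)
        for l, m in config.affected_pairs:
            w = rng.normal(size=n_stats)
            for r in (l, m):
                noise[r - 1] = np.sqrt(1.0 - a) * noise[r - 1] + np.sqrt(a) * w
    else:
        # burn the same number of draws so class 0/1 streams stay aligned
        if config.effect_size > 0:
            for _ in config.affected_pairs:
                rng.normal(size=n_stats)
    return profile[None, :] + noise


def simulate_feature_cohort(config: SimulationConfig) -> CohortMatrix:
    """Generate a labelled cohort of pair-correlation feature vectors.

    Per-subject regional matrices come from the latent coupling model; the
    real pair-correlation stage (correlation matrix + upper-triangle
    serialization) then produces F-hat. Ground-truth planted pair feature
    indices are recorded on the returned cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3001]))
    profile = config.profile_scale * rng.normal(size=len(FEATURE_COLUMNS))

    vectors, labels, ids = [], [], []
    for class_label in (0, 1):
        for i in range(config.n_per_class):
            mat = _subject_feature_matrix(config, class_label, profile, rng)
            corr, flagged = pair_correlation_matrix(mat)
            vectors.append(upper_triangle_vector(corr, flagged))
            labels.append(class_label)
            ids.append(f"sub-c{class_label}-{i:04d}")

    if config.n_regions == 48:
        names = pair_feature_names(load_region_table())
    else:
        names = [f"pair:{l}|{m}" for l in range(1, config.n_regions + 1)
                 for m in range(l + 1, config.n_regions + 1)]
    cohort = assemble_cohort(vectors, labels, ids, names, representation="corr")
    planted = sorted(
        pair_index(min(l, m), max(l, m), config.n_regions) for l, m in config.affected_pairs
    )
    cohort.ground_truth = {
        "planted_pair_indices": planted,
        "affected_pairs": [list(p) for p in config.affected_pairs],
        "effect_size": config.effect_size,
        "seed": config.seed,
        "model": "shared-profile latent Gaussian; case-only pair coupling "
                 "a = effect_size/(1+effect_size)",
    }
    return cohort


def write_subject_dataset(
    dwi: DWIVolume,
    labels: LabelVolume,
    ground_truth: dict,
    out_dir: str | Path,
    subject_id: str,
) -> dict[str, Path]:
    """Write one subject to disk: 4D NIfTI, FSL bval/bvec, label NIfTI and a
    JSON ground-truth sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths = {
        "dwi": out_dir / f"{subject_id}_dwi.nii.gz",
        "bval": out_dir / f"{subject_id}.bval",
        "bvec": out_dir / f"{subject_id}.bvec",
        "labels": out_dir / f"{subject_id}_labels.nii.gz",
        "truth": out_dir / f"{subject_id}_truth.json",
    }
    nib.save(nib.Nifti1Image(dwi.signal.astype(np.float64), affine), paths["dwi"])
    write_bval_bvec(dwi.gtab, paths["bval"], paths["bvec"])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int32), affine), paths["labels"])
    with open(paths["truth"], "w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
    return paths
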