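"""Atlas-region aggregation of scalar maps into per-subject feature matrices.

Each subject's six scalar metric volumes are reduced over the 48 regions of
the JHU ICBM-DTI-81 white-matter atlas to three summary statistics per
metric — mean, standard deviation (ddof=1) and moment skewness g1 — giving
a 48 x 18 matrix F per subject. Column order is metric-major
(FA, MD, AD, RD1, RD2, TSkew), statistic-minor (mu, sd, sk).

A subject-level QC rule rejects subjects whose metric volumes are mostly
"blank" (zero) inside the brain mask, the signature of a failed upstream fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor import METRIC_NAMES, ScalarMaps

__all__ = [
    "RegionTable",
    "SubjectFeatures",
    "FEATURE_COLUMNS",
    "STAT_NAMES",
    "load_region_table",
    "extract_region_values",
    "summary_stats",
    "build_subject_matrix",
    "qc_subject",
    "flatten_subject",
    "unflatten_subject",
]

STAT_NAMES = ("mu", "sd", "sk")

#: the frozen 18-column order: FA_mu, FA_sd, FA_sk, MD_mu, ..., TSkew_sk
FEATURE_COLUMNS = tuple(f"{m}_{s}" for m in METRIC_NAMES for s in STAT_NAMES)

N_REGIONS = 48
N_FEATURES_FLAT = N_REGIONS * len(FEATURE_COLUMNS)  # 864


@dataclass(frozen=True)
class RegionTable:
    """Ordered (label id, region name) pairs for an atlas parcellation."""

    ids: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.names):
            raise ValueError("ids and names differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("region ids must be unique")
        if list(self.ids) != list(range(1, len(self.ids) + 1)):
            raise ValueError("region ids must be 1..n in order")

    def __len__(self) -> int:
        return len(self.ids)

    def name_of(self, region_id: int) -> str:
        return self.names[region_id - 1]


def load_region_table(path: str | Path | None = None) -> RegionTable:
    """Load a region table TSV (columns region_id, region_name).

    With no path, the packaged JHU ICBM-DTI-81 48-region table is returned.
    """
    if path is None:
        source = resources.files("dtipair.data").joinpath("jhu_regions.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return RegionTable(
        ids=tuple(int(i) for i in df["region_id"]),
        names=tuple(str(n) for n in df["region_name"]),
    )


@dataclass
class SubjectFeatures:
    """Per-subject regional feature matrix F.

    ``values`` is (n_regions, 18) in the FEATURE_COLUMNS order. ``missing``
    flags cells whose statistic was undefined (too few voxels or zero
    variance); such cells hold 0. ``voxel_counts`` records region sizes.
    """

    subject_id: str
    values: np.ndarray
    missing: np.ndarray
    voxel_counts: np.ndarray
    region_table: RegionTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing shape mismatch")
        if self.values.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError(f"expected {len(FEATURE_COLUMNS)} columns")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def region_missing(self) -> np.ndarray:
        """Regions with no voxels at all."""
        return self.voxel_counts == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(FEATURE_COLUMNS))
        df.insert(0, "region_id", np.arange(1, self.n_regions + 1))
        names = (
            list(self.region_table.names)
            if self.region_table is not None and len(self.region_table) == self.n_regions
            else [f"region_{i}" for i in range(1, self.n_regions + 1)]
        )
        df.insert(1, "region_name", names)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def extract_region_values(scalar_map: np.ndarray, labels: np.ndarray, region_id: int) -> np.ndarray:
    """Values of a scalar volume at voxels carrying ``region_id``.

    An absent region yields an empty array (handled downstream) with a
    warning.
    """
    if region_id < 1:
        raise ValueError("region ids start at 1")
    vals = np.asarray(scalar_map)[np.asarray(labels) == region_id]
    if vals.size == 0:
        warnings.warn(f"region {region_id} has no voxels", stacklevel=2)
    return vals


def summary_stats(values: np.ndarray) -> tuple[tuple[float, float, float], tuple[bool, bool, bool]]:
    """(mu, sd, sk) of a value list plus per-statistic missing flags.

    mu needs >= 1 value, sd (ddof=1) needs >= 2, skewness g1 = m3 / m2^(3/2)
    needs >= 3 values and nonzero variance. Undefined statistics are
    reported as 0 and flagged.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n == 0:
        return (0.0, 0.0, 0.0), (True, True, True)
    mu = float(v.mean())
    if n < 2:
        return (mu, 0.0, 0.0), (False, True, True)
    sd = float(v.std(ddof=1))
    m2 = float(np.mean((v - mu) ** 2))
    if n < 3 or m2 == 0.0:
        return (mu, sd, 0.0), (False, False, True)
    m3 = float(np.mean((v - mu) ** 3))
    sk = m3 / m2**1.5
    return (mu, sd, sk), (False, False, False)


def build_subject_matrix(
    maps: ScalarMaps,
    labels: np.ndarray,
    regions: RegionTable,
    subject_id: str = "subject",
) -> SubjectFeatures:
    """Aggregate the six metric maps over every atlas region into F.

    Missing regions are flagged and the run continues; rejection decisions
    belong to :func:`qc_subject` alone.
    """
    labels = np.asarray(labels)
    any_map = maps[METRIC_NAMES[0]]
    if labels.shape != any_map.shape:
        raise ValueError(
            f"label grid {labels.shape} does not match map grid {any_map.shape}"
        )
    n = len(regions)
    values = np.zeros((n, len(FEATURE_COLUMNS)))
    missing = np.zeros_like(values, dtype=bool)
    counts = np.zeros(n, dtype=int)
    for r_idx, rid in enumerate(regions.ids):
        where = labels == rid
        counts[r_idx] = int(where.sum())
        if counts[r_idx] == 0:
            warnings.warn(
                f"region {rid} ({regions.name_of(rid)}) has no voxels; "
                "row flagged missing",
                stacklevel=2,
            )
        for m_idx, metric in enumerate(METRIC_NAMES):
            vals = maps[metric][where]
            (mu, sd, sk), flags = summary_stats(vals)
            col = 3 * m_idx
            values[r_idx, col : col + 3] = (mu, sd, sk)
            missing[r_idx, col : col + 3] = flags
    return SubjectFeatures(
        subject_id=subject_id,
        values=values,
        missing=missing,
        voxel_counts=counts,
        region_table=regions,
    )


def qc_subject(
    maps: ScalarMaps,
    mask: np.ndarray,
    zero_fraction_threshold: float = 0.5,
) -> tuple[bool, dict]:
    """Blank-volume QC: fail a subject whose metric maps are mostly zero.

    The subject fails if, in any metric volume, the fraction of zero-valued
    voxels inside the mask exceeds the threshold. Returns (passed, report)
    where the report carries the per-metric zero fractions.
    """
    if not 0.0 < zero_fraction_threshold < 1.0:
        raise ValueError("zero_fraction_threshold must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    report: dict = {"threshold": zero_fraction_threshold, "zero_fractions": {}}
    if not mask.any():
        report["reason"] = "empty mask"
        return False, report
    n = mask.sum()
    passed = True
    for metric in METRIC_NAMES:
        frac = float(np.count_nonzero(maps[metric][mask] == 0.0) / n)
        report["zero_fractions"][metric] = frac
        if frac > zero_fraction_threshold:
            passed = False
    if not passed:
        report["reason"] = "zero fraction above threshold"
    return passed, report


def save_qc_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def flatten_subject(features: SubjectFeatures) -> np.ndarray:
    """Row-major flattening of F: region 1's 18 columns first, then region 2,
    ...; for the 48-region atlas the result has exactly 864 entries."""
    return features.values.ravel().copy()


def unflatten_subject(flat: np.ndarray, n_regions: int = N_REGIONS) -> np.ndarray:
    """Inverse of :func:`flatten_subject` (values only)."""
    flat = np.asarray(flat, dtype=float)
    return flat.reshape(n_regions, len(FEATURE_COLUMNS))


def flat_feature_names(regions: RegionTable) -> list[str]:
    """Names for the flattened-F representation, aligned with flatten_subject."""
    return [f"{name}|{col}" for name in regions.names for col in FEATURE_COLUMNS]
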