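"""Interpretability outputs: ranked region-pair importances and
selected-feature-type histograms.

A selected pair-correlation feature is mapped back to its two atlas region
names via the inverse of the serialization index; linear-kernel selections
carry signed coefficients (negative = the pair's correlation votes against
the case class), which are ranked by magnitude.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import n_pairs, pair_from_index
from .regional import FEATURE_COLUMNS, STAT_NAMES, RegionTable
from .selection import SelectionResult
from .tensor import METRIC_NAMES

__all__ = [
    "PairImportance",
    "name_pairs",
    "importance_table",
    "selection_histogram",
    "write_report",
]


@dataclass(frozen=True)
class PairImportance:
    region_l: str
    region_m: str
    coefficient: float
    rank: int


def name_pairs(
    selected_indices,
    regions: RegionTable,
) -> list[tuple[str, str]]:
    """Region-name pairs for serialized pair-feature indices (index-formula
    inverse)."""
    n = len(regions)
    limit = n_pairs(n)
    out = []
    for idx in np.asarray(selected_indices, dtype=int).ravel():
        if not 0 <= idx < limit:
            raise ValueError(f"pair index {idx} out of range 0..{limit - 1}")
        l, m = pair_from_index(int(idx), n)
        out.append((regions.name_of(l), regions.name_of(m)))
    return out


def importance_table(
    selection: SelectionResult,
    regions: RegionTable,
    top_n: int = 50,
) -> list[PairImportance]:
    """Top pairs by |coefficient|, sign preserved, stable order.

    Forest-kernel selections have unsigned importances; they are reported
    as-is with a warning (the sign column then means magnitude only).
    """
    if selection.coefficients is None:
        raise ValueError("selection carries no importance coefficients")
    coefs = np.asarray(selection.coefficients, dtype=float)
    if not selection.signed:
        warnings.warn(
            "forest-kernel importances are unsigned; coefficients are magnitudes",
            stacklevel=2,
        )
    if np.all(coefs == 0):
        warnings.warn("all importance coefficients are zero; empty table", stacklevel=2)
        return []
    pairs = name_pairs(selection.selected_indices, regions)
    order = np.argsort(-np.abs(coefs), kind="stable")[: min(top_n, coefs.size)]
    return [
        PairImportance(
            region_l=pairs[i][0],
            region_m=pairs[i][1],
            coefficient=float(coefs[i]),
            rank=rank + 1,
        )
        for rank, i in enumerate(order)
    ]


def selection_histogram(selected_indices, representation: str = "summary",
                        n_regions: int = 48) -> dict:
    """Occurrence counts of selected features by type.

    For the flattened summary representation: counts over the six metrics
    and over the three statistics (each selected feature contributes one
    count to each family; both families sum to the selection size). For the
    pair-correlation representation a single feature has no metric/statistic
    identity, so per-region degree counts are returned instead.
    """
    idx = np.asarray(selected_indices, dtype=int).ravel()
    if representation == "summary":
        n_cols = len(FEATURE_COLUMNS)
        if idx.size and (idx.min() < 0 or idx.max() >= n_regions * n_cols):
            raise ValueError("summary feature index out of range")
        metric_counts = {m: 0 for m in METRIC_NAMES}
        stat_counts = {s: 0 for s in STAT_NAMES}
        for i in idx:
            col = i % n_cols
            metric_counts[METRIC_NAMES[col // 3]] += 1
            stat_counts[STAT_NAMES[col % 3]] += 1
        return {
            "representation": "summary",
            "n_selected": int(idx.size),
            "metric_counts": metric_counts,
            "stat_counts": stat_counts,
        }
    if representation == "corr":
        degree = {r: 0 for r in range(1, n_regions + 1)}
        for i in idx:
            l, m = pair_from_index(int(i), n_regions)
            degree[l] += 1
            degree[m] += 1
        return {
            "representation": "corr",
            "n_selected": int(idx.size),
            "region_degree": degree,
        }
    raise ValueError("representation must be 'summary' or 'corr'")


def write_report(
    selection: SelectionResult,
    regions: RegionTable,
    out_dir: str | Path,
    top_n: int = 50,
    representation: str = "corr",
) -> dict[str, Path]:
    """Write top_pairs.tsv, importances.tsv and histogram.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = importance_table(selection, regions, top_n=top_n)
    paths = {
        "top_pairs": out_dir / "top_pairs.tsv",
        "importances": out_dir / "importances.tsv",
        "histogram": out_dir / "histogram.json",
    }
    pd.DataFrame(
        [(t.rank, t.region_l, t.region_m) for t in table[:12]],
        columns=["rank", "region_l", "region_m"],
    ).to_csv(paths["top_pairs"], sep="\t", index=False)
    pd.DataFrame(
        [(t.rank, t.region_l, t.region_m, t.coefficient) for t in table],
        columns=["rank", "region_l", "region_m", "coefficient"],
    ).to_csv(paths["importances"], sep="\t", index=False, float_format="%.12g")
    hist = selection_histogram(
        selection.selected_indices, representation=representation, n_regions=len(regions)
    )
    with open(paths["histogram"], "w") as fh:
        json.dump(hist, fh, indent=2, sort_keys=True)
    return paths


def plot_importances(table: list[PairImportance], path: str | Path) -> None:
    """Optional horizontal-bar rendering of signed pair importances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{t.region_l} | {t.region_m}" for t in table][::-1]
    coefs = [t.coefficient for t in table][::-1]
    colors = ["tab:blue" if c < 0 else "tab:orange" for c in coefs]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(table))))
    ax.barh(labels, coefs, color=colors)
    ax.set_xlabel("importance coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
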