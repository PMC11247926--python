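"""Median spatial-distance matrices, log2 fold-change maps, and compaction QC.

The imaging analog of a contact map: for every pair of panel loci, the
median 3D Euclidean distance across traces in which both loci were
localized (pairwise-complete).  Condition contrasts are entrywise log2
ratios of two such matrices — e.g. maternal-deletion versus
paternal-deletion fibroblasts, or inhibitor-treated versus control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trace_linking import ChromatinTrace

__all__ = [
    "DistanceMatrix",
    "FoldChangeMatrix",
    "median_distance_matrix",
    "log2_fold_change",
    "detection_stats",
    "radius_of_gyration",
    "compaction_score",
    "stack_traces",
]


@dataclass
class DistanceMatrix:
    """Symmetric locus x locus median-distance matrix (nm), NaN where undefined."""

    values: np.ndarray
    n_obs: np.ndarray
    condition: str = ""
    bins: pd.DataFrame | None = None  # (chrom, start, end) per locus, panel order

    @property
    def n_loci(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        labels = (
            [f"{r.chrom}:{r.start}-{r.end}" for r in self.bins.itertuples()]
            if self.bins is not None
            else [str(i) for i in range(self.n_loci)]
        )
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass
class FoldChangeMatrix:
    """Entrywise log2 ratio of two conditions' median-distance matrices."""

    values: np.ndarray
    numerator: str
    denominator: str
    bins: pd.DataFrame | None = None


def stack_traces(traces: Sequence[ChromatinTrace]) -> tuple[np.ndarray, np.ndarray]:
    """(n_traces, n_loci, 3) coordinate stack and presence mask from traces."""
    if len(traces) == 0:
        raise ValueError("no traces supplied")
    coords = np.stack([t.coords for t in traces])
    mask = np.stack([t.present for t in traces])
    return coords, mask


def _pairwise_distances(coords: np.ndarray, mask: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
    both = mask[:, :, None] & mask[:, None, :]
    return np.where(both, d, np.nan)


def median_distance_matrix(
    traces: Sequence[ChromatinTrace] | tuple[np.ndarray, np.ndarray],
    min_pairs: int = 10,
    condition: str = "",
    bins: pd.DataFrame | None = None,
) -> DistanceMatrix:
    """Pairwise-complete median 3D distance per locus pair.

    Accepts either reconstructed traces or a raw ``(coords, mask)`` pair
    (e.g. a ground-truth ensemble).  Entries supported by fewer than
    ``min_pairs`` traces are reported missing (NaN), not as noisy numbers;
    the even-count median is the usual midpoint.
    """
    if isinstance(traces, tuple):
        coords, mask = traces
    else:
        coords, mask = stack_traces(traces)
        if not condition and len(traces) and traces[0].condition:
            condition = traces[0].condition
    d = _pairwise_distances(coords, mask)
    n_obs = np.sum(~np.isnan(d), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(d, axis=0)
    med = np.where(n_obs >= min_pairs, med, np.nan)
    np.fill_diagonal(med, 0.0)
    return DistanceMatrix(values=med, n_obs=n_obs, condition=condition, bins=bins)


def log2_fold_change(d_num: DistanceMatrix, d_den: DistanceMatrix) -> FoldChangeMatrix:
    """Entrywise log2(numerator / denominator); NaN where either side is undefined."""
    if d_num.values.shape != d_den.values.shape:
        raise ValueError("distance matrices cover different panels")
    a = d_num.values.astype(float).copy()
    b = d_den.values.astype(float).copy()
    np.fill_diagonal(a, np.nan)
    np.fill_diagonal(b, np.nan)
    bad_zero = np.isclose(b, 0.0) & ~np.isnan(b)
    if bad_zero.any():
        warnings.warn(
            f"{int(bad_zero.sum())} zero-median denominator entries set missing",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(a / b)
    fc[~np.isfinite(fc)] = np.nan
    return FoldChangeMatrix(
        values=fc,
        numerator=d_num.condition,
        denominator=d_den.condition,
        bins=d_num.bins,
    )


def detection_stats(traces: Sequence[ChromatinTrace]) -> dict:
    """Per-locus detection efficiency and the per-trace completeness histogram."""
    if len(traces) == 0:
        return dict(per_locus_efficiency=[], completeness=[], mean_efficiency=float("nan"))
    _, mask = stack_traces(traces)
    completeness = mask.mean(axis=1)
    return dict(
        per_locus_efficiency=mask.mean(axis=0).tolist(),
        completeness=completeness.tolist(),
        mean_efficiency=float(mask.mean()),
    )


def radius_of_gyration(coords: np.ndarray, mask: np.ndarray | None = None) -> float:
    """RMS distance of present loci from their centroid; NaN for < 2 loci."""
    pts = np.asarray(coords, dtype=float)
    if mask is not None:
        pts = pts[np.asarray(mask, bool)]
    else:
        pts = pts[~np.isnan(pts[:, 0])]
    if len(pts) < 2:
        return float("nan")
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum(axis=1).mean()))


def compaction_score(
    traces: Sequence[ChromatinTrace] | tuple[np.ndarray, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Condition-level compaction summary: Rg and median all-pairs distance.

    Reports per-trace radii of gyration and the overall median of all
    pairwise distances, each with a seeded percentile bootstrap CI over
    traces.
    """
    if isinstance(traces, tuple):
        coords, mask = traces
    else:
        coords, mask = stack_traces(traces)
    rgs = np.array([radius_of_gyration(coords[i], mask[i]) for i in range(len(coords))])
    rgs = rgs[~np.isnan(rgs)]
    d = _pairwise_distances(coords, mask)
    iu = np.triu_indices(coords.shape[1], k=1)
    per_trace_pairs = d[:, iu[0], iu[1]]
    med_all = float(np.nanmedian(per_trace_pairs))
    rng = np.random.default_rng(seed)
    n = len(coords)
    boot_rg = np.empty(n_boot)
    boot_med = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sel = np.array([radius_of_gyration(coords[i], mask[i]) for i in idx])
        boot_rg[b] = np.nanmean(sel)
        boot_med[b] = np.nanmedian(per_trace_pairs[idx])
    return dict(
        mean_rg=float(rgs.mean()) if len(rgs) else float("nan"),
        rg_ci=[float(np.percentile(boot_rg, 2.5)), float(np.percentile(boot_rg, 97.5))],
        median_pair_distance=med_all,
        median_pair_ci=[float(np.percentile(boot_med, 2.5)), float(np.percentile(boot_med, 97.5))],
        n_traces=int(n),
    )


# ---------------------------------------------------------------------------
# I/O and plotting


def write_distance_matrix(dm: DistanceMatrix, path, n_obs_path=None) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", na_rep="NA")
    if n_obs_path is not None:
        pd.DataFrame(
            dm.n_obs,
            index=dm.to_dataframe().index,
            columns=dm.to_dataframe().columns,
        ).to_csv(n_obs_path, sep="\t")


def plot_matrix(values: np.ndarray, path, title: str = "", cmap: str = "RdBu_r", symmetric: bool = False):
    """Heatmap export (locus order = genomic order, origin upper-left)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    kw = {}
    if symmetric:
        vmax = np.nanmax(np.abs(values)) or 1.0
        kw = dict(vmin=-vmax, vmax=vmax)
    im = ax.imshow(values, cmap=cmap, origin="upper", **kw)
    ax.set_title(title)
    ax.set_xlabel("locus")
    ax.set_ylabel("locus")
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
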