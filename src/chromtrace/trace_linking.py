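"""Assembly of registered foci into per-nucleus chromatin traces.

In this panel every (round, channel) slot reads out exactly one genomic
segment, so decoding is not combinatorial: each focus is a candidate for
exactly one locus, and linking reduces to picking, per locus, the focus
that best fits the spatially clustered trace.  Each nucleus is expected to
hold a single traceable allele (hemizygous-deletion lines); a
multi-allele mode seeds additional trace centers and resolves per-locus
contention by exact minimum-cost assignment.

The per-focus cost is ``distance to the evolving trace centroid −
intensity_weight · log(intensity)``; with the cost separable across loci,
per-locus minimization attains the global exhaustive minimum for a single
trace.  Ties break toward higher intensity, then lower round index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .panel_design import SegmentPanel

__all__ = [
    "LinkingConfig",
    "ChromatinTrace",
    "link_traces",
    "refit_missing",
    "trace_qc",
    "traces_to_dataframe",
    "traces_from_dataframe",
]

XYZ = ["x_nm", "y_nm", "z_nm"]

ASSIGNED = "assigned"
REFIT = "refit"
MISSING = "missing"


@dataclass
class LinkingConfig:
    """Tuning knobs for linking and missing-locus refitting (lengths nm)."""

    r_max: float = 1500.0
    expected_traces_per_nucleus: int = 1
    intensity_weight: float = 0.0  # nm credit per unit log-intensity
    refit_radius: float = 500.0
    refit_threshold_factor: float = 0.5
    intensity_threshold: float = 400.0
    n_passes: int = 3

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.refit_radius <= 0:
            raise ValueError("radii must be positive")
        if self.expected_traces_per_nucleus < 1:
            raise ValueError("expected_traces_per_nucleus must be >= 1")


@dataclass
class ChromatinTrace:
    """One reconstructed allele: ordered per-locus 3D coordinates.

    ``coords`` is (n_loci, 3) with NaN rows at missing loci; ``source``
    flags each locus as assigned, refit, or missing.
    """

    trace_id: int
    nucleus_id: int
    coords: np.ndarray
    source: np.ndarray
    condition: str = ""
    focus_rows: np.ndarray | None = None  # original foci row index per locus (-1 none)
    link_center: np.ndarray | None = None  # centroid used in the final linking pass

    @property
    def n_loci(self) -> int:
        return len(self.coords)

    @property
    def present(self) -> np.ndarray:
        return self.source != MISSING

    @property
    def completeness(self) -> float:
        return float(self.present.mean())


def _locus_lookup(panel: SegmentPanel) -> dict[tuple[int, str], int]:
    if not panel.has_codebook:
        raise ValueError("panel codebook must be built before linking")
    return {(seg.hyb_round, seg.channel): seg.index for seg in panel.segments}


def _cost(dist: np.ndarray, intensity: np.ndarray, w: float) -> np.ndarray:
    return dist - w * np.log(np.maximum(intensity, 1e-12))


def _seed_centers(pts: np.ndarray, intens: np.ndarray, k: int, r_max: float) -> np.ndarray:
    """Density-peak seeding: densest focus first, next seeds >= 2 r_max away."""
    counts = np.array([np.sum(np.linalg.norm(pts - p, axis=1) <= r_max) for p in pts])
    # deterministic ordering: density desc, intensity desc, index asc
    order = np.lexsort((np.arange(len(pts)), -intens, -counts))
    centers = [pts[order[0]]]
    for idx in order[1:]:
        if len(centers) >= k:
            break
        if all(np.linalg.norm(pts[idx] - c) > 2 * r_max for c in centers):
            centers.append(pts[idx])
    return np.asarray(centers)


def _link_nucleus(
    sub: pd.DataFrame,
    locus_of: dict[tuple[int, str], int],
    n_loci: int,
    config: LinkingConfig,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Link one nucleus; returns (coords, source, focus_rows) per emitted trace."""
    pts = sub[XYZ].to_numpy(dtype=float)
    intens = sub["intensity"].to_numpy(dtype=float)
    rounds = sub["round"].to_numpy()
    loci = np.array(
        [locus_of.get((int(r), str(c)), -1) for r, c in zip(sub["round"], sub["channel"])]
    )
    rows = sub.index.to_numpy()
    valid = loci >= 0
    if not valid.any():
        return []
    pts, intens, rounds, loci, rows = (
        pts[valid], intens[valid], rounds[valid], loci[valid], rows[valid]
    )

    centers = _seed_centers(pts, intens, config.expected_traces_per_nucleus, config.r_max)
    k = len(centers)

    coords = np.full((k, n_loci, 3), np.nan)
    srcrow = np.full((k, n_loci), -1, dtype=int)
    centers_used = centers.copy()
    for _ in range(config.n_passes):
        centers_used = centers.copy()
        coords[:] = np.nan
        srcrow[:] = -1
        for locus in range(n_loci):
            cand = np.flatnonzero(loci == locus)
            if len(cand) == 0:
                continue
            # cost matrix traces x candidates, gated at r_max
            d = np.linalg.norm(pts[cand][None, :, :] - centers[:, None, :], axis=2)
            cost = _cost(d, intens[cand][None, :], config.intensity_weight)
            cost = np.where(d <= config.r_max, cost, np.inf)
            if k == 1:
                finite = np.isfinite(cost[0])
                if not finite.any():
                    continue
                # deterministic tie-break: min cost, then max intensity, then low round
                best = min(
                    np.flatnonzero(finite),
                    key=lambda j: (cost[0, j], -intens[cand[j]], rounds[cand[j]]),
                )
                chosen = {0: best}
            else:
                feasible = np.isfinite(cost).any(axis=1)
                chosen = {}
                if feasible.any():
                    big = 1e12
                    ti, cj = linear_sum_assignment(np.where(np.isfinite(cost), cost, big))
                    for t, j in zip(ti, cj):
                        if np.isfinite(cost[t, j]):
                            chosen[t] = j
            for t, j in chosen.items():
                coords[t, locus] = pts[cand[j]]
                srcrow[t, locus] = rows[cand[j]]
        # update centroids from assignments
        for t in range(k):
            present = ~np.isnan(coords[t, :, 0])
            if present.any():
                centers[t] = coords[t, present].mean(axis=0)

    out = []
    for t in range(k):
        present = ~np.isnan(coords[t, :, 0])
        source = np.where(present, ASSIGNED, MISSING)
        out.append((coords[t], source, srcrow[t], centers_used[t]))
    return out


def link_traces(
    registered_foci: pd.DataFrame,
    panel: SegmentPanel,
    config: LinkingConfig | None = None,
    condition: str = "",
) -> tuple[list[ChromatinTrace], dict]:
    """Assemble registered foci into chromatin traces, one nucleus at a time.

    Returns (traces, qc); nuclei with zero usable foci produce no trace and
    are counted in the QC dict.
    """
    config = config or LinkingConfig()
    locus_of = _locus_lookup(panel)
    n_loci = panel.n_segments
    traces: list[ChromatinTrace] = []
    qc = dict(n_nuclei=0, n_empty_nuclei=0, n_foci_in=len(registered_foci), n_assigned=0)
    # stable nucleus order regardless of input row order
    for nid in sorted(pd.unique(registered_foci["nucleus_id"])):
        qc["n_nuclei"] += 1
        sub = registered_foci[registered_foci["nucleus_id"] == nid]
        sub = sub.sort_values(["round", "channel", "x_nm", "y_nm", "z_nm"], kind="mergesort")
        linked = _link_nucleus(sub, locus_of, n_loci, config)
        if not linked:
            qc["n_empty_nuclei"] += 1
            continue
        for coords, source, rowix, center in linked:
            traces.append(
                ChromatinTrace(
                    trace_id=len(traces),
                    nucleus_id=int(nid),
                    coords=coords,
                    source=source,
                    condition=condition,
                    focus_rows=rowix,
                    link_center=center,
                )
            )
            qc["n_assigned"] += int((source == ASSIGNED).sum())
    qc["n_traces"] = len(traces)
    return traces, qc


def refit_missing(
    trace: ChromatinTrace,
    candidate_pool: pd.DataFrame,
    panel: SegmentPanel,
    config: LinkingConfig | None = None,
) -> ChromatinTrace:
    """Recover missing loci from relaxed-threshold detections near the trace.

    The expected position of a missing locus is linearly interpolated (or
    extrapolated at the ends) from the nearest assigned loci along the
    genomic coordinate; the nearest same-(round, channel) candidate within
    ``refit_radius`` whose intensity clears ``intensity_threshold *
    refit_threshold_factor`` is adopted and flagged ``refit``.  Assigned
    loci are never overwritten.
    """
    config = config or LinkingConfig()
    present = trace.present
    if present.sum() < 2 or present.all():
        return trace
    locus_of = _locus_lookup(panel)
    coords = trace.coords.copy()
    source = trace.source.copy()
    known = np.flatnonzero(present)
    pool = candidate_pool[candidate_pool["nucleus_id"] == trace.nucleus_id]
    relaxed = config.intensity_threshold * config.refit_threshold_factor
    pool = pool[pool["intensity"] >= relaxed]
    if len(pool) == 0:
        return trace
    ppts = pool[XYZ].to_numpy(dtype=float)
    ploci = np.array(
        [locus_of.get((int(r), str(c)), -1) for r, c in zip(pool["round"], pool["channel"])]
    )
    for locus in np.flatnonzero(~present):
        # linear interpolation/extrapolation from the two nearest assigned loci
        lo = known[known < locus]
        hi = known[known > locus]
        if len(lo) and len(hi):
            i, j = lo[-1], hi[0]
        elif len(hi) >= 2:
            i, j = hi[0], hi[1]
        elif len(lo) >= 2:
            i, j = lo[-2], lo[-1]
        else:
            continue
        frac = (locus - i) / (j - i)
        expect = coords[i] + frac * (coords[j] - coords[i])
        cand = np.flatnonzero(ploci == locus)
        if len(cand) == 0:
            continue
        d = np.linalg.norm(ppts[cand] - expect, axis=1)
        best = cand[np.argmin(d)]
        if d.min() <= config.refit_radius:
            coords[locus] = ppts[best]
            source[locus] = REFIT
    return ChromatinTrace(
        trace_id=trace.trace_id,
        nucleus_id=trace.nucleus_id,
        coords=coords,
        source=source,
        condition=trace.condition,
        focus_rows=trace.focus_rows,
    )


def trace_qc(
    traces: Sequence[ChromatinTrace], min_completeness: float = 0.5
) -> tuple[list[ChromatinTrace], dict]:
    """Drop incomplete traces; report per-locus efficiency and refit fraction."""
    kept = [t for t in traces if t.completeness >= min_completeness]
    dropped = len(traces) - len(kept)
    if traces:
        n_loci = traces[0].n_loci
        present = np.array([t.present for t in traces])
        refit = np.array([t.source == REFIT for t in traces])
        per_locus = present.mean(axis=0)
        refit_fraction = float(refit.sum() / max(present.sum(), 1))
    else:
        per_locus = np.array([])
        refit_fraction = 0.0
    report = dict(
        n_input=len(traces),
        n_kept=len(kept),
        n_dropped=dropped,
        min_completeness=min_completeness,
        per_locus_efficiency=per_locus.tolist(),
        refit_fraction=refit_fraction,
        mean_completeness=float(np.mean([t.completeness for t in traces])) if traces else 0.0,
    )
    return kept, report


# ---------------------------------------------------------------------------
# (de)serialization


def traces_to_dataframe(traces: Sequence[ChromatinTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        for locus in range(t.n_loci):
            x, y, z = t.coords[locus]
            rows.append(
                dict(
                    trace_id=t.trace_id,
                    nucleus_id=t.nucleus_id,
                    condition=t.condition,
                    locus_index=locus,
                    x=x,
                    y=y,
                    z=z,
                    source=t.source[locus],
                )
            )
    return pd.DataFrame(rows)


def traces_from_dataframe(df: pd.DataFrame) -> list[ChromatinTrace]:
    traces = []
    for tid, sub in df.groupby("trace_id", sort=True):
        sub = sub.sort_values("locus_index")
        coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
        traces.append(
            ChromatinTrace(
                trace_id=int(tid),
                nucleus_id=int(sub["nucleus_id"].iloc[0]),
                coords=coords,
                source=sub["source"].to_numpy(),
                condition=str(sub["condition"].iloc[0]),
            )
        )
    return traces
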