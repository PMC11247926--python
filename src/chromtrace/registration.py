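"""Chromatic/drift correction, nucleus masking, and 3D foci fitting.

The camera frame wanders between sequential hybridization rounds (stage
drift) and differs between dye channels (chromatic shift).  Both are
estimated from bead images — multicolor calibration beads for the
chromatic offset, per-round fiducial beads for drift — and inverted so
that every localization lands in a common reference frame (round 0 of the
647-nm channel).  Foci are fit in 3D only inside segmented nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform3D",
    "RegistrationError",
    "match_points",
    "estimate_chromatic_transform",
    "estimate_drift",
    "segment_nuclei",
    "fit_foci",
    "fit_foci_zstack",
    "apply_corrections",
]

XYZ = ["x_nm", "y_nm", "z_nm"]


class RegistrationError(ValueError):
    pass


@dataclass
class RigidTransform3D:
    """Affine map y = M x + t (M = identity in pure-translation mode)."""

    translation: np.ndarray
    matrix: np.ndarray | None = None
    frame_from: str = ""
    frame_to: str = ""
    rms: float = 0.0
    n_matches: int = 0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.matrix is not None:
            pts = pts @ self.matrix.T
        return pts + self.translation

    def inverse(self) -> "RigidTransform3D":
        if self.matrix is None:
            return RigidTransform3D(
                translation=-self.translation,
                frame_from=self.frame_to,
                frame_to=self.frame_from,
                rms=self.rms,
                n_matches=self.n_matches,
            )
        inv = np.linalg.inv(self.matrix)
        return RigidTransform3D(
            translation=-inv @ self.translation,
            matrix=inv,
            frame_from=self.frame_to,
            frame_to=self.frame_from,
            rms=self.rms,
            n_matches=self.n_matches,
        )

    def to_dict(self) -> dict:
        d = {
            "dx": float(self.translation[0]),
            "dy": float(self.translation[1]),
            "dz": float(self.translation[2]),
            "rms": float(self.rms),
            "n_matches": int(self.n_matches),
            "frame_from": self.frame_from,
            "frame_to": self.frame_to,
        }
        if self.matrix is not None:
            d["matrix"] = self.matrix.tolist()
        return d


def match_points(
    a: np.ndarray, b: np.ndarray, gate: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbor pairs (indices into a, b) within ``gate`` nm."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if len(a) == 0 or len(b) == 0:
        return np.empty(0, int), np.empty(0, int)
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, distance_upper_bound=gate)
    d_ba, j_ba = ta.query(b, distance_upper_bound=gate)
    ia = []
    ib = []
    for i, j in enumerate(j_ab):
        if j < len(b) and j_ba[j] == i:
            ia.append(i)
            ib.append(j)
    return np.asarray(ia, int), np.asarray(ib, int)


def _as_xyz(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[XYZ].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(table, dtype=float))


def estimate_chromatic_transform(
    beads_moving: pd.DataFrame | np.ndarray,
    beads_reference: pd.DataFrame | np.ndarray,
    mode: str = "translation",
    gate: float = 500.0,
) -> RigidTransform3D:
    """Least-squares map from the moving (560-nm) into the reference (647-nm) frame.

    Beads are paired by mutual nearest neighbor within ``gate``.  Translation
    mode needs >= 1 pair; affine mode needs >= 4 non-coplanar pairs.
    """
    a = _as_xyz(beads_moving)
    b = _as_xyz(beads_reference)
    ia, ib = match_points(a, b, gate=gate)
    if mode == "translation":
        if len(ia) < 1:
            raise RegistrationError("need at least 1 matched bead pair for translation")
        t = (b[ib] - a[ia]).mean(axis=0)
        resid = b[ib] - (a[ia] + t)
        return RigidTransform3D(
            translation=t,
            frame_from="560",
            frame_to="647",
            rms=float(np.sqrt((resid**2).sum(axis=1).mean())),
            n_matches=len(ia),
        )
    if mode == "affine":
        if len(ia) < 4:
            raise RegistrationError("need at least 4 matched bead pairs for affine")
        src = np.column_stack([a[ia], np.ones(len(ia))])
        if np.linalg.matrix_rank(src) < 4:
            raise RegistrationError("matched beads are coplanar; affine underdetermined")
        sol, *_ = np.linalg.lstsq(src, b[ib], rcond=None)
        M = sol[:3].T
        t = sol[3]
        resid = b[ib] - (a[ia] @ M.T + t)
        return RigidTransform3D(
            translation=t,
            matrix=M,
            frame_from="560",
            frame_to="647",
            rms=float(np.sqrt((resid**2).sum(axis=1).mean())),
            n_matches=len(ia),
        )
    raise RegistrationError(f"unknown mode {mode!r}")


def estimate_drift(
    fiducials_round: pd.DataFrame | np.ndarray,
    fiducials_reference: pd.DataFrame | np.ndarray,
    gate: float = 1000.0,
    robust: bool = False,
    trim_fraction: float = 0.2,
) -> RigidTransform3D:
    """Per-round stage drift: mean matched fiducial displacement vs the reference round.

    The returned transform maps reference-frame points into the drifted
    round's frame (its translation is the drift itself); subtract it — or
    apply its inverse — to register a round back onto the reference.  The
    robust variant drops the ``trim_fraction`` worst-residual matches.
    """
    a = _as_xyz(fiducials_reference)
    b = _as_xyz(fiducials_round)
    ia, ib = match_points(a, b, gate=gate)
    if len(ia) == 0:
        raise RegistrationError("no fiducials matched between rounds")
    disp = b[ib] - a[ia]
    t = disp.mean(axis=0)
    if robust and len(ia) > 2:
        resid = np.linalg.norm(disp - t, axis=1)
        keep = resid.argsort()[: max(1, int(np.ceil(len(ia) * (1 - trim_fraction))))]
        t = disp[keep].mean(axis=0)
        disp = disp[keep]
    resid = disp - t
    return RigidTransform3D(
        translation=t,
        frame_from="reference",
        frame_to="round",
        rms=float(np.sqrt((resid**2).sum(axis=1).mean())),
        n_matches=len(disp),
    )


# ---------------------------------------------------------------------------
# nucleus segmentation


def segment_nuclei(
    image: np.ndarray | None = None,
    nuclei_table: pd.DataFrame | None = None,
    min_volume: int = 50,
    voxel_size: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Segment nuclei, returning a table (nucleus_id, cx, cy, cz, radius, volume).

    Raster mode thresholds a DAPI-like image (Otsu), labels connected
    components, and drops objects below ``min_volume`` voxels; centers and
    equivalent-sphere radii are reported in nm when ``voxel_size`` is given
    (else in voxels).  Vector mode passes a declared nucleus table through.
    """
    if nuclei_table is not None:
        return nuclei_table.copy()
    if image is None:
        raise RegistrationError("either an image or a nucleus table is required")
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(image, dtype=float)
    if img.max() <= img.min():
        return pd.DataFrame(columns=["nucleus_id", "cx", "cy", "cz", "radius", "volume"])
    mask = img > threshold_otsu(img)
    labels = label(mask)
    rows = []
    scale = np.array(voxel_size[::-1]) if voxel_size is not None else np.ones(img.ndim)
    for prop in regionprops(labels):
        if prop.area < min_volume:
            continue
        c = np.asarray(prop.centroid) * scale  # (z, y, x) order
        vol_scale = float(np.prod(scale))
        radius = (3.0 * prop.area * vol_scale / (4.0 * np.pi)) ** (1.0 / 3.0)
        if img.ndim == 2:
            radius = np.sqrt(prop.area * float(np.prod(scale)) / np.pi)
            c = np.array([0.0, *c])
        rows.append(
            dict(
                nucleus_id=len(rows),
                cx=c[-1],
                cy=c[-2],
                cz=c[0] if img.ndim == 3 else 0.0,
                radius=radius,
                volume=prop.area * vol_scale,
            )
        )
    return pd.DataFrame(rows, columns=["nucleus_id", "cx", "cy", "cz", "radius", "volume"])


# ---------------------------------------------------------------------------
# foci fitting


def _gauss3d_model(params: np.ndarray, zyx: tuple[np.ndarray, ...]) -> np.ndarray:
    a, x0, y0, z0, sx, sy, sz, b = params
    zz, yy, xx = zyx
    return b + a * np.exp(
        -0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2 + ((zz - z0) / sz) ** 2)
    )


def fit_foci_zstack(
    stack: np.ndarray,
    intensity_threshold: float,
    voxel_size: tuple[float, float, float] = (108.0, 108.0, 200.0),
    min_distance: int = 2,
    cutout: int = 4,
) -> pd.DataFrame:
    """Detect and localize spots in a (z, y, x) stack.

    Local maxima above ``intensity_threshold`` are refined by least-squares
    3D Gaussian fits on a local cutout; fits that do not converge (or leave
    the cutout) fall back to an intensity-weighted centroid, flagged in
    ``fit_quality``.  Coordinates are returned in nm (x, y, z).
    """
    from skimage.feature import peak_local_max

    img = np.asarray(stack, dtype=float)
    peaks = peak_local_max(
        img, min_distance=min_distance, threshold_abs=intensity_threshold, exclude_border=False
    )
    vx, vy, vz = voxel_size
    rows = []
    for pz, py, px in peaks:
        zlo, zhi = max(0, pz - cutout // 2), min(img.shape[0], pz + cutout // 2 + 1)
        ylo, yhi = max(0, py - cutout), min(img.shape[1], py + cutout + 1)
        xlo, xhi = max(0, px - cutout), min(img.shape[2], px + cutout + 1)
        sub = img[zlo:zhi, ylo:yhi, xlo:xhi]
        zz, yy, xx = np.meshgrid(
            np.arange(zlo, zhi), np.arange(ylo, yhi), np.arange(xlo, xhi), indexing="ij"
        )
        bg = float(sub.min())
        amp = float(sub.max() - bg)
        p0 = np.array([amp, px, py, pz, 1.5, 1.5, 1.2, bg])

        def resid(p):
            return (_gauss3d_model(p, (zz, yy, xx)) - sub).ravel()

        quality = "gauss"
        try:
            fit = least_squares(resid, p0, max_nfev=200)
            a, x0, y0, z0 = fit.x[0], fit.x[1], fit.x[2], fit.x[3]
            converged = (
                fit.success
                and a > 0
                and xlo - 1 <= x0 <= xhi
                and ylo - 1 <= y0 <= yhi
                and zlo - 1 <= z0 <= zhi
            )
        except Exception:
            converged = False
        if not converged:
            w = np.clip(sub - bg, 0, None)
            tot = w.sum()
            if tot <= 0:
                continue
            x0 = float((w * xx).sum() / tot)
            y0 = float((w * yy).sum() / tot)
            z0 = float((w * zz).sum() / tot)
            a = float(sub.max() - bg)
            quality = "centroid"
        rows.append(
            dict(
                # voxel centers sit at (i + 0.5) * pitch
                x_nm=(x0 + 0.5) * vx,
                y_nm=(y0 + 0.5) * vy,
                z_nm=(z0 + 0.5) * vz,
                intensity=float(img[pz, py, px]),
                fit_quality=quality,
            )
        )
    return pd.DataFrame(rows, columns=["x_nm", "y_nm", "z_nm", "intensity", "fit_quality"])


def fit_foci(
    foci: pd.DataFrame,
    masks: pd.DataFrame,
    intensity_threshold: float = 0.0,
    containment_margin: float = 600.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Vector-mode foci filtering: keep localizations inside a nucleus mask.

    Returns ``(accepted, subthreshold, qc)``: accepted foci at or above the
    intensity threshold, dimmer in-mask detections kept aside as the relaxed
    candidate pool for missing-locus refitting, and QC counters.  The
    containment test is against the nucleus sphere inflated by
    ``containment_margin`` (uncorrected drift can move foci slightly out).
    """
    if masks is None or len(masks) == 0:
        qc = dict(n_input=len(foci), n_accepted=0, n_subthreshold=0, n_outside=len(foci))
        empty = foci.iloc[0:0].copy()
        return empty, empty.copy(), qc
    centers = masks[["cx", "cy", "cz"]].to_numpy(dtype=float)
    radii = masks["radius"].to_numpy(dtype=float) + containment_margin
    pts = foci[XYZ].to_numpy(dtype=float)
    tree = cKDTree(centers)
    dist, idx = tree.query(pts)
    inside = dist <= radii[idx]
    contained = foci[inside].copy()
    contained["nucleus_id"] = masks["nucleus_id"].to_numpy()[idx[inside]]
    bright = contained["intensity"] >= intensity_threshold
    accepted = contained[bright].copy()
    pool = contained[~bright].copy()
    qc = dict(
        n_input=len(foci),
        n_accepted=int(bright.sum()),
        n_subthreshold=int((~bright).sum()),
        n_outside=int((~inside).sum()),
    )
    return accepted, pool, qc


def apply_corrections(
    foci: pd.DataFrame,
    chromatic: RigidTransform3D | None,
    drift_by_round: dict[int, RigidTransform3D] | dict[int, np.ndarray],
    chromatic_channel: str = "560",
) -> pd.DataFrame:
    """Register foci: chromatic map on the offset channel, then undo per-round drift.

    Original coordinates are preserved in ``*_raw`` columns and the
    ``registered`` flag is set.  A round present in the table but absent
    from ``drift_by_round`` is an error.
    """
    out = foci.copy()
    for c in XYZ:
        out[c + "_raw"] = out[c]
    missing = set(out["round"].unique()) - set(drift_by_round)
    if missing:
        raise RegistrationError(f"no drift transform for rounds {sorted(missing)}")
    pts = out[XYZ].to_numpy(dtype=float)
    if chromatic is not None:
        sel = (out["channel"].astype(str) == chromatic_channel).to_numpy()
        if sel.any():
            pts[sel] = chromatic.apply(pts[sel])
    for r, tr in drift_by_round.items():
        vec = tr.translation if isinstance(tr, RigidTransform3D) else np.asarray(tr, float)
        sel = (out["round"] == r).to_numpy()
        pts[sel] = pts[sel] - vec
    out[XYZ] = pts
    out["registered"] = True
    return out
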