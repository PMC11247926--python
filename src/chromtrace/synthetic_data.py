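"""Ground-truth polymer and sequential-imaging simulator.

Generates Gaussian-chain conformations of the traced domain with a
condition-dependent compaction scale (e.g. the maternal-deletion line more
compact than the paternal-deletion line, with one sub-block reversed), the
matched proximity-ligation-style contact matrix, and the imaging
observations a sequential-hybridization experiment would record: per-round
drifted foci with chromatic offset on one channel, localization jitter,
detection dropout, nonspecific foci, fiducial beads, and nucleus masks.

Each simulated nucleus carries exactly one traceable allele by default,
mirroring hemizygous-deletion patient fibroblasts where only one homolog of
the imprinted domain remains.  All lengths are in nanometers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_design import SegmentPanel

__all__ = [
    "SimulationConfig",
    "ConformationEnsemble",
    "ImagingExperiment",
    "simulate_conformations",
    "conformations_to_contact_matrix",
    "simulate_imaging",
    "render_zstack",
    "rng_for",
]

#: Voxel size (x, y, z) in nm for raster (z-stack) rendering; the axial
#: pitch matches the 200-nm z-stepping of the acquisition.
VOXEL_SIZE_NM = (108.0, 108.0, 200.0)


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named random substream derived from one top-level seed."""
    import zlib

    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])


@dataclass
class SimulationConfig:
    """Knobs of the polymer + observation model (all lengths nm).

    The polymer is an ideal (Gaussian) chain: each 50-kb step is an
    isotropic Gaussian displacement with per-axis standard deviation
    ``scale * step_sigma``; squared inter-locus distance therefore grows
    linearly with genomic separation.  ``sub_block`` overrides the scale on
    a contiguous run of steps to plant a locally reversed compaction
    difference between conditions.
    """

    seed: int = 0
    n_traces: int = 200
    n_loci: int = 42
    step_sigma: float = 120.0  # nm per-axis per 50-kb step
    scale: float = 1.0  # condition compaction factor s
    sub_block: tuple[int, int, float] | None = None  # (locus_lo, locus_hi, scale)
    confinement_radius: float | None = None
    sigma_xy: float = 50.0  # localization jitter, lateral
    sigma_z: float = 100.0  # localization jitter, axial
    p_det: float = 0.9  # per-focus detection probability
    false_positive_rate: float = 3.0  # Poisson mean spurious foci / nucleus / round
    drift_mag: float = 300.0  # per-round drift ~ U(-drift_mag, drift_mag) per axis
    chromatic_offset: tuple[float, float, float] = (60.0, 40.0, 0.0)
    n_fiducials: int = 20
    nucleus_radius: float = 6000.0
    intensity_median: float = 1000.0
    intensity_sigma: float = 0.5  # lognormal sigma of true-focus brightness
    fp_intensity_median: float = 500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_det <= 1.0):
            raise ValueError("p_det must lie in [0, 1]")
        if self.scale <= 0 or self.step_sigma <= 0:
            raise ValueError("scales must be positive")
        if self.sub_block is not None and self.sub_block[2] <= 0:
            raise ValueError("sub_block scale must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2, sort_keys=True)


@dataclass
class ConformationEnsemble:
    """Ground-truth 3D conformations: (n_traces, n_loci, 3) nm coordinates."""

    condition: str
    traces: np.ndarray
    mask: np.ndarray  # bool, (n_traces, n_loci); all-True at generation
    nucleus_ids: np.ndarray  # (n_traces,) int
    config: SimulationConfig

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    @property
    def n_loci(self) -> int:
        return self.traces.shape[1]


@dataclass
class ImagingExperiment:
    """Simulated observations of one ensemble under sequential imaging.

    ``foci`` holds all observed localizations (true and spurious), in the
    drifted/offset camera frame; ``fiducials`` one row per (bead, round);
    ``chromatic_beads`` a two-channel bead table for color calibration;
    ``nuclei`` the vector nucleus masks (center + radius).  Ground-truth
    linkage lives in the ``truth_trace`` / ``truth_locus`` columns (−1 for
    spurious foci) so reconstructions can be scored.
    """

    foci: pd.DataFrame
    fiducials: pd.DataFrame
    chromatic_beads: pd.DataFrame
    nuclei: pd.DataFrame
    drifts: dict[int, np.ndarray]
    chromatic_offset: np.ndarray
    subthreshold: pd.DataFrame | None = None  # populated downstream by foci fitting
    ensemble: ConformationEnsemble | None = None


# ---------------------------------------------------------------------------
# polymer model


def _nucleus_centers(n: int, radius: float) -> np.ndarray:
    """Disjoint nucleus centers on a square grid, 4 radii apart."""
    side = int(np.ceil(np.sqrt(n)))
    pitch = 4.0 * radius
    ix, iy = np.divmod(np.arange(n), side)
    return np.column_stack([ix * pitch, iy * pitch, np.zeros(n)])


def simulate_conformations(
    config: SimulationConfig,
    panel: SegmentPanel | None = None,
    condition: str = "sim",
    rng: np.random.Generator | None = None,
) -> ConformationEnsemble:
    """Draw Gaussian-chain conformations, one traced allele per nucleus.

    Step k (between loci k and k+1) has per-axis sd ``scale * step_sigma``,
    except steps whose left locus lies inside ``sub_block`` which use the
    override scale.  Each chain is centered on its nucleus center so that
    ``E[d^2(i, j)] = 3 (s * step_sigma)^2 |i - j|`` away from the block.
    """
    n_loci = panel.n_segments if panel is not None else config.n_loci
    rng = rng if rng is not None else rng_for(config.seed, f"conformations:{condition}")
    n = config.n_traces
    step_sd = np.full(n_loci - 1, config.scale * config.step_sigma)
    if config.sub_block is not None:
        lo, hi, s_block = config.sub_block
        if not (0 <= lo < hi <= n_loci):
            raise ValueError("sub_block locus range outside the panel")
        step_sd[lo:hi - 1] = s_block * config.step_sigma
    steps = rng.normal(size=(n, n_loci - 1, 3)) * step_sd[None, :, None]
    coords = np.concatenate([np.zeros((n, 1, 3)), np.cumsum(steps, axis=1)], axis=1)
    coords -= coords.mean(axis=1, keepdims=True)
    if config.confinement_radius is not None:
        # crude confinement hook: shrink chains that overflow the radius
        rmax = np.linalg.norm(coords, axis=2).max(axis=1, keepdims=True)[..., None]
        factor = np.minimum(1.0, config.confinement_radius / np.maximum(rmax, 1e-9))
        coords = coords * factor
    centers = _nucleus_centers(n, config.nucleus_radius)
    coords = coords + centers[:, None, :]
    return ConformationEnsemble(
        condition=condition,
        traces=coords,
        mask=np.ones((n, n_loci), dtype=bool),
        nucleus_ids=np.arange(n),
        config=config,
    )


def conformations_to_contact_matrix(
    ensemble: ConformationEnsemble, capture_radius: float
) -> np.ndarray:
    """Contact frequency: fraction of traces with d(i, j) < capture_radius.

    Computed over traces where both loci are present; the diagonal is 1.
    Serves as the ground-truth analog of a binned proximity-ligation map.
    """
    if capture_radius <= 0:
        raise ValueError("capture_radius must be positive")
    if ensemble.n_traces == 0:
        raise ValueError("empty ensemble")
    x = ensemble.traces
    m = ensemble.mask
    d = np.linalg.norm(x[:, :, None, :] - x[:, None, :, :], axis=-1)
    both = m[:, :, None] & m[:, None, :]
    hits = (d < capture_radius) & both
    with np.errstate(invalid="ignore"):
        freq = hits.sum(axis=0) / np.maximum(both.sum(axis=0), 1)
    np.fill_diagonal(freq, 1.0)
    return freq


# ---------------------------------------------------------------------------
# imaging observation model


def simulate_imaging(
    ensemble: ConformationEnsemble,
    panel: SegmentPanel,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ImagingExperiment:
    """Render an ensemble into per-round, per-channel foci observations.

    Per round r the whole field acquires a rigid drift (zero in round 0,
    the registration reference); foci on the second (560-nm) channel
    additionally carry the chromatic offset.  True foci are jittered by the
    localization noise, kept with probability ``p_det``, and joined by
    Poisson-distributed spurious foci uniform within each nucleus.
    Fiducial beads appear in every round in their own channel; a separate
    two-channel bead table supports chromatic calibration.
    """
    config = config if config is not None else ensemble.config
    if not panel.has_codebook:
        raise ValueError("panel codebook must be built before imaging simulation")
    if panel.n_segments != ensemble.n_loci:
        raise ValueError("panel size does not match ensemble loci")
    rng = rng if rng is not None else rng_for(config.seed, f"imaging:{ensemble.condition}")
    n_rounds = panel.n_rounds
    chan_of = {seg.index: seg.channel for seg in panel.segments}
    round_of = {seg.index: seg.hyb_round for seg in panel.segments}
    offset_channel = panel.channel_names[1] if len(panel.channel_names) > 1 else None
    offset = np.asarray(config.chromatic_offset, dtype=float)
    jitter_sd = np.array([config.sigma_xy, config.sigma_xy, config.sigma_z])

    drifts = {0: np.zeros(3)}
    for r in range(1, n_rounds):
        drifts[r] = rng.uniform(-config.drift_mag, config.drift_mag, size=3)

    centers = _nucleus_centers(ensemble.n_traces, config.nucleus_radius)
    nuclei = pd.DataFrame(
        {
            "nucleus_id": np.arange(ensemble.n_traces),
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "cz": centers[:, 2],
            "radius": config.nucleus_radius,
        }
    )

    rows: list[dict] = []
    for t in range(ensemble.n_traces):
        nid = int(ensemble.nucleus_ids[t])
        for locus in range(ensemble.n_loci):
            if not ensemble.mask[t, locus]:
                continue
            if rng.random() > config.p_det:
                continue
            r = round_of[locus]
            ch = chan_of[locus]
            pos = ensemble.traces[t, locus] + drifts[r]
            if ch == offset_channel:
                pos = pos + offset
            pos = pos + rng.normal(size=3) * jitter_sd
            inten = config.intensity_median * np.exp(rng.normal(0, config.intensity_sigma))
            rows.append(
                dict(
                    nucleus_id=nid, round=r, channel=ch,
                    x_nm=pos[0], y_nm=pos[1], z_nm=pos[2],
                    intensity=inten, is_truth=True, truth_trace=t, truth_locus=locus,
                )
            )
    # spurious foci: uniform within the nucleus sphere, split across channels
    channels = list(panel.channel_names)
    for t in range(ensemble.n_traces):
        nid = int(ensemble.nucleus_ids[t])
        c = centers[t]
        for r in range(n_rounds):
            n_fp = rng.poisson(config.false_positive_rate)
            for _ in range(n_fp):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                p = c + u * config.nucleus_radius * rng.random() ** (1 / 3)
                ch = channels[rng.integers(len(channels))]
                pos = p + drifts[r]
                if ch == offset_channel:
                    pos = pos + offset
                inten = config.fp_intensity_median * np.exp(
                    rng.normal(0, config.intensity_sigma)
                )
                rows.append(
                    dict(
                        nucleus_id=nid, round=r, channel=ch,
                        x_nm=pos[0], y_nm=pos[1], z_nm=pos[2],
                        intensity=inten, is_truth=False, truth_trace=-1, truth_locus=-1,
                    )
                )
    foci = pd.DataFrame(
        rows,
        columns=[
            "nucleus_id", "round", "channel", "x_nm", "y_nm", "z_nm",
            "intensity", "is_truth", "truth_trace", "truth_locus",
        ],
    )

    # fiducial beads: stationary, imaged every round in the 488-nm channel
    fid_pos = rng.uniform(-config.nucleus_radius, config.nucleus_radius, size=(config.n_fiducials, 2))
    fid_pos = np.column_stack([fid_pos, rng.uniform(-1000, 1000, size=config.n_fiducials)])
    frows = []
    for r in range(n_rounds):
        for i in range(config.n_fiducials):
            p = fid_pos[i] + drifts[r] + rng.normal(size=3) * jitter_sd * 0.2
            frows.append(
                dict(fiducial_id=i, round=r, channel="488", x_nm=p[0], y_nm=p[1], z_nm=p[2])
            )
    fiducials = pd.DataFrame(frows)

    # multicolor calibration beads: same physical bead seen in both channels
    brows = []
    for i in range(config.n_fiducials):
        p = fid_pos[i]
        brows.append(dict(bead_id=i, channel=channels[0], x_nm=p[0], y_nm=p[1], z_nm=p[2]))
        q = p + offset if offset_channel is not None else p
        brows.append(dict(bead_id=i, channel=offset_channel or channels[0], x_nm=q[0], y_nm=q[1], z_nm=q[2]))
    chromatic_beads = pd.DataFrame(brows)

    return ImagingExperiment(
        foci=foci,
        fiducials=fiducials,
        chromatic_beads=chromatic_beads,
        nuclei=nuclei,
        drifts=drifts,
        chromatic_offset=offset,
        ensemble=ensemble,
    )


# ---------------------------------------------------------------------------
# raster rendering


def render_zstack(
    foci: np.ndarray,
    intensities: np.ndarray | float = 1000.0,
    psf_sigma: tuple[float, float, float] = (130.0, 130.0, 280.0),
    fov_shape: tuple[int, int, int] = (16, 64, 64),
    voxel_size: tuple[float, float, float] = VOXEL_SIZE_NM,
    background: float = 10.0,
    shot_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rasterize point emitters into a (z, y, x) stack of Gaussian spots.

    ``foci`` is (n, 3) nm in (x, y, z); intensity is the total photon budget
    per focus.  Emitters outside the field of view are skipped with a
    warning.  With ``shot_noise`` the voxel counts are Poisson draws.
    """
    foci = np.atleast_2d(np.asarray(foci, dtype=float))
    inten = np.broadcast_to(np.asarray(intensities, dtype=float), (len(foci),))
    nz, ny, nx = fov_shape
    vx, vy, vz = voxel_size
    sx, sy, sz = psf_sigma
    zc = (np.arange(nz) + 0.5) * vz
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    img = np.zeros(fov_shape, dtype=float)
    for (x, y, z), a in zip(foci, inten):
        if not (0 <= x <= nx * vx and 0 <= y <= ny * vy and 0 <= z <= nz * vz):
            warnings.warn("focus outside the field of view; skipped", stacklevel=2)
            continue
        gx = np.exp(-0.5 * ((xc - x) / sx) ** 2)
        gy = np.exp(-0.5 * ((yc - y) / sy) ** 2)
        gz = np.exp(-0.5 * ((zc - z) / sz) ** 2)
        blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        total = blob.sum()
        if total > 0:
            img += a * blob / total
    img += background
    if shot_noise:
        rng = rng if rng is not None else np.random.default_rng(0)
        img = rng.poisson(img).astype(float)
    return img
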