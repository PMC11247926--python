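"""End-to-end orchestration: panel → simulate → register → link → stats → concordance.

One top-level seed drives every stage through named substreams, so a run is
reproducible bit-for-bit from its config.  Artifacts land under
``out_dir/<stage>/`` and a JSON run report reconciles record counts across
stage boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .distance_stats import (
    DistanceMatrix,
    compaction_score,
    detection_stats,
    log2_fold_change,
    median_distance_matrix,
    plot_matrix,
    write_distance_matrix,
)
from .hic_concordance import (
    align_bins,
    contact_matrix_from_array,
    distance_contact_correlation,
    fold_change_region_summary,
    write_contact_matrix,
)
from .panel_design import (
    DEFAULT_REGION,
    GenomicInterval,
    SegmentPanel,
    build_codebook,
    partition_region,
)
from .registration import (
    apply_corrections,
    estimate_chromatic_transform,
    estimate_drift,
    fit_foci,
    segment_nuclei,
)
from .synthetic_data import (
    ConformationEnsemble,
    SimulationConfig,
    conformations_to_contact_matrix,
    rng_for,
    simulate_conformations,
    simulate_imaging,
)
from .trace_linking import LinkingConfig, link_traces, refit_missing, trace_qc, traces_to_dataframe

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every offending field."""


@dataclass
class PanelConfig:
    chrom: str = DEFAULT_REGION.chrom
    start: int = DEFAULT_REGION.start
    end: int = DEFAULT_REGION.end
    assembly: str = "hg38"
    segment_length: int = 50_000
    n_channels: int = 2
    channel_names: tuple[str, ...] = ("647", "560")


@dataclass
class ConditionConfig:
    name: str = "PWS"
    scale: float = 1.0
    sub_block: tuple[int, int, float] | None = None
    n_traces: int = 200


@dataclass
class ImagingConfig:
    step_sigma: float = 120.0
    sigma_xy: float = 50.0
    sigma_z: float = 100.0
    p_det: float = 0.9
    false_positive_rate: float = 3.0
    drift_mag: float = 300.0
    chromatic_offset: tuple[float, float, float] = (60.0, 40.0, 0.0)
    n_fiducials: int = 20
    nucleus_radius: float = 6000.0


@dataclass
class LinkStageConfig:
    r_max: float = 1500.0
    expected_traces_per_nucleus: int = 1
    intensity_weight: float = 0.0
    refit_radius: float = 500.0
    refit_threshold_factor: float = 0.5
    intensity_threshold: float = 400.0
    min_completeness: float = 0.5


@dataclass
class StatsConfig:
    min_pairs: int = 10
    capture_radius: float = 150.0
    sub_block_range: tuple[int, int] | None = None


@dataclass
class ConcordanceConfig:
    method: str = "spearman"
    transform: str = "identity"
    min_separation: int = 1


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "run"
    panel: PanelConfig = field(default_factory=PanelConfig)
    conditions: list[ConditionConfig] = field(
        default_factory=lambda: [
            # maternal-deletion (PWS) allele: globally more compact, with the
            # PWRN-containing sub-block reversed (more compact in AS instead)
            ConditionConfig(name="PWS", scale=0.8, sub_block=(16, 23, 1.25), n_traces=200),
            ConditionConfig(name="AS", scale=1.0, sub_block=None, n_traces=200),
        ]
    )
    contrast: tuple[str, str] = ("PWS", "AS")
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    linking: LinkStageConfig = field(default_factory=LinkStageConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    version: str = "chromtrace-0.1.0"


# ---------------------------------------------------------------------------
# config loading / validation


def _build(cls, data: Any, path: str, errors: list[str]):
    """Construct dataclass ``cls`` from a mapping, rejecting unknown keys."""
    if isinstance(data, cls):
        return data
    if not isinstance(data, dict):
        errors.append(f"{path}: expected a mapping for {cls.__name__}")
        return cls() if cls is not RunConfig else None
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{path}.{key}: unknown key")
            continue
        f = known[key]
        sub = _SUBCONFIGS.get((cls, key))
        if sub is not None:
            if key == "conditions":
                if not isinstance(value, list):
                    errors.append(f"{path}.{key}: expected a list")
                    continue
                kwargs[key] = [
                    _build(ConditionConfig, v, f"{path}.{key}[{i}]", errors)
                    for i, v in enumerate(value)
                ]
            else:
                kwargs[key] = _build(sub, value, f"{path}.{key}", errors)
        else:
            if isinstance(value, list) and key in ("sub_block", "chromatic_offset", "contrast", "channel_names", "sub_block_range"):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{path}: {exc}")
        return None


_SUBCONFIGS = {
    (RunConfig, "panel"): PanelConfig,
    (RunConfig, "conditions"): ConditionConfig,
    (RunConfig, "imaging"): ImagingConfig,
    (RunConfig, "linking"): LinkStageConfig,
    (RunConfig, "stats"): StatsConfig,
    (RunConfig, "concordance"): ConcordanceConfig,
}


def _check_semantics(cfg: RunConfig, errors: list[str]) -> None:
    if cfg.seed is None:
        errors.append("seed: mandatory")
    if cfg.panel.end <= cfg.panel.start:
        errors.append("panel.end: must exceed panel.start")
    if cfg.panel.segment_length <= 0:
        errors.append("panel.segment_length: must be positive")
    if cfg.linking.r_max <= 0:
        errors.append("linking.r_max: must be positive")
    if cfg.linking.refit_radius <= 0:
        errors.append("linking.refit_radius: must be positive")
    if not (0 <= cfg.imaging.p_det <= 1):
        errors.append("imaging.p_det: must lie in [0, 1]")
    for i, c in enumerate(cfg.conditions):
        if c.scale <= 0:
            errors.append(f"conditions[{i}].scale: must be positive")
        if c.n_traces < 1:
            errors.append(f"conditions[{i}].n_traces: must be >= 1")
    names = [c.name for c in cfg.conditions]
    if len(set(names)) != len(names):
        errors.append("conditions: duplicate names")
    for side in cfg.contrast:
        if side not in names:
            errors.append(f"contrast: condition {side!r} not defined")
    if cfg.stats.capture_radius <= 0:
        errors.append("stats.capture_radius: must be positive")


def validate_config(source: str | Path | dict | RunConfig) -> RunConfig:
    """Load, default-fill, and validate a run config; raise ConfigError on problems."""
    if isinstance(source, RunConfig):
        data: Any = source
    elif isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text)
    errors: list[str] = []
    if isinstance(data, RunConfig):
        cfg = data
    else:
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        if "seed" not in data:
            errors.append("seed: mandatory")
            data = {**data, "seed": 0}
        cfg = _build(RunConfig, data, "config", errors)
    if cfg is not None:
        _check_semantics(cfg, errors)
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg), default=list))


# ---------------------------------------------------------------------------
# stage runners


def build_panel(cfg: RunConfig) -> SegmentPanel:
    region = GenomicInterval(cfg.panel.chrom, cfg.panel.start, cfg.panel.end, cfg.panel.assembly)
    panel = partition_region(region, cfg.panel.segment_length)
    return build_codebook(panel, cfg.panel.n_channels, cfg.panel.channel_names)


def _sim_config(cfg: RunConfig, cond: ConditionConfig, n_loci: int) -> SimulationConfig:
    im = cfg.imaging
    return SimulationConfig(
        seed=cfg.seed,
        n_traces=cond.n_traces,
        n_loci=n_loci,
        step_sigma=im.step_sigma,
        scale=cond.scale,
        sub_block=cond.sub_block,
        sigma_xy=im.sigma_xy,
        sigma_z=im.sigma_z,
        p_det=im.p_det,
        false_positive_rate=im.false_positive_rate,
        drift_mag=im.drift_mag,
        chromatic_offset=im.chromatic_offset,
        n_fiducials=im.n_fiducials,
        nucleus_radius=im.nucleus_radius,
    )


def reconstruct_condition(
    cfg: RunConfig, panel: SegmentPanel, cond: ConditionConfig, out: Path | None = None
) -> dict:
    """Simulate one condition and run the full reconstruction on it."""
    sim_cfg = _sim_config(cfg, cond, panel.n_segments)
    ens = simulate_conformations(
        sim_cfg, panel, condition=cond.name,
        rng=rng_for(cfg.seed, f"conformations:{cond.name}"),
    )
    exp = simulate_imaging(
        ens, panel, sim_cfg, rng=rng_for(cfg.seed, f"imaging:{cond.name}")
    )

    # registration: chromatic (two-color beads), then per-round drift (fiducials)
    ref_chan, mov_chan = panel.channel_names[0], panel.channel_names[1]
    beads_ref = exp.chromatic_beads[exp.chromatic_beads["channel"] == ref_chan]
    beads_mov = exp.chromatic_beads[exp.chromatic_beads["channel"] == mov_chan]
    chromatic = estimate_chromatic_transform(beads_mov, beads_ref, mode="translation")
    ref_fid = exp.fiducials[exp.fiducials["round"] == 0]
    drifts = {
        int(r): estimate_drift(exp.fiducials[exp.fiducials["round"] == r], ref_fid)
        for r in sorted(exp.fiducials["round"].unique())
    }
    registered = apply_corrections(exp.foci, chromatic, drifts, chromatic_channel=mov_chan)

    masks = segment_nuclei(nuclei_table=exp.nuclei)
    link_cfg = LinkingConfig(
        r_max=cfg.linking.r_max,
        expected_traces_per_nucleus=cfg.linking.expected_traces_per_nucleus,
        intensity_weight=cfg.linking.intensity_weight,
        refit_radius=cfg.linking.refit_radius,
        refit_threshold_factor=cfg.linking.refit_threshold_factor,
        intensity_threshold=cfg.linking.intensity_threshold,
    )
    accepted, pool, fit_qc = fit_foci(
        registered, masks, intensity_threshold=link_cfg.intensity_threshold,
        containment_margin=200.0,
    )
    traces, link_qc = link_traces(accepted, panel, link_cfg, condition=cond.name)
    traces = [refit_missing(t, pool, panel, link_cfg) for t in traces]
    kept, qc_report = trace_qc(traces, cfg.linking.min_completeness)

    dm = median_distance_matrix(
        kept, min_pairs=cfg.stats.min_pairs, condition=cond.name, bins=panel.bins()
    )
    truth_dm = median_distance_matrix(
        (ens.traces, ens.mask), min_pairs=1, condition=cond.name + "_truth", bins=panel.bins()
    )
    contact = contact_matrix_from_array(
        conformations_to_contact_matrix(ens, cfg.stats.capture_radius), panel.bins()
    )
    pairs = align_bins(dm, contact)
    conc = distance_contact_correlation(
        pairs, method=cfg.concordance.method, transform=cfg.concordance.transform,
        min_separation=cfg.concordance.min_separation,
    )

    result = dict(
        condition=cond.name,
        ensemble=ens,
        experiment=exp,
        traces=kept,
        distance=dm,
        truth_distance=truth_dm,
        contact=contact,
        concordance=conc,
        qc=dict(fit=fit_qc, link=link_qc, trace=qc_report),
        detection=detection_stats(kept) if kept else {},
        compaction=compaction_score(kept, seed=cfg.seed) if kept else {},
    )
    if out is not None:
        cdir = out / "conditions" / cond.name
        cdir.mkdir(parents=True, exist_ok=True)
        ctio.write_tsv(exp.foci, cdir / "foci.tsv")
        ctio.write_tsv(exp.fiducials, cdir / "fiducials.tsv")
        ctio.write_tsv(exp.nuclei, cdir / "nuclei.tsv")
        ctio.write_tsv(traces_to_dataframe(kept), cdir / "traces.tsv")
        write_distance_matrix(dm, cdir / "median_distance.tsv", cdir / "median_distance_nobs.tsv")
        write_contact_matrix(result["contact"], cdir / "contact.tsv")
        plot_matrix(dm.values, cdir / "median_distance.png", title=f"median distance ({cond.name})", cmap="magma_r")
        (cdir / "concordance.json").write_text(json.dumps(conc.to_dict(), indent=2))
        (cdir / "qc.json").write_text(json.dumps(result["qc"], indent=2, default=float))
    return result


def run_pipeline(config: RunConfig | dict | str | Path, write: bool = True) -> dict:
    """Execute every stage; return the run report (also written as JSON)."""
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    t0 = time.time()
    report: dict[str, Any] = {"seed": cfg.seed, "version": cfg.version, "stages": {}}
    if write:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(config_to_dict(cfg), indent=2))

    stage_t = time.time()
    panel = build_panel(cfg)
    if write:
        pdir = out / "panel"
        pdir.mkdir(exist_ok=True)
        ctio.write_segments_bed(panel, pdir / "segments.bed")
        ctio.write_codebook(panel, pdir / "codebook.tsv")
    report["stages"]["panel"] = dict(
        n_segments=panel.n_segments,
        n_rounds=panel.n_rounds,
        span_bp=panel.n_segments * panel.segment_length,
        remainder_bp=panel.remainder_bp,
        seconds=round(time.time() - stage_t, 3),
    )

    results: dict[str, dict] = {}
    for cond in cfg.conditions:
        stage_t = time.time()
        res = reconstruct_condition(cfg, panel, cond, out if write else None)
        results[cond.name] = res
        report["stages"][f"condition:{cond.name}"] = dict(
            n_traces_simulated=cond.n_traces,
            n_foci=int(len(res["experiment"].foci)),
            n_traces_kept=len(res["traces"]),
            mean_completeness=res["qc"]["trace"]["mean_completeness"],
            concordance=res["concordance"].to_dict(),
            seconds=round(time.time() - stage_t, 3),
        )

    num, den = cfg.contrast
    stage_t = time.time()
    fc = log2_fold_change(results[num]["distance"], results[den]["distance"])
    off = fc.values[np.triu_indices(len(fc.values), k=1)]
    fc_summary = dict(
        numerator=num,
        denominator=den,
        median_log2fc=float(np.nanmedian(off)),
        n_entries=int(np.isfinite(off).sum()),
    )
    if cfg.stats.sub_block_range is not None:
        fc_summary["region_summary"] = fold_change_region_summary(
            fc, cfg.stats.sub_block_range, seed=cfg.seed
        )
    else:
        num_cfg = next(c for c in cfg.conditions if c.name == num)
        if num_cfg.sub_block is not None:
            fc_summary["region_summary"] = fold_change_region_summary(
                fc, (num_cfg.sub_block[0], num_cfg.sub_block[1]), seed=cfg.seed
            )
    if write:
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        labels = results[num]["distance"].to_dataframe().index
        pd.DataFrame(fc.values, index=labels, columns=labels).to_csv(
            sdir / f"log2fc_{num}_vs_{den}.tsv", sep="\t", na_rep="NA"
        )
        plot_matrix(fc.values, sdir / f"log2fc_{num}_vs_{den}.png",
                    title=f"log2 {num}/{den}", symmetric=True)
    report["stages"]["fold_change"] = dict(**fc_summary, seconds=round(time.time() - stage_t, 3))

    report["wall_clock_seconds"] = round(time.time() - t0, 3)
    report["conditions"] = {
        name: dict(
            concordance=res["concordance"].to_dict(),
            compaction={k: v for k, v in res["compaction"].items()},
        )
        for name, res in results.items()
    }
    report["fold_change"] = fc_summary
    if write:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    report["_results"] = results
    report["_panel"] = panel
    report["_fold_change_matrix"] = fc
    return report
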