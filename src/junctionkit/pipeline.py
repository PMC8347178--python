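"""End-to-end workflow orchestration.

Runs the four-step experiment on simulated (or previously generated) data:

1. functional assays — TER fold changes and dextran flux vs control,
2. widefield immunofluorescence — junction intensity per area,
3. SMLM localization — blinking movies to localization tables,
4. spatial statistics — clustering excess at 40 nm and colocalization.

Each stage writes its artifacts (CSV/TIFF) and a JSON summary fragment
under ``outdir/<stage>/``; a completed stage is skipped on re-run so that
deleting later-stage outputs re-executes only those stages.  All
randomness flows from the named seeds in the configuration, making re-runs
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from . import functional as fn
from . import ifquant, localize, simulate, spatial

log = logging.getLogger("junctionkit")

STAGES = ("functional", "ifquant", "localize", "spatial")


@dataclass
class WorkflowConfig:
    """Workflow parameters with the study's defaults.

    The constants every stage shares live here once: effective filter area
    0.33 cm², 30 discarded frames, detection threshold 3, 80 nm/px,
    same/cross-channel histogram ranges 200/400 nm, colocalization radius
    90 nm, clustering evaluation at 40 nm.
    """

    seed: int = 1
    outdir: str = "workflow_out"
    # simulation geometry
    n_cells: int = 6
    field_size_um: tuple[float, float] = (12.8, 12.8)
    # channel placements (CLDN5-like clustered vs ZO-1-like dispersed)
    channel_a: str = "CLDN5"
    channel_b: str = "ZO1"
    channel_a_mode: str = "clustered"
    channel_b_mode: str = "dispersed"
    linear_density_per_um: float = 15.0
    cluster_sigma_nm: float = 20.0
    mean_molecules_per_cluster: float = 8.0
    coloc_fraction: float = 0.4
    # functional assays
    effects: simulate.EffectParams = field(default_factory=simulate.EffectParams)
    n_replicates: int = 6
    substrate: str = "PE"
    # widefield
    wf_pixel_nm: float = 160.0
    wf_n_slices: int = 10
    wf_belt_intensity_treated: float = 900.0
    wf_belt_intensity_control: float = 450.0
    n_junction_rois: int = 5
    roi_patch_nm: float = 1600.0
    # SMLM acquisition + detection
    acquisition: simulate.AcquisitionParams = field(
        default_factory=simulate.AcquisitionParams
    )
    detection: localize.DetectionParams = field(
        default_factory=localize.DetectionParams
    )
    mask_halfwidth_nm: float = 400.0
    # CSR null conditioning: thin rasterization of the belt support, so that
    # molecules spread uniformly along the junction are the null, not 2D CSR
    # in the (much wider) membrane mask
    csr_mask_pixel_nm: float = 20.0
    csr_mask_halfwidth_nm: float = 0.0
    # spatial statistics
    r_max_same_nm: float = 200.0
    r_max_cross_nm: float = 400.0
    bin_width_nm: float = 10.0
    coloc_radius_nm: float = 90.0
    r_eval_nm: float = 40.0
    n_csr_sim: int = 50
    render_pixel_nm: float = 20.0

    @property
    def field_size_nm(self) -> tuple[float, float]:
        return (self.field_size_um[0] * 1000.0, self.field_size_um[1] * 1000.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "WorkflowConfig":
        kwargs = dict(raw)
        if "effects" in kwargs and isinstance(kwargs["effects"], dict):
            kwargs["effects"] = simulate.EffectParams(**kwargs["effects"])
        if "acquisition" in kwargs and isinstance(kwargs["acquisition"], dict):
            kwargs["acquisition"] = simulate.AcquisitionParams(**kwargs["acquisition"])
        if "detection" in kwargs and isinstance(kwargs["detection"], dict):
            kwargs["detection"] = localize.DetectionParams(**kwargs["detection"])
        if "field_size_um" in kwargs:
            kwargs["field_size_um"] = tuple(kwargs["field_size_um"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % 2**31
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_dir(cfg: WorkflowConfig, stage: str) -> Path:
    d = Path(cfg.outdir) / f"{STAGES.index(stage):02d}_{stage}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _fragment_path(cfg: WorkflowConfig, stage: str) -> Path:
    return _stage_dir(cfg, stage) / "summary.json"


def _write_fragment(cfg: WorkflowConfig, stage: str, payload: dict) -> dict:
    _fragment_path(cfg, stage).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_functional_stage(cfg: WorkflowConfig) -> dict:
    out = _stage_dir(cfg, "functional")
    ds = simulate.generate_functional_dataset(
        cfg.effects, cfg.n_replicates, seed=cfg.stage_seed("functional"),
        substrate=cfg.substrate,
    )
    ds.ter.to_csv(out / "ter_records.csv", index=False)
    ds.flux.to_csv(out / "flux_records.csv", index=False)
    ds.standards.to_csv(out / "calibration_standards.csv", index=False)
    simulate.write_parameter_sidecar(
        out / "parameters.json", effects=cfg.effects, n_replicates=cfg.n_replicates
    )

    folds = fn.recover_ter_fold_changes(ds.ter)
    flux_pct = fn.recover_flux_percent(ds.flux, ds.standards)
    summary: dict = {"flux_percent_of_control": flux_pct}
    baseline = ds.ter.query("timepoint_h == 0")
    summary["baseline_ter_ohm_cm2"] = float(
        np.mean(
            [
                fn.compute_ter(fn.TERMeasurement(r.raw_ohm, r.blank_ohm, r.area_cm2))
                for r in baseline.itertuples()
            ]
        )
    )
    from scipy import stats

    for t, grp in folds.groupby("timepoint_h"):
        label = f"ter_fold_{t:g}h"
        summary[label] = float(grp.fold_change.mean())
        summary[label + "_sd"] = float(grp.fold_change.std(ddof=1))
        t_stat, p = stats.ttest_1samp(grp.fold_change, 1.0)
        summary[label + "_t_vs_unity"] = float(t_stat)
        summary[label + "_p_vs_unity"] = float(p)
    folds.to_csv(out / "ter_fold_changes.csv", index=False)
    return _write_fragment(cfg, "functional", summary)


def run_ifquant_stage(cfg: WorkflowConfig) -> dict:
    out = _stage_dir(cfg, "ifquant")
    seed = cfg.stage_seed("ifquant")
    geometry = simulate.generate_junction_network(
        cfg.n_cells, cfg.field_size_nm, seed=seed
    )
    mask = simulate.belt_mask(geometry, cfg.wf_pixel_nm, halfwidth_nm=cfg.wf_pixel_nm)
    rows = []
    summary: dict = {}
    for cond_idx, (condition, intensity) in enumerate(
        (
            ("treated", cfg.wf_belt_intensity_treated),
            ("control", cfg.wf_belt_intensity_control),
        )
    ):
        stack = simulate.render_widefield_if(
            geometry, intensity, substrate=cfg.substrate,  # type: ignore[arg-type]
            n_slices=cfg.wf_n_slices, seed=seed + 100 + cond_idx,
            pixel_nm=cfg.wf_pixel_nm,
        )
        tifffile.imwrite(out / f"widefield_{condition}.tif", stack)
        proj = ifquant.max_project(stack)
        rois = ifquant.sample_junction_rois(
            mask, cfg.n_junction_rois, cfg.roi_patch_nm, seed=seed
        )
        vals = [ifquant.quantify_intensity(proj, r) for r in rois]
        for i, (r, v) in enumerate(zip(rois, vals)):
            rows.append(dict(condition=condition, roi_id=i, area_px=r.area_px,
                             mean_intensity=v))
        whole = ifquant.quantify_intensity(
            proj, ifquant.ROIMask(np.ones_like(proj, dtype=bool), cfg.wf_pixel_nm)
        )
        summary[f"junction_intensity_{condition}"] = float(np.mean(vals))
        summary[f"whole_image_intensity_{condition}"] = whole
    df = pd.DataFrame(rows)
    df.to_csv(out / "roi_intensities.csv", index=False)
    cmp = fn.compare_conditions(
        df.query("condition == 'treated'").mean_intensity,
        df.query("condition == 'control'").mean_intensity,
    )
    summary["junction_intensity_t"] = cmp.t_statistic
    summary["junction_intensity_p"] = cmp.p_value
    return _write_fragment(cfg, "ifquant", summary)


def run_localize_stage(cfg: WorkflowConfig) -> dict:
    out = _stage_dir(cfg, "localize")
    seed = cfg.stage_seed("localize")
    geometry = simulate.generate_junction_network(
        cfg.n_cells, cfg.field_size_nm, seed=cfg.stage_seed("ifquant")
    )
    params_a = simulate.ClusteringParams(
        mode=cfg.channel_a_mode,  # type: ignore[arg-type]
        linear_density_per_um=cfg.linear_density_per_um,
        cluster_sigma_nm=cfg.cluster_sigma_nm,
        mean_molecules_per_cluster=cfg.mean_molecules_per_cluster,
    )
    params_b = dataclasses.replace(params_a, mode=cfg.channel_b_mode)  # type: ignore[arg-type]
    mol_a = simulate.place_fluorophores(
        geometry, params_a, seed=seed, channel=cfg.channel_a
    )
    mol_b = simulate.place_fluorophores(
        geometry, params_b, seed=seed + 1, channel=cfg.channel_b
    )
    simulate.save_ground_truth_csv(out / "ground_truth.csv", mol_a, mol_b)

    mask = simulate.belt_mask(
        geometry, cfg.acquisition.pixel_nm, halfwidth_nm=cfg.mask_halfwidth_nm
    )
    tifffile.imwrite(out / "roi_mask.tif", mask.mask.astype(np.uint8) * 255)
    csr_mask = simulate.belt_mask(
        geometry, cfg.csr_mask_pixel_nm, halfwidth_nm=cfg.csr_mask_halfwidth_nm
    )
    tifffile.imwrite(out / "csr_mask.tif", csr_mask.mask.astype(np.uint8) * 255)

    summary: dict = {}
    for mol, offset in ((mol_a, 0), (mol_b, 1)):
        stack = simulate.render_smlm_stack(
            mol, cfg.acquisition, seed=seed + 10 + offset,
            field_size_nm=cfg.field_size_nm,
        )
        tifffile.imwrite(out / f"smlm_{mol.channel}.tif", stack)
        table = localize.localize_stack(stack, cfg.detection, channel=mol.channel)
        table = localize.apply_mask(table, mask)
        table.to_csv(out / f"localizations_{mol.channel}.csv")
        img = localize.render_pointillist(table, cfg.render_pixel_nm)
        tifffile.imwrite(
            out / f"pointillist_{mol.channel}.tif",
            np.clip(img, 0, 2**16 - 1).astype(np.uint16),
        )
        summary[f"n_localizations_{mol.channel}"] = len(table)
        summary[f"density_per_nm2_{mol.channel}"] = localize.density(table)
        summary[f"n_rejections_{mol.channel}"] = len(table.rejections)
    return _write_fragment(cfg, "localize", summary)


def run_spatial_stage(cfg: WorkflowConfig) -> dict:
    loc_dir = _stage_dir(cfg, "localize")
    out = _stage_dir(cfg, "spatial")
    csr_mask = ifquant.ROIMask(
        tifffile.imread(loc_dir / "csr_mask.tif") > 0,
        pixel_nm=cfg.csr_mask_pixel_nm,
    )
    seed = cfg.stage_seed("spatial")

    tables = {
        ch: localize.LocalizationTable.from_csv(
            loc_dir / f"localizations_{ch}.csv", pixel_nm=cfg.acquisition.pixel_nm,
            channel=ch,
        )
        for ch in (cfg.channel_a, cfg.channel_b)
    }
    summary: dict = {}
    hist_rows = []
    for i, (ch, table) in enumerate(tables.items()):
        obs = spatial.pairwise_distance_histogram(
            table, cfg.r_max_same_nm, cfg.bin_width_nm
        )
        csr = spatial.csr_reference(
            len(table), csr_mask, cfg.r_max_same_nm, cfg.bin_width_nm,
            n_sim=cfg.n_csr_sim, seed=seed + i,
        )
        metric = spatial.clustering_excess(obs, csr, cfg.r_eval_nm)
        summary[f"excess_ratio_{ch}"] = metric.excess_ratio
        summary[f"clustered_{ch}"] = metric.clustered
        for lo, hi, rf, cm, cl, chi_ in zip(
            obs.bin_edges_nm[:-1], obs.bin_edges_nm[1:], obs.rel_freq,
            csr.mean, csr.envelope_lo, csr.envelope_hi,
        ):
            hist_rows.append(dict(channel=ch, bin_lo=lo, bin_hi=hi, rel_freq=rf,
                                  csr_mean=cm, csr_lo=cl, csr_hi=chi_))
    pd.DataFrame(hist_rows).to_csv(out / "distance_histograms.csv", index=False)

    coloc = spatial.colocalize(
        tables[cfg.channel_a], tables[cfg.channel_b], cfg.coloc_radius_nm
    )
    summary[f"pct_{cfg.channel_a}_coloc"] = coloc.pct_A_coloc
    summary[f"pct_{cfg.channel_b}_coloc"] = coloc.pct_B_coloc
    (out / "colocalization.json").write_text(
        json.dumps(dataclasses.asdict(coloc), indent=2)
    )
    cross = spatial.cross_pairwise_histogram(
        tables[cfg.channel_a], tables[cfg.channel_b],
        cfg.r_max_cross_nm, cfg.bin_width_nm,
    )
    pd.DataFrame(
        dict(bin_lo=cross.bin_edges_nm[:-1], bin_hi=cross.bin_edges_nm[1:],
             rel_freq=cross.rel_freq)
    ).to_csv(out / "cross_channel_histogram.csv", index=False)
    return _write_fragment(cfg, "spatial", summary)


_STAGE_RUNNERS = {
    "functional": run_functional_stage,
    "ifquant": run_ifquant_stage,
    "localize": run_localize_stage,
    "spatial": run_spatial_stage,
}


def run_workflow(cfg: WorkflowConfig, force: bool = False) -> dict:
    """Execute all stages in order and write the merged summary.

    A stage whose summary fragment already exists is skipped unless
    ``force``; any stage failure raises :class:`StageError` with the stage
    name, retaining partial outputs.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log_lines = [
        f"junctionkit {__version__} on python {platform.python_version()}",
        f"seed {cfg.seed}",
        "config " + json.dumps(dataclasses.asdict(cfg), default=str, sort_keys=True),
    ]
    summary: dict = {}
    for stage in STAGES:
        frag = _fragment_path(cfg, stage)
        if frag.exists() and not force:
            log.info("stage %s: reusing existing outputs", stage)
            summary.update(json.loads(frag.read_text()))
            log_lines.append(f"stage {stage}: reused")
            continue
        log.info("stage %s: running", stage)
        try:
            summary.update(_STAGE_RUNNERS[stage](cfg))
        except Exception as exc:  # noqa: BLE001 - tag the failing stage
            raise StageError(stage, exc) from exc
        log_lines.append(f"stage {stage}: completed")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "workflow.log").write_text("\n".join(log_lines) + "\n")
    return summary


def demo_config(outdir: str, seed: int = 1) -> WorkflowConfig:
    """Reference experiment: clustered CLDN5-like vs dispersed ZO-1-like.

    Sized to run the full four-stage workflow in a few minutes on one CPU:
    a 12.8 µm field of 6 cells, 2000-frame movies at 80 nm/px.
    """
    return WorkflowConfig(seed=seed, outdir=outdir)
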