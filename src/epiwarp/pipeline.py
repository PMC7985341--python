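"""End-to-end run: simulate -> correct (both approaches) -> assess.

One :class:`RunConfig` describes a fully reproducible experiment.  The
report mirrors the table structure of a distortion-correction assessment:
shift-map ranges, PA/AP difference statistics, between-method consistency,
boundary-registration cost, network Dice overlap, per-network shift ranges
and task-activation Z summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import fmri, metrics, phantom, topup
from .fieldmap import correct_gre
from .phantom import PhantomSpec, TaskDesign
from .topup import ReversedPair, TopupParams
from .warp import EPIGeometry, PEResamplePlan, db0_to_vsm

METHODS = ("uncorrected", "topup", "gre")


class RunConfig(BaseModel):
    """Schema-validated configuration of one simulated experiment."""

    # grid / acquisition
    grid_shape: tuple[int, int, int] = (48, 64, 32)
    voxel_size_mm: float = 2.5
    n_pe: int = 78
    echo_spacing_s: float = 0.57e-3
    accel: int = 2
    pe_axis: int = 1
    # task design
    tr_s: float = 1.0
    n_volumes: int = Field(default=140, ge=8)
    block_on_s: float = 14.0
    block_off_s: float = 14.0
    task_amplitude_pct: float = 2.0
    network_amplitude_pct: float = 1.0
    # noise
    epi_noise_frac: float = 0.02   # sd as a fraction of mean in-brain baseline
    gre_snr: float = 50.0          # 0 disables GRE image noise
    # correction
    gre_fwhm_mm: float = 4.0
    topup_knot_mm: float = 12.0
    topup_lambda_rel: float = 0.01
    topup_max_iter: int = 15
    topup_pyramid_mm: tuple[float, ...] = (8.0, 4.0, 2.0)
    n_pa: int = 10
    # analysis
    highpass_s: float = 100.0
    smooth_fwhm_mm: float = 4.0
    ica_components: int = 6
    rsn_z_thresh: float = 3.0
    glm_z_thresh: float = 2.5
    min_extent_vox: int = 10
    assign_max_orders: int = 10000
    field_scale: float = 1.0  # scales all field sources; 0 = undistorted control
    seed: int = 0

    def geometry(self) -> EPIGeometry:
        return EPIGeometry(voxel_size_pe=self.voxel_size_mm, n_pe=self.n_pe,
                           echo_spacing_s=self.echo_spacing_s, accel=self.accel,
                           pe_axis=self.pe_axis, pe_polarity=+1)

    def phantom_spec(self, seed: int) -> PhantomSpec:
        base = PhantomSpec()
        blobs = tuple((c, wdt, a * self.field_scale) for c, wdt, a in base.sinus_blobs)
        background = tuple(c * self.field_scale for c in base.background_field)
        return PhantomSpec(grid_shape=tuple(self.grid_shape),
                           voxel_size=(self.voxel_size_mm,) * 3,
                           sinus_blobs=blobs, background_field=background,
                           seed=seed)

    def task_design(self) -> TaskDesign:
        period = self.block_on_s + self.block_off_s
        total = self.tr_s * self.n_volumes
        blocks = []
        onset = self.block_off_s
        while onset + self.block_on_s <= total:
            blocks.append((onset, self.block_on_s))
            onset += period
        if not blocks:
            raise ValueError("run too short for a single task block")
        return TaskDesign(tr_s=self.tr_s, n_volumes=self.n_volumes,
                          blocks=tuple(blocks), amplitude_pct=self.task_amplitude_pct)

    def topup_params(self) -> TopupParams:
        return TopupParams(pyramid_smooth_mm=tuple(self.topup_pyramid_mm),
                           lambda_rel=self.topup_lambda_rel,
                           max_iter=self.topup_max_iter,
                           knot_spacing_mm=self.topup_knot_mm)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


#: required columns per report table; used to validate round trips
REPORT_SCHEMA = {
    "vsm_range": ["method", "min_mm", "max_mm"],
    "pair_difference": ["method", "nmse", "cross_correlation"],
    "method_consistency": ["image", "nmse", "cross_correlation"],
    "bbr": ["method", "cost"],
    "rsn_dice": ["method", "template", "component", "dice", "mean_dice"],
    "rsn_shift_range": ["method", "template", "min_mm", "max_mm"],
    "activation": ["method", "mean_z", "max_z", "n_voxels", "dice_vs_truth"],
}


@dataclass
class AssessmentReport:
    """Tabular assessment of one simulated run."""

    tables: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def __getitem__(self, key) -> pd.DataFrame:
        return self.tables[key]


def _analysis_stage(series, cfg: RunConfig, truth, ica_seed: int):
    """Preprocess one branch's series, then GLM + ICA summaries."""
    vs = (cfg.voxel_size_mm,) * 3
    pre = fmri.preprocess(series, cfg.tr_s, cfg.highpass_s, cfg.smooth_fwhm_mm, vs)
    design = cfg.task_design()
    glm_design = fmri.GLMDesign(regressor=design.regressor(), tr_s=cfg.tr_s)
    zmap, effect = fmri.fit_glm(pre, glm_design)
    act = fmri.cluster_threshold(zmap, cfg.glm_z_thresh, cfg.min_extent_vox)
    z = zmap.z_values
    act_stats = {
        "mean_z": float(z[act].mean()) if act.any() else 0.0,
        "max_z": float(z.max()),
        "n_voxels": int(act.sum()),
        "dice_vs_truth": metrics.dice(act, truth.active_mask),
    }
    maps = fmri.extract_components([pre], cfg.ica_components,
                                   mask=truth.brain_mask, seed=ica_seed)
    dmat = np.zeros((len(truth.network_masks), len(maps)))
    for ti, tmpl in enumerate(truth.network_masks):
        for ci, comp in enumerate(maps):
            dmat[ti, ci] = metrics.dice(metrics.threshold_component(comp, cfg.rsn_z_thresh), tmpl)
    assignment = metrics.assign_rsns(metrics.DiceMatrix(dmat),
                                     max_orders=cfg.assign_max_orders, seed=ica_seed)
    return act_stats, dmat, assignment


def full_run(config: RunConfig) -> AssessmentReport:
    """Simulate one run, correct it with both approaches, assess everything."""
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    geom = config.geometry()
    spec = config.phantom_spec(int(seeds[0]) % (2 ** 31))
    structural, truth = phantom.make_phantom(spec)
    field = phantom.make_field(spec)
    truth.true_field = field
    truth.true_vsm = db0_to_vsm(field, geom)
    design = config.task_design()

    base = phantom.epi_baseline(truth.tissue_labels, spec)
    noise_sd = config.epi_noise_frac * float(base[truth.brain_mask].mean())
    run = phantom.synth_epi_run(truth, field, geom, design, spec,
                                noise_sd=noise_sd,
                                network_amp_pct=config.network_amplitude_pct,
                                n_pa=config.n_pa, seed=int(seeds[1]) % (2 ** 31))
    gre_noise = 0.0 if config.gre_snr <= 0 else \
        float(structural[truth.brain_mask].mean()) / config.gre_snr
    dual = phantom.synth_dual_echo(structural, field, noise_sd=gre_noise,
                                   seed=int(seeds[2]) % (2 ** 31))

    ap_mid = np.asarray(run.ap[..., run.ap.shape[-1] // 2], dtype=float)
    pa_last = np.asarray(run.pa[..., -1], dtype=float)

    # --- correction branches -------------------------------------------------
    pair = ReversedPair(ap_volume=ap_mid, pa_volume=pa_last, geom=geom)
    topup_res = topup.estimate_field_topup(pair, config.topup_params())
    ap_c_t, pa_c_t, _mid = topup.correct_pair(pair, topup_res.vsm)
    series_t = topup.correct_series(np.asarray(run.ap, dtype=float), topup_res.vsm, geom)

    series_g, gre_field, gre_vsm = correct_gre(np.asarray(run.ap, dtype=float),
                                               dual, geom, fwhm_mm=config.gre_fwhm_mm)
    ap_c_g = PEResamplePlan(gre_vsm, geom.with_polarity(+1), "unwarp")(ap_mid)
    pa_c_g = PEResamplePlan(gre_vsm, geom.with_polarity(-1), "unwarp")(pa_last)

    mask = truth.brain_mask
    vsms = {"topup": topup_res.vsm, "gre": gre_vsm}
    pairs = {"uncorrected": (ap_mid, pa_last),
             "topup": (ap_c_t, pa_c_t),
             "gre": (ap_c_g, pa_c_g)}
    series = {"uncorrected": np.asarray(run.ap, dtype=float),
              "topup": series_t, "gre": series_g}

    # --- tables ---------------------------------------------------------------
    rows = [{"method": "truth",
             "min_mm": float(truth.true_vsm.values[mask].min()),
             "max_mm": float(truth.true_vsm.values[mask].max())}]
    for name, v in vsms.items():
        rows.append({"method": name, "min_mm": float(v.values[mask].min()),
                     "max_mm": float(v.values[mask].max())})
    vsm_range = pd.DataFrame(rows)

    pair_rows = []
    for name in METHODS:
        a, p = pairs[name]
        pair_rows.append({"method": name, "nmse": metrics.nmse(p, a, mask),
                          "cross_correlation": metrics.cross_correlation(p, a, mask)})
    pair_difference = pd.DataFrame(pair_rows)

    method_consistency = pd.DataFrame([
        {"image": "PA", "nmse": metrics.nmse(pa_c_t, pa_c_g, mask),
         "cross_correlation": metrics.cross_correlation(pa_c_t, pa_c_g, mask)},
        {"image": "AP", "nmse": metrics.nmse(ap_c_t, ap_c_g, mask),
         "cross_correlation": metrics.cross_correlation(ap_c_t, ap_c_g, mask)},
    ])

    # EPI contrast has GM (outside) brighter than WM, i.e. the expected
    # boundary contrast is inverted relative to T1; encoded as slope < 0
    bbr = pd.DataFrame([
        {"method": name,
         "cost": metrics.bbr_cost(pairs[name][0], truth.boundary_points,
                                  truth.boundary_normals, (config.voxel_size_mm,) * 3,
                                  slope=-0.5)}
        for name in METHODS])

    act_rows, dice_rows, shift_rows = [], [], []
    for mi, name in enumerate(METHODS):
        act_stats, dmat, assignment = _analysis_stage(
            series[name], config, truth, ica_seed=int(seeds[3]) % (2 ** 31) + mi)
        act_rows.append({"method": name, **act_stats})
        for ti in range(dmat.shape[0]):
            ci = assignment.mapping[ti]
            dice_rows.append({"method": name, "template": f"RSN{ti+1}",
                              "component": ci, "dice": dmat[ti, ci],
                              "mean_dice": assignment.mean_dice})
        for ti, tmpl in enumerate(truth.network_masks):
            for est_name, v in vsms.items():
                if name != est_name:
                    continue
                lo, hi = metrics.vsm_roi_range(v, tmpl & mask)
                shift_rows.append({"method": name, "template": f"RSN{ti+1}",
                                   "min_mm": lo, "max_mm": hi})

    report = AssessmentReport(
        tables={
            "vsm_range": vsm_range,
            "pair_difference": pair_difference,
            "method_consistency": method_consistency,
            "bbr": bbr,
            "rsn_dice": pd.DataFrame(dice_rows),
            "rsn_shift_range": pd.DataFrame(shift_rows),
            "activation": pd.DataFrame(act_rows),
        },
        meta={"seed": config.seed, "grid_shape": list(config.grid_shape),
              "n_volumes": config.n_volumes,
              "topup_converged": bool(topup_res.converged)},
    )
    return report


def report_tables(report: AssessmentReport, out_dir) -> list:
    """Write every table as CSV plus a short human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    lines = ["assessment summary", "=================="]
    pdiff = report["pair_difference"].set_index("method")
    for name in METHODS:
        lines.append(f"PA/AP nMSE {name:>12}: {pdiff.loc[name, 'nmse']:.4f}  "
                     f"xcorr: {pdiff.loc[name, 'cross_correlation']:.4f}")
    bbr = report["bbr"].set_index("method")
    for name in METHODS:
        lines.append(f"BBR cost   {name:>12}: {bbr.loc[name, 'cost']:.4f}")
    act = report["activation"].set_index("method")
    for name in METHODS:
        lines.append(f"activation {name:>12}: mean Z {act.loc[name, 'mean_z']:.2f}  "
                     f"max Z {act.loc[name, 'max_z']:.2f}  "
                     f"Dice vs truth {act.loc[name, 'dice_vs_truth']:.3f}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out_dir / "summary.txt")
    return written


def read_report(out_dir) -> AssessmentReport:
    """Load a written report back, validating the column schema."""
    out_dir = Path(out_dir)
    tables = {}
    for name, cols in REPORT_SCHEMA.items():
        path = out_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing report table: {path.name}")
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table {name} lacks required column(s): {missing}")
        tables[name] = df
    return AssessmentReport(tables=tables)
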