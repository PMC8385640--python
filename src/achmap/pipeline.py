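"""Configuration-driven experiment orchestration.

One experiment = (substrate condition x fibrosis layout x ACh geometry x
electrode height x noise level): build the tissue, produce the Vm movie
(phantom engine by default, monodomain solver on request), compute the
normalized/filtered 16 x 16 unipolar EGM grid, run delineation + amplitude
extraction + ROC thresholding + classification, and score against the
generator's ground-truth registry.

Profiles fix the spatial scale:

* ``full`` — 5 x 5 cm, dx 0.02 cm (251 x 251 nodes), 16 x 16 electrodes;
* ``desk`` — same physical domain and electrode mesh, dx 0.04 cm;
* ``mini`` — 2.5 x 2.5 cm, dx 0.04 cm, 8 x 8 electrodes, ACh/fibrosis
  radii scaled by half (CI-speed smoke profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from achmap import detection, tissue as tis_mod
from achmap.egm import ElectrodeGrid, compute_egm_grid, normalize, filter_egm, add_noise
from achmap.ionic import IonicParams, apply_condition
from achmap.phantom import PhantomSpec, coupled_template_bank, phantom_vm, synth_noise
from achmap.solver import PacingProtocol, initialize_states, simulate
from achmap.tissue import TissueModel, fnu_preset, ach_geometry_spec

__all__ = ["ExperimentConfig", "run_experiment", "threshold_table",
           "robustness_sweep", "PROFILES"]

PROFILES = {
    "full": {"size_cm": 5.0, "dx_cm": 0.02, "n_rows": 16, "n_cols": 16,
             "geom_scale": 1.0},
    "desk": {"size_cm": 5.0, "dx_cm": 0.04, "n_rows": 16, "n_cols": 16,
             "geom_scale": 1.0},
    "mini": {"size_cm": 2.5, "dx_cm": 0.04, "n_rows": 8, "n_cols": 8,
             "geom_scale": 0.5},
}

# Table-1 pairing of substrate condition and fibrosis burden
_CONDITION_FIBROSIS = {
    "nonAF": {"none"},
    "PxAF": {"Fu20", "Fnu1_20", "Fnu2_20"},
    "PsAF": {"Fu40", "Fnu1_40", "Fnu2_40"},
}
_D_LONG = {"nonAF": 0.003, "PxAF": 0.003, "PsAF": 0.002}
# phantom kinematics: longitudinal CV for the non-AF diffusion coefficient,
# scaled as sqrt(D) for the remodeled substrate
_CV_REF_CM_S = 70.0
_D_REF = 0.003


@dataclass(frozen=True)
class ExperimentConfig:
    condition: str = "nonAF"              # nonAF | PxAF | PsAF
    fibrosis: str = "none"                # none | Fu20 | Fu40 | Fnu{1,2}_{20,40}
    ach_geometry: str = "r050"            # r032 | r050 | r076 | mixed_050_024
    z_mm: float = 1.0
    snr_db: float | None = None
    seed: int = 0
    engine: str = "phantom"               # phantom | monodomain
    profile: str = "desk"
    allow_mismatch: bool = False
    template_beats: int = 60              # single-cell pre-pacing beats (phantom)
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in _CONDITION_FIBROSIS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.engine not in ("phantom", "monodomain"):
            raise ValueError(f"unknown engine {self.engine!r}")
        valid = _CONDITION_FIBROSIS[self.condition]
        if self.fibrosis not in valid and not self.allow_mismatch:
            raise ValueError(
                f"fibrosis {self.fibrosis!r} inconsistent with condition "
                f"{self.condition!r} (expected one of {sorted(valid)}); "
                "set allow_mismatch=True to override")
        ach_geometry_spec(self.ach_geometry)   # validates the name

    @property
    def mode(self) -> str:
        """Two-stage classification only for non-uniform diffuse fibrosis."""
        return "two_stage" if self.fibrosis.startswith("Fnu") else "one_stage"


_template_cache: dict = {}
_state_cache: dict = {}


def _get_template_bank(condition: str, zone_radius_cm: float, beats: int):
    """Distance-resolved coupled-cable template bank, memoized per process."""
    key = (condition, round(float(zone_radius_cm), 3), int(beats))
    if key not in _template_cache:
        _template_cache[key] = coupled_template_bank(
            condition, zone_radius_cm, init_s=float(beats),
            state_cache=_state_cache)
    return _template_cache[key]


def build_tissue(cfg: ExperimentConfig) -> TissueModel:
    """Construct the tissue geometry (labels, ACh map, registry) for a config."""
    prof = dict(PROFILES[cfg.profile])
    prof.update(cfg.overrides.get("profile", {}))
    size, dx = prof["size_cm"], prof["dx_cm"]
    n = int(round(size / dx)) + 1
    gs = prof["geom_scale"]
    rng = np.random.default_rng(cfg.seed)
    fib_seed = int(rng.integers(2 ** 31))
    ach_seed = int(rng.integers(2 ** 31))

    registry = []
    if cfg.fibrosis == "none":
        labels = np.zeros((n, n), dtype=np.uint8)
    elif cfg.fibrosis.startswith("Fu"):
        density = float(cfg.fibrosis[2:]) / 100.0
        labels = tis_mod.uniform_fibrosis(n, n, density, fib_seed)
    else:
        name, pct = cfg.fibrosis.split("_")
        patches = fnu_preset(name, size_cm=size)
        labels = tis_mod.patchy_fibrosis(n, n, patches, float(pct) / 100.0,
                                         fib_seed, dx=dx)
        registry.extend(patches)

    # ACh circles confined to the centrally mapped region
    radii, counts = ach_geometry_spec(cfg.ach_geometry)
    radii = [r * gs for r in radii]
    span_x = (prof["n_cols"] - 1) * 0.2      # electrode pitch 2 mm = 0.2 cm
    span_y = (prof["n_rows"] - 1) * 0.2
    margin = 0.1
    x0 = (size - span_x) / 2.0 - margin
    y0 = (size - span_y) / 2.0 - margin
    region = (x0, size - x0, y0, size - y0)
    ach, ach_patches = tis_mod.place_ach_patches(
        n, n, radii, counts, ach_seed, min_separation=0.05 * gs, dx=dx,
        region=region)
    registry.extend(ach_patches)

    return TissueModel(nx=n, ny=n, dx=dx, cell_label=labels, ach_map=ach,
                       d_long=_D_LONG[cfg.condition],
                       patch_registry=registry)


def _make_vm(cfg: ExperimentConfig, tissue: TissueModel):
    if cfg.engine == "phantom":
        cv = _CV_REF_CM_S * np.sqrt(tissue.d_long / _D_REF)
        radii, _ = ach_geometry_spec(cfg.ach_geometry)
        gs = PROFILES[cfg.profile]["geom_scale"]
        bank = _get_template_bank(cfg.condition, max(radii) * gs,
                                  cfg.template_beats)
        spec = PhantomSpec(
            tissue=tissue, cv_cm_s=cv, bank=bank,
            **cfg.overrides.get("phantom", {}))
        return phantom_vm(spec, seed=cfg.seed)
    params = apply_condition(IonicParams(), cfg.condition)
    pacing = PacingProtocol(**cfg.overrides.get("pacing", {}))
    states = initialize_states(tissue, params,
                               duration_s=cfg.overrides.get("init_s", 60.0))
    return simulate(tissue, pacing, states, params,
                    **cfg.overrides.get("solver", {}))


def _regional_r_threshold(r_a, truth_ach, sel, fallback_scores=None):
    """ROC-optimal R threshold on a subset of electrodes; falls back to the
    whole grid when the subset lacks one of the classes."""
    grid = detection.r_threshold_grid(float(np.max(r_a)))
    sub_scores, sub_truth = r_a[sel], truth_ach[sel]
    if sub_truth.size and 0 < sub_truth.sum() < sub_truth.size:
        th, se, sp, _ = detection.roc_optimal_threshold(sub_scores, sub_truth, grid)
    else:
        th, se, sp, _ = detection.roc_optimal_threshold(r_a, truth_ach, grid)
    return th


def run_experiment(cfg: ExperimentConfig, return_artifacts: bool = False):
    """Execute one configuration end to end; returns a results row (dict).

    With ``return_artifacts`` also returns a dict of the intermediate
    objects (tissue, Vm field, EGM grids, amplitude map, detection map).
    """
    tissue = build_tissue(cfg)
    field = _make_vm(cfg, tissue)

    grid = ElectrodeGrid(
        n_rows=PROFILES[cfg.profile]["n_rows"],
        n_cols=PROFILES[cfg.profile]["n_cols"],
        z_mm=cfg.z_mm, footprint="square")
    raw = compute_egm_grid(field, grid)
    base = filter_egm(normalize(raw, z_mm=cfg.z_mm), "hp2")
    # the analysis window belongs to the simulated case: delineated once on
    # the clean preprocessed EGMs and reused for every noise level
    window = detection.delineate(base)
    if cfg.snr_db is not None:
        noisy = add_noise(base, cfg.snr_db, synth_noise, seed=cfg.seed + 7919)
        egm_repol = filter_egm(noisy, "bp2_30")
        egm_depol = filter_egm(noisy, "bp2_250")
    else:
        egm_repol = egm_depol = base

    amps = detection.amplitude_maps(egm_repol, egm_depol, window=window)
    truth_ach, truth_fibro = detection.ground_truth(base.positions_mm, tissue)

    r_a, d_a = amps.r_a, amps.d_a
    row = {k: v for k, v in asdict(cfg).items() if k != "overrides"}
    if cfg.mode == "one_stage":
        r_th = _regional_r_threshold(r_a, truth_ach, np.ones_like(truth_ach))
        det = detection.classify(amps, r_th_nonfibro=r_th, mode="one_stage")
        d_th = None
        r_th_fibro = None
    else:
        d_grid = detection.d_threshold_grid(d_a)
        d_th, _, _, _ = detection.roc_optimal_threshold(
            d_a, truth_fibro, d_grid, positive_above=False)
        pred_fibro = d_a < d_th
        r_th = _regional_r_threshold(r_a, truth_ach, ~pred_fibro)
        r_th_fibro = _regional_r_threshold(r_a, truth_ach, pred_fibro)
        det = detection.classify(amps, d_th=d_th, r_th_nonfibro=r_th,
                                 r_th_fibro=r_th_fibro, mode="two_stage")
    det.truth_ach, det.truth_fibro = truth_ach, truth_fibro
    det.ac, det.se, det.fpr = detection.metrics(det.pred_ach, truth_ach)

    row.update({
        "mode": cfg.mode,
        "r_a_max": amps.r_a_max, "d_a_max": amps.d_a_max,
        "r_th_mV": r_th, "r_th_pct": 100.0 * r_th / amps.r_a_max,
        "r_th_fibro_mV": r_th_fibro,
        "r_th_fibro_pct": (100.0 * r_th_fibro / amps.r_a_max
                           if r_th_fibro is not None else np.nan),
        "d_th_mV": d_th,
        "d_th_pct": (100.0 * d_th / amps.d_a_max
                     if d_th is not None else np.nan),
        "ac": det.ac, "se": det.se, "fpr": det.fpr,
    })
    if return_artifacts:
        return row, {"tissue": tissue, "field": field, "egm_repol": egm_repol,
                     "egm_depol": egm_depol, "amps": amps, "detmap": det}
    return row


def threshold_table(rows) -> pd.DataFrame:
    """Optimal thresholds (as % of the grid maxima) grouped by fibrosis x
    ACh geometry, with row/column means appended."""
    df = pd.DataFrame(list(rows))
    tab = df.pivot_table(index="ach_geometry", columns="fibrosis",
                         values="r_th_pct", aggfunc="mean")
    tab["Mean"] = tab.mean(axis=1)
    tab.loc["Mean"] = tab.mean(axis=0)
    return tab


def robustness_sweep(base: ExperimentConfig, axis: str, values) -> pd.DataFrame:
    """Re-run one configuration along a noise (snr_db) or height (z_mm)
    axis, sharing the seed so differences are attributable to the axis."""
    if axis not in ("snr_db", "z_mm"):
        raise ValueError("axis must be 'snr_db' or 'z_mm'")
    rows = []
    for v in values:
        cfg = ExperimentConfig(**{**{k: getattr(base, k) for k in
                                     ("condition", "fibrosis", "ach_geometry",
                                      "z_mm", "snr_db", "seed", "engine",
                                      "profile", "allow_mismatch",
                                      "template_beats")},
                                  "overrides": base.overrides, axis: v})
        rows.append(run_experiment(cfg))
    return pd.DataFrame(rows)
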