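"""Fast phantom Vm movies and synthetic noise.

The phantom replaces the monodomain solve with a kinematic construction: a
planar wave of action-potential templates travels along the fiber axis at a
fixed conduction velocity, and each node plays a zone-dependent template.
Only the features the EGM/detection stages read (activation delay, upstroke
amplitude, repolarization timing and steepness) are modeled.

Templates come in three flavors: piecewise-analytic (:func:`ap_template`),
isolated-cell waveforms from paced single-cell runs
(:func:`template_from_model`), or — the default used by the experiment
pipeline — a distance-resolved bank extracted from a 1D monodomain cable
through an ACh segment (:func:`coupled_template_bank`), which captures the
electrotonic blending of repolarization across zone boundaries that
dominates the electrogram amplitude structure.  Fibroblast nodes play an
attenuated, low-pass-filtered copy of the local myocyte waveform around the
fibroblast resting potential; spatially correlated APD dispersion and
smoothing over one electrotonic space constant finish the movie.

The synthetic noise source emulates band-limited broadband electrogram
noise: Gaussian, flat across the 1-100 Hz band (an optional 1/f^alpha tilt
is available), zero mean and exactly unit power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from achmap.ionic import IonicParams, paced_trace, apd90
from achmap.solver import VmField
from achmap.tissue import TissueModel, FIBROBLAST

__all__ = ["PhantomSpec", "ap_template", "template_from_model",
           "coupled_templates", "coupled_template_bank", "phantom_vm",
           "synth_noise"]


def ap_template(duration_ms: float, sample_dt: float = 1.0,
                rest: float = -81.0, amplitude: float = 105.0,
                apd90_ms: float = 280.0, phase3_tau: float = 12.0,
                upstroke_tau: float = 0.4) -> np.ndarray:
    """Piecewise-analytic AP waveform sampled every ``sample_dt`` ms.

    Fast exponential upstroke, gently sloping plateau, exponential phase-3
    collapse; the plateau end time is calibrated so the waveform's APD90
    matches ``apd90_ms``.  Smaller ``phase3_tau`` means a steeper phase 3
    (the ACh signature).
    """
    t = np.arange(0.0, duration_ms, sample_dt)

    def wave(t_end):
        up = 1.0 - np.exp(-np.maximum(t, 0.0) / upstroke_tau)
        plateau = 1.0 - 0.30 * np.clip(t / max(t_end, 1e-6), 0.0, 1.5)
        gate = 1.0 / (1.0 + np.exp((t - t_end) / phase3_tau))
        return rest + amplitude * up * np.maximum(plateau, 0.0) * gate

    # calibrate t_end by bisection on the measured APD90
    lo, hi = 5.0, duration_ms
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        v = wave(mid)
        try:
            a = apd90(t, v)
        except ValueError:
            hi = mid
            continue
        if a < apd90_ms:
            lo = mid
        else:
            hi = mid
    return wave(0.5 * (lo + hi))


def template_from_model(params: IonicParams, cl: float = 1000.0,
                        n_beats: int = 60, dt: float = 0.01,
                        sample_dt: float = 1.0) -> np.ndarray:
    """Last-beat AP waveform of a paced single cell, t = 0 at stimulus onset.

    ``n_beats`` at the tissue cycle length reproduces the steady-state
    pre-pacing used to initialize tissue nodes (60 beats at CL 1000 ms = 1
    minute).
    """
    t, vm, _ = paced_trace(params, cl=cl, n_beats=n_beats, dt=dt,
                           sample_dt=sample_dt)
    return vm


ZONE_WIDTH_FACTOR = 1.4   # slab width emulating a disc of radius r (see note)


def coupled_templates(condition: str, zone_radius_cm: float,
                      dx: float = 0.04, length_cm: float = 5.0,
                      dt: float = 0.01, init_s: float = 60.0,
                      record_ms: float = 600.0, dose_uM: float = 0.1,
                      state_cache: dict | None = None):
    """Tissue-coupled AP templates from a 1D monodomain cable.

    Electrotonic loading markedly slows phase 3 inside small ACh patches
    (surrounding plateau tissue feeds depolarizing current into the zone),
    so isolated-cell waveforms overstate the zone/surround repolarization
    contrast.  A cable of ``length_cm`` with a central ACh slab of width
    ``ZONE_WIDTH_FACTOR * zone_radius_cm`` — the slab whose boundary-to-area
    loading matches a disc of the given radius, calibrated once against a
    2D reference solve — is paced for one beat from single-cell steady
    state; the activation-aligned waveforms at the slab center and far from
    the slab become the phantom's ACh and background templates.

    Returns ``(tpl_myo, tpl_ach)`` sampled at 1 ms, index 10 = activation.
    """
    from achmap.solver import PacingProtocol, initialize_states, simulate
    from achmap.tissue import TissueModel
    from achmap.ionic import apply_condition

    n = int(round(length_cm / dx)) + 1
    y = np.arange(n) * dx
    ach = np.zeros((n, 1))
    half = 0.5 * ZONE_WIDTH_FACTOR * zone_radius_cm
    ach[np.abs(y - length_cm / 2) <= half, 0] = dose_uM
    d_long = 0.002 if condition == "PsAF" else 0.003
    tis = TissueModel(nx=1, ny=n, dx=dx, ach_map=ach, d_long=d_long)
    params = apply_condition(IonicParams(), condition)
    states = initialize_states(tis, params, duration_s=init_s,
                               cache=state_cache)
    f = simulate(tis, PacingProtocol(cl=record_ms, n_beats=1), states, params,
                 dt_range=(dt, dt), sample_dt=1.0)
    vm = f.vm[:, :, 0]

    def aligned(node):
        w = vm[:, node]
        act = int(np.argmax(np.diff(w)))
        pre = 10
        out = np.empty(vm.shape[0])
        out[:] = w[-1]
        seg = w[max(act - pre, 0):]
        out[: seg.size] = seg
        out[seg.size:] = seg[-1]
        return out

    return aligned(int(0.8 * n)), aligned(n // 2)


def coupled_template_bank(condition: str, zone_radius_cm: float,
                          dx: float = 0.04, length_cm: float = 5.0,
                          dt: float = 0.01, init_s: float = 60.0,
                          record_ms: float = 600.0, dose_uM: float = 0.1,
                          reach_cm: float = 1.0,
                          state_cache: dict | None = None):
    """Distance-resolved coupled AP templates from the same 1D cable.

    Electrotonic coupling blends repolarization across the zone boundary in
    BOTH directions: tissue just outside an ACh patch repolarizes earlier
    than the far field, and the zone core later than an isolated ACh cell.
    The bank samples the cable's activation-aligned waveforms as a function
    of signed distance to the slab boundary (positive inside, negative
    outside, clamped at ``reach_cm`` outside and the slab half-width
    inside), averaging the entering- and leaving-side nodes so the template
    is orientation-agnostic.

    Returns ``(distances_cm, waveforms)`` with ``waveforms[k]`` the template
    for signed rim distance ``distances_cm[k]``; index 10 = activation.
    """
    from achmap.solver import PacingProtocol, initialize_states, simulate
    from achmap.tissue import TissueModel
    from achmap.ionic import apply_condition

    n = int(round(length_cm / dx)) + 1
    y = np.arange(n) * dx
    half = 0.5 * ZONE_WIDTH_FACTOR * zone_radius_cm
    ach = np.zeros((n, 1))
    ach[np.abs(y - length_cm / 2) <= half, 0] = dose_uM
    d_long = 0.002 if condition == "PsAF" else 0.003
    tis = TissueModel(nx=1, ny=n, dx=dx, ach_map=ach, d_long=d_long)
    params = apply_condition(IonicParams(), condition)
    states = initialize_states(tis, params, duration_s=init_s,
                               cache=state_cache)
    f = simulate(tis, PacingProtocol(cl=record_ms, n_beats=1), states, params,
                 dt_range=(dt, dt), sample_dt=1.0)
    vm = f.vm[:, :, 0]
    nt = vm.shape[0]

    def aligned(node):
        w = vm[:, node]
        act = int(np.argmax(np.diff(w)))
        out = np.empty(nt)
        seg = w[max(act - 10, 0):]
        out[: seg.size] = seg
        out[seg.size:] = seg[-1]
        return out

    y_in = length_cm / 2 - half          # entering-side boundary
    y_out = length_cm / 2 + half         # leaving-side boundary
    dists = np.arange(-reach_cm, half + dx / 2, dx)
    waveforms = np.empty((dists.size, nt))
    for k, s in enumerate(dists):
        n1 = int(round((y_in + s) / dx))
        n2 = int(round((y_out - s) / dx))
        waveforms[k] = 0.5 * (aligned(n1) + aligned(n2))
    return dists, waveforms


@dataclass
class PhantomSpec:
    """Geometry, kinematics and waveform assignment of a phantom movie."""
    tissue: TissueModel
    cv_cm_s: float = 70.0
    sample_dt: float = 1.0
    duration_ms: float = 500.0
    tpl_myo: np.ndarray | None = None      # sampled at sample_dt, t0 = activation
    tpl_ach: np.ndarray | None = None
    bank: tuple | None = None              # (distances_cm, waveforms): overrides
                                           # the two-template mode when given
    fibro_amp_scale: float = 1.0           # extra myocyte depression in fibrotic
                                           # patches; depolarization-amplitude loss
                                           # emerges from fibroblast mixing alone,
                                           # as in the monodomain reference
    fibro_delay_ms: float = 4.0            # activation delay inside fibrotic patches
    fibro_jitter_ms: float = 2.0           # per-node activation jitter (uniform +-)
    fibroblast_gain: float = 0.30          # electrotonic attenuation at fibroblasts
    fibroblast_rest: float = -49.6
    fibroblast_smooth_ms: float = 6.0
    space_constant_cm: float = 0.05        # electrotonic smoothing of the movie
    apd_cv: float = 0.04                   # cell-to-cell APD dispersion (std/mean)
    apd_corr_cm: float = 0.3               # correlation length of the dispersion
    ap_kwargs: dict = field(default_factory=dict)

    def resolve_templates(self):
        if self.bank is not None:
            return
        if self.tpl_myo is None:
            self.tpl_myo = ap_template(self.duration_ms, self.sample_dt,
                                       apd90_ms=280.0, phase3_tau=12.0,
                                       **self.ap_kwargs)
        if self.tpl_ach is None:
            self.tpl_ach = ap_template(self.duration_ms, self.sample_dt,
                                       rest=-85.0, apd90_ms=150.0,
                                       phase3_tau=4.0, **self.ap_kwargs)


def _sample_delayed(tpl: np.ndarray, t: np.ndarray, delay: np.ndarray,
                    dt: float, stretch: np.ndarray | None = None) -> np.ndarray:
    """Linear interpolation of a template at (t - delay); clamped ends.

    ``stretch`` locally rescales the template's time axis (per node), which
    lengthens or shortens the played-back APD without moving activation.
    """
    rest = tpl[0]
    phase = (t[:, None] - delay[None, :]) / dt
    if stretch is not None:
        phase = phase / stretch[None, :]
    k = np.floor(phase).astype(np.int64)
    frac = phase - k
    k0 = np.clip(k, 0, tpl.size - 1)
    k1 = np.clip(k + 1, 0, tpl.size - 1)
    out = tpl[k0] * (1.0 - frac) + tpl[k1] * frac
    out[k < 0] = rest
    return out


def _fibro_region_mask(tissue: TissueModel) -> np.ndarray:
    """Nodes inside fibrotic patches (Fnu), or any fibroblast-bearing node
    neighborhood for uniform fibrosis."""
    fib_patches = [p for p in tissue.patch_registry if p.kind == "fibrosis"]
    if fib_patches:
        xg, yg = tissue.node_coords()
        mask = np.zeros((tissue.ny, tissue.nx), dtype=bool)
        for p in fib_patches:
            mask |= (xg - p.cx) ** 2 + (yg - p.cy) ** 2 <= p.r ** 2
        return mask
    return tissue.cell_label == FIBROBLAST


def phantom_vm(spec: PhantomSpec, seed: int = 0) -> VmField:
    """Build the phantom Vm movie for the spec's tissue geometry."""
    if spec.cv_cm_s <= 0:
        raise ValueError("conduction velocity must be > 0")
    spec.resolve_templates()
    tis = spec.tissue
    ny, nx = tis.ny, tis.nx
    n = ny * nx
    dt = spec.sample_dt
    t = np.arange(0.0, spec.duration_ms, dt)
    rng = np.random.default_rng(seed)

    # activation delay: planar wave along the fiber axis from the paced edge
    xg, yg = tis.node_coords()
    coord = yg if tis.fiber_axis == "y" else xg
    delay = coord / spec.cv_cm_s * 1000.0          # ms
    region = _fibro_region_mask(tis)
    is_fib = (tis.cell_label == FIBROBLAST)
    in_region = region | is_fib
    if np.any(in_region):
        jit = rng.uniform(-spec.fibro_jitter_ms, spec.fibro_jitter_ms, (ny, nx))
        delay = delay + in_region * (spec.fibro_delay_ms + jit)
    delay = delay.ravel()

    is_ach = (tis.ach_map > 0).ravel()
    is_fib = is_fib.ravel()
    in_region = in_region.ravel()

    # spatially correlated repolarization-time dispersion (cell-to-cell
    # variability): a smoothed Gaussian field stretches each node's template
    # time axis, leaving activation untouched
    if spec.apd_cv > 0:
        from scipy.ndimage import gaussian_filter
        g = rng.standard_normal((ny, nx))
        g = gaussian_filter(g, spec.apd_corr_cm / tis.dx, mode="nearest")
        g *= spec.apd_cv / max(g.std(), 1e-12)
        stretch = (1.0 + g).ravel()
    else:
        stretch = np.ones(n)

    vm = np.empty((t.size, n))
    rests = np.empty(n)
    if spec.bank is not None:
        # distance-resolved templates: each node plays the cable waveform of
        # its signed distance to the nearest ACh-zone boundary
        from scipy.ndimage import distance_transform_edt
        dists_b, wfs = spec.bank
        mask = tis.ach_map > 0
        if mask.any():
            d_in = distance_transform_edt(mask) * tis.dx
            d_out = distance_transform_edt(~mask) * tis.dx
            signed = np.where(mask, d_in, -d_out).ravel()
        else:
            signed = np.full(n, dists_b[0])
        idx = np.clip(np.searchsorted(dists_b, signed), 0, dists_b.size - 1)
        for k in np.unique(idx):
            sel = idx == k
            vm[:, sel] = _sample_delayed(wfs[k], t, delay[sel], dt, stretch[sel])
            rests[sel] = wfs[k][0]
    else:
        for ach_flag, tpl in ((False, spec.tpl_myo), (True, spec.tpl_ach)):
            sel = is_ach == ach_flag
            if not np.any(sel):
                continue
            vm[:, sel] = _sample_delayed(tpl, t, delay[sel], dt, stretch[sel])
            rests[sel] = tpl[0]

    # depressed upstroke for myocytes inside fibrotic patches
    dep = in_region & ~is_fib
    if np.any(dep):
        vm[:, dep] = rests[dep] + spec.fibro_amp_scale * (vm[:, dep] - rests[dep])
    # passive fibroblast response: attenuated, smoothed local waveform
    if np.any(is_fib):
        w = max(int(round(spec.fibroblast_smooth_ms / dt)), 1)
        kern = np.ones(w) / w
        sig = vm[:, is_fib]
        pad = np.concatenate([np.tile(rests[is_fib], (w, 1)), sig,
                              sig[-1:].repeat(w, axis=0)], axis=0)
        sm = np.apply_along_axis(
            lambda s: np.convolve(s, kern, mode="same"), 0, pad)[w:w + t.size]
        vm[:, is_fib] = (spec.fibroblast_rest
                         + spec.fibroblast_gain * (sm - rests[is_fib]))
    movie = vm.reshape(t.size, ny, nx)
    if spec.space_constant_cm > 0:
        # electrotonic coupling smooths Vm over roughly one space constant;
        # without this the sharp zone boundaries overstate the EGM peaks
        from scipy.ndimage import gaussian_filter1d
        sigma = spec.space_constant_cm / tis.dx
        movie = gaussian_filter1d(movie, sigma, axis=1, mode="nearest")
        movie = gaussian_filter1d(movie, sigma, axis=2, mode="nearest")
    field = VmField(vm=movie, sample_dt=dt, dx=tis.dx,
                    t0=0.0, meta={"source": "phantom", "cv_cm_s": spec.cv_cm_s,
                                  "seed": seed})
    return field


def synth_noise(n_samples: int, sample_dt: float, band=(1.0, 100.0),
                seed: int = 0, alpha: float = 0.0) -> np.ndarray:
    """Zero-mean, exactly unit-power, band-limited noise segment.

    Gaussian white noise is band-limited to ``band`` (Hz) — flat by
    default, with an optional 1/f^alpha tilt — then renormalized to unit
    empirical power.  The flat default keeps the in-band share of the
    2-30 Hz repolarization band comparable to broadband clinical EGM noise,
    whose power sits mostly above 30 Hz.
    """
    fs = 1000.0 / sample_dt
    lo, hi = band
    if not 0 < lo < hi or hi > fs / 2:
        raise ValueError(f"band {band} infeasible at fs = {fs} Hz")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    f = np.fft.rfftfreq(n_samples, d=sample_dt / 1000.0)
    X = np.fft.rfft(x)
    shape = np.zeros_like(f)
    inband = (f >= lo) & (f <= hi)
    shape[inband] = (f[inband] / lo) ** (-alpha)
    y = np.fft.irfft(X * shape, n=n_samples)
    y -= y.mean()
    p = np.mean(y ** 2)
    if p <= 0:
        raise ValueError("degenerate noise segment")
    return y / np.sqrt(p)
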