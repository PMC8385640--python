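"""ACh-release-site detection from a grid of unipolar EGMs.

Pipeline: (1) automatic delineation of the repolarization time window TW
around the grid-wide absolute repolarization peak; (2) per-electrode signed
repolarization amplitude R_A (largest-|.|(local extremum) inside TW, sign
kept) and depolarization peak-to-peak amplitude D_A (EGM onset to TW onset);
(3) ROC-scanned thresholds — D_th flags fibrotic electrodes (low D_A), R_th
flags ACh electrodes (high R_A), with separate R_th in fibrotic vs
non-fibrotic regions when fibrosis is non-uniform; (4) accuracy /
sensitivity / false-positive-rate scoring against the generator's patch
registry.

Label codes: 0 non-ACh, 1 ACh, 2 non-ACh+fibro, 3 ACh+fibro.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from achmap.egm import EgmGrid
from achmap.tissue import TissueModel

__all__ = [
    "LABEL_NONACH", "LABEL_ACH", "LABEL_NONACH_FIBRO", "LABEL_ACH_FIBRO",
    "RepolWindow", "AmplitudeMap", "DetectionMap",
    "delineate", "repol_amplitude", "depol_amplitude", "amplitude_maps",
    "d_threshold_grid", "r_threshold_grid", "roc_optimal_threshold",
    "classify", "ground_truth", "metrics",
]

LABEL_NONACH = 0
LABEL_ACH = 1
LABEL_NONACH_FIBRO = 2
LABEL_ACH_FIBRO = 3

T_R_SEARCH_DELAY = 100.0   # ms after t_ref before searching the repol peak
TW_BEFORE = 30.0           # ms of window before t_R
TW_AFTER = 150.0           # ms of window after t_R
ONSET_FRACTION = 0.05      # depol onset: first |phi| above 5% of depol max


@dataclass(frozen=True)
class RepolWindow:
    """Repolarization analysis window, absolute times on the EGM time axis."""
    t_ref: float     # max depolarization slope (grid reference, t = 0)
    t_R: float       # grid-global absolute repolarization peak
    tw_on: float
    tw_off: float

    def __post_init__(self):
        if not self.tw_off > self.tw_on:
            raise ValueError("tw_off must exceed tw_on")
        if self.tw_on < self.t_ref + T_R_SEARCH_DELAY - TW_BEFORE - 1e-9:
            raise ValueError("window starts before the delineation search range")


@dataclass
class AmplitudeMap:
    r_a: np.ndarray           # signed repolarization amplitude (mV)
    d_a: np.ndarray           # depolarization peak-to-peak (mV), >= 0
    r_tie: np.ndarray         # flag: |min| == |max| tie broken positive
    window: RepolWindow
    depol_onset: float        # ms, absolute

    @property
    def r_a_max(self) -> float:
        return float(np.max(self.r_a))

    @property
    def d_a_max(self) -> float:
        return float(np.max(self.d_a))


@dataclass
class DetectionMap:
    label: np.ndarray
    truth_ach: np.ndarray | None = None
    truth_fibro: np.ndarray | None = None
    thresholds: dict = field(default_factory=dict)
    ac: float | None = None
    se: float | None = None
    fpr: float | None = None

    @property
    def pred_ach(self) -> np.ndarray:
        return (self.label == LABEL_ACH) | (self.label == LABEL_ACH_FIBRO)

    @property
    def pred_fibro(self) -> np.ndarray:
        return self.label >= LABEL_NONACH_FIBRO


# ---------------------------------------------------------------------------
# Delineation and amplitudes
# ---------------------------------------------------------------------------
def delineate(egm: EgmGrid) -> RepolWindow:
    """Locate the repolarization window of one mapped case.

    The depolarization reference t_ref is the median over electrodes of each
    electrode's steepest-negative-slope time.  The grid-global repolarization
    peak t_R is the maximum |phi| over all electrodes at least 100 ms after
    t_ref; TW = [t_R - 30 ms, t_R + 150 ms].
    """
    phi = egm.phi
    t = egm.t
    dphi = np.diff(phi, axis=-1)
    steepest = np.argmin(dphi, axis=-1)          # most negative slope
    t_ref = float(np.median(t[steepest]))
    sel = t >= t_ref + T_R_SEARCH_DELAY
    if not np.any(sel):
        raise ValueError("no samples beyond the repolarization search onset")
    absphi = np.abs(phi[..., sel])
    peak = float(absphi.max())
    depol_scale = float(np.abs(phi).max())
    if peak < 1e-9 or peak < 1e-6 * depol_scale:
        raise ValueError("no repolarization peak found (flat after depolarization)")
    k = int(np.argmax(absphi.max(axis=(0, 1))))
    t_r = float(t[sel][k])
    return RepolWindow(t_ref=t_ref, t_R=t_r, tw_on=t_r - TW_BEFORE,
                       tw_off=t_r + TW_AFTER)


def _local_extrema(x: np.ndarray):
    """Indices of strict-sign-change local extrema; plateaus resolve to the
    earliest sample of the plateau."""
    dx = np.diff(x)
    sign = np.sign(dx)
    # propagate the last nonzero slope sign across plateaus
    for k in range(1, sign.size):
        if sign[k] == 0:
            sign[k] = sign[k - 1]
    turn = np.nonzero((sign[1:] * sign[:-1]) < 0)[0] + 1
    # map each turning point to the earliest sample of a flat top
    out = []
    for k in turn:
        j = k
        while j > 0 and x[j - 1] == x[j]:
            j -= 1
        out.append(j)
    return np.array(sorted(set(out)), dtype=int)


def repol_amplitude(x: np.ndarray, t: np.ndarray, window: RepolWindow,
                    with_flag: bool = False):
    """Signed repolarization amplitude: the in-window local extremum of
    largest absolute value, sign preserved.

    An exact |min| == |max| tie resolves to the positive value (positive
    peaks are the ACh signature) and is flagged.  If the signal is monotonic
    inside TW the window endpoints supply the extrema.
    """
    sel = (t >= window.tw_on) & (t <= window.tw_off)
    if not np.any(sel):
        raise ValueError("empty repolarization window")
    xs = np.asarray(x, dtype=float)[sel]
    idx = _local_extrema(xs)
    if idx.size:
        cand = xs[idx]
        lo, hi = float(cand.min()), float(cand.max())
    else:
        lo, hi = float(xs.min()), float(xs.max())
    tie = bool(abs(lo) == abs(hi) and lo != hi)
    val = hi if abs(hi) >= abs(lo) else lo
    if with_flag:
        return float(val), tie
    return float(val)


def depol_amplitude(x: np.ndarray, t: np.ndarray, seg_on: float,
                    seg_off: float) -> float:
    """Depolarization peak-to-peak amplitude over [seg_on, seg_off]."""
    sel = (t >= seg_on) & (t <= seg_off)
    if not np.any(sel):
        raise ValueError("empty depolarization segment")
    xs = np.asarray(x, dtype=float)[sel]
    return float(xs.max() - xs.min())


def _grid_onset(phi: np.ndarray, t: np.ndarray, t_ref: float) -> float:
    """EGM onset: first sample where the grid-max |phi| exceeds 5% of the
    grid depolarization maximum, searched before t_ref."""
    env = np.abs(phi).max(axis=(0, 1))
    pre = t <= t_ref
    if not np.any(pre):
        return float(t[0])
    dmax = float(env[pre].max())
    above = np.nonzero(env >= ONSET_FRACTION * dmax)[0]
    return float(t[above[0]]) if above.size else float(t[0])


def amplitude_maps(egm_repol: EgmGrid, egm_depol: EgmGrid | None = None,
                   window: RepolWindow | None = None) -> AmplitudeMap:
    """Per-electrode R_A and D_A maps.

    ``egm_repol`` drives delineation and the repolarization amplitudes; the
    depolarization amplitudes are taken from ``egm_depol`` when given (the
    wide-band filtered signals under noise), else from ``egm_repol``.
    """
    if egm_depol is None:
        egm_depol = egm_repol
    if window is None:
        window = delineate(egm_repol)
    t = egm_repol.t
    nr, nc, _ = egm_repol.phi.shape
    r_a = np.empty((nr, nc))
    tie = np.zeros((nr, nc), dtype=bool)
    d_a = np.empty((nr, nc))
    onset = _grid_onset(egm_depol.phi, egm_depol.t, window.t_ref)
    for r in range(nr):
        for c in range(nc):
            r_a[r, c], tie[r, c] = repol_amplitude(
                egm_repol.phi[r, c], t, window, with_flag=True)
            d_a[r, c] = depol_amplitude(egm_depol.phi[r, c], egm_depol.t,
                                        onset, window.tw_on)
    return AmplitudeMap(r_a=r_a, d_a=d_a, r_tie=tie, window=window,
                        depol_onset=onset)


# ---------------------------------------------------------------------------
# ROC threshold search
# ---------------------------------------------------------------------------
def d_threshold_grid(d_a: np.ndarray, n: int = 40, step_mv: float = 0.1):
    """40 candidate D thresholds centered at the global mean, 0.1 mV steps."""
    mean = float(np.mean(d_a))
    return mean + step_mv * np.arange(-n // 2, n // 2)


def r_threshold_grid(r_a_max: float, span=(-0.80, 0.80), step: float = 0.01):
    """Candidate R thresholds in 1% steps of the grid maximum R_A.

    The default span covers -80%..+80% (about 160 values): fibrotic-region
    optima can be negative.
    """
    pct = np.arange(span[0], span[1] + step / 2, step)
    return pct * r_a_max


def roc_optimal_threshold(scores: np.ndarray, truth: np.ndarray,
                          thresholds: np.ndarray, positive_above: bool = True):
    """Exhaustive ROC scan: the threshold whose (FPR, Se) point is nearest
    (Euclidean) to the perfect corner (0, 1).

    Ties resolve to the median of the tied thresholds, which places the
    operating point mid-gap when the classes are separable.  Returns
    ``(threshold, se, sp, roc)`` with ``roc`` a dict of arrays.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both classes in the truth labels")
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    se = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for k, th in enumerate(thresholds):
        pred = scores > th if positive_above else scores < th
        se[k] = np.count_nonzero(pred & truth) / n_pos
        fpr[k] = np.count_nonzero(pred & ~truth) / n_neg
    dist = np.hypot(fpr, 1.0 - se)
    best = np.nonzero(np.isclose(dist, dist.min(), rtol=0, atol=1e-12))[0]
    k = int(best[best.size // 2])
    roc = {"thresholds": thresholds, "se": se, "fpr": fpr, "distance": dist}
    return float(thresholds[k]), float(se[k]), float(1.0 - fpr[k]), roc


# ---------------------------------------------------------------------------
# Classification and scoring
# ---------------------------------------------------------------------------
def classify(amps: AmplitudeMap, d_th: float | None = None,
             r_th_nonfibro: float | None = None,
             r_th_fibro: float | None = None,
             mode: str = "one_stage") -> DetectionMap:
    """Label every electrode.

    ``one_stage`` (no fibrosis, or uniform diffuse fibrosis): ACh iff
    R_A > r_th_nonfibro.  ``two_stage``: an electrode is fibrotic iff
    D_A < d_th, then ACh iff R_A exceeds the threshold of its region.
    """
    if mode not in ("one_stage", "two_stage"):
        raise ValueError(f"unknown mode {mode!r}")
    if r_th_nonfibro is None:
        raise ValueError("r_th_nonfibro is required")
    label = np.full(amps.r_a.shape, LABEL_NONACH, dtype=np.int8)
    if mode == "one_stage":
        label[amps.r_a > r_th_nonfibro] = LABEL_ACH
    else:
        if d_th is None or r_th_fibro is None:
            raise ValueError("two_stage requires d_th and r_th_fibro")
        fibro = amps.d_a < d_th
        ach = np.where(fibro, amps.r_a > r_th_fibro, amps.r_a > r_th_nonfibro)
        label[~fibro & ach] = LABEL_ACH
        label[fibro & ~ach] = LABEL_NONACH_FIBRO
        label[fibro & ach] = LABEL_ACH_FIBRO
    ths = {"d_th": d_th, "r_th_nonfibro": r_th_nonfibro,
           "r_th_fibro": r_th_fibro, "mode": mode}
    return DetectionMap(label=label, thresholds=ths)


def ground_truth(positions_mm: np.ndarray, tissue: TissueModel):
    """Per-electrode truth from the tissue's patch registry.

    An electrode is ACh-true iff its center lies inside an ACh circle
    (boundary counts as inside) and fibrosis-true iff inside a fibrotic
    patch; the two flags are independent.
    """
    pos_cm = positions_mm / 10.0
    x = pos_cm[..., 0]
    y = pos_cm[..., 1]
    ach = np.zeros(x.shape, dtype=bool)
    fib = np.zeros(x.shape, dtype=bool)
    for p in tissue.patch_registry:
        mask = (x - p.cx) ** 2 + (y - p.cy) ** 2 <= p.r ** 2
        if p.kind == "ACh":
            ach |= mask
        else:
            fib |= mask
    return ach, fib


def metrics(pred: np.ndarray, truth: np.ndarray):
    """(accuracy, sensitivity, false-positive rate); positives are ACh."""
    pred = np.asarray(pred, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    n = pred.size
    if n == 0:
        raise ValueError("empty prediction")
    tp = np.count_nonzero(pred & truth)
    tn = np.count_nonzero(~pred & ~truth)
    fp = np.count_nonzero(pred & ~truth)
    fn = np.count_nonzero(~pred & truth)
    ac = (tp + tn) / n
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return ac, se, fpr
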