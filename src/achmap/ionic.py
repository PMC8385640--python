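"""Atrial cell electrophysiology: Courtemanche myocyte and MacCannell fibroblast.

The myocyte is the Courtemanche–Ramirez–Nattel human atrial model (21 state
variables) extended with the acetylcholine-activated potassium current IKACh
in the Kneller formulation.  Persistent-AF electrical remodeling is expressed
as multiplicative scalings of the Ito, ICaL and IKur maximal conductances.
Fibroblasts follow the MacCannell "active" model (membrane potential plus the
r/s gates of the time-dependent K+ current; intracellular ion concentrations
held at their steady values).

All transmembrane currents are expressed in pA/pF; voltages in mV; time in ms;
concentrations in mM.  A positive stimulus current depolarizes.

Integration uses Rush–Larsen exponential updates for the 15 gating variables
and forward Euler for Vm and the 5 concentration variables, stable for
dt <= 0.01 ms at the doses and pacing rates used here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "IonicParams",
    "CellState",
    "MYOCYTE_STATE_NAMES",
    "FIBROBLAST_STATE_NAMES",
    "myocyte_rhs",
    "fibroblast_rhs",
    "ikach",
    "apply_condition",
    "variability_grid",
    "steady_state_init",
    "paced_trace",
    "apd90",
]

# ---------------------------------------------------------------------------
# Physical constants and maximal conductances (Courtemanche et al. 1998)
# ---------------------------------------------------------------------------
R_GAS = 8.3143          # J/(mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C/mmol
RTF = R_GAS * TEMP / FARADAY

CM_MYO = 100.0          # pF
V_CELL = 20100.0        # um^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

K_O = 5.4               # mM
NA_O = 140.0
CA_O = 1.8

G_NA = 7.8              # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

K_REL = 30.0
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8
TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0
KQ10 = 3.0

# IKACh dose-response ([ACh] in uM): Kneller-form conductance
# GMAX/(1 + 9.13652/[ACh]^0.477811) nS/pF with inward-rectifying voltage
# dependence 0.0517 + 0.4516/(1 + exp((V + 59.53)/17.18)).  The saturating
# conductance is rescaled from Kneller's canine value (10 nS/pF) to 2 nS/pF,
# which places the updated dose-response in the submicromolar range: 0.1 uM
# then shortens the human atrial APD90 by roughly half (about 300 -> 150 ms)
# instead of nearly abolishing the plateau, keeping the ACh repolarization
# wave inside the delineated analysis window across substrates.
IKACH_GMAX = 2.0
IKACH_KD = 9.13652
IKACH_HILL = 0.477811
IKACH_C1 = 0.0517
IKACH_C2 = 0.4516
IKACH_V_HALF = 59.53
IKACH_V_SLOPE = 17.18

# MacCannell et al. 2007 active fibroblast constants
CM_FIB = 6.3            # pF
G_KV_FIB = 0.25         # nS/pF
G_K1_FIB = 0.4822
G_B_NA_FIB = 0.0095
I_NAK_MAX_FIB = 2.002
KM_K_FIB = 1.0
KM_NA_FIB = 11.0
KI_FIB = 129.4349       # mM, held fixed
NAI_FIB = 8.5547

MYOCYTE_STATE_NAMES = (
    "vm", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "nai", "ki", "cai", "ca_up", "ca_rel",
)
FIBROBLAST_STATE_NAMES = ("vm", "r", "s")

N_STATE = 21
N_GATE = 15      # state indices 1..15 are gates
N_STATE_FIB = 3

# Published initial conditions (quiescent, Courtemanche et al. 1998 Table)
MYOCYTE_Y0 = np.array([
    -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1, 4.966e-3,
    9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1, 7.755e-1, 0.0, 1.0,
    9.992e-1, 11.17, 139.0, 1.013e-4, 1.488, 1.488,
])

# Fibroblast rest found by integrating the model to equilibrium (see tests)
FIBROBLAST_Y0 = np.array([-49.6, 0.06, 0.97])


# ---------------------------------------------------------------------------
# Parameter / state containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class IonicParams:
    """Conductance scalings, ACh dose and model variant for one cell."""

    scale_gto: float = 1.0
    scale_gCaL: float = 1.0
    scale_gKur: float = 1.0
    scale_gK1: float = 1.0
    ach_uM: float = 0.0
    cm: float = CM_MYO
    model_variant: str = "myocyte"

    def __post_init__(self):
        for name in ("scale_gto", "scale_gCaL", "scale_gKur", "scale_gK1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ach_uM < 0:
            raise ValueError("ach_uM must be >= 0")
        if self.model_variant not in ("myocyte", "fibroblast"):
            raise ValueError(f"unknown model_variant {self.model_variant!r}")


@dataclass
class CellState:
    """Full ODE state of a single cell, with named access.

    ``y`` is the flat state vector in the order of
    :data:`MYOCYTE_STATE_NAMES` (myocyte) or
    :data:`FIBROBLAST_STATE_NAMES` (fibroblast).
    """

    y: np.ndarray
    variant: str = "myocyte"

    @classmethod
    def resting(cls, variant: str = "myocyte") -> "CellState":
        y0 = MYOCYTE_Y0 if variant == "myocyte" else FIBROBLAST_Y0
        return cls(y=y0.copy(), variant=variant)

    @property
    def names(self) -> tuple:
        return MYOCYTE_STATE_NAMES if self.variant == "myocyte" else FIBROBLAST_STATE_NAMES

    @property
    def vm(self) -> float:
        return float(self.y[0])

    def __getitem__(self, name: str) -> float:
        return float(self.y[self.names.index(name)])

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.names, self.y)}

    @classmethod
    def from_dict(cls, d: dict, variant: str = "myocyte") -> "CellState":
        names = MYOCYTE_STATE_NAMES if variant == "myocyte" else FIBROBLAST_STATE_NAMES
        return cls(y=np.array([d[n] for n in names], dtype=float), variant=variant)

    def validate(self):
        if not np.all(np.isfinite(self.y)):
            raise FloatingPointError("non-finite cell state (numerical blow-up)")
        if self.variant == "myocyte":
            gates = self.y[1:1 + N_GATE]
            if np.any(gates < -1e-9) or np.any(gates > 1 + 1e-9):
                raise ValueError("gating variables out of [0, 1]")
            if np.any(self.y[16:] <= 0):
                raise ValueError("intracellular concentrations must be > 0")


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------
@njit(cache=True)
def _ikach_current(vm, ach, ek):
    if ach <= 0.0:
        return 0.0
    g = IKACH_GMAX / (1.0 + IKACH_KD / ach ** IKACH_HILL)
    rect = IKACH_C1 + IKACH_C2 / (1.0 + math.exp((vm + IKACH_V_HALF) / IKACH_V_SLOPE))
    return g * rect * (vm - ek)


@njit(cache=True)
def _myocyte_eval(y, gto_s, gcal_s, gkur_s, gk1_s, ach, inf, tau, dconc):
    """Evaluate currents, gate targets/time-constants and concentration rates.

    Fills ``inf``/``tau`` (length 15, aligned with state indices 1..15) and
    ``dconc`` (length 5: Nai, Ki, Cai, Ca_up, Ca_rel).  Returns total ionic
    current in pA/pF.
    """
    v = y[0]
    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]; d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; vv = y[14]; w = y[15]
    nai = y[16]; ki = y[17]; cai = y[18]; caup = y[19]; carel = y[20]

    ena = RTF * math.log(NA_O / nai)
    ek = RTF * math.log(K_O / ki)
    eca = 0.5 * RTF * math.log(CA_O / cai)

    # --- currents (pA/pF) ---
    ina = G_NA * m * m * m * h * jj * (v - ena)
    ik1 = gk1_s * G_K1 * (v - ek) / (1.0 + math.exp(0.07 * (v + 80.0)))
    ito = gto_s * G_TO * oa * oa * oa * oi * (v - ek)
    gkur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    ikur = gkur_s * gkur * ua * ua * ua * ui * (v - ek)
    ikr = G_KR * xr * (v - ek) / (1.0 + math.exp((v + 15.0) / 22.4))
    iks = G_KS * xs * xs * (v - ek)
    ical = gcal_s * G_CAL * d * f * fca * (v - 65.0)
    ipca = I_PCA_MAX * cai / (0.0005 + cai)
    sigma = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                  + 0.0365 * sigma * math.exp(-v / RTF))
    inak = I_NAK_MAX * fnak / (1.0 + (KM_NA_I / nai) ** 1.5) * K_O / (K_O + KM_K_O)
    expg = math.exp(GAMMA * v / RTF)
    expg1 = math.exp((GAMMA - 1.0) * v / RTF)
    inaca = I_NACA_MAX * (expg * nai ** 3 * CA_O - expg1 * NA_O ** 3 * cai) / (
        (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * expg1))
    ibna = G_B_NA * (v - ena)
    ibca = G_B_CA * (v - eca)
    ikach = _ikach_current(v, ach, ek)

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak + inaca
            + ibna + ibca + ikach)

    # --- SR fluxes ---
    irel = K_REL * u * u * vv * w * (carel - cai)
    itr = (caup - carel) / TAU_TR
    iup = I_UP_MAX / (1.0 + K_UP / cai)
    iupleak = I_UP_MAX * caup / CA_UP_MAX

    # --- gates: m h j ---
    dv = v + 47.13
    if abs(dv) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-v / 11.0)
    inf[0] = am / (am + bm); tau[0] = 1.0 / (am + bm)

    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp(-(v + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    inf[1] = ah / (ah + bh); tau[1] = 1.0 / (ah + bh)
    inf[2] = aj / (aj + bj); tau[2] = 1.0 / (aj + bj)

    # --- gates: oa oi (Ito) ---
    aoa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    boa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau[3] = 1.0 / ((aoa + boa) * KQ10)
    inf[3] = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    aoi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    boi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    tau[4] = 1.0 / ((aoi + boi) * KQ10)
    inf[4] = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))

    # --- gates: ua ui (IKur) ---
    aua = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    bua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau[5] = 1.0 / ((aua + bua) * KQ10)
    inf[5] = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    aui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    bui = math.exp((v - 158.0) / 16.0)
    tau[6] = 1.0 / ((aui + bui) * KQ10)
    inf[6] = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))

    # --- gates: xr xs ---
    dv = v + 14.1
    if abs(dv) < 1e-10:
        axr = 0.0015
    else:
        axr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = v - 3.3328
    if abs(dv) < 1e-10:
        bxr = 3.7836118e-4
    else:
        bxr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    tau[7] = 1.0 / (axr + bxr)
    inf[7] = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5))

    dv = v - 19.9
    if abs(dv) < 1e-10:
        axs = 6.8e-4
        bxs = 3.15e-4
    else:
        axs = 4e-5 * dv / (1.0 - math.exp(-dv / 17.0))
        bxs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    tau[8] = 0.5 / (axs + bxs)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-(v - 19.9) / 12.7))

    # --- gates: d f fca ---
    dv = v + 10.0
    if abs(dv) < 1e-10:
        tau[9] = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e = math.exp(-dv / 6.24)
        tau[9] = (1.0 - e) / (0.035 * dv * (1.0 + e))
    inf[9] = 1.0 / (1.0 + math.exp(-dv / 8.0))
    tau[10] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * dv * dv) + 0.02)
    inf[10] = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    tau[11] = TAU_F_CA
    inf[11] = 1.0 / (1.0 + cai / 0.00035)

    # --- gates: u v w (SR release), driven by Fn ---
    # Fn uses currents in pA (scaled by Cm)
    fn = 1e-12 * V_REL * irel - (5e-13 / FARADAY) * (
        0.5 * ical * CM_MYO - 0.2 * inaca * CM_MYO)
    tau[12] = TAU_U
    inf[12] = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau[13] = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    inf[13] = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    dv = v - 7.9
    if abs(dv) < 1e-10:
        tau[14] = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-dv / 5.0)
        tau[14] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)
    inf[14] = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))

    # --- concentrations ---
    dconc[0] = CM_MYO * (-3.0 * inak - 3.0 * inaca - ibna - ina) / (FARADAY * V_I)
    dconc[1] = CM_MYO * (2.0 * inak - ik1 - ito - ikur - ikr - iks - ikach) / (
        FARADAY * V_I)
    b1 = (CM_MYO * (2.0 * inaca - ipca - ical - ibca) / (2.0 * FARADAY * V_I)
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) ** 2)
          + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) ** 2))
    dconc[2] = b1 / b2
    dconc[3] = iup - iupleak - itr * V_REL / V_UP
    dconc[4] = (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN / ((carel + KM_CSQN) ** 2))

    return iion


@njit(cache=True)
def _myocyte_derivs(y, gto_s, gcal_s, gkur_s, gk1_s, ach, istim, dy):
    inf = np.empty(N_GATE)
    tau = np.empty(N_GATE)
    dconc = np.empty(5)
    iion = _myocyte_eval(y, gto_s, gcal_s, gkur_s, gk1_s, ach, inf, tau, dconc)
    dy[0] = -iion + istim
    for k in range(N_GATE):
        dy[1 + k] = (inf[k] - y[1 + k]) / tau[k]
    for k in range(5):
        dy[16 + k] = dconc[k]
    return iion


@njit(cache=True)
def _myocyte_step(y, dt, gto_s, gcal_s, gkur_s, gk1_s, ach, istim, lap,
                  inf, tau, dconc):
    """One Rush–Larsen / forward-Euler step in place; returns dVm/dt."""
    iion = _myocyte_eval(y, gto_s, gcal_s, gkur_s, gk1_s, ach, inf, tau, dconc)
    dvdt = -iion + istim + lap
    y[0] += dt * dvdt
    for k in range(N_GATE):
        y[1 + k] = inf[k] + (y[1 + k] - inf[k]) * math.exp(-dt / tau[k])
    for k in range(5):
        y[16 + k] += dt * dconc[k]
    return dvdt


@njit(cache=True)
def _fibroblast_eval(y, inf, tau):
    v = y[0]
    r = y[1]
    s = y[2]
    ekf = RTF * math.log(K_O / KI_FIB)
    enaf = RTF * math.log(NA_O / NAI_FIB)

    ikv = G_KV_FIB * r * s * (v - ekf)
    vk = v - ekf
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (vk - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (vk + 100.0)) + math.exp(0.1 * (vk - 10.0))) / (
        1.0 + math.exp(-0.5 * vk))
    ik1 = G_K1_FIB * ak1 / (ak1 + bk1) * vk
    inak = (I_NAK_MAX_FIB * K_O / (K_O + KM_K_FIB)
            * NAI_FIB ** 1.5 / (NAI_FIB ** 1.5 + KM_NA_FIB ** 1.5)
            * (v + 150.0) / (v + 200.0))
    ibna = G_B_NA_FIB * (v - enaf)

    inf[0] = 1.0 / (1.0 + math.exp(-(v + 20.0) / 11.0))
    tau[0] = 20.3 + 138.0 * math.exp(-((v + 20.0) / 25.9) ** 2)
    inf[1] = 1.0 / (1.0 + math.exp((v + 23.0) / 7.0))
    tau[1] = 1574.0 + 5268.0 * math.exp(-((v + 23.0) / 22.7) ** 2)

    return ikv + ik1 + inak + ibna


@njit(cache=True)
def _fibroblast_derivs(y, i_coupling, dy):
    inf = np.empty(2)
    tau = np.empty(2)
    iion = _fibroblast_eval(y, inf, tau)
    dy[0] = -iion + i_coupling
    dy[1] = (inf[0] - y[1]) / tau[0]
    dy[2] = (inf[1] - y[2]) / tau[1]
    return iion


@njit(cache=True)
def _fibroblast_step(y, dt, i_coupling, lap, inf, tau):
    iion = _fibroblast_eval(y, inf, tau)
    dvdt = -iion + i_coupling + lap
    y[0] += dt * dvdt
    y[1] = inf[0] + (y[1] - inf[0]) * math.exp(-dt / tau[0])
    y[2] = inf[1] + (y[2] - inf[1]) * math.exp(-dt / tau[1])
    return dvdt


@njit(cache=True)
def _pace_single_cell(y, variant_fib, duration_ms, dt, cl, stim_amp, stim_dur,
                      gto_s, gcal_s, gkur_s, gk1_s, ach,
                      sample_dt, record):
    """Integrate one cell with edge pacing; optionally record Vm.

    ``record`` is a preallocated float64 array; Vm is written every
    ``sample_dt`` ms until the array is full (pass a length-0 array to skip
    recording).  Returns the number of samples written.
    """
    n_steps = int(round(duration_ms / dt))
    inf = np.empty(N_GATE)
    tau = np.empty(N_GATE)
    dconc = np.empty(5)
    n_rec = record.shape[0]
    k_rec = 0
    next_rec = 0.0
    for step in range(n_steps):
        t = step * dt
        phase = t % cl
        istim = stim_amp if phase < stim_dur else 0.0
        if variant_fib:
            _fibroblast_step(y, dt, 0.0, 0.0, inf, tau)
        else:
            _myocyte_step(y, dt, gto_s, gcal_s, gkur_s, gk1_s, ach, istim,
                          0.0, inf, tau, dconc)
        if k_rec < n_rec and t + dt >= next_rec - 1e-9:
            record[k_rec] = y[0]
            k_rec += 1
            next_rec += sample_dt
        if not math.isfinite(y[0]):
            return -1
    return k_rec


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------
def ikach(vm, ach_uM, ek):
    """IKACh current density (pA/pF), Kneller formulation, [ACh] in uM.

    Zero at zero agonist, reverses at ``vm == ek``, magnitude strictly
    increasing with dose at fixed driving force.
    """
    if np.any(np.asarray(ach_uM) < 0):
        raise ValueError("ach_uM must be >= 0")
    vm = np.asarray(vm, dtype=float)
    ach = np.asarray(ach_uM, dtype=float)
    g = np.where(ach > 0, IKACH_GMAX / (1.0 + IKACH_KD / np.where(ach > 0, ach, 1.0) ** IKACH_HILL), 0.0)
    rect = IKACH_C1 + IKACH_C2 / (1.0 + np.exp((vm + IKACH_V_HALF) / IKACH_V_SLOPE))
    out = g * rect * (vm - ek)
    return out if out.ndim else float(out)


def myocyte_rhs(state: CellState, params: IonicParams, t: float = 0.0,
                i_stim: float = 0.0) -> np.ndarray:
    """Time-derivatives of the full Courtemanche(+IKACh) state (units/ms)."""
    state.validate()
    dy = np.empty(N_STATE)
    _myocyte_derivs(state.y, params.scale_gto, params.scale_gCaL,
                    params.scale_gKur, params.scale_gK1, params.ach_uM,
                    i_stim, dy)
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite derivative (numerical blow-up)")
    return dy


def fibroblast_rhs(state: CellState, params: IonicParams | None = None,
                   coupling_current: float = 0.0) -> np.ndarray:
    """Time-derivatives of the MacCannell fibroblast state (units/ms)."""
    if state.variant != "fibroblast":
        raise ValueError("state is not a fibroblast state")
    if not np.all(np.isfinite(state.y)):
        raise FloatingPointError("non-finite cell state (numerical blow-up)")
    dy = np.empty(N_STATE_FIB)
    _fibroblast_derivs(state.y, coupling_current, dy)
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite derivative (numerical blow-up)")
    return dy


def apply_condition(params: IonicParams, condition: str) -> IonicParams:
    """Apply AF electrical remodeling: PsAF scales Ito x0.5, ICaL x0.3, IKur x0.5."""
    if condition in ("nonAF", "PxAF"):
        return params
    if condition == "PsAF":
        return replace(params, scale_gto=params.scale_gto * 0.5,
                       scale_gCaL=params.scale_gCaL * 0.3,
                       scale_gKur=params.scale_gKur * 0.5)
    raise ValueError(f"unknown condition {condition!r}")


def variability_grid(levels=(-30.0, -15.0, 0.0, 15.0, 30.0)):
    """Cartesian product of percent offsets applied to gK1 and gCaL.

    The default five levels give the 25 ionic combinations used for
    cell-to-cell variability studies.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    mult = [1.0 + l / 100.0 for l in levels]
    return [(mk1, mcal) for mk1 in mult for mcal in mult]


def apd90(t: np.ndarray, vm: np.ndarray) -> float:
    """APD at 90% repolarization from a single-AP Vm trace.

    Activation is the time of maximum dVm/dt; the AP ends when Vm first
    crosses ``peak - 0.9 * (peak - rest)`` after the peak (linear
    interpolation between samples).  Raises if no AP is present.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    dv = np.diff(vm) / np.diff(t)
    i_act = int(np.argmax(dv))
    if dv[i_act] < 1.0:
        raise ValueError("no action potential upstroke in trace")
    rest = vm[:max(i_act, 1)].min() if i_act > 0 else vm[0]
    i_peak = i_act + int(np.argmax(vm[i_act:]))
    peak = vm[i_peak]
    v90 = peak - 0.9 * (peak - rest)
    below = np.nonzero(vm[i_peak:] <= v90)[0]
    if below.size == 0:
        raise ValueError("AP does not reach 90% repolarization in trace")
    k = i_peak + below[0]
    # linear interpolation of the crossing time
    t_cross = t[k - 1] + (t[k] - t[k - 1]) * (vm[k - 1] - v90) / (vm[k - 1] - vm[k])
    return float(t_cross - t[i_act])


DEFAULT_STIM_AMP = 20.0     # pA/pF depolarizing
DEFAULT_STIM_DUR = 2.0      # ms


def paced_trace(params: IonicParams, cl: float = 1000.0, n_beats: int = 5,
                dt: float = 0.01, sample_dt: float = 0.5,
                y0: np.ndarray | None = None,
                stim_amplitude: float = DEFAULT_STIM_AMP,
                stim_duration: float = DEFAULT_STIM_DUR):
    """Pace a single cell and return ``(t, vm, state)`` for the last beat.

    ``t`` is relative to the last stimulus onset.
    """
    fib = params.model_variant == "fibroblast"
    y = (y0.copy() if y0 is not None
         else (FIBROBLAST_Y0.copy() if fib else MYOCYTE_Y0.copy()))
    pre_ms = cl * (n_beats - 1)
    if pre_ms > 0:
        rc = _pace_single_cell(y, fib, pre_ms, dt, cl, stim_amplitude,
                               stim_duration, params.scale_gto, params.scale_gCaL,
                               params.scale_gKur, params.scale_gK1, params.ach_uM,
                               1.0, np.empty(0))
        if rc < 0:
            raise FloatingPointError("single-cell integration blew up")
    n_rec = int(round(cl / sample_dt))
    record = np.empty(n_rec)
    rc = _pace_single_cell(y, fib, cl, dt, cl, stim_amplitude, stim_duration,
                           params.scale_gto, params.scale_gCaL,
                           params.scale_gKur, params.scale_gK1, params.ach_uM,
                           sample_dt, record)
    if rc < 0:
        raise FloatingPointError("single-cell integration blew up")
    t = np.arange(rc) * sample_dt
    return t, record[:rc], CellState(y=y, variant=params.model_variant)


def steady_state_init(params: IonicParams, cl: float = 1000.0,
                      duration_s: float = 60.0, dt: float = 0.01,
                      apd_tol: float = 0.01) -> CellState:
    """State after pacing at fixed cycle length for ``duration_s`` seconds.

    Emulates pre-pacing to steady state at CL 1000 ms for 1 min; warns if the
    APD90 of the last two beats still differs by more than ``apd_tol``
    (relative).  ``duration_s = 0`` returns the published initial conditions.
    """
    if cl <= 0:
        raise ValueError("cl must be > 0")
    fib = params.model_variant == "fibroblast"
    y = FIBROBLAST_Y0.copy() if fib else MYOCYTE_Y0.copy()
    if duration_s == 0:
        return CellState(y=y, variant=params.model_variant)
    total_beats = max(int(round(duration_s * 1000.0 / cl)), 1)
    stim = 0.0 if fib else DEFAULT_STIM_AMP
    if total_beats > 2:
        rc = _pace_single_cell(y, fib, cl * (total_beats - 2), dt, cl, stim,
                               DEFAULT_STIM_DUR, params.scale_gto,
                               params.scale_gCaL, params.scale_gKur,
                               params.scale_gK1, params.ach_uM, 1.0, np.empty(0))
        if rc < 0:
            raise FloatingPointError("single-cell integration blew up")
    apds = []
    for _ in range(min(total_beats, 2)):
        n_rec = int(round(cl / 0.5))
        record = np.empty(n_rec)
        rc = _pace_single_cell(y, fib, cl, dt, cl, stim, DEFAULT_STIM_DUR,
                               params.scale_gto, params.scale_gCaL,
                               params.scale_gKur, params.scale_gK1,
                               params.ach_uM, 0.5, record)
        if rc < 0:
            raise FloatingPointError("single-cell integration blew up")
        if not fib:
            try:
                apds.append(apd90(np.arange(rc) * 0.5, record[:rc]))
            except ValueError:
                apds.append(np.nan)
    if len(apds) == 2 and np.all(np.isfinite(apds)):
        rel = abs(apds[1] - apds[0]) / max(apds[1], 1e-9)
        if rel > apd_tol:
            warnings.warn(
                f"steady-state pacing not converged: APD90 changed by "
                f"{100 * rel:.2f}% between the last two beats "
                f"({apds[0]:.1f} -> {apds[1]:.1f} ms)", RuntimeWarning)
    return CellState(y=y, variant=params.model_variant)
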