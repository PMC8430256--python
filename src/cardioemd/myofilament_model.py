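"""Myofilament contraction driven by an imposed calcium transient.

Implements the Rice-type lumped sarcomere model: calcium binding to high-
and low-affinity troponin sites, cooperative regulatory-unit switching
between non-permissive (N) and permissive (P) states, a four-state
crossbridge cycle (N, P, pre-rotation XB, post-rotation XB) with
mean-distortion dynamics, filament-overlap geometry, passive/preload/
afterload force balance, and sarcomere-length (SL) evolution against a
series elastic element.

Coupling to the electrophysiology is one-way: the model consumes the
final-beat Ca_i(t) trace; neither force nor length feeds back.

Units: time in ms, lengths in μm, Ca in mM, rates in 1/ms, forces
normalized (the kPa conversion is a single output scale ``t_max_kpa``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .ionic_model import EPTrace

__all__ = [
    "MechParameters",
    "MechState",
    "MechTrace",
    "MechDivergenceError",
    "troponin_update",
    "single_overlap",
    "regulatory_rates",
    "crossbridge_rates",
    "duty_fractions",
    "xb_cycle_update",
    "distortion_update",
    "total_force",
    "step_sl",
    "initial_mech_state",
    "run_twitch",
]


class MechDivergenceError(RuntimeError):
    """Mechanics integration left its physical operating range."""

    def __init__(self, message: str, time_ms: float | None = None):
        super().__init__(message)
        self.time_ms = time_ms


@dataclass(frozen=True)
class MechParameters:
    """Constants of the myofilament model (source-model values).

    Base transition rates are referenced to 37 °C; each carries a Q10-style
    temperature factor with exponent (TmpC − 37)/10, so at the default
    temperature every factor is exactly 1.
    """

    tmpc: float = 37.0              # operating temperature, °C

    # Ca–troponin binding (mM⁻¹ms⁻¹ / ms⁻¹)
    k_on: float = 50.0
    k_off_l: float = 0.25
    k_off_h: float = 0.025
    q_kon: float = 1.5
    q_koff: float = 1.3

    # regulatory N<->P switching (ms⁻¹)
    k_n_p: float = 0.5              # N→P base rate (500 s⁻¹)
    k_p_n: float = 0.05             # P→N base rate (50 s⁻¹)
    q_kn_p: float = 1.6
    q_kp_n: float = 1.6
    perm50: float = 0.5             # half-activation constant
    n_perm: float = 15.0            # Hill coefficient of activation
    inverse_perm_cap: float = 100.0

    # crossbridge cycle base rates (ms⁻¹)
    f_app: float = 0.5
    g_app: float = 0.07
    h_f: float = 2.0
    h_b: float = 0.4
    g_xb: float = 0.07
    q_fapp: float = 6.25
    q_gapp: float = 2.5
    q_hf: float = 6.25
    q_hb: float = 6.25
    q_gxb: float = 6.25
    g_sl_mod: float = 6.0           # detachment speed-up at low thick overlap
    h_f_mdc: float = 5.0            # strain sensitivity of isomerization
    h_b_mdc: float = 0.0
    sigma_p: float = 8.0            # strain sensitivity of gxb (shortening)
    sigma_n: float = 1.0            # strain sensitivity of gxb (stretch)

    # strain / distortion
    x_0: float = 0.007              # mean strain of the post-rotation state, μm
    phi: float = 2.0                # empirical distortion scale

    # sarcomere geometry (μm)
    len_thin: float = 1.2
    len_thick: float = 1.65
    len_hbare: float = 0.1
    sl_0: float = 1.9               # initial sarcomere length
    sl_rest: float = 1.85           # passive-force rest length
    sl_min: float = 1.4
    sl_max: float = 2.4

    # passive force (normalized force units)
    p_con_titin: float = 0.002
    p_exp_titin: float = 10.0
    sl_collagen: float = 2.25
    p_con_collagen: float = 0.02
    p_exp_collagen: float = 70.0

    # force balance
    kse: float = 1.0                # series-element stiffness, norm force/μm
    viscosity: float = 0.003        # norm force·ms/μm
    mass: float = 5e-5              # norm force·ms²/μm
    # default mode: the cell contracts against a constant 20 kPa "weight"
    # with a rigid stop at SL_0, so shortening begins only once developed
    # tension exceeds the weight; "series_elastic" swaps in the
    # KSE·(SL − SL_0) afterload instead
    contraction_mode: str = "afterloaded_isotonic"
    afterload_kpa: float = 20.0     # weight in afterloaded_isotonic mode

    # reporting
    t_max_kpa: float = 250.0        # kPa per unit normalized force
    # internal Euler step: the SL/series-element/mass subsystem oscillates at
    # sqrt(KSE/mass) ≈ 141 rad/ms, so explicit Euler needs dt well under
    # 2·(visc/mass)/(KSE/mass) ≈ 0.003 ms to be stable
    dt: float = 0.001

    def __post_init__(self):
        if not (1.4 <= self.sl_0 <= 2.4):
            raise ValueError("SL_0 outside the sarcomere operating range")
        if self.contraction_mode not in ("series_elastic", "afterloaded_isotonic"):
            raise ValueError(
                "contraction_mode must be series_elastic or afterloaded_isotonic")

    def _tf(self, q: float) -> float:
        """Temperature factor Q^((TmpC−37)/10)."""
        return q ** ((self.tmpc - 37.0) / 10.0)

    def as_array(self) -> np.ndarray:
        p = np.zeros(34)
        p[0] = self.k_on * self._tf(self.q_kon)
        p[1] = self.k_off_l * self._tf(self.q_koff)
        p[2] = self.k_off_h * self._tf(self.q_koff)
        p[3] = self.k_n_p * self._tf(self.q_kn_p)
        p[4] = self.k_p_n * self._tf(self.q_kp_n)
        p[5] = self.perm50
        p[6] = self.n_perm
        p[7] = self.inverse_perm_cap
        p[8] = self.f_app * self._tf(self.q_fapp)
        p[9] = self.g_app * self._tf(self.q_gapp)
        p[10] = self.h_f * self._tf(self.q_hf)
        p[11] = self.h_b * self._tf(self.q_hb)
        p[12] = self.g_xb * self._tf(self.q_gxb)
        p[13] = self.g_sl_mod
        p[14] = self.h_f_mdc
        p[15] = self.h_b_mdc
        p[16] = self.sigma_p
        p[17] = self.sigma_n
        p[18] = self.x_0
        p[19] = self.phi
        p[20] = self.len_thin
        p[21] = self.len_thick
        p[22] = self.len_hbare
        p[23] = self.sl_0
        p[24] = self.sl_rest
        p[25] = self.p_con_titin
        p[26] = self.p_exp_titin
        p[27] = self.sl_collagen
        p[28] = self.p_con_collagen
        p[29] = self.p_exp_collagen
        p[30] = self.kse
        p[31] = self.viscosity
        p[32] = self.mass
        p[33] = (self.afterload_kpa / self.t_max_kpa
                 if self.contraction_mode == "afterloaded_isotonic" else -1.0)
        return p


# state-vector order used by the kernel
MECH_STATE_NAMES = (
    "n_noxb", "p_noxb", "n_xb", "p_xb", "xb_prer", "xb_postr",
    "x_prer", "x_postr", "catrop_l", "catrop_h", "sl", "integral_force",
)


@dataclass
class MechState:
    """Myofilament state: regulatory pools, crossbridge occupancies,
    mean distortions, troponin saturations, SL and the force integral."""

    n_noxb: float
    p_noxb: float
    n_xb: float
    p_xb: float
    xb_prer: float
    xb_postr: float
    x_prer: float
    x_postr: float
    catrop_l: float
    catrop_h: float
    sl: float
    integral_force: float = 0.0

    def validate(self):
        occ = (self.n_noxb, self.p_noxb, self.n_xb, self.p_xb,
               self.xb_prer, self.xb_postr)
        if any(o < -1e-9 for o in occ):
            raise MechDivergenceError("negative state occupancy")
        if not (0.0 <= self.catrop_l <= 1.0 and 0.0 <= self.catrop_h <= 1.0):
            raise MechDivergenceError("troponin saturation outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MECH_STATE_NAMES])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MechState":
        return cls(*[float(v) for v in y])

    def copy(self) -> "MechState":
        return MechState.from_array(self.as_array())


@dataclass
class MechTrace:
    """Twitch output: normalized/physical tension and normalized length."""

    dt: float
    tension_norm: np.ndarray
    tension_kpa: np.ndarray
    length_norm: np.ndarray

    def __post_init__(self):
        self.tension_norm = np.asarray(self.tension_norm, dtype=np.float64)
        self.tension_kpa = np.asarray(self.tension_kpa, dtype=np.float64)
        self.length_norm = np.asarray(self.length_norm, dtype=np.float64)
        n = len(self.tension_norm)
        if len(self.tension_kpa) != n or len(self.length_norm) != n:
            raise ValueError("trace arrays must have equal length")
        for arr in (self.tension_norm, self.tension_kpa, self.length_norm):
            if not np.all(np.isfinite(arr)):
                raise ValueError("trace contains non-finite samples")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.tension_norm)) * self.dt

    def to_csv(self, path, sep=","):
        """Write columns time_ms, tension_norm, tension_kPa, length_norm."""
        data = np.column_stack([self.time, self.tension_norm,
                                self.tension_kpa, self.length_norm])
        np.savetxt(path, data, delimiter=sep,
                   header=sep.join(["time_ms", "tension_norm", "tension_kPa",
                                    "length_norm"]), comments="")


# ---------------------------------------------------------------------------
# Elementary operations (scalar reference implementations)
# ---------------------------------------------------------------------------


def troponin_update(catrop_h: float, catrop_l: float, cai: float,
                    params: MechParameters, dt: float):
    """One Euler step of the two troponin binding ODEs.

    d/dt CaTrop_X = k_onT·Ca_i·(1 − CaTrop_X) − k_offXT·CaTrop_X for both
    the high- and low-affinity populations; outputs clamped to [0, 1].
    """
    if cai < 0:
        raise ValueError("Ca_i must be non-negative")
    kon = params.k_on * params._tf(params.q_kon)
    koffh = params.k_off_h * params._tf(params.q_koff)
    koffl = params.k_off_l * params._tf(params.q_koff)
    h = catrop_h + dt * (kon * cai * (1.0 - catrop_h) - koffh * catrop_h)
    l = catrop_l + dt * (kon * cai * (1.0 - catrop_l) - koffl * catrop_l)
    return min(max(h, 0.0), 1.0), min(max(l, 0.0), 1.0)


def single_overlap(sl: float, params: MechParameters):
    """Single-overlap fractions (SOVF_thin, SOVF_thick) at sarcomere length ``sl``.

    Standard sliding-filament geometry: the overlap region is bounded by the
    thick-filament tip (or half-SL) and by the bare zone / double-overlap
    limit of the thin filament.
    """
    sovr_ze = min(params.len_thick / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - params.len_thin), params.len_hbare / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    sovf_thick = len_sovr * 2.0 / (params.len_thick - params.len_hbare)
    sovf_thin = len_sovr / params.len_thin
    return sovf_thin, sovf_thick


def regulatory_rates(sl: float, catrop_h: float, catrop_l: float,
                     params: MechParameters):
    """Cooperative N↔P transition rates (k_n−pT, k_p−nT) in 1/ms.

    Trop_Regulatory mixes the low- and high-affinity saturations by thin-
    filament overlap; permtot = sqrt(1/(1+(perm50/Trop_Regulatory)^n_perm))
    accelerates N→P, and its capped inverse accelerates P→N, each with its
    temperature factor.
    """
    sovf_thin, _ = single_overlap(sl, params)
    trop_reg = (1.0 - sovf_thin) * catrop_l + sovf_thin * catrop_h
    if trop_reg <= 0.0:
        permtot = 0.0
        inv = params.inverse_perm_cap
    else:
        permtot = math.sqrt(1.0 / (1.0 + (params.perm50 / trop_reg) ** params.n_perm))
        inv = min(1.0 / permtot, params.inverse_perm_cap)
    kn_pt = params.k_n_p * permtot * params._tf(params.q_kn_p)
    kp_nt = params.k_p_n * inv * params._tf(params.q_kp_n)
    return kn_pt, kp_nt


def crossbridge_rates(sl: float, x_prer: float, x_postr: float,
                      params: MechParameters):
    """Strain- and overlap-modified crossbridge rates
    (f_appT, g_appT, h_fT, h_bT, g_xbT) in 1/ms."""
    _, sovf_thick = single_overlap(sl, params)
    x0 = params.x_0
    fappt = params.f_app * params._tf(params.q_fapp)
    gappt = (params.g_app * (1.0 + (1.0 - sovf_thick) * params.g_sl_mod)
             * params._tf(params.q_gapp))
    hfmd = math.exp(-math.copysign(1.0, x_prer) * params.h_f_mdc
                    * (x_prer / x0) ** 2)
    hft = params.h_f * hfmd * params._tf(params.q_hf)
    hbmd = math.exp(-math.copysign(1.0, x_postr - x0) * params.h_b_mdc
                    * ((x_postr - x0) / x0) ** 2)
    hbt = params.h_b * hbmd * params._tf(params.q_hb)
    if x_postr <= x0:
        gxbmd = math.exp(params.sigma_p * ((x0 - x_postr) / x0) ** 2)
    else:
        gxbmd = math.exp(params.sigma_n * ((x_postr - x0) / x0) ** 2)
    gxbt = params.g_xb * gxbmd * params._tf(params.q_gxb)
    return fappt, gappt, hft, hbt, gxbt


def duty_fractions(fappt, gappt, hft, hbt, gxbt):
    """Steady-state strongly-bound fractions of the crossbridge cycle under
    permissive conditions (closed forms)."""
    denom = (gxbt * hft + fappt * hft + gappt * hbt + gappt * gxbt
             + fappt * hbt + fappt * gxbt)
    prer = (fappt * hbt + fappt * gxbt) / denom
    postr = fappt * hft / denom
    return prer, postr


def xb_cycle_update(state: MechState, kn_pt: float, kp_nt: float,
                    fappt: float, gappt: float, hft: float, hbt: float,
                    gxbt: float, dt: float) -> MechState:
    """One Euler step of the regulatory/crossbridge occupancy ODEs.

    Advances the four-state cycle (N_XB, P_XB, XB_PreR, XB_PostR) and the
    crossbridge-free two-state pair (N_NoXB, P_NoXB); both pool sums are
    conserved exactly by construction of the flux terms.
    """
    s = state.copy()
    dn_noxb = -kn_pt * s.n_noxb + kp_nt * s.p_noxb
    dn = -kn_pt * s.n_xb + kp_nt * s.p_xb
    dp = (kn_pt * s.n_xb - (kp_nt + fappt) * s.p_xb + gappt * s.xb_prer
          + gxbt * s.xb_postr)
    dprer = fappt * s.p_xb - (gappt + hft) * s.xb_prer + hbt * s.xb_postr
    dpostr = hft * s.xb_prer - (hbt + gxbt) * s.xb_postr
    s.n_noxb += dt * dn_noxb
    s.p_noxb -= dt * dn_noxb
    s.n_xb += dt * dn
    s.p_xb += dt * dp
    s.xb_prer += dt * dprer
    s.xb_postr += dt * dpostr
    s.validate()
    return s


def distortion_update(x_prer: float, x_postr: float, dsl_dt: float,
                      xb_prer: float, xb_postr: float,
                      fappt: float, gappt: float, hft: float, hbt: float,
                      gxbt: float, params: MechParameters, dt: float):
    """One Euler step of the two mean-distortion ODEs.

    Each distortion advects with ½·dSL/dt and relaxes at a rate scaled by
    φ over the state's duty fraction.
    """
    denom = (gxbt * hft + fappt * hft + gappt * hbt + gappt * gxbt
             + fappt * hbt + fappt * gxbt)
    x0 = params.x_0
    dxprer = 0.5 * dsl_dt
    dxpostr = 0.5 * dsl_dt
    if denom > 0.0:  # all-zero rates degenerate to pure advection
        duty_prer, duty_postr = duty_fractions(fappt, gappt, hft, hbt, gxbt)
        dxprer += ((params.phi / duty_prer)
                   * (fappt * (-x_prer) + hbt * (x_postr - x0 - x_prer)))
        dxpostr += (params.phi / duty_postr) * hft * (x_prer + x0 - x_postr)
    return x_prer + dt * dxprer, x_postr + dt * dxpostr


def _passive_force(sl: float, params: MechParameters) -> float:
    titin = math.copysign(1.0, sl - params.sl_rest) * params.p_con_titin * (
        math.exp(params.p_exp_titin * abs(sl - params.sl_rest)) - 1.0)
    collagen = 0.0
    if sl > params.sl_collagen:
        collagen = params.p_con_collagen * (
            math.exp(params.p_exp_collagen * (sl - params.sl_collagen)) - 1.0)
    return titin + collagen


def total_force(state: MechState, params: MechParameters):
    """Force components at ``state``.

    Returns (F_active, F_passive, F_afterload, F_total) in normalized force
    units. F_total is the integrand accumulated into Integral_Force,
    F_total = −(F_active + F_passive − F_preload) − F_afterload: developed
    tension and net passive stretch act in the shortening direction, while
    the series element resists the excursion from SL_0. Active force is the
    distortion-weighted strongly-bound occupancy, normalized by the maximal
    post-rotation duty fraction at optimal activation.
    """
    _, sovf_thick = single_overlap(state.sl, params)
    fappt = params.f_app * params._tf(params.q_fapp)
    gappt = params.g_app * params._tf(params.q_gapp)
    hft = params.h_f * params._tf(params.q_hf)
    hbt = params.h_b * params._tf(params.q_hb)
    gxbt = params.g_xb * params._tf(params.q_gxb)
    _, postr_max = duty_fractions(fappt, gappt, hft, hbt, gxbt)
    f_active = (sovf_thick
                * (state.x_prer * state.xb_prer + state.x_postr * state.xb_postr)
                / (params.x_0 * postr_max))
    f_passive = _passive_force(state.sl, params)
    f_preload = _passive_force(params.sl_0, params)
    if params.contraction_mode == "afterloaded_isotonic":
        f_afterload = params.afterload_kpa / params.t_max_kpa
        f_total = -(f_active + f_passive - f_preload) + f_afterload
    else:
        f_afterload = params.kse * (state.sl - params.sl_0)
        f_total = -(f_active + f_passive - f_preload) - f_afterload
    return f_active, f_passive, f_afterload, f_total


def step_sl(state: MechState, params: MechParameters, dt: float) -> MechState:
    """Accumulate the force integral and advance SL one Euler step.

    dSL/dt = (Integral_Force + (SL_0 − SL)·viscosity)/mass.
    """
    s = state.copy()
    _, _, _, f_total = total_force(s, params)
    dsl_dt = (s.integral_force + (params.sl_0 - s.sl) * params.viscosity) / params.mass
    s.integral_force += dt * f_total
    s.sl += dt * dsl_dt
    if not (1.2 <= s.sl <= 2.6):
        raise MechDivergenceError(f"sarcomere length diverged: SL = {s.sl:.3f} μm")
    return s


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mech_step_kernel(y, cai, p, dt):
    """One Euler step of the full mechanics; mutates ``y``. Returns 0, or 1
    if SL left [1.2, 2.6] μm."""
    sl = y[10]
    x0 = p[18]

    # overlap geometry
    sovr_ze = min(p[21] / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - p[20]), p[22] / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    sovf_thick = len_sovr * 2.0 / (p[21] - p[22])
    sovf_thin = len_sovr / p[20]

    # troponin
    catrop_l = y[8]
    catrop_h = y[9]
    dtrop_l = p[0] * cai * (1.0 - catrop_l) - p[1] * catrop_l
    dtrop_h = p[0] * cai * (1.0 - catrop_h) - p[2] * catrop_h

    # regulatory rates
    trop_reg = (1.0 - sovf_thin) * catrop_l + sovf_thin * catrop_h
    if trop_reg <= 0.0:
        permtot = 0.0
        inv = p[7]
    else:
        permtot = math.sqrt(1.0 / (1.0 + (p[5] / trop_reg) ** p[6]))
        inv = min(1.0 / permtot, p[7])
    kn_pt = p[3] * permtot
    kp_nt = p[4] * inv

    # crossbridge rates with overlap/strain modifiers
    x_prer = y[6]
    x_postr = y[7]
    fappt = p[8]
    gappt = p[9] * (1.0 + (1.0 - sovf_thick) * p[13])
    hft = p[10] * math.exp(-math.copysign(1.0, x_prer) * p[14] * (x_prer / x0) ** 2)
    hbt = p[11] * math.exp(-math.copysign(1.0, x_postr - x0) * p[15]
                           * ((x_postr - x0) / x0) ** 2)
    if x_postr <= x0:
        gxbmd = math.exp(p[16] * ((x0 - x_postr) / x0) ** 2)
    else:
        gxbmd = math.exp(p[17] * ((x_postr - x0) / x0) ** 2)
    gxbt = p[12] * gxbmd

    # constant optimal-condition duty fractions (unstrained base rates):
    # normalize both the distortion dynamics and the force scale
    gappt0 = p[9]
    hft0 = p[10]
    hbt0 = p[11]
    gxbt0 = p[12]
    denom0 = (gxbt0 * hft0 + fappt * hft0 + gappt0 * hbt0 + gappt0 * gxbt0
              + fappt * hbt0 + fappt * gxbt0)
    duty_prer = (fappt * hbt0 + fappt * gxbt0) / denom0
    duty_postr = fappt * hft0 / denom0
    postr_max = duty_postr

    # forces
    f_active = (sovf_thick * (x_prer * y[4] + x_postr * y[5]) / (x0 * postr_max))
    titin = math.copysign(1.0, sl - p[24]) * p[25] * (
        math.exp(p[26] * abs(sl - p[24])) - 1.0)
    if sl > p[27]:
        titin += p[28] * (math.exp(p[29] * (sl - p[27])) - 1.0)
    titin0 = math.copysign(1.0, p[23] - p[24]) * p[25] * (
        math.exp(p[26] * abs(p[23] - p[24])) - 1.0)
    if p[23] > p[27]:
        titin0 += p[28] * (math.exp(p[29] * (p[23] - p[27])) - 1.0)
    # force integrand: tension and net passive stretch act to shorten SL,
    # the series element (afterload) resists the excursion from SL_0.
    # The (SL, Integral_Force) pair is a stiff linear oscillator
    # (sqrt(KSE/mass) ≈ 141 rad/ms); it is advanced by backward Euler with
    # the slowly varying drive g frozen over the step, which is
    # unconditionally stable and damps only the unresolved sub-ms ringing.
    g = -(f_active + titin - titin0)
    sl0 = p[23]
    visc = p[31]
    mass = p[32]
    a = dt / mass
    if p[33] >= 0.0:
        # afterloaded isotonic: the constant weight resists shortening and a
        # rigid stop at SL_0 prevents lengthening, so the cell lifts off
        # (starts to shorten) only once developed tension exceeds the weight
        intf_new = y[11] + dt * (g + p[33])
        sl_new = (sl + a * (intf_new + visc * sl0)) / (1.0 + a * visc)
        if sl_new >= sl0:
            sl_new = sl0
            if intf_new > 0.0:
                intf_new = 0.0
    else:
        kse = p[30]
        sl_new = ((sl + a * (y[11] + dt * g) + a * (dt * kse + visc) * sl0)
                  / (1.0 + a * (dt * kse + visc)))
        intf_new = y[11] + dt * (g - kse * (sl_new - sl0))
    dsl_dt = (sl_new - sl) / dt

    # occupancy derivatives
    dn_noxb = -kn_pt * y[0] + kp_nt * y[1]
    dn = -kn_pt * y[2] + kp_nt * y[3]
    dp = kn_pt * y[2] - (kp_nt + fappt) * y[3] + gappt * y[4] + gxbt * y[5]
    dprer = fappt * y[3] - (gappt + hft) * y[4] + hbt * y[5]
    dpostr = hft * y[4] - (hbt + gxbt) * y[5]

    # distortion derivatives
    dxprer = (0.5 * dsl_dt + (p[19] / duty_prer)
              * (fappt * (-x_prer) + hbt * (x_postr - x0 - x_prer)))
    dxpostr = 0.5 * dsl_dt + (p[19] / duty_postr) * hft * (x_prer + x0 - x_postr)

    y[0] += dt * dn_noxb
    y[1] -= dt * dn_noxb
    y[2] += dt * dn
    y[3] += dt * dp
    y[4] += dt * dprer
    y[5] += dt * dpostr
    y[6] += dt * dxprer
    y[7] += dt * dxpostr
    y[8] = min(max(catrop_l + dt * dtrop_l, 0.0), 1.0)
    y[9] = min(max(catrop_h + dt * dtrop_h, 0.0), 1.0)
    y[10] = sl_new
    y[11] = intf_new

    if y[10] < 1.2 or y[10] > 2.6 or not math.isfinite(y[10]):
        return 1
    return 0


@njit(cache=True)
def _mech_force_kernel(y, p):
    """Normalized active force at state ``y`` (matches the step kernel)."""
    sl = y[10]
    x0 = p[18]
    sovr_ze = min(p[21] / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - p[20]), p[22] / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    sovf_thick = len_sovr * 2.0 / (p[21] - p[22])
    fappt = p[8]
    denom0 = (p[12] * p[10] + fappt * p[10] + p[9] * p[11] + p[9] * p[12]
              + fappt * p[11] + fappt * p[12])
    postr_max = fappt * p[10] / denom0
    return sovf_thick * (y[6] * y[4] + y[7] * y[5]) / (x0 * postr_max)


@njit(cache=True)
def _run_twitch_kernel(y, cai_samples, cai_dt, p, dt, out_stride,
                       force_out, sl_out):
    n_out = force_out.shape[0]
    n_steps = n_out * out_stride
    n_cai = cai_samples.shape[0]
    for k in range(n_steps):
        if k % out_stride == 0:
            idx = k // out_stride
            force_out[idx] = _mech_force_kernel(y, p)
            sl_out[idx] = y[10]
        t = k * dt
        # linear interpolation of the imposed Ca transient
        pos = t / cai_dt
        i = int(pos)
        if i >= n_cai - 1:
            cai = cai_samples[n_cai - 1]
        else:
            frac = pos - i
            cai = cai_samples[i] * (1.0 - frac) + cai_samples[i + 1] * frac
        bad = _mech_step_kernel(y, cai, p, dt)
        if bad:
            return k
    return -1


# ---------------------------------------------------------------------------
# Initialization and twitch driver
# ---------------------------------------------------------------------------


def initial_mech_state(cai0: float, params: MechParameters) -> MechState:
    """Mechanical rest state equilibrated to the diastolic Ca level ``cai0``.

    Troponin saturations and the regulatory/crossbridge occupancies are set
    to their steady state at (Ca_i = cai0, SL = SL_0); distortions sit at
    their isometric fixed point (0, x_0); the force integral starts at 0, so
    normalized length is exactly 1 at t = 0.
    """
    kon = params.k_on * params._tf(params.q_kon)
    koffh = params.k_off_h * params._tf(params.q_koff)
    koffl = params.k_off_l * params._tf(params.q_koff)
    catrop_h = kon * cai0 / (kon * cai0 + koffh)
    catrop_l = kon * cai0 / (kon * cai0 + koffl)
    kn_pt, kp_nt = regulatory_rates(params.sl_0, catrop_h, catrop_l, params)
    fappt, gappt, hft, hbt, gxbt = crossbridge_rates(
        params.sl_0, 0.0, params.x_0, params)
    # steady state of the linear 4-state cycle under the conservation law
    a = np.array([
        [-kn_pt, kp_nt, 0.0, 0.0],
        [kn_pt, -(kp_nt + fappt), gappt, gxbt],
        [0.0, fappt, -(gappt + hft), hbt],
        [1.0, 1.0, 1.0, 1.0],
    ])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    n_xb, p_xb, xb_prer, xb_postr = np.linalg.solve(a, b)
    p_noxb = kn_pt / (kn_pt + kp_nt) if (kn_pt + kp_nt) > 0 else 0.0
    return MechState(
        n_noxb=1.0 - p_noxb, p_noxb=p_noxb,
        n_xb=float(n_xb), p_xb=float(p_xb),
        xb_prer=float(xb_prer), xb_postr=float(xb_postr),
        x_prer=0.0, x_postr=params.x_0,
        catrop_l=catrop_l, catrop_h=catrop_h,
        sl=params.sl_0, integral_force=0.0,
    )


def run_twitch(cai_trace: EPTrace, params: MechParameters | None = None,
               out_dt: float = 1.0, return_final_state: bool = False):
    """Integrate the mechanics over one beat driven by the trace's Ca_i(t).

    The Ca transient is linearly interpolated onto the internal Euler grid
    (``params.dt``, default 0.01 ms); tension and normalized length are
    recorded every ``out_dt`` ms. Mechanics starts from rest equilibrated to
    the trace's initial (diastolic) Ca level.
    """
    if params is None:
        params = MechParameters()
    state = initial_mech_state(float(cai_trace.cai[0]), params)
    y = state.as_array()
    p = params.as_array()
    out_stride = int(round(out_dt / params.dt))
    n_out = int(round(cai_trace.bcl / out_dt))
    force_out = np.empty(n_out)
    sl_out = np.empty(n_out)
    bad_step = _run_twitch_kernel(y, cai_trace.cai, cai_trace.dt, p,
                                  params.dt, out_stride, force_out, sl_out)
    if bad_step >= 0:
        t_bad = bad_step * params.dt
        raise MechDivergenceError(
            f"mechanics diverged at t = {t_bad:.2f} ms", time_ms=t_bad)
    trace = MechTrace(
        dt=out_dt,
        tension_norm=force_out,
        tension_kpa=force_out * params.t_max_kpa,
        length_norm=sl_out / params.sl_0,
    )
    if return_final_state:
        return trace, MechState.from_array(y)
    return trace
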