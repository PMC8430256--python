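"""Human ventricular myocyte electrophysiology.

Implements the ten Tusscher–Panfilov human ventricular ionic model with
per-channel maximum-conductance scaling, the reduced Markov ryanodine
receptor (four states collapsed to one tracked aggregate R̄ = R + O), and
three-compartment calcium dynamics (cytosol, sarcoplasmic reticulum,
diadic subspace) with rapid-equilibrium buffering.

The scalable channels are the ten sarcolemmal conductances/permeabilities
(Na, CaL, to, Kr, Ks, K1, pK, pCa, bNa, bCa); the NCX exchanger and the
Na/K pump are never scaled. Integration is an operator-split explicit
scheme: Rush–Larsen exponential updates for the Hodgkin–Huxley gates,
explicit Euler for the membrane potential, the ionic concentrations and R̄.

Units follow the source model conventions: time in ms, voltage in mV,
concentrations in mM, membrane currents in pA/pF, compartment volumes in
μm³, Faraday constant in C/mmol.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ChannelId",
    "CHANNEL_ORDER",
    "ConductanceScaling",
    "EPParameters",
    "EPState",
    "EPTrace",
    "EPDivergenceError",
    "InvalidStateError",
    "ryr_update",
    "compute_currents",
    "update_calcium",
    "step_ep",
    "run_paced_ep",
    "resting_state",
    "paced_state",
]


class ChannelId(enum.Enum):
    """The ten scalable sarcolemmal channels/transporters.

    The enumeration order is the canonical channel ordering used by sweep
    indexing and by dimensional-stacking layouts.
    """

    Na = 0
    CaL = 1
    to = 2
    Kr = 3
    Ks = 4
    K1 = 5
    pK = 6
    pCa = 7
    bNa = 8
    bCa = 9


#: Canonical channel ordering (position = mixed-radix digit significance).
CHANNEL_ORDER: tuple[ChannelId, ...] = tuple(ChannelId)

#: Canonical channel names, in order.
CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in CHANNEL_ORDER)


class InvalidStateError(ValueError):
    """A model state violates a physical invariant (e.g. negative Ca)."""


class EPDivergenceError(RuntimeError):
    """The explicit integration produced a non-finite state variable."""

    def __init__(self, message: str, beat: int | None = None):
        super().__init__(message)
        self.beat = beat


@dataclass(frozen=True)
class ConductanceScaling:
    """Dimensionless multipliers on the ten maximum conductances.

    The sweep enumerator only produces factors in {0.25, 0.5, 0.75, 1.0};
    the simulator itself accepts any strictly positive factors.
    """

    factors: dict[ChannelId, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHANNEL_ORDER}
    )

    def __post_init__(self):
        missing = [c for c in CHANNEL_ORDER if c not in self.factors]
        if missing:
            complete = {c: 1.0 for c in CHANNEL_ORDER}
            complete.update(self.factors)
            object.__setattr__(self, "factors", complete)
        for c, v in self.factors.items():
            if not (v > 0 and math.isfinite(v)):
                raise InvalidStateError(f"scaling factor for {c.name} must be positive, got {v}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ConductanceScaling":
        """Build from a {ChannelId|name: factor} mapping; unnamed channels stay at 1."""
        factors = {c: 1.0 for c in CHANNEL_ORDER}
        for key, value in mapping.items():
            cid = key if isinstance(key, ChannelId) else ChannelId[str(key)]
            factors[cid] = float(value)
        return cls(factors)

    @classmethod
    def normal(cls) -> "ConductanceScaling":
        return cls()

    def as_array(self) -> np.ndarray:
        """Factors as a float64 array in canonical channel order."""
        return np.array([self.factors[c] for c in CHANNEL_ORDER], dtype=np.float64)

    def __getitem__(self, channel: ChannelId) -> float:
        return self.factors[channel]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

_CELL_TYPES = ("epi", "endo", "m")


@dataclass(frozen=True)
class EPParameters:
    """Constants of the ionic model (source-model values, epicardial default).

    ``g_to`` and ``g_ks`` depend on the transmural cell type; all other
    constants are shared. Volumes are in μm³ and the Faraday constant in
    C/mmol, matching the model's published values.
    """

    cell_type: str = "epi"

    # physical constants
    gas_constant: float = 8314.472      # mJ/(mol·K)
    temperature: float = 310.0          # K
    faraday: float = 96.4867            # C/mmol
    cm: float = 0.185                   # μF; couples currents to concentration fluxes

    # external concentrations (mM)
    ko: float = 5.4
    cao: float = 2.0
    nao: float = 140.0

    # compartment volumes (μm³)
    v_c: float = 16.404
    v_sr: float = 1.094
    v_ss: float = 0.05468

    # maximum conductances / permeabilities (nS/pF unless noted)
    g_na: float = 14.838
    g_cal: float = 3.980e-5             # cm³/(μF·s) permeability scale
    g_to: float = 0.294                 # epi/M 0.294, endo 0.073
    g_kr: float = 0.153
    g_ks: float = 0.392                 # epi/endo 0.392, M 0.098
    g_k1: float = 5.405
    g_pk: float = 0.0146
    g_pca: float = 0.1238
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    k_pca: float = 0.0005

    # NCX exchanger
    k_naca: float = 1000.0
    km_nai: float = 87.5
    km_ca: float = 1.38
    k_sat: float = 0.1
    gamma: float = 0.35

    # Na/K pump
    p_nak: float = 2.724
    km_k: float = 1.0
    km_na: float = 40.0
    p_kna: float = 0.03

    # SR calcium handling
    v_maxup: float = 0.006375
    k_up: float = 0.00025
    v_rel: float = 0.102
    v_leak: float = 0.00036
    v_xfer: float = 0.0038

    # RyR Markov rates
    k1_prime: float = 0.15
    k2_prime: float = 0.045
    k3: float = 0.060
    k4: float = 0.005
    ec: float = 1.5
    max_sr: float = 2.5
    min_sr: float = 1.0

    # buffering
    buf_c: float = 0.2
    k_buf_c: float = 0.001
    buf_sr: float = 10.0
    k_buf_sr: float = 0.3
    buf_ss: float = 0.4
    k_buf_ss: float = 0.00025

    def __post_init__(self):
        if self.cell_type not in _CELL_TYPES:
            raise ValueError(f"cell_type must be one of {_CELL_TYPES}")
        if self.cell_type == "endo":
            object.__setattr__(self, "g_to", 0.073)
        elif self.cell_type == "m":
            object.__setattr__(self, "g_ks", 0.098)
        for name in ("v_c", "v_sr", "v_ss", "faraday", "v_rel", "k1_prime",
                     "k2_prime", "k3", "k4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rtonf(self) -> float:
        """Thermal voltage RT/F in mV."""
        return self.gas_constant * self.temperature / (self.faraday * 1000.0)

    def as_array(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the numba kernel."""
        p = np.zeros(48)
        p[0] = self.rtonf
        p[1] = self.faraday
        p[2] = self.cm
        p[3] = self.ko
        p[4] = self.cao
        p[5] = self.nao
        p[6] = self.v_c
        p[7] = self.v_sr
        p[8] = self.v_ss
        p[9] = self.g_na
        p[10] = self.g_cal
        p[11] = self.g_to
        p[12] = self.g_kr
        p[13] = self.g_ks
        p[14] = self.g_k1
        p[15] = self.g_pk
        p[16] = self.g_pca
        p[17] = self.g_bna
        p[18] = self.g_bca
        p[19] = self.k_pca
        p[20] = self.k_naca
        p[21] = self.km_nai
        p[22] = self.km_ca
        p[23] = self.k_sat
        p[24] = self.gamma
        p[25] = self.p_nak
        p[26] = self.km_k
        p[27] = self.km_na
        p[28] = self.p_kna
        p[29] = self.v_maxup
        p[30] = self.k_up
        p[31] = self.v_rel
        p[32] = self.v_leak
        p[33] = self.v_xfer
        p[34] = self.k1_prime
        p[35] = self.k2_prime
        p[36] = self.k3
        p[37] = self.k4
        p[38] = self.ec
        p[39] = self.max_sr
        p[40] = self.min_sr
        p[41] = self.buf_c
        p[42] = self.k_buf_c
        p[43] = self.buf_sr
        p[44] = self.k_buf_sr
        p[45] = self.buf_ss
        p[46] = self.k_buf_ss
        p[47] = 1.0 if self.cell_type == "endo" else 0.0
        return p


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

#: names of the state-vector entries, in kernel order
STATE_NAMES = (
    "v", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "cai", "casr", "cass", "rbar", "nai", "ki",
)

_GATE_SLICE = slice(1, 13)

# source-model published resting values
_REST = np.array([
    -86.2,        # v (mV)
    0.0,          # m
    0.75,         # h
    0.75,         # j
    0.0,          # xr1
    1.0,          # xr2
    0.0,          # xs
    0.0,          # r
    1.0,          # s
    0.0,          # d
    1.0,          # f
    1.0,          # f2
    1.0,          # fcass
    0.00007,      # cai (mM)
    1.3,          # casr (mM)
    0.00007,      # cass (mM)
    1.0,          # rbar
    7.67,         # nai (mM)
    138.3,        # ki (mM)
])


@dataclass
class EPState:
    """Full ionic-model state: V, 12 gates, 5 concentrations/R̄."""

    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64).copy()
        if self.vector.shape != (19,):
            raise InvalidStateError("EPState vector must have 19 entries")
        self.validate()

    def validate(self):
        y = self.vector
        if not np.all(np.isfinite(y)):
            bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(y))[0])]
            raise InvalidStateError(f"non-finite state variable: {bad}")
        gates = y[_GATE_SLICE]
        if np.any(gates < -1e-12) or np.any(gates > 1 + 1e-12):
            raise InvalidStateError("gating variable outside [0, 1]")
        if not (-1e-12 <= y[16] <= 1 + 1e-12):
            raise InvalidStateError("R̄ outside [0, 1]")
        if np.any(y[13:16] < 0) or y[17] < 0 or y[18] < 0:
            raise InvalidStateError("negative ion concentration")

    def __getattr__(self, name):
        try:
            idx = STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.vector[idx]

    def copy(self) -> "EPState":
        return EPState(self.vector.copy())


def resting_state() -> EPState:
    """The source model's published resting state (identical for all cases)."""
    return EPState(_REST.copy())


# 1-Hz paced steady-state values from the curated distribution of the source
# model (epicardial variant); used as the pre-pacing starting point of the
# two-BCL protocol.
_PACED = np.array([
    -85.23,       # v (mV)
    0.00172,      # m
    0.7444,       # h
    0.7045,       # j
    0.00621,      # xr1
    0.4712,       # xr2
    0.0095,       # xs
    2.42e-8,      # r
    0.999998,     # s
    3.373e-5,     # d
    0.7888,       # f
    0.9755,       # f2
    0.9953,       # fcass
    0.000126,     # cai (mM)
    3.64,         # casr (mM)
    0.00036,      # cass (mM)
    0.9073,       # rbar
    8.604,        # nai (mM)
    136.89,       # ki (mM)
])


def paced_state() -> EPState:
    """Steady-state initial values after prolonged 1-Hz pacing.

    The population protocol pre-paces every case from this state; identical
    for every sweep case, so the 50-beat runs wash out residual sensitivity.
    """
    return EPState(_PACED.copy())


@dataclass
class EPTrace:
    """Final-beat membrane-potential and calcium time series.

    Samples cover exactly one basic cycle length at step ``dt``; the pacing
    stimulus is delivered at ``stim_onset`` (beat-local time, ms).
    """

    dt: float
    v: np.ndarray
    cai: np.ndarray
    bcl: float
    stim_onset: float = 0.0

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=np.float64)
        self.cai = np.asarray(self.cai, dtype=np.float64)
        if self.v.shape != self.cai.shape:
            raise ValueError("V and Cai arrays must have equal length")
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.cai))):
            raise ValueError("trace contains non-finite samples")
        if abs(len(self.v) * self.dt - self.bcl) > 0.5 * self.dt:
            raise ValueError("trace length × dt must equal the BCL")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.v)) * self.dt

    def to_csv(self, path, sep=","):
        """Write columns time_ms, V_mV, Cai_mM as delimited text."""
        data = np.column_stack([self.time, self.v, self.cai])
        np.savetxt(path, data, delimiter=sep, header=sep.join(["time_ms", "V_mV", "Cai_mM"]),
                   comments="")


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ryr_kernel(rbar, cass, casr, p, dt):
    """Advance R̄ one explicit-Euler step; return (R̄', O, I_rel)."""
    kcasr = p[39] - (p[39] - p[40]) / (1.0 + (p[38] / casr) ** 2)
    k1 = p[34] / kcasr
    k2 = p[35] * kcasr
    o = k1 * cass * cass * rbar / (p[36] + k1 * cass * cass)
    irel = p[31] * o * (casr - cass)
    rbar_new = rbar + dt * (-k2 * cass * rbar + p[37] * (1.0 - rbar))
    if rbar_new < 0.0:
        rbar_new = 0.0
    elif rbar_new > 1.0:
        rbar_new = 1.0
    return rbar_new, o, irel


@njit(cache=True)
def _currents_kernel(y, p, scal):
    """All twelve membrane currents (pA/pF) at the given state.

    Returns (INa, ICaL, Ito, IKr, IKs, IK1, IpK, IpCa, IbNa, IbCa,
    INaCa, INaK). The first ten are scaled by the matching factor in
    ``scal``; the exchanger and pump are never scaled.
    """
    v = y[0]
    cai = y[13]
    cass = y[15]
    nai = y[17]
    ki = y[18]
    rtonf = p[0]

    ek = rtonf * math.log(p[3] / ki)
    ena = rtonf * math.log(p[5] / nai)
    eks = rtonf * math.log((p[3] + p[28] * p[5]) / (ki + p[28] * nai))
    eca = 0.5 * rtonf * math.log(p[4] / cai)

    i_na = scal[0] * p[9] * y[1] ** 3 * y[2] * y[3] * (v - ena)

    # L-type Ca current (GHK-type driving term on the subspace Ca)
    vshift = v - 15.0
    if abs(vshift) < 1e-6:
        vshift = 1e-6
    e2 = math.exp(2.0 * vshift / rtonf)
    i_cal = (scal[1] * p[10] * y[9] * y[10] * y[11] * y[12] * 4.0 * vshift
             * (1000.0 * p[1] / rtonf)
             * (0.25 * cass * e2 - p[4]) / (e2 - 1.0))

    i_to = scal[2] * p[11] * y[7] * y[8] * (v - ek)
    i_kr = scal[3] * p[12] * math.sqrt(p[3] / 5.4) * y[4] * y[5] * (v - ek)
    i_ks = scal[4] * p[13] * y[6] * y[6] * (v - eks)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (v - ek + 100.0)) + math.exp(0.1 * (v - ek - 10.0)))
           / (1.0 + math.exp(-0.5 * (v - ek))))
    i_k1 = scal[5] * p[14] * math.sqrt(p[3] / 5.4) * ak1 / (ak1 + bk1) * (v - ek)

    i_pk = scal[6] * p[15] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    i_pca = scal[7] * p[16] * cai / (p[19] + cai)
    i_bna = scal[8] * p[17] * (v - ena)
    i_bca = scal[9] * p[18] * (v - eca)

    i_naca = (p[20]
              * (1.0 / (p[21] ** 3 + p[5] ** 3)) * (1.0 / (p[22] + p[4]))
              * (1.0 / (1.0 + p[23] * math.exp((p[24] - 1.0) * v / rtonf)))
              * (math.exp(p[24] * v / rtonf) * nai ** 3 * p[4]
                 - math.exp((p[24] - 1.0) * v / rtonf) * p[5] ** 3 * cai * 2.5))

    i_nak = (p[25] * (p[3] / (p[3] + p[26])) * (nai / (nai + p[27]))
             / (1.0 + 0.1245 * math.exp(-0.1 * v / rtonf)
                + 0.0353 * math.exp(-v / rtonf)))

    return i_na, i_cal, i_to, i_kr, i_ks, i_k1, i_pk, i_pca, i_bna, i_bca, i_naca, i_nak


@njit(cache=True)
def _gates_kernel(y, p, dt):
    """Rush–Larsen exponential update of the twelve gating variables."""
    v = y[0]
    endo = p[47] > 0.5

    # m
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = am * bm
    # h
    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tau_h = 1.0 / (ah + bh)
    # j
    j_inf = h_inf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    tau_j = 1.0 / (aj + bj)
    # xr1
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1
    # xr2
    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2
    # xs
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0
    # r and s (transmural variants)
    if endo:
        r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
        tau_r = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        tau_s = 1000.0 * math.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
    else:
        r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
        tau_r = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        tau_s = (85.0 * math.exp(-(v + 45.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)
    # d
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    cd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = ad * bd + cd
    # f
    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    af = 1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
    bf = 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
    cf = 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0
    tau_f = af + bf + cf
    # f2
    f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    af2 = 600.0 * math.exp(-((v + 25.0) ** 2) / 170.0)
    bf2 = 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
    cf2 = 16.0 / (1.0 + math.exp((v + 30.0) / 10.0))
    tau_f2 = af2 + bf2 + cf2
    # fcass (depends on subspace Ca, not V)
    cass = y[15]
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    y[1] = m_inf - (m_inf - y[1]) * math.exp(-dt / tau_m)
    y[2] = h_inf - (h_inf - y[2]) * math.exp(-dt / tau_h)
    y[3] = j_inf - (j_inf - y[3]) * math.exp(-dt / tau_j)
    y[4] = xr1_inf - (xr1_inf - y[4]) * math.exp(-dt / tau_xr1)
    y[5] = xr2_inf - (xr2_inf - y[5]) * math.exp(-dt / tau_xr2)
    y[6] = xs_inf - (xs_inf - y[6]) * math.exp(-dt / tau_xs)
    y[7] = r_inf - (r_inf - y[7]) * math.exp(-dt / tau_r)
    y[8] = s_inf - (s_inf - y[8]) * math.exp(-dt / tau_s)
    y[9] = d_inf - (d_inf - y[9]) * math.exp(-dt / tau_d)
    y[10] = f_inf - (f_inf - y[10]) * math.exp(-dt / tau_f)
    y[11] = f2_inf - (f2_inf - y[11]) * math.exp(-dt / tau_f2)
    y[12] = fcass_inf - (fcass_inf - y[12]) * math.exp(-dt / tau_fcass)


@njit(cache=True)
def _calcium_kernel(y, i_cal, i_bca, i_pca, i_naca, irel, p, dt):
    """Advance Cai, CaSR, CaSS one Euler step with analytic rapid buffering.

    The three balance equations advance *total* calcium; free concentrations
    are recovered by solving the single-buffer equilibrium quadratic.
    """
    f = p[1]
    cm = p[2]
    v_c = p[6]
    v_sr = p[7]
    v_ss = p[8]
    cai = y[13]
    casr = y[14]
    cass = y[15]

    iup = p[29] / (1.0 + (p[30] * p[30]) / (cai * cai))
    ileak = p[32] * (casr - cai)
    ixfer = p[33] * (cass - cai)

    # SR
    casr_buf = p[43] * casr / (casr + p[44])
    dcasr = dt * (iup - irel - ileak)
    b = p[43] - casr_buf - dcasr - casr + p[44]
    c = p[44] * (casr_buf + dcasr + casr)
    y[14] = (math.sqrt(b * b + 4.0 * c) - b) / 2.0

    # subspace
    cass_buf = p[45] * cass / (cass + p[46])
    dcass = dt * (-ixfer * (v_c / v_ss) + irel * (v_sr / v_ss)
                  + (-i_cal * cm / (2.0 * v_ss * f)))
    b = p[45] - cass_buf - dcass - cass + p[46]
    c = p[46] * (cass_buf + dcass + cass)
    y[15] = (math.sqrt(b * b + 4.0 * c) - b) / 2.0

    # cytosol
    cai_buf = p[41] * cai / (cai + p[42])
    dcai = dt * (-(i_bca + i_pca - 2.0 * i_naca) * cm / (2.0 * v_c * f)
                 - (iup - ileak) * (v_sr / v_c) + ixfer)
    b = p[41] - cai_buf - dcai - cai + p[42]
    c = p[42] * (cai_buf + dcai + cai)
    y[13] = (math.sqrt(b * b + 4.0 * c) - b) / 2.0


@njit(cache=True)
def _step_kernel(y, p, scal, dt, i_stim):
    """One operator-split step; mutates ``y``. Returns 0 or a 1-based index
    of the first non-finite state variable."""
    (i_na, i_cal, i_to, i_kr, i_ks, i_k1, i_pk, i_pca, i_bna, i_bca,
     i_naca, i_nak) = _currents_kernel(y, p, scal)

    rbar_new, _o, irel = _ryr_kernel(y[16], y[15], y[14], p, dt)
    _calcium_kernel(y, i_cal, i_bca, i_pca, i_naca, irel, p, dt)
    y[16] = rbar_new

    # Na and K bookkeeping
    f = p[1]
    cm = p[2]
    v_c = p[6]
    y[17] += dt * (-(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * cm / (v_c * f))
    y[18] += dt * (-(i_stim + i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk)
                   * cm / (v_c * f))

    _gates_kernel(y, p, dt)

    i_ion = (i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_pk + i_pca + i_bna
             + i_bca + i_naca + i_nak)
    y[0] += dt * (-(i_ion + i_stim))

    for k in range(19):
        if not math.isfinite(y[k]):
            return k + 1
    return 0


@njit(cache=True)
def _run_kernel(y, p, scal, bcl, n_beats, dt, stim_amp, stim_dur, out_dt,
                v_out, cai_out):
    """Pace ``n_beats`` cycles; record the last beat into the out arrays.

    Returns 0 on success or the 1-based beat number at which the state
    diverged (encoded with the offending variable: beat*100 + var_index).
    """
    steps_per_beat = int(round(bcl / dt))
    sample_stride = int(round(out_dt / dt))
    n_out = v_out.shape[0]
    for beat in range(n_beats):
        last = beat == n_beats - 1
        for k in range(steps_per_beat):
            if last and k % sample_stride == 0:
                idx = k // sample_stride
                if idx < n_out:
                    v_out[idx] = y[0]
                    cai_out[idx] = y[13]
            t_local = k * dt
            i_stim = stim_amp if t_local < stim_dur else 0.0
            bad = _step_kernel(y, p, scal, dt, i_stim)
            if bad != 0:
                return (beat + 1) * 100 + bad
    return 0


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def ryr_update(rbar: float, ca_ss: float, ca_sr: float, params: EPParameters,
               dt: float):
    """Ryanodine-receptor update.

    The four-state Markov receptor is reduced to the tracked aggregate
    R̄ = R + O.  The open fraction is the algebraic quasi-steady expression
    O = k1·Ca_SS²·R̄ / (k3 + k1·Ca_SS²) and the release flux is
    I_rel = V_rel·O·(Ca_SR − Ca_SS); R̄ advances one explicit-Euler step of
    dR̄/dt = −k2·Ca_SS·R̄ + k4·(1 − R̄).  k1 and k2 depend on the SR calcium
    level through the CSQN-sensing factor; k3 and k4 are constant.

    Returns ``(rbar_new, open_fraction, i_rel)``.
    """
    if not (0.0 <= rbar <= 1.0):
        raise InvalidStateError(f"R̄ must lie in [0, 1], got {rbar}")
    if ca_ss < 0 or ca_sr < 0:
        raise InvalidStateError("negative calcium concentration")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return _ryr_kernel(float(rbar), float(ca_ss), float(ca_sr),
                       params.as_array(), float(dt))


_CURRENT_NAMES = ("i_na", "i_cal", "i_to", "i_kr", "i_ks", "i_k1", "i_pk",
                  "i_pca", "i_bna", "i_bca", "i_naca", "i_nak")


def compute_currents(state: EPState, params: EPParameters,
                     scaling: ConductanceScaling | None = None) -> dict:
    """All twelve membrane currents (pA/pF) at ``state``.

    Each of the ten scalable currents is the source-model value multiplied
    by its scaling factor; I_NaCa and I_NaK are never scaled.
    """
    state.validate()
    if scaling is None:
        scaling = ConductanceScaling.normal()
    vals = _currents_kernel(state.vector, params.as_array(), scaling.as_array())
    return dict(zip(_CURRENT_NAMES, vals))


def update_calcium(state: EPState, currents: dict, params: EPParameters,
                   dt: float) -> EPState:
    """Advance the three-compartment calcium concentrations one step.

    ``currents`` must provide i_cal, i_bca, i_pca, i_naca (pA/pF) and i_rel
    (mM/ms). The SERCA uptake, SR leak and subspace-transfer fluxes are
    evaluated internally from the state.
    """
    new = state.copy()
    _calcium_kernel(new.vector, currents["i_cal"], currents["i_bca"],
                    currents["i_pca"], currents["i_naca"], currents["i_rel"],
                    params.as_array(), dt)
    if np.any(new.vector[13:16] < 0):
        raise InvalidStateError("negative total calcium after update")
    return new


def step_ep(state: EPState, params: EPParameters,
            scaling: ConductanceScaling | None = None, dt: float = 0.02,
            i_stim: float = 0.0) -> EPState:
    """One operator-split integration step of the full ionic model.

    V, concentrations and R̄ advance by explicit Euler; gates by the
    Rush–Larsen exponential update. ``dt`` must not exceed 0.02 ms.
    """
    if dt > 0.02 + 1e-12:
        raise ValueError("explicit scheme requires dt ≤ 0.02 ms")
    if scaling is None:
        scaling = ConductanceScaling.normal()
    new = state.copy()
    bad = _step_kernel(new.vector, params.as_array(), scaling.as_array(),
                       dt, i_stim)
    if bad:
        raise EPDivergenceError(
            f"state variable '{STATE_NAMES[bad - 1]}' became non-finite")
    return new


def run_paced_ep(scaling: ConductanceScaling | None = None, bcl: float = 1000.0,
                 n_beats: int = 50, params: EPParameters | None = None,
                 dt: float = 0.02, out_dt: float = 1.0,
                 stim_amplitude: float = -52.0, stim_duration: float = 1.0,
                 initial_state: EPState | None = None,
                 return_final_state: bool = False):
    """Pace the cell at a fixed BCL and return the final beat's trace.

    The stimulus (default −52 pA/pF for 1 ms) is delivered at the start of
    each cycle; the returned :class:`EPTrace` holds V(t) and Ca_i(t) of the
    last beat sampled every ``out_dt`` ms. Every run starts from the source
    model's published resting state unless ``initial_state`` is given.
    """
    if bcl < 300:
        raise ValueError("bcl must be at least 300 ms")
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    if dt > 0.02 + 1e-12:
        raise ValueError("explicit scheme requires dt ≤ 0.02 ms")
    if scaling is None:
        scaling = ConductanceScaling.normal()
    if params is None:
        params = EPParameters()
    state = (initial_state.copy() if initial_state is not None
             else resting_state())
    n_out = int(round(bcl / out_dt))
    v_out = np.empty(n_out)
    cai_out = np.empty(n_out)
    status = _run_kernel(state.vector, params.as_array(), scaling.as_array(),
                         float(bcl), int(n_beats), float(dt),
                         float(stim_amplitude), float(stim_duration),
                         float(out_dt), v_out, cai_out)
    if status:
        beat, var = divmod(status, 100)
        raise EPDivergenceError(
            f"state variable '{STATE_NAMES[var - 1]}' became non-finite "
            f"during beat {beat}", beat=beat)
    trace = EPTrace(dt=out_dt, v=v_out, cai=cai_out, bcl=float(bcl),
                    stim_onset=0.0)
    if return_final_state:
        return trace, state
    return trace
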