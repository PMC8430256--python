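"""Per-case simulation protocol and scalar biomarker extraction.

A case is one conductance-scaling vector. The protocol pre-paces the cell
from the 1-Hz steady state, runs 50 beats at BCL 600 ms, then continues 50
further beats at BCL 1000 ms; the final beat of each phase feeds the
myofilament model. From the electrical trace we extract the action-
potential onset (V crossing −40 mV), APD90, and the calcium-transient
attributes (max/rest Cai, duration, upstroke slope); from the mechanical
trace, the contraction onset (normalized length falling to 99%, valid only
if tension reaches the 20 kPa weight) and the electromechanical delay
EMD = contraction onset − AP onset.

All threshold crossings are linearly interpolated between output samples.
Missing quantities (no contraction, no repolarization) are stored as NaN
sentinels, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .ionic_model import (
    ConductanceScaling,
    EPDivergenceError,
    EPParameters,
    EPTrace,
    paced_state,
    run_paced_ep,
)
from .myofilament_model import (
    MechDivergenceError,
    MechParameters,
    MechTrace,
    run_twitch,
)

__all__ = [
    "SimulationConfig",
    "BiomarkerRecord",
    "RECORD_COLUMNS",
    "ap_onset",
    "apd90",
    "cai_attributes",
    "contraction_onset",
    "run_protocol",
    "run_case",
    "run_case_pair",
]

#: fixed CSV schema for per-case records
RECORD_COLUMNS = (
    "case_id", "bcl_ms", "apd90_ms", "max_cai_mM", "rest_cai_mM",
    "cai_dur_ms", "cai_slope_mM_per_ms", "emd_ms", "contracted", "diverged",
)

#: the two pacing rates of the study protocol, in the order they are run
PROTOCOL_BCLS = (600.0, 1000.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Plain-value configuration of the per-case pipeline."""

    # electrophysiology
    cell_type: str = "epi"
    dt_ms: float = 0.02
    output_dt_ms: float = 1.0
    stim_amplitude: float = -52.0       # pA/pF
    stim_duration_ms: float = 1.0
    n_beats: int = 50
    bcl_ms: tuple = PROTOCOL_BCLS

    # mechanics
    tmpc: float = 37.0
    sl0_um: float = 1.9
    kse: float = 1.0
    t_max_kpa: float = 250.0
    mech_dt_ms: float = 0.001
    contraction_mode: str = "afterloaded_isotonic"

    # contraction criteria
    tension_threshold_kpa: float = 20.0
    length_threshold: float = 0.99

    def ep_parameters(self) -> EPParameters:
        return EPParameters(cell_type=self.cell_type)

    def mech_parameters(self) -> MechParameters:
        return MechParameters(
            tmpc=self.tmpc, sl_0=self.sl0_um, kse=self.kse,
            t_max_kpa=self.t_max_kpa, dt=self.mech_dt_ms,
            contraction_mode=self.contraction_mode,
            afterload_kpa=self.tension_threshold_kpa,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bcl_ms" in raw and not isinstance(raw["bcl_ms"], (list, tuple)):
            raw["bcl_ms"] = [raw["bcl_ms"]]
        if "bcl_ms" in raw:
            raw["bcl_ms"] = tuple(float(b) for b in raw["bcl_ms"])
        return cls(**raw)


@dataclass
class BiomarkerRecord:
    """Scalar outputs of one (case, BCL) simulation."""

    case_id: int
    bcl: float
    apd90: float = math.nan
    max_cai: float = math.nan
    rest_cai: float = math.nan
    cai_duration: float = math.nan
    cai_slope: float = math.nan
    ap_onset_time: float = math.nan
    contraction_onset_time: float = math.nan
    emd: float = math.nan
    contracted: bool = False
    diverged: bool = False

    def __post_init__(self):
        if self.contracted != (not math.isnan(self.emd)):
            raise ValueError("emd must be present iff contracted")
        if self.contracted and self.emd < 0:
            raise ValueError("emd must be non-negative")

    def as_row(self) -> dict:
        return {
            "case_id": self.case_id,
            "bcl_ms": self.bcl,
            "apd90_ms": self.apd90,
            "max_cai_mM": self.max_cai,
            "rest_cai_mM": self.rest_cai,
            "cai_dur_ms": self.cai_duration,
            "cai_slope_mM_per_ms": self.cai_slope,
            "emd_ms": self.emd,
            "contracted": self.contracted,
            "diverged": self.diverged,
        }


def _interp_crossing(t0, y0, t1, y1, thr):
    """Linear interpolation of the crossing time of ``thr`` in [t0, t1]."""
    if y1 == y0:
        return t0
    return t0 + (thr - y0) / (y1 - y0) * (t1 - t0)


def ap_onset(trace: EPTrace) -> float | None:
    """Time (ms) at which V first reaches −40 mV, or None if never."""
    v = trace.v
    t = trace.time
    idx = np.flatnonzero(v >= -40.0)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    return float(_interp_crossing(t[i - 1], v[i - 1], t[i], v[i], -40.0))


def apd90(trace: EPTrace) -> float:
    """Action potential duration at 90 % repolarization.

    Amplitude is V_peak − V_rest with V_rest the pre-stimulus potential
    (first sample; the stimulus starts the beat). Duration runs from the
    maximum-upstroke instant to the first later downward crossing of
    V_rest + 0.1·amplitude, linearly interpolated. If the beat never
    repolarizes to that level the beat length is returned.
    """
    v = trace.v
    t = trace.time
    v_rest = v[0]
    v_peak = float(v.max())
    thr = v_rest + 0.1 * (v_peak - v_rest)
    i_up = int(np.argmax(np.diff(v))) + 1
    below = np.flatnonzero((v[:-1] >= thr) & (v[1:] < thr))
    below = below[below >= i_up]
    if below.size == 0:
        return float(trace.bcl)
    i = int(below[0])
    t_cross = _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], thr)
    return float(t_cross - t[i_up])


def cai_attributes(trace: EPTrace):
    """Calcium-transient attributes (max, rest, duration, upstroke slope).

    rest is the final sample of the beat; max the beat maximum. Duration is
    the interpolated width of the interval where Cai exceeds
    peak − 0.9·(peak − rest); the slope is the mean upstroke gradient
    0.9·(peak − rest) / (time-to-peak − 10 %-rise crossing time). A flat
    transient yields NaN duration and slope.
    """
    c = trace.cai
    t = trace.time
    rest = float(c[-1])
    peak = float(c.max())
    if peak <= rest:
        return peak, rest, math.nan, math.nan
    thr = peak - 0.9 * (peak - rest)
    i_peak = int(np.argmax(c))
    above = c >= thr
    up = np.flatnonzero(~above[:-1] & above[1:])
    up = up[up < i_peak] if up.size else up
    if up.size:
        i = int(up[-1])
        t_rise = _interp_crossing(t[i], c[i], t[i + 1], c[i + 1], thr)
    else:
        t_rise = float(t[0])
    down = np.flatnonzero(above[:-1] & ~above[1:])
    down = down[down >= i_peak]
    if down.size:
        i = int(down[0])
        t_fall = _interp_crossing(t[i], c[i], t[i + 1], c[i + 1], thr)
    else:
        t_fall = float(t[-1])
    duration = t_fall - t_rise
    t_peak = float(t[i_peak])
    slope = math.nan
    if t_peak > t_rise:
        slope = 0.9 * (peak - rest) / (t_peak - t_rise)
    return peak, rest, float(duration), float(slope)


def contraction_onset(mech: MechTrace, tension_threshold: float = 20.0,
                      length_threshold: float = 0.99) -> float | None:
    """Onset of cell shortening, or None for a no-contraction case.

    A case counts as contracted only if physical tension reaches
    ``tension_threshold`` (kPa) AND normalized length falls to
    ``length_threshold``; the onset is the interpolated time of the length
    crossing.
    """
    if mech.tension_kpa.max() < tension_threshold:
        return None
    ln = mech.length_norm
    t = mech.time
    idx = np.flatnonzero(ln <= length_threshold)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    return float(_interp_crossing(t[i - 1], ln[i - 1], t[i], ln[i],
                                  length_threshold))


def run_protocol(scaling: ConductanceScaling | None = None,
                 config: SimulationConfig | None = None) -> dict[float, EPTrace]:
    """Run the two-BCL pacing protocol for one case.

    From the 1-Hz paced steady state: ``n_beats`` beats at 600 ms, whose
    final beat is the BCL-600 trace, then ``n_beats`` further beats at
    1000 ms continuing from that state, whose final beat is the BCL-1000
    trace. Returns {bcl: EPTrace} for the configured BCLs.
    """
    if config is None:
        config = SimulationConfig()
    params = config.ep_parameters()
    traces: dict[float, EPTrace] = {}
    state = paced_state()
    for bcl in PROTOCOL_BCLS:
        trace, state = run_paced_ep(
            scaling=scaling, bcl=bcl, n_beats=config.n_beats, params=params,
            dt=config.dt_ms, out_dt=config.output_dt_ms,
            stim_amplitude=config.stim_amplitude,
            stim_duration=config.stim_duration_ms,
            initial_state=state, return_final_state=True)
        if bcl in config.bcl_ms:
            traces[bcl] = trace
        if bcl >= max(config.bcl_ms):
            break
    return traces


def _extract(case_id: int, bcl: float, trace: EPTrace,
             mech: MechTrace | None, config: SimulationConfig) -> BiomarkerRecord:
    max_cai, rest_cai, dur, slope = cai_attributes(trace)
    onset = ap_onset(trace)
    rec = BiomarkerRecord(
        case_id=case_id, bcl=bcl,
        apd90=apd90(trace),
        max_cai=max_cai, rest_cai=rest_cai,
        cai_duration=dur, cai_slope=slope,
        ap_onset_time=math.nan if onset is None else onset,
    )
    if mech is not None and onset is not None:
        c_on = contraction_onset(mech, config.tension_threshold_kpa,
                                 config.length_threshold)
        if c_on is not None:
            rec.contraction_onset_time = c_on
            rec.emd = max(c_on - onset, 0.0)
            rec.contracted = True
    return rec


_LEVEL_OF_FACTOR = {0.25: 0, 0.50: 1, 0.75: 2, 1.00: 3}


def _default_case_id(scaling: ConductanceScaling | None) -> int:
    """Population index of a scaling on the quarter-level grid (else 0)."""
    from .ionic_model import CHANNEL_ORDER
    from .population_sweep import encode_index
    if scaling is None:
        return encode_index([3] * 10)
    try:
        levels = [_LEVEL_OF_FACTOR[round(scaling[c], 6)] for c in CHANNEL_ORDER]
    except KeyError:
        return 0
    return encode_index(levels)


def run_case_pair(scaling: ConductanceScaling | None, case_id: int | None = None,
                  config: SimulationConfig | None = None,
                  mechanics: bool = True) -> list[BiomarkerRecord]:
    """Run one case at every configured BCL and extract all biomarkers.

    Electrophysiology or mechanics divergence is recorded in the affected
    records' ``diverged`` flag; it is never raised past this boundary.
    """
    if config is None:
        config = SimulationConfig()
    if case_id is None:
        case_id = _default_case_id(scaling)
    try:
        traces = run_protocol(scaling, config)
    except EPDivergenceError:
        return [BiomarkerRecord(case_id=case_id, bcl=b, diverged=True)
                for b in config.bcl_ms]
    records = []
    for bcl in config.bcl_ms:
        trace = traces[bcl]
        mech = None
        if mechanics:
            try:
                mech = run_twitch(trace, config.mech_parameters(),
                                  out_dt=config.output_dt_ms)
            except MechDivergenceError:
                records.append(BiomarkerRecord(case_id=case_id, bcl=bcl,
                                               diverged=True))
                continue
        records.append(_extract(case_id, bcl, trace, mech, config))
    return records


def run_case(scaling: ConductanceScaling | None, bcl: float,
             config: SimulationConfig | None = None, case_id: int | None = None,
             mechanics: bool = True) -> BiomarkerRecord:
    """Run one case at one BCL (600 or 1000 ms) and extract its biomarkers."""
    if config is None:
        config = SimulationConfig()
    config = replace(config, bcl_ms=(float(bcl),))
    return run_case_pair(scaling, case_id=case_id, config=config,
                         mechanics=mechanics)[0]
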