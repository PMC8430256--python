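"""Analytic surrogate biomarker generator.

A fast, deterministic stand-in for the ODE pipeline: it emits
BiomarkerRecords whose qualitative structure mirrors the population
results — APD driven up by CaL and down by Ks/Kr/K1 (with a CaL×Ks
interaction), max Cai driven by CaL/Ks/bCa/Kr, long EMD confined to
intermediate CaL levels, and no-contraction at low CaL with low bCa — so
the sweep, table, and stacking machinery are fully testable without ODE
cost. All numbers here are synthetic test fixtures, not model output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ionic_model import CHANNEL_NAMES, ChannelId
from .population_sweep import (
    LEVEL_FACTORS,
    ResultsTable,
    SweepIndex,
    enumerate_scalings,
)
from .protocol_biomarkers import BiomarkerRecord

__all__ = ["SurrogateSpec", "surrogate_record", "generate_surrogate_sweep"]


def _levels_of(levels) -> dict:
    if isinstance(levels, dict):
        out = {name: 3 for name in CHANNEL_NAMES}
        for k, v in levels.items():
            name = k.name if isinstance(k, ChannelId) else str(k)
            out[name] = int(v)
        return out
    return {name: int(l) for name, l in zip(CHANNEL_NAMES, levels)}


@dataclass(frozen=True)
class SurrogateSpec:
    """Response definition of the surrogate generator.

    Per-channel effects are additive level curves (index = level 0..3,
    level 3 = 100 % contributes 0 so the all-normal case returns the base
    values exactly); multiplicative curves scale the calcium attributes.
    ``noise`` is the additive Gaussian sd applied to every biomarker
    (0 = pure function of levels and BCL).
    """

    # APD90 (ms): base per bcl, additive per-level effects, CaL×Ks interaction
    apd_base: dict = field(default_factory=lambda: {600.0: 300.0, 1000.0: 310.0})
    apd_effects: dict = field(default_factory=lambda: {
        "CaL": (-80.0, -40.0, -15.0, 0.0),
        "Ks": (150.0, 90.0, 35.0, 0.0),
        "Kr": (60.0, 35.0, 15.0, 0.0),
        "K1": (40.0, 25.0, 10.0, 0.0),
    })
    apd_cal_ks_interaction: float = 30.0

    # max Cai (mM): base per bcl, multiplicative per-level factors
    cai_base: dict = field(default_factory=lambda: {600.0: 1.247e-3, 1000.0: 0.889e-3})
    cai_factors: dict = field(default_factory=lambda: {
        "CaL": (0.15, 0.5, 0.8, 1.0),
        "Ks": (1.8, 1.5, 1.2, 1.0),
        "bCa": (0.6, 0.8, 0.9, 1.0),
        "Kr": (1.35, 1.25, 1.1, 1.0),
    })
    rest_cai_base: float = 7.0e-5
    rest_cai_fraction: float = 0.056    # rest tracks max Cai weakly

    # EMD (ms): additive effects peaking at intermediate CaL
    emd_base: float = 8.0
    emd_effects: dict = field(default_factory=lambda: {
        "CaL": (15.0, 65.0, 50.0, 0.0),
        "bCa": (10.0, 6.0, 3.0, 0.0),
    })
    # no contraction when CaL is at its lowest level and bCa is low
    no_contraction_bca_max_level: int = 1

    ap_onset: float = 1.0               # ms
    cai_duration_base: dict = field(default_factory=lambda: {600.0: 320.0, 1000.0: 380.0})

    noise: float = 0.0
    seed: int = 0

    def contracts(self, levels: dict) -> bool:
        return not (levels["CaL"] == 0
                    and levels["bCa"] <= self.no_contraction_bca_max_level)


def _case_rng(spec: SurrogateSpec, case_id: int, bcl: float, seed) -> np.random.Generator:
    # stable per-(seed, case, bcl) stream, independent of evaluation order
    return np.random.default_rng([int(seed), int(case_id), int(bcl)])


def surrogate_record(levels, bcl: float, spec: SurrogateSpec | None = None,
                     seed: int | None = None) -> BiomarkerRecord:
    """Evaluate the surrogate at a level vector; deterministic given seed."""
    if spec is None:
        spec = SurrogateSpec()
    lv = _levels_of(levels)
    from .population_sweep import encode_index
    case_id = encode_index(lv)

    apd = spec.apd_base[float(bcl)]
    for name, curve in spec.apd_effects.items():
        apd += curve[lv[name]]
    apd += (spec.apd_cal_ks_interaction
            * (lv["CaL"] / 3.0) * ((3 - lv["Ks"]) / 3.0))

    max_cai = spec.cai_base[float(bcl)]
    for name, curve in spec.cai_factors.items():
        max_cai *= curve[lv[name]]
    rest_cai = spec.rest_cai_base + spec.rest_cai_fraction * (
        max_cai - min(spec.cai_base.values()))
    rest_cai = max(rest_cai, 0.0)

    duration = spec.cai_duration_base[float(bcl)] * (
        1.0 + 0.4 * (3 - lv["CaL"]) / 3.0)
    slope = 0.9 * (max_cai - rest_cai) / 30.0

    contracted = spec.contracts(lv)
    emd = math.nan
    if contracted:
        emd = spec.emd_base
        for name, curve in spec.emd_effects.items():
            emd += curve[lv[name]]

    if spec.noise > 0:
        rng = _case_rng(spec, case_id, bcl, spec.seed if seed is None else seed)
        apd += spec.noise * rng.standard_normal()
        max_cai += 1e-5 * spec.noise * rng.standard_normal()
        rest_cai += 1e-6 * spec.noise * rng.standard_normal()
        duration += spec.noise * rng.standard_normal()
        slope += 1e-6 * spec.noise * rng.standard_normal()
        if contracted:
            emd = max(emd + spec.noise * rng.standard_normal(), 0.0)

    rec = BiomarkerRecord(
        case_id=case_id, bcl=float(bcl),
        apd90=apd, max_cai=max_cai, rest_cai=rest_cai,
        cai_duration=duration, cai_slope=slope,
        ap_onset_time=spec.ap_onset,
        contracted=contracted,
        emd=emd,
    )
    if contracted:
        rec.contraction_onset_time = spec.ap_onset + emd
    return rec


def generate_surrogate_sweep(channels=None, levels: Sequence[int] = (0, 1, 2, 3),
                             bcls: Sequence[float] = (600.0, 1000.0),
                             spec: SurrogateSpec | None = None,
                             seed: int | None = None) -> ResultsTable:
    """Full factorial surrogate table, schema-identical to real sweep output."""
    if spec is None:
        spec = SurrogateSpec()
    records = []
    for sweep_idx, _scaling in enumerate_scalings(channels, levels):
        for bcl in bcls:
            records.append(surrogate_record(sweep_idx.levels, bcl, spec, seed))
    return ResultsTable.from_records(
        records, {"source": "surrogate", "seed": spec.seed if seed is None else seed})
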