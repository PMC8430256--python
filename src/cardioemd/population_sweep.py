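"""Factorial conductance-population enumeration and batch execution.

The full population scales each of the ten channels to 25/50/75/100 % of
its maximum conductance: 4^10 = 1,048,576 cases. A case is identified by a
mixed-radix index over the canonical channel ordering (Na, CaL, to, Kr,
Ks, K1, pK, pCa, bNa, bCa), level digit 0..3 ↦ factor 0.25..1.00, with the
channel's canonical position as its digit significance. Scaled-down sweeps
fix the unswept channels at level 3 (factor 1.00).

Execution is resumable: rows are appended to a checkpoint CSV as they
complete, and a restarted sweep skips every (case, bcl) key already on
disk. Cases are independent, so any execution order yields the same
sorted table.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .ionic_model import CHANNEL_NAMES, CHANNEL_ORDER, ChannelId, ConductanceScaling
from .protocol_biomarkers import (
    RECORD_COLUMNS,
    BiomarkerRecord,
    SimulationConfig,
    run_case_pair,
)

__all__ = [
    "LEVEL_FACTORS",
    "SweepIndex",
    "ResultsTable",
    "encode_index",
    "decode_index",
    "enumerate_scalings",
    "run_sweep",
]

#: level digit → conductance factor
LEVEL_FACTORS = (0.25, 0.50, 0.75, 1.00)

_N_LEVELS = len(LEVEL_FACTORS)
_N_CHANNELS = len(CHANNEL_ORDER)
TOTAL_CASES = _N_LEVELS ** _N_CHANNELS


@dataclass(frozen=True)
class SweepIndex:
    """A case's integer index and its per-channel level vector."""

    index: int
    levels: tuple  # one level digit per channel, canonical order

    def __post_init__(self):
        if not (0 <= self.index < TOTAL_CASES):
            raise ValueError("case index out of range")
        if len(self.levels) != _N_CHANNELS:
            raise ValueError("level vector must have one digit per channel")

    def scaling(self) -> ConductanceScaling:
        return ConductanceScaling(
            {c: LEVEL_FACTORS[l] for c, l in zip(CHANNEL_ORDER, self.levels)})


def encode_index(levels: Sequence[int] | dict) -> int:
    """Mixed-radix case index of a level vector.

    ``levels`` is either a 10-vector in canonical channel order or a
    {channel: level} mapping (missing channels default to level 3).
    """
    if isinstance(levels, dict):
        lv = [3] * _N_CHANNELS
        for key, val in levels.items():
            cid = key if isinstance(key, ChannelId) else ChannelId[str(key)]
            lv[cid.value] = int(val)
        levels = lv
    if len(levels) != _N_CHANNELS:
        raise ValueError("level vector must have one digit per channel")
    index = 0
    for pos, lev in enumerate(levels):
        if not 0 <= int(lev) < _N_LEVELS:
            raise ValueError("level digits must lie in 0..3")
        index += int(lev) * _N_LEVELS ** pos
    return index


def decode_index(index: int) -> tuple:
    """Inverse of :func:`encode_index`: level vector in canonical order."""
    if not (0 <= index < TOTAL_CASES):
        raise ValueError("case index out of range")
    levels = []
    for _ in range(_N_CHANNELS):
        index, rem = divmod(index, _N_LEVELS)
        levels.append(rem)
    return tuple(levels)


def enumerate_scalings(channels: Sequence | None = None,
                       levels: Sequence[int] = (0, 1, 2, 3),
                       ) -> Iterator[tuple[SweepIndex, ConductanceScaling]]:
    """Yield the factorial sub-sweep over ``channels`` in ascending index order.

    Unswept channels stay fixed at level 3 (factor 1.00). The full
    population (all ten channels, four levels) yields 4^10 = 1,048,576
    cases.
    """
    if channels is None:
        channels = CHANNEL_ORDER
    cids = [c if isinstance(c, ChannelId) else ChannelId[str(c)] for c in channels]
    if not cids:
        raise ValueError("channels must be non-empty")
    if len(set(cids)) != len(cids):
        raise ValueError("duplicate channels")
    levels = tuple(int(l) for l in levels)
    # ascending global index order: most significant swept channel varies
    # slowest; unswept digits are constant
    order = sorted(cids, key=lambda c: c.value, reverse=True)
    for combo in product(levels, repeat=len(order)):
        lv = [3] * _N_CHANNELS
        for cid, lev in zip(order, combo):
            lv[cid.value] = lev
        idx = SweepIndex(encode_index(lv), tuple(lv))
        yield idx, idx.scaling()


@dataclass
class ResultsTable:
    """Per-(case, bcl) biomarker rows plus reproducibility metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        dup = self.frame.duplicated(subset=["case_id", "bcl_ms"])
        if dup.any():
            raise ValueError("duplicate (case, bcl) keys in results table")

    @classmethod
    def from_records(cls, records: Iterable[BiomarkerRecord],
                     metadata: dict | None = None) -> "ResultsTable":
        rows = [r.as_row() for r in records]
        frame = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
        frame = frame.sort_values(["case_id", "bcl_ms"]).reset_index(drop=True)
        return cls(frame, metadata or {})

    def to_csv(self, path):
        """Write the table with a commented metadata header."""
        with open(path, "w") as fh:
            for key, val in self.metadata.items():
                fh.write(f"# {key}: {json.dumps(val)}\n")
            self.frame.to_csv(fh, index=False)

    def to_hdf5(self, path):
        """Optional HDF5 mirror: one dataset per column plus metadata attrs."""
        import h5py
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("results")
            for col in self.frame.columns:
                data = self.frame[col].to_numpy()
                if data.dtype == object:
                    data = data.astype(bool)
                grp.create_dataset(col, data=data)
            for key, val in self.metadata.items():
                grp.attrs[key] = json.dumps(val)

    @classmethod
    def read_csv(cls, path) -> "ResultsTable":
        metadata = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body_start += 1
            key, _, val = line[1:].strip().partition(":")
            try:
                metadata[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                metadata[key.strip()] = val.strip()
        frame = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        return cls(frame, metadata)


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.__dict__, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _default_metadata(config: SimulationConfig) -> dict:
    return {
        "config_hash": _config_hash(config),
        "channel_order": list(CHANNEL_NAMES),
        "level_factors": list(LEVEL_FACTORS),
    }


def run_sweep(cases: Iterable[tuple[SweepIndex, ConductanceScaling]] | None = None,
              bcls: Sequence[float] = (600.0, 1000.0),
              config: SimulationConfig | None = None,
              checkpoint: str | os.PathLike | None = None,
              mechanics: bool = True,
              progress: bool = False) -> ResultsTable:
    """Execute ``cases`` at the requested BCLs and collect biomarker rows.

    Each case runs the sequential two-BCL protocol once, so requesting both
    BCLs costs a single pre-paced simulation. With ``checkpoint`` set, rows
    append to that CSV as they complete and completed (case, bcl) keys are
    skipped on restart; per-case divergence is recorded in the row, never
    raised. Returns the full table (checkpointed rows included), sorted by
    (case, bcl).
    """
    if config is None:
        config = SimulationConfig()
    config_bcls = tuple(float(b) for b in bcls)
    from dataclasses import replace
    config = replace(config, bcl_ms=config_bcls)
    if cases is None:
        cases = enumerate_scalings()

    done: set[tuple[int, float]] = set()
    existing_rows: list[dict] = []
    ck_fh = None
    metadata = _default_metadata(config)
    if checkpoint is not None:
        checkpoint = os.fspath(checkpoint)
        if os.path.exists(checkpoint):
            prior = ResultsTable.read_csv(checkpoint)
            if prior.metadata.get("config_hash") not in (
                    None, metadata["config_hash"]):
                raise ValueError(
                    "checkpoint was produced under a different configuration")
            existing_rows = prior.frame.to_dict("records")
            done = {(int(r["case_id"]), float(r["bcl_ms"]))
                    for r in existing_rows}
            ck_fh = open(checkpoint, "a")
        else:
            parent = os.path.dirname(checkpoint) or "."
            if not os.access(parent, os.W_OK):
                raise OSError(f"checkpoint location not writable: {parent}")
            ck_fh = open(checkpoint, "w")
            for key, val in metadata.items():
                ck_fh.write(f"# {key}: {json.dumps(val)}\n")
            ck_fh.write(",".join(RECORD_COLUMNS) + "\n")
            ck_fh.flush()

    rows = list(existing_rows)
    n_run = 0
    try:
        for sweep_idx, scaling in cases:
            todo = [b for b in config_bcls if (sweep_idx.index, b) not in done]
            if not todo:
                continue
            records = run_case_pair(scaling, case_id=sweep_idx.index,
                                    config=config, mechanics=mechanics)
            for rec in records:
                if (rec.case_id, rec.bcl) in done:
                    continue
                row = rec.as_row()
                rows.append(row)
                if ck_fh is not None:
                    ck_fh.write(",".join(str(row[c]) for c in RECORD_COLUMNS)
                                + "\n")
                    ck_fh.flush()
            n_run += 1
            if progress and n_run % 10 == 0:
                contracted = sum(bool(r["contracted"]) for r in rows)
                diverged = sum(bool(r["diverged"]) for r in rows)
                print(f"[sweep] {n_run} cases run, {len(rows)} rows "
                      f"({contracted} contracted, {diverged} diverged)")
    finally:
        if ck_fh is not None:
            ck_fh.close()

    frame = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    for col in ("contracted", "diverged"):
        frame[col] = frame[col].map(
            lambda v: v if isinstance(v, bool) else str(v) == "True")
    frame = frame.sort_values(["case_id", "bcl_ms"]).reset_index(drop=True)
    return ResultsTable(frame, metadata)
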