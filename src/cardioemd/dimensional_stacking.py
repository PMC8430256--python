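"""Dimensional stacking of factorial sweep results into 2-D maps.

Dimensional stacking nests several discrete factors onto each axis of a
pixel map: with five 4-level channels per axis every pixel of a 1024×1024
grid is one of the 4^10 population cases. The axis assignment/order is
free, and is chosen by minimizing the map's roughness — the summed
absolute difference between each cell and its four axis-aligned
neighbors — so that channels with the strongest effect on the biomarker
end up on the coarsest (outermost, longest-label) positions. Exhaustive
search covers small problems; a seeded pairwise-swap hill climb with
restarts covers the full 10-channel space, whose 10!/2 layout classes
(x/y swap leaves the cost invariant) are out of reach of enumeration at
full map size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .ionic_model import CHANNEL_NAMES, ChannelId
from .population_sweep import LEVEL_FACTORS, ResultsTable, decode_index

__all__ = [
    "StackLayout",
    "StackedMap",
    "stack_coordinates",
    "build_map",
    "roughness_cost",
    "optimize_layout",
    "render_map",
]

_N_LEVELS = len(LEVEL_FACTORS)

#: default cap on exhaustively enumerated layout classes (8!/4·... ≈ 8 channels)
EXHAUSTIVE_CAP = 10080


def _as_name(channel) -> str:
    if isinstance(channel, ChannelId):
        return channel.name
    name = str(channel)
    ChannelId[name]  # raises KeyError for unknown channels
    return name


@dataclass(frozen=True)
class StackLayout:
    """Ordered split of the swept channels onto the two axes.

    ``x_order`` / ``y_order`` list channel names outermost → innermost; the
    outermost channel is the most significant digit of its axis coordinate.
    Together the two lists form a permutation of the swept channels.
    """

    x_order: tuple
    y_order: tuple

    def __post_init__(self):
        x = tuple(_as_name(c) for c in self.x_order)
        y = tuple(_as_name(c) for c in self.y_order)
        object.__setattr__(self, "x_order", x)
        object.__setattr__(self, "y_order", y)
        if set(x) & set(y):
            raise ValueError("x_order and y_order must be disjoint")
        if len(set(x)) != len(x) or len(set(y)) != len(y):
            raise ValueError("duplicate channel in layout")

    @property
    def channels(self) -> tuple:
        return self.x_order + self.y_order

    def swapped(self) -> "StackLayout":
        return StackLayout(self.y_order, self.x_order)


def stack_coordinates(levels, layout: StackLayout) -> tuple[int, int]:
    """Map a per-channel level vector to its (x, y) cell of the stacked map.

    ``levels`` is a {channel: level} mapping (canonical 10-vectors work
    too). x = Σ_k level(x_order[k])·4^(n−1−k) with the outermost channel as
    the most significant digit; y analogously. The mapping is bijective
    over the layout's channels.
    """
    if not isinstance(levels, dict):
        levels = {name: lev for name, lev in zip(CHANNEL_NAMES, levels)}
    else:
        levels = {_as_name(k): v for k, v in levels.items()}
    x = 0
    for name in layout.x_order:
        x = x * _N_LEVELS + int(levels[name])
    y = 0
    for name in layout.y_order:
        y = y * _N_LEVELS + int(levels[name])
    return x, y


@dataclass
class StackedMap:
    """A biomarker laid out on the stacked grid (NaN = missing sentinel)."""

    grid: np.ndarray            # shape (4^|y|, 4^|x|), row y, column x
    biomarker: str
    layout: StackLayout
    bcl: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        ny, nx = self.grid.shape
        if (nx != _N_LEVELS ** len(self.layout.x_order)
                or ny != _N_LEVELS ** len(self.layout.y_order)):
            raise ValueError("grid shape does not match the layout")


def _values_nd(table: ResultsTable, biomarker: str, bcl: float,
               channels: tuple) -> np.ndarray:
    """Biomarker values on the dense level grid of ``channels``.

    Requires the table to cover the full factorial over ``channels`` at
    ``bcl`` (all other channels at level 3); missing cases are an error.
    """
    frame = table.frame
    sub = frame[frame["bcl_ms"] == bcl]
    if biomarker not in sub.columns:
        raise KeyError(f"unknown biomarker column: {biomarker}")
    positions = [ChannelId[name].value for name in channels]
    others = [c.value for c in ChannelId if c.name not in channels]
    shape = (_N_LEVELS,) * len(channels)
    values = np.full(shape, np.nan)
    filled = np.zeros(shape, dtype=bool)
    for case_id, value in zip(sub["case_id"].to_numpy(),
                              sub[biomarker].to_numpy()):
        lv = decode_index(int(case_id))
        if any(lv[p] != 3 for p in others):
            continue
        key = tuple(lv[p] for p in positions)
        values[key] = value
        filled[key] = True
    if not filled.all():
        missing = np.argwhere(~filled)[:10]
        raise ValueError(
            f"incomplete factorial for channels {channels} at bcl {bcl}: "
            f"{(~filled).sum()} cases missing, first {missing.tolist()}")
    return values


def build_map(table: ResultsTable, biomarker: str, layout: StackLayout,
              bcl: float) -> StackedMap:
    """Fill the stacked grid from a results table.

    Every cell holds the biomarker value of its decoded case, or the NaN
    sentinel for missing quantities (no-contraction EMD, diverged cases).
    """
    channels = layout.channels
    values = _values_nd(table, biomarker, bcl, channels)
    grid = _grid_from_values(values, channels, layout)
    return StackedMap(grid=grid, biomarker=biomarker, layout=layout, bcl=bcl)


def _grid_from_values(values: np.ndarray, value_channels: tuple,
                      layout: StackLayout) -> np.ndarray:
    """Reshape a dense level grid (axes ordered as ``value_channels``) into
    the layout's 2-D map."""
    pos = {name: k for k, name in enumerate(value_channels)}
    axes = [pos[name] for name in layout.y_order] + \
           [pos[name] for name in layout.x_order]
    ny = _N_LEVELS ** len(layout.y_order)
    nx = _N_LEVELS ** len(layout.x_order)
    return values.transpose(axes).reshape(ny, nx)


def roughness_cost(stacked: StackedMap | np.ndarray) -> float:
    """Summed absolute difference over all axis-aligned neighbor pairs.

    Each unordered adjacent pair is counted once; pairs involving a NaN
    sentinel contribute 0, and borders do not wrap.
    """
    grid = stacked.grid if isinstance(stacked, StackedMap) else np.asarray(stacked)
    h = np.abs(np.diff(grid, axis=1))
    v = np.abs(np.diff(grid, axis=0))
    return float(np.nansum(h) + np.nansum(v))


def _layout_classes(channels: tuple, nx: int):
    """All layouts over ``channels`` with |x_order| = nx, modulo x/y swap."""
    channels = tuple(channels)
    n = len(channels)
    seen = set()
    for x_set in combinations(channels, nx):
        y_set = tuple(c for c in channels if c not in x_set)
        for x_perm in permutations(x_set):
            for y_perm in permutations(y_set):
                key = min((x_perm, y_perm), (y_perm, x_perm))
                if key in seen:
                    continue
                seen.add(key)
                # canonical class representative: lexicographically smaller
                # of the two swap-equivalent layouts (same cost either way)
                yield StackLayout(*key)


def _count_layout_classes(n: int, nx: int) -> int:
    total = math.comb(n, nx) * math.factorial(nx) * math.factorial(n - nx)
    return total // 2 if 2 * nx == n else total


def optimize_layout(table: ResultsTable, biomarker: str, bcl: float,
                    channels=None, mode: str = "exhaustive",
                    seed: int = 0, n_restarts: int = 10,
                    exhaustive_cap: int = EXHAUSTIVE_CAP,
                    ) -> tuple[StackLayout, float]:
    """Find the layout minimizing the roughness cost.

    ``exhaustive`` enumerates every layout class (x/y swap excluded) and is
    provably global; it refuses when the class count exceeds
    ``exhaustive_cap``. ``heuristic`` runs seeded pairwise-swap hill
    climbing with restarts over the concatenated (x, y) channel sequence.
    Equal-cost ties resolve to the lexicographically smallest
    (x_order, y_order).
    """
    if channels is None:
        channels = _swept_channels(table, bcl)
    channels = tuple(_as_name(c) for c in channels)
    n = len(channels)
    nx = (n + 1) // 2
    if mode == "exhaustive":
        n_classes = _count_layout_classes(n, nx)
        if n_classes > exhaustive_cap:
            raise ValueError(
                f"exhaustive mode refused: {n_classes} layout classes exceed "
                f"the cap of {exhaustive_cap}")
    elif mode != "heuristic":
        raise ValueError("mode must be 'exhaustive' or 'heuristic'")
    values = _values_nd(table, biomarker, bcl, channels)

    def cost_of(layout: StackLayout) -> float:
        return roughness_cost(_grid_from_values(values, channels, layout))

    if mode == "exhaustive":
        best = None
        for layout in _layout_classes(channels, nx):
            c = cost_of(layout)
            key = (c, layout.x_order, layout.y_order)
            if best is None or key < best:
                best = key
        return StackLayout(best[1], best[2]), best[0]

    rng = np.random.default_rng(seed)
    best_layout = None
    best_cost = math.inf
    for _ in range(n_restarts):
        perm = list(rng.permutation(n))
        seq = [channels[i] for i in perm]
        layout = StackLayout(tuple(seq[:nx]), tuple(seq[nx:]))
        cost = cost_of(layout)
        improved = True
        while improved:
            improved = False
            for i in range(n - 1):
                for j in range(i + 1, n):
                    cand = seq.copy()
                    cand[i], cand[j] = cand[j], cand[i]
                    cand_layout = StackLayout(tuple(cand[:nx]), tuple(cand[nx:]))
                    cand_cost = cost_of(cand_layout)
                    if cand_cost < cost - 1e-12:
                        seq, layout, cost = cand, cand_layout, cand_cost
                        improved = True
        key = (cost, layout.x_order, layout.y_order)
        if best_layout is None or key < (best_cost, best_layout.x_order,
                                         best_layout.y_order):
            best_layout, best_cost = layout, cost
    return best_layout, best_cost


def _swept_channels(table: ResultsTable, bcl: float) -> tuple:
    """Channels that actually vary in the table at the given BCL."""
    frame = table.frame
    ids = frame.loc[frame["bcl_ms"] == bcl, "case_id"].astype(int)
    levels = np.array([decode_index(i) for i in ids])
    varying = [CHANNEL_NAMES[k] for k in range(levels.shape[1])
               if len(np.unique(levels[:, k])) > 1]
    return tuple(varying)


def render_map(stacked: StackedMap, out_image=None, out_grid=None,
               cmap: str = "jet", sentinel_color: str = "navy"):
    """Write the map as an image with nested axis labels and/or a TSV grid.

    Sentinel (NaN) cells render in the reserved ``sentinel_color``. The
    tick structure follows the nesting convention: the outermost channel
    splits its axis into 4 blocks, each inner channel into 4 sub-blocks of
    the previous size.
    """
    if out_grid is not None:
        np.savetxt(out_grid, stacked.grid, delimiter="\t", fmt="%.6g")
    if out_image is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = stacked.grid
    fig, ax = plt.subplots(figsize=(7, 7))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(sentinel_color)
    im = ax.imshow(np.ma.masked_invalid(grid), origin="lower", cmap=cm,
                   interpolation="nearest", aspect="auto")
    fig.colorbar(im, ax=ax, label=stacked.biomarker)

    def _nested_ticks(axis_orders, length, which):
        block = length
        for depth, name in enumerate(axis_orders):
            block //= _N_LEVELS
            if depth >= 2:       # labelling deeper nests is unreadable
                break
            centers = np.arange(_N_LEVELS ** (depth + 1)) * block + block / 2 - 0.5
            if depth == 0:
                labels = [f"{name}\n{int(f * 100)}%" for f in LEVEL_FACTORS]
                if which == "x":
                    ax.set_xticks(centers)
                    ax.set_xticklabels(labels, fontsize=8)
                else:
                    ax.set_yticks(centers)
                    ax.set_yticklabels(labels, fontsize=8)

    _nested_ticks(stacked.layout.x_order, grid.shape[1], "x")
    _nested_ticks(stacked.layout.y_order, grid.shape[0], "y")
    ax.set_xlabel(" → ".join(stacked.layout.x_order))
    ax.set_ylabel(" → ".join(stacked.layout.y_order))
    ax.set_title(f"{stacked.biomarker}, BCL {stacked.bcl:.0f} ms")
    fig.tight_layout()
    fig.savefig(out_image, dpi=150)
    plt.close(fig)
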