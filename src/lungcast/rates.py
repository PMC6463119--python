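"""Finite-dimensional parameterization of the rate surfaces.

Each of the five transition rates is piecewise constant on rectangular
(time block) x (age block) cells; the free parameter vector ``theta`` holds
one log-rate per block so that unconstrained optimization keeps every rate
positive.  Ages below a symbol's first age edge are structurally zero (e.g.
smoking uptake before the youngest surveyed age), and forecast-horizon years
are filled by carrying the most recent fitted year's age profile forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .model import SYMBOLS, Grid, RateSet, RateSurface


class StructureError(ValueError):
    """Parameter vector and block structure disagree."""


def _check_edges(name: str, edges: Sequence[int]) -> Tuple[int, ...]:
    t = tuple(int(e) for e in edges)
    if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])):
        raise StructureError(f"{name}: edges must be strictly increasing, got {t}")
    return t


@dataclass(frozen=True)
class BlockStructure:
    """Closed-open block edges per rate symbol.

    ``age_edges[s] = (e0, e1, ..., ek)`` defines age blocks ``[e0,e1), ...``;
    ages below ``e0`` (or at/above ``ek``) carry rate 0 and no parameter.
    ``time_edges`` is shared by all symbols and must cover every grid year.
    """

    age_edges: Mapping[str, Tuple[int, ...]]
    time_edges: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_edges", _check_edges("time", self.time_edges))
        ae = {}
        for s in SYMBOLS:
            if s not in self.age_edges:
                raise StructureError(f"age_edges missing symbol {s!r}")
            ae[s] = _check_edges(f"age[{s}]", self.age_edges[s])
        object.__setattr__(self, "age_edges", ae)

    @property
    def n_time_blocks(self) -> int:
        return len(self.time_edges) - 1

    def n_age_blocks(self, symbol: str) -> int:
        return len(self.age_edges[symbol]) - 1

    @property
    def n_params(self) -> int:
        return self.n_time_blocks * sum(self.n_age_blocks(s) for s in SYMBOLS)

    def labels(self) -> List[Tuple[str, int, int]]:
        """(symbol, time_lo, age_lo) per parameter, in theta order."""
        out = []
        for s in SYMBOLS:
            for ti in range(self.n_time_blocks):
                for ai in range(self.n_age_blocks(s)):
                    out.append((s, self.time_edges[ti], self.age_edges[s][ai]))
        return out

    def blocks(self) -> List[Tuple[str, int, int, int, int]]:
        """(symbol, t_lo, t_hi, a_lo, a_hi) per parameter, closed-open."""
        out = []
        for s in SYMBOLS:
            for ti in range(self.n_time_blocks):
                for ai in range(self.n_age_blocks(s)):
                    out.append(
                        (
                            s,
                            self.time_edges[ti],
                            self.time_edges[ti + 1],
                            self.age_edges[s][ai],
                            self.age_edges[s][ai + 1],
                        )
                    )
        return out

    def check_covers(self, grid: Grid) -> None:
        if self.time_edges[0] > grid.t0 or self.time_edges[-1] <= grid.t_max:
            raise StructureError(
                f"time edges {self.time_edges} do not cover grid years "
                f"[{grid.t0}, {grid.t_max}]"
            )

    def to_dict(self) -> dict:
        return {
            "age_edges": {s: list(self.age_edges[s]) for s in SYMBOLS},
            "time_edges": list(self.time_edges),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BlockStructure":
        return cls(
            age_edges={s: tuple(d["age_edges"][s]) for s in SYMBOLS},
            time_edges=tuple(d["time_edges"]),
        )


def _block_slices(
    blocks: BlockStructure, symbol: str, grid: Grid
) -> List[Tuple[int, slice, slice]]:
    """Per-parameter (local index, year slice, age slice) into a surface."""
    out = []
    te = blocks.time_edges
    ae = blocks.age_edges[symbol]
    k = 0
    for ti in range(len(te) - 1):
        y0 = max(te[ti], grid.t0) - grid.t0
        y1 = min(te[ti + 1], grid.t_max + 1) - grid.t0
        for ai in range(len(ae) - 1):
            a0 = min(max(ae[ai], grid.a0), grid.a_max + 1) - grid.a0
            a1 = min(max(ae[ai + 1], grid.a0), grid.a_max + 1) - grid.a0
            out.append((k, slice(y0, max(y1, y0)), slice(a0, max(a1, a0))))
            k += 1
    return out


def expand(theta: np.ndarray, blocks: BlockStructure, grid: Grid) -> RateSet:
    """Map log-rate parameters to the five piecewise-constant rate surfaces.

    Surfaces cover every grid year ``t0..t_max``; cells outside a symbol's age
    blocks are zero.  ``collapse(expand(theta))`` recovers ``theta`` to within
    one unit in the last place (the exp/log pair is not bit-exact in floating
    point).
    """
    theta = np.asarray(theta, dtype=float)
    blocks.check_covers(grid)
    if theta.shape != (blocks.n_params,):
        raise StructureError(
            f"theta length {theta.shape} != block count ({blocks.n_params},)"
        )
    if not np.isfinite(theta).all():
        raise StructureError("theta must be finite")
    rates: RateSet = {}
    offset = 0
    for s in SYMBOLS:
        n_b = blocks.n_time_blocks * blocks.n_age_blocks(s)
        vals = np.zeros((grid.n_years, grid.n_ages))
        for k, ys, as_ in _block_slices(blocks, s, grid):
            vals[ys, as_] = np.exp(theta[offset + k])
        rates[s] = RateSurface(name=s, t0=grid.t0, a0=grid.a0, values=vals)
        offset += n_b
    return rates


def collapse(
    rates: Mapping[str, RateSurface],
    blocks: BlockStructure,
    grid: Grid,
    how: str = "first",
) -> np.ndarray:
    """Project rate surfaces onto the block structure, returning log rates.

    ``how='first'`` reads each block's first covered cell (the exact inverse
    of :func:`expand` for block-constant surfaces); ``how='mean'`` averages
    over the block, which is how smooth ground-truth surfaces are snapped onto
    a block structure.  Blocks with no covered cell get log-rate -inf guard of
    a tiny floor.
    """
    blocks.check_covers(grid)
    out = np.empty(blocks.n_params)
    offset = 0
    for s in SYMBOLS:
        surf = rates[s]
        vals = surf.values
        for k, ys, as_ in _block_slices(blocks, s, grid):
            cellblock = vals[ys, as_]
            if cellblock.size == 0:
                v = 1e-300
            elif how == "first":
                v = cellblock.flat[0]
            elif how == "mean":
                v = float(cellblock.mean())
            else:
                raise StructureError(f"unknown collapse mode {how!r}")
            out[offset + k] = np.log(max(v, 1e-300))
        offset += blocks.n_time_blocks * blocks.n_age_blocks(s)
    return out


def extend_forecast(
    rates: Mapping[str, RateSurface], last_fitted_year: int, horizon_end: int
) -> RateSet:
    """Carry each surface's age profile at ``last_fitted_year`` forward.

    Every forecast-horizon cell (years ``last_fitted_year+1..horizon_end``)
    takes the value of the same age in the most recent fitted year, so the
    final age profile is preserved verbatim.  Idempotent; a horizon at or
    before the last fitted year is a no-op.
    """
    out: RateSet = {}
    for s, surf in rates.items():
        base = surf.at_year(last_fitted_year)
        n_keep = last_fitted_year - surf.t0 + 1
        n_extra = max(horizon_end - last_fitted_year, 0)
        vals = np.vstack([surf.values[:n_keep]] + [base] * n_extra) if n_extra \
            else surf.values.copy()
        out[s] = RateSurface(name=surf.name, t0=surf.t0, a0=surf.a0, values=vals)
    return out
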