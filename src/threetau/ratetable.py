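"""Precomputed component-rate tables on a 16-per-decade time-constant grid.

The forward model is cheap enough to evaluate directly, but fitting
benefits from tables of unit-density component rates precomputed on a
logarithmic (tau, frequency) grid, mirroring the datafile architecture of
the original 3TM software.  Each component kind is tabulated against its
governing time constant (ll, sl: tau_l; lb, bl, bb, sb: tau_b) with the
remaining time constants held at the values of a base parameter set.

Interpolation is bilinear in (log10 tau, log10 f) on log10 rate, which is
accurate to better than 2% for these smooth power-law-like surfaces.
Queries outside the grid raise; there is no silent extrapolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .constants import DELTA
from .model import COMPONENT_KINDS, ThreeTauParams, component_rate, intensity_constants

#: Nodes per decade of the tau grids.
NODES_PER_DECADE = 16

#: Which time constant governs each component kind's table axis.
GOVERNING_TAU = {"ll": "tau_l", "sl": "tau_l",
                 "lb": "tau_b", "bl": "tau_b", "bb": "tau_b", "sb": "tau_b"}


class TauRangeError(ValueError):
    """Query tau or frequency outside the tabulated grid."""


def tau_grid(decade_min: float, decade_max: float) -> np.ndarray:
    """Logarithmic grid with exactly 16 nodes per decade, endpoints included.

    decade_min/decade_max are powers of ten spanning whole decades.
    """
    lo = np.log10(decade_min)
    hi = np.log10(decade_max)
    n_dec = hi - lo
    if abs(n_dec - round(n_dec)) > 1e-9:
        raise ValueError("tau range must span whole decades")
    n = int(round(n_dec)) * NODES_PER_DECADE
    return 10.0 ** (lo + np.arange(n + 1) / NODES_PER_DECADE)


@dataclass
class RateTable:
    """Unit-density component rates tabulated on (tau, frequency) grids."""

    frequency_grid: np.ndarray                  # MHz, log-spaced
    tau_grids: Dict[str, np.ndarray]            # per kind, seconds
    rates: Dict[str, np.ndarray]                # per kind, (n_tau, n_freq)
    base_params: ThreeTauParams
    metadata: dict = field(default_factory=dict)


def build_rate_table(tau_ranges: Dict[str, Tuple[float, float]],
                     frequency_grid,
                     base_params: ThreeTauParams | None = None,
                     bulk_form: str = "translational") -> RateTable:
    """Tabulate unit-density rates for every component kind.

    tau_ranges maps "tau_l" and "tau_b" to (decade_min, decade_max) in
    seconds; whole decades are required so that consecutive grid nodes
    keep the exact 10^(1/16) ratio.
    """
    f = np.asarray(frequency_grid, dtype=float)
    if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
        raise ValueError("frequency grid must be increasing with >= 2 points")
    if base_params is None:
        from . import reference
        ref = reference.healthy_reference()
        base_params = ThreeTauParams.from_report_units(
            ref["tau_l_us"], ref["tau_d_us"], ref["tau_b_ps"],
            ref["x"], ref["N_l"], ref["N_sigma"])

    grids = {}
    rates = {}
    for kind in COMPONENT_KINDS:
        role = GOVERNING_TAU[kind]
        grid = tau_grid(*tau_ranges[role])
        table = np.empty((grid.size, f.size))
        for i, tau in enumerate(grid):
            params = _with_unit_density(base_params, kind, role, tau)
            table[i] = component_rate(kind, f, params, bulk_form=bulk_form)
        grids[kind] = grid
        rates[kind] = table
    a_hh, a_hm = intensity_constants(bulk_form)
    meta = {
        "delta_m": DELTA,
        "A_HH": a_hh,
        "A_HM": a_hm,
        "bulk_form": bulk_form,
        "nodes_per_decade": NODES_PER_DECADE,
        "base_params": base_params.to_report_units(),
    }
    return RateTable(frequency_grid=f, tau_grids=grids, rates=rates,
                     base_params=base_params, metadata=meta)


def _with_unit_density(base: ThreeTauParams, kind: str, role: str,
                       tau: float) -> ThreeTauParams:
    kw = {"tau_l": base.tau_l, "tau_d": base.tau_d, "tau_b": base.tau_b,
          "x": base.x, "N_l": base.N_l, "N_sigma": base.N_sigma}
    kw[role] = tau
    if kind in ("sl", "sb"):
        kw["N_sigma"] = 1.0
    else:
        kw["N_l"] = 1.0  # bb ignores N_l; harmless
    return ThreeTauParams(**kw)


def interpolate_rate(table: RateTable, kind: str, f_mhz: float, tau: float) -> float:
    """Bilinear log-log interpolation of the unit-density rate.

    Exactly reproduces direct evaluation at grid nodes; raises
    TauRangeError outside the tabulated tau or frequency range.
    """
    if kind not in COMPONENT_KINDS:
        raise ValueError(f"unknown component kind {kind!r}")
    grid = table.tau_grids[kind]
    f_grid = table.frequency_grid
    if not (grid[0] <= tau <= grid[-1]):
        raise TauRangeError(
            f"tau {tau:g} outside table range [{grid[0]:g}, {grid[-1]:g}]")
    if not (f_grid[0] <= f_mhz <= f_grid[-1]):
        raise TauRangeError(
            f"frequency {f_mhz:g} outside table range "
            f"[{f_grid[0]:g}, {f_grid[-1]:g}]")
    lt = np.log10(grid)
    lf = np.log10(f_grid)
    lr = np.log10(table.rates[kind])
    i = int(np.clip(np.searchsorted(lt, np.log10(tau)) - 1, 0, lt.size - 2))
    j = int(np.clip(np.searchsorted(lf, np.log10(f_mhz)) - 1, 0, lf.size - 2))
    u = (np.log10(tau) - lt[i]) / (lt[i + 1] - lt[i])
    v = (np.log10(f_mhz) - lf[j]) / (lf[j + 1] - lf[j])
    val = ((1 - u) * (1 - v) * lr[i, j] + u * (1 - v) * lr[i + 1, j]
           + (1 - u) * v * lr[i, j + 1] + u * v * lr[i + 1, j + 1])
    return float(10.0 ** val)


def save_rate_table(table: RateTable, path) -> None:
    """Persist as a single self-describing .npz archive (exact round-trip)."""
    arrays = {"frequency_grid": table.frequency_grid}
    for kind in COMPONENT_KINDS:
        arrays[f"tau_{kind}"] = table.tau_grids[kind]
        arrays[f"rates_{kind}"] = table.rates[kind]
    arrays["metadata_json"] = np.array(json.dumps(table.metadata))
    np.savez(path, **arrays)


def load_rate_table(path) -> RateTable:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["metadata_json"]))
        base = ThreeTauParams.from_report_units(**meta["base_params"])
        return RateTable(
            frequency_grid=z["frequency_grid"],
            tau_grids={k: z[f"tau_{k}"] for k in COMPONENT_KINDS},
            rates={k: z[f"rates_{k}"] for k in COMPONENT_KINDS},
            base_params=base,
            metadata=meta,
        )
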