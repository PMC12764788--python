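"""Synthetic murine FFC-NMR cohort generator.

Emulates the statistical structure the biomarker screen assumes: three
supplier groups (11/11/10 samples), tumour fractions spanning 0-83% with
one healthy control per group, per-sample 3TM parameters following
linear trends with group intercept offsets and between-sample scatter,
and forward-simulated dispersion profiles carrying the two instrument
artifacts the pre-fit filter exists for (a weak quadrupolar bump at
2 MHz and a discontinuity above the 8 MHz protocol switch) plus 3%
multiplicative measurement noise.

The low-field rate R1(0.01 MHz) is never generated independently: it is
computed from each sample's parameters through the forward model, so its
effective trend is an emergent property, validated rather than imposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ThreeTauParams, r1_total
from .profiles import GROUPS, NMRDProfile
from .reference import QUANTITIES, QuantityTrend, default_trends

logger = logging.getLogger(__name__)

#: Truth-table columns in file order.
TRUTH_COLUMNS = ("sample_id", "group", "tumour_fraction_percent",
                 "tau_l_us", "tau_d_us", "tau_b_ps", "x", "N_l", "N_sigma")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the simulated cohort."""

    group_sizes: Tuple[int, int, int] = (11, 11, 10)
    c_range: Tuple[float, float] = (0.0, 83.0)
    n_freq: int = 28
    f_min_mhz: float = 0.01
    f_max_mhz: float = 40.0
    noise_rel_sd: float = 0.03
    quad_center_mhz: float = 2.0
    quad_log_width: float = 0.05      # decades
    quad_rel_amplitude: float = 0.05
    switch_mhz: float = 8.0
    switch_rel_offset: float = -0.05
    seed: int = 0
    trends: Dict[str, QuantityTrend] = field(default_factory=default_trends)

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("each group needs at least 2 samples")
        if self.f_min_mhz <= 0 or self.f_max_mhz <= self.f_min_mhz:
            raise ValueError("frequency range must be positive and increasing")

    @property
    def frequency_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.f_min_mhz), np.log10(self.f_max_mhz),
                           self.n_freq)


def sample_parameters(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-sample tumour fractions and true 3TM parameters.

    Within each group the first sample is a healthy control (c = 0) and
    the rest draw c uniformly over the configured range.  Each parameter
    follows intercept + group offset + gradient*c + Normal(0, scatter),
    truncated to its physical bounds; heavy truncation (> 20% of draws)
    triggers a spec-inconsistency warning.
    """
    rows = []
    n_trunc = 0
    n_draws = 0
    param_names = [q for q in QUANTITIES if q != "R1_001MHz"]
    for gi, (group, size) in enumerate(zip(GROUPS, spec.group_sizes)):
        cs = np.concatenate([[0.0],
                             rng.uniform(spec.c_range[0], spec.c_range[1],
                                         size - 1)])
        for j, c in enumerate(cs):
            row = {"sample_id": f"{group}-{j + 1:02d}", "group": group,
                   "tumour_fraction_percent": float(c)}
            for q in param_names:
                tr = spec.trends[q]
                mean = tr.intercept + tr.group_offsets[gi] + tr.gradient * c
                val = mean + tr.scatter_sd * rng.standard_normal()
                n_draws += 1
                lo, hi = tr.bounds
                if val < lo or val > hi:
                    n_trunc += 1
                    val = float(np.clip(val, lo, hi))
                row[q] = float(val)
            rows.append(row)
    if n_draws and n_trunc / n_draws > 0.2:
        warnings.warn(
            f"parameter truncation hit on {n_trunc}/{n_draws} draws; "
            "trend table and bounds look inconsistent", stacklevel=2)
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def params_from_row(row) -> ThreeTauParams:
    return ThreeTauParams.from_report_units(
        row["tau_l_us"], row["tau_d_us"], row["tau_b_ps"],
        row["x"], row["N_l"], row["N_sigma"])


def simulate_profile(params: ThreeTauParams, spec: CohortSpec,
                     rng: np.random.Generator, *, sample_id: str = "sim",
                     group: str = "4T1", tumour_fraction: float = 0.0,
                     max_retries: int = 20) -> NMRDProfile:
    """Forward-simulate one noisy profile with instrument artifacts.

    r1(f) = R1_model(f) * (1 + quad_bump(f)) * (1 + switch_step(f))
                         * (1 + eps),  eps ~ N(0, noise_rel_sd) per point.
    The bump is Gaussian in log10 f around the quadrupolar peak; the step
    applies only beyond the protocol-switch frequency.  Non-positive
    draws are resampled (bounded retries).
    """
    f = spec.frequency_grid
    clean = r1_total(f, params)
    logf = np.log10(f)
    bump = spec.quad_rel_amplitude * np.exp(
        -0.5 * ((logf - np.log10(spec.quad_center_mhz)) / spec.quad_log_width) ** 2)
    step = np.where(f > spec.switch_mhz, spec.switch_rel_offset, 0.0)
    base = clean * (1.0 + bump) * (1.0 + step)
    r1 = base * (1.0 + spec.noise_rel_sd * rng.standard_normal(f.size))
    for _ in range(max_retries):
        bad = r1 <= 0
        if not bad.any():
            break
        r1[bad] = base[bad] * (1.0 + spec.noise_rel_sd
                               * rng.standard_normal(int(bad.sum())))
    else:
        raise RuntimeError("could not draw positive R1 values")
    return NMRDProfile(sample_id=sample_id, group=group,
                       tumour_fraction=tumour_fraction,
                       frequency_mhz=f, r1=r1)


def generate_cohort(spec: CohortSpec) -> Tuple[List[NMRDProfile], pd.DataFrame]:
    """Generate the full cohort: profiles plus the truth table.

    Deterministic end-to-end under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    truth = sample_parameters(spec, rng)
    profiles = []
    for _, row in truth.iterrows():
        p = params_from_row(row)
        profiles.append(simulate_profile(
            p, spec, rng, sample_id=row["sample_id"], group=row["group"],
            tumour_fraction=row["tumour_fraction_percent"]))
    return profiles, truth


def write_truth(truth: pd.DataFrame, sink) -> None:
    """Write the truth table at 9 significant digits (exact CSV round-trip)."""
    out = truth.copy()
    for col in TRUTH_COLUMNS[2:]:
        out[col] = out[col].map(lambda v: f"{v:.9g}")
    out.to_csv(sink, index=False)


def read_truth(source) -> pd.DataFrame:
    return pd.read_csv(source)
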