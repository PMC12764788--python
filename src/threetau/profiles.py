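"""NMRD profile containers, CSV I/O and the pre-fit exclusion rules.

Measured dispersion profiles carry two instrument artifacts that must not
enter the fit: a discontinuity at the pulse-sequence switching frequency
(data beyond 8 MHz are dropped) and a weak quadrupolar 1H-14N peak near
2 MHz (the two log-nearest points are dropped).  Masked points are never
deleted - they stay in the container with a reason flag and are simply
skipped by the fit.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("4T1", "FARN", "TSA")

#: Exclusion reasons.
REASON_NONE = "none"
REASON_ABOVE_SWITCH = "above_switch"
REASON_QUADRUPOLAR = "quadrupolar"

#: Minimum unmasked points for a profile to be fittable (six parameters).
MIN_FITTABLE_POINTS = 6

REQUIRED_COLUMNS = ("sample_id", "group", "tumour_fraction_percent",
                    "frequency_MHz", "R1_per_s")


class ProfileFormatError(ValueError):
    """Malformed profile table (missing column, bad value, duplicate row)."""


class UnfittableProfileError(ValueError):
    """Too few unmasked points survive the exclusion rules."""


@dataclass(frozen=True)
class FilterPolicy:
    """Pre-fit exclusion policy.

    f_max: retain points with frequency <= f_max MHz ("beyond" is
    exclusive, so 8 MHz itself survives the default policy).
    quad_center / quad_exclusion_count: mask the count points nearest the
    quadrupolar peak in log-frequency distance.
    """

    f_max: float = 8.0
    quad_center: float = 2.0
    quad_exclusion_count: int = 2

    def __post_init__(self) -> None:
        if not (self.f_max > self.quad_center > 0):
            raise ValueError("require f_max > quad_center > 0")
        if self.quad_exclusion_count < 0:
            raise ValueError("quad_exclusion_count must be >= 0")


@dataclass(frozen=True)
class NMRDProfile:
    """One sample's dispersion curve R1(f) with metadata and mask."""

    sample_id: str
    group: str
    tumour_fraction: float  # percent, 0..100
    frequency_mhz: np.ndarray
    r1: np.ndarray
    r1_sd: Optional[np.ndarray] = None
    exclusion_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_mhz, dtype=float)
        r = np.asarray(self.r1, dtype=float)
        object.__setattr__(self, "frequency_mhz", f)
        object.__setattr__(self, "r1", r)
        if self.r1_sd is not None:
            object.__setattr__(self, "r1_sd", np.asarray(self.r1_sd, dtype=float))
        if self.exclusion_reason is None:
            object.__setattr__(self, "exclusion_reason",
                               np.full(f.shape, REASON_NONE, dtype=object))
        else:
            object.__setattr__(self, "exclusion_reason",
                               np.asarray(self.exclusion_reason, dtype=object))
        if self.group not in GROUPS:
            raise ProfileFormatError(
                f"sample {self.sample_id!r}: group {self.group!r} not in {GROUPS}")
        if not (0.0 <= self.tumour_fraction <= 100.0):
            raise ProfileFormatError(
                f"sample {self.sample_id!r}: tumour fraction "
                f"{self.tumour_fraction} outside [0, 100]")
        if f.ndim != 1 or f.size == 0:
            raise ProfileFormatError(f"sample {self.sample_id!r}: empty profile")
        if np.any(f <= 0):
            raise ProfileFormatError(
                f"sample {self.sample_id!r}: frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ProfileFormatError(
                f"sample {self.sample_id!r}: frequencies must be strictly increasing")
        if np.any(r <= 0):
            raise ProfileFormatError(
                f"sample {self.sample_id!r}: R1 must be positive")

    @property
    def n_points(self) -> int:
        return int(self.frequency_mhz.size)

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean selector of points that participate in fitting."""
        return self.exclusion_reason == REASON_NONE

    def masked_profile(self) -> "NMRDProfile":
        return self


def apply_exclusions(profile: NMRDProfile,
                     policy: FilterPolicy = FilterPolicy()) -> NMRDProfile:
    """Populate the exclusion mask from scratch (deterministic, idempotent).

    Points with f > f_max are flagged above_switch; the
    quad_exclusion_count points with smallest |log f - log quad_center|
    are flagged quadrupolar (ties resolved toward the lower frequency).
    Raises UnfittableProfileError when fewer than six points survive.
    """
    f = profile.frequency_mhz
    reason = np.full(f.shape, REASON_NONE, dtype=object)
    reason[f > policy.f_max] = REASON_ABOVE_SWITCH
    if policy.quad_exclusion_count > 0:
        logdist = np.abs(np.log10(f) - math.log10(policy.quad_center))
        # stable argsort on (distance, frequency): lower frequency wins ties
        order = np.lexsort((f, logdist))
        take = order[: policy.quad_exclusion_count]
        reason[take] = REASON_QUADRUPOLAR
    out = replace(profile, exclusion_reason=reason)
    n_ok = int(np.sum(out.unmasked))
    if n_ok < MIN_FITTABLE_POINTS:
        raise UnfittableProfileError(
            f"sample {profile.sample_id!r}: only {n_ok} unmasked points remain "
            f"after exclusions (need >= {MIN_FITTABLE_POINTS})")
    return out


def read_profiles(source) -> List[NMRDProfile]:
    """Read profiles from CSV (path, file object or string buffer).

    Expected columns: sample_id, group, tumour_fraction_percent,
    frequency_MHz, R1_per_s and optionally R1_sd_per_s and
    excluded_reason.  One row per (sample, frequency); rows are sorted by
    frequency per sample (with a warning when re-ordering was needed).
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # noqa: BLE001 - surface parse failures with context
        raise ProfileFormatError(f"could not parse profile CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in ("frequency_MHz", "R1_per_s", "tumour_fraction_percent"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()
            raise ProfileFormatError(f"non-numeric {col} at row(s) {rows}")
        df[col] = pd.to_numeric(df[col])
    dupes = df.duplicated(subset=["sample_id", "frequency_MHz"])
    if dupes.any():
        raise ProfileFormatError(
            f"duplicate (sample, frequency) rows: {df.index[dupes].tolist()}")

    profiles = []
    for sample_id, part in df.groupby("sample_id", sort=False):
        if not part["frequency_MHz"].is_monotonic_increasing:
            logger.warning("sample %r: frequencies out of order; re-sorting", sample_id)
        part = part.sort_values("frequency_MHz")
        groups = part["group"].unique()
        tfs = part["tumour_fraction_percent"].unique()
        if len(groups) != 1 or len(tfs) != 1:
            raise ProfileFormatError(
                f"sample {sample_id!r}: inconsistent group/tumour-fraction metadata")
        sd = None
        if "R1_sd_per_s" in part.columns and part["R1_sd_per_s"].notna().all():
            sd = part["R1_sd_per_s"].to_numpy(dtype=float)
        reason = None
        if "excluded_reason" in part.columns:
            reason = part["excluded_reason"].fillna(REASON_NONE).to_numpy(dtype=object)
        profiles.append(NMRDProfile(
            sample_id=str(sample_id),
            group=str(groups[0]),
            tumour_fraction=float(tfs[0]),
            frequency_mhz=part["frequency_MHz"].to_numpy(dtype=float),
            r1=part["R1_per_s"].to_numpy(dtype=float),
            r1_sd=sd,
            exclusion_reason=reason,
        ))
    return profiles


def write_profiles(profiles: Sequence[NMRDProfile], sink,
                   include_mask: bool = False) -> None:
    """Write profiles as CSV; numeric values at 9 significant digits.

    include_mask adds the excluded_reason column (post-filter export).
    """
    rows = []
    any_sd = any(p.r1_sd is not None for p in profiles)
    for p in profiles:
        for i in range(p.n_points):
            row = {
                "sample_id": p.sample_id,
                "group": p.group,
                "tumour_fraction_percent": _fmt(p.tumour_fraction),
                "frequency_MHz": _fmt(p.frequency_mhz[i]),
                "R1_per_s": _fmt(p.r1[i]),
            }
            if any_sd:
                row["R1_sd_per_s"] = _fmt(p.r1_sd[i]) if p.r1_sd is not None else ""
            if include_mask:
                row["excluded_reason"] = p.exclusion_reason[i]
            rows.append(row)
    cols = list(REQUIRED_COLUMNS)
    if any_sd:
        cols.append("R1_sd_per_s")
    if include_mask:
        cols.append("excluded_reason")
    df = pd.DataFrame(rows, columns=cols)
    try:
        df.to_csv(sink, index=False)
    except OSError as exc:
        raise OSError(f"failed writing profiles to {sink!r}: {exc}") from exc


def _fmt(v: float) -> str:
    return f"{v:.9g}"
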