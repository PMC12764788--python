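"""Multi-start nonlinear least-squares fitting of the 3-Tau model.

The objective is the sum of squared *relative* residuals over unmasked
points,

    rss = sum_i [ (R1_model(f_i) - R1_i) / R1_i ]^2,

which balances low- and high-field data across the decade-wide dynamic
range of a dispersion profile.

Search strategy: a coarse scan over (tau_l, tau_d, tau_b) restricted to
16-per-decade grid nodes and a small x ladder, solving the two
near-linear amplitudes (N_l, N_sigma) per node in closed form under box
constraints; the best nodes seed bounded local refinements of all six
parameters (trust-region reflective, log scale for the time constants).

A single profile does not identify all six parameters with equal
strength: N_l enters chiefly through the product x*N_l and a modest
share of the bulk-shaped amplitude, and tau_l/tau_d trade off along a
ridge of near-equivalent surface line shapes.  The refinement therefore
supports a mild adaptive ridge tethering the weakly identified trio
(tau_l, tau_d on log scale, N_l) to the canonical healthy-tissue
operating point.  The ridge weight is proportional to the unpenalised
optimum's rss (a discrepancy-principle weighting): for noiseless data it
vanishes and the fit is exact; for noisy data it stops the flat-valley
directions - and with them x = (x*N_l)/N_l - from wandering.  Reported
rss is always the pure objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .constants import ELECTRON_PROTON_FREQ_RATIO, N_BULK, omega_rad_per_s
from .model import ThreeTauParams, intensity_constants, r1_total, component_shares
from .profiles import NMRDProfile
from .spectral import spectral_density, _surface_j, _powerlaw_j, _lorentzian_j
from . import reference

_R = ELECTRON_PROTON_FREQ_RATIO


def _fast_r1(omega: np.ndarray, params: ThreeTauParams, a_hh: float,
             a_hm: float, bulk_form: str) -> np.ndarray:
    """Fused R1 evaluation: identical to r1_total, one special-function
    call per correlation family over a stacked frequency vector."""
    nf = omega.size
    w4 = np.concatenate([omega, 2.0 * omega, (_R - 1.0) * omega,
                         (_R + 1.0) * omega])
    js = _surface_j(w4, params.tau_l, params.tau_d)
    if bulk_form == "lorentzian":
        jb = _lorentzian_j(w4, params.tau_b)
        tau_c = 1.0 / (1.0 / params.tau_l + 1.0 / params.tau_b)
        jc = _lorentzian_j(w4[: 2 * nf], 1.0 / (1.0 / tau_c + 1.0 / params.tau_d))
    else:
        jb = _powerlaw_j(w4, params.tau_b)
        tau_c = 1.0 / (1.0 / params.tau_l + 1.0 / params.tau_b)
        jc = _powerlaw_j(w4[: 2 * nf], tau_c, rate_cut=1.0 / params.tau_d)
    homo_s = js[:nf] + 4.0 * js[nf:2 * nf]
    het_s = js[2 * nf:3 * nf] + 3.0 * js[:nf] + 6.0 * js[3 * nf:]
    homo_b = jb[:nf] + 4.0 * jb[nf:2 * nf]
    het_b = jb[2 * nf:3 * nf] + 3.0 * jb[:nf] + 6.0 * jb[3 * nf:]
    homo_c = jc[:nf] + 4.0 * jc[nf:]
    x = params.x
    hh = a_hh * (x * params.N_l * homo_s + params.N_l * homo_c
                 + (1.0 - x) * N_BULK * homo_b)
    hm = a_hm * params.N_sigma * (x * het_s + (1.0 - x) * het_b)
    return hh + hm


class FitNonConvergenceError(RuntimeError):
    """Every local start failed to converge."""


@dataclass(frozen=True)
class FitConfig:
    """Bounds, start count and numerical policy of the profile fit.

    Bounds are in reporting units: tau_l, tau_d in us; tau_b in ps.
    """

    tau_l_bounds_us: Tuple[float, float] = (0.01, 10.0)
    tau_d_bounds_us: Tuple[float, float] = (0.01, 10.0)
    tau_b_bounds_ps: Tuple[float, float] = (1.0, 1000.0)
    x_bounds: Tuple[float, float] = (1e-4, 0.2)
    n_l_bounds: Tuple[float, float] = (5.0, 60.0)
    n_sigma_bounds: Tuple[float, float] = (0.0, 5.0)
    n_starts: int = 12
    seed: int = 0
    max_nfev: int = 500
    ftol: float = 1e-10
    ridge_kappa: float = 3.0        # adaptive ridge weight, x rss of pass 1
    ridge_scales: Tuple[float, float, float, float] = (0.5, 0.5, 10.0, 1.0)
    # ^ soft scales for (log10 tau_l, log10 tau_d, N_l, N_sigma) deviations
    coarse_tau_stride: int = 5      # stride over the 16-per-decade grid
    bulk_form: str = "translational"


def _ridge_center() -> np.ndarray:
    """Canonical healthy-tissue operating point for the tethered set."""
    ref = reference.healthy_reference()
    return np.array([np.log10(ref["tau_l_us"]), np.log10(ref["tau_d_us"]),
                     ref["N_l"], ref["N_sigma"]])


@dataclass
class FitResult:
    """Best-fit parameters and fit diagnostics for one profile."""

    params: ThreeTauParams
    rss: float
    rss_ml: float            # best unpenalised rss found (pass-1 optimum)
    per_point_residuals: np.ndarray
    r1_at_lowfield: float
    component_shares_lowfield: Dict[str, float]
    converged: bool
    n_starts: int
    seed: int
    hh_only: bool = False
    sample_id: Optional[str] = None


def objective(params: ThreeTauParams, profile: NMRDProfile,
              bulk_form: str = "translational") -> float:
    """Sum of squared relative residuals over the unmasked points."""
    sel = profile.unmasked
    f = profile.frequency_mhz[sel]
    y = profile.r1[sel]
    m = r1_total(f, params, bulk_form=bulk_form)
    return float(np.sum(((m - y) / y) ** 2))


# ---------------------------------------------------------------------------
# coarse scan


def _coarse_tau_nodes(lo: float, hi: float, stride: int = 5) -> np.ndarray:
    """Every stride-th node of the 16-per-decade grid spanning [lo, hi]."""
    n = int(round(np.log10(hi / lo) * 16))
    k = np.arange(0, n + 1, stride)
    if k[-1] != n:
        k = np.append(k, n)
    return lo * 10.0 ** (k / 16.0)


def _homo(j_of_w, omega):
    return j_of_w(omega) + 4.0 * j_of_w(2.0 * omega)


def _het(j_of_w, omega):
    r = ELECTRON_PROTON_FREQ_RATIO
    return (j_of_w((r - 1.0) * omega) + 3.0 * j_of_w(omega)
            + 6.0 * j_of_w((r + 1.0) * omega))


def _coarse_scan(f_mhz: np.ndarray, y: np.ndarray, config: FitConfig,
                 hh_only: bool) -> list:
    """Rank (tau_l, tau_d, tau_b, x, N_l, N_sigma) candidates by coarse rss."""
    omega = omega_rad_per_s(f_mhz)
    a_hh, a_hm = intensity_constants(config.bulk_form)
    bf = config.bulk_form

    stride = config.coarse_tau_stride
    tl = _coarse_tau_nodes(*(np.array(config.tau_l_bounds_us) * 1e-6), stride)
    td = _coarse_tau_nodes(*(np.array(config.tau_d_bounds_us) * 1e-6), stride)
    tb = _coarse_tau_nodes(*(np.array(config.tau_b_bounds_ps) * 1e-12), stride)
    xs = np.array([1e-4, 0.003, 0.008, 0.015, 0.03, 0.06, 0.12])
    xs = np.clip(xs, *config.x_bounds)

    nf = f_mhz.size
    # surface J sums on the (tau_l, tau_d) grid
    homo_s = np.empty((tl.size, td.size, nf))
    het_s = np.empty((tl.size, td.size, nf))
    for i, a in enumerate(tl):
        for j, b in enumerate(td):
            js = lambda w: spectral_density("surface", w, tau_l=a, tau_d=b)
            homo_s[i, j] = _homo(js, omega)
            het_s[i, j] = _het(js, omega)
    # bulk J sums on the tau_b grid
    homo_b = np.empty((tb.size, nf))
    het_b = np.empty((tb.size, nf))
    for k, c in enumerate(tb):
        jb = lambda w: spectral_density("bulk", w, tau_b=c, bulk_form=bf)
        homo_b[k] = _homo(jb, omega)
        het_b[k] = _het(jb, omega)
    # cross J sums on the full (tau_l, tau_d, tau_b) grid
    homo_c = np.empty((tl.size, td.size, tb.size, nf))
    for i, a in enumerate(tl):
        for j, b in enumerate(td):
            for k, c in enumerate(tb):
                jc = lambda w: spectral_density("cross", w, tau_l=a, tau_d=b,
                                                tau_b=c, bulk_form=bf)
                homo_c[i, j, k] = _homo(jc, omega)

    nl_lo, nl_hi = config.n_l_bounds
    ns_lo, ns_hi = config.n_sigma_bounds
    if hh_only:
        ns_lo = ns_hi = 0.0

    results = []
    w = 1.0 / y
    for x in xs:
        # basis vectors, shape (ntl, ntd, ntb, nf)
        v_l = a_hh * (x * homo_s[:, :, None, :] + homo_c)
        v_s = a_hm * (x * het_s[:, :, None, :]
                      + (1.0 - x) * het_b[None, None, :, :])
        base = a_hh * (1.0 - x) * N_BULK * homo_b[None, None, :, :]
        A1 = v_l * w
        A2 = v_s * w
        b = (y - base) * w

        s11 = np.sum(A1 * A1, axis=-1)
        s12 = np.sum(A1 * A2, axis=-1)
        s22 = np.sum(A2 * A2, axis=-1)
        t1 = np.sum(A1 * b, axis=-1)
        t2 = np.sum(A2 * b, axis=-1)
        bb = np.sum(b * b, axis=-1)

        def rss_of(nl, ns):
            return (s11 * nl ** 2 + 2.0 * s12 * nl * ns + s22 * ns ** 2
                    - 2.0 * t1 * nl - 2.0 * t2 * ns + bb)

        det = s11 * s22 - s12 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            nl_int = np.where(det > 0, (t1 * s22 - t2 * s12) / det, np.nan)
            ns_int = np.where(det > 0, (t2 * s11 - t1 * s12) / det, np.nan)
            nl_at = lambda ns: np.clip((t1 - s12 * ns) / s11, nl_lo, nl_hi)
            ns_at = lambda nl: np.clip((t2 - s12 * nl) / np.where(s22 > 0, s22, 1.0),
                                       ns_lo, ns_hi)
        candidates = []
        interior_ok = (np.isfinite(nl_int) & (nl_int >= nl_lo) & (nl_int <= nl_hi)
                       & (ns_int >= ns_lo) & (ns_int <= ns_hi))
        candidates.append((np.where(interior_ok, nl_int, nl_lo),
                           np.where(interior_ok, ns_int, ns_lo),
                           np.where(interior_ok, 0.0, np.inf)))
        for nl_edge in (nl_lo, nl_hi):
            ns_e = ns_at(np.full_like(s11, nl_edge))
            candidates.append((np.full_like(s11, nl_edge), ns_e, None))
        for ns_edge in (ns_lo, ns_hi):
            nl_e = nl_at(np.full_like(s11, ns_edge))
            candidates.append((nl_e, np.full_like(s11, ns_edge), None))

        best_rss = np.full(s11.shape, np.inf)
        best_nl = np.empty(s11.shape)
        best_ns = np.empty(s11.shape)
        for nl_c, ns_c, penalty in candidates:
            r = rss_of(nl_c, ns_c)
            if penalty is not None:
                r = r + penalty
            better = r < best_rss
            best_rss = np.where(better, r, best_rss)
            best_nl = np.where(better, nl_c, best_nl)
            best_ns = np.where(better, ns_c, best_ns)

        flat = np.argsort(best_rss, axis=None)[: config.n_starts]
        for idx in flat:
            i, j, k = np.unravel_index(idx, best_rss.shape)
            results.append((float(best_rss[i, j, k]),
                            (tl[i], td[j], tb[k], x,
                             float(best_nl[i, j, k]), float(best_ns[i, j, k]))))
    results.sort(key=lambda t: t[0])
    return results


# ---------------------------------------------------------------------------
# local refinement


def _theta_from_params(p: ThreeTauParams) -> np.ndarray:
    return np.array([np.log10(p.tau_l * 1e6), np.log10(p.tau_d * 1e6),
                     np.log10(p.tau_b * 1e12), p.x, p.N_l, p.N_sigma])


def _params_from_theta(theta: np.ndarray) -> ThreeTauParams:
    return ThreeTauParams.from_report_units(
        10.0 ** theta[0], 10.0 ** theta[1], 10.0 ** theta[2],
        theta[3], theta[4], theta[5])


def _bounds_theta(config: FitConfig, hh_only: bool):
    lo = np.array([np.log10(config.tau_l_bounds_us[0]),
                   np.log10(config.tau_d_bounds_us[0]),
                   np.log10(config.tau_b_bounds_ps[0]),
                   config.x_bounds[0], config.n_l_bounds[0],
                   config.n_sigma_bounds[0]])
    hi = np.array([np.log10(config.tau_l_bounds_us[1]),
                   np.log10(config.tau_d_bounds_us[1]),
                   np.log10(config.tau_b_bounds_ps[1]),
                   config.x_bounds[1], config.n_l_bounds[1],
                   config.n_sigma_bounds[1]])
    if hh_only:
        hi[5] = 0.0
        lo[5] = 0.0
    return lo, hi


def _refine(f, y, theta0, config: FitConfig, hh_only: bool, ridge: float):
    lo, hi = _bounds_theta(config, hh_only)
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12 * (hi > lo))
    if hh_only:
        theta0[5] = 0.0
    omega = omega_rad_per_s(f)
    a_hh, a_hm = intensity_constants(config.bulk_form)

    center = _ridge_center()
    scales = np.asarray(config.ridge_scales)

    def resid(theta):
        p = _params_from_theta(theta)
        m = _fast_r1(omega, p, a_hh, a_hm, config.bulk_form)
        r = (m - y) / y
        if ridge > 0.0:
            dev = (theta[[0, 1, 4, 5]] - center) / scales
            r = np.concatenate([r, np.sqrt(ridge) * dev])
        return r

    if hh_only:
        # freeze N_sigma by collapsing its bounds to a point
        free = np.arange(5)

        def resid5(t5):
            theta = np.append(t5, 0.0)
            return resid(theta)

        sol = least_squares(resid5, theta0[free], bounds=(lo[free], hi[free]),
                            method="trf", ftol=config.ftol, xtol=1e-12,
                            max_nfev=config.max_nfev)
        theta = np.append(sol.x, 0.0)
    else:
        sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                            ftol=config.ftol, xtol=1e-12,
                            max_nfev=config.max_nfev)
        theta = sol.x
    return theta, bool(sol.success)


def _fit(profile: NMRDProfile, config: FitConfig, hh_only: bool) -> FitResult:
    sel = profile.unmasked
    f = profile.frequency_mhz[sel]
    y = profile.r1[sel]
    if f.size < 6:
        raise ValueError("profile has fewer than 6 unmasked points; "
                         "apply_exclusions must succeed before fitting")

    candidates = _coarse_scan(f, y, config, hh_only)
    rng = np.random.default_rng(config.seed)
    starts = []
    for rss0, (a, b, c, x, nl, ns) in candidates[: config.n_starts]:
        jitter = 1.0 + 0.02 * rng.standard_normal(3)
        p0 = ThreeTauParams(tau_l=a * jitter[0], tau_d=b * jitter[1],
                            tau_b=c * jitter[2], x=x, N_l=nl, N_sigma=ns)
        starts.append(_theta_from_params(p0))

    # pass 1: unpenalised refinement from every start
    best = None
    any_ok = False
    for theta0 in starts:
        theta, ok = _refine(f, y, theta0, config, hh_only, ridge=0.0)
        any_ok = any_ok or ok
        p = _params_from_theta(theta)
        rss = objective(p, profile, config.bulk_form)
        if best is None or rss < best[0]:
            best = (rss, theta)
    if not any_ok:
        raise FitNonConvergenceError(
            f"no local start converged for sample {profile.sample_id!r}")

    rss1, theta1 = best
    # pass 2: adaptive ridge proportional to the unpenalised optimum rss
    if config.ridge_kappa > 0.0 and rss1 > 0.0:
        ridge = config.ridge_kappa * rss1
        theta2, _ = _refine(f, y, theta1, config, hh_only, ridge=ridge)
        theta_final = theta2
    else:
        theta_final = theta1

    params = _params_from_theta(theta_final)
    m = r1_total(f, params, bulk_form=config.bulk_form)
    residuals = (m - y) / y
    rss = float(np.sum(residuals ** 2))
    shares = component_shares(reference.LOWFIELD_MHZ, params,
                              bulk_form=config.bulk_form)
    return FitResult(
        params=params,
        rss=rss,
        rss_ml=min(rss1, rss),
        per_point_residuals=residuals,
        r1_at_lowfield=float(r1_total(reference.LOWFIELD_MHZ, params,
                                      bulk_form=config.bulk_form)),
        component_shares_lowfield=shares,
        converged=any_ok,
        n_starts=config.n_starts,
        seed=config.seed,
        hh_only=hh_only,
        sample_id=profile.sample_id,
    )


def fit_profile(profile: NMRDProfile, config: FitConfig = FitConfig()) -> FitResult:
    """Fit all six 3TM parameters to a filtered profile."""
    return _fit(profile, config, hh_only=False)


def fit_profile_hh_only(profile: NMRDProfile,
                        config: FitConfig = FitConfig()) -> FitResult:
    """Fit with the paramagnetic (HM) part removed: N_sigma pinned to zero."""
    return _fit(profile, config, hh_only=True)


def decompose_lowfield(params: ThreeTauParams, f_mhz: float = reference.LOWFIELD_MHZ,
                       bulk_form: str = "translational") -> Dict[str, float]:
    """x-weighted fractional component contributions at f (sum to 1)."""
    return component_shares(f_mhz, params, bulk_form=bulk_form)
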