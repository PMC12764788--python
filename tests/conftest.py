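"""Shared fixtures: reference parameter sets, synthetic profiles, and the
session-scoped default-cohort pipeline run used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

from threetau import reference
from threetau.cohort import CohortSpec, generate_cohort
from threetau.fitting import FitConfig, fit_profile
from threetau.model import ThreeTauParams, r1_total
from threetau.pipeline import fit_table_from_results, screen_fit_table
from threetau.profiles import NMRDProfile, apply_exclusions
from threetau.spectral import correlation_function


@pytest.fixture(scope="session")
def healthy_params() -> ThreeTauParams:
    ref = reference.healthy_reference()
    return ThreeTauParams.from_report_units(
        ref["tau_l_us"], ref["tau_d_us"], ref["tau_b_ps"],
        ref["x"], ref["N_l"], ref["N_sigma"])


@pytest.fixture()
def freq_grid() -> np.ndarray:
    return np.logspace(np.log10(0.01), np.log10(40.0), 28)


@pytest.fixture()
def noiseless_profile(healthy_params, freq_grid) -> NMRDProfile:
    r1 = r1_total(freq_grid, healthy_params)
    return apply_exclusions(NMRDProfile(
        sample_id="clean", group="4T1", tumour_fraction=0.0,
        frequency_mhz=freq_grid, r1=r1))


def quadrature_j(kind: str, omega: float, tau_l=None, tau_d=None,
                 tau_b=None) -> float:
    """Independent spectral-density oracle: piecewise oscillatory
    quadrature of the correlation function plus a two-term
    integration-by-parts tail correction."""

    def g(t):
        return correlation_function(kind, t, tau_l=tau_l, tau_d=tau_d,
                                    tau_b=tau_b)

    tau_char = tau_b if kind in ("bulk", "paramagnetic-bulk") else tau_d
    t_max = max(120.0 * tau_char, 40.0 / omega)
    edges = np.concatenate([[0.0], t_max * np.logspace(-12, 0, 41)])
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = quad(g, a, b, weight="cos", wvar=omega, limit=600)
        total += val
    eps = 1e-6 * t_max
    g_prime = (g(t_max + eps) - g(t_max - eps)) / (2.0 * eps)
    total += (-g(t_max) * np.sin(omega * t_max) / omega
              - g_prime * np.cos(omega * t_max) / omega ** 2)
    return 2.0 * total


@pytest.fixture(scope="session")
def default_study():
    """Full pipeline on the default seeded cohort: simulate, filter, fit
    all 32 profiles, screen the seven quantities.  Shared across the
    end-to-end tests because the fits dominate runtime."""
    spec = CohortSpec(seed=0)
    profiles, truth = generate_cohort(spec)
    filtered = [apply_exclusions(p) for p in profiles]
    config = FitConfig(seed=0)
    results = [fit_profile(p, config) for p in filtered]
    fits = fit_table_from_results(results, filtered)
    screens = screen_fit_table(fits)
    return {"spec": spec, "profiles": filtered, "truth": truth,
            "config": config, "results": results, "fits": fits,
            "screens": {s.quantity: s for s in screens}}
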