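"""Shared fixtures: formulations, illustrative PK sets, and an
independent numerical-ODE oracle for the closed-form PK solution."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from quinpk import (
    CHLOROQUINE_PHOSPHATE,
    DoseSchedule,
    PKParameters,
    build_treatment_schedule,
    make_fixture_pk_set,
)


@pytest.fixture
def cq():
    return CHLOROQUINE_PHOSPHATE


@pytest.fixture
def cq_params() -> PKParameters:
    return make_fixture_pk_set("chloroquine")


@pytest.fixture
def hcq_params() -> PKParameters:
    return make_fixture_pk_set("hydroxychloroquine")


@pytest.fixture
def fast_params() -> PKParameters:
    """A deliberately fast-equilibrating parameter set so short grids
    capture several half-lives (for AUC-to-infinity style checks)."""
    return PKParameters(
        cl_f=10.0, vc_f=50.0, q_f=5.0, vp_f=100.0, ka=1.0, tlag=0.0, mw_base=319.87
    )


@pytest.fixture
def treatment_7d(cq) -> DoseSchedule:
    return build_treatment_schedule("flat", 62.0, cq, days=7)


def ode_profile(
    params: PKParameters,
    schedule: DoseSchedule,
    time_grid: np.ndarray,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    track_elimination: bool = False,
):
    """Numerically integrate the absorption + disposition ODE system.

    Independent of the analytic path: builds the ODE right-hand side
    explicitly and integrates piecewise between dose events (depot
    boluses of F x dose at each event time + tlag), with an LSODA
    stiff-capable solver at tight tolerance.  Returns concentrations in
    uM; with ``track_elimination`` also returns the cumulative
    eliminated amount (mg) for mass-balance checks.
    """
    p = params
    k10, k12, k21 = p.cl_f / p.vc_f, p.q_f / p.vc_f, p.q_f / p.vp_f

    def rhs(_t, y):
        depot, central, peri, elim = y
        return [
            -p.ka * depot,
            p.ka * depot - (k10 + k12) * central + k21 * peri,
            k12 * central - k21 * peri,
            k10 * central,
        ]

    t_grid = np.asarray(time_grid, dtype=float)
    dose_times = np.array([e.time + p.tlag for e in schedule.events])
    dose_amounts = np.array([e.amount * p.f_rel for e in schedule.events])
    t0 = min(0.0, t_grid[0])
    breakpoints = np.unique(np.concatenate([[t0], dose_times, [t_grid[-1]]]))
    breakpoints = breakpoints[breakpoints <= t_grid[-1]]

    y = np.zeros(4)
    for dt, da in zip(dose_times, dose_amounts):
        if dt <= t0:
            y[0] += da
    out_t, out_y = [], []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        seg = t_grid[(t_grid >= a) & (t_grid <= b)]
        eval_pts = np.unique(np.concatenate([[a], seg, [b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=eval_pts, method="LSODA", rtol=rtol, atol=atol)
        for ti, yi in zip(sol.t, sol.y.T):
            out_t.append(ti)
            out_y.append(yi)
        y = sol.y[:, -1].copy()
        for dt, da in zip(dose_times, dose_amounts):
            if np.isclose(dt, b) and dt > t0:
                y[0] += da
    out_t = np.asarray(out_t)
    out_y = np.asarray(out_y)
    # keep the last state seen at each requested grid point (post-dose)
    conc = np.empty_like(t_grid)
    states = np.empty((t_grid.size, 4))
    for i, t in enumerate(t_grid):
        idx = np.where(np.isclose(out_t, t))[0][-1]
        states[i] = out_y[idx]
        conc[i] = out_y[idx, 1] / p.vc_f / p.mw_base * 1000.0
    if track_elimination:
        return conc, states
    return conc
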