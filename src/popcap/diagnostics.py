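"""Derived run diagnostics: steady-state detection, elasticity series,
endpoint error, projection-range check, and the plain-text/CSV report
bundle.

Everything here is a pure function of an already-simulated trajectory;
nothing re-runs the dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .benchmarks import P2012_REFERENCE, UN_2100_RANGE
from .dynamics import Trajectory

__all__ = [
    "EquilibriumSummary",
    "summarize_equilibrium",
    "elasticity_series",
    "pct_error_2012",
    "un_range_check",
    "write_report",
]

STEADY_STATE_THRESHOLD = 1e-4  # %/yr


@dataclass(frozen=True)
class EquilibriumSummary:
    reached: bool
    year_of_steady_state: Optional[int]
    P_infinity: Optional[float]
    K_infinity: Optional[float]
    peak_K: tuple[int, float]
    min_elasticity_after_peak: Optional[float]
    collapse_year: Optional[int] = None
    oscillating: bool = False


def summarize_equilibrium(
    traj: Trajectory,
    threshold: float = STEADY_STATE_THRESHOLD,
) -> EquilibriumSummary:
    """Detect a demographic steady state.

    The steady state is declared at the first year from which |pct_growth|
    stays below ``threshold`` (percent per year) through the end of the
    trajectory; P_infinity and K_infinity are then the end-of-run values.
    A collapsed trajectory reports its collapse year instead; a trajectory
    whose increments keep changing sign is flagged oscillating.
    """
    pct = traj.pct_growth
    peak_i = int(np.argmax(traj.K))
    peak = (int(traj.years[peak_i]), float(traj.K[peak_i]))

    c_after = traj.c_realized[peak_i:]
    c_after = c_after[np.isfinite(c_after)]
    min_c = float(c_after.min()) if len(c_after) else None

    signs = np.sign(traj.dP[np.abs(traj.dP) > 0])
    oscillating = int(np.sum(signs[1:] != signs[:-1])) >= 2

    if traj.collapsed:
        return EquilibriumSummary(
            reached=False,
            year_of_steady_state=None,
            P_infinity=None,
            K_infinity=None,
            peak_K=peak,
            min_elasticity_after_peak=min_c,
            collapse_year=traj.collapse_event[0],
            oscillating=oscillating,
        )

    quiet = np.abs(pct) < threshold
    # first index from which every later year is quiet
    idx = None
    run = len(quiet)
    for i in range(len(quiet) - 1, -1, -1):
        if quiet[i]:
            run = i
        else:
            break
    if run < len(quiet):
        idx = run
    if idx is None:
        return EquilibriumSummary(
            reached=False,
            year_of_steady_state=None,
            P_infinity=None,
            K_infinity=None,
            peak_K=peak,
            min_elasticity_after_peak=min_c,
            oscillating=oscillating,
        )
    return EquilibriumSummary(
        reached=True,
        year_of_steady_state=int(traj.years[idx]),
        P_infinity=float(traj.P[-1]),
        K_infinity=float(traj.K[-1]),
        peak_K=peak,
        min_elasticity_after_peak=min_c,
        oscillating=oscillating,
    )


def elasticity_series(traj: Trajectory) -> pd.DataFrame:
    """(year, c_realized, pct_growth) rows for the two-axis diagnostic plot.

    c_realized is missing (NaN) wherever dP = 0.
    """
    return pd.DataFrame(
        {
            "year": traj.years,
            "c_realized": traj.c_realized,
            "pct_growth": traj.pct_growth,
        }
    )


def pct_error_2012(traj: Trajectory) -> float:
    """Signed percent deviation of P(2012) from the observed 7.00e9."""
    p = traj.population_at(2012)
    return 100.0 * (p - P2012_REFERENCE) / P2012_REFERENCE


def un_range_check(traj: Trajectory) -> tuple[bool, float]:
    """Whether P(2100) falls inside the projection fan; margin to the
    nearest bound (non-negative inside, negative outside)."""
    p = traj.population_at(2100)
    lo, hi = UN_2100_RANGE
    if lo <= p <= hi:
        return True, float(min(p - lo, hi - p))
    return False, float(-(lo - p) if p < lo else -(p - hi))


def write_report(
    traj: Trajectory,
    out_dir,
    threshold: float = STEADY_STATE_THRESHOLD,
    overlay_csv=None,
    plots: bool = False,
) -> Path:
    """Write the per-run report bundle: trajectory CSV, summary key-values,
    elasticity series, and (optionally) plots.

    ``overlay_csv`` may point at an external (year, value) series to carry
    through for juxtaposition; it is copied into the bundle untouched.
    Returns the bundle directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.to_csv(out / "trajectory.csv")
    elasticity_series(traj).to_csv(out / "elasticity.csv", index=False)

    summary = summarize_equilibrium(traj, threshold)
    payload: dict = {"equilibrium": asdict(summary)}
    if traj.covers(2012):
        payload["pct_error_2012"] = pct_error_2012(traj)
    if traj.covers(2100):
        within, margin = un_range_check(traj)
        payload["P_2100_within_projection_range"] = within
        payload["P_2100_margin"] = margin
    spec = traj.spec
    payload["spec"] = {
        "law": spec.law,
        "r_soc": spec.rates.r_soc,
        "r_max": spec.rates.r_max,
        "L": spec.structure.L,
        "a": spec.structure.a,
        "b": spec.structure.b,
        "t0": spec.init.t0,
        "P0": spec.init.P0,
        "K0": spec.init.K0,
        "t_end": spec.t_end,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)

    if overlay_csv is not None:
        pd.read_csv(overlay_csv).to_csv(out / "overlay.csv", index=False)

    if plots:
        _write_plots(traj, out)
    return out


def _write_plots(traj: Trajectory, out: Path) -> None:
    # plotting is best-effort and never load-bearing
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.semilogy(traj.years, traj.P, label="P")
    ax.semilogy(traj.years, traj.K, label="K", linestyle="--")
    ax.set_xlabel("year CE")
    ax.set_ylabel("persons")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "population.png", dpi=120)
    plt.close(fig)

    fig, ax1 = plt.subplots(figsize=(7, 4.5))
    ax1.plot(traj.years, traj.c_realized, color="tab:blue")
    ax1.set_xlabel("year CE")
    ax1.set_ylabel("realized elasticity dK/dP", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(traj.years, traj.pct_growth, color="tab:red")
    ax2.set_ylabel("% annual population change", color="tab:red")
    fig.tight_layout()
    fig.savefig(out / "elasticity.png", dpi=120)
    plt.close(fig)
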