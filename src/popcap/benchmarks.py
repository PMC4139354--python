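"""Published sensitivity-analysis reference rows used as replication inputs.

These constants mirror the published per-case best-fit tables for the
gain-only ("oc") and consumption-cost ("cc") capacity laws: six cases
formed by crossing two initial populations with three social growth rates.
Populations are in persons, rates per person per year.

They are inputs to the replication protocol (anchor values for K0
calibration and targets for cost-law identification), not test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "OCBenchmarkRow",
    "CCBenchmarkRow",
    "OC_BENCHMARK_ROWS",
    "CC_BENCHMARK_ROWS",
    "P2012_REFERENCE",
    "UN_2100_RANGE",
    "FIG6_STEADY_STATE_P2500",
]

#: observed 2012 world population used for percent-error columns (persons)
P2012_REFERENCE = 7.00e9

#: span of the 2100 demographic-projection fan (persons): imminent decline
#: toward ~6-7 billion up to continued growth to ~17 billion
UN_2100_RANGE = (6.0e9, 17.0e9)

#: published steady-state population of the gain-only law for the
#: (P0=2.25e8, r=1.5e-13) case, reached by 2500 CE (persons)
FIG6_STEADY_STATE_P2500 = 286e9


@dataclass(frozen=True)
class OCBenchmarkRow:
    P0: float
    r_soc: float
    L: float
    d_avg: float
    P_1800: float
    P_2012: float
    P_2100: float


@dataclass(frozen=True)
class CCBenchmarkRow:
    P0: float
    r_soc: float
    a: float
    b: float
    d_avg: float
    P_1800: float
    P_2012: float
    P_2100: float
    pct_error_2012: float
    #: the matching gain-only row supplies L ("the OC trajectory that
    #: minimized d_avg for each case provided the value of L")
    L: float = 0.0


OC_BENCHMARK_ROWS: tuple[OCBenchmarkRow, ...] = (
    OCBenchmarkRow(2.25e8, 1.00e-13, 6.1677e10, 0.048, 6.1026e8, 8.1964e9, 7.8536e10),
    OCBenchmarkRow(2.25e8, 1.50e-13, 3.9684e10, 0.044, 6.3341e8, 7.7096e9, 5.8960e10),
    OCBenchmarkRow(2.25e8, 2.00e-13, 2.9045e10, 0.042, 6.5758e8, 7.6053e9, 4.9666e10),
    OCBenchmarkRow(3.75e8, 1.00e-13, 6.0711e10, 0.030, 8.6160e8, 6.9992e9, 4.4469e10),
    OCBenchmarkRow(3.75e8, 1.50e-13, 3.9112e10, 0.033, 8.9298e8, 6.7589e9, 3.6172e10),
    OCBenchmarkRow(3.75e8, 2.00e-13, 2.8640e10, 0.035, 9.1781e8, 6.5800e9, 3.0971e10),
)

CC_BENCHMARK_ROWS: tuple[CCBenchmarkRow, ...] = (
    CCBenchmarkRow(2.25e8, 1.00e-13, 5.0e-13, 1.92, 0.047, 6.0980e8, 7.5609e9, 1.4505e10, 8.01, 6.1677e10),
    CCBenchmarkRow(2.25e8, 1.50e-13, 5.0e-14, 2.10, 0.044, 6.3321e8, 7.3432e9, 1.5301e10, 4.90, 3.9684e10),
    CCBenchmarkRow(2.25e8, 2.00e-13, 5.0e-14, 2.04, 0.043, 6.5736e8, 7.3043e9, 1.6335e10, 4.35, 2.9045e10),
    CCBenchmarkRow(3.75e8, 1.00e-13, 2.0e-14, 2.20, 0.031, 8.6111e8, 6.7968e9, 1.6684e10, -2.90, 6.0711e10),
    CCBenchmarkRow(3.75e8, 1.50e-13, 8.0e-14, 2.00, 0.035, 8.9200e8, 6.5294e9, 1.6364e10, -6.72, 3.9112e10),
    CCBenchmarkRow(3.75e8, 2.00e-13, 2.0e-14, 2.10, 0.037, 9.1717e8, 6.4193e9, 1.6579e10, -8.30, 2.8640e10),
)
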