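"""Centralised unit conversions.

Every conversion used in quantification lives here so that the dimensional
chain is tested in one place.  Conventions: flows are entered in mL/min
(instrument convention) and used internally in L/s; masses are computed in
ng and reported in fg (1 ng = 10⁶ fg).
"""

from __future__ import annotations

FG_PER_NG = 1.0e6
S_PER_MIN = 60.0
L_PER_ML = 1.0e-3


def flow_L_per_s(flow_mL_min: float) -> float:
    """Convert a sample flow rate from mL/min to L/s."""
    return flow_mL_min * L_PER_ML / S_PER_MIN


def ng_to_fg(mass_ng: float) -> float:
    return mass_ng * FG_PER_NG
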