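"""Lipid utilities."""
from __future__ import annotations

from typing import NamedTuple

# Friedewald estimation is unreliable at high triglycerides; the standard
# clinical validity bound is 400 mg/dL.
FRIEDEWALD_TG_LIMIT = 400.0


class FriedewaldResult(NamedTuple):
    ldl: float
    valid: bool


def friedewald_ldl(tc: float, hdl: float, tg: float) -> FriedewaldResult:
    """Estimate LDL cholesterol (mg/dL) as TC - HDL - TG/5.

    Returns the estimate flagged invalid when triglycerides exceed
    400 mg/dL, where the TG/5 VLDL approximation breaks down.
    """
    if min(tc, hdl, tg) < 0:
        raise ValueError("lipid inputs must be non-negative")
    return FriedewaldResult(ldl=tc - hdl - tg / 5.0, valid=tg <= FRIEDEWALD_TG_LIMIT)
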