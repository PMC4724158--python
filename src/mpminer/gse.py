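"""General solubility equation (GSE).

The GSE links intrinsic aqueous solubility to melting point and
lipophilicity::

    log S = 0.5 - 0.01 (MP - 25) - log P

with MP in °C and logS in log molar units.  Its MP coefficient of
-0.01 log units per °C means a melting-point prediction error of σ °C
propagates to 0.01·σ log units of solubility error.  logP is an input
(measured or externally predicted); no logP model is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GSEInput", "gse_logs", "gse_error_contribution"]

_ABS_ZERO_C = -273.15


@dataclass(frozen=True)
class GSEInput:
    mp_c: float  # melting point, °C
    logp: float  # octanol/water partition coefficient

    def __post_init__(self):
        if self.mp_c <= _ABS_ZERO_C:
            raise ValueError("melting point below absolute zero")


def gse_logs(inp: GSEInput) -> float:
    """Intrinsic log molar solubility from melting point and logP."""
    return 0.5 - 0.01 * (inp.mp_c - 25.0) - inp.logp


def gse_error_contribution(mp_rmse: float) -> float:
    """Solubility error (log units) contributed by an MP error of ``mp_rmse`` °C."""
    if mp_rmse < 0:
        raise ValueError("RMSE cannot be negative")
    return 0.01 * mp_rmse
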