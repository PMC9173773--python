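"""Binding-readout arithmetic: FRET transfer efficiency and size scaling.

Small, exact computations: donor-quenching transfer efficiency
E = (I0 - I) / I0, and the cubic hydrodynamic-radius to molecular-weight
scaling for globular species (MW proportional to R_h^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "EmissionMeasurement",
    "fret_efficiency",
    "mw_ratio_from_rh",
    "max_monomers_per_complex",
]


@dataclass(frozen=True)
class EmissionMeasurement:
    """Background-subtracted donor emission with and without transfer."""

    I: float
    I0: float
    sample_id: str = ""
    time_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if self.I < 0:
            raise ValueError("I must be >= 0")


def fret_efficiency(I: float, I0: float) -> float:
    """Transfer efficiency E = (I0 - I) / I0.

    Negative values (donor enhancement artifacts) are passed through with a
    warning rather than rejected.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    E = (I0 - I) / I0
    if E < 0:
        warnings.warn(
            f"negative transfer efficiency {E:.3g}: donor enhancement artifact",
            stacklevel=2,
        )
    return E


def mw_ratio_from_rh(rh_ratio: float) -> float:
    """Apparent molecular-weight ratio under globular scaling: rh_ratio**3."""
    if rh_ratio <= 0:
        raise ValueError("hydrodynamic radius ratio must be positive")
    return rh_ratio**3


def max_monomers_per_complex(
    rh_ratio: float,
    reference_mw: float,
    monomer_mw: float,
    binders_per_complex: int = 1,
    binder_mw: Optional[float] = None,
) -> float:
    """Upper bound on monomers per diffusing complex from a radius ratio.

    The apparent complex mass is ``reference_mw * rh_ratio**3`` (globular
    assumption); subtracting the bound binder mass and dividing by the
    monomer mass bounds the monomer count.
    """
    if reference_mw <= 0 or monomer_mw <= 0:
        raise ValueError("masses must be positive")
    if binders_per_complex < 0:
        raise ValueError("binders_per_complex must be >= 0")
    binder_mw = reference_mw if binder_mw is None else binder_mw
    complex_mw = reference_mw * mw_ratio_from_rh(rh_ratio)
    return (complex_mw - binders_per_complex * binder_mw) / monomer_mw
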