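"""Field-dependent tissue conductivity.

Electroporation raises cell-membrane permeability and with it the bulk
electrical conductivity of tissue.  This is modelled per tissue as a smoothed
step in the local field magnitude E (V/cm):

    sigma(E) = sigma0 * (1 + (f - 1) * S(t)),
    t = clamp((E - c + w/2) / w, 0, 1),
    S(t) = 6 t^5 - 15 t^4 + 10 t^3,

where ``sigma0`` is the baseline conductivity (S/m), ``f`` the saturation
multiplier, ``c`` the center of the transition zone (V/cm) and ``w`` its
width (V/cm).  The quintic smoothstep S has continuous second derivative, so
sigma(E) is C^2 — the smoothness class required for stable fixed-point
(Picard) iteration of the nonlinear Laplace problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BONE, SURROUNDING, TUMOR


@dataclass(frozen=True)
class ConductivityLaw:
    """Smoothed-step conductivity increase for one tissue."""

    sigma0: float  # baseline conductivity, S/m
    factor: float  # saturation multiplier (>= 1)
    center: float  # transition-zone center, V/cm
    width: float  # transition-zone width, V/cm

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def sigma_max(self) -> float:
        return self.sigma0 * self.factor


#: default electrical parameters per tissue label; the surrounding soft
#: tissue carries adipose-tissue properties
TISSUE_LAWS: dict[int, ConductivityLaw] = {
    BONE: ConductivityLaw(sigma0=0.07, factor=2.9, center=600.0, width=400.0),
    TUMOR: ConductivityLaw(sigma0=0.30, factor=2.8, center=600.0, width=400.0),
    SURROUNDING: ConductivityLaw(sigma0=0.02, factor=3.0, center=300.0, width=400.0),
}


def smoothstep(t):
    """Quintic smoothstep 6t^5 - 15t^4 + 10t^3 on clamped t."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def sigma_of_E(E, law: ConductivityLaw):
    """Conductivity (S/m) at field magnitude ``E`` (V/cm); vectorized.

    Raises
    ------
    ValueError
        If any field magnitude is negative.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("field magnitude must be non-negative")
    t = (E - law.center + law.width / 2.0) / law.width
    out = law.sigma0 * (1.0 + (law.factor - 1.0) * smoothstep(t))
    return out if out.ndim else float(out)
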