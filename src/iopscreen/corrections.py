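"""Analytic tonometry correction formulas.

Goldmann applanation tonometry (GAT) assumes a 520 um cornea of fixed
curvature; real corneas deviate, biasing the reading IOPG. The classical
literature offers closed-form corrections in terms of central corneal
thickness (CCT), curvature radius and age. These are exact, side-effect-free
formula evaluations kept as reference comparators for the learned pipeline.

All interfaces take CCT in micrometres (the clinical convention) and convert
to millimetres internally where a formula is written in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CorrectionInput",
    "ehlers_correct",
    "shell_correct",
    "linear_correct",
    "elsheikh_factor",
    "elsheikh_correct",
]

#: GAT reference geometry: corneal thickness (mm) and curvature radius (mm).
REFERENCE_CCT_MM = 0.520
REFERENCE_RADIUS_MM = 7.8


@dataclass(frozen=True)
class CorrectionInput:
    """Inputs for the multiparameter (Elsheikh-style) correction factor.

    Coefficients are deliberately caller-supplied: published values live in
    the source literature and depend on the fitted population.
    """

    iopg: float  # tonometer reading, mmHg
    cct: float  # central corneal thickness, micrometres
    radius: float  # central anterior curvature radius, mm
    age: float  # years
    a_cct: float = 0.0
    a_r: float = 0.0
    a_age: float = 0.0
    a_iopg: float = 0.0

    def __post_init__(self) -> None:
        if self.iopg <= 0:
            raise ValueError(f"iopg must be positive, got {self.iopg}")
        if self.cct <= 0:
            raise ValueError(f"cct must be positive, got {self.cct}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


def ehlers_correct(iopg: float, cct: float) -> float:
    """Ehlers CCT correction: subtract 5 mmHg per 70 um of excess thickness.

    ``IOP = IOPG - 5.0 * ((CCT_mm - 0.520) / 0.070)`` with CCT given in um.
    Zero correction at the 520 um reference thickness.
    """
    if cct <= 0:
        raise ValueError(f"cct must be positive micrometres, got {cct}")
    cct_mm = cct / 1000.0
    return iopg - 5.0 * ((cct_mm - REFERENCE_CCT_MM) / 0.070)


def shell_correct(iopg: float, k: float) -> float:
    """Thin-shell correction ``IOP = IOPG / K``.

    K aggregates corneal dimensions, radius and thickness into a single
    multiplicative factor; K = 1 recovers the raw reading.
    """
    if k <= 0:
        raise ValueError(f"correction factor K must be positive, got {k}")
    return iopg / k


def linear_correct(iopg: float, cct: float) -> float:
    """Linear pachymetry correction ``IOP = IOPG + (23.28 - 0.0423 * CCT)``.

    CCT in micrometres. The additive term vanishes at CCT = 23.28/0.0423
    (about 550 um) and is strictly decreasing in thickness.
    """
    return iopg + (23.28 - 0.0423 * cct)


def elsheikh_factor(inp: CorrectionInput) -> float:
    """Multiparameter correction factor C = IOPG / IOP.

    ``C = A_CCT*(CCT_mm - 0.520)^2 + A_R*(R - 7.8) + A_Age*Age + A_IOPG``
    with CCT converted from um to mm. At the reference geometry
    (CCT = 520 um, R = 7.8 mm, age 0) every deviation term vanishes and
    C reduces to A_IOPG.

    Raises
    ------
    ValueError
        If the evaluated factor is non-positive (unphysical).
    """
    cct_mm = inp.cct / 1000.0
    c = (
        inp.a_cct * (cct_mm - REFERENCE_CCT_MM) ** 2
        + inp.a_r * (inp.radius - REFERENCE_RADIUS_MM)
        + inp.a_age * inp.age
        + inp.a_iopg
    )
    if c <= 0:
        raise ValueError(f"correction factor must be positive, got {c}")
    return c


def elsheikh_correct(inp: CorrectionInput) -> float:
    """Corrected pressure ``IOP = IOPG / C`` using :func:`elsheikh_factor`."""
    return inp.iopg / elsheikh_factor(inp)
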