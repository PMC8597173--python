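"""The five visual-acuity health states of the disease model.

Diabetic macular oedema (DMO) is tracked on the visual acuity of the
better-seeing eye (Snellen decimal).  A patient enters the model with one
affected eye and good acuity (state 1); once both eyes are affected the
patient moves through progressively worse acuity bands down to bilateral
blindness (state 5), which is absorbing.  There is no cured state and no
return to state 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

N_STATES = 5

#: states whose occupants accrue rehabilitation costs (visual impairment)
REHAB_STATES = frozenset({4, 5})


@dataclass(frozen=True)
class HealthState:
    """One disease state, with the flags the cost rules key on.

    ``va_band`` is the half-open acuity interval ``[lo, hi)`` of the
    better-seeing eye in Snellen decimal units (``hi`` may be ``inf``).
    ``treated_eyes`` is the number of eyes receiving drug each cycle:
    one in state 1 (only one eye has DMO), two in states 2-4 (bilateral
    disease, both eyes treated), zero in state 5 (blindness is the model
    endpoint; see :func:`treated_eyes_vector` for the optional override).
    """

    index: int
    label: str
    va_band: tuple[float, float]
    bilateral_dmo: bool
    treated_eyes: int
    rehab_eligible: bool


HEALTH_STATES: tuple[HealthState, ...] = (
    HealthState(1, "One eye healthy, one eye DMO; good acuity",
                (0.5, math.inf), False, 1, False),
    HealthState(2, "Bilateral DMO; good acuity",
                (0.5, math.inf), True, 2, False),
    HealthState(3, "Bilateral DMO; mild visual impairment",
                (0.3, 0.5), True, 2, False),
    HealthState(4, "Bilateral DMO; moderate to severe visual impairment",
                (0.05, 0.3), True, 2, True),
    HealthState(5, "Bilateral DMO; blindness",
                (0.0, 0.05), True, 0, True),
)


def treated_eyes_vector(treat_in_state5: bool = False) -> np.ndarray:
    """Eyes receiving drug per state, as a length-5 integer vector.

    By default state 5 receives no treatment (blindness is the model
    endpoint).  With ``treat_in_state5=True`` both eyes of blind patients
    keep receiving injections/implants, the alternative reading of
    treatment being "continued during the whole follow-up".
    """
    eyes = np.array([s.treated_eyes for s in HEALTH_STATES], dtype=float)
    if treat_in_state5:
        eyes[4] = 2.0
    return eyes


def rehab_mask() -> np.ndarray:
    """Boolean mask of states that accrue rehabilitation costs."""
    return np.array([s.rehab_eligible for s in HEALTH_STATES])
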