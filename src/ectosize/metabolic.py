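"""Q10 temperature- and mass-scaling of ectotherm standard metabolic rate.

The model combines an allometric mass term with a Q10 temperature term:

    rate(mass, T) = MR20 * mass**b * Q10**((T - 20)/10)   [mL O2 / h]

where MR20 is the standard metabolic rate of a 1 g animal at the 20 degC
reference temperature, b is the (hypoallometric, b < 1) mass exponent, and
Q10 is the factor by which the rate changes per 10 degC.  Defaults are the
amphibian literature values Q10 = 2.21, MR20 = 0.081 mL O2/h, b = 0.884.
Temperature ratios at equal mass reduce to Q10**((Ta - Tb)/10), independent
of both mass and MR20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetabolicParams:
    q10: float = 2.21
    mr20: float = 0.081  # mL O2/h for a 1 g animal at 20 degC
    b: float = 0.884     # allometric mass exponent
    reference_temp: float = 20.0  # degC

    def __post_init__(self):
        if self.q10 <= 1:
            raise ValueError("q10 must exceed 1")
        if self.mr20 <= 0:
            raise ValueError("mr20 must be positive")
        if not 0 < self.b <= 1.5:
            raise ValueError("allometric exponent b must lie in (0, 1.5]")


DEFAULT_PARAMS = MetabolicParams()


def metabolic_rate(mass_g, temp_c, params: MetabolicParams = DEFAULT_PARAMS):
    """Standard metabolic rate (mL O2/h) at the given mass (g) and temperature (degC)."""
    mass = np.asarray(mass_g, float)
    if np.any(mass <= 0):
        raise ValueError("mass must be strictly positive")
    temp = np.asarray(temp_c, float)
    out = params.mr20 * mass**params.b * params.q10 ** ((temp - params.reference_temp) / 10.0)
    if np.isscalar(mass_g) and np.isscalar(temp_c):
        return float(out)
    return out


def rate_ratio(temp_a_c, temp_b_c, params: MetabolicParams = DEFAULT_PARAMS) -> float:
    """Metabolic-rate ratio of equal-mass animals at two temperatures (degC)."""
    return float(params.q10 ** ((temp_a_c - temp_b_c) / 10.0))
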