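"""Published posterior-mean covariance matrices for beef-cattle growth traits.

These are the posterior means of the additive genetic (G) and residual (R)
covariance matrices from a published Bayesian multiple-trait analysis of the
Pirenaica beef cattle breed, for five traits: birth weight (BW), weight at 90
days (W90), weight at 210 days (W210), cold carcass weight (CCW) and carcass
conformation score (CONF). Weights are in kg, conformation on an 18-point
numeric scale, so variances are kg² or score².

They serve as realistic default parameters for the synthetic-data generator
and as worked-example inputs for the recursive-model transformations: the
three causal scenarios returned by :func:`scenario_structures` are the
orderings a breeder would consider given when each trait is recorded (on farm
at birth / 90 d / 210 d, then at the slaughterhouse).
"""

from __future__ import annotations

import numpy as np

from .transforms import CausalStructure

__all__ = [
    "TRAITS",
    "cattle_G",
    "cattle_R",
    "cattle_trait_means",
    "scenario_structures",
]

#: trait recording order: farm (birth, 90 d, 210 d) then slaughterhouse
TRAITS = ("BW", "W90", "W210", "CCW", "CONF")


def _sym(diag, upper) -> np.ndarray:
    m = len(diag)
    M = np.zeros((m, m))
    M[np.diag_indices(m)] = diag
    iu = np.triu_indices(m, 1)
    M[iu] = upper
    M[(iu[1], iu[0])] = upper
    return M


def cattle_G() -> np.ndarray:
    """Additive genetic covariance matrix (posterior mean), 5x5."""
    return _sym(
        [4.85, 297.46, 629.70, 540.36, 0.86],
        [9.85, 16.50, 20.70, -0.01,
         288.29, 171.06, 1.69,
         347.78, -0.76,
         6.10],
    )


def cattle_R() -> np.ndarray:
    """Residual covariance matrix (posterior mean), 5x5."""
    return _sym(
        [8.93, 452.24, 1268.18, 791.88, 0.65],
        [11.85, 14.91, 13.64, 0.37,
         452.16, 228.91, 1.16,
         482.62, 5.06,
         10.33],
    )


def cattle_trait_means() -> np.ndarray:
    """Reported phenotypic means for the five traits (kg / kg / kg / kg / score)."""
    return np.array([41.12, 134.46, 250.71, 300.29, 11.86])


def scenario_structures() -> dict[str, CausalStructure]:
    """The three causal orderings by recording time.

    scenario1
        fully recursive chain BW -> W90 -> W210 -> CCW -> CONF
        (five singleton blocks; scalar LDL' of R).
    scenario2
        farm traits {BW, W90, W210} -> slaughterhouse traits {CCW, CONF}
        (two blocks; block LDL').
    scenario3
        {BW} -> {W90, W210} -> {CCW, CONF} (three blocks).
    """
    return {
        "scenario1": CausalStructure([[t] for t in TRAITS], traits=TRAITS),
        "scenario2": CausalStructure(
            [["BW", "W90", "W210"], ["CCW", "CONF"]], traits=TRAITS
        ),
        "scenario3": CausalStructure(
            [["BW"], ["W90", "W210"], ["CCW", "CONF"]], traits=TRAITS
        ),
    }
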