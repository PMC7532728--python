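"""Reference parameter estimates for the worked example species pair.

The package's worked example is the pair of annual forbs *Plectritis
congesta* (native to Pacific-Northwest oak savanna; species *i*, "P") and
*Valerianella locusta* (introduced from Eurasia; species *j*, "V"), grown in
a density-gradient pot experiment under two watering treatments.  The point
estimates and standard errors below are the published bootstrap means (and
bootstrap SDs) of the Beverton--Holt parameters from that experiment.  They
serve as inputs for the ``table1-check`` pipeline mode, for the synthetic
generator defaults, and for closed-form checks of the coexistence algebra.

Index convention used throughout the package: ``alpha_xy`` is the effect
*on* species *x* of one individual of species *y*; ``lambda_x`` is the
per-germinant fecundity of *x* with no neighbours.
"""

from __future__ import annotations

# Point estimates per watering treatment.  Keys follow the i/j convention
# above with i = P. congesta (native), j = V. locusta (introduced).
REFERENCE_ESTIMATES: dict[str, dict[str, float]] = {
    "dry": {
        "lambda_i": 365.9,
        "lambda_j": 650.0,
        "alpha_ii": 0.25,
        "alpha_ij": 0.29,
        "alpha_jj": 0.73,
        "alpha_ji": 0.45,
    },
    "wet": {
        "lambda_i": 391.23,
        "lambda_j": 327.4,
        "alpha_ii": 0.37,
        "alpha_ij": 0.27,
        "alpha_jj": 0.47,
        "alpha_ji": 0.42,
    },
}

# Bootstrap standard errors accompanying the point estimates.
REFERENCE_SE: dict[str, dict[str, float]] = {
    "dry": {
        "lambda_i": 17.7,
        "lambda_j": 57.4,
        "alpha_ii": 0.02,
        "alpha_ij": 0.03,
        "alpha_jj": 0.11,
        "alpha_ji": 0.05,
    },
    "wet": {
        "lambda_i": 27.8,
        "lambda_j": 24.8,
        "alpha_ii": 0.04,
        "alpha_ij": 0.07,
        "alpha_jj": 0.06,
        "alpha_ji": 0.04,
    },
}

# Pooled germination fractions from the 72-pot x 3-seed germination trials.
REFERENCE_GERMINATION: dict[str, float] = {"i": 0.670, "j": 0.891}

#: Human-readable species names for report output.
SPECIES_NAMES: dict[str, str] = {"i": "P. congesta", "j": "V. locusta"}

TREATMENTS = ("dry", "wet")
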