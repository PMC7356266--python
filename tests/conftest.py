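"""Shared reference data: published measurements for a micronised / spray-dried
drug blended on a coarse lactose carrier, with and without a magnesium
stearate surface coat.  Used as ground truth across the test modules."""

import pytest

# material -> (theta_water_deg, theta_diiodomethane_deg,
#              gamma_sd, gamma_sp, gamma_s, polarity_pct, cohesion_work)
REFERENCE_MATERIALS = {
    "drug_micronised": (25.13, 23.53, 42.07, 33.18, 75.25, 44.09, 150.50),
    "drug_spray_dried": (26.40, 29.90, 39.93, 33.44, 73.37, 45.58, 146.74),
    "carrier": (3.30, 6.00, 45.58, 36.88, 82.46, 44.72, 164.92),
    "carrier_coated": (64.60, 62.00, 26.07, 19.22, 45.29, 42.44, None),
    "coating_agent": (102.63, 68.64, 24.33, 2.64, 26.96, 9.79, 53.92),
}

#: median particle diameters, um
REFERENCE_D50 = {
    "drug_micronised": 3.602,
    "drug_spray_dried": 2.109,
    "carrier": 215.00,
    "carrier_coated": 215.00,
    "coating_agent": 6.92,
}

# (drug, substrate) -> (published w_adh mN/m, published f_adh mN, published s21)
REFERENCE_PAIRS = {
    ("drug_micronised", "carrier"): (104.98, 1.168e-3, 6.87),
    ("drug_micronised", "carrier_coated"): (76.55, 0.849e-3, -37.44),
    ("drug_spray_dried", "carrier"): (102.67, 0.674e-3, 8.55),
    ("drug_spray_dried", "carrier_coated"): (76.80, 0.493e-3, -34.83),
}


@pytest.fixture(scope="session")
def solved_energies():
    from dpikit.energetics import ContactAngleSet, solve_wu

    return {
        name: solve_wu(
            ContactAngleSet(name, {"water": tw, "diiodomethane": td})
        )
        for name, (tw, td, *_rest) in REFERENCE_MATERIALS.items()
    }
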