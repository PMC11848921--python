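"""Pinned atomic masses and isotopic abundances.

Values are the IUPAC/CODATA monoisotopic masses and representative isotopic
abundances, frozen here so that every mass printed by this package is
reproducible independent of any external library version.

TABLE_VERSION identifies the constants; bump it if any number changes.
"""

from __future__ import annotations

TABLE_VERSION = "2021-iupac-1"

#: Mass of a proton (Da); used for [M+H]+ m/z arithmetic.
PROTON_MASS = 1.007276466

#: element -> list of (isotope mass in Da, relative abundance), most abundant
#: (lightest-first where that is also the most abundant) isotope first.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483780, 0.0107)],
    "N": [(14.00307400480, 0.99636), (15.00010889820, 0.00364)],
    "O": [
        (15.99491461960, 0.99757),
        (16.99913170, 0.00038),
        (17.99916040, 0.00205),
    ],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "Na": [(22.98976928, 1.0)],
    "K": [
        (38.96370668, 0.932581),
        (39.96399848, 0.000117),
        (40.96182576, 0.067302),
    ],
}

#: element -> monoisotopic (most abundant isotope) mass in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    el: isos[0][0] for el, isos in ISOTOPES.items()
}
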