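"""Independently tabulated reference values for the packaged 26-fiber
database, used as frozen regression targets by the test suite.

``CW_FRACTIONS_AVG``: representative-average cell-wall volume fractions in
integer percent, order (NF, amcel, hemcel, lig, pec, ash, npor).
``RHO_CW``: average cell-wall densities [g/cm^3].
``LUMEN_AVG``: average lumen porosities in integer percent.
"""

CW_FRACTIONS_AVG = {
    "Banana": (31, 38, 10, 10, 4, 3, 3),
    "Flax": (54, 15, 18, 4, 1, 0, 8),
    "Hemp": (50, 17, 20, 6, 1, 0, 7),
    "Isora": (46, 19, 3, 24, 0, 0, 8),
    "Jute": (37, 16, 18, 20, 0, 0, 9),
    "Kenaf": (34, 18, 22, 19, 2, 0, 5),
    "Ramie": (49, 28, 14, 1, 2, 0, 5),
    "Sorghum": (27, 36, 20, 12, 0, 3, 2),
    "Alfa": (21, 12, 30, 35, 0, 0, 3),
    "Bagasse": (15, 17, 21, 7, 9, 2, 28),
    "Bamboo": (16, 13, 19, 26, 0, 0, 26),
    "Abaca": (30, 28, 20, 10, 1, 1, 10),
    "Curaua": (45, 23, 10, 9, 0, 0, 13),
    "Henequen": (28, 32, 23, 9, 0, 1, 8),
    "Phormium": (41, 19, 29, 12, 0, 0, 0),
    "Pineapple": (36, 33, 18, 9, 4, 1, 0),
    "Sisal": (42, 16, 14, 14, 9, 0, 5),
    "Coir": (11, 25, 18, 37, 3, 6, 0),
    "Kapok": (23, 27, 27, 17, 0, 1, 6),
    "Oil Palm": (11, 34, 22, 19, 0, 2, 10),
    "Barley": (17, 17, 31, 18, 0, 0, 18),
    "Cornhusk": (39, 14, 33, 4, 0, 6, 5),
    "Cornstalk": (25, 8, 25, 15, 0, 0, 28),
    "Rice": (18, 12, 26, 15, 0, 11, 19),
    "Soybean": (38, 43, 5, 13, 0, 1, 0),
    "Wheat": (16, 15, 26, 19, 0, 0, 25),
}

RHO_CW = {
    "Banana": 1.51, "Flax": 1.48, "Hemp": 1.48, "Isora": 1.44, "Jute": 1.42,
    "Kenaf": 1.45, "Ramie": 1.51, "Sorghum": 1.5, "Alfa": 1.41,
    "Bagasse": 1.34, "Bamboo": 1.29, "Abaca": 1.45, "Curaua": 1.44,
    "Henequen": 1.45, "Phormium": 1.5, "Pineapple": 1.51, "Sisal": 1.47,
    "Coir": 1.46, "Kapok": 1.44, "Oil Palm": 1.41, "Barley": 1.35,
    "Cornhusk": 1.52, "Cornstalk": 1.31, "Rice": 1.43, "Soybean": 1.51,
    "Wheat": 1.31,
}

LUMEN_AVG = {
    "Banana": 7, "Flax": 7, "Hemp": 6, "Isora": 9, "Jute": 5, "Kenaf": 16,
    "Ramie": 4, "Sorghum": 41, "Alfa": 37, "Bagasse": 10, "Bamboo": 0,
    "Abaca": 0, "Curaua": 3, "Henequen": 3, "Phormium": 15, "Pineapple": 1,
    "Sisal": 8, "Coir": 18, "Kapok": 73, "Oil Palm": 4, "Barley": 61,
    "Cornhusk": 66, "Cornstalk": 60, "Rice": 0, "Soybean": 66, "Wheat": 0,
}
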