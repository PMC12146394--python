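"""Published summary tables from the field campaigns behind the packaged
parameter sets: the two-year greenhouse heat-stress trial (per-plant masses,
morphology, dispersion), the multi-site open-field yield survey used for
heat-unit calibration, and the multi-site warming-scenario yield table.

These printed summaries are inputs: the reporting arithmetic in
:mod:`peppersim.metrics` and :mod:`peppersim.calibration` recomputes every
derived cell (harvest indices, percent differences, measured/simulated
ratios, fit statistics) from them.

One scenario-table cell (PHR23, Hamyang, +5 C) prints a percent loss of
-48 although its two printed yields give -47.47, which rounds to -47 under
any convention; the percent was evidently computed from unrounded yields.
That cell is flagged ``pct_inconsistent`` so consistency checks can treat
it separately instead of silently passing or failing.
"""

from __future__ import annotations

__all__ = [
    "GREENHOUSE_MASS_TABLE",
    "TRIAL_DISPERSION",
    "SITE_YIELD_TABLE",
    "PHU_TEST_SITE_ROWS",
    "SCENARIO_YIELD_TABLE",
]

# Greenhouse trial, per-plant fresh masses (g) averaged over 2022-2023:
# (days, accession) -> condition -> (total, fruit, printed harvest index),
# plus the printed integer percent differences (total, fruit) heat vs control.
GREENHOUSE_MASS_TABLE = {
    (35, "PHR18"): {
        "control": (326.0, 91.0, 0.28),
        "heat": (178.0, 60.0, 0.34),
        "printed_pct": (-45, -34),
    },
    (35, "PHR23"): {
        "control": (803.0, 312.0, 0.39),
        "heat": (950.0, 513.0, 0.54),
        "printed_pct": (18, 64),
    },
    (75, "PHR18"): {
        "control": (1508.0, 825.0, 0.55),
        "heat": (980.0, 565.0, 0.58),
        "printed_pct": (-35, -32),
    },
    (75, "PHR23"): {
        "control": (2002.0, 1303.0, 0.65),
        "heat": (1560.0, 846.0, 0.54),
        "printed_pct": (-22, -35),
    },
}

# Printed dispersion (± values, treated as standard deviations) across the
# eight greenhouse-trial cells, per variable.  Used as defaults by the
# synthetic trial generator (medians across cells).
TRIAL_DISPERSION = {
    "total_fresh_g": [108, 123, 180, 507, 314, 290, 401, 208],
    "fruit_fresh_g": [51, 36, 105, 286, 150, 228, 277, 152],
    "lai": [0.48, 0.61, 0.62, 2.14, 0.37, 0.64, 0.95, 0.78],
    "height_cm": [9, 13, 18, 27, 12, 13, 27, 33],
    "stem_mm": [1.42, 2.27, 2.84, 4.30, 1.94, 3.17, 2.47, 6.02],
    "moisture_pct": [2, 1, 22, 2, 4, 1, 2, 3],
    "total_n_g": [0.05, 0.13, 0.05, 0.30, 0.11, 0.23, 0.17, 0.14],
}

# Open-field survey: measured vs simulated dry yields (Mg ha-1) at the field
# calibration site (Cheonan) and the nine heat-unit test sites.
# Columns: site kind, province, city, year, measured, measured sd, simulated,
# printed measured/simulated ratio.
SITE_YIELD_TABLE = [
    ("field_study", "CN", "Cheonan", 2024, 8.13, 1.77, 8.05, 1.01),
    ("phu_test", "GW", "Hoengseong", 2021, 8.23, 0.54, 7.81, 1.05),
    ("phu_test", "GG", "Anseong", 2021, 9.01, 1.48, 8.18, 1.10),
    ("phu_test", "GG", "Anseong", 2023, 8.89, 1.73, 7.30, 1.22),
    ("phu_test", "CB", "Jecheon", 2021, 8.57, 2.78, 9.42, 0.91),
    ("phu_test", "CB", "Jecheon", 2022, 7.87, 0.19, 8.49, 0.93),
    ("phu_test", "CB", "Jecheon", 2023, 8.93, 0.00, 9.46, 0.94),
    ("phu_test", "CN", "Dangjin", 2021, 7.16, 2.27, 7.79, 0.92),
    ("phu_test", "CN", "Cheongyang", 2021, 6.17, 0.09, 7.26, 0.85),
    ("phu_test", "CN", "Cheongyang", 2022, 7.68, 0.82, 8.66, 0.89),
    ("phu_test", "GB", "Yeongyang", 2021, 7.83, 1.47, 7.70, 1.02),
    ("phu_test", "GB", "Yeongyang", 2022, 7.07, 1.11, 7.30, 0.97),
    ("phu_test", "GB", "Yeongyang", 2023, 8.39, 0.31, 9.49, 0.88),
    ("phu_test", "GN", "Hamyang", 2021, 11.71, 2.02, 11.18, 1.05),
    ("phu_test", "GN", "Hamyang", 2023, 11.28, 1.69, 11.16, 1.01),
    ("phu_test", "JN", "Sinan", 2021, 10.85, 1.18, 10.59, 1.02),
    ("phu_test", "JN", "Haenam", 2021, 7.46, 2.61, 7.43, 1.00),
]

PHU_TEST_SITE_ROWS = [r for r in SITE_YIELD_TABLE if r[0] == "phu_test"]

# Warming-scenario yields (Mg ha-1 dry) per accession and site: reference
# (2014-2023 mean) and +3/+4/+5 C values with the printed integer percent
# loss.  'pct_inconsistent' flags cells whose printed percent cannot be
# recomputed from the two printed yields (see module docstring).
SCENARIO_YIELD_TABLE = {
    "PHR18": [
        {"province": "GW", "city": "Hoengseong", "reference": 7.53,
         "scenarios": {3: (4.88, -35), 4: (4.85, -36), 5: (4.82, -36)}},
        {"province": "GG", "city": "Anseong", "reference": 8.13,
         "scenarios": {3: (5.57, -31), 4: (5.58, -31), 5: (5.54, -32)}},
        {"province": "CB", "city": "Jecheon", "reference": 9.04,
         "scenarios": {3: (5.99, -34), 4: (6.15, -32), 5: (6.04, -33)}},
        {"province": "CN", "city": "Dangjin", "reference": 10.61,
         "scenarios": {3: (6.12, -42), 4: (5.95, -44), 5: (5.94, -44)}},
        {"province": "CN", "city": "Cheongyang", "reference": 9.58,
         "scenarios": {3: (5.56, -42), 4: (5.45, -43), 5: (5.37, -44)}},
        {"province": "GB", "city": "Yeongyang", "reference": 9.21,
         "scenarios": {3: (6.20, -33), 4: (6.21, -33), 5: (6.21, -33)}},
        {"province": "GN", "city": "Hamyang", "reference": 11.16,
         "scenarios": {3: (7.24, -35), 4: (7.18, -36), 5: (7.14, -36)}},
        {"province": "JN", "city": "Sinan", "reference": 11.17,
         "scenarios": {3: (6.69, -40), 4: (6.63, -41), 5: (6.56, -41)}},
        {"province": "JN", "city": "Haenam", "reference": 10.92,
         "scenarios": {3: (6.20, -43), 4: (6.41, -41), 5: (5.99, -45)}},
    ],
    "PHR23": [
        {"province": "GW", "city": "Hoengseong", "reference": 9.36,
         "scenarios": {3: (4.97, -47), 4: (4.93, -47), 5: (4.88, -48)}},
        {"province": "GG", "city": "Anseong", "reference": 10.12,
         "scenarios": {3: (5.65, -44), 4: (5.65, -44), 5: (5.61, -45)}},
        {"province": "CB", "city": "Jecheon", "reference": 11.15,
         "scenarios": {3: (6.15, -45), 4: (6.20, -44), 5: (6.15, -45)}},
        {"province": "CN", "city": "Dangjin", "reference": 13.17,
         "scenarios": {3: (6.24, -53), 4: (6.10, -54), 5: (6.09, -54)}},
        {"province": "CN", "city": "Cheongyang", "reference": 11.90,
         "scenarios": {3: (5.83, -51), 4: (5.71, -52), 5: (5.62, -53)}},
        {"province": "GB", "city": "Yeongyang", "reference": 11.48,
         "scenarios": {3: (6.31, -45), 4: (6.31, -45), 5: (6.29, -45)}},
        {"province": "GN", "city": "Hamyang", "reference": 13.84,
         "scenarios": {3: (7.37, -47), 4: (7.31, -47), 5: (7.27, -48)},
         "pct_inconsistent": [5]},
        {"province": "JN", "city": "Sinan", "reference": 13.90,
         "scenarios": {3: (6.94, -50), 4: (6.87, -51), 5: (6.80, -51)}},
        {"province": "JN", "city": "Haenam", "reference": 13.39,
         "scenarios": {3: (6.33, -53), 4: (6.50, -51), 5: (6.41, -52)}},
    ],
}
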