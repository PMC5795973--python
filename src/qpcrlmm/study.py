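"""Reference values from the Iberian/Duroc feeding trial this package models.

The trial compared 30 Iberian and 19 Duroc growing pigs (born in 19
contemporary litters) fed isocaloric diets differing in energy source — a
high-oleic sunflower-oil diet (HO, 17 Iberian / 10 Duroc) versus a standard
carbohydrate diet (CH, 13 Iberian / 9 Duroc) — with ham adipose biopsies taken
after a 24 h fast and 3 h postprandially.  The constants below are the trial's
published summary statistics: per-gene qPCR amplification efficiencies,
least-squares means of the fatty-acid composition of backfat and ham
subcutaneous fat (inner layer), diet fatty-acid contents, and the reported
fold changes with asymmetric 95 % confidence bounds for the three main
effects.  They serve as simulator defaults, internal-consistency fixtures and
acceptance inputs; the trial's raw well-level measurements are not public.
"""

from __future__ import annotations

import pandas as pd

#: 13 lipid-metabolism target genes assayed in ham adipose tissue.
TARGET_GENES: tuple[str, ...] = (
    "RXRG", "PPARG", "SREBP1", "LEP", "ME1", "SCD", "ACACA",
    "FASN", "ELOVL6", "ATGL", "HSL", "PLIN1", "G0S2",
)

#: Endogenous genes retained for normalization after stability screening.
REFERENCE_GENES: tuple[str, ...] = ("ACTB", "PPIA")

#: Full candidate panel screened for reference-gene stability.
CANDIDATE_REFERENCES: tuple[str, ...] = ("GAPDH", "ACTB", "TBP", "18S", "PPIA", "B2M")

#: qPCR amplification efficiencies (percent above 1x per cycle; 100 = perfect
#: doubling), from standard-curve estimation for each assay.
EFFICIENCY_PERCENT: dict[str, float] = {
    "RXRG": 84.8,
    "PPARG": 93.5,
    "SREBP1": 91.5,
    "LEP": 92.8,
    "ME1": 86.5,
    "SCD": 89.6,
    "ACACA": 85.2,
    "FASN": 85.1,
    "ELOVL6": 89.5,
    "ATGL": 87.2,
    "HSL": 82.8,
    "PLIN1": 87.9,
    "G0S2": 83.7,
    "ACTB": 90.7,
    "PPIA": 96.9,
}

#: Animals per breed x diet cell.
CELL_COUNTS: dict[tuple[str, str], int] = {
    ("Iberian", "HO"): 17,
    ("Iberian", "CH"): 13,
    ("Duroc", "HO"): 10,
    ("Duroc", "CH"): 9,
}

N_LITTERS = 19

# ---------------------------------------------------------------------------
# Fatty-acid least-squares means (% of total FA, wt/wt), inner layer.
# Columns: diet margins (CH, HO) and breed margins (Duroc, Iberian).
# ---------------------------------------------------------------------------

_FA_ROWS = (
    "C14:0", "C16:0", "C16:1n-9", "C16:1n-7", "C17:0", "C17:1", "C18:0",
    "C18:1n-9", "C18:1n-7", "C18:2n-6", "C18:3n-3", "C18:4n-3", "C20:0",
    "C20:1n-9", "C20:2", "C20:4n-6", "C20:3n-3", "C22:4n-6", "C22:5n-3",
    "C22:6n-3",
)

_BACKFAT = {
    #            CH     HO     Duroc  Iberian
    "C14:0":    (1.24,  1.12,  1.08,  1.25),
    "C16:0":    (23.68, 20.91, 20.32, 24.27),
    "C16:1n-9": (0.33,  0.44,  0.45,  0.31),
    "C16:1n-7": (1.97,  1.60,  1.97,  1.60),
    "C17:0":    (0.46,  0.39,  0.41,  0.44),
    "C17:1":    (0.35,  0.28,  0.29,  0.34),
    "C18:0":    (13.35, 10.35, 10.31, 13.39),
    "C18:1n-9": (40.23, 46.49, 44.20, 42.53),
    "C18:1n-7": (1.64,  1.68,  1.77,  1.55),
    "C18:2n-6": (13.42, 13.41, 16.13, 10.70),
    "C18:3n-3": (0.84,  0.88,  1.00,  0.72),
    "C18:4n-3": (0.06,  0.07,  0.07,  0.06),
    "C20:0":    (0.22,  0.18,  0.18,  0.22),
    "C20:1n-9": (0.97,  1.03,  0.90,  1.10),
    "C20:2":    (0.68,  0.61,  0.71,  0.59),
    "C20:4n-6": (0.22,  0.22,  0.26,  0.18),
    "C20:3n-3": (0.12,  0.11,  0.12,  0.11),
    "C22:4n-6": (0.10,  0.09,  0.10,  0.09),
    "C22:5n-3": (0.09,  0.09,  0.07,  0.11),
    "C22:6n-3": (0.03,  0.05,  0.04,  0.04),
}

_HAM = {
    "C14:0":    (1.24,  1.18,  1.15,  1.27),
    "C16:0":    (22.57, 20.54, 20.38, 22.73),
    "C16:1n-9": (0.28,  0.39,  0.36,  0.31),
    "C16:1n-7": (2.57,  2.16,  2.28,  2.45),
    "C17:0":    (0.33,  0.41,  0.33,  0.42),
    "C17:1":    (0.40,  0.31,  0.30,  0.41),
    "C18:0":    (10.48, 8.79,  9.33,  9.94),
    "C18:1n-9": (44.75, 49.40, 47.26, 46.89),
    "C18:1n-7": (1.84,  1.69,  1.67,  1.85),
    "C18:2n-6": (12.11, 11.87, 13.58, 10.41),
    "C18:3n-3": (0.80,  0.80,  0.87,  0.73),
    "C18:4n-3": (0.08,  0.09,  0.09,  0.08),
    "C20:0":    (0.16,  0.14,  0.15,  0.15),
    "C20:1n-9": (1.00,  1.04,  0.91,  1.13),
    "C20:2":    (0.67,  0.61,  0.68,  0.61),
    "C20:4n-6": (0.25,  0.25,  0.27,  0.23),
    "C20:3n-3": (0.13,  0.13,  0.13,  0.11),
    "C22:4n-6": (0.10,  0.09,  0.10,  0.10),
    "C22:5n-3": (0.13,  0.11,  0.09,  0.15),
    "C22:6n-3": (0.07,  0.07,  0.07,  0.07),
}

_MARGINS = ("CH", "HO", "Duroc", "Iberian")


def _table(data: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(data, orient="index", columns=_MARGINS).loc[list(_FA_ROWS)]


def backfat_lsmeans() -> pd.DataFrame:
    """Backfat inner-layer FA LS means (% of total FA) by diet/breed margin."""
    return _table(_BACKFAT)


def ham_lsmeans() -> pd.DataFrame:
    """Ham-fat inner-layer FA LS means (% of total FA) by diet/breed margin."""
    return _table(_HAM)


#: Printed index rows (sums of member FA percentages) for the same margins.
INDEX_LSMEANS = {
    "backfat": {
        "SFA":  {"CH": 38.93, "HO": 32.96, "Duroc": 32.31, "Iberian": 39.57},
        "MUFA": {"CH": 45.13, "HO": 51.24, "Duroc": 49.28, "Iberian": 47.09},
        "PUFA": {"CH": 14.86, "HO": 14.93, "Duroc": 17.79, "Iberian": 12.01},
    },
    "ham": {
        "SFA":  {"CH": 34.78, "HO": 31.06, "Duroc": 31.33, "Iberian": 34.52},
        "MUFA": {"CH": 50.43, "HO": 54.68, "Duroc": 52.48, "Iberian": 52.63},
        "PUFA": {"CH": 13.67, "HO": 13.41, "Duroc": 15.20, "Iberian": 11.87},
    },
}

#: Diet fatty-acid content (g/kg feed, as-fed); simulator input only.
DIET_FA_G_PER_KG = {
    "CH": {"C14:0": 0.14, "C16:0": 4.83, "C18:0": 0.84, "C18:1n-9": 9.47,
           "C18:2n-6": 14.24, "C18:3n-3": 0.99},
    "HO": {"C14:0": 0.13, "C16:0": 7.19, "C18:0": 1.83, "C18:1n-9": 36.82,
           "C18:2n-6": 16.68, "C18:3n-3": 1.21},
}

#: Reported fold changes and asymmetric 95 % CI bounds for the three main
#: effects (breed Iberian/Duroc, status fed/fasting, diet HO/CH).
REPORTED_FOLD_CHANGES: dict[str, dict[str, tuple[float, float, float]]] = {
    # gene: effect -> (FC, ci_low, ci_high)
    "RXRG":   {"breed": (1.33, 0.90, 1.96), "status": (1.27, 1.08, 1.49), "diet": (1.12, 0.91, 1.39)},
    "PPARG":  {"breed": (1.07, 0.84, 1.36), "status": (1.22, 1.07, 1.38), "diet": (0.87, 0.69, 1.09)},
    "SREBP1": {"breed": (0.87, 0.65, 1.17), "status": (1.11, 0.93, 1.32), "diet": (0.99, 0.74, 1.33)},
    "LEP":    {"breed": (2.85, 1.23, 6.64), "status": (2.05, 1.69, 2.48), "diet": (0.99, 0.68, 1.45)},
    "ME1":    {"breed": (1.80, 1.03, 3.14), "status": (1.12, 1.00, 1.24), "diet": (1.18, 0.70, 2.00)},
    "SCD":    {"breed": (2.21, 1.49, 3.27), "status": (1.30, 1.21, 1.40), "diet": (1.05, 0.74, 1.49)},
    "ACACA":  {"breed": (1.49, 0.90, 2.46), "status": (2.10, 1.87, 2.35), "diet": (0.97, 0.61, 1.53)},
    "FASN":   {"breed": (1.36, 0.95, 1.94), "status": (1.13, 1.02, 1.24), "diet": (1.16, 0.81, 1.63)},
    "ELOVL6": {"breed": (1.60, 1.06, 2.40), "status": (1.22, 1.10, 1.37), "diet": (0.94, 0.68, 1.31)},
    "ATGL":   {"breed": (0.89, 0.78, 1.01), "status": (0.99, 0.92, 1.07), "diet": (1.01, 0.92, 1.11)},
    "HSL":    {"breed": (0.94, 0.79, 1.13), "status": (0.96, 0.89, 1.03), "diet": (0.96, 0.82, 1.14)},
    "PLIN1":  {"breed": (1.93, 0.90, 4.14), "status": (1.07, 0.92, 1.25), "diet": (0.79, 0.63, 1.00)},
    "G0S2":   {"breed": (0.89, 0.47, 1.70), "status": (1.50, 1.16, 1.95), "diet": (0.82, 0.51, 1.30)},
}
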