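"""Domain types, validation and tabular I/O for qPCR and fatty-acid data.

The canonical in-memory containers are tidy :class:`pandas.DataFrame` objects,
one well (or one fat sample) per row; the dataclasses below give a typed view
of a single record and carry the validation contracts.  On disk everything is
plain UTF-8 CSV with ``.`` as decimal separator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "WellMeasurement",
    "FattyAcidProfile",
    "TreatmentDesign",
    "BREEDS",
    "DIETS",
    "STATUSES",
    "CP_COLUMNS",
    "FA_META_COLUMNS",
    "CANONICAL_FA_NAMES",
    "treatment_design",
    "efficiencies_from_percent",
    "validate_wells",
    "validate_efficiencies",
    "read_cp_table",
    "write_cp_table",
    "read_fa_table",
    "write_fa_table",
    "n_biopsy_samples",
]


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed header."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


# First-named class first: fold changes > 1 mean higher expression in the
# first level of each factor (Iberian, fed, HO).
BREEDS = ("Iberian", "Duroc")
DIETS = ("HO", "CH")
STATUSES = ("fed", "fasting")

CP_COLUMNS = ["gene", "animal", "breed", "diet", "status", "plate", "box", "replicate", "cp"]
EFFICIENCY_COLUMNS = ["gene", "efficiency_percent"]
FA_META_COLUMNS = ["sample", "depot", "layer", "breed", "diet", "litter", "box"]

CANONICAL_FA_NAMES = (
    "C14:0", "C16:0", "C16:1n-9", "C16:1n-7", "C17:0", "C17:1", "C18:0",
    "C18:1n-9", "C18:1n-7", "C18:2n-6", "C18:3n-3", "C18:4n-3", "C20:0",
    "C20:1n-9", "C20:2", "C20:4n-6", "C20:3n-3", "C22:4n-6", "C22:5n-3",
    "C22:6n-3",
)


@dataclass(frozen=True)
class WellMeasurement:
    """One qPCR well: a Cp observation with its design labels.

    ``(breed, diet, status)`` locate the well in one of the 8 treatment cells;
    ``(animal, status)`` identify the biopsy sample the cDNA came from.
    """

    gene: str
    animal: str
    breed: str
    diet: str
    status: str
    plate: str
    box: str
    replicate: int
    cp: float

    def __post_init__(self) -> None:
        if self.breed not in BREEDS:
            raise ValidationError(f"unknown breed {self.breed!r}; expected one of {BREEDS}")
        if self.diet not in DIETS:
            raise ValidationError(f"unknown diet {self.diet!r}; expected one of {DIETS}")
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}; expected one of {STATUSES}")
        if not (0.0 < self.cp < 45.0):
            raise ValidationError(f"cp={self.cp} outside the valid cycle range (0, 45)")


@dataclass
class FattyAcidProfile:
    """One fat sample's FA composition (weight % of total fatty acids)."""

    sample: str
    depot: str
    layer: str
    breed: str
    diet: str
    litter: str
    box: str
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.percentages.items():
            if value < 0:
                raise ValidationError(f"negative percentage {value} for {name!r}")
        total = sum(self.percentages.values())
        if total > 100.0 + 0.5:
            raise ValidationError(f"FA percentages sum to {total:.2f} > 100")


@dataclass(frozen=True)
class TreatmentDesign:
    """The 8 treatment cells (breed x diet x status) and named contrasts.

    Each contrast is a weight vector over the cells summing to zero; main
    effects average the first-named class's 4 cells against the other 4, and
    interactions are differences of differences.
    """

    cells: tuple[tuple[str, str, str], ...]
    contrasts: dict[str, np.ndarray]

    def cell_index(self, breed: str, diet: str, status: str) -> int:
        return self.cells.index((breed, diet, status))


def treatment_design() -> TreatmentDesign:
    """Build the standard 2x2x2 design with its six effect contrasts.

    Sign convention: a positive weight goes to the first-named class (Iberian,
    HO, fed), so on the transformed scale (where larger y means lower
    expression) a negative contrast estimate back-transforms to a fold change
    above 1 in favour of that class.
    """
    cells = tuple(
        (breed, diet, status) for breed in BREEDS for diet in DIETS for status in STATUSES
    )
    sign = {
        "breed": np.array([+1 if c[0] == BREEDS[0] else -1 for c in cells], float),
        "diet": np.array([+1 if c[1] == DIETS[0] else -1 for c in cells], float),
        "status": np.array([+1 if c[2] == STATUSES[0] else -1 for c in cells], float),
    }
    contrasts = {name: s / 4.0 for name, s in sign.items()}
    for a, b in (("breed", "status"), ("breed", "diet"), ("diet", "status")):
        contrasts[f"{a}x{b}"] = sign[a] * sign[b] / 4.0
    return TreatmentDesign(cells=cells, contrasts=contrasts)


def efficiencies_from_percent(percent: dict[str, float]) -> dict[str, float]:
    """Convert percent efficiencies to amplification factors E = 1 + p/100."""
    out = {}
    for gene, p in percent.items():
        if not (0.0 < p <= 100.0):
            raise ValidationError(
                f"efficiency for {gene!r} is {p}%; must lie in (0, 100]"
            )
        out[gene] = 1.0 + p / 100.0
    return out


def validate_efficiencies(eff: dict[str, float]) -> None:
    for gene, e in eff.items():
        if not (1.0 < e <= 2.0):
            raise ValidationError(f"amplification factor for {gene!r} is {e}; must lie in (1, 2]")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def validate_wells(df: pd.DataFrame) -> None:
    """Check a tidy well table against the domain invariants."""
    _require_columns(df, CP_COLUMNS, "Cp table")
    cp = df["cp"].to_numpy(float)
    if np.any(~np.isfinite(cp)) or np.any(cp <= 0) or np.any(cp >= 45):
        bad = df.loc[(cp <= 0) | (cp >= 45) | ~np.isfinite(cp)].index[:5].tolist()
        raise ValidationError(f"cp values outside (0, 45) at rows {bad}")
    for col, levels in (("breed", BREEDS), ("diet", DIETS), ("status", STATUSES)):
        unknown = set(df[col].unique()) - set(levels)
        if unknown:
            raise ValidationError(f"unknown {col} level(s) {sorted(unknown)}; expected {levels}")
    # each animal must sit in exactly one (breed, diet, box) combination
    per_animal = df.groupby("animal")[["breed", "diet", "box"]].nunique()
    bad = per_animal[(per_animal > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValidationError(f"animals with inconsistent breed/diet/box labels: {bad}")


def n_biopsy_samples(df: pd.DataFrame) -> int:
    """Number of distinct biopsy samples, i.e. distinct (animal, status) pairs."""
    return df[["animal", "status"]].drop_duplicates().shape[0]


def read_cp_table(path, efficiency_path) -> tuple[pd.DataFrame, dict[str, float]]:
    """Read a tidy Cp table and per-gene efficiency table from CSV.

    Returns the validated well table and the efficiency map as amplification
    factors E in (1, 2].  Every gene in the Cp table must have an efficiency.
    """
    wells = pd.read_csv(path, comment="#")
    validate_wells(wells)
    eff_df = pd.read_csv(efficiency_path, comment="#")
    _require_columns(eff_df, EFFICIENCY_COLUMNS, "efficiency table")
    eff = efficiencies_from_percent(
        dict(zip(eff_df["gene"].astype(str), eff_df["efficiency_percent"].astype(float)))
    )
    missing = sorted(set(wells["gene"].unique()) - set(eff))
    if missing:
        raise ValidationError(f"genes without an efficiency entry: {missing}")
    return wells, eff


def write_cp_table(wells: pd.DataFrame, path, efficiencies=None, efficiency_path=None,
                  header_lines: list[str] | None = None) -> None:
    """Write a well table (and optionally an efficiency table) to CSV."""
    validate_wells(wells)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        wells[CP_COLUMNS].to_csv(fh, index=False)
    if efficiencies is not None:
        if efficiency_path is None:
            raise ValueError("efficiency_path is required when efficiencies are given")
        out = pd.DataFrame(
            {"gene": list(efficiencies), "efficiency_percent": [
                (e - 1.0) * 100.0 for e in efficiencies.values()]}
        )
        out.to_csv(efficiency_path, index=False)


def normalize_fa_name(name: str) -> str:
    """Map an FA column label to its canonical spelling (e.g. ``C18:1n-9``)."""
    cleaned = name.strip().replace(" ", "")
    compact = {c.replace("n-", "n"): c for c in CANONICAL_FA_NAMES}
    if cleaned in CANONICAL_FA_NAMES:
        return cleaned
    if cleaned in compact:
        return compact[cleaned]
    return cleaned


def read_fa_table(path) -> pd.DataFrame:
    """Read fatty-acid profiles from CSV; one sample per row.

    FA column labels are normalized to canonical spellings; unknown FA names
    are kept with a warning.  An empty file yields an empty table.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FA_META_COLUMNS)
    if df.empty and len(df.columns) == 0:
        return pd.DataFrame(columns=FA_META_COLUMNS)
    _require_columns(df, FA_META_COLUMNS, "FA table")
    rename = {}
    for col in df.columns:
        if col in FA_META_COLUMNS:
            continue
        canon = normalize_fa_name(col)
        if canon not in CANONICAL_FA_NAMES:
            warnings.warn(f"unknown fatty acid column {col!r}; retained as-is", stacklevel=2)
        if canon != col:
            rename[col] = canon
    df = df.rename(columns=rename)
    fa_cols = [c for c in df.columns if c not in FA_META_COLUMNS]
    values = df[fa_cols].to_numpy(float)
    if np.any(values < 0):
        raise ValidationError("negative fatty-acid percentage in FA table")
    totals = np.nansum(values, axis=1)
    if np.any(totals > 100.0 + 0.5):
        raise ValidationError("fatty-acid percentages sum above 100 for at least one sample")
    return df


def write_fa_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
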