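"""Domain types, code systems, and delimited-file I/O for the registry tables.

The pipeline consumes five administrative tables — hospital discharges (HDR),
drug claims (PHARMED), ticket exemptions (TER), mortality (ReNCaM) and the
health-assistance/residency file — plus a population denominator table
stratified by area x age band x gender, and an area hierarchy table mapping
health districts to Local Health Units (LHUs).  All tables are headered CSV,
UTF-8, ISO-8601 dates, keyed by a pseudonymous person identifier whose exact
string equality is the record-linkage key.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("msprev")

# ---------------------------------------------------------------------------
# Code systems
# ---------------------------------------------------------------------------

#: ICD-9-CM code for multiple sclerosis.  340 has no subdivisions, so prefix
#: matching after dot-stripping absorbs coding dialects ("340", "340.0", "3400").
MS_ICD9_PREFIX = "340"

#: Ticket-exemption code granting co-pay exemption for multiple sclerosis.
MS_EXEMPTION_CODE = "046.340"

#: Canonical disease-modifying-drug (DMD) tokens used for PHARMED selection.
MS_DMD_TOKENS = frozenset({"IFNB1A", "IFNB1B", "GLATIRAMER", "NATALIZUMAB"})

#: Brand-name and ATC-code aliases mapped onto the canonical DMD tokens.
DMD_ALIASES: dict[str, str] = {
    "AVONEX": "IFNB1A",
    "REBIF": "IFNB1A",
    "L03AB07": "IFNB1A",
    "BETAFERON": "IFNB1B",
    "EXTAVIA": "IFNB1B",
    "L03AB08": "IFNB1B",
    "COPAXONE": "GLATIRAMER",
    "GLATIRAMER ACETATE": "GLATIRAMER",
    "L03AX13": "GLATIRAMER",
    "TYSABRI": "NATALIZUMAB",
    "L04AA23": "NATALIZUMAB",
}

#: Default prevalence day for the study.
DEFAULT_PREVALENCE_DAY = dt.date(2011, 12, 31)

#: Default case-ascertainment window.
DEFAULT_STUDY_WINDOW = (dt.date(2006, 1, 1), dt.date(2011, 12, 31))

SOURCES = ("HDR", "PHARMED", "TER")

HDR_DX_COLUMNS = [f"dx{i}" for i in range(1, 7)]


def normalize_icd9(code: str) -> str:
    """Strip dots and whitespace from an ICD-9-CM code string."""
    return str(code).strip().replace(".", "")


def is_ms_diagnosis_code(code: str) -> bool:
    """True iff an ICD-9-CM code denotes multiple sclerosis (340.x)."""
    norm = normalize_icd9(code)
    if not norm:
        return False
    if not norm[0].isdigit():
        logger.warning("malformed ICD-9 code %r treated as non-matching", code)
        return False
    return norm.startswith(MS_ICD9_PREFIX)


def is_ms_discharge(diagnoses: Sequence[str]) -> bool:
    """True iff any discharge diagnosis, primary or secondary, is MS.

    Position is irrelevant: a hospitalization qualifies whether MS is the
    primary diagnosis (first slot) or appears in any secondary slot.
    """
    return any(is_ms_diagnosis_code(c) for c in diagnoses if c and not pd.isna(c))


def is_ms_dmd(drug: str) -> bool:
    """True iff a drug token denotes one of the four MS disease-modifying drugs.

    Accepts the canonical tokens (IFNB1A, IFNB1B, GLATIRAMER, NATALIZUMAB) and
    the alias table of brand names and ATC codes.  Unknown tokens are
    non-matching and logged.
    """
    token = str(drug).strip().upper()
    if token in MS_DMD_TOKENS:
        return True
    if token in DMD_ALIASES:
        return True
    logger.debug("drug token %r is not an MS DMD", drug)
    return False


def is_ms_exemption(exemption_code: str) -> bool:
    """True iff an exemption code equals the MS code 046.340 (whitespace-insensitive)."""
    return str(exemption_code).strip() == MS_EXEMPTION_CODE


def age_on(birth_date: dt.date, reference_date: dt.date) -> int:
    """Completed years of age at ``reference_date``.

    The year difference is reduced by one when the birthday has not yet been
    reached in the reference year.  Raises ``ValueError`` when the birth date
    lies after the reference date.
    """
    if birth_date > reference_date:
        raise ValueError(
            f"birth_date {birth_date} is after reference_date {reference_date}"
        )
    years = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# Age banding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeBand:
    """A closed age interval in completed years; ``upper=None`` means open-ended."""

    lower: int
    upper: int | None

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    @classmethod
    def parse(cls, label: str) -> "AgeBand":
        label = str(label).strip()
        if label.endswith("+"):
            return cls(int(label[:-1]), None)
        lo, hi = label.split("-")
        return cls(int(lo), int(hi))


@dataclass(frozen=True)
class AgeBanding:
    """An ordered, disjoint, exhaustive partition of [0, inf) into age bands."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("banding must contain at least one band")
        if self.bands[0].lower != 0:
            raise ValueError("first band must start at age 0")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper is None or b.lower != a.upper + 1:
                raise ValueError(f"bands {a.label} and {b.label} are not contiguous")
        if self.bands[-1].upper is not None:
            raise ValueError("last band must be open-ended")

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def band_of(self, age: int) -> AgeBand:
        if age < 0:
            raise ValueError(f"negative age {age}")
        for band in self.bands:
            if band.contains(age):
                return band
        raise AssertionError("unreachable: banding is exhaustive")

    def label_of(self, age: int) -> str:
        return self.band_of(age).label

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "AgeBanding":
        return cls(tuple(AgeBand.parse(lab) for lab in labels))


#: The study's working banding (Table-style 10-year classes, children pooled).
DEFAULT_BANDING = AgeBanding.from_labels(
    ["0-14", "15-24", "25-34", "35-44", "45-54", "55-64", "65+"]
)

GENDERS = ("female", "male")


# ---------------------------------------------------------------------------
# Registry bundle and delimited I/O
# ---------------------------------------------------------------------------

#: Required columns per table; hdr additionally accepts dx1..dx6.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "hdr": ["person_id", "discharge_date"] + HDR_DX_COLUMNS,
    "pharmed": ["person_id", "dispense_date", "drug"],
    "ter": ["person_id", "exemption_code", "start_date"],
    "rencam": ["person_id", "death_date"],
    "assistance": [
        "person_id",
        "birth_date",
        "gender",
        "district_id",
        "lhu_id",
        "registered",
    ],
    "population": ["area_id", "area_level", "age_band", "gender", "population"],
    "areas": ["district_id", "lhu_id"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "hdr": ["discharge_date"],
    "pharmed": ["dispense_date"],
    "ter": ["start_date"],
    "rencam": ["death_date"],
    "assistance": ["birth_date"],
    "population": [],
    "areas": [],
}


@dataclass
class RegistryBundle:
    """The five administrative tables plus denominators and area hierarchy.

    Each attribute is a pandas DataFrame with the canonical column schema of
    :data:`TABLE_SCHEMAS`; date columns hold ``datetime.date`` objects.
    """

    hdr: pd.DataFrame
    pharmed: pd.DataFrame
    ter: pd.DataFrame
    rencam: pd.DataFrame
    assistance: pd.DataFrame
    population: pd.DataFrame
    areas: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}


class SchemaError(ValueError):
    """A registry file violates the expected column schema."""


def _parse_date_column(df: pd.DataFrame, col: str, table: str) -> None:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"table {table!r}: unparseable date {df[col].iloc[row]!r} "
            f"in column {col!r} at row {row}"
        )
    df[col] = parsed.dt.date


def read_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one registry table, validating schema and parsing dates."""
    required = TABLE_SCHEMAS[table]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} at {path}: missing column(s) {missing}")
    df = df[required].copy()
    for col in DATE_COLUMNS[table]:
        _parse_date_column(df, col, table)
    if table == "assistance":
        df["registered"] = df["registered"].astype(int).astype(bool)
    if table == "population":
        df["population"] = df["population"].astype(int)
    logger.info("read %d rows from %s (%s)", len(df), path, table)
    return df


def read_registry_bundle(
    paths: Mapping[str, str | Path] | None = None, directory: str | Path | None = None
) -> RegistryBundle:
    """Load a full registry bundle from per-table paths or a directory.

    ``paths`` maps table names (hdr, pharmed, ter, rencam, assistance,
    population, areas) to CSV files; alternatively ``directory`` locates
    ``<table>.csv`` files by convention.
    """
    if paths is None:
        if directory is None:
            raise ValueError("either paths or directory is required")
        paths = {t: Path(directory) / f"{t}.csv" for t in TABLE_SCHEMAS}
    tables = {t: read_table(paths[t], t) for t in TABLE_SCHEMAS}
    return RegistryBundle(**tables)


def write_registry_bundle(bundle: RegistryBundle, directory: str | Path) -> dict[str, Path]:
    """Write all bundle tables as ``<table>.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, df in bundle.tables().items():
        df = df.copy()
        if name == "assistance":
            df["registered"] = df["registered"].astype(int)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        out[name] = path
    return out
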