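"""CSV readers and writers for the three experiment tables.

All files are comma-separated UTF-8 with a mandatory header row and a
schema-version comment line ``#schema=photothermal-v1`` emitted first by
every writer.  Readers tolerate (and skip) any leading ``#`` comment lines.

Schemas
-------
phenotypes.csv : genotype,group,elf3,ppdh1,phyc,photoperiod_h,replicate,
                 repetition,days_to_heading,thermal_time_cd
temperature.csv: timestamp_iso8601,temp_c
ct.csv         : gene,genotype,photoperiod_h,zt,bio_rep,tech_rep,ct,undetected
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .types import (
    CtRecord,
    Elf3Allele,
    GenotypeSpec,
    Group,
    PhyCAllele,
    PlantRecord,
    PpdH1Allele,
    TemperatureLog,
    ValidationError,
)

SCHEMA_COMMENT = "#schema=photothermal-v1"

PHENOTYPE_COLUMNS = [
    "genotype", "group", "elf3", "ppdh1", "phyc",
    "photoperiod_h", "replicate", "repetition",
    "days_to_heading", "thermal_time_cd",
]
TEMPERATURE_COLUMNS = ["timestamp_iso8601", "temp_c"]
CT_COLUMNS = [
    "gene", "genotype", "photoperiod_h", "zt",
    "bio_rep", "tech_rep", "ct", "undetected",
]

PathLike = Union[str, Path]


class SchemaError(ValidationError):
    """A file's header does not match the documented schema."""


class RowError(ValidationError):
    """A data row failed validation; carries its 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # track how many leading comment lines precede the header so row errors
    # can report true file line numbers
    n_comments = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    df.attrs["header_line"] = n_comments + 1
    return df


def _num(df: pd.DataFrame, row: int, col: str, *, optional: bool = False):
    raw = df.iloc[row][col]
    if pd.isna(raw) or raw == "":
        if optional:
            return None
        raise RowError(_line(df, row), f"missing value in column {col!r}")
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowError(
            _line(df, row), f"non-numeric value {raw!r} in column {col!r}"
        ) from None


def _line(df: pd.DataFrame, row: int) -> int:
    return df.attrs.get("header_line", 1) + 1 + row


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: PathLike) -> list[PlantRecord]:
    """Read a phenotype CSV into validated plant records (row order kept)."""
    df = _read_csv(path, PHENOTYPE_COLUMNS)
    records: list[PlantRecord] = []
    for i in range(len(df)):
        days = _num(df, i, "days_to_heading", optional=True)
        try:
            records.append(
                PlantRecord(
                    genotype=str(df.iloc[i]["genotype"]),
                    photoperiod_h=_num(df, i, "photoperiod_h"),
                    replicate=int(_num(df, i, "replicate")),
                    repetition=int(_num(df, i, "repetition")),
                    days_to_heading=days,
                    thermal_time_cd=_num(df, i, "thermal_time_cd"),
                )
            )
        except ValidationError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(_line(df, i), str(exc)) from exc
    return records


def read_genotype_specs(path: PathLike) -> dict[str, GenotypeSpec]:
    """Read the allele columns of a phenotype CSV into GenotypeSpec objects."""
    df = _read_csv(path, PHENOTYPE_COLUMNS)
    specs: dict[str, GenotypeSpec] = {}
    for i in range(len(df)):
        gid = str(df.iloc[i]["genotype"])
        if gid in specs:
            continue
        try:
            specs[gid] = GenotypeSpec(
                id=gid,
                group=Group(str(df.iloc[i]["group"])),
                elf3_allele=Elf3Allele(str(df.iloc[i]["elf3"])),
                ppdh1_allele=PpdH1Allele(str(df.iloc[i]["ppdh1"])),
                phyc_allele=PhyCAllele(str(df.iloc[i]["phyc"])),
            )
        except (ValueError, ValidationError) as exc:
            raise RowError(_line(df, i), str(exc)) from exc
    return specs


def write_phenotypes(
    path: PathLike,
    records: Sequence[PlantRecord],
    genotypes: Mapping[str, GenotypeSpec],
) -> None:
    rows = []
    for r in records:
        spec = genotypes[r.genotype]
        rows.append(
            {
                "genotype": r.genotype,
                "group": spec.group.value,
                "elf3": spec.elf3_allele.value,
                "ppdh1": spec.ppdh1_allele.value,
                "phyc": spec.phyc_allele.value,
                "photoperiod_h": r.photoperiod_h,
                "replicate": r.replicate,
                "repetition": r.repetition,
                "days_to_heading": "" if r.days_to_heading is None else r.days_to_heading,
                "thermal_time_cd": r.thermal_time_cd,
            }
        )
    _write(path, pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS))


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def read_temperature(path: PathLike) -> TemperatureLog:
    df = _read_csv(path, TEMPERATURE_COLUMNS)
    if len(df) == 0:
        raise ValidationError(f"{Path(path).name}: temperature log is empty")
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(df["timestamp_iso8601"]))
        temps = df["temp_c"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{Path(path).name}: {exc}") from exc
    return TemperatureLog(pd.Series(temps.to_numpy(), index=idx, name="temp_c"))


def write_temperature(path: PathLike, log: TemperatureLog) -> None:
    df = pd.DataFrame(
        {
            "timestamp_iso8601": log.series.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_c": log.series.to_numpy(),
        }
    )
    _write(path, df)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def read_ct(path: PathLike) -> list[CtRecord]:
    df = _read_csv(path, CT_COLUMNS)
    records: list[CtRecord] = []
    for i in range(len(df)):
        undet = str(df.iloc[i]["undetected"]).strip().lower() in {
            "1", "true", "yes",
        }
        ct = None if undet else _num(df, i, "ct")
        try:
            records.append(
                CtRecord(
                    gene=str(df.iloc[i]["gene"]),
                    genotype=str(df.iloc[i]["genotype"]),
                    photoperiod_h=_num(df, i, "photoperiod_h"),
                    zt=_num(df, i, "zt"),
                    bio_rep=int(_num(df, i, "bio_rep")),
                    tech_rep=int(_num(df, i, "tech_rep")),
                    ct=ct,
                    undetected=undet,
                )
            )
        except ValidationError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(_line(df, i), str(exc)) from exc
    return records


def write_ct(path: PathLike, records: Sequence[CtRecord]) -> None:
    rows = [
        {
            "gene": r.gene,
            "genotype": r.genotype,
            "photoperiod_h": r.photoperiod_h,
            "zt": r.zt,
            "bio_rep": r.bio_rep,
            "tech_rep": r.tech_rep,
            "ct": "" if r.ct is None else r.ct,
            "undetected": str(r.undetected).lower(),
        }
        for r in records
    ]
    _write(path, pd.DataFrame(rows, columns=CT_COLUMNS))


def _write(path: PathLike, df: pd.DataFrame) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(SCHEMA_COMMENT + "\n" + buf.getvalue(), encoding="utf-8")
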