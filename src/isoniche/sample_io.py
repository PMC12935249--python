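"""Reading, validating and writing per-individual isotope sample tables.

The canonical on-disk format is a UTF-8 CSV/TSV with a header row, one row
per individual cat. Mandatory columns: ``sample_id``, ``taxon``,
``d13C_measured``, ``d15N``, ``pctC``, ``pctN``. Everything else (region,
dates, sex, d34S, pctS, morphometrics) is optional; unknown numeric columns
are preserved in each sample's ``covariates`` map so land-use and climate
variables ride along without schema changes.

Missing values may be written as empty cells or ``NA``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

__all__ = [
    "IsotopeSample",
    "SampleTable",
    "SchemaError",
    "RowError",
    "ValidationError",
    "read_sample_table",
    "write_report",
    "normalize_taxon",
    "normalize_sex",
    "normalize_region",
]

MANDATORY_COLUMNS = ("sample_id", "taxon", "d13C_measured", "d15N", "pctC", "pctN")

#: Optional, schema-known columns mapped 1:1 onto IsotopeSample fields.
OPTIONAL_COLUMNS = (
    "region",
    "d13C_cor",
    "case_study",
    "year",
    "month",
    "sex",
    "d34S",
    "pctS",
    "weight",
    "body_length",
    "hindfoot_length",
    "age_class",
)

TAXA = ("wildcat", "domestic_cat", "hybrid")
SEXES = ("male", "female", "unknown")

#: Canonical spellings for the study regions; arbitrary other regions pass
#: through after whitespace trimming and umlaut folding.
KNOWN_REGIONS = (
    "Taunus",
    "Markgraeflerland",
    "Hainich",
    "East Thuringia",
    "Harz Foreland",
    "Thuringian Basin",
    "Thuringian Forest",
)

# Sanity windows: violations are validation errors, never silent drops.
_SANITY = {
    "d13C_measured": (-40.0, 0.0),
    "d15N": (-10.0, 20.0),
    "d34S": (-20.0, 25.0),
}


class ValidationError(ValueError):
    """A sample or table violates an invariant."""


class SchemaError(ValidationError):
    """A mandatory column is missing from the input file."""


class RowError(ValidationError):
    """A row could not be parsed; carries the zero-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class IsotopeSample:
    """One individual's isotopic, elemental and contextual record."""

    sample_id: str
    taxon: str
    d13C_measured: float
    d15N: float
    pctC: float
    pctN: float
    region: str | None = None
    case_study: int | None = None
    year: int | None = None
    month: int | None = None
    sex: str = "unknown"
    d13C_cor: float | None = None  # lipid- and Suess-corrected; set by qc_corrections
    d34S: float | None = None
    pctS: float | None = None
    weight: float | None = None
    body_length: float | None = None
    hindfoot_length: float | None = None
    age_class: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.taxon not in TAXA:
            raise ValidationError(f"unknown taxon {self.taxon!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        for name in ("pctC", "pctN", "pctS"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name}={v} outside [0, 100] for {self.sample_id}")
        for name, (lo, hi) in _SANITY.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValidationError(
                    f"{name}={v} outside sanity bounds [{lo}, {hi}] for {self.sample_id}"
                )
        if self.month is not None and self.month not in range(1, 13):
            raise ValidationError(f"month={self.month} outside 1..12 for {self.sample_id}")


@dataclass
class SampleTable:
    """Ordered collection of IsotopeSample with a provenance note."""

    samples: list[IsotopeSample]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            s.validate()

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame; covariates become plain columns."""
        rows = []
        for s in self.samples:
            d = dataclasses.asdict(s)
            cov = d.pop("covariates")
            d.update(cov)
            rows.append(d)
        return pd.DataFrame(rows)

    def subset(self, predicate) -> "SampleTable":
        return SampleTable([s for s in self.samples if predicate(s)], self.provenance)


def _fold(text: str) -> str:
    """Trim, transliterate German umlauts, strip remaining diacritics."""
    text = text.strip()
    for src, dst in (("ä", "ae"), ("ö", "oe"), ("ü", "ue"), ("ß", "ss"),
                     ("Ä", "Ae"), ("Ö", "Oe"), ("Ü", "Ue")):
        text = text.replace(src, dst)
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


_TAXON_ALIASES = {
    "wildcat": "wildcat",
    "wild cat": "wildcat",
    "felis silvestris": "wildcat",
    "domestic_cat": "domestic_cat",
    "domestic cat": "domestic_cat",
    "domesticcat": "domestic_cat",
    "felis catus": "domestic_cat",
    "hybrid": "hybrid",
}

_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "w": "female",
    "u": "unknown",
    "unknown": "unknown",
    "na": "unknown",
    "": "unknown",
}


def normalize_taxon(raw: str) -> str:
    key = _fold(raw).casefold().replace("-", " ")
    try:
        return _TAXON_ALIASES[key] if key in _TAXON_ALIASES else _TAXON_ALIASES[key.replace(" ", "_")]
    except KeyError:
        raise ValidationError(f"unrecognised taxon {raw!r}") from None


def normalize_sex(raw: str | None) -> str:
    if raw is None:
        return "unknown"
    key = _fold(str(raw)).casefold()
    if key not in _SEX_ALIASES:
        raise ValidationError(f"unrecognised sex {raw!r}")
    return _SEX_ALIASES[key]


def normalize_region(raw: str | None) -> str | None:
    """Map a region string to its canonical spelling (exact match after folding)."""
    if raw is None:
        return None
    folded = _fold(str(raw))
    if not folded or folded.casefold() in ("na", "nan"):
        return None
    for canon in KNOWN_REGIONS:
        if _fold(canon).casefold() == folded.casefold():
            return canon
    return folded


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    s = str(value).strip()
    return s == "" or s.upper() == "NA"


def _as_float(value: Any, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(row, f"unparseable numeric cell {value!r} in column {column!r}")


def _as_int(value: Any, column: str, row: int) -> int:
    f = _as_float(value, column, row)
    if f != int(f):
        raise RowError(row, f"non-integer value {value!r} in column {column!r}")
    return int(f)


def read_sample_table(path: str | Path, dialect: str = "csv") -> SampleTable:
    """Read a sample table from CSV or TSV.

    Every row becomes an :class:`IsotopeSample`; columns outside the known
    schema are kept (when numeric) in ``covariates``. Enum-like fields are
    normalised case-insensitively ("Domestic Cat" -> domestic_cat, "F" ->
    female). A missing mandatory column raises :class:`SchemaError`; a cell
    that cannot be parsed raises :class:`RowError` with the row index.
    """
    path = Path(path)
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"{path} contains no data rows")

    extra_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    samples: list[IsotopeSample] = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        for col in MANDATORY_COLUMNS:
            if _is_missing(rec[col]):
                raise RowError(i, f"missing mandatory value in column {col!r}")
        kwargs: dict[str, Any] = {
            "sample_id": str(rec["sample_id"]).strip(),
            "taxon": normalize_taxon(str(rec["taxon"])),
            "d13C_measured": _as_float(rec["d13C_measured"], "d13C_measured", i),
            "d15N": _as_float(rec["d15N"], "d15N", i),
            "pctC": _as_float(rec["pctC"], "pctC", i),
            "pctN": _as_float(rec["pctN"], "pctN", i),
        }
        if "region" in df.columns:
            kwargs["region"] = normalize_region(rec["region"])
        if "sex" in df.columns:
            kwargs["sex"] = normalize_sex(rec["sex"]) if not _is_missing(rec["sex"]) else "unknown"
        for col, caster in (("case_study", _as_int), ("year", _as_int), ("month", _as_int)):
            if col in df.columns and not _is_missing(rec[col]):
                kwargs[col] = caster(rec[col], col, i)
        for col in ("d13C_cor", "d34S", "pctS", "weight", "body_length", "hindfoot_length"):
            if col in df.columns and not _is_missing(rec[col]):
                kwargs[col] = _as_float(rec[col], col, i)
        if "age_class" in df.columns and not _is_missing(rec["age_class"]):
            kwargs["age_class"] = str(rec["age_class"]).strip()
        cov: dict[str, float] = {}
        for col in extra_cols:
            if not _is_missing(rec[col]):
                cov[col] = _as_float(rec[col], col, i)
        kwargs["covariates"] = cov
        samples.append(IsotopeSample(**kwargs))

    table = SampleTable(samples, provenance=str(path))
    table.validate()
    return table


def write_sample_table(table: SampleTable, path: str | Path, dialect: str = "csv") -> None:
    """Write a table back to CSV/TSV with full numeric precision."""
    sep = "," if dialect == "csv" else "\t"
    df = table.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.12g", na_rep="")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(
    table: SampleTable,
    metrics: Any,
    path: str | Path,
    *,
    metadata: Mapping[str, Any] | None = None,
    timestamp: str | None = None,
) -> None:
    """Emit a CSV of tabular results plus a JSON run-metadata sidecar.

    ``metrics`` may be a DataFrame, a list of dataclasses/dicts, or empty.
    Numeric content survives a CSV round-trip to 12 significant digits.
    The JSON sidecar (``<path>.json``) records counts, metadata (config,
    seed, versions) and an optional timestamp; with a fixed timestamp two
    identical runs produce byte-identical JSON.
    """
    path = Path(path)
    if isinstance(metrics, pd.DataFrame):
        df = metrics
    elif metrics:
        rows = [dataclasses.asdict(m) if dataclasses.is_dataclass(m) else dict(m) for m in metrics]
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.12g")
    report = {
        "n_samples": len(table),
        "n_result_rows": int(len(df)),
        "provenance": table.provenance,
        "metadata": _jsonable(dict(metadata or {})),
    }
    if timestamp is not None:
        report["timestamp"] = timestamp
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def group_key(sample: IsotopeSample) -> tuple[str, str]:
    """(taxon, region) grouping key; region None maps to 'unassigned'."""
    return sample.taxon, sample.region or "unassigned"


def iter_groups(table: SampleTable) -> Iterable[tuple[tuple[str, str], list[IsotopeSample]]]:
    """Yield (taxon, region) groups in first-appearance order."""
    order: dict[tuple[str, str], list[IsotopeSample]] = {}
    for s in table:
        order.setdefault(group_key(s), []).append(s)
    return order.items()
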