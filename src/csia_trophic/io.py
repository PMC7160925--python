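"""Sample data model and delimited-text I/O.

Isotope values are δ-notation per mil (‰): δ13C relative to V-PDB, δ15N
relative to atmospheric N2. Per-amino-acid δ15N columns are named
``d15N_<AA>`` with three-letter codes (Glx, Phe, Ala, Leu, Ile, Pro, Asp);
Glx denotes the combined glutamic acid + glutamine pool as measured after
acid hydrolysis. Missing values are empty cells (or "NA") and stay absent
in memory — they are never coerced to zero. The Unicode minus "−" and
en-dash "–" are accepted as negative signs so table-derived fixtures
ingest cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    ParseError,
    ValidationError,
    VocabularyError,
)

SOURCE_AA = "Phe"
TROPHIC_AAS = ("Glx", "Ala", "Leu", "Ile", "Pro", "Asp")
AA_CODES = (SOURCE_AA,) + TROPHIC_AAS

TISSUES = ("feather", "red_blood_cells", "egg_membrane")
PERIODS = ("breeding", "moult", "historical")

# Canonical CSV column order; a user schema may remap any of these names.
_META_COLUMNS = (
    "sample_id",
    "species",
    "group",
    "tissue",
    "period",
    "collection_year",
    "replicate_id",
    "d13C_bulk",
    "d15N_bulk",
)
_AA_COLUMNS = tuple(f"d15N_{aa}" for aa in AA_CODES)
COLUMNS = _META_COLUMNS + _AA_COLUMNS

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _normalise_number(token: str) -> str:
    return token.strip().replace("−", "-").replace("–", "-")


@dataclass(frozen=True)
class AAProfile:
    """Per-sample δ15N values (‰) keyed by amino-acid code."""

    d15N_by_aa: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for code, value in dict(self.d15N_by_aa).items():
            if code not in AA_CODES:
                raise VocabularyError(
                    f"unknown amino-acid code {code!r}; expected one of {AA_CODES}"
                )
            value = float(value)
            if not math.isfinite(value):
                raise ValidationError(f"non-finite δ15N for {code}: {value!r}")
            clean[code] = value
        object.__setattr__(self, "d15N_by_aa", clean)

    def __contains__(self, code: str) -> bool:
        return code in self.d15N_by_aa

    def __getitem__(self, code: str) -> float:
        return self.d15N_by_aa[code]

    def get(self, code: str):
        return self.d15N_by_aa.get(code)

    @property
    def codes(self) -> tuple:
        return tuple(self.d15N_by_aa)


@dataclass(frozen=True)
class SampleRecord:
    """One measurement row: metadata, bulk isotopes and the amino-acid profile.

    ``replicate_id`` distinguishes duplicate CSIA measurements of the same
    physical sample (1 = first measurement).
    """

    sample_id: str
    species: str
    tissue: str
    period: str
    aa: AAProfile = field(default_factory=AAProfile)
    group: str | None = None
    collection_year: int | None = None
    d13C_bulk: float | None = None
    d15N_bulk: float | None = None
    replicate_id: int = 1

    def __post_init__(self):
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        if self.tissue not in TISSUES:
            raise VocabularyError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if self.period not in PERIODS:
            raise VocabularyError(
                f"unknown period {self.period!r}; expected one of {PERIODS}"
            )
        for name in ("d13C_bulk", "d15N_bulk"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(float(v)):
                raise ValidationError(f"non-finite {name}: {v!r}")
        if self.replicate_id < 1:
            raise ValidationError("replicate_id must be >= 1")


@dataclass(frozen=True)
class TDFConfig:
    """Constants of the trophic-position equations, all in ‰.

    beta: Glx–Phe offset in primary producers (plankton), 3.4.
    tdf_glx_phe: meta-analytic per-step Glx–Phe enrichment, 6.2.
    tdf_classic: classic per-step enrichment of the original equation, 7.6.
    tissue_tdf: extra tissue-specific discrimination subtracted in the
        multi-TDF equations (feather 3.5, red blood cells 4.0; egg
        membranes use the feather value).
    per_aa_params: (beta, tdf) per trophic amino acid for the
        multi-amino-acid estimator; only Glx ships with defaults.
    """

    beta: float = 3.4
    tdf_glx_phe: float = 6.2
    tdf_classic: float = 7.6
    tissue_tdf: Mapping[str, float] = field(
        default_factory=lambda: {
            "feather": 3.5,
            "red_blood_cells": 4.0,
            "egg_membrane": 3.5,
        }
    )
    per_aa_params: Mapping[str, tuple] = field(
        default_factory=lambda: {"Glx": (3.4, 6.2)}
    )

    def __post_init__(self):
        for name in ("beta", "tdf_glx_phe", "tdf_classic"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if self.tdf_glx_phe <= 0 or self.tdf_classic <= 0:
            raise ConfigurationError("trophic discrimination factors must be > 0")
        object.__setattr__(self, "tissue_tdf", dict(self.tissue_tdf))
        per_aa = {}
        for code, pair in dict(self.per_aa_params).items():
            if code not in TROPHIC_AAS:
                raise VocabularyError(f"per-AA constants for non-trophic code {code!r}")
            beta_aa, tdf_aa = (float(pair[0]), float(pair[1]))
            if not (math.isfinite(beta_aa) and math.isfinite(tdf_aa)) or tdf_aa <= 0:
                raise ConfigurationError(f"invalid per-AA constants for {code}: {pair!r}")
            per_aa[code] = (beta_aa, tdf_aa)
        object.__setattr__(self, "per_aa_params", per_aa)

    def tdf_for_tissue(self, tissue: str) -> float:
        try:
            return float(self.tissue_tdf[tissue])
        except KeyError:
            raise ConfigurationError(
                f"no tissue TDF configured for {tissue!r}"
            ) from None

    def with_overrides(self, **kwargs) -> "TDFConfig":
        return replace(self, **kwargs)


def load_tdf_config(path) -> TDFConfig:
    """Read a YAML file materialising a :class:`TDFConfig`.

    Recognised keys: beta, tdf_glx_phe, tdf_classic, tissue_tdf.<tissue>,
    per_aa.<AA>.beta and per_aa.<AA>.tdf. Absent keys keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("beta", "tdf_glx_phe", "tdf_classic"):
        if key in raw:
            kwargs[key] = float(raw[key])
    default = TDFConfig()
    if "tissue_tdf" in raw:
        tissue = dict(default.tissue_tdf)
        tissue.update({k: float(v) for k, v in raw["tissue_tdf"].items()})
        kwargs["tissue_tdf"] = tissue
    if "per_aa" in raw:
        per_aa = dict(default.per_aa_params)
        for code, entry in raw["per_aa"].items():
            per_aa[code] = (float(entry["beta"]), float(entry["tdf"]))
        kwargs["per_aa_params"] = per_aa
    return TDFConfig(**kwargs)


def _parse_float(token, row: int, column: str) -> float | None:
    if token is None:
        return None
    token = str(token).strip()
    if token in _MISSING_TOKENS:
        return None
    try:
        return float(_normalise_number(token))
    except ValueError:
        raise ParseError(
            f"row {row}: cannot parse {column}={token!r} as a number"
        ) from None


def _parse_int(token, row: int, column: str) -> int | None:
    value = _parse_float(token, row, column)
    if value is None:
        return None
    if value != int(value):
        raise ParseError(f"row {row}: {column}={token!r} is not an integer")
    return int(value)


def read_samples(path, schema: Mapping[str, str] | None = None) -> list:
    """Read sample records from a comma-separated UTF-8 file.

    ``schema`` maps canonical column names (see :data:`COLUMNS`) to the
    names actually present in the file. Missing cells become absent fields.
    Row order is preserved.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise OSError(f"cannot read samples file: {path}") from None
    colmap = {name: name for name in COLUMNS}
    if schema:
        colmap.update(schema)

    records = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        def cell(name):
            return row.get(colmap[name])

        aa_values = {}
        for aa in AA_CODES:
            col = colmap[f"d15N_{aa}"]
            if col in row:
                v = _parse_float(row[col], i, col)
                if v is not None:
                    aa_values[aa] = v
        tissue = (cell("tissue") or "").strip()
        period = (cell("period") or "").strip()
        group = (cell("group") or "").strip() if colmap["group"] in row else ""
        records.append(
            SampleRecord(
                sample_id=(cell("sample_id") or "").strip(),
                species=(cell("species") or "").strip(),
                group=group or None,
                tissue=tissue,
                period=period,
                collection_year=_parse_int(cell("collection_year"), i, colmap["collection_year"]),
                replicate_id=_parse_int(cell("replicate_id"), i, colmap["replicate_id"]) or 1,
                d13C_bulk=_parse_float(cell("d13C_bulk"), i, colmap["d13C_bulk"]),
                d15N_bulk=_parse_float(cell("d15N_bulk"), i, colmap["d15N_bulk"]),
                aa=AAProfile(aa_values),
            )
        )
    _check_replicates(records)
    return records


def _check_replicates(records: Sequence[SampleRecord]) -> None:
    firsts = {r.sample_id for r in records if r.replicate_id == 1}
    for r in records:
        if r.replicate_id > 1 and r.sample_id not in firsts:
            raise ValidationError(
                f"replicate {r.replicate_id} of {r.sample_id!r} has no replicate 1"
            )


def write_samples(records: Sequence[SampleRecord], path) -> Path:
    """Write records as CSV with stable column order and full float precision.

    ``read_samples`` inverts the output field-for-field (str(float) is the
    shortest round-tripping decimal representation).
    """
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "species": r.species,
            "group": r.group or "",
            "tissue": r.tissue,
            "period": r.period,
            "collection_year": "" if r.collection_year is None else r.collection_year,
            "replicate_id": r.replicate_id,
            "d13C_bulk": "" if r.d13C_bulk is None else repr(float(r.d13C_bulk)),
            "d15N_bulk": "" if r.d15N_bulk is None else repr(float(r.d15N_bulk)),
        }
        for aa in AA_CODES:
            v = r.aa.get(aa)
            row[f"d15N_{aa}"] = "" if v is None else repr(float(v))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write samples file {path}: {exc}") from None
    return path
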