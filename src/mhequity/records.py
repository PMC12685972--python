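"""Ingestion of individual-level survey records and construction of the CMHS outcome.

The unit of analysis is one woman with a recent live birth.  The binary
outcome of interest is the *complete continuum of maternal healthcare
services* (CMHS): at least four antenatal care visits (ANC4+), delivery at a
health facility, and at least one postnatal check (PNC).  A woman completes
the continuum only if she used all three services, so the outcome is the
logical AND of its components.

Input is a delimited text file with one row per woman.  Column names are
mapped explicitly through a :class:`RecordSchema`; there is no column-name
guessing, because survey extracts vary in naming.  Unparseable required
fields flag the record as missing rather than dropping it silently; missing
records are removed later, at a dedicated eligibility-filter step
(complete-case analysis).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import NoEligibleRecordsError, SchemaError, ValidationError

#: Values treated as "missing" for categorical covariates (case-insensitive).
MISSING_SENTINELS = frozenset(
    {"", ".", "na", "n/a", "nan", "none", "don't know", "dont know", "dk",
     "missing", "refused"}
)

_YES_NO = {"yes": 1.0, "y": 1.0, "no": 0.0, "n": 0.0, "true": 1.0, "false": 0.0}

#: Outcome component columns, in reporting order.
COMPONENTS = ("anc4plus", "facility_delivery", "pnc")


@dataclass(frozen=True)
class RecordSchema:
    """Explicit mapping from canonical variable names to input column names.

    ``anc_any`` (a yes/no item) and ``anc_visits`` (a visit count, eligible if
    > 0) are alternative ways to express the at-least-one-ANC-visit
    eligibility condition; if neither is mapped, all records are assumed to
    satisfy it (a pre-restricted extract).
    """

    weight: str
    anc4plus: str
    facility_delivery: str
    pnc: str
    wealth_score: str | None = None
    wealth_quintile: str | None = None
    anc_any: str | None = None
    anc_visits: str | None = None
    gave_birth: str | None = None
    de_jure: str | None = None
    id: str | None = None
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wealth_score is None and self.wealth_quintile is None:
            raise SchemaError("schema must map wealth_score or wealth_quintile")

    @property
    def anc_rule(self) -> str:
        if self.anc_any is not None:
            return "flag"
        if self.anc_visits is not None:
            return "count"
        return "assumed_present"

    def mapped_columns(self) -> dict[str, str]:
        cols = {}
        for f in dataclasses.fields(self):
            if f.name == "covariates":
                continue
            v = getattr(self, f.name)
            if v is not None:
                cols[f.name] = v
        for name, col in self.covariates.items():
            cols[name] = col
        return cols

    @classmethod
    def from_json(cls, path: str | Path) -> "RecordSchema":
        with open(path) as fh:
            raw = json.load(fh)
        cov = raw.pop("covariates", {})
        return cls(covariates=cov, **raw)


@dataclass(frozen=True)
class MaternalRecord:
    """One woman's service components, covariates, wealth and survey weight."""

    id: Any
    weight: float
    anc_any: float
    anc4plus: float
    facility_delivery: float
    pnc: float
    gave_birth: float
    de_jure: float
    has_missing: int
    wealth_score: float | None = None
    wealth_quintile: int | None = None
    covariates: dict[str, Any] = field(default_factory=dict)


@dataclass
class SurveyDataset:
    """An ordered collection of maternal records backed by a DataFrame.

    The frame holds canonical columns (``id``, ``weight``, binary service
    components, eligibility fields, ``has_missing``, and optionally
    ``wealth_score`` / ``wealth_quintile`` / ``cmhs``) plus one column per
    categorical covariate.
    """

    df: pd.DataFrame
    covariates: tuple[str, ...] = ()
    provenance: str = ""
    anc_rule: str = "flag"

    def __post_init__(self) -> None:
        w = self.df["weight"].to_numpy(float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            bad = self.df.loc[~(np.isfinite(w) & (w > 0)), "id"].tolist()
            raise ValidationError(f"non-positive or non-numeric weights for ids {bad}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_weight(self) -> float:
        return float(self.df["weight"].sum())

    @property
    def records(self) -> Iterator[MaternalRecord]:
        core = {f.name for f in dataclasses.fields(MaternalRecord)} - {"covariates"}
        for _, row in self.df.iterrows():
            kwargs = {}
            for name in core:
                if name in self.df.columns:
                    v = row[name]
                    kwargs[name] = None if pd.isna(v) else v
                elif name in ("wealth_score", "wealth_quintile"):
                    kwargs[name] = None
            kwargs["covariates"] = {c: row[c] for c in self.covariates}
            yield MaternalRecord(**kwargs)

    def with_frame(self, df: pd.DataFrame) -> "SurveyDataset":
        return SurveyDataset(df.reset_index(drop=True), self.covariates,
                             self.provenance, self.anc_rule)


@dataclass(frozen=True)
class FilterLog:
    """Per-step removal counts of the fixed eligibility-filter sequence."""

    input_count: int
    removed: dict[str, int]
    retained_count: int
    anc_rule: str

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def _parse_binary(col: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Parse a yes/no column to float {0,1}; anything else is missing.

    Returns (values with NaN for missing, missing mask).  Numeric codes other
    than 0/1 (e.g. the common 8 = don't know, 9 = no answer) are missing.
    """
    s = col.astype(str).str.strip().str.lower()
    vals = s.map(_YES_NO)
    num = pd.to_numeric(s, errors="coerce")
    num = num.where(num.isin([0.0, 1.0]))
    vals = vals.fillna(num)
    return vals.to_numpy(float), vals.isna().to_numpy()


def load_records(path: str | Path, schema: RecordSchema) -> SurveyDataset:
    """Read a CSV of individual records into a :class:`SurveyDataset`.

    Rows with unparseable required fields are flagged ``has_missing`` (they
    are removed later by the eligibility filters, not silently dropped).
    Non-positive or non-numeric survey weights are a hard error, since every
    downstream quantity is weight-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    for canonical, col in schema.mapped_columns().items():
        if col not in raw.columns:
            raise SchemaError(f"mapped column '{col}' (for '{canonical}') not in file")

    n = len(raw)
    ids = (raw[schema.id].to_numpy() if schema.id is not None
           else np.arange(n))

    w = pd.to_numeric(raw[schema.weight].str.strip(), errors="coerce").to_numpy(float)
    bad = ~np.isfinite(w) | (w <= 0)
    if bad.any():
        raise ValidationError(
            f"non-positive or non-numeric weight for row ids {list(ids[bad])}")

    missing = np.zeros(n, dtype=bool)
    out = pd.DataFrame({"id": ids, "weight": w})

    for name in COMPONENTS:
        vals, miss = _parse_binary(raw[getattr(schema, name)])
        out[name] = vals
        missing |= miss

    if schema.anc_any is not None:
        vals, miss = _parse_binary(raw[schema.anc_any])
        out["anc_any"] = vals
        missing |= miss
    elif schema.anc_visits is not None:
        cnt = pd.to_numeric(raw[schema.anc_visits].str.strip(), errors="coerce")
        out["anc_any"] = (cnt > 0).astype(float).where(cnt.notna())
        missing |= cnt.isna().to_numpy()
    else:
        out["anc_any"] = 1.0

    for name in ("gave_birth", "de_jure"):
        col = getattr(schema, name)
        if col is not None:
            vals, miss = _parse_binary(raw[col])
            out[name] = vals
            missing |= miss
        else:
            out[name] = 1.0

    if schema.wealth_score is not None:
        ws = pd.to_numeric(raw[schema.wealth_score].str.strip(), errors="coerce")
        out["wealth_score"] = ws.to_numpy(float)
        missing |= ws.isna().to_numpy()
    if schema.wealth_quintile is not None:
        wq = pd.to_numeric(raw[schema.wealth_quintile].str.strip(), errors="coerce")
        ok = wq.isin([1, 2, 3, 4, 5])
        out["wealth_quintile"] = wq.where(ok).to_numpy(float)
        if schema.wealth_score is None:
            missing |= (~ok).to_numpy()

    for name, col in schema.covariates.items():
        s = raw[col].astype(str).str.strip()
        sent = s.str.lower().isin(MISSING_SENTINELS)
        out[name] = s.where(~sent)
        missing |= sent.to_numpy()

    out["has_missing"] = missing.astype(int)
    return SurveyDataset(out, covariates=tuple(schema.covariates),
                         provenance=str(path), anc_rule=schema.anc_rule)


def apply_eligibility_filters(ds: SurveyDataset) -> tuple[SurveyDataset, FilterLog]:
    """Apply the four eligibility filters in their fixed order.

    Steps: (1) drop women with no birth before the survey, (2) drop women
    with no ANC visit, (3) drop records with missing required fields
    (complete-case), (4) drop non-de-jure residents.  Records failing an
    eligibility field that is itself missing are removed at that field's own
    step.
    """
    if len(ds) == 0:
        raise NoEligibleRecordsError("input dataset is empty")
    df = ds.df
    steps = (
        ("no_birth", df["gave_birth"] == 1),
        ("no_anc_visit", df["anc_any"] == 1),
        ("missing_data", df["has_missing"] == 0),
        ("not_de_jure", df["de_jure"] == 1),
    )
    removed: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    for name, cond in steps:
        newly_removed = int((keep & ~cond).sum())
        removed[name] = newly_removed
        keep &= cond
    retained = df.loc[keep]
    log = FilterLog(input_count=len(df), removed=removed,
                    retained_count=len(retained), anc_rule=ds.anc_rule)
    if len(retained) == 0:
        raise NoEligibleRecordsError(
            f"no eligible records after filtering (removed: {removed})")
    return ds.with_frame(retained), log


def derive_cmhs(record: MaternalRecord) -> int:
    """CMHS = ANC4+ AND facility delivery AND PNC, coded 1/0."""
    vals = (record.anc4plus, record.facility_delivery, record.pnc)
    if any(v is None or pd.isna(v) for v in vals):
        raise ValidationError(
            f"record {record.id}: outcome component missing; "
            "record should have been filtered")
    return int(all(v == 1 for v in vals))


def add_cmhs(ds: SurveyDataset) -> SurveyDataset:
    """Vectorised CMHS derivation: append a ``cmhs`` column."""
    df = ds.df
    comp = df[list(COMPONENTS)].to_numpy(float)
    if np.isnan(comp).any():
        bad = df.loc[np.isnan(comp).any(axis=1), "id"].tolist()
        raise ValidationError(f"outcome component missing for ids {bad}")
    out = df.copy()
    out["cmhs"] = (comp == 1).all(axis=1).astype(float)
    return ds.with_frame(out)


@dataclass(frozen=True)
class CoverageTable:
    """Weighted service coverage (percent) by level of a grouping variable."""

    grouping_variable: str
    table: pd.DataFrame  # index: levels + "Overall"; columns: components, cmhs, n, weight_share

    def __post_init__(self) -> None:
        pct = self.table[list(COMPONENTS) + ["cmhs"]]
        if ((pct < -1e-9) | (pct > 100 + 1e-9)).any().any():
            raise ValidationError("coverage proportions outside [0, 100]")
        # a logical-AND outcome can never exceed any of its components
        if (self.table["cmhs"] > pct[list(COMPONENTS)].min(axis=1) + 1e-9).any():
            raise ValidationError("cmhs coverage exceeds a component coverage")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label=self.grouping_variable)

    def to_dict(self) -> dict:
        return {"grouping_variable": self.grouping_variable,
                "rows": json.loads(self.table.to_json(orient="index"))}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def coverage_table(ds: SurveyDataset, grouping: str = "wealth_quintile") -> CoverageTable:
    """Weighted coverage of each service component and CMHS, by subgroup.

    Proportions are Σ w_i x_i / Σ w_i per level, reported in percent; the
    ``Overall`` row pools all records.
    """
    if "cmhs" not in ds.df.columns:
        ds = add_cmhs(ds)
    df = ds.df
    if grouping not in df.columns:
        raise SchemaError(f"unknown grouping variable '{grouping}'")
    cols = list(COMPONENTS) + ["cmhs"]
    W = df["weight"].sum()

    def _row(sub: pd.DataFrame) -> dict:
        sw = sub["weight"].to_numpy(float)
        out = {c: 100.0 * float(sw @ sub[c].to_numpy(float)) / sw.sum() for c in cols}
        out["n"] = len(sub)
        out["weight_share"] = float(sw.sum() / W)
        return out

    rows = {level: _row(sub) for level, sub in df.groupby(grouping, sort=True)}
    rows["Overall"] = _row(df)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return CoverageTable(grouping_variable=grouping, table=table)
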