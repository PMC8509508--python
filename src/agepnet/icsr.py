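"""Reading, validation and exclusion filtering of ICSR tables and ATC maps.

The input is the common pharmacovigilance extract layout: one row per
(report, drug) with per-report demographics repeated on each row, plus a
two-column drug-name -> ATC-code mapping.  The exclusion cascade mirrors
standard practice for combination analyses:

1. drop reports flagged as possible duplicates;
2. drop drug entries whose name is unknown or cannot be assigned an ATC code;
3. collapse repeated ingredients within a report to a set;
4. keep only reports with two or more distinct drugs.

Drug role (suspected / interacting / concomitant) is retained as metadata
but never used to filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    AGE_GROUPS,
    REGIONS,
    REPORTER_TYPES,
    SEX_VALUES,
    FlowCounters,
    Report,
    ReportSet,
    age_to_group,
)

logger = logging.getLogger(__name__)

#: full 7-character ATC code: letter, 2 digits, 2 letters, 2 digits
ATC_FULL_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
#: any truncated ATC level prefix (levels 1-5)
ATC_PREFIX_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


class ConfigurationError(Exception):
    """Bad dialect/config: missing columns, malformed mapping, etc."""


class DataError(Exception):
    """Structurally unusable input data."""


def normalize_name(name: str) -> str:
    """Lowercase and collapse internal whitespace of a free-text drug name."""
    return " ".join(str(name).split()).lower()


@dataclass
class TableDialect:
    """Delimited-text dialect for ICSR tables (default: tab-separated UTF-8)."""

    sep: str = "\t"
    encoding: str = "utf-8"
    columns: dict[str, str] = field(default_factory=dict)

    _DEFAULT_COLUMNS = {
        "report_id": "report_id",
        "drug_name": "drug_name",
        "role": "role",
        "age": "age",
        "sex": "sex",
        "region": "region",
        "reporter": "reporter",
        "serious": "serious",
        "death": "death",
        "duplicate": "duplicate",
    }

    def column(self, key: str) -> str:
        return self.columns.get(key, self._DEFAULT_COLUMNS[key])


class AtcMap:
    """Mapping from normalized drug name to ATC code.

    Ingredients listed under several ATC codes resolve to the
    lexicographically smallest code (deterministic; a warning is logged).
    Unmapped names are simply absent.
    """

    def __init__(self, mapping: Mapping[str, str]):
        clean: dict[str, str] = {}
        for name, code in mapping.items():
            code = str(code).strip().upper()
            if not (ATC_FULL_RE.match(code) or ATC_PREFIX_RE.match(code)):
                raise ConfigurationError(
                    f"invalid ATC code {code!r} for drug {name!r}"
                )
            clean[normalize_name(name)] = code
        self._map = clean

    @classmethod
    def from_pairs(cls, pairs) -> "AtcMap":
        """Build from (name, code) pairs, resolving multi-code ingredients."""
        by_name: dict[str, set[str]] = {}
        for name, code in pairs:
            by_name.setdefault(normalize_name(name), set()).add(
                str(code).strip().upper()
            )
        resolved: dict[str, str] = {}
        for name, codes in by_name.items():
            code = min(codes)
            if len(codes) > 1:
                logger.warning(
                    "drug %r maps to multiple ATC codes %s; using %s",
                    name, sorted(codes), code,
                )
            resolved[name] = code
        return cls(resolved)

    @classmethod
    def from_table(cls, path, sep: str = "\t") -> "AtcMap":
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] < 2:
            raise ConfigurationError(
                "ATC map must have two columns: drug name, ATC code"
            )
        return cls.from_pairs(df.iloc[:, :2].dropna().itertuples(index=False))

    def get(self, name: str) -> Optional[str]:
        return self._map.get(normalize_name(name))

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    return None


def _canonical_category(value, allowed, aliases=None) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    token = str(value).strip()
    if not token:
        return "unknown"
    lowered = token.lower()
    for cand in allowed:
        if lowered == cand.lower():
            return cand
    if aliases and lowered in aliases:
        return aliases[lowered]
    return "unknown"


def parse_icsr_table(
    source: Union[str, "pd.DataFrame"],
    dialect: Optional[TableDialect] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Parse an ICSR table into drug entries and per-report metadata.

    Parameters
    ----------
    source:
        Path to a delimited text file, or an already-loaded DataFrame in the
        same layout (one row per reported drug per report).
    dialect:
        Column names, separator and encoding; defaults to
        :class:`TableDialect` (tab-separated UTF-8).

    Returns
    -------
    entries:
        DataFrame with columns ``report_id, drug_name, role`` — whitespace
        trimmed, drug names lowercased, row order preserved.
    meta:
        One row per report id (first occurrence), with the available
        demographic columns.
    counters:
        ``{"rows": ..., "rejected_rows": ...}`` where rejected rows are
        those with an empty/missing drug name.
    """
    dialect = dialect or TableDialect()
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = pd.read_csv(source, sep=dialect.sep, encoding=dialect.encoding,
                          dtype=str)

    for key in ("report_id", "drug_name"):
        if dialect.column(key) not in raw.columns:
            raise ConfigurationError(
                f"required column {dialect.column(key)!r} (for {key}) missing"
            )

    rid_col = dialect.column("report_id")
    name_col = dialect.column("drug_name")

    names = raw[name_col].map(
        lambda v: normalize_name(v) if isinstance(v, str) or not pd.isna(v) else ""
    )
    bad = (names == "") | names.isna()
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning("skipped %d rows with empty drug names", n_rejected)
    kept = raw.loc[~bad].copy()
    kept["__drug"] = names.loc[~bad]

    role_col = dialect.column("role")
    if role_col in kept.columns:
        roles = kept[role_col].map(
            lambda v: _canonical_category(
                v, ("suspected", "interacting", "concomitant", "unknown"))
        )
    else:
        roles = pd.Series("unknown", index=kept.index)

    entries = pd.DataFrame(
        {
            "report_id": kept[rid_col].astype(str).str.strip(),
            "drug_name": kept["__drug"].astype(str),
            "role": roles.values,
        }
    ).reset_index(drop=True)

    # per-report metadata from the first occurrence of each report id
    meta_rows = []
    seen: set[str] = set()
    all_ids = raw[rid_col].astype(str).str.strip()
    for idx in raw.index:
        rid = all_ids.loc[idx]
        if rid in seen:
            continue
        seen.add(rid)
        row = raw.loc[idx]

        def col(key):
            c = dialect.column(key)
            return row[c] if c in raw.columns else None

        age_raw = col("age")
        try:
            age = float(age_raw) if age_raw not in (None, "") and not pd.isna(age_raw) else None
        except (TypeError, ValueError):
            age = None
        meta_rows.append(
            {
                "report_id": rid,
                "age": age,
                "sex": _canonical_category(col("sex"), SEX_VALUES,
                                           aliases={"f": "female", "m": "male"}),
                "region": _canonical_category(col("region"), REGIONS),
                "reporter": _canonical_category(col("reporter"), REPORTER_TYPES),
                "serious": _parse_bool(col("serious")),
                "death": _parse_bool(col("death")),
                "duplicate": bool(_parse_bool(col("duplicate")) or False),
            }
        )
    meta = pd.DataFrame(meta_rows)
    counters = {"rows": int(len(raw)), "rejected_rows": n_rejected}
    return entries, meta, counters


def assign_atc(entries: pd.DataFrame, atc_map: AtcMap) -> pd.DataFrame:
    """Attach ``atc_code`` and ``atc1`` columns; unmapped entries get None."""
    out = entries.copy()
    codes = out["drug_name"].map(atc_map.get)
    out["atc_code"] = codes
    out["atc1"] = codes.map(lambda c: c[0] if isinstance(c, str) else None)
    return out


def apply_exclusions(
    entries: pd.DataFrame,
    meta: pd.DataFrame,
    atc_map: AtcMap,
) -> ReportSet:
    """Run the inclusion cascade and return the retained cohort.

    Order: duplicate-flagged reports out first, then unmapped/unknown drug
    entries, then set-collapse of repeated ingredients, then the >=2 distinct
    drugs restriction.  Flow counters record each stage.  An empty result is
    valid (the flow records it).
    """
    meta = meta.set_index("report_id", drop=False)
    extracted_ids = list(meta.index)
    n_extracted = len(extracted_ids)

    dup_flag = meta["duplicate"].astype(bool) if "duplicate" in meta else pd.Series(False, index=meta.index)
    nondup_ids = [rid for rid in extracted_ids if not dup_flag.get(rid, False)]
    n_after_dup = len(nondup_ids)
    nondup_set = set(nondup_ids)

    mapped = assign_atc(entries, atc_map)
    mapped = mapped[mapped["report_id"].isin(nondup_set)]
    n_entries = int(len(mapped))
    unmapped = mapped["atc_code"].isna()
    n_dropped_entries = int(unmapped.sum())
    mapped = mapped[~unmapped]

    drug_sets: dict[str, set[str]] = {}
    for rid, name in zip(mapped["report_id"], mapped["drug_name"]):
        drug_sets.setdefault(rid, set()).add(name)

    with_drugs = [rid for rid in nondup_ids if drug_sets.get(rid)]
    n_after_drug_excl = len(with_drugs)
    retained_ids = [rid for rid in with_drugs if len(drug_sets[rid]) >= 2]

    atc_assignments: dict[str, str] = {}
    reports: list[Report] = []
    for rid in retained_ids:
        row = meta.loc[rid]
        age = row.get("age")
        age = None if age is None or pd.isna(age) else float(age)
        reports.append(
            Report(
                report_id=rid,
                drugs=frozenset(drug_sets[rid]),
                age_years=age,
                age_group=age_to_group(age),
                sex=row.get("sex", "unknown"),
                region=row.get("region", "unknown"),
                reporter=row.get("reporter", "unknown"),
                serious=row.get("serious"),
                death=row.get("death"),
                duplicate_flag=False,
            )
        )
        for name in drug_sets[rid]:
            atc_assignments.setdefault(name, atc_map.get(name))

    flow = FlowCounters(
        extracted=n_extracted,
        after_duplicate_removal=n_after_dup,
        after_drug_exclusions=n_after_drug_excl,
        retained=len(reports),
        entries_total=n_entries,
        entries_dropped_unmapped=n_dropped_entries,
    )
    return ReportSet(reports=reports, flow=flow, atc=atc_assignments)


def load_report_set(
    table_path,
    atc_map_path,
    dialect: Optional[TableDialect] = None,
    map_sep: str = "\t",
) -> ReportSet:
    """Convenience: parse table + map and run the exclusion cascade."""
    atc_map = AtcMap.from_table(atc_map_path, sep=map_sep)
    entries, meta, _ = parse_icsr_table(table_path, dialect)
    return apply_exclusions(entries, meta, atc_map)


def write_icsr_table(
    entries: pd.DataFrame,
    meta: pd.DataFrame,
    path,
    dialect: Optional[TableDialect] = None,
) -> None:
    """Write entries + per-report metadata back to the delimited layout."""
    dialect = dialect or TableDialect()
    merged = entries.merge(
        meta.rename(columns={"duplicate": dialect.column("duplicate")}),
        on="report_id", how="left",
    )
    rename = {
        "report_id": dialect.column("report_id"),
        "drug_name": dialect.column("drug_name"),
        "role": dialect.column("role"),
        "age": dialect.column("age"),
        "sex": dialect.column("sex"),
        "region": dialect.column("region"),
        "reporter": dialect.column("reporter"),
        "serious": dialect.column("serious"),
        "death": dialect.column("death"),
    }
    merged = merged.rename(columns=rename)
    merged.to_csv(path, sep=dialect.sep, index=False, encoding=dialect.encoding)
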