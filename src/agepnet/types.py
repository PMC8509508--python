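"""Core domain containers for spontaneous-report (ICSR) drug-combination analysis.

An *individual case safety report* (ICSR) is one spontaneous adverse-event
report: patient demographics plus the set of distinct medicinal ingredients
reported for that patient.  The analysis pipeline works on a
:class:`ReportSet` — the retained cohort after the exclusion cascade — and
keeps the cascade bookkeeping in :class:`FlowCounters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

DRUG_ROLES = ("suspected", "interacting", "concomitant", "unknown")
SEX_VALUES = ("female", "male", "unknown")
AGE_GROUPS = ("<16", "16-44", "45-64", "65-84", "85+", "unknown")
REGIONS = (
    "Europe",
    "Asia",
    "Africa",
    "North America",
    "Oceania",
    "South America",
    "unknown",
)
REPORTER_TYPES = (
    "physician",
    "other health professional",
    "nonhealth professional",
    "unknown",
)


def age_to_group(age_years: Optional[float]) -> str:
    """Map an age in years onto the standard reporting brackets."""
    if age_years is None or pd.isna(age_years):
        return "unknown"
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    if age_years < 16:
        return "<16"
    if age_years < 45:
        return "16-44"
    if age_years < 65:
        return "45-64"
    if age_years < 85:
        return "65-84"
    return "85+"


@dataclass(frozen=True)
class DrugEntry:
    """One (report, drug) row of an ICSR table, after name normalization."""

    report_id: str
    raw_name: str
    role: str = "unknown"
    atc_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.raw_name or not self.raw_name.strip():
            raise ValueError("drug name empty after whitespace normalization")
        if self.role not in DRUG_ROLES:
            raise ValueError(f"unknown drug role {self.role!r}")

    @property
    def atc1(self) -> Optional[str]:
        """Anatomical main group: the first letter of the ATC code."""
        return self.atc_code[0] if self.atc_code else None


@dataclass
class Report:
    """One ICSR: demographics plus the set of distinct reported ingredients."""

    report_id: str
    drugs: frozenset[str]
    age_years: Optional[float] = None
    age_group: str = "unknown"
    sex: str = "unknown"
    region: str = "unknown"
    reporter: str = "unknown"
    serious: Optional[bool] = None
    death: Optional[bool] = None
    duplicate_flag: bool = False

    def __post_init__(self) -> None:
        self.drugs = frozenset(self.drugs)
        if self.sex not in SEX_VALUES:
            raise ValueError(f"unknown sex value {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.age_years is not None and not pd.isna(self.age_years):
            derived = age_to_group(self.age_years)
            if self.age_group == "unknown":
                self.age_group = derived
            elif self.age_group != derived:
                raise ValueError(
                    f"age_group {self.age_group!r} inconsistent with age "
                    f"{self.age_years}"
                )

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)


@dataclass(frozen=True)
class FlowCounters:
    """Inclusion-flowchart counters for the exclusion cascade.

    Stages, in order: reports extracted, after removal of flagged
    duplicates, after dropping unknown-name / ATC-unmappable drug entries
    (reports left with at least one drug), and after restricting to
    reports with two or more distinct drugs.
    """

    extracted: int
    after_duplicate_removal: int
    after_drug_exclusions: int
    retained: int
    entries_total: int = 0
    entries_dropped_unmapped: int = 0

    def __post_init__(self) -> None:
        stages = (
            self.extracted,
            self.after_duplicate_removal,
            self.after_drug_exclusions,
            self.retained,
        )
        if any(a < b for a, b in zip(stages, stages[1:])):
            raise ValueError(f"flow counters must be non-increasing: {stages}")

    @property
    def excluded_duplicates(self) -> int:
        return self.extracted - self.after_duplicate_removal

    @property
    def excluded_no_mapped_drug(self) -> int:
        return self.after_duplicate_removal - self.after_drug_exclusions

    @property
    def excluded_single_drug(self) -> int:
        return self.after_drug_exclusions - self.retained

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("extracted", self.extracted, 0),
            ("after duplicate removal", self.after_duplicate_removal,
             self.excluded_duplicates),
            ("after drug exclusions", self.after_drug_exclusions,
             self.excluded_no_mapped_drug),
            ("retained (>=2 drugs)", self.retained, self.excluded_single_drug),
        ]
        return pd.DataFrame(rows, columns=["stage", "reports", "excluded"])


@dataclass
class ReportSet:
    """A collection of reports plus cascade provenance and ATC assignments.

    ``atc`` maps every retained ingredient name to its (possibly truncated)
    ATC code; it is the source for node colors (anatomical main group) in
    the co-reporting network.
    """

    reports: list[Report]
    flow: Optional[FlowCounters] = None
    atc: dict[str, str] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def drug_names(self) -> set[str]:
        names: set[str] = set()
        for r in self.reports:
            names.update(r.drugs)
        return names

    def atc1_of(self, drug: str) -> str:
        code = self.atc.get(drug)
        return code[0] if code else "unknown"

    def subset(self, predicate) -> "ReportSet":
        """A new ReportSet of the reports satisfying ``predicate`` (no flow)."""
        kept = [r for r in self.reports if predicate(r)]
        return ReportSet(reports=kept, flow=None, atc=dict(self.atc))


@dataclass(frozen=True)
class Partition:
    """A community assignment for a graph, with its modularity Q.

    Labels are contiguous integers from 0 in order of first appearance over
    the graph's node list.
    """

    labels: dict
    modularity: float

    def __post_init__(self) -> None:
        seen = sorted(set(self.labels.values()))
        if seen != list(range(len(seen))):
            raise ValueError(f"community labels not contiguous from 0: {seen}")

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values())) if self.labels else 0

    def communities(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_communities)]
        for node, c in self.labels.items():
            out[c].add(node)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.labels.items(), key=lambda kv: (kv[1], str(kv[0])))
        return pd.DataFrame(rows, columns=["drug", "community"])


def relabel_contiguous(labels: Mapping, order: Iterable) -> dict:
    """Relabel communities as 0,1,... in order of first appearance along ``order``."""
    remap: dict = {}
    out: dict = {}
    for node in order:
        c = labels[node]
        if c not in remap:
            remap[c] = len(remap)
        out[node] = remap[c]
    return out
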