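"""Synthetic stand-in for the published AGEP spontaneous-report cohort.

The real cohort (2649 individual case safety reports from the WHO global
pharmacovigilance database) is not publicly redistributable.  This module
builds a fully synthetic cohort of the same size that *exactly* realizes
the published count structure needed to validate the statistics pipeline:

* marginal report counts for the six drugs whose marginals are published
  (amoxicillin 573, paracetamol 397, furosemide 197, acetylsalicylic acid
  189, bisoprolol 108, ibuprofen 102);
* every published pair and triad count among those six drugs (e.g.
  paracetamol+amoxicillin in 109 reports, bisoprolol+furosemide in 44,
  ibuprofen+amoxicillin+paracetamol in 17);
* the acetylsalicylic acid + atorvastatin co-reporting edge (46 reports);
* the published demographics margins (1571 female / 1020 male / 58 unknown,
  the age-group distribution, 66 fatal outcomes of which 43 in the 65+
  group, 2179 serious of 2371 with known seriousness).

The remaining reports are filled with synthetic filler drugs so the cohort
totals N = 2649.  Exact simultaneous realization of *all* published pair
and triad counts is impossible with small reports (several published triads
overlap inside larger real-world reports), so the cohort realizes the
closed subset above; it is a validation fixture, not a reconstruction of
the real data.
"""

from __future__ import annotations

import numpy as np

from .types import FlowCounters, Report, ReportSet

N_REPORTS = 2649

ASA = "acetylsalicylic acid"

#: published marginal report counts (drug -> n of 2649)
PUBLISHED_MARGINALS: dict[str, int] = {
    "amoxicillin": 573,
    "paracetamol": 397,
    "furosemide": 197,
    ASA: 189,
    "bisoprolol": 108,
    "ibuprofen": 102,
}

#: published pair counts among the six drugs above
PUBLISHED_PAIRS: dict[frozenset, int] = {
    frozenset({"paracetamol", "amoxicillin"}): 109,
    frozenset({"amoxicillin", "furosemide"}): 57,
    frozenset({"amoxicillin", ASA}): 45,
    frozenset({"bisoprolol", "furosemide"}): 44,
    frozenset({"paracetamol", "ibuprofen"}): 41,
    frozenset({"paracetamol", "furosemide"}): 41,
    frozenset({"furosemide", ASA}): 39,
    frozenset({"amoxicillin", "ibuprofen"}): 35,
    frozenset({"paracetamol", ASA}): 34,
    frozenset({"bisoprolol", ASA}): 33,
}

#: published triad counts among the six drugs above
PUBLISHED_TRIADS: dict[frozenset, int] = {
    frozenset({"ibuprofen", "amoxicillin", "paracetamol"}): 17,
    frozenset({ASA, "furosemide", "amoxicillin"}): 15,
    frozenset({"furosemide", "bisoprolol", "amoxicillin"}): 15,
    frozenset({ASA, "amoxicillin", "paracetamol"}): 14,
    frozenset({ASA, "furosemide", "bisoprolol"}): 11,
    frozenset({ASA, "furosemide", "paracetamol"}): 10,
    frozenset({"furosemide", "amoxicillin", "paracetamol"}): 10,
}

#: thickest published cardiovascular edge (atorvastatin marginal unpublished)
EXTRA_PAIRS: dict[frozenset, int] = {
    frozenset({ASA, "atorvastatin"}): 46,
}

_ATC = {
    "amoxicillin": "J01CA04",
    "paracetamol": "N02BE01",
    "furosemide": "C03CA01",
    ASA: "B01AC06",
    "bisoprolol": "C07AB07",
    "ibuprofen": "M01AE01",
    "atorvastatin": "C10AA05",
}

_N_FILLERS = 30
_FILLER_ATC1 = "ANCJBMRHLD"

# demographics margins of the published cohort
_SEX_COUNTS = {"female": 1571, "male": 1020, "unknown": 58}
_AGE_COUNTS = {
    "<16": 114, "16-44": 542, "45-64": 723,
    "65-84": 853, "85+": 190, "unknown": 227,
}
_AGE_VALUE = {"<16": 10.0, "16-44": 30.0, "45-64": 55.0,
              "65-84": 75.0, "85+": 90.0, "unknown": None}
_REGION_COUNTS = {
    "Europe": 1585, "Asia": 619, "Africa": 26,
    "North America": 374, "Oceania": 35, "South America": 10,
}
_REPORTER_COUNTS = {
    "physician": 1739, "other health professional": 296,
    "nonhealth professional": 53, "unknown": 561,
}
_SERIOUS_COUNTS = {"yes": 2179, "no": 192, "unknown": 278}
_N_DEATHS_OLDER = 43   # fatal outcomes in the 65+ strata
_N_DEATHS_YOUNGER = 23


def _drug_blocks() -> list[frozenset]:
    """Report drug sets realizing the published counts exactly.

    Triads are emitted verbatim; each published pair is then topped up to
    its total after subtracting the triads that contain it; finally each
    marginal is topped up with (drug, dedicated filler) reports, and
    filler-filler reports pad the cohort to N.  Raises if the published
    counts were ever mutually inconsistent (negative top-up).
    """
    blocks: list[frozenset] = []
    for triad, count in PUBLISHED_TRIADS.items():
        blocks.extend([triad] * count)

    for pair, total in {**PUBLISHED_PAIRS, **EXTRA_PAIRS}.items():
        from_triads = sum(
            c for t, c in PUBLISHED_TRIADS.items() if pair <= t
        )
        top_up = total - from_triads
        if top_up < 0:
            raise ValueError(f"inconsistent counts for pair {sorted(pair)}")
        blocks.extend([pair] * top_up)

    for i, (drug, total) in enumerate(sorted(PUBLISHED_MARGINALS.items())):
        have = sum(c for b, c in _block_counter(blocks).items() if drug in b)
        top_up = total - have
        if top_up < 0:
            raise ValueError(f"inconsistent marginal for {drug}")
        partner = f"syn_partner_{i:02d}"
        blocks.extend([frozenset({drug, partner})] * top_up)

    n_fill = N_REPORTS - len(blocks)
    if n_fill < 0:
        raise ValueError("count blocks exceed cohort size")
    for j in range(n_fill):
        a = f"syn_filler_{j % _N_FILLERS:02d}"
        b = f"syn_filler_{(j + 1 + j // _N_FILLERS) % _N_FILLERS:02d}"
        if a == b:
            b = f"syn_filler_{(j + 2) % _N_FILLERS:02d}"
        blocks.append(frozenset({a, b}))
    return blocks


def _block_counter(blocks):
    from collections import Counter

    return Counter(blocks)


def _scatter(rng, counts: dict) -> list:
    """A length-N list with exact level counts, in seeded random order."""
    values: list = []
    for level, count in counts.items():
        values.extend([level] * count)
    assert len(values) == N_REPORTS
    values = np.array(values, dtype=object)
    rng.shuffle(values)
    return list(values)


def synthetic_atc_map() -> dict[str, str]:
    out = dict(_ATC)
    for i in range(len(PUBLISHED_MARGINALS)):
        out[f"syn_partner_{i:02d}"] = f"{_FILLER_ATC1[i % len(_FILLER_ATC1)]}01XX{i + 1:02d}"
    for j in range(_N_FILLERS):
        out[f"syn_filler_{j:02d}"] = f"{_FILLER_ATC1[j % len(_FILLER_ATC1)]}02XX{j + 1:02d}"
    return out


def synthetic_reference_cohort(seed: int = 0) -> ReportSet:
    """Build the deterministic synthetic cohort (N = 2649).

    ``seed`` only shuffles which demographics land on which report; every
    count the cohort is designed to realize is identical for all seeds.
    """
    rng = np.random.default_rng(seed)
    blocks = _drug_blocks()
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    sex = _scatter(rng, _SEX_COUNTS)
    age_group = _scatter(rng, _AGE_COUNTS)
    region = _scatter(rng, _REGION_COUNTS)
    reporter = _scatter(rng, _REPORTER_COUNTS)
    serious = _scatter(rng, _SERIOUS_COUNTS)

    death = [False] * N_REPORTS
    older, younger = _N_DEATHS_OLDER, _N_DEATHS_YOUNGER
    for i in range(N_REPORTS):
        if older and age_group[i] in ("65-84", "85+"):
            death[i] = True
            older -= 1
        elif younger and age_group[i] in ("<16", "16-44", "45-64"):
            death[i] = True
            younger -= 1
    if older or younger:
        raise RuntimeError("could not place all fatal outcomes")

    serious_map = {"yes": True, "no": False, "unknown": None}
    reports = []
    for i in range(N_REPORTS):
        age = _AGE_VALUE[age_group[i]]
        reports.append(
            Report(
                report_id=f"s{i:06d}",
                drugs=blocks[i],
                age_years=age,
                age_group=age_group[i],
                sex=sex[i],
                region=region[i],
                reporter=reporter[i],
                serious=serious_map[serious[i]],
                death=death[i],
            )
        )
    flow = FlowCounters(
        extracted=N_REPORTS,
        after_duplicate_removal=N_REPORTS,
        after_drug_exclusions=N_REPORTS,
        retained=N_REPORTS,
    )
    return ReportSet(reports=reports, flow=flow, atc=synthetic_atc_map())
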