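"""Shared fixtures: reference cohort, simulated cohorts, hand-built cascade."""

from __future__ import annotations

import networkx as nx
import pandas as pd
import pytest

from agepnet import (
    AtcMap,
    apply_exclusions,
    default_agep_like_config,
    parse_icsr_table,
    planted_two_profile_config,
    simulate_report_set,
    synthetic_reference_cohort,
)


@pytest.fixture(scope="session")
def reference_cohort():
    """Deterministic synthetic cohort realizing the published count structure."""
    return synthetic_reference_cohort(seed=1)


@pytest.fixture(scope="session")
def default_cohort():
    """Retained cohort from the default generator config (one fixed seed)."""
    report_set, truth = simulate_report_set(default_agep_like_config(seed=0))
    return report_set, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Two disjoint 5-drug profiles over a broad background (benchmark seed)."""
    config = planted_two_profile_config(seed=11)
    report_set, truth = simulate_report_set(config)
    return report_set, truth, config


def clique_bridge_graph() -> nx.Graph:
    """Two unit-weight 3-cliques joined by one bridge edge (max Q = 5/14)."""
    g = nx.Graph()
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
        g.add_edge(a, b, weight=1)
    return g


def two_four_cliques() -> nx.Graph:
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = 1
    return g


# --- hand-built 20-report cascade fixture ---------------------------------

CASCADE_ATC = {
    "alpha": "A01AA01",
    "beta": "B01AA01",
    "gamma": "C01AA01",
    "delta": "D01AA01",
    "epsilon": "J01AA01",
    "zeta": "N01AA01",
}

#: report id -> (drug rows, duplicate flag); "mystery*" names are unmappable
CASCADE_REPORTS = {
    "r01": (["alpha", "beta"], False),
    "r02": (["alpha", "beta", "gamma"], False),
    "r03": (["alpha", "beta"], True),            # flagged duplicate
    "r04": (["alpha"], False),                   # single drug
    "r05": (["alpha", "mystery1"], False),       # 1 mapped drug after drop
    "r06": (["mystery2"], False),                # 0 mapped drugs
    "r07": (["alpha", "alpha", "beta"], False),  # repeated ingredient rows
    "r08": (["gamma", "delta"], False),
    "r09": (["epsilon", "zeta"], False),
    "r10": (["gamma", "delta"], True),           # flagged duplicate
    "r11": (["beta", "mystery3", "gamma"], False),
    "r12": (["zeta"], False),                    # single drug
    "r13": (["delta", "epsilon", "zeta"], False),
    "r14": (["mystery4", "mystery5"], False),    # 0 mapped drugs
    "r15": (["alpha", "gamma"], False),
    "r16": (["beta", "delta"], False),
    "r17": (["gamma"], False),                   # single drug
    "r18": (["epsilon", "mystery6"], False),     # 1 mapped drug after drop
    "r19": (["alpha", "beta", "gamma", "delta"], False),
    "r20": (["alpha"], True),                    # flagged duplicate
}

#: hand-derived expectations for the cascade fixture
CASCADE_EXPECTED_FLOW = {
    "extracted": 20,
    "after_duplicate_removal": 17,
    "after_drug_exclusions": 15,
    "retained": 10,
}
CASCADE_RETAINED = {
    "r01": {"alpha", "beta"},
    "r02": {"alpha", "beta", "gamma"},
    "r07": {"alpha", "beta"},
    "r08": {"gamma", "delta"},
    "r09": {"epsilon", "zeta"},
    "r11": {"beta", "gamma"},
    "r13": {"delta", "epsilon", "zeta"},
    "r15": {"alpha", "gamma"},
    "r16": {"beta", "delta"},
    "r19": {"alpha", "beta", "gamma", "delta"},
}


def cascade_table() -> pd.DataFrame:
    rows = []
    for rid, (drugs, dup) in CASCADE_REPORTS.items():
        for d in drugs:
            rows.append(
                {"report_id": rid, "drug_name": d, "role": "suspected",
                 "sex": "female", "age": 50, "duplicate": dup}
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def cascade_report_set():
    entries, meta, _ = parse_icsr_table(cascade_table())
    return apply_exclusions(entries, meta, AtcMap(CASCADE_ATC))
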