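"""Synthetic-report generator: determinism, planted structure, calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from agepnet import (
    SimConfig,
    TherapyProfile,
    count_ksets,
    default_agep_like_config,
    generate_reports,
    simulate_report_set,
)
from agepnet.simulate import NoiseConfig, expected_marginal_rates
from agepnet.types import ReportSet


def _tiny_universe():
    return [("a", "A01AA01"), ("b", "B01AA01"), ("c", "C01AA01"),
            ("d", "D01AA01")]


def test_same_config_same_seed_is_byte_identical(tmp_path):
    config = default_agep_like_config(n_reports=300, seed=42)
    paths = []
    for tag in ("x", "y"):
        entries, meta, _ = generate_reports(config)
        p = tmp_path / f"{tag}.tsv"
        entries.merge(meta, on="report_id").to_csv(p, sep="\t", index=False)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_degenerate_profile_yields_constant_drug_set():
    config = SimConfig(
        n_reports=50,
        drug_universe=_tiny_universe(),
        profiles=[TherapyProfile("only", ["a", "b"], [1.0, 1.0], 1.0)],
        seed=3,
    )
    entries, _, _ = generate_reports(config)
    sets = entries.groupby("report_id")["drug_name"].apply(set)
    assert all(s == {"a", "b"} for s in sets)


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError):
        TherapyProfile("bad", ["a"], [1.5], 0.5)
    with pytest.raises(ValueError):
        SimConfig(n_reports=0, drug_universe=_tiny_universe(), profiles=[])
    with pytest.raises(ValueError):
        SimConfig(n_reports=10, drug_universe=_tiny_universe(), profiles=[],
                  background_rates={"a": 2.0})
    with pytest.raises(ValueError):
        NoiseConfig(duplicate_fraction=-0.1)


def test_default_cohort_matches_published_margins(default_cohort):
    """Retained cohort: median 3 (IQR 2-5) drugs, 59.3% female, 2.5% fatal."""
    report_set, _ = default_cohort
    counts = np.array([r.n_drugs for r in report_set.reports])
    assert np.median(counts) == 3
    assert tuple(np.percentile(counts, [25, 75])) == (2.0, 5.0)

    sex = np.array([r.sex for r in report_set.reports])
    assert abs((sex == "female").mean() - 0.593) < 0.02

    death = np.array([bool(r.death) for r in report_set.reports])
    assert abs(death.mean() - 0.025) < 0.01

    ages = np.array([r.age_years for r in report_set.reports
                     if r.age_years is not None])
    assert 54 < ages.mean() < 60

    serious = [r.serious for r in report_set.reports if r.serious is not None]
    assert abs(np.mean(serious) - 0.919) < 0.02


def test_default_cohort_mirrors_extraction_cascade(default_cohort):
    """~5983 extracted reports filter down to about 2649 retained."""
    report_set, _ = default_cohort
    assert report_set.flow.extracted == 5983
    assert abs(report_set.n_reports - 2649) / 2649 < 0.05
    # cascade stages all active: duplicates, unmapped names, single-drug
    assert report_set.flow.excluded_duplicates > 0
    assert report_set.flow.excluded_no_mapped_drug > 0
    assert report_set.flow.excluded_single_drug > 0


def test_marginal_prevalence_converges_to_analytic_rate():
    """Profile-drug marginals converge to activation x inclusion at large n."""
    config = SimConfig(
        n_reports=50_000,
        drug_universe=_tiny_universe(),
        profiles=[
            TherapyProfile("p1", ["a", "b"], [0.7, 0.4], 0.6),
            TherapyProfile("p2", ["c", "d"], [0.5, 0.9], 0.5),
        ],
        seed=7,
    )
    entries, meta, _ = generate_reports(config)
    n = meta.shape[0]
    rates = expected_marginal_rates(config)
    # unconditional cohort (no >=2 filter) so the analytic rate applies;
    # the empty-set redraw is rare here (<0.1%) and within the tolerance
    observed = entries.groupby("drug_name")["report_id"].nunique() / n
    for drug in ("a", "b", "c", "d"):
        p = rates[drug]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed[drug] - p) < 3 * se + 1e-3


def test_disjoint_profiles_without_background_share_no_cross_pairs():
    """Reports activating exactly one profile never mix profile drugs."""
    config = SimConfig(
        n_reports=4000,
        drug_universe=_tiny_universe(),
        profiles=[
            TherapyProfile("p1", ["a", "b"], [0.9, 0.9], 0.5),
            TherapyProfile("p2", ["c", "d"], [0.9, 0.9], 0.5),
        ],
        seed=9,
    )
    entries, meta, truth = generate_reports(config)
    single_profile = {
        rid for rid, profs in truth.report_profiles.items() if len(profs) == 1
    }
    sets = entries.groupby("report_id")["drug_name"].apply(set)
    for rid in single_profile:
        drugs = sets.get(rid, set())
        assert not ({"a", "b"} & drugs and {"c", "d"} & drugs)


def test_filters_recover_noise_free_cohort():
    """Honoring duplicate flags/unmappable names recovers the clean cohort."""
    from agepnet import AtcMap, apply_exclusions, parse_icsr_table

    config = default_agep_like_config(n_reports=500, seed=21)
    config.noise = NoiseConfig(duplicate_fraction=0.1,
                               unknown_name_fraction=0.05)
    entries, meta, _ = generate_reports(config)

    # hand-cleaned version: drop flagged duplicates and mangled names
    clean_meta = meta[~meta["duplicate"]].copy()
    clean_entries = entries[
        entries["report_id"].isin(clean_meta["report_id"])
        & ~entries["drug_name"].str.startswith("illegible")
    ]
    amap = config.atc_map()
    e1, m1, _ = parse_icsr_table(entries.merge(meta, on="report_id"))
    noisy_rs = apply_exclusions(e1, m1, amap)
    e2, m2, _ = parse_icsr_table(clean_entries.merge(clean_meta, on="report_id"))
    clean_rs = apply_exclusions(e2, m2, amap)

    assert {r.report_id: r.drugs for r in noisy_rs.reports} == \
        {r.report_id: r.drugs for r in clean_rs.reports}
    assert not any(r.report_id.startswith("dup") for r in noisy_rs.reports)


def test_background_scale_bisection_moves_median_to_target():
    from agepnet.simulate import calibrate_background_scale

    config = default_agep_like_config(n_reports=2000, seed=13)
    mult = calibrate_background_scale(
        config, target_median=4.0, n_sim=4000, seed=99, iterations=8)
    assert mult > 1.0  # more background drugs needed to push the median up

    from dataclasses import replace

    scaled = replace(
        config,
        background_rates={k: min(1.0, v * mult)
                          for k, v in config.background_rates.items()},
        noise=NoiseConfig(), seed=99,
    )
    rs, _ = simulate_report_set(scaled)
    counts = np.array([r.n_drugs for r in rs.reports])
    assert abs(np.median(counts) - 4.0) <= 1.0


def test_planted_cohort_pair_structure(planted_cohort):
    """Within-profile pairs dominate cross-profile pairs in raw counts."""
    report_set, truth, _ = planted_cohort
    pairs = count_ksets(report_set, 2)
    alpha = [d for d, lbl in truth.drug_labels.items() if lbl == "alpha"]
    beta = [d for d, lbl in truth.drug_labels.items() if lbl == "beta"]
    within = [pairs[frozenset({a, b})] for i, a in enumerate(alpha)
              for b in alpha[i + 1:]]
    cross = [pairs[frozenset({a, b})] for a in alpha for b in beta]
    assert min(within) > max(cross)
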