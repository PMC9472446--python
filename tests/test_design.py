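"""Candidate filtering, community assembly, inoculum plan and depletion."""

import numpy as np
import pandas as pd
import pytest

from fermentome import datasets
from fermentome.design import (
    assemble_community,
    compare_communities,
    deplete,
    depletion_series,
    inoculum_plan,
    member_role,
    select_candidates,
)
from fermentome.errors import ConfigurationError, DesignError, ValidationError
from fermentome.model import (
    CommunityDesign,
    CommunityMember,
    DesignThresholds,
    GeneContentMatrix,
    PathwayMap,
)
from fermentome.simulate import SimulationSpec, gen_candidates


def _gene_content_for(taxon_functions, samples=("S1",), tpm=1.0):
    rows = []
    for taxon, fns in taxon_functions.items():
        for s in samples:
            for fn in fns:
                rows.append((taxon, s, fn, 1, tpm, "none"))
    return GeneContentMatrix(
        pd.DataFrame(
            rows,
            columns=["taxon", "sample", "function_id", "copy_number", "tpm", "phase"],
        )
    )


def _key_map(n=25):
    fns = [f"EC:1.1.1.{i}" for i in range(n)]
    return (
        PathwayMap(
            pd.DataFrame(
                {
                    "pathway": ["p"] * n,
                    "mega_pathway": ["carbohydrate"] * n,
                    "function_id": fns,
                    "is_key": [True] * n,
                }
            )
        ),
        fns,
    )


def test_candidate_filter_boundaries():
    pm, fns = _key_map(25)
    gene = _gene_content_for(
        {"pass_exact": fns[:20], "fail_keys": fns[:19], "pass_easy": fns}
    )
    prevalence = {"pass_exact": 0.5, "fail_keys": 1.0, "pass_easy": 0.4}
    out = select_candidates(gene, pm, prevalence)
    # 20 key genes at 4/8 prevalence: both boundaries inclusive
    assert out.loc["pass_exact", "selected"]
    # 19 key genes rejected even at full prevalence
    assert not out.loc["fail_keys", "selected"]
    # 25 key genes but 0.4 prevalence rejected
    assert not out.loc["pass_easy", "selected"]
    assert out.loc["fail_keys", "key_gene_count"] == 19


def test_candidate_filter_needs_key_flags():
    pm, fns = _key_map(5)
    pm = PathwayMap(pm.df.assign(is_key=False))
    gene = _gene_content_for({"t": fns})
    with pytest.raises(ConfigurationError):
        select_candidates(gene, pm, {"t": 1.0})


def test_candidate_filter_monotone_in_thresholds():
    spec = SimulationSpec(seed=3)
    gene, pm, prevalence, _ = gen_candidates(spec)
    base = select_candidates(gene, pm, prevalence)
    sel_base = set(base.index[base["selected"]])
    for thr in (
        DesignThresholds(min_key_genes=25),
        DesignThresholds(min_prevalence=0.75),
    ):
        harder = select_candidates(gene, pm, prevalence, thr)
        assert set(harder.index[harder["selected"]]) <= sel_base


def test_planted_13_of_49_recovered():
    gene, pm, prevalence, qualifiers = gen_candidates(SimulationSpec(seed=11))
    out = select_candidates(gene, pm, prevalence)
    assert set(out.index[out["selected"]]) == set(qualifiers)
    assert len(qualifiers) == 13 and len(out) == 49


def test_full_roster_assembly_reproduces_sd43():
    survey, _ = datasets.load_culturomics_survey()
    labels = pd.DataFrame(
        {
            "guild": survey.df.drop_duplicates("taxon").set_index("taxon")["guild"],
        }
    )
    labels["label"] = [
        "satellite" if g == "other_bacterium" else "core-subdominant"
        for g in labels["guild"]
    ]
    smc = assemble_community(None, labels, survey, "SD43", name="SMC-SD43")
    assert len(smc) == 9
    assert set(smc.taxa) == set(
        datasets.load_smc_compositions()["SMC-SD43"].taxa
    )


def test_quota_assembly_reproduces_sdg_size():
    sdg = datasets.load_smc_compositions()["SDG"]
    labels = pd.DataFrame(
        {
            "guild": {m.taxon: m.guild for m in sdg.members},
            "label": {m.taxon: m.group_label for m in sdg.members},
        }
    )
    cult = pd.DataFrame(
        {
            "sample": "SD104",
            "taxon": [m.taxon for m in sdg.members],
            "guild": [m.guild for m in sdg.members],
            "isolate_count": 1,
            "cell_density": [m.density for m in sdg.members],
        }
    )
    from fermentome.model import CulturomicsTable

    community = assemble_community(
        list(sdg.taxa),
        labels,
        CulturomicsTable(cult),
        "SD104",
        quotas={"dominant_lab": 2, "subdominant_lab": 2, "satellite": 1, "yeast": 2},
        name="SDG",
    )
    assert len(community) == 7
    assert sorted(community.taxa) == sorted(sdg.taxa)


def test_empty_candidate_list_is_design_error(tiny_culturomics):
    labels = pd.DataFrame({"guild": ["LAB"], "label": ["core-dominant"]}, index=["T1"])
    with pytest.raises(DesignError):
        assemble_community([], labels, tiny_culturomics, "S1", quotas={"yeast": 1})


def test_unfillable_quota_names_the_group(tiny_culturomics):
    labels = pd.DataFrame(
        {"guild": ["LAB"], "label": ["core-dominant"]}, index=["T1"]
    )
    with pytest.raises(DesignError, match="yeast"):
        assemble_community(
            ["T1"], labels, tiny_culturomics, "S1", quotas={"yeast": 1}
        )


def test_inoculum_plan_follows_group_rules():
    members = (
        CommunityMember("dom_lab", "LAB", "core-dominant", 9.0),
        CommunityMember("sub_lab", "LAB", "core-subdominant", 3.0),
        CommunityMember("disp_dom_lab", "LAB", "dispensable-dominant", 7.0),
        CommunityMember("sat", "other_bacterium", "satellite", 2.0),
        CommunityMember("yeast_dom", "yeast", "core-dominant", 6.0),
        CommunityMember("yeast_disp", "yeast", "dispensable-dominant", 5.9),
    )
    plan = inoculum_plan(CommunityDesign(name="x", members=members))
    assert plan["dom_lab"] == 7.0
    assert plan["disp_dom_lab"] == 7.0
    assert plan["sub_lab"] == 5.0
    assert plan["sat"] == 5.0
    assert plan["yeast_dom"] == 6.0 and plan["yeast_disp"] == 6.0


def test_member_role_mapping():
    assert member_role("LAB", "core-dominant") == "dominant_lab"
    assert member_role("LAB", "dispensable-subdominant") == "subdominant_lab"
    assert member_role("yeast", "core-dominant") == "yeast"
    assert member_role("other_bacterium", "satellite") == "satellite"


def test_deplete_sole_contributor(tiny_gene_content):
    report = deplete(["T1", "T2", "T3"], "T1", tiny_gene_content)
    assert "fB" in report.lost  # T1 is the only encoder of fB
    assert report.covered_after == report.covered_before - report.lost


def test_deplete_redundant_member_loses_nothing(tiny_gene_content):
    # every function T2 encodes (fA, fC) has another contributor
    report = deplete(["T1", "T2", "T3"], "T2", tiny_gene_content)
    assert report.lost == frozenset()


def test_deplete_unknown_member(tiny_gene_content):
    with pytest.raises(KeyError):
        deplete(["T1"], "T9", tiny_gene_content)


def test_expressed_switch_restricts_to_transcribed(tiny_gene_content):
    # fC is encoded by T2 and T3 but transcribed only by T3
    report = deplete(["T2", "T3"], "T3", tiny_gene_content, expressed=True)
    assert "fC" in report.lost


def _random_instance(rng, n_taxa=5, n_functions=10):
    taxa = [f"T{i}" for i in range(n_taxa)]
    tf = {
        t: {f"f{j}" for j in range(n_functions) if rng.random() < 0.4} for t in taxa
    }
    tf = {t: fns for t, fns in tf.items() if fns}
    if len(tf) < 2:
        tf = {"T0": {"f0"}, "T1": {"f1"}}
    return tf


def test_depletion_matches_brute_force_oracle(rng):
    """Lost sets equal a from-scratch coverage difference on random instances."""
    for _ in range(200):
        tf = _random_instance(rng)
        gene = _gene_content_for(tf)
        taxa = sorted(tf)
        baseline, reports = depletion_series(taxa, gene)
        assert baseline == frozenset().union(*tf.values())
        for r in reports:
            brute_after = set().union(
                *(tf[t] for t in taxa if t != r.removed)
            ) if len(taxa) > 1 else set()
            assert set(r.covered_after) == brute_after
            assert set(r.lost) == set(baseline) - brute_after
            # set identity: coverage = coverage-without-m union contributions(m)
            assert baseline == r.covered_after | frozenset(tf[r.removed])


def test_depletion_series_count_and_identity(tiny_gene_content):
    baseline, reports = depletion_series(["T1", "T2", "T3"], tiny_gene_content)
    assert len(reports) == 3
    for r in reports:
        assert r.covered_before == baseline


def test_identical_members_lose_nothing():
    gene = _gene_content_for({"A": {"f1", "f2"}, "B": {"f1", "f2"}})
    _, reports = depletion_series(["A", "B"], gene)
    assert all(r.lost == frozenset() for r in reports)


def test_compare_communities_planted_ratio():
    # A transcribes 8 functions, B the 2-function subset: ratio 4 recovered
    fns = [f"f{i}" for i in range(8)]
    gene = _gene_content_for({"a1": fns[:4], "a2": fns[4:], "b1": fns[:2]})
    out = compare_communities(["a1", "a2"], ["b1"], gene)
    assert out.loc["all", "functions_a"] == 8
    assert out.loc["all", "functions_b"] == 2
    assert out.loc["all", "function_ratio"] == pytest.approx(4.0)


def test_compare_identical_communities_ratio_one(tiny_gene_content):
    out = compare_communities(["T1", "T3"], ["T1", "T3"], tiny_gene_content)
    assert out.loc["all", "function_ratio"] == pytest.approx(1.0)
    assert out.loc["all", "copy_ratio"] == pytest.approx(1.0)


def test_compare_empty_community_b(tiny_gene_content):
    out = compare_communities(["T1"], [], tiny_gene_content)
    assert out.loc["all", "functions_b"] == 0
    assert np.isinf(out.loc["all", "function_ratio"])
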