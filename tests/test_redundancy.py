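"""Function partitions, contribution matrices and differential count tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fermentome.errors import ValidationError
from fermentome.model import GeneContentMatrix, PathwayMap
from fermentome.redundancy import (
    bh_adjust,
    contribution_matrix,
    g_test_functions,
    partition_functions,
    pathway_copy_number,
    redundancy_profile,
)


def _random_gene_content(rng, n_taxa=4, n_samples=4, n_functions=12):
    rows = []
    for f in range(n_functions):
        for s in range(n_samples):
            for t in range(n_taxa):
                if rng.random() < 0.3:
                    rows.append(
                        (
                            f"T{t}",
                            f"S{s}",
                            f"f{f:02d}",
                            int(rng.integers(1, 5)),
                            float(rng.choice([0.0, 2.0])),
                            "none",
                        )
                    )
    if not rows:
        rows.append(("T0", "S0", "f00", 1, 0.0, "none"))
        rows.append(("T0", "S1", "f01", 1, 0.0, "none"))
    return GeneContentMatrix(
        pd.DataFrame(
            rows,
            columns=["taxon", "sample", "function_id", "copy_number", "tpm", "phase"],
        )
    )


def _brute_force_partition(gene):
    by_fn = {}
    samples = set(gene.df["sample"])
    for _, r in gene.df.iterrows():
        by_fn.setdefault(r["function_id"], set()).add(r["sample"])
    core = {f for f, s in by_fn.items() if s == samples}
    unique = {f for f, s in by_fn.items() if len(s) == 1}
    accessory = set(by_fn) - core - unique
    return core, unique, accessory


def test_partition_recovers_planted_and_matches_brute_force(tiny_gene_content):
    part = partition_functions(tiny_gene_content)
    assert part.core == {"fA", "fD"}
    assert part.unique["S1"] == {"fB"}
    assert part.unique["S2"] == {"fC"}
    assert part.accessory == frozenset()


def test_partition_is_disjoint_and_exhaustive(rng):
    for _ in range(20):
        gene = _random_gene_content(rng)
        part = partition_functions(gene)
        core, unique, accessory = _brute_force_partition(gene)
        assert set(part.core) == core
        assert set().union(*part.unique.values()) == unique
        assert set(part.accessory) == accessory
        all_unique = set().union(*part.unique.values())
        assert part.core | all_unique | part.accessory == part.universe
        assert not (part.core & all_unique)
        assert not (part.core & part.accessory)
        assert not (all_unique & part.accessory)


def test_adding_a_sample_never_grows_the_core(rng):
    for _ in range(10):
        gene = _random_gene_content(rng, n_samples=5)
        samples = sorted(set(gene.df["sample"]))
        for k in range(2, len(samples)):
            small = partition_functions(gene, samples[:k])
            big = partition_functions(gene, samples[: k + 1])
            assert big.core <= small.core


def test_single_sample_partition_rejected(tiny_gene_content):
    with pytest.raises(ValidationError):
        partition_functions(tiny_gene_content, ["S1"])


def test_pathway_copy_number_sums(tiny_gene_content, tiny_pathways):
    copies = pathway_copy_number(tiny_gene_content, tiny_pathways, "S1")
    # glycolysis = fA(2+1) + fB(3) + fD(1) = 7; proteolysis = fC absent in S1
    assert copies["glycolysis"] == 7
    assert copies["proteolysis"] == 0


def test_pathway_copy_number_matches_double_loop(rng):
    gene = _random_gene_content(rng)
    fns = sorted(set(gene.df["function_id"]))
    pm = PathwayMap(
        pd.DataFrame(
            {
                "pathway": ["p1" if f < "f06" else "p2" for f in fns],
                "mega_pathway": ["carbohydrate"] * len(fns),
                "function_id": fns,
                "is_key": [False] * len(fns),
            }
        )
    )
    for sample in sorted(set(gene.df["sample"])):
        got = pathway_copy_number(gene, pm, sample)
        for pathway in ("p1", "p2"):
            members = set(pm.df.loc[pm.df["pathway"] == pathway, "function_id"])
            brute = sum(
                r["copy_number"]
                for _, r in gene.df.iterrows()
                if r["sample"] == sample and r["function_id"] in members
            )
            assert got[pathway] == brute


def test_contribution_matrix_flags(tiny_gene_content, tiny_pathways):
    contrib = contribution_matrix(tiny_gene_content, tiny_pathways, "glycolysis")
    assert contrib.encoded.loc["fA", "T1"] and contrib.expressed.loc["fA", "T1"]
    # copy present, never transcribed -> encoded, not expressed
    assert contrib.encoded.loc["fA", "T2"] and not contrib.expressed.loc["fA", "T2"]
    # taxon absent from the pathway -> all-false row entries
    assert not contrib.encoded.loc["fB", "T3"]
    # expressed implies encoded everywhere
    assert not (contrib.expressed & ~contrib.encoded).any().any()
    # pathway-core split: fA,fD in both samples; fB only S1
    assert contrib.core_functions == {"fA", "fD"}
    assert contrib.accessory_functions == {"fB"}


def test_unique_contributor_is_detectable(tiny_gene_content, tiny_pathways):
    contrib = contribution_matrix(tiny_gene_content, tiny_pathways, "glycolysis")
    encoders = contrib.encoded.loc["fB"]
    assert list(encoders[encoders].index) == ["T1"]


def test_unknown_pathway_raises(tiny_gene_content, tiny_pathways):
    with pytest.raises(KeyError):
        contribution_matrix(tiny_gene_content, tiny_pathways, "nope")


def test_redundancy_profile_counts_and_monotonicity(tiny_gene_content, tiny_pathways):
    contrib = contribution_matrix(tiny_gene_content, tiny_pathways, "glycolysis")
    full = redundancy_profile(contrib, ["T1", "T2", "T3"])
    assert full.multiplicity["fA"] == 2
    sub = redundancy_profile(contrib, ["T2"])
    assert sub.coverage <= full.coverage
    empty = redundancy_profile(contrib, [])
    assert (empty.multiplicity == 0).all()
    # brute force multiplicity check
    for fn in contrib.encoded.index:
        brute = sum(bool(contrib.encoded.loc[fn, t]) for t in ["T1", "T2", "T3"])
        assert full.multiplicity[fn] == brute


def _bh_brute(p):
    """Textbook step-up: q_(i) = min over j>=i of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


def test_bh_single_and_hand_example():
    assert bh_adjust([0.04]) == pytest.approx([0.04])
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert len(bh_adjust([])) == 0


@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
)
def test_bh_matches_brute_force_definition(p):
    got = bh_adjust(p)
    want = _bh_brute(p)
    assert np.allclose(got, want)
    assert (got >= np.asarray(p) - 1e-12).all()


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration."""
    n = a + b + c + d
    row = a + b
    col = a + c
    rv = stats.hypergeom(n, row, col)
    p_obs = rv.pmf(a)
    support = range(max(0, row + col - n), min(row, col) + 1)
    return sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9))


def test_fisher_fallback_matches_enumeration():
    # expected cell (3+4)/2 = 3.5 < 5 -> Fisher branch
    out = g_test_functions(
        pd.Series({"f": 3}), pd.Series({"f": 4}), total_a=100, total_b=100
    )
    assert out.loc["f", "test"] == "fisher"
    want = _fisher_enumeration(3, 97, 4, 96)
    assert out.loc["f", "p"] == pytest.approx(want, rel=1e-9)


def test_g_test_matches_hand_computation():
    # expected cells all >= 5 -> Yates-corrected G branch
    a, b, total = 30, 60, 200
    out = g_test_functions(
        pd.Series({"f": a}), pd.Series({"f": b}), total_a=total, total_b=total
    )
    assert out.loc["f", "test"] == "g"
    table = np.array([[a, total - a], [b, total - b]], float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    adj = table + np.where(np.abs(table - expected) > 0.5, 0.5 * np.sign(expected - table), expected - table)
    g_hand = 2 * np.sum(adj * np.log(adj / expected))
    assert out.loc["f", "G"] == pytest.approx(g_hand, rel=1e-9)
    assert out.loc["f", "p"] == pytest.approx(stats.chi2.sf(g_hand, 1), rel=1e-9)


def test_identical_proportions_not_significant():
    out = g_test_functions(
        pd.Series({"f": 50, "g": 0}), pd.Series({"f": 50, "g": 0}), 100, 100
    )
    assert (out["p"] == 1.0).all()
    assert not out["significant"].any()


def test_g_and_fisher_agree_for_large_balanced_tables():
    a, b, total = 400, 500, 2000
    table = np.array([[a, total - a], [b, total - b]])
    _, p_fisher = stats.fisher_exact(table)
    g, p_g, _, _ = stats.chi2_contingency(
        table, correction=True, lambda_="log-likelihood"
    )
    assert p_g == pytest.approx(p_fisher, rel=0.10)


def test_zero_total_rejected():
    with pytest.raises(ValidationError):
        g_test_functions(pd.Series({"f": 1}), pd.Series({"f": 1}), 0, 10)
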