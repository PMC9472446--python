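"""Functional-redundancy accounting over KEGG/EC function matrices.

Partitions the observed function universe into core (all samples), unique
(exactly one sample) and accessory (the remainder); builds per-pathway
contribution matrices (which taxon encodes / transcribes which function);
and tests per-function count differences between two samples with a
G-test (Yates-corrected, Fisher fallback) under Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .model import GeneContentMatrix, PathwayMap


@dataclass(frozen=True)
class FunctionPartition:
    """Core / per-sample-unique / accessory split of the function universe."""

    core: frozenset[str]
    unique: dict[str, frozenset[str]]  # sample -> functions found only there
    accessory: frozenset[str]

    @property
    def universe(self) -> frozenset[str]:
        u: frozenset[str] = self.core | self.accessory
        for s in self.unique.values():
            u = u | s
        return u

    def counts(self) -> dict[str, int]:
        out = {"core": len(self.core), "accessory": len(self.accessory)}
        out.update({f"unique:{s}": len(v) for s, v in sorted(self.unique.items())})
        return out


def partition_functions(
    gene_content: GeneContentMatrix, samples: Optional[Sequence[str]] = None
) -> FunctionPartition:
    """Split observed functions by how many samples encode them.

    core = present in every sample; unique = present in exactly one;
    accessory = everything else in the union.  Requires >= 2 samples.
    """
    presence = gene_content.presence_by_sample()
    if samples is not None:
        keep = [s for s in samples if s in presence.columns]
        presence = presence[keep]
    n = presence.shape[1]
    if n < 2:
        raise ValidationError("core/unique partition needs at least 2 samples")
    n_present = presence.sum(axis=1)
    observed = presence.index[n_present > 0]
    core = frozenset(presence.index[n_present == n])
    unique: dict[str, frozenset[str]] = {}
    singletons = presence.loc[n_present == 1]
    for sample in presence.columns:
        unique[sample] = frozenset(singletons.index[singletons[sample]])
    in_unique = frozenset().union(*unique.values()) if unique else frozenset()
    accessory = frozenset(observed) - core - in_unique
    return FunctionPartition(core=core, unique=unique, accessory=accessory)


def pathway_copy_number(
    gene_content: GeneContentMatrix, pathway_map: PathwayMap, sample: str
) -> pd.Series:
    """Total gene copies per pathway in one sample, summed over taxa.

    Pathway member functions never observed in the gene content warn but do
    not fail; a pathway with no observed members scores 0.
    """
    known = set(gene_content.df["function_id"].unique())
    unknown = set(pathway_map.df["function_id"]) - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} pathway function id(s) absent from gene content",
            stacklevel=2,
        )
    sub = gene_content.df[gene_content.df["sample"] == sample]
    per_function = sub.groupby("function_id")["copy_number"].sum()
    out = {}
    for pathway, grp in pathway_map.df.groupby("pathway"):
        fns = grp["function_id"].unique()
        if len(fns) == 0:
            warnings.warn(f"pathway {pathway!r} has no member functions", stacklevel=2)
        out[pathway] = int(per_function.reindex(fns).fillna(0).sum())
    return pd.Series(out, name=sample).sort_index()


@dataclass(frozen=True)
class ContributionMatrix:
    """Per-(function, taxon) encoded/expressed flags for one pathway.

    ``encoded``/``expressed`` are boolean function x taxon frames;
    ``core_functions`` are the pathway members encoded in every sample (by
    any taxon), the rest of the observed members are pathway-accessory.
    """

    pathway: str
    encoded: pd.DataFrame
    expressed: pd.DataFrame
    core_functions: frozenset[str]
    accessory_functions: frozenset[str]

    def __post_init__(self) -> None:
        if (self.expressed & ~self.encoded).any().any():
            raise ValidationError("expressed implies encoded")


def contribution_matrix(
    gene_content: GeneContentMatrix,
    pathway_map: PathwayMap,
    pathway: str,
    taxa: Optional[Sequence[str]] = None,
) -> ContributionMatrix:
    """Who encodes and who transcribes each function of one pathway."""
    functions = sorted(pathway_map.functions(pathway))  # KeyError if unknown
    taxa = list(taxa) if taxa is not None else gene_content.taxa
    sub = gene_content.df[gene_content.df["function_id"].isin(functions)]
    enc = pd.DataFrame(False, index=functions, columns=taxa)
    exp = pd.DataFrame(False, index=functions, columns=taxa)
    for (fn, taxon), grp in sub.groupby(["function_id", "taxon"]):
        if taxon in enc.columns:
            enc.loc[fn, taxon] = True
            exp.loc[fn, taxon] = bool((grp["tpm"] > 0).any())
    presence = gene_content.presence_by_sample()
    n_samples = presence.shape[1]
    observed = [f for f in functions if f in presence.index]
    core = frozenset(
        f for f in observed if int(presence.loc[f].sum()) == n_samples
    )
    accessory = frozenset(observed) - core
    return ContributionMatrix(
        pathway=pathway,
        encoded=enc,
        expressed=exp,
        core_functions=core,
        accessory_functions=accessory,
    )


@dataclass(frozen=True)
class RedundancyProfile:
    """Contributor multiplicities of one community over one pathway."""

    multiplicity: pd.Series  # function -> number of community encoders
    coverage: float  # covered fraction of the pathway
    n_singly_covered: int
    min_multiplicity: int


def redundancy_profile(
    contrib: ContributionMatrix, community: Iterable[str]
) -> RedundancyProfile:
    members = list(community)
    unknown = set(members) - set(contrib.encoded.columns)
    if unknown:
        raise KeyError(f"community member(s) not in matrix: {sorted(unknown)}")
    mult = (
        contrib.encoded[members].sum(axis=1).astype(int)
        if members
        else pd.Series(0, index=contrib.encoded.index, dtype=int)
    )
    n_fun = len(mult)
    covered = int((mult >= 1).sum())
    return RedundancyProfile(
        multiplicity=mult,
        coverage=covered / n_fun if n_fun else 0.0,
        n_singly_covered=int((mult == 1).sum()),
        min_multiplicity=int(mult.min()) if n_fun else 0,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _g_test_2x2(a: int, rest_a: int, b: int, rest_b: int) -> tuple[float, float, str]:
    """One 2x2 table: G w/ Yates, or Fisher when any expected cell < 5."""
    table = np.array([[a, rest_a], [b, rest_b]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        # a zero margin means identical proportions: no evidence either way
        return 0.0, 1.0, "degenerate"
    expected = np.outer(row, col) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return float("nan"), float(p), "fisher"
    g, p, _, _ = stats.chi2_contingency(
        table, correction=True, lambda_="log-likelihood"
    )
    return float(g), float(p), "g"


def g_test_functions(
    count_a: pd.Series,
    count_b: pd.Series,
    total_a: int,
    total_b: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-function differential test between two samples' count profiles.

    Each function gets a 2x2 table (count vs remainder in each sample),
    a Yates-corrected G-test (Fisher's exact when any expected cell < 5)
    and a BH-adjusted q-value over the whole function set.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValidationError("sample totals must be positive")
    functions = sorted(set(count_a.index) | set(count_b.index))
    a = count_a.reindex(functions).fillna(0).astype(int)
    b = count_b.reindex(functions).fillna(0).astype(int)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("counts must be non-negative")
    if (a > total_a).any() or (b > total_b).any():
        raise ValidationError("counts exceed declared totals")
    rows = []
    for fn in functions:
        g, p, which = _g_test_2x2(
            int(a[fn]), total_a - int(a[fn]), int(b[fn]), total_b - int(b[fn])
        )
        rows.append({"function_id": fn, "G": g, "p": p, "test": which})
    out = pd.DataFrame(rows).set_index("function_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
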