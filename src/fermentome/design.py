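"""Rule-based synthetic-community design and in-silico member depletion.

Candidate taxa must encode at least ``min_key_genes`` distinct key-flagged
functions over the carbohydrate / pyruvate-energy / nitrogen mega-pathways
and be shared by at least ``min_prevalence`` of the samples.  A community
is then assembled per group quota (or as the full culturable roster of one
source sample), inoculated at 7 / 5 / 6 log cfu/mL for dominant bacteria,
subdominant bacteria + satellites, and yeasts, and stress-tested by
removing one member at a time and recording which functions lose their
last contributor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, ValidationError
from .model import (
    CommunityDesign,
    CommunityMember,
    CulturomicsTable,
    DESIGN_MEGA_PATHWAYS,
    DesignThresholds,
    GeneContentMatrix,
    PathwayMap,
)

#: quota roles, derived from (guild, group label)
ROLES = ("dominant_lab", "subdominant_lab", "yeast", "satellite")


def member_role(guild: str, label: str) -> str:
    if label == "satellite" or guild == "other_bacterium":
        return "satellite"
    if guild == "yeast":
        return "yeast"
    return "dominant_lab" if label.endswith("-dominant") else "subdominant_lab"


def select_candidates(
    gene_content: GeneContentMatrix,
    pathway_map: PathwayMap,
    prevalence: Mapping[str, float],
    thresholds: Optional[DesignThresholds] = None,
) -> pd.DataFrame:
    """Score every taxon against the key-gene + prevalence filter.

    Returns a DataFrame (taxon, key_gene_count, prevalence_fraction,
    selected) covering every taxon in the gene content; the key-gene count
    is over *distinct* key-flagged functions encoded anywhere.
    """
    thresholds = thresholds or DesignThresholds()
    key_fns = pathway_map.key_functions(DESIGN_MEGA_PATHWAYS)
    if not key_fns:
        raise ConfigurationError(
            "pathway map carries no key-flagged functions in the design "
            "mega-pathways"
        )
    sub = gene_content.df[gene_content.df["function_id"].isin(key_fns)]
    per_taxon = sub.groupby("taxon")["function_id"].nunique()
    rows = []
    for taxon in gene_content.taxa:
        k = int(per_taxon.get(taxon, 0))
        prev = float(prevalence.get(taxon, 0.0))
        rows.append(
            {
                "taxon": taxon,
                "key_gene_count": k,
                "prevalence_fraction": prev,
                "selected": k >= thresholds.min_key_genes
                and prev >= thresholds.min_prevalence,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def assemble_community(
    candidates: Optional[Sequence[str]],
    classification: pd.DataFrame,
    culturomics: CulturomicsTable,
    source_sample: str,
    quotas: Optional[Mapping[str, int]] = None,
    *,
    name: str = "SMC",
    thresholds: Optional[DesignThresholds] = None,
    density_overrides: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> CommunityDesign:
    """Assemble a community from the candidate pool.

    With ``quotas`` (role -> member count over dominant_lab /
    subdominant_lab / yeast / satellite), each quota is filled from the
    candidate pool in lexicographic order, or uniformly at random when a
    ``seed`` is given.  With ``quotas=None`` the community is the full
    culturable roster of ``source_sample``.

    Inoculum densities are copied from the source sample's culturomics
    record; members without one fall back to their highest density in any
    sample.  ``density_overrides`` wins over both.
    """
    thresholds = thresholds or DesignThresholds()
    cdf = culturomics.df
    if source_sample not in set(cdf["sample"]):
        raise DesignError(f"source sample {source_sample!r} not in culturomics")
    overrides = dict(density_overrides or {})

    def density_for(taxon: str) -> float:
        if taxon in overrides:
            return float(overrides[taxon])
        here = cdf[(cdf["sample"] == source_sample) & (cdf["taxon"] == taxon)]
        dens = here["cell_density"].dropna()
        if len(dens):
            return float(dens.iloc[0])
        anywhere = cdf[cdf["taxon"] == taxon]["cell_density"].dropna()
        if len(anywhere):
            return float(anywhere.max())
        raise DesignError(f"no cell density available for {taxon!r}")

    def record_for(taxon: str) -> tuple[str, str]:
        if taxon not in classification.index:
            raise DesignError(f"{taxon!r} has no classification record")
        row = classification.loc[taxon]
        return str(row["guild"]), str(row["label"])

    if quotas is None:
        roster = cdf[(cdf["sample"] == source_sample) & (cdf["isolate_count"] > 0)]
        chosen = sorted(roster["taxon"].unique())
        if not chosen:
            raise DesignError(f"no culturable taxa in {source_sample!r}")
    else:
        pool = sorted(set(candidates or []))
        if not pool:
            raise DesignError("empty candidate list")
        rng = np.random.default_rng(seed) if seed is not None else None
        by_role: dict[str, list[str]] = {r: [] for r in ROLES}
        for taxon in pool:
            guild, label = record_for(taxon)
            by_role[member_role(guild, label)].append(taxon)
        chosen = []
        deficient = {}
        for role, want in quotas.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown quota role {role!r}")
            avail = by_role[role]
            if len(avail) < want:
                deficient[role] = (want, len(avail))
                continue
            if rng is not None:
                picked = list(rng.choice(avail, size=want, replace=False))
            else:
                picked = avail[:want]
            chosen.extend(picked)
        if deficient:
            raise DesignError(f"quota unfillable for group(s): {deficient}")

    members = []
    for taxon in chosen:
        guild, label = record_for(taxon)
        members.append(
            CommunityMember(
                taxon=taxon,
                guild=guild,
                group_label=label,
                density=density_for(taxon),
                source_sample=source_sample,
            )
        )
    return CommunityDesign(name=name, members=tuple(members), thresholds=thresholds)


def inoculum_plan(
    community: CommunityDesign, thresholds: Optional[DesignThresholds] = None
) -> dict[str, float]:
    """Liquid-medium inoculum density (log cfu/mL) per member.

    Dominant bacteria 7, subdominant bacteria and satellites 5, yeasts 6.
    """
    thresholds = thresholds or community.thresholds
    plan = {}
    for m in community.members:
        if m.group_label not in (
            "core-dominant",
            "core-subdominant",
            "dispensable-dominant",
            "dispensable-subdominant",
            "satellite",
        ):
            raise ValidationError(f"unlabelled member {m.taxon!r}")
        if m.guild == "yeast":
            plan[m.taxon] = thresholds.inoculum_yeasts
        elif m.group_label == "satellite":
            plan[m.taxon] = thresholds.inoculum_subdominant_bacteria
        elif m.group_label.endswith("-dominant"):
            plan[m.taxon] = thresholds.inoculum_dominant_bacteria
        else:
            plan[m.taxon] = thresholds.inoculum_subdominant_bacteria
    return plan


def _encoded_functions(
    gene_content: GeneContentMatrix,
    taxa: Iterable[str],
    expressed: bool,
    functions: Optional[frozenset[str]] = None,
    phase: Optional[str] = None,
) -> dict[str, frozenset[str]]:
    """taxon -> set of functions it contributes (encoded, or transcribed)."""
    df = gene_content.df[gene_content.df["taxon"].isin(set(taxa))]
    if expressed:
        df = df[df["tpm"] > 0]
    if functions is not None:
        df = df[df["function_id"].isin(functions)]
    if phase is not None:
        df = df[df["phase"] == phase]
    out: dict[str, frozenset[str]] = {t: frozenset() for t in taxa}
    for taxon, grp in df.groupby("taxon"):
        out[taxon] = frozenset(grp["function_id"])
    return out


@dataclass(frozen=True)
class DepletionReport:
    """Effect of removing one member from a community."""

    removed: str
    covered_before: frozenset[str]
    covered_after: frozenset[str]
    lost: frozenset[str]
    per_category_lost: dict[str, frozenset[str]]
    member_function_counts: pd.DataFrame  # remaining member x phase counts

    def __post_init__(self) -> None:
        if not self.lost <= self.covered_before:
            raise ValidationError("lost functions must come from prior coverage")
        if self.covered_after != self.covered_before - self.lost:
            raise ValidationError("covered_after must equal before minus lost")


def deplete(
    community: CommunityDesign | Sequence[str],
    member: str,
    gene_content: GeneContentMatrix,
    pathway_map: Optional[PathwayMap] = None,
    *,
    expressed: bool = False,
) -> DepletionReport:
    """Remove one member and report functions losing their last contributor.

    ``expressed=True`` restricts the accounting to transcribed (tpm > 0)
    functions, matching a transcriptome readout.
    """
    taxa = list(community.taxa if isinstance(community, CommunityDesign) else community)
    if member not in taxa:
        raise KeyError(f"{member!r} is not a community member")
    contribs = _encoded_functions(gene_content, taxa, expressed)
    before = frozenset().union(*contribs.values()) if contribs else frozenset()
    remaining = [t for t in taxa if t != member]
    after = (
        frozenset().union(*(contribs[t] for t in remaining))
        if remaining
        else frozenset()
    )
    lost = before - after

    per_cat: dict[str, frozenset[str]] = {}
    if pathway_map is not None:
        for mega, grp in pathway_map.df.groupby("mega_pathway"):
            fns = frozenset(grp["function_id"])
            per_cat[str(mega)] = lost & fns

    phases = sorted(gene_content.df["phase"].dropna().unique()) or ["none"]
    counts = pd.DataFrame(
        {
            ph: {
                t: len(
                    _encoded_functions(
                        gene_content, [t], expressed, phase=ph if ph != "none" else None
                    )[t]
                )
                for t in remaining
            }
            for ph in phases
        }
    )
    return DepletionReport(
        removed=member,
        covered_before=before,
        covered_after=after,
        lost=lost,
        per_category_lost=per_cat,
        member_function_counts=counts,
    )


def depletion_series(
    community: CommunityDesign | Sequence[str],
    gene_content: GeneContentMatrix,
    pathway_map: Optional[PathwayMap] = None,
    *,
    expressed: bool = False,
) -> tuple[frozenset[str], list[DepletionReport]]:
    """One depletion report per member, plus the full-community baseline."""
    taxa = list(community.taxa if isinstance(community, CommunityDesign) else community)
    if len(taxa) < 2:
        raise ValidationError("depletion series needs at least 2 members")
    contribs = _encoded_functions(gene_content, taxa, expressed)
    baseline = frozenset().union(*contribs.values())
    reports = [
        deplete(taxa, m, gene_content, pathway_map, expressed=expressed) for m in taxa
    ]
    return baseline, reports


def compare_communities(
    community_a: CommunityDesign | Sequence[str],
    community_b: CommunityDesign | Sequence[str],
    gene_content: GeneContentMatrix,
    pathway_map: Optional[PathwayMap] = None,
    categories: Sequence[str] = ("all",),
) -> pd.DataFrame:
    """Transcribed-function counts and copy totals, community A vs B.

    Per category (a mega-pathway or "all"): the number of distinct
    functions with tpm > 0 among each community's members, the summed copy
    numbers of those transcribed rows, and the A/B ratios.
    """
    taxa_a = set(community_a.taxa if isinstance(community_a, CommunityDesign) else community_a)
    taxa_b = set(community_b.taxa if isinstance(community_b, CommunityDesign) else community_b)
    known = set(DESIGN_MEGA_PATHWAYS) | {"stress", "peptidases", "all"}
    bad = set(categories) - known
    if bad:
        raise ConfigurationError(f"unknown categories: {sorted(bad)}")

    def stats_for(taxa: set[str], fns: Optional[frozenset[str]]) -> tuple[int, int]:
        df = gene_content.df
        df = df[df["taxon"].isin(taxa) & (df["tpm"] > 0)]
        if fns is not None:
            df = df[df["function_id"].isin(fns)]
        return int(df["function_id"].nunique()), int(df["copy_number"].sum())

    rows = []
    for cat in categories:
        if cat == "all":
            fns = None
        else:
            if pathway_map is None:
                raise ConfigurationError("mega-pathway categories need a pathway map")
            fns = frozenset(
                pathway_map.df.loc[
                    pathway_map.df["mega_pathway"] == cat, "function_id"
                ]
            )
        na, ca = stats_for(taxa_a, fns)
        nb, cb = stats_for(taxa_b, fns)
        rows.append(
            {
                "category": cat,
                "functions_a": na,
                "functions_b": nb,
                "copies_a": ca,
                "copies_b": cb,
                "function_ratio": na / nb if nb else float("inf") if na else float("nan"),
                "copy_ratio": ca / cb if cb else float("inf") if ca else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")
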