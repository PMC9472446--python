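"""Taxon classification: core/dispensable x dominant/subdominant, satellite.

Dominance is called per omic layer: cell density >= 6 log cfu/g
(culturomics) or relative abundance >= 5% in at least one sample
(metagenomics).  Core means present in every sample; anything shared by
only a subset is dispensable.  Non-lactic-acid bacteria occasionally found
at low density are satellites regardless of dominance.  When the two omic
layers disagree on dominance the culturomics call wins, because inoculum
densities downstream are culturomics values.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import FermentomeError, ValidationError
from .model import (
    AbundanceMatrix,
    CulturomicsTable,
    DesignThresholds,
    GeneContentMatrix,
)

DOMINANT = "dominant"
SUBDOMINANT = "subdominant"
CORE = "core"
DISPENSABLE = "dispensable"


class NotClassifiedError(FermentomeError):
    """Raised when a taxon appears in no omic input."""


def compute_prevalence_pct(isolate_count: int, sample_subtotal: int) -> int:
    """Integer prevalence percent: round(100 * count / subtotal).

    Rounds half away from zero, which reproduces the printed survey
    percentages (e.g. 17/190 -> 9, 128/190 -> 67).
    """
    if sample_subtotal <= 0:
        raise ValidationError("sample subtotal must be positive")
    if not 0 <= isolate_count <= sample_subtotal:
        raise ValidationError(
            f"isolate count {isolate_count} outside [0, {sample_subtotal}]"
        )
    return int(math.floor(100.0 * isolate_count / sample_subtotal + 0.5))


def classify_culturomics(
    cell_density: float, thresholds: Optional[DesignThresholds] = None
) -> str:
    """dominant iff cell density >= the 6-log cutoff (boundary inclusive)."""
    thresholds = thresholds or DesignThresholds()
    if cell_density < 0 or not np.isfinite(cell_density):
        raise ValidationError(f"invalid cell density: {cell_density}")
    return DOMINANT if cell_density >= thresholds.dominance_cfu else SUBDOMINANT


def classify_metagenomics(
    abundances: Iterable[float], thresholds: Optional[DesignThresholds] = None
) -> str:
    """dominant iff relative abundance >= 5% in at least one sample."""
    thresholds = thresholds or DesignThresholds()
    arr = np.asarray(list(abundances), dtype=float)
    if arr.size and (((arr < 0) | (arr > 100)).any()):
        raise ValidationError("abundances must lie in [0, 100]")
    return DOMINANT if arr.size and (arr >= thresholds.dominance_abund).any() else SUBDOMINANT


def partition_core_dispensable(presence_by_sample: Iterable[bool]) -> str:
    """core iff present in every sample."""
    presence = list(presence_by_sample)
    if not presence:
        raise ValidationError("at least one sample required")
    return CORE if all(presence) else DISPENSABLE


def assign_overall_label(guild: str, core_call: str, dominance_call: str) -> str:
    """Combine guild, sharing and dominance into the final group label.

    Non-LAB bacteria are satellites; everything else gets
    (core|dispensable)-(dominant|subdominant).
    """
    if guild == "other_bacterium":
        return "satellite"
    return f"{core_call}-{dominance_call}"


def activity_consensus(
    culturomics: Optional[CulturomicsTable],
    abundance: Optional[AbundanceMatrix],
    gene_content: Optional[GeneContentMatrix],
    thresholds: Optional[DesignThresholds] = None,
) -> pd.DataFrame:
    """Cross-omics activity flags per taxon.

    culturable: isolated at least once.  metagenome_detected: abundance > 0
    anywhere.  transcriptionally_active: any transcription (tpm > 0) AND
    abundance above the 0.1% floor in at least one sample.  Taxa never
    reaching the floor get activity_evaluated = False ("not evaluated").
    """
    thresholds = thresholds or DesignThresholds()
    taxa: set[str] = set()
    if culturomics is not None:
        taxa |= set(culturomics.df["taxon"])
    if abundance is not None:
        taxa |= set(abundance.df["taxon"])
    if gene_content is not None:
        taxa |= set(gene_content.df["taxon"])

    cult_pos: Mapping[str, bool] = {}
    if culturomics is not None:
        cult_pos = (
            culturomics.df.groupby("taxon")["isolate_count"].sum().gt(0).to_dict()
        )
    abund_max: Mapping[str, float] = {}
    if abundance is not None:
        abund_max = abundance.df.groupby("taxon")["rel_abundance_pct"].max().to_dict()
    tpm_pos: Mapping[str, bool] = {}
    if gene_content is not None:
        tpm_pos = gene_content.df.groupby("taxon")["tpm"].max().gt(0).to_dict()

    rows = []
    for taxon in sorted(taxa):
        amax = float(abund_max.get(taxon, 0.0))
        evaluated = amax > thresholds.activity_abund
        rows.append(
            {
                "taxon": taxon,
                "culturable": bool(cult_pos.get(taxon, False)),
                "metagenome_detected": amax > 0,
                "activity_evaluated": evaluated,
                "transcriptionally_active": bool(
                    evaluated and tpm_pos.get(taxon, False)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def classify_taxa(
    culturomics: Optional[CulturomicsTable] = None,
    abundance: Optional[AbundanceMatrix] = None,
    gene_content: Optional[GeneContentMatrix] = None,
    guilds: Optional[Mapping[str, str]] = None,
    thresholds: Optional[DesignThresholds] = None,
    n_samples: Optional[int] = None,
) -> pd.DataFrame:
    """Full classification table for every taxon seen in any omic input.

    Returns a DataFrame indexed by taxon with prevalence, per-omic dominance
    calls, the final group label and activity flags.  ``guilds`` supplies
    labels for taxa absent from the culturomics table; ``n_samples``
    overrides the sample universe (default: union observed across inputs).
    """
    thresholds = thresholds or DesignThresholds()
    if culturomics is None and abundance is None:
        raise NotClassifiedError("no omic input supplied")

    samples: set[str] = set()
    if culturomics is not None:
        samples |= set(culturomics.df["sample"])
    if abundance is not None:
        samples |= set(abundance.df["sample"])
    total_samples = n_samples if n_samples is not None else len(samples)
    if total_samples == 0:
        raise NotClassifiedError("no samples in any input")

    guild_map: dict[str, str] = dict(guilds or {})
    if culturomics is not None:
        for _, row in culturomics.df.iterrows():
            guild_map.setdefault(row["taxon"], row["guild"])

    # presence per (taxon, sample): isolated, or above the metagenomic floor
    presence: dict[str, set[str]] = {}
    if culturomics is not None:
        hit = culturomics.df[culturomics.df["isolate_count"] > 0]
        for taxon, grp in hit.groupby("taxon"):
            presence.setdefault(taxon, set()).update(grp["sample"])
    if abundance is not None:
        hit = abundance.df[abundance.df["rel_abundance_pct"] > thresholds.presence_floor]
        for taxon, grp in hit.groupby("taxon"):
            presence.setdefault(taxon, set()).update(grp["sample"])
    if not presence:
        raise NotClassifiedError("no taxon present in any sample")

    cult_dom: dict[str, str] = {}
    if culturomics is not None:
        for taxon, grp in culturomics.df.groupby("taxon"):
            dens = grp["cell_density"].dropna()
            if len(dens):
                calls = [classify_culturomics(d, thresholds) for d in dens]
                cult_dom[taxon] = DOMINANT if DOMINANT in calls else SUBDOMINANT
    meta_dom: dict[str, str] = {}
    if abundance is not None:
        for taxon, grp in abundance.df.groupby("taxon"):
            meta_dom[taxon] = classify_metagenomics(grp["rel_abundance_pct"], thresholds)

    activity = activity_consensus(culturomics, abundance, gene_content, thresholds)

    rows = []
    for taxon in sorted(presence):
        n_present = len(presence[taxon])
        prevalence = n_present / total_samples
        core_call = CORE if n_present == total_samples else DISPENSABLE
        # culturomics precedence when both layers carry a call
        if taxon in cult_dom:
            dominance = cult_dom[taxon]
        elif taxon in meta_dom:
            dominance = meta_dom[taxon]
        else:
            dominance = SUBDOMINANT
        guild = guild_map.get(taxon, "LAB")
        label = assign_overall_label(guild, core_call, dominance)
        act = activity.loc[taxon] if taxon in activity.index else None
        rows.append(
            {
                "taxon": taxon,
                "guild": guild,
                "n_samples_present": n_present,
                "prevalence_fraction": prevalence,
                "dominance_culturomics": cult_dom.get(taxon, ""),
                "dominance_metagenomics": meta_dom.get(taxon, ""),
                "label": label,
                "culturable": bool(act["culturable"]) if act is not None else False,
                "metagenome_detected": (
                    bool(act["metagenome_detected"]) if act is not None else False
                ),
                "activity_evaluated": (
                    bool(act["activity_evaluated"]) if act is not None else False
                ),
                "transcriptionally_active": (
                    bool(act["transcriptionally_active"]) if act is not None else False
                ),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")
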