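"""Bundled reference fixtures.

Three small plain-text datasets ship with the package:

* the eight-sourdough culturomics survey (isolate counts, printed
  prevalence percentages and cell densities per species row, with the
  declared per-sourdough subtotals);
* the compositions of the two synthetic communities, SDG (the de novo
  seven-member design) and SMC-SD43 (the nine-member full roster of
  sourdough SD43), with their published group labels and inoculum
  densities;
* a default pathway map covering the starch/sucrose, pentose-phosphate,
  pyruvate and nitrogen enzyme portfolios, with key-gene flags for the
  community-design filter.

The back-slopping persistence logs for both communities are reconstructed
programmatically from the reported loss timeline.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .model import (
    CommunityDesign,
    CommunityMember,
    CulturomicsTable,
    PathwayMap,
    PersistenceLog,
)

#: declared per-sourdough isolate subtotals
SURVEY_SUBTOTALS: dict[str, int] = {
    "SD1": 190,
    "SD43": 163,
    "SD44": 234,
    "SD69": 186,
    "SD88": 229,
    "SD93": 205,
    "SD102": 234,
    "SD104": 220,
}


def _data_path(name: str):
    return resources.files("fermentome.data").joinpath(name)


def load_culturomics_survey() -> tuple[CulturomicsTable, pd.Series]:
    """The eight-sourdough culturomics survey.

    Returns the validated table (subtotal-checked) and the printed
    prevalence percentages as a Series indexed by (sample, taxon), kept
    separate so recomputation can be checked against them.
    """
    with resources.as_file(_data_path("sourdough_survey.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    printed = df.set_index(["sample", "taxon"])["prevalence_pct"]
    table = CulturomicsTable(
        df.drop(columns=["prevalence_pct"]).assign(
            cell_density=df["cell_density"].astype(float)
        ),
        subtotals=SURVEY_SUBTOTALS,
    )
    return table, printed


def load_smc_compositions() -> dict[str, CommunityDesign]:
    """The two synthetic community designs with published labels/densities."""
    with resources.as_file(_data_path("smc_compositions.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    out = {}
    for name, grp in df.groupby("community"):
        members = tuple(
            CommunityMember(
                taxon=r["taxon"],
                guild=r["guild"],
                group_label=r["group"],
                density=float(r["cell_density"]),
            )
            for _, r in grp.iterrows()
        )
        out[str(name)] = CommunityDesign(name=str(name), members=members)
    return out


def load_default_pathways() -> PathwayMap:
    """Default pathway map with key-gene flags for the design filter."""
    from .io import read_table

    with resources.as_file(_data_path("pathways_default.tsv")) as p:
        return read_table(p, "pathways")  # type: ignore[return-value]


def _persistence_from_timeline(
    members: list[str], last_detected: dict[str, int], days: tuple[int, ...]
) -> PersistenceLog:
    rows = []
    for d in days:
        for m in members:
            det = d <= last_detected.get(m, days[-1])
            rows.append(
                {"day": d, "member": m, "detected": det, "dilution": np.nan}
            )
    return PersistenceLog(pd.DataFrame(rows))


def load_smc_sd43_persistence() -> PersistenceLog:
    """Back-slopping detection log for SMC-SD43.

    Three strains vanish before the first 10-day sampling
    (Fru. sanfranciscensis, Lac. lactis, Staphylococcus sp.), two more are
    last seen at day 10 (Lac. paracasei, Lac. rhamnosus), leaving four of
    the nine initial strains at day 30.
    """
    smc = load_smc_compositions()["SMC-SD43"]
    members = list(smc.taxa)
    last = {
        "Fructilactobacillus sanfranciscensis": 0,
        "Lactococcus lactis": 0,
        "Staphylococcus sp.": 0,
        "Lacticaseibacillus paracasei": 10,
        "Lacticaseibacillus rhamnosus": 10,
    }
    return _persistence_from_timeline(members, last, (0, 10, 20, 30))


def load_sdg_persistence() -> PersistenceLog:
    """Back-slopping detection log for SDG.

    Every member persists through day 30 except Pic. kudriavzevii, last
    detected at the day-10 sampling.
    """
    sdg = load_smc_compositions()["SDG"]
    last = {"Pichia kudriavzevii": 10}
    return _persistence_from_timeline(list(sdg.taxa), last, (0, 10, 20, 30))
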