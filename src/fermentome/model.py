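"""Domain types for fermenting-community multi-omics tables.

The in-memory container for every tabular input is a tidy
:class:`pandas.DataFrame` wrapped in a thin dataclass that validates the
domain invariants on construction.  Scalar configuration (classification
thresholds, GC-MS quantification constants, growth-model parameters) is
held in pydantic models so a JSON config file round-trips losslessly.

Units
-----
* cell densities: log10 cfu per g (dough) or per mL (liquid medium); the
  unit is contextual, never converted.
* relative abundance: percent of the total metagenome, in [0, 100].
* transcript abundance: TPM (transcripts per million).
* VOC concentration: internal-standard mg/l equivalents (µg/g for dough).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import ClassVar, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError

Guild = Literal["LAB", "other_bacterium", "yeast"]
GUILDS: tuple[str, ...] = ("LAB", "other_bacterium", "yeast")

GroupLabel = Literal[
    "core-dominant",
    "core-subdominant",
    "dispensable-dominant",
    "dispensable-subdominant",
    "satellite",
]
GROUP_LABELS: tuple[str, ...] = (
    "core-dominant",
    "core-subdominant",
    "dispensable-dominant",
    "dispensable-subdominant",
    "satellite",
)

MEGA_PATHWAYS: tuple[str, ...] = (
    "carbohydrate",
    "pyruvate/energy",
    "nitrogen",
    "stress",
    "peptidases",
)

#: mega-pathways whose key-flagged functions feed the candidate filter
DESIGN_MEGA_PATHWAYS: tuple[str, ...] = ("carbohydrate", "pyruvate/energy", "nitrogen")

CHEM_CLASSES: tuple[str, ...] = (
    "alcohols",
    "aldehydes",
    "esters",
    "organic acids",
    "others",
)

GROWTH_PHASES: tuple[str, ...] = ("exponential", "stationary", "none")


class TaxonRecord(BaseModel):
    """A species-level taxon; ambiguous pairs keep a single ``a/b`` label."""

    label: str
    guild: Guild

    @model_validator(mode="after")
    def _nonempty(self) -> "TaxonRecord":
        if not self.label.strip():
            raise ValueError("taxon label must be non-empty")
        return self


class SampleMetadata(BaseModel):
    """Technology card for one spontaneously fermented sample."""

    sample_id: str
    country: str = ""
    flour: str = ""
    dough_yield: float = Field(gt=100.0, description="(dough wt / flour wt) x 100")
    backslop_pct: float = Field(ge=0.0, le=100.0, default=10.0)
    temperature_c: float = Field(gt=0.0)
    fermentation_h: float = Field(gt=0.0)


class DesignThresholds(BaseModel):
    """All classification and community-design cutoffs in one place.

    Defaults are the operating point of the whole pipeline: dominance at
    6 log cfu/g (culturomics) or 5% relative abundance (metagenomics) in at
    least one sample, a 0.1% abundance floor below which transcriptional
    activity is not evaluated, and a candidate filter of >= 20 distinct
    key genes over the carbohydrate/pyruvate-energy/nitrogen mega-pathways
    in taxa shared by >= 50% of samples.  Inoculum plan (log cfu/mL):
    dominant bacteria 7, subdominant bacteria and satellites 5, yeasts 6.
    """

    dominance_cfu: float = Field(default=6.0, gt=0)
    dominance_abund: float = Field(default=5.0, gt=0)
    activity_abund: float = Field(default=0.1, gt=0)
    min_key_genes: int = Field(default=20, gt=0)
    min_prevalence: float = Field(default=0.5, gt=0, le=1.0)
    inoculum_dominant_bacteria: float = Field(default=7.0, gt=0)
    inoculum_subdominant_bacteria: float = Field(default=5.0, gt=0)
    inoculum_yeasts: float = Field(default=6.0, gt=0)
    presence_floor: float = Field(
        default=0.0, ge=0, description="metagenomic detection floor (%) for presence"
    )


class VocConfig(BaseModel):
    """GC-MS peak acceptance and internal-standard quantification constants."""

    internal_standard: str = "2-methyl-4-pentanol"
    internal_standard_mg_l: float = Field(default=33.0, gt=0)
    peak_area_threshold: float = Field(default=1e6, gt=0)
    spectral_match_threshold: float = Field(default=85.0, gt=0, le=100.0)


class GrowthModel(BaseModel):
    """Reparameterized Gompertz growth parameters.

    ``a`` is the asymptotic log-increase, ``mu_m`` the maximum specific
    growth rate (1/h) and ``lag`` the lag time (h).
    """

    a: float = Field(ge=0)
    mu_m: float = Field(ge=0)
    lag: float = Field(ge=0)

    def curve(self, t: np.ndarray) -> np.ndarray:
        from .stability import gompertz

        return gompertz(np.asarray(t, dtype=float), self.a, self.mu_m, self.lag)


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")


@dataclass(frozen=True)
class CulturomicsTable:
    """Isolate counts and cell densities per (sample, taxon).

    ``subtotals``, when supplied, are declared per-sample isolate totals and
    are checked against the column sums.
    """

    df: pd.DataFrame
    subtotals: Optional[dict[str, int]] = None
    COLUMNS: ClassVar[tuple[str, ...]] = (
        "sample",
        "taxon",
        "guild",
        "isolate_count",
        "cell_density",
    )

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, self.COLUMNS, "CulturomicsTable")
        counts = df["isolate_count"]
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts), equal_nan=False):
                raise ValidationError("isolate_count must be integral")
        if (counts < 0).any():
            raise ValidationError("isolate_count must be non-negative")
        bad_guild = set(df["guild"].unique()) - set(GUILDS)
        if bad_guild:
            raise ValidationError(f"unknown guild value(s): {sorted(bad_guild)}")
        dens = df["cell_density"].dropna()
        if (dens < 0).any():
            raise ValidationError("cell_density (log cfu) must be >= 0")
        if self.subtotals is not None:
            sums = df.groupby("sample")["isolate_count"].sum()
            for sample, declared in self.subtotals.items():
                got = int(sums.get(sample, 0))
                if got != declared:
                    raise ValidationError(
                        f"sample {sample}: isolate counts sum to {got}, "
                        f"declared subtotal is {declared}"
                    )

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())


@dataclass(frozen=True)
class AbundanceMatrix:
    """Relative abundances (% of total metagenome) per (sample, taxon)."""

    df: pd.DataFrame
    COLUMNS: ClassVar[tuple[str, ...]] = ("sample", "taxon", "rel_abundance_pct")
    SUM_TOL: ClassVar[float] = 1e-6

    def __post_init__(self) -> None:
        _require_columns(self.df, self.COLUMNS, "AbundanceMatrix")
        v = self.df["rel_abundance_pct"]
        if ((v < 0) | (v > 100)).any():
            raise ValidationError("rel_abundance_pct must lie in [0, 100]")
        sums = self.df.groupby("sample")["rel_abundance_pct"].sum()
        over = sums[sums > 100 + self.SUM_TOL]
        if not over.empty:
            raise ValidationError(
                f"per-sample abundance exceeds 100%: {over.to_dict()}"
            )

    def wide(self) -> pd.DataFrame:
        """taxon x sample matrix, absent entries filled with 0."""
        return self.df.pivot_table(
            index="taxon", columns="sample", values="rel_abundance_pct", fill_value=0.0
        )


@dataclass(frozen=True)
class GeneContentMatrix:
    """Per (taxon, sample, KEGG/EC function): copy number and TPM.

    Presence is implied: a row exists iff the function is encoded
    (copy_number >= 1) by that taxon in that sample.  ``tpm > 0`` marks the
    function as transcribed.  ``phase`` optionally tags the sample's growth
    phase (exponential / stationary / none).
    """

    df: pd.DataFrame
    COLUMNS: ClassVar[tuple[str, ...]] = (
        "taxon",
        "sample",
        "function_id",
        "copy_number",
        "tpm",
        "phase",
    )

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, self.COLUMNS, "GeneContentMatrix")
        if (df["copy_number"] < 1).any():
            raise ValidationError("rows must have copy_number >= 1 (presence)")
        cn = df["copy_number"]
        if not np.issubdtype(cn.dtype, np.integer):
            if not np.allclose(cn, np.round(cn)):
                raise ValidationError("copy_number must be integral")
        if (df["tpm"] < 0).any():
            raise ValidationError("tpm must be non-negative")
        bad = set(df["phase"].dropna().unique()) - set(GROWTH_PHASES)
        if bad:
            raise ValidationError(f"unknown growth phase(s): {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    @property
    def taxa(self) -> list[str]:
        return sorted(self.df["taxon"].unique())

    def presence_by_sample(self) -> pd.DataFrame:
        """function x sample boolean presence, any contributing taxon."""
        return (
            self.df.assign(present=True)
            .pivot_table(
                index="function_id",
                columns="sample",
                values="present",
                aggfunc="any",
                fill_value=False,
            )
            .astype(bool)
        )


@dataclass(frozen=True)
class PathwayMap:
    """pathway -> member functions, with mega-pathway group and key flags."""

    df: pd.DataFrame
    COLUMNS: ClassVar[tuple[str, ...]] = (
        "pathway",
        "mega_pathway",
        "function_id",
        "is_key",
    )

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, self.COLUMNS, "PathwayMap")
        bad = set(df["mega_pathway"].unique()) - set(MEGA_PATHWAYS)
        if bad:
            raise ValidationError(f"unknown mega-pathway value(s): {sorted(bad)}")
        empty = df["function_id"].astype(str).str.strip() == ""
        if empty.any():
            raise ValidationError("empty function_id in pathway map")

    @property
    def pathways(self) -> list[str]:
        return sorted(self.df["pathway"].unique())

    def functions(self, pathway: str) -> frozenset[str]:
        sub = self.df[self.df["pathway"] == pathway]
        if sub.empty:
            raise KeyError(f"unknown pathway: {pathway!r}")
        return frozenset(sub["function_id"])

    def key_functions(self, mega_pathways: tuple[str, ...] = DESIGN_MEGA_PATHWAYS) -> frozenset[str]:
        sub = self.df[self.df["is_key"] & self.df["mega_pathway"].isin(mega_pathways)]
        return frozenset(sub["function_id"])


@dataclass(frozen=True)
class VOCTable:
    """Volatile compound concentrations per (community, timepoint, replicate)."""

    df: pd.DataFrame
    COLUMNS: ClassVar[tuple[str, ...]] = (
        "community",
        "timepoint",
        "replicate",
        "compound",
        "chem_class",
        "concentration",
    )

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, self.COLUMNS, "VOCTable")
        if (df["concentration"] < 0).any():
            raise ValidationError("concentrations must be non-negative")
        bad = set(df["chem_class"].unique()) - set(CHEM_CLASSES)
        if bad:
            raise ValidationError(f"unknown chemical class(es): {sorted(bad)}")
        nclass = df.groupby("compound")["chem_class"].nunique()
        multi = nclass[nclass > 1]
        if not multi.empty:
            raise ValidationError(
                f"compound(s) mapped to multiple classes: {list(multi.index)}"
            )

    def compound_classes(self) -> pd.Series:
        return self.df.drop_duplicates("compound").set_index("compound")["chem_class"]


@dataclass(frozen=True)
class PeakTable:
    """Raw GC-MS peak candidates prior to identification filtering."""

    df: pd.DataFrame
    COLUMNS: ClassVar[tuple[str, ...]] = (
        "compound",
        "retention_time",
        "peak_area",
        "spectral_match",
    )

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, self.COLUMNS, "PeakTable")
        if (df["peak_area"] < 0).any():
            raise ValidationError("peak_area must be non-negative")
        m = df["spectral_match"]
        if ((m < 0) | (m > 100)).any():
            raise ValidationError("spectral_match must lie in [0, 100]")


@dataclass(frozen=True)
class PersistenceLog:
    """Member detection records over back-slopping days."""

    df: pd.DataFrame
    COLUMNS: ClassVar[tuple[str, ...]] = ("day", "member", "detected", "dilution")

    def __post_init__(self) -> None:
        df = self.df
        _require_columns(df, self.COLUMNS, "PersistenceLog")
        if (df["day"] < 0).any():
            raise ValidationError("days must be non-negative")
        first = int(df["day"].min()) if len(df) else 0
        if first not in (0, 1) and len(df):
            raise ValidationError("log must start at day 0 or day 1")
        if len(df):
            day0 = set(df.loc[df["day"] == first, "member"])
            missing = set(df["member"]) - day0
            if missing:
                raise ValidationError(
                    f"member(s) without a day-{first} record: {sorted(missing)}"
                )

    @property
    def sampling_days(self) -> list[int]:
        return sorted(int(d) for d in self.df["day"].unique())


@dataclass(frozen=True)
class CommunityMember:
    taxon: str
    guild: str
    group_label: str
    density: float
    source_sample: str = ""


@dataclass(frozen=True)
class CommunityDesign:
    """A designed synthetic community: labelled members with densities."""

    name: str
    members: tuple[CommunityMember, ...]
    thresholds: DesignThresholds = field(default_factory=DesignThresholds)

    def __post_init__(self) -> None:
        labels = [m.taxon for m in self.members]
        if len(labels) != len(set(labels)):
            raise ValidationError("community member labels must be unique")
        for m in self.members:
            if m.group_label not in GROUP_LABELS:
                raise ValidationError(
                    f"{m.taxon}: unknown group label {m.group_label!r}"
                )
            if not m.density > 0:
                raise ValidationError(f"{m.taxon}: density must be positive")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(m.taxon for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "members": [
                {
                    "taxon": m.taxon,
                    "guild": m.guild,
                    "group_label": m.group_label,
                    "density": m.density,
                    "source_sample": m.source_sample,
                }
                for m in self.members
            ],
            "thresholds": self.thresholds.model_dump(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityDesign":
        return cls(
            name=d["name"],
            members=tuple(CommunityMember(**m) for m in d["members"]),
            thresholds=DesignThresholds(**d.get("thresholds", {})),
        )
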