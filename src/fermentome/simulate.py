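"""Seeded synthetic-data generators with planted ground truth.

Every generator emulates the statistical structure the analysis stages
assume — a function universe with a planted core/unique/accessory split,
culturomics counts with planted dominance, a candidate pool in which a
known subset passes the design filter, stable vs. unstable volatilomes,
scheduled strain losses and Gompertz growth — and returns the planted
truth alongside the fixture so downstream recovery is checkable exactly.

Defaults mirror the study conditions: 8 samples, a 1163-function core
with per-sample unique sets spanning 33-684 functions, a 49-taxon
dominant/subdominant pool of which 13 qualify, 54 volatile compounds with
45 planted shifts in the unstable community, and a 9-member persistence
schedule losing 3 + 2 strains by day 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError
from .model import (
    CHEM_CLASSES,
    CulturomicsTable,
    DESIGN_MEGA_PATHWAYS,
    DesignThresholds,
    GeneContentMatrix,
    GrowthModel,
    PathwayMap,
    PersistenceLog,
    VOCTable,
)
from .redundancy import FunctionPartition

_SD43_MEMBERS = 9


class SimulationSpec(BaseModel):
    """All knobs for the synthetic fixtures, with study-scale defaults."""

    seed: int = 0
    n_samples: int = Field(default=8, ge=2)
    n_lab: int = Field(default=20, ge=1)
    n_other: int = Field(default=5, ge=0)
    n_yeast: int = Field(default=4, ge=0)
    # planted function partition
    core_functions: int = Field(default=1163, ge=0)
    unique_functions: tuple[int, ...] = (684, 33, 100, 100, 100, 100, 100, 100)
    accessory_functions: int = Field(default=500, ge=0)
    active_taxon_fraction: float = Field(default=0.7, ge=0.0, le=1.0)
    # culturomics
    sample_subtotal: int = Field(default=200, ge=1)
    dominant_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    dirichlet_dominant_mass: float = Field(default=8.0, gt=0)
    dirichlet_rare_mass: float = Field(default=0.3, gt=0)
    # candidate filter
    candidate_pool: int = Field(default=49, ge=1)
    planted_candidates: int = Field(default=13, ge=0)
    n_key_functions: int = Field(default=40, ge=1)
    # volatilome
    n_compounds: int = Field(default=54, ge=2)
    n_shifted: int = Field(default=45, ge=0)
    n_replicates: int = Field(default=3, ge=2)
    effect_size_sd: float = Field(default=8.0, ge=0)
    noise_cv: float = Field(default=0.05, gt=0)
    # persistence: member index -> last detected day (others persist)
    n_members: int = Field(default=_SD43_MEMBERS, ge=1)
    loss_schedule: dict[int, int] = Field(
        default_factory=lambda: {0: 0, 1: 0, 2: 0, 3: 10, 4: 10}
    )
    sampling_days: tuple[int, ...] = (0, 10, 20, 30)
    # growth
    growth: GrowthModel = Field(
        default_factory=lambda: GrowthModel(a=3.0, mu_m=0.5, lag=2.0)
    )
    growth_sigma: float = Field(default=0.15, ge=0)
    # online OD reads every 10 min over 24 h
    growth_points: int = Field(default=145, ge=4)
    growth_t_max: float = Field(default=24.0, gt=0)

    @model_validator(mode="after")
    def _consistent(self) -> "SimulationSpec":
        if len(self.unique_functions) != self.n_samples:
            raise ValueError("unique_functions must have one count per sample")
        if self.planted_candidates > self.candidate_pool:
            raise ValueError("planted candidates exceed the pool")
        if self.n_shifted > self.n_compounds:
            raise ValueError("shifted compounds exceed the compound set")
        if any(d < 0 for d in self.loss_schedule.values()):
            raise ValueError("loss days must be non-negative")
        if any(i >= self.n_members for i in self.loss_schedule):
            raise ValueError("loss schedule indexes a missing member")
        return self

    def samples(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def taxa(self) -> list[tuple[str, str]]:
        out = [(f"Lab_taxon_{i + 1:02d}", "LAB") for i in range(self.n_lab)]
        out += [(f"Other_taxon_{i + 1:02d}", "other_bacterium") for i in range(self.n_other)]
        out += [(f"Yeast_taxon_{i + 1:02d}", "yeast") for i in range(self.n_yeast)]
        return out


def _truncated_geometric(rng: np.random.Generator, size: int, p: float = 0.5, high: int = 10) -> np.ndarray:
    """Small positive integer copy numbers, support 1..high."""
    draws = rng.geometric(p, size=size)
    return np.minimum(draws, high)


def gen_gene_content(
    spec: SimulationSpec,
) -> tuple[GeneContentMatrix, FunctionPartition]:
    """Gene-content matrix realizing exactly the planted partition.

    Each function is assigned its sample set per the planted counts, then
    one or more carrier taxa per (function, sample).  Copy numbers are
    truncated-geometric on 1..10; TPM is positive for the planted active
    taxon subset, zero elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    samples = spec.samples()
    taxa = [t for t, _ in spec.taxa()]
    n = spec.n_samples
    universe_size = spec.core_functions + sum(spec.unique_functions) + spec.accessory_functions
    if universe_size == 0:
        raise ValidationError("empty function universe")
    if spec.accessory_functions > 0 and n < 3:
        raise ValidationError("accessory functions need >= 3 samples (2..n-1 sharing)")

    fids = [f"K{i:05d}" for i in range(universe_size)]
    cursor = 0
    core = fids[cursor : cursor + spec.core_functions]
    cursor += spec.core_functions
    unique: dict[str, list[str]] = {}
    for s, k in zip(samples, spec.unique_functions):
        unique[s] = fids[cursor : cursor + k]
        cursor += k
    accessory = fids[cursor:]

    n_active = int(round(spec.active_taxon_fraction * len(taxa)))
    active = set(rng.choice(taxa, size=n_active, replace=False)) if n_active else set()

    records: list[tuple[str, str, str, int, float]] = []

    def emit(fid: str, sample_set: list[str]) -> None:
        for s in sample_set:
            k = int(rng.integers(1, 3))  # 1-2 carrier taxa per sample
            carriers = rng.choice(taxa, size=min(k, len(taxa)), replace=False)
            for taxon in carriers:
                cn = int(_truncated_geometric(rng, 1)[0])
                tpm = float(rng.lognormal(3.0, 1.0)) if taxon in active else 0.0
                records.append((taxon, s, fid, cn, tpm))

    for fid in core:
        emit(fid, samples)
    for s in samples:
        for fid in unique[s]:
            emit(fid, [s])
    for fid in accessory:
        k = int(rng.integers(2, n))  # shared by 2..n-1 samples
        emit(fid, list(rng.choice(samples, size=k, replace=False)))

    df = pd.DataFrame.from_records(
        records, columns=["taxon", "sample", "function_id", "copy_number", "tpm"]
    )
    # one row per (taxon, sample, function): sum copies, max tpm
    df = (
        df.groupby(["taxon", "sample", "function_id"], as_index=False)
        .agg(copy_number=("copy_number", "sum"), tpm=("tpm", "max"))
    )
    df["phase"] = "none"
    truth = FunctionPartition(
        core=frozenset(core),
        unique={s: frozenset(v) for s, v in unique.items()},
        accessory=frozenset(accessory),
    )
    return GeneContentMatrix(df), truth


def gen_culturomics(
    spec: SimulationSpec,
) -> tuple[CulturomicsTable, dict[str, str]]:
    """Culturomics counts with planted dominance labels.

    Counts per sample are multinomial over a Dirichlet composition whose
    mass concentrates on the planted dominant taxa; densities land above
    or below the 6-log cutoff according to the planted label.
    """
    rng = np.random.default_rng(spec.seed + 1)
    taxa = spec.taxa()
    labels = [t for t, _ in taxa]
    n_dom = max(1, int(round(spec.dominant_fraction * len(labels))))
    dominant = set(rng.choice(labels, size=n_dom, replace=False))
    truth = {t: ("dominant" if t in dominant else "subdominant") for t in labels}
    thr = DesignThresholds().dominance_cfu
    rows = []
    for sample in spec.samples():
        mass = np.array(
            [
                spec.dirichlet_dominant_mass if t in dominant else spec.dirichlet_rare_mass
                for t in labels
            ]
        )
        comp = rng.dirichlet(mass)
        counts = rng.multinomial(spec.sample_subtotal, comp)
        for (taxon, guild), c in zip(taxa, counts):
            dens = (
                rng.uniform(thr, thr + 4.0)
                if taxon in dominant
                else rng.uniform(2.0, thr - 0.01)
            )
            rows.append(
                {
                    "sample": sample,
                    "taxon": taxon,
                    "guild": guild,
                    "isolate_count": int(c),
                    "cell_density": round(float(dens), 2),
                }
            )
    return CulturomicsTable(pd.DataFrame(rows)), truth


def gen_candidates(
    spec: SimulationSpec,
) -> tuple[GeneContentMatrix, PathwayMap, dict[str, float], frozenset[str]]:
    """Candidate pool in which exactly the planted taxa pass the filter.

    Qualifiers carry >= 20 distinct key functions and >= 4/8 prevalence;
    non-qualifiers miss at least one criterion.  One qualifier sits exactly
    on both boundaries.  Returns gene content, pathway map, prevalence per
    taxon and the planted qualifying set.
    """
    thr = DesignThresholds()
    rng = np.random.default_rng(spec.seed + 2)
    if spec.n_key_functions < thr.min_key_genes:
        raise ValidationError("key-function pool smaller than the filter cutoff")
    pool = [f"Pool_taxon_{i + 1:02d}" for i in range(spec.candidate_pool)]
    qualifiers = frozenset(pool[: spec.planted_candidates])
    samples = spec.samples()
    n = spec.n_samples
    min_k = int(np.ceil(thr.min_prevalence * n))

    key_fns = [f"EC:9.9.{i}.1" for i in range(spec.n_key_functions)]
    decoy_fns = [f"EC:8.8.{i}.1" for i in range(10)]
    mega_cycle = list(DESIGN_MEGA_PATHWAYS)
    pm_rows = [
        {
            "pathway": f"key pathway {i % 3 + 1}",
            "mega_pathway": mega_cycle[i % len(mega_cycle)],
            "function_id": fn,
            "is_key": True,
        }
        for i, fn in enumerate(key_fns)
    ]
    pm_rows += [
        {
            "pathway": "decoy pathway",
            "mega_pathway": "stress",
            "function_id": fn,
            "is_key": False,
        }
        for fn in decoy_fns
    ]
    pathway_map = PathwayMap(pd.DataFrame(pm_rows))

    rows = []
    prevalence: dict[str, float] = {}
    for i, taxon in enumerate(pool):
        if taxon in qualifiers:
            if i == 0:  # boundary plant: exactly the cutoffs
                n_key, n_prev = thr.min_key_genes, min_k
            else:
                n_key = int(rng.integers(thr.min_key_genes, spec.n_key_functions + 1))
                n_prev = int(rng.integers(min_k, n + 1))
        else:
            fail_key = rng.random() < 0.5
            fail_prev = (not fail_key) or rng.random() < 0.5
            n_key = (
                int(rng.integers(0, thr.min_key_genes))
                if fail_key
                else int(rng.integers(thr.min_key_genes, spec.n_key_functions + 1))
            )
            n_prev = (
                int(rng.integers(1, min_k))
                if fail_prev
                else int(rng.integers(min_k, n + 1))
            )
        fns = list(rng.choice(key_fns, size=n_key, replace=False)) if n_key else []
        fns += list(rng.choice(decoy_fns, size=3, replace=False))
        present = list(rng.choice(samples, size=n_prev, replace=False))
        prevalence[taxon] = n_prev / n
        for s in present:
            for fn in fns:
                rows.append(
                    {
                        "taxon": taxon,
                        "sample": s,
                        "function_id": fn,
                        "copy_number": int(_truncated_geometric(rng, 1)[0]),
                        "tpm": float(rng.lognormal(2.0, 1.0)),
                        "phase": "none",
                    }
                )
    return GeneContentMatrix(pd.DataFrame(rows)), pathway_map, prevalence, qualifiers


@dataclass(frozen=True)
class VocTruth:
    shifted: frozenset[str]
    stable_community: str
    unstable_community: str
    t0: str
    t1: str


def gen_voc(spec: SimulationSpec) -> tuple[VOCTable, VocTruth]:
    """Volatilomes for one stable and one unstable community.

    The stable community has no planted effects; the unstable one shifts
    ``n_shifted`` compounds at t1 by ``effect_size_sd`` replicate standard
    deviations.  Replicate noise is multiplicative lognormal with CV
    ``noise_cv``.
    """
    rng = np.random.default_rng(spec.seed + 3)
    compounds = [f"voc_{i + 1:02d}" for i in range(spec.n_compounds)]
    classes = {c: CHEM_CLASSES[i % len(CHEM_CLASSES)] for i, c in enumerate(compounds)}
    shifted = frozenset(compounds[: spec.n_shifted])
    base = {c: float(rng.lognormal(1.5, 0.8)) for c in compounds}
    sigma_ln = np.sqrt(np.log1p(spec.noise_cv**2))
    rows = []
    for community, unstable in (("stable", False), ("unstable", True)):
        for tp in ("T0", "T30"):
            for rep in range(1, spec.n_replicates + 1):
                for c in compounds:
                    mean = base[c]
                    if unstable and tp == "T30" and c in shifted:
                        mean = mean + spec.effect_size_sd * (spec.noise_cv * base[c])
                    conc = mean * float(rng.lognormal(-0.5 * sigma_ln**2, sigma_ln))
                    rows.append(
                        {
                            "community": community,
                            "timepoint": tp,
                            "replicate": f"r{rep}",
                            "compound": c,
                            "chem_class": classes[c],
                            "concentration": conc,
                        }
                    )
    truth = VocTruth(
        shifted=shifted,
        stable_community="stable",
        unstable_community="unstable",
        t0="T0",
        t1="T30",
    )
    return VOCTable(pd.DataFrame(rows)), truth


def gen_persistence(spec: SimulationSpec) -> tuple[PersistenceLog, dict[str, int]]:
    """Detection log realizing the planted loss schedule.

    ``loss_schedule`` maps member index -> last day the member is
    detected; everyone else persists through the final sampling day.
    """
    members = [f"member_{i + 1:02d}" for i in range(spec.n_members)]
    last_day = {
        m: spec.loss_schedule.get(i, spec.sampling_days[-1])
        for i, m in enumerate(members)
    }
    rows = []
    for d in spec.sampling_days:
        for m in members:
            detected = d <= last_day[m]
            rows.append(
                {
                    "day": d,
                    "member": m,
                    "detected": detected,
                    "dilution": 7.0 if detected else np.nan,
                }
            )
    return PersistenceLog(pd.DataFrame(rows)), last_day


def gen_growth(
    spec: SimulationSpec, sigma: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray, GrowthModel]:
    """Noisy Gompertz growth series from the spec's planted parameters."""
    rng = np.random.default_rng(spec.seed + 4)
    model = spec.growth
    t = np.linspace(0.0, spec.growth_t_max, spec.growth_points)
    s = spec.growth_sigma if sigma is None else sigma
    y = model.curve(t) + rng.normal(0.0, s, size=t.size)
    return t, y, model
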