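"""End-to-end pipeline: classify -> redundancy -> design -> deplete -> stability.

Each stage reads validated tables, writes plain-text artifacts into the
output directory, and a JSON manifest records versions, seed and
thresholds so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .classification import classify_taxa
from .design import assemble_community, depletion_series, select_candidates
from .errors import FermentomeError, StageError
from .io import read_table
from .model import DesignThresholds, VocConfig
from .redundancy import partition_functions
from .stability import metabolic_delta, pca_projection, track_persistence, voc_differential


class RunConfig(BaseModel):
    """Paths + knobs for one pipeline run."""

    culturomics: Optional[str] = None
    abundance: Optional[str] = None
    gene_content: Optional[str] = None
    pathways: Optional[str] = None
    voc: Optional[str] = None
    persistence: Optional[str] = None
    source_sample: Optional[str] = None
    community_name: str = "SMC"
    t0: str = "T0"
    t1: str = "T30"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0
    out_dir: str = "fermentome_out"
    thresholds: DesignThresholds = Field(default_factory=DesignThresholds)
    voc_config: VocConfig = Field(default_factory=VocConfig)


def _require(path: Optional[str], stage: str) -> Path:
    if path is None:
        raise StageError(stage, "required input not configured")
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"input path does not exist: {p}")
    return p


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Stages whose inputs are not configured are skipped.  Any failure is
    re-raised as a StageError naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fermentome_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": config.thresholds.model_dump(),
        "voc_config": config.voc_config.model_dump(),
        "stages": [],
    }

    classification = None
    culturomics = None
    gene = None
    pathways = None

    if config.culturomics or config.abundance:
        stage = "classify"
        try:
            culturomics = (
                read_table(_require(config.culturomics, stage), "culturomics")
                if config.culturomics
                else None
            )
            abundance = (
                read_table(_require(config.abundance, stage), "abundance")
                if config.abundance
                else None
            )
            gene = (
                read_table(_require(config.gene_content, stage), "gene_content")
                if config.gene_content
                else None
            )
            classification = classify_taxa(
                culturomics, abundance, gene, thresholds=config.thresholds
            )
            classification.to_csv(out / "labels.tsv", sep="\t")
            manifest["stages"].append(stage)
        except FermentomeError:
            raise
        except Exception as e:  # pragma: no cover - defensive
            raise StageError(stage, str(e)) from e

    if config.gene_content:
        stage = "redundancy"
        try:
            if gene is None:
                gene = read_table(_require(config.gene_content, stage), "gene_content")
            part = partition_functions(gene)
            pd.Series(part.counts()).to_csv(
                out / "partition.tsv", sep="\t", header=["n_functions"]
            )
            manifest["stages"].append(stage)
        except FermentomeError:
            raise
        except Exception as e:
            raise StageError(stage, str(e)) from e

    if config.gene_content and config.pathways and config.source_sample:
        stage = "design"
        try:
            pathways = read_table(_require(config.pathways, stage), "pathways")
            if culturomics is None or classification is None:
                raise StageError(stage, "design needs culturomics + classification")
            prevalence = {
                t: row["prevalence_fraction"]
                for t, row in classification.iterrows()
            }
            candidates = select_candidates(
                gene, pathways, prevalence, config.thresholds
            )
            candidates.to_csv(out / "candidates.tsv", sep="\t")
            community = assemble_community(
                None,
                classification,
                culturomics,
                config.source_sample,
                name=config.community_name,
                thresholds=config.thresholds,
            )
            (out / "community.json").write_text(
                json.dumps(community.to_dict(), indent=2) + "\n"
            )
            manifest["stages"].append(stage)

            stage = "deplete"
            baseline, reports = depletion_series(community, gene, pathways)
            dep = pd.DataFrame(
                [
                    {
                        "removed": r.removed,
                        "covered_before": len(r.covered_before),
                        "covered_after": len(r.covered_after),
                        "n_lost": len(r.lost),
                        "lost": ";".join(sorted(r.lost)),
                    }
                    for r in reports
                ]
            )
            dep.to_csv(out / "depletion.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)
        except FermentomeError:
            raise
        except Exception as e:
            raise StageError(stage, str(e)) from e

    if config.voc or config.persistence:
        stage = "stability"
        try:
            report: dict = {}
            if config.voc:
                voc = read_table(_require(config.voc, stage), "voc")
                report["communities"] = {}
                for community in sorted(voc.df["community"].unique()):
                    diff = voc_differential(
                        voc, community, config.t0, config.t1, config.alpha
                    )
                    sig = list(diff.index[diff["significant"]])
                    delta = metabolic_delta(voc, sig, community, config.t0, config.t1)
                    report["communities"][community] = {
                        "n_significant": len(sig),
                        "significant": sig,
                        "class_delta": delta.to_dict(),
                    }
                scores = pca_projection(voc)
                report["pca"] = {
                    f"{c}|{t}": [float(a), float(b)]
                    for (c, t), (a, b) in scores.iterrows()
                }
            if config.persistence:
                log = read_table(_require(config.persistence, stage), "persistence")
                summary = track_persistence(log)
                report["persistence"] = {
                    "last_detected": summary.last_detected.to_dict(),
                    "survivor_counts": {
                        str(d): int(v) for d, v in summary.survivor_counts.items()
                    },
                }
            (out / "stability_report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
            manifest["stages"].append(stage)
        except FermentomeError:
            raise
        except Exception as e:
            raise StageError(stage, str(e)) from e

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
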