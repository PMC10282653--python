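"""End-to-end orchestration of the profiling study.

Ties the stages together in the order of the study workflow: tag database
(build or load) -> per-sample QC + profiling -> merged abundance table ->
alpha/beta diversity with group tests -> differential-abundance screen ->
random-forest marker discovery.  Emits a machine-readable summary plus the
per-stage tables, all reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import classifier as clf
from . import diffabund, ecology
from .digest import UniqueTagDB
from .ecology import AbundanceTable
from .profiler import DEFAULT_G_THRESHOLD, SampleProfile, merge_profiles, profile_sample
from .readqc import QCPolicy

__all__ = [
    "StudyParams",
    "StudyResult",
    "stage_seed",
    "venn_counts",
    "venn_union_total",
    "run_study",
]

log = logging.getLogger("twobrad")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministically derive a per-stage sub-seed from the global seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def venn_counts(presence: Mapping[str, set]) -> dict[str, int]:
    """Shared/exclusive species counts for a two-group presence map."""
    (ga, sa), (gb, sb) = sorted(presence.items())
    return {
        "shared": len(sa & sb),
        f"only_{ga}": len(sa - sb),
        f"only_{gb}": len(sb - sa),
        "total": len(sa | sb),
    }


def venn_union_total(shared: int, only_a: int, only_b: int) -> int:
    """|A ∪ B| from the shared and exclusive counts (inclusion-exclusion)."""
    return shared + only_a + only_b


@dataclass(frozen=True)
class StudyParams:
    """Stage parameters for a full study run."""

    qc: QCPolicy = field(default_factory=QCPolicy)
    g_threshold: float = DEFAULT_G_THRESHOLD
    beta_metrics: tuple[str, ...] = ecology.BETA_METRICS
    n_permutations: int = 999
    alpha: float = 0.05
    lda_cutoff: float = 4.0
    lda_boots: int = 30
    positive_group: str | None = None
    top_n: int = 30
    n_trees: int = 500
    folds: int = 5
    seed: int = 0


@dataclass
class StudyResult:
    summary: dict
    table: AbundanceTable
    profiles: list[SampleProfile]
    alpha: pd.DataFrame
    lefse_report: pd.DataFrame
    classifier: clf.ClassifierResult | None


def run_study(
    db: UniqueTagDB,
    fastq_paths: Mapping[str, str | Path],
    groups: pd.Series,
    taxonomy: pd.DataFrame | None = None,
    params: StudyParams | None = None,
    outdir: str | Path | None = None,
) -> StudyResult:
    """Execute the full workflow and return (and optionally write) results."""
    params = params or StudyParams()
    seed = params.seed
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("profiling %d samples", len(fastq_paths))
    profiles = [
        profile_sample(path, db, params.qc, params.g_threshold, sample_id=sid)
        for sid, path in fastq_paths.items()
    ]
    abund, counts = merge_profiles(profiles)
    table = AbundanceTable(
        values=abund, counts=counts, groups=groups.reindex(abund.index),
        taxonomy=taxonomy,
    )

    group_names = table.group_names()
    presence = {
        g: set(sub.columns[(sub > 0).any(axis=0)])
        for g, sub in table.split_by_group().items()
    }
    venn = venn_counts(presence)
    venn["identity_ok"] = (
        venn_union_total(
            venn["shared"],
            venn[f"only_{group_names[0]}"],
            venn[f"only_{group_names[1]}"],
        )
        == venn["total"]
    )

    alpha = ecology.alpha_diversity(table)
    alpha_p = {
        metric: ecology.compare_alpha(alpha[metric].to_numpy(), alpha["group"])
        for metric in ("chao1", "shannon", "simpson")
    }

    beta = {}
    for metric in params.beta_metrics:
        dist = ecology.beta_distance(table, metric)
        coords, eigvals = ecology.pcoa(dist, k=min(3, len(table.samples) - 1))
        F, p = ecology.permanova(
            dist, table.groups, params.n_permutations,
            seed=stage_seed(seed, f"permanova:{metric}"),
        )
        beta[metric] = {"pseudo_F": F, "p": p}
        if outdir is not None:
            dist.to_frame().to_csv(outdir / f"distance_{metric}.tsv", sep="\t",
                                   float_format="%.6g")
            coords.to_csv(outdir / f"pcoa_{metric}.tsv", sep="\t",
                          float_format="%.6g")

    lefse_report = diffabund.lefse(
        table, alpha=params.alpha, lda_cutoff=params.lda_cutoff,
        n_boot=params.lda_boots, seed=stage_seed(seed, "lefse"),
    )

    result_clf = None
    positive = params.positive_group or group_names[-1]
    sizes = table.groups.value_counts()
    if len(group_names) == 2 and (sizes >= 2).all():
        result_clf = clf.run_classifier(
            table, positive=positive, top_n=params.top_n, folds=params.folds,
            config=clf.ForestConfig(n_trees=params.n_trees),
            seed=stage_seed(seed, "classifier"),
        )

    summary = {
        "seed": seed,
        "n_samples": len(table.samples),
        "group_sizes": {g: int(sizes[g]) for g in group_names},
        "clean_reads": {
            p.sample_id: (p.qc.n_pass if p.qc is not None else None)
            for p in profiles
        },
        "n_species_detected": int((table.values > 0).any(axis=0).sum()),
        "venn": venn,
        "alpha_p": alpha_p,
        "beta": beta,
        "n_discriminative_taxa": int(len(lefse_report)),
        "classifier": (
            None
            if result_clf is None
            else {
                "positive_group": positive,
                "selected_markers": result_clf.selected_markers,
                "auc": result_clf.auc,
                "pod_group_p": result_clf.pod_group_p,
            }
        ),
    }

    if outdir is not None:
        out_abund = table.values.copy()
        out_abund.index.name = "#sample_id"
        out_abund.to_csv(outdir / "abundance.tsv", sep="\t", float_format="%.6g")
        alpha.to_csv(outdir / "alpha.tsv", sep="\t", float_format="%.6g")
        lefse_report.to_csv(outdir / "lefse.tsv", sep="\t", index=False,
                            float_format="%.6g")
        for p in profiles:
            p.to_tsv(outdir / f"{p.sample_id}.profile.tsv")
        if result_clf is not None:
            result_clf.ranking.to_csv(outdir / "importance.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            result_clf.cv_error_curve.to_csv(outdir / "cv_curve.tsv", sep="\t",
                                             index=False, float_format="%.6g")
            result_clf.pod.to_csv(outdir / "pod.tsv", sep="\t",
                                  float_format="%.6g")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    return StudyResult(
        summary=summary, table=table, profiles=profiles, alpha=alpha,
        lefse_report=lefse_report, classifier=result_clf,
    )
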