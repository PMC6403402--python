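"""End-to-end orchestration: counts in, classified tables and report out.

Stage order: I/O -> SNV filtering -> diagnostic-SNP identification -> bias
estimation -> per-transcript quantification -> classification -> chi-squared
tests -> MGE grouping and enrichment.  All thresholds live in one
PipelineConfig so a run is fully described by a single document; outputs are
deterministic (no timestamps) so re-running on identical inputs is
byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as hio
from .bias import BiasModel, estimate_correction_factor, no_bias_model
from .classify import (
    ClassificationSummary,
    ClassifierConfig,
    TranscriptCall,
    consistent_mge,
    summarize_classification,
)
from .enrichment import EnrichmentResult, MgeGroup, assemble_mge_groups, hypergeometric_enrichment
from .io import DataError, LibraryMeta, SnvRecord
from .quant import TranscriptASE, quantify_library
from .snps import (
    DiagnosticSnp,
    SnvFilterCriteria,
    call_candidate_sites,
    identify_diagnostic_snps,
    partition_polymorphisms,
)
from .stats import TestResult, direction_test, ploidy_test

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_path: str | Path = "counts.tsv"
    meta_path: str | Path = "meta.tsv"
    annotation_path: str | Path | None = None
    out_dir: str | Path = "out"
    criteria: SnvFilterCriteria = field(default_factory=SnvFilterCriteria)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    min_reads: int = 20
    assume_no_bias: bool = False
    use_log_mean_bias: bool = False
    filter_after_correction: bool = False
    alpha: float = 0.05
    ease: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        crit = SnvFilterCriteria(**doc.pop("criteria", {}))
        clf = doc.pop("classifier", {})
        classifier = ClassifierConfig(
            diploid_window=tuple(clf.get("diploid_window", (0.3, 0.7))),
            triploid_window=tuple(clf.get("triploid_window", (0.5, 0.9))),
            silencing_cutoff=clf.get("silencing_cutoff", 0.1),
        )
        return cls(criteria=crit, classifier=classifier, **doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "counts_path": str(self.counts_path),
            "meta_path": str(self.meta_path),
            "annotation_path": (
                str(self.annotation_path) if self.annotation_path else None
            ),
            "out_dir": str(self.out_dir),
            "criteria": {
                "min_consensus_quality": self.criteria.min_consensus_quality,
                "min_depth": self.criteria.min_depth,
                "min_spacing": self.criteria.min_spacing,
                "min_border_distance": self.criteria.min_border_distance,
            },
            "classifier": {
                "diploid_window": list(self.classifier.diploid_window),
                "triploid_window": list(self.classifier.triploid_window),
                "silencing_cutoff": self.classifier.silencing_cutoff,
            },
            "min_reads": self.min_reads,
            "assume_no_bias": self.assume_no_bias,
            "use_log_mean_bias": self.use_log_mean_bias,
            "filter_after_correction": self.filter_after_correction,
            "alpha": self.alpha,
            "ease": self.ease,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class PipelineBundle:
    """Everything a run produces, in memory."""

    meta: list[LibraryMeta]
    n_input_sites: int
    n_candidate_sites: int
    snps: list[DiagnosticSnp]
    bias_model: BiasModel
    ase: dict[str, list[TranscriptASE]]
    calls: dict[str, list[TranscriptCall]]
    summaries: dict[str, ClassificationSummary]
    tests: list[tuple[str, str, TestResult]]  # (name, kind, result)
    groups: list[MgeGroup]
    consistent_p: set[str]
    consistent_a: set[str]
    enrichment: list[EnrichmentResult]
    config: PipelineConfig


def run_from_records(
    records: Sequence[SnvRecord],
    meta: Sequence[LibraryMeta],
    config: PipelineConfig,
    annotation: hio.AnnotationMap | None = None,
) -> PipelineBundle:
    """Run every analysis stage on in-memory records."""
    records = sorted(records, key=lambda r: r.key)
    meta = list(meta)
    candidates = call_candidate_sites(records, config.criteria)
    log.info("stage filter: %d -> %d sites", len(records), len(candidates))

    parental = [m for m in meta if m.is_parental]
    fixed, het_sites = partition_polymorphisms(candidates, parental)
    snps = identify_diagnostic_snps(candidates, fixed, meta)
    log.info(
        "stage diagnostic: %d SNPs, %d intragenomic het sites",
        len(snps),
        len(het_sites),
    )
    if not snps:
        raise DataError("pipeline: no diagnostic SNPs survive the filters")

    if config.assume_no_bias:
        model = no_bias_model()
    else:
        model = estimate_correction_factor(
            het_sites, meta, use_log_mean=config.use_log_mean_bias
        )
    log.info("stage bias: C = %.4f", model.correction_factor)

    rec_by_key = {r.key: r for r in records}
    hybrids = [m for m in meta if m.is_hybrid]
    ase: dict[str, list[TranscriptASE]] = {}
    calls: dict[str, list[TranscriptCall]] = {}
    summaries: dict[str, ClassificationSummary] = {}
    meta_by_id = {m.library_id: m for m in meta}
    from .classify import classify_transcript

    for m in hybrids:
        lib_ase = quantify_library(
            rec_by_key,
            snps,
            m.library_id,
            model,
            min_reads=config.min_reads,
            filter_after_correction=config.filter_after_correction,
        )
        if not lib_ase:
            raise DataError(
                f"pipeline: hybrid library {m.library_id!r} has no transcripts "
                "with sufficient diagnostic-site support"
            )
        ase[m.library_id] = lib_ase
        lib_calls = [
            classify_transcript(
                t.transcript_id, m.library_id, t.f_a, m.ploidy, config.classifier
            )
            for t in lib_ase
        ]
        calls[m.library_id] = lib_calls
        summaries[m.library_id] = summarize_classification(lib_calls)

    tests: list[tuple[str, str, TestResult]] = []
    for lib, s in summaries.items():
        if s.n_heb >= 1:
            tests.append(
                (lib, "direction", direction_test(s.n_heb_p, s.n_heb_a, config.alpha))
            )
    by_tissue: dict[str, dict[int, ClassificationSummary]] = {}
    for lib, s in summaries.items():
        by_tissue.setdefault(meta_by_id[lib].tissue, {})[meta_by_id[lib].ploidy] = s
    for tissue, per_ploidy in sorted(by_tissue.items()):
        if {2, 3} <= set(per_ploidy):
            s2, s3 = per_ploidy[2], per_ploidy[3]
            table = [[s2.n_heb, s2.n_bhe], [s3.n_heb, s3.n_bhe]]
            if min(s2.n_heb + s3.n_heb, s2.n_bhe + s3.n_bhe) > 0:
                tests.append((tissue, "ploidy", ploidy_test(table)))
            else:
                log.info(
                    "ploidy test skipped for %s: a category is empty", tissue
                )

    groups = assemble_mge_groups(calls, meta)
    cons_p, cons_a = consistent_mge(calls)

    enrichment: list[EnrichmentResult] = []
    if annotation is not None:
        group_libs = {m.library_id: m for m in hybrids}
        for g in groups:
            label = g.group_id.rsplit("_", 1)[0]
            background = set()
            for lib, m in group_libs.items():
                key = m.tissue if g.axis == "tissue" else m.genomotype
                if key == label:
                    background.update(t.transcript_id for t in ase[lib])
            if not background:
                continue
            enrichment.extend(
                hypergeometric_enrichment(g, background, annotation, ease=config.ease)
            )

    return PipelineBundle(
        meta=meta,
        n_input_sites=len(records),
        n_candidate_sites=len(candidates),
        snps=snps,
        bias_model=model,
        ase=ase,
        calls=calls,
        summaries=summaries,
        tests=tests,
        groups=groups,
        consistent_p=cons_p,
        consistent_a=cons_a,
        enrichment=enrichment,
        config=config,
    )


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Load inputs from the configured paths, run all stages, write outputs."""
    meta = hio.read_meta(config.meta_path)
    records = hio.read_count_table(config.counts_path, meta)
    annotation = (
        hio.read_annotation(config.annotation_path)
        if config.annotation_path
        else None
    )
    bundle = run_from_records(records, meta, config, annotation)
    write_bundle(bundle, Path(config.out_dir))
    return bundle


# ---------------------------------------------------------------------------
# output


def write_bundle(bundle: PipelineBundle, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "library_id": c.library_id,
                "transcript_id": c.transcript_id,
                "ploidy": c.ploidy,
                "f_A": f"{c.f_a:.6f}",
                "category": c.category,
                "mge": c.mge,
            }
            for lib in sorted(bundle.calls)
            for c in sorted(bundle.calls[lib], key=lambda c: c.transcript_id)
        ]
    ).to_csv(out_dir / "calls.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "BHE": s.n_bhe,
                "BHE_pct": s.percentages["BHE"],
                "HEB": s.n_heb,
                "HEB_pct": s.percentages["HEB"],
                "HEB_P": s.n_heb_p,
                "HEB_P_pct": s.percentages["HEB_P"],
                "HEB_A": s.n_heb_a,
                "HEB_A_pct": s.percentages["HEB_A"],
                "MGE_P": s.n_mge_p,
                "MGE_P_pct": s.percentages["MGE_P"],
                "MGE_A": s.n_mge_a,
                "MGE_A_pct": s.percentages["MGE_A"],
                "total": s.n_total,
            }
            for _, s in sorted(bundle.summaries.items())
        ]
    ).to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "name": name,
                "test": kind,
                "chi2": f"{r.statistic:.4f}",
                "df": r.df,
                "p_value": f"{r.p_value:.3e}",
                "direction": r.direction,
            }
            for name, kind, r in bundle.tests
        ]
    ).to_csv(out_dir / "tests.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "axis": g.axis,
                "genome": g.genome,
                "n_members": len(g.members),
                "members": ",".join(sorted(g.members)),
            }
            for g in bundle.groups
        ]
    ).to_csv(out_dir / "groups.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"mge": "P", "transcript_id": t}
            for t in sorted(bundle.consistent_p)
        ]
        + [
            {"mge": "A", "transcript_id": t}
            for t in sorted(bundle.consistent_a)
        ]
    ).to_csv(out_dir / "consistent_mge.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "term_id": r.term_id,
                "namespace": r.namespace,
                "k": r.k,
                "K": r.big_k,
                "n": r.n,
                "N": r.big_n,
                "p": f"{r.p_value:.4e}",
                "p_benjamini": f"{r.p_adjusted:.4e}",
            }
            for r in bundle.enrichment
        ]
    ).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    with open(out_dir / "bias.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "correction_factor": float(bundle.bias_model.correction_factor),
                "per_sample_mean": {
                    k: float(v)
                    for k, v in sorted(bundle.bias_model.per_sample_mean.items())
                },
                "n_sites_used": dict(sorted(bundle.bias_model.n_sites_used.items())),
                "excluded_libraries": bundle.bias_model.excluded_libraries,
            },
            fh,
            sort_keys=False,
        )

    cfg = bundle.config
    run_log = [
        "homeobias run log",
        f"input sites: {bundle.n_input_sites}",
        f"sites after SNV filters: {bundle.n_candidate_sites}",
        f"diagnostic SNPs: {len(bundle.snps)}",
        f"correction factor C: {bundle.bias_model.correction_factor:.6f}",
        f"min consensus quality: {cfg.criteria.min_consensus_quality}",
        f"min depth: {cfg.criteria.min_depth}",
        f"min spacing: {cfg.criteria.min_spacing}",
        f"min border distance: {cfg.criteria.min_border_distance}",
        f"min supporting reads: {cfg.min_reads}",
        f"diploid balance window: {cfg.classifier.diploid_window}",
        f"triploid balance window: {cfg.classifier.triploid_window}",
        f"silencing cutoff: {cfg.classifier.silencing_cutoff}",
        f"alpha: {cfg.alpha}",
    ]
    (out_dir / "run_log.txt").write_text("\n".join(run_log) + "\n")
    (out_dir / "report.md").write_text(render_report(bundle))


def render_report(bundle: PipelineBundle) -> str:
    """Human-readable markdown summary of a run."""
    lines = ["# Homoeolog expression analysis", ""]
    lines.append(
        f"Diagnostic SNPs: {len(bundle.snps)}; reference-bias correction "
        f"factor C = {bundle.bias_model.correction_factor:.4f}"
    )
    lines += ["", "## Per-library classification", ""]
    lines.append(
        "| library | BHE | HEB | HEB(P) | HEB(A) | MGE(P) | MGE(A) | total |"
    )
    lines.append("|---|---|---|---|---|---|---|---|")
    for lib in sorted(bundle.summaries):
        s = bundle.summaries[lib]
        p = s.percentages
        lines.append(
            f"| {lib} | {s.n_bhe} ({p['BHE']}%) | {s.n_heb} ({p['HEB']}%) "
            f"| {s.n_heb_p} ({p['HEB_P']}%) | {s.n_heb_a} ({p['HEB_A']}%) "
            f"| {s.n_mge_p} ({p['MGE_P']}%) | {s.n_mge_a} ({p['MGE_A']}%) "
            f"| {s.n_total} |"
        )
    lines += ["", "## Chi-squared tests", ""]
    lines.append("| comparison | test | chi2 | p | direction |")
    lines.append("|---|---|---|---|---|")
    for name, kind, r in bundle.tests:
        lines.append(
            f"| {name} | {kind} | {r.statistic:.2f} | {r.p_value:.2e} "
            f"| {r.direction} |"
        )
    lines += ["", "## Monogenomic expression groups", ""]
    for g in bundle.groups:
        lines.append(f"- {g.group_id} ({g.axis}): {len(g.members)} transcripts")
    lines.append(
        f"- consistent MGE(P) across all hybrid libraries: "
        f"{len(bundle.consistent_p)}"
    )
    lines.append(
        f"- consistent MGE(A) across all hybrid libraries: "
        f"{len(bundle.consistent_a)}"
    )
    lines += ["", "## Functional enrichment", ""]
    sig = [r for r in bundle.enrichment if r.p_adjusted <= 0.05]
    if sig:
        lines.append("| group | term | namespace | k | p (Benjamini) |")
        lines.append("|---|---|---|---|---|")
        for r in sig:
            lines.append(
                f"| {r.group_id} | {r.term_id} | {r.namespace} | {r.k} "
                f"| {r.p_adjusted:.3e} |"
            )
    else:
        lines.append("no significant enrichment")
    return "\n".join(lines) + "\n"
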