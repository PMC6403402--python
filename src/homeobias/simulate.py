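"""Synthetic allele-count libraries with known ground truth.

The generator emulates the study design this pipeline targets: several PP and
AA parental libraries plus PA (diploid) and PAA (triploid) hybrid libraries,
counted per site against a transcriptome assembly.  It produces

* diagnostic sites — fixed for the P variant in every PP library and for the
  A variant in every AA library; hybrid reads split between the two variants
  according to the transcript's true A-fraction theta;
* intragenomic heterozygous sites — one parental library heterozygous for
  (assembly reference base, other base) with a true 1:1 ratio distorted only
  by the mapping bias; these calibrate the correction factor;
* optional decoy sites that each violate exactly one SNV filter criterion.

Reference-mapping bias is a single multiplicative factor b shared by all
libraries: at any site the odds of a read carrying the assembly reference
base are multiplied by b.  Read depth is negative-binomial per site per
library (RNA-seq overdispersion).  True theta per transcript is drawn from a
beta distribution truncated to the transcript class's fraction window at the
library's ploidy, so truth labels and classifier geometry agree by
construction.

What it does not emulate: read-level errors, alignment, isoforms, varying
bias across loci, or expression-level differences between transcripts beyond
the allele split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .classify import (
    CATEGORY_BHE,
    CATEGORY_HEB_A,
    CATEGORY_HEB_P,
    MGE_A,
    MGE_P,
    ClassifierConfig,
)
from .io import BASES, DataError, LibraryMeta, SnvRecord

log = logging.getLogger(__name__)

CLASSES = (CATEGORY_BHE, CATEGORY_HEB_P, CATEGORY_HEB_A, MGE_P, MGE_A)

DECOY_REASONS = ("low_quality", "shallow_depth", "spacing", "border")

#: the study's library design: 5 PP and 4 AA parental libraries, with the
#: mixed-ploidy AA brain/gonad pools excluded from bias estimation, and four
#: hybrid libraries crossing tissue with ploidy.
DEFAULT_PARENTAL = (
    ("liv-PP", "PP", "liver", True),
    ("brainF-PP", "PP", "brain", True),
    ("brainM-PP", "PP", "brain", True),
    ("gonF-PP", "PP", "gonad", True),
    ("gonM-PP", "PP", "gonad", True),
    ("liv-AA", "AA", "liver", True),
    ("juv-AA", "AA", "juvenile", True),
    ("brain-AA", "AA", "brain", False),
    ("gon-AA", "AA", "gonad", False),
)
DEFAULT_HYBRIDS = (
    ("liv-PA", "PA", "liver"),
    ("liv-PAA", "PAA", "liver"),
    ("juv-PA", "PA", "juvenile"),
    ("juv-PAA", "PAA", "juvenile"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the target study where it states them: ~2.5 diagnostic
    SNVs per transcript (2807 SNPs over 1121 transcripts in the diploid
    liver library), the 5 PP / 4 AA parental panel with two AA libraries
    excluded from bias estimation, and a class mixture matching the diploid
    liver summary row (68% balanced, 12%/3% monogenomic).  Where the study
    is silent the values are chosen as typical bulk RNA-seq conditions:
    negative-binomial depth (mean 100, dispersion 5), 800 bp mean contig
    length, bias factor 1.2, ref-is-A probability 0.5.
    """

    n_transcripts: int = 1000
    transcript_length_mean: int = 800
    sites_per_transcript_mean: float = 2.5
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0
    class_mixture: tuple[float, float, float, float, float] = (
        0.68,
        0.11,
        0.06,
        0.12,
        0.03,
    )  # (BHE, HEB_P, HEB_A, MGE_P, MGE_A)
    class_theta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {c: (3.0, 3.0) for c in CLASSES}
    )
    reference_bias: float = 1.2
    ref_is_A_prob: float = 0.5
    parental_het_rate: float = 0.1
    parental_libraries: tuple[tuple[str, str, str, bool], ...] = DEFAULT_PARENTAL
    hybrid_libraries: tuple[tuple[str, str, str], ...] = DEFAULT_HYBRIDS
    n_decoys_per_criterion: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-12:
            raise DataError("class mixture must sum to 1")
        if self.reference_bias <= 0:
            raise DataError("reference bias factor must be positive")
        if not 0 <= self.ref_is_A_prob <= 1:
            raise DataError("ref_is_A_prob must be a probability")
        if self.sites_per_transcript_mean < 1:
            raise DataError("sites_per_transcript_mean must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "class_mixture" in doc:
            doc["class_mixture"] = tuple(doc["class_mixture"])
        if "class_theta" in doc:
            doc["class_theta"] = {
                k: tuple(v) for k, v in doc["class_theta"].items()
            }
        if "parental_libraries" in doc:
            doc["parental_libraries"] = tuple(
                tuple(x) for x in doc["parental_libraries"]
            )
        if "hybrid_libraries" in doc:
            doc["hybrid_libraries"] = tuple(
                tuple(x) for x in doc["hybrid_libraries"]
            )
        if "classifier" in doc:
            clf = doc["classifier"]
            doc["classifier"] = ClassifierConfig(
                diploid_window=tuple(clf.get("diploid_window", (0.3, 0.7))),
                triploid_window=tuple(clf.get("triploid_window", (0.5, 0.9))),
                silencing_cutoff=clf.get("silencing_cutoff", 0.1),
            )
        return cls(**doc)

    def build_meta(self) -> list[LibraryMeta]:
        metas = [
            LibraryMeta(lib, g, t, 2, use_bias)
            for lib, g, t, use_bias in self.parental_libraries
        ]
        metas += [
            LibraryMeta(lib, g, t, 3 if g == "PAA" else 2, False)
            for lib, g, t in self.hybrid_libraries
        ]
        return metas


@dataclass(frozen=True)
class SiteTruth:
    kind: str  # "diagnostic" | "het" | "decoy"
    p_base: str
    a_base: str
    ref_matches: str  # "P" or "A"
    het_library: str | None = None
    decoy_reason: str | None = None


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    transcript_class: dict[str, str] = field(default_factory=dict)
    theta: dict[tuple[str, int], float] = field(default_factory=dict)
    sites: dict[tuple[str, int], SiteTruth] = field(default_factory=dict)
    bias: float = 1.0

    def diagnostic_keys(self) -> set[tuple[str, int]]:
        return {k for k, s in self.sites.items() if s.kind == "diagnostic"}

    def expected_call(
        self, transcript_id: str, ploidy: int, config: ClassifierConfig
    ) -> tuple[str, str]:
        """(category, mge) the classifier should assign at this ploidy,
        implied by the true theta (the mixture label is per transcript, but
        the category it maps to depends on the ploidy's windows)."""
        from .classify import classify_transcript

        theta = self.theta[(transcript_id, ploidy)]
        call = classify_transcript(transcript_id, "truth", theta, ploidy, config)
        return call.category, call.mge


def effective_a_probability(theta_a: float, b: float, ref_is_a: bool) -> float:
    """Probability that a mapped read carries the A variant, given the true
    A-fraction theta and bias b favouring the reference-matching variant."""
    if not 0 <= theta_a <= 1:
        raise DataError(f"theta must be in [0, 1], got {theta_a}")
    if ref_is_a:
        return theta_a * b / (theta_a * b + (1 - theta_a))
    return theta_a / (theta_a + (1 - theta_a) * b)


def simulate_site_counts(
    theta_a: float,
    depth: int,
    b: float,
    ref_is_a: bool,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Binomially split ``depth`` reads into (reads_P, reads_A)."""
    if depth < 0:
        raise DataError("depth must be non-negative")
    p_a = effective_a_probability(theta_a, b, ref_is_a)
    reads_a = int(rng.binomial(depth, p_a))
    return depth - reads_a, reads_a


def _class_window(
    label: str, ploidy: int, cfg: ClassifierConfig
) -> tuple[float, float]:
    lo, hi = cfg.window(ploidy)
    tau = cfg.silencing_cutoff
    return {
        CATEGORY_BHE: (lo, hi),
        CATEGORY_HEB_P: (tau, lo),
        CATEGORY_HEB_A: (hi, 1 - tau),
        MGE_P: (0.0, tau),
        MGE_A: (1 - tau, 1.0),
    }[label]


def draw_theta(
    label: str,
    ploidy: int,
    cfg: ClassifierConfig,
    shape: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """Sample theta from a Beta(shape) rescaled onto the class window at
    this ploidy (theta = lo + (hi - lo) * Beta), so the class's mass sits
    mid-window and classes are separable when the shape is peaked.

    A class window can be degenerate at some ploidy (with the default
    config, biased-toward-A-but-not-silenced at triploidy is exactly the
    boundary point 0.9); then the boundary value itself is returned.
    """
    lo, hi = _class_window(label, ploidy, cfg)
    if hi - lo <= 0:
        return lo
    a, b = shape
    theta = lo + (hi - lo) * float(rng.beta(a, b))
    return min(max(theta, np.nextafter(lo, 1.0)), np.nextafter(hi, 0.0))


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # negative binomial parameterised by mean and size (dispersion)
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _site_positions(
    length: int, n_sites: int, rng: np.random.Generator, spacing: int = 5, border: int = 5
) -> list[int]:
    lo, hi = border + 2, length - border - 1  # min(pos-1, len-pos) > border
    if hi < lo:
        return []
    pool = np.arange(lo, hi + 1)
    take = min(n_sites * 3, pool.size)
    cand = np.sort(rng.choice(pool, size=take, replace=False))
    kept: list[int] = []
    for pos in cand:
        if not kept or pos - kept[-1] >= spacing:
            kept.append(int(pos))
        if len(kept) == n_sites:
            break
    return kept


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in BASES if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def simulate_complex(
    config: SimulationConfig,
) -> tuple[list[SnvRecord], list[LibraryMeta], GroundTruth]:
    """Generate the full library panel with ground truth.

    Parental libraries are homozygous for their genome's variant at
    diagnostic sites; each heterozygous site belongs to one parental library
    with a true 1:1 allele ratio distorted only by the bias; hybrid counts
    at diagnostic sites follow the transcript's theta at the library's
    ploidy.  Output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    meta = config.build_meta()
    truth = GroundTruth(bias=config.reference_bias)
    records: list[SnvRecord] = []
    mix = np.asarray(config.class_mixture)
    cls_cfg = config.classifier
    b = config.reference_bias

    for i in range(config.n_transcripts):
        tid = f"tr{i:05d}"
        length = max(60, int(rng.normal(config.transcript_length_mean,
                                        config.transcript_length_mean / 4)))
        n_sites = 1 + int(rng.poisson(config.sites_per_transcript_mean - 1))
        positions = _site_positions(length, n_sites, rng)
        if not positions:
            continue
        label = CLASSES[int(rng.choice(len(CLASSES), p=mix))]
        truth.transcript_class[tid] = label
        for ploidy in (2, 3):
            truth.theta[(tid, ploidy)] = draw_theta(
                label, ploidy, cls_cfg, config.class_theta[label], rng
            )
        for pos in positions:
            is_het = rng.uniform() < config.parental_het_rate
            if is_het:
                rec, site = _make_het_site(tid, pos, length, config, meta, rng)
            else:
                rec, site = _make_diagnostic_site(
                    tid, pos, length, config, meta, truth, rng
                )
            records.append(rec)
            truth.sites[(tid, pos)] = site

    if config.n_decoys_per_criterion > 0:
        decoys, decoy_truth = emit_decoy_sites(
            config, rng, anchors=records, n_per_criterion=config.n_decoys_per_criterion
        )
        records.extend(decoys)
        truth.sites.update(decoy_truth)

    records.sort(key=lambda r: r.key)
    return records, meta, truth


def _counts_for(base_reads: dict[str, int]) -> tuple[int, int, int, int]:
    cs = [0, 0, 0, 0]
    for base, n in base_reads.items():
        cs[BASES.index(base)] += n
    return tuple(cs)  # type: ignore[return-value]


def _make_diagnostic_site(
    tid: str,
    pos: int,
    length: int,
    config: SimulationConfig,
    meta: Sequence[LibraryMeta],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[SnvRecord, SiteTruth]:
    p_base = BASES[int(rng.integers(4))]
    a_base = _other_base(rng, p_base)
    ref_is_a = rng.uniform() < config.ref_is_A_prob
    ref_base = a_base if ref_is_a else p_base
    b = config.reference_bias
    counts = {}
    for m in meta:
        depth = _nb_depth(rng, config.depth_mean, config.depth_dispersion)
        if m.genomotype == "PP":
            counts[m.library_id] = _counts_for({p_base: depth})
        elif m.genomotype == "AA":
            counts[m.library_id] = _counts_for({a_base: depth})
        else:
            theta = truth.theta[(tid, m.ploidy)]
            reads_p, reads_a = simulate_site_counts(theta, depth, b, ref_is_a, rng)
            counts[m.library_id] = _counts_for({p_base: reads_p, a_base: reads_a})
    rec = SnvRecord(
        transcript_id=tid,
        position=pos,
        transcript_length=length,
        ref_base=ref_base,
        consensus_quality=40,
        counts=counts,
    )
    site = SiteTruth(
        kind="diagnostic",
        p_base=p_base,
        a_base=a_base,
        ref_matches="A" if ref_is_a else "P",
    )
    return rec, site


def _make_het_site(
    tid: str,
    pos: int,
    length: int,
    config: SimulationConfig,
    meta: Sequence[LibraryMeta],
    rng: np.random.Generator,
) -> tuple[SnvRecord, SiteTruth]:
    """One parental library heterozygous (ref base vs other); everyone else
    monomorphic for the reference base, so the site is never diagnostic."""
    ref_base = BASES[int(rng.integers(4))]
    alt_base = _other_base(rng, ref_base)
    parental = [m for m in meta if m.is_parental]
    het_lib = parental[int(rng.integers(len(parental)))].library_id
    b = config.reference_bias
    counts = {}
    for m in meta:
        depth = _nb_depth(rng, config.depth_mean, config.depth_dispersion)
        if m.library_id == het_lib:
            n_ref = int(rng.binomial(depth, b / (1.0 + b)))
            counts[m.library_id] = _counts_for(
                {ref_base: n_ref, alt_base: depth - n_ref}
            )
        else:
            counts[m.library_id] = _counts_for({ref_base: depth})
    rec = SnvRecord(
        transcript_id=tid,
        position=pos,
        transcript_length=length,
        ref_base=ref_base,
        consensus_quality=40,
        counts=counts,
    )
    site = SiteTruth(
        kind="het",
        p_base=ref_base,
        a_base=alt_base,
        ref_matches="P",
        het_library=het_lib,
    )
    return rec, site


def write_simulation(
    records: Sequence[SnvRecord],
    meta: Sequence[LibraryMeta],
    truth: GroundTruth,
    out_dir,
) -> None:
    """Write counts.tsv, meta.tsv and truth.tsv (+ truth_transcripts.tsv)."""
    import pandas as pd

    from .io import write_count_table, write_meta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(records, out / "counts.tsv")
    write_meta(meta, out / "meta.tsv")
    pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "pos": pos,
                "kind": s.kind,
                "p_base": s.p_base,
                "a_base": s.a_base,
                "ref_matches": s.ref_matches,
                "het_library": s.het_library or "",
                "decoy_reason": s.decoy_reason or "",
            }
            for (tid, pos), s in sorted(truth.sites.items())
        ]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "class": truth.transcript_class[tid],
                "theta_diploid": f"{truth.theta[(tid, 2)]:.6f}",
                "theta_triploid": f"{truth.theta[(tid, 3)]:.6f}",
                "bias": truth.bias,
            }
            for tid in sorted(truth.transcript_class)
        ]
    ).to_csv(out / "truth_transcripts.tsv", sep="\t", index=False)


def emit_decoy_sites(
    config: SimulationConfig,
    rng: np.random.Generator,
    anchors: Sequence[SnvRecord] = (),
    n_per_criterion: int = 1,
) -> tuple[list[SnvRecord], dict[tuple[str, int], SiteTruth]]:
    """Build sites that each violate exactly one SNV filter criterion.

    Criteria: low consensus quality, shallow depth in one library, spacing
    (< 5 bp after an anchor site — requires ``anchors``), and border
    proximity.  Decoys otherwise look like clean diagnostic sites, so a
    correct filter removes the decoys and nothing else.
    """
    meta = config.build_meta()
    decoys: list[SnvRecord] = []
    truth: dict[tuple[str, int], SiteTruth] = {}
    anchor_keys = {r.key for r in anchors}

    def fresh_site(tid: str, pos: int, length: int, qual: int = 40,
                   shallow_lib: str | None = None) -> SnvRecord:
        p_base, a_base = "C", "T"
        counts = {}
        for m in meta:
            depth = 2 if m.library_id == shallow_lib else 30
            base = p_base if m.genomotype in ("PP", "PA", "PAA") else a_base
            if m.genomotype in ("PA", "PAA"):
                counts[m.library_id] = _counts_for(
                    {p_base: depth // 2, a_base: depth - depth // 2}
                )
            else:
                counts[m.library_id] = _counts_for({base: depth})
        return SnvRecord(
            transcript_id=tid, position=pos, transcript_length=length,
            ref_base=p_base, consensus_quality=qual, counts=counts,
        )

    # anchors must themselves survive filtering, or the spacing violation
    # would never be evaluated against them
    from .snps import call_candidate_sites

    kept_anchors = call_candidate_sites(sorted(anchors, key=lambda r: r.key))
    spacing_anchors = [
        r for r in kept_anchors
        if r.position + 2 <= r.transcript_length - 6
        and (r.transcript_id, r.position + 2) not in anchor_keys
    ]
    for j in range(n_per_criterion):
        for reason in DECOY_REASONS:
            if reason == "low_quality":
                rec = fresh_site(f"decoyq{j:03d}", 100, 300, qual=19)
            elif reason == "shallow_depth":
                rec = fresh_site(
                    f"decoyd{j:03d}", 100, 300,
                    shallow_lib=meta[0].library_id,
                )
            elif reason == "border":
                rec = fresh_site(f"decoyb{j:03d}", 4, 300)
            else:  # spacing
                if not spacing_anchors:
                    raise DataError(
                        "spacing decoys need anchor sites to violate against"
                    )
                a = spacing_anchors[j % len(spacing_anchors)]
                rec = fresh_site(a.transcript_id, a.position + 2, a.transcript_length)
            if rec.key in truth:
                continue
            decoys.append(rec)
            truth[rec.key] = SiteTruth(
                kind="decoy", p_base="C", a_base="T", ref_matches="P",
                decoy_reason=reason,
            )
    return decoys, truth
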