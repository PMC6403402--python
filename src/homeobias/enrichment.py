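"""Monogenomic-expression groups and functional-term enrichment.

Transcripts with a monogenomic flag are pooled on two axes — sample type
(irrespective of ploidy) and genomotype (irrespective of sample type) — into
eight groups for liver/juvenile x PA/PAA designs: liver_P, liver_A,
juvenile_P, juvenile_A, PA_P, PA_A, PAA_P, PAA_A.  Each group is tested for
term over-representation against a background with the exact hypergeometric
upper tail P(X >= k), Benjamini–Hochberg-adjusted within (group, namespace).
An optional EASE-style conservative variant subtracts one from k before
taking the tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .classify import MGE_A, MGE_P, TranscriptCall
from .io import AnnotationMap, DataError, LibraryMeta
from .stats import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass
class MgeGroup:
    group_id: str
    axis: str  # "tissue" or "genomotype"
    genome: str  # "P" or "A"
    members: set[str]


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: str
    term_id: str
    namespace: str
    k: int  # group members with the term
    big_k: int  # background members with the term
    n: int  # group size
    big_n: int  # background size
    p_value: float
    p_adjusted: float


def assemble_mge_groups(
    calls_by_library: Mapping[str, Sequence[TranscriptCall]],
    meta: Sequence[LibraryMeta],
) -> list[MgeGroup]:
    """Pool MGE transcripts by tissue and by genomotype (union semantics:
    a transcript joins tissue group liver_P if it is MGE_P in any liver
    hybrid library, and so on)."""
    meta_by_id = {m.library_id: m for m in meta}
    hybrid_libs = [
        lib for lib in calls_by_library if meta_by_id[lib].is_hybrid
    ]
    tissues = sorted({meta_by_id[lib].tissue for lib in hybrid_libs})
    genomotypes = sorted({meta_by_id[lib].genomotype for lib in hybrid_libs})
    groups: list[MgeGroup] = []
    for axis, labels in (("tissue", tissues), ("genomotype", genomotypes)):
        for label in labels:
            for genome, flag in (("P", MGE_P), ("A", MGE_A)):
                members = set()
                for lib in hybrid_libs:
                    m = meta_by_id[lib]
                    key = m.tissue if axis == "tissue" else m.genomotype
                    if key != label:
                        continue
                    members.update(
                        c.transcript_id
                        for c in calls_by_library[lib]
                        if c.mge == flag
                    )
                groups.append(
                    MgeGroup(
                        group_id=f"{label}_{genome}",
                        axis=axis,
                        genome=genome,
                        members=members,
                    )
                )
    if not hybrid_libs:
        log.warning("no hybrid libraries supplied; all MGE groups empty")
    return groups


def hypergeometric_enrichment(
    group: MgeGroup,
    background: Iterable[str],
    annotation: AnnotationMap,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of the group's terms.

    ``background`` is the transcript universe (the group must be a subset);
    p = P(X >= k) for k group members annotated with the term out of K
    annotated background members, group size n, background size N.  BH
    adjustment runs within each namespace; results sorted by adjusted then
    raw p-value.
    """
    bg = set(background)
    if not bg:
        raise DataError("empty enrichment background")
    if not group.members <= bg:
        raise DataError(f"group {group.group_id} is not a subset of the background")
    big_n = len(bg)
    n = len(group.members)
    terms = sorted(
        {t for tid in bg for t in annotation.terms_of(tid)}
    )
    raw: list[tuple[str, str, int, int, float]] = []
    for term in terms:
        with_term = annotation.transcripts_with(term) & bg
        big_k = len(with_term)
        k = len(with_term & group.members)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, big_n, big_k, n))
        ns, _ = annotation.term_info[term]
        raw.append((term, ns, k, big_k, p))
    results: list[EnrichmentResult] = []
    for ns in sorted({r[1] for r in raw}):
        ns_rows = [r for r in raw if r[1] == ns]
        adj = benjamini_hochberg([r[4] for r in ns_rows])
        for (term, _, k, big_k, p), pa in zip(ns_rows, adj):
            results.append(
                EnrichmentResult(
                    group_id=group.group_id,
                    term_id=term,
                    namespace=ns,
                    k=k,
                    big_k=big_k,
                    n=n,
                    big_n=big_n,
                    p_value=p,
                    p_adjusted=float(pa),
                )
            )
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term_id))
    return results
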