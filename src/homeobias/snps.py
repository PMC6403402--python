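"""SNV filtering and genome-diagnostic SNP identification.

A diagnostic SNP is a transcript position fixed for one base across every AA
(Anaecypris-like) parental library and for a different base across every PP
(S. pyrenaicus) library.  At such positions hybrid reads can be assigned to
the P or A genome.  Heterozygous sites inside a single parental library
(intragenomic polymorphisms) are split off separately: under a true 1:1
allelic expectation they calibrate the reference-mapping bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import BASES, DataError, LibraryMeta, SnvRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnvFilterCriteria:
    """Site-acceptance thresholds applied before any downstream analysis.

    Defaults: consensus quality >= 20, per-library depth >= 3 wherever the
    site is covered, spacing to the previously kept candidate >= 5 bp, and
    distance from both transcript ends strictly > 5 bp.
    """

    min_consensus_quality: int = 20
    min_depth: int = 3
    min_spacing: int = 5
    min_border_distance: int = 5

    def __post_init__(self) -> None:
        if min(
            self.min_consensus_quality,
            self.min_depth,
            self.min_spacing,
            self.min_border_distance,
        ) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class DiagnosticSnp:
    """A genome-diagnostic position: P and A variants and which one equals
    the assembly reference base."""

    transcript_id: str
    position: int
    p_base: str
    a_base: str
    ref_matches: str  # "P" or "A"

    def __post_init__(self) -> None:
        if self.p_base == self.a_base:
            raise DataError("diagnostic SNP variants must differ")
        if self.ref_matches not in ("P", "A"):
            raise DataError("ref_matches must be 'P' or 'A'")

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass(frozen=True)
class HetSite:
    """An intragenomic heterozygous site in one parental library.

    ``count_ref`` is the reads of the reference-matching variant,
    ``count_alt`` the reads of the other variant; both are positive by
    definition of heterozygosity.
    """

    library_id: str
    transcript_id: str
    position: int
    count_ref: int
    count_alt: int

    def __post_init__(self) -> None:
        if self.count_ref <= 0 or self.count_alt <= 0:
            raise DataError("heterozygous site needs both counts > 0")


def call_candidate_sites(
    records: Sequence[SnvRecord], criteria: SnvFilterCriteria | None = None
) -> list[SnvRecord]:
    """Apply the SNV acceptance criteria; input must be (transcript, pos) sorted.

    Quality, border and depth rules act per site; the spacing rule is greedy
    left-to-right within each transcript: a candidate survives only if it
    lies >= min_spacing bp from the previously *kept* candidate.  Depth is
    checked in every library that covers the site at all (libraries with
    zero reads there are simply uninformative, not disqualifying).
    """
    criteria = criteria or SnvFilterCriteria()
    keys = [r.key for r in records]
    if keys != sorted(keys):
        raise DataError("call_candidate_sites requires (transcript, pos)-sorted input")
    kept: list[SnvRecord] = []
    last_kept_pos: dict[str, int] = {}
    for rec in records:
        if rec.consensus_quality < criteria.min_consensus_quality:
            continue
        if min(rec.position - 1, rec.transcript_length - rec.position) <= (
            criteria.min_border_distance
        ):
            continue
        depths = [rec.depth(lib) for lib in rec.counts]
        covered = [d for d in depths if d > 0]
        if covered and min(covered) < criteria.min_depth:
            continue
        prev = last_kept_pos.get(rec.transcript_id)
        if prev is not None and rec.position - prev < criteria.min_spacing:
            continue
        last_kept_pos[rec.transcript_id] = rec.position
        kept.append(rec)
    log.info("candidate filter: %d of %d sites retained", len(kept), len(records))
    return kept


def _call_library_base(
    counts: tuple[int, int, int, int],
    min_minor_reads: int = 2,
    min_minor_fraction: float = 0.1,
) -> tuple[str | None, tuple[str, str] | None]:
    """Classify one library's counts at a site.

    Returns (fixed_base, het_pair).  Exactly one is non-None for covered
    sites; both are None for uncovered sites.  A library is heterozygous when
    its second-most-common base has >= min_minor_reads reads AND >=
    min_minor_fraction of the site depth — singleton sequencing errors must
    not destroy a fixed call.
    """
    total = sum(counts)
    if total == 0:
        return None, None
    order = sorted(range(4), key=lambda i: (-counts[i], i))
    major, minor = order[0], order[1]
    if (
        counts[minor] >= min_minor_reads
        and counts[minor] / total >= min_minor_fraction
    ):
        return None, (BASES[major], BASES[minor])
    return BASES[major], None


def partition_polymorphisms(
    records: Iterable[SnvRecord],
    parental_meta: Sequence[LibraryMeta],
    min_minor_reads: int = 2,
    min_minor_fraction: float = 0.1,
) -> tuple[dict[tuple[str, int], dict[str, str]], list[HetSite]]:
    """Split parental-library calls into fixed bases and heterozygous sites.

    Returns ``(fixed, het_sites)`` where ``fixed`` maps
    (transcript, position) -> {library_id: fixed_base} over the parental
    libraries that are fixed there, and ``het_sites`` lists the intragenomic
    polymorphisms (ref/alt orientation taken from the record's reference
    base; a het pair not containing the reference base is oriented
    major/minor and still recorded).
    """
    parental = [m for m in parental_meta if m.is_parental]
    fixed: dict[tuple[str, int], dict[str, str]] = {}
    het_sites: list[HetSite] = []
    for rec in records:
        for m in parental:
            if m.library_id not in rec.counts:
                continue
            cs = rec.counts[m.library_id]
            base, het = _call_library_base(cs, min_minor_reads, min_minor_fraction)
            if base is not None:
                fixed.setdefault(rec.key, {})[m.library_id] = base
            elif het is not None:
                b1, b2 = het
                if rec.ref_base == b2:
                    b1, b2 = b2, b1
                het_sites.append(
                    HetSite(
                        library_id=m.library_id,
                        transcript_id=rec.transcript_id,
                        position=rec.position,
                        count_ref=cs[BASES.index(b1)],
                        count_alt=cs[BASES.index(b2)],
                    )
                )
    return fixed, het_sites


def identify_diagnostic_snps(
    records: Iterable[SnvRecord],
    fixed: dict[tuple[str, int], dict[str, str]],
    meta: Sequence[LibraryMeta],
    n_aa_required: int | None = None,
    n_pp_required: int | None = None,
) -> list[DiagnosticSnp]:
    """Emit sites fixed for different bases in all AA vs all PP libraries.

    A site qualifies only if every one of the required AA libraries has a
    fixed call, all calls agree, the same holds for PP, and the two bases
    differ.  By default every parental library present in ``meta`` is
    required; pass smaller ``n_*_required`` to tolerate missingness (the
    site then needs fixed, concordant calls in at least that many
    libraries and no discordant or heterozygous call in any).
    Sites whose assembly reference base equals neither variant are excluded
    and logged (assembly/variant inconsistency).
    """
    aa_libs = [m.library_id for m in meta if m.genomotype == "AA"]
    pp_libs = [m.library_id for m in meta if m.genomotype == "PP"]
    if n_aa_required is None:
        n_aa_required = len(aa_libs)
    if n_pp_required is None:
        n_pp_required = len(pp_libs)
    out: list[DiagnosticSnp] = []
    n_ref_mismatch = 0
    for rec in records:
        calls = fixed.get(rec.key, {})
        aa_calls = [calls[l] for l in aa_libs if l in calls]
        pp_calls = [calls[l] for l in pp_libs if l in calls]
        # heterozygous or uncovered libraries have no fixed call; a site is
        # only diagnostic if enough libraries are fixed and none disagree
        if len(aa_calls) < n_aa_required or len(set(aa_calls)) != 1:
            continue
        if len(pp_calls) < n_pp_required or len(set(pp_calls)) != 1:
            continue
        a_base, p_base = aa_calls[0], pp_calls[0]
        if a_base == p_base:
            continue
        if rec.ref_base == p_base:
            ref_matches = "P"
        elif rec.ref_base == a_base:
            ref_matches = "A"
        else:
            n_ref_mismatch += 1
            continue
        out.append(
            DiagnosticSnp(
                transcript_id=rec.transcript_id,
                position=rec.position,
                p_base=p_base,
                a_base=a_base,
                ref_matches=ref_matches,
            )
        )
    if n_ref_mismatch:
        log.info(
            "diagnostic SNPs: %d sites dropped, reference base matched "
            "neither parental variant",
            n_ref_mismatch,
        )
    return out
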