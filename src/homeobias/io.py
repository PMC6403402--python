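"""Reading and writing the tabular formats shared by all pipeline stages.

Coordinates are 1-based and transcript-relative throughout (the reference is a
transcriptome assembly, so strand is irrelevant and never stored).

The project count-table dialect is a plain TSV with header::

    transcript_id  pos  length  ref  qual  <lib>:A  <lib>:C  <lib>:G  <lib>:T ...

one row per (transcript, position), rows sorted by (transcript_id, pos).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

VALID_GENOMOTYPES = ("PP", "AA", "PA", "PAA")

#: nuclear genome composition -> expected ploidy
GENOMOTYPE_PLOIDY = {"PP": 2, "AA": 2, "PA": 2, "PAA": 3}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class LibraryMeta:
    """One RNA-seq library: a sequenced individual (or pool) of known genomotype.

    Parameters
    ----------
    library_id : str
        Unique label, e.g. ``"liv-PA"``.
    genomotype : str
        Nuclear genome composition: ``PP``/``AA`` (non-hybrid parental forms),
        ``PA`` (diploid hybrid) or ``PAA`` (triploid hybrid).
    tissue : str
        Sample type label (``"liver"``, ``"juvenile"``, ``"brain"``, ...).
    ploidy : int
        2 or 3; must agree with the genomotype.
    use_for_bias : bool
        Whether this parental library contributes to reference-bias
        estimation.  Only meaningful (and only allowed) for PP/AA libraries;
        libraries contaminated with other ploidies are excluded by setting it
        to False.
    """

    library_id: str
    genomotype: str
    tissue: str
    ploidy: int
    use_for_bias: bool = False

    def __post_init__(self) -> None:
        if self.genomotype not in VALID_GENOMOTYPES:
            raise DataError(
                f"library {self.library_id!r}: unknown genomotype {self.genomotype!r}"
            )
        expected = GENOMOTYPE_PLOIDY[self.genomotype]
        if self.ploidy != expected:
            raise DataError(
                f"library {self.library_id!r}: genomotype {self.genomotype} "
                f"implies ploidy {expected}, got {self.ploidy}"
            )
        if self.use_for_bias and not self.is_parental:
            raise DataError(
                f"library {self.library_id!r}: use_for_bias is only valid for "
                "parental (PP/AA) libraries"
            )

    @property
    def is_parental(self) -> bool:
        return self.genomotype in ("PP", "AA")

    @property
    def is_hybrid(self) -> bool:
        return self.genomotype in ("PA", "PAA")


@dataclass
class SnvRecord:
    """Per-site, per-library base counts at one transcript position.

    ``counts`` maps library_id -> (count_A, count_C, count_G, count_T).
    """

    transcript_id: str
    position: int  # 1-based on the transcript
    transcript_length: int
    ref_base: str
    consensus_quality: int
    counts: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.position <= self.transcript_length:
            raise DataError(
                f"{self.transcript_id}:{self.position}: position outside "
                f"transcript of length {self.transcript_length}"
            )
        if self.ref_base not in BASES:
            raise DataError(
                f"{self.transcript_id}:{self.position}: bad reference base "
                f"{self.ref_base!r}"
            )
        for lib, cs in self.counts.items():
            if len(cs) != 4 or any(c < 0 for c in cs):
                raise DataError(
                    f"{self.transcript_id}:{self.position}: invalid counts "
                    f"{cs!r} for library {lib!r}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)

    def base_count(self, library_id: str, base: str) -> int:
        return self.counts[library_id][BASES.index(base)]

    def depth(self, library_id: str) -> int:
        return sum(self.counts[library_id])


class AnnotationMap:
    """Transcript -> functional-term memberships plus term metadata.

    Namespaces follow the GO/KEGG convention: BP, CC, MF and KEGG.
    """

    def __init__(self) -> None:
        self.transcript_terms: dict[str, set[str]] = {}
        self.term_info: dict[str, tuple[str, str]] = {}  # term -> (namespace, desc)

    def add(
        self,
        transcript_id: str,
        term_id: str,
        namespace: str = "BP",
        description: str = "",
    ) -> None:
        if not transcript_id:
            raise DataError("annotated transcript id must be non-empty")
        self.transcript_terms.setdefault(transcript_id, set()).add(term_id)
        self.term_info.setdefault(term_id, (namespace, description))

    def terms_of(self, transcript_id: str) -> set[str]:
        return self.transcript_terms.get(transcript_id, set())

    def transcripts_with(self, term_id: str) -> set[str]:
        return {t for t, terms in self.transcript_terms.items() if term_id in terms}

    @property
    def all_terms(self) -> set[str]:
        return set(self.term_info)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return (
            self.transcript_terms == other.transcript_terms
            and self.term_info == other.term_info
        )


# ---------------------------------------------------------------------------
# library metadata


def read_meta(path: str | Path) -> list[LibraryMeta]:
    """Read a library-metadata TSV with columns
    ``library_id genomotype tissue ploidy use_for_bias``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "genomotype", "tissue", "ploidy", "use_for_bias"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"metadata file missing columns: {sorted(missing)}")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            LibraryMeta(
                library_id=row.library_id,
                genomotype=row.genomotype,
                tissue=row.tissue,
                ploidy=int(row.ploidy),
                use_for_bias=str(row.use_for_bias).strip().lower()
                in ("1", "true", "yes"),
            )
        )
    ids = [m.library_id for m in metas]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate library_id in metadata")
    return metas


def write_meta(metas: Iterable[LibraryMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "library_id": m.library_id,
                "genomotype": m.genomotype,
                "tissue": m.tissue,
                "ploidy": m.ploidy,
                "use_for_bias": str(m.use_for_bias).lower(),
            }
            for m in metas
        ],
        columns=["library_id", "genomotype", "tissue", "ploidy", "use_for_bias"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count tables


def _count_columns(library_ids: list[str]) -> list[str]:
    return [f"{lib}:{b}" for lib in library_ids for b in BASES]


def read_count_table(
    path: str | Path, meta: Iterable[LibraryMeta]
) -> list[SnvRecord]:
    """Read the project count-table TSV into SnvRecords.

    Every library declared in ``meta`` must have its four ``lib:base``
    columns; extra columns in the file are ignored.  Records come back sorted
    by (transcript_id, position); duplicated positions are a hard error.
    """
    metas = list(meta)
    df = pd.read_csv(path, sep="\t")
    fixed = ["transcript_id", "pos", "length", "ref", "qual"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise DataError(f"count table missing columns: {sorted(missing)}")
    lib_ids = [m.library_id for m in metas]
    for lib in lib_ids:
        lacking = [c for c in _count_columns([lib]) if c not in df.columns]
        if lacking:
            raise DataError(
                f"count table has no columns for declared library {lib!r}: "
                f"missing {lacking}"
            )
    records: list[SnvRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        # pandas itertuples mangles "lib:A" names; index by position instead
        vals = dict(zip(df.columns, row))
        key = (str(vals["transcript_id"]), int(vals["pos"]))
        if key in seen:
            raise DataError(f"duplicate site {key[0]}:{key[1]} (file line {i})")
        seen.add(key)
        counts = {}
        for lib in lib_ids:
            cs = tuple(int(vals[f"{lib}:{b}"]) for b in BASES)
            if any(c < 0 for c in cs):
                raise DataError(
                    f"negative count at {key[0]}:{key[1]} (file line {i}), "
                    f"library {lib!r}"
                )
            counts[lib] = cs
        records.append(
            SnvRecord(
                transcript_id=key[0],
                position=key[1],
                transcript_length=int(vals["length"]),
                ref_base=str(vals["ref"]),
                consensus_quality=int(vals["qual"]),
                counts=counts,
            )
        )
    records.sort(key=lambda r: r.key)
    return records


def write_count_table(records: Iterable[SnvRecord], path: str | Path) -> None:
    """Write SnvRecords as the project TSV dialect.

    Column order is fixed (libraries sorted lexicographically) and rows are
    sorted by (transcript, position), so two writes of the same data are
    byte-identical.
    """
    records = sorted(records, key=lambda r: r.key)
    lib_ids = sorted({lib for r in records for lib in r.counts})
    cols = ["transcript_id", "pos", "length", "ref", "qual"] + _count_columns(lib_ids)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "transcript_id": r.transcript_id,
            "pos": r.position,
            "length": r.transcript_length,
            "ref": r.ref_base,
            "qual": r.consensus_quality,
        }
        for lib in lib_ids:
            cs = r.counts.get(lib, (0, 0, 0, 0))
            for b, c in zip(BASES, cs):
                row[f"{lib}:{b}"] = c
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def read_vcf_allele_depths(
    path: str | Path, sample_map: Mapping[str, str]
) -> tuple[list[SnvRecord], int]:
    """Import biallelic SNVs from a VCF with per-sample AD fields.

    ``sample_map`` maps library_id -> VCF sample name.  Multiallelic records
    and indels are skipped; the number skipped is returned alongside the
    records.  Positions stay 1-based as in the VCF; contig lengths come from
    the header.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    header_samples = list(vcf.header.samples)
    for lib, sample in sample_map.items():
        if sample not in header_samples:
            raise DataError(
                f"sample {sample!r} (library {lib!r}) absent from VCF header"
            )
    contig_len = {name: c.length for name, c in vcf.header.contigs.items()}
    records: list[SnvRecord] = []
    skipped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        if rec.ref not in BASES or alts[0] not in BASES:
            skipped += 1
            continue
        length = contig_len.get(rec.chrom) or rec.pos
        counts = {}
        for lib, sample in sample_map.items():
            ad = rec.samples[sample].get("AD")
            cs = [0, 0, 0, 0]
            if ad is not None:
                ref_d = int(ad[0]) if ad[0] is not None else 0
                alt_d = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                cs[BASES.index(rec.ref)] = ref_d
                cs[BASES.index(alts[0])] = alt_d
            counts[lib] = tuple(cs)
        records.append(
            SnvRecord(
                transcript_id=rec.chrom,
                position=rec.pos,
                transcript_length=int(length),
                ref_base=rec.ref,
                consensus_quality=int(rec.qual) if rec.qual is not None else 0,
                counts=counts,
            )
        )
    if skipped:
        log.info("VCF import: skipped %d multiallelic/indel records", skipped)
    records.sort(key=lambda r: r.key)
    return records, skipped


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read an annotation TSV: ``transcript  term  [namespace]  [description]``.

    Duplicate (transcript, term) rows collapse to one membership.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[0] == 0:
        raise DataError(f"annotation file {path} is empty")
    if df.shape[1] < 2:
        raise DataError("annotation file needs at least transcript and term columns")
    amap = AnnotationMap()
    ncol = df.shape[1]
    for row in df.itertuples(index=False):
        transcript, term = str(row[0]), str(row[1])
        namespace = str(row[2]) if ncol > 2 and not pd.isna(row[2]) else "BP"
        desc = str(row[3]) if ncol > 3 and not pd.isna(row[3]) else ""
        amap.add(transcript, term, namespace, desc)
    return amap


def write_annotation(amap: AnnotationMap, path: str | Path) -> None:
    rows = []
    for transcript in sorted(amap.transcript_terms):
        for term in sorted(amap.transcript_terms[transcript]):
            ns, desc = amap.term_info[term]
            rows.append(
                {
                    "transcript_id": transcript,
                    "term_id": term,
                    "namespace": ns,
                    "description": desc,
                }
            )
    pd.DataFrame(
        rows, columns=["transcript_id", "term_id", "namespace", "description"]
    ).to_csv(path, sep="\t", index=False)
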