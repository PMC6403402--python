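"""Per-transcript homoeolog quantification in hybrid libraries.

At each diagnostic SNP the hybrid library's reads split into P-variant and
A-variant counts.  Sites with fewer than ``min_reads`` supporting reads (raw,
before bias correction) are dropped; surviving site counts are bias-corrected
and averaged per transcript, giving the A-genome fraction

    f_A = mean_reads_A / (mean_reads_A + mean_reads_P)

the axis on which every transcript is classified.  In PAA triploids the two A
homoeolog copies are indistinguishable, so "A" pools both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .bias import BiasModel, apply_correction, no_bias_model
from .io import DataError, SnvRecord
from .snps import DiagnosticSnp


@dataclass(frozen=True)
class TranscriptASE:
    """Per (hybrid library, transcript) allele-specific expression summary."""

    library_id: str
    transcript_id: str
    n_sites: int
    mean_reads_p: float
    mean_reads_a: float

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise DataError("TranscriptASE needs at least one informative site")
        if self.mean_reads_p + self.mean_reads_a <= 0:
            raise DataError("TranscriptASE needs positive total reads")

    @property
    def f_a(self) -> float:
        """A-genome fraction of expression."""
        return self.mean_reads_a / (self.mean_reads_a + self.mean_reads_p)


def site_allele_counts(
    record: SnvRecord, snp: DiagnosticSnp, library_id: str
) -> tuple[int, int]:
    """Raw (reads_P, reads_A) for one library at one diagnostic site."""
    return (
        record.base_count(library_id, snp.p_base),
        record.base_count(library_id, snp.a_base),
    )


def filter_min_reads(
    sites: Iterable[tuple[DiagnosticSnp, float, float]], min_reads: int = 20
) -> list[tuple[DiagnosticSnp, float, float]]:
    """Keep sites whose summed supporting reads reach ``min_reads``.

    ``sites`` yields (snp, reads_P, reads_A) triples; the threshold is
    applied to the raw sum reads_P + reads_A.
    """
    return [(s, p, a) for s, p, a in sites if p + a >= min_reads]


def quantify_library(
    records: dict[tuple[str, int], SnvRecord],
    snps: Sequence[DiagnosticSnp],
    library_id: str,
    model: BiasModel | None = None,
    min_reads: int = 20,
    filter_after_correction: bool = False,
) -> list[TranscriptASE]:
    """Quantify one hybrid library across all diagnostic SNPs.

    The read-support filter is by default applied to raw counts (it
    describes sequencing evidence); ``filter_after_correction=True`` applies
    it to the corrected counts instead.
    """
    model = model or no_bias_model()
    raw = []
    for snp in snps:
        rec = records.get(snp.key)
        if rec is None or library_id not in rec.counts:
            continue
        p, a = site_allele_counts(rec, snp, library_id)
        raw.append((snp, p, a))
    if filter_after_correction:
        corrected = [
            (snp, *apply_correction(p, a, snp, model)) for snp, p, a in raw
        ]
        retained = filter_min_reads(corrected, min_reads)
    else:
        retained = [
            (snp, *apply_correction(p, a, snp, model))
            for snp, p, a in filter_min_reads(raw, min_reads)
        ]
    return transcript_fractions(retained, library_id)


def transcript_fractions(
    sites: Iterable[tuple[DiagnosticSnp, float, float]], library_id: str
) -> list[TranscriptASE]:
    """Average corrected site counts per transcript; sorted by transcript id."""
    per_transcript: dict[str, list[tuple[float, float]]] = {}
    for snp, p, a in sites:
        per_transcript.setdefault(snp.transcript_id, []).append((p, a))
    out = []
    for tid in sorted(per_transcript):
        pairs = per_transcript[tid]
        mean_p = sum(p for p, _ in pairs) / len(pairs)
        mean_a = sum(a for _, a in pairs) / len(pairs)
        out.append(
            TranscriptASE(
                library_id=library_id,
                transcript_id=tid,
                n_sites=len(pairs),
                mean_reads_p=mean_p,
                mean_reads_a=mean_a,
            )
        )
    return out
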