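"""Reference-mapping-bias estimation and correction.

Reads that carry the assembly reference base map more efficiently than reads
carrying the alternative variant, inflating the reference count.  Parental
(PP/AA) libraries are heterozygous at some sites within their own genome;
there the true allelic contribution is 1:1, so the observed reference/other
ratio measures the bias.  The correction factor C is the mean over usable
parental libraries of each library's mean site ratio; applying it divides
every reference-matching count by C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import DataError, LibraryMeta
from .snps import DiagnosticSnp, HetSite

log = logging.getLogger(__name__)


@dataclass
class BiasModel:
    """Estimated reference-bias model.

    ``per_sample_mean`` holds each contributing parental library's mean
    allelic ratio D_j (reference-matching reads / other reads, dimensionless);
    ``correction_factor`` C is the unweighted mean of those means.
    """

    per_sample_mean: dict[str, float]
    correction_factor: float
    n_sites_used: dict[str, int] = field(default_factory=dict)
    excluded_libraries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.correction_factor > 0:
            raise DataError("correction factor must be positive")


def site_ratio(count_ref: int | float, count_alt: int | float) -> float:
    """Reference/other read ratio at a heterozygous site (expectation 1
    under no bias)."""
    if count_alt <= 0:
        raise DataError("site_ratio requires count_alt > 0 (het sites only)")
    return count_ref / count_alt


def estimate_correction_factor(
    het_sites: Iterable[HetSite],
    meta: Sequence[LibraryMeta],
    use_log_mean: bool = False,
) -> BiasModel:
    """Estimate C from parental intragenomic heterozygous sites.

    Only libraries flagged ``use_for_bias`` contribute.  D_j is the
    arithmetic mean of the site ratios within library j and C the arithmetic
    mean of the D_j (the mean of raw ratios is upward-biased at low depth;
    ``use_log_mean=True`` averages log-ratios and exponentiates instead).
    """
    usable = {m.library_id for m in meta if m.is_parental and m.use_for_bias}
    excluded = sorted(
        {m.library_id for m in meta if m.is_parental and not m.use_for_bias}
    )
    ratios: dict[str, list[float]] = {}
    for hs in het_sites:
        if hs.library_id not in usable:
            continue
        ratios.setdefault(hs.library_id, []).append(
            site_ratio(hs.count_ref, hs.count_alt)
        )
    if not ratios:
        raise DataError(
            "cannot estimate bias: no heterozygous sites in any library "
            "flagged use_for_bias"
        )
    per_sample = {}
    for lib, rs in ratios.items():
        if use_log_mean:
            per_sample[lib] = math.exp(sum(math.log(r) for r in rs) / len(rs))
        else:
            per_sample[lib] = sum(rs) / len(rs)
    c = sum(per_sample.values()) / len(per_sample)
    log.info(
        "bias estimate: C=%.4f from %d libraries (%s)",
        c,
        len(per_sample),
        ", ".join(f"{l}: D={d:.4f}" for l, d in sorted(per_sample.items())),
    )
    return BiasModel(
        per_sample_mean=per_sample,
        correction_factor=c,
        n_sites_used={lib: len(rs) for lib, rs in ratios.items()},
        excluded_libraries=excluded,
    )


def no_bias_model() -> BiasModel:
    """An explicit C=1 model for the ``--assume-no-bias`` path."""
    return BiasModel(per_sample_mean={}, correction_factor=1.0)


def apply_correction(
    reads_p: float, reads_a: float, snp: DiagnosticSnp, model: BiasModel
) -> tuple[float, float]:
    """Divide the reference-matching variant's count by C at one site.

    Returns possibly fractional (reads_P, reads_A).
    """
    c = model.correction_factor
    if snp.ref_matches == "P":
        return reads_p / c, float(reads_a)
    return float(reads_p), reads_a / c
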