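"""Ploidy-aware classification of transcripts by A-genome expression fraction.

Balanced homoeolog expression (BHE) is an A-fraction inside the ploidy's
balance window — the open interval (0.3, 0.7) for PA diploids (expected 1:1
dosage) and (0.5, 0.9) for PAA triploids (expected 1 P : 2 A dosage, the
diploid criterion extrapolated proportionally).  Anything outside the window
is homoeolog expression bias, toward P (HEB_P, f_A <= L) or toward A (HEB_A,
f_A >= U).  When the minor genome's contribution drops below the silencing
cutoff 0.1, the transcript shows monogenomic expression: MGE_P (only P
expressed, f_A < 0.1) or MGE_A (only A expressed, f_A > 0.9).

Boundary convention: "balanced" is the open interval, so boundary values fall
to HEB; MGE cutoffs are strict.  With the defaults this makes the triploid
MGE_A region equal to HEB_A minus the single point f_A = 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import DataError

CATEGORY_BHE = "BHE"
CATEGORY_HEB_P = "HEB_P"
CATEGORY_HEB_A = "HEB_A"
MGE_NONE = "none"
MGE_P = "MGE_P"
MGE_A = "MGE_A"


@dataclass(frozen=True)
class ClassifierConfig:
    """Balance windows per ploidy and the allelic-silencing cutoff."""

    diploid_window: tuple[float, float] = (0.3, 0.7)
    triploid_window: tuple[float, float] = (0.5, 0.9)
    silencing_cutoff: float = 0.1

    def __post_init__(self) -> None:
        for lo, hi in (self.diploid_window, self.triploid_window):
            if not 0 < self.silencing_cutoff <= lo < hi < 1:
                raise DataError(
                    "classifier windows must satisfy 0 < tau <= L < U < 1"
                )

    def window(self, ploidy: int) -> tuple[float, float]:
        if ploidy == 2:
            return self.diploid_window
        if ploidy == 3:
            return self.triploid_window
        raise DataError(f"unsupported ploidy {ploidy}")


@dataclass(frozen=True)
class TranscriptCall:
    """One transcript's category in one hybrid library."""

    transcript_id: str
    library_id: str
    ploidy: int
    category: str  # BHE / HEB_P / HEB_A
    mge: str  # none / MGE_P / MGE_A
    f_a: float


def classify_transcript(
    transcript_id: str,
    library_id: str,
    f_a: float,
    ploidy: int,
    config: ClassifierConfig | None = None,
) -> TranscriptCall:
    """Assign BHE/HEB and the MGE flag from the A-fraction."""
    config = config or ClassifierConfig()
    if not 0 <= f_a <= 1:
        raise DataError(f"f_A must be in [0, 1], got {f_a}")
    lo, hi = config.window(ploidy)
    tau = config.silencing_cutoff
    if lo < f_a < hi:
        category, mge = CATEGORY_BHE, MGE_NONE
    elif f_a <= lo:
        category = CATEGORY_HEB_P
        mge = MGE_P if f_a < tau else MGE_NONE
    else:
        category = CATEGORY_HEB_A
        mge = MGE_A if f_a > 1 - tau else MGE_NONE
    return TranscriptCall(
        transcript_id=transcript_id,
        library_id=library_id,
        ploidy=ploidy,
        category=category,
        mge=mge,
        f_a=f_a,
    )


def round_percent(n: int, total: int) -> int:
    """Nearest-integer percentage, ties away from zero (68% from 764/1121)."""
    if total <= 0:
        raise DataError("cannot take a percentage of zero transcripts")
    import math

    return int(math.floor(100 * n / total + 0.5))


@dataclass
class ClassificationSummary:
    """Per-library category counts and rounded percentages."""

    library_id: str
    n_bhe: int
    n_heb_p: int
    n_heb_a: int
    n_mge_p: int
    n_mge_a: int
    n_total: int
    percentages: dict[str, int] = field(default_factory=dict)

    @property
    def n_heb(self) -> int:
        return self.n_heb_p + self.n_heb_a

    @property
    def n_mge(self) -> int:
        return self.n_mge_p + self.n_mge_a


def summarize_classification(calls: Sequence[TranscriptCall]) -> ClassificationSummary:
    """Count calls per category for one library (the shape of the per-library
    summary tables: BHE / HEB / HEB(P) / HEB(A) / MGE(P) / MGE(A) / total)."""
    if not calls:
        raise DataError("cannot summarize an empty call set")
    libs = {c.library_id for c in calls}
    if len(libs) != 1:
        raise DataError(f"summarize_classification got calls from {sorted(libs)}")
    n_bhe = sum(c.category == CATEGORY_BHE for c in calls)
    n_heb_p = sum(c.category == CATEGORY_HEB_P for c in calls)
    n_heb_a = sum(c.category == CATEGORY_HEB_A for c in calls)
    n_mge_p = sum(c.mge == MGE_P for c in calls)
    n_mge_a = sum(c.mge == MGE_A for c in calls)
    total = len(calls)
    pct = {
        "BHE": round_percent(n_bhe, total),
        "HEB": round_percent(n_heb_p + n_heb_a, total),
        "HEB_P": round_percent(n_heb_p, total),
        "HEB_A": round_percent(n_heb_a, total),
        "MGE_P": round_percent(n_mge_p, total),
        "MGE_A": round_percent(n_mge_a, total),
        "MGE": round_percent(n_mge_p + n_mge_a, total),
    }
    return ClassificationSummary(
        library_id=calls[0].library_id,
        n_bhe=n_bhe,
        n_heb_p=n_heb_p,
        n_heb_a=n_heb_a,
        n_mge_p=n_mge_p,
        n_mge_a=n_mge_a,
        n_total=total,
        percentages=pct,
    )


def consistent_mge(
    calls_by_library: Mapping[str, Iterable[TranscriptCall]],
    required_libraries: Sequence[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Transcripts with the same monogenomic flag in every requested library.

    Strict membership: a transcript qualifies only if it is quantified in
    all requested libraries and carries MGE_P (resp. MGE_A) in each.
    """
    libs = list(required_libraries or calls_by_library.keys())
    flag: dict[str, dict[str, str]] = {}
    for lib in libs:
        for call in calls_by_library.get(lib, ()):  # type: ignore[arg-type]
            flag.setdefault(call.transcript_id, {})[lib] = call.mge
    p_set, a_set = set(), set()
    for tid, per_lib in flag.items():
        if len(per_lib) != len(libs):
            continue
        values = set(per_lib.values())
        if values == {MGE_P}:
            p_set.add(tid)
        elif values == {MGE_A}:
            a_set.add(tid)
    return p_set, a_set
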