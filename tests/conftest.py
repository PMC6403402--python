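"""Shared fixtures: a hand-computed golden dataset and small simulations.

The golden dataset has two PP and two AA parental libraries plus one diploid
(liv-PA) and one triploid (liv-PAA) hybrid library.  Two transcripts carry a
parental heterozygous site each (ratios 1.5 and 1.0, so the correction
factor is exactly C = 1.25); transcripts t01..t09 carry diagnostic sites
with hybrid counts chosen so every classification category is hit and all
per-transcript fractions are exact rationals; t08's diploid site fails the
20-read filter and t10 fails the consensus-quality filter.
"""

from __future__ import annotations

import pytest

from homeobias.io import BASES, LibraryMeta, SnvRecord

PARENTAL_META = [
    LibraryMeta("PP1", "PP", "liver", 2, True),
    LibraryMeta("PP2", "PP", "liver", 2, True),
    LibraryMeta("AA1", "AA", "liver", 2, True),
    LibraryMeta("AA2", "AA", "liver", 2, True),
]
HYBRID_META = [
    LibraryMeta("liv-PA", "PA", "liver", 2, False),
    LibraryMeta("liv-PAA", "PAA", "liver", 3, False),
]
GOLDEN_META = PARENTAL_META + HYBRID_META

ALL_LIBS = [m.library_id for m in GOLDEN_META]


def make_record(
    tid: str,
    pos: int,
    ref: str,
    per_lib: dict[str, dict[str, int]],
    length: int = 200,
    qual: int = 40,
) -> SnvRecord:
    counts = {}
    for lib in ALL_LIBS:
        cs = [0, 0, 0, 0]
        for base, n in per_lib.get(lib, {}).items():
            cs[BASES.index(base)] = n
        counts[lib] = tuple(cs)
    return SnvRecord(
        transcript_id=tid,
        position=pos,
        transcript_length=length,
        ref_base=ref,
        consensus_quality=qual,
        counts=counts,
    )


def diagnostic_record(
    tid: str,
    pa_counts: tuple[int, int],
    paa_counts: tuple[int, int],
    pos: int = 100,
    qual: int = 40,
) -> SnvRecord:
    """P base C (reference), A base T; parental libraries fixed at depth 30."""
    p_pa, a_pa = pa_counts
    p_paa, a_paa = paa_counts
    return make_record(
        tid,
        pos,
        "C",
        {
            "PP1": {"C": 30},
            "PP2": {"C": 30},
            "AA1": {"T": 30},
            "AA2": {"T": 30},
            "liv-PA": {"C": p_pa, "T": a_pa},
            "liv-PAA": {"C": p_paa, "T": a_paa},
        },
        qual=qual,
    )


def golden_records() -> list[SnvRecord]:
    recs = [
        # het sites: PP1 ratio 12/8 = 1.5, AA1 ratio 10/10 = 1.0 -> C = 1.25
        make_record(
            "t_het1",
            100,
            "C",
            {
                "PP1": {"C": 12, "T": 8},
                "PP2": {"C": 30},
                "AA1": {"C": 30},
                "AA2": {"C": 30},
                "liv-PA": {"C": 30},
                "liv-PAA": {"C": 30},
            },
        ),
        make_record(
            "t_het2",
            100,
            "G",
            {
                "PP1": {"G": 30},
                "PP2": {"G": 30},
                "AA1": {"G": 10, "A": 10},
                "AA2": {"G": 30},
                "liv-PA": {"G": 30},
                "liv-PAA": {"G": 30},
            },
        ),
        diagnostic_record("t01", (40, 40), (20, 60)),
        diagnostic_record("t02", (100, 20), (60, 40)),
        diagnostic_record("t03", (95, 5), (95, 5)),
        diagnostic_record("t04", (5, 95), (3, 97)),
        diagnostic_record("t05", (30, 50), (40, 40)),
        diagnostic_record("t06", (50, 30), (25, 50)),
        diagnostic_record("t07", (10, 12), (50, 12)),
        # t08 diploid site sum = 19 < 20 -> dropped for liv-PA only
        diagnostic_record("t08", (12, 7), (30, 30)),
        # t09: two sites, exercises per-transcript averaging
        diagnostic_record("t09", (10, 10), (20, 20), pos=100),
        diagnostic_record("t09", (30, 10), (20, 20), pos=120),
        # t10 fails the consensus-quality filter; would be diagnostic otherwise
        diagnostic_record("t10", (40, 40), (40, 40), qual=19),
    ]
    return sorted(recs, key=lambda r: r.key)


#: expected diploid-library A-fractions after correction with C = 1.25
GOLDEN_F_A_PA = {
    "t01": 40 / 72,
    "t02": 20 / 100,
    "t03": 5 / 81,
    "t04": 95 / 99,
    "t05": 50 / 74,
    "t06": 30 / 70,
    "t07": 12 / 20,
    "t09": 10 / 26,
}

#: expected triploid-library A-fractions after correction with C = 1.25
GOLDEN_F_A_PAA = {
    "t01": 60 / 76,
    "t02": 40 / 88,
    "t03": 5 / 81,
    "t04": 97 / 99.4,
    "t05": 40 / 72,
    "t06": 50 / 70,
    "t07": 12 / 52,
    "t08": 30 / 54,
    "t09": 20 / 36,
}

GOLDEN_SUMMARY = {
    # library: (BHE, HEB_P, HEB_A, MGE_P, MGE_A, total)
    "liv-PA": (5, 2, 1, 1, 1, 8),
    "liv-PAA": (5, 3, 1, 1, 1, 9),
}

GOLDEN_C = 1.25


@pytest.fixture(scope="session")
def golden():
    return golden_records(), list(GOLDEN_META)


@pytest.fixture(scope="session")
def small_simulation():
    """A modest simulated complex shared across tests (read-only)."""
    from homeobias.simulate import SimulationConfig, simulate_complex

    cfg = SimulationConfig(
        n_transcripts=300,
        depth_mean=150.0,
        parental_het_rate=0.1,
        seed=20240601,
    )
    records, meta, truth = simulate_complex(cfg)
    return cfg, records, meta, truth
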