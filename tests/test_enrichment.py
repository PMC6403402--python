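"""MGE group assembly and hypergeometric term enrichment."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from homeobias.classify import classify_transcript
from homeobias.enrichment import (
    MgeGroup,
    assemble_mge_groups,
    hypergeometric_enrichment,
)
from homeobias.io import AnnotationMap, DataError, LibraryMeta

META = [
    LibraryMeta("liv-PA", "PA", "liver", 2),
    LibraryMeta("liv-PAA", "PAA", "liver", 3),
    LibraryMeta("juv-PA", "PA", "juvenile", 2),
    LibraryMeta("juv-PAA", "PAA", "juvenile", 3),
]


def calls_for(lib, ploidy, fractions):
    return [
        classify_transcript(t, lib, f, ploidy) for t, f in fractions.items()
    ]


def group_map(groups):
    return {g.group_id: g.members for g in groups}


class TestGroups:
    def test_union_semantics_across_pooling_axes(self):
        calls = {
            "liv-PA": calls_for("liv-PA", 2, {"t1": 0.05, "t2": 0.5}),
            "liv-PAA": calls_for("liv-PAA", 3, {"t1": 0.5, "t2": 0.5}),
            "juv-PA": calls_for("juv-PA", 2, {"t3": 0.95}),
            "juv-PAA": calls_for("juv-PAA", 3, {"t3": 0.95}),
        }
        gm = group_map(assemble_mge_groups(calls, META))
        assert set(gm) == {
            "liver_P", "liver_A", "juvenile_P", "juvenile_A",
            "PA_P", "PA_A", "PAA_P", "PAA_A",
        }
        # t1 MGE_P in liv-PA only -> liver_P and PA_P
        assert gm["liver_P"] == {"t1"} and gm["PA_P"] == {"t1"}
        assert gm["PAA_P"] == set()
        # t3 MGE_A in both juvenile libraries -> juvenile_A, PA_A, PAA_A
        assert gm["juvenile_A"] == {"t3"}
        assert gm["PA_A"] == {"t3"} and gm["PAA_A"] == {"t3"}

    def test_no_mge_calls_gives_all_empty_groups(self):
        calls = {
            m.library_id: calls_for(m.library_id, m.ploidy, {"t1": 0.55})
            for m in META
        }
        gm = group_map(assemble_mge_groups(calls, META))
        assert all(members == set() for members in gm.values())

    def test_assembly_is_order_independent_and_idempotent(self):
        calls = {
            "liv-PA": calls_for("liv-PA", 2, {"t1": 0.05, "t2": 0.95}),
            "liv-PAA": calls_for("liv-PAA", 3, {"t1": 0.05}),
            "juv-PA": calls_for("juv-PA", 2, {"t2": 0.95}),
            "juv-PAA": calls_for("juv-PAA", 3, {"t1": 0.5}),
        }
        g1 = group_map(assemble_mge_groups(calls, META))
        reordered = dict(reversed(list(calls.items())))
        g2 = group_map(assemble_mge_groups(reordered, META))
        assert g1 == g2
        assert g1 == group_map(assemble_mge_groups(calls, META))


def brute_force_upper_tail(big_n, big_k, n, k):
    """P(X >= k) by enumerating all n-subsets of an N-element background."""
    universe = list(range(big_n))
    annotated = set(range(big_k))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        hits += len(annotated & set(subset)) >= k
    return hits / total


class TestHypergeometric:
    def test_small_worked_example(self):
        # group of 2, background 4 of which 2 annotated, both in group:
        # p = C(2,2)C(2,0)/C(4,2) = 1/6
        ann = AnnotationMap()
        for t in ("g1", "g2"):
            ann.add(t, "T", "BP")
        group = MgeGroup("liver_P", "tissue", "P", {"g1", "g2"})
        (res,) = hypergeometric_enrichment(group, {"g1", "g2", "b1", "b2"}, ann)
        assert res.p_value == pytest.approx(1 / 6)
        assert (res.k, res.big_k, res.n, res.big_n) == (2, 2, 2, 4)

    def test_term_absent_from_group_gives_p_one(self):
        ann = AnnotationMap()
        ann.add("b1", "T", "BP")
        group = MgeGroup("liver_P", "tissue", "P", {"g1"})
        (res,) = hypergeometric_enrichment(group, {"g1", "b1"}, ann)
        assert res.k == 0 and res.p_value == pytest.approx(1.0)

    def test_group_equal_to_background_cannot_be_enriched(self):
        ann = AnnotationMap()
        ann.add("g1", "T", "BP")
        group = MgeGroup("liver_P", "tissue", "P", {"g1", "g2"})
        results = hypergeometric_enrichment(group, {"g1", "g2"}, ann)
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_empty_background_is_error(self):
        group = MgeGroup("liver_P", "tissue", "P", set())
        with pytest.raises(DataError):
            hypergeometric_enrichment(group, set(), AnnotationMap())

    def test_agrees_with_enumeration_oracle_up_to_n_twelve(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            big_n = int(rng.integers(2, 13))
            big_k = int(rng.integers(1, big_n + 1))
            n = int(rng.integers(1, big_n + 1))
            background = {f"x{i}" for i in range(big_n)}
            annotated = {f"x{i}" for i in range(big_k)}
            members = set(rng.choice(sorted(background), size=n, replace=False))
            ann = AnnotationMap()
            for t in annotated:
                ann.add(t, "T", "BP")
            group = MgeGroup("liver_P", "tissue", "P", members)
            (res,) = hypergeometric_enrichment(group, background, ann)
            expected = brute_force_upper_tail(big_n, big_k, n, res.k)
            assert res.p_value == pytest.approx(expected, abs=1e-9)

    def test_ease_variant_is_more_conservative(self):
        ann = AnnotationMap()
        for t in ("g1", "g2"):
            ann.add(t, "T", "BP")
        group = MgeGroup("liver_P", "tissue", "P", {"g1", "g2"})
        bg = {"g1", "g2", "b1", "b2", "b3"}
        (plain,) = hypergeometric_enrichment(group, bg, ann)
        (eased,) = hypergeometric_enrichment(group, bg, ann, ease=True)
        assert eased.p_value > plain.p_value

    def test_planted_term_detected_in_most_replicates(self):
        """A term with strong over-representation in a sizeable group
        reaches Benjamini-adjusted significance in >= 90% of replicates."""
        rng = np.random.default_rng(88)
        n_rep, detected = 25, 0
        for _ in range(n_rep):
            background = [f"t{i}" for i in range(400)]
            group = set(background[:40])
            ann = AnnotationMap()
            for t in background:
                in_group = t in group
                # planted term: 50% prevalence inside, 5% outside (~OR 19)
                if rng.uniform() < (0.5 if in_group else 0.05):
                    ann.add(t, "PLANTED", "BP")
                for j in range(3):  # background noise terms, 10% everywhere
                    if rng.uniform() < 0.1:
                        ann.add(t, f"NOISE{j}", "BP")
            g = MgeGroup("liver_P", "tissue", "P", group)
            results = hypergeometric_enrichment(g, set(background), ann)
            by_term = {r.term_id: r for r in results}
            if (
                "PLANTED" in by_term
                and by_term["PLANTED"].p_adjusted <= 0.05
            ):
                detected += 1
        assert detected / n_rep >= 0.9
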