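"""Enumeration order, rule filtering, naming, and scar-less assembly."""

import itertools
import random
from collections import Counter

import pytest
from Bio.Seq import Seq

from partforge import (
    FixtureSpec,
    add_rule,
    assemble_construct,
    enumerate_constructs,
    enumeration_report,
    filter_by_rules,
    generate_design,
    generate_frame_fixture,
    name_constructs,
    prdr_like_design,
    total_combinations,
)
from partforge.errors import StructureError

from conftest import attach_random_rules, random_valid_design


def _brute_force_kept(design):
    """Independent filter: direct product over part-name lists, with the
    operator definitions written out longhand."""
    kept = []
    for combo in itertools.product(*[[p.name for p in b.parts] for b in design.bins]):
        counts = Counter(combo)
        ok = True
        for r in design.rules:
            op = r.operator.value
            if op == "WITH":
                ok = counts[r.operand1] == 0 or counts[str(r.operand2)] > 0
            elif op == "NOTWITH":
                ok = not (counts[r.operand1] > 0 and counts[str(r.operand2)] > 0)
            else:  # NOTMORETHAN
                ok = counts[r.operand1] <= int(r.operand2)
            if not ok:
                break
        if ok:
            kept.append(combo)
    return kept


class TestEnumeration:
    def test_prdr_shape_yields_eight(self, prdr_design):
        assert sum(1 for _ in enumerate_constructs(prdr_design)) == 8

    def test_library_scale_lazy_count(self):
        design = generate_design(
            FixtureSpec(bin_sizes=(38, 38, 38), seed=5, part_length_range=(20, 30))
        )
        assert total_combinations(design) == 54_872
        assert sum(1 for _ in enumerate_constructs(design)) == 54_872

    def test_singleton_bins_yield_one(self):
        design = generate_design(FixtureSpec(bin_sizes=(1, 1, 1), seed=2))
        (only,) = list(enumerate_constructs(design))
        assert only.index == 0

    def test_order_is_lexicographic_leftmost_slowest(self, prdr_design):
        combos = [c.part_names() for c in enumerate_constructs(prdr_design)]
        expected = [
            list(t)
            for t in itertools.product(
                *[[p.name for p in b.parts] for b in prdr_design.bins]
            )
        ]
        assert combos == expected

    def test_empty_bin_is_structure_error(self, prdr_design):
        prdr_design.bins[1].parts.clear()
        with pytest.raises(StructureError):
            list(enumerate_constructs(prdr_design))

    def test_count_equals_product_on_random_designs(self):
        rng = random.Random(12)
        for _ in range(15):
            d = random_valid_design(rng)
            product = 1
            for b in d.bins:
                product *= len(b.parts)
            assert sum(1 for _ in enumerate_constructs(d)) == product


class TestFiltering:
    def test_with_rule_eliminates_two_of_eight(self, prdr_with_rule):
        report = enumeration_report(prdr_with_rule)
        assert (report.total, report.kept, report.eliminated) == (8, 6, 2)
        for c in filter_by_rules(prdr_with_rule):
            names = c.part_names()
            assert not ("short" in names and "sig2" in names)

    def test_no_rules_eliminates_nothing(self, prdr_design):
        report = enumeration_report(prdr_design)
        assert report.eliminated == 0 and report.kept == 8

    def test_kept_set_matches_brute_force_on_random_designs(self):
        rng = random.Random(77)
        for _ in range(30):
            d = attach_random_rules(
                random_valid_design(rng), rng, rng.randint(1, 4)
            )
            got = [c.part_names() for c in filter_by_rules(d)]
            assert got == [list(t) for t in _brute_force_kept(d)]

    def test_adding_rules_is_monotone(self, prdr_design):
        kept0 = enumeration_report(prdr_design).kept
        add_rule(prdr_design, "r1", "WITH", "short", "sig1")
        kept1 = enumeration_report(prdr_design).kept
        add_rule(prdr_design, "r2", "NOTWITH", "long", "enh_tag")
        kept2 = enumeration_report(prdr_design).kept
        assert kept0 >= kept1 >= kept2

    def test_per_rule_counts_are_independent_of_other_rules(self, prdr_design):
        add_rule(prdr_design, "r1", "WITH", "short", "sig1")
        add_rule(prdr_design, "r2", "WITH", "long", "sig1")
        report = enumeration_report(prdr_design)
        assert report.per_rule_eliminations == {"r1": 2, "r2": 2}
        # the two rules never bite the same combination here
        assert report.eliminated == 4


class TestAssembly:
    def test_single_part_design_assembles_to_that_part(self):
        design = generate_design(
            FixtureSpec(bin_sizes=(1,), seed=4, topology="circular")
        )
        (c,) = list(enumerate_constructs(design))
        assembled = assemble_construct(design, c)
        assert assembled.residues == design.part_sequence(c.parts[0]).residues
        assert assembled.circular

    def test_length_is_sum_of_part_lengths(self):
        rng = random.Random(21)
        for _ in range(25):
            d = random_valid_design(rng)
            c = next(enumerate_constructs(d))
            assembled = assemble_construct(d, c)
            assert len(assembled) == sum(
                len(d.part_sequence(p)) for p in c.parts
            )

    def test_annotation_count_invariant(self):
        # features fully inside each part, plus one spanning feature per part
        rng = random.Random(8)
        for _ in range(10):
            d = random_valid_design(rng)
            c = next(enumerate_constructs(d))
            assembled = assemble_construct(d, c)
            inside = sum(
                sum(1 for f in d.part_sequence(p).features if not f.truncated)
                for p in c.parts
            )
            assert len(assembled.features) == inside + len(c.parts)

    def test_part_spanning_features_at_correct_offsets(self, prdr_design):
        c = next(enumerate_constructs(prdr_design))
        assembled = assemble_construct(prdr_design, c)
        spans = {f.label: (f.start, f.end) for f in assembled.features
                 if f.label in {p.name for p in c.parts}}
        offset = 0
        for p in c.parts:
            plen = len(prdr_design.part_sequence(p))
            assert spans[p.name] == (offset + 1, offset + plen)
            offset += plen

    def test_topology_follows_design_flag(self, prdr_design):
        prdr_design.topology = "linear"
        c = next(enumerate_constructs(prdr_design))
        assert not assemble_construct(prdr_design, c).circular

    def test_frame_fixture_translates_without_internal_stop(self):
        design = generate_frame_fixture(seed=0)
        for c in enumerate_constructs(design):
            assembled = assemble_construct(design, c)
            assert len(assembled) % 3 == 0
            aa = str(Seq(assembled.residues).translate())
            assert "*" not in aa[:-1] and aa[-1] == "*"
            assert aa[0] == "M"

    def test_reverse_oriented_cds_breaks_the_frame(self):
        design = generate_frame_fixture(seed=0)
        orf = design.find_part("orf_main")
        design.edit_part_definition(orf.definition_id, reverse=True)
        c = next(enumerate_constructs(design))
        aa = str(Seq(assemble_construct(design, c).residues).translate())
        assert "*" in aa[:-1]


class TestNaming:
    def test_prdr_prefix_reproduces_plasmid_names(self, prdr_design):
        names = name_constructs(prdr_design, "pRDR0000")
        assert sorted(names.values()) == [f"pRDR0000{i}" for i in range(1, 9)]

    def test_names_only_cover_kept_constructs(self, prdr_with_rule):
        names = name_constructs(prdr_with_rule, "pRDR0000")
        assert len(names) == 6

    def test_bijection_and_order(self):
        rng = random.Random(31)
        d = attach_random_rules(random_valid_design(rng, 4, 3), rng, 2)
        names = name_constructs(d, "c_")
        kept_indices = [c.index for c in filter_by_rules(d)]
        assert list(names) == kept_indices
        assert len(set(names.values())) == len(names)
        assert sorted(names.values()) == [names[i] for i in kept_indices]

    def test_single_construct(self):
        d = generate_design(FixtureSpec(bin_sizes=(1,), seed=1))
        assert list(name_constructs(d, "only_").values()) == ["only_1"]
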