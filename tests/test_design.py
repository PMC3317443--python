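"""Parts, bins, linked repeats, and correct-by-construction validation."""

import itertools
import random

import pytest

from partforge import (
    AnnotatedSequence,
    Bin,
    Design,
    Part,
    PartDefinition,
    Strategy,
    add_rule,
    bin_consensus_strategy,
    errors_of,
    validate_design,
)
from partforge.errors import (
    NamingError,
    RangeError,
    StructureError,
    UniquenessError,
)


def _source(n=100, name="src", seed=0):
    rng = random.Random(seed)
    return AnnotatedSequence(name, "".join(rng.choice("ACGT") for _ in range(n)))


class TestCreatePart:
    def test_out_of_range_coordinate_is_impossible(self):
        # base pair 500 of a 100 bp source must be rejected at creation
        d = Design()
        d.add_bin("b1")
        with pytest.raises(RangeError):
            d.create_part("p", _source(100), 1, 500, bin_index=0)

    def test_duplicate_part_name_rejected(self):
        d = Design()
        d.add_bin("b1")
        src = _source()
        d.create_part("vector_backbone", src, 1, 50, bin_index=0)
        with pytest.raises(UniquenessError):
            d.create_part("vector_backbone", src, 51, 100, bin_index=0)

    def test_prohibited_characters_listed_in_error(self):
        d = Design()
        with pytest.raises(NamingError, match=r"'!'"):
            d.create_part("my part!", _source(), 1, 10)
        with pytest.raises(NamingError, match=r"' '"):
            d.create_part("my part!", _source(), 1, 10)

    def test_unbinned_part_is_peripheral(self):
        d = Design()
        p = d.create_part("lone", _source(), 1, 10)
        assert p in d.peripheral_parts


class TestLinkedRepeats:
    def _design(self):
        d = Design()
        for i in range(3):
            d.add_bin(f"b{i + 1}")
        src = _source(200, "rbs_src")
        p = d.create_part("RBS_pET29_5prime", src, 10, 40, bin_index=0)
        return d, p

    def test_edit_propagates_to_all_replicates(self):
        d, p = self._design()
        d.replicate_part(p, 1)
        d.replicate_part(p, 2)
        d.edit_part_definition(p.definition_id, stop=55)
        stops = [q.stop for b in d.bins for q in b.parts]
        assert stops == [55, 55, 55]

    def test_delete_one_instance_leaves_others(self):
        d, p = self._design()
        clone = d.replicate_part(p, 1)
        d.remove_part(clone)
        assert [len(b.parts) for b in d.bins] == [1, 0, 0]
        assert p.stop == 40

    def test_extracted_sequences_agree_across_instances_after_edits(self):
        d, p = self._design()
        clones = [d.replicate_part(p, 1), d.replicate_part(p, 2)]
        rng = random.Random(3)
        for _ in range(20):
            a, b = sorted(rng.sample(range(1, 201), 2))
            d.edit_part_definition(p.definition_id, start=a, stop=b)
            seqs = {d.part_sequence(q).residues for q in [p, *clones]}
            assert len(seqs) == 1

    def test_invalid_update_is_atomic(self):
        d, p = self._design()
        before = (p.start, p.stop)
        with pytest.raises(RangeError):
            d.edit_part_definition(p.definition_id, stop=999)
        assert (p.start, p.stop) == before

    def test_rename_follows_through_to_rules(self):
        d, p = self._design()
        other = d.create_part("anchor", d.sources["rbs_src"], 50, 80, bin_index=1)
        d.bins[2].parts.append(Part(other.definition))
        add_rule(d, "r1", "WITH", "RBS_pET29_5prime", "anchor")
        d.edit_part_definition(p.definition_id, name="RBS_new")
        assert d.rules[0].operand1 == "RBS_new"
        assert not errors_of(validate_design(d))

    def test_digest_strategy_blocked_in_first_bin(self):
        d, p = self._design()
        with pytest.raises(StructureError, match="E_DIGEST_FIRST_BIN"):
            d.edit_part_definition(
                p.definition_id, forced_strategy=Strategy.DIGEST
            )
        # the check is a toggle
        d.edit_part_definition(
            p.definition_id,
            forced_strategy=Strategy.DIGEST,
            check_digest_first_bin=False,
        )
        assert p.forced_strategy is Strategy.DIGEST


class TestBinConsensus:
    def _bin(self, strategies):
        b = Bin("b")
        for i, s in enumerate(strategies):
            b.parts.append(
                Part(PartDefinition(i + 1, f"p{i}", "src", 1, 10,
                                    forced_strategy=s))
            )
        return b

    def test_majority_wins(self):
        b = self._bin([Strategy.PCR, Strategy.PCR, Strategy.DIGEST])
        assert bin_consensus_strategy(b) is Strategy.PCR

    def test_none_when_nothing_forced(self):
        assert bin_consensus_strategy(self._bin([None, None])) is None

    @pytest.mark.parametrize(
        "a,b", list(itertools.combinations(list(Strategy), 2))
    )
    def test_ties_broken_by_vocabulary_order_exhaustively(self, a, b):
        order = list(Strategy)
        expected = a if order.index(a) < order.index(b) else b
        assert bin_consensus_strategy(self._bin([a, b])) is expected
        assert bin_consensus_strategy(self._bin([b, a])) is expected

    def test_empty_bin_is_structure_error(self):
        with pytest.raises(StructureError):
            bin_consensus_strategy(Bin("b"))


class TestValidateDesign:
    def test_empty_design_diagnosed(self):
        codes = [d.code for d in validate_design(Design())]
        assert "E_EMPTY_DESIGN" in codes

    def test_strategy_mismatch_warns_on_minority_part(self):
        d = Design()
        d.add_bin("b1")
        d.add_bin("b2")
        src = _source(300)
        d.create_part("filler", src, 1, 20, bin_index=0)
        d.create_part(
            "a", src, 21, 60,
            forced_strategy=Strategy.DIRECT_SYNTHESIS, bin_index=1,
        )
        d.create_part(
            "b", src, 61, 100, forced_strategy=Strategy.PCR, bin_index=1
        )
        warned = [x for x in validate_design(d) if x.code == "W_STRATEGY_MISMATCH"]
        assert len(warned) == 1
        assert warned[0].subject == "a"  # PCR wins the tie, DS part breaks it

    def test_rule_operand_missing_diagnosed(self, prdr_design):
        from partforge import EugeneRule, Operator

        prdr_design.rules.append(
            EugeneRule("bad", Operator.NOTMORETHAN, "ispA", 1)
        )
        codes = [d.code for d in validate_design(prdr_design)]
        assert "E_RULE_OPERAND_MISSING" in codes

    def test_digest_first_bin_toggle(self, prdr_design):
        p = prdr_design.bins[0].parts[0]
        p.definition.forced_strategy = Strategy.DIGEST
        assert any(
            d.code == "E_DIGEST_FIRST_BIN" for d in validate_design(prdr_design)
        )
        assert not any(
            d.code == "E_DIGEST_FIRST_BIN"
            for d in validate_design(prdr_design, digest_first_bin=False)
        )

    def test_method_arity_warnings(self, prdr_design):
        prdr_design.declared_arity = "single"
        assert any(
            d.code == "W_METHOD_ARITY" for d in validate_design(prdr_design)
        )
        prdr_design.declared_arity = "combinatorial"
        assert not any(
            d.code == "W_METHOD_ARITY" for d in validate_design(prdr_design)
        )

    def test_indicator_surrogates(self, prdr_with_rule):
        d = prdr_with_rule
        short = d.find_part("short")
        sig2 = d.find_part("sig2")
        assert d.part_has_rules(short)
        assert not d.part_has_rules(sig2)
        long_ = d.find_part("long")
        long_.definition.forced_strategy = Strategy.PCR
        assert d.part_forces_consensus(long_)
        short.definition.forced_strategy = Strategy.DIGEST
        assert d.part_breaks_consensus(short)
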