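import numpy as np
import pytest

from _oracles import hamming_window_oracle
from srna_census.formats_io import ReferenceSet, SequenceRecord, TagCount, reverse_complement
from srna_census.homology import (
    HomologyPolicy,
    annotate_tags,
    classify_against_mirna_refs,
    classify_special,
    hamming_match,
    mirna_family,
    sense_antisense_filter,
)

MIR1 = "AAATGTAAAGAAGTATGGAG"            # a conserved mature miRNA
MIR29 = "TAGCACCATTTGAAACCAGTAT"          # 22 nt
MIR29B = "TAGCACCATTTGAAACCAGT"           # 20 nt paralog
MIR184 = "AGGACGGAGAACTGATAAAGGC"


def refset(kind, *pairs, name="refs"):
    return ReferenceSet(name, kind, [SequenceRecord(id=i, seq=s) for i, s in pairs])


def mutate(seq, positions):
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    chars = list(seq)
    for p in positions:
        chars[p] = swap[chars[p]]
    return "".join(chars)


class TestHammingMatch:
    def test_self_zero_mismatches(self):
        hit = hamming_match(MIR1, MIR1, 2)
        assert hit.mismatches == 0

    def test_equal_length_mode_requires_equal_length(self):
        assert hamming_match(MIR29, MIR29B, 2) is None

    def test_mismatch_budget(self):
        assert hamming_match(mutate(MIR1, [2, 7, 11]), MIR1, 2) is None
        hit = hamming_match(mutate(MIR1, [2, 7]), MIR1, 2)
        assert hit.mismatches == 2

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            hamming_match(MIR1, MIR1, -1)

    def test_window_mode_vs_bruteforce(self, rng):
        """Window search agrees with a position-by-position oracle on random
        (query, reference) pairs of lengths <= 30 / 60."""
        for _ in range(300):
            lq = int(rng.integers(8, 31))
            lr = int(rng.integers(lq, 61))
            q = "".join(rng.choice(list("ACGT"), lq))
            r = "".join(rng.choice(list("ACGT"), lr))
            if rng.random() < 0.5:  # ensure frequent hits
                pos = int(rng.integers(0, lr - lq + 1))
                chunk = list(q)
                r = r[:pos] + "".join(chunk) + r[pos + lq:]
            max_mm = int(rng.integers(0, 3))
            got = hamming_match(q, r, max_mm, mode="window")
            want = hamming_window_oracle(q, r, max_mm)
            if want is None:
                assert got is None
            else:
                best_mm, placements = want
                assert got.mismatches == best_mm
                assert (got.strand, got.position) in placements


class TestFamilyGrammar:
    @pytest.mark.parametrize("rid,family", [
        ("api-miR-252b", "miR-252"),
        ("miR-2a-1b", "miR-2"),
        ("let-7d", "let-7"),
        ("miR-iab-4-5p", "miR-iab-4"),
        ("bmo-bantam", "bantam"),
        ("aps-miR-X12", "miR-X12"),
        ("miR-184", "miR-184"),
        ("sim-miR-100", "miR-100"),
    ])
    def test_examples(self, rid, family):
        assert mirna_family(rid) == family


class TestClassification:
    def test_exact_conserved_hit(self):
        refs = refset("mirna", ("dme-miR-184", MIR184))
        recs = classify_against_mirna_refs([TagCount(seq=MIR184, count=5)], refs, None)
        r = recs[0]
        assert r.assigned_class == "conserved_mirna"
        assert r.family == "miR-184" and r.mismatches == 0

    def test_equidistant_tie_lexicographic(self):
        a = mutate(MIR1, [3])
        b = mutate(MIR1, [9])
        refs = refset("mirna", ("zzz-miR-9", b), ("aaa-miR-1", a))
        # tag at 1 mismatch from both references: enumerate hits, apply rule
        tag = mutate(MIR1, [3, 9])
        dists = {rid: sum(x != y for x, y in zip(tag, s))
                 for rid, s in [("zzz-miR-9", b), ("aaa-miR-1", a)]}
        assert set(dists.values()) == {1}
        rec = classify_against_mirna_refs([TagCount(seq=tag, count=1)], refs, None)[0]
        assert rec.best_hit == "aaa-miR-1"

    def test_conserved_precedes_aphid_specific(self):
        conserved = refset("mirna", ("sim-miR-1", MIR1))
        aphid = refset("mirna", ("aps-miR-X10", mutate(MIR1, [4, 8])))
        tag = TagCount(seq=mutate(MIR1, [4]), count=1)  # 1 mm from each set
        d_cons = sum(x != y for x, y in zip(tag.seq, MIR1))
        d_aphid = sum(x != y for x, y in zip(tag.seq, mutate(MIR1, [4, 8])))
        assert d_cons == 1 and d_aphid == 1
        rec = classify_against_mirna_refs([tag], conserved, aphid)[0]
        assert rec.assigned_class == "conserved_mirna"

    def test_three_mismatches_unassigned(self):
        refs = refset("mirna", ("sim-miR-1", MIR1))
        rec = classify_against_mirna_refs(
            [TagCount(seq=mutate(MIR1, [1, 5, 9]), count=1)], refs, None)[0]
        assert rec.assigned_class == "unassigned"


class TestSpecialClasses:
    def test_plant_requires_exact(self):
        plant = refset("plant_mirna", ("pla-miR-901", MIR184))
        rec = classify_special([TagCount(seq=MIR184, count=1)], plant, None)[0]
        assert rec.assigned_class == "plant_mirna"
        rec = classify_special(
            [TagCount(seq=mutate(MIR184, [3]), count=1)], plant, None)[0]
        assert rec.assigned_class == "unassigned"

    def test_endosymbiont_one_mismatch_window(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 500))
        endo = refset("endosymbiont", ("endo", genome))
        window = genome[100:127]
        one_mm = mutate(window, [5])
        two_mm = mutate(window, [5, 19])
        assert classify_special([TagCount(seq=one_mm, count=1)], None, endo)[0] \
            .assigned_class == "endosymbiont"
        assert classify_special([TagCount(seq=two_mm, count=1)], None, endo)[0] \
            .assigned_class == "unassigned"

    def test_endosymbiont_only_long_reads(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 500))
        endo = refset("endosymbiont", ("endo", genome))
        short = genome[100:122]  # 22-nt exact match, outside the long range
        assert classify_special([TagCount(seq=short, count=1)], None, endo)[0] \
            .assigned_class == "unassigned"


class TestSenseAntisense:
    @pytest.fixture
    def ests(self, rng):
        return refset("est", ("e1", "".join(rng.choice(list("ACGT"), 200))))

    def test_sense_is_degraded_mrna(self, ests):
        tag = TagCount(seq=ests.records[0].seq[50:72], count=1)
        deg, anti, rest = sense_antisense_filter([tag], ests)
        assert deg == [tag] and not anti and not rest

    def test_antisense_retained(self, ests):
        tag = TagCount(seq=reverse_complement(ests.records[0].seq[50:72]), count=1)
        deg, anti, rest = sense_antisense_filter([tag], ests)
        assert anti == [tag] and not deg and not rest

    def test_both_strand_match_is_sense(self):
        # palindromic context occurs on both strands; sense wins
        pal = "ACGTACGTACGTACGTACGT"
        assert pal in reverse_complement("X".replace("X", pal))  # self-revcomp
        ests = refset("est", ("e1", "TTTTT" + pal + "GGGGG"))
        deg, anti, rest = sense_antisense_filter([TagCount(seq=pal, count=1)], ests)
        assert deg and not anti


class TestPartition:
    def test_every_tag_exactly_one_class(self, small_pair):
        result = small_pair["resistant"]["result"]
        assert len(result.annotations) == len(result.distinct)
        assert sum(result.class_counts().values()) == len(result.distinct)

    def test_single_mutation_absorbed_by_budget(self, rng):
        """One substitution per read stays within the 2-mismatch allowance."""
        refs = [SequenceRecord(id=f"sim-miR-{100 + i}",
                               seq="".join(rng.choice(list("ACGT"), 22)))
                for i in range(30)]
        # space references out so a 1-mm mutant cannot jump family
        refs = [r for i, r in enumerate(refs)
                if all(sum(a != b for a, b in zip(r.seq, o.seq)) > 4
                       for o in refs[:i])]
        rs = ReferenceSet("m", "mirna", refs)
        ok = total = 0
        for rec in rs:
            for _ in range(5):
                tag = TagCount(seq=mutate(rec.seq, [int(rng.integers(0, 22))]),
                               count=1)
                out = classify_against_mirna_refs([tag], rs, None)[0]
                total += 1
                ok += out.best_hit == rec.id
        assert ok / total >= 0.99
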