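import numpy as np
import pytest

from _oracles import mfe_oracle
from srna_census.folding import DUPLEX_INIT, STACK
from srna_census.formats_io import SequenceRecord, reverse_complement
from srna_census.target_prediction import (
    MODERATE,
    STRINGENT,
    TargetSite,
    duplex_energy,
    find_seed_sites,
    go_tally,
    open_energy,
    predict_targets,
    rnahybrid_mode,
)

MIRNA = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt


def utr_with_site(mirna, span=8, context="A" * 40):
    """UTR carrying the perfect complement of miRNA positions 2..1+span."""
    site = reverse_complement(mirna[1:1 + span])
    return context + site + context


class TestSeedSites:
    def test_exact_eight_mer(self):
        utr = utr_with_site(MIRNA, 8)
        sites = find_seed_sites(MIRNA, utr, STRINGENT)
        assert any(s.seed_len == 8 for s in sites)

    def test_wobble_forbidden_stringent_allowed_moderate(self):
        site = list(reverse_complement(MIRNA[1:9]))
        # make one seed pair a G:T wobble: miRNA G pairs site T (instead of C)
        g_positions = [k for k in range(8) if MIRNA[1 + k] == "G"]
        k = g_positions[0]
        site[7 - k] = "T"
        utr = "A" * 40 + "".join(site) + "A" * 40
        stringent = find_seed_sites(MIRNA, utr, STRINGENT)
        moderate = find_seed_sites(MIRNA, utr, MODERATE)
        anchor = 40 + 8
        assert not any(s.site_end == anchor and s.seed_len >= 7 for s in stringent)
        assert any(s.seed_len >= 7 for s in moderate)

    def test_stringent_subset_of_moderate(self, rng):
        for _ in range(20):
            mir = "".join(rng.choice(list("ACGT"), 22))
            utr = "".join(rng.choice(list("ACGT"), 150))
            s_str = {(s.site_end, s.seed_len)
                     for s in find_seed_sites(mir, utr, STRINGENT)}
            s_mod = {(s.site_end, s.seed_len)
                     for s in find_seed_sites(mir, utr, MODERATE)}
            anchors_str = {a for a, _ in s_str}
            anchors_mod = {a for a, _ in s_mod}
            assert anchors_str <= anchors_mod

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites("ACGTACGT", "A" * 50, STRINGENT)


class TestDuplexEnergy:
    def test_gc_seed_lower_than_at_seed(self):
        gc = duplex_energy("AGGGGGGGG", reverse_complement("GGGGGGGG"))
        at = duplex_energy("AAAAAAAAA", reverse_complement("AAAAAAAA"))
        assert gc < at

    def test_seed_only_stack_sum(self):
        # 8 consecutive G:C pairs, nothing else pairable (A opposite A)
        e = duplex_energy("G" * 8 + "A", "A" + "C" * 8)
        assert e == pytest.approx(DUPLEX_INIT + 7 * float(STACK[2, 2]))


class TestOpenEnergy:
    def test_polya_context_zero(self):
        utr = "A" * 70
        assert open_energy(utr, 30, 40) == 0.0

    def test_hairpin_stem_positive(self):
        stem = "GGCGGCGGCGGC"
        utr = "A" * 30 + stem + "TTTT" + reverse_complement(stem) + "A" * 30
        s0 = 31  # 1-based start of the stem
        assert open_energy(utr, s0, s0 + len(stem) - 1) > 0.0

    def test_matches_constrained_enumeration(self, rng):
        """dg_open equals the constrained-minus-free difference computed by
        exhaustive structure enumeration on short windows."""
        for _ in range(15):
            n = int(rng.integers(12, 16))
            utr = "".join(rng.choice(list("ACGT"), n))
            s0 = int(rng.integers(1, n - 3))
            s1 = min(n, s0 + 3)
            got = open_energy(utr, s0, s1, flank=50)
            banned = frozenset(range(s0 - 1, s1))
            want = max(0.0, mfe_oracle(utr, banned=banned) - mfe_oracle(utr))
            assert got == pytest.approx(want, abs=1e-6)

    def test_monotone_in_constraint_size(self, rng):
        for _ in range(10):
            utr = "".join(rng.choice(list("ACGT"), 60))
            small = open_energy(utr, 25, 30)
            large = open_energy(utr, 20, 35)
            assert large >= small - 1e-9

    def test_bad_coordinates_rejected(self):
        with pytest.raises(ValueError):
            open_energy("A" * 50, 0, 10)


class TestPredictTargets:
    def _study(self):
        mirnas = [SequenceRecord(id="m1", seq=MIRNA)]
        utrs = [SequenceRecord(id="u1", seq=utr_with_site(MIRNA, 8))]
        return mirnas, utrs

    def test_accessible_site_retained(self):
        mirnas, utrs = self._study()
        sites, summary = predict_targets(mirnas, utrs, STRINGENT)
        assert summary["pairs"] == 1
        s = sites[0]
        assert s.dg_open == pytest.approx(0.0, abs=1e-9)
        assert s.ddg == pytest.approx(s.dg_duplex)
        assert s.ddg <= -10.0

    def test_threshold_arithmetic(self):
        site = TargetSite(mirna_id="m", utr_id="u", site_start=1, site_end=8,
                          seed_len=8, dg_duplex=-18.0, dg_open=12.0)
        assert site.ddg == pytest.approx(-6.0)
        site2 = TargetSite(mirna_id="m", utr_id="u", site_start=1, site_end=8,
                           seed_len=8, dg_duplex=-18.0, dg_open=0.0)
        assert site2.ddg == pytest.approx(-18.0)

    def test_threshold_anti_monotone(self):
        mirnas, utrs, _ = _mini_study()
        kept = {}
        for thr in (-8.0, -10.0, -14.0):
            sites, _ = predict_targets(mirnas, utrs, STRINGENT, ddg_threshold=thr)
            kept[thr] = {(s.mirna_id, s.utr_id) for s in sites}
        assert kept[-14.0] <= kept[-10.0] <= kept[-8.0]

    def test_counting_convention(self):
        # 3 miRNAs each hitting the same 2 UTRs -> 2 targets, 6 pairs
        mirnas = [SequenceRecord(id=f"m{i}", seq=MIRNA) for i in range(3)]
        utrs = [SequenceRecord(id=f"u{i}", seq=utr_with_site(MIRNA, 8))
                for i in range(2)]
        _, summary = predict_targets(mirnas, utrs, STRINGENT)
        assert summary["targets"] == 2 and summary["pairs"] == 6


def _mini_study():
    import srna_census as sc

    return sc.make_target_study(seed=3, n_mirnas=5, n_utrs=8, n_planted=4)


class TestRNAhybridMode:
    def test_planted_site_significant(self, rng):
        import srna_census as sc

        mirnas, utrs, planted = sc.make_target_study(
            seed=4, n_mirnas=2, n_utrs=3, n_planted=2)
        records, retained = rnahybrid_mode(mirnas, utrs, n_shuffles=60, rng=rng)
        assert all(0.0 <= r["p"] <= 1.0 for r in records)
        planted_pairs = {(p["mirna_id"], p["utr_id"]) for p in planted}
        hit_ps = [r["p"] for r in records
                  if (r["mirna_id"], r["utr_id"]) in planted_pairs]
        assert hit_ps and min(hit_ps) <= 0.01

    def test_p_monotone_in_energy(self, rng):
        from srna_census.target_prediction import extreme_value_p

        null = rng.normal(-18.0, 2.5, 200)
        energies = [-35.0, -25.0, -20.0, -15.0, -10.0]
        ps = [extreme_value_p(e, null) for e in energies]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert ps == sorted(ps)
        assert ps[0] < 0.01


class TestGOTally:
    def _sites(self, n, utr_prefix="g"):
        return [TargetSite(mirna_id=f"m{i}", utr_id=f"{utr_prefix}{i}",
                           site_start=1, site_end=8, seed_len=8)
                for i in range(n)]

    def test_single_category(self):
        sites = self._sites(10)
        mapping = {f"g{i}": ["morphogenesis"] for i in range(10)}
        out = go_tally(sites, mapping)
        assert out["fractions"] == {"morphogenesis": 1.0}

    def test_empty_mapping(self):
        out = go_tally(self._sites(3), {})
        assert out["counts"] == {} and out["total_terms"] == 0

    def test_fractions_sum_to_one(self):
        mapping = {"g0": ["a", "b"], "g1": ["b"], "g2": ["c", "c"]}
        out = go_tally(self._sites(3), mapping)
        assert sum(out["fractions"].values()) == pytest.approx(1.0)
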