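"""Simulator anatomy, RIP rules, structural events, exact hits, alignment."""

import numpy as np
import pytest

from ripnet.core_io import SequenceRecord, gc_content
from ripnet.pairscore import merge_hsps
from ripnet.simulate import (
    SimConfig,
    _Block,
    _Unit,
    apply_rip,
    local_align,
    make_solo_ltr,
    rip_mutate_seq,
    simulate_family,
    truth_hits,
)


def solo_unit(uid, seq_codes, u3_len):
    """A solo-LTR unit from raw base codes (test helper)."""
    return _Unit(uid, 0, "solo", [
        _Block("u3", 0, u3_len, seq_codes[:u3_len].copy()),
        _Block("ru5", 0, len(seq_codes) - u3_len, seq_codes[u3_len:].copy()),
    ])


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(u3_divergence=1.5)
        with pytest.raises(ValueError):
            SimConfig(p_solo=-0.1)

    def test_u3_must_fit_in_ltr(self):
        with pytest.raises(ValueError):
            SimConfig(u3_len=400, ltr_len=400)

    def test_cpa_preference_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(rip_p_cpa=0.01, rip_p_other=0.05)

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_family(SimConfig(copies_per_subfamily=50, genome_len=500))


class TestInsertionAnatomy:
    def test_single_copy_layout_and_tsd(self):
        cfg = SimConfig(n_subfamilies=1, copies_per_subfamily=1, n_cycles=0,
                        ltr_len=100, u3_len=50, internal_len=300, seed=1)
        sim = simulate_family(cfg)
        (fc,) = sim.full_copies
        genome = sim.genome.seq
        # LTR|internal|LTR layout with identical LTRs
        ltr5 = genome[fc.ltr5.start : fc.ltr5.end]
        ltr3 = genome[fc.ltr3.start : fc.ltr3.end]
        assert ltr5 == ltr3 and len(ltr5) == 100
        assert fc.internal.length == 300
        # identical target-site duplications flank the element
        tsd_left = genome[fc.element.start - cfg.tsd_len : fc.element.start]
        tsd_right = genome[fc.element.end : fc.element.end + cfg.tsd_len]
        assert tsd_left == tsd_right

    def test_copy_ids_encode_coordinates(self):
        cfg = SimConfig(n_subfamilies=1, copies_per_subfamily=2, n_cycles=0, seed=2)
        sim = simulate_family(cfg)
        for c in sim.copies:
            assert c.id == f"{c.interval.contig}_{c.interval.start + 1}-{c.interval.end}"
            assert sim.genome.seq[c.interval.start : c.interval.end] == c.sequence

    def test_within_subfamily_identity_at_insertion(self):
        cfg = SimConfig(n_subfamilies=2, copies_per_subfamily=3, n_cycles=0, seed=3)
        sim = simulate_family(cfg)
        by_subfam = {}
        for c in sim.copies:
            by_subfam.setdefault(c.subfamily, []).append(c.codes)
        for seqs in by_subfam.values():
            for s in seqs[1:]:
                assert np.array_equal(s, seqs[0])

    def test_between_subfamily_ltr_identity_matches_per_site_expectation(self):
        # each founder U3 site mutates independently with probability d to a
        # random other base, so two founders agree per U3 site with
        # probability (1-d)^2 + d^2/3; the conserved half always matches.
        d = 0.5
        u3, ru5 = 200, 200
        expected = 100 * (u3 * ((1 - d) ** 2 + d**2 / 3) + ru5) / (u3 + ru5)
        obs = []
        for seed in range(30):
            cfg = SimConfig(n_subfamilies=2, copies_per_subfamily=1, n_cycles=0,
                            internal_len=600, u3_divergence=d, seed=seed)
            sim = simulate_family(cfg)
            a = next(c.codes for c in sim.copies if c.subfamily == "SF1")
            b = next(c.codes for c in sim.copies if c.subfamily == "SF2")
            obs.append(100 * float((a == b).mean()))
        assert np.mean(obs) == pytest.approx(expected, abs=1.5)


class TestRip:
    def test_cpa_context_hand_scan(self):
        rng = np.random.default_rng(0)
        assert rip_mutate_seq("ACACA", 1.0, 0.0, rng) == "ATATA"

    def test_tpg_context_is_complement_symmetry(self):
        rng = np.random.default_rng(0)
        assert rip_mutate_seq("TGTG", 1.0, 0.0, rng) == "TATA"

    def test_non_context_sites_untouched_when_p_other_zero(self):
        rng = np.random.default_rng(0)
        assert rip_mutate_seq("GGCC", 1.0, 0.0, rng) == "GGCC"

    def test_never_creates_c_or_g(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        out = rip_mutate_seq(seq, 0.5, 0.2, rng)
        for a, b in zip(seq, out):
            if a != b:
                assert (a, b) in {("C", "T"), ("G", "A")}
        assert gc_content(out) <= gc_content(seq)

    def test_short_copies_never_exposed(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 4, 300).astype(np.uint8)
        units = [solo_unit(0, codes, 150), solo_unit(1, codes, 150)]
        cfg = SimConfig(rip_min_len=400, rip_p_cpa=1.0, rip_p_other=1.0)
        exposed = apply_rip(units, cfg, rng)
        assert exposed == []
        assert np.array_equal(units[0].concat()[0], codes)

    def test_similar_long_pair_both_exposed(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 4, 500).astype(np.uint8)
        units = [solo_unit(0, codes, 200), solo_unit(1, codes, 200)]
        cfg = SimConfig(rip_min_len=400, rip_p_cpa=1.0, rip_p_other=1.0,
                        ltr_len=500, u3_len=200)
        exposed = apply_rip(units, cfg, rng)
        assert exposed == [0, 1]
        assert units[0].rip_exposures == 1
        assert not np.array_equal(units[0].concat()[0], codes)

    def test_dissimilar_pair_not_exposed(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 500).astype(np.uint8)
        b = rng.integers(0, 4, 500).astype(np.uint8)
        units = [solo_unit(0, a, 200), solo_unit(1, b, 200)]
        cfg = SimConfig(rip_min_len=400, rip_p_cpa=1.0, rip_p_other=1.0)
        assert apply_rip(units, cfg, rng) == []


class TestSoloFormation:
    def _full_unit(self, rng, cfg):
        from ripnet.simulate import _full_blocks

        ltr = rng.integers(0, 4, cfg.ltr_len).astype(np.uint8)
        internal = rng.integers(0, 4, cfg.internal_len).astype(np.uint8)
        return _Unit(0, 0, "full", _full_blocks(ltr, internal, cfg.u3_len)), ltr

    def test_identical_ltrs_give_that_ltr(self):
        cfg = SimConfig(ltr_len=100, u3_len=40, internal_len=200)
        unit, ltr = self._full_unit(np.random.default_rng(2), cfg)
        make_solo_ltr(unit, np.random.default_rng(3))
        assert unit.cls == "solo"
        assert np.array_equal(unit.concat()[0], ltr)

    def test_breakpoint_bookkeeping(self):
        cfg = SimConfig(ltr_len=100, u3_len=40, internal_len=200)
        unit, ltr = self._full_unit(np.random.default_rng(2), cfg)
        # plant a difference at site 10: 5' LTR carries X, 3' LTR carries Y
        blocks = unit.seq_blocks()
        x = blocks[0].seq[10]
        y = (x + 1) % 4
        blocks[3].seq[10] = y
        bp = make_solo_ltr(unit, np.random.default_rng(4))
        solo = unit.concat()[0]
        expected = x if bp > 10 else y
        assert solo[10] == expected

    def test_length_shrinks_by_internal_plus_one_ltr(self):
        cfg = SimConfig(ltr_len=100, u3_len=40, internal_len=200)
        unit, _ = self._full_unit(np.random.default_rng(2), cfg)
        before = unit.own_len()
        make_solo_ltr(unit, np.random.default_rng(5))
        assert before - unit.own_len() == cfg.internal_len + cfg.ltr_len

    def test_requires_full_copy(self):
        cfg = SimConfig(ltr_len=100, u3_len=40, internal_len=200)
        unit, _ = self._full_unit(np.random.default_rng(2), cfg)
        make_solo_ltr(unit, np.random.default_rng(6))
        with pytest.raises(ValueError):
            make_solo_ltr(unit, np.random.default_rng(7))


class TestTruthHits:
    def _sim(self, **kw):
        base = dict(n_subfamilies=2, copies_per_subfamily=3, n_cycles=0,
                    internal_len=600, seed=11)
        base.update(kw)
        return simulate_family(SimConfig(**base))

    def test_identical_copies_one_full_length_hsp(self):
        sim = self._sim(n_subfamilies=1, copies_per_subfamily=2)
        a, b = sim.copies[:2]
        hits = [h for h in truth_hits(sim) if h.qid == a.id and h.sid == b.id]
        assert len(hits) == 1
        (h,) = hits
        assert h.pident == 100.0 and h.alen == a.length
        assert (h.qstart, h.qend) == (0, a.length)

    def test_diverged_u3_splits_hsps(self):
        sim = self._sim(u3_divergence=0.5)
        a = sim.copies[0]
        b = next(c for c in sim.copies if c.subfamily != a.subfamily)
        hits = [h for h in truth_hits(sim) if h.qid == a.id and h.sid == b.id]
        # the ~33%-identity U3 block is below the emission floor: only the
        # conserved half survives
        assert len(hits) == 1
        (h,) = hits
        assert h.qstart == sim.config.u3_len and h.pident > 95

    def test_moderately_diverged_u3_emitted_separately(self):
        sim = self._sim(u3_divergence=0.15)
        a = sim.copies[0]
        b = next(c for c in sim.copies if c.subfamily != a.subfamily)
        hits = [h for h in truth_hits(sim) if h.qid == a.id and h.sid == b.id]
        assert len(hits) == 2
        u3_hit = min(hits, key=lambda h: h.pident)
        assert u3_hit.qend <= sim.config.u3_len

    def test_solo_vs_full_hits_stay_in_ltr_space(self):
        cfg = SimConfig(n_subfamilies=1, copies_per_subfamily=8, n_cycles=1,
                        p_solo=0.5, p_frag=0.0, internal_len=600,
                        neutral_mut_rate=0.0, rip_p_cpa=0.0, rip_p_other=0.0,
                        seed=13)
        sim = simulate_family(cfg)
        classes = {c.copy_class for c in sim.copies}
        assert "solo" in classes and "full" in classes
        for h in truth_hits(sim):
            assert h.qend <= cfg.ltr_len and h.send <= cfg.ltr_len

    def test_hits_agree_with_merged_identity_of_local_alignment(self):
        # an ungapped, lightly diverged pair: Smith-Waterman should recover
        # essentially the same identity as the exact bookkeeping
        sim = self._sim(n_subfamilies=1, neutral_mut_rate=0.01, n_cycles=1)
        a = sim.copies[0]
        b = next(c for c in sim.copies[1:] if c.interval.start >= a.interval.end)
        exact = [h for h in truth_hits(sim) if h.qid == a.id and h.sid == b.id]
        aligned = local_align(SequenceRecord(a.id, a.sequence),
                              SequenceRecord(b.id, b.sequence))
        exact_merged = merge_hsps(exact, a.length).merged_identity
        sw_merged = merge_hsps(aligned, a.length).merged_identity
        assert sw_merged == pytest.approx(exact_merged, abs=2.0)


class TestLocalAlign:
    def test_identical_sequences_single_full_hsp(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), 400))
        (h,) = local_align(SequenceRecord("a", seq), SequenceRecord("b", seq))
        assert h.pident == 100.0
        assert (h.qstart, h.qend, h.sstart, h.send) == (0, 400, 0, 400)

    def test_shared_block_confined(self):
        rng = np.random.default_rng(22)
        block = "".join(rng.choice(list("ACGT"), 200))
        left = "".join(rng.choice(list("ACGT"), 150))
        right = "".join(rng.choice(list("ACGT"), 150))
        a = SequenceRecord("a", left + block + "".join(rng.choice(list("ACGT"), 150)))
        b = SequenceRecord("b", right + block)
        hits = local_align(a, b)
        top = hits[0]
        assert top.pident > 95
        assert abs(top.qstart - 150) <= 5 and abs(top.qend - 350) <= 5

    def test_unrelated_sequences_no_hits(self):
        rng = np.random.default_rng(23)
        a = SequenceRecord("a", "".join(rng.choice(list("ACGT"), 300)))
        b = SequenceRecord("b", "".join(rng.choice(list("ACGT"), 300)))
        assert local_align(a, b) == []


class TestDeterminism:
    def test_identical_seeds_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_subfamilies=2, copies_per_subfamily=8, n_cycles=2,
                        p_solo=0.1, p_frag=0.05, p_nest=0.05, seed=99)
        for d in ("run1", "run2"):
            simulate_family(cfg).write(tmp_path / d)
        for name in ("genome.fa", "copies.fa", "truth.tsv", "hits.tsv",
                     "full_copies.bed"):
            b1 = (tmp_path / "run1" / name).read_bytes()
            b2 = (tmp_path / "run2" / name).read_bytes()
            assert b1 == b2, name

    def test_different_seeds_differ(self):
        a = simulate_family(SimConfig(n_subfamilies=1, copies_per_subfamily=2, seed=1))
        b = simulate_family(SimConfig(n_subfamilies=1, copies_per_subfamily=2, seed=2))
        assert a.genome.seq != b.genome.seq


class TestNestedInsertions:
    def test_nested_copies_annotated(self):
        cfg = SimConfig(n_subfamilies=1, copies_per_subfamily=6, n_cycles=3,
                        p_solo=0.0, p_frag=0.0, p_nest=0.5,
                        internal_len=600, seed=31)
        sim = simulate_family(cfg)
        classes = {c.copy_class for c in sim.copies}
        assert "nested" in classes
        # genome stays consistent: every copy's recorded coordinates match
        for c in sim.copies:
            assert sim.genome.seq[c.interval.start : c.interval.end] == c.sequence
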