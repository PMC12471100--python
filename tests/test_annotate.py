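import numpy as np
import pytest

from retroburst import annotate as ann
from retroburst import simulate as sim
from retroburst.seqio import PipelineConfig, SequenceRecord

from .conftest import TRNA_3P


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestExtractWindow:
    def test_centered_window(self):
        rng = np.random.default_rng(0)
        contig = SequenceRecord("c", _random_dna(rng, 40000))
        win, off = ann.extract_window(contig, (20000, 20100), 15000)
        assert len(win) == 15000
        assert off <= 20000 <= off + 15000

    def test_truncated_at_start(self):
        rng = np.random.default_rng(1)
        contig = SequenceRecord("c", _random_dna(rng, 12000))
        win, off = ann.extract_window(contig, (1000, 1100), 15000)
        assert off == 0 and len(win) == 12000

    def test_roundtrip_coordinates(self):
        rng = np.random.default_rng(2)
        contig = SequenceRecord("c", _random_dna(rng, 30000))
        win, off = ann.extract_window(contig, (9000, 9050), 15000)
        assert win == contig.seq[off:off + len(win)]

    def test_anchor_outside_errors(self):
        contig = SequenceRecord("c", "ACGT" * 100)
        with pytest.raises(ValueError):
            ann.extract_window(contig, (500, 600))


def _planted_window(rng, ltr, gap=4000, flank=3000, tsd="GATC"):
    """Random window with two identical LTR copies and a TSD."""
    internal = _random_dna(rng, gap)
    left = _random_dna(rng, flank - len(tsd))
    right = _random_dna(rng, flank - len(tsd))
    win = left + tsd + ltr + internal + ltr + tsd + right
    start = len(left) + len(tsd)
    return win, (start, start + len(ltr)), \
        (start + len(ltr) + gap, start + 2 * len(ltr) + gap)


class TestFindLtrPairs:
    def test_planted_identical_repeats(self, rng):
        ltr = "TGT" + _random_dna(rng, 294) + "ACA"
        win, left, right = _planted_window(rng, ltr)
        cands = ann.find_ltr_pairs(win)
        assert len(cands) == 1
        c = cands[0]
        assert (c.left, c.right) == (left, right)
        assert c.identity == 1.0 and c.termini_ok

    def test_bad_terminus_rejected_when_required(self, rng):
        ltr = "TGT" + _random_dna(rng, 294) + "ACA"
        win, left, right = _planted_window(rng, ltr)
        # mutate the right repeat's final ACA -> ACC
        win = win[:right[1] - 1] + "C" + win[right[1]:]
        assert ann.find_ltr_pairs(win, require_termini=True) == []
        relaxed = ann.find_ltr_pairs(win, require_termini=True,
                                     termini_mismatch=2)
        assert len(relaxed) == 1
        assert not relaxed[0].termini_ok

    def test_short_window_returns_empty(self):
        assert ann.find_ltr_pairs("ACGT" * 20) == []

    def test_diverged_repeat_exact_intervals(self, burst_result):
        """Simulator truth: candidate intervals match the truth table."""
        genomes = {c.id: c.seq for c in burst_result.contigs}
        ltr = len(burst_result.template.ltr)
        hits = 0
        for r in burst_result.truth:
            contig = next(c for c in burst_result.contigs
                          if c.id == r.contig_id)
            mid = sum(r.interval) // 2
            win, off = ann.extract_window(contig, (mid - 50, mid + 50), 15000)
            cands = ann.find_ltr_pairs(win, termini_mismatch=3)
            want_left = (r.interval[0] - off, r.interval[0] - off + ltr)
            want_right = (r.interval[1] - off - ltr, r.interval[1] - off)
            if any((c.left, c.right) == (want_left, want_right)
                   for c in cands):
                hits += 1
        assert hits >= len(burst_result.truth) - 1


class TestConfirmElement:
    def test_simulated_tsd_recovered(self, burst_result):
        cfg = PipelineConfig()
        seeds = [(r.contig_id, sum(r.interval) // 2 - 50,
                  sum(r.interval) // 2 + 50) for r in burst_result.truth]
        res = ann.annotate_genome(burst_result.contigs, seeds, cfg)
        truth = {(r.contig_id, r.interval): r.tsd for r in burst_result.truth}
        for e in res.elements:
            key = (e.contig_id, e.interval)
            if key in truth:
                assert e.tsd_confirmed
                assert e.tsd_left == truth[key]

    def test_mismatched_flanks_unconfirmed(self, rng):
        ltr = "TGT" + _random_dna(rng, 294) + "ACA"
        internal = _random_dna(rng, 2000)
        win = ("ACGT" + ltr + internal + ltr + "ACGA"
               + _random_dna(rng, 200))
        cand = ann.LtrCandidate(left=(4, 4 + 300),
                                right=(4 + 300 + 2000, 4 + 600 + 2000),
                                identity=1.0, termini_ok=True)
        elem = ann.confirm_element(win, cand)
        assert not elem.tsd_confirmed
        assert elem.tsd_left == "ACGT" and elem.tsd_right == "ACGA"

    def test_window_edge_flank_too_short(self, rng):
        ltr = "TGT" + _random_dna(rng, 94) + "ACA"
        win = ltr + _random_dna(rng, 500) + ltr + "GGAA"
        cand = ann.LtrCandidate(left=(0, 100), right=(600, 700),
                                identity=1.0, termini_ok=True)
        elem = ann.confirm_element(win, cand)
        assert not elem.tsd_confirmed
        assert "edge" in elem.notes

    def test_no_cross_element_tsd_consensus_needed(self, burst_result):
        """TSDs differ between elements; each is confirmed on its own."""
        tsds = {r.tsd for r in burst_result.truth}
        assert len(tsds) > 1


class TestLtrPairIdentity:
    def test_identical_is_one(self, rng):
        ltr = "TGT" + _random_dna(rng, 294) + "ACA"
        win, left, right = _planted_window(rng, ltr)
        contig = SequenceRecord("c", win)
        cand = ann.LtrCandidate(left=left, right=right, identity=1.0,
                                termini_ok=True)
        elem = ann.confirm_element(win, cand, contig_id="c")
        assert ann.ltr_pair_identity(elem, contig) == 1.0

    def test_three_mismatches_in_300(self, rng):
        ltr = "TGT" + _random_dna(rng, 294) + "ACA"
        mutated = list(ltr)
        for pos in (50, 150, 250):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        seq = "AAAA" + ltr + _random_dna(rng, 1000) + "".join(mutated) + "AAAA"
        contig = SequenceRecord("c", seq)
        elem = ann.LtrElement(
            contig_id="c", interval=(4, 4 + 300 + 1000 + 300), strand="+",
            ltr5_interval=(4, 304), ltr3_interval=(1304, 1604),
            internal_interval=(304, 1304), tsd_left="AAAA", tsd_right="AAAA",
            tsd_confirmed=True, ltr_identity=0.99)
        assert ann.ltr_pair_identity(elem, contig) == pytest.approx(0.99)


class TestAnnotateGenome:
    def test_short_contig_skipped(self, rng):
        contig = SequenceRecord("short", _random_dna(rng, 8000))
        res = ann.annotate_genome([contig], [("short", 4000, 4100)],
                                  PipelineConfig())
        assert res.n_skipped_contigs == 1
        assert res.elements == []

    def test_two_seeds_one_element_dedup(self, burst_result):
        r = burst_result.truth[0]
        s, e = r.interval
        seeds = [(r.contig_id, s + 700, s + 800),
                 (r.contig_id, e - 800, e - 700)]
        res = ann.annotate_genome(burst_result.contigs, seeds,
                                  PipelineConfig())
        assert len(res.elements) == 1
        assert res.n_deduplicated == 1

    def test_unknown_contig_raises(self, burst_result):
        with pytest.raises(KeyError):
            ann.annotate_genome(burst_result.contigs, [("nope", 0, 10)],
                                PipelineConfig())

    def test_element_invariants_on_genome(self, burst_result):
        cfg = PipelineConfig()
        seeds = [(r.contig_id, sum(r.interval) // 2 - 50,
                  sum(r.interval) // 2 + 50) for r in burst_result.truth]
        res = ann.annotate_genome(burst_result.contigs, seeds, cfg)
        genomes = {c.id: c.seq for c in burst_result.contigs}
        for e in res.elements:
            g = genomes[e.contig_id]
            if e.termini_ok:
                assert g[e.ltr5_interval[0]:e.ltr5_interval[0] + 3] == "TGT"
                assert g[e.ltr3_interval[1] - 3:e.ltr3_interval[1]] == "ACA"
            if e.tsd_confirmed:
                s, en = e.interval
                assert g[s - 4:s] == g[en:en + 4]

    def test_zero_divergence_recovery_is_exact(self, small_template):
        evo = sim.EvoParams(burst_schedule=[(0.0, 10)], mu_r=0.0, mu_h=0.0,
                            seed=8, end_time=0.0)
        res = sim.simulate_expansion(small_template, 10, 42000, evo,
                                     min_spacing=16000)
        seeds = [(r.contig_id, sum(r.interval) // 2 - 50,
                  sum(r.interval) // 2 + 50) for r in res.truth]
        out = ann.annotate_genome(res.contigs, seeds, PipelineConfig())
        found = {(e.contig_id, e.interval, e.tsd_left) for e in out.elements}
        want = {(r.contig_id, r.interval, r.tsd) for r in res.truth}
        assert found == want


def test_global_identity_n_never_matches():
    assert ann.global_identity("ANGT", "ANGT") == pytest.approx(0.75)
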