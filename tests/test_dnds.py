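import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroburst import dnds as dn
from retroburst import simulate as sim
from retroburst.seqio import Alignment, SequenceRecord

from . import oracles
from .conftest import make_alignment

SENSE = [c for c in dn.ALL_CODONS if c not in dn.STOP_CODONS]


class TestCodonChangeCounts:
    def test_identical(self):
        assert dn.codon_change_counts("TTT", "TTT") == (0.0, 0.0)

    def test_single_synonymous(self):
        # AAA and AAG both encode Lys
        assert dn.codon_change_counts("AAA", "AAG") == (1.0, 0.0)

    def test_double_hit_all_leucine(self):
        # TTG -> CTG -> CTA and TTG -> TTA -> CTA stay Leu throughout
        assert dn.codon_change_counts("TTG", "CTA") == (2.0, 0.0)

    def test_stop_input_rejected(self):
        with pytest.raises(ValueError):
            dn.codon_change_counts("TAA", "AAA")

    def test_exhaustive_oracle_equivalence(self):
        for a, b in itertools.product(SENSE, repeat=2):
            got = dn.codon_change_counts(a, b)
            want = oracles.codon_counts_oracle(a, b)
            assert math.isclose(got[0], want[0], abs_tol=1e-12), (a, b)
            assert math.isclose(got[1], want[1], abs_tol=1e-12), (a, b)

    def test_symmetry_and_step_conservation(self):
        for a, b in itertools.product(SENSE, repeat=2):
            sd, nd = dn.codon_change_counts(a, b)
            assert (sd, nd) == dn.codon_change_counts(b, a)
            hamming = sum(x != y for x, y in zip(a, b))
            assert math.isclose(sd + nd, hamming, abs_tol=1e-12)

    def test_skip_multihit_mode(self):
        assert dn.codon_change_counts("TTG", "CTA", skip_multihit=True) == \
            (0.0, 0.0)
        assert dn.codon_change_counts("AAA", "AAG", skip_multihit=True) == \
            (1.0, 0.0)


def _random_codon_rows(rng, n_codons=60, mut=6, gaps=2, stops=1):
    a = list(rng.choice(SENSE, size=n_codons))
    b = list(a)
    for _ in range(mut):
        j = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        base = b[j][pos]
        b[j] = b[j][:pos] + rng.choice([x for x in "ACGT" if x != base]) \
            + b[j][pos + 1:]
    for _ in range(gaps):
        j = int(rng.integers(n_codons))
        a[j] = "---"
    for _ in range(stops):
        j = int(rng.integers(n_codons))
        b[j] = rng.choice(sorted(dn.STOP_CODONS))
    return "".join(a), "".join(b)


class TestPairDnds:
    def test_identical_rows_undefined_ratio(self):
        row = "ATGAAATTTGGG"
        pr = dn.pair_dnds(row, row)
        assert pr.nd == pr.sd == 0
        assert pr.ratio is None

    def test_single_synonymous_ratio_zero(self):
        pr = dn.pair_dnds("ATGAAA", "ATGAAG")
        assert (pr.sd, pr.nd) == (1.0, 0.0)
        assert pr.ratio == 0.0

    def test_gap_and_stop_exclusion(self):
        pr = dn.pair_dnds("ATG---AAA", "ATGAAATAA")
        assert pr.codons_compared == 1
        assert pr.excluded_codons == 2

    def test_brute_force_oracle_100_instances(self, rng):
        for i in range(100):
            ra, rb = _random_codon_rows(rng)
            pr = dn.pair_dnds(ra, rb)
            sd, nd, used = oracles.pair_counts_oracle(ra, rb)
            assert math.isclose(pr.sd, sd, abs_tol=1e-9), i
            assert math.isclose(pr.nd, nd, abs_tol=1e-9), i
            assert pr.codons_compared == used

    def test_stop_exclusion_locality(self, rng):
        ra, rb = _random_codon_rows(rng, stops=0, gaps=0)
        pr0 = dn.pair_dnds(ra, rb)
        # introduce a stop at codon 0 of rb; other codons must be untouched
        rb2 = "TAA" + rb[3:]
        pr1 = dn.pair_dnds(ra, rb2)
        s0, n0 = dn.codon_change_counts(ra[:3], rb[:3])
        assert math.isclose(pr1.sd, pr0.sd - s0, abs_tol=1e-9)
        assert math.isclose(pr1.nd, pr0.nd - n0, abs_tol=1e-9)


class TestFamilyDnds:
    def _codon_aln(self, rows, groups):
        return dn.CodonAlignment(make_alignment(rows, groups=groups))

    def test_identical_group_flagged(self):
        rows = {"a": "ATGAAATTT", "b": "ATGAAATTT", "c": "ATGAAATTT"}
        out = dn.family_dnds(self._codon_aln(rows, {k: "g" for k in rows}))
        assert len(out) == 1 and out[0].flagged
        assert out[0].n_undefined == 3

    def test_omega_one_matches_opportunity_ratio(self, small_template):
        meds = []
        for rep in range(12):
            evo = sim.EvoParams(burst_schedule=[(0.0, 12)], mu_r=0.02,
                                mu_h=0.0, omega=1.0, master_succession_p=1.0,
                                ts_tv_ratio=2.0, seed=rep, end_time=0.0)
            res = sim.simulate_expansion(small_template, 3,
                                         10 * small_template.full_len, evo,
                                         min_spacing=small_template.full_len
                                         + 50)
            s, e = res.region_columns["RT"]
            rt = res.alignment.slice_columns(s, e)
            rt.groups = {i: "fam" for i in rt.ids}
            meds.append(dn.family_dnds(dn.CodonAlignment(rt))[0].median)
        s, e = small_template.rt_interval
        codons = [small_template.internal[i:i + 3] for i in range(s, e, 3)]
        expected = sim.mutational_opportunity_ratio(codons, 2.0)
        mc_sd = np.std(meds, ddof=1)
        assert abs(np.mean(meds) - expected) < 3 * mc_sd

    def test_median_increases_with_omega(self, small_template):
        means = []
        for omega in (0.05, 0.3, 1.0):
            meds = []
            for rep in range(8):
                evo = sim.EvoParams(burst_schedule=[(0.0, 10)], mu_r=0.02,
                                    mu_h=0.0, omega=omega,
                                    master_succession_p=1.0, ts_tv_ratio=2.0,
                                    seed=100 * rep + int(100 * omega),
                                    end_time=0.0)
                res = sim.simulate_expansion(
                    small_template, 3, 10 * small_template.full_len, evo,
                    min_spacing=small_template.full_len + 50)
                s, e = res.region_columns["RT"]
                rt = res.alignment.slice_columns(s, e)
                rt.groups = {i: "fam" for i in rt.ids}
                meds.append(dn.family_dnds(dn.CodonAlignment(rt))[0].median)
            means.append(np.mean(meds))
        assert means[0] < means[1] < means[2]


class TestMannWhitney:
    def test_identical_distributions(self):
        r = dn.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.u == pytest.approx(4.5)
        assert r.p == pytest.approx(1.0)

    def test_separated_groups_exact(self):
        r = dn.mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.u == 0
        assert r.method == "exact"
        assert r.p == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            a = sorted(set(rng.normal(size=5).round(6)))
            b = sorted(set(rng.normal(loc=0.5, size=6).round(6)))
            if set(a) & set(b):
                continue
            r = dn.mann_whitney(list(a), list(b))
            u, p = oracles.mwu_oracle(list(a), list(b))
            assert r.u == pytest.approx(u)
            assert r.p == pytest.approx(p, abs=1e-9)

    def test_p_decreases_with_shift(self, rng):
        a = list(rng.normal(size=40))
        ps = []
        for shift in (0.2, 0.8, 2.0):
            b = list(rng.normal(loc=shift, size=40))
            ps.append(dn.mann_whitney(a, b).p)
        assert ps[0] > ps[2]

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            dn.mann_whitney([], [1.0])

    def test_group_tests_tiers(self):
        dists = [
            dn.FamilyDnds("a", 10, 10, 0, 0.1, 0.05, 0.2,
                          ratios=[0.1] * 5 + [0.12] * 5),
            dn.FamilyDnds("b", 10, 10, 0, 0.9, 0.8, 1.0,
                          ratios=[0.9] * 5 + [0.95] * 5),
        ]
        rows = dn.group_tests(dists)
        assert rows[0]["significance"] in {"*", "**", "***"}


@settings(max_examples=40, deadline=None)
@given(st.sampled_from(SENSE), st.sampled_from(SENSE))
def test_counts_property(a, b):
    sd, nd = dn.codon_change_counts(a, b)
    assert sd >= 0 and nd >= 0
    assert math.isclose(sd + nd, sum(x != y for x, y in zip(a, b)),
                        abs_tol=1e-12)
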