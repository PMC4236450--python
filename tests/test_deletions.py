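"""Deletion-callset algebra: reciprocal overlap, merging, novelty,
het-SNP validation, genotype filtering and frequency."""

import itertools

import numpy as np
import pandas as pd
import pytest

import popvar as pv
from popvar.deletions import sites_to_frame
from popvar.errors import ContractError


def call(chrom, start, end, sample="S", genotype=1, genotyped=True):
    return pv.DeletionCall(chrom=str(chrom), start=start, end=end,
                           sample=sample, genotype=genotype,
                           genotyped=genotyped)


class TestReciprocalOverlap:
    def test_identical(self):
        assert pv.reciprocal_overlap(call(1, 100, 200), call(1, 100, 200)) == 1.0

    def test_disjoint(self):
        assert pv.reciprocal_overlap(call(1, 100, 200), call(1, 300, 400)) == 0.0

    def test_half_overlap_by_enumeration(self):
        a, b = call(1, 100, 200), call(1, 150, 250)
        # position-enumeration oracle
        shared = len(set(range(100, 200)) & set(range(150, 250)))
        expected = min(shared / 100, shared / 100)
        assert pv.reciprocal_overlap(a, b) == pytest.approx(expected) == 0.5

    def test_cross_chromosome_zero(self):
        assert pv.reciprocal_overlap(call(1, 0, 100), call(2, 0, 100)) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ContractError):
            pv.reciprocal_overlap(("1", 5, 5), ("1", 0, 10))


class TestSizeFilter:
    def test_strict_bounds(self):
        calls = [call(1, 0, 50), call(1, 0, 51), call(1, 0, 100_000),
                 call(1, 0, 99_999)]
        kept = pv.size_filter(calls)
        assert [c.length for c in kept] == [51, 99_999]


def brute_force_merge(calls, threshold=0.8):
    """O(n^2) oracle: all-pairs adjacency, transitive closure via repeated
    set expansion, then the same canonical-seed splitting, all recomputed
    from scratch."""
    calls = sorted(calls)
    n = len(calls)
    adj = [
        {
            j
            for j in range(n)
            if j != i and pv.reciprocal_overlap(calls[i], calls[j]) >= threshold
        }
        for i in range(n)
    ]
    unassigned = set(range(n))
    components = []
    while unassigned:
        seed = min(unassigned)
        comp = {seed}
        frontier = {seed}
        while frontier:
            nxt = set()
            for i in frontier:
                nxt |= adj[i] & unassigned - comp
            comp |= nxt
            frontier = nxt
        unassigned -= comp
        components.append(sorted(comp))
    sites = []
    for comp in components:
        pending = list(comp)
        while pending:
            seed = pending[0]
            members = [
                i for i in pending
                if pv.reciprocal_overlap(calls[seed], calls[i]) >= threshold
            ]
            sites.append(tuple(members))
            pending = [i for i in pending if i not in members]
    return calls, sorted(
        sites, key=lambda ms: (calls[ms[0]].chrom, calls[ms[0]].start,
                               calls[ms[0]].end)
    )


def random_calls(rng, n=150, n_chroms=4, span=6000):
    calls = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(60, 800))
        calls.append(
            call(int(rng.integers(1, n_chroms + 1)), start, start + length,
                 sample=f"S{int(rng.integers(6))}")
        )
    return calls


class TestMergeCallsets:
    def test_two_sample_overlap_merges(self):
        sites = pv.merge_callsets(
            [call(1, 100, 200, "A"), call(1, 105, 205, "B")]
        )
        assert len(sites) == 1
        assert sites[0].carriers == ("A", "B")
        assert (sites[0].start, sites[0].end) == (100, 200)  # seed interval

    def test_insufficient_overlap_stays_split(self):
        sites = pv.merge_callsets(
            [call(1, 100, 200, "A"), call(1, 170, 270, "B")]
        )
        assert len(sites) == 2

    def test_idempotent(self, rng):
        calls = random_calls(rng)
        sites = pv.merge_callsets(calls)
        again = pv.merge_callsets(
            [
                call(s.chrom, s.start, s.end, s.members[0].sample)
                for s in sites
            ]
        )
        assert [(s.chrom, s.start, s.end) for s in again] == [
            (s.chrom, s.start, s.end) for s in sites
        ]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            calls = random_calls(rng)
            sites = pv.merge_callsets(calls)
            sorted_calls, oracle_sites = brute_force_merge(calls)
            got = [
                tuple(sorted_calls.index(m) for m in s.members)
                for s in sites
            ]
            assert got == [tuple(ms) for ms in oracle_sites]

    def test_invariant_under_input_permutation(self, rng):
        calls = random_calls(rng)
        sites1 = pv.merge_callsets(calls)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        sites2 = pv.merge_callsets(shuffled)
        assert [(s.chrom, s.start, s.end, s.carriers) for s in sites1] == [
            (s.chrom, s.start, s.end, s.carriers) for s in sites2
        ]

    def test_every_member_overlaps_seed(self, rng):
        calls = random_calls(rng, n=300, span=3000)
        for site in pv.merge_callsets(calls):
            seed = (site.chrom, site.start, site.end)
            for m in site.members:
                assert pv.reciprocal_overlap(seed, m) >= 0.8


def brute_force_novelty(sites, refs, threshold=0.5):
    flags = []
    for s in sites:
        known = any(
            pv.reciprocal_overlap((s.chrom, s.start, s.end), r) > threshold
            for r in refs
        )
        flags.append(not known)
    return flags


class TestNoveltyFilter:
    def test_sixty_percent_overlap_is_known(self):
        sites = pv.merge_callsets([call(1, 100, 200)])
        out = pv.novelty_filter(sites, [("1", 140, 240)])
        assert out[0].novel is False

    def test_no_reference_on_chromosome_is_novel(self):
        sites = pv.merge_callsets([call(1, 100, 200)])
        out = pv.novelty_filter(sites, [("2", 100, 200)])
        assert out[0].novel is True

    def test_exactly_half_is_novel(self):
        # strict '>' at the threshold: 50% reciprocal overlap stays novel
        sites = pv.merge_callsets([call(1, 100, 200)])
        out = pv.novelty_filter(sites, [("1", 150, 250)])
        assert pv.reciprocal_overlap(("1", 100, 200), ("1", 150, 250)) == 0.5
        assert out[0].novel is True

    def test_matches_brute_force(self, rng):
        calls = random_calls(rng, n=120)
        refs = [(c.chrom, c.start, c.end) for c in random_calls(rng, n=80)]
        sites = pv.merge_callsets(calls)
        flags = [s.novel for s in pv.novelty_filter(sites, refs)]
        assert flags == brute_force_novelty(sites, refs)


class TestHetSnpValidation:
    def _het(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos"])

    def test_contained_het_snps_counted(self):
        sites = pv.merge_callsets([call(1, 1000, 2000, "A")])
        het = self._het([("A", "1", 1500), ("A", "1", 1800)])
        out, summary = pv.het_snp_validation(sites, het)
        assert out[0].het_snp_count == 2
        assert summary["fraction_zero_het"] == 0.0

    def test_clean_site_passes(self):
        sites = pv.merge_callsets([call(1, 1000, 2000, "A")])
        het = self._het([("A", "1", 5000), ("B", "1", 1500)])  # B not carrier
        out, summary = pv.het_snp_validation(sites, het)
        assert out[0].het_snp_count == 0
        assert summary["fraction_zero_het"] == 1.0

    def test_boundary_position_excluded(self):
        # 1-based 2001 is 0-based 2000, the half-open end: outside
        sites = pv.merge_callsets([call(1, 1000, 2000, "A")])
        out, _ = pv.het_snp_validation(sites, self._het([("A", "1", 2001)]))
        assert out[0].het_snp_count == 0
        # 1-based 2000 is 0-based 1999: the last contained base
        out, _ = pv.het_snp_validation(sites, self._het([("A", "1", 2000)]))
        assert out[0].het_snp_count == 1

    def test_pipeline_invariant_under_callset_permutation(self, rng):
        calls = random_calls(rng, n=100)
        refs = [(c.chrom, c.start, c.end) for c in random_calls(rng, n=40)]
        het = self._het(
            [(f"S{i}", str(c), int(p))
             for i, c, p in zip(rng.integers(0, 6, 50),
                                rng.integers(1, 5, 50),
                                rng.integers(1, 6000, 50))]
        )

        def run(cs):
            sites = pv.novelty_filter(pv.merge_callsets(cs), refs)
            out, summary = pv.het_snp_validation(sites, het)
            return [
                (s.chrom, s.start, s.end, s.novel, s.het_snp_count)
                for s in out
            ]

        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert run(calls) == run(shuffled)


class TestGenotypedFilterAndFrequency:
    def test_filter_keeps_flag_order(self):
        calls = [call(1, 0, 100, "A", genotyped=True),
                 call(2, 0, 100, "B", genotyped=False),
                 call(3, 0, 100, "C", genotyped=True)]
        kept = pv.genotyped_filter(calls)
        assert [c.sample for c in kept] == ["A", "C"]
        assert pv.genotyped_filter([]) == []

    def test_frequency_arithmetic(self):
        site = pv.merge_callsets(
            [call(1, 0, 1000, "A", genotype=1), call(1, 0, 1000, "B",
                                                     genotype=1)]
        )[0]
        assert pv.deletion_frequency(site, 16) == pytest.approx(0.0625)
        single = pv.merge_callsets([call(1, 0, 1000, "A", genotype=1)])[0]
        assert pv.deletion_frequency(single, 16) == pytest.approx(1 / 32)

    def test_no_genotyped_carrier_rejected(self):
        site = pv.merge_callsets([call(1, 0, 1000, "A", genotyped=False)])[0]
        with pytest.raises(ContractError):
            pv.deletion_frequency(site, 16)


class TestBedRoundTrip:
    def test_callset_round_trip(self, tmp_path, rng):
        calls = sorted(random_calls(rng, n=30))
        path = tmp_path / "calls.bed"
        pv.deletions.write_bed_callset(path, calls)
        back = pv.deletions.read_bed_callset(path)
        assert back == calls
        assert [c.genotype for c in back] == [c.genotype for c in calls]
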