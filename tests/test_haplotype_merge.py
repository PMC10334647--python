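"""Merge stage: self-alignment, opposite assignment, mincing, consensus."""

import numpy as np
import pytest

from hicphase.assembly_model import AssemblyError, Contig, PipelineConfig
from hicphase.diploid_sim import fragment_to_style, make_diploid
from hicphase.haplotype_merge import (
    Alignment,
    assign_opposites,
    build_consensus,
    classify_nonbubble,
    merge_assembly,
    mince_and_tag,
    self_align,
)


def _random_contig(rng, name, n):
    return Contig(name, "".join(rng.choice(list("ACGT"), n)))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


class TestSelfAlign:
    """These run the external aligner on tiny inputs."""

    def test_identical_sequences_align_at_full_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        hits = self_align([Contig("a", seq), Contig("b", seq)])
        assert hits, "identical 10 kb sequences must align"
        assert max(h.identity for h in hits) >= 0.99
        assert all({h.qname, h.tname} == {"a", "b"} for h in hits)

    def test_unrelated_sequences_produce_no_retained_alignment(self):
        rng = np.random.default_rng(1)
        contigs = [_random_contig(rng, "a", 10_000), _random_contig(rng, "b", 10_000)]
        assert self_align(contigs) == []

    def test_low_identity_copy_filtered(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        contigs = [Contig("a", seq), Contig("b", _mutate(rng, seq, 0.25))]
        hits = self_align(contigs, identity_min=0.80)
        assert all(h.identity >= 0.80 for h in hits)
        # a 75%-identity copy must not survive the identity filter
        assert not [h for h in hits if h.identity < 0.80]

    def test_half_percent_divergence_survives(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        hits = self_align([Contig("a", seq), Contig("b", _mutate(rng, seq, 0.005))])
        assert hits and max(h.tend - h.tstart for h in hits) > 15_000


def _al(a, sa, ea, b, sb, eb, length=None, strand="+", identity=0.95):
    return Alignment(a, sa, ea, b, sb, eb, strand, identity, length or min(ea - sa, eb - sb))


class TestAssignOpposites:
    def test_longest_alignment_wins(self):
        contigs = [Contig(x, "A" * 10_000) for x in "ABC"]
        als = [_al("A", 0, 8000, "B", 0, 8000), _al("A", 0, 2000, "C", 0, 2000)]
        assignments, removed = assign_opposites(contigs, als)
        pairs = {(x.contig_id, x.opposite_id) for x in assignments}
        assert ("A", "B") in pairs or ("B", "A") in pairs
        # C's shorter claim overlaps B's committed interval on A -> repeat
        assert removed == {"C"}

    def test_overlapping_claim_removed_as_repeat(self):
        contigs = [Contig(x, "A" * 12_000) for x in "ABD"]
        als = [
            _al("A", 0, 8000, "B", 0, 8000),
            _al("D", 0, 2000, "B", 1000, 3000),  # overlaps A's claim on B
        ]
        assignments, removed = assign_opposites(contigs, als)
        assert removed == {"D"}
        assert all("D" not in (x.contig_id, x.opposite_id) for x in assignments)

    def test_disjoint_claim_pairs_with_unclaimed_region(self):
        contigs = [Contig(x, "A" * 12_000) for x in "ABD"]
        als = [
            _al("A", 0, 8000, "B", 0, 8000),
            _al("D", 0, 3000, "B", 9000, 12_000),
        ]
        assignments, removed = assign_opposites(contigs, als)
        assert not removed
        partners = {frozenset((x.contig_id, x.opposite_id)) for x in assignments}
        assert partners == {frozenset("AB"), frozenset("DB")}

    def test_exhaustive_four_contig_toy(self):
        # greedy by decreasing length: A-B (8k) commits, C-B overlapping claim
        # removed, D-B disjoint commits
        contigs = [Contig(x, "A" * 20_000) for x in "ABCD"]
        als = [
            _al("A", 0, 8000, "B", 0, 8000),
            _al("C", 0, 5000, "B", 4000, 9000),
            _al("D", 0, 3000, "B", 10_000, 13_000),
        ]
        assignments, removed = assign_opposites(contigs, als)
        assert removed == {"C"}
        partners = {frozenset((x.contig_id, x.opposite_id)) for x in assignments}
        assert partners == {frozenset("AB"), frozenset("DB")}


class TestMince:
    def test_partially_associated_contig_cut_into_three(self):
        rng = np.random.default_rng(4)
        u = _random_contig(rng, "U", 10_000)
        o = Contig("O", u.sequence[2000:7000])
        als = [_al("U", 2000, 7000, "O", 0, 5000)]
        assignments, removed = assign_opposites([u, o], als)
        pieces = {c.id: c for c in mince_and_tag([u, o], assignments, removed, 40.0)}
        assert set(pieces) == {"U:0-2000", "U:2000-7000", "U:7000-10000", "O"}
        assert pieces["U:2000-7000"].coverage == 40.0
        assert pieces["U:2000-7000"].partner == "O"
        assert pieces["U:0-2000"].coverage == 80.0
        assert pieces["U:7000-10000"].coverage == 80.0
        # associated piece carries the source slice verbatim
        assert pieces["U:2000-7000"].sequence == u.sequence[2000:7000]

    def test_fully_associated_and_unassociated(self):
        rng = np.random.default_rng(5)
        u = _random_contig(rng, "U", 5000)
        o = Contig("O", u.sequence)
        w = _random_contig(rng, "W", 4000)
        als = [_al("U", 0, 5000, "O", 0, 5000)]
        assignments, removed = assign_opposites([u, o, w], als)
        pieces = {c.id: c for c in mince_and_tag([u, o, w], assignments, removed, 40.0)}
        assert pieces["U"].coverage == 40.0 and pieces["U"].partner == "O"
        assert pieces["W"].coverage == 80.0 and pieces["W"].partner is None


class TestClassify:
    @pytest.mark.parametrize(
        "coverage,expected",
        [(40.0, "heterozygous_unpaired"), (80.0, "homozygous"), (70.0, "homozygous")],
    )
    def test_threshold_is_strict(self, coverage, expected):
        c = Contig("x", "ACGT", coverage=coverage, style_tag="non_bubble")
        assert classify_nonbubble(c, C_hetero=40.0, r_upper_threshold=1.75) == expected

    def test_invalid_c_hetero(self):
        with pytest.raises(AssemblyError):
            classify_nonbubble(Contig("x", "ACGT"), C_hetero=0.0)


class TestBuildConsensus:
    def _bubble(self, name, partner, primary, cov=40.0):
        return Contig(name, "ACGTACGT", cov,
                      "primary_bubble" if primary else "secondary_bubble", partner=partner)

    def test_t_array_patterns(self):
        contigs = [
            self._bubble("a", "b", True),
            self._bubble("b", "a", False),
            self._bubble("c", "d", True),
            self._bubble("d", "c", False),
            Contig("e", "ACGT", 80.0, "non_bubble"),
            Contig("f", "ACGT", 40.0, "non_bubble"),
        ]
        result = build_consensus(contigs, C_hetero=40.0)
        entries = {(m0, m1, cls) for _, m0, m1, cls in result.T}
        assert entries == {
            ("a", "b", "het_paired"),
            ("c", "d", "het_paired"),
            ("e", "e", "homo"),
            ("f", "-", "het_unpaired"),
        }
        # every input contig appears exactly once across T
        members = [m for _, m0, m1, _ in result.T for m in (m0, m1) if m != "-"]
        assert sorted(set(members)) == list("abcdef")

    def test_empty_input(self):
        assert build_consensus([], C_hetero=1.0).T == []

    def test_broken_pairing_is_integrity_error(self):
        contigs = [self._bubble("a", "b", True)]
        with pytest.raises(AssemblyError):
            build_consensus(contigs, C_hetero=40.0)

    def test_consensus_sequence_is_primary_member(self):
        contigs = [self._bubble("a", "b", True), self._bubble("b", "a", False)]
        result = build_consensus(contigs, C_hetero=40.0)
        cc = next(iter(result.consensus.values()))
        assert cc.primary.member_id == "a"
        assert cc.sequence == contigs[0].sequence


@pytest.fixture(scope="module")
def sim():
    truth = make_diploid(1, 300_000, 0.01, seed=9)
    return truth, fragment_to_style(truth, "haplotype_ignorant", seed=10)


class TestMergeOnSimulatedInput:

    def test_recovers_truth_pairs(self, sim):
        truth, asm = sim
        result = merge_assembly(asm.contigs, PipelineConfig.desk())
        frags = asm.fragments.set_index("contig")
        good = 0
        total = 0
        for cc in result.consensus.values():
            if cc.coverage_class != "het_paired":
                continue
            total += cc.length
            fa = frags.loc[cc.primary.src]
            fb = frags.loc[cc.secondary.src]
            same_locus = (
                fa.chrom == fb.chrom
                and {str(fa.hap), str(fb.hap)} == {"0", "1"}
                and min(fa.end0, fb.end0) - max(fa.start0, fb.start0) > 0
            )
            if same_locus:
                good += cc.length
        het_truth = frags[frags.hap == "0"].length.sum()
        assert total >= 0.9 * het_truth
        assert good >= 0.9 * total

    def test_base_conservation(self, sim):
        _, asm = sim
        result = merge_assembly(asm.contigs, PipelineConfig.desk())
        removed_len = sum(c.length for c in asm.contigs if c.id in result.removed)
        member_len = 0
        for cc in result.consensus.values():
            member_len += cc.primary.length
            if cc.secondary is not None:
                member_len += cc.secondary.length
        input_len = sum(c.length for c in asm.contigs)
        assert member_len == input_len - removed_len

    def test_idempotent_on_paired_input(self):
        truth = make_diploid(1, 200_000, 0.005, seed=11)
        asm = fragment_to_style(truth, "paired_haplotype", seed=12)
        result = merge_assembly(asm.contigs, PipelineConfig.desk())
        assert not result.removed
        members = {cc.primary.member_id for cc in result.consensus.values()}
        members |= {
            cc.secondary.member_id
            for cc in result.consensus.values()
            if cc.secondary is not None
        }
        # direct merge: every contig kept whole, no mincing
        assert members == {c.id for c in asm.contigs}
        for cc in result.consensus.values():
            assert cc.primary.start == 0
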