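"""Scaffolding: long-read chains, Hi-C end graph, splitting, conservation."""

import numpy as np
import pytest

from hicphase.assembly_model import Contig, PafRecord, PipelineConfig
from hicphase.diploid_sim import make_diploid, simulate_hic
from hicphase.haplotype_merge import build_consensus
from hicphase.read_links import select_long_read_alignments
from hicphase.scaffolder import (
    ScaffolderState,
    correct_misassemblies,
    detect_erroneous_edge_longread,
    end_edge_weights,
    hic_scaffold_round,
    link_counts_between,
    longread_scaffold,
)


def _homo_state(lengths, contacts=None, paf=None, cfg=None, seed=0):
    """State over homozygous single-member consensus contigs named like the
    input contigs (cc order follows input order)."""
    rng = np.random.default_rng(seed)
    contigs = [
        Contig(name, "".join(rng.choice(list("ACGT"), n)), 80.0, "non_bubble")
        for name, n in lengths.items()
    ]
    merge = build_consensus(contigs, C_hetero=40.0)
    cfg = cfg or PipelineConfig.desk()
    chosen = select_long_read_alignments(paf or [], cfg.min_longread_align)
    state = ScaffolderState(merge, cfg, contacts or [], chosen)
    return state


def _cc_of(state, contig):
    for cc in state.merge.consensus.values():
        if cc.primary.src == contig:
            return cc.id
    raise KeyError(contig)


def _scaffold_members(state):
    return {
        sid: [(state.merge.consensus[m.cc_id].primary.src, m.orientation)
              for m in s.members]
        for sid, s in state.scaffolds.items()
    }


def _spanning_paf(name, a, b, alen=60_000, blen=60_000, n=10, strand_a="+", strand_b="+"):
    """Reads covering the 3' end of a and the 5' end of b."""
    out = []
    for i in range(n):
        q = f"{name}{i}"
        out.append(PafRecord(q, 20_000, 0, 10_000, strand_a, a, alen,
                             alen - 10_000 if strand_a == "+" else 0,
                             alen if strand_a == "+" else 10_000, 9_500, 10_000))
        out.append(PafRecord(q, 20_000, 10_000, 20_000, strand_b, b, blen,
                             0 if strand_b == "+" else blen - 10_000,
                             10_000 if strand_b == "+" else blen, 9_500, 10_000))
    return out


class TestLongReadStage:
    def test_concordant_links_join_two_contigs(self):
        paf = _spanning_paf("r", "A", "B")
        state = _homo_state({"A": 60_000, "B": 60_000}, paf=paf)
        assert longread_scaffold(state) == 1
        (members,) = _scaffold_members(state).values()
        assert members in ([("A", "+"), ("B", "+")], [("B", "-"), ("A", "-")])

    def test_branching_end_stays_unjoined(self):
        paf = _spanning_paf("r", "A", "B") + _spanning_paf("s", "A", "C")
        state = _homo_state({"A": 60_000, "B": 60_000, "C": 60_000}, paf=paf)
        assert longread_scaffold(state) == 0
        assert len(state.scaffolds) == 3

    def test_linear_chain_of_five_matches_truth_order(self):
        names = ["C1", "C2", "C3", "C4", "C5"]
        paf = []
        for a, b in zip(names, names[1:]):
            paf += _spanning_paf(f"r{a}{b}", a, b)
        state = _homo_state({n: 60_000 for n in names}, paf=paf)
        longread_scaffold(state)
        (members,) = _scaffold_members(state).values()
        order = [m[0] for m in members]
        assert order == names or order == names[::-1]

    def test_reverse_strand_alignment_flips_orientation(self):
        paf = _spanning_paf("r", "A", "B", strand_b="-")
        state = _homo_state({"A": 60_000, "B": 60_000}, paf=paf)
        longread_scaffold(state)
        (members,) = _scaffold_members(state).values()
        assert members in ([("A", "+"), ("B", "-")], [("B", "+"), ("A", "-")])


class TestLinkVerdicts:
    def test_supported_edge_is_correct(self):
        paf = _spanning_paf("r", "A", "B", n=3)
        state = _homo_state({"A": 60_000, "B": 60_000}, paf=paf)
        sa, sb = sorted(state.scaffolds)
        verdict, _ = detect_erroneous_edge_longread(state, (sa, "R"), (sb, "L"))
        assert verdict == "correct"

    def test_opposite_end_support_replaces_edge(self):
        paf = _spanning_paf("r", "A", "B", n=3)
        state = _homo_state({"A": 60_000, "B": 60_000}, paf=paf)
        sa, sb = sorted(state.scaffolds)
        verdict, alt = detect_erroneous_edge_longread(state, (sa, "L"), (sb, "L"))
        assert verdict == "replaced_by"
        assert set(alt) == {(sa, "R"), (sb, "L")}

    def test_unsupported_edge_is_erroneous(self):
        state = _homo_state({"A": 60_000, "B": 60_000})
        sa, sb = sorted(state.scaffolds)
        verdict, extra = detect_erroneous_edge_longread(state, (sa, "R"), (sb, "L"))
        assert verdict == "erroneous" and extra == []


def _contacts_from_truth(con, split=250_000):
    """Map single-chromosome truth contacts onto two half contigs."""
    out = []
    for pa, pb in zip(con.pos_a, con.pos_b):
        sa, qa = ("H1", int(pa)) if pa < split else ("H2", int(pa) - split)
        sb, qb = ("H1", int(pb)) if pb < split else ("H2", int(pb) - split)
        out.append((sa, qa, sb, qb))
    return out


@pytest.fixture(scope="module")
def flat_truth():
    # zero heterozygosity: both haplotypes share coordinates exactly
    return make_diploid(1, 500_000, 0.0, sv_rate=0.0, seed=5)


class TestHiCStage:

    def test_edge_weight_threshold_is_strict(self):
        # 49 contacts between two ends at the 50-count threshold: filtered
        cfg = PipelineConfig.desk()
        cfg.hic_edge_min_weight_small_L = 50
        contacts = [("A", 59_000 + i, "B", 100 + i) for i in range(49)]
        state = _homo_state({"A": 60_000, "B": 60_000}, contacts=contacts, cfg=cfg)
        w = end_edge_weights(state, L=5_000)
        assert list(w.values()) == [49]
        assert hic_scaffold_round(state, L=5_000, check_long_reads=False) == 0
        # one more contact crosses the threshold
        contacts.append(("A", 59_500, "B", 50))
        state = _homo_state({"A": 60_000, "B": 60_000}, contacts=contacts, cfg=cfg)
        assert hic_scaffold_round(state, L=5_000, check_long_reads=False) == 1

    def test_true_adjacency_joins_in_correct_orientation(self, flat_truth):
        con = simulate_hic(flat_truth, coverage=30, inter_frac=0.0, seed=6)
        state = _homo_state({"H1": 250_000, "H2": 250_000},
                            contacts=_contacts_from_truth(con))
        joins = hic_scaffold_round(state, L=5_000, check_long_reads=False)
        assert joins == 1
        (members,) = _scaffold_members(state).values()
        assert members in ([("H1", "+"), ("H2", "+")], [("H2", "-"), ("H1", "-")])

    def test_misassembly_correction_splits_chimera(self, flat_truth):
        truth2 = make_diploid(2, 500_000, 0.0, sv_rate=0.0, seed=7)
        con = simulate_hic(truth2, coverage=30, seed=8)
        # one chimeric contig: chr1 and chr2 concatenated
        contacts = [
            ("X", int(pa + ca * 500_000), "X", int(pb + cb * 500_000))
            for ca, pa, cb, pb in zip(con.chrom_a, con.pos_a, con.chrom_b, con.pos_b)
        ]
        state = _homo_state({"X": 1_000_000}, contacts=contacts)
        assert correct_misassemblies(state) >= 1
        lengths = sorted(
            s.length({c: cc.length for c, cc in state.merge.consensus.items()})
            for s in state.scaffolds.values()
        )
        # breakpoint within one 5 kb bin of the true junction
        assert abs(lengths[0] - 500_000) <= 5_000

    def test_intact_chromosome_left_alone(self, flat_truth):
        con = simulate_hic(flat_truth, coverage=30, inter_frac=0.0, seed=9)
        contacts = [("X", int(a), "X", int(b)) for a, b in zip(con.pos_a, con.pos_b)]
        state = _homo_state({"X": 500_000}, contacts=contacts)
        assert correct_misassemblies(state) == 0
        assert len(state.scaffolds) == 1


class TestSurgery:
    def test_split_mid_member_conserves_bases(self):
        state = _homo_state({"A": 10_000})
        (sid,) = state.scaffolds
        res = state.split_at(sid, 4_000)
        assert res is not None
        lens = {c: cc.length for c, cc in state.merge.consensus.items()}
        pieces = sorted(s.length(lens) for s in state.scaffolds.values())
        assert pieces == [4_000, 6_000]
        # provenance offsets recorded on the new pieces
        ccs = sorted(state.merge.consensus.values(), key=lambda c: c.primary.start)
        assert (ccs[0].primary.start, ccs[0].primary.end) == (0, 4_000)
        assert (ccs[1].primary.start, ccs[1].primary.end) == (4_000, 10_000)

    def test_split_het_pair_divides_secondary_proportionally(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        u = Contig("u", seq, 40.0, "primary_bubble", partner="v")
        v = Contig("v", seq[:9_000], 40.0, "secondary_bubble", partner="u")
        merge = build_consensus([u, v], C_hetero=40.0)
        state = ScaffolderState(merge, PipelineConfig.desk())
        (sid,) = state.scaffolds
        state.split_at(sid, 5_000)
        secs = sorted(
            (cc.secondary.start, cc.secondary.end)
            for cc in state.merge.consensus.values()
        )
        assert secs[0][0] == 0 and secs[1][1] == 9_000
        assert secs[0][1] == secs[1][0]  # secondary tiles without overlap
        assert abs(secs[0][1] - 4_500) <= 1  # proportional cut

    def test_join_consumes_gap_parameter(self):
        state = _homo_state({"A": 10_000, "B": 10_000})
        sa, sb = sorted(state.scaffolds)
        nid = state.join((sa, "R"), (sb, "L"), gap=123)
        lens = {c: cc.length for c, cc in state.merge.consensus.items()}
        assert state.scaffolds[nid].length(lens) == 20_123


class TestEndToEndInvariants:
    def test_base_conservation(self, desk_paired):
        state = desk_paired.result.state
        lens = {c: cc.length for c, cc in state.merge.consensus.items()}
        non_gap = sum(sum(lens[m.cc_id] for m in s.members)
                      for s in state.scaffolds.values())
        assert non_gap == sum(lens.values())

    def test_link_table_symmetric_keys(self, desk_paired):
        state = desk_paired.result.state
        table = link_counts_between(state, state.cfg.end_search_window)
        for (na, nb) in table:
            assert na <= nb
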