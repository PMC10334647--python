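"""Divide consensus scaffolds into haplotype blocks and phase them.

Each scaffold member expands into its merge-stage entry: a merged pair
[u, v] becomes a haplotype block (haplotype0=u, haplotype1=v), an unpaired
heterozygous contig [u, -] a block whose second haplotype is an equal-length
N placeholder, and a homozygous contig [u, u] a homozygous block copied into
both output haplotypes. Long-read and Hi-C links between members of two
haplotype blocks count as *parallel* (same slot on both blocks) or *cross*
(opposite slots) evidence; blocks are then connected greedily in decreasing
|parallel - cross|, swapping one side's phases when the cross path wins, and
scaffolds are divided between blocks that never connect. An unphased block
strictly inside one connected stretch receives a seeded random phase and no
division. Consensus-kind links never reach the phaser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly_model import AssemblyError, Scaffold, reverse_complement
from .scaffolder import ScaffolderState

__all__ = [
    "HaplotypeBlock",
    "PhaseLinkCount",
    "PhasedPiece",
    "extract_blocks",
    "count_phase_links",
    "greedy_phase",
    "emit_phased_scaffolds",
    "phase_scaffold",
]


@dataclass
class HaplotypeBlock:
    index: int  # position along the scaffold (member order)
    cc_id: str
    haplotype0: str  # member id
    haplotype1: str | None  # None: [u,-] placeholder; == haplotype0: homozygous
    kind: str  # "haplotype" | "homozygous"
    phase_state: int | None = None  # None=unset, 0, 1 (1 = swapped)
    component: int | None = None
    random_phase: bool = False


@dataclass
class PhaseLinkCount:
    i: int
    j: int
    parallel: int = 0
    cross: int = 0

    @property
    def margin(self) -> int:
        return abs(self.parallel - self.cross)


@dataclass
class PhasedPiece:
    """One output piece of a scaffold after division at phase breaks."""

    scaffold_id: str
    piece_index: int
    member_range: tuple[int, int]  # member index range [lo, hi)
    blocks: list[HaplotypeBlock] = field(default_factory=list)


def extract_blocks(scaffold: Scaffold, state: ScaffolderState) -> list[HaplotypeBlock]:
    """Expand scaffold members into their haplotype blocks, in order."""
    blocks = []
    for i, m in enumerate(scaffold.members):
        cc = state.merge.consensus.get(m.cc_id)
        if cc is None:
            raise AssemblyError(f"scaffold member {m.cc_id!r} has no merge entry")
        if cc.coverage_class == "het_paired":
            blocks.append(
                HaplotypeBlock(i, cc.id, cc.primary.member_id, cc.secondary.member_id, "haplotype")
            )
        elif cc.coverage_class == "het_unpaired":
            blocks.append(HaplotypeBlock(i, cc.id, cc.primary.member_id, None, "haplotype"))
        else:
            blocks.append(
                HaplotypeBlock(i, cc.id, cc.primary.member_id, cc.primary.member_id, "homozygous")
            )
    return blocks


def count_phase_links(
    scaffold: Scaffold, blocks: list[HaplotypeBlock], state: ScaffolderState
) -> list[PhaseLinkCount]:
    """Parallel/cross link counts between haplotype blocks of one scaffold.

    Link endpoints are expressed against member contigs; the lift map gives
    (consensus contig, slot). Endpoints in slots (0,0) or (1,1) support the
    parallel path, (0,1)/(1,0) the cross path. Links touching homozygous
    blocks, intra-block links and consensus-kind records are ignored.
    """
    lf = state.lift
    block_of_cc = np.full(len(lf.cc_ids), -1, dtype=np.int64)
    het = np.zeros(len(lf.cc_ids), dtype=bool)
    for b in blocks:
        ci = lf.cc_index[b.cc_id]
        block_of_cc[ci] = b.index
        het[ci] = b.kind == "haplotype"
    counts: dict[tuple[int, int], PhaseLinkCount] = {}

    def add(ci1, sl1, ci2, sl2):
        if len(ci1) == 0:
            return
        b1, b2 = block_of_cc[ci1], block_of_cc[ci2]
        ok = (b1 >= 0) & (b2 >= 0) & (b1 != b2) & het[ci1] & het[ci2]
        b_lo = np.minimum(b1, b2)[ok]
        b_hi = np.maximum(b1, b2)[ok]
        par = (sl1 == sl2)[ok]
        for lo, hi, p in zip(b_lo, b_hi, par):
            c = counts.setdefault((int(lo), int(hi)), PhaseLinkCount(int(lo), int(hi)))
            if p:
                c.parallel += 1
            else:
                c.cross += 1

    ca, _, sla, cb, _, slb = state.cc_contacts()
    add(ca, sla, cb, slb)
    arrays, _ = state.cc_links()
    add(arrays["c1"], arrays["sl1"], arrays["c2"], arrays["sl2"])
    return sorted(counts.values(), key=lambda c: (c.i, c.j))


def greedy_phase(
    blocks: list[HaplotypeBlock], counts: list[PhaseLinkCount]
) -> list[HaplotypeBlock]:
    """Greedy phasing by decreasing |parallel - cross|.

    Union-find with parity: connecting blocks i and j when the cross path
    wins flips one component's phases before merging; pairs with
    parallel == cross never connect. Ties in the margin are broken toward
    the smaller (i, j) for determinism.
    """
    het = {b.index: b for b in blocks if b.kind == "haplotype"}
    parent = {i: i for i in het}
    parity = {i: 0 for i in het}

    def find(i):
        root, p = i, 0
        while parent[root] != root:
            p ^= parity[root]
            root = parent[root]
        node, acc = i, p
        while parent[node] != root:
            nxt, nxt_par = parent[node], parity[node]
            parent[node], parity[node] = root, acc
            acc ^= nxt_par
            node = nxt
        return root, p

    usable = sorted(
        (c for c in counts if c.margin > 0 and c.i in het and c.j in het),
        key=lambda c: (-c.margin, c.i, c.j),
    )
    for c in usable:
        ri, pi = find(c.i)
        rj, pj = find(c.j)
        if ri == rj:
            continue
        want = 0 if c.parallel > c.cross else 1
        parent[rj] = ri
        parity[rj] = pi ^ pj ^ want
    comp_ids: dict[int, int] = {}
    for b in blocks:
        if b.kind != "haplotype":
            continue
        r, p = find(b.index)
        comp_ids.setdefault(r, len(comp_ids))
        b.component = comp_ids[r]
        b.phase_state = p
    return blocks


def _assign_interior_unphased(blocks: list[HaplotypeBlock], rng: np.random.Generator) -> None:
    """Unphased singleton blocks strictly inside one component's span get a
    seeded random phase and are absorbed into that component (no division)."""
    het = [b for b in blocks if b.kind == "haplotype"]
    comp_sizes: dict[int, int] = {}
    for b in het:
        comp_sizes[b.component] = comp_sizes.get(b.component, 0) + 1
    for k, b in enumerate(het):
        if comp_sizes.get(b.component, 0) != 1:
            continue
        prev = next((x for x in reversed(het[:k]) if comp_sizes.get(x.component, 0) > 1), None)
        nxt = next((x for x in het[k + 1 :] if comp_sizes.get(x.component, 0) > 1), None)
        if prev is not None and nxt is not None and prev.component == nxt.component:
            b.component = prev.component
            b.phase_state = int(rng.integers(0, 2))
            b.random_phase = True


def phase_scaffold(scaffold: Scaffold, state: ScaffolderState, seed: int = 1):
    """Blocks + link counts + greedy phase for one scaffold."""
    blocks = extract_blocks(scaffold, state)
    counts = count_phase_links(scaffold, blocks, state)
    greedy_phase(blocks, counts)
    _assign_interior_unphased(blocks, np.random.default_rng(seed))
    return blocks, counts


def emit_phased_scaffolds(
    scaffold: Scaffold,
    blocks: list[HaplotypeBlock],
    state: ScaffolderState,
):
    """Emit the two haplotype sequences of a phased scaffold.

    The scaffold is divided between adjacent haplotype blocks belonging to
    different components; homozygous blocks attach to the preceding piece
    and are copied into both haplotype outputs. Returns
    (records, pieces, report_rows): records is (name, sequence) for both
    haplotypes of every piece, mirrored so that swapping all phase states
    exchanges the hap0 and hap1 outputs exactly.
    """
    members = scaffold.members
    by_index = {b.index: b for b in blocks}
    breaks = []
    prev_het = None
    for b in blocks:
        if b.kind != "haplotype":
            continue
        if prev_het is not None and b.component != prev_het.component:
            breaks.append(b.index)  # cut before this member
        prev_het = b
    ranges = []
    lo = 0
    for cut in breaks:
        ranges.append((lo, cut))
        lo = cut
    ranges.append((lo, len(members)))

    records = []
    pieces = []
    report = []
    for pi, (lo, hi) in enumerate(ranges):
        hap_seqs = {0: [], 1: []}
        piece_blocks = []
        for idx in range(lo, hi):
            m = members[idx]
            b = by_index[idx]
            cc = state.merge.consensus[b.cc_id]
            gap = "N" * m.gap_after if idx + 1 < hi else ""
            if b.kind == "homozygous":
                seq = cc.sequence if m.orientation == "+" else reverse_complement(cc.sequence)
                hap_seqs[0].append(seq + gap)
                hap_seqs[1].append(seq + gap)
            else:
                p = b.phase_state if b.phase_state is not None else 0
                seq0 = cc.sequence
                seq1 = cc.secondary_sequence
                if seq1 is not None and cc.secondary_strand == "-":
                    seq1 = reverse_complement(seq1)
                if seq1 is None:
                    seq1 = "N" * cc.length
                out0, out1 = (seq0, seq1) if p == 0 else (seq1, seq0)
                if m.orientation == "-":
                    out0 = reverse_complement(out0)
                    out1 = reverse_complement(out1)
                hap_seqs[0].append(out0 + gap)
                hap_seqs[1].append(out1 + gap)
            piece_blocks.append(b)
            report.append(
                (
                    scaffold.id,
                    pi,
                    b.cc_id,
                    b.haplotype0,
                    b.haplotype1 or "-",
                    b.kind,
                    "-" if b.phase_state is None else str(b.phase_state),
                    "-" if b.component is None else str(b.component),
                    "random" if b.random_phase else ("linked" if b.kind == "haplotype" else "homo"),
                )
            )
        name = f"{scaffold.id}_p{pi}" if len(ranges) > 1 else scaffold.id
        records.append((f"{name}_hap0", "".join(hap_seqs[0])))
        records.append((f"{name}_hap1", "".join(hap_seqs[1])))
        pieces.append(PhasedPiece(scaffold.id, pi, (lo, hi), piece_blocks))
    return records, pieces, report
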