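"""Turn read alignments into typed link evidence.

Three evidence channels feed the scaffolder and phaser:

* long-read links: per read, PAF alignments are greedily selected in
  decreasing sequence identity (#match-sites / alignment length), skipping
  read-interval overlaps; consecutive accepted alignments to different
  contigs become links with an estimated gap;
* short-read (PE/MP) links via k-mer exact unique matching, with the
  consensus-link extension: a k-mer hitting exactly the two members of one
  consensus contig still maps (to the primary member) and the record is
  tagged ``consensus`` — used by the scaffolder, excluded from phasing;
* Hi-C contacts: mapped pair records, insert length and orientation ignored.

Link endpoints carry a direction (``+1`` = the read continues past the
contig's high-coordinate side) instead of a hard 5'/3' label so that they
lift cleanly through mincing, consensus merging and scaffolding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .assembly_model import AssemblyError, PafRecord

__all__ = [
    "LinkEnd",
    "LinkRecord",
    "HiCContact",
    "select_long_read_alignments",
    "links_from_paf",
    "map_short_reads",
    "collect_hic_contacts",
]


@dataclass(frozen=True)
class LinkEnd:
    seq: str
    pos: int
    direction: int  # +1: read continues past the high-coordinate side; -1: low side

    @property
    def end(self) -> str:
        """Conventional 5'/3' label of the contig end this link supports."""
        return "3" if self.direction > 0 else "5"


@dataclass
class LinkRecord:
    kind: str  # long_read | paired_end | mate_pair | hic | consensus
    a: LinkEnd
    b: LinkEnd
    read_id: str
    gap: int = 0


@dataclass(frozen=True)
class HiCContact:
    seq_a: str
    pos_a: int
    seq_b: str
    pos_b: int


# ---------------------------------------------------------------------------
# Long reads


def select_long_read_alignments(
    paf: Sequence[PafRecord],
    min_align: int = 500,
) -> dict[str, list[PafRecord]]:
    """Greedy per-read alignment selection in decreasing identity order.

    Candidates shorter than ``min_align`` on the read are dropped; among the
    rest, alignments are accepted greedily by (identity, block length,
    target name) provided their read interval does not overlap an already
    accepted one. Returns the accepted alignments per read, sorted by read
    start.
    """
    by_read: dict[str, list[PafRecord]] = {}
    for r in paf:
        if r.qend - r.qstart >= min_align:
            by_read.setdefault(r.qname, []).append(r)
    chosen: dict[str, list[PafRecord]] = {}
    for qname, recs in by_read.items():
        recs.sort(key=lambda r: (-r.identity, -(r.qend - r.qstart), r.tname, r.tstart))
        accepted: list[PafRecord] = []
        for r in recs:
            if all(r.qend <= a.qstart or a.qend <= r.qstart for a in accepted):
                accepted.append(r)
        accepted.sort(key=lambda r: r.qstart)
        chosen[qname] = accepted
    return chosen


def links_from_paf(
    paf: Sequence[PafRecord],
    min_align: int = 500,
) -> tuple[list[LinkRecord], list[tuple[str, int, int]]]:
    """Long-read links between consecutive accepted alignments, plus the
    accepted alignment intervals (per target) for coverage tracks."""
    chosen = select_long_read_alignments(paf, min_align)
    links: list[LinkRecord] = []
    intervals: list[tuple[str, int, int]] = []
    for qname, accepted in chosen.items():
        for r in accepted:
            intervals.append((r.tname, r.tstart, r.tend))
        for r1, r2 in zip(accepted, accepted[1:]):
            if r1.tname == r2.tname:
                continue
            if r1.strand == "+":
                ea = LinkEnd(r1.tname, r1.tend - 1, +1)
            else:
                ea = LinkEnd(r1.tname, r1.tstart, -1)
            if r2.strand == "+":
                eb = LinkEnd(r2.tname, r2.tstart, -1)
            else:
                eb = LinkEnd(r2.tname, r2.tend - 1, +1)
            links.append(LinkRecord("long_read", ea, eb, qname, gap=r2.qstart - r1.qend))
    return links, intervals


# ---------------------------------------------------------------------------
# Short reads: k-mer exact unique matching


class _KmerIndex:
    """k-mer -> up to two (contig, pos) locations; more than two poisons the k-mer."""

    _POISON = object()

    def __init__(self, contigs: dict[str, str], k: int):
        self.k = k
        self.table: dict[str, object] = {}
        from .assembly_model import reverse_complement

        for cid, seq in contigs.items():
            for strand_seq, strand in ((seq, "+"), (reverse_complement(seq), "-")):
                for i in range(len(strand_seq) - k + 1):
                    kmer = strand_seq[i : i + k]
                    if "N" in kmer:
                        continue
                    pos = i if strand == "+" else len(seq) - i - k
                    cur = self.table.get(kmer)
                    hit = (cid, pos, strand)
                    if cur is None:
                        self.table[kmer] = hit
                    elif cur is self._POISON:
                        continue
                    elif isinstance(cur, tuple):
                        if cur[:2] != hit[:2]:
                            self.table[kmer] = [cur, hit]
                    else:  # list of two
                        if all(c[:2] != hit[:2] for c in cur):
                            self.table[kmer] = self._POISON

    def lookup(self, kmer: str):
        hit = self.table.get(kmer)
        if hit is None or hit is self._POISON:
            return None
        return hit


def _place_read(index: _KmerIndex, seq: str, member_of: dict[str, tuple[str, int]]):
    """Map one read: returns (contig, pos, consensus_flag) or None."""
    k = index.k
    for i in range(0, max(1, len(seq) - k + 1)):
        hit = index.lookup(seq[i : i + k])
        if hit is None:
            continue
        if isinstance(hit, tuple):
            cid, pos, _ = hit
            return cid, pos, False
        # exactly two locations: only usable if they are the two members of
        # one consensus contig; the read is assigned to the primary member
        (c1, p1, _), (c2, p2, _) = hit
        m1, m2 = member_of.get(c1), member_of.get(c2)
        if m1 is not None and m2 is not None and m1[0] == m2[0] and m1[1] != m2[1]:
            if m1[1] == 0:
                return c1, p1, True
            return c2, p2, True
        # two unrelated places: try the next k-mer
    return None


def map_short_reads(
    reads: Iterable[tuple[str, str, str]],
    contigs: dict[str, str],
    member_of: dict[str, tuple[str, int]],
    k: int = 32,
    kind: str = "paired_end",
) -> list[LinkRecord]:
    """Map read pairs by k-mer exact unique match.

    ``reads`` yields (read_id, seq1, seq2). A k-mer matching exactly the two
    members of one consensus contig maps to the primary member with the
    record tagged ``consensus``; k-mers matching two unrelated contigs or
    more than two places are discarded. Pairs with an unmapped mate are
    dropped.
    """
    index = _KmerIndex(contigs, k)
    out: list[LinkRecord] = []
    for rid, s1, s2 in reads:
        if len(s1) < k or len(s2) < k:
            continue
        h1 = _place_read(index, s1, member_of)
        h2 = _place_read(index, s2, member_of)
        if h1 is None or h2 is None:
            continue
        c1, p1, cons1 = h1
        c2, p2, cons2 = h2
        record_kind = "consensus" if (cons1 or cons2) else kind
        out.append(
            LinkRecord(
                record_kind,
                LinkEnd(c1, p1, +1),
                LinkEnd(c2, p2, -1),
                rid,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hi-C contacts


def collect_hic_contacts(
    pairs: Iterable[tuple[str, str, int, str, int]],
    known_sequences: dict[str, int] | None = None,
) -> list[HiCContact]:
    """Validate mapped pair records and return contacts (unordered pairs)."""
    out = []
    for rid, sa, pa, sb, pb in pairs:
        if known_sequences is not None:
            for s, p in ((sa, pa), (sb, pb)):
                if s not in known_sequences:
                    raise AssemblyError(f"contact {rid!r}: unknown sequence {s!r}")
                if not (0 <= p < known_sequences[s]):
                    raise AssemblyError(f"contact {rid!r}: position {p} outside {s!r}")
        out.append(HiCContact(sa, pa, sb, pb))
    return out
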