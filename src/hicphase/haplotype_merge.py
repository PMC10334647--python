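"""Convert any input style to paired-haplotype form and merge homologous
contig pairs into consensus contigs.

Pseudo-haplotype and haplotype-ignorant inputs are first converted: the
contig set is self-aligned (minimap2), each contig is assigned its *opposite*
(the contig with the longest retained alignment), associations are committed
greedily in decreasing alignment length with repeats removed on interval
overlap, and contigs are minced at association boundaries. Associated pieces
receive coverage C (default 40), unassociated pieces 2C. Bubble pairs are
then merged into consensus contigs; non-bubble contigs are classified as
heterozygous-unpaired or homozygous by coverage against
C_hetero * r_upper_threshold.

The merge result is the array T: one entry [u, v] per merged pair, [u, -]
per unpaired heterozygous contig, and [u, u] per homozygous contig.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly_model import (
    AssemblyError,
    Contig,
    PafRecord,
    PipelineConfig,
    read_paf,
    write_fasta,
)

__all__ = [
    "Alignment",
    "OppositeAssignment",
    "Piece",
    "ConsensusContig",
    "MergeResult",
    "self_align",
    "chain_alignments",
    "assign_opposites",
    "mince_and_tag",
    "classify_nonbubble",
    "build_consensus",
    "merge_assembly",
]


@dataclass
class Alignment:
    """A (possibly chained) local alignment between two contigs."""

    a: str
    a_start: int
    a_end: int
    b: str
    b_start: int
    b_end: int
    strand: str
    identity: float
    length: int  # total aligned length

    def on(self, contig: str) -> tuple[int, int]:
        if contig == self.a:
            return self.a_start, self.a_end
        if contig == self.b:
            return self.b_start, self.b_end
        raise KeyError(contig)

    def other(self, contig: str) -> str:
        return self.b if contig == self.a else self.a


@dataclass
class OppositeAssignment:
    contig_id: str
    opposite_id: str
    alignment: Alignment


@dataclass
class Piece:
    """A slice of a source contig, tracked for truth evaluation and lifting."""

    member_id: str
    src: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusContig:
    """A merged homologous pair ([u,v]), an unpaired heterozygous contig
    ([u,-]) or a homozygous contig ([u,u]); the consensus sequence is the
    primary member's sequence verbatim."""

    id: str
    primary: Piece
    secondary: Piece | None
    sequence: str
    secondary_sequence: str | None
    secondary_strand: str  # alignment orientation of secondary onto primary
    coverage_class: str  # het_paired | het_unpaired | homo

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def t_entry(self) -> tuple[str, str, str]:
        if self.coverage_class == "het_paired":
            return (self.primary.member_id, self.secondary.member_id, "het_paired")
        if self.coverage_class == "het_unpaired":
            return (self.primary.member_id, "-", "het_unpaired")
        return (self.primary.member_id, self.primary.member_id, "homo")


@dataclass
class MergeResult:
    consensus: dict[str, ConsensusContig]
    removed: set[str] = field(default_factory=set)

    @property
    def T(self) -> list[tuple[str, str, str, str]]:
        return [(cc.id,) + cc.t_entry for cc in self.consensus.values()]

    def member_map(self) -> dict[str, tuple[str, int]]:
        """member_id -> (consensus id, slot)."""
        out = {}
        for cc in self.consensus.values():
            out[cc.primary.member_id] = (cc.id, 0)
            if cc.secondary is not None:
                out[cc.secondary.member_id] = (cc.id, 1)
        return out

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#consensus_id\tmember0\tmember1\tclass\n")
            for row in self.T:
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Self-alignment


def self_align(
    contigs: list[Contig],
    identity_min: float = 0.80,
    min_align_len: int = 1000,
    paf: list[PafRecord] | None = None,
) -> list[PafRecord]:
    """All-vs-all local alignment of the contig set, self-hits excluded.

    Runs minimap2 (``-c -D --secondary=no``) unless a pre-computed PAF is
    supplied. Alignments below ``identity_min`` or shorter than
    ``min_align_len`` are filtered out.
    """
    if not contigs:
        raise AssemblyError("self_align requires at least one contig")
    if paf is None:
        if shutil.which("minimap2") is None:
            raise AssemblyError("minimap2 not found on PATH and no PAF supplied")
        with tempfile.TemporaryDirectory() as tmp:
            fa = str(Path(tmp) / "contigs.fa")
            out = str(Path(tmp) / "self.paf")
            write_fasta([(c.id, c.sequence) for c in contigs], fa)
            with open(out, "w") as fh:
                subprocess.run(
                    ["minimap2", "-c", "-D", "--secondary=no", fa, fa],
                    stdout=fh,
                    stderr=subprocess.DEVNULL,
                    check=True,
                )
            paf = read_paf(out)
    kept = [
        r
        for r in paf
        if r.qname != r.tname
        and r.identity >= identity_min
        and min(r.qend - r.qstart, r.tend - r.tstart) >= min_align_len
    ]
    return kept


def chain_alignments(paf: list[PafRecord], max_gap: int = 20_000) -> list[Alignment]:
    """Merge colinear same-strand alignments between each contig pair.

    minimap2 may split one homologous relationship into several chunks (e.g.
    around heterozygous inversions); for the purpose of opposite assignment
    the chunks are chained into one interval hull per (pair, strand).
    """
    groups: dict[tuple[str, str, str], list[PafRecord]] = {}
    for r in paf:
        key = (min(r.qname, r.tname), max(r.qname, r.tname), r.strand)
        groups.setdefault(key, []).append(r)
    chains: list[Alignment] = []
    for (a, b, strand), recs in groups.items():
        # orient records so that .q is contig a
        ivals = []
        for r in recs:
            if r.qname == a:
                ivals.append((r.qstart, r.qend, r.tstart, r.tend, r.nmatch, r.blocklen))
            else:
                ivals.append((r.tstart, r.tend, r.qstart, r.qend, r.nmatch, r.blocklen))
        ivals.sort()
        cur = list(ivals[0])
        merged = []
        for iv in ivals[1:]:
            if iv[0] <= cur[1] + max_gap:
                cur[1] = max(cur[1], iv[1])
                cur[2] = min(cur[2], iv[2])
                cur[3] = max(cur[3], iv[3])
                cur[4] += iv[4]
                cur[5] += iv[5]
            else:
                merged.append(cur)
                cur = list(iv)
        merged.append(cur)
        for qs, qe, ts, te, nm, bl in merged:
            chains.append(
                Alignment(a, qs, qe, b, ts, te, strand, nm / bl if bl else 0.0, min(qe - qs, te - ts))
            )
    return chains


# ---------------------------------------------------------------------------
# Opposite assignment with greedy repeat removal


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def assign_opposites(
    contigs: list[Contig], alignments: list[Alignment]
) -> tuple[list[OppositeAssignment], set[str]]:
    """Greedy association of each contig with its opposite.

    Each contig's opposite is the partner of its longest retained alignment
    chain. Candidates are committed in decreasing length; if a contig's
    claim on its opposite overlaps an already-committed claim by another
    contig, the claimant is removed as a repeat. Disjoint claims on an
    already-associated opposite are allowed (they pair with the opposite's
    unclaimed region and are separated by mincing).
    """
    best: dict[str, Alignment] = {}
    for al in alignments:
        for cid in (al.a, al.b):
            if cid not in best or al.length > best[cid].length:
                best[cid] = al
    order = sorted(best.items(), key=lambda kv: (-kv[1].length, kv[0]))
    claims: dict[str, list[tuple[int, int, str]]] = {}  # contig -> [(s, e, partner)]
    assignments: list[OppositeAssignment] = []
    removed: set[str] = set()
    committed_pairs: set[tuple[str, str, int, int]] = set()

    for cid, al in order:
        if cid in removed:
            continue
        opp = al.other(cid)
        if opp in removed:
            continue
        s_self, e_self = al.on(cid)
        s_opp, e_opp = al.on(opp)
        key = (min(cid, opp), max(cid, opp), min(s_self, s_opp), min(e_self, e_opp))
        if key in committed_pairs:
            continue  # same pair committed from the other side
        conflict = False
        for (s, e, partner) in claims.get(opp, []):
            if partner != cid and _overlaps((s_opp, e_opp), (s, e)):
                conflict = True
                break
        if not conflict:
            for (s, e, partner) in claims.get(cid, []):
                if partner != opp and _overlaps((s_self, e_self), (s, e)):
                    conflict = True
                    break
        if conflict:
            removed.add(cid)
            claims.pop(cid, None)
            assignments = [x for x in assignments if cid not in (x.contig_id, x.opposite_id)]
            continue
        claims.setdefault(cid, []).append((s_self, e_self, opp))
        claims.setdefault(opp, []).append((s_opp, e_opp, cid))
        committed_pairs.add(key)
        assignments.append(OppositeAssignment(cid, opp, al))
    return assignments, removed


# ---------------------------------------------------------------------------
# Mincing


def mince_and_tag(
    contigs: list[Contig],
    assignments: list[OppositeAssignment],
    removed: set[str],
    C_consensus: float = 40.0,
    min_piece_len: int = 200,
) -> list[Contig]:
    """Cut contigs at association boundaries and tag pieces as bubbles.

    Every resulting piece is either fully associated with one opposite piece
    (coverage C, a bubble pair) or unassociated (coverage 2C, non-bubble).
    Pieces shorter than ``min_piece_len`` are absorbed into their neighbour.
    Piece ids encode provenance as ``<src>:<start>-<end>``.
    """
    by_id = {c.id: c for c in contigs}
    cuts: dict[str, set[int]] = {c.id: {0, c.length} for c in contigs if c.id not in removed}
    for asg in assignments:
        al = asg.alignment
        for cid in (al.a, al.b):
            if cid in removed:
                continue
            s, e = al.on(cid)
            cuts[cid].update((s, e))

    # snap out slivers: drop cut points closer than min_piece_len to a neighbour
    boundaries: dict[str, list[int]] = {}
    for cid, cs in cuts.items():
        pts = sorted(cs)
        keep = [pts[0]]
        for p in pts[1:-1]:
            if p - keep[-1] >= min_piece_len and pts[-1] - p >= min_piece_len:
                keep.append(p)
        keep.append(pts[-1])
        boundaries[cid] = keep

    def piece_at(cid: str, pos: int) -> tuple[int, int]:
        b = boundaries[cid]
        i = int(np.searchsorted(b, pos, side="right")) - 1
        i = min(max(i, 0), len(b) - 2)
        return b[i], b[i + 1]

    def piece_id(cid: str, s: int, e: int) -> str:
        if s == 0 and e == by_id[cid].length:
            return cid
        return f"{cid}:{s}-{e}"

    paired: dict[str, tuple[str, str]] = {}  # piece -> (partner piece, strand)
    for asg in assignments:
        al = asg.alignment
        if al.a in removed or al.b in removed:
            continue
        sa, ea = piece_at(al.a, (al.a_start + al.a_end) // 2)
        sb, eb = piece_at(al.b, (al.b_start + al.b_end) // 2)
        pa = piece_id(al.a, sa, ea)
        pb = piece_id(al.b, sb, eb)
        paired[pa] = (pb, al.strand)
        paired[pb] = (pa, al.strand)

    out: list[Contig] = []
    for cid, b in boundaries.items():
        src = by_id[cid]
        for s, e in zip(b[:-1], b[1:]):
            pid = piece_id(cid, s, e)
            if pid in paired:
                partner, _ = paired[pid]
                out.append(
                    Contig(pid, src.sequence[s:e], C_consensus, "primary_bubble", partner=partner)
                )
            else:
                out.append(Contig(pid, src.sequence[s:e], 2 * C_consensus, "non_bubble"))
    # fix primary/secondary tags: longer piece of each pair is primary
    by_pid = {c.id: c for c in out}
    for c in out:
        if c.partner is None:
            continue
        p = by_pid[c.partner]
        if (c.length, p.id) > (p.length, c.id):
            c.style_tag, p.style_tag = "primary_bubble", "secondary_bubble"
    # attach strand info for downstream consensus build
    for c in out:
        if c.partner is not None:
            c._pair_strand = paired[c.id][1]  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Classification and consensus construction


def classify_nonbubble(contig: Contig, C_hetero: float, r_upper_threshold: float = 1.75) -> str:
    """Heterozygous iff coverage < C_hetero * r_upper_threshold (strict)."""
    if C_hetero <= 0:
        raise AssemblyError("C_hetero must be positive")
    if contig.coverage < C_hetero * r_upper_threshold:
        return "heterozygous_unpaired"
    return "homozygous"


def estimate_c_hetero(contigs: list[Contig]) -> float:
    """Mean coverage of contigs committed as bubble pairs; falls back to half
    the main coverage-histogram peak when no bubbles exist."""
    bubble = [c.coverage for c in contigs if c.style_tag in ("primary_bubble", "secondary_bubble")]
    if bubble:
        return float(np.mean(bubble))
    covs = np.array([c.coverage for c in contigs if c.coverage > 0])
    if len(covs) == 0:
        raise AssemblyError("cannot estimate heterozygous coverage: no coverage information")
    hist, edges = np.histogram(covs, bins=max(10, int(covs.max() / 5) or 10))
    peak = edges[int(np.argmax(hist))] + (edges[1] - edges[0]) / 2
    return float(peak / 2)


def _provenance_piece(cid: str, length: int) -> Piece:
    if ":" in cid and "-" in cid.rsplit(":", 1)[-1]:
        src, rng = cid.rsplit(":", 1)
        s, e = rng.split("-")
        return Piece(cid, src, int(s), int(e))
    return Piece(cid, cid, 0, length)


def build_consensus(
    paired_contigs: list[Contig],
    r_upper_threshold: float = 1.75,
    C_hetero: float | None = None,
) -> MergeResult:
    """Merge paired-haplotype-style contigs into consensus contigs (array T)."""
    if C_hetero is None and any(c.partner is None for c in paired_contigs):
        if any(c.partner is not None for c in paired_contigs):
            C_hetero = estimate_c_hetero(paired_contigs)
        else:
            C_hetero = estimate_c_hetero(paired_contigs) if paired_contigs else 1.0
    by_id = {c.id: c for c in paired_contigs}
    consensus: dict[str, ConsensusContig] = {}
    done: set[str] = set()
    n = 0
    for c in paired_contigs:
        if c.id in done:
            continue
        n += 1
        cc_id = f"cc{n}"
        if c.partner is not None:
            p = by_id.get(c.partner)
            if p is None or p.partner != c.id:
                raise AssemblyError(f"contig {c.id!r}: broken bubble pairing")
            if p.id in done:
                raise AssemblyError(f"partner {p.id!r} referenced twice")
            prim, sec = (c, p) if c.style_tag == "primary_bubble" else (p, c)
            strand = getattr(c, "_pair_strand", "+")
            sec_seq = sec.sequence
            consensus[cc_id] = ConsensusContig(
                cc_id,
                _provenance_piece(prim.id, prim.length),
                _provenance_piece(sec.id, sec.length),
                prim.sequence,
                sec_seq,
                strand,
                "het_paired",
            )
            done.update((c.id, p.id))
        else:
            cls = classify_nonbubble(c, C_hetero, r_upper_threshold)
            consensus[cc_id] = ConsensusContig(
                cc_id,
                _provenance_piece(c.id, c.length),
                None,
                c.sequence,
                None,
                "+",
                "het_unpaired" if cls == "heterozygous_unpaired" else "homo",
            )
            done.add(c.id)
    return MergeResult(consensus)


def merge_assembly(contigs: list[Contig], config: PipelineConfig | None = None,
                   paf: list[PafRecord] | None = None) -> MergeResult:
    """Full merge stage: dispatches on input style.

    Contigs carrying mutual ``partner`` references (paired-haplotype style)
    are merged directly; any other input is converted via self-alignment,
    opposite assignment and mincing first.
    """
    config = config or PipelineConfig()
    has_pairs = any(c.partner is not None for c in contigs)
    styles = {c.style_tag for c in contigs}
    if has_pairs or styles <= {"primary_bubble", "secondary_bubble", "non_bubble"}:
        result = build_consensus(contigs, config.r_upper_threshold)
    else:
        paf_kept = self_align(contigs, config.identity_min, config.min_align_len, paf=paf)
        chains = chain_alignments(paf_kept)
        assignments, removed = assign_opposites(contigs, chains)
        pieces = mince_and_tag(contigs, assignments, removed, config.C_consensus, config.min_piece_len)
        result = build_consensus(pieces, config.r_upper_threshold, C_hetero=config.C_consensus)
        result.removed = removed
    return result
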