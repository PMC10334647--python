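"""Two-stage consensus scaffolding.

Stage one builds a scaffold graph from long-read (and PE) links between
consensus contigs, joins non-branching chains (each sequence end with exactly
one incident edge), and vets every tentative junction with the Hi-C
erroneous-edge test. Stage two iterates Hi-C end-graph scaffolding: nodes are
scaffold ends, edge weights count Hi-C pairs with both ends within L of the
respective scaffold ends; the maximum-weight edge is repeatedly tested (Hi-C
separation scores, plus long-read link confirmation) and either joined or
discarded, while L grows along a schedule; before each round, misassemblies
are detected on the contact map and scaffolds are split at the
minimum-coverage point inside each flagged bin. A final pass repeats the
schedule without the long-read check to jump long repeats.

All read evidence stays expressed in *source contig* coordinates and is
lifted on demand through two maps: source -> consensus contig (updated when
a consensus contig is split) and consensus contig -> scaffold (updated on
every join/split). This keeps joins and splits cheap and exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly_model import AssemblyError, PipelineConfig, Scaffold, ScaffoldMember
from .haplotype_merge import ConsensusContig, MergeResult, Piece
from . import hic_matrix as hm

__all__ = [
    "ScaffolderState",
    "SourceLift",
    "longread_scaffold",
    "detect_erroneous_edge_longread",
    "hic_scaffold_round",
    "hic_scaffold_iterate",
    "correct_misassemblies",
    "end_edge_weights",
    "link_counts_between",
    "junction_scores",
]

_KEY = 1 << 42  # combined (source code, position) sort key stride
_FLIP = {"L": "R", "R": "L"}


# ---------------------------------------------------------------------------
# Lifting machinery


class SourceLift:
    """Piecewise-affine map from source-contig positions to consensus contigs."""

    def __init__(self, merge: MergeResult, src_code: dict[str, int]):
        self.cc_ids = sorted(merge.consensus)
        self.cc_index = {c: i for i, c in enumerate(self.cc_ids)}
        self.cc_len = np.array([merge.consensus[c].length for c in self.cc_ids], dtype=np.int64)
        segs = []
        for cid in self.cc_ids:
            cc = merge.consensus[cid]
            ci = self.cc_index[cid]
            p = cc.primary
            segs.append((src_code[p.src], p.start, p.end, ci, 0, 1.0, 0.0))
            if cc.secondary is not None:
                s = cc.secondary
                plen = max(1, s.length)
                scale = cc.length / plen
                if cc.secondary_strand == "+":
                    segs.append((src_code[s.src], s.start, s.end, ci, 1, scale, 0.0))
                else:
                    segs.append((src_code[s.src], s.start, s.end, ci, 1, -scale, scale * (plen - 1)))
        segs.sort()
        self.seg_src = np.array([x[0] for x in segs], dtype=np.int64)
        self.seg_s = np.array([x[1] for x in segs], dtype=np.int64)
        self.seg_e = np.array([x[2] for x in segs], dtype=np.int64)
        self.seg_cc = np.array([x[3] for x in segs], dtype=np.int64)
        self.seg_slot = np.array([x[4] for x in segs], dtype=np.int8)
        self.seg_slope = np.array([x[5] for x in segs], dtype=np.float64)
        self.seg_const = np.array([x[6] for x in segs], dtype=np.float64)
        self.seg_key = self.seg_src * _KEY + self.seg_s

    def lift(self, src_codes: np.ndarray, pos: np.ndarray):
        """Vectorized: returns (cc_idx, cc_pos, slot, sign, valid)."""
        key = src_codes * _KEY + pos
        i = np.searchsorted(self.seg_key, key, side="right") - 1
        i0 = np.clip(i, 0, max(0, len(self.seg_key) - 1))
        valid = (i >= 0) & (self.seg_src[i0] == src_codes) & (pos < self.seg_e[i0])
        rel = pos - self.seg_s[i0]
        ccp = self.seg_const[i0] + self.seg_slope[i0] * rel
        cc = self.seg_cc[i0]
        ccp = np.clip(np.rint(ccp).astype(np.int64), 0, self.cc_len[cc] - 1)
        return cc, ccp, self.seg_slot[i0], np.sign(self.seg_slope[i0]).astype(np.int8), valid

    def boundaries(self, src_code: int) -> np.ndarray:
        m = self.seg_src == src_code
        return np.unique(np.concatenate([self.seg_s[m], self.seg_e[m]]))


@dataclass
class Layout:
    """Consensus-contig placement inside the current scaffold set."""

    scaf_ids: list[str]
    scaf_len: np.ndarray
    scaf_of_cc: np.ndarray  # aligned with SourceLift.cc_ids
    off_cc: np.ndarray
    orient_cc: np.ndarray  # +1 / -1
    cc_len: np.ndarray

    def cc_to_scaf(self, cc_idx, cc_pos):
        s = self.scaf_of_cc[cc_idx]
        pos = np.where(
            self.orient_cc[cc_idx] > 0,
            self.off_cc[cc_idx] + cc_pos,
            self.off_cc[cc_idx] + (self.cc_len[cc_idx] - 1 - cc_pos),
        )
        return s, pos

    def index(self, sid: str) -> int:
        return self.scaf_ids.index(sid)


class ScaffolderState:
    """Mutable scaffolding state: consensus contigs, read evidence, scaffolds."""

    def __init__(
        self,
        merge: MergeResult,
        config: PipelineConfig,
        contacts: list[tuple[str, int, str, int]] | None = None,
        long_alignments: dict[str, list] | None = None,
        libraries=None,
    ):
        self.merge = merge
        self.cfg = config
        self.libraries = libraries or []
        srcs = set()
        for cc in merge.consensus.values():
            srcs.add(cc.primary.src)
            if cc.secondary is not None:
                srcs.add(cc.secondary.src)
        if contacts:
            srcs.update(c[0] for c in contacts)
            srcs.update(c[2] for c in contacts)
        if long_alignments:
            for recs in long_alignments.values():
                srcs.update(r.tname for r in recs)
        self.src_code = {s: i for i, s in enumerate(sorted(srcs))}
        if contacts:
            self._ct_src_a = np.array([self.src_code[c[0]] for c in contacts], dtype=np.int64)
            self._ct_pos_a = np.array([c[1] for c in contacts], dtype=np.int64)
            self._ct_src_b = np.array([self.src_code[c[2]] for c in contacts], dtype=np.int64)
            self._ct_pos_b = np.array([c[3] for c in contacts], dtype=np.int64)
        else:
            self._ct_src_a = self._ct_pos_a = self._ct_src_b = self._ct_pos_b = np.empty(0, dtype=np.int64)
        # per read: [(src_code, tstart, tend, strand, qstart, qend)] in read order
        self.read_aligns: list[list[tuple[int, int, int, str, int, int]]] = []
        if long_alignments:
            for qname in sorted(long_alignments):
                recs = sorted(long_alignments[qname], key=lambda r: r.qstart)
                self.read_aligns.append(
                    [(self.src_code[r.tname], r.tstart, r.tend, r.strand, r.qstart, r.qend)
                     for r in recs]
                )
        self.scaffolds: dict[str, Scaffold] = {}
        self._next = 0
        for cid in sorted(merge.consensus):
            nid = self._new_id()
            self.scaffolds[nid] = Scaffold(nid, [ScaffoldMember(cid, "+", 0)])
        self._lift: SourceLift | None = None
        self._layout: Layout | None = None
        self._cc_contacts = None
        self._cc_links = None

    # -- caches ------------------------------------------------------------

    def _new_id(self) -> str:
        self._next += 1
        return f"s{self._next}"

    def invalidate(self, lift: bool = False) -> None:
        self._layout = None
        if lift:
            self._lift = None
            self._cc_contacts = None
            self._cc_links = None

    @property
    def lift(self) -> SourceLift:
        if self._lift is None:
            self._lift = SourceLift(self.merge, self.src_code)
        return self._lift

    @property
    def layout(self) -> Layout:
        if self._layout is None:
            lift = self.lift
            n_cc = len(lift.cc_ids)
            scaf_of = np.full(n_cc, -1, dtype=np.int64)
            off = np.zeros(n_cc, dtype=np.int64)
            orient = np.ones(n_cc, dtype=np.int8)
            ids = sorted(self.scaffolds)
            slen = np.zeros(len(ids), dtype=np.int64)
            lengths = {c: int(lift.cc_len[i]) for i, c in enumerate(lift.cc_ids)}
            for si, sid in enumerate(ids):
                s = self.scaffolds[sid]
                offs = s.member_offsets(lengths)
                slen[si] = s.length(lengths)
                for m, o in zip(s.members, offs):
                    ci = lift.cc_index[m.cc_id]
                    scaf_of[ci] = si
                    off[ci] = o
                    orient[ci] = 1 if m.orientation == "+" else -1
            self._layout = Layout(ids, slen, scaf_of, off, orient, lift.cc_len)
        return self._layout

    def cc_contacts(self):
        """Contacts lifted to consensus coordinates (cached per merge version)."""
        if self._cc_contacts is None:
            lf = self.lift
            ca, pa, sla, _, va = lf.lift(self._ct_src_a, self._ct_pos_a)
            cb, pb, slb, _, vb = lf.lift(self._ct_src_b, self._ct_pos_b)
            ok = va & vb
            self._cc_contacts = (ca[ok], pa[ok], sla[ok], cb[ok], pb[ok], slb[ok])
        return self._cc_contacts

    def scaffold_contacts(self):
        """Contacts in scaffold coordinates: (scaf_a, pos_a, scaf_b, pos_b)."""
        ca, pa, _, cb, pb, _ = self.cc_contacts()
        lay = self.layout
        sa, qa = lay.cc_to_scaf(ca, pa)
        sb, qb = lay.cc_to_scaf(cb, pb)
        return sa, qa, sb, qb

    def cc_links(self):
        """Long-read links and coverage intervals at consensus coordinates.

        Accepted alignments are split at source-segment boundaries (mincing
        cuts, consensus splits) so links appear between every pair of
        consecutive consensus contigs a read crosses. Returns
        (arrays dict, cov dict) where the arrays are c1, p1, d1, c2, p2, d2,
        gap and cov maps cc_idx -> list of (lo, hi) covered intervals.
        """
        if self._cc_links is None:
            lf = self.lift
            codes = {a[0] for read in self.read_aligns for a in read}
            bounds = {code: lf.boundaries(code) for code in codes}
            raw = []
            cov: dict[int, list[tuple[int, int]]] = {}
            for read in self.read_aligns:
                pieces = []  # (cc_idx, lo, hi, cc_strand, slot)
                for code, ts, te, strand, qs, qe in read:
                    bs = bounds.get(code)
                    if bs is None or len(bs) == 0:
                        continue
                    inner = bs[(bs > ts) & (bs < te)]
                    cuts = [ts] + [int(x) for x in inner] + [te]
                    subs = list(zip(cuts[:-1], cuts[1:]))
                    if strand == "-":
                        subs = subs[::-1]
                    for s_, e_ in subs:
                        cc, pp, slot, sg, vv = lf.lift(
                            np.array([code, code], dtype=np.int64),
                            np.array([s_, e_ - 1], dtype=np.int64),
                        )
                        if not (vv[0] and vv[1]) or cc[0] != cc[1]:
                            continue
                        lo, hi = sorted((int(pp[0]), int(pp[1])))
                        cc_strand = int(sg[0]) if strand == "+" else -int(sg[0])
                        pieces.append((int(cc[0]), lo, hi, cc_strand, int(slot[0])))
                        cov.setdefault(int(cc[0]), []).append((lo, hi + 1))
                for (c1, lo1, hi1, st1, sl1), (c2, lo2, hi2, st2, sl2) in zip(pieces, pieces[1:]):
                    if c1 == c2:
                        continue
                    pa, da = (hi1, 1) if st1 > 0 else (lo1, -1)
                    pb, db = (lo2, -1) if st2 > 0 else (hi2, 1)
                    raw.append((c1, pa, da, sl1, c2, pb, db, sl2, 0))
            cols = ("c1", "p1", "d1", "sl1", "c2", "p2", "d2", "sl2", "gap")
            if raw:
                arr = np.array(raw, dtype=np.int64)
                arrays = {k: arr[:, i] for i, k in enumerate(cols)}
            else:
                arrays = {k: np.empty(0, dtype=np.int64) for k in cols}
            self._cc_links = (arrays, cov)
        return self._cc_links

    def scaffold_links(self):
        """Links lifted to scaffold ends: (s1, q1, e1, s2, q2, e2, gap) arrays
        where e is 0 for the L end, 1 for the R end (by pointing direction)."""
        arrays, _ = self.cc_links()
        lay = self.layout
        s1, q1 = lay.cc_to_scaf(arrays["c1"], arrays["p1"])
        s2, q2 = lay.cc_to_scaf(arrays["c2"], arrays["p2"])
        e1 = (arrays["d1"] * lay.orient_cc[arrays["c1"]]) > 0
        e2 = (arrays["d2"] * lay.orient_cc[arrays["c2"]]) > 0
        return s1, q1, e1.astype(np.int8), s2, q2, e2.astype(np.int8), arrays["gap"]

    def scaffold_cov(self, sid: str, res: int | None = None) -> np.ndarray:
        """Approximate long-read alignment depth along a scaffold."""
        res = res or self.cfg.coverage_resolution
        lay = self.layout
        si = lay.index(sid)
        n = int(lay.scaf_len[si]) // res + 1
        diff = np.zeros(n + 1)
        _, cc_cov = self.cc_links()
        for ci, ivals in cc_cov.items():
            if lay.scaf_of_cc[ci] != si:
                continue
            iv = np.array(ivals, dtype=np.int64)
            _, a = lay.cc_to_scaf(np.full(len(iv), ci), iv[:, 0])
            _, b = lay.cc_to_scaf(np.full(len(iv), ci), iv[:, 1] - 1)
            lo = np.minimum(a, b) // res
            hi = np.minimum(np.maximum(a, b) // res + 1, n)
            np.add.at(diff, lo, 1.0)
            np.add.at(diff, hi, -1.0)
        return np.cumsum(diff)[:n]

    # -- scaffold surgery --------------------------------------------------

    def join(self, end_a: tuple[str, str], end_b: tuple[str, str], gap: int | None = None) -> str:
        """Join scaffold end_a=(sid, 'L'|'R') to end_b; returns the new id."""
        (sa, ea), (sb, eb) = end_a, end_b
        if sa == sb:
            raise AssemblyError("cannot join a scaffold to itself")
        gap = self.cfg.hic_join_gap if gap is None else gap
        ma = _oriented(self.scaffolds[sa].members, flip=(ea == "L"))
        mb = _oriented(self.scaffolds[sb].members, flip=(eb == "R"))
        ma[-1].gap_after = max(1, gap)
        nid = self._new_id()
        self.scaffolds[nid] = Scaffold(nid, ma + mb)
        del self.scaffolds[sa]
        del self.scaffolds[sb]
        self.invalidate()
        return nid

    def split_at(self, sid: str, pos: int) -> tuple[str, str] | None:
        """Split a scaffold at coordinate ``pos`` (left piece = [0, pos)),
        cutting the containing consensus contig mid-sequence when needed."""
        s = self.scaffolds[sid]
        lengths = {m.cc_id: self.merge.consensus[m.cc_id].length for m in s.members}
        offs = s.member_offsets(lengths)
        total = s.length(lengths)
        if pos <= 0 or pos >= total:
            return None
        cut_index = None
        for i, (m, o) in enumerate(zip(s.members, offs)):
            ln = lengths[m.cc_id]
            if o <= pos < o + ln:
                local = pos - o
                if local == 0:
                    cut_index = i
                else:
                    q = local if m.orientation == "+" else ln - local
                    if not (0 < q < ln):
                        cut_index = i + (0 if q <= 0 else 1)
                    else:
                        left_cc, right_cc = self._split_consensus(m.cc_id, q)
                        if m.orientation == "+":
                            new = [ScaffoldMember(left_cc, "+", 0),
                                   ScaffoldMember(right_cc, "+", m.gap_after)]
                        else:
                            new = [ScaffoldMember(right_cc, "-", 0),
                                   ScaffoldMember(left_cc, "-", m.gap_after)]
                        s.members[i : i + 1] = new
                        cut_index = i + 1
                break
            if pos < o + ln + (m.gap_after if i + 1 < len(s.members) else 0):
                cut_index = i + 1  # inside the gap
                break
        if cut_index is None or cut_index <= 0 or cut_index >= len(s.members):
            self.invalidate(lift=True)  # a consensus split may have happened
            return None
        left = s.members[:cut_index]
        right = s.members[cut_index:]
        left[-1] = ScaffoldMember(left[-1].cc_id, left[-1].orientation, 0)
        id1, id2 = self._new_id(), self._new_id()
        self.scaffolds[id1] = Scaffold(id1, left)
        self.scaffolds[id2] = Scaffold(id2, right)
        del self.scaffolds[sid]
        self.invalidate(lift=True)
        return id1, id2

    def _split_consensus(self, cc_id: str, q: int) -> tuple[str, str]:
        cc = self.merge.consensus.pop(cc_id)
        p = cc.primary

        def mk(src, s_, e_):
            return Piece(f"{src}:{s_}-{e_}", src, s_, e_)

        pl = mk(p.src, p.start, p.start + q)
        pr = mk(p.src, p.start + q, p.end)
        seq_l, seq_r = cc.sequence[:q], cc.sequence[q:]
        sl = sr = None
        sseq_l = sseq_r = None
        if cc.secondary is not None:
            sp = cc.secondary
            plen = sp.length
            t = int(np.clip(round(q * plen / cc.length), 1, plen - 1))
            if cc.secondary_strand == "+":
                sl, sr = mk(sp.src, sp.start, sp.start + t), mk(sp.src, sp.start + t, sp.end)
                sseq_l, sseq_r = cc.secondary_sequence[:t], cc.secondary_sequence[t:]
            else:
                sl, sr = mk(sp.src, sp.end - t, sp.end), mk(sp.src, sp.start, sp.end - t)
                sseq_l = cc.secondary_sequence[plen - t :]
                sseq_r = cc.secondary_sequence[: plen - t]
        lid, rid = f"{cc.id}.L", f"{cc.id}.R"
        self.merge.consensus[lid] = ConsensusContig(
            lid, pl, sl, seq_l, sseq_l, cc.secondary_strand, cc.coverage_class
        )
        self.merge.consensus[rid] = ConsensusContig(
            rid, pr, sr, seq_r, sseq_r, cc.secondary_strand, cc.coverage_class
        )
        return lid, rid


def _oriented(members: list[ScaffoldMember], flip: bool) -> list[ScaffoldMember]:
    """Copy of a member list, reverse-complemented as a whole when ``flip``."""
    if not flip:
        return [ScaffoldMember(m.cc_id, m.orientation, m.gap_after) for m in members]
    out = []
    for i in range(len(members) - 1, -1, -1):
        m = members[i]
        out.append(
            ScaffoldMember(
                m.cc_id,
                "-" if m.orientation == "+" else "+",
                members[i - 1].gap_after if i > 0 else 0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Edge weights and junction tests


def _end_assign(pos, slen, L):
    """Nearer scaffold end (0=L, 1=R) if within L of it; -1 otherwise."""
    d5 = pos
    d3 = slen - 1 - pos
    side = np.where(d5 <= d3, 0, 1)
    near = np.minimum(d5, d3) < L
    return np.where(near, side, -1)


def end_edge_weights(state: ScaffolderState, L: int) -> dict:
    """Hi-C end-graph edge weights at window L, keyed by the canonical
    ((sid, 'L'|'R'), (sid, 'L'|'R')) node pair."""
    sa, qa, sb, qb = state.scaffold_contacts()
    lay = state.layout
    if len(sa) == 0:
        return {}
    ea = _end_assign(qa, lay.scaf_len[sa], L)
    eb = _end_assign(qb, lay.scaf_len[sb], L)
    ok = (ea >= 0) & (eb >= 0) & (sa != sb)
    if not np.any(ok):
        return {}
    stride = 2 * len(lay.scaf_ids)
    ka = sa[ok] * 2 + ea[ok]
    kb = sb[ok] * 2 + eb[ok]
    lo = np.minimum(ka, kb)
    hi = np.maximum(ka, kb)
    keys, counts = np.unique(lo * stride + hi, return_counts=True)
    out = {}
    for key, cnt in zip(keys, counts):
        lo_k, hi_k = int(key // stride), int(key % stride)
        na = (lay.scaf_ids[lo_k // 2], "L" if lo_k % 2 == 0 else "R")
        nb = (lay.scaf_ids[hi_k // 2], "L" if hi_k % 2 == 0 else "R")
        out[(na, nb)] = int(cnt)
    return out


def junction_scores(state: ScaffolderState, end_a, end_b):
    """Separation scores at the tentative junction joining end_a to end_b,
    or None when either side is shorter than one bin (untestable)."""
    (sa, ea), (sb, eb) = end_a, end_b
    lay = state.layout
    ia, ib = lay.index(sa), lay.index(sb)
    la, lb = int(lay.scaf_len[ia]), int(lay.scaf_len[ib])
    bs = state.cfg.bin_size
    na, nb = la // bs, lb // bs
    if na < 1 or nb < 1:
        return None
    csa, qa, csb, qb = state.scaffold_contacts()
    keep = ((csa == ia) | (csa == ib)) & ((csb == ia) | (csb == ib))
    if not np.any(keep):
        return None
    xa, pa_, xb, pb_ = csa[keep], qa[keep], csb[keep], qb[keep]

    def to_joint(scaf, pos):
        pos_a = pos if ea == "R" else la - 1 - pos
        pos_b = (pos if eb == "L" else lb - 1 - pos) + na * bs
        return np.where(scaf == ia, pos_a, pos_b)

    bin_a = to_joint(xa, pa_) // bs
    bin_b = to_joint(xb, pb_) // bs
    ok = np.where(xa == ia, bin_a < na, bin_a < na + nb) & np.where(
        xb == ia, bin_b < na, bin_b < na + nb
    )
    M = np.zeros((na + nb, na + nb))
    np.add.at(M, (bin_a[ok], bin_b[ok]), 1.0)
    np.add.at(M, (bin_b[ok], bin_a[ok]), 1.0)
    np.fill_diagonal(M, np.diagonal(M) / 2)
    mat = hm.HiCMatrix((sa, sb), bs, M, junction_bin=na)
    return hm.separation_scores(mat, state.cfg.k_max)


def edge_is_hic_erroneous(state: ScaffolderState, end_a, end_b) -> bool:
    sc = junction_scores(state, end_a, end_b)
    if sc is None:
        return False  # untestable; weight/link criteria decide
    return hm.is_erroneous_edge_hic(sc, state.cfg.s_threshold, state.cfg.r_threshold)


def link_counts_between(state: ScaffolderState, window: int) -> dict:
    """Aggregated long-read link support between scaffold ends.

    Returns {((sid, end), (sid, end)): (count, median_gap)} for links whose
    endpoints lie within ``window`` of the ends they point out of.
    """
    s1, q1, e1, s2, q2, e2, gap = state.scaffold_links()
    lay = state.layout
    if len(s1) == 0:
        return {}
    d1 = np.where(e1 == 1, lay.scaf_len[s1] - 1 - q1, q1)
    d2 = np.where(e2 == 1, lay.scaf_len[s2] - 1 - q2, q2)
    ok = (s1 != s2) & (d1 <= window) & (d2 <= window)
    if not np.any(ok):
        return {}
    stride = 2 * len(lay.scaf_ids)
    ka = s1[ok] * 2 + e1[ok]
    kb = s2[ok] * 2 + e2[ok]
    lo = np.minimum(ka, kb)
    hi = np.maximum(ka, kb)
    enc = lo * stride + hi
    out: dict = {}
    order = np.argsort(enc, kind="stable")
    enc_s, gap_s = enc[order], gap[ok][order]
    uniq, starts = np.unique(enc_s, return_index=True)
    starts = list(starts) + [len(enc_s)]
    for u, st, en in zip(uniq, starts[:-1], starts[1:]):
        lo_k, hi_k = int(u // stride), int(u % stride)
        na = (lay.scaf_ids[lo_k // 2], "L" if lo_k % 2 == 0 else "R")
        nb = (lay.scaf_ids[hi_k // 2], "L" if hi_k % 2 == 0 else "R")
        out[(na, nb)] = (en - st, int(max(1, np.median(gap_s[st:en]))))
    return out


# ---------------------------------------------------------------------------
# Long-read scaffolding (stage one)


def longread_scaffold(state: ScaffolderState) -> int:
    """Join non-branching chains of the long-read scaffold graph.

    An edge is used only when it is the sole incident edge above minLink at
    both of its sequence ends (the in/out-degree-one rule) and it survives
    the Hi-C erroneous-edge test at the tentative junction. Cycles resolve
    naturally: the weakest edge of a cycle is processed last and skipped.
    Returns the number of joins made.
    """
    cfg = state.cfg
    table = link_counts_between(state, cfg.end_search_window)
    table = {k: v for k, v in table.items() if v[0] > cfg.min_link}
    incident: dict = {}
    for (na, nb) in table:
        incident.setdefault(na, []).append((na, nb))
        incident.setdefault(nb, []).append((na, nb))
    joinable = [
        e
        for e in sorted(table, key=lambda e: (-table[e][0], e))
        if len(incident[e[0]]) == 1 and len(incident[e[1]]) == 1 and e[0][0] != e[1][0]
    ]
    end_map: dict = {}  # surviving outward end -> its current (sid, side)

    def resolve(node):
        while node in end_map:
            node = end_map[node]
        return node

    joins = 0
    consumed: set = set()
    for (na, nb) in joinable:
        ra, rb = resolve(na), resolve(nb)
        if ra in consumed or rb in consumed or ra[0] == rb[0]:
            continue
        if ra[0] not in state.scaffolds or rb[0] not in state.scaffolds:
            continue
        if edge_is_hic_erroneous(state, ra, rb):
            continue
        gap = table[(na, nb)][1]
        (sa, ea), (sb, eb) = ra, rb
        nid = state.join(ra, rb, gap)
        end_map[(sa, _FLIP[ea])] = (nid, "L")
        end_map[(sb, _FLIP[eb])] = (nid, "R")
        consumed.update((ra, rb))
        joins += 1
    return joins


# ---------------------------------------------------------------------------
# Long-read edge verdicts (stage two helper)


def detect_erroneous_edge_longread(
    state: ScaffolderState, end_a, end_b, link_table: dict | None = None
):
    """Check a Hi-C edge with long-read link information.

    Returns ("correct", None), ("replaced_by", (end_a', end_b')) when an
    alternative end pairing has the link support, or ("erroneous",
    breakpoints) where breakpoints is a possibly-empty list of
    (scaffold_id, position) misassembly corrections found in the end
    windows (split there and retry when non-empty).
    """
    cfg = state.cfg
    if link_table is None:
        link_table = link_counts_between(state, cfg.end_search_window)

    def count(na, nb):
        return link_table.get(tuple(sorted((na, nb))), (0, 0))[0]

    (sa, ea), (sb, eb) = end_a, end_b
    if count(end_a, end_b) > cfg.min_link:
        return ("correct", None)
    best = None
    for alt in (
        ((sa, ea), (sb, _FLIP[eb])),
        ((sa, _FLIP[ea]), (sb, eb)),
        ((sa, _FLIP[ea]), (sb, _FLIP[eb])),
    ):
        c = count(*alt)
        if c > cfg.min_link and (best is None or c > best[0]):
            best = (c, alt)
    if best is not None:
        return ("replaced_by", best[1])
    return ("erroneous", _end_misassembly_breakpoints(state, end_a, end_b))


def _end_misassembly_breakpoints(state: ScaffolderState, end_a, end_b):
    """Misassembly candidates in the two end windows: a link endpoint whose
    mate maps to a third scaffold marks a candidate region between that
    endpoint and the scaffold end; the region is cut at minimum coverage.

    For paired libraries the candidate region extent is the insert-length
    tolerance a + 3d; long-read regions run from the alignment endpoint to
    the scaffold end (the projected other-scaffold alignment position lies
    beyond the end)."""
    cfg = state.cfg
    lay = state.layout
    s1, q1, e1, s2, q2, e2, gap = state.scaffold_links()
    pair_scafs = {end_a[0], end_b[0]}
    out = []
    tol = max((int(lib.insert_tolerance) for lib in state.libraries
               if lib.kind in ("paired_end", "mate_pair")), default=None)
    for sid, side in (end_a, end_b):
        si = lay.index(sid)
        slen = int(lay.scaf_len[si])
        regions = []
        for (ss, qq, dd, so) in (
            (s1, q1, e1, s2),
            (s2, q2, e2, s1),
        ):
            m = ss == si
            if not np.any(m):
                continue
            others = so[m]
            for q, other in zip(qq[m], others):
                if lay.scaf_ids[int(other)] in pair_scafs:
                    continue
                q = int(q)
                dist = q if side == "L" else slen - 1 - q
                if dist > cfg.end_search_window:
                    continue
                if tol is not None:
                    lo, hi = (max(0, q - tol), q) if side == "L" else (q, min(slen, q + tol))
                else:
                    lo, hi = (0, q) if side == "L" else (q, slen)
                if hi > lo:
                    regions.append((lo, hi))
        if regions:
            lo = min(r[0] for r in regions)
            hi = max(r[1] for r in regions)
            cov = state.scaffold_cov(sid)
            res = cfg.coverage_resolution
            seg = cov[lo // res : max(lo // res + 1, hi // res)]
            if len(seg):
                mins = np.flatnonzero(seg == seg.min())
                mid = int(mins[len(mins) // 2])  # plateau midpoint
                out.append((sid, (lo // res + mid) * res + res // 2))
    return out


# ---------------------------------------------------------------------------
# Hi-C rounds (stage two)


def hic_scaffold_round(state: ScaffolderState, L: int, check_long_reads: bool = True) -> int:
    """One fixed-L round: repeatedly take the maximum-weight end edge, test
    it, and join or discard until the graph is stable. Returns #joins."""
    cfg = state.cfg
    threshold = (
        cfg.hic_edge_min_weight_small_L
        if L < cfg.hic_large_L_cutoff
        else cfg.hic_edge_min_weight_large_L
    )
    blacklist: set = set()
    joins = 0
    while True:
        weights = {
            k: w
            for k, w in end_edge_weights(state, L).items()
            if w >= threshold and k not in blacklist
        }
        if not weights:
            break
        edge = min(weights, key=lambda k: (-weights[k], k))
        na, nb = edge
        if edge_is_hic_erroneous(state, na, nb):
            blacklist.add(edge)
            continue
        if check_long_reads:
            verdict, extra = detect_erroneous_edge_longread(state, na, nb)
            if verdict == "replaced_by":
                alt = tuple(sorted(extra))
                if alt in blacklist or edge_is_hic_erroneous(state, *extra):
                    blacklist.add(edge)
                    continue
                na, nb = extra
            elif verdict == "erroneous":
                did = False
                for sid, pos in extra:
                    if sid in state.scaffolds and state.split_at(sid, pos):
                        did = True
                if did:
                    blacklist = set()
                    continue  # re-evaluate with corrected scaffolds
                blacklist.add(edge)
                continue
        state.join(na, nb)
        joins += 1
        alive = state.scaffolds
        blacklist = {e for e in blacklist if e[0][0] in alive and e[1][0] in alive}
    return joins


def correct_misassemblies(state: ScaffolderState) -> int:
    """Detect misassemblies on every scaffold's contact map and split at the
    minimum-coverage point inside each flagged bin. Returns #splits."""
    cfg = state.cfg
    lay = state.layout
    bs = cfg.bin_size
    sa, qa, sb, qb = state.scaffold_contacts()
    matrices = {}
    for si, sid in enumerate(lay.scaf_ids):
        n = int(lay.scaf_len[si]) // bs
        if n < cfg.k_max + 1:
            continue
        m_mask = (sa == si) & (sb == si)
        M = np.zeros((n, n))
        ba = qa[m_mask] // bs
        bb = qb[m_mask] // bs
        ok = (ba < n) & (bb < n)
        np.add.at(M, (ba[ok], bb[ok]), 1.0)
        np.add.at(M, (bb[ok], ba[ok]), 1.0)
        np.fill_diagonal(M, np.diagonal(M) / 2)
        matrices[sid] = hm.HiCMatrix((sid,), bs, M)
    if not matrices:
        return 0
    qualifying = [
        m for sid, m in matrices.items()
        if int(lay.scaf_len[lay.index(sid)]) >= cfg.min_matrix_scaffold
    ]
    mu_all = hm.global_distance_profile(qualifying or list(matrices.values()), cfg.k_max)
    if not np.any(mu_all[1:] > 0):
        return 0
    splits = 0
    for sid in sorted(matrices):
        mat = matrices[sid]
        prof = hm.misassembly_score_profile(
            mat, mu_all, cfg.k_max, cfg.motif_halfwidth, cfg.zero_mean_floor
        )
        _, candidates = hm.select_threshold_P(
            prof, mat, cfg.k_max, cfg.s_threshold, cfg.r_threshold, cfg.peak_window
        )
        if not candidates:
            continue
        cur = sid
        for b in sorted(candidates, reverse=True):
            lo, hi = b * bs, (b + 1) * bs
            cov = state.scaffold_cov(cur)
            res = cfg.coverage_resolution
            seg = cov[lo // res : hi // res]
            if len(seg):
                mins = np.flatnonzero(seg == seg.min())
                pos = (lo // res + int(mins[len(mins) // 2])) * res + res // 2
            else:
                pos = (lo + hi) // 2
            result = state.split_at(cur, pos)
            if result:
                cur = result[0]  # lower-coordinate piece keeps earlier bins
                splits += 1
    return splits


def hic_scaffold_iterate(state: ScaffolderState) -> None:
    """Full Hi-C stage: per L in the schedule, misassembly correction then an
    end-graph round; the schedule is then repeated once more without the
    long-read check to jump repeats long reads cannot span."""
    for check_lr in (True, False):
        for L in state.cfg.L_schedule:
            correct_misassemblies(state)
            hic_scaffold_round(state, L, check_long_reads=check_lr)
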