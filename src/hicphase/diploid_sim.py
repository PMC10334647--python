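"""Diploid genome and read-evidence simulator with full truth tracking.

The simulator produces everything the pipeline consumes, so the whole tool can
be exercised without external data: a two-haplotype genome with configurable
per-base heterozygosity (SNVs and small indels, plus optional inversions),
Hi-C read pairs with a power-law intra-chromosomal distance decay and a
uniform inter-chromosomal background, long reads emitted together with their
truth alignments as PAF, short paired-end reads as mapped pair records, and
fragmentation of the truth genome into the three supported contig-input
styles with truth coordinates retained throughout.

Haplotype 1 is derived from haplotype 0; the liftover between the two
coordinate systems is the cumulative indel shift map (inversions preserve
length, so positions inside an inversion are mapped affinely).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly_model import (
    Contig,
    PafRecord,
    ReadLibrary,
    reverse_complement,
)

__all__ = [
    "DiploidTruth",
    "SimAssembly",
    "make_diploid",
    "simulate_hic",
    "simulate_long_reads",
    "simulate_paired_end",
    "fragment_to_style",
    "map_ends_to_contigs",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# small-variant mix: 10:1 SNV:indel (the 90%/9% split renormalised)
_P_SNV = 10 / 11


@dataclass
class LiftMap:
    """Monotone piecewise shift between hap0 and hap1 coordinates."""

    b0: np.ndarray  # hap0 breakpoints (starts with 0)
    b1: np.ndarray  # matching hap1 positions

    def to1(self, pos):
        pos = np.asarray(pos)
        i = np.searchsorted(self.b0, pos, side="right") - 1
        return pos + (self.b1[i] - self.b0[i])

    def to0(self, pos):
        pos = np.asarray(pos)
        i = np.searchsorted(self.b1, pos, side="right") - 1
        return pos + (self.b0[i] - self.b1[i])


@dataclass
class TruthChromosome:
    name: str
    hap0: str
    hap1: str
    lift: LiftMap
    # small-variant marker positions in each haplotype's coordinates
    var_pos0: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    var_pos1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass
class DiploidTruth:
    chromosomes: list[TruthChromosome]
    variants: pd.DataFrame  # chrom, pos0, pos1, type, length

    def chrom(self, name: str) -> TruthChromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def hap_length(self, ci: int, hap: int) -> int:
        c = self.chromosomes[ci]
        return len(c.hap0) if hap == 0 else len(c.hap1)

    @property
    def total_hap0(self) -> int:
        return sum(len(c.hap0) for c in self.chromosomes)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


_COMP = np.array([3, 2, 1, 0], dtype=np.int8)


def make_diploid(
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    heterozygosity: float = 0.005,
    sv_rate: float = 1e-6,
    seed: int = 1,
) -> DiploidTruth:
    """Build a diploid truth genome.

    ``heterozygosity`` is the per-base small-variant rate (SNVs and 1-10 bp
    indels at a 10:1 ratio); ``sv_rate`` is the per-base rate of heterozygous
    inversions (1-10 kb). The realized small-variant count is binomial, so it
    stays within a few percent of the requested rate for megabase genomes.
    """
    if not (0 <= heterozygosity <= 0.05):
        raise ValueError("heterozygosity must be in [0, 0.05]")
    if chrom_length < 50_000:
        raise ValueError("chromosome length must be >= 50 kb")
    rng = np.random.default_rng(seed)
    chroms: list[TruthChromosome] = []
    var_rows = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        hap0 = _random_seq(rng, chrom_length)
        n_small = rng.binomial(chrom_length, heterozygosity)
        pos = np.sort(rng.choice(chrom_length, size=n_small, replace=False))
        is_snv = rng.random(n_small) < _P_SNV
        n_inv = rng.poisson(chrom_length * sv_rate)
        inv_start = np.sort(rng.integers(0, max(1, chrom_length - 10_000), n_inv))
        inv_len = rng.integers(1_000, 10_001, n_inv)

        events = []  # (pos0, kind, payload)
        for p, s in zip(pos, is_snv):
            if s:
                events.append((int(p), "snv", 1))
            else:
                ell = int(rng.integers(1, 11))
                kind = "ins" if rng.random() < 0.5 else "del"
                events.append((int(p), kind, ell))
        for s, ell in zip(inv_start, inv_len):
            events.append((int(s), "inv", int(ell)))
        events.sort(key=lambda e: e[0])

        out = []
        b0, b1 = [0], [0]
        cursor = 0  # hap0 position
        offset = 0  # hap1 - hap0
        vpos0, vpos1 = [], []
        for p, kind, ell in events:
            if p < cursor:
                continue  # overlapping event dropped
            out.append(hap0[cursor:p])
            if kind == "snv":
                ref = hap0[p]
                alt = (ref + int(rng.integers(1, 4))) % 4
                out.append(np.array([alt], dtype=np.int8))
                vpos0.append(p)
                vpos1.append(p + offset)
                cursor = p + 1
                var_rows.append((name, p, p + offset, "snv", 1))
            elif kind == "ins":
                out.append(_random_seq(rng, ell))
                vpos0.append(p)
                vpos1.append(p + offset)
                var_rows.append((name, p, p + offset, "ins", ell))
                offset += ell
                b0.append(p)
                b1.append(p + offset)
                cursor = p
            elif kind == "del":
                if p + ell > chrom_length:
                    continue
                vpos0.append(p)
                vpos1.append(p + offset)
                var_rows.append((name, p, p + offset, "del", ell))
                offset -= ell
                b0.append(p + ell)
                b1.append(p + ell + offset)
                cursor = p + ell
            else:  # inversion
                if p + ell > chrom_length:
                    continue
                out.append(_COMP[hap0[p : p + ell]][::-1])
                var_rows.append((name, p, p + offset, "inv", ell))
                cursor = p + ell
        out.append(hap0[cursor:])
        hap1 = np.concatenate(out) if out else hap0.copy()
        lift = LiftMap(np.array(b0, dtype=np.int64), np.array(b1, dtype=np.int64))
        chroms.append(
            TruthChromosome(
                name,
                _decode(hap0),
                _decode(hap1),
                lift,
                np.array(vpos0, dtype=np.int64),
                np.array(vpos1, dtype=np.int64),
            )
        )
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos0", "pos1", "type", "length"])
    return DiploidTruth(chroms, variants)


# ---------------------------------------------------------------------------
# Hi-C pair simulation


@dataclass
class TruthContacts:
    """Hi-C pair ends in truth coordinates: chromosome index, haplotype, position."""

    chrom_a: np.ndarray
    hap_a: np.ndarray
    pos_a: np.ndarray
    chrom_b: np.ndarray
    hap_b: np.ndarray
    pos_b: np.ndarray

    def __len__(self) -> int:
        return len(self.pos_a)


def _powerlaw_sample(rng, n, alpha, dmin, dmax):
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        return np.exp(np.log(dmin) + u * (np.log(dmax) - np.log(dmin)))
    a1 = 1.0 - alpha
    return (dmin**a1 + u * (dmax**a1 - dmin**a1)) ** (1.0 / a1)


def simulate_hic(
    truth: DiploidTruth,
    coverage: float = 30.0,
    decay_exponent: float = 1.0,
    inter_frac: float = 0.05,
    trans_hap_frac: float = 0.5,
    seed: int = 1,
    read_len: int = 150,
    min_sep: int = 1_000,
) -> TruthContacts:
    """Simulate Hi-C pairs with power-law intra-chromosomal distance decay.

    Intra-chromosomal separations follow P(d) ~ d^-decay_exponent on
    [min_sep, chromosome length]; a fraction ``inter_frac`` of pairs is a
    uniform inter-chromosomal background. With probability ``trans_hap_frac``
    the haplotype of the second end is re-drawn uniformly, degrading the
    haplotype-specific contact signal the phaser relies on (at 1.0 parallel
    and cross link counts become statistically indistinguishable).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    lens = np.array([len(c.hap0) for c in truth.chromosomes], dtype=np.int64)
    n_pairs = int(coverage * lens.sum() / (2 * read_len))
    p_chrom = lens / lens.sum()
    ca = rng.choice(len(lens), size=n_pairs, p=p_chrom)
    ha = rng.integers(0, 2, n_pairs)
    pa = (rng.random(n_pairs) * lens[ca]).astype(np.int64)
    inter = rng.random(n_pairs) < inter_frac

    # intra: power-law separation
    d = _powerlaw_sample(rng, n_pairs, decay_exponent, min_sep, lens[ca].astype(float))
    sign = rng.choice([-1, 1], n_pairs)
    pb = np.clip(pa + (sign * d).astype(np.int64), 0, lens[ca] - 1)
    cb = ca.copy()
    hb = ha.copy()

    # inter background: uniform on another chromosome, haplotypes independent
    if inter.any() and len(lens) > 1:
        k = int(inter.sum())
        shift = rng.integers(1, len(lens), k)
        cb[inter] = (ca[inter] + shift) % len(lens)
        pb[inter] = (rng.random(k) * lens[cb[inter]]).astype(np.int64)
        hb[inter] = rng.integers(0, 2, k)

    # haplotype-nonspecific fraction
    trans = rng.random(n_pairs) < trans_hap_frac
    hb[trans] = rng.integers(0, 2, int(trans.sum()))

    # positions were drawn in hap0 coordinates; lift hap-1 ends
    for ci, c in enumerate(truth.chromosomes):
        m = (ca == ci) & (ha == 1)
        if m.any():
            pa[m] = np.clip(c.lift.to1(pa[m]), 0, len(c.hap1) - 1)
        m = (cb == ci) & (hb == 1)
        if m.any():
            pb[m] = np.clip(c.lift.to1(pb[m]), 0, len(c.hap1) - 1)
    return TruthContacts(ca, ha, pa, cb, hb, pb)


# ---------------------------------------------------------------------------
# Fragmentation into the three contig-input styles


@dataclass
class SimAssembly:
    """Simulated input assembly with truth coordinates retained."""

    style: str
    contigs: list[Contig]
    # columns: contig, hap ('0'/'1'/'both'), chrom, start0, end0, start1, end1,
    # orient, length  (start1/end1 are the fragment's interval in hap1 coords)
    fragments: pd.DataFrame
    sidecar: dict[str, tuple[str, float]] = field(default_factory=dict)

    def fragment_row(self, contig: str) -> pd.Series:
        return self.fragments.set_index("contig").loc[contig]


def fragment_to_style(
    truth: DiploidTruth,
    style: str,
    mean_fragment: int = 50_000,
    collapse_threshold: float = 0.001,
    seed: int = 1,
) -> SimAssembly:
    """Cut the truth genome into contigs packaged in one of the input styles.

    Haplotype-0 cut points are random with mean spacing ``mean_fragment``;
    haplotype-1 cut points are their liftover images, so homologous pieces
    correspond end to end (as assembler bubble arms do). Fragments whose
    small-variant density is below ``collapse_threshold`` (per bp) are
    emitted once as a collapsed, homozygous-like contig. In pseudo-haplotype
    style each alternative partner is additionally split in two, mimicking
    the shorter alternative contigs of pseudo-haplotype assemblers.
    """
    if style not in ("paired_haplotype", "pseudo_haplotype", "haplotype_ignorant"):
        raise ValueError(f"unknown style {style!r}")
    if mean_fragment < 20_000:
        raise ValueError("mean_fragment too small")
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    frag_rows = []
    sidecar: dict[str, tuple[str, float]] = {}
    k = 0

    def _cov(base: float) -> float:
        return float(base * rng.normal(1.0, 0.03))

    for ci, chrom in enumerate(truth.chromosomes):
        L = len(chrom.hap0)
        cuts = [0]
        while cuts[-1] < L:
            step = int(rng.normal(mean_fragment, mean_fragment / 4))
            step = max(mean_fragment // 2, min(2 * mean_fragment, step))
            cuts.append(min(L, cuts[-1] + step))
        if cuts[-1] - cuts[-2] < mean_fragment // 2 and len(cuts) > 2:
            cuts.pop(-2)
        for s0, e0 in zip(cuts[:-1], cuts[1:]):
            k += 1
            n_var = int(np.searchsorted(chrom.var_pos0, e0) - np.searchsorted(chrom.var_pos0, s0))
            s1 = int(chrom.lift.to1(s0))
            e1 = int(chrom.lift.to1(e0)) if e0 < L else len(chrom.hap1)
            if n_var / (e0 - s0) < collapse_threshold:
                cid = f"ctg{k}h"
                orient = "+" if rng.random() < 0.5 else "-"
                seq = chrom.hap0[s0:e0]
                if orient == "-":
                    seq = reverse_complement(seq)
                contigs.append(Contig(cid, seq, _cov(80.0), _collapsed_tag(style)))
                sidecar[cid] = ("-", contigs[-1].coverage)
                frag_rows.append((cid, "both", chrom.name, s0, e0, s1, e1, orient, e0 - s0))
                continue
            # heterozygous fragment: one piece per haplotype
            id0, id1 = f"ctg{k}a", f"ctg{k}b"
            seq0 = chrom.hap0[s0:e0]
            seq1 = chrom.hap1[s1:e1]
            if style == "paired_haplotype":
                orient = "+" if rng.random() < 0.5 else "-"
                o0 = o1 = orient  # bubble arms are emitted co-oriented
            else:
                o0 = "+" if rng.random() < 0.5 else "-"
                o1 = "+" if rng.random() < 0.5 else "-"
            out0 = seq0 if o0 == "+" else reverse_complement(seq0)
            tag0 = {
                "paired_haplotype": "primary_bubble" if len(seq0) >= len(seq1) else "secondary_bubble",
                "pseudo_haplotype": "pseudo_primary",
                "haplotype_ignorant": "plain",
            }[style]
            contigs.append(Contig(id0, out0, _cov(40.0), tag0, partner=id1 if style == "paired_haplotype" else None))
            sidecar[id0] = (id1, contigs[-1].coverage)
            frag_rows.append((id0, "0", chrom.name, s0, e0, s1, e1, o0, e0 - s0))
            if style == "pseudo_haplotype":
                # alternative partners come as two shorter pieces
                m1 = int(chrom.lift.to1((s0 + e0) // 2))
                m1 = min(max(m1, s1 + 1), e1 - 1)
                for sub, (ss, ee) in enumerate(((s1, m1), (m1, e1))):
                    aid = f"ctg{k}b{sub + 1}"
                    oo = "+" if rng.random() < 0.5 else "-"
                    sseq = chrom.hap1[ss:ee]
                    if oo == "-":
                        sseq = reverse_complement(sseq)
                    contigs.append(Contig(aid, sseq, 0.0, "alternative"))
                    ss0 = int(chrom.lift.to0(ss))
                    ee0 = int(chrom.lift.to0(ee)) if ee < len(chrom.hap1) else L
                    frag_rows.append((aid, "1", chrom.name, ss0, ee0, ss, ee, oo, ee - ss))
            else:
                out1 = seq1 if o1 == "+" else reverse_complement(seq1)
                tag1 = {
                    "paired_haplotype": "secondary_bubble" if tag0 == "primary_bubble" else "primary_bubble",
                    "haplotype_ignorant": "plain",
                }[style]
                contigs.append(Contig(id1, out1, _cov(40.0), tag1, partner=id0 if style == "paired_haplotype" else None))
                sidecar[id1] = (id0, contigs[-1].coverage)
                frag_rows.append((id1, "1", chrom.name, s0, e0, s1, e1, o1, e1 - s1))
    fragments = pd.DataFrame(
        frag_rows,
        columns=["contig", "hap", "chrom", "start0", "end0", "start1", "end1", "orient", "length"],
    )
    return SimAssembly(style, contigs, fragments, sidecar)


def _collapsed_tag(style: str) -> str:
    return {
        "paired_haplotype": "non_bubble",
        "pseudo_haplotype": "pseudo_primary",
        "haplotype_ignorant": "plain",
    }[style]


# ---------------------------------------------------------------------------
# Mapping truth coordinates onto simulated contigs


class _FragIndex:
    """Per (chromosome, haplotype) interval index over fragments."""

    def __init__(self, asm: SimAssembly, chrom_names: list[str]):
        self.tables = {}
        fr = asm.fragments
        for ci, cname in enumerate(chrom_names):
            sub = fr[fr.chrom == cname]
            for hap in (0, 1):
                rows = sub[(sub.hap == "both") | (sub.hap == str(hap))]
                scol, ecol = (f"start{hap}", f"end{hap}")
                rows = rows.sort_values(scol)
                self.tables[(ci, hap)] = (
                    rows[scol].to_numpy(np.int64),
                    rows[ecol].to_numpy(np.int64),
                    rows["contig"].to_numpy(),
                    rows["orient"].to_numpy(),
                    rows["length"].to_numpy(np.int64),
                )

    def locate(self, ci, hap, pos):
        """Vectorized: positions (one chrom/hap) -> (contig array, pos-in-contig, ok mask)."""
        starts, ends, names, orients, lens = self.tables[(ci, hap)]
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
        i = np.clip(i, 0, len(starts) - 1)
        off = np.clip(pos - starts[i], 0, lens[i] - 1)
        cpos = np.where(orients[i] == "+", off, lens[i] - 1 - off)
        return names[i], cpos.astype(np.int64), ok


def map_ends_to_contigs(
    truth: DiploidTruth, asm: SimAssembly, contacts: TruthContacts
) -> list[tuple[str, str, int, str, int]]:
    """Express truth-coordinate Hi-C pairs as mapped pair records on contigs."""
    idx = _FragIndex(asm, [c.name for c in truth.chromosomes])
    n = len(contacts)
    name_a = np.empty(n, dtype=object)
    name_b = np.empty(n, dtype=object)
    pos_a = np.zeros(n, dtype=np.int64)
    pos_b = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for ci in range(len(truth.chromosomes)):
        for hap in (0, 1):
            for (carr, harr, parr, names, poss) in (
                (contacts.chrom_a, contacts.hap_a, contacts.pos_a, name_a, pos_a),
                (contacts.chrom_b, contacts.hap_b, contacts.pos_b, name_b, pos_b),
            ):
                m = (carr == ci) & (harr == hap)
                if not m.any():
                    continue
                nm, cp, good = idx.locate(ci, hap, parr[m])
                names[m] = nm
                poss[m] = cp
                ok[m] &= good
    return [
        (f"hic{i}", name_a[i], int(pos_a[i]), name_b[i], int(pos_b[i]))
        for i in range(n)
        if ok[i]
    ]


# ---------------------------------------------------------------------------
# Long reads and paired-end reads


def simulate_long_reads(
    truth: DiploidTruth,
    asm: SimAssembly,
    coverage: float = 20.0,
    mean_len: int = 15_000,
    min_len: int = 1_000,
    error_rate: float = 0.1,
    seed: int = 1,
    min_align: int = 500,
    emit_sequences: bool = False,
):
    """Sample long reads per haplotype and emit their truth alignments as PAF.

    Alignment identity reflects ``error_rate``. Sequences are only
    materialised on request (the pipeline contract is PAF).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    idx = _FragIndex(asm, [c.name for c in truth.chromosomes])
    paf: list[PafRecord] = []
    seqs: list[tuple[str, str]] = []
    rid = 0
    for ci, chrom in enumerate(truth.chromosomes):
        for hap in (0, 1):
            hseq = chrom.hap0 if hap == 0 else chrom.hap1
            L = len(hseq)
            target = coverage * L
            emitted = 0
            starts, ends, names, orients, lens = idx.tables[(ci, hap)]
            while emitted < target:
                rlen = int(np.clip(rng.gamma(4.0, mean_len / 4.0), min_len, 4 * mean_len))
                s = int(rng.integers(0, max(1, L - min_len)))
                e = min(L, s + rlen)
                rlen = e - s
                emitted += rlen
                rid += 1
                qname = f"lr{rid}"
                # truth alignments: intersect [s,e) with this haplotype's fragments
                i0 = max(0, int(np.searchsorted(ends, s, side="right")))
                for i in range(i0, len(starts)):
                    if starts[i] >= e:
                        break
                    os_, oe = max(s, int(starts[i])), min(e, int(ends[i]))
                    if oe - os_ < min_align:
                        continue
                    off = os_ - int(starts[i])
                    alen = oe - os_
                    if orients[i] == "+":
                        tstart, tend, strand = off, off + alen, "+"
                    else:
                        tstart, tend, strand = int(lens[i]) - off - alen, int(lens[i]) - off, "-"
                    paf.append(
                        PafRecord(
                            qname, rlen, os_ - s, oe - s, strand,
                            str(names[i]), int(lens[i]), tstart, tend,
                            max(1, round(alen * (1 - error_rate))), alen,
                        )
                    )
                if emit_sequences:
                    read = list(hseq[s:e])
                    n_err = rng.binomial(rlen, error_rate)
                    for p in rng.integers(0, rlen, n_err):
                        read[p] = "ACGT"[int(rng.integers(0, 4))]
                    seqs.append((qname, "".join(read)))
    return (paf, seqs) if emit_sequences else (paf, None)


def simulate_paired_end(
    truth: DiploidTruth,
    asm: SimAssembly,
    coverage: float = 10.0,
    a: float = 500.0,
    d: float = 50.0,
    read_len: int = 100,
    seed: int = 1,
):
    """Sample paired-end pairs and return mapped pair records plus the library."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    idx = _FragIndex(asm, [c.name for c in truth.chromosomes])
    lens = np.array([len(c.hap0) for c in truth.chromosomes], dtype=np.int64)
    n_pairs = int(coverage * lens.sum() / (2 * read_len))
    ca = rng.choice(len(lens), size=n_pairs, p=lens / lens.sum())
    hap = rng.integers(0, 2, n_pairs)
    pa = (rng.random(n_pairs) * (lens[ca] - a - 4 * d)).astype(np.int64)
    ins = np.maximum(2 * read_len, rng.normal(a, d, n_pairs)).astype(np.int64)
    pb = np.minimum(pa + ins, lens[ca] - 1)
    pairs = []
    for ci in range(len(lens)):
        for h in (0, 1):
            m = (ca == ci) & (hap == h)
            if not m.any():
                continue
            qa, qb = pa[m], pb[m]
            if h == 1:
                lift = truth.chromosomes[ci].lift
                hl = len(truth.chromosomes[ci].hap1)
                qa = np.clip(lift.to1(qa), 0, hl - 1)
                qb = np.clip(lift.to1(qb), 0, hl - 1)
            na, cpa, oka = idx.locate(ci, h, qa)
            nb, cpb, okb = idx.locate(ci, h, qb)
            ok = oka & okb
            for j in np.nonzero(ok)[0]:
                pairs.append((f"pe{ci}_{h}_{j}", na[j], int(cpa[j]), nb[j], int(cpb[j])))
    return pairs, ReadLibrary("paired_end", a=a, d=d, coverage=coverage)
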