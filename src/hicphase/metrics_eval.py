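"""Assembly evaluation: N50, phasing accuracy, truth-based error counts.

Phasing accuracy follows the hap-mer convention: per scaffold, the fraction
of haplotype-specific markers belonging to the majority haplotype, in
[0.5, 1]; the overall value weights scaffolds by their marker totals. On
simulated data the markers are the truth heterozygous variant positions, an
exact stand-in for hap-mers. Misassemblies and switch errors are counted
against the simulator's truth coordinates: a misassembly is an adjacent
member pair whose truth placements are not collinear on one chromosome, a
switch error an adjacent pair of phased blocks drawn from different truth
haplotypes in one output haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly_model import AssemblyError
from .diploid_sim import DiploidTruth, SimAssembly
from .haplotype_merge import _provenance_piece

__all__ = [
    "n50",
    "phasing_accuracy",
    "hap_marker_counts",
    "truth_errors",
    "switch_errors",
]

MIN_REPORT_LEN = 500  # evaluation convention: sequences >= 500 bp


def n50(lengths) -> int:
    """Length of the shortest sequence such that it and all longer sequences
    cover at least half of the total assembly."""
    lengths = [int(x) for x in lengths]
    if not lengths or any(x <= 0 for x in lengths):
        raise AssemblyError("n50 requires a nonempty list of positive lengths")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def phasing_accuracy(markers: list[tuple[str, int, int]]):
    """Per-scaffold and marker-weighted overall phasing accuracy.

    ``markers`` rows are (scaffold_id, n_hap0_markers, n_hap1_markers).
    Marker-free scaffolds are excluded (reported with accuracy None);
    returns (per_scaffold dict, overall or None).
    """
    per = {}
    tot_w = 0
    tot_maj = 0
    for sid, n0, n1 in markers:
        if n0 < 0 or n1 < 0:
            raise AssemblyError("negative marker count")
        if n0 + n1 == 0:
            per[sid] = None
            continue
        per[sid] = max(n0, n1) / (n0 + n1)
        tot_w += n0 + n1
        tot_maj += max(n0, n1)
    overall = tot_maj / tot_w if tot_w else None
    return per, overall


# ---------------------------------------------------------------------------
# Truth-based evaluation on simulated data


def _member_truth(member_id: str, asm: SimAssembly, truth: DiploidTruth):
    """Truth placement of a member piece: (chrom, hap, native interval,
    hap0-projected interval, orientation) or None for collapsed fragments."""
    piece = _provenance_piece(member_id, 0)
    try:
        frag = asm.fragment_row(piece.src)
    except KeyError:
        raise AssemblyError(f"member {member_id!r}: no truth fragment for {piece.src!r}")
    s, e = piece.start, piece.end
    if piece.src == piece.member_id:
        e = int(frag.length)
    hap = str(frag.hap)
    h = 0 if hap in ("0", "both") else 1
    start_h = int(frag.start0 if h == 0 else frag.start1)
    end_h = int(frag.end0 if h == 0 else frag.end1)
    if frag.orient == "+":
        iv = (start_h + s, min(end_h, start_h + e))
    else:
        iv = (max(start_h, end_h - e), end_h - s)
    chrom = truth.chrom(frag.chrom)
    if h == 1:
        iv0 = tuple(sorted((int(chrom.lift.to0(iv[0])), int(chrom.lift.to0(max(iv[0], iv[1] - 1))) + 1)))
    else:
        iv0 = iv
    return frag.chrom, hap, iv, iv0, frag.orient


def truth_errors(state, asm: SimAssembly, truth: DiploidTruth, tol: int = 10_000):
    """Count misassemblies in the final scaffolds against truth coordinates.

    Adjacent members must lie on the same chromosome, with consistent net
    orientation, and with facing truth coordinates within ``tol``.
    Returns (count, breakpoint table rows).
    """
    mis = 0
    table = []
    for sid in sorted(state.scaffolds):
        s = state.scaffolds[sid]
        placed = []
        for m in s.members:
            cc = state.merge.consensus[m.cc_id]
            chrom, hap, iv, iv0, forient = _member_truth(cc.primary.member_id, asm, truth)
            net = 1 if (m.orientation == "+") == (forient == "+") else -1
            placed.append((m.cc_id, chrom, iv0, net, cc.length))
        for (ida, ca, iva, oa, la), (idb, cb, ivb, ob, lb) in zip(placed, placed[1:]):
            bad = False
            if ca != cb or oa != ob:
                bad = True
            elif oa > 0:
                bad = abs(ivb[0] - iva[1]) > tol
            else:
                bad = abs(iva[0] - ivb[1]) > tol
            if bad:
                mis += 1
                table.append((sid, ida, idb, ca, cb, iva, ivb, oa, ob))
    return mis, table


def hap_marker_counts(pieces, state, asm: SimAssembly, truth: DiploidTruth, min_len: int = MIN_REPORT_LEN):
    """Truth marker counts (n_hap0, n_hap1) per emitted phased piece.

    For each haplotype-0 output piece, the chosen member of every haplotype
    block contributes the truth heterozygous variants inside its truth
    interval, attributed to the member's truth haplotype. Homozygous
    (collapsed) members carry no haplotype-specific markers.
    """
    rows = []
    for piece in pieces:
        n = {0: 0, 1: 0}
        total_len = 0
        for b in piece.blocks:
            cc = state.merge.consensus[b.cc_id]
            total_len += cc.length
            if b.kind != "haplotype":
                continue
            p = b.phase_state if b.phase_state is not None else 0
            member = b.haplotype0 if p == 0 else b.haplotype1
            if member is None:
                continue
            chrom, hap, iv, _, _ = _member_truth(member, asm, truth)
            if hap == "both":
                continue
            h = int(hap)
            c = truth.chrom(chrom)
            vpos = c.var_pos0 if h == 0 else c.var_pos1
            cnt = int(np.searchsorted(vpos, iv[1]) - np.searchsorted(vpos, iv[0]))
            n[h] += cnt
        if total_len >= min_len:
            rows.append((f"{piece.scaffold_id}_p{piece.piece_index}", n[0], n[1]))
    return rows


def switch_errors(pieces, state, asm: SimAssembly, truth: DiploidTruth) -> int:
    """Adjacent haplotype blocks whose chosen members come from different
    truth haplotypes, within each haplotype-0 output piece."""
    errors = 0
    for piece in pieces:
        prev_hap = None
        for b in piece.blocks:
            if b.kind != "haplotype":
                continue
            p = b.phase_state if b.phase_state is not None else 0
            member = b.haplotype0 if p == 0 else b.haplotype1
            if member is None:
                prev_hap = None
                continue
            _, hap, _, _, _ = _member_truth(member, asm, truth)
            if hap == "both":
                continue
            if prev_hap is not None and hap != prev_hap:
                errors += 1
            prev_hap = hap
    return errors
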