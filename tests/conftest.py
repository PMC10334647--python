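"""Shared fixtures and independent oracles for the test-suite.

The oracles here deliberately re-derive quantities by direct pixel or prefix
enumeration, independent of the library's vectorised implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from hicphase import hic_matrix as hm
from hicphase.diploid_sim import make_diploid, simulate_hic
from hicphase.pipeline import run_desk


# ---------------------------------------------------------------------------
# Independent oracles


def separation_oracle(M: np.ndarray, b: int, k_max: int):
    """Pixel-enumeration oracle for the junction separation scores."""
    n = M.shape[0]
    S = {"u": 0.0, "l": 0.0}
    S0 = {"u": 0.0, "l": 0.0}
    Lc = {"u": 0.0, "l": 0.0}
    n_out_total = 0
    for k in range(1, k_max + 1):
        outer = [M[i, i + k] for i in range(n - k) if i < b <= i + k]
        for side in ("u", "l"):
            if side == "u":
                inner = [M[i, i + k] for i in range(n - k) if b - k <= i + k <= b - 1]
            else:
                inner = [M[i, i + k] for i in range(n - k) if b <= i <= b + k - 1]
            mu_in = sum(inner) / len(inner) if inner else 0.0
            mu_out = sum(outer) / len(outer) if outer else 0.0
            ni, no = len(inner), len(outer)
            if ni + no:
                S[side] += ni * no * (mu_in - mu_out) ** 2 / (ni + no) ** 2
                S0[side] += ni * no * mu_in**2 / (ni + no) ** 2
            Lc[side] += sum(1 for v in outer if v < mu_in)
        n_out_total += len(outer)
    Ru = Lc["u"] / n_out_total if n_out_total else 0.0
    Rl = Lc["l"] / n_out_total if n_out_total else 0.0
    return S["u"], S["l"], Ru, Rl, S0["u"], S0["l"]


def n50_oracle(lengths):
    vals = sorted(lengths, reverse=True)
    half = sum(vals) / 2
    acc = 0
    for v in vals:
        acc += v
        if acc >= half:
            return v
    raise AssertionError


def random_symmetric(rng: np.random.Generator, n: int, scale: float = 20.0) -> np.ndarray:
    A = rng.poisson(scale, size=(n, n)).astype(float)
    return np.triu(A) + np.triu(A, 1).T


# ---------------------------------------------------------------------------
# Truth-level Hi-C matrix builders (used by the discrimination/localization
# checks; haplotype-1 coordinates are lifted back to haplotype 0 so both
# haplotypes share one coordinate system)


def _hap0_positions(truth, contacts):
    pa = contacts.pos_a.copy()
    pb = contacts.pos_b.copy()
    for ci, c in enumerate(truth.chromosomes):
        L = len(c.hap0)
        m = (contacts.chrom_a == ci) & (contacts.hap_a == 1)
        pa[m] = np.clip(c.lift.to0(pa[m]), 0, L - 1)
        m = (contacts.chrom_b == ci) & (contacts.hap_b == 1)
        pb[m] = np.clip(c.lift.to0(pb[m]), 0, L - 1)
    return pa, pb


def _binned(ja, jb, n, bs):
    M = np.zeros((n, n))
    ba, bb = ja // bs, jb // bs
    ok = (ba < n) & (bb < n) & (ba >= 0) & (bb >= 0)
    np.add.at(M, (ba[ok], bb[ok]), 1.0)
    np.add.at(M, (bb[ok], ba[ok]), 1.0)
    np.fill_diagonal(M, np.diagonal(M) / 2)
    return M


def desk_contact_maps(seed: int, bin_size: int = 5_000, coverage: float = 30.0):
    """Three matrices from one simulated genome: the intact chr1 map with a
    true mid-chromosome junction, an inter-chromosomal chimera of two
    half-chromosomes, and the full chr1+chr2 chimera."""
    truth = make_diploid(2, 500_000, 0.005, seed=seed)
    contacts = simulate_hic(truth, coverage=coverage, seed=seed + 10_000)
    pa, pb = _hap0_positions(truth, contacts)
    L = 500_000
    half = L // 2
    # intact chr1, junction at the middle bin boundary
    m = (contacts.chrom_a == 0) & (contacts.chrom_b == 0)
    intra = hm.HiCMatrix(("chr1",), bin_size, _binned(pa[m], pb[m], L // bin_size, bin_size),
                         junction_bin=half // bin_size)
    # chr1 first half + chr2 first half
    in_a = pa < half
    in_b = pb < half
    m = in_a & in_b
    ja = np.where(contacts.chrom_a[m] == 0, pa[m], pa[m] + half)
    jb = np.where(contacts.chrom_b[m] == 0, pb[m], pb[m] + half)
    inter = hm.HiCMatrix(("halfhalf",), bin_size, _binned(ja, jb, L // bin_size, bin_size),
                         junction_bin=half // bin_size)
    # full chimera chr1 + chr2
    ja = pa + contacts.chrom_a * L
    jb = pb + contacts.chrom_b * L
    chimera = hm.HiCMatrix(("chimera",), bin_size, _binned(ja, jb, 2 * L // bin_size, bin_size),
                           junction_bin=L // bin_size)
    return intra, inter, chimera


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def desk_paired():
    """One end-to-end desk run (paired-haplotype style, seed 1), shared."""
    return run_desk("paired_haplotype", seed=1)


@pytest.fixture(scope="session")
def small_truth():
    return make_diploid(2, 200_000, 0.005, seed=7)
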