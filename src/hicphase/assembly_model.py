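"""Core data types, configuration and text-format I/O shared by all stages.

The pipeline works on plain-text interchange formats throughout: FASTA for
sequences, PAF for long-read alignments, a "pairs"-style TSV for mapped Hi-C
read pairs, AGP v2.1 for scaffold structure, and small TSV sidecars/reports.
Internal coordinates are 0-based half-open; AGP and reports are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Contig",
    "ReadLibrary",
    "ScaffoldMember",
    "Scaffold",
    "PipelineConfig",
    "PafRecord",
    "reverse_complement",
    "read_assembly",
    "write_fasta",
    "write_scaffolds",
    "read_paf",
    "write_paf",
    "read_pairs_tsv",
    "write_pairs_tsv",
]

VALID_BASES = frozenset("ACGTN")
STYLE_TAGS = (
    "primary_bubble",
    "secondary_bubble",
    "non_bubble",
    "pseudo_primary",
    "alternative",
    "plain",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AssemblyError(ValueError):
    """Raised on malformed or inconsistent assembly inputs."""


@dataclass
class Contig:
    """One input sequence with coverage and style annotation.

    ``partner`` carries the bubble pairing for paired-haplotype style input
    (mutual references between a primary and a secondary bubble arm).
    """

    id: str
    sequence: str
    coverage: float = 0.0
    style_tag: str = "plain"
    partner: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise AssemblyError(
                f"contig {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )
        self.sequence = self.sequence.upper()
        if self.coverage < 0:
            raise AssemblyError(f"contig {self.id!r}: negative coverage")
        if self.style_tag not in STYLE_TAGS:
            raise AssemblyError(f"contig {self.id!r}: unknown style tag {self.style_tag!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadLibrary:
    """A sequencing library; ``a``/``d`` are insert-size mean/sd for paired libraries."""

    kind: str  # paired_end | mate_pair | long_read | hic | linked_read
    a: float | None = None
    d: float | None = None
    coverage: float = 0.0

    def __post_init__(self) -> None:
        paired = self.kind in ("paired_end", "mate_pair", "linked_read")
        if paired:
            if self.a is None or self.a <= 0 or self.d is None or self.d < 0:
                raise AssemblyError(f"{self.kind} library requires a > 0 and d >= 0")
        elif self.a is not None or self.d is not None:
            raise AssemblyError(f"{self.kind} library takes no insert-size statistics")

    @property
    def insert_tolerance(self) -> float:
        """Maximum plausible span of a read pair: a + 3*d."""
        if self.a is None:
            raise AssemblyError("insert tolerance undefined for unpaired library")
        return self.a + 3 * self.d


@dataclass
class ScaffoldMember:
    cc_id: str
    orientation: str  # '+' or '-'
    gap_after: int = 0  # Ns to the next member; ignored for the last member


@dataclass
class Scaffold:
    id: str
    members: list[ScaffoldMember]

    def length(self, lengths: dict[str, int]) -> int:
        total = 0
        for i, m in enumerate(self.members):
            total += lengths[m.cc_id]
            if i + 1 < len(self.members):
                total += m.gap_after
        return total

    def member_offsets(self, lengths: dict[str, int]) -> list[int]:
        offs = []
        pos = 0
        for i, m in enumerate(self.members):
            offs.append(pos)
            pos += lengths[m.cc_id]
            if i + 1 < len(self.members):
                pos += m.gap_after
        return offs


def _default_L_schedule(step_small: int, stop_small: int, step_large: int, stop_large: int) -> list[int]:
    sched = list(range(step_small, stop_small + 1, step_small))
    sched += list(range(stop_small + step_large, stop_large + 1, step_large))
    return sched


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline.

    The defaults are the genome-scale values; :meth:`desk` returns a profile
    for small simulated genomes where every length-like parameter is scaled
    with the bin size (5 kb instead of 100 kb, factor 1/20) and the Hi-C
    edge-weight count thresholds are scaled with Hi-C coverage (30x vs 60x).
    """

    bin_size: int = 100_000
    s_threshold: float = 1.0
    r_threshold: float = 1.6
    k_max: int = 10
    min_matrix_scaffold: int = 300_000
    min_link: int = 0
    hic_edge_min_weight_small_L: int = 50
    hic_edge_min_weight_large_L: int = 100
    hic_large_L_cutoff: int = 100_000
    L_schedule: list[int] = field(
        default_factory=lambda: _default_L_schedule(10_000, 100_000, 100_000, 1_000_000)
    )
    C_consensus: float = 40.0
    r_upper_threshold: float = 1.75
    identity_min: float = 0.80
    end_search_window: int = 300_000
    hic_join_gap: int = 500
    seed: int = 1
    # merge details
    min_align_len: int = 1000
    min_piece_len: int = 200
    # read-link details
    kmer_size: int = 32
    min_longread_align: int = 500
    # misassembly-score details
    peak_window: int = 2
    motif_halfwidth: int = 10
    zero_mean_floor: float = 0.5
    coverage_resolution: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.k_max < 1:
            raise AssemblyError("bin_size and k_max must be positive")
        if any(b <= a for a, b in zip(self.L_schedule, self.L_schedule[1:])):
            raise AssemblyError("L_schedule must be strictly increasing")
        for name in ("s_threshold", "r_threshold", "C_consensus", "r_upper_threshold", "identity_min"):
            if getattr(self, name) <= 0:
                raise AssemblyError(f"{name} must be positive")

    @classmethod
    def desk(cls, seed: int = 1) -> "PipelineConfig":
        return cls(
            bin_size=5_000,
            min_matrix_scaffold=15_000,
            hic_edge_min_weight_small_L=25,
            hic_edge_min_weight_large_L=50,
            hic_large_L_cutoff=5_000,
            L_schedule=_default_L_schedule(500, 5_000, 5_000, 50_000),
            end_search_window=15_000,
            min_align_len=1000,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# FASTA / assembly input


def _parse_fasta(path: str) -> list[tuple[str, str]]:
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise AssemblyError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    return records


def _read_sidecar(path: str) -> dict[str, tuple[str, float]]:
    """Sidecar TSV: contig_id, partner_id ('-' for none), coverage."""
    table: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AssemblyError(f"{path}:{lineno}: expected 3 columns")
            table[parts[0]] = (parts[1], float(parts[2]))
    return table


def read_assembly(
    fasta_path: str,
    style: str,
    pairing_sidecar: str | None = None,
    alternative_path: str | None = None,
) -> list[Contig]:
    """Read contigs in one of the three supported input styles.

    paired_haplotype requires a sidecar TSV (contig_id, partner_id, coverage)
    carrying the bubble pairing; pseudo_haplotype takes a second FASTA of
    alternative sequences; haplotype_ignorant is a flat contig set.
    """
    if style == "paired_haplotype":
        if pairing_sidecar is None:
            raise AssemblyError("paired_haplotype style requires a pairing sidecar TSV")
        sidecar = _read_sidecar(pairing_sidecar)
        contigs: dict[str, Contig] = {}
        seqs = dict(_parse_fasta(fasta_path))
        for cid, seq in seqs.items():
            if cid not in sidecar:
                raise AssemblyError(f"contig {cid!r} missing from pairing sidecar")
            partner, cov = sidecar[cid]
            if partner == "-":
                contigs[cid] = Contig(cid, seq, cov, "non_bubble")
            else:
                if partner not in seqs:
                    raise AssemblyError(f"contig {cid!r}: partner {partner!r} not in FASTA")
                primary = len(seq.replace("N", "")) >= len(seqs[partner].replace("N", "")) and (
                    len(seq.replace("N", "")) > len(seqs[partner].replace("N", "")) or cid < partner
                )
                tag = "primary_bubble" if primary else "secondary_bubble"
                contigs[cid] = Contig(cid, seq, cov, tag, partner=partner)
        for c in contigs.values():
            if c.partner is not None and contigs[c.partner].partner != c.id:
                raise AssemblyError(f"non-mutual bubble pairing at {c.id!r}")
        return list(contigs.values())

    if style == "pseudo_haplotype":
        contigs = [Contig(cid, seq, style_tag="pseudo_primary") for cid, seq in _parse_fasta(fasta_path)]
        if alternative_path is not None:
            alts = [Contig(cid, seq, style_tag="alternative") for cid, seq in _parse_fasta(alternative_path)]
            ids = {c.id for c in contigs}
            for a in alts:
                if a.id in ids:
                    raise AssemblyError(f"duplicate contig id {a.id!r} across primary/alternative")
            contigs += alts
        return contigs

    if style == "haplotype_ignorant":
        return [Contig(cid, seq, style_tag="plain") for cid, seq in _parse_fasta(fasta_path)]

    raise AssemblyError(f"unknown input style {style!r}")


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_scaffolds(
    scaffolds: Sequence[Scaffold],
    sequences: dict[str, str],
    out_fasta: str,
    out_agp: str,
) -> None:
    """Write scaffold FASTA and the matching AGP v2.1 description.

    Members with orientation '-' are emitted reverse-complemented; gaps are
    runs of N of the member's ``gap_after``. AGP coordinates are 1-based
    inclusive and tile each scaffold exactly.
    """
    lengths = {}
    for s in scaffolds:
        for m in s.members:
            if m.cc_id not in sequences:
                raise AssemblyError(f"scaffold {s.id!r}: unknown member {m.cc_id!r}")
    seen: set[str] = set()
    for s in scaffolds:
        for m in s.members:
            if m.cc_id in seen:
                raise AssemblyError(f"member {m.cc_id!r} placed twice")
            seen.add(m.cc_id)
    fasta_records = []
    agp_rows = []
    for s in scaffolds:
        parts = []
        pos = 0
        part_no = 0
        for i, m in enumerate(s.members):
            seq = sequences[m.cc_id]
            if m.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            part_no += 1
            agp_rows.append(
                (s.id, pos + 1, pos + len(seq), part_no, "W", m.cc_id, 1, len(seq), m.orientation)
            )
            pos += len(seq)
            if i + 1 < len(s.members) and m.gap_after > 0:
                parts.append("N" * m.gap_after)
                part_no += 1
                agp_rows.append(
                    (s.id, pos + 1, pos + m.gap_after, part_no, "N", m.gap_after,
                     "scaffold", "yes", "proximity_ligation")
                )
                pos += m.gap_after
        fasta_records.append((s.id, "".join(parts)))
    write_fasta(fasta_records, out_fasta)
    with open(out_agp, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for row in agp_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# PAF and Hi-C pairs


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int = 60

    @property
    def identity(self) -> float:
        return self.nmatch / self.blocklen if self.blocklen else 0.0


def read_paf(path: str) -> list[PafRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AssemblyError(f"{path}:{lineno}: PAF row has {len(f)} < 12 columns")
            try:
                records.append(
                    PafRecord(
                        f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                        f[5], int(f[6]), int(f[7]), int(f[8]),
                        int(f[9]), int(f[10]), int(f[11]),
                    )
                )
            except ValueError as exc:
                raise AssemblyError(f"{path}:{lineno}: malformed PAF row: {exc}") from exc
    return records


def write_paf(records: Iterable[PafRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.qname}\t{r.qlen}\t{r.qstart}\t{r.qend}\t{r.strand}\t"
                f"{r.tname}\t{r.tlen}\t{r.tstart}\t{r.tend}\t{r.nmatch}\t{r.blocklen}\t{r.mapq}\n"
            )


def read_pairs_tsv(path: str) -> list[tuple[str, str, int, str, int]]:
    """Mapped Hi-C pairs TSV: read_id, seq_a, pos_a, seq_b, pos_b."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise AssemblyError(f"{path}:{lineno}: expected 5 columns")
            out.append((f[0], f[1], int(f[2]), f[3], int(f[4])))
    return out


def write_pairs_tsv(pairs: Iterable[tuple[str, str, int, str, int]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tseq_a\tpos_a\tseq_b\tpos_b\n")
        for rid, sa, pa, sb, pb in pairs:
            fh.write(f"{rid}\t{sa}\t{pa}\t{sb}\t{pb}\n")
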