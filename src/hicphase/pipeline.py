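"""End-to-end orchestration: merge -> scaffold -> phase, plus the desk-scale
simulated benchmark used throughout the test-suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly_model import Contig, PafRecord, PipelineConfig, ReadLibrary
from .diploid_sim import (
    DiploidTruth,
    SimAssembly,
    fragment_to_style,
    make_diploid,
    map_ends_to_contigs,
    simulate_hic,
    simulate_long_reads,
)
from .haplotype_merge import MergeResult, merge_assembly
from .metrics_eval import hap_marker_counts, n50, phasing_accuracy, switch_errors, truth_errors
from .phaser import emit_phased_scaffolds, phase_scaffold
from .read_links import select_long_read_alignments
from .scaffolder import ScaffolderState, hic_scaffold_iterate, longread_scaffold

__all__ = ["PipelineResult", "run_pipeline", "DeskRun", "run_desk"]


@dataclass
class PipelineResult:
    merge: MergeResult
    state: ScaffolderState
    records: list[tuple[str, str]] = field(default_factory=list)  # phased FASTA records
    pieces: list = field(default_factory=list)
    report: list = field(default_factory=list)

    @property
    def n_scaffolds(self) -> int:
        return len(self.state.scaffolds)

    def scaffold_lengths(self) -> list[int]:
        lengths = {c: cc.length for c, cc in self.merge.consensus.items()}
        return [s.length(lengths) for s in self.state.scaffolds.values()]


def run_pipeline(
    contigs: list[Contig],
    hic_pairs: list[tuple[str, str, int, str, int]],
    long_paf: list[PafRecord],
    config: PipelineConfig | None = None,
    libraries: list[ReadLibrary] | None = None,
    self_paf: list[PafRecord] | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory inputs.

    ``hic_pairs`` are mapped pair records against the input contigs;
    ``long_paf`` holds long-read-to-contig alignments. ``self_paf``
    optionally supplies a pre-computed self-alignment for the merge stage.
    """
    config = config or PipelineConfig()
    merge = merge_assembly(contigs, config, paf=self_paf)
    chosen = select_long_read_alignments(long_paf, config.min_longread_align)
    contacts = [(sa, pa, sb, pb) for _, sa, pa, sb, pb in hic_pairs]
    state = ScaffolderState(merge, config, contacts, chosen, libraries=libraries)
    longread_scaffold(state)
    hic_scaffold_iterate(state)
    result = PipelineResult(merge, state)
    for k, sid in enumerate(sorted(state.scaffolds)):
        scaffold = state.scaffolds[sid]
        blocks, counts = phase_scaffold(scaffold, state, seed=config.seed * 1000 + k)
        recs, pieces, rep = emit_phased_scaffolds(scaffold, blocks, state)
        result.records += recs
        result.pieces += pieces
        result.report += rep
    return result


# ---------------------------------------------------------------------------
# Desk-scale simulated benchmark


@dataclass
class DeskRun:
    truth: DiploidTruth
    asm: SimAssembly
    result: PipelineResult
    misassemblies: int
    switches: int
    marker_rows: list
    accuracy: float | None

    @property
    def n_scaffolds(self) -> int:
        return self.result.n_scaffolds


def run_desk(
    style: str = "paired_haplotype",
    seed: int = 1,
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    heterozygosity: float = 0.005,
    hic_coverage: float = 30.0,
    long_coverage: float = 20.0,
) -> DeskRun:
    """The desk-scale benchmark: simulate a small diploid genome, fragment it
    into the requested input style, and run the full pipeline against the
    simulated truth."""
    truth = make_diploid(n_chrom, chrom_length, heterozygosity, seed=seed)
    asm = fragment_to_style(truth, style, seed=seed + 101)
    contacts = simulate_hic(truth, coverage=hic_coverage, seed=seed + 202)
    pairs = map_ends_to_contigs(truth, asm, contacts)
    paf, _ = simulate_long_reads(truth, asm, coverage=long_coverage, seed=seed + 303)
    config = PipelineConfig.desk(seed)
    result = run_pipeline(asm.contigs, pairs, paf, config)
    mis, _ = truth_errors(result.state, asm, truth)
    marker_rows = hap_marker_counts(result.pieces, result.state, asm, truth)
    _, overall = phasing_accuracy(marker_rows)
    sw = switch_errors(result.pieces, result.state, asm, truth)
    return DeskRun(truth, asm, result, mis, sw, marker_rows, overall)
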