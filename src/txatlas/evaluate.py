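"""End-to-end annotation driver and truth-based scoring helpers.

`annotate_genome` runs the full feature-annotation cascade (TSS detection
and classification, terminators, operons, transcripts, sRNA classification
and curation, inverted repeats) with one parameter dictionary; the scoring
functions compare its output against a generator :class:`TruthSet`.
Operon assembly uses the coverage-drop terminator track (hairpin hits are a
sequence-only annotation and are reported separately, never merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import inverton, srna, terminator_operon, tss
from .models import CoverageSet, GenomeBundle
from .synthetic import TruthSet


@dataclass
class AnnotationResult:
    tss_records: list = field(default_factory=list)
    processing_sites: list = field(default_factory=list)
    drop_terminators: list = field(default_factory=list)
    hairpin_terminators: list = field(default_factory=list)
    transcripts: list = field(default_factory=list)
    operons: list = field(default_factory=list)
    srnas_accepted: list = field(default_factory=list)
    srnas_rejected: list = field(default_factory=list)
    inverted_repeats: list = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "n_tss": len(self.tss_records),
            "n_processing_sites": len(self.processing_sites),
            "n_drop_terminators": len(self.drop_terminators),
            "n_hairpin_terminators": len(self.hairpin_terminators),
            "n_transcripts": len(self.transcripts),
            "n_operons": len(self.operons),
            "n_srnas": len(self.srnas_accepted),
            "n_srnas_rejected": len(self.srnas_rejected),
            "n_inverted_repeats": len(self.inverted_repeats),
        }


DEFAULT_IR_PARAMS = dict(arm_min=10, arm_max=25, spacer_min=30, spacer_max=200)


def annotate_genome(
    genome: GenomeBundle,
    coverage: CoverageSet,
    ir_params: dict | None = None,
    scan_hairpins: bool = False,
) -> AnnotationResult:
    res = AnnotationResult()
    res.tss_records = tss.detect_tss(coverage)
    tss.classify_tss(res.tss_records, genome.genes)
    res.processing_sites = srna.detect_processing_sites(coverage)
    res.drop_terminators = terminator_operon.find_coverage_drop_terminators(
        coverage, genome.genes
    )
    if scan_hairpins:
        for rep, seq in genome.replicons.items():
            for strand in ("+", "-"):
                res.hairpin_terminators.extend(
                    terminator_operon.find_hairpin_terminators(seq, strand, replicon=rep)
                )
    res.operons = terminator_operon.assemble_operons(
        genome.genes, res.tss_records, res.drop_terminators, coverage
    )
    res.transcripts = srna.call_transcripts(coverage)
    records = srna.classify_srnas(
        res.transcripts,
        res.tss_records,
        res.processing_sites,
        genome.genes,
        res.operons,
        res.drop_terminators,
    )
    res.srnas_accepted, res.srnas_rejected = srna.curate_srnas(
        records,
        res.tss_records,
        res.processing_sites,
        genome.genes,
        res.drop_terminators,
        genome,
        coverage=coverage,
    )
    params = dict(DEFAULT_IR_PARAMS, **(ir_params or {}))
    for rep, seq in genome.replicons.items():
        hits = inverton.find_inverted_repeats(seq, replicon=rep, **params)
        hits = inverton.filter_inverted_repeats(hits)
        inverton.flag_promoter_invertons(hits, res.tss_records)
        res.inverted_repeats.extend(hits)
    return res


# ---------------------------------------------------------------------------
# Truth-based scoring
# ---------------------------------------------------------------------------

def tss_recovery(result: AnnotationResult, truth: TruthSet, tolerance: int = 1):
    """(recall, spurious calls per kb) against the planted TSS positions."""
    detected = {(r.replicon, r.strand): [] for r in result.tss_records}
    for r in result.tss_records:
        detected[(r.replicon, r.strand)].append(r.position)
    hit = 0
    for t in truth.planted_tss:
        positions = detected.get((t.replicon, t.strand), [])
        if any(abs(p - t.position) <= tolerance for p in positions):
            hit += 1
    recall = hit / len(truth.planted_tss) if truth.planted_tss else 1.0
    planted = {
        (t.replicon, t.strand): [x.position for x in truth.planted_tss
                                 if (x.replicon, x.strand) == (t.replicon, t.strand)]
        for t in truth.planted_tss
    }
    spurious = 0
    genome_bp = 0
    for r in result.tss_records:
        near = planted.get((r.replicon, r.strand), [])
        if not any(abs(p - r.position) <= tolerance for p in near):
            spurious += 1
    return recall, spurious


def operon_exactness(result: AnnotationResult, truth: TruthSet) -> float:
    """Fraction of planted transcription units whose gene membership is
    reproduced exactly by an assembled operon."""
    assembled = {tuple(op.gene_ids) for op in result.operons}
    if not truth.planted_operons:
        return 1.0
    ok = sum(1 for unit in truth.planted_operons if tuple(unit) in assembled)
    return ok / len(truth.planted_operons)


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0] + 1, b[1] - b[0] + 1)


def srna_recovery(result: AnnotationResult, truth: TruthSet, min_overlap: float = 0.7) -> float:
    """Fraction of planted sRNAs recovered with the correct class and a
    reciprocal interval overlap of at least ``min_overlap``."""
    if not truth.planted_srnas:
        return 1.0
    ok = 0
    for p in truth.planted_srnas:
        for rec in result.srnas_accepted:
            if (
                rec.replicon == p.replicon
                and rec.strand == p.strand
                and rec.srna_class == p.srna_class
                and _overlap_frac((rec.start, rec.end), (p.start, p.end)) >= min_overlap
            ):
                ok += 1
                break
    return ok / len(truth.planted_srnas)


def ir_recall(result: AnnotationResult, truth: TruthSet, min_overlap: float = 0.8) -> float:
    """Fraction of planted non-decoy inverted repeats matched by a detected
    hit (both arms overlapping reciprocally by >= ``min_overlap``)."""
    planted = [p for p in truth.planted_irs if not p.homopolymeric]
    if not planted:
        return 1.0
    ok = 0
    for p in planted:
        for h in result.inverted_repeats:
            if h.replicon != p.replicon:
                continue
            if (
                _overlap_frac((h.left_start, h.left_end), (p.left_start, p.left_end)) >= min_overlap
                and _overlap_frac((h.right_start, h.right_end), (p.right_start, p.right_end)) >= min_overlap
            ):
                ok += 1
                break
    return ok / len(planted)


def decoys_removed(result: AnnotationResult, truth: TruthSet) -> bool:
    """True when no filtered hit matches a planted homopolymeric decoy."""
    for p in truth.planted_irs:
        if not p.homopolymeric:
            continue
        for h in result.inverted_repeats:
            if (
                h.replicon == p.replicon
                and _overlap_frac((h.left_start, h.left_end), (p.left_start, p.left_end)) >= 0.8
            ):
                return False
    return True
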