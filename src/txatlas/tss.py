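"""TSS detection from TEX+/TEX- start-count enrichment and positional
classification against the gene annotation.

A transcription start site shows a 5'-read-start pileup that is enriched in
the exonuclease-treated (TEX+) library relative to the untreated (TEX-)
library, because processed 5'-monophosphate ends are degraded by the
treatment while triphosphorylated primary 5' ends are protected.

Classes, relative to a gene on the same replicon:

* ``primary``   — highest-enrichment candidate on the gene's strand within
  the 300-bp window upstream of the gene start (ties: closer to the start).
* ``secondary`` — any other same-strand candidate in that window.
* ``internal``  — sense-strand candidate inside the gene body.
* ``antisense`` — antisense-strand candidate overlapping the gene or its
  100-bp flanks.
* ``orphan``    — candidate acquiring no class for any gene.

A single TSS may hold several classes with respect to different genes; it is
emitted as one record with the full assignment list.
"""

from __future__ import annotations

import numpy as np

from .models import CoverageSet, Gene, TSSRecord, TEX_MINUS, TEX_PLUS

DEFAULT_MIN_HEIGHT = 10
DEFAULT_MIN_ENRICHMENT = 2.0
DEFAULT_CLUSTER_WINDOW = 3
DEFAULT_PSEUDOCOUNT = 1
UPSTREAM_WINDOW = 300
ANTISENSE_FLANK = 100


def detect_tss(
    coverage: CoverageSet,
    min_height: int = DEFAULT_MIN_HEIGHT,
    min_enrichment: float = DEFAULT_MIN_ENRICHMENT,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    pseudocount: int = DEFAULT_PSEUDOCOUNT,
) -> list[TSSRecord]:
    """Call unclassified TSS candidates from the start-count tracks.

    A position is a candidate iff its TEX+ start count is >= ``min_height``
    and the TEX+/max(TEX-, pseudocount) ratio is >= ``min_enrichment``.
    Candidates within ``cluster_window`` bp on the same strand are merged
    keeping the highest TEX+ count (ties: most upstream in transcription
    direction).
    """
    if min_height < 1:
        raise ValueError("min_height must be >= 1")
    if min_enrichment <= 1:
        raise ValueError("min_enrichment must be > 1")
    records: list[TSSRecord] = []
    for rep in sorted(coverage.replicon_lengths):
        for strand in ("+", "-"):
            plus = coverage.starts(rep, strand, TEX_PLUS)
            minus = coverage.starts(rep, strand, TEX_MINUS)
            enr = plus / np.maximum(minus, pseudocount)
            mask = (plus >= min_height) & (enr >= min_enrichment)
            positions = np.flatnonzero(mask) + 1
            cands = [
                TSSRecord(
                    replicon=rep,
                    position=int(p),
                    strand=strand,
                    tex_plus_height=int(plus[p - 1]),
                    tex_minus_height=int(minus[p - 1]),
                    enrichment=float(enr[p - 1]),
                )
                for p in positions
            ]
            records.extend(_merge_clusters(cands, cluster_window, strand))
    records.sort(key=lambda r: (r.replicon, r.position, r.strand))
    return records


def _merge_clusters(cands: list[TSSRecord], window: int, strand: str) -> list[TSSRecord]:
    """Merge candidates within ``window`` bp, keeping the highest TEX+ count.

    Upstream means lower coordinate on + and higher coordinate on -, so ties
    are broken toward the transcriptionally upstream position.
    """
    if not cands:
        return []
    cands = sorted(cands, key=lambda r: r.position)
    clusters: list[list[TSSRecord]] = [[cands[0]]]
    for rec in cands[1:]:
        if rec.position - clusters[-1][-1].position <= window:
            clusters[-1].append(rec)
        else:
            clusters.append([rec])
    out = []
    for cluster in clusters:
        if strand == "+":
            best = max(cluster, key=lambda r: (r.tex_plus_height, -r.position))
        else:
            best = max(cluster, key=lambda r: (r.tex_plus_height, r.position))
        out.append(best)
    return out


def upstream_window(gene: Gene, window: int = UPSTREAM_WINDOW) -> tuple[int, int]:
    """The window upstream of the gene start, 1-based inclusive."""
    if gene.strand == "+":
        return (gene.start - window, gene.start - 1)
    return (gene.end + 1, gene.end + window)


def classify_tss(
    candidates: list[TSSRecord],
    genes: list[Gene],
    upstream: int = UPSTREAM_WINDOW,
    antisense_flank: int = ANTISENSE_FLANK,
) -> list[TSSRecord]:
    """Assign primary/secondary/internal/antisense/orphan classes in place.

    Candidates must carry enrichment values (from :func:`detect_tss`).
    Returns the same records with ``assignments`` populated.
    """
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id} lacks a strand")
    for rec in candidates:
        rec.assignments = []
    for gene in genes:
        lo, hi = upstream_window(gene, upstream)
        in_window = [
            r
            for r in candidates
            if r.replicon == gene.replicon
            and r.strand == gene.strand
            and lo <= r.position <= hi
        ]
        if in_window:
            # highest enrichment wins primary; ties resolved toward the start
            def dist(r: TSSRecord) -> int:
                return abs(gene.start - r.position) if gene.strand == "+" else abs(r.position - gene.end)

            primary = max(in_window, key=lambda r: (r.enrichment, -dist(r)))
            primary.assignments.append(("primary", gene.id))
            for r in in_window:
                if r is not primary:
                    r.assignments.append(("secondary", gene.id))
        for r in candidates:
            if r.replicon != gene.replicon:
                continue
            if r.strand == gene.strand and gene.start <= r.position <= gene.end:
                r.assignments.append(("internal", gene.id))
            if (
                r.strand != gene.strand
                and gene.start - antisense_flank <= r.position <= gene.end + antisense_flank
            ):
                r.assignments.append(("antisense", gene.id))
    for rec in candidates:
        if not rec.assignments:
            rec.assignments.append(("orphan", None))
        rec.classes = {}
        for cls, gid in rec.assignments:
            rec.classes.setdefault(cls, []).append(gid)
    return candidates


def primary_tss_of(candidates: list[TSSRecord], gene_id: str) -> TSSRecord | None:
    for r in candidates:
        if ("primary", gene_id) in r.assignments:
            return r
    return None


def compare_tss_sets(
    set_a: list[TSSRecord], set_b: list[TSSRecord], tolerance: int = 0
) -> tuple[int, int, int]:
    """Greedy nearest matching within ``tolerance`` bp on the same
    replicon/strand. Returns (shared, unique_to_a, unique_to_b); the counts
    partition both sets."""
    used_b: set[int] = set()
    shared = 0
    b_index = list(enumerate(set_b))
    for a in set_a:
        best = None
        best_d = None
        for j, b in b_index:
            if j in used_b or b.replicon != a.replicon or b.strand != a.strand:
                continue
            d = abs(b.position - a.position)
            if d <= tolerance and (best_d is None or d < best_d):
                best, best_d = j, d
        if best is not None:
            used_b.add(best)
            shared += 1
    return shared, len(set_a) - shared, len(set_b) - shared
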