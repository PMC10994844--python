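"""Intrinsic-terminator prediction and operon/sub-operon assembly.

Two independent terminator heuristics are provided and their outputs are
kept separate (labelled by ``method``), never merged:

* a hairpin scanner for Rho-independent terminators — a stem of
  complementary pairs (G·U wobble pairs count as matches, as is standard
  for RNA stems), a short loop, and a U-rich tail shortly downstream;
* a coverage-drop detector that scans each intergenic span between
  same-strand adjacent genes for the position with the largest relative
  drop in read coverage.

Operons are assembled from genes, classified TSSs, terminators and
coverage: consecutive same-strand genes are joined when the intergenic gap
is small, intergenic coverage stays above a joining floor, and no
terminator lies between them. Internal primary/secondary TSSs at non-first
members open sub-operons running to the operon end.
"""

from __future__ import annotations

import numpy as np

from .models import CoverageSet, Gene, Operon, TerminatorRecord, TSSRecord, TEX_MINUS
from .synthetic import revcomp

DEFAULT_STEM_RANGE = (5, 12)
DEFAULT_LOOP_RANGE = (3, 8)
DEFAULT_MAX_STEM_MISMATCHES = 1
DEFAULT_MIN_U_TAIL = 4
DEFAULT_DROP_WINDOW = 50
DEFAULT_MIN_DROP = 0.5
DEFAULT_MIN_UPSTREAM_COV = 10
DEFAULT_MAX_GAP = 300
DEFAULT_MIN_JOINING_COV = 5

# RNA-context pairing on the DNA alphabet: Watson-Crick plus G·T (G·U) wobble
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _paired(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def find_hairpin_terminators(
    sequence: str,
    strand: str,
    replicon: str = "replicon1",
    stem_range: tuple[int, int] = DEFAULT_STEM_RANGE,
    loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE,
    max_stem_mismatches: int = DEFAULT_MAX_STEM_MISMATCHES,
    min_u_tail: int = DEFAULT_MIN_U_TAIL,
    u_tail_search: int = 8,
) -> list[TerminatorRecord]:
    """Scan one strand for hairpin + U-tail terminator loci.

    Score = (matched stem pairs - mismatches) + U-tail length. Overlapping
    hits are reduced to the maximum-score hit. Coordinates are reported on
    the forward strand of ``sequence`` regardless of ``strand``.
    """
    if not (4 <= stem_range[0] and stem_range[1] <= 30):
        raise ValueError("stem_range must lie within [4, 30]")
    if not (3 <= loop_range[0] and loop_range[1] <= 10):
        raise ValueError("loop_range must lie within [3, 10]")
    n = len(sequence)
    seq = sequence.upper() if strand == "+" else revcomp(sequence.upper())
    hits: list[tuple[int, int, float, int]] = []  # (start0, end0, score, u_tail)
    for i in range(n):
        best_here: tuple[int, int, float, int] | None = None
        for stem in range(stem_range[0], stem_range[1] + 1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                end = i + 2 * stem + loop
                if end > n:
                    continue
                left = seq[i : i + stem]
                right = seq[i + stem + loop : end]
                matches = sum(
                    1 for k in range(stem) if _paired(left[k], right[stem - 1 - k])
                )
                mism = stem - matches
                if mism > max_stem_mismatches:
                    continue
                u_tail = _u_tail_length(seq, end, min_u_tail, u_tail_search)
                if u_tail < min_u_tail:
                    continue
                score = (matches - mism) + u_tail
                span = (i, end + u_tail - 1, float(score), u_tail)
                if best_here is None or score > best_here[2]:
                    best_here = span
        if best_here is not None:
            hits.append(best_here)
    hits = _suppress_overlaps(hits)
    records = []
    for s0, e0, score, u_tail in hits:
        if strand == "+":
            start, end = s0 + 1, e0 + 1
        else:
            start, end = n - e0, n - s0
        records.append(
            TerminatorRecord(
                replicon=replicon, start=start, end=end, strand=strand,
                method="hairpin", score=score, u_tail_length=u_tail,
            )
        )
    records.sort(key=lambda r: r.start)
    return records


def _u_tail_length(seq: str, from_idx: int, min_u_tail: int, search: int) -> int:
    """Length of the first T-run of >= min_u_tail starting within ``search``
    nt downstream of ``from_idx`` (0-based)."""
    for off in range(search):
        j = from_idx + off
        run = 0
        while j + run < len(seq) and seq[j + run] == "T":
            run += 1
        if run >= min_u_tail:
            return run
    return 0


def _suppress_overlaps(hits):
    """Keep only the maximum-score hit among mutually overlapping hits."""
    kept: list[tuple[int, int, float, int]] = []
    for hit in sorted(hits, key=lambda h: (-h[2], h[0])):
        if all(hit[1] < k[0] or hit[0] > k[1] for k in kept):
            kept.append(hit)
    return sorted(kept)


def find_coverage_drop_terminators(
    coverage: CoverageSet,
    genes: list[Gene],
    window: int = DEFAULT_DROP_WINDOW,
    min_drop: float = DEFAULT_MIN_DROP,
    min_upstream_cov: float = DEFAULT_MIN_UPSTREAM_COV,
    library: str = TEX_MINUS,
) -> list[TerminatorRecord]:
    """Report, per same-strand adjacent gene pair, the intergenic position
    maximizing 1 - downstream/upstream mean coverage (windows of ``window``
    bp), when the drop is >= ``min_drop`` and the upstream mean is
    >= ``min_upstream_cov``. Score = drop ratio."""
    if not 0 < min_drop < 1:
        raise ValueError("min_drop must be in (0, 1)")
    records: list[TerminatorRecord] = []
    by_key: dict[tuple[str, str], list[Gene]] = {}
    for g in genes:
        by_key.setdefault((g.replicon, g.strand), []).append(g)
    for (rep, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda g: g.start)
        cov = coverage.coverage(rep, strand, library).astype(float)
        for a, b in zip(group[:-1], group[1:]):
            span = (a.end + 1, b.start - 1)
            if span[1] - span[0] + 1 < 2:
                continue
            hit = _best_drop(cov, span, window, strand, min_upstream_cov)
            if hit is None:
                continue
            pos, drop, up_mean = hit
            if drop >= min_drop:
                records.append(
                    TerminatorRecord(
                        replicon=rep, start=pos, end=pos, strand=strand,
                        method="coverage_drop", score=float(drop),
                    )
                )
    records.sort(key=lambda r: (r.replicon, r.start))
    return records


def _best_drop(
    cov: np.ndarray, span: tuple[int, int], window: int, strand: str, min_upstream: float
):
    """Max-drop position among positions with adequate upstream support."""
    n = len(cov)
    best = None
    for pos in range(span[0], span[1] + 1):
        i = pos - 1
        if strand == "+":
            up = cov[max(0, i - window) : i]
            down = cov[i : min(n, i + window)]
        else:
            up = cov[i + 1 : min(n, i + 1 + window)]
            down = cov[max(0, i + 1 - window) : i + 1]
        if len(up) == 0 or len(down) == 0:
            continue
        up_mean = float(up.mean())
        if up_mean < min_upstream:
            continue
        drop = 1.0 - float(down.mean()) / up_mean
        if best is None or drop > best[1]:
            best = (pos, drop, up_mean)
    return best


def assemble_operons(
    genes: list[Gene],
    tss_records: list[TSSRecord],
    terminators: list[TerminatorRecord],
    coverage: CoverageSet,
    max_gap: int = DEFAULT_MAX_GAP,
    min_joining_cov: float = DEFAULT_MIN_JOINING_COV,
    library: str = TEX_MINUS,
) -> list[Operon]:
    """Join consecutive same-strand genes into operons and derive
    sub-operons from internal primary/secondary TSSs."""
    operons: list[Operon] = []
    by_key: dict[tuple[str, str], list[Gene]] = {}
    for g in genes:
        by_key.setdefault((g.replicon, g.strand), []).append(g)
    term_pos = [
        (t.replicon, t.strand, t.start, t.end) for t in terminators
    ]
    counter = 0
    for (rep, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda g: g.start)
        cov = coverage.coverage(rep, strand, library)
        blocks: list[list[Gene]] = [[group[0]]] if group else []
        for prev, cur in zip(group[:-1], group[1:]):
            gap = cur.start - prev.end - 1
            joined = gap <= max_gap
            if joined and gap > 0:
                inter = cov[prev.end : cur.start - 1]
                joined = inter.size == 0 or float(inter.min()) >= min_joining_cov
            if joined:
                joined = not any(
                    r == rep and s == strand and prev.end < ts and te < cur.start
                    for r, s, ts, te in term_pos
                )
            if joined:
                blocks[-1].append(cur)
            else:
                blocks.append([cur])
        for block in blocks:
            counter += 1
            ordered = block if strand == "+" else list(reversed(block))
            first = ordered[0]
            lead = None
            for r in tss_records:
                if ("primary", first.id) in r.assignments:
                    lead = r.position
                    break
            term = _terminal_terminator(ordered[-1], term_pos, rep, strand, max_gap)
            sub: list[tuple[int, list[str]]] = []
            for i, member in enumerate(ordered[1:], start=1):
                for r in tss_records:
                    if ("primary", member.id) in r.assignments or (
                        "secondary", member.id) in r.assignments:
                        sub.append((r.position, [g.id for g in ordered[i:]]))
                        break
            operons.append(
                Operon(
                    id=f"operon{counter:04d}",
                    replicon=rep,
                    strand=strand,
                    gene_ids=[g.id for g in ordered],
                    lead_tss=lead,
                    terminator=term,
                    sub_operons=sub,
                )
            )
    return operons


def _terminal_terminator(last: Gene, term_pos, rep: str, strand: str, max_gap: int):
    cands = []
    for r, s, ts, te in term_pos:
        if r != rep or s != strand:
            continue
        if strand == "+" and last.end < ts <= last.end + max_gap:
            cands.append((ts - last.end, (ts, te)))
        if strand == "-" and last.start - max_gap <= te < last.start:
            cands.append((last.start - te, (ts, te)))
    return min(cands)[1] if cands else None


def operon_span(operon: Operon, genes: dict[str, Gene]) -> tuple[int, int]:
    members = [genes[g] for g in operon.gene_ids]
    return (min(g.start for g in members), max(g.end for g in members))
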