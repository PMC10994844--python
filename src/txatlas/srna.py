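"""Small-RNA discovery: transcript calling, candidate segmentation, a
folding-stability score, five-way classification and automated curation.

Transcripts are maximal runs of read coverage. Candidate sRNA intervals are
the transcripts themselves plus their segmentation at internal TSSs and
processing sites (a stable fragment of a longer transcript is only visible
as a boundary change, not as a separate coverage island).

Processing sites are defined operationally as 5'-start pileups present in
the untreated (TEX-) library but not enriched after exonuclease treatment:
a processed, monophosphorylated 5' end is degraded by the treatment, so it
steps up in TEX- without qualifying as a TSS.

The folding score is a Nussinov-style minimum-"energy" dynamic program with
per-pair weights (GC = -3, AU = -2, GU = -1, hairpin loops >= 3 nt). It is
a stability proxy, not a thermodynamic model: the acceptance threshold
(normalized score < -0.05 per nt) applies on this scale and is configurable.
Because G·U wobble pairs are scored, the score is not exactly invariant
under reverse complement (wobble pairs are not closed under complement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    CoverageSet,
    ExpressionMatrix,
    Gene,
    GenomeBundle,
    Operon,
    SRNARecord,
    TerminatorRecord,
    TSSRecord,
    TEX_MINUS,
    TEX_PLUS,
)

CLASS_PRECEDENCE = ("intergenic", "antisense", "utr5_derived", "utr3_derived", "intra_operonic")

DEFAULT_MIN_COV = 10
DEFAULT_MIN_LEN = 30
DEFAULT_MERGE_GAP = 10
DEFAULT_LENGTH_RANGE = (30, 500)
DEFAULT_FOLDING_THRESHOLD = -0.05
DEFAULT_CURATION_WINDOW = 50
DEFAULT_UTR_WINDOW = 300
DEFAULT_END_TOLERANCE = 20
DEFAULT_ANCHOR_TOLERANCE = 5
DEFAULT_COVERAGE_FOLD = 2.0


@dataclass
class Transcript:
    replicon: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SRNACandidate:
    replicon: str
    start: int
    end: int
    strand: str
    parent: tuple[int, int]  # parent transcript interval

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


def call_transcripts(
    coverage: CoverageSet,
    min_cov: int = DEFAULT_MIN_COV,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    library: str = TEX_MINUS,
) -> list[Transcript]:
    """Maximal runs of full coverage >= min_cov; runs separated by
    <= merge_gap are merged; runs shorter than min_len are dropped."""
    out: list[Transcript] = []
    for rep in sorted(coverage.replicon_lengths):
        for strand in ("+", "-"):
            cov = coverage.coverage(rep, strand, library)
            mask = cov >= min_cov
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(idx) - 1]))
            for a, b in zip(starts, ends):
                s, e = int(idx[a]) + 1, int(idx[b]) + 1
                if e - s + 1 >= min_len:
                    out.append(Transcript(replicon=rep, start=s, end=e, strand=strand))
    return out


def detect_processing_sites(
    coverage: CoverageSet,
    min_height: int = 10,
    step_ratio: float = 3.0,
    max_enrichment: float = 2.0,
    local_window: int = 25,
) -> list[tuple[str, int, str]]:
    """5'-step positions in the TEX- start track not enriched in TEX+."""
    sites: list[tuple[str, int, str]] = []
    for rep in sorted(coverage.replicon_lengths):
        for strand in ("+", "-"):
            minus = coverage.starts(rep, strand, TEX_MINUS).astype(float)
            plus = coverage.starts(rep, strand, TEX_PLUS).astype(float)
            enr = plus / np.maximum(minus, 1.0)
            for i in np.flatnonzero(minus >= min_height):
                lo, hi = max(0, i - local_window), min(len(minus), i + local_window + 1)
                local = (minus[lo:hi].sum() - minus[i]) / max(hi - lo - 1, 1)
                if minus[i] >= step_ratio * (local + 1.0) and enr[i] < max_enrichment:
                    sites.append((rep, int(i) + 1, strand))
    return sites


# ---------------------------------------------------------------------------
# Folding-stability proxy
# ---------------------------------------------------------------------------

_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}
MIN_LOOP = 3


def folding_energy(sequence: str) -> tuple[float, float]:
    """Minimum pairing score of a nested secondary structure.

    Returns ``(energy, energy / length)``; zero when no pairing is possible.
    RNA input (U) is accepted and treated as T.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    n = len(seq)
    # integer-coded pair-energy lookup table
    code = np.frombuffer(seq.encode(), dtype=np.int8)
    lut = np.zeros((128, 128))
    for (a, b), e in _PAIR_ENERGY.items():
        lut[ord(a), ord(b)] = e
    E = np.zeros((n + 1, n + 1))  # E[i][j] over seq[i:j], 0-based half-open
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = min(E[i + 1, j], E[i, j - 1])
            pe = lut[code[i], code[j - 1]]
            if pe < 0:
                best = min(best, E[i + 1, j - 1] + pe)
            # bifurcation into two independent sub-structures
            bif = float((E[i, i + 1 : j] + E[i + 1 : j, j]).min())
            E[i, j] = min(best, bif)
    energy = float(E[0, n])
    return energy, energy / n


# ---------------------------------------------------------------------------
# Candidate derivation and classification
# ---------------------------------------------------------------------------

def derive_candidates(
    transcripts: list[Transcript],
    tss_records: list[TSSRecord],
    processing_sites: list[tuple[str, int, str]],
) -> list[SRNACandidate]:
    """Each transcript plus its segmentation at internal 5' anchors."""
    anchors_by_key: dict[tuple[str, str], list[int]] = {}
    for r in tss_records:
        anchors_by_key.setdefault((r.replicon, r.strand), []).append(r.position)
    for rep, pos, strand in processing_sites:
        anchors_by_key.setdefault((rep, strand), []).append(pos)
    out: list[SRNACandidate] = []
    seen: set[tuple] = set()

    def add(rep, s, e, strand, parent):
        key = (rep, s, e, strand)
        if s <= e and key not in seen:
            seen.add(key)
            out.append(SRNACandidate(rep, s, e, strand, parent))

    for tr in transcripts:
        parent = (tr.start, tr.end)
        add(tr.replicon, tr.start, tr.end, tr.strand, parent)
        anchors = sorted(
            a
            for a in anchors_by_key.get((tr.replicon, tr.strand), [])
            if tr.start < a < tr.end
        )
        if not anchors:
            continue
        if tr.strand == "+":
            bounds = [tr.start] + anchors + [tr.end + 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                add(tr.replicon, a, b - 1, "+", parent)
        else:
            bounds = [tr.end] + sorted(anchors, reverse=True) + [tr.start - 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                add(tr.replicon, b + 1, a, "-", parent)
    return out


def _anchor_near(positions: list[int], pos: int, tol: int) -> int | None:
    best = None
    for p in positions:
        d = abs(p - pos)
        if d <= tol and (best is None or d < abs(best - pos)):
            best = p
    return best


def classify_srnas(
    transcripts: list[Transcript] | list[SRNACandidate],
    tss_records: list[TSSRecord],
    processing_sites: list[tuple[str, int, str]],
    genes: list[Gene],
    operons: list[Operon] | None = None,
    terminators: list[TerminatorRecord] | None = None,
    utr_window: int = DEFAULT_UTR_WINDOW,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    anchor_tolerance: int = DEFAULT_ANCHOR_TOLERANCE,
) -> list[SRNARecord]:
    """Assign exactly one class per candidate by precedence
    intergenic -> antisense -> 5'UTR -> 3'UTR -> intra-operonic; candidates
    satisfying none are rejected as unclassifiable."""
    operons = operons or []
    terminators = terminators or []
    if transcripts and isinstance(transcripts[0], Transcript):
        candidates = derive_candidates(transcripts, tss_records, processing_sites)
    else:
        candidates = list(transcripts)

    tss_by_key: dict[tuple[str, str], list[TSSRecord]] = {}
    for r in tss_records:
        tss_by_key.setdefault((r.replicon, r.strand), []).append(r)
    proc_by_key: dict[tuple[str, str], list[int]] = {}
    for rep, pos, strand in processing_sites:
        proc_by_key.setdefault((rep, strand), []).append(pos)
    genes_by_rep: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_rep.setdefault(g.replicon, []).append(g)
    gene_index = {g.id: g for g in genes}

    records: list[SRNARecord] = []
    for i, c in enumerate(candidates):
        rep_genes = genes_by_rep.get(c.replicon, [])
        tss_here = tss_by_key.get((c.replicon, c.strand), [])
        proc_here = proc_by_key.get((c.replicon, c.strand), [])
        p5 = c.five_prime()
        p3 = c.three_prime()
        tss5 = None
        for r in tss_here:
            if abs(r.position - p5) <= anchor_tolerance:
                tss5 = r
                break
        proc5 = _anchor_near(proc_here, p5, anchor_tolerance)

        sense_overlap = [g for g in rep_genes if g.strand == c.strand and g.overlaps(c.start, c.end)]
        anti_overlap = [g for g in rep_genes if g.strand != c.strand and g.overlaps(c.start, c.end)]
        parent_overlaps_any = any(
            g.overlaps(c.parent[0], c.parent[1]) for g in rep_genes
        )

        cls: str | None = None
        if tss5 is not None and not parent_overlaps_any:
            cls = "intergenic"
        elif (tss5 is not None or proc5 is not None) and anti_overlap:
            cls = "antisense"
        elif tss5 is not None:
            # shared TSS with an mRNA, ending before its coding start
            for cname, gid in tss5.assignments:
                if cname not in ("primary", "secondary") or gid is None:
                    continue
                gene = gene_index.get(gid)
                if gene is None or gene.replicon != c.replicon:
                    continue
                before = c.end < gene.start if c.strand == "+" else c.start > gene.end
                if gene.strand == c.strand and before:
                    cls = "utr5_derived"
                    break
        if cls is None and (tss5 is not None or proc5 is not None):
            # 3' UTR: 5' anchor downstream of a same-strand gene end
            in_utr3 = any(
                (g.end < p5 <= g.end + utr_window)
                if c.strand == "+"
                else (g.start - utr_window <= p5 < g.start)
                for g in rep_genes
                if g.strand == c.strand
            )
            # termination shared with the mRNA: an annotated terminator, a
            # processing site, or the parent transcript's own 3' end
            end_support = (
                _end_supported(c, p3, terminators, proc_here, end_tolerance)
                or abs(p3 - (c.parent[1] if c.strand == "+" else c.parent[0])) <= end_tolerance
            )
            if in_utr3 and end_support:
                cls = "utr3_derived"
        if cls is None and (tss5 is not None or proc5 is not None):
            inside_operon = False
            for op in operons:
                if op.replicon != c.replicon or op.strand != c.strand:
                    continue
                members = [gene_index[g] for g in op.gene_ids if g in gene_index]
                if not members:
                    continue
                lo = min(g.start for g in members)
                hi = max(g.end for g in members)
                if lo <= c.start and c.end <= hi:
                    inside_operon = True
                    break
            end_support = (
                _end_supported(c, p3, terminators, proc_here, end_tolerance)
                or abs(p3 - (c.parent[1] if c.strand == "+" else c.parent[0])) <= end_tolerance
            )
            if inside_operon and end_support:
                cls = "intra_operonic"

        rec = SRNARecord(
            id=f"srna{i + 1:04d}",
            replicon=c.replicon,
            start=c.start,
            end=c.end,
            strand=c.strand,
            srna_class=cls,
            tss_support=tss5.position if tss5 is not None else None,
            processing_support=proc5,
        )
        if cls is None:
            rec.rejection_reasons.append("unclassifiable")
        records.append(rec)
    return records


def _end_supported(c, p3, terminators, proc_here, tol) -> bool:
    for t in terminators:
        if t.replicon == c.replicon and (t.start - tol) <= p3 <= (t.end + tol):
            return True
    return any(abs(p - p3) <= tol for p in proc_here)


# ---------------------------------------------------------------------------
# Automated curation
# ---------------------------------------------------------------------------

def curate_srnas(
    records: list[SRNARecord],
    tss_records: list[TSSRecord],
    processing_sites: list[tuple[str, int, str]],
    genes: list[Gene],
    terminators: list[TerminatorRecord],
    genome: GenomeBundle,
    coverage: CoverageSet | None = None,
    window: int = DEFAULT_CURATION_WINDOW,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    folding_threshold: float = DEFAULT_FOLDING_THRESHOLD,
    coverage_fold: float = DEFAULT_COVERAGE_FOLD,
    cis_elements: list[tuple[str, int, int]] | None = None,
    library: str = TEX_MINUS,
) -> tuple[list[SRNARecord], list[SRNARecord]]:
    """Apply the exclusion rules; returns (accepted, rejected).

    Rules applied automatically: (1) no promoter or processing site within
    ``window`` bp upstream of the 5' end; (2) complete overlap with a
    same-strand annotated mRNA; (3) complete overlap with an annotated
    terminator; (4) overlap with supplied cis-regulatory element intervals
    (only when provided); (5) no evident coverage change relative to the
    flanking regions. Accepted records additionally satisfy the length
    range and the folding-stability threshold. Every violated rule is
    listed on the record.
    """
    tss_positions: dict[tuple[str, str], list[int]] = {}
    for r in tss_records:
        tss_positions.setdefault((r.replicon, r.strand), []).append(r.position)
    proc_positions: dict[tuple[str, str], list[int]] = {}
    for rep, pos, strand in processing_sites:
        proc_positions.setdefault((rep, strand), []).append(pos)

    accepted: list[SRNARecord] = []
    rejected: list[SRNARecord] = []
    for rec in records:
        reasons = [r for r in rec.rejection_reasons if r == "unclassifiable"]
        p5 = rec.start if rec.strand == "+" else rec.end
        anchors = tss_positions.get((rec.replicon, rec.strand), []) + proc_positions.get(
            (rec.replicon, rec.strand), []
        )
        if rec.strand == "+":
            has_promoter = any(p5 - window <= a <= p5 for a in anchors)
        else:
            has_promoter = any(p5 <= a <= p5 + window for a in anchors)
        if not has_promoter:
            reasons.append("no_promoter_or_processing_site")
        if any(
            g.replicon == rec.replicon
            and g.strand == rec.strand
            and g.start <= rec.start
            and rec.end <= g.end
            for g in genes
        ):
            reasons.append("overlaps_mrna")
        if any(
            t.replicon == rec.replicon and t.start <= rec.start and rec.end <= t.end
            for t in terminators
        ):
            reasons.append("within_terminator")
        if cis_elements is not None and any(
            rep == rec.replicon and s <= rec.end and rec.start <= e
            for rep, s, e in cis_elements
        ):
            reasons.append("cis_regulatory_overlap")
        if coverage is not None:
            cov = coverage.coverage(rec.replicon, rec.strand, library).astype(float)
            inside = cov[rec.start - 1 : rec.end].mean()
            left = cov[max(0, rec.start - 1 - window) : rec.start - 1]
            right = cov[rec.end : rec.end + window]
            flank = np.mean([x.mean() for x in (left, right) if x.size])
            if inside < coverage_fold * (flank + 1e-9):
                reasons.append("no_coverage_change")
        if not (length_range[0] <= rec.length <= length_range[1]):
            reasons.append("length_out_of_range")
        else:
            # folding is only meaningful (and affordable) at sRNA lengths
            seq = genome.replicons[rec.replicon][rec.start - 1 : rec.end]
            if rec.strand == "-":
                from .synthetic import revcomp

                seq = revcomp(seq)
            energy, norm = folding_energy(seq)
            rec.folding_energy = energy
            rec.normalized_folding_energy = norm
            if norm >= folding_threshold:
                reasons.append("unstable_structure")
        rec.rejection_reasons = reasons
        (rejected if reasons else accepted).append(rec)
    return accepted, rejected


# ---------------------------------------------------------------------------
# Antisense RNA / target co-expression
# ---------------------------------------------------------------------------

def pair_asrna_with_targets(
    asrna_records: list[SRNARecord],
    operons: list[Operon],
    genes: list[Gene],
    expression: ExpressionMatrix,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Correlate each antisense RNA with its cognate operon's expression.

    Returns one row per (asRNA, overlapping opposite-strand operon) pair:
    the Pearson r between the asRNA's z-scored CPM profile and the mean
    member-gene z-profile, labelled anti-correlated (r < -threshold),
    correlated (r > threshold) or neutral. Zero-variance profiles are
    reported neutral with a flag; pairs absent from the matrix are skipped
    with a note."""
    cpm = expression.cpm()
    gene_index = {g.id: g for g in genes}
    rows = []
    for rec in asrna_records:
        if rec.id not in cpm.index:
            rows.append({"asrna": rec.id, "operon": None, "r": np.nan,
                         "label": "skipped", "note": "asRNA absent from matrix"})
            continue
        for op in operons:
            members = [gene_index[g] for g in op.gene_ids if g in gene_index]
            if not members or op.replicon != rec.replicon or op.strand == rec.strand:
                continue
            lo = min(g.start for g in members)
            hi = max(g.end for g in members)
            if not (lo <= rec.end and rec.start <= hi):
                continue
            present = [g.id for g in members if g.id in cpm.index]
            if not present:
                rows.append({"asrna": rec.id, "operon": op.id, "r": np.nan,
                             "label": "skipped", "note": "operon absent from matrix"})
                continue
            a = _zscore(cpm.loc[rec.id].to_numpy(float))
            b = _zscore(cpm.loc[present].to_numpy(float).mean(axis=0))
            if a is None or b is None:
                rows.append({"asrna": rec.id, "operon": op.id, "r": np.nan,
                             "label": "neutral", "note": "zero-variance profile"})
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            label = (
                "anti-correlated" if r < -threshold
                else "correlated" if r > threshold
                else "neutral"
            )
            rows.append({"asrna": rec.id, "operon": op.id, "r": r, "label": label, "note": ""})
    return pd.DataFrame(rows, columns=["asrna", "operon", "r", "label", "note"])


def _zscore(x: np.ndarray):
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd
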