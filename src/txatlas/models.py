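"""Shared in-memory containers for the pipeline.

Coordinate convention: 1-based, inclusive on both ends (GFF3-native)
everywhere in memory. BED/bedGraph files are converted at the I/O boundary.
Strand is ``"+"`` or ``"-"``. Position ``p`` of a replicon maps to index
``p - 1`` of the dense per-replicon vectors held by :class:`CoverageSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
TEX_PLUS = "TEX+"
TEX_MINUS = "TEX-"
LIBRARIES = (TEX_PLUS, TEX_MINUS)


@dataclass
class Gene:
    """A gene feature with 1-based inclusive coordinates."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    biotype: str = "CDS"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.id}: invalid strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.id}: invalid interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class GenomeBundle:
    """Replicon sequences plus gene annotation."""

    replicons: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            if g.replicon not in self.replicons:
                raise ValueError(f"gene {g.id} on undeclared replicon {g.replicon}")
            if g.end > len(self.replicons[g.replicon]):
                raise ValueError(f"gene {g.id} extends past replicon end")

    @property
    def replicon_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.replicons.items()}

    def genes_on(self, replicon: str, strand: str | None = None) -> list[Gene]:
        out = [g for g in self.genes if g.replicon == replicon]
        if strand is not None:
            out = [g for g in out if g.strand == strand]
        return sorted(out, key=lambda g: g.start)


class CoverageSet:
    """Dense per-position 5'-start counts and full read coverage.

    One integer vector per (replicon, strand, library) for each of the two
    track kinds. Libraries are the exonuclease-treated (``TEX+``) and
    untreated (``TEX-``) dRNA-seq libraries.
    """

    def __init__(self, replicon_lengths: dict[str, int]):
        self.replicon_lengths = dict(replicon_lengths)
        self._starts: dict[tuple[str, str, str], np.ndarray] = {}
        self._cov: dict[tuple[str, str, str], np.ndarray] = {}
        for rep, n in self.replicon_lengths.items():
            for strand in STRANDS:
                for lib in LIBRARIES:
                    self._starts[(rep, strand, lib)] = np.zeros(n, dtype=np.int64)
                    self._cov[(rep, strand, lib)] = np.zeros(n, dtype=np.int64)

    def _check(self, replicon: str, strand: str, library: str) -> tuple[str, str, str]:
        key = (replicon, strand, library)
        if key not in self._starts:
            raise KeyError(f"no track for {key}")
        return key

    def starts(self, replicon: str, strand: str, library: str) -> np.ndarray:
        return self._starts[self._check(replicon, strand, library)]

    def coverage(self, replicon: str, strand: str, library: str) -> np.ndarray:
        return self._cov[self._check(replicon, strand, library)]

    def set_starts(self, replicon: str, strand: str, library: str, values: np.ndarray) -> None:
        key = self._check(replicon, strand, library)
        values = np.asarray(values, dtype=np.int64)
        if values.shape != self._starts[key].shape:
            raise ValueError("vector length must equal replicon length")
        if (values < 0).any():
            raise ValueError("coverage values must be non-negative")
        self._starts[key] = values

    def set_coverage(self, replicon: str, strand: str, library: str, values: np.ndarray) -> None:
        key = self._check(replicon, strand, library)
        values = np.asarray(values, dtype=np.int64)
        if values.shape != self._cov[key].shape:
            raise ValueError("vector length must equal replicon length")
        if (values < 0).any():
            raise ValueError("coverage values must be non-negative")
        self._cov[key] = values

    def items(self):
        return list(self._starts.keys())


@dataclass
class TSSRecord:
    replicon: str
    position: int
    strand: str
    tex_plus_height: int
    tex_minus_height: int
    enrichment: float
    # class name -> gene id (orphan maps to None)
    classes: dict[str, object] = field(default_factory=dict)
    # per-gene assignments, e.g. [("primary", "g1"), ("antisense", "g2")]
    assignments: list[tuple[str, str | None]] = field(default_factory=list)

    @property
    def class_names(self) -> set[str]:
        return {c for c, _ in self.assignments} or set(self.classes)

    @property
    def is_orphan(self) -> bool:
        return self.class_names == {"orphan"}


@dataclass
class TerminatorRecord:
    replicon: str
    start: int
    end: int
    strand: str
    method: str  # "hairpin" | "coverage_drop"
    score: float
    u_tail_length: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("terminator score must be finite")


@dataclass
class Operon:
    id: str
    replicon: str
    strand: str
    gene_ids: list[str]  # in transcription order
    lead_tss: int | None = None  # TSS position
    terminator: tuple[int, int] | None = None
    sub_operons: list[tuple[int, list[str]]] = field(default_factory=list)


@dataclass
class SRNARecord:
    id: str
    replicon: str
    start: int
    end: int
    strand: str
    srna_class: str | None = None
    tss_support: int | None = None  # TSS position, or None
    processing_support: int | None = None
    folding_energy: float = 0.0
    normalized_folding_energy: float = 0.0
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def accepted(self) -> bool:
        return not self.rejection_reasons


@dataclass
class InvertedRepeat:
    replicon: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int
    gc_fraction: float = 0.0
    homopolymeric: bool = False
    promoter_flag: bool = False
    supporting_tss: list[int] = field(default_factory=list)

    @property
    def arm_length(self) -> int:
        return self.left_end - self.left_start + 1

    @property
    def spacer_length(self) -> int:
        return self.right_start - self.left_end - 1

    def key(self) -> tuple[int, int, int, int]:
        return (self.left_start, self.left_end, self.right_start, self.right_end)


class ExpressionMatrix:
    """Gene x sample counts with a sample -> condition map.

    CPM(g, s) = counts(g, s) / library_size(s) * 1e6; library sizes default
    to column sums.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        condition_map: dict[str, str],
        library_sizes: dict[str, float] | None = None,
    ):
        counts = counts.copy()
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in condition_map]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")
        self.counts = counts
        self.condition_map = dict(condition_map)
        if library_sizes is None:
            library_sizes = counts.sum(axis=0).astype(float).to_dict()
        self.library_sizes = {s: float(library_sizes[s]) for s in counts.columns}
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        self.provenance: dict = {}

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.condition_map[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_map[s] == condition]

    def cpm(self) -> pd.DataFrame:
        libs = pd.Series(self.library_sizes)[self.counts.columns]
        return self.counts / libs * 1e6

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        m = ExpressionMatrix(
            self.counts.loc[list(genes)], self.condition_map, self.library_sizes
        )
        m.provenance = dict(self.provenance)
        return m


@dataclass
class FitnessEntry:
    srna: str
    experiment: str
    fit: float
    t: float
    success: bool = True


class FitnessTable:
    """Per-(sRNA, experiment) mutant fitness (fit) and t statistic."""

    def __init__(self, entries: list[FitnessEntry]):
        for e in entries:
            if e.success and not np.isfinite(e.t):
                raise ValueError(f"non-finite t for successful entry {e.srna}/{e.experiment}")
        self.entries = list(entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "srna": e.srna,
                    "experiment": e.experiment,
                    "fit": e.fit,
                    "t": e.t,
                    "success": e.success,
                }
                for e in self.entries
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FitnessTable":
        required = {"srna", "experiment", "fit", "t", "success"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"fitness table missing columns: {sorted(missing)}")
        entries = [
            FitnessEntry(
                srna=str(r.srna),
                experiment=str(r.experiment),
                fit=float(r.fit),
                t=float(r.t),
                success=bool(r.success),
            )
            for r in df.itertuples()
        ]
        return cls(entries)
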