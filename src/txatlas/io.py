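"""Readers and writers for the standard formats the pipeline touches.

All in-memory coordinates are 1-based inclusive; BED and bedGraph use their
native 0-based half-open convention on disk and are converted here, at the
single I/O boundary.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    LIBRARIES,
    STRANDS,
    CoverageSet,
    FitnessTable,
    Gene,
    GenomeBundle,
    ExpressionMatrix,
)

IUPAC_DNA = set("ACGTURYSWKMBDHVN")


class ParseError(ValueError):
    """Malformed input; carries the file and, where known, the line number."""

    def __init__(self, path, message, line: int | None = None):
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> upper-case sequence map.

    Rejects duplicate headers and non-IUPAC characters with the offending
    line number. Lower-case input is upper-cased.
    """
    replicons: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    replicons[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(path, "empty FASTA header", lineno)
                if name in replicons:
                    raise ParseError(path, f"duplicate FASTA header {name!r}", lineno)
                chunks = []
            else:
                if name is None:
                    raise ParseError(path, "sequence before first header", lineno)
                seq = line.upper()
                bad = set(seq) - IUPAC_DNA
                if bad:
                    raise ParseError(
                        path, f"non-IUPAC characters {sorted(bad)}", lineno
                    )
                chunks.append(seq)
    if name is not None:
        replicons[name] = "".join(chunks)
    return replicons


def write_fasta(replicons: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in replicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path, replicon_lengths: dict[str, int] | None = None) -> list[Gene]:
    """Read gene-like features from a GFF3 file (1-based inclusive)."""
    genes: list[Gene] = []
    saw_pragma = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if lineno == 1 and line.startswith("##gff-version"):
                saw_pragma = True
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, f"expected 9 columns, got {len(fields)}", lineno)
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, "non-integer coordinates", lineno) from None
            if end < start:
                raise ParseError(path, f"end {end} < start {start}", lineno)
            if strand not in STRANDS:
                raise ParseError(path, f"invalid strand {strand!r}", lineno)
            if replicon_lengths is not None:
                if seqid not in replicon_lengths:
                    raise ParseError(path, f"feature on undeclared replicon {seqid!r}", lineno)
                if end > replicon_lengths[seqid]:
                    raise ParseError(path, f"feature extends past end of {seqid!r}", lineno)
            attrs = _parse_gff_attributes(attr_s)
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ParseError(path, "feature without ID or Name attribute", lineno)
            genes.append(Gene(id=gid, replicon=seqid, start=start, end=end, strand=strand, biotype=ftype))
    if not saw_pragma:
        raise ParseError(path, "missing ##gff-version pragma", 1)
    return genes


def write_gff3(features: list[Gene], path, source: str = "txatlas", extra_attrs=None) -> None:
    """Write features as GFF3. ``extra_attrs`` maps feature id -> dict."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = {"ID": f.id, "Name": f.id}
            attrs.update(extra_attrs.get(f.id, {}))
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{f.replicon}\t{source}\t{f.biotype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------

def _read_bedgraph_vector(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    vectors = {rep: np.zeros(n, dtype=np.int64) for rep, n in lengths.items()}
    filled = {rep: np.zeros(n, dtype=bool) for rep, n in lengths.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(path, "expected 4 bedGraph columns", lineno)
            rep, start_s, end_s, val_s = fields
            if rep not in lengths:
                raise ParseError(path, f"interval on undeclared replicon {rep!r}", lineno)
            start, end = int(start_s), int(end_s)  # 0-based half-open on disk
            value = int(float(val_s))
            if start < 0 or end > lengths[rep] or end <= start:
                raise ParseError(path, f"interval [{start},{end}) out of bounds", lineno)
            if value < 0:
                raise ParseError(path, "negative coverage value", lineno)
            if filled[rep][start:end].any():
                raise ParseError(path, "overlapping intervals are ambiguous", lineno)
            vectors[rep][start:end] = value
            filled[rep][start:end] = True
    return vectors


def _bedgraph_name(library: str, strand: str, kind: str) -> str:
    lib = "texplus" if library == "TEX+" else "texminus"
    st = "fwd" if strand == "+" else "rev"
    return f"{lib}_{st}_{kind}.bedgraph"


def write_bedgraph(coverage: CoverageSet, outdir) -> list[Path]:
    """One file per (library, strand, track kind); track line encodes all three."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for lib in LIBRARIES:
        for strand in STRANDS:
            for kind, getter in (("starts", coverage.starts), ("coverage", coverage.coverage)):
                path = outdir / _bedgraph_name(lib, strand, kind)
                with open(path, "w") as fh:
                    fh.write(f'track type=bedGraph name="{lib} {strand} {kind}"\n')
                    for rep, n in coverage.replicon_lengths.items():
                        vec = getter(rep, strand, lib)
                        # run-length encode
                        change = np.flatnonzero(np.diff(vec)) + 1
                        bounds = np.concatenate(([0], change, [n]))
                        for a, b in zip(bounds[:-1], bounds[1:]):
                            v = int(vec[a])
                            if v != 0:
                                fh.write(f"{rep}\t{a}\t{b}\t{v}\n")
                written.append(path)
    return written


def read_bedgraph(indir, replicon_lengths: dict[str, int]) -> CoverageSet:
    """Read the bedGraph bundle written by :func:`write_bedgraph`."""
    indir = Path(indir)
    cov = CoverageSet(replicon_lengths)
    for lib in LIBRARIES:
        for strand in STRANDS:
            for kind in ("starts", "coverage"):
                path = indir / _bedgraph_name(lib, strand, kind)
                if not path.exists():
                    raise FileNotFoundError(f"missing coverage track {path}")
                vectors = _read_bedgraph_vector(path, replicon_lengths)
                for rep, vec in vectors.items():
                    if kind == "starts":
                        cov.set_starts(rep, strand, lib, vec)
                    else:
                        cov.set_coverage(rep, strand, lib, vec)
    return cov


# ---------------------------------------------------------------------------
# GMT gene sets, count matrices, fitness tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into set name -> member list.

    Duplicate members within a set are de-duplicated preserving order; a
    set name appearing twice is an error (ambiguous definition).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, "GMT line needs set, description, >=1 member", lineno)
            name, _desc, *members = fields
            if not name:
                raise ParseError(path, "empty gene-set name", lineno)
            if name in sets:
                raise ParseError(path, f"gene set {name!r} defined twice", lineno)
            seen: list[str] = []
            for m in members:
                if m and m not in seen:
                    seen.append(m)
            sets[name] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_counts_tsv(path) -> ExpressionMatrix:
    """Read a gene x sample count TSV whose header row carries
    ``sample:condition`` column labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    condition_map: dict[str, str] = {}
    rename: dict[str, str] = {}
    for col in df.columns:
        if ":" not in col:
            raise ParseError(path, f"column {col!r} lacks a sample:condition label")
        sample, condition = col.split(":", 1)
        rename[col] = sample
        condition_map[sample] = condition
    df = df.rename(columns=rename)
    return ExpressionMatrix(df.astype(np.int64), condition_map)


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.counts.copy()
    df.columns = [f"{s}:{matrix.condition_map[s]}" for s in matrix.samples]
    df.to_csv(path, sep="\t")


def read_fitness_tsv(path) -> FitnessTable:
    df = pd.read_csv(path, sep="\t")
    try:
        return FitnessTable.from_frame(df)
    except ValueError as exc:
        raise ParseError(path, str(exc)) from None


def write_fitness_tsv(table: FitnessTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_inverted_repeats_bed(hits, path) -> None:
    """BED6 with blocked (BED12-style) notation: one record per arm pair."""
    with open(path, "w") as fh:
        for i, ir in enumerate(hits):
            chrom_start = ir.left_start - 1
            chrom_end = ir.right_end
            name = f"IR{i + 1:04d}"
            block_sizes = f"{ir.arm_length},{ir.arm_length}"
            block_starts = f"0,{ir.right_start - ir.left_start}"
            fh.write(
                "\t".join(
                    [
                        ir.replicon,
                        str(chrom_start),
                        str(chrom_end),
                        name,
                        str(ir.mismatches),
                        "+",
                        str(chrom_start),
                        str(chrom_end),
                        "0,0,0",
                        "2",
                        block_sizes,
                        block_starts,
                    ]
                )
                + "\n"
            )
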