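"""Stage orchestration: configuration, the end-to-end run, and the demo
dataset writer.

A run reads the configured inputs, executes the annotation cascade (and,
when counts / gene sets / fitness tables are configured, the expression and
integration stages), writes every output with a checksum, and records a
manifest with versions, parameters and seeds. Reruns with the same
configuration are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, evaluate, expression as expr, integrate, io as tio
from .demo import build_demo
from .models import Gene

_STAGE_KEYS = {"tss", "terminator", "srna", "inverton", "expression", "integrate"}


@dataclass
class PipelineConfig:
    genome_fasta: str | None = None
    genes_gff: str | None = None
    coverage_dir: str | None = None
    counts_tsv: str | None = None
    gene_sets_gmt: str | None = None
    fitness_tsv: str | None = None
    outdir: str = "txatlas_out"
    seed: int = 0
    control_condition: str | None = None
    scan_hairpins: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - _STAGE_KEYS
        if unknown:
            raise ValueError(f"unknown parameter blocks: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_feature_gff(path: Path, rows: list[tuple[Gene, dict]]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feature, attrs in rows:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{feature.replicon}\ttxatlas\t{feature.biotype}\t{feature.start}\t"
                f"{feature.end}\t.\t{feature.strand}\t.\t{attr_s}\n"
            )


def run(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "outputs": {},
        "counts": {},
    }
    try:
        written = _run_stages(config, outdir, manifest)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    written: list[Path] = []
    if not config.genome_fasta or not config.genes_gff or not config.coverage_dir:
        raise FileNotFoundError("run() needs genome_fasta, genes_gff and coverage_dir")
    for key in ("genome_fasta", "genes_gff", "counts_tsv", "gene_sets_gmt", "fitness_tsv"):
        value = getattr(config, key)
        if value:
            if not Path(value).exists():
                raise FileNotFoundError(f"{key}: no such file {value}")
            manifest["inputs"][key] = {"path": value, "sha256": _sha256(Path(value))}

    replicons = tio.read_fasta(config.genome_fasta)
    genes = tio.read_gff3(config.genes_gff, {n: len(s) for n, s in replicons.items()})
    from .models import GenomeBundle

    genome = GenomeBundle(replicons=replicons, genes=genes)
    coverage = tio.read_bedgraph(config.coverage_dir, genome.replicon_lengths)

    result = evaluate.annotate_genome(
        genome, coverage,
        ir_params=config.params.get("inverton"),
        scan_hairpins=config.scan_hairpins,
    )
    manifest["counts"].update(result.counts())

    # --- annotation outputs -------------------------------------------------
    tss_rows = [
        (
            Gene(f"TSS{i + 1:05d}", r.replicon, r.position, r.position, r.strand, "TSS"),
            {
                "ID": f"TSS{i + 1:05d}",
                "class": ",".join(sorted(r.class_names)),
                "gene": ",".join(str(g) for _, g in r.assignments if g),
                "enrichment": f"{r.enrichment:.3f}",
            },
        )
        for i, r in enumerate(result.tss_records)
    ]
    terms = result.drop_terminators + result.hairpin_terminators
    term_rows = [
        (
            Gene(f"TERM{i + 1:05d}", t.replicon, t.start, t.end, t.strand, "terminator"),
            {"ID": f"TERM{i + 1:05d}", "method": t.method, "score": f"{t.score:.3f}"},
        )
        for i, t in enumerate(terms)
    ]
    operon_rows = []
    gene_index = {g.id: g for g in genes}
    for op in result.operons:
        members = [gene_index[g] for g in op.gene_ids]
        lo = min(g.start for g in members)
        hi = max(g.end for g in members)
        operon_rows.append(
            (
                Gene(op.id, op.replicon, lo, hi, op.strand, "operon"),
                {"ID": op.id, "genes": ",".join(op.gene_ids),
                 "n_sub_operons": len(op.sub_operons)},
            )
        )
    srna_rows = [
        (
            Gene(s.id, s.replicon, s.start, s.end, s.strand, "ncRNA"),
            {"ID": s.id, "class": s.srna_class or "NA",
             "normalized_folding_energy": f"{s.normalized_folding_energy:.4f}"},
        )
        for s in result.srnas_accepted
    ]
    for name, rows in (
        ("tss.gff3", tss_rows),
        ("terminators.gff3", term_rows),
        ("operons.gff3", operon_rows),
        ("ncrnas.gff3", srna_rows),
    ):
        path = outdir / name
        _write_feature_gff(path, rows)
        written.append(path)

    rejected = pd.DataFrame(
        [
            {"id": s.id, "replicon": s.replicon, "start": s.start, "end": s.end,
             "strand": s.strand, "reasons": ";".join(s.rejection_reasons)}
            for s in result.srnas_rejected
        ]
    )
    path = outdir / "srna_rejections.tsv"
    rejected.to_csv(path, sep="\t", index=False)
    written.append(path)

    tio.write_inverted_repeats_bed(result.inverted_repeats, outdir / "inverted_repeats.bed")
    written.append(outdir / "inverted_repeats.bed")
    ir_table = pd.DataFrame(
        [
            {
                "replicon": h.replicon, "left_start": h.left_start, "left_end": h.left_end,
                "right_start": h.right_start, "right_end": h.right_end,
                "arm_length": h.arm_length, "mismatches": h.mismatches,
                "spacer_length": h.spacer_length, "gc_fraction": round(h.gc_fraction, 4),
                "promoter_flag": h.promoter_flag,
                "supporting_tss": ",".join(map(str, h.supporting_tss)),
            }
            for h in result.inverted_repeats
        ]
    )
    ir_table.to_csv(outdir / "inverted_repeats.tsv", sep="\t", index=False)
    written.append(outdir / "inverted_repeats.tsv")
    manifest["counts"]["n_promoter_invertons"] = int(
        sum(1 for h in result.inverted_repeats if h.promoter_flag)
    )

    # --- expression stage ---------------------------------------------------
    if config.counts_tsv:
        matrix = tio.read_counts_tsv(config.counts_tsv)
        retained = expr.filter_expressed(matrix)
        manifest["counts"]["n_expressed_genes"] = len(retained)
        filtered = matrix.subset(retained)
        control = config.control_condition or matrix.conditions[0]
        de_tables = {}
        for cond in matrix.conditions:
            if cond == control:
                continue
            de = expr.nb_de_test(filtered, (cond, control))
            de_tables[cond] = de
            out = de.table.assign(call=expr.significant_de(de))
            path = outdir / f"de_{cond}_vs_{control}.tsv"
            out.to_csv(path, sep="\t")
            written.append(path)
        if config.gene_sets_gmt and de_tables:
            sets = tio.read_gmt(config.gene_sets_gmt)
            gsea_params = config.params.get("expression", {})
            for cond, de in de_tables.items():
                ranking = expr.rank_metric(de)
                enr = expr.preranked_gsea(
                    ranking, sets, seed=config.seed,
                    n_perm=int(gsea_params.get("n_perm", 1000)),
                    exempt_sets=gsea_params.get("exempt_sets"),
                )
                path = outdir / f"gsea_{cond}_vs_{control}.tsv"
                enr.table.to_csv(path, sep="\t")
                written.append(path)

    # --- integration stage --------------------------------------------------
    if config.fitness_tsv:
        table = tio.read_fitness_tsv(config.fitness_tsv)
        calls, summary = integrate.categorize_fitness(table)
        ranked = integrate.prioritize_srnas(summary)
        calls.to_csv(outdir / "fitness_calls.tsv", sep="\t", index=False)
        ranked.to_csv(outdir / "fitness_ranked.tsv", sep="\t")
        written += [outdir / "fitness_calls.tsv", outdir / "fitness_ranked.tsv"]
        manifest["counts"]["n_significant_srnas"] = int(summary["any_significant"].sum())
    return written


def make_demo(seed: int, outdir) -> dict:
    """Write the self-contained synthetic demo bundle plus a digest file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = build_demo(seed)
    tio.write_fasta(bundle.genome.replicons, outdir / "genome.fasta")
    tio.write_gff3(bundle.genome.genes, outdir / "genes.gff3")
    tio.write_bedgraph(bundle.coverage, outdir / "coverage")
    tio.write_counts_tsv(bundle.matrix, outdir / "counts.tsv")
    tio.write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    tio.write_fitness_tsv(bundle.fitness, outdir / "fitness.tsv")

    truth = {
        "seed": seed,
        "params": bundle.params,
        "tss": [[t.replicon, t.position, t.strand, t.label] for t in bundle.truth.planted_tss],
        "terminators": list(bundle.truth.planted_terminators),
        "srnas": [
            [s.replicon, s.start, s.end, s.strand, s.srna_class]
            for s in bundle.truth.planted_srnas
        ],
        "inverted_repeats": [
            [p.replicon, p.left_start, p.left_end, p.right_start, p.right_end,
             p.mismatches, p.homopolymeric]
            for p in bundle.truth.planted_irs
        ],
        "operons": bundle.truth.planted_operons,
        "fitness_hits": bundle.fitness_truth.planted_fitness_hits,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))

    digests = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "digests.json":
            digests[str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "digests.json").write_text(json.dumps(digests, indent=2))
    return digests
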