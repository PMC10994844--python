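"""A self-contained synthetic demo dataset exercising every pipeline stage.

The demo genome is 50 kb with 20 genes arranged into 14 transcription units
(two 3-gene and two 2-gene operons plus ten singletons), 40 planted TSSs
(unit leads, sRNA starts, secondary, internal, antisense and orphan sites),
10 intrinsic terminators, 12 sRNAs spanning four classes (intergenic,
antisense, 5'-UTR- and 3'-UTR-derived) and 8 detectable inverted repeats
plus two filter decoys. A count matrix, gene sets and a fitness table with
5 planted hits accompany the genome. Everything derives from one seed.

Intra-operonic sRNAs are not planted here: recovering one requires an
expressed multi-gene operon whose internal segment boundaries survive
coverage noise, which makes the truth ill-defined at this scale; the class
logic is exercised on constructed geometries in the unit tests instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import CoverageSet, ExpressionMatrix, FitnessTable, Gene, GenomeBundle
from .synthetic import (
    PlantedIR,
    PlantedSRNA,
    PlantedTSS,
    PlantedTranscript,
    TruthSet,
    plant_inverted_repeats,
    random_sequence,
    simulate_counts,
    simulate_drnaseq_coverage,
    simulate_fitness_table,
)

REPLICON = "replicon1"
GENOME_LENGTH = 50_000
UNIT_SIZES = [3, 3, 2, 2] + [1] * 10
BASE_INTER_GAP = 800
EDGE_RESERVE_5P = 200   # room upstream of a unit for its (utr5) lead TSS
EDGE_RESERVE_3P = 320   # room downstream for terminator + readthrough

DEMO_COVERAGE_PARAMS = dict(
    enrichment_factor=10.0, tss_height=100.0, noise_rate=0.1, terminator_drop=0.95
)

IR_SPECS = [
    (12, 0, 60, False),
    (11, 0, 40, False),
    (15, 1, 80, False),
    (13, 1, 100, False),
    (18, 1, 50, False),
    (20, 2, 70, False),
    (22, 2, 120, False),
    (25, 2, 90, False),
    (15, 0, 60, True),   # homopolymer-filter decoy
    (14, 0, 50, True),   # homopolymer-filter decoy
]


class _GapAllocator:
    """Hands out non-overlapping sub-intervals of the inter-unit gaps."""

    def __init__(self, rng: np.random.Generator, zones: list[tuple[int, int]]):
        self.rng = rng
        self.zones = [z for z in zones if z[1] >= z[0]]

    def take(self, length: int, margin: int) -> tuple[int, int]:
        need = length + 2 * margin
        fits = [i for i, (s, e) in enumerate(self.zones) if e - s + 1 >= need]
        if not fits:
            raise RuntimeError(f"demo layout: no room for a {length}-bp feature")
        i = fits[int(self.rng.integers(0, len(fits)))]
        s, e = self.zones[i]
        offset = int(self.rng.integers(s + margin, e - margin - length + 2))
        self.zones[i : i + 1] = [
            z for z in [(s, offset - margin - 1), (offset + length + margin, e)] if z[1] >= z[0]
        ]
        return offset, offset + length - 1


@dataclass
class DemoBundle:
    genome: GenomeBundle
    truth: TruthSet
    coverage: CoverageSet
    matrix: ExpressionMatrix
    counts_truth: TruthSet
    gene_sets: dict[str, list[str]]
    exempt_sets: list[str]
    fitness: FitnessTable
    fitness_truth: TruthSet
    params: dict = field(default_factory=dict)


def build_demo(seed: int) -> DemoBundle:
    rng = np.random.default_rng(seed)
    truth = TruthSet(seed=seed)

    # ---- layout: units along the genome ------------------------------------
    unit_sizes = list(UNIT_SIZES)
    rng.shuffle(unit_sizes)
    gene_lengths = [
        [int(rng.integers(750, 951)) for _ in range(k)] for k in unit_sizes
    ]
    intra_gaps = [[int(rng.integers(60, 201)) for _ in range(k - 1)] for k in unit_sizes]
    spans = [sum(gl) + sum(ig) for gl, ig in zip(gene_lengths, intra_gaps)]
    n_units = len(unit_sizes)
    needed = sum(spans) + (n_units + 1) * BASE_INTER_GAP
    slack = GENOME_LENGTH - needed
    if slack < 0:
        raise RuntimeError("demo layout does not fit the genome length")
    cuts = np.sort(rng.integers(0, slack + 1, size=n_units))
    extra = np.diff(np.concatenate(([0], cuts, [slack])))
    gaps = [BASE_INTER_GAP + int(x) for x in extra]

    genome = GenomeBundle(replicons={REPLICON: random_sequence(rng, GENOME_LENGTH)})
    genes: list[Gene] = []
    units: list[dict] = []
    pos = 1
    gid = 0
    for u in range(n_units):
        pos += gaps[u]
        strand = "+" if rng.random() < 0.5 else "-"
        member_ids = []
        gstart = pos
        for j, gl in enumerate(gene_lengths[u]):
            gid += 1
            g = Gene(
                id=f"gene{gid:04d}", replicon=REPLICON, start=pos, end=pos + gl - 1,
                strand=strand,
            )
            genes.append(g)
            member_ids.append(g.id)
            pos += gl
            if j < len(intra_gaps[u]):
                pos += intra_gaps[u][j]
        units.append(
            {
                "genes": member_ids,
                "strand": strand,
                "start": gstart,
                "end": pos - 1,
                "size": unit_sizes[u],
            }
        )
    genome = GenomeBundle(replicons=genome.replicons, genes=genes)
    gene_by_id = {g.id: g for g in genes}
    for u in units:
        order = u["genes"] if u["strand"] == "+" else list(reversed(u["genes"]))
        truth.planted_operons.append(order)

    # ---- roles -------------------------------------------------------------
    singles = [u for u in units if u["size"] == 1]
    multis = [u for u in units if u["size"] > 1]
    rng.shuffle(singles)
    utr5_hosts = singles[0:2]
    utr3_hosts = singles[2:4]
    plain_terminated = singles[4:6]
    terminated_units = multis + utr5_hosts + utr3_hosts + plain_terminated

    def transcription_ends(u):
        """(5'-most gene boundary, 3'-most gene boundary) in genome coords."""
        if u["strand"] == "+":
            return u["start"], u["end"]
        return u["end"], u["start"]

    # ---- unit transcripts, lead TSSs, terminators --------------------------
    for u in units:
        strand = u["strand"]
        sgn = 1 if strand == "+" else -1
        p5_gene, p3_gene = transcription_ends(u)
        h1 = int(rng.integers(40, 51)) if u in utr3_hosts else int(rng.integers(40, 71))
        u["height"] = h1
        terminated = u in terminated_units
        if u in utr5_hosts:
            tss = p5_gene - sgn * 130
        else:
            tss = p5_gene - sgn * 25
        if terminated:
            t_end = p3_gene + sgn * (150 if u in utr3_hosts else int(rng.integers(20, 61)))
            truth.planted_terminators.append((REPLICON, t_end, strand))
        else:
            t_end = p3_gene + sgn * 10
        u["tss"] = tss
        u["t_end"] = t_end
        lo, hi = sorted((tss, t_end))
        truth.planted_tss.append(PlantedTSS(REPLICON, tss, strand, label="unit_lead"))
        truth.transcripts.append(
            PlantedTranscript(REPLICON, lo, hi, strand, float(h1), terminated=terminated)
        )
        if u in utr5_hosts:
            # stable 5'-UTR fragment sharing the mRNA's TSS
            s_end = p5_gene - sgn * 8
            proc = p5_gene - sgn * 7
            lo_s, hi_s = sorted((tss, s_end))
            truth.planted_srnas.append(PlantedSRNA(REPLICON, lo_s, hi_s, strand, "utr5_derived"))
            truth.planted_processing_sites.append((REPLICON, proc, strand))
            truth.transcripts.append(
                PlantedTranscript(REPLICON, lo_s, hi_s, strand, 4.0 * h1, terminated=False)
            )
        if u in utr3_hosts:
            s_start = p3_gene + sgn * 10
            lo_s, hi_s = sorted((s_start, t_end))
            truth.planted_srnas.append(PlantedSRNA(REPLICON, lo_s, hi_s, strand, "utr3_derived"))
            truth.planted_tss.append(PlantedTSS(REPLICON, s_start, strand, label="utr3_srna"))
            truth.transcripts.append(
                PlantedTranscript(REPLICON, lo_s, hi_s, strand, 4.0 * h1, terminated=False)
            )

    # ---- secondary / internal / antisense-only TSSs ------------------------
    for u in multis:
        sgn = 1 if u["strand"] == "+" else -1
        truth.planted_tss.append(
            PlantedTSS(
                REPLICON, u["tss"] - sgn * 55, u["strand"],
                height_scale=0.6, enrich_scale=0.5, label="secondary",
            )
        )
    internal_hosts = [u["genes"][0] for u in multis]
    for gid_ in internal_hosts:
        g = gene_by_id[gid_]
        truth.planted_tss.append(
            PlantedTSS(
                REPLICON, (g.start + g.end) // 2, g.strand,
                height_scale=0.5, label="internal",
            )
        )
    anti_tss_hosts = [u["genes"][-1] for u in multis[:3]]
    for gid_ in anti_tss_hosts:
        g = gene_by_id[gid_]
        strand = "-" if g.strand == "+" else "+"
        truth.planted_tss.append(
            PlantedTSS(REPLICON, g.start + 2 * g.length // 3, strand, label="antisense")
        )

    # ---- antisense sRNAs inside gene bodies --------------------------------
    as_hosts = [u["genes"][0] for u in multis[:2]] + [plain_terminated[0]["genes"][0]]
    for gid_ in as_hosts:
        g = gene_by_id[gid_]
        strand = "-" if g.strand == "+" else "+"
        l = int(rng.integers(100, 151))
        s = g.start + 40
        e = s + l - 1
        tss = s if strand == "+" else e
        truth.planted_srnas.append(PlantedSRNA(REPLICON, s, e, strand, "antisense"))
        truth.planted_tss.append(PlantedTSS(REPLICON, tss, strand, label="as_srna"))
        truth.transcripts.append(
            PlantedTranscript(REPLICON, s, e, strand, float(rng.integers(40, 121)))
        )

    # ---- gap allocator for free-standing features --------------------------
    zones = []
    bounds = [(u["start"], u["end"]) for u in units]
    prev_end = 0
    for (s, e) in bounds:
        lo = prev_end + 1 + EDGE_RESERVE_3P
        hi = s - 1 - EDGE_RESERVE_5P
        if hi >= lo:
            zones.append((lo, hi))
        prev_end = e
    if prev_end + 1 + EDGE_RESERVE_3P <= GENOME_LENGTH:
        zones.append((prev_end + 1 + EDGE_RESERVE_3P, GENOME_LENGTH))
    alloc = _GapAllocator(rng, zones)

    for _ in range(5):  # intergenic sRNAs
        l = int(rng.integers(90, 161))
        s, e = alloc.take(l, margin=60)
        strand = "+" if rng.random() < 0.5 else "-"
        tss = s if strand == "+" else e
        truth.planted_srnas.append(PlantedSRNA(REPLICON, s, e, strand, "intergenic"))
        truth.planted_tss.append(PlantedTSS(REPLICON, tss, strand, label="ig_srna"))
        truth.transcripts.append(
            PlantedTranscript(REPLICON, s, e, strand, float(rng.integers(40, 121)))
        )
    for _ in range(5):  # orphan TSSs
        p, _ = alloc.take(1, margin=60)
        strand = "+" if rng.random() < 0.5 else "-"
        truth.planted_tss.append(PlantedTSS(REPLICON, p, strand, label="orphan"))

    # ---- inverted repeats ---------------------------------------------------
    plant_inverted_repeats(genome, IR_SPECS, truth=truth, seed=int(rng.integers(2**31)))
    truth.validate_against(genome)

    # ---- coverage -----------------------------------------------------------
    coverage = simulate_drnaseq_coverage(
        genome, truth, seed=int(rng.integers(2**31)), **DEMO_COVERAGE_PARAMS
    )

    # ---- counts, gene sets, fitness -----------------------------------------
    filler = [f"g{i + 1:05d}" for i in range(580)]
    count_genes = [g.id for g in genes] + filler
    condition_map = {
        f"{cond}_r{r}": cond
        for cond in ["glucose", "arabinose", "mucin", "bile", "coldshock"]
        for r in (1, 2, 3)
    }
    de_up = filler[0:20]
    de_down = filler[20:40]
    planted_de = {g: 4.0 for g in de_up} | {g: -4.0 for g in de_down}
    regulons = {
        "regulonA": {"members": filler[40:55], "target_r": 0.9, "amplitude": 2.0},
    }
    matrix, counts_truth = simulate_counts(
        n_genes=len(count_genes),
        condition_map=condition_map,
        libsizes=2e6,
        dispersion=0.05,
        planted_de=planted_de,
        planted_regulons=regulons,
        seed=int(rng.integers(2**31)),
        control="glucose",
        gene_ids=count_genes,
    )
    gene_sets = {
        "regulonA": filler[40:55],
        "PUL_small": filler[60:65],  # exempt from the size filter
        "set_up": de_up[:12],
        "set_rand1": list(rng.choice(filler, 12, replace=False)),
        "set_rand2": list(rng.choice(filler, 12, replace=False)),
    }
    exempt = ["PUL_small"]
    hits = [
        (f"sRNA{i:04d}", f"exp{3 * i:04d}", -2.5, 6.0) for i in (1, 3, 5, 7, 9)
    ]
    fitness, fitness_truth = simulate_fitness_table(
        80, 100, planted_hits=hits, seed=int(rng.integers(2**31))
    )
    return DemoBundle(
        genome=genome,
        truth=truth,
        coverage=coverage,
        matrix=matrix,
        counts_truth=counts_truth,
        gene_sets=gene_sets,
        exempt_sets=exempt,
        fitness=fitness,
        fitness_truth=fitness_truth,
        params={
            "seed": seed,
            "genome_length": GENOME_LENGTH,
            **DEMO_COVERAGE_PARAMS,
            "n_tss": len(truth.planted_tss),
            "n_terminators": len(truth.planted_terminators),
            "n_srnas": len(truth.planted_srnas),
            "n_irs": sum(1 for ir in truth.planted_irs if not ir.homopolymeric),
        },
    )
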