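"""Synthetic genomes, dRNA-seq coverage, count matrices and fitness tables
with known planted truth.

Every generator takes an explicit seed (never global RNG state) and records
what it planted in a :class:`TruthSet`, so each downstream stage can be
scored against ground truth. Background noise on the coverage tracks is
Poisson; over-dispersion is modelled only in the count simulator
(negative binomial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    CoverageSet,
    ExpressionMatrix,
    FitnessEntry,
    FitnessTable,
    Gene,
    GenomeBundle,
    TEX_MINUS,
    TEX_PLUS,
)

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PlacementError(RuntimeError):
    """Raised when planted features cannot be placed without overlap."""


@dataclass
class PlantedTSS:
    replicon: str
    position: int
    strand: str
    height_scale: float = 1.0
    enrich_scale: float = 1.0
    label: str = ""

    def as_tuple(self) -> tuple[str, int, str]:
        return (self.replicon, self.position, self.strand)


@dataclass
class PlantedTranscript:
    replicon: str
    start: int
    end: int
    strand: str
    height: float
    terminated: bool = False  # coverage reads through at (1 - drop) when True


@dataclass
class PlantedSRNA:
    replicon: str
    start: int
    end: int
    strand: str
    srna_class: str


@dataclass
class PlantedIR:
    replicon: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int
    homopolymeric: bool = False

    @property
    def arm_length(self) -> int:
        return self.left_end - self.left_start + 1


@dataclass
class TruthSet:
    """Ground truth for everything a generator planted."""

    seed: int
    planted_tss: list[PlantedTSS] = field(default_factory=list)
    planted_terminators: list[tuple[str, int, str]] = field(default_factory=list)
    planted_processing_sites: list[tuple[str, int, str]] = field(default_factory=list)
    transcripts: list[PlantedTranscript] = field(default_factory=list)
    planted_srnas: list[PlantedSRNA] = field(default_factory=list)
    planted_irs: list[PlantedIR] = field(default_factory=list)
    planted_operons: list[list[str]] = field(default_factory=list)
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_regulons: dict[str, dict] = field(default_factory=dict)
    planted_fitness_hits: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def validate_against(self, genome: GenomeBundle) -> None:
        lengths = genome.replicon_lengths
        for t in self.planted_tss:
            if not 1 <= t.position <= lengths[t.replicon]:
                raise ValueError(f"planted TSS out of bounds: {t}")
        for rep, pos, _ in self.planted_terminators:
            if not 1 <= pos <= lengths[rep]:
                raise ValueError("planted terminator out of bounds")
        for s in self.planted_srnas:
            if not 1 <= s.start <= s.end <= lengths[s.replicon]:
                raise ValueError("planted sRNA out of bounds")
        for ir in self.planted_irs:
            if not 1 <= ir.left_start <= ir.right_end <= lengths[ir.replicon]:
                raise ValueError("planted inverted repeat out of bounds")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_genome(
    seed: int,
    replicon_lengths: list[int],
    n_genes: int,
    mean_gene_len: int,
    min_gap: int = 0,
) -> tuple[GenomeBundle, TruthSet]:
    """Uniform-random genome with non-overlapping genes on both strands.

    Genes are distributed across replicons proportionally to length and
    placed uniformly at random subject to non-overlap (and ``min_gap``
    spacing). Placement that cannot fit raises :class:`PlacementError`
    rather than silently truncating.
    """
    if any(l < 10 * mean_gene_len for l in replicon_lengths) and n_genes > 0:
        raise ValueError("replicon lengths must be >= 10x mean gene length")
    rng = np.random.default_rng(seed)
    replicons = {
        f"replicon{i + 1}": random_sequence(rng, l) for i, l in enumerate(replicon_lengths)
    }
    genes: list[Gene] = []
    total = sum(replicon_lengths)
    counts = [round(n_genes * l / total) for l in replicon_lengths]
    # fix rounding so the total matches
    while sum(counts) > n_genes:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_genes:
        counts[int(np.argmin(counts))] += 1
    gid = 0
    for (name, seq), k in zip(replicons.items(), counts):
        if k == 0:
            continue
        lengths = np.maximum(
            60, np.round(rng.normal(mean_gene_len, 0.2 * mean_gene_len, size=k))
        ).astype(int)
        for s, l in _place_intervals(rng, len(seq), lengths, min_gap):
            gid += 1
            genes.append(
                Gene(
                    id=f"gene{gid:04d}",
                    replicon=name,
                    start=int(s),
                    end=int(s + l - 1),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    truth = TruthSet(seed=seed)
    return GenomeBundle(replicons=replicons, genes=genes), truth


def _place_intervals(
    rng: np.random.Generator, total_len: int, lengths: np.ndarray, min_gap: int
) -> list[tuple[int, int]]:
    """Uniform non-overlapping placement via a random partition of the slack.

    Returns ``(start, length)`` pairs in genome order (1-based starts).
    """
    n = len(lengths)
    lengths = [int(l) for l in rng.permutation(lengths)]
    slack = total_len - sum(lengths) - (n + 1) * min_gap
    if slack < 0:
        raise PlacementError(
            f"cannot place genes: {n} intervals of total {sum(lengths)} bp "
            f"do not fit in {total_len} bp with min_gap={min_gap}"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    gaps = np.diff(np.concatenate(([0], cuts, [slack]))) + min_gap
    placed: list[tuple[int, int]] = []
    pos = 1
    for i in range(n):
        pos += int(gaps[i])
        placed.append((pos, lengths[i]))
        pos += lengths[i]
    return placed


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

def free_intervals(genome: GenomeBundle, truth: TruthSet, replicon: str) -> list[tuple[int, int]]:
    """Gene-free, feature-free intervals (1-based inclusive) of a replicon."""
    n = genome.replicon_lengths[replicon]
    occupied: list[tuple[int, int]] = [
        (g.start, g.end) for g in genome.genes if g.replicon == replicon
    ]
    occupied += [
        (ir.left_start, ir.right_end) for ir in truth.planted_irs if ir.replicon == replicon
    ]
    occupied += [
        (s.start, s.end) for s in truth.planted_srnas if s.replicon == replicon
    ]
    occupied.sort()
    out: list[tuple[int, int]] = []
    pos = 1
    for s, e in occupied:
        if s > pos:
            out.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= n:
        out.append((pos, n))
    return out


def _edit_sequence(genome: GenomeBundle, replicon: str, start: int, piece: str) -> None:
    seq = genome.replicons[replicon]
    genome.replicons[replicon] = seq[: start - 1] + piece + seq[start - 1 + len(piece) :]


def plant_inverted_repeats(
    genome: GenomeBundle,
    specs: list[tuple[int, int, int, bool]],
    truth: TruthSet | None = None,
    seed: int | None = None,
) -> tuple[GenomeBundle, TruthSet]:
    """Write inverted repeats into intergenic space.

    Each spec is ``(arm_len, mismatches, spacer_len, homopolymeric)``: the
    right arm is the reverse complement of the left arm with exactly
    ``mismatches`` substitutions; homopolymeric specs use an all-A left arm
    (a decoy for the homopolymer filter).
    """
    truth = truth if truth is not None else TruthSet(seed=seed if seed is not None else 0)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    margin = 25
    for arm_len, mismatches, spacer_len, homopolymeric in specs:
        if arm_len < 1:
            raise ValueError("arm_len must be >= 1")
        if spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if mismatches >= arm_len:
            raise ValueError("mismatches must be < arm_len")
        total = 2 * arm_len + spacer_len
        placed = False
        for replicon in genome.replicons:
            slots = [
                (s, e) for s, e in free_intervals(genome, truth, replicon)
                if e - s + 1 >= total + 2 * margin
            ]
            if not slots:
                continue
            s, e = slots[int(rng.integers(0, len(slots)))]
            offset = int(rng.integers(s + margin, e - margin - total + 2))
            if homopolymeric:
                left = "A" * arm_len
            else:
                # mixed-base arm: redraw until not homopolymeric and GC moderate
                for _ in range(100):
                    left = random_sequence(rng, arm_len)
                    gc = (left.count("G") + left.count("C")) / arm_len
                    if len(set(left)) > 1 and 0.2 <= gc <= 0.8:
                        break
            right = list(revcomp(left))
            if mismatches:
                pos_choices = rng.choice(arm_len, size=mismatches, replace=False)
                for p in pos_choices:
                    alternatives = [b for b in "ACGT" if b != right[p]]
                    right[p] = alternatives[int(rng.integers(0, 3))]
            spacer = random_sequence(rng, spacer_len)
            if homopolymeric:
                # A-pad the flanks and spacer edges so arm extensions stay
                # GC-free (a decoy must not survive as an extended mixed arm)
                pad = min(3, spacer_len // 2)
                spacer = "A" * pad + spacer[pad : spacer_len - pad] + "A" * pad
                piece = "AAA" + left + spacer + "".join(right) + "AAA"
                _edit_sequence(genome, replicon, offset - 3, piece)
            else:
                piece = left + spacer + "".join(right)
                _edit_sequence(genome, replicon, offset, piece)
            truth.planted_irs.append(
                PlantedIR(
                    replicon=replicon,
                    left_start=offset,
                    left_end=offset + arm_len - 1,
                    right_start=offset + arm_len + spacer_len,
                    right_end=offset + 2 * arm_len + spacer_len - 1,
                    mismatches=mismatches,
                    homopolymeric=homopolymeric,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"cannot place inverted repeat spec {(arm_len, mismatches, spacer_len)}"
            )
    return genome, truth


# ---------------------------------------------------------------------------
# dRNA-seq coverage simulation
# ---------------------------------------------------------------------------

def simulate_drnaseq_coverage(
    genome: GenomeBundle,
    truth: TruthSet,
    enrichment_factor: float = 10.0,
    tss_height: float = 100.0,
    noise_rate: float = 0.1,
    terminator_drop: float = 0.9,
    seed: int = 0,
    readthrough: int = 100,
) -> CoverageSet:
    """Poisson-sampled start-count and coverage tracks from the planted truth.

    5'-start counts at a planted TSS average ``tss_height`` in the treated
    (TEX+) library and ``tss_height / enrichment_factor`` in the untreated
    one; processing sites show the opposite pattern. Full coverage follows
    the planted transcripts; terminated transcripts read through for
    ``readthrough`` bp at ``(1 - terminator_drop)`` of their height.
    """
    if enrichment_factor <= 1:
        raise ValueError("enrichment_factor must be > 1")
    if not 0 < terminator_drop <= 1:
        raise ValueError("terminator_drop must be in (0, 1]")
    if noise_rate < 0 or tss_height < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = genome.replicon_lengths
    cov = CoverageSet(lengths)

    lam_cov = {
        (rep, strand): np.full(n, float(noise_rate))
        for rep, n in lengths.items()
        for strand in ("+", "-")
    }
    for tr in truth.transcripts:
        arr = lam_cov[(tr.replicon, tr.strand)]
        arr[tr.start - 1 : tr.end] += tr.height
        if tr.terminated and readthrough > 0:
            if tr.strand == "+":
                lo, hi = tr.end, min(tr.end + readthrough, lengths[tr.replicon])
                arr[lo:hi] += tr.height * (1 - terminator_drop)
            else:
                lo, hi = max(tr.start - 1 - readthrough, 0), tr.start - 1
                arr[lo:hi] += tr.height * (1 - terminator_drop)

    for (rep, strand), lam in lam_cov.items():
        for lib in (TEX_PLUS, TEX_MINUS):
            cov.set_coverage(rep, strand, lib, rng.poisson(lam))

    lam_starts = {
        (rep, strand, lib): np.full(n, float(noise_rate))
        for rep, n in lengths.items()
        for strand in ("+", "-")
        for lib in (TEX_PLUS, TEX_MINUS)
    }
    for t in truth.planted_tss:
        h = tss_height * t.height_scale
        enr = enrichment_factor * t.enrich_scale
        lam_starts[(t.replicon, t.strand, TEX_PLUS)][t.position - 1] += h
        lam_starts[(t.replicon, t.strand, TEX_MINUS)][t.position - 1] += h / max(enr, 1.01)
    for rep, pos, strand in truth.planted_processing_sites:
        lam_starts[(rep, strand, TEX_MINUS)][pos - 1] += tss_height
        lam_starts[(rep, strand, TEX_PLUS)][pos - 1] += tss_height / enrichment_factor
    for (rep, strand, lib), lam in lam_starts.items():
        cov.set_starts(rep, strand, lib, rng.poisson(lam))
    return cov


# ---------------------------------------------------------------------------
# Count matrix simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    n_genes: int,
    condition_map: dict[str, str],
    libsizes: dict[str, float] | float,
    dispersion: float,
    planted_de: dict[str, float] | None = None,
    planted_regulons: dict[str, dict] | None = None,
    seed: int = 0,
    control: str | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, TruthSet]:
    """Negative-binomial counts with planted fold changes and regulon blocks.

    ``planted_de`` maps gene id -> true log2 fold change applied in every
    non-control condition. A regulon spec
    ``{"members": {...gene: sign...} or [genes], "target_r": 0.9, "amplitude": 1.0}``
    gives its members a shared latent condition profile mixed so the
    expected pairwise correlation of the log-mean profiles equals
    ``target_r``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    planted_de = dict(planted_de or {})
    planted_regulons = dict(planted_regulons or {})
    rng = np.random.default_rng(seed)
    samples = list(condition_map)
    conditions = list(dict.fromkeys(condition_map.values()))
    if control is None:
        control = conditions[0]
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    if isinstance(libsizes, (int, float)):
        libsizes = {s: float(libsizes) for s in samples}

    truth = TruthSet(seed=seed, planted_de=planted_de, planted_regulons=planted_regulons)
    rep_counts = pd.Series(list(condition_map.values())).value_counts()
    for cond, k in rep_counts.items():
        if k < 2:
            truth.notes.append(f"condition {cond!r} has a single replicate")

    idx = {g: i for i, g in enumerate(gene_ids)}
    n_cond = len(conditions)
    cond_idx = {c: j for j, c in enumerate(conditions)}

    base = rng.normal(0.0, 1.5, size=n_genes)  # log2 relative abundance
    effect = np.zeros((n_genes, n_cond))
    for g, lfc in planted_de.items():
        if g not in idx:
            raise ValueError(f"planted DE gene {g!r} not among gene ids")
        for c in conditions:
            if c != control:
                effect[idx[g], cond_idx[c]] += lfc
    for name, spec in planted_regulons.items():
        members = spec["members"]
        signs = members if isinstance(members, dict) else {m: 1.0 for m in members}
        r = float(spec.get("target_r", 0.9))
        # amplitude ~1 (log2): large enough to dominate count noise, small
        # enough that the exponentiation to the CPM scale barely shrinks the
        # planted correlation (lognormal Pearson shrinkage)
        amp = float(spec.get("amplitude", 1.0))
        # the target correlation applies on the (linear) CPM scale the
        # co-expression method measures; undo, analytically, the two
        # systematic shrinkages between the latent log-profile and the
        # measured correlation: counting-noise attenuation (dispersion over
        # replicates, relative to the signal variance e^{sigma2}-1) and
        # lognormal correlation shrinkage
        sigma2 = (amp * np.log(2.0)) ** 2
        reps = min(
            (list(condition_map.values()).count(c) for c in conditions),
            default=1,
        )
        noise_var = dispersion / max(reps, 1)
        attenuation = np.expm1(sigma2) / (np.expm1(sigma2) + noise_var)
        r_linear = min(r / attenuation, 0.999)
        r_latent = float(np.log1p(r_linear * np.expm1(sigma2)) / sigma2)
        r_latent = min(max(r_latent, r), 0.999)
        latent = rng.normal(0.0, 1.0, size=n_cond)
        latent = (latent - latent.mean()) / latent.std()
        for g, sign in signs.items():
            noise = rng.normal(0.0, 1.0, size=n_cond)
            # orthogonalize and standardize the private noise so the realized
            # (sample) inter-member correlation matches the target, not just
            # its expectation
            noise = noise - (noise @ latent / n_cond) * latent
            sd = noise.std()
            if sd > 0:
                noise = (noise - noise.mean()) / sd
            profile = np.sqrt(r_latent) * latent + np.sqrt(1 - r_latent) * noise
            effect[idx[g]] += np.sign(sign) * amp * profile

    w0 = (2.0 ** base).sum()
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = libsizes[s] * (2.0 ** (base + effect[:, cond_idx[condition_map[s]]])) / w0
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / dispersion
            counts[:, j] = rng.poisson(rng.gamma(shape, mu / shape))
    df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    matrix = ExpressionMatrix(df, condition_map)
    matrix.provenance["notes"] = list(truth.notes)
    matrix.provenance["control"] = control
    return matrix, truth


# ---------------------------------------------------------------------------
# Fitness tables
# ---------------------------------------------------------------------------

def simulate_fitness_table(
    n_srnas: int,
    n_experiments: int,
    planted_hits: list[tuple] | None = None,
    seed: int = 0,
    unsuccessful_rate: float = 0.05,
) -> tuple[FitnessTable, TruthSet]:
    """Background fitness entries with |t| < 3 plus planted hits.

    ``planted_hits`` entries are ``(srna, experiment, fit, t)`` with an
    optional fifth ``success`` element (default True). A random subset of
    background entries is flagged unsuccessful.
    """
    planted_hits = planted_hits or []
    rng = np.random.default_rng(seed)
    srnas = [f"sRNA{i + 1:04d}" for i in range(n_srnas)]
    experiments = [f"exp{j + 1:04d}" for j in range(n_experiments)]
    for hit in planted_hits:
        if abs(hit[3]) < 3:
            raise ValueError("planted |t| values must be outside the null band (|t| >= 3)")
    t_bg = np.clip(rng.normal(0.0, 1.0, size=(n_srnas, n_experiments)), -2.99, 2.99)
    fit_bg = rng.normal(0.0, 0.3, size=(n_srnas, n_experiments))
    success = rng.random(size=(n_srnas, n_experiments)) >= unsuccessful_rate

    entries: dict[tuple[str, str], FitnessEntry] = {}
    for i, s in enumerate(srnas):
        for j, e in enumerate(experiments):
            entries[(s, e)] = FitnessEntry(
                srna=s, experiment=e, fit=float(fit_bg[i, j]),
                t=float(t_bg[i, j]), success=bool(success[i, j]),
            )
    truth = TruthSet(seed=seed)
    for hit in planted_hits:
        srna, experiment, fit, t = hit[:4]
        ok = bool(hit[4]) if len(hit) > 4 else True
        if (srna, experiment) not in entries:
            raise ValueError(f"planted hit names unknown ids: {(srna, experiment)}")
        entries[(srna, experiment)] = FitnessEntry(
            srna=srna, experiment=experiment, fit=float(fit), t=float(t), success=ok
        )
        if ok:
            truth.planted_fitness_hits.append((srna, experiment))
    return FitnessTable(list(entries.values())), truth
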