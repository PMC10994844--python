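import itertools

import numpy as np
import pandas as pd
import pytest

from txatlas.evaluate import srna_recovery
from txatlas.models import (
    CoverageSet,
    ExpressionMatrix,
    Gene,
    GenomeBundle,
    Operon,
    TerminatorRecord,
    TSSRecord,
)
from txatlas.srna import (
    MIN_LOOP,
    _PAIR_ENERGY,
    SRNACandidate,
    Transcript,
    call_transcripts,
    classify_srnas,
    curate_srnas,
    derive_candidates,
    folding_energy,
    pair_asrna_with_targets,
)
from txatlas.synthetic import random_sequence, revcomp
from txatlas.tss import classify_tss


def coverage_block(blocks, length=4000, strand="+"):
    cov = CoverageSet({"replicon1": length})
    vec = np.zeros(length, int)
    for s, e, h in blocks:
        vec[s - 1 : e] = h
    cov.set_coverage("replicon1", strand, "TEX-", vec)
    return cov


class TestCallTranscripts:
    def test_single_block(self):
        cov = coverage_block([(501, 620, 50)])
        trs = call_transcripts(cov, min_cov=10, min_len=30, merge_gap=10)
        assert [(t.start, t.end, t.strand) for t in trs] == [(501, 620, "+")]

    def test_nearby_blocks_merged(self):
        cov = coverage_block([(501, 600, 50), (606, 700, 50)])
        trs = call_transcripts(cov, min_cov=10, min_len=30, merge_gap=10)
        assert [(t.start, t.end) for t in trs] == [(501, 700)]

    def test_short_run_dropped(self):
        cov = coverage_block([(501, 520, 50)])
        assert call_transcripts(cov, min_cov=10, min_len=30, merge_gap=10) == []


def exhaustive_min_energy(seq):
    """Enumerate every nested pairing with loops >= MIN_LOOP (tiny n only)."""
    n = len(seq)

    def best(i, j, memo={}):
        if j - i <= MIN_LOOP:
            return 0.0
        key = (seq, i, j)
        if key in memo:
            return memo[key]
        # leave i unpaired, or pair i with any admissible k
        out = best(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j):
            e = _PAIR_ENERGY.get((seq[i], seq[k]))
            if e is not None:
                out = min(out, e + best(i + 1, k) + best(k + 1, j))
        memo[key] = out
        return out

    return best(0, n)


class TestFoldingEnergy:
    def test_poly_a_is_zero_and_unstable(self):
        energy, norm = folding_energy("A" * 50)
        assert energy == 0.0 and norm == 0.0
        assert not norm < -0.05

    def test_gc_hairpin_is_stable(self):
        stem = "G" * 20
        seq = stem + "AAAA" + "C" * 20
        energy, norm = folding_energy(seq)
        assert energy == pytest.approx(-60.0)
        assert norm < -0.05

    def test_reverse_complement_symmetry_for_watson_crick(self):
        seq = "GGGGAAACCCC"
        assert folding_energy(seq)[0] == folding_energy(revcomp(seq))[0]

    def test_rna_alphabet_accepted(self):
        assert folding_energy("GGGGAAACCCC") == folding_energy("GGGGAAACCCC".replace("T", "U"))

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            folding_energy("ACGTX")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, int(rng.integers(8, 17)))
        assert folding_energy(seq)[0] == pytest.approx(exhaustive_min_energy(seq))


def geometry(genome_len=10_000):
    """A constructed genome exercising every sRNA class."""
    genes = [
        Gene("mrna1", "replicon1", 2000, 2900, "+"),   # utr5/antisense host
        Gene("mrna2", "replicon1", 4000, 4900, "+"),   # utr3 host
        Gene("op1", "replicon1", 6000, 6600, "+"),
        Gene("op2", "replicon1", 7000, 7700, "+"),
    ]
    rng = np.random.default_rng(99)
    genome = GenomeBundle({"replicon1": random_sequence(rng, genome_len)}, genes)
    tss = [
        TSSRecord("replicon1", 500, "+", 100, 5, 20.0),    # intergenic sRNA
        TSSRecord("replicon1", 1870, "+", 100, 5, 20.0),   # shared mRNA TSS (utr5)
        TSSRecord("replicon1", 2350, "-", 100, 5, 20.0),   # antisense sRNA
        TSSRecord("replicon1", 4950, "+", 100, 5, 20.0),   # TSS in 3' UTR
        TSSRecord("replicon1", 5950, "+", 100, 5, 20.0),   # operon lead
        TSSRecord("replicon1", 6950, "+", 100, 5, 20.0),   # intra-operonic 5' end
    ]
    classify_tss(tss, genes)
    processing = [("replicon1", 1992, "+"), ("replicon1", 7101, "+")]
    terminators = [
        TerminatorRecord("replicon1", 5100, 5100, "+", "coverage_drop", 0.9),
        TerminatorRecord("replicon1", 7750, 7750, "+", "coverage_drop", 0.9),
    ]
    operons = [Operon("operon1", "replicon1", "+", ["op1", "op2"], lead_tss=5950)]
    return genome, tss, processing, terminators, operons


class TestClassification:
    def test_each_class_assigned(self):
        genome, tss, processing, terminators, operons = geometry()
        cands = [
            SRNACandidate("replicon1", 500, 620, "+", parent=(500, 620)),
            SRNACandidate("replicon1", 1870, 1991, "+", parent=(1870, 3000)),
            SRNACandidate("replicon1", 2230, 2350, "-", parent=(2230, 2350)),
            SRNACandidate("replicon1", 4950, 5100, "+", parent=(3970, 5100)),
            SRNACandidate("replicon1", 6950, 7100, "+", parent=(5950, 7700)),
        ]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        assert [r.srna_class for r in recs] == [
            "intergenic", "utr5_derived", "antisense", "utr3_derived", "intra_operonic",
        ]

    def test_classification_is_a_partition(self):
        genome, tss, processing, terminators, operons = geometry()
        rng = np.random.default_rng(3)
        cands = []
        for _ in range(60):
            s = int(rng.integers(1, 9000))
            e = s + int(rng.integers(40, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            cands.append(SRNACandidate("replicon1", s, e, strand, parent=(s, e)))
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        for r in recs:
            assigned = r.srna_class is not None
            rejected = "unclassifiable" in r.rejection_reasons
            assert assigned != rejected

    def test_candidate_segmentation_at_anchors(self):
        transcripts = [Transcript("replicon1", 1000, 1500, "+")]
        tss = [TSSRecord("replicon1", 1000, "+", 100, 5, 20.0)]
        processing = [("replicon1", 1200, "+")]
        cands = derive_candidates(transcripts, tss, processing)
        intervals = {(c.start, c.end) for c in cands}
        assert {(1000, 1500), (1000, 1199), (1200, 1500)} <= intervals


class TestCuration:
    def test_rule1_no_promoter_within_window(self):
        genome, tss, processing, terminators, operons = geometry()
        cands = [SRNACandidate("replicon1", 8000, 8120, "+", parent=(8000, 8120))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        _, rejected = curate_srnas(recs, tss, processing, genome.genes, terminators, genome)
        assert "no_promoter_or_processing_site" in rejected[0].rejection_reasons

    def test_rule2_same_strand_mrna_containment(self):
        genome, tss, processing, terminators, operons = geometry()
        tss.append(TSSRecord("replicon1", 2100, "+", 100, 5, 20.0))
        cands = [SRNACandidate("replicon1", 2100, 2220, "+", parent=(2100, 2220))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        _, rejected = curate_srnas(recs, tss, processing, genome.genes, terminators, genome)
        assert "overlaps_mrna" in rejected[0].rejection_reasons

    def test_antisense_not_rejected_by_rule2(self):
        genome, tss, processing, terminators, operons = geometry()
        cands = [SRNACandidate("replicon1", 2230, 2350, "-", parent=(2230, 2350))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        accepted, rejected = curate_srnas(
            recs, tss, processing, genome.genes, terminators, genome
        )
        all_reasons = [r.rejection_reasons for r in accepted + rejected]
        assert "overlaps_mrna" not in itertools.chain.from_iterable(all_reasons)

    def test_rule3_terminator_containment(self):
        genome, tss, processing, terminators, operons = geometry()
        terminators.append(TerminatorRecord("replicon1", 480, 700, "+", "hairpin", 10))
        cands = [SRNACandidate("replicon1", 500, 620, "+", parent=(500, 620))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        _, rejected = curate_srnas(recs, tss, processing, genome.genes, terminators, genome)
        assert "within_terminator" in rejected[0].rejection_reasons

    def test_rule4_applied_only_with_elements(self):
        genome, tss, processing, terminators, operons = geometry()
        cands = [SRNACandidate("replicon1", 500, 620, "+", parent=(500, 620))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        _, rejected = curate_srnas(
            recs, tss, processing, genome.genes, terminators, genome,
            cis_elements=[("replicon1", 600, 640)],
        )
        assert rejected and "cis_regulatory_overlap" in rejected[0].rejection_reasons

    def test_rule5_needs_coverage_change(self):
        genome, tss, processing, terminators, operons = geometry()
        cov = coverage_block([(1, 4000, 50)], length=10_000)  # flat everywhere
        cands = [SRNACandidate("replicon1", 500, 620, "+", parent=(500, 620))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        _, rejected = curate_srnas(
            recs, tss, processing, genome.genes, terminators, genome, coverage=cov
        )
        assert "no_coverage_change" in rejected[0].rejection_reasons

    def test_length_filter(self):
        genome, tss, processing, terminators, operons = geometry()
        tss.append(TSSRecord("replicon1", 8000, "+", 100, 5, 20.0))
        cands = [SRNACandidate("replicon1", 8000, 8024, "+", parent=(8000, 8024))]
        recs = classify_srnas(cands, tss, processing, genome.genes, operons, terminators)
        _, rejected = curate_srnas(recs, tss, processing, genome.genes, terminators, genome)
        assert "length_out_of_range" in rejected[0].rejection_reasons

    def test_unstable_structure_filter(self):
        genes = []
        genome = GenomeBundle({"replicon1": "A" * 2000}, genes)
        tss = [TSSRecord("replicon1", 500, "+", 100, 5, 20.0)]
        cands = [SRNACandidate("replicon1", 500, 620, "+", parent=(500, 620))]
        recs = classify_srnas(cands, tss, [], genes, [], [])
        _, rejected = curate_srnas(recs, tss, [], genes, [], genome)
        assert "unstable_structure" in rejected[0].rejection_reasons


class TestDemoRecovery:
    def test_planted_class_recovery(self, demo_bundle, demo_annotation):
        assert srna_recovery(demo_annotation, demo_bundle.truth) >= 0.90

    def test_no_intergenic_call_overlaps_genes(self, demo_bundle, demo_annotation):
        genes = demo_bundle.genome.genes
        for rec in demo_annotation.srnas_accepted:
            if rec.srna_class != "intergenic":
                continue
            assert not any(
                g.replicon == rec.replicon and g.overlaps(rec.start, rec.end)
                for g in genes
            )


class TestAsrnaPairing:
    def matrix(self, profiles):
        samples = [f"s{i}" for i in range(len(next(iter(profiles.values()))))]
        counts = pd.DataFrame(profiles, index=samples).T
        counts.columns = samples
        return ExpressionMatrix(
            counts.astype(int),
            {s: f"c{i}" for i, s in enumerate(samples)},
            library_sizes={s: 1e6 for s in samples},
        )

    def setup_pair(self):
        genes = [Gene("op1", "replicon1", 1000, 1600, "+")]
        operons = [Operon("operonX", "replicon1", "+", ["op1"])]
        from txatlas.models import SRNARecord

        rec = SRNARecord("as1", "replicon1", 1100, 1250, "-", srna_class="antisense")
        return genes, operons, rec

    def test_anticorrelated_pair_labelled(self):
        genes, operons, rec = self.setup_pair()
        base = np.array([100, 800, 200, 900, 50, 600], float)
        m = self.matrix({"op1": base, "as1": 1000 - base})
        out = pair_asrna_with_targets([rec], operons, genes, m)
        assert out.loc[0, "label"] == "anti-correlated"

    def test_constant_profile_is_neutral_with_flag(self):
        genes, operons, rec = self.setup_pair()
        m = self.matrix({"op1": np.full(6, 100.0), "as1": np.arange(6) * 50.0 + 10})
        out = pair_asrna_with_targets([rec], operons, genes, m)
        assert out.loc[0, "label"] == "neutral"
        assert "zero-variance" in out.loc[0, "note"]

    def test_absent_asrna_skipped_with_note(self):
        genes, operons, rec = self.setup_pair()
        m = self.matrix({"op1": np.array([1.0, 2, 3, 4, 5, 6])})
        out = pair_asrna_with_targets([rec], operons, genes, m)
        assert out.loc[0, "label"] == "skipped"
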