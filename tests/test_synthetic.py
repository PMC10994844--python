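import numpy as np
import pytest

from txatlas import io as tio
from txatlas.models import TEX_MINUS, TEX_PLUS
from txatlas.synthetic import (
    PlacementError,
    PlantedTranscript,
    PlantedTSS,
    TruthSet,
    generate_genome,
    plant_inverted_repeats,
    revcomp,
    simulate_counts,
    simulate_drnaseq_coverage,
    simulate_fitness_table,
)


class TestGenerateGenome:
    def test_genes_non_overlapping_and_in_bounds(self):
        genome, _ = generate_genome(1, [50_000], n_genes=20, mean_gene_len=900)
        genes = sorted(genome.genes, key=lambda g: g.start)
        assert len(genes) == 20
        assert all(1 <= g.start <= g.end <= 50_000 for g in genes)
        assert all(b.start > a.end for a, b in zip(genes, genes[1:]))

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for run in ("x", "y"):
            genome, _ = generate_genome(11, [20_000], n_genes=5, mean_gene_len=800)
            tio.write_fasta(genome.replicons, tmp_path / f"{run}.fasta")
            tio.write_gff3(genome.genes, tmp_path / f"{run}.gff3")
        assert (tmp_path / "x.fasta").read_bytes() == (tmp_path / "y.fasta").read_bytes()
        assert (tmp_path / "x.gff3").read_bytes() == (tmp_path / "y.gff3").read_bytes()

    def test_no_genes_is_valid(self):
        genome, _ = generate_genome(3, [15_000], n_genes=0, mean_gene_len=900)
        assert genome.genes == [] and len(genome.replicons["replicon1"]) == 15_000

    def test_unplaceable_genes_raise(self):
        with pytest.raises(PlacementError, match="cannot place genes"):
            generate_genome(4, [10_000], n_genes=50, mean_gene_len=1000)


class TestPlantInvertedRepeats:
    def test_perfect_arm_is_reverse_complement(self):
        genome, truth = generate_genome(5, [20_000], n_genes=5, mean_gene_len=800)
        plant_inverted_repeats(genome, [(12, 0, 100, False)], truth=truth)
        ir = truth.planted_irs[0]
        seq = genome.replicons[ir.replicon]
        left = seq[ir.left_start - 1 : ir.left_end]
        right = seq[ir.right_start - 1 : ir.right_end]
        assert right == revcomp(left)
        assert ir.right_start - ir.left_end - 1 == 100

    def test_mismatch_count_exact(self):
        genome, truth = generate_genome(6, [20_000], n_genes=5, mean_gene_len=800)
        plant_inverted_repeats(genome, [(20, 2, 200, False)], truth=truth)
        ir = truth.planted_irs[0]
        seq = genome.replicons[ir.replicon]
        left = seq[ir.left_start - 1 : ir.left_end]
        right = seq[ir.right_start - 1 : ir.right_end]
        diffs = sum(a != b for a, b in zip(right, revcomp(left)))
        assert diffs == 2

    def test_homopolymeric_decoy_arm(self):
        genome, truth = generate_genome(7, [20_000], n_genes=5, mean_gene_len=800)
        plant_inverted_repeats(genome, [(15, 0, 80, True)], truth=truth)
        ir = truth.planted_irs[0]
        seq = genome.replicons[ir.replicon]
        assert seq[ir.left_start - 1 : ir.left_end] == "A" * 15
        assert ir.homopolymeric

    @pytest.mark.parametrize("spec", [(0, 0, 10, False), (10, 0, -1, False)])
    def test_invalid_spec_rejected(self, spec):
        genome, truth = generate_genome(8, [20_000], n_genes=0, mean_gene_len=800)
        with pytest.raises(ValueError):
            plant_inverted_repeats(genome, [spec], truth=truth)


class TestSimulateCoverage:
    def _truth_with_tss(self, genome, n=60, spacing=300):
        truth = TruthSet(seed=0)
        for i in range(n):
            truth.planted_tss.append(PlantedTSS("replicon1", 500 + i * spacing, "+"))
        return truth

    def test_tex_ratio_at_planted_tss(self):
        genome, _ = generate_genome(9, [25_000], n_genes=0, mean_gene_len=800)
        truth = self._truth_with_tss(genome, n=60, spacing=400)
        cov = simulate_drnaseq_coverage(
            genome, truth, enrichment_factor=10, tss_height=100, noise_rate=0.1, seed=1
        )
        plus = cov.starts("replicon1", "+", TEX_PLUS)
        minus = cov.starts("replicon1", "+", TEX_MINUS)
        ratios = [
            plus[t.position - 1] / max(minus[t.position - 1], 1)
            for t in truth.planted_tss
        ]
        assert 5 <= np.mean(ratios) <= 20

    def test_terminator_drop_in_coverage(self):
        genome, _ = generate_genome(10, [25_000], n_genes=0, mean_gene_len=800)
        truth = TruthSet(seed=0)
        truth.transcripts.append(
            PlantedTranscript("replicon1", 1000, 2000, "+", 100.0, terminated=True)
        )
        truth.planted_terminators.append(("replicon1", 2000, "+"))
        cov = simulate_drnaseq_coverage(
            genome, truth, terminator_drop=0.9, noise_rate=0.1, seed=2
        )
        full = cov.coverage("replicon1", "+", TEX_MINUS).astype(float)
        up = full[1949:1999].mean()
        down = full[2001:2051].mean()
        assert down <= 0.2 * up

    def test_no_signal_gives_zero_tracks(self):
        genome, _ = generate_genome(11, [12_000], n_genes=0, mean_gene_len=800)
        truth = TruthSet(seed=0)
        cov = simulate_drnaseq_coverage(
            genome, truth, tss_height=0, noise_rate=0.0, seed=3
        )
        for strand in ("+", "-"):
            for lib in (TEX_PLUS, TEX_MINUS):
                assert cov.starts("replicon1", strand, lib).sum() == 0
                assert cov.coverage("replicon1", strand, lib).sum() == 0

    def test_parameter_validation(self):
        genome, _ = generate_genome(12, [12_000], n_genes=0, mean_gene_len=800)
        with pytest.raises(ValueError):
            simulate_drnaseq_coverage(genome, TruthSet(seed=0), enrichment_factor=1.0)
        with pytest.raises(ValueError):
            simulate_drnaseq_coverage(genome, TruthSet(seed=0), terminator_drop=0.0)


class TestSimulateCounts:
    CMAP = {f"s{i}": ("A" if i < 2 else "B") for i in range(4)}

    def test_planted_log2fc_recovered(self):
        genes = [f"g{i + 1:05d}" for i in range(2000)]
        planted = {g: 4.0 for g in genes[:100]}
        matrix, _ = simulate_counts(
            2000, self.CMAP, 1e6, dispersion=0.05, planted_de=planted, seed=3
        )
        counts = matrix.counts
        a = counts[["s0", "s1"]].mean(axis=1)
        b = counts[["s2", "s3"]].mean(axis=1)
        lfc = np.log2((b.loc[list(planted)] + 0.5) / (a.loc[list(planted)] + 0.5))
        assert 3.7 <= lfc.mean() <= 4.3

    def test_regulon_block_correlated(self):
        cmap = {f"s{i}": f"c{i // 2}" for i in range(16)}  # 8 conditions x 2
        members = [f"g{i + 1:05d}" for i in range(50)]
        matrix, _ = simulate_counts(
            500,
            cmap,
            1e6,
            dispersion=0.05,
            planted_regulons={"reg": {"members": members, "target_r": 0.9}},
            seed=4,
        )
        cpm = matrix.cpm().loc[members]
        cond_means = np.column_stack(
            [cpm[[s for s, c in cmap.items() if c == f"c{k}"]].mean(axis=1) for k in range(8)]
        )
        log_means = np.log2(cond_means + 1)
        r = np.corrcoef(log_means)
        upper = r[np.triu_indices_from(r, k=1)]
        assert np.median(upper) >= 0.8

    def test_poisson_limit_at_zero_dispersion(self):
        matrix, _ = simulate_counts(10_000, self.CMAP, 1e6, dispersion=0.0, seed=5)
        counts = matrix.counts[["s0", "s1", "s2", "s3"]].to_numpy(float)
        m = counts.mean(axis=1)
        v = counts.var(axis=1, ddof=1)
        big = m > 50
        # variance/mean ratio concentrates around 1 in the Poisson limit
        assert abs(np.mean(v[big] / m[big]) - 1.0) < 0.1

    def test_single_replicate_warning_recorded(self):
        cmap = {"s0": "A", "s1": "A", "s2": "B"}
        matrix, truth = simulate_counts(100, cmap, 1e5, dispersion=0.1, seed=6)
        assert any("single replicate" in n for n in truth.notes)
        assert any("single replicate" in n for n in matrix.provenance["notes"])


class TestSimulateFitness:
    def test_planted_hits_and_null_band(self):
        hits = [(f"sRNA{i:04d}", f"exp{i:04d}", -2.5, 6.0) for i in (1, 2, 3, 4, 5)]
        table, truth = simulate_fitness_table(80, 100, planted_hits=hits, seed=7)
        df = table.to_frame()
        planted_keys = {(s, e) for s, e, *_ in hits}
        background = df[~df.apply(lambda r: (r.srna, r.experiment) in planted_keys, axis=1)]
        assert (background["t"].abs() < 3).all()
        assert len(truth.planted_fitness_hits) == 5

    def test_no_hits_means_no_large_t(self):
        table, _ = simulate_fitness_table(30, 40, seed=8)
        assert (table.to_frame()["t"].abs() < 3).all()

    def test_planted_t_inside_null_band_rejected(self):
        with pytest.raises(ValueError, match="null band"):
            simulate_fitness_table(10, 10, planted_hits=[("sRNA0001", "exp0001", 1.0, 2.0)])
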