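import numpy as np
import pytest

from sap._codec import revcomp
from sap.simulator import (
    SimulationConfig,
    apply_variants,
    fragment_regions,
    generate_reads,
    make_regions,
    mutate_reference,
    random_reference,
    simulate_dataset,
)


class TestMutate:
    def test_zero_rates_identity(self):
        ref = random_reference(5_000, seed=1)
        cfg = SimulationConfig(snp_rate=0.0, indel_rate=0.0)
        mut, truth = mutate_reference(ref, cfg, np.random.default_rng(0))
        assert mut.sequence == ref.sequence
        assert truth == []

    def test_snp_count_within_binomial_bounds(self):
        # Binomial(1e6, 2e-4): mean 200, sd ~14.1; central 99.9% ~ +/-3.3 sd
        ref = random_reference(1_000_000, seed=2)
        cfg = SimulationConfig()
        _, truth = mutate_reference(ref, cfg, np.random.default_rng(3))
        n_snp = sum(v.type == "SNP" for v in truth)
        n_indel = len(truth) - n_snp
        assert 200 - 47 <= n_snp <= 200 + 47
        assert 90 - 32 <= n_indel <= 90 + 32  # Binomial(1e6, 9e-5)

    def test_truth_alleles_consistent_with_reference(self):
        ref = random_reference(200_000, seed=4)
        _, truth = mutate_reference(ref, SimulationConfig(), np.random.default_rng(5))
        for v in truth:
            if v.type == "SNP":
                assert v.ref == ref.sequence[v.pos] and v.alt != v.ref
            elif v.type == "DEL":
                assert v.ref == ref.sequence[v.pos : v.pos + len(v.ref)]

    def test_applying_truth_reproduces_mutated_sequence(self):
        ref = random_reference(300_000, seed=6)
        mut, truth = mutate_reference(ref, SimulationConfig(), np.random.default_rng(7))
        assert apply_variants(ref, truth).sequence == mut.sequence


class TestFragments:
    def test_regions_partition_sequence(self):
        cfg = SimulationConfig()
        regions = make_regions(100_000, cfg, np.random.default_rng(1))
        assert regions[0][0] == 0 and regions[-1][1] == 100_000
        for (s0, e0), (s1, e1) in zip(regions, regions[1:]):
            assert e0 == s1 and e0 > s0

    def test_fragments_lie_within_their_regions(self):
        cfg = SimulationConfig(coverage=10)
        rng = np.random.default_rng(2)
        regions = [(1000, 3000), (5000, 5250)]
        frags = fragment_regions(regions, cfg, rng, seq_len=10_000)
        for fs, flen in frags:
            assert any(s <= fs and fs + flen <= e for s, e in regions)
        # a region shorter than the minimum fragment length still yields
        # fragments (clipped to the region)
        assert any(5000 <= fs < 5250 for fs, _ in frags)

    def test_zero_coverage_no_fragments(self):
        cfg = SimulationConfig()
        assert fragment_regions([(0, 1000)], cfg, np.random.default_rng(3), coverage=0.0) == []

    def test_realized_coverage_near_target(self):
        cfg = SimulationConfig(read_len=75, coverage=20)
        rng = np.random.default_rng(4)
        frags = fragment_regions([(0, 10_000)], cfg, rng)
        read_bases = sum(min(75, flen) for _, flen in frags)
        assert 0.7 * 20 <= read_bases / 10_000 <= 1.3 * 20


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        src = random_reference(20_000, seed=8)
        cfg = SimulationConfig(read_len=75, coverage=2, error_rate=0.0)
        rng = np.random.default_rng(9)
        frags = fragment_regions([(0, src.length)], cfg, rng, seq_len=src.length)
        reads = generate_reads(frags, src, cfg, rng)
        assert reads
        for r in reads:
            _, _, fs, fe, strand, _ = r.id.split(":")
            frag = src.sequence[int(fs) : int(fe)]
            expected = frag[: len(r)] if strand == "5p" else revcomp(frag)[: len(r)]
            assert r.bases == expected

    def test_error_rate_recovered_within_binomial_bounds(self):
        src = random_reference(30_000, seed=10)
        cfg = SimulationConfig(read_len=100, coverage=35, error_rate=0.02)
        rng = np.random.default_rng(11)
        frags = fragment_regions([(0, src.length)], cfg, rng, seq_len=src.length)[:10_000]
        reads = generate_reads(frags, src, cfg, rng)
        mism = total = 0
        for r in reads:
            _, _, fs, fe, strand, _ = r.id.split(":")
            frag = src.sequence[int(fs) : int(fe)]
            expected = frag[: len(r)] if strand == "5p" else revcomp(frag)[: len(r)]
            mism += sum(a != b for a, b in zip(r.bases, expected))
            total += len(r)
        assert total > 500_000
        assert 0.018 <= mism / total <= 0.022

    def test_two_tier_qualities_are_calibrated(self):
        src = random_reference(10_000, seed=12)
        cfg = SimulationConfig(read_len=100, coverage=20)
        rng = np.random.default_rng(13)
        frags = fragment_regions([(0, src.length)], cfg, rng, seq_len=src.length)
        reads = generate_reads(frags, src, cfg, rng)
        quals = np.concatenate([r.quals for r in reads])
        implied = (10.0 ** (-quals / 10.0)).mean()
        assert implied == pytest.approx(0.02, rel=0.15)


class TestDataset:
    def test_same_seed_byte_identical(self):
        ref = random_reference(30_000, seed=14)
        cfg = SimulationConfig(read_len=75, coverage=3, seed=99)
        a = simulate_dataset(ref, cfg)
        b = simulate_dataset(ref, cfg)
        assert [(r.id, r.bases, r.quals.tolist()) for r in a.reads] == [
            (r.id, r.bases, r.quals.tolist()) for r in b.reads
        ]
        assert [(v.pos, v.type, v.ref, v.alt) for v in a.truth] == [
            (v.pos, v.type, v.ref, v.alt) for v in b.truth
        ]

    def test_read_count_tracks_coverage_arithmetic(self):
        ref = random_reference(100_000, seed=15)
        ds = simulate_dataset(ref, SimulationConfig(read_len=75, coverage=5, seed=16))
        # coverage * L / read_len reads expected, +/- Poisson noise
        assert len(ds.reads) == pytest.approx(5 * 100_000 / 75, rel=0.1)

    def test_truth_vcf_roundtrips(self, tmp_path):
        from sap.io_formats import read_vcf, write_vcf

        ref = random_reference(150_000, seed=17)
        ds = simulate_dataset(ref, SimulationConfig(seed=18))
        path = tmp_path / "truth.vcf"
        write_vcf(ds.truth, [ref], path)
        back = read_vcf(path)
        assert {(v.pos, v.type, v.ref, v.alt) for v in back} == {
            (v.pos, v.type, v.ref, v.alt) for v in ds.truth
        }

    def test_diploid_model_keeps_het_variants_off_second_haplotype(self):
        ref = random_reference(100_000, seed=19)
        cfg = SimulationConfig(seed=20, ploidy_model="diploid-5050")
        ds = simulate_dataset(ref, cfg)
        assert len(ds.haplotypes) == 2
        hom = [v for v in ds.truth if v.zygosity == "hom"]
        het = [v for v in ds.truth if v.zygosity == "het"]
        assert hom and het
        assert ds.haplotypes[1].sequence == apply_variants(ref, hom).sequence
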