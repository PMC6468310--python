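"""Per-pair sequence features: composition, folding profiles, codon usage."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from plastoperon import (
    FeatureConfig,
    FeatureExtractor,
    FeatureUndefined,
    GeneModel,
    PlastomeAnnotation,
    codon_usage_distance,
    compute_pair_features,
    enumerate_adjacent_pairs,
    extract_5utr_region,
    folding_profile,
    gc_content,
    gravy_margin,
    intergenic_distance,
    pair_conservation,
    position_margin_profile,
    profile_similarity,
)
from plastoperon.features import (
    FoldingProfile,
    expected_window_count,
    gravy,
    rscu_vector,
)
from plastoperon.genome_io import reverse_complement

from conftest import toy_genes


def random_seq(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("GGCC", 1.0), ("AT", 0.0), ("ANGN", 0.5)],
    )
    def test_worked_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_undefined_on_empty_or_all_n(self):
        for seq in ("", "NNNN"):
            with pytest.raises(FeatureUndefined):
                gc_content(seq)

    def test_binomial_sampling_recovers_rate(self):
        rng = np.random.default_rng(42)
        seq = random_seq(rng, 10_000, gc=0.3)
        assert gc_content(seq) == pytest.approx(0.30, abs=0.02)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = random_seq(rng, int(rng.integers(10, 500)))
            assert gc_content(s) == pytest.approx(gc_content(reverse_complement(s)))


class TestIntergenicDistance:
    def make_pair(self, span5, span3, genome_length=15_000, wraps=False):
        from plastoperon.genome_io import _make_pair

        g5 = GeneModel("g5", "CDS", "+", *span5)
        g3 = GeneModel("g3", "CDS", "+", *span3)
        return _make_pair(g5, g3, genome_length, wraps)

    def test_simple_gap(self):
        assert intergenic_distance(self.make_pair((0, 100), (150, 300))) == 50

    def test_overlap_negative(self):
        assert intergenic_distance(self.make_pair((0, 100), (90, 200))) == -10

    def test_wrap_modular(self):
        pair = self.make_pair((14_900, 15_000), (20, 120), wraps=True)
        assert intergenic_distance(pair) == 20


class TestFoldingProfile:
    def test_window_count_50nt(self):
        rng = np.random.default_rng(1)
        prof = folding_profile(random_seq(rng, 50), window=40, step=1)
        assert len(prof) == 11

    def test_homopolymer_zero_energy(self):
        prof = folding_profile("A" * 40, window=40)
        assert prof.energies.tolist() == [0.0]

    def test_short_sequence_empty_profile(self):
        assert len(folding_profile("ACGT" * 5, window=40)) == 0

    def test_energies_never_positive(self):
        rng = np.random.default_rng(3)
        prof = folding_profile(random_seq(rng, 120, gc=0.6))
        assert np.all(prof.energies <= 0)

    def test_structured_window_matches_standalone_engine(self):
        """Each window's energy equals RNAfold run standalone on that window."""
        seq = ("GGGGGAAAAAAAACCCCC" + "A" * 22)[:40]
        prof = folding_profile(seq, window=40)
        assert prof.energies[0] < 0
        out = subprocess.run(
            ["RNAfold", "--noPS"],
            input=seq.replace("T", "U") + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        standalone = float(out.splitlines()[1].rsplit("(", 1)[1].strip(" )"))
        assert prof.energies[0] == pytest.approx(standalone, abs=1e-6)


class TestUTRExtraction:
    def build(self, strand, start, end, length=2000):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, length)
        gene = GeneModel("g", "CDS", strand, start, end)
        ann = PlastomeAnnotation("toy", seq, circular=False, genes=[gene])
        return gene, ann

    def test_plus_strand_region(self):
        gene, ann = self.build("+", 500, 800)
        region = extract_5utr_region(gene, ann, upstream=100, downstream=50)
        assert region == ann.sequence[400:550]

    def test_minus_strand_region(self):
        gene, ann = self.build("-", 500, 800)
        region = extract_5utr_region(gene, ann, upstream=100, downstream=50)
        assert region == reverse_complement(ann.sequence[750:900])

    def test_linear_truncation(self):
        gene, ann = self.build("+", 30, 400)
        region = extract_5utr_region(gene, ann, upstream=100, downstream=50)
        assert region == ann.sequence[0:80]

    def test_roundtrip_on_synthetic_genome(self, sim_small):
        """Extracted regions re-locate to their recorded coordinates."""
        ann = sim_small.annotation
        checked = 0
        for gene in ann.genes:
            if gene.strand != "+" or gene.start < 100:
                continue
            region = extract_5utr_region(gene, ann)
            found = ann.sequence.find(region)
            if ann.sequence.count(region) == 1:
                assert found == gene.start - 100
                checked += 1
        assert checked >= 3


class TestProfileSimilarity:
    def profile(self, values):
        return FoldingProfile("x", 40, 1, np.asarray(values, dtype=float))

    def test_identical_profiles(self):
        p = self.profile([-1, -3, -2, -5, -4])
        assert profile_similarity(p, p) == pytest.approx(1.0)

    def test_negated_shifted_profile(self):
        p = self.profile([-1, -3, -2, -5, -4])
        q = self.profile(-p.energies + 2.0)
        assert profile_similarity(p, q) == pytest.approx(-1.0)

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        p = self.profile(-rng.random(30))
        q = self.profile(-rng.random(30))
        assert profile_similarity(p, q) == pytest.approx(profile_similarity(q, p))
        shifted = self.profile(q.energies - 1.5)
        assert profile_similarity(p, shifted) == pytest.approx(
            profile_similarity(p, q)
        )

    def test_too_few_windows_undefined(self):
        p = self.profile([-1, -2])
        with pytest.raises(FeatureUndefined):
            profile_similarity(p, p)

    def test_constant_profile_undefined(self):
        p = self.profile([-1, -1, -1, -1])
        q = self.profile([-1, -2, -3, -4])
        with pytest.raises(FeatureUndefined):
            profile_similarity(p, q)

    def test_null_correlation_small_for_independent_sequences(self):
        """Independent random sequences give |r| < 0.3 nearly always when the
        111 windows are non-overlapping (step = window), per a null
        simulation with independent window energies."""
        rng = np.random.default_rng(12)
        n_inside = 0
        reps = 200
        for _ in range(reps):
            a = folding_profile(random_seq(rng, 111 * 40), window=40, step=40)
            b = folding_profile(random_seq(rng, 111 * 40), window=40, step=40)
            if abs(profile_similarity(a, b)) < 0.3:
                n_inside += 1
        assert n_inside >= 0.95 * reps


class TestPositionMargins:
    def profile(self, values):
        return FoldingProfile("x", 40, 1, np.asarray(values, dtype=float))

    def test_identical_profiles_zero_margin(self):
        p = self.profile([-1, -2, -3])
        margins = position_margin_profile([p], [p])
        assert [m for _, m in margins] == [0.0, 0.0, 0.0]

    def test_constant_offsets_average(self):
        base = self.profile([-2.0, -4.0, -6.0])
        off1 = self.profile(base.energies - 1.0)
        off3 = self.profile(base.energies - 3.0)
        margins = position_margin_profile([base, base], [off1, off3])
        assert [m for _, m in margins] == pytest.approx([2.0, 2.0, 2.0])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(8)
        p5 = [self.profile(-rng.random(rng.integers(5, 12))) for _ in range(6)]
        p3 = [self.profile(-rng.random(rng.integers(5, 12))) for _ in range(6)]
        margins = dict(position_margin_profile(p5, p3))
        max_len = max(min(len(a), len(b)) for a, b in zip(p5, p3))
        for pos in range(max_len):
            diffs = [
                abs(a.energies[pos] - b.energies[pos])
                for a, b in zip(p5, p3)
                if pos < min(len(a), len(b))
            ]
            assert margins[pos] == pytest.approx(np.mean(diffs))


class TestCodonUsage:
    def test_identical_cds_zero(self):
        cds = "ATGTTTAAAGGGTAA"
        assert codon_usage_distance(cds, cds) == 0.0

    def test_two_family_hand_oracle(self):
        """Disjoint synonymous codons for a Phe+Lys toy protein.

        RSCU with family size 2: the used codon scores 2, the unused 0, so
        each of the four differing components contributes 2^2 = 4 and the
        distance is sqrt(16) = 4.
        """
        assert codon_usage_distance("TTTAAA", "TTCAAG") == pytest.approx(4.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            codons = [c for c in
                      ("".join(rng.choice(list("ACGT"), 3)) for _ in range(60))
                      if c not in ("TAA", "TAG", "TGA")]
            a = "".join(codons[:25])
            b = "".join(codons[25:50])
            assert codon_usage_distance(a, b) == pytest.approx(
                codon_usage_distance(b, a)
            )

    def test_rscu_vector_dimension(self):
        assert len(rscu_vector("ATGTTTAAA")) == 59

    def test_non_cds_rejected(self):
        with pytest.raises(ValueError):
            codon_usage_distance("ATGT", "ATGC")


class TestGravy:
    def test_hand_computed_margin(self):
        """M,I,I vs M,D,D on the Kyte-Doolittle scale: margin 16/3."""
        assert gravy_margin("ATGATTATTTAA", "ATGGATGATTAA") == pytest.approx(16 / 3)

    def test_identical_cds_zero(self):
        assert gravy_margin("ATGATTATTTAA", "ATGATTATTTAA") == 0.0

    def test_synonymous_recoding_invariance(self):
        a = "ATGATTATTTAA"
        b = "ATGATCATATAA"  # same protein M,I,I via different codons
        assert gravy(a) == pytest.approx(gravy(b))

    def test_internal_stop_reported(self):
        with pytest.raises(ValueError, match="stop"):
            gravy("ATGTAAATTTAA")


class TestPairConservation:
    def test_adjacent_in_three_of_four(self, sim_small):
        from plastoperon import make_reference_panel

        ann = sim_small.annotation
        conserved = make_reference_panel(ann, 3, rearrangement_rate=0.0, seed=1)
        shuffled = make_reference_panel(ann, 1, rearrangement_rate=1.0, seed=2)
        pairs = enumerate_adjacent_pairs(ann)
        values = [pair_conservation(p, conserved + shuffled) for p in pairs]
        assert all(v >= 0.75 for v in values)

    def test_never_cooccurring_pair_zero(self, sim_small):
        from plastoperon import make_reference_panel
        from plastoperon.genome_io import _make_pair

        ann = sim_small.annotation
        panel = make_reference_panel(ann, 4, rearrangement_rate=0.0, seed=3)
        alien5 = GeneModel("alienA", "CDS", "+", 0, 30)
        alien3 = GeneModel("alienB", "CDS", "+", 50, 90)
        pair = _make_pair(alien5, alien3, 1000, wraps=False)
        assert pair_conservation(pair, panel) == 0.0

    def test_matches_bruteforce_bigram_scan(self, sim_small):
        from plastoperon import make_reference_panel
        from plastoperon.features import normalize_gene_name

        ann = sim_small.annotation
        panel = make_reference_panel(ann, 5, rearrangement_rate=0.5, seed=4)
        pairs = enumerate_adjacent_pairs(ann)[:10]
        for pair in pairs:
            expected = 0
            n5, n3 = (
                normalize_gene_name(pair.gene5.gene_id),
                normalize_gene_name(pair.gene3.gene_id),
            )
            s5, s3 = pair.gene5.strand, pair.gene3.strand
            flip = {"+": "-", "-": "+"}
            for ref in panel:
                names = [normalize_gene_name(g.gene_id) for g in ref.genes]
                strands = [g.strand for g in ref.genes]
                k = len(names)
                hit = False
                for i in range(k):
                    j = (i + 1) % k
                    if names[i] == n5 and names[j] == n3 and (
                        strands[i], strands[j]) == (s5, s3):
                        hit = True
                    if names[i] == n3 and names[j] == n5 and (
                        strands[j], strands[i]) == (flip[s5], flip[s3]):
                        hit = True
                expected += hit
            assert pair_conservation(pair, panel) == pytest.approx(expected / 5)


class TestAssembledVectors:
    def test_mixed_pair_lacks_cds_only_features(self, sim_small, small_pairs):
        mixed = next(p for p in small_pairs if p.pair_group == "mixed")
        vec = compute_pair_features(mixed, sim_small.annotation)
        assert "cub_distance" not in vec.features
        assert "gravy_margin" not in vec.features

    def test_cds_pair_has_cds_features(self, sim_small, small_pairs):
        cds = next(p for p in small_pairs if p.pair_group == "CDS")
        vec = compute_pair_features(cds, sim_small.annotation)
        assert "cub_distance" in vec.features
        assert "gravy_margin" in vec.features

    def test_deterministic(self, sim_small, small_pairs):
        pair = small_pairs[0]
        v1 = compute_pair_features(pair, sim_small.annotation)
        v2 = compute_pair_features(pair, sim_small.annotation)
        assert v1.features == v2.features

    def test_planted_directions(self, small_table, small_labels):
        """OP pairs show shorter spacers, lower spacer GC and higher
        folding-profile correlation than NOP pairs, as planted."""
        y = small_labels.reindex(small_table.index)
        op, nop = small_table[y == 1], small_table[y == 0]
        assert op["igs_length"].mean() < nop["igs_length"].mean()
        assert op["igs_gc"].mean() < nop["igs_gc"].mean()
        assert op["fold_profile_pearson"].mean() > nop["fold_profile_pearson"].mean()

    def test_missing_features_are_empty_cells(self, small_table, tmp_path):
        from plastoperon.features import write_feature_table

        path = tmp_path / "features.tsv"
        write_feature_table(small_table, path)
        body = path.read_text()
        assert "\t\t" in body or body.count("nan") == 0
        back = pd.read_csv(path, sep="\t", index_col="pair_id")
        assert back.shape == small_table.shape
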