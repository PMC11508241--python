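"""SNV ingestion, channel classification, catalogs and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bactsig as bs
from bactsig.channels import (
    BASES,
    CHANNELS_96,
    COMPLEMENT,
    PYRIMIDINES,
    channel_of,
)
from bactsig.catalog import gene_position, read_calls
from bactsig.errors import (
    ClassificationError,
    ConfigurationError,
    FormatError,
    ReferenceMismatchError,
)

# ---------------------------------------------------------------------------
# independent brute-force classifier (string-based, enumerates both strands)


def _brute_force_channel(seq, pos, ref, alt):
    window = seq[pos - 2 : pos + 1]
    if ref in "CT":
        return f"{window[0]}[{ref}>{alt}]{window[2]}"
    rc = "".join(COMPLEMENT[b] for b in reversed(window))
    return f"{rc[0]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{rc[2]}"


class TestReadSnvs:
    def test_empty_body(self, vcf_writer):
        assert bs.read_snvs(vcf_writer([]), "s") == []

    def test_pass_filter_and_indel_tally(self, vcf_writer):
        path = vcf_writer(
            [
                (100, "A", "G", "PASS"),
                (200, "C", "T", "PASS"),
                (300, "G", "T", "PASS"),
                (400, "T", "C", "q10"),
                (500, "CTT", "C", "PASS"),  # deletion
            ]
        )
        cs = read_calls(path, "s")
        assert len(cs.snvs) == 3
        assert cs.n_deletions == 1
        assert cs.n_insertions == 0
        assert cs.n_non_pass == 1

    def test_multiallelic_split(self, vcf_writer):
        path = vcf_writer([(100, "A", "G,T", "PASS")])
        snvs = bs.read_snvs(path, "s")
        assert sorted(s.alt for s in snvs) == ["G", "T"]

    def test_malformed_vcf(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a VCF\n")
        with pytest.raises(FormatError):
            bs.read_snvs(bad, "s")

    def test_invalid_snv_record(self):
        with pytest.raises(FormatError):
            bs.SnvRecord("s", "chr", 10, "C", "C")
        with pytest.raises(FormatError):
            bs.SnvRecord("s", "chr", 0, "C", "T")


class TestTrinucleotideContext:
    def test_pyrimidine_reference(self):
        genome = bs.Genome("g", "ACGTA")
        snv = bs.SnvRecord("s", "g", 2, "C", "T")
        assert bs.trinucleotide_context(genome, snv) == "A[C>T]G"

    def test_purine_reference_collapses(self):
        genome = bs.Genome("g", "ACGTA")
        snv = bs.SnvRecord("s", "g", 3, "G", "A")
        assert bs.trinucleotide_context(genome, snv) == "A[C>T]G"

    def test_reference_mismatch(self):
        genome = bs.Genome("g", "ACGTA")
        with pytest.raises(ReferenceMismatchError):
            bs.trinucleotide_context(genome, bs.SnvRecord("s", "g", 2, "G", "A"))

    def test_terminal_position(self):
        genome = bs.Genome("g", "ACGTA")
        with pytest.raises(ClassificationError):
            bs.trinucleotide_context(genome, bs.SnvRecord("s", "g", 1, "A", "G"))

    def test_brute_force_equivalence_random_genome(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list(BASES), size=1000))
        genome = bs.Genome("g", seq)
        for pos in range(2, 1000):
            ref = seq[pos - 1]
            for alt in BASES.replace(ref, ""):
                snv = bs.SnvRecord("s", "g", pos, ref, alt)
                assert bs.trinucleotide_context(genome, snv) == _brute_force_channel(
                    seq, pos, ref, alt
                )

    @settings(max_examples=200, derandomize=True)
    @given(
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
        five=st.sampled_from("ACGT"),
        three=st.sampled_from("ACGT"),
    )
    def test_strand_collapse_idempotent(self, ref, alt, five, three):
        """A variant and its complementary rendering share one channel."""
        if ref == alt:
            return
        direct = channel_of(ref, alt, five, three)
        flipped = channel_of(
            COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[three], COMPLEMENT[five]
        )
        assert direct == flipped
        assert direct in CHANNELS_96


class TestBuildCatalog:
    def test_zero_snvs_zero_row(self, default_sim):
        cat = bs.build_catalog({"empty": []}, default_sim.genome)
        assert cat.shape == (1, 96) and cat.to_numpy().sum() == 0

    def test_one_snv_per_channel(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(BASES), size=20_000))
        genome = bs.Genome("g", seq)
        snvs = []
        for channel in CHANNELS_96:
            found = False
            for pos in range(2, len(seq)):
                ref = seq[pos - 1]
                for alt in BASES.replace(ref, ""):
                    if _brute_force_channel(seq, pos, ref, alt) == channel:
                        snvs.append(bs.SnvRecord("s", "g", pos, ref, alt))
                        found = True
                        break
                if found:
                    break
            assert found, channel
        cat = bs.build_catalog({"s": snvs}, genome)
        assert (cat.loc["s"].to_numpy() == 1).all()

    def test_catalog_matches_truth_histogram(self, default_sim, catalog96):
        truth = default_sim.result.channel_histogram()
        assert (catalog96.loc[truth.index].to_numpy() == truth.to_numpy()).all()

    def test_row_sums_conserved(self, catalog96, sim_vcfs):
        for sid, snvs in sim_vcfs.snv_lists.items():
            assert catalog96.loc[sid].sum() == len(snvs)

    def test_stranded_marginalizes_to_96(self, catalog96, stranded_catalog):
        marg = stranded_catalog.marginal_96()
        assert (marg.loc[catalog96.index].to_numpy() == catalog96.to_numpy()).all()

    def test_stranded_requires_annotation(self, default_sim):
        with pytest.raises(ConfigurationError):
            bs.build_catalog({"s": []}, default_sim.genome, stranded=True)


class TestClassifyStrand:
    genes = pd.DataFrame(
        {
            "gene_id": ["fwd", "rev"],
            "start": [100, 500],
            "end": [200, 600],
            "strand": ["+", "-"],
        }
    )

    def _snv(self, pos, ref="C", alt="T"):
        return bs.SnvRecord("s", "g", pos, ref, alt)

    def test_pyrimidine_on_coding_strand_is_untranscribed(self):
        assert bs.classify_strand(self._snv(150), self.genes) == "untranscribed"

    def test_same_variant_minus_strand_gene_is_transcribed(self):
        assert bs.classify_strand(self._snv(550), self.genes) == "transcribed"

    def test_purine_reference_flips_label(self):
        assert bs.classify_strand(self._snv(150, "G", "A"), self.genes) == "transcribed"

    def test_inverted_convention(self):
        assert (
            bs.classify_strand(self._snv(150), self.genes, convention="inverted")
            == "transcribed"
        )

    def test_intergenic_and_ambiguous(self):
        assert bs.classify_strand(self._snv(300), self.genes) == "intergenic"
        overlapping = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "start": [100, 150],
                "end": [200, 250],
                "strand": ["+", "-"],
            }
        )
        assert bs.classify_strand(self._snv(160), overlapping) == "ambiguous"

    def test_planted_labels_recovered(self, default_sim):
        """classify_strand reproduces the simulator's per-mutation labels."""
        index = bs.GeneIndex(default_sim.genes)
        for clone in default_sim.result.clones:
            for m in clone.mutations:
                snv = bs.SnvRecord(
                    clone.clone_id, default_sim.genome.name, m.pos, m.ref, m.alt
                )
                assert bs.classify_strand(snv, index) == m.strand_label


class TestTrinucFrequencies:
    def test_homopolymer(self):
        freqs = bs.genome_trinucleotide_frequencies("AAAA")
        assert freqs["TTT"] == 1.0  # AAA pooled into its pyrimidine-centered class

    def test_acgt_hand_enumeration(self):
        freqs = bs.genome_trinucleotide_frequencies("ACGT")
        assert freqs["ACG"] == 1.0  # windows ACG and CGT both collapse to ACG

    def test_sums_to_one(self, default_sim):
        freqs = bs.genome_trinucleotide_frequencies(default_sim.genome)
        assert abs(freqs.sum() - 1.0) <= 1e-12

    def test_brute_force_sliding_window(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(BASES), size=10_000))
        counts = {}
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if tri[1] not in PYRIMIDINES:
                tri = "".join(COMPLEMENT[b] for b in reversed(tri))
            counts[tri] = counts.get(tri, 0) + 1
        total = sum(counts.values())
        freqs = bs.genome_trinucleotide_frequencies(seq)
        for ctx, n in counts.items():
            assert freqs[ctx] == pytest.approx(n / total, abs=1e-12)

    def test_non_acgt_skipped(self):
        freqs = bs.genome_trinucleotide_frequencies("ACGTNACGT")
        assert abs(freqs.sum() - 1.0) <= 1e-12


def _table1_records(n_gc_at, n_at_gc, n_gc_ta, n_at_ta, n_at_cg=0, n_del=0):
    """Render six-type counts as VCF tuples, alternating the two strand
    representations of each base-pair substitution."""
    recs = []
    pos = 1000
    renderings = {
        "G:C>A:T": [("C", "T"), ("G", "A")],
        "A:T>G:C": [("A", "G"), ("T", "C")],
        "G:C>T:A": [("C", "A"), ("G", "T")],
        "A:T>T:A": [("A", "T"), ("T", "A")],
        "A:T>C:G": [("A", "C"), ("T", "G")],
    }
    for six, n in [
        ("G:C>A:T", n_gc_at),
        ("A:T>G:C", n_at_gc),
        ("G:C>T:A", n_gc_ta),
        ("A:T>T:A", n_at_ta),
        ("A:T>C:G", n_at_cg),
    ]:
        for i in range(n):
            ref, alt = renderings[six][i % 2]
            recs.append((pos, ref, alt, "PASS"))
            pos += 10
    for _ in range(n_del):
        recs.append((pos, "CAT", "C", "PASS"))
        pos += 10
    return recs


class TestMutationTypeSummary:
    def test_no_tca_like_group_total(self, vcf_writer):
        """A fixture shaped like a treated-group column (260 G:C→A:T in mixed
        strand renderings, 7 A:T→G:C, 1 G:C→T:A, 1 A:T→T:A) totals 269."""
        path = vcf_writer(_table1_records(260, 7, 1, 1), name="notca.vcf")
        summary = bs.mutation_type_summary({"NO-TCA": [path]})
        assert summary.loc["G:C>A:T", "NO-TCA"] == 260
        assert summary.loc["A:T>G:C", "NO-TCA"] == 7
        assert summary.loc["G:C>T:A", "NO-TCA"] == 1
        assert summary.loc["A:T>T:A", "NO-TCA"] == 1
        assert summary.loc["Total", "NO-TCA"] == 269

    def test_control_like_group_total(self, vcf_writer):
        path = vcf_writer(_table1_records(1, 0, 0, 0, n_at_cg=1), name="ctrl.vcf")
        summary = bs.mutation_type_summary({"control": [path]})
        assert summary.loc["G:C>A:T", "control"] == 1
        assert summary.loc["A:T>C:G", "control"] == 1
        assert summary.loc["Total", "control"] == 2

    def test_empty_input(self, vcf_writer):
        summary = bs.mutation_type_summary({"empty": [vcf_writer([])]})
        assert (summary["empty"] == 0).all()

    def test_indels_counted_in_total(self, vcf_writer):
        path = vcf_writer(_table1_records(2, 0, 0, 0, n_del=1), name="d.vcf")
        summary = bs.mutation_type_summary({"g": [path]})
        assert summary.loc["Deletion", "g"] == 1
        assert summary.loc["Total", "g"] == 3


class TestTargetSiteReport:
    def test_flagged_at_position_205(self):
        snvs = {"c1": [bs.SnvRecord("c1", "g", 1204, "C", "T")]}
        report = bs.target_site_report(snvs, (1000, 1299, "+"), {205, 206})
        assert list(report.gene_pos) == [205]
        assert list(report.substitution) == ["G:C>A:T"]

    def test_unflagged_without_target_hits(self):
        snvs = {"c1": [bs.SnvRecord("c1", "g", 50, "C", "T")]}
        report = bs.target_site_report(snvs, (1000, 1299, "+"), {205, 206})
        assert report.empty

    def test_minus_strand_coordinate_oracle(self):
        """gene_position agrees with full enumeration over a 300-bp gene."""
        start, end = 1001, 1300
        for genome_pos in range(start, end + 1):
            assert gene_position(genome_pos, start, end, "-") == end - genome_pos + 1
            assert gene_position(genome_pos, start, end, "+") == genome_pos - start + 1
        snvs = {"c1": [bs.SnvRecord("c1", "g", end - 205 + 1, "C", "T")]}
        report = bs.target_site_report(snvs, (start, end, "-"), {205, 206})
        assert list(report.gene_pos) == [205]

    def test_position_outside_gene(self):
        with pytest.raises(ConfigurationError):
            bs.target_site_report({}, (1000, 1299, "+"), {500})


def test_six_type_total_includes_indels_invariant(sim_vcfs, catalog96):
    """Six-type grand total equals classified SNVs + indels per sample."""
    groups = {sid: [path] for sid, path in sim_vcfs.paths.items()}
    summary = bs.mutation_type_summary(groups)
    for sid in catalog96.index:
        assert summary.loc["Total", sid] == catalog96.loc[sid].sum()
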