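"""Mutation rates, spectra, synonymity and support-group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longumi.mut_report import (
    NONCODING,
    NONSYNONYMOUS,
    SYNONYMOUS,
    CdsRecord,
    aggregate_rates,
    classify_synonymity,
    compare_support_groups,
    mutation_rate,
    mutation_spectrum,
    partition_by_sharing,
    synonymity_table,
)
from longumi.variant_call import Variant


def _variant(position, ref, alt, cluster="M0"):
    return Variant(
        cluster_id=cluster, position=position, ref_allele=ref, alt_allele=alt,
        base_called_support=0.9, forward_support_reads=5, reverse_support_reads=5,
    )


class TestMutationRate:
    def test_zero_mutations_rate_zero(self):
        report = mutation_rate(0, coverage=5000)
        assert report.rate_per_bp == 0.0
        assert report.rate_per_genome == 0.0

    def test_arithmetic(self):
        report = mutation_rate(10, coverage=12_500, genome_length=12_500)
        assert report.rate_per_bp == pytest.approx(8.0e-4)
        assert report.rate_per_genome == pytest.approx(10.0)

    def test_per_genome_is_rate_times_genome_length(self):
        report = mutation_rate(3, coverage=2000, genome_length=16_000)
        assert report.rate_per_genome == pytest.approx(report.rate_per_bp * 16_000)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(1, coverage=0)

    def test_parameter_recovery_from_simulated_molecules(self):
        # 200 molecules mutated at 8e-4/bp: the recovered mean rate must sit
        # within 3 SEM of the generating value
        from longumi.simdata import SimConfig, generate_molecules, generate_reference

        ref = generate_reference(2000, 0.5, 19)
        cfg = SimConfig(reference_length=2000, n_molecules=200, mutation_rate=8e-4, seed=19)
        molecules, _ = generate_molecules(ref, cfg)
        reports = [
            mutation_rate(len(m.mutations), coverage=2000, cluster_id=m.molecule_id)
            for m in molecules
        ]
        agg = aggregate_rates(reports)
        assert abs(agg["mean_rate_per_bp"] - 8e-4) <= 3 * agg["sem_rate_per_bp"]


class TestMutationSpectrum:
    def test_single_substitution_type_dominates_its_row(self):
        variants = [_variant(p, "A", "G", f"M{p}") for p in (5, 9, 13)]
        table = mutation_spectrum(variants, "")
        row = table.set_index(["ref_base", "alt_base"])
        assert row.loc[("A", "G"), "proportion"] == 1.0
        assert row.loc[("A", "T"), "proportion"] == 0.0

    def test_proportions_follow_caption_formula(self):
        variants = [
            _variant(1, "A", "G", "M0"), _variant(2, "A", "G", "M1"),
            _variant(3, "A", "G", "M2"), _variant(4, "A", "T", "M3"),
        ]
        table = mutation_spectrum(variants, "").set_index(["ref_base", "alt_base"])
        assert table.loc[("A", "G"), "proportion"] == pytest.approx(0.75)
        assert table.loc[("A", "T"), "proportion"] == pytest.approx(0.25)

    def test_rows_renormalise_after_any_subset_filter(self):
        rng = np.random.default_rng(7)
        variants = []
        for i in range(200):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(_variant(i + 1, str(ref), str(alt), f"M{i}"))
        table = mutation_spectrum(variants[:120], "")
        for ref_base, group in table.groupby("ref_base"):
            if group["count"].sum():
                assert group["proportion"].sum() == pytest.approx(1.0)

    def test_uniform_substitution_choice_near_one_third(self):
        rng = np.random.default_rng(11)
        variants = []
        for i in range(3000):
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(_variant(i + 1, ref, alt, f"M{i}"))
        table = mutation_spectrum(variants, "")
        # each conditional proportion within a few multinomial SDs of 1/3
        assert (table["proportion"] - 1 / 3).abs().max() < 0.05

    def test_indel_variants_rejected(self):
        with pytest.raises(ValueError):
            mutation_spectrum([_variant(1, "A", "DEL")], "")


class TestClassifySynonymity:
    # reference holding codons CTA (Leu) and ATA (Met, mito code) in frame
    reference = "CTAATA" + "A" * 24

    def _cds(self, strand="+"):
        return [CdsRecord(gene="g", start=1, end=6, strand=strand, frame=0)]

    def test_third_position_leu_to_leu_synonymous(self):
        # CTA -> CTG is Leu -> Leu under the vertebrate mitochondrial code
        v = _variant(3, "A", "G")
        assert classify_synonymity(v, self._cds(), self.reference) == SYNONYMOUS

    def test_first_position_met_to_leu_nonsynonymous(self):
        # ATA (Met in the mito code) -> TTA (Leu)
        v = _variant(4, "A", "T")
        assert classify_synonymity(v, self._cds(), self.reference) == NONSYNONYMOUS

    def test_outside_cds_is_noncoding(self):
        v = _variant(20, "A", "G")
        assert classify_synonymity(v, self._cds(), self.reference) == NONCODING

    def test_minus_strand_codon_reconstruction(self):
        # reference TAG on + strand = CTA codon on - strand (Leu);
        # + strand T>C at the codon's last - strand position: CTA -> CTG? work
        # through revcomp: ref segment positions 1..3 'TAG' -> revcomp 'CTA';
        # changing position 1 T>C gives 'CAG' -> revcomp 'CTG' (still Leu)
        reference = "TAG" + "A" * 27
        cds = [CdsRecord(gene="g", start=1, end=3, strand="-", frame=0)]
        v = _variant(1, "T", "C")
        assert classify_synonymity(v, cds, reference) == SYNONYMOUS

    def test_synonymity_table_proportions(self):
        variants = [_variant(3, "A", "G"), _variant(4, "A", "T"), _variant(20, "A", "G")]
        table = synonymity_table(variants, self._cds(), self.reference).set_index("class")
        assert table.loc[SYNONYMOUS, "count"] == 1
        assert table.loc[SYNONYMOUS, "proportion_of_coding"] == pytest.approx(0.5)
        assert table.loc[NONCODING, "count"] == 1


class TestCompareSupportGroups:
    def test_identical_groups_p_value_one(self):
        group = [0.9, 0.85, 0.8, 0.95]
        out = compare_support_groups(group, group)
        assert out.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.9, 0.02, size=50)
        out = compare_support_groups(a, a - 0.5)
        assert out.p_value < 1e-3

    def test_type_one_error_calibrated(self):
        # equal-mean groups over 1,000 replicates: rejection rate at
        # alpha = 0.05 within 0.05 +/- 0.02
        rng = np.random.default_rng(5)
        a = rng.normal(0.9, 0.05, size=(1000, 30))
        b = rng.normal(0.9, 0.05, size=(1000, 30))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert abs((p < 0.05).mean() - 0.05) <= 0.02

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_support_groups([0.9], [0.8, 0.9])


class TestPartitionBySharing:
    def test_planted_polymorphisms_labelled_polymorphic(self, zero_error_polymorphic_pipeline):
        result, manifest = zero_error_polymorphic_pipeline
        frame = pd.DataFrame(
            [
                {"POS": v.position, "REF": v.ref_allele, "ALT": v.alt_allele,
                 "CLUSTER": v.cluster_id}
                for v in result.variants
            ]
        )
        labelled = partition_by_sharing(frame)
        poly_positions = {p for p, _, _ in manifest.polymorphic_positions}
        assert poly_positions  # scenario plants shared variants
        for _, row in labelled.iterrows():
            expected = "polymorphic" if row["POS"] in poly_positions else "heteroplasmic"
            assert row["SHARING"] == expected
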