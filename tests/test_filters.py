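"""The four exclusion steps, their composition, and the audit trace."""

import pytest

from conftest import brute_force_survivors, random_cohort
from mendelsieve.filters import (
    run_cascade,
    step1_consequence,
    step2_frequency,
    step3_recessive_zygosity,
    step4_benign_consensus,
)
from mendelsieve.model import (
    FrequencyEvidence,
    GenePanelEntry,
    GenotypeCall,
    PredictorCalls,
    VariantRecord,
)


def make_variant(**overrides):
    base = dict(
        variant_id="ABCA4:c.1A>G",
        gene="ABCA4",
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        cdna_name="c.1A>G",
        protein_name="p.X1Y",
        consequence="missense",
    )
    base.update(overrides)
    return VariantRecord(**base)


class TestStep1Consequence:
    def test_canonical_splice_intronic_kept(self):
        v = make_variant(consequence="intronic", cdna_name="c.4773+1G>T", protein_name="")
        assert step1_consequence(v)

    def test_external_splice_flag_rescues_synonymous(self):
        v = make_variant(consequence="synonymous", splice_flag=True)
        assert step1_consequence(v)

    def test_synonymous_without_splice_effect_dropped(self):
        v = make_variant(consequence="synonymous", cdna_name="c.300G>A")
        assert not step1_consequence(v)

    def test_protein_altering_classes_always_kept(self):
        for csq in ("missense", "nonsense", "frameshift", "inframe_indel", "splice_site"):
            assert step1_consequence(make_variant(consequence=csq))

    def test_deep_intronic_dropped(self):
        v = make_variant(consequence="intronic", cdna_name="c.100-100A>G")
        assert not step1_consequence(v)

    def test_unparseable_name_means_no_rescue_with_warning(self):
        v = make_variant(consequence="intronic", cdna_name="IVS40+1G>T")
        with pytest.warns(UserWarning, match="unparseable"):
            assert not step1_consequence(v)


class TestStep2Frequency:
    def test_common_variant_dropped(self):
        v = make_variant(freq_evidence=(FrequencyEvidence("S", maf=0.02),))
        assert not step2_frequency(v)

    def test_rare_counted_variant_kept(self):
        v = make_variant(
            freq_evidence=(FrequencyEvidence("ExAC", allele_count=21, allele_number=121302),)
        )
        assert step2_frequency(v)

    def test_boundary_exactly_at_threshold_kept(self):
        v = make_variant(freq_evidence=(FrequencyEvidence("S", maf=0.01),))
        assert step2_frequency(v)

    def test_missing_frequency_kept(self):
        assert step2_frequency(make_variant())

    def test_threshold_is_configurable(self):
        v = make_variant(freq_evidence=(FrequencyEvidence("S", maf=0.02),))
        assert step2_frequency(v, threshold=0.05)


class TestStep4BenignConsensus:
    def test_one_damaging_call_keeps(self):
        v = make_variant(predictor_calls=PredictorCalls("B", "D", "D"))
        assert step4_benign_consensus(v)

    def test_unanimous_benign_drops(self):
        v = make_variant(predictor_calls=PredictorCalls("B", "T", "N"))
        assert not step4_benign_consensus(v)

    def test_na_never_counts_toward_consensus(self):
        v = make_variant(predictor_calls=PredictorCalls("B", "T", "NA"))
        assert step4_benign_consensus(v)

    def test_truncating_bypasses_even_all_na(self):
        v = make_variant(consequence="frameshift", predictor_calls=PredictorCalls())
        assert step4_benign_consensus(v)

    def test_splice_site_bypasses(self):
        v = make_variant(consequence="splice_site", predictor_calls=PredictorCalls())
        assert step4_benign_consensus(v)


class TestStep3RecessiveZygosity:
    AR = GenePanelEntry("ABCA4", "AR")
    AD = GenePanelEntry("PRPH2", "AD")

    def test_single_het_in_recessive_gene_dropped(self):
        calls = [GenotypeCall("P1", "V1", "het")]
        assert step3_recessive_zygosity(self.AR, calls) == {("P1", "V1"): False}

    def test_homozygote_kept(self):
        calls = [GenotypeCall("P1", "V1", "hom")]
        assert step3_recessive_zygosity(self.AR, calls) == {("P1", "V1"): True}

    def test_two_distinct_hets_kept(self):
        calls = [GenotypeCall("P1", "V1", "het"), GenotypeCall("P1", "V2", "het")]
        assert all(step3_recessive_zygosity(self.AR, calls).values())

    def test_dominant_gene_single_het_kept(self):
        calls = [GenotypeCall("P1", "V1", "het")]
        assert step3_recessive_zygosity(self.AD, calls) == {("P1", "V1"): True}


class TestRunCascade:
    def test_fixture_survivors_are_exactly_the_published_pairs(self, table1_pipeline, table1):
        cascade, _ = table1_pipeline
        assert cascade.survivor_pairs == table1.table1_pairs

    def test_every_decoy_removed_at_designed_step(self, table1_pipeline, table1):
        cascade, _ = table1_pipeline
        for (pid, vid), decision in cascade.trace.decisions.items():
            if vid in table1.decoy_expected_step:
                assert decision.status == table1.decoy_expected_step[vid], (pid, vid)

    def test_empty_cohort_empty_trace(self, full_panel):
        result = run_cascade({}, [], full_panel)
        assert result.trace.decisions == {}
        assert result.survivors == []

    def test_all_common_cohort_fully_removed_at_step2(self, full_panel):
        v = make_variant(freq_evidence=(FrequencyEvidence("S", maf=0.3),))
        calls = [GenotypeCall("P1", v.variant_id, "het"), GenotypeCall("P2", v.variant_id, "hom")]
        result = run_cascade({v.variant_id: v}, calls, full_panel)
        assert result.trace.counts()["removed_step2"] == 2
        assert result.survivors == []

    def test_trace_partitions_input_pairs(self, table1_pipeline, table1):
        cascade, _ = table1_pipeline
        counts = cascade.trace.counts()
        assert sum(counts.values()) == len(table1.genotypes)
        assert set(cascade.trace.decisions) == {
            (c.proband_id, c.variant_id) for c in table1.genotypes
        }

    def test_monotone_survivors_subset_of_input(self, full_panel):
        variants, genotypes, panel = random_cohort(seed=11)
        result = run_cascade(variants, genotypes, panel)
        assert result.survivor_pairs <= {(c.proband_id, c.variant_id) for c in genotypes}

    def test_off_panel_gene_flagged_not_zygosity_filtered(self):
        v = make_variant(variant_id="ZZZ9:c.1A>G", gene="ZZZ9")
        calls = [GenotypeCall("P1", v.variant_id, "het")]
        result = run_cascade({v.variant_id: v}, calls, {"ABCA4": GenePanelEntry("ABCA4", "AR")})
        assert result.off_panel_genes == {"ZZZ9"}
        # a lone het in an off-panel gene is NOT removed by the recessive rule
        assert result.survivor_pairs == {("P1", v.variant_id)}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        variants, genotypes, panel = random_cohort(seed=seed)
        result = run_cascade(variants, genotypes, panel)
        assert result.survivor_pairs == brute_force_survivors(variants, genotypes, panel)

    def test_step_order_insensitive_on_published_calls(self, table1, full_panel):
        """On the published genotype calls, applying the recessive-zygosity
        rule before the benign consensus (the strict printed 1-2-3-4 order)
        yields the same survivors as applying it last.  The two orders can
        differ only for probands whose gene group mixes a pathogenic het
        with unanimously benign hets — a pattern the published causative
        table has none of."""
        published = {
            vid for vid in table1.variants if vid not in table1.decoy_expected_step
        }
        calls = [c for c in table1.genotypes if c.variant_id in published]

        survivors_strict = set()
        passing12 = [
            c
            for c in calls
            if step1_consequence(table1.variants[c.variant_id])
            and step2_frequency(table1.variants[c.variant_id])
        ]
        groups = {}
        for c in passing12:
            groups.setdefault((c.proband_id, table1.variants[c.variant_id].gene), []).append(c)
        for (pid, gene), members in groups.items():
            verdicts = step3_recessive_zygosity(full_panel.get(gene), members)
            for c in members:
                if verdicts[(c.proband_id, c.variant_id)] and step4_benign_consensus(
                    table1.variants[c.variant_id]
                ):
                    survivors_strict.add((c.proband_id, c.variant_id))
        result = run_cascade(table1.variants, calls, full_panel)
        assert result.survivor_pairs == survivors_strict
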