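"""Synthetic call-set generator: determinism, noise model, scenario
structure, fixture round-trips, and the encoded six-patient cohort."""

import json

import numpy as np
import pytest

from mmclone import (
    classify_patient_clonality,
    expected_vaf,
    load_case,
    load_manifest,
    shared_private_partition,
    simulate_patient,
    write_fixture,
)
from mmclone.features import snv_feature_key
from mmclone.simulate import SimulationConfig, SimulationError, TruthRecord


class TestExpectedVaf:
    @pytest.mark.parametrize("c,state,want", [
        (0.80, "het_diploid", 0.40),
        (0.0, "het_diploid", 0.0),
        (0.0, "hemizygous", 0.0),
        (1.0, "hemizygous", 1.0),
        (0.6, "cn_loh", 0.6),
        (0.5, "hemizygous", 0.5 / 1.5),
    ])
    def test_copy_state_formulas(self, c, state, want):
        assert expected_vaf(c, state) == pytest.approx(want)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_vaf(1.5)
        with pytest.raises(ValueError):
            expected_vaf(0.5, "triploid")


class TestConfigValidation:
    def test_invalid_scenario_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(scenario="polyclonal")

    def test_single_lesion_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(lesions_per_patient=1)

    def test_bad_clonal_fraction_range_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(clonal_fraction_range=(0.0, 0.5))
        with pytest.raises(SimulationError):
            SimulationConfig(clonal_fraction_range=(0.9, 0.5))


class TestSimulatePatient:
    def test_deterministic_given_seed_and_index(self):
        config = SimulationConfig(seed=17)
        assert simulate_patient(config, 4) == simulate_patient(config, 4)

    def test_different_indices_differ(self):
        config = SimulationConfig(seed=17)
        assert simulate_patient(config, 0) != simulate_patient(config, 1)

    def test_independent_scenario_shares_nothing(self):
        config = SimulationConfig(scenario="independent", seed=5)
        case, truth = simulate_patient(config, 0)
        assert truth.truncal_features == []
        partition = shared_private_partition(case)
        assert partition.shared_by_all == set()

    def test_monoclonal_scenario_has_truncal_features(self):
        config = SimulationConfig(seed=5)
        case, truth = simulate_patient(config, 0)
        assert truth.truncal_features
        partition = shared_private_partition(case)
        assert set(truth.truncal_features) <= partition.shared_by_all

    def test_s4_like_configuration_classified_monoclonal(self):
        """A founding clone with a chr22 deletion, branching into lesions
        with distinct private driver SNVs, is called monoclonal."""
        config = SimulationConfig(
            seed=23, n_truncal_snv=0,
            truncal_cnv_events=(("chr22", "deletion"),),
            n_private_snv_per_lesion=1, sequencing_depth=100000)
        case, truth = simulate_patient(config, 0)
        assert truth.truncal_features == ["chr22:deletion"]
        assert classify_patient_clonality(case).verdict == "monoclonal"

    def test_observed_vaf_binomial_mean(self):
        """Mean observed VAF over replicate draws at depth 1e4 sits inside
        the 99% CI of the analytic binomial mean c/2 = 0.40."""
        config = SimulationConfig(
            seed=101, clonal_fraction_range=(0.8, 0.8),
            sequencing_depth=10_000, n_truncal_snv=1,
            n_private_snv_per_lesion=0, truncal_cnv_events=(),
            private_cnv_events_per_lesion=0,
            n_artifact_snv_per_lesion=0, driver_panel_injection=False)
        vafs = []
        for i in range(200):
            case, truth = simulate_patient(config, i)
            for lesion in case.lesions:
                (variant,) = lesion.variants
                vafs.append(variant.vaf)
        p = 0.40
        se = np.sqrt(p * (1 - p) / config.sequencing_depth / len(vafs))
        assert abs(np.mean(vafs) - p) < 2.58 * se

    def test_vaf_mean_converges_at_high_depth(self):
        """Empirical mean of observed VAF matches expected_vaf within 3
        standard errors at depth 1e5."""
        rng_checks = [(0.7, "het_diploid"), (0.5, "hemizygous"),
                      (0.9, "cn_loh")]
        config = SimulationConfig(seed=55, sequencing_depth=100_000)
        for c, state in rng_checks:
            p = expected_vaf(c, state)
            rng = np.random.default_rng(1)
            draws = rng.binomial(config.sequencing_depth, p, size=50) \
                / config.sequencing_depth
            se = np.sqrt(p * (1 - p) / config.sequencing_depth / 50)
            assert abs(draws.mean() - p) < 3 * se

    def test_truth_clonal_fractions_cover_every_truth_feature(self):
        config = SimulationConfig(seed=9)
        case, truth = simulate_patient(config, 0)
        for lesion in case.lesion_ids:
            keys = set(truth.truncal_features) | set(
                truth.private_features[lesion])
            assert keys <= set(truth.clonal_fractions[lesion])

    def test_artifact_variants_removed_by_filters(self):
        from mmclone.features import extract_case_features
        config = SimulationConfig(seed=3, n_artifact_snv_per_lesion=4)
        case, truth = simulate_patient(config, 0)
        features = extract_case_features(case)
        for lesion in case.lesions:
            artifact_keys = {
                snv_feature_key(v) for v in lesion.variants
                if (v.gnomad_af is not None and v.gnomad_af > 0.01)
                or v.consequence == "synonymous"}
            kept = {snv_feature_key(v)
                    for v in features.filtered_variants[lesion.lesion_id]}
            assert not artifact_keys & kept


class TestWriteFixture:
    def test_round_trip_field_by_field(self, tmp_path):
        config = SimulationConfig(seed=31, lesions_per_patient=3)
        case, truth = simulate_patient(config, 0)
        manifest_path = write_fixture(case, tmp_path, truth)
        (manifest,) = load_manifest(manifest_path)
        loaded = load_case(manifest)
        assert loaded.patient_id == case.patient_id
        for original, reread in zip(case.lesions, loaded.lesions):
            assert reread.variants == original.variants
            assert reread.segments == original.segments

    def test_truth_record_round_trips_through_json(self, tmp_path):
        config = SimulationConfig(seed=31)
        case, truth = simulate_patient(config, 0)
        manifest_path = write_fixture(case, tmp_path, truth)
        data = json.loads(manifest_path.read_text())
        reread = TruthRecord.from_dict(
            json.loads((tmp_path / data["truth"]).read_text()))
        assert reread == truth

    def test_empty_lesion_writes_header_only_table(self, tmp_path):
        from mmclone.case import LesionProfile, PatientCase
        from mmclone.variants import read_variant_table
        case = PatientCase("P", [LesionProfile("T1", [], []),
                                 LesionProfile("T2", [], [])])
        write_fixture(case, tmp_path)
        assert read_variant_table(tmp_path / "T1.variants.tsv") == []

    def test_five_lesion_fixture_file_count(self, tmp_path, cases_by_id):
        manifest_path = write_fixture(cases_by_id["S1"], tmp_path)
        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["lesions"]) == 5
        assert len(list(tmp_path.glob("*.variants.tsv"))) == 6  # 5 + dura
        assert len(list(tmp_path.glob("*.segments.seg"))) == 6


class TestInPaperFixture:
    def test_cohort_size(self, cohort):
        assert len(cohort) == 6
        assert sum(len(case.lesions) for case in cohort) == 15
        assert sum(case.normal is not None for case in cohort) == 1

    def test_s6_shares_nothing(self, cases_by_id):
        partition = shared_private_partition(cases_by_id["S6"])
        assert partition.shared_by_all == set()

    def test_s5_printed_values_encoded(self, cases_by_id):
        s5 = cases_by_id["S5"]
        t2 = next(p for p in s5.lesions if p.lesion_id == "S5-T2")
        (traf7,) = [v for v in t2.variants if v.gene == "TRAF7"]
        assert traf7.vaf == pytest.approx(0.40)
        (segment,) = t2.segments
        assert segment.maf == pytest.approx(0.11)

    def test_s1_partition_matches_description(self, cases_by_id):
        partition = shared_private_partition(cases_by_id["S1"])
        shared_snvs = {k for k in partition.shared_by_all if ">" in k}
        assert len(shared_snvs) == 1                 # the shared NF2 SNV
        assert "chr22:deletion" in partition.shared_by_all
        smarcb1 = [k for k in partition.private if k.startswith("22:24145000")]
        assert smarcb1  # SMARCB1 p.R377H private to S1-T5
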