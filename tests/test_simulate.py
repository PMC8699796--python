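"""Generator statistics: HWE fidelity, drift calibration, cohort structure."""

import numpy as np
import pytest

from pdxdrift import (
    InvalidConfigError,
    MISSING,
    SimulationConfig,
    StabilityClass,
    concordance,
    derive_rng,
    simulate_cohort,
    simulate_contaminated_sample,
    simulate_markers,
    simulate_patient_genotypes,
    simulate_pdx_passage,
)

from conftest import make_panel


class TestSimulateMarkers:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=1, n_candidate_markers=1000, panel_size=10)
        a = simulate_markers(cfg)
        b = simulate_markers(cfg)
        assert len(a) == 1000
        assert a == b

    def test_enough_common_markers_for_panel(self):
        cfg = SimulationConfig(seed=2, n_candidate_markers=10_000)
        markers = simulate_markers(cfg)
        n_common = sum(m.maf >= 0.40 for m in markers)
        assert n_common >= 300

    def test_positions_strictly_increasing_within_chromosome(self):
        cfg = SimulationConfig(seed=3, n_candidate_markers=2000, panel_size=10)
        markers = simulate_markers(cfg)
        by_chrom: dict[str, list[int]] = {}
        for m in markers:
            by_chrom.setdefault(m.chromosome, []).append(m.position)
        for positions in by_chrom.values():
            assert all(a < b for a, b in zip(positions, positions[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_candidate_markers=100, panel_size=300),
            dict(maf_range=(0.5, 0.4)),
            dict(maf_range=(0.0, 0.5)),
            dict(n_lineages=4, n_unstable=5),
            dict(initiation_drift_stable=1.2),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(seed=0, **kwargs)


class TestPatientGenotypes:
    def test_hwe_proportions_at_half(self):
        """At MAF 0.5 the heterozygote fraction converges to 2pq = 0.5."""
        panel = make_panel(100, maf=0.5)
        rng = derive_rng(7)
        calls = np.stack(
            [simulate_patient_genotypes(panel, rng).calls for _ in range(1000)]
        )
        n = calls.size
        het_frac = (calls == 1).mean()
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het_frac - 0.5) < 3 * se

    def test_hwe_genotype_frequencies_all_states(self):
        """Per-marker genotype frequencies match (p^2, 2pq, q^2) within 4 SE."""
        maf = 0.42
        panel = make_panel(10, maf=maf)
        rng = derive_rng(11)
        n = 10_000
        mat = np.stack(
            [simulate_patient_genotypes(panel, rng).calls for _ in range(n)]
        )
        p, q = 1 - maf, maf
        for state, expected in ((0, p * p), (1, 2 * p * q), (2, q * q)):
            freq = (mat == state).mean()  # pooled over 10 identical markers
            se = np.sqrt(expected * (1 - expected) / mat.size)
            assert abs(freq - expected) < 4 * se

    def test_maf_zero_limit_all_major_homozygote(self):
        panel = make_panel(50, maf=0.0)
        v = simulate_patient_genotypes(panel, derive_rng(1))
        assert (v.calls == 0).all()

    def test_same_seed_identical(self):
        panel = make_panel(30)
        assert simulate_patient_genotypes(panel, 5) == simulate_patient_genotypes(
            panel, 5
        )

    def test_unrelated_pair_concordance_closed_form(self):
        """At fixed MAF p the chance concordance is sum of squared genotype freqs."""
        panel = make_panel(300, maf=0.5)
        rng = derive_rng(13)
        concs = []
        for _ in range(400):
            a = simulate_patient_genotypes(panel, rng, sample_id="a")
            b = simulate_patient_genotypes(panel, rng, sample_id="b")
            concs.append(concordance(a, b).concordance)
        # genotype freqs (1/4, 1/2, 1/4): 1/16 + 1/4 + 1/16 = 0.375 at p = 0.5
        mean = np.mean(concs)
        se = np.std(concs, ddof=1) / np.sqrt(len(concs))
        assert abs(mean - 0.375) < 4 * se


class TestPassageDrift:
    def test_zero_drift_is_identity(self):
        panel = make_panel(100)
        parent = simulate_patient_genotypes(panel, 1, missing_rate=0.05)
        child = simulate_pdx_passage(parent, drift_rate=0.0, seed=2)
        assert np.array_equal(parent.calls, child.calls)

    def test_total_drift_zero_concordance(self):
        panel = make_panel(100)
        parent = simulate_patient_genotypes(panel, 3)
        child = simulate_pdx_passage(parent, drift_rate=1.0, seed=4)
        assert concordance(parent, child).concordance == 0.0

    def test_alteration_rate_calibrated_to_drift(self):
        """Measured PT-vs-child alteration rate is an unbiased estimate of d."""
        panel = make_panel(300)
        rng = derive_rng(17)
        d = 0.047
        rates = []
        for _ in range(2000):
            parent = simulate_patient_genotypes(panel, rng)
            child = simulate_pdx_passage(parent, drift_rate=d, seed=rng)
            rates.append(concordance(parent, child).alteration_rate)
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - d) < 3 * se

    def test_alteration_kernel_always_changes_state(self):
        panel = make_panel(200)
        parent = simulate_patient_genotypes(panel, 5)
        child = simulate_pdx_passage(parent, drift_rate=0.5, seed=6)
        altered = (parent.calls != child.calls) & (child.calls != MISSING)
        # het -> hom and hom -> het only
        assert ((parent.calls[altered] == 1) == (child.calls[altered] != 1)).all()

    def test_stromal_fraction_adds_missingness(self):
        panel = make_panel(2000)
        parent = simulate_patient_genotypes(panel, 7)
        child = simulate_pdx_passage(
            parent, drift_rate=0.0, stromal_fraction=0.5, seed=8,
            stromal_missing_scale=0.2,
        )
        dropped = (child.calls == MISSING).mean()
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert abs(dropped - 0.1) < 4 * se

    def test_drift_rate_out_of_range(self):
        panel = make_panel(10)
        parent = simulate_patient_genotypes(panel, 1)
        with pytest.raises(ValueError):
            simulate_pdx_passage(parent, drift_rate=1.5)


class TestContamination:
    def test_match_rate_zero_never_matches_reference(self):
        panel = make_panel(300)
        cfg = SimulationConfig(seed=0, contamination_match_rate=0.0)
        ref = simulate_patient_genotypes(panel, 1, sample_id="PT")
        contam = simulate_contaminated_sample(panel, cfg, seed=2, reference=ref)
        assert concordance(ref, contam).concordance == 0.0

    def test_concordance_vs_reference_near_21_percent(self):
        panel = make_panel(300)
        cfg = SimulationConfig(seed=0)
        rng = derive_rng(23)
        concs = []
        for _ in range(500):
            ref = simulate_patient_genotypes(panel, rng, sample_id="PT")
            contam = simulate_contaminated_sample(panel, cfg, seed=rng, reference=ref)
            concs.append(concordance(ref, contam).concordance)
        mean = np.mean(concs)
        se = np.std(concs, ddof=1) / np.sqrt(len(concs))
        assert abs(mean - 0.21) < 3 * se

    def test_call_rate_binomial(self):
        panel = make_panel(300)
        cfg = SimulationConfig(seed=0, contamination_call_rate=0.5)
        contam = simulate_contaminated_sample(panel, cfg, seed=9)
        n_called = contam.n_called
        se = np.sqrt(300 * 0.25)
        assert abs(n_called - 150) < 4 * se


class TestCohort:
    def test_default_structure_17_lineages_8_unstable(self):
        cfg = SimulationConfig(seed=1, n_candidate_markers=10_000)
        cohort = simulate_cohort(cfg)
        assert len(cohort.lineages) == 17
        unstable = [
            ln
            for ln in cohort.lineages
            if ln.stability_class is StabilityClass.UNSTABLE
        ]
        assert len(unstable) == 8
        assert cohort.panel.size == 300
        for ln in cohort.lineages:
            assert ln.n_passages == 7

    def test_byte_identical_given_config(self):
        cfg = SimulationConfig(seed=5, n_candidate_markers=3000, n_lineages=2,
                               n_unstable=1, max_passage=2)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.samples.keys() == b.samples.keys()
        for sid in a.samples:
            assert a.samples[sid] == b.samples[sid]

    def test_zero_drift_single_passage_identical(self):
        cfg = SimulationConfig(
            seed=2, n_candidate_markers=3000, n_lineages=1, n_unstable=0,
            max_passage=1, initiation_drift_stable=0.0, missing_rate_base=0.0,
            stromal_fraction_range=(0.0, 0.0),
        )
        cohort = simulate_cohort(cfg)
        ln = cohort.lineages[0]
        pt = cohort.samples[ln.patient_sample_id]
        p1 = cohort.samples[ln.passage_sample_id(1)]
        assert np.array_equal(pt.calls, p1.calls)

    def test_manifest_records_ground_truth(self):
        cfg = SimulationConfig(seed=3, n_candidate_markers=3000, n_lineages=3,
                               n_unstable=1, max_passage=2,
                               contaminated_passages=((1, 2),), n_duplicates=1)
        cohort = simulate_cohort(cfg)
        truth = cohort.manifest.lineage_truth
        assert truth[0]["initiation_drift"] == cfg.initiation_drift_unstable
        assert truth[2]["initiation_drift"] == cfg.initiation_drift_stable
        assert cohort.manifest.contaminated_sample_ids == ("PDX-0002-P2",)
        assert cohort.manifest.duplicate_pairs == (("PDX-0001-PT", "PDX-0001-PT-DUP"),)
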