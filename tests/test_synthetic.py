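import dataclasses

import numpy as np
import pandas as pd
import pytest

from scplex.qc import completeness
from scplex.synthetic import (
    AcquisitionConfig,
    GroundTruthConfig,
    detection_probability,
    generate_reference,
    generate_truth,
    simulate_acquisition,
)


class TestGenerateTruth:
    def test_zero_permeabilization_fraction_flags_nobody(self):
        cfg = GroundTruthConfig(n_batches=2, n_proteins=50, permeabilized_fraction=0.0, seed=3)
        truth = generate_truth(cfg)
        assert not truth.cells["permeabilized"].any()

    def test_marker_effect_is_exact_in_type_profiles(self):
        cfg = GroundTruthConfig(
            n_batches=1,
            n_proteins=100,
            type_proportions={"t1": 0.5, "t2": 0.5},
            marker_log2_effect=2.0,
            seed=4,
        )
        truth = generate_truth(cfg)
        prof = truth.type_profiles_log2
        markers_t1 = truth.features.loc[truth.features["marker_type"] == "t1", "protein_id"].unique()
        assert len(markers_t1) > 0
        diff = prof.loc[markers_t1, "t1"] - prof.loc[markers_t1, "t2"]
        assert np.allclose(diff, 2.0)

    def test_same_seed_is_bit_identical(self):
        cfg = GroundTruthConfig(n_batches=2, n_proteins=60, seed=9)
        a, b = generate_truth(cfg), generate_truth(cfg)
        pd.testing.assert_frame_equal(a.abundance, b.abundance)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_permeabilized_cells_lose_cytosolic_content(self):
        cfg = GroundTruthConfig(n_batches=2, n_proteins=80, permeabilized_fraction=0.5, seed=5)
        truth = generate_truth(cfg)
        perm = truth.cells["permeabilized"]
        assert perm.any() and (~perm).any()
        # realized input of permeabilized cells falls short of the drawn input
        ratio = truth.cells["input_pg"] / truth.cells["drawn_input_pg"]
        assert np.allclose(ratio[~perm], 1.0)
        assert (ratio[perm] < 1.0).all()

    def test_batch_layout_matches_config(self):
        cfg = GroundTruthConfig(n_batches=3, n_bridge=2, n_blank=3, n_cells_per_batch=27, n_proteins=40, seed=1)
        truth = generate_truth(cfg)
        assert len(truth.designs) == 3
        for d in truth.designs:
            assert d.role_counts() == {"bridge": 2, "blank": 3, "single_cell": 27}

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthConfig(permeabilization_lambda=1.0)
        with pytest.raises(ValueError):
            GroundTruthConfig(marker_fraction=1.5)
        with pytest.raises(ValueError):
            GroundTruthConfig(type_proportions={"a": 0.7, "b": 0.7})


class TestSimulateAcquisition:
    def test_zero_budget_yields_all_missing(self, small_truth):
        res = simulate_acquisition(small_truth, AcquisitionConfig(ms2_budget=0, seed=2))
        assert res.quant.values.shape[0] == 0
        assert all(len(s) == 0 for s in res.id_sets)

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(ms2_budget=-1)

    def test_determinism(self, small_truth):
        acq = AcquisitionConfig(mode="rtls", seed=7)
        a = simulate_acquisition(small_truth, acq)
        b = simulate_acquisition(small_truth, acq)
        pd.testing.assert_frame_equal(a.quant.values, b.quant.values)
        assert a.identified == b.identified

    def test_rtls_dominates_standard_with_perfect_screen(self, small_truth):
        """Library gating with a perfect screen never identifies fewer peptides."""
        for seed in range(20):
            common = dict(
                ms2_budget=400,
                noise_fraction=0.5,
                screen_sensitivity=1.0,
                screen_specificity=1.0,
                seed=seed,
            )
            std = simulate_acquisition(small_truth, AcquisitionConfig(mode="standard", **common))
            rtl = simulate_acquisition(small_truth, AcquisitionConfig(mode="rtls", **common))
            n_std = len(set().union(*std.id_sets))
            n_rtl = len(set().union(*rtl.id_sets))
            assert n_rtl >= n_std

    def test_modes_agree_without_noise_features(self, small_truth):
        """With no noise in the candidate pool the screen has nothing to gain."""
        diffs = []
        for seed in range(50):
            common = dict(
                ms2_budget=400,
                noise_fraction=0.0,
                screen_sensitivity=1.0,
                screen_specificity=1.0,
                seed=seed,
            )
            std = simulate_acquisition(small_truth, AcquisitionConfig(mode="standard", **common))
            rtl = simulate_acquisition(small_truth, AcquisitionConfig(mode="rtls", **common))
            diffs.append(len(set().union(*rtl.id_sets)) - len(set().union(*std.id_sets)))
        mean = np.mean(diffs)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs)) if np.std(diffs) > 0 else 1.0
        assert abs(mean) <= max(3 * se, 1e-9)

    def test_observability_monotone_in_abundance(self):
        """Raising one peptide's abundance never lowers its identification rate."""
        cfg = GroundTruthConfig(n_batches=1, n_proteins=20, n_cells_per_batch=5, seed=6)
        truth = generate_truth(cfg)
        target = truth.abundance.index[0]
        boosted = dataclasses.replace(truth, abundance=truth.abundance.copy())
        boosted.abundance.loc[target] *= 8.0
        hits_lo = hits_hi = 0
        for seed in range(1000):
            acq = AcquisitionConfig(ms2_budget=10_000, noise_fraction=0.0, seed=seed)
            hits_lo += target in simulate_acquisition(truth, acq).identified["batch00"]
            hits_hi += target in simulate_acquisition(boosted, acq).identified["batch00"]
        assert hits_hi >= hits_lo
        # and the underlying detection-probability curve is monotone
        ab = np.logspace(-4, 1, 30)
        p = detection_probability(ab, AcquisitionConfig())
        assert np.all(np.diff(p) >= 0)

    def test_blank_leak_monotone_in_bridge_input(self):
        """More bridge input pushes more interference above the quant limit
        in the blank channels (matched seeds)."""
        counts = []
        for pg in (50.0, 100.0, 250.0, 1000.0):
            cfg = GroundTruthConfig(n_batches=2, n_proteins=200, bridge_pg=pg, seed=21)
            truth = generate_truth(cfg)
            res = simulate_acquisition(
                truth, AcquisitionConfig(ms2_budget=10_000, noise_fraction=0.0, seed=22)
            )
            blanks = [s for s in res.quant.sample_ids if "_blank" in s]
            counts.append(int(res.quant.mask[blanks].to_numpy().sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]

    def test_rtls_improves_completeness_with_noise(self, small_truth):
        common = dict(ms2_budget=400, noise_fraction=0.5,
                      screen_sensitivity=1.0, screen_specificity=1.0, seed=13)
        std = simulate_acquisition(small_truth, AcquisitionConfig(mode="standard", **common))
        rtl = simulate_acquisition(small_truth, AcquisitionConfig(mode="rtls", **common))
        cells = [s for s in std.quant.sample_ids if "_sc" in s]
        assert completeness(rtl.quant, cells) >= completeness(std.quant, cells)


class TestGenerateReference:
    def test_overlap_extremes(self, small_truth):
        none = generate_reference(small_truth, overlap_fraction=0.0, n_reference_cells=50, seed=1)
        assert len(none.shared_ids) == 0
        full = generate_reference(small_truth, overlap_fraction=1.0, n_reference_cells=50, seed=1)
        prot_ids = set(small_truth.type_profiles_log2.index)
        assert prot_ids <= set(full.values.index)

    def test_determinism(self, small_truth):
        a = generate_reference(small_truth, seed=8, n_reference_cells=100)
        b = generate_reference(small_truth, seed=8, n_reference_cells=100)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_excluded_type_absent(self, small_truth):
        ref = generate_reference(small_truth, n_reference_cells=100, seed=2,
                                 exclude_types=("granulocyte",))
        assert "granulocyte" not in set(ref.labels)

    def test_too_few_reference_cells_rejected(self, small_truth):
        with pytest.raises(ValueError):
            generate_reference(small_truth, n_reference_cells=1, seed=0)

    def test_shared_profiles_track_protein_profiles(self, small_truth):
        """Per-type mean expression on shared genes correlates with the
        protein log2 profile — the premise of cross-modality mapping."""
        ref = generate_reference(small_truth, overlap_fraction=0.5, n_reference_cells=300, seed=5)
        types = sorted(set(ref.labels))
        for t in types:
            cells = ref.labels.index[ref.labels == t]
            mean_expr = ref.values.loc[ref.shared_ids, cells].mean(axis=1)
            prot = small_truth.type_profiles_log2.loc[ref.shared_ids, t]
            assert np.corrcoef(mean_expr, prot)[0, 1] > 0.8
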