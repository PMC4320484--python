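"""Tests of NSAF quantitation, presence filters, normalizations and merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timeomics.datatypes import SpectralCountTable
from timeomics.errors import (
    DegenerateBaselineError,
    DegenerateSampleError,
    ParameterError,
    SchemaError,
)
from timeomics.quantify import (
    FilterParams,
    compute_nsaf,
    filter_metabolite_presence,
    filter_min_abundance,
    filter_replicate_presence,
    merge_blocks,
    normalize_metabolites,
    normalize_physio_t0,
)
from timeomics.synthetic import DesignSpec, SimParams, TruthConfig, generate_design, simulate_proteome


def _table(counts: dict, lengths: dict) -> SpectralCountTable:
    frame = pd.DataFrame(counts)
    return SpectralCountTable(counts=frame, lengths=pd.Series(lengths).loc[frame.index])


class TestComputeNsaf:
    def test_hand_formula(self):
        """Two proteins, SAF 0.1 and 0.05 -> NSAF 2/3 and 1/3."""
        table = _table({"s1": [10, 10]}, {0: 100, 1: 200})
        nsaf = compute_nsaf(table)
        assert np.allclose(nsaf["s1"], [2 / 3, 1 / 3])

    def test_single_protein_normalizes_to_one(self):
        table = _table({"s1": [7]}, {0: 350})
        assert compute_nsaf(table).iloc[0, 0] == 1.0

    def test_all_zero_sample_raises_naming_it(self):
        table = _table({"good": [3, 1], "dead": [0, 0]}, {0: 100, 1: 100})
        with pytest.raises(DegenerateSampleError, match="dead"):
            compute_nsaf(table)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_sum_to_one_property(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.poisson(5, size=(8, 4)) + np.eye(8, 4, dtype=int))
        counts.iloc[0] += 1  # ensure every column has signal
        table = SpectralCountTable(
            counts=counts, lengths=pd.Series(rng.integers(50, 2000, size=8))
        )
        nsaf = compute_nsaf(table)
        assert np.allclose(nsaf.sum(axis=0), 1.0, atol=1e-12)

    def test_scale_invariance_under_integer_doubling(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(10, 3)) + 1)
        lengths = pd.Series(rng.integers(100, 1500, size=10))
        doubled = SpectralCountTable(counts=counts * 2, lengths=lengths)
        base = SpectralCountTable(counts=counts, lengths=lengths)
        pd.testing.assert_frame_equal(compute_nsaf(base), compute_nsaf(doubled))

    def test_recovers_planted_abundances_without_noise(self):
        """With zero noise, NSAF of the expected counts equals the planted
        relative abundance profile exactly."""
        design = generate_design(DesignSpec())
        params = SimParams(n_proteins=40, rep_noise_sd=0.0, dropout_threshold=0.0)
        table, truth = simulate_proteome(
            design, params, TruthConfig(responder_fraction=0.2, n_factors=0), rng=8
        )
        exp = truth.expected_psm.round(0) + 1  # any positive scaling of L*a
        nsaf = compute_nsaf(
            SpectralCountTable(counts=truth.expected_psm, lengths=table.lengths)
        )
        # rebuild the planted relative abundances from the truth record
        shape_map = {t: i for i, t in enumerate(sorted(design["time_h"].unique()))}
        a = pd.DataFrame(1.0, index=table.counts.index, columns=design.index)
        for rid, profile in truth.responders.items():
            for s in design.index:
                a.loc[rid, s] = profile[shape_map[design.at[s, "time_h"]]]
        baseline = nsaf.div(a).iloc[:, 0]
        planted = a.mul(baseline, axis=0)
        planted = planted.div(planted.sum(axis=0), axis=1)
        assert np.allclose(nsaf, planted, atol=1e-9)


class TestMinAbundanceFilter:
    def test_threshold_drops_low_max(self):
        nsaf = pd.DataFrame({"s1": [0.0009, 0.9991]}, index=["low", "high"])
        kept = filter_min_abundance(nsaf, tau=0.001)
        assert list(kept.index) == ["high"]

    def test_tiny_tau_keeps_all_nonzero(self):
        nsaf = pd.DataFrame({"s1": [0.5, 0.5]}, index=["a", "b"])
        assert len(filter_min_abundance(nsaf, tau=np.nextafter(0, 1))) == 2

    def test_matches_brute_force_scan(self, rng):
        values = rng.uniform(0.0005, 0.0015, size=(100, 6))
        nsaf = pd.DataFrame(values)
        kept = filter_min_abundance(nsaf, tau=0.001)
        brute = [i for i in range(100) if values[i].max() >= 0.001]
        assert list(kept.index) == brute

    def test_idempotent(self, rng):
        nsaf = pd.DataFrame(rng.uniform(0, 0.01, size=(50, 4)))
        once = filter_min_abundance(nsaf, tau=0.001)
        twice = filter_min_abundance(once, tau=0.001)
        pd.testing.assert_frame_equal(once, twice)


class TestReplicatePresenceFilter:
    @pytest.fixture()
    def design(self, default_design):
        return default_design

    def _matrix(self, design, detected_samples) -> pd.DataFrame:
        row = pd.Series(0.0, index=design.index)
        row[list(detected_samples)] = 1.0
        return pd.DataFrame([row], index=["f"])

    def test_full_replicate_set_at_one_time_retained(self, design):
        m = self._matrix(design, [s for s in design.index if s.startswith("T72_")])
        assert len(filter_replicate_presence(m, design)) == 1

    def test_five_distinct_times_retained(self, design):
        m = self._matrix(design, ["T0_R1", "T5_R2", "T24_R3", "T72_R4", "T77_R1"])
        assert len(filter_replicate_presence(m, design)) == 1

    def test_three_of_four_replicates_only_dropped(self, design):
        m = self._matrix(design, ["T24_R1", "T24_R2", "T24_R3"])
        assert len(filter_replicate_presence(m, design)) == 0

    def test_any_samples_fallback_mode(self, design):
        # five detections at only two distinct times: kept only in the loose mode
        m = self._matrix(design, ["T0_R1", "T0_R2", "T0_R3", "T5_R1", "T5_R2"])
        strict = filter_replicate_presence(m, design, FilterParams())
        loose = filter_replicate_presence(m, design, FilterParams(alt_mode="any_samples"))
        assert len(strict) == 0 and len(loose) == 1

    def test_sample_missing_from_design_raises(self, design):
        m = pd.DataFrame({"unknown_sample": [1.0]}, index=["f"])
        with pytest.raises(SchemaError):
            filter_replicate_presence(m, design)

    def test_idempotent(self, design, rng):
        m = pd.DataFrame(
            rng.poisson(0.5, size=(40, 24)).astype(float), columns=design.index
        )
        once = filter_replicate_presence(m, design)
        pd.testing.assert_frame_equal(once, filter_replicate_presence(once, design))


class TestNormalizeMetabolites:
    def test_hand_example(self):
        peaks = pd.DataFrame({"s1": [2.0, 3.0, 5.0]})
        assert np.allclose(normalize_metabolites(peaks)["s1"], [0.2, 0.3, 0.5])

    def test_single_metabolite(self):
        peaks = pd.DataFrame({"s1": [123.0]})
        assert normalize_metabolites(peaks).iloc[0, 0] == 1.0

    def test_negative_area_rejected(self):
        with pytest.raises(ParameterError):
            normalize_metabolites(pd.DataFrame({"s1": [-1.0, 2.0]}))

    def test_zero_total_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            normalize_metabolites(pd.DataFrame({"s1": [0.0, 0.0]}))

    def test_columns_sum_to_one_ignoring_missing(self, rng):
        peaks = pd.DataFrame(rng.uniform(1, 100, size=(10, 4)))
        peaks.iloc[0, 0] = np.nan
        out = normalize_metabolites(peaks)
        assert np.allclose(out.sum(axis=0, skipna=True), 1.0, atol=1e-12)


class TestMetabolitePresenceFilter:
    def test_nineteen_scattered_samples_retained(self, default_design, rng):
        row = pd.Series(0.0, index=default_design.index)
        # 19 detections but never a complete replicate set
        detected = [s for s in default_design.index if not s.endswith("_R4")] + ["T0_R4"]
        row[detected[:19]] = 1.0
        m = pd.DataFrame([row], index=["m"])
        assert len(filter_metabolite_presence(m, default_design)) == 1

    def test_exactly_eighteen_dropped(self, default_design):
        row = pd.Series(0.0, index=default_design.index)
        detected = [s for s in default_design.index if not s.endswith("_R4")]  # 18, no full set
        row[detected] = 1.0
        m = pd.DataFrame([row], index=["m"])
        assert len(filter_metabolite_presence(m, default_design)) == 0

    def test_detected_everywhere_retained(self, default_design):
        m = pd.DataFrame(1.0, index=["m"], columns=default_design.index)
        assert len(filter_metabolite_presence(m, default_design)) == 1


class TestPhysioT0Normalization:
    def test_fold_change_relative_to_t0_mean(self, default_design):
        values = pd.DataFrame(2.0, index=["FW"], columns=default_design.index)
        values.loc["FW", [s for s in default_design.index if s.startswith("T96_")]] = 3.0
        out = normalize_physio_t0(values, default_design)
        assert np.allclose(out.loc["FW", "T96_R1"], 1.5)
        assert np.allclose(out.loc["FW", "T0_R1"], 1.0)

    def test_exempt_variable_passes_through(self, default_design, rng):
        values = pd.DataFrame(
            rng.uniform(0.4, 0.8, size=(1, 24)), index=["FvFm"], columns=default_design.index
        )
        out = normalize_physio_t0(values, default_design, exempt=("FvFm",))
        pd.testing.assert_frame_equal(out, values)

    def test_constant_variable_becomes_ones(self, default_design):
        values = pd.DataFrame(7.0, index=["lipids"], columns=default_design.index)
        out = normalize_physio_t0(values, default_design)
        assert np.allclose(out, 1.0)

    def test_zero_t0_mean_rejected(self, default_design):
        values = pd.DataFrame(1.0, index=["v"], columns=default_design.index)
        values.loc["v", [s for s in default_design.index if s.startswith("T0_")]] = 0.0
        with pytest.raises(DegenerateBaselineError):
            normalize_physio_t0(values, default_design)


class TestMergeBlocks:
    def test_counts_and_labels(self, default_design, rng):
        cols = default_design.index
        prot = pd.DataFrame(rng.random((10, 24)), columns=cols)
        met = pd.DataFrame(rng.random((5, 24)), columns=cols)
        phys = pd.DataFrame(rng.random((2, 24)), columns=cols)
        fm = merge_blocks(prot, met, phys, default_design)
        assert len(fm.values) == 17
        assert (fm.blocks.value_counts()[["protein", "metabolite", "physiology"]] == [10, 5, 2]).all()

    def test_duplicate_ids_across_blocks_prefixed(self, default_design, rng):
        cols = default_design.index
        prot = pd.DataFrame(rng.random((1, 24)), index=["X"], columns=cols)
        met = pd.DataFrame(rng.random((1, 24)), index=["X"], columns=cols)
        phys = pd.DataFrame(rng.random((1, 24)), index=["X"], columns=cols)
        fm = merge_blocks(prot, met, phys, default_design)
        assert sorted(fm.values.index) == ["met:X", "phys:X", "prot:X"]

    def test_disjoint_sample_sets_rejected(self, default_design, rng):
        cols = default_design.index
        prot = pd.DataFrame(rng.random((2, 24)), columns=cols)
        met = pd.DataFrame(rng.random((2, 23)), columns=cols[:-1])
        with pytest.raises(SchemaError):
            merge_blocks(prot, met, pd.DataFrame(columns=cols), default_design)
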