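"""Tests of the synthetic-data generator: design, count law, blocks,
causal series, missingness, determinism."""

import numpy as np
import pandas as pd
import pytest

from timeomics.errors import InvalidDesignError, ParameterError
from timeomics.synthetic import (
    DesignSpec,
    SimParams,
    TruthConfig,
    generate_design,
    inject_missingness,
    simulate_causal_series,
    simulate_dataset,
    simulate_metabolome_physio,
    simulate_proteome,
)


class TestGenerateDesign:
    def test_default_design_has_24_samples(self):
        design = generate_design(DesignSpec())
        assert len(design) == 24
        assert sorted(design["time_h"].unique()) == [0, 5, 24, 72, 77, 96]
        assert design.index[0] == "T0_R1"
        assert design.index[-1] == "T96_R4"

    def test_minimal_design(self):
        design = generate_design(DesignSpec(timepoints=(0,), n_replicates=1))
        assert len(design) == 1

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(InvalidDesignError):
            DesignSpec(timepoints=(5, 0))


class TestProteomeCountLaw:
    def test_single_protein_receives_full_depth(self):
        """Normalization forces all expected mass onto a lone protein."""
        design = generate_design(DesignSpec())
        params = SimParams(n_proteins=1, rep_noise_sd=0.0, dropout_threshold=0.0, depth=5000)
        table, truth = simulate_proteome(
            design, params, TruthConfig(responder_fraction=0, n_factors=0), rng=0
        )
        assert np.allclose(truth.expected_psm.to_numpy(), 5000.0)

    def test_expected_counts_conserve_depth(self, small_dataset):
        totals = small_dataset.truth.expected_psm.sum(axis=0)
        assert np.allclose(totals, 20000.0, atol=1e-9)

    def test_mean_observed_matches_closed_form_expectation(self):
        """Monte-Carlo over many replicates against the analytic count law."""
        n_mc = 1670  # x 6 timepoints ~ 10k draws per protein
        design = generate_design(DesignSpec(n_replicates=n_mc))
        params = SimParams(
            n_proteins=200, rep_noise_sd=0.0, dropout_threshold=0.0, depth=10000
        )
        table, truth = simulate_proteome(
            design, params, TruthConfig(responder_fraction=0, n_factors=0), rng=42
        )
        expected = truth.expected_psm.iloc[:, 0].to_numpy()  # constant across samples
        observed_mean = table.counts.mean(axis=1).to_numpy()
        se = np.sqrt(expected / table.counts.shape[1])
        assert (np.abs(observed_mean - expected) <= 3 * se + 1e-9).mean() > 0.99

    def test_responder_profile_induces_monotone_expected_nsaf(self):
        """An induced responder's analytic NSAF profile rises through starvation."""
        design = generate_design(DesignSpec())
        params = SimParams(n_proteins=50, rep_noise_sd=0.0, dropout_threshold=0.0)
        table, truth = simulate_proteome(
            design, params, TruthConfig(responder_fraction=0.1, n_factors=0), rng=3
        )
        exp = truth.expected_psm
        nsaf = exp.div(table.lengths, axis=0)
        nsaf = nsaf.div(nsaf.sum(axis=0), axis=1)
        times = design["time_h"]
        induced = [r for r, prof in truth.responders.items() if max(prof) > 1][0]
        profile = nsaf.loc[induced].groupby(times.values).mean()
        first_four = profile.loc[[0, 5, 24, 72]].to_numpy()
        assert (np.diff(first_four) >= -1e-12).all()

    def test_dropout_zeroes_low_expectations(self):
        design = generate_design(DesignSpec())
        params = SimParams(n_proteins=300, dropout_threshold=5.0, depth=2000)
        table, truth = simulate_proteome(
            design, params, TruthConfig(responder_fraction=0, n_factors=0), rng=1
        )
        low = truth.expected_psm.to_numpy() < 5.0
        assert (table.counts.to_numpy()[low] == 0).all()


class TestBlocksAndPhysio:
    def test_perfect_loading_gives_exact_collinearity(self):
        design = generate_design(DesignSpec())
        params = SimParams(n_metabolites=12, factor_loading=1.0, rep_noise_sd=0.0)
        met, phys, truth = simulate_metabolome_physio(
            design, params, TruthConfig(n_factors=2, metabolites_per_block=3), rng=5
        )
        members = [m for m, f in truth.block_memberships.items() if f == 0 and m.startswith("M")]
        logs = np.log(met.loc[members])
        corr = np.corrcoef(logs)
        assert np.allclose(np.abs(corr), 1.0, atol=1e-10)

    def test_within_block_correlation_exceeds_between(self):
        design = generate_design(DesignSpec())
        params = SimParams(n_metabolites=40, factor_loading=0.9)
        met, phys, truth = simulate_metabolome_physio(
            design, params, TruthConfig(n_factors=3, metabolites_per_block=5), rng=6
        )
        logs = np.log(met)
        corr = pd.DataFrame(np.corrcoef(logs), index=met.index, columns=met.index)
        mem = {m: f for m, f in truth.block_memberships.items() if m.startswith("M")}
        within, between = [], []
        for a in mem:
            for b in mem:
                if a < b:
                    (within if mem[a] == mem[b] else between).append(abs(corr.at[a, b]))
        assert np.mean(within) > np.mean(between) + 0.3

    def test_zero_physio_variables_is_valid(self):
        design = generate_design(DesignSpec())
        met, phys, truth = simulate_metabolome_physio(
            design, SimParams(n_physio=0), TruthConfig(), rng=0
        )
        assert phys.empty and len(phys.columns) == 24

    def test_bad_factor_loading_rejected(self):
        with pytest.raises(ParameterError):
            SimParams(factor_loading=1.5)


class TestCausalSeries:
    def test_null_series_nearly_uncorrelated(self):
        series, truth = simulate_causal_series(
            SimParams(series_length=200),
            TruthConfig(n_causal_pairs=0, n_null_series=6),
            rng=0,
        )
        corr = np.corrcoef(series.to_numpy())
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.abs(off).max() < 0.3

    def test_lagged_correlation_of_planted_pair(self):
        series, truth = simulate_causal_series(
            SimParams(series_length=50, noise_sd=0.1),
            TruthConfig(n_causal_pairs=1, n_null_series=0, causal_beta=0.9),
            rng=7,
        )
        driver, target, beta = truth.causal_pairs[0]
        x = series.loc[driver].to_numpy()
        y = series.loc[target].to_numpy()
        assert np.corrcoef(x[:-1], y[1:])[0, 1] > 0.9

    def test_short_series_rejected(self):
        with pytest.raises(ParameterError):
            simulate_causal_series(SimParams(series_length=9), TruthConfig(), rng=0)


class TestInjectMissingness:
    def test_zero_rate_is_identity(self, rng):
        table = pd.DataFrame(rng.normal(size=(6, 4)))
        out, mask = inject_missingness(table, 0.0, seed=0)
        pd.testing.assert_frame_equal(out, table)
        assert not mask.any().any()

    def test_exact_blank_count(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 10)))
        out, mask = inject_missingness(table, 0.1, seed=1)
        assert int(mask.sum().sum()) == 10
        assert int(out.isna().sum().sum()) == 10

    @pytest.mark.parametrize("seed", range(8))
    def test_never_blanks_full_row_or_column(self, seed, rng):
        table = pd.DataFrame(rng.normal(size=(5, 6)))
        out, mask = inject_missingness(table, 0.4, seed=seed)
        assert not mask.all(axis=1).any()
        assert not mask.all(axis=0).any()

    def test_infeasible_rate_rejected(self, rng):
        table = pd.DataFrame(rng.normal(size=(2, 2)))
        with pytest.raises(ParameterError):
            inject_missingness(table, 0.99, seed=0)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        spec = DesignSpec(seed=99)
        params = SimParams(n_proteins=60, n_metabolites=20, n_physio=3)
        a = simulate_dataset(spec, params, TruthConfig())
        b = simulate_dataset(spec, params, TruthConfig())
        pd.testing.assert_frame_equal(a.proteome.counts, b.proteome.counts)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.physio, b.physio)
        pd.testing.assert_frame_equal(a.causal_series, b.causal_series)
        assert a.truth.responders == b.truth.responders
        assert a.truth.block_memberships == b.truth.block_memberships
        assert a.truth.causal_pairs == b.truth.causal_pairs
        assert a.truth.missing_cells == b.truth.missing_cells
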