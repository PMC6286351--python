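import numpy as np
import pandas as pd
import pytest

from turnoverlab.curation import curate_kcat_records
from turnoverlab.fba import solve_fba
from turnoverlab.ml import ModelSpec, train_cv
from turnoverlab.synthetic import (
    COPIES_PER_MMOL_PER_GDW,
    PlantedTurnoverModel,
    ToyGemSpec,
    generate_planted_regression,
    generate_proteomics,
    generate_toy_gem,
    generate_turnover_dataset,
    write_fixtures,
)
from turnoverlab.experiments import carbon_source_conditions


class TestToyGem:
    def test_minimal_spec_grows(self):
        spec = ToyGemSpec(
            n_carbon_sources=1, n_nitrogen_sources=1, n_sulfur_sources=1,
            n_phosphate_sources=1, n_internal_reactions=3, seed=0,
        )
        net = generate_toy_gem(spec)
        net.validate()
        for rid in net.exchange_reactions():
            net.reactions[rid].lower_bound = -10.0
        assert solve_fba(net).objective_value > 0

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_every_internal_reaction_balanced(self, seed):
        net = generate_toy_gem(ToyGemSpec(seed=seed))
        net.validate()  # raises on any C/N/S/P imbalance

    def test_seeded_regeneration_is_byte_identical(self):
        spec = ToyGemSpec(seed=5)
        assert (
            generate_toy_gem(spec).to_json()
            == generate_toy_gem(ToyGemSpec(seed=5)).to_json()
        )

    def test_gpr_variety_present(self, toy_gem):
        kinds = set()
        for r in toy_gem.reactions.values():
            if r.gpr is None:
                continue
            kinds.add(r.gpr[0])
        assert kinds == {"gene", "and", "or"}

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ToyGemSpec(n_carbon_sources=0)
        with pytest.raises(ValueError):
            ToyGemSpec(n_internal_reactions=1)


class TestPlantedModel:
    def test_exactly_one_noise_specification(self):
        with pytest.raises(ValueError):
            PlantedTurnoverModel()
        with pytest.raises(ValueError):
            PlantedTurnoverModel(noise_sigma=0.1, target_r2=0.5)
        with pytest.raises(ValueError):
            PlantedTurnoverModel(target_r2=1.5)

    def test_implied_r2_matches_large_sample_fit(self):
        planted = PlantedTurnoverModel(target_r2=0.7, seed=0)
        d = generate_planted_regression(4000, planted)
        signal = planted.signal(d.features_complete)
        resid = d.y - signal
        empirical = 1.0 - resid.var() / d.y.var()
        assert d.implied_r2 == pytest.approx(0.7, abs=1e-9)
        assert empirical == pytest.approx(0.7, abs=0.03)

    def test_noiseless_signal_supports_perfect_regression(self):
        d = generate_planted_regression(
            200, PlantedTurnoverModel(noise_sigma=0.0, seed=3)
        )
        _, cv = train_cv(
            d.features_complete, d.y,
            ModelSpec("elastic_net", seed=3,
                      grid=[{"alpha": 1e-4, "l1_ratio": 0.5}]),
        )
        assert cv.median_r2 >= 0.99

    def test_missingness_pattern_applied(self):
        planted = PlantedTurnoverModel(
            target_r2=0.7, seed=1,
            missing_fractions={"km": 0.5}, block_missing_fraction=0.2,
        )
        d = generate_planted_regression(500, planted)
        assert 0.3 < d.features["km"].isna().mean() < 0.7
        block = d.features["active_site_depth"].isna() & d.features[
            "active_site_exposure"
        ].isna()
        assert 0.05 < block.mean() < 0.4
        assert d.features_complete.notna().all().all()


class TestTurnoverDataset:
    @pytest.fixture(scope="class")
    def dataset(self, toy_gem):
        planted = PlantedTurnoverModel(target_r2=0.76, seed=2)
        return generate_turnover_dataset(toy_gem, planted, n_environments=40)

    def test_features_cover_catalyzed_reactions(self, toy_gem, dataset):
        catalyzed = {
            r.id for r in toy_gem.reactions.values() if r.gpr is not None
        }
        assert set(dataset.features.index) == catalyzed

    def test_in_vivo_set_restricted_to_single_gene_reactions(
        self, toy_gem, dataset
    ):
        for rid in dataset.kapp_observations.index:
            assert toy_gem.reactions[rid].gpr[0] == "gene"

    def test_curation_decoys_filtered_with_hand_tally(self, dataset):
        n_records = len(dataset.kcat_records)
        res = curate_kcat_records(dataset.kcat_records, dataset.reaction_map)
        # decoys: mutant, inhibitor, cross-db duplicate, unmapped
        assert len(res.kept) == n_records - 4
        assert set(res.drop_log.rule) == {
            "mutant", "inhibitor", "cross_database_duplicate", "unmapped",
        }

    def test_keff_consistent_with_log_truth(self, dataset):
        np.testing.assert_allclose(
            dataset.keff_true.to_numpy(),
            10.0 ** dataset.y_true_log10.to_numpy(),
        )


class TestProteomics:
    def test_identical_conditions_identical_columns_at_zero_noise(self, toy_gem):
        keff = {r.id: 10.0 for r in toy_gem.reactions.values() if r.gpr}
        conds = carbon_source_conditions(toy_gem)
        first = next(iter(conds))
        doubled = {"a": conds[first], "b": dict(conds[first])}
        prot = generate_proteomics(toy_gem, pd.Series(keff), doubled,
                                   noise_sigma_log10=0.0, seed=0)
        pd.testing.assert_series_equal(
            prot.abundances["a"], prot.abundances["b"], check_names=False
        )

    def test_lognormal_noise_magnitude(self, toy_gem):
        """log10 SD across replicate draws within 3 sigma of the nominal 0.2."""
        keff = {r.id: 10.0 for r in toy_gem.reactions.values() if r.gpr}
        conds = carbon_source_conditions(toy_gem)
        first = next(iter(conds))
        n_rep = 50
        reps = {f"r{i}": dict(conds[first]) for i in range(n_rep)}
        prot = generate_proteomics(toy_gem, pd.Series(keff), reps,
                                   noise_sigma_log10=0.2, seed=4)
        expressed = prot.abundances[(prot.abundances > 0).all(axis=1)]
        sds = np.log10(expressed).std(axis=1, ddof=1)
        # SE of the SD estimate ~ sigma/sqrt(2(n-1)); 3 sigma band, averaged
        # over genes for stability
        assert abs(sds.mean() - 0.2) < 3 * 0.2 / np.sqrt(2 * (n_rep - 1))

    def test_infeasible_condition_skipped_with_warning(self, toy_gem):
        keff = {r.id: 10.0 for r in toy_gem.reactions.values() if r.gpr}
        conds = carbon_source_conditions(toy_gem)
        # forced biomass export with no nutrients: infeasible LP
        conds["impossible"] = {"EX_biomass": 5.0}
        with pytest.warns(UserWarning, match="skipped"):
            prot = generate_proteomics(toy_gem, pd.Series(keff), conds,
                                       seed=0)
        assert "impossible" not in prot.abundances.columns

    def test_copies_constant_round_trip(self, toy_gem):
        keff = {r.id: 10.0 for r in toy_gem.reactions.values() if r.gpr}
        conds = carbon_source_conditions(toy_gem)
        prot = generate_proteomics(toy_gem, pd.Series(keff), conds,
                                   noise_sigma_log10=0.0, seed=0)
        name = next(iter(prot.solutions))
        sol = prot.solutions[name]
        for gene, conc in sol.enzyme_concentration.items():
            assert prot.abundances.at[gene, name] == pytest.approx(
                conc * COPIES_PER_MMOL_PER_GDW
            )


def test_fixture_writer_round_trip(tmp_path):
    paths = write_fixtures(tmp_path, seed=1)
    from turnoverlab.network import MetabolicNetwork

    net = MetabolicNetwork.from_json(paths["network"])
    net.validate()
    features = pd.read_csv(paths["features"], index_col=0)
    assert len(features) > 0
    turnover = pd.read_csv(paths["turnover"])
    assert {"reaction", "log10_kapp_max"} <= set(turnover.columns)
    prot = pd.read_csv(paths["proteomics"], index_col=0)
    assert (prot.to_numpy() >= 0).all()
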