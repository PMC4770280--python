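"""Least-squares calibration: goodness of fit, self-consistency, masked refits."""

import numpy as np
import pytest

from mscpbk import (
    BiodistributionDataset,
    fit_parameters,
    generate_dataset,
    goodness_of_fit,
    organ_block,
)
from mscpbk.synthetic import NoiseModel


@pytest.fixture(scope="module")
def noiseless_data(mouse, reference_params, iv_dose):
    return generate_dataset(
        mouse, reference_params, iv_dose, noise=NoiseModel(coefficient_of_variation=0.0)
    )


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        obs = np.array([10.0, 100.0, 1000.0, 1e4])
        assert goodness_of_fit(obs, obs) == pytest.approx(1.0)

    def test_constant_fold_error_still_perfect(self):
        """R^2 of the regression is invariant to a constant fold change."""
        obs = np.array([10.0, 100.0, 1000.0, 1e4])
        assert goodness_of_fit(2 * obs, obs) == pytest.approx(1.0)

    def test_matches_closed_form(self):
        """Four-point example checked against the textbook formula
        R^2 = 1 - SS_res / SS_tot of the least-squares line."""
        obs = np.array([10.0, 50.0, 400.0, 5000.0])
        pred = np.array([15.0, 40.0, 700.0, 3000.0])
        x = np.log10(obs)
        y = np.log10(pred)
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - (slope * x + intercept)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert goodness_of_fit(pred, obs) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            goodness_of_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestFitParameters:
    def test_truth_is_a_fixed_point(self, mouse, reference_params, noiseless_data):
        """Starting from the generating parameters on noiseless data, the
        optimizer stays there with a near-zero objective and R^2 = 1."""
        result = fit_parameters(
            noiseless_data, mouse, reference_params, free_mask=organ_block("lung")
        )
        assert result.objective < 1e-12
        assert result.r2_overall == pytest.approx(1.0, abs=1e-6)
        for p in organ_block("lung"):
            assert result.params.get(p) == pytest.approx(reference_params.get(p), rel=1e-4)

    def test_refit_from_estimate_reproduces_it(self, mouse, reference_params, noiseless_data):
        perturbed = reference_params.with_values(
            {p: reference_params.get(p) * 1.3 for p in organ_block("liver")}
        )
        first = fit_parameters(noiseless_data, mouse, perturbed, free_mask=organ_block("liver"))
        second = fit_parameters(noiseless_data, mouse, first.params, free_mask=organ_block("liver"))
        for p in organ_block("liver"):
            assert second.params.get(p) == pytest.approx(first.params.get(p), rel=1e-6)

    def test_fixed_parameters_unchanged(self, mouse, reference_params, noiseless_data):
        result = fit_parameters(
            noiseless_data, mouse, reference_params, free_mask=organ_block("lung")
        )
        for organ in ("liver", "spleen", "kidney", "heart", "rest_of_body"):
            for p in organ_block(organ):
                assert result.params.get(p) == reference_params.get(p)
        assert result.params.blood_k_depletion == reference_params.blood_k_depletion

    def test_disease_refit_recovers_directions(self, mouse, reference_params, iv_dose):
        """Refitting only the heart block against data generated with doubled
        heart arrest and halved heart depletion moves the heart estimates in
        the generating directions."""
        from mscpbk import generate_disease_variant

        diseased = generate_disease_variant(
            reference_params, "heart", arrest_multiplier=2.0, depletion_multiplier=0.5
        )
        data = generate_dataset(
            mouse, diseased, iv_dose, noise=NoiseModel(coefficient_of_variation=0.0)
        )
        result = fit_parameters(data, mouse, reference_params, free_mask=organ_block("heart"))
        assert result.params.get("heart.k_arrest") > reference_params.get("heart.k_arrest")
        assert result.params.get("heart.k_depletion") < reference_params.get("heart.k_depletion")

    def test_empty_dataset_rejected(self, mouse, reference_params, noiseless_data):
        import pandas as pd

        empty = BiodistributionDataset(
            records=pd.DataFrame(columns=noiseless_data.records.columns),
            dose_events=noiseless_data.dose_events,
        )
        with pytest.raises(ValueError, match="empty"):
            fit_parameters(empty, mouse, reference_params)

    def test_unknown_free_parameter_rejected(self, mouse, reference_params, noiseless_data):
        with pytest.raises(ValueError, match="unknown"):
            fit_parameters(noiseless_data, mouse, reference_params, free_mask=("liver.k_magic",))

    def test_init_outside_bounds_rejected(self, mouse, reference_params, noiseless_data):
        with pytest.raises(ValueError, match="bounds"):
            fit_parameters(
                noiseless_data,
                mouse,
                reference_params,
                free_mask=("lung.k_arrest",),
                bounds={"lung.k_arrest": (10.0, 100.0)},
            )


def test_dataset_rejects_unknown_compartment():
    import pandas as pd

    with pytest.raises(ValueError, match="unknown compartments"):
        BiodistributionDataset(
            records=pd.DataFrame(
                {"time_h": [1.0], "compartment": ["brain"], "conc_cells_per_kg": [1.0], "sd": [0.1], "n": [5]}
            )
        )


def test_dataset_csv_round_trip(noiseless_data, tmp_path):
    path = tmp_path / "data.csv"
    noiseless_data.to_csv(path)
    reloaded = BiodistributionDataset.from_csv(
        path, species=noiseless_data.species, dose_events=noiseless_data.dose_events
    )
    np.testing.assert_allclose(
        reloaded.records["conc_cells_per_kg"], noiseless_data.records["conc_cells_per_kg"]
    )
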