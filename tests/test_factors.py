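import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wastewater.factors import (
    FIOWeights,
    RemovalRates,
    RFSpec,
    build_factor_table,
    combined_fio_factor,
    group_treatment_categories,
    impute_fio_factors,
    impute_from_region_median,
    impute_protein,
    impute_strata_from_national,
    n_production_coefficient,
)
from wastewater.synth import WorldConfig, generate_sanitation_table


@pytest.mark.parametrize(
    "mix,expected",
    [
        ((1.0, 0.0, 0.0), 1.0),  # open defecation: no removal
        ((0.0, 1.0, 0.0), 0.20),  # septic removes 80%
        ((0.0, 0.0, 1.0), 0.45),  # treatment plants remove 55%
        ((0.2, 0.3, 0.5), 0.2 * 1 + 0.3 * 0.2 + 0.5 * 0.45),  # weighted sum = 0.485
    ],
)
def test_n_production_coefficient(mix, expected):
    c = n_production_coefficient(mix)
    assert c["c_total"] == pytest.approx(expected)
    assert c["c_total"] == pytest.approx(c["c_direct"] + c["c_septic"] + c["c_sewered"])


@given(
    f=st.tuples(st.floats(0, 1), st.floats(0, 1)).filter(lambda t: t[0] + t[1] <= 1.0)
)
@settings(derandomize=True, max_examples=50)
def test_coefficient_bounds_and_monotonicity(f):
    """c_total stays in [0,1] and shrinks when direct share shifts to
    septic or sewered at default removal rates."""
    f_septic, f_sewered = f
    f_direct = 1.0 - f_septic - f_sewered
    c = n_production_coefficient((f_direct, f_septic, f_sewered))["c_total"]
    assert 0.0 <= c <= 1.0 + 1e-12
    if f_direct >= 0.1:
        shifted = n_production_coefficient((f_direct - 0.1, f_septic + 0.1, f_sewered))["c_total"]
        assert shifted < c


def test_group_treatment_categories_mapping_and_renorm(caplog):
    raw = pd.DataFrame(
        {
            "country": [0, 1],
            "strata": ["urban", "urban"],
            "open": [0.5, 0.4],
            "septic_tank": [0.2, 0.2],
            "sewer_secondary": [0.3, 0.2],
        }
    )
    mapping = {"open": "direct", "septic_tank": "septic", "sewer_*": "sewered"}
    out = group_treatment_categories(raw, mapping)
    np.testing.assert_allclose(
        out.loc[0, ["f_direct", "f_septic", "f_sewered"]].astype(float), [0.5, 0.2, 0.3]
    )
    # second row sums to 0.8 -> renormalised with a warning
    np.testing.assert_allclose(
        out.loc[1, ["f_direct", "f_septic", "f_sewered"]].astype(float),
        [0.5, 0.25, 0.25],
    )
    assert any("renormalising" in r.message for r in caplog.records)
    np.testing.assert_allclose(out[["f_direct", "f_septic", "f_sewered"]].sum(axis=1), 1.0)


def test_group_treatment_strict_unmapped():
    raw = pd.DataFrame({"country": [0], "strata": ["urban"], "mystery": [1.0]})
    with pytest.raises(ValueError):
        group_treatment_categories(raw, {}, strict=True)


def test_impute_strata_from_national():
    table = pd.DataFrame(
        {
            "country": [0, 0, 0, 1],
            "strata": ["urban", "rural", "national", "national"],
            "f_direct": [0.2, 0.4, 0.3, 0.1],
            "f_septic": [0.3, 0.3, 0.3, 0.2],
            "f_sewered": [0.5, 0.3, 0.4, 0.7],
        }
    )
    out = impute_strata_from_national(table)
    # country 0 untouched
    c0 = out[(out.country == 0) & (out.strata == "urban")].iloc[0]
    assert c0.f_direct == 0.2 and c0.provenance == "observed"
    # country 1 urban and rural copied from national
    for stratum in ("urban", "rural"):
        row = out[(out.country == 1) & (out.strata == stratum)].iloc[0]
        assert (row.f_direct, row.f_septic, row.f_sewered) == (0.1, 0.2, 0.7)
        assert row.provenance == "national_imputed"
    # fully absent country stays absent at this stage
    assert 2 not in set(out.country)


def test_impute_from_region_median():
    table = pd.DataFrame(
        {
            "country": [0, 1, 2],
            "strata": ["urban"] * 3,
            "f_direct": [0.5, 0.4, 0.1],
            "f_septic": [0.3, 0.2, 0.3],
            "f_sewered": [0.2, 0.4, 0.6],
        }
    )
    regions = pd.DataFrame({"country": [0, 1, 2, 3], "region": ["A"] * 4})
    out = impute_from_region_median(table, regions, countries=[0, 1, 2, 3])
    row = out[(out.country == 3) & (out.strata == "urban")].iloc[0]
    # medians (0.4, 0.3, 0.4) renormalised to sum 1
    np.testing.assert_allclose(
        [row.f_direct, row.f_septic, row.f_sewered],
        np.array([0.4, 0.3, 0.4]) / 1.1,
    )
    assert row.provenance == "region_median_imputed"
    # every requested country x strata now present
    assert (
        out.groupby("country").strata.nunique().reindex([0, 1, 2, 3]).eq(3).all()
    )


def test_region_median_single_observed_country_copied():
    table = pd.DataFrame(
        {"country": [0], "strata": ["urban"], "f_direct": [0.25], "f_septic": [0.25], "f_sewered": [0.5]}
    )
    regions = pd.DataFrame({"country": [0, 1], "region": ["A", "A"]})
    out = impute_from_region_median(table, regions)
    row = out[(out.country == 1) & (out.strata == "urban")].iloc[0]
    assert (row.f_direct, row.f_septic, row.f_sewered) == (0.25, 0.25, 0.5)


def test_impute_protein_noiseless_regression_recovery():
    rng = np.random.default_rng(0)
    gdp = rng.lognormal(9, 1, 60)
    protein = 2000.0 + 3100.0 * np.log(gdp)
    table = pd.DataFrame({"country": range(60), "protein": protein, "gdp": gdp})
    table.loc[:9, "protein"] = np.nan  # ten regression-path countries
    regions = pd.DataFrame({"country": range(60), "region": "A"})
    out = impute_protein(table, regions)
    truth = 2000.0 + 3100.0 * np.log(gdp[:10])
    np.testing.assert_allclose(out.protein[:10], truth, rtol=1e-9)
    assert (out.provenance[:10] == "regression_imputed").all()
    assert (out.provenance[10:] == "observed").all()


def test_impute_protein_median_and_uninhabited_paths():
    table = pd.DataFrame(
        {
            "country": [0, 1, 2, 3, 4, 5],
            "protein": [30.0, 40.0, 50.0, np.nan, np.nan, 25.0],
            "gdp": [1e4, 2e4, 3e4, np.nan, np.nan, 1e4],
            "uninhabited": [False, False, False, False, True, False],
        }
    )
    regions = pd.DataFrame(
        {"country": [0, 1, 2, 3, 4, 5], "region": ["A", "A", "A", "A", "A", "B"]}
    )
    out = impute_protein(table, regions)
    # country 3: no gdp -> region A median of observed {30, 40, 50}
    assert out.loc[out.country == 3, "protein"].iloc[0] == 40.0
    assert out.loc[out.country == 3, "provenance"].iloc[0] == "region_median_imputed"
    # uninhabited country left alone
    assert np.isnan(out.loc[out.country == 4, "protein"].iloc[0])
    assert out.loc[out.country == 4, "provenance"].iloc[0] == "uninhabited"


def test_impute_protein_all_observed_noop():
    table = pd.DataFrame({"country": [0, 1, 2], "protein": [1.0, 2.0, 3.0], "gdp": [1.0, 2.0, 3.0]})
    regions = pd.DataFrame({"country": [0, 1, 2], "region": "A"})
    out = impute_protein(table, regions)
    np.testing.assert_array_equal(out.protein, table.protein)
    assert (out.provenance == "observed").all()


def test_impute_protein_too_few_complete_cases():
    table = pd.DataFrame(
        {"country": [0, 1, 2], "protein": [1.0, 2.0, np.nan], "gdp": [1.0, np.nan, 3.0]}
    )
    regions = pd.DataFrame({"country": [0, 1, 2], "region": "A"})
    with pytest.raises(ValueError, match="3 complete"):
        impute_protein(table, regions)


def _fio_fixture(n=200, missing=40, seed=0):
    rng = np.random.default_rng(seed)
    population = rng.lognormal(13, 1.5, n)
    rural = rng.uniform(0, 1, n)
    factor = 0.05 + 0.9 * rural  # deterministic in rural share
    table = pd.DataFrame({"country": range(n), "fio_factor": factor})
    table.loc[: missing - 1, "fio_factor"] = np.nan
    features = pd.DataFrame(
        {"country": range(n), "population": population, "rural_fraction": rural}
    )
    truth = 0.05 + 0.9 * rural[:missing]
    return table, features, truth


def test_fio_rf_beats_global_mean_baseline():
    table, features, truth = _fio_fixture()
    out, diag = impute_fio_factors(table, features, RFSpec(seed=1))
    assert diag["holdout_rmse"] < diag["baseline_rmse"]
    pred = out.fio_factor[:40].to_numpy()
    assert np.sqrt(np.mean((pred - truth) ** 2)) < np.std(truth)
    assert (out.provenance[:40] == "rf_imputed").all()
    assert out.fio_factor.notna().all()


def test_fio_rf_deterministic():
    table, features, _ = _fio_fixture()
    out1, _ = impute_fio_factors(table, features, RFSpec(seed=7))
    out2, _ = impute_fio_factors(table, features, RFSpec(seed=7))
    np.testing.assert_array_equal(out1.fio_factor, out2.fio_factor)


def test_fio_rf_no_missing_is_noop():
    table, features, _ = _fio_fixture(missing=0)
    out, _ = impute_fio_factors(table, features, RFSpec(seed=1))
    np.testing.assert_array_equal(out.fio_factor, table.fio_factor)


def test_fio_rf_fold_reduction_and_region_fallback(caplog):
    table, features, _ = _fio_fixture(n=12, missing=2, seed=3)
    # one country entirely absent from features -> regional median path
    features = features[features.country != 0]
    regions = pd.DataFrame({"country": range(12), "region": "A"})
    out, diag = impute_fio_factors(
        table, features, RFSpec(seed=1, cv_folds=12), region_table=regions
    )
    assert diag["cv_folds"] < 12
    assert out.fio_factor.notna().all()
    assert out.loc[out.country == 0, "provenance"].iloc[0] == "region_median_imputed"


def test_combined_fio_factor_weighting():
    w = FIOWeights(1.0, 0.5, 0.05)
    assert combined_fio_factor((1.0, 0.0, 0.0), w) == 1.0
    assert combined_fio_factor((0.0, 0.4, 0.6), w) == pytest.approx(0.4 * 0.5 + 0.6 * 0.05)


def test_full_cascade_completeness(small_world):
    """After the cascade no inhabited country x strata lacks anything, and
    provenance counts partition the table."""
    w = small_world
    ft = build_factor_table(w.sanitation, w.regions, w.protein_gdp, countries=w.countries)
    for country in w.countries:
        for stratum in ("urban", "rural", "national"):
            rows = ft.mixes[(ft.mixes.country == country) & (ft.mixes.strata == stratum)]
            assert len(rows) == 1
            row = rows.iloc[0]
            assert 0.0 <= row.c_total <= 1.0
            assert row.fio_factor >= 0.0
    inhabited = ft.protein[~ft.protein.uninhabited]
    assert inhabited.protein.notna().all()
    assert ft.mixes.provenance.value_counts().sum() == len(ft.mixes)
    assert ft.protein.provenance.value_counts().sum() == len(ft.protein)
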