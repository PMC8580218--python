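"""Country-level sanitation factors: treatment mixes, nitrogen production
coefficients, pathogen (FIO) emission factors, and the imputation cascade
that fills gaps in national statistics.

The cascade mirrors how national sanitation reporting is actually patched
up: urban/rural strata missing -> copy the national row; whole country
missing -> per-category median of observed countries in the same
geopolitical region (renormalised, since medians of compositions need not
sum to one); protein consumption missing -> linear regression on log GDP
per capita where GDP is known, else the regional median; FIO factors for
unreported countries -> a random-forest regressor trained on reporting
countries, with regional medians as the last resort. Every filled value is
tagged with the rule that produced it.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, train_test_split

logger = logging.getLogger(__name__)

CATEGORIES = ("direct", "septic", "sewered")
MIX_COLS = ("f_direct", "f_septic", "f_sewered")
STRATA = ("urban", "rural", "national")


@dataclass
class RemovalRates:
    """Fraction of excreted N removed before reaching water, per disposal
    category: sewered treatment plants remove 55%, septic systems (soil
    uptake) 80%, open defecation nothing."""

    r_sewered: float = 0.55
    r_septic: float = 0.80
    r_direct: float = 0.0

    def validate(self):
        for name in ("r_sewered", "r_septic", "r_direct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        return self


@dataclass
class FIOWeights:
    """Unitless per-person FIO emission weights by disposal category.

    Placeholder defaults ordered direct > septic > sewered (untreated waste
    carries the most indicator organisms, sewered treatment removes most);
    no published per-category values are available, so these are explicitly
    configurable stand-ins.
    """

    w_direct: float = 1.0
    w_septic: float = 0.5
    w_sewered: float = 0.05

    def validate(self):
        if min(self.w_direct, self.w_septic, self.w_sewered) < 0:
            raise ValueError("FIO weights must be >= 0")
        return self


@dataclass
class RFSpec:
    """Random-forest imputation settings: small seeded hyperparameter grid
    tuned by k-fold CV, then a 70/30 split to report held-out RMSE."""

    n_estimators_grid: tuple = (100, 500)
    max_depth_grid: tuple = (None, 8)
    cv_folds: int = 10
    test_fraction: float = 0.3
    seed: int = 0


def n_production_coefficient(mix, rates: RemovalRates = RemovalRates()):
    """Per-category N production coefficients c_t = f_t * (1 - r_t).

    ``mix`` is ``(f_direct, f_septic, f_sewered)`` (array-likes broadcast).
    Returns a dict with ``c_direct, c_septic, c_sewered, c_total`` where
    ``c_total`` is the fraction of excreted N that escapes treatment — the
    complement of the population-weighted removal efficiency.
    """
    rates.validate()
    f_direct, f_septic, f_sewered = (np.asarray(m, dtype=float) for m in mix)
    c = {
        "c_direct": f_direct * (1.0 - rates.r_direct),
        "c_septic": f_septic * (1.0 - rates.r_septic),
        "c_sewered": f_sewered * (1.0 - rates.r_sewered),
    }
    c["c_total"] = c["c_direct"] + c["c_septic"] + c["c_sewered"]
    return c


def combined_fio_factor(mix, weights: FIOWeights = FIOWeights()):
    """Population-mix-weighted FIO emission factor sum_t f_t * w_t."""
    weights.validate()
    f_direct, f_septic, f_sewered = (np.asarray(m, dtype=float) for m in mix)
    return f_direct * weights.w_direct + f_septic * weights.w_septic + f_sewered * weights.w_sewered


def group_treatment_categories(raw, mapping, strict=False, renorm_tol=0.01, audit=None):
    """Collapse raw access columns into the three disposal categories.

    ``mapping`` maps raw column names (fnmatch patterns allowed, e.g.
    ``"sewer_*"``) to one of ``direct | septic | sewered``. Rows are
    renormalised to sum to 1; a warning is logged (and an audit row written)
    when the raw sum differs from 1 by more than ``renorm_tol``.
    """
    raw = raw.copy()
    id_cols = [c for c in ("country", "strata") if c in raw.columns]
    data_cols = [c for c in raw.columns if c not in id_cols]
    sums = {cat: np.zeros(len(raw)) for cat in CATEGORIES}
    for col in data_cols:
        cat = None
        for pattern, target in mapping.items():
            if fnmatch.fnmatch(col, pattern):
                cat = target
                break
        if cat is None:
            if strict:
                raise ValueError(f"unmapped sanitation column: {col!r}")
            logger.info("ignoring unmapped sanitation column %r", col)
            continue
        if cat not in CATEGORIES:
            raise ValueError(f"mapping target {cat!r} not one of {CATEGORIES}")
        sums[cat] += raw[col].fillna(0.0).to_numpy(dtype=float)
    out = raw[id_cols].copy()
    total = sum(sums.values())
    if np.any(total <= 0):
        raise ValueError("row with zero total sanitation access cannot be renormalised")
    for i, t in enumerate(total):
        if abs(t - 1.0) > renorm_tol:
            logger.warning("sanitation row %d sums to %.4f; renormalising", i, t)
            if audit is not None:
                row = raw.iloc[i]
                audit.append(
                    {
                        "country": row.get("country", i),
                        "field": "treatment_mix",
                        "rule": f"renormalised_from_{t:.4f}",
                    }
                )
    for cat in CATEGORIES:
        out[f"f_{cat}"] = sums[cat] / total
    return out


def _renormalise_mix(df):
    total = df[list(MIX_COLS)].sum(axis=1)
    for col in MIX_COLS:
        df[col] = df[col] / total
    return df


def impute_strata_from_national(table, audit=None):
    """Fill missing urban/rural rows with the country's national row.

    Countries with no rows at all pass through untouched (regional
    imputation handles them later). Adds/extends a ``provenance`` column.
    """
    table = table.copy()
    if "provenance" not in table.columns:
        table["provenance"] = "observed"
    out = [table]
    for country, grp in table.groupby("country", sort=False):
        have = set(grp["strata"])
        if "national" not in have:
            continue
        national = grp[grp.strata == "national"].iloc[0]
        for stratum in ("urban", "rural"):
            if stratum not in have:
                row = national.copy()
                row["strata"] = stratum
                row["provenance"] = "national_imputed"
                out.append(row.to_frame().T)
                if audit is not None:
                    audit.append(
                        {"country": country, "field": f"mix_{stratum}", "rule": "national_imputed"}
                    )
    result = pd.concat(out, ignore_index=True)
    result[list(MIX_COLS)] = result[list(MIX_COLS)].astype(float)
    return result


def impute_from_region_median(table, region_table, countries=None, audit=None):
    """Fill countries/strata absent from ``table`` with per-category medians
    of observed same-region, same-strata values, renormalised to sum to 1.

    ``countries`` is the full roster that must end up covered (defaults to
    the region table's). A region with no observed values for a stratum
    falls back to the global median (logged).
    """
    table = table.copy()
    if "provenance" not in table.columns:
        table["provenance"] = "observed"
    region_of = dict(zip(region_table["country"], region_table["region"]))
    if countries is None:
        countries = list(region_table["country"])
    missing_region = [c for c in countries if c not in region_of]
    if missing_region:
        raise ValueError(f"countries without region membership: {missing_region}")
    table["_region"] = table["country"].map(region_of)
    new_rows = []
    for country in countries:
        have = set(table.loc[table.country == country, "strata"])
        for stratum in STRATA:
            if stratum in have:
                continue
            region = region_of[country]
            pool = table[
                (table["_region"] == region)
                & (table.strata == stratum)
                & (table.provenance == "observed")
            ]
            rule = "region_median_imputed"
            if pool.empty:
                pool = table[(table.strata == stratum) & (table.provenance == "observed")]
                rule = "global_median_imputed"
                logger.warning(
                    "region %s has no observed %s rows; falling back to global median", region, stratum
                )
            if pool.empty:
                # last resort: observed rows of any stratum
                pool = table[table.provenance == "observed"]
                rule = "global_median_imputed"
            if pool.empty:
                raise ValueError("no observed sanitation rows anywhere to impute from")
            med = {col: float(pool[col].median()) for col in MIX_COLS}
            row = {"country": country, "strata": stratum, **med, "provenance": rule}
            new_rows.append(row)
            if audit is not None:
                audit.append({"country": country, "field": f"mix_{stratum}", "rule": rule})
    if new_rows:
        table = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
    table = table.drop(columns=["_region"])
    return _renormalise_mix(table)


def impute_protein(table, region_table, audit=None):
    """Fill missing protein consumption values.

    Order: countries with GDP observed get the prediction of an OLS fit of
    protein on ln(GDP per capita) over complete cases; countries with
    neither value get the regional median of observed protein (global median
    if the region has none). Uninhabited jurisdictions are skipped (protein
    is not relevant there). Requires >= 3 complete cases for the regression.
    Returns the table with a ``provenance`` column.
    """
    table = table.copy()
    if "uninhabited" not in table.columns:
        table["uninhabited"] = False
    table["provenance"] = "observed"
    table.loc[table["uninhabited"], "provenance"] = "uninhabited"
    obs = table[table.protein.notna() & table.gdp.notna() & ~table.uninhabited]
    need_reg = table.protein.isna() & table.gdp.notna() & ~table.uninhabited
    if need_reg.any():
        if len(obs) < 3:
            raise ValueError("protein regression needs >= 3 complete (protein, GDP) cases")
        beta, alpha = np.polyfit(np.log(obs.gdp.to_numpy()), obs.protein.to_numpy(), 1)
        table.loc[need_reg, "protein"] = alpha + beta * np.log(table.loc[need_reg, "gdp"])
        table.loc[need_reg, "provenance"] = "regression_imputed"
        if audit is not None:
            for c in table.loc[need_reg, "country"]:
                audit.append({"country": c, "field": "protein", "rule": "regression_imputed"})
    region_of = dict(zip(region_table["country"], region_table["region"]))
    need_med = table.protein.isna() & ~table.uninhabited
    if need_med.any():
        observed = table[(table.provenance == "observed") & table.protein.notna()]
        global_median = float(observed.protein.median()) if len(observed) else np.nan
        for i in table.index[need_med]:
            region = region_of.get(table.at[i, "country"])
            pool = observed[observed.country.map(region_of) == region]
            if len(pool):
                table.at[i, "protein"] = float(pool.protein.median())
                table.at[i, "provenance"] = "region_median_imputed"
                rule = "region_median_imputed"
            else:
                if np.isnan(global_median):
                    raise ValueError("no observed protein values to impute from")
                table.at[i, "protein"] = global_median
                table.at[i, "provenance"] = "global_median_imputed"
                rule = "global_median_imputed"
            if audit is not None:
                audit.append({"country": table.at[i, "country"], "field": "protein", "rule": rule})
    return table


def impute_fio_factors(table, features, rf_spec: RFSpec = RFSpec(), region_table=None, audit=None):
    """Predict missing national FIO factors with a random forest.

    ``table`` has columns ``country, fio_factor`` (NaN where missing);
    ``features`` has ``country, population, rural_fraction``. Hyperparameters
    (tree count, depth) are tuned by k-fold CV on the observed countries, a
    70/30 train/test split reports held-out RMSE, the forest is refit on all
    observed data and applied to the gaps. Countries absent from the feature
    table fall back to the regional median. Returns
    ``(table_with_provenance, diagnostics_dict)``.
    """
    table = table.copy()
    table["provenance"] = np.where(table.fio_factor.notna(), "observed", "missing")
    merged = table.merge(features, on="country", how="left")
    feat_cols = ["population", "rural_fraction"]
    obs = merged[merged.fio_factor.notna() & merged[feat_cols].notna().all(axis=1)]
    if len(obs) < 10:
        raise ValueError("FIO imputation needs >= 10 countries with observed factors")
    folds = rf_spec.cv_folds
    if len(obs) < folds:
        folds = max(2, len(obs) // 2)
        logger.warning("fewer observed countries than CV folds; reducing folds to %d", folds)
    X = obs[feat_cols].to_numpy(dtype=float)
    y = obs.fio_factor.to_numpy(dtype=float)
    grid = {
        "n_estimators": list(rf_spec.n_estimators_grid),
        "max_depth": list(rf_spec.max_depth_grid),
    }
    search = GridSearchCV(
        RandomForestRegressor(random_state=rf_spec.seed),
        grid,
        cv=KFold(folds, shuffle=True, random_state=rf_spec.seed),
        scoring="neg_root_mean_squared_error",
    )
    search.fit(X, y)
    best = search.best_params_
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=rf_spec.test_fraction, random_state=rf_spec.seed
    )
    holdout_model = RandomForestRegressor(random_state=rf_spec.seed, **best).fit(X_tr, y_tr)
    rmse = float(np.sqrt(np.mean((holdout_model.predict(X_te) - y_te) ** 2)))
    baseline_rmse = float(np.sqrt(np.mean((y.mean() - y_te) ** 2)))
    model = RandomForestRegressor(random_state=rf_spec.seed, **best).fit(X, y)

    need = merged.fio_factor.isna() & merged[feat_cols].notna().all(axis=1)
    if need.any():
        preds = model.predict(merged.loc[need, feat_cols].to_numpy(dtype=float))
        table.loc[need.to_numpy(), "fio_factor"] = preds
        table.loc[need.to_numpy(), "provenance"] = "rf_imputed"
        if audit is not None:
            for c in merged.loc[need, "country"]:
                audit.append({"country": c, "field": "fio_factor", "rule": "rf_imputed"})
    still = table.fio_factor.isna()
    if still.any():
        if region_table is None:
            raise ValueError("countries lack features for RF imputation and no region table given")
        region_of = dict(zip(region_table["country"], region_table["region"]))
        observed = table[table.provenance == "observed"]
        for i in table.index[still]:
            region = region_of.get(table.at[i, "country"])
            pool = observed[observed.country.map(region_of) == region]
            if not len(pool):
                pool = observed
            table.at[i, "fio_factor"] = float(pool.fio_factor.median())
            table.at[i, "provenance"] = "region_median_imputed"
            if audit is not None:
                audit.append(
                    {"country": table.at[i, "country"], "field": "fio_factor", "rule": "region_median_imputed"}
                )
    diagnostics = {
        "best_params": best,
        "holdout_rmse": rmse,
        "baseline_rmse": baseline_rmse,
        "cv_folds": folds,
        "n_observed": len(obs),
    }
    return table, diagnostics


@dataclass
class FactorTable:
    """Complete per-country x strata factor set plus the imputation audit."""

    mixes: pd.DataFrame  # country, strata, f_*, c_*, c_total, fio_factor, provenance
    protein: pd.DataFrame  # country, protein, gdp, provenance
    audit: list = field(default_factory=list)
    fio_diagnostics: dict = field(default_factory=dict)


def build_factor_table(
    sanitation,
    region_table,
    protein_gdp,
    countries=None,
    rates: RemovalRates = RemovalRates(),
    fio_weights: FIOWeights = FIOWeights(),
) -> FactorTable:
    """Run the full imputation cascade and attach coefficients.

    After this, every country in ``countries`` (default: the region table's
    roster) has urban/rural/national treatment mixes, N production
    coefficients, a combined FIO factor, and (unless uninhabited) a protein
    value — each row tagged with how it was obtained.
    """
    audit: list = []
    mixes = impute_strata_from_national(sanitation, audit=audit)
    mixes = impute_from_region_median(mixes, region_table, countries=countries, audit=audit)
    coeffs = n_production_coefficient(
        tuple(mixes[c].to_numpy() for c in MIX_COLS), rates
    )
    for key, val in coeffs.items():
        mixes[key] = val
    mixes["fio_factor"] = combined_fio_factor(
        tuple(mixes[c].to_numpy() for c in MIX_COLS), fio_weights
    )
    protein = impute_protein(protein_gdp, region_table, audit=audit)
    return FactorTable(mixes=mixes, protein=protein, audit=audit)


def write_audit(audit, path) -> None:
    pd.DataFrame(audit, columns=["country", "field", "rule"]).to_csv(path, index=False)
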