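"""Mixed-model inference on synchrony with permutation F-tests.

The modelled response is pairwise population synchrony (one row per species x
site-pair x window). Controls are pair distance, mean northing, habitat
similarity and window mid-year; the eight seasonal climate-synchrony
variables are screened in a joint all-species model and significant ones kept
as covariates; species attributes (specialism, mobility, mean abundance,
abundance-change class) enter one-per-model, with an attribute-by-mid-year
interaction testing for trends in synchrony. Species and pair id (optionally
taxonomic family, dropped again on singular fits) are crossed random
intercepts.

Because pairwise synchrony rows are not independent, significance comes from
permutation: the predictor is shuffled (whole-species blocks for species
attributes, rows for pair-window-level predictors), the model is refitted by
REML, and the Wald F of the focal term is compared with the observed one via
the add-one empirical p-value ``(1 + #{F_perm >= F_obs}) / (B + 1)``. The
identical code path produces observed and permuted statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from synchroscope.lmm import LMMData, LMMFit, ConvergenceError

CONTROLS = ("distance_km", "mean_northing_km", "habitat_similarity", "mid_year")


def standardise(x: Sequence[float]) -> np.ndarray:
    """Centre to zero mean, scale to unit sample standard deviation (n-1)."""
    x = np.asarray(x, float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardise a constant column")
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one synchrony model."""

    response: str = "r"
    continuous: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()  # (attribute, time column)
    random: tuple[str, ...] = ("species", "pair_id")


class Design:
    """Materialised design matrix with term bookkeeping.

    Continuous predictors are standardised; categorical ones are dummy-coded
    against their first (sorted) level; an interaction (a, t) multiplies a's
    design columns by the standardised time column. The per-term column
    recipes are retained so a permuted raw predictor can be re-materialised
    without touching the rest of the matrix.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec) -> None:
        self.spec = spec
        self.table = table.reset_index(drop=True)
        n = len(self.table)
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        self.terms: dict[str, list[int]] = {}
        self.scalers: dict[str, tuple[float, float]] = {}
        self.cat_levels: dict[str, list[str]] = {}

        for c in spec.continuous:
            raw = self.table[c].to_numpy(float)
            mu, sd = raw.mean(), raw.std(ddof=1)
            if sd == 0:
                raise ValueError(f"cannot standardise constant column '{c}'")
            self.scalers[c] = (mu, sd)
            self.terms[c] = [len(cols)]
            cols.append((raw - mu) / sd)
            names.append(c)
        for c in spec.categorical:
            levels = sorted(self.table[c].astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"categorical '{c}' has a single level")
            self.cat_levels[c] = levels
            idxs = []
            for lev in levels[1:]:
                idxs.append(len(cols))
                cols.append((self.table[c].astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
            self.terms[c] = idxs
        for a, t in spec.interactions:
            if t not in self.terms:
                raise ValueError(f"interaction time column '{t}' must be a fixed effect")
            if a not in self.terms:
                raise ValueError(f"interaction attribute '{a}' must be a fixed effect")
            zt = cols[self.terms[t][0]]
            idxs = []
            for j in self.terms[a]:
                idxs.append(len(cols))
                cols.append(cols[j] * zt)
                names.append(f"{names[j]}:{t}")
            self.terms[f"{a}:{t}"] = idxs

        self.X = np.column_stack(cols)
        self.colnames = names
        self.y = self.table[spec.response].to_numpy(float)

    # -- permutation support -------------------------------------------------

    def attr_columns(self, name: str, raw: np.ndarray) -> dict[int, np.ndarray]:
        """Design columns for predictor ``name`` rebuilt from raw row values."""
        out: dict[int, np.ndarray] = {}
        if name in self.scalers:
            mu, sd = self.scalers[name]
            out[self.terms[name][0]] = (np.asarray(raw, float) - mu) / sd
        elif name in self.cat_levels:
            raw = np.asarray(raw).astype(str)
            for j, lev in zip(self.terms[name], self.cat_levels[name][1:]):
                out[j] = (raw == lev).astype(float)
        else:
            raise KeyError(f"'{name}' is not a materialised predictor")
        return out

    def interaction_columns(
        self, a: str, t: str, attr_cols: Mapping[int, np.ndarray]
    ) -> dict[int, np.ndarray]:
        zt = self.X[:, self.terms[t][0]]
        main = dict(zip(self.terms[a], [attr_cols[j] for j in self.terms[a]]))
        return {
            jint: main[jmain] * zt
            for jmain, jint in zip(self.terms[a], self.terms[f"{a}:{t}"])
        }


@dataclass
class ModelResult:
    """A fitted synchrony model with term-level summaries."""

    fit: LMMFit
    design: Design
    dropped_random: tuple[str, ...] = ()

    def term_F(self, term: str) -> float:
        return self.fit.wald_F(self.design.terms[term])

    def term_estimate(self, term: str) -> float:
        return float(self.fit.beta[self.design.terms[term][0]])

    def term_se(self, term: str) -> float:
        return float(self.fit.se[self.design.terms[term][0]])

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.fit.beta, index=self.design.colnames)


def _make_data(design: Design, random: Sequence[str]) -> LMMData:
    factors = {name: design.table[name].to_numpy() for name in random}
    return LMMData(design.y, design.X, factors, colnames=design.colnames)


def fit_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    droppable_random: tuple[str, ...] = ("family",),
) -> ModelResult:
    """REML fit of ``spec`` on ``table`` with the singular-fit fallback.

    If a droppable random factor (taxonomic family by default) is estimated on
    the boundary (singular), the model is refitted without it and the dropped
    factor recorded on the result.
    """
    design = Design(table, spec)
    random = list(spec.random)
    data = _make_data(design, random)
    fit = data.fit()
    dropped: list[str] = []
    for name in droppable_random:
        if name in random and fit.singular.get(name, False) and len(random) > 1:
            random.remove(name)
            dropped.append(name)
    if dropped:
        warnings.warn(f"singular fit; refitting without random factor(s) {dropped}")
        data = _make_data(design, random)
        fit = data.fit()
    return ModelResult(fit=fit, design=design, dropped_random=tuple(dropped))


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed F, its permutation distribution, and the empirical p-value."""

    predictor: str
    F_observed: float
    F_permuted: np.ndarray
    p_empirical: float
    n_failed: int = 0
    estimate: float = float("nan")
    dropped_random: tuple[str, ...] = ()

    @property
    def B(self) -> int:
        return len(self.F_permuted)


def _infer_unit(design: Design, attr: str) -> str:
    """Species-block permutation when the raw predictor is constant within species."""
    if "species" not in design.table.columns:
        return "rows"
    nun = design.table.groupby("species")[attr].nunique(dropna=False)
    return "species" if (nun <= 1).all() else "rows"


def _permute_predictor(
    data: LMMData,
    design: Design,
    predictor: str,
    B: int,
    rng: np.random.Generator,
    start_lambdas: np.ndarray,
    unit: str | None = None,
) -> tuple[np.ndarray, int]:
    """Permutation distribution of the Wald F for ``predictor``.

    Row-level predictors are shuffled across rows; species-level attributes
    are shuffled as whole-species blocks (label permutation across species),
    and any interaction built on the attribute is recomputed from the permuted
    labels before each refit. The original columns are restored afterwards.
    """
    if ":" in predictor:
        attr, tcol = predictor.split(":", 1)
        target_term = predictor
    else:
        attr, tcol = predictor, None
        target_term = predictor
    unit = unit or _infer_unit(design, attr)
    raw = design.table[attr].to_numpy()
    if unit == "species":
        sp_codes, sp_index = pd.factorize(design.table["species"])
        by_species = (
            design.table.groupby("species")[attr].first().reindex(sp_index).to_numpy()
        )

    affected = list(design.terms[attr])
    if tcol is not None:
        affected += list(design.terms[target_term])
    originals = {j: data.X[:, j].copy() for j in affected}

    F_perm = np.empty(B)
    failed = 0
    for b in range(B):
        if unit == "species":
            perm_raw = by_species[rng.permutation(len(by_species))][sp_codes]
        else:
            perm_raw = raw[rng.permutation(len(raw))]
        try:
            new_cols = design.attr_columns(attr, perm_raw)
            if tcol is not None:
                new_cols.update(design.interaction_columns(attr, tcol, new_cols))
            for j, v in new_cols.items():
                data.set_column(j, v)
            fit_b = data.fit(start_lambdas=start_lambdas)
            F_perm[b] = fit_b.wald_F(design.terms[target_term])
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            F_perm[b] = np.nan
            failed += 1
    for j, v in originals.items():
        data.set_column(j, v)
    return F_perm[~np.isnan(F_perm)], failed


def permutation_test(
    table: pd.DataFrame,
    spec: ModelSpec,
    predictor: str,
    B: int = 1000,
    seed: int = 0,
    unit: str | None = None,
    droppable_random: tuple[str, ...] = ("family",),
) -> PermutationResult:
    """Permutation F-test of one predictor (or 'attr:mid_year' interaction).

    p = (1 + #{F_perm >= F_obs}) / (B_completed + 1), never exactly zero.
    """
    if B < 19:
        raise ValueError("B < 19 cannot resolve significance at alpha = 0.05")
    result = fit_lmm(table, spec, droppable_random=droppable_random)
    design = result.design
    random = [f for f in spec.random if f not in result.dropped_random]
    data = _make_data(design, random)
    start = np.array([result.fit.lambdas[f] for f in random])
    target_term = predictor
    F_obs = result.fit.wald_F(design.terms[target_term])
    rng = np.random.default_rng(seed)
    F_perm, failed = _permute_predictor(data, design, predictor, B, rng, start, unit=unit)
    if failed > 0.01 * B:
        warnings.warn(f"{failed}/{B} permutation refits failed; p uses completed ones")
    p = (1.0 + float(np.sum(F_perm >= F_obs))) / (len(F_perm) + 1.0)
    return PermutationResult(
        predictor=predictor,
        F_observed=F_obs,
        F_permuted=F_perm,
        p_empirical=p,
        n_failed=failed,
        estimate=result.term_estimate(target_term),
        dropped_random=result.dropped_random,
    )


# ---------------------------------------------------------------------------
# climate-covariate selection
# ---------------------------------------------------------------------------


def select_climate_covariates(
    table: pd.DataFrame,
    candidate_vars: Sequence[str],
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    controls: Sequence[str] = CONTROLS,
    random: tuple[str, ...] = ("species", "pair_id"),
    collinearity_threshold: float = 0.7,
) -> tuple[list[str], dict[str, float]]:
    """Screen the eight climate-synchrony variables in one joint model.

    All candidates enter the all-species model together with the controls;
    each candidate's permutation p (row-level shuffling) is computed and those
    with p < alpha are kept as covariates for the attribute models. Candidate
    pairs correlated beyond ``collinearity_threshold`` trigger a warning.
    """
    cand = list(candidate_vars)
    corr = table[cand].corr().abs()
    high = [
        (cand[i], cand[j])
        for i in range(len(cand))
        for j in range(i + 1, len(cand))
        if corr.iloc[i, j] > collinearity_threshold
    ]
    if high:
        warnings.warn(f"collinear climate-synchrony candidates: {high}")
    spec = ModelSpec(
        continuous=tuple(controls) + tuple(cand), categorical=(), random=random
    )
    result = fit_lmm(table, spec, droppable_random=())
    design = result.design
    data = _make_data(design, list(random))
    start = np.array([result.fit.lambdas[f] for f in random])
    rng = np.random.default_rng(seed)
    pvals: dict[str, float] = {}
    for var in cand:
        F_obs = result.fit.wald_F(design.terms[var])
        F_perm, failed = _permute_predictor(
            data, design, var, B, rng, start, unit="rows"
        )
        if failed > 0.01 * B:
            warnings.warn(f"{var}: {failed}/{B} permutation refits failed")
        pvals[var] = (1.0 + float(np.sum(F_perm >= F_obs))) / (len(F_perm) + 1.0)
    kept = [v for v in cand if pvals[v] < alpha]
    return kept, pvals


# ---------------------------------------------------------------------------
# attribute models
# ---------------------------------------------------------------------------


def attribute_models(
    table: pd.DataFrame,
    attributes: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    climate_covariates: Sequence[str] = (),
    controls: Sequence[str] = CONTROLS,
    random: tuple[str, ...] = ("species", "pair_id"),
    family_col: str | None = None,
) -> pd.DataFrame:
    """Average-synchrony and synchrony-trend tests for each species attribute.

    Each attribute gets two models: model A adds the attribute's main effect
    to the controls and selected climate covariates (average synchrony);
    model B adds the attribute x mid-year interaction (trend in synchrony).
    Both are tested by species-block permutation. Species with a missing
    attribute are dropped per model; an attribute left with a single level is
    skipped with a warning. Returns one row per attribute x model.
    """
    rng = np.random.default_rng(seed)
    rand = tuple(random) + ((family_col,) if family_col else ())
    rows: list[dict] = []
    for attr in attributes:
        sub = table.dropna(subset=[attr]).reset_index(drop=True)
        values = sub[attr]
        is_cat = values.dtype == object or isinstance(
            values.dtype, pd.CategoricalDtype
        )
        n_levels = values.astype(str).nunique() if is_cat else values.nunique()
        if n_levels < 2:
            warnings.warn(f"attribute '{attr}' constant after join; skipped")
            continue
        cont = tuple(controls) + tuple(climate_covariates) + (() if is_cat else (attr,))
        cat = (attr,) if is_cat else ()
        seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
        spec_a = ModelSpec(continuous=cont, categorical=cat, random=rand)
        res_a = permutation_test(
            sub, spec_a, attr, B=B, seed=int(seed_a), unit="species"
        )
        spec_b = replace(spec_a, interactions=((attr, "mid_year"),))
        res_b = permutation_test(
            sub, spec_b, f"{attr}:mid_year", B=B, seed=int(seed_b), unit="species"
        )
        common = {
            "attribute": attr,
            "n_rows": len(sub),
            "n_species": sub["species"].nunique(),
        }
        rows.append(
            {
                "model": "average_synchrony",
                "term": attr,
                "estimate": res_a.estimate,
                "F": res_a.F_observed,
                "p_perm": res_a.p_empirical,
                "significant": res_a.p_empirical < alpha,
                "singular_family_dropped": bool(res_a.dropped_random),
                **common,
            }
        )
        rows.append(
            {
                "model": "synchrony_trend",
                "term": f"{attr}:mid_year",
                "estimate": res_b.estimate,
                "F": res_b.F_observed,
                "p_perm": res_b.p_empirical,
                "significant": res_b.p_empirical < alpha,
                "singular_family_dropped": bool(res_b.dropped_random),
                **common,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-table assembly
# ---------------------------------------------------------------------------


def pair_id(site_a: pd.Series | str, site_b: pd.Series | str) -> pd.Series | str:
    """Canonical pair identifier (sites are already lexicographically ordered)."""
    if isinstance(site_a, str):
        return f"{site_a}~{site_b}"
    return site_a.astype(str) + "~" + site_b.astype(str)


def build_model_table(
    population: pd.DataFrame,
    climate: pd.DataFrame,
    covariates: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join synchrony records, climate synchrony, covariates and attributes.

    Climate records are widened to one column per climate variable keyed by
    (pair, window). Rows that lack any climate variable, covariate or (when
    an attribute table is supplied) attribute row are dropped and counted.
    Returns (model table, accounting dict).
    """
    pop = population.copy()
    pop["pair_id"] = pair_id(pop["site_a"], pop["site_b"])
    clim = climate.copy()
    clim["pair_id"] = pair_id(clim["site_a"], clim["site_b"])
    wide = clim.pivot_table(
        index=["pair_id", "start_year"], columns="variable", values="r"
    ).reset_index()
    cov = covariates.copy()
    cov["pair_id"] = pair_id(cov["site_a"], cov["site_b"])
    cov = cov.drop(columns=["site_a", "site_b"])

    n0 = len(pop)
    out = pop.merge(wide, on=["pair_id", "start_year"], how="inner")
    n_after_climate = len(out)
    out = out.merge(cov, on="pair_id", how="inner")
    n_after_cov = len(out)
    if attributes is not None:
        out = out.merge(attributes, on="species", how="left")
    out = out.dropna(
        subset=[c for c in out.columns if c in set(wide.columns) | set(cov.columns)]
    ).reset_index(drop=True)
    counts = {
        "population_records": n0,
        "dropped_no_climate": n0 - n_after_climate,
        "dropped_no_covariates": n_after_climate - n_after_cov,
        "model_rows": len(out),
    }
    return out, counts
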