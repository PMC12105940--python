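"""Growth rates and moving-window pairwise synchrony with exclusion rules.

Population synchrony for a pair of sites is the Pearson correlation of their
yearly log growth rates, ``r_t = ln(N_t + 1) - ln(N_{t-1} + 1)``, inside a
10-year moving window. Climate synchrony is the Pearson correlation of the
raw seasonal climate values of the 5-km grid cells the sites fall in, over
the same windows. Pair-windows are excluded when

* the pair is more than 100 km apart,
* fewer than 7 growth-rate years are shared inside the window,
* either site's counts in the window show a zero followed by a positive
  count at the next surveyed year (colonisation chains inflate synchrony), or
* either growth-rate vector has zero variance (correlation undefined).

Every exclusion is recorded with a reason code so that the pipeline's filter
accounting reconciles exactly: eligible = kept + dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

# dropped-record reason codes
REASON_DISTANCE = "distance_gt_max"
REASON_FEW_SHARED = "too_few_shared_years"
REASON_ZERO_POSITIVE = "zero_then_positive"
REASON_ZERO_VARIANCE = "zero_variance"


@dataclass(frozen=True)
class Window:
    """A 10-calendar-year window [start_year, start_year + length - 1]."""

    start_year: int
    length: int = 10

    @property
    def end_year(self) -> int:
        return self.start_year + self.length - 1

    @property
    def mid_year(self) -> float:
        return (self.start_year + self.end_year) / 2.0


def windows_for_years(years: Iterable[int], length: int = 10) -> list[Window]:
    """All length-`length` windows (step one year) inside the span of ``years``."""
    ys = sorted(set(int(y) for y in years))
    if not ys or ys[-1] - ys[0] + 1 < length:
        warnings.warn("year span shorter than the window length; no windows")
        return []
    return [Window(start, length) for start in range(ys[0], ys[-1] - length + 2)]


@dataclass
class SynchronyParams:
    """Tuning knobs for pair eligibility and window filtering."""

    max_distance_km: float = 100.0
    max_pairs: int = 10_000
    min_shared: int = 7
    min_series_years: int | None = None  # BBS-style series-length screen
    window_length: int = 10
    min_shared_climate: int = 2
    seed: int = 0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def log_growth_rates(counts: pd.Series) -> pd.Series:
    """Yearly log growth rates with the +1 offset.

    ``counts`` maps year -> non-negative count; r_t = ln(N_t+1) - ln(N_{t-1}+1)
    is defined only where both t and t-1 were surveyed.
    """
    counts = counts.dropna().sort_index()
    if (counts < 0).any():
        raise ValueError("negative abundance count")
    years = counts.index.to_numpy(int)
    vals = np.log(counts.to_numpy(float) + 1.0)
    consecutive = np.diff(years) == 1
    r = vals[1:][consecutive] - vals[:-1][consecutive]
    return pd.Series(r, index=years[1:][consecutive], dtype=float)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN when either input has zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def site_to_grid_cell(easting_m: float, northing_m: float, cell_size_m: float = 5000.0) -> str:
    """Stable id of the grid cell containing a point (half-open floor convention)."""
    if not (np.isfinite(easting_m) and np.isfinite(northing_m)):
        raise ValueError("coordinates must be finite")
    ix = math.floor(easting_m / cell_size_m)
    iy = math.floor(northing_m / cell_size_m)
    return f"c_{ix}_{iy}"


# ---------------------------------------------------------------------------
# pair eligibility
# ---------------------------------------------------------------------------


def _pair_distances(sites: pd.DataFrame) -> pd.DataFrame:
    ids = sites["site_id"].to_numpy()
    coords = sites[["easting_m", "northing_m"]].to_numpy(float)
    d = squareform(pdist(coords)) / 1000.0
    iu, ju = np.triu_indices(len(ids), k=1)
    a, b = ids[iu], ids[ju]
    # canonical lexicographic ordering for stable pair ids
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return pd.DataFrame({"site_a": a2, "site_b": b2, "distance_km": d[iu, ju]})


def eligible_pairs(
    sites: pd.DataFrame,
    max_distance_km: float = 100.0,
    max_pairs: int = 10_000,
    min_series_years: int | None = None,
    seed: int = 0,
    abundance: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unordered site pairs within ``max_distance_km``, subsampled to ``max_pairs``.

    When ``min_series_years`` is given (BBS-style screening), sites whose
    abundance series span fewer surveyed years are removed first. Returns
    (eligible pairs, distance-excluded pairs), both with a distance_km column.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    sites = sites.reset_index(drop=True)
    if min_series_years is not None:
        if abundance is None:
            raise ValueError("min_series_years screening needs the abundance table")
        n_years = abundance.groupby("site")["year"].nunique()
        keep = n_years[n_years >= min_series_years].index
        sites = sites[sites["site_id"].isin(keep)].reset_index(drop=True)
    all_pairs = _pair_distances(sites)
    excluded = all_pairs[all_pairs["distance_km"] > max_distance_km].reset_index(drop=True)
    kept = all_pairs[all_pairs["distance_km"] <= max_distance_km].reset_index(drop=True)
    if len(kept) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(kept), size=max_pairs, replace=False)
        kept = kept.iloc[np.sort(idx)].reset_index(drop=True)
    return kept, excluded


# ---------------------------------------------------------------------------
# window-level synchrony
# ---------------------------------------------------------------------------


def _zero_then_positive(counts: pd.Series, window: Window) -> bool:
    """True if the window's surveyed counts contain a 0 followed (at the next
    surveyed year, gaps allowed) by a positive count."""
    sub = counts.dropna().sort_index()
    sub = sub[(sub.index >= window.start_year) & (sub.index <= window.end_year)]
    v = sub.to_numpy(float)
    return bool(np.any((v[:-1] == 0) & (v[1:] > 0)))


def window_synchrony(
    counts_a: pd.Series,
    counts_b: pd.Series,
    window: Window,
    min_shared: int = 7,
) -> tuple[float, int] | tuple[None, str]:
    """Population synchrony of one pair in one window, or a drop reason.

    Growth-rate years eligible inside window [y, y+9] are y+1 .. y+9 (both the
    rate's years lie inside the window), giving at most 9 shared rates.
    Returns (r, n_shared) on success or (None, reason_code) when dropped.
    """
    ra = log_growth_rates(counts_a)
    rb = log_growth_rates(counts_b)
    lo, hi = window.start_year + 1, window.end_year
    ra = ra[(ra.index >= lo) & (ra.index <= hi)]
    rb = rb[(rb.index >= lo) & (rb.index <= hi)]
    shared = ra.index.intersection(rb.index)
    if len(shared) < min_shared:
        return None, REASON_FEW_SHARED
    if _zero_then_positive(counts_a, window) or _zero_then_positive(counts_b, window):
        return None, REASON_ZERO_POSITIVE
    r = pearson(ra.loc[shared].to_numpy(), rb.loc[shared].to_numpy())
    if math.isnan(r):
        return None, REASON_ZERO_VARIANCE
    return r, len(shared)


# ---------------------------------------------------------------------------
# moving-window tables (vectorised over pairs)
# ---------------------------------------------------------------------------


def _growth_matrix(counts: pd.DataFrame, years: np.ndarray) -> np.ndarray:
    """Growth-rate matrix (sites x years) with NaN where undefined.

    ``counts`` is a sites x years pivot (NaN for unsurveyed site-years);
    column j holds r for year years[j].
    """
    logs = np.log(counts.to_numpy(float) + 1.0)
    out = np.full_like(logs, np.nan)
    out[:, 1:] = logs[:, 1:] - logs[:, :-1]
    return out


def _masked_pearson(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r over shared non-NaN columns of two (m, k) arrays."""
    valid = ~np.isnan(xa) & ~np.isnan(xb)
    n = valid.sum(axis=1)
    a = np.where(valid, xa, 0.0)
    b = np.where(valid, xb, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = a.sum(axis=1) / n
        mb = b.sum(axis=1) / n
        ac = np.where(valid, xa - ma[:, None], 0.0)
        bc = np.where(valid, xb - mb[:, None], 0.0)
        cov = (ac * bc).sum(axis=1)
        va = (ac * ac).sum(axis=1)
        vb = (bc * bc).sum(axis=1)
        r = cov / np.sqrt(va * vb)
    return np.clip(r, -1.0, 1.0), n


def moving_window_synchrony(
    abundance: pd.DataFrame,
    sites: pd.DataFrame,
    params: SynchronyParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-synchrony records for every species x pair x window.

    Returns (records, dropped): one record per surviving combination with
    columns (variable, species, site_a, site_b, start_year, mid_year, r,
    n_shared), and one dropped row with a reason code per excluded
    combination. Equals brute-force pair-window recomputation exactly.
    """
    params = params or SynchronyParams()
    pairs, excluded = eligible_pairs(
        sites,
        params.max_distance_km,
        params.max_pairs,
        params.min_series_years,
        params.seed,
        abundance=abundance,
    )
    years_all = np.arange(abundance["year"].min(), abundance["year"].max() + 1)
    windows = windows_for_years(years_all, params.window_length)
    species_list = sorted(abundance["species"].unique())

    records: list[dict] = []
    dropped: list[dict] = []
    site_index = pd.Index(sites["site_id"].unique())

    for sp in species_list:
        sub = abundance[abundance["species"] == sp]
        surveyed_sites = set(sub["site"].unique())
        # pairs are considered for a species only where both sites monitor it
        sp_mask = pairs["site_a"].isin(surveyed_sites) & pairs["site_b"].isin(surveyed_sites)
        sp_pairs = pairs[sp_mask].reset_index(drop=True)
        exc_mask = excluded["site_a"].isin(surveyed_sites) & excluded["site_b"].isin(
            surveyed_sites
        )
        for _, row in excluded[exc_mask].iterrows():
            for w in windows:
                dropped.append(
                    {
                        "species": sp,
                        "site_a": row["site_a"],
                        "site_b": row["site_b"],
                        "start_year": w.start_year,
                        "reason": REASON_DISTANCE,
                    }
                )
        ia = site_index.get_indexer(sp_pairs["site_a"])
        ib = site_index.get_indexer(sp_pairs["site_b"])
        pivot = sub.pivot_table(index="site", columns="year", values="count", aggfunc="first")
        pivot = pivot.reindex(index=site_index, columns=years_all)
        counts = pivot.to_numpy(float)
        growth = _growth_matrix(pivot, years_all)
        surveyed = ~np.isnan(counts)
        year0 = years_all[0]
        for w in windows:
            j0, j1 = w.start_year - year0, w.end_year - year0 + 1
            gw = growth[:, j0 + 1 : j1]  # growth years start_year+1 .. end_year
            r, n = _masked_pearson(gw[ia], gw[ib])
            # zero-then-positive: both pattern years inside the window
            cw = counts[:, j0:j1]
            sw = surveyed[:, j0:j1]
            ztp = _window_ztp(cw, sw)
            ztp_pair = ztp[ia] | ztp[ib]
            for p in range(len(sp_pairs)):
                if n[p] < params.min_shared:
                    reason = REASON_FEW_SHARED
                elif ztp_pair[p]:
                    reason = REASON_ZERO_POSITIVE
                elif np.isnan(r[p]):
                    reason = REASON_ZERO_VARIANCE
                else:
                    records.append(
                        {
                            "variable": "population",
                            "species": sp,
                            "site_a": sp_pairs["site_a"].iat[p],
                            "site_b": sp_pairs["site_b"].iat[p],
                            "start_year": w.start_year,
                            "mid_year": w.mid_year,
                            "r": r[p],
                            "n_shared": int(n[p]),
                        }
                    )
                    continue
                dropped.append(
                    {
                        "species": sp,
                        "site_a": sp_pairs["site_a"].iat[p],
                        "site_b": sp_pairs["site_b"].iat[p],
                        "start_year": w.start_year,
                        "reason": reason,
                    }
                )
    rec_df = pd.DataFrame(
        records,
        columns=[
            "variable",
            "species",
            "site_a",
            "site_b",
            "start_year",
            "mid_year",
            "r",
            "n_shared",
        ],
    )
    drop_df = pd.DataFrame(
        dropped, columns=["species", "site_a", "site_b", "start_year", "reason"]
    )
    return rec_df, drop_df


def _window_ztp(cw: np.ndarray, sw: np.ndarray) -> np.ndarray:
    """Per-site flag: a surveyed 0 followed by a surveyed positive inside the window."""
    n_sites = cw.shape[0]
    out = np.zeros(n_sites, bool)
    for i in range(n_sites):
        ys = np.where(sw[i])[0]
        if len(ys) < 2:
            continue
        v = cw[i, ys]
        if np.any((v[:-1] == 0) & (v[1:] > 0)):
            out[i] = True
    return out


# ---------------------------------------------------------------------------
# climate synchrony
# ---------------------------------------------------------------------------


def climate_synchrony(
    climate: pd.DataFrame,
    sites: pd.DataFrame,
    pairs: pd.DataFrame,
    windows: Sequence[Window] | None = None,
    cell_size_m: float = 5000.0,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Pairwise climate synchrony: Pearson r of raw seasonal values per window.

    One record per pair x window x variable (4 seasons x {temperature,
    precipitation} = 8 variables); no growth-rate transform. Pairs falling in
    the same grid cell have identical series and keep r = 1 where the series
    varies. Zero-variance or under-length windows are silently dropped (the
    climate table is gap-free in practice; population-side accounting is the
    audited one).
    """
    cell_of = {
        r["site_id"]: site_to_grid_cell(r["easting_m"], r["northing_m"], cell_size_m)
        for _, r in sites.iterrows()
    }
    missing = sorted(
        set(pairs["site_a"]).union(pairs["site_b"]) - set(cell_of)
    )
    if missing:
        raise ValueError(f"no grid-cell mapping for sites: {missing}")
    have_cells = set(climate["grid_cell"].unique())
    missing_cells = sorted(
        {cell_of[s] for s in set(pairs["site_a"]).union(pairs["site_b"])} - have_cells
    )
    if missing_cells:
        raise ValueError(f"climate table lacks grid cells: {missing_cells}")

    years_all = np.arange(climate["year"].min(), climate["year"].max() + 1)
    if windows is None:
        windows = windows_for_years(years_all)
    df = climate.copy()
    df["label"] = df["season"] + "_" + df["variable"]
    records: list[dict] = []
    ca = pairs["site_a"].map(cell_of)
    cb = pairs["site_b"].map(cell_of)
    for label, sub in df.groupby("label"):
        wide = sub.pivot_table(index="grid_cell", columns="year", values="value")
        wide = wide.reindex(columns=years_all)
        xa = wide.reindex(ca).to_numpy(float)
        xb = wide.reindex(cb).to_numpy(float)
        year0 = years_all[0]
        for w in windows:
            j0, j1 = w.start_year - year0, w.end_year - year0 + 1
            r, n = _masked_pearson(xa[:, j0:j1], xb[:, j0:j1])
            ok = (n >= min_shared) & ~np.isnan(r)
            for p in np.where(ok)[0]:
                records.append(
                    {
                        "variable": label,
                        "species": "",
                        "site_a": pairs["site_a"].iat[p],
                        "site_b": pairs["site_b"].iat[p],
                        "start_year": w.start_year,
                        "mid_year": w.mid_year,
                        "r": r[p],
                        "n_shared": int(n[p]),
                    }
                )
    return pd.DataFrame(
        records,
        columns=[
            "variable",
            "species",
            "site_a",
            "site_b",
            "start_year",
            "mid_year",
            "r",
            "n_shared",
        ],
    )
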