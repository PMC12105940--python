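"""Species attributes: inclusion filter, abundance-change classes, mean abundance.

Species enter the analysis only when their monitoring coverage is adequate
(at least 75% of study years with >= 50 surveyed sites by default). Change in
abundance between two non-overlapping 10-year windows is classified twice:
for all species by the sign of the mean difference, and again keeping only
species whose change is significant under a two-sample t-test.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd
from scipy import stats

INCREASE = "increase"
DECREASE = "decrease"
EXCLUDED = "excluded"


def species_inclusion_filter(
    abundance: pd.DataFrame,
    min_prop_years: float = 0.75,
    min_sites: int = 50,
    study_years: Sequence[int] | None = None,
) -> list[str]:
    """Species with >= ``min_sites`` surveyed sites in >= ``min_prop_years`` of years.

    ``study_years`` defaults to the full span of years in the table (so a year
    in which nothing was surveyed still counts against every species).
    """
    if abundance.empty:
        return []
    if study_years is None:
        study_years = range(int(abundance["year"].min()), int(abundance["year"].max()) + 1)
    n_years = len(list(study_years))
    per_year = (
        abundance.dropna(subset=["count"])
        .groupby(["species", "year"])["site"]
        .nunique()
        .reset_index(name="n_sites")
    )
    good = per_year[per_year["n_sites"] >= min_sites].groupby("species")["year"].nunique()
    kept = good[good / n_years >= min_prop_years].index
    return sorted(kept)


def abundance_change(
    index_series: pd.Series,
    window1: tuple[int, int],
    window2: tuple[int, int],
    alpha: float = 0.05,
    test: str = "welch",
) -> tuple[float, str, str]:
    """Mean abundance difference between two non-overlapping year windows.

    Returns (mean_diff, class_all, class_sig): mean_diff = mean(window2) -
    mean(window1); class_all is increase/decrease by sign (an exact tie is
    classed decrease with a warning); class_sig is increase/decrease when the
    two-sample t-test (Welch by default, Student via ``test='student'``) is
    significant at ``alpha`` with the matching sign, else 'excluded'.
    """
    if max(window1[0], window2[0]) <= min(window1[1], window2[1]):
        raise ValueError("abundance-change windows must not overlap")
    s = index_series.dropna()
    v1 = s[(s.index >= window1[0]) & (s.index <= window1[1])].to_numpy(float)
    v2 = s[(s.index >= window2[0]) & (s.index <= window2[1])].to_numpy(float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each window needs at least 2 index values")
    mean_diff = float(v2.mean() - v1.mean())
    if mean_diff == 0.0:
        warnings.warn("mean abundance difference is exactly 0; tie classed as decrease")
    class_all = INCREASE if mean_diff > 0 else DECREASE
    if v1.var(ddof=1) == 0.0 and v2.var(ddof=1) == 0.0:
        # degenerate: no within-window variation; any non-zero shift is certain
        significant = mean_diff != 0.0
    else:
        equal_var = test == "student"
        _, p = stats.ttest_ind(v2, v1, equal_var=equal_var)
        significant = bool(p < alpha)
    class_sig = class_all if significant else EXCLUDED
    return mean_diff, class_all, class_sig


def mean_abundance(
    abundance: pd.DataFrame, species: str, years: tuple[int, int]
) -> float:
    """Arithmetic mean count for one species over sites and years in range."""
    sub = abundance[
        (abundance["species"] == species)
        & (abundance["year"] >= years[0])
        & (abundance["year"] <= years[1])
    ].dropna(subset=["count"])
    if sub.empty:
        raise ValueError(f"no abundance data for {species} in {years[0]}-{years[1]}")
    return float(sub["count"].mean())


def build_attribute_table(
    abundance: pd.DataFrame,
    base_attributes: pd.DataFrame,
    change_window1: tuple[int, int],
    change_window2: tuple[int, int],
    mean_abundance_years: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attribute table with abundance-change classes appended.

    ``base_attributes`` supplies species, specialism and mobility (external
    inputs in real studies, ground truth in simulations). The per-year index
    series used for the change classes is the cross-site mean count, a
    stand-in for a national collated index.
    """
    rows = []
    for sp, grp in abundance.groupby("species"):
        index_series = grp.groupby("year")["count"].mean()
        mean_diff, c_all, c_sig = abundance_change(
            index_series, change_window1, change_window2, alpha=alpha
        )
        row = {
            "species": sp,
            "abundance_change": mean_diff,
            "change_class_all": c_all,
            "change_class_sig": c_sig,
        }
        if mean_abundance_years is not None:
            row["mean_abundance"] = mean_abundance(abundance, sp, mean_abundance_years)
        rows.append(row)
    changes = pd.DataFrame(rows)
    return base_attributes.merge(changes, on="species", how="left", suffixes=("", "_computed"))
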