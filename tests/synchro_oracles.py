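"""Independent brute-force oracle for moving-window synchrony.

Deliberately naive: plain dictionaries, nested loops over species, site pairs
and windows, and scipy.stats.pearsonr. Shares no code with the package's
vectorised implementation so the two can cross-validate each other exactly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats


def _growth(counts: dict[int, float]) -> dict[int, float]:
    return {
        t: math.log(counts[t] + 1.0) - math.log(counts[t - 1] + 1.0)
        for t in counts
        if t - 1 in counts
    }


def _zero_then_positive(counts: dict[int, float], start: int, end: int) -> bool:
    ys = sorted(t for t in counts if start <= t <= end)
    return any(counts[a] == 0 and counts[b] > 0 for a, b in zip(ys, ys[1:]))


def oracle_moving_window(
    abundance: pd.DataFrame,
    sites: pd.DataFrame,
    max_distance_km: float = 100.0,
    min_shared: int = 7,
    window_length: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nested-loop recomputation of (records, dropped) for small fixtures."""
    counts: dict[tuple[str, str], dict[int, float]] = {}
    for row in abundance.itertuples(index=False):
        counts.setdefault((row.species, row.site), {})[int(row.year)] = float(row.count)
    coords = {r.site_id: (r.easting_m, r.northing_m) for r in sites.itertuples(index=False)}
    y0, y1 = int(abundance["year"].min()), int(abundance["year"].max())
    starts = list(range(y0, y1 - window_length + 2))
    records, dropped = [], []
    for sp in sorted(set(abundance["species"])):
        sp_sites = sorted({site for (s, site) in counts if s == sp})
        for a, b in itertools.combinations(sp_sites, 2):
            d = math.dist(coords[a], coords[b]) / 1000.0
            ga, gb = _growth(counts[(sp, a)]), _growth(counts[(sp, b)])
            for w in starts:
                end = w + window_length - 1
                if d > max_distance_km:
                    dropped.append((sp, a, b, w, "distance_gt_max"))
                    continue
                shared = sorted(
                    t for t in range(w + 1, end + 1) if t in ga and t in gb
                )
                if len(shared) < min_shared:
                    dropped.append((sp, a, b, w, "too_few_shared_years"))
                    continue
                if _zero_then_positive(counts[(sp, a)], w, end) or _zero_then_positive(
                    counts[(sp, b)], w, end
                ):
                    dropped.append((sp, a, b, w, "zero_then_positive"))
                    continue
                xa = np.array([ga[t] for t in shared])
                xb = np.array([gb[t] for t in shared])
                if xa.var() == 0.0 or xb.var() == 0.0:
                    dropped.append((sp, a, b, w, "zero_variance"))
                    continue
                r = stats.pearsonr(xa, xb).statistic
                records.append((sp, a, b, w, (w + end) / 2.0, r, len(shared)))
    rec = pd.DataFrame(
        records,
        columns=["species", "site_a", "site_b", "start_year", "mid_year", "r", "n_shared"],
    )
    drop = pd.DataFrame(
        dropped, columns=["species", "site_a", "site_b", "start_year", "reason"]
    )
    return rec, drop
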