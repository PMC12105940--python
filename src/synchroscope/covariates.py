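"""Pair-level control covariates: distance, mean northing, habitat similarity.

Sites closer together, further north, or embedded in similar habitat tend to
be more synchronous; these three quantities enter every model as fixed-effect
controls. Habitat similarity is the Renkonen percentage similarity of the two
sites' biotope-proportion vectors (or a same-type indicator in the binary
woodland-type mode).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd


def pair_distance_km(a_coords_m: Sequence[float], b_coords_m: Sequence[float]) -> float:
    """Euclidean distance in km between two planar points given in metres."""
    a = np.asarray(a_coords_m, float)
    b = np.asarray(b_coords_m, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(a[0] - b[0], a[1] - b[1]) / 1000.0)


def mean_northing_km(a_coords_m: Sequence[float], b_coords_m: Sequence[float]) -> float:
    """Mean of the two northings, in km (proxy for latitudinal range position)."""
    a = np.asarray(a_coords_m, float)
    b = np.asarray(b_coords_m, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float((a[1] + b[1]) / 2.0 / 1000.0)


def renkonen_similarity(p: Sequence[float], q: Sequence[float]) -> float:
    """Renkonen percentage similarity: sum_i min(p_i, q_i) over proportions.

    Bounded in [0, 1]; 1 for identical composition, 0 for disjoint supports.
    Inputs that do not sum to 1 (within 1e-6) are renormalised with a warning.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("habitat vectors must cover the same biotopes in the same order")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("habitat proportions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        s = v.sum()
        if s == 0:
            raise ValueError(f"habitat vector {name} sums to zero")
        if abs(s - 1.0) > 1e-6:
            warnings.warn(f"habitat vector {name} sums to {s:.6f}; renormalising")
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())


def binary_habitat_match(type_a: object, type_b: object) -> int | None:
    """1 iff the two categorical habitat types are equal; None when either is missing."""
    if pd.isna(type_a) or pd.isna(type_b):
        warnings.warn("missing habitat type; pair dropped from binary habitat matching")
        return None
    return int(type_a == type_b)


def pair_covariates(
    pairs: pd.DataFrame,
    sites: pd.DataFrame,
    habitat: pd.DataFrame | None = None,
    habitat_mode: str = "proportions",
    habitat_type_col: str = "habitat_type",
) -> pd.DataFrame:
    """Covariate table for a list of site pairs.

    ``pairs`` needs columns site_a/site_b; ``habitat`` is the long
    (site_id, biotope, proportion) table in proportions mode, or ``sites``
    must carry ``habitat_type_col`` in binary mode. Pairs with a missing
    binary habitat type are dropped (with a warning from the matcher).
    """
    coords = sites.set_index("site_id")[["easting_m", "northing_m"]]
    a = coords.loc[pairs["site_a"]].to_numpy(float)
    b = coords.loc[pairs["site_b"]].to_numpy(float)
    dist = np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1]) / 1000.0
    northing = (a[:, 1] + b[:, 1]) / 2.0 / 1000.0
    out = pd.DataFrame(
        {
            "site_a": pairs["site_a"].to_numpy(),
            "site_b": pairs["site_b"].to_numpy(),
            "distance_km": dist,
            "mean_northing_km": northing,
        }
    )
    if habitat_mode == "proportions":
        if habitat is None:
            raise ValueError("proportions mode needs the habitat table")
        wide = habitat.pivot(index="site_id", columns="biotope", values="proportion")
        pa = wide.loc[pairs["site_a"]].to_numpy(float)
        pb = wide.loc[pairs["site_b"]].to_numpy(float)
        out["habitat_similarity"] = np.minimum(pa, pb).sum(axis=1)
    elif habitat_mode == "binary":
        types = sites.set_index("site_id")[habitat_type_col]
        sim = [
            binary_habitat_match(types.get(ra), types.get(rb))
            for ra, rb in zip(pairs["site_a"], pairs["site_b"])
        ]
        out["habitat_similarity"] = [np.nan if s is None else float(s) for s in sim]
        out = out.dropna(subset=["habitat_similarity"]).reset_index(drop=True)
    else:
        raise ValueError("habitat_mode must be 'proportions' or 'binary'")
    return out
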