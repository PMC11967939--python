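"""Inverse Simpson diversity from per-station MaxN species counts.

MaxN — the maximum number of individuals of a species visible in any
single video frame of a deployment — is a conservative relative-abundance
index.  Diversity is the inverse Simpson index D = 1 / sum(p_i^2) on the
relative MaxN abundances: the effective number of equally abundant
species, 1 <= D <= S.  The plug-in estimator is used directly (no
small-sample bias correction): MaxN is itself an index rather than a true
abundance, so a bias-corrected estimator would suggest spurious precision.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["inverse_simpson", "diversity_table"]


def inverse_simpson(counts: Mapping[str, float] | np.ndarray) -> float:
    """Inverse Simpson diversity D = 1 / sum((n_i / N)^2).

    Parameters
    ----------
    counts
        Species -> MaxN mapping, or an array of nonnegative counts.

    Raises
    ------
    ValueError
        If any count is negative or the total is zero (diversity is
        undefined with no individuals observed).
    """
    arr = np.asarray(list(counts.values()) if isinstance(counts, Mapping)
                     else counts, dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("species counts must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("diversity undefined: total count is zero")
    p = arr / total
    if total == 1:
        warnings.warn("single individual observed: D=1 is low-information",
                      stacklevel=2)
    return float(1.0 / np.sum(p ** 2))


def diversity_table(species_long: pd.DataFrame) -> pd.DataFrame:
    """Per-station diversity from a long table (station_id, species, maxn).

    Returns a frame with station_id, inverse_simpson, species_richness and
    total_maxn.  Stations with a zero total are dropped with a warning
    (diversity is undefined there).
    """
    required = {"station_id", "species", "maxn"}
    missing = required - set(species_long.columns)
    if missing:
        raise ValueError(f"species table missing columns {sorted(missing)}")
    rows = []
    dropped = []
    for sid, grp in species_long.groupby("station_id", sort=True):
        counts = grp.groupby("species")["maxn"].sum()
        counts = counts[counts > 0]
        if counts.sum() <= 0:
            dropped.append(sid)
            continue
        rows.append({
            "station_id": sid,
            "inverse_simpson": inverse_simpson(counts.to_numpy()),
            "species_richness": int((counts > 0).sum()),
            "total_maxn": float(counts.sum()),
        })
    if dropped:
        warnings.warn(
            f"{len(dropped)} stations with zero total MaxN dropped: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}", stacklevel=2)
    return pd.DataFrame(rows)
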