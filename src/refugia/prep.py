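"""Occurrence preprocessing and environmental-variable screening.

Occurrences are a tidy table (``species``, ``lon``, ``lat``). Preprocessing
runs in a fixed order: spatial thinning (one record per species per 0.1
degree cell, grid anchored at (0, 0), first record in input order wins),
then removal of species with fewer than five thinned records, then
collinearity screening of the environmental layers.

Screening is iterative: while any pair of layers has |Pearson r| >= 0.8
(over cells jointly valid in all layers), drop the member of the worst
pair with the larger mean |r| to all remaining layers; afterwards, while
any variance inflation factor VIF_j = 1/(1-R^2_j) >= 10, drop the worst
layer. Ties break alphabetically so the procedure is deterministic; every
drop is recorded with its reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EnvStack

logger = logging.getLogger(__name__)

__all__ = [
    "thin_occurrences",
    "filter_rare_species",
    "screen_variables",
    "vif_values",
    "ScreeningReport",
    "prepare_occurrences",
]

THIN_CELL_DEG = 0.1
MIN_RECORDS = 5
R_MAX = 0.8
VIF_MAX = 10.0


def _check_table(occ: pd.DataFrame) -> pd.DataFrame:
    missing = {"species", "lon", "lat"} - set(occ.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    if occ.empty:
        return occ
    bad = ~np.isfinite(occ["lon"].astype(float)) | ~np.isfinite(occ["lat"].astype(float))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} records with non-finite coordinates")
    return occ


def thin_occurrences(occ: pd.DataFrame, cell_size_deg: float = THIN_CELL_DEG) -> pd.DataFrame:
    """Keep at most one record per species per thinning cell.

    The thinning grid is anchored at (0 deg, 0 deg) with half-open cells;
    the first record in input order is retained. Idempotent.
    """
    occ = _check_table(occ)
    if occ.empty:
        return occ.copy()
    cell_x = np.floor(occ["lon"].to_numpy() / cell_size_deg).astype(np.int64)
    cell_y = np.floor(occ["lat"].to_numpy() / cell_size_deg).astype(np.int64)
    key = pd.DataFrame({"species": occ["species"].to_numpy(), "cx": cell_x, "cy": cell_y})
    keep = ~key.duplicated()
    return occ.loc[keep.to_numpy()].reset_index(drop=True)


def filter_rare_species(occ: pd.DataFrame, min_records: int = MIN_RECORDS) -> pd.DataFrame:
    """Drop species with fewer than ``min_records`` records (boundary kept)."""
    occ = _check_table(occ)
    if occ.empty:
        return occ.copy()
    counts = occ["species"].value_counts()
    kept = counts[counts >= min_records].index
    out = occ[occ["species"].isin(kept)].reset_index(drop=True)
    if out.empty:
        warnings.warn("all species fall below the minimum record count")
    return out


def prepare_occurrences(
    occ: pd.DataFrame,
    cell_size_deg: float = THIN_CELL_DEG,
    min_records: int = MIN_RECORDS,
) -> pd.DataFrame:
    """Thin then filter, in the fixed pipeline order."""
    return filter_rare_species(thin_occurrences(occ, cell_size_deg), min_records)


@dataclass
class ScreeningReport:
    kept: list[str]
    dropped: list[dict]  # {"name", "reason"}
    r_max: float
    vif_max: float

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": self.dropped,
            "thresholds": {"r_max": self.r_max, "vif_max": self.vif_max},
        }


def _env_matrix(env: EnvStack, names: list[str]) -> np.ndarray:
    valid = env.valid_mask()
    return np.column_stack([env[n].values[valid].astype(float) for n in names])


def vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R^2_j) from regressing column j on the others (with
    intercept). Perfectly collinear columns return inf."""
    n, p = X.shape
    if p < 2:
        return np.ones(p)
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def screen_variables(
    env: EnvStack,
    r_max: float = R_MAX,
    vif_max: float = VIF_MAX,
) -> ScreeningReport:
    """Iterative pairwise-|r| elimination followed by a VIF sweep.

    All statistics are computed over cells valid in *all* layers (one
    common support). The returned kept set satisfies |r| < r_max and
    VIF < vif_max on recomputation.
    """
    names = sorted(env.names)
    if len(names) < 2:
        raise ValueError("screening needs at least 2 layers")
    dropped: list[dict] = []

    # constant layers cannot enter a correlation
    valid = env.valid_mask()
    keep = []
    for n in names:
        if np.std(env[n].values[valid].astype(float)) == 0:
            dropped.append({"name": n, "reason": "zero variance"})
            logger.info("screen: dropped %s (zero variance)", n)
        else:
            keep.append(n)

    # pairwise |r| elimination
    while len(keep) >= 2:
        X = _env_matrix(env, keep)
        r = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] < r_max:
            break
        mean_r = absr.mean(axis=0) * len(keep) / (len(keep) - 1)
        # drop the member of the worst pair with larger mean |r|; tie -> alphabetical
        if (mean_r[i], keep[i]) >= (mean_r[j], keep[j]):
            victim, partner = i, j
        else:
            victim, partner = j, i
        dropped.append(
            {
                "name": keep[victim],
                "reason": f"|r|={absr[i, j]:.4f} with {keep[partner]} (>= {r_max})",
            }
        )
        logger.info("screen: dropped %s (%s)", keep[victim], dropped[-1]["reason"])
        keep.pop(victim)

    # VIF sweep
    while len(keep) >= 2:
        X = _env_matrix(env, keep)
        vifs = vif_values(X)
        worst = int(np.argmax(vifs))
        if vifs[worst] < vif_max:
            break
        dropped.append({"name": keep[worst], "reason": f"VIF={vifs[worst]:.4f} (>= {vif_max})"})
        logger.info("screen: dropped %s (%s)", keep[worst], dropped[-1]["reason"])
        keep.pop(worst)

    return ScreeningReport(kept=keep, dropped=dropped, r_max=r_max, vif_max=vif_max)
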