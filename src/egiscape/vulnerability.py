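"""Genetic offset, ecoclimatic-index change, and their normalizations.

Genetic offset is the GDM-predicted dissimilarity between a grid cell's
current and future climates: go = 1 - exp(-sum_p |f_p(x_cur) - f_p(x_fut)|),
with the intercept deliberately excluded so that zero climate change gives
zero offset.  DEI = EI_F - EI_C; cells with declining suitability (DEI < 0)
form the mask on which the eco-genetic index is defined.  Both quantities
are normalized to [0.1, 0.9] so their natural logs stay finite and strictly
negative downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gdm import GDMFit, GEO_PREDICTOR

__all__ = ["genetic_offset", "rescale_interval", "compute_dei",
           "build_vulnerability"]


def genetic_offset(fit: GDMFit, grid: pd.DataFrame) -> np.ndarray:
    """Raw genetic offset per grid cell from a fitted GDM.

    Requires ``{p}_cur`` and ``{p}_fut`` columns for every climate predictor
    in the fit; the geographic-distance predictor does not participate
    (a cell does not move).
    """
    preds = [p for p in fit.predictors if p != GEO_PREDICTOR]
    total = np.zeros(len(grid))
    for p in preds:
        cur_col, fut_col = f"{p}_cur", f"{p}_fut"
        if fut_col not in grid.columns:
            raise ValueError(f"grid lacks future values for predictor {p!r}")
        f_cur = fit.transform(p, grid[cur_col].to_numpy(dtype=float))
        f_fut = fit.transform(p, grid[fut_col].to_numpy(dtype=float))
        total += np.abs(f_cur - f_fut)
    return 1.0 - np.exp(-total)


def rescale_interval(values, lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """Affine map of values onto [lo, hi] (min -> lo, max -> hi).

    A constant input maps to the midpoint (lo + hi) / 2.  Callers apply
    absolute values first where magnitude is what matters.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rescale an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.full_like(v, (lo + hi) / 2.0)
    return lo + (hi - lo) * (v - vmin) / (vmax - vmin)


def compute_dei(grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """DEI = EI_F - EI_C per cell and the declining-suitability mask."""
    for col in ("EI_C", "EI_F"):
        if col not in grid.columns:
            raise ValueError(f"grid lacks column {col!r}")
    dei = grid["EI_F"].to_numpy(dtype=float) - grid["EI_C"].to_numpy(dtype=float)
    return dei, dei < 0


def build_vulnerability(fit: GDMFit, grid: pd.DataFrame,
                        normalize_on: str = "masked",
                        lo: float = 0.1, hi: float = 0.9) -> pd.DataFrame:
    """Per-cell vulnerability table: offset, DEI, mask and normalized values.

    ``normalize_on='masked'`` (default) rescales |DEI| and the offset over
    the DEI < 0 cells only, since only those cells enter the eco-genetic
    index; ``'all'`` rescales over every cell instead.  Normalized columns
    are NaN outside the mask under the default.
    """
    if normalize_on not in ("masked", "all"):
        raise ValueError("normalize_on must be 'masked' or 'all'")
    go_raw = genetic_offset(fit, grid)
    dei, mask = compute_dei(grid)
    out = pd.DataFrame({
        "cell_id": grid["cell_id"],
        "go_raw": go_raw,
        "EI_C": grid["EI_C"].to_numpy(dtype=float),
        "EI_F": grid["EI_F"].to_numpy(dtype=float),
        "DEI": dei,
        "mask_decreasing": mask,
    })
    go_i = np.full(len(out), np.nan)
    dei_i = np.full(len(out), np.nan)
    sel = mask if normalize_on == "masked" else np.ones(len(out), dtype=bool)
    if sel.any():
        go_i[sel] = rescale_interval(go_raw[sel], lo, hi)
        dei_i[sel] = rescale_interval(np.abs(dei[sel]), lo, hi)
    out["go_i"] = go_i
    out["dei_i"] = dei_i
    return out
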