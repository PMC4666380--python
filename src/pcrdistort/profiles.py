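"""Read-count-vs-rank profiles: building, scaling, windows, resampling.

A rank profile is the read counts of all barcode pairs sorted descending
(rank 1 = most abundant).  Profiles from different runs are made
comparable by linear scale factors in the rank (x) and read-count (y)
dimensions, fitted by least squares on log10 reads; named windows
(plateau, shoulder+tail) are defined on the scaled rank axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._util import as_rng

#: Window bounds are (low, high] on the scaled rank axis.
DEFAULT_WINDOWS = {"plateau": (0.0, 2900.0), "shoulder_tail": (2900.0, 10000.0)}


@dataclass
class RankProfile:
    """Ordered read counts with optional x/y scale factors and windows.

    ``df`` has columns ``rank`` (1-based), ``reads`` and ``sequence``
    (plus any passthrough columns such as ``origin``).  Reads are
    non-increasing with rank.
    """

    df: pd.DataFrame
    scale_x: float = 1.0
    scale_y: float = 1.0
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self):
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scale factors must be > 0")
        reads = self.df["reads"].to_numpy()
        if reads.size and (np.diff(reads) > 0).any():
            raise ValueError("reads must be non-increasing with rank")

    @property
    def scaled_rank(self) -> np.ndarray:
        return self.df["rank"].to_numpy(dtype=float) * self.scale_x

    @property
    def scaled_reads(self) -> np.ndarray:
        return self.df["reads"].to_numpy(dtype=float) * self.scale_y

    def window_mask(self, name: str) -> np.ndarray:
        lo, hi = self.windows[name]
        r = self.scaled_rank
        return (r > lo) & (r <= hi)

    def window_rows(self, name: str) -> pd.DataFrame:
        return self.df.loc[self.window_mask(name)]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def build_profile(table, windows: dict | None = None) -> RankProfile:
    """Sort a count table into a rank profile.

    ``table`` is a :class:`~pcrdistort.preprocess.CountTable` or a
    DataFrame with ``sequence`` and ``read_count``/``reads`` columns.
    Descending read count; ties broken lexicographically by sequence.
    """
    from .preprocess import CountTable

    df = table.df if isinstance(table, CountTable) else table
    if df.empty:
        raise ValueError("cannot build a rank profile from an empty table")
    df = df.copy()
    if "reads" not in df.columns:
        df = df.rename(columns={"read_count": "reads"})
    df = df.sort_values(
        ["reads", "sequence"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RankProfile(df, windows=dict(windows or DEFAULT_WINDOWS))


def _log_interp(x, xp, fp):
    """Linear interpolation of log10 reads over log10 rank."""
    return np.interp(np.log10(x), np.log10(xp), fp, left=np.nan, right=np.nan)


def fit_scale(
    profile: RankProfile,
    reference: RankProfile,
    log_space: bool = True,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Scale factors (scale_x, scale_y) aligning ``profile`` to ``reference``.

    Minimises the squared error between reference log10 reads at its
    integer ranks and the linearly interpolated scaled profile, by a
    coarse log-spaced grid search followed by Nelder-Mead refinement.
    Ties on the grid (e.g. perfectly flat profiles) resolve toward (1, 1).
    """
    p_rank = profile.df["rank"].to_numpy(dtype=float)
    p_reads = profile.df["reads"].to_numpy(dtype=float)
    r_rank = reference.df["rank"].to_numpy(dtype=float)
    r_reads = reference.df["reads"].to_numpy(dtype=float)
    if p_rank.size == 0 or r_rank.size == 0:
        raise ValueError("profiles must be non-empty")
    r_y = np.log10(np.maximum(r_reads, 0.5)) if log_space else r_reads

    def objective(params):
        sx, sy = np.exp(params)
        x = p_rank * sx
        y = np.log10(np.maximum(p_reads * sy, 0.5)) if log_space else p_reads * sy
        interp = _log_interp(r_rank, x, y)
        ok = ~np.isnan(interp)
        if ok.sum() < 2:
            return np.inf
        return float(np.mean((r_y[ok] - interp[ok]) ** 2))

    if grid is None:
        grid = np.exp(np.linspace(np.log(0.2), np.log(5.0), 33))
    best, best_val = (0.0, 0.0), objective((0.0, 0.0))
    for gx in np.log(grid):
        for gy in np.log(grid):
            v = objective((gx, gy))
            # strict improvement keeps ties resolved toward (1, 1)
            if v < best_val - 1e-15:
                best, best_val = (gx, gy), v
    if not np.isfinite(best_val):
        raise ValueError("profiles do not overlap after scaling")
    res = minimize(objective, best, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12})
    sx, sy = np.exp(res.x if res.fun <= best_val else best)
    # degenerate flat profiles: x scaling is unidentifiable; report 1
    if abs(objective((0.0, np.log(sy))) - res.fun) <= 1e-15:
        sx = 1.0
    return float(sx), float(sy)


def poisson_resample(profile: RankProfile, lam: float, rng) -> RankProfile:
    """Poisson-thin a profile: reads -> Poisson(lam * reads), drop zeros, re-rank.

    With lam = 0.1 this reproduces the resampling used to purge rare
    sequencing errors before estimating the erroneous-read fraction.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = as_rng(rng)
    df = profile.df.drop(columns=["rank"]).copy()
    df["reads"] = rng.poisson(lam * profile.df["reads"].to_numpy(dtype=float))
    df = df[df["reads"] > 0]
    if df.empty:
        return RankProfile(
            df.assign(rank=pd.Series(dtype=int)),
            profile.scale_x,
            profile.scale_y,
            dict(profile.windows),
        )
    df = df.sort_values(
        ["reads", "sequence"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RankProfile(df, profile.scale_x, profile.scale_y, dict(profile.windows))
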