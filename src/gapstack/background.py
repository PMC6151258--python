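"""Road-buffer background points and per-species pseudo-absence training data.

Survey effort in the emulated study concentrates near roads, so the contrast
class for presence/pseudo-absence modeling is drawn from a pool of random
points inside a 2-km buffer around the road network (2,000 points by
default).  Per species, pseudo-absences are sampled from that pool after
excluding points that fall in presence cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .envstack import EnvStack, extract_values
from .grid import Grid
from .synthgen import distance_to_roads

__all__ = ["BackgroundSet", "TrainingSet", "buffer_roads", "sample_background",
           "build_training_set"]


@dataclass
class BackgroundSet:
    points: np.ndarray          # (n, 2) x/y
    buffer_width: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class TrainingSet:
    """Presence (label 1) and pseudo-absence (label 0) feature rows sharing
    one feature-column set."""

    species_id: str
    X: pd.DataFrame
    y: np.ndarray
    presence_xy: np.ndarray
    pa_xy: np.ndarray
    pa_seed: int

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def buffer_roads(roads: list[LineString], grid: Grid, width: float = 2000.0) -> np.ndarray:
    """Boolean mask of cells whose center lies within ``width`` m of a road."""
    if not roads:
        raise ValueError("empty road set")
    return distance_to_roads(roads, grid) <= width


def sample_background(mask: np.ndarray, grid: Grid, n: int = 2000,
                      seed: int = 0, buffer_width: float = 2000.0) -> BackgroundSet:
    """``n`` points uniform over mask cells, one uniform jitter per point.

    Every returned point lies in a mask cell (the buffer predicate is
    evaluated cell-wise).  Deterministic per seed.
    """
    cells = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
    if cells.size == 0:
        raise ValueError("background mask is empty")
    rng = np.random.default_rng(seed)
    if n == 0:
        return BackgroundSet(points=np.empty((0, 2)), buffer_width=buffer_width, seed=seed)
    pick = cells[rng.integers(0, cells.size, size=n)]
    r, c = pick // grid.ncols, pick % grid.ncols
    cs = grid.cell_size
    x = grid.xmin + (c + rng.uniform(0.001, 0.999, n)) * cs
    y = grid.ymax - (r + rng.uniform(0.001, 0.999, n)) * cs
    return BackgroundSet(points=np.column_stack([x, y]),
                         buffer_width=buffer_width, seed=seed)


def build_training_set(species_id: str,
                       presences: pd.DataFrame | np.ndarray,
                       background: BackgroundSet,
                       env: EnvStack,
                       pa_per_set: int | None = None,
                       seed: int = 0) -> TrainingSet:
    """Assemble the presence/pseudo-absence design matrix for one species.

    Background points whose cell contains a presence are excluded from the
    pseudo-absence pool; ``pa_per_set`` (default ``min(1000, pool size)``)
    points are then drawn without replacement.
    """
    if isinstance(presences, pd.DataFrame):
        pres_xy = presences[["x", "y"]].to_numpy(dtype=float)
    else:
        pres_xy = np.asarray(presences, dtype=float)
    if len(pres_xy) == 0:
        raise ValueError(f"{species_id}: no presence points")

    grid = env.grid
    pr, pc = grid.points_to_cells(pres_xy)
    pres_cells = set(zip(pr.tolist(), pc.tolist()))
    br, bc = grid.points_to_cells(background.points)
    eligible = np.array([(r, c) not in pres_cells for r, c in zip(br.tolist(), bc.tolist())])
    pool = background.points[eligible]
    if pa_per_set is None:
        pa_per_set = min(1000, len(pool))
    if pa_per_set > len(pool):
        raise ValueError(
            f"{species_id}: pa_per_set={pa_per_set} exceeds available background "
            f"({len(pool)} after presence-cell exclusion)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=pa_per_set, replace=False)
    pa_xy = pool[idx]

    X = pd.concat([extract_values(pres_xy, env), extract_values(pa_xy, env)],
                  ignore_index=True)
    y = np.concatenate([np.ones(len(pres_xy), dtype=int),
                        np.zeros(len(pa_xy), dtype=int)])
    return TrainingSet(species_id=species_id, X=X, y=y,
                       presence_xy=pres_xy, pa_xy=pa_xy, pa_seed=seed)
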