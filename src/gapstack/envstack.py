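"""Environmental raster stack: seasonal grouping, point extraction, VIF selection.

The stack mirrors the study design of two topography variables (elevation,
slope) that are valid year-round plus climate variables tagged ``annual``,
``summer`` or ``winter``.  Collinearity among candidate predictors is screened
with variance inflation factors (VIF = 1 / (1 - R^2) of each predictor
regressed on all the others) and backward elimination at a threshold of 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "EnvStack", "VariableDiagnostics",
    "extract_values", "compute_vif", "backward_eliminate_vif",
    "select_variables_vif", "seasonal_subset",
]

SEASONS = {"annual", "summer", "winter"}
SCENARIOS = ("all", "resident", "summer", "winter")

#: Which climate season each scenario uses (topography is always included).
SCENARIO_SEASON = {"all": "annual", "resident": "annual",
                   "summer": "summer", "winter": "winter"}


@dataclass
class EnvStack:
    """Named, congruent raster layers on a shared grid.

    ``season`` tags each layer annual/summer/winter; ``topography`` names the
    layers (elevation, slope) kept in every seasonal subset.
    """

    layers: dict[str, np.ndarray]
    season: dict[str, str]
    grid: Grid
    topography: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if name not in self.season:
                raise ValueError(f"layer {name!r} has no season group")
            if self.season[name] not in SEASONS:
                raise ValueError(f"layer {name!r}: unknown season {self.season[name]!r}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(layers={n: self.layers[n] for n in names},
                        season={n: self.season[n] for n in names},
                        grid=self.grid,
                        topography=frozenset(n for n in names if n in self.topography))

    def to_matrix(self) -> pd.DataFrame:
        """All cells as rows (row-major) with one column per layer."""
        return pd.DataFrame({n: self.layers[n].ravel() for n in self.layers})


def extract_values(points: np.ndarray | pd.DataFrame, stack: EnvStack) -> pd.DataFrame:
    """Layer values at the cell containing each point (nearest-cell rule).

    Row order preserves point order; points outside the extent raise an error
    naming the offending point.
    """
    if isinstance(points, pd.DataFrame):
        pts = points[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    rows, cols = stack.grid.points_to_cells(pts)
    return pd.DataFrame({n: stack.layers[n][rows, cols] for n in stack.layers})


def compute_vif(features: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor of every column.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from an ordinary least-squares
    regression (with intercept) of column j on all the other columns.
    Perfectly collinear columns are reported as ``inf``.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if n <= p:
        raise ValueError(f"VIF needs more rows ({n}) than columns ({p})")
    for j, name in enumerate(features.columns):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"column {name!r} is constant")
    out: dict[str, float] = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(features.columns):
        y = X[:, j]
        A = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst
        out[str(name)] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class VariableDiagnostics:
    """Result of backward VIF elimination."""

    vif: dict[str, float]                 # final VIFs of the survivors
    selected: list[str]                   # surviving names, stack order
    dropped: list[tuple[str, int]]        # (name, 1-based round it was dropped)
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": n, "round_dropped": r, "final_vif": np.nan}
                for n, r in self.dropped]
        rows += [{"variable": n, "round_dropped": 0, "final_vif": self.vif.get(n, np.nan)}
                 for n in self.selected]
        return pd.DataFrame(rows, columns=["variable", "round_dropped", "final_vif"])


def backward_eliminate_vif(features: pd.DataFrame, threshold: float = 10.0) -> VariableDiagnostics:
    """Iteratively drop the worst-VIF column until all VIF < threshold.

    Ties on the maximal VIF (including inf/inf) drop the later column in
    stack order, keeping elimination deterministic.
    """
    cols = [str(c) for c in features.columns]
    dropped: list[tuple[str, int]] = []
    rnd = 0
    while True:
        if len(cols) < 2:
            warnings.warn("fewer than 2 variables survive VIF elimination", stacklevel=2)
            final = {c: 1.0 for c in cols}
            return VariableDiagnostics(vif=final, selected=cols, dropped=dropped,
                                       threshold=threshold)
        vifs = compute_vif(features[cols])
        worst = max(vifs.values())
        if worst < threshold:
            return VariableDiagnostics(vif=vifs, selected=cols, dropped=dropped,
                                       threshold=threshold)
        rnd += 1
        tied = [c for c in cols if vifs[c] == worst]
        victim = tied[-1]  # later in stack order
        cols = [c for c in cols if c != victim]
        dropped.append((victim, rnd))


def select_variables_vif(stack: EnvStack, sample_points: np.ndarray | pd.DataFrame,
                         threshold: float = 10.0) -> VariableDiagnostics:
    """VIF-screen a stack's layers using values extracted at sample points."""
    feats = extract_values(sample_points, stack)
    return backward_eliminate_vif(feats, threshold=threshold)


def seasonal_subset(stack: EnvStack, scenario: str) -> EnvStack:
    """Layers relevant to one scenario: topography plus that season's climate.

    ``all``/``resident`` keep annual climate; ``summer``/``winter`` keep their
    own seasonal climate group.
    """
    if scenario not in SCENARIO_SEASON:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    keep_season = SCENARIO_SEASON[scenario]
    names = [n for n in stack.names
             if n in stack.topography or stack.season[n] == keep_season]
    return stack.subset(names)
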