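"""Distance-weighted inter-tree competition indices.

Three Hegyi-type formulations generalised to arbitrary crown/size metrics:

    CIA_i = sum_j (c_j/c_i) / L_ij
    CIB_i = sum_j (c_j/c_i) / L_ij^2
    CIC_i = sum_j (c_j/c_i)^2 / L_ij

with neighbourhoods defined either by a fixed radius around the subject
tree (area method, N_A) or by shared watershed-segment boundaries on the
canopy height model (boundary method, N_B). With c = DBH and the area
neighbourhood, CIA reduces to the classic Hegyi index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodSpec",
    "CompetitionSpec",
    "FORMULATIONS",
    "CROWN_METRIC_NAMES",
    "radius_for_mean_count",
    "neighbors_area",
    "neighbors_boundary",
    "compute_ci",
    "standardize",
    "enumerate_specs",
]

FORMULATIONS = ("CIA", "CIB", "CIC")
#: the nine crown metrics eligible as competition size variables
CROWN_METRIC_NAMES = ("CR", "CL", "GA_P", "CA_P", "A_CG",
                      "CS_C", "CS_T", "CV_F", "CV_P")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """method 'area' (fixed radius, N_A) or 'boundary' (shared segment edge, N_B)."""

    method: str
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("area", "boundary"):
            raise ValueError("neighborhood method must be 'area' or 'boundary'")
        if self.method == "area" and (self.radius is None or self.radius <= 0):
            raise ValueError("area neighborhood requires radius > 0")

    @property
    def label(self) -> str:
        return "NA" if self.method == "area" else "NB"


@dataclass(frozen=True)
class CompetitionSpec:
    """One of the candidate competition-index configurations."""

    crown_metric: str
    formulation: str
    neighborhood: NeighborhoodSpec

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"formulation must be one of {FORMULATIONS}")

    @property
    def label(self) -> str:
        return f"{self.crown_metric.replace('_', '')}_{self.formulation}_{self.neighborhood.label}"


def radius_for_mean_count(spacing: float, k: int) -> float:
    """Radius containing on average ``k`` neighbours on a square grid.

    On a uniform grid of pitch ``spacing`` the expected number of grid
    points in a circle of radius r is pi r^2 / spacing^2; solving for the
    circle holding the subject tree plus k neighbours gives
    r = spacing * sqrt((k + 1) / pi). For a 3.2 m pitch and 20 neighbours
    this is the conventional 8.273 m competition radius.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    return spacing * np.sqrt((k + 1) / np.pi)


def neighbors_area(positions: np.ndarray, radius: float,
                   include_self: bool = False,
                   active: Optional[np.ndarray] = None) -> list[np.ndarray]:
    """Fixed-radius neighbourhoods (N_A).

    positions: (n, 2) array of x/y in metres. ``active`` marks trees
    eligible as competitors (dead/removed trees excluded); inactive trees
    still receive their own neighbour list. Raises on duplicate
    coordinates (zero distance is undefined in the indices).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pos = np.asarray(positions, dtype=float)
    if active is None:
        active = np.ones(len(pos), dtype=bool)
    active = np.asarray(active, dtype=bool)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=1e-9)
    if pairs:
        raise ValueError(f"duplicate coordinates at indices {sorted(pairs)[0]}")
    out: list[np.ndarray] = []
    lists = tree.query_ball_point(pos, r=radius)
    for i, lst in enumerate(lists):
        arr = np.array([j for j in lst if active[j] and (include_self or j != i)],
                       dtype=int)
        arr.sort()
        out.append(arr)
    return out


def neighbors_boundary(labels: np.ndarray, connectivity: int = 4) -> dict[int, np.ndarray]:
    """Shared-boundary neighbourhoods (N_B) from a segment label raster.

    Two segments are neighbours iff they have a pair of adjacent cells
    (4-connectivity by default, 8 optional). Label 0 (unassigned) is
    ignored. Returns {label: sorted array of neighbour labels}.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = np.asarray(labels)
    pairs: set[tuple[int, int]] = set()

    def add_pairs(a: np.ndarray, b: np.ndarray) -> None:
        m = (a != b) & (a != 0) & (b != 0)
        for u, v in zip(a[m].ravel(), b[m].ravel()):
            pairs.add((min(int(u), int(v)), max(int(u), int(v))))

    add_pairs(lab[:, :-1], lab[:, 1:])
    add_pairs(lab[:-1, :], lab[1:, :])
    if connectivity == 8:
        add_pairs(lab[:-1, :-1], lab[1:, 1:])
        add_pairs(lab[:-1, 1:], lab[1:, :-1])

    adj: dict[int, set[int]] = {int(l): set() for l in np.unique(lab) if l != 0}
    for u, v in pairs:
        adj[u].add(v)
        adj[v].add(u)
    return {k: np.array(sorted(v), dtype=int) for k, v in adj.items()}


def _ci_terms(ratio: np.ndarray, dist: np.ndarray, formulation: str) -> np.ndarray:
    if formulation == "CIA":
        return ratio / dist
    if formulation == "CIB":
        return ratio / dist ** 2
    if formulation == "CIC":
        return ratio ** 2 / dist
    raise ValueError(f"unknown formulation {formulation!r}")


def compute_ci(values: np.ndarray, positions: np.ndarray,
               adjacency: Sequence[np.ndarray], formulation: str,
               subject: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Competition index for each subject tree.

    values: size metric c for every tree (subjects and competitors);
    positions: (n, 2) metres; adjacency: neighbour index arrays as from
    :func:`neighbors_area`; ``subject`` restricts which trees get an index
    (competitors outside it still contribute). Empty neighbourhoods yield
    0 with a logged count. A non-positive c on a subject tree is an error.
    """
    c = np.asarray(values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = len(c)
    if subject is None:
        subject = np.ones(n, dtype=bool)
    subject = np.asarray(subject, dtype=bool)
    raw = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    n_empty = 0
    for i in np.flatnonzero(subject):
        if not c[i] > 0:
            raise ValueError(f"non-positive crown metric for subject tree index {i}")
        nb = np.asarray(adjacency[i], dtype=int)
        counts[i] = len(nb)
        if len(nb) == 0:
            raw[i] = 0.0
            n_empty += 1
            continue
        d = np.hypot(pos[nb, 0] - pos[i, 0], pos[nb, 1] - pos[i, 1])
        if np.any(d <= 0):
            raise ValueError(f"zero distance between tree {i} and a neighbour")
        raw[i] = _ci_terms(c[nb] / c[i], d, formulation).sum()
    if n_empty:
        logger.warning("%d subject trees had empty neighbourhoods (CI set to 0)", n_empty)
    return pd.DataFrame({"ci": raw, "n_neighbors": counts})


def standardize(values: Iterable[float]) -> np.ndarray:
    """Centre and scale to zero mean, unit sample SD (ddof=1)."""
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    v = np.asarray(v, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("standardize needs at least 2 values")
    sd = np.std(v[ok], ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize constant values (zero SD)")
    out = np.full_like(v, np.nan)
    out[ok] = (v[ok] - np.mean(v[ok])) / sd
    return out


def enumerate_specs(crown_metrics: Sequence[str] = CROWN_METRIC_NAMES,
                    formulations: Sequence[str] = FORMULATIONS,
                    neighborhoods: Optional[Sequence[NeighborhoodSpec]] = None,
                    radius: float = 8.273) -> list[CompetitionSpec]:
    """Cartesian product of crown metrics x formulations x neighbourhoods."""
    if neighborhoods is None:
        neighborhoods = (NeighborhoodSpec("area", radius), NeighborhoodSpec("boundary"))
    if not (crown_metrics and formulations and neighborhoods):
        raise ValueError("all input lists must be non-empty")
    specs = [CompetitionSpec(m, f, n) for m, f, n in
             itertools.product(crown_metrics, formulations, neighborhoods)]
    labels = [s.label for s in specs]
    assert len(set(labels)) == len(labels)
    return specs
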