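"""Incomplete-block progeny trial layouts.

The trial emulated here is a single-tree-plot incomplete block design:
replicates are divided into incomplete blocks, each block is a rectangular
grid of single-tree plots on a uniform spacing, a small set of control
families appears in every block and the remaining families are partitioned
across the incomplete blocks of each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TrialDesignParams",
    "TrialLayout",
    "generate_layout",
    "assign_families",
    "apply_mortality",
]


class DesignError(ValueError):
    """Raised when trial design parameters are inconsistent."""


@dataclass(frozen=True)
class TrialDesignParams:
    """Parameters of the trial layout.

    Defaults reproduce a 75-block trial: 25 replicates of 3 incomplete
    blocks, 6x6 single-tree plots on a 3.2 m square grid, 96 families of
    which 6 are controls present in every block, surrounded by a 50 m
    buffer stand at 786 stems/ha.
    """

    n_replicates: int = 25
    iblocks_per_replicate: int = 3
    block_rows: int = 6
    block_cols: int = 6
    spacing: float = 3.2
    n_families: int = 96
    n_controls: int = 6
    buffer_width: float = 50.0
    buffer_density: float = 786.0
    #: arrangement of replicates as (rows, cols) of replicate tiles;
    #: None picks the most square exact factorisation.
    replicate_arrangement: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for name in ("n_replicates", "iblocks_per_replicate", "block_rows",
                     "block_cols", "n_families", "n_controls"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be a positive count")
        if self.spacing <= 0:
            raise DesignError("spacing must be > 0")
        if self.n_controls >= self.n_families:
            raise DesignError("n_controls must be < n_families")
        if self.buffer_width < 0 or self.buffer_density < 0:
            raise DesignError("buffer parameters must be non-negative")

    @property
    def n_blocks(self) -> int:
        return self.n_replicates * self.iblocks_per_replicate

    @property
    def trees_per_block(self) -> int:
        return self.block_rows * self.block_cols

    @property
    def n_positions(self) -> int:
        return self.n_blocks * self.trees_per_block

    def block_extent(self) -> tuple[float, float]:
        """Block footprint (width, height) in metres."""
        return (self.block_cols * self.spacing, self.block_rows * self.spacing)


def _replicate_grid(params: TrialDesignParams) -> tuple[int, int]:
    if params.replicate_arrangement is not None:
        r, c = params.replicate_arrangement
        if r * c != params.n_replicates:
            raise DesignError("replicate_arrangement does not factor n_replicates")
        return r, c
    n = params.n_replicates
    best = 1
    for d in range(1, int(np.sqrt(n)) + 1):
        if n % d == 0:
            best = d
    return n // best, best


@dataclass
class TrialLayout:
    """Complete rectangular grid of planting positions with blocking factors.

    ``positions`` has one row per grid position with columns
    row, col (0-based grid indices), x, y (metres, x = col*spacing,
    y = row*spacing), rep, iblock (1-based within replicate), block
    (1-based global).
    """

    params: TrialDesignParams
    positions: pd.DataFrame = field(repr=False)

    @property
    def n_rows(self) -> int:
        return int(self.positions["row"].max()) + 1

    @property
    def n_cols(self) -> int:
        return int(self.positions["col"].max()) + 1

    def extent(self) -> tuple[float, float]:
        """Ground footprint (width, height) in metres, counting the full
        plot area of every tree (one spacing per row/column)."""
        return (self.n_cols * self.params.spacing,
                self.n_rows * self.params.spacing)

    def area_ha(self) -> float:
        w, h = self.extent()
        return w * h / 10_000.0


def generate_layout(params: TrialDesignParams) -> TrialLayout:
    """Build the complete planting grid.

    Replicates are tiled on a near-square grid; within a replicate the
    incomplete blocks are stacked vertically, so a replicate tile is
    (iblocks_per_replicate * block_rows) rows by block_cols columns of
    trees. Deterministic given ``params``.
    """
    rep_rows, rep_cols = _replicate_grid(params)
    rows_per_rep = params.iblocks_per_replicate * params.block_rows

    recs = []
    block_id = 0
    for rep_idx in range(params.n_replicates):
        rr, rc = divmod(rep_idx, rep_cols)
        row0 = rr * rows_per_rep
        col0 = rc * params.block_cols
        for ib in range(params.iblocks_per_replicate):
            block_id += 1
            brow0 = row0 + ib * params.block_rows
            for i in range(params.block_rows):
                for j in range(params.block_cols):
                    recs.append((brow0 + i, col0 + j, rep_idx + 1, ib + 1, block_id))
    pos = pd.DataFrame(recs, columns=["row", "col", "rep", "iblock", "block"])
    pos["x"] = pos["col"] * params.spacing
    pos["y"] = pos["row"] * params.spacing
    pos = pos[["row", "col", "x", "y", "rep", "iblock", "block"]]
    assert len(pos) == params.n_positions
    assert not pos.duplicated(["row", "col"]).any()
    return TrialLayout(params=params, positions=pos.reset_index(drop=True))


def assign_families(layout: TrialLayout, params: TrialDesignParams,
                    seed: int) -> pd.DataFrame:
    """Assign families to planting positions.

    Control families (ids 1..n_controls) occur in every block; the
    remaining families are partitioned at random across the incomplete
    blocks of each replicate (a fresh partition per replicate), and every
    block holds distinct families at randomized positions. When a block
    has more non-control slots than its incomplete-block family group, a
    DesignError is raised; when it has fewer, a random subset of the group
    is planted (each family still appears at most once per block).

    Returns the tree table: one row per position with tree_id, family,
    control flag, the layout's blocking columns, and alive=True.
    """
    rng = np.random.default_rng(seed)
    n_nc = params.n_families - params.n_controls
    per_block = params.trees_per_block
    nc_slots = per_block - params.n_controls
    if nc_slots < 0:
        raise DesignError("block smaller than the control set")

    controls = np.arange(1, params.n_controls + 1)
    noncontrols = np.arange(params.n_controls + 1, params.n_families + 1)
    k = params.iblocks_per_replicate
    # group sizes: remainder spread over the first iblocks
    base, rem = divmod(n_nc, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    if min(sizes) < nc_slots:
        raise DesignError(
            f"incomplete-block family group ({min(sizes)}) cannot fill "
            f"{nc_slots} non-control positions with distinct families")

    pos = layout.positions.sort_values(["block", "row", "col"]).reset_index(drop=True)
    fam_col = np.empty(len(pos), dtype=int)
    for rep in range(1, params.n_replicates + 1):
        perm = rng.permutation(noncontrols)
        groups, off = [], 0
        for s in sizes:
            groups.append(perm[off:off + s])
            off += s
        for ib in range(1, k + 1):
            mask = (pos["rep"] == rep) & (pos["iblock"] == ib)
            idx = np.flatnonzero(mask.to_numpy())
            grp = groups[ib - 1]
            chosen = grp if len(grp) == nc_slots else rng.choice(
                grp, size=nc_slots, replace=False)
            fams = np.concatenate([controls, chosen])
            rng.shuffle(fams)
            fam_col[idx] = fams
    trees = pos.copy()
    trees.insert(0, "tree_id", np.arange(1, len(trees) + 1) + params.n_families)
    trees.insert(1, "family", fam_col)
    trees.insert(2, "control", trees["family"] <= params.n_controls)
    trees["alive"] = True
    return trees


def apply_mortality(trees: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Flag trees dead independently with probability ``rate``.

    Dead trees keep their grid coordinates (the gap remains in the grid);
    any trait columns (H, DBH, V, D38, A) present are set to NaN for dead
    trees.
    """
    if not 0 <= rate < 1:
        raise ValueError("mortality rate must be in [0, 1)")
    out = trees.copy()
    rng = np.random.default_rng(seed)
    dead = rng.random(len(out)) < rate
    out["alive"] = out["alive"] & ~dead
    for col in ("H", "DBH", "V", "D38", "A"):
        if col in out.columns:
            out.loc[~out["alive"], col] = np.nan
    return out
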