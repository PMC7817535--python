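"""Pedigrees and the additive (numerator) relationship matrix.

Individuals are integer ids; 0 denotes an unknown parent. Records must be
topologically ordered (parents before offspring), the convention of the
tabular method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "simulate_pedigree", "additive_matrix", "gene_drop"]

UNKNOWN = 0


@dataclass
class Pedigree:
    """records: DataFrame with columns id, sire, dam (0 = unknown)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"id", "sire", "dam"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"pedigree needs columns {sorted(need)}")
        self.validate()

    def validate(self) -> None:
        ids = self.records["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        seen: set[int] = set()
        for rec in self.records.itertuples(index=False):
            for par in (rec.sire, rec.dam):
                if par != UNKNOWN and par not in seen:
                    raise ValueError(
                        f"individual {rec.id}: parent {par} not defined earlier "
                        "(pedigree must list parents before offspring)")
            if rec.sire == rec.id or rec.dam == rec.id:
                raise ValueError(f"individual {rec.id} is its own parent")
            seen.add(rec.id)

    @property
    def ids(self) -> np.ndarray:
        return self.records["id"].to_numpy()

    def __len__(self) -> int:
        return len(self.records)


def simulate_pedigree(n_families: int, family_type: str, seed: int = 0,
                      offspring_ids: "list[list[int]] | None" = None,
                      n_offspring: int = 0) -> Pedigree:
    """Build a one-generation pedigree for ``n_families`` families.

    half_sib: each family is one known founder sire with unknown dams
    (open-pollinated); full_sib: each family has a known sire and a known
    dam. Founder ids are 1..n_families (sires) and, for full-sib families,
    n_families+1..2*n_families (dams). Offspring ids either come from
    ``offspring_ids`` (one list per family) or are generated sequentially,
    ``n_offspring`` per family.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if family_type not in ("half_sib", "full_sib"):
        raise ValueError(f"unknown family_type {family_type!r}")

    recs: list[tuple[int, int, int]] = []
    sires = list(range(1, n_families + 1))
    for s in sires:
        recs.append((s, UNKNOWN, UNKNOWN))
    dams = [UNKNOWN] * n_families
    next_id = n_families + 1
    if family_type == "full_sib":
        dams = list(range(n_families + 1, 2 * n_families + 1))
        for d in dams:
            recs.append((d, UNKNOWN, UNKNOWN))
        next_id = 2 * n_families + 1

    if offspring_ids is None:
        offspring_ids = []
        for _ in range(n_families):
            offspring_ids.append(list(range(next_id, next_id + n_offspring)))
            next_id += n_offspring
    if len(offspring_ids) != n_families:
        raise ValueError("offspring_ids must have one list per family")
    for fam in range(n_families):
        for oid in offspring_ids[fam]:
            recs.append((oid, sires[fam], dams[fam]))
    return Pedigree(pd.DataFrame(recs, columns=["id", "sire", "dam"]))


def additive_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix A by the tabular method.

    A_ii = 1 + 0.5 * A[sire, dam]; A_ij = 0.5 * (A[j, sire(i)] + A[j, dam(i)]),
    unknown parents contributing 0. Returned as a DataFrame indexed by
    individual id in pedigree order.
    """
    ids = pedigree.ids
    n = len(ids)
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = pedigree.records["sire"].to_numpy()
    dam = pedigree.records["dam"].to_numpy()
    A = np.zeros((n, n))
    for i in range(n):
        s = pos.get(int(sire[i]), -1)
        d = pos.get(int(dam[i]), -1)
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        A[i, :i] = 0.5 * row
        A[:i, i] = A[i, :i]
    return pd.DataFrame(A, index=ids, columns=ids)


def gene_drop(pedigree: Pedigree, sigma2_a: float, rng: np.random.Generator) -> pd.Series:
    """Simulate additive genetic values by gene dropping.

    a_i = 0.5*(a_sire + a_dam) + Mendelian deviation; an unknown parent
    contributes an independent draw of half the founder variance, so the
    marginal variance of every non-inbred individual is sigma2_a and the
    covariance between relatives follows the numerator relationship.
    """
    if sigma2_a < 0:
        raise ValueError("sigma2_a must be >= 0")
    ids = pedigree.ids
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = pedigree.records["sire"].to_numpy()
    dam = pedigree.records["dam"].to_numpy()
    a = np.zeros(len(ids))
    # diagonal of A (inbreeding) needed for exact Mendelian variances
    diag = np.ones(len(ids))
    Adf = additive_matrix(pedigree)
    A = Adf.to_numpy()
    diag = np.diag(A)
    for i in range(len(ids)):
        s = pos.get(int(sire[i]), -1)
        d = pos.get(int(dam[i]), -1)
        mean = 0.0
        var = sigma2_a
        if s >= 0 and d >= 0:
            mean = 0.5 * (a[s] + a[d])
            var = sigma2_a * (diag[i] - 0.25 * (diag[s] + diag[d]) - 0.5 * A[s, d])
        elif s >= 0:
            mean = 0.5 * a[s]
            var = sigma2_a * (diag[i] - 0.25 * diag[s])
        elif d >= 0:
            mean = 0.5 * a[d]
            var = sigma2_a * (diag[i] - 0.25 * diag[d])
        a[i] = mean + rng.normal(0.0, np.sqrt(max(var, 0.0)))
    return pd.Series(a, index=ids)
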