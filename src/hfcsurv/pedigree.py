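"""Pedigree kinship, inbreeding coefficients, and dataset restriction.

Kinship is the standard recursive coefficient of coancestry with
memoization: founders (unknown parents) are treated as unrelated and
non-inbred, and an individual's inbreeding coefficient ``f`` is the
kinship of its parents (0 if either is unknown).  Individuals with
``f >= 0.125`` are classified inbred.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

UNKNOWN = None

RESTRICTION_LEVELS = ("both_parents", "ge1_grandparent", "all4_grandparents")

__all__ = ["Pedigree", "InbreedingRecord", "read_pedigree", "kinship",
           "inbreeding_f", "restrict", "classify_inbred", "inbreeding_table",
           "RESTRICTION_LEVELS", "PedigreeCycleError"]


class PedigreeCycleError(ValueError):
    """An individual is its own ancestor; message names the cycle."""


@dataclass(frozen=True)
class InbreedingRecord:
    id: str
    f: float
    restriction_level: str
    inbred: int


class Pedigree:
    """id -> (dam, sire) links plus cohort/sex/group metadata.

    ``records`` maps each id to a ``(dam, sire)`` tuple where either slot may
    be ``None`` (unknown).  Any dam/sire named must itself be a record.
    """

    def __init__(self, records: dict[str, tuple[Optional[str], Optional[str]]],
                 meta: pd.DataFrame | None = None):
        self.records = dict(records)
        for child, (dam, sire) in self.records.items():
            for par in (dam, sire):
                if par is not None and par not in self.records:
                    raise ValueError(f"parent {par!r} of {child!r} has no record")
        self.meta = meta if meta is not None else pd.DataFrame(
            index=pd.Index(list(records), name="id"))
        self._depth = self._compute_depths()
        self._kin_cache: dict[tuple[str, str], float] = {}

    def _compute_depths(self) -> dict[str, int]:
        # iterative DFS with cycle detection; depth = topological rank
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 1 = on stack, 2 = done
        for root in self.records:
            if root in depth:
                continue
            stack = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    d = 0
                    for par in self.records[node]:
                        if par is not None:
                            d = max(d, depth[par] + 1)
                    depth[node] = d
                    state[node] = 2
                    continue
                if state.get(node) == 2:
                    continue
                if state.get(node) == 1:
                    raise PedigreeCycleError(f"pedigree cycle through {node!r}")
                state[node] = 1
                stack.append((node, True))
                for par in self.records[node]:
                    if par is not None and state.get(par) != 2:
                        if state.get(par) == 1:
                            raise PedigreeCycleError(
                                f"pedigree cycle through {par!r}")
                        stack.append((par, False))
        return depth

    def parents(self, ind: str) -> tuple[Optional[str], Optional[str]]:
        try:
            return self.records[ind]
        except KeyError:
            raise KeyError(f"unknown individual: {ind!r}") from None

    def grandparents(self, ind: str) -> list[Optional[str]]:
        """The four grandparent slots (dam's dam, dam's sire, sire's dam,
        sire's sire); a slot is None if unreachable."""
        dam, sire = self.parents(ind)
        out: list[Optional[str]] = []
        for par in (dam, sire):
            if par is None:
                out.extend([None, None])
            else:
                out.extend(self.records[par])
        return out

    def __contains__(self, ind: str) -> bool:
        return ind in self.records

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV: id,dam,sire[,cohort,sex,group]; empty = unknown."""
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "dam", "sire"):
        if col not in df.columns:
            raise ValueError(f"pedigree CSV missing column {col!r}")
    records = {}
    for rec in df.itertuples(index=False):
        dam = None if pd.isna(rec.dam) or rec.dam == "" else rec.dam
        sire = None if pd.isna(rec.sire) or rec.sire == "" else rec.sire
        records[rec.id] = (dam, sire)
    meta = df.set_index("id")
    return Pedigree(records, meta)


def write_pedigree(p: Pedigree, path) -> None:
    rows = [(i, d or "", s or "") for i, (d, s) in p.records.items()]
    df = pd.DataFrame(rows, columns=["id", "dam", "sire"])
    for col in ("cohort", "sex", "group"):
        if col in p.meta.columns:
            df[col] = p.meta[col].reindex(df["id"]).to_numpy()
    df.to_csv(path, index=False)


def kinship(p: Pedigree, a: str, b: str) -> float:
    """Coefficient of coancestry between ``a`` and ``b``.

    Recursive with memoization; ``kinship(a, a) = 0.5 * (1 + f_a)``.
    Founders are unrelated and non-inbred.
    """
    for x in (a, b):
        if x not in p:
            raise KeyError(f"unknown individual: {x!r}")
    return _kin(p, a, b)


def _kin(p: Pedigree, a: str, b: str) -> float:
    key = (a, b) if a <= b else (b, a)
    cached = p._kin_cache.get(key)
    if cached is not None:
        return cached
    if a == b:
        dam, sire = p.records[a]
        f = _kin(p, dam, sire) if dam is not None and sire is not None else 0.0
        val = 0.5 * (1.0 + f)
    else:
        # recurse through the parents of the deeper individual: guarantees
        # termination and correctness (the deeper one cannot be an ancestor
        # of the shallower one)
        if p._depth[a] < p._depth[b]:
            a, b = b, a
        dam, sire = p.records[a]
        val = 0.0
        if dam is not None:
            val += 0.5 * _kin(p, dam, b)
        if sire is not None:
            val += 0.5 * _kin(p, sire, b)
    p._kin_cache[key] = val
    return val


def inbreeding_f(p: Pedigree, ind: str) -> float:
    """Pedigree inbreeding coefficient: kinship of the parents; 0 if either
    parent is unknown."""
    dam, sire = p.parents(ind)
    if dam is None or sire is None:
        return 0.0
    return kinship(p, dam, sire)


def restrict(p: Pedigree, inds: Iterable[str], level: str) -> set[str]:
    """Subset of ``inds`` passing the named pedigree-completeness rule.

    ``both_parents``: dam and sire known; ``ge1_grandparent``: additionally
    at least one of the four grandparent slots known; ``all4_grandparents``:
    all four known.
    """
    if level not in RESTRICTION_LEVELS:
        raise ValueError(f"unknown restriction level {level!r}; "
                         f"expected one of {RESTRICTION_LEVELS}")
    out = set()
    for ind in inds:
        dam, sire = p.parents(ind)
        if dam is None or sire is None:
            continue
        if level == "both_parents":
            out.add(ind)
            continue
        gps = p.grandparents(ind)
        n_known = sum(g is not None for g in gps)
        if level == "ge1_grandparent" and n_known >= 1:
            out.add(ind)
        elif level == "all4_grandparents" and n_known == 4:
            out.add(ind)
    return out


def classify_inbred(f: float) -> int:
    """1 iff f >= 0.125 (inbred), else 0."""
    if f < 0:
        raise ValueError(f"negative inbreeding coefficient: {f}")
    return int(f >= 0.125)


def inbreeding_table(p: Pedigree, inds: Iterable[str] | None = None,
                     level: str = "both_parents") -> pd.DataFrame:
    """InbreedingRecords for the restricted subset of ``inds`` at ``level``."""
    inds = list(inds) if inds is not None else list(p)
    keep = restrict(p, inds, level)
    rows = []
    for ind in inds:
        if ind not in keep:
            continue
        f = inbreeding_f(p, ind)
        rows.append((ind, f, level, classify_inbred(f)))
    return pd.DataFrame(rows, columns=["id", "f", "restriction_level", "inbred"]
                        ).set_index("id")
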