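"""Microsatellite genotype tables and per-individual diversity measures.

The central object is :class:`GenotypeTable`, a dense individuals x loci
store of diploid allele calls with an explicit MISSING state.  From it we
derive per-locus allele frequencies and summaries, and the three
per-individual multilocus heterozygosity measures used in
heterozygosity-fitness work:

* SH -- standardized heterozygosity: the proportion of an individual's
  typed loci that are heterozygous, divided by the mean population
  observed heterozygosity over exactly those typed loci.
* HL -- homozygosity by locus: expected-heterozygosity-weighted
  homozygosity, ``sum(E_h over homozygous loci) / sum(E_h over typed
  loci)``, in [0, 1].
* IR -- internal relatedness: ``(2H - sum f) / (2N - sum f)`` where H is
  the number of homozygous typed loci, N the number of typed loci and the
  sum runs over the population frequencies of all 2N allele copies the
  individual carries; in [-1, 1].

Missingness is first-class everywhere: untyped loci never enter any
measure, and no silent zero-fill occurs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel allele code for an untyped call

__all__ = [
    "MISSING",
    "Locus",
    "GenotypeTable",
    "HetProfile",
    "RareAlleleScore",
    "read_genotypes",
    "write_genepop",
    "write_long_csv",
    "allele_frequencies",
    "het_profile",
    "het_profiles",
    "rare_allele_score",
    "marker_summary",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Locus:
    """Per-locus summary record."""

    name: str
    alleles: frozenset
    obs_het: float
    exp_het: float
    n_typed: int

    def __post_init__(self):
        if not 0.0 <= self.obs_het <= 1.0 or not 0.0 <= self.exp_het <= 1.0:
            raise ValueError(f"locus {self.name}: heterozygosities must lie in [0,1]")
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele")
        if self.n_typed < 0:
            raise ValueError(f"locus {self.name}: n_typed must be >= 0")


@dataclass(frozen=True)
class HetProfile:
    """Per-individual multilocus heterozygosity profile."""

    individual: str
    sh: float
    hl: float
    ir: float
    ir_defined: bool
    slh: np.ndarray  # per-locus 1.0 het / 0.0 hom / nan missing
    n_typed: int


@dataclass(frozen=True)
class RareAlleleScore:
    individual: str
    score: float
    n_rare: int
    n_alleles_typed: int


class GenotypeTable:
    """Individuals x loci diploid calls; allele pairs are unordered.

    Parameters
    ----------
    individuals : ordered individual identifiers (unique)
    loci : ordered locus names
    a1, a2 : integer arrays of shape (n_individuals, n_loci) with allele
        labels, ``MISSING`` (= -1) in both marks an untyped call.
    """

    def __init__(self, individuals: Sequence[str], loci: Sequence[str],
                 a1: np.ndarray, a2: np.ndarray):
        individuals = list(individuals)
        if len(set(individuals)) != len(individuals):
            dupes = sorted({i for i in individuals if individuals.count(i) > 1})
            raise ValueError(f"duplicate individual id(s): {dupes}")
        self.individuals = individuals
        self.loci = list(loci)
        a1 = np.asarray(a1, dtype=np.int64).copy()
        a2 = np.asarray(a2, dtype=np.int64).copy()
        if a1.shape != (len(individuals), len(loci)) or a2.shape != a1.shape:
            raise ValueError("allele arrays must be (n_individuals, n_loci)")
        # normalise: unordered pair stored sorted, and missingness is all-or-none
        miss = (a1 == MISSING) | (a2 == MISSING)
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        lo[miss] = MISSING
        hi[miss] = MISSING
        self.a1, self.a2 = lo, hi
        self._index = {ind: i for i, ind in enumerate(individuals)}

    # -- basic structure ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"unknown individual: {individual!r}") from None

    @property
    def typed(self) -> np.ndarray:
        """Boolean (n, L): call present."""
        return self.a1 != MISSING

    @property
    def het(self) -> np.ndarray:
        """Float (n, L): 1 heterozygous, 0 homozygous, nan missing."""
        h = (self.a1 != self.a2).astype(float)
        h[~self.typed] = np.nan
        return h

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.loci.index(l) for l in loci]
        return GenotypeTable(self.individuals, [self.loci[i] for i in idx],
                             self.a1[:, idx], self.a2[:, idx])

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeTable)
                and self.individuals == other.individuals
                and self.loci == other.loci
                and np.array_equal(self.a1, other.a1)
                and np.array_equal(self.a2, other.a2))


# ---------------------------------------------------------------------------
# IO: GENEPOP and long CSV
# ---------------------------------------------------------------------------

def _parse_genepop_allele(code: str, width: int, lineno: int) -> tuple[int, int]:
    if len(code) != 2 * width or not code.isdigit():
        raise GenotypeParseError(f"line {lineno}: bad genotype field {code!r}")
    x, y = int(code[:width]), int(code[width:])
    return (MISSING if x == 0 else x, MISSING if y == 0 else y)


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError("line 1: empty GENEPOP file")
    # line 1 is a title; locus names follow (one per line, or comma-separated)
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"line {len(lines)}: no 'POP' line found")
    individuals: list[str] = []
    rows1: list[list[int]] = []
    rows2: list[list[int]] = []
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            continue
        if "," not in line:
            raise GenotypeParseError(f"line {lineno}: expected 'id , genotypes'")
        ind, rest = line.split(",", 1)
        ind = ind.strip()
        codes = rest.split()
        if len(codes) != len(loci):
            raise GenotypeParseError(
                f"line {lineno}: {len(codes)} genotype fields for {len(loci)} loci")
        width = len(codes[0]) // 2
        if width not in (2, 3):
            raise GenotypeParseError(f"line {lineno}: allele codes must be 2 or 3 digits")
        r1, r2 = [], []
        for code in codes:
            x, y = _parse_genepop_allele(code, width, lineno)
            r1.append(x)
            r2.append(y)
        individuals.append(ind)
        rows1.append(r1)
        rows2.append(r2)
    if not individuals:
        raise GenotypeParseError("line 1: GENEPOP file contains no individuals")
    return GenotypeTable(individuals, loci, np.array(rows1), np.array(rows2))


def _read_long_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"individual": str, "locus": str})
    required = {"individual", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"line 1: long CSV must have columns {sorted(required)}")
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    n, L = len(individuals), len(loci)
    a1 = np.full((n, L), MISSING, dtype=np.int64)
    a2 = np.full((n, L), MISSING, dtype=np.int64)
    irow = {v: k for k, v in enumerate(individuals)}
    lcol = {v: k for k, v in enumerate(loci)}
    for rec in df.itertuples(index=False):
        i, j = irow[rec.individual], lcol[rec.locus]
        if pd.isna(rec.allele1) or pd.isna(rec.allele2):
            continue
        a1[i, j], a2[i, j] = int(rec.allele1), int(rec.allele2)
    return GenotypeTable(individuals, loci, a1, a2)


def read_genotypes(path, format: str = "genepop") -> GenotypeTable:
    """Read a genotype table from ``path`` in the named dialect.

    ``format`` is ``"genepop"`` (2- or 3-digit allele codes, all-zero code =
    missing) or ``"long_csv"`` (columns individual,locus,allele1,allele2 with
    empty = missing).
    """
    path = Path(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "long_csv":
        return _read_long_csv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genepop(g: GenotypeTable, path, title: str = "hfcsurv export") -> None:
    width = 3 if max(int(g.a1.max(initial=0)), int(g.a2.max(initial=0))) > 99 else 2
    zero = "0" * width
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        fh.write("POP\n")
        for i, ind in enumerate(g.individuals):
            codes = []
            for j in range(g.n_loci):
                x, y = g.a1[i, j], g.a2[i, j]
                if x == MISSING:
                    codes.append(zero + zero)
                else:
                    codes.append(f"{x:0{width}d}{y:0{width}d}")
            fh.write(f"{ind} , " + " ".join(codes) + "\n")


def write_long_csv(g: GenotypeTable, path) -> None:
    recs = []
    for i, ind in enumerate(g.individuals):
        for j, locus in enumerate(g.loci):
            x, y = g.a1[i, j], g.a2[i, j]
            recs.append((ind, locus,
                         "" if x == MISSING else int(x),
                         "" if y == MISSING else int(y)))
    pd.DataFrame(recs, columns=["individual", "locus", "allele1", "allele2"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Frequencies and per-locus summaries
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeTable) -> dict[str, dict[int, float]]:
    """Per-locus allele frequencies, counting two alleles per typed individual."""
    out: dict[str, dict[int, float]] = {}
    empty = []
    for j, locus in enumerate(g.loci):
        typed = g.typed[:, j]
        if not typed.any():
            empty.append(locus)
            continue
        alleles = np.concatenate([g.a1[typed, j], g.a2[typed, j]])
        labels, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        out[locus] = {int(a): c / total for a, c in zip(labels, counts)}
    if empty:
        raise ValueError(f"loci with zero typed individuals: {empty}")
    return out


def _locus_stats(g: GenotypeTable, j: int, freqs: Mapping[int, float]) -> Locus:
    typed = g.typed[:, j]
    n = int(typed.sum())
    het = float((g.a1[typed, j] != g.a2[typed, j]).mean()) if n else 0.0
    p = np.array(list(freqs.values()))
    # unbiased (small-sample corrected) expected heterozygosity:
    # 2n/(2n-1) * (1 - sum p^2), the CERVUS convention
    if n > 0 and len(p) > 1:
        eh = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p ** 2)))
        eh = min(eh, 1.0)
    else:
        eh = 0.0
    return Locus(name=g.loci[j], alleles=frozenset(int(a) for a in freqs),
                 obs_het=het, exp_het=eh, n_typed=n)


def locus_records(g: GenotypeTable,
                  freqs: Mapping[str, Mapping[int, float]] | None = None) -> list[Locus]:
    if freqs is None:
        freqs = allele_frequencies(g)
    return [_locus_stats(g, j, freqs[locus]) for j, locus in enumerate(g.loci)]


def marker_summary(g: GenotypeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus table (n_alleles, obs_het, exp_het, n_typed) and unweighted
    across-locus means with 95% CI (mean +/- 1.96 SE)."""
    if g.n_loci < 1:
        raise ValueError("marker_summary requires at least one locus")
    recs = locus_records(g)
    table = pd.DataFrame({
        "locus": [r.name for r in recs],
        "n_alleles": [len(r.alleles) for r in recs],
        "obs_het": [r.obs_het for r in recs],
        "exp_het": [r.exp_het for r in recs],
        "n_typed": [r.n_typed for r in recs],
    })
    rows = []
    for col in ["n_alleles", "obs_het", "exp_het"]:
        x = table[col].to_numpy(dtype=float)
        mean = x.mean()
        se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        rows.append((col, mean, mean - 1.96 * se, mean + 1.96 * se))
    means = pd.DataFrame(rows, columns=["measure", "mean", "ci_lo", "ci_hi"])
    return table, means


# ---------------------------------------------------------------------------
# Per-individual measures
# ---------------------------------------------------------------------------

def het_profile(g: GenotypeTable, individual: str,
                freqs: Mapping[str, Mapping[int, float]] | None = None,
                obs_het: np.ndarray | None = None,
                exp_het: np.ndarray | None = None) -> HetProfile:
    """SH / HL / IR profile of one individual (typed loci only).

    ``freqs``, ``obs_het`` and ``exp_het`` may be passed to amortize the
    population-level computation across calls; see :func:`het_profiles`.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    if obs_het is None or exp_het is None:
        recs = locus_records(g, freqs)
        obs_het = np.array([r.obs_het for r in recs])
        exp_het = np.array([r.exp_het for r in recs])
    i = g.row(individual)
    typed = g.typed[i]
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError(f"individual {individual!r} typed at zero loci")
    het = (g.a1[i] != g.a2[i]) & typed

    # SH: proportion typed loci het / mean population obs-het over those loci
    mean_obs = float(obs_het[typed].mean())
    prop_het = het.sum() / n_typed
    sh = prop_het / mean_obs if mean_obs > 0 else np.nan

    # HL: sum of exp-het over homozygous typed loci / over all typed loci
    denom_hl = float(exp_het[typed].sum())
    hom = typed & ~het
    hl = float(exp_het[hom].sum()) / denom_hl if denom_hl > 0 else np.nan

    # IR: (2H - sum f) / (2N - sum f), f over the 2N carried allele copies
    fsum = 0.0
    for j in np.nonzero(typed)[0]:
        fj = freqs[g.loci[j]]
        fsum += fj[int(g.a1[i, j])] + fj[int(g.a2[i, j])]
    H = int(hom.sum())
    denom_ir = 2 * n_typed - fsum
    ir_defined = abs(denom_ir) > 1e-12
    ir = (2 * H - fsum) / denom_ir if ir_defined else np.nan

    slh = np.where(typed, het.astype(float), np.nan)
    return HetProfile(individual=individual, sh=sh,
                      hl=hl, ir=ir, ir_defined=ir_defined,
                      slh=slh, n_typed=n_typed)


def het_profiles(g: GenotypeTable) -> pd.DataFrame:
    """SH/HL/IR for every individual typed at >= 1 locus, as a DataFrame."""
    freqs = allele_frequencies(g)
    recs = locus_records(g, freqs)
    obs = np.array([r.obs_het for r in recs])
    exp = np.array([r.exp_het for r in recs])
    rows = []
    for ind in g.individuals:
        if not g.typed[g.row(ind)].any():
            continue
        p = het_profile(g, ind, freqs=freqs, obs_het=obs, exp_het=exp)
        rows.append((ind, p.sh, p.hl, p.ir, p.n_typed))
    return pd.DataFrame(rows, columns=["individual", "sh", "hl", "ir", "n_typed"]
                        ).set_index("individual")


def rare_allele_score(g: GenotypeTable, individual: str, threshold: float = 0.05,
                      freqs: Mapping[str, Mapping[int, float]] | None = None
                      ) -> RareAlleleScore:
    """Proportion of an individual's allele copies that are population-rare.

    ``n_rare`` counts allele copies with population frequency strictly below
    ``threshold`` (a homozygous rare genotype counts 2); the denominator is
    2 x the number of typed loci.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    i = g.row(individual)
    typed = g.typed[i]
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError(f"individual {individual!r} typed at zero loci")
    n_rare = 0
    for j in np.nonzero(typed)[0]:
        fj = freqs[g.loci[j]]
        n_rare += int(fj[int(g.a1[i, j])] < threshold)
        n_rare += int(fj[int(g.a2[i, j])] < threshold)
    n_copies = 2 * n_typed
    return RareAlleleScore(individual=individual, score=n_rare / n_copies,
                           n_rare=n_rare, n_alleles_typed=n_copies)
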