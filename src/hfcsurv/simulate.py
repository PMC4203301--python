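"""Synthetic populations with known truth for every downstream module.

The generator builds a group-structured, multi-cohort population:
founders receive genotypes drawn from Dirichlet allele frequencies; each
year breeding pairs form (a configurable fraction incestuous, i.e. between
first-order relatives), offspring genotypes follow Mendelian transmission,
survival over each annual interval is Bernoulli on a logit-linear
predictor built from the configured coefficients (standardized
covariates), and detection is Bernoulli given alive.  Observed genotypes
are then corrupted with allelic dropout (eps1) and false alleles (eps2)
and thinned to the configured typing completeness.

Everything is reproducible from the mandatory seed, and the emitted
:class:`SimTruth` retains the uncorrupted state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import cjs as _cjs
from . import genotypes as _gt
from . import pedigree as _ped

__all__ = ["SimConfig", "SimTruth", "simulate_population", "simulate_climate",
           "scenario", "write_fixture_dir"]

SCENARIOS = ("null", "general_effect", "local_effect", "paternal_x_rain")


@dataclass
class SimConfig:
    seed: int
    n_founders: int = 150
    n_years: int = 24
    n_groups: int = 19
    n_loci: int = 35
    mean_alleles: float = 4.5
    incest_rate: float = 0.05
    completeness: float = 0.97
    eps1: float = 0.005           # allelic dropout
    eps2: float = 0.005           # false allele
    extra_group_rate: float = 0.5
    # demography
    breeding_females_per_group: int = 2
    litter_mean: float = 1.4
    # survival model (logit scale)
    cub_intercept: float = 0.75   # invlogit ~ 0.68
    adult_intercept: float = 1.52  # invlogit ~ 0.82
    adult_sex_effect: float = -0.3  # male penalty (sex coded -0.5 F / +0.5 M)
    cub_year_sd: float = 0.4
    beta: dict = field(default_factory=dict)
    # recapture
    recapture_p: float = 0.7
    # climate
    sr_mean: float = 665.0
    sr_sd: float = 43.0
    tsm_mean: float = 15.5
    tsm_sd: float = 0.8
    twt_mean: float = 4.2
    twt_sd: float = 1.1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("incest_rate", "completeness", "eps1", "eps2",
                     "extra_group_rate", "recapture_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0,1]")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")


@dataclass
class SimTruth:
    pedigree: "_ped.Pedigree"
    true_f: dict[str, float]
    true_genotypes: "_gt.GenotypeTable"
    config: SimConfig
    realized_incest: float
    incest_offspring: list[str]
    allele_freqs: list[dict[int, float]]
    phi_true: dict
    p_true: float
    n_pairs_feasible: int = 0


def simulate_climate(n_years: int, seed: int, sr_mean: float = 665.0,
                     sr_sd: float = 43.0, tsm_mean: float = 15.5,
                     tsm_sd: float = 0.8, twt_mean: float = 4.2,
                     twt_sd: float = 1.1) -> pd.DataFrame:
    """Gaussian yearly climate: total summer rainfall (SR), mean summer
    temperature (Tsm), mean winter temperature (Twt), unstandardized."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "SR": rng.normal(sr_mean, sr_sd, n_years),
        "Tsm": rng.normal(tsm_mean, tsm_sd, n_years),
        "Twt": rng.normal(twt_mean, twt_sd, n_years),
    }, index=pd.RangeIndex(n_years, name="year"))


def scenario(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named coefficient presets for the generator.

    null: no heterozygosity or inbreeding effects; general_effect: survival
    declines with true f; local_effect: one causal locus; paternal_x_rain:
    paternal-heterozygosity x summer-rainfall interaction (beta = 1).
    """
    base = {"SR": 0.3, "Twt": 0.6}
    if name == "null":
        beta = dict(base)
    elif name == "general_effect":
        beta = dict(base, f=-10.0)
    elif name == "local_effect":
        beta = dict(base, **{"SLH:L000": 2.5})
    elif name == "paternal_x_rain":
        beta = dict(base, SH_Pat=0.3, **{"SH_Pat*SR": 1.0})
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    cfg = SimConfig(seed=seed, beta=beta)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------

class _Sim:
    """Mutable simulation state."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        # allele frequencies per locus
        self.freqs: list[np.ndarray] = []
        self.alleles: list[np.ndarray] = []
        for j in range(cfg.n_loci):
            n_all = 2 + self.rng.poisson(max(cfg.mean_alleles - 2.0, 0.0))
            self.alleles.append(100 + 2 * np.arange(n_all))  # fragment lengths
            self.freqs.append(self.rng.dirichlet(np.ones(n_all)))
        # per-locus expected heterozygosity under the drawn frequencies
        self.h_exp = np.array([1.0 - np.sum(f ** 2) for f in self.freqs])
        # theoretical mean/SD of an outbred individual's proportion-het,
        # used to standardize heterozygosity inside the generator
        L = cfg.n_loci
        self.het_mu = float(self.h_exp.mean())
        self.het_sd = float(np.sqrt(np.sum(self.h_exp * (1 - self.h_exp))) / L)
        # individual state (parallel lists)
        self.ids: list[str] = []
        self.sex: list[int] = []      # 0 F, 1 M
        self.group: list[int] = []
        self.cohort: list[int] = []
        self.dam: list[Optional[int]] = []
        self.sire: list[Optional[int]] = []
        self.geno: list[np.ndarray] = []  # (L, 2) int
        self.f: list[float] = []
        self.alive: list[bool] = []
        self._kin_cache: dict[tuple[int, int], float] = {}

    # -- pedigree-aware kinship on the growing population -----------------
    def kin(self, a: int, b: int) -> float:
        key = (a, b) if a <= b else (b, a)
        v = self._kin_cache.get(key)
        if v is not None:
            return v
        if a == b:
            val = 0.5 * (1.0 + self.f[a])
        else:
            hi = a if a > b else b  # larger index = born later, never ancestor
            lo = b if a > b else a
            val = 0.0
            if self.dam[hi] is not None:
                val += 0.5 * self.kin(self.dam[hi], lo)
            if self.sire[hi] is not None:
                val += 0.5 * self.kin(self.sire[hi], lo)
        self._kin_cache[key] = val
        return val

    def add(self, sex, group, cohort, dam, sire) -> int:
        i = len(self.ids)
        self.ids.append(f"B{i:05d}")
        self.sex.append(int(sex))
        self.group.append(int(group))
        self.cohort.append(int(cohort))
        self.dam.append(dam)
        self.sire.append(sire)
        self.alive.append(True)
        if dam is None or sire is None:
            self.f.append(0.0)
            g = np.empty((self.cfg.n_loci, 2), dtype=np.int64)
            for j in range(self.cfg.n_loci):
                g[j] = self.rng.choice(self.alleles[j], size=2, p=self.freqs[j])
            self.geno.append(g)
        else:
            self.f.append(self.kin(dam, sire))
            gd, gs = self.geno[dam], self.geno[sire]
            pick = self.rng.integers(0, 2, size=(self.cfg.n_loci, 2))
            g = np.empty((self.cfg.n_loci, 2), dtype=np.int64)
            g[:, 0] = gd[np.arange(self.cfg.n_loci), pick[:, 0]]
            g[:, 1] = gs[np.arange(self.cfg.n_loci), pick[:, 1]]
            self.geno.append(g)
        return i

    def prop_het(self, i: int) -> float:
        g = self.geno[i]
        return float((g[:, 0] != g[:, 1]).mean())

    def sh_std(self, i: int) -> float:
        """Generator-internal standardized heterozygosity: proportion-het
        centred at its theoretical mean and scaled by 2x its theoretical SD."""
        return (self.prop_het(i) - self.het_mu) / (2.0 * self.het_sd)

    def first_order_males(self, mother: int, candidates: set[int]) -> list[int]:
        out = []
        md, ms = self.dam[mother], self.sire[mother]
        for c in candidates:
            if c == ms:  # her sire
                out.append(c)
                continue
            if self.dam[c] is not None and self.dam[c] == mother:  # her son
                out.append(c)
                continue
            if (self.dam[c] is not None and md is not None
                    and self.dam[c] == md and self.sire[c] == ms):  # full sib
                out.append(c)
        return out


def simulate_population(cfg: SimConfig) -> tuple["_ped.Pedigree",
                                                 "_gt.GenotypeTable",
                                                 "_cjs.CaptureData", SimTruth]:
    """Run the generator; see the module docstring for the process."""
    sim = _Sim(cfg)
    rng = sim.rng
    climate = simulate_climate(cfg.n_years, seed=cfg.seed + 104729,
                               sr_mean=cfg.sr_mean, sr_sd=cfg.sr_sd,
                               tsm_mean=cfg.tsm_mean, tsm_sd=cfg.tsm_sd,
                               twt_mean=cfg.twt_mean, twt_sd=cfg.twt_sd)
    clim_std = (climate - climate.mean()) / (2.0 * climate.std(ddof=1))
    year_eff = rng.normal(0.0, cfg.cub_year_sd, cfg.n_years)

    # founders: adults spread over groups
    for i in range(cfg.n_founders):
        sim.add(sex=rng.integers(0, 2), group=i % cfg.n_groups, cohort=-1,
                dam=None, sire=None)
    age = {i: 1 for i in range(cfg.n_founders)}  # 1 = adult

    causal_locus = 0  # for local-effect coefficients, locus L000
    n_incest_pairs = 0
    n_pairs_feasible = 0  # pairs where a first-order male relative existed
    incest_offspring: list[int] = []
    detections: dict[int, set[int]] = {}
    pop_size = np.zeros(cfg.n_years)
    cohort_size = np.zeros(cfg.n_years)

    beta = cfg.beta

    def cub_eta(i: int, year: int) -> float:
        eta = cfg.cub_intercept + year_eff[year]
        eta += (0.5 if sim.sex[i] else -0.5) * 0.0  # no cub sex effect by default
        for key, b in beta.items():
            if b == 0.0:
                continue
            if key in ("SR", "Tsm", "Twt"):
                eta += b * clim_std.loc[year, key]
            elif key == "f":
                eta += b * sim.f[i]
            elif key == "SH_Ind":
                eta += b * sim.sh_std(i)
            elif key == "SH_Mat":
                eta += b * sim.sh_std(sim.dam[i]) if sim.dam[i] is not None else 0.0
            elif key == "SH_Pat":
                eta += b * sim.sh_std(sim.sire[i]) if sim.sire[i] is not None else 0.0
            elif key in ("SH_Pat*SR", "SH_Mat*SR", "SH_Ind*SR"):
                who = key.split("*")[0]
                parent = {"SH_Pat": sim.sire[i], "SH_Mat": sim.dam[i],
                          "SH_Ind": i}[who]
                if parent is not None:
                    eta += b * sim.sh_std(parent) * clim_std.loc[year, "SR"]
            elif key.startswith("SLH:"):
                j = int(key.split(":L")[1])
                g = sim.geno[i]
                slh = float(g[j, 0] != g[j, 1])
                eta += b * (slh - sim.h_exp[j])
            else:
                raise ValueError(f"unknown survival coefficient {key!r}")
        return eta

    for year in range(cfg.n_years):
        alive_idx = [i for i, a in enumerate(sim.alive) if a]
        adults = [i for i in alive_idx if age[i] >= 1]
        females = [i for i in adults if sim.sex[i] == 0]
        males = [i for i in adults if sim.sex[i] == 1]
        if not females or not males:
            raise RuntimeError(
                f"population lost a sex by year {year}; increase n_founders "
                "or survival rates")
        male_set = set(males)

        # births
        born = []
        by_group: dict[int, list[int]] = {}
        for i in females:
            by_group.setdefault(sim.group[i], []).append(i)
        for grp, moms in by_group.items():
            rng.shuffle(moms)
            for mom in moms[:cfg.breeding_females_per_group]:
                n_cubs = rng.poisson(cfg.litter_mean)
                if n_cubs == 0:
                    continue
                # choose one sire per litter; incest_rate applies among
                # matings where a first-order male relative is available
                rel = sim.first_order_males(mom, male_set)
                incest = bool(rel) and rng.random() < cfg.incest_rate
                sire = None
                if rel:
                    n_pairs_feasible += 1
                if incest:
                    sire = rel[rng.integers(0, len(rel))]
                    n_incest_pairs += 1
                if sire is None:
                    extra = rng.random() < cfg.extra_group_rate
                    pool = ([m for m in males if sim.group[m] != grp] if extra
                            else [m for m in males if sim.group[m] == grp])
                    if not pool:
                        pool = males
                    sire = pool[rng.integers(0, len(pool))]
                for _ in range(n_cubs):
                    c = sim.add(sex=rng.integers(0, 2), group=grp, cohort=year,
                                dam=mom, sire=sire)
                    age[c] = 0
                    born.append(c)
                    if incest:
                        incest_offspring.append(c)
        cohort_size[year] = len(born)
        alive_idx = [i for i, a in enumerate(sim.alive) if a]
        pop_size[year] = len(alive_idx)

        # detection at this occasion (before the survival interval)
        for i in alive_idx:
            if rng.random() < cfg.recapture_p:
                detections.setdefault(i, set()).add(year)

        # survival over the interval year -> year+1
        if year < cfg.n_years - 1:
            for i in alive_idx:
                if age[i] == 0:
                    eta = cub_eta(i, year)
                else:
                    eta = (cfg.adult_intercept
                           + cfg.adult_sex_effect * (0.5 if sim.sex[i] else -0.5))
                if rng.random() >= expit(eta):
                    sim.alive[i] = False
            for i in alive_idx:
                age[i] += 1

    # ---- assemble outputs -------------------------------------------------
    n = len(sim.ids)
    L = cfg.n_loci
    true_a1 = np.array([g[:, 0] for g in sim.geno])
    true_a2 = np.array([g[:, 1] for g in sim.geno])
    true_table = _gt.GenotypeTable(sim.ids, [f"L{j:03d}" for j in range(L)],
                                   true_a1, true_a2)

    # observed genotypes: dropout, false alleles, completeness thinning
    a1 = true_a1.copy()
    a2 = true_a2.copy()
    if cfg.eps1 > 0:
        het = a1 != a2
        drop1 = (rng.random((n, L)) < cfg.eps1) & het
        drop2 = (rng.random((n, L)) < cfg.eps1) & het & ~drop1
        a1[drop1] = a2[drop1]
        a2[drop2] = a1[drop2]
    if cfg.eps2 > 0:
        for arr in (a1, a2):
            hit = rng.random((n, L)) < cfg.eps2
            for i, j in zip(*np.nonzero(hit)):
                others = sim.alleles[j][sim.alleles[j] != arr[i, j]]
                if len(others):
                    arr[i, j] = rng.choice(others)
    if cfg.completeness < 1.0:
        gone = rng.random((n, L)) > cfg.completeness
        a1[gone] = _gt.MISSING
        a2[gone] = _gt.MISSING
    obs_table = _gt.GenotypeTable(sim.ids, true_table.loci, a1, a2)

    # pedigree
    records = {sim.ids[i]: (sim.ids[sim.dam[i]] if sim.dam[i] is not None else None,
                            sim.ids[sim.sire[i]] if sim.sire[i] is not None else None)
               for i in range(n)}
    meta = pd.DataFrame({"cohort": sim.cohort,
                         "sex": ["F" if s == 0 else "M" for s in sim.sex],
                         "group": sim.group},
                        index=pd.Index(sim.ids, name="id"))
    pedigree = _ped.Pedigree(records, meta)

    # capture data over detected individuals
    det_ids = sorted(detections)
    hist = np.zeros((len(det_ids), cfg.n_years), dtype=np.int8)
    for r, i in enumerate(det_ids):
        for y in detections[i]:
            hist[r, y] = 1
    first = hist.argmax(axis=1)
    age_at_first = np.array([0 if (sim.cohort[i] >= 0
                                   and first[r] == sim.cohort[i]) else 1
                             for r, i in enumerate(det_ids)], dtype=np.int8)

    profiles = _gt.het_profiles(obs_table)
    freqs = _gt.allele_frequencies(obs_table)

    def sh_of(idx: Optional[int]) -> float:
        if idx is None:
            return np.nan
        iid = sim.ids[idx]
        return profiles["sh"].get(iid, np.nan)

    cov = pd.DataFrame(index=pd.Index([sim.ids[i] for i in det_ids], name="id"))
    cov["SH_Ind"] = [sh_of(i) for i in det_ids]
    cov["SH_Mat"] = [sh_of(sim.dam[i]) for i in det_ids]
    cov["SH_Pat"] = [sh_of(sim.sire[i]) for i in det_ids]
    cov["f"] = [sim.f[i] for i in det_ids]
    cov["cohort"] = [sim.cohort[i] for i in det_ids]
    rare = []
    for i in det_ids:
        s = sim.sire[i]
        if s is None or not obs_table.typed[s].any():
            rare.append(np.nan)
        else:
            rare.append(_gt.rare_allele_score(obs_table, sim.ids[s],
                                              freqs=freqs).score)
    cov["rare_allele_score"] = rare

    year_cov = clim_std.iloc[:-1].copy()
    year_cov["population_size"] = pop_size[:-1]
    year_cov["cohort_size"] = cohort_size[:-1]
    year_cov.index = pd.RangeIndex(cfg.n_years - 1)

    capture = _cjs.CaptureData(hist, age_at_first,
                               sex=np.array([sim.sex[i] for i in det_ids]),
                               ids=[sim.ids[i] for i in det_ids],
                               covariates=cov, year_covariates=year_cov,
                               groups=np.array([sim.group[i] for i in det_ids]))

    truth = SimTruth(
        pedigree=pedigree,
        true_f={sim.ids[i]: sim.f[i] for i in range(n)},
        true_genotypes=true_table,
        config=cfg,
        realized_incest=((n_incest_pairs / n_pairs_feasible)
                         if n_pairs_feasible else 0.0),
        incest_offspring=[sim.ids[i] for i in incest_offspring],
        n_pairs_feasible=n_pairs_feasible,
        allele_freqs=[{int(a): float(p) for a, p in zip(al, fr)}
                      for al, fr in zip(sim.alleles, sim.freqs)],
        phi_true={"cub_intercept": cfg.cub_intercept,
                  "adult_intercept": cfg.adult_intercept,
                  "beta": dict(cfg.beta)},
        p_true=cfg.recapture_p)
    return pedigree, obs_table, capture, truth


def write_fixture_dir(outdir, pedigree, genotype_table, capture, truth,
                      climate: pd.DataFrame | None = None) -> None:
    """Write an analysis-ready plain-text fixture directory: pedigree CSV,
    GENEPOP genotypes, long-CSV genotypes, MARK-style .inp, covariate CSVs
    and a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _ped.write_pedigree(pedigree, out / "pedigree.csv")
    _gt.write_genepop(genotype_table, out / "genotypes.gen")
    _gt.write_long_csv(genotype_table, out / "genotypes_long.csv")
    _cjs.write_inp(capture.histories, out / "captures.inp")
    hist_df = pd.DataFrame(capture.histories,
                           index=pd.Index(capture.ids, name="id"),
                           columns=[f"occ{t}" for t in
                                    range(capture.n_occasions)])
    hist_df["age_at_first"] = capture.age_at_first
    hist_df["sex"] = capture.sex
    hist_df.to_csv(out / "captures.csv")
    capture.covariates.to_csv(out / "individual_covariates.csv")
    capture.year_covariates.to_csv(out / "year_covariates.csv",
                                   index_label="interval")
    if climate is not None:
        climate.to_csv(out / "climate.csv")
    cfg = asdict(truth.config)
    payload = {
        "config": cfg,
        "realized_incest": truth.realized_incest,
        "true_f": truth.true_f,
        "phi_true": truth.phi_true,
        "p_true": truth.p_true,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
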