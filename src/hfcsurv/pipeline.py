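"""End-to-end orchestration: the staged reduced-model search and the full
heterozygosity/inbreeding survival analysis, with seeded reproducibility
and CSV reporting.

``run_reduced_model_search`` executes the four-stage structural sequence
(age classes, then sex, then cohort size, then population size), carrying
the winning structure forward at each stage and emitting a model table per
stage.

``run_hfc_analysis`` produces, from genotypes + pedigree + captures:
heterozygosity profiles; inbreeding at three pedigree-restriction levels;
the identity-disequilibrium block (g2, HHC, expected vs observed r);
candidate covariate model sets for individual, maternal, and paternal
heterozygosity with climate interactions and quadratics; model-averaged
estimates under the natural and zero methods; and the single-locus vs
multilocus comparison -- all written as CSV plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import cjs as _cjs
from . import genotypes as _gt
from . import identity as _id
from . import mmi as _mmi
from . import pedigree as _ped

__all__ = ["RunConfig", "run_reduced_model_search", "run_hfc_analysis",
           "candidate_models", "REDUCED_STAGES"]


@dataclass
class RunConfig:
    out_dir: str = "hfc_out"
    seed: int = 0
    plausible_delta: float = 7.0
    c_hat: Optional[float] = None      # None -> bootstrap
    n_boot: int = 100
    restriction_levels: tuple = _ped.RESTRICTION_LEVELS
    max_interactions: int = 2
    n_starts: int = 2


REDUCED_STAGES: dict[str, list[str]] = {
    "age": ["Phi(a2-t/.) p(t)", "Phi(a2-t/t) p(t)", "Phi(a2-./.) p(t)",
            "Phi(.) p(t)"],
    "sex": [],          # built from the stage-1 winner
    "cohort": [],
    "population": [],
}


def _stage_models(stage: str, carried: str) -> list[str]:
    """Candidate notations for a stage, derived from the carried structure."""
    if stage == "age":
        return REDUCED_STAGES["age"]
    spec = _cjs.parse_model(carried)
    cub = "+".join(spec.phi_cub_terms) or "."
    adult = list(spec.phi_adult_terms)
    adult_txt = "+".join(adult) or "."
    p_txt = "+".join(spec.p_terms) or "."
    if stage == "sex":
        with_sex = "+".join(adult + ["sex"])
        return [f"Phi(a2-{cub}/{with_sex}) p({p_txt})",
                f"Phi(a2-{cub}/{adult_txt}) p({p_txt})",
                f"Phi(a2-{cub}/{with_sex}) p(sex*t)"]
    if stage == "cohort":
        with_c = "+".join([t for t in adult if t != "t"] + ["sex*cohort_size"]) \
            if "sex" in adult else "cohort_size"
        return [carried, f"Phi(a2-{cub}/{with_c}) p({p_txt})"]
    if stage == "population":
        with_n = "+".join(adult + ["population_size"])
        return [f"Phi(a2-{cub}/{with_n}) p({p_txt})",
                f"Phi(a2-{cub}/{adult_txt}) p({p_txt})"]
    raise ValueError(f"unknown stage {stage!r}")


def run_reduced_model_search(data: "_cjs.CaptureData",
                             config: RunConfig | None = None,
                             out_dir=None) -> tuple[dict, str]:
    """Four-stage structural search; returns ({stage: ModelSet}, winner).

    At the cohort and population stages a numeric year-level covariate model
    is compared against the carried structure; the carried structure is kept
    unless beaten.  The returned winner is the reduced model notation.
    """
    config = config or RunConfig()
    results: dict[str, _mmi.ModelSet] = {}
    carried = None
    for stage in ("age", "sex", "cohort", "population"):
        notations = _stage_models(stage, carried)
        fits = {}
        for nota in notations:
            try:
                fit = _cjs.fit_cjs(data, nota, n_starts=config.n_starts,
                                   seed=config.seed, compute_se=False)
                if fit.converged and np.isfinite(fit.deviance):
                    fits[nota] = fit
            except Exception:
                continue
        if not fits:
            raise RuntimeError(f"no converged models at stage {stage!r}")
        q = {m: _cjs.qaicc(f, c_hat=config.c_hat or 1.0) for m, f in fits.items()}
        mset = _mmi.rank_models(q, k={m: f.k for m, f in fits.items()},
                                deviance={m: f.deviance for m, f in fits.items()},
                                fits=fits,
                                plausible_delta=config.plausible_delta)
        results[stage] = mset
        top = mset.table.iloc[0]["model"]
        # keep the carried structure unless the richer model wins
        carried = top if stage != "cohort" or top != carried else carried
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            mset.table.rename(columns={"deviance": "QDeviance", "delta": "Delta",
                                       "weight": "omega"}).to_csv(
                Path(out_dir) / f"stage_{stage}.csv", index=False)
        # at the population stage, prefer the simpler carried model unless the
        # covariate model is decisively better (mirrors keeping B1 over D1
        # when the covariate CI overlaps zero); structural winner still logged
        if stage == "population" and len(mset.table) > 1:
            deltas = mset.deltas
            if carried != notations[1] and deltas.get(notations[1], np.inf) < 2.0:
                carried = notations[1]
    return results, carried


# ---------------------------------------------------------------------------
# Candidate covariate model sets
# ---------------------------------------------------------------------------

def candidate_models(sh_term: str, climate: Sequence[str] = ("SR", "Tsm", "Twt"),
                     max_interactions: int = 2,
                     extra_terms: Sequence[str] = ()) -> list[list[str]]:
    """Combinatorial candidate list for one heterozygosity measure.

    Terms: the SH main effect, its quadratic (only with the main), the three
    climate mains, and SH x climate interactions (only with both mains
    present, at most ``max_interactions`` per model).  Always includes the
    intercept-only model.
    """
    models: list[list[str]] = []
    climate = list(climate)
    for clim_sub in itertools.chain.from_iterable(
            itertools.combinations(climate, r) for r in range(len(climate) + 1)):
        for has_sh in (False, True):
            for has_q in ((False, True) if has_sh else (False,)):
                inter_pool = [f"{sh_term}*{c}" for c in clim_sub] if has_sh else []
                for n_int in range(min(len(inter_pool), max_interactions) + 1):
                    for inters in itertools.combinations(inter_pool, n_int):
                        terms = list(clim_sub)
                        if has_sh:
                            terms.append(sh_term)
                        if has_q:
                            terms.append(f"{sh_term}^2")
                        terms.extend(inters)
                        terms.extend(extra_terms)
                        models.append(terms)
    # dedupe
    seen = set()
    out = []
    for t in models:
        key = tuple(sorted(t))
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def _notation_for(terms: Sequence[str], reduced_adult: str = "sex",
                  p_text: str = ".") -> str:
    cub = "+".join(terms) if terms else "."
    return f"Phi(a2-{cub}/{reduced_adult}) p({p_text})"


def fit_model_set(data: "_cjs.CaptureData", term_lists: Sequence[Sequence[str]],
                  c_hat: float = 1.0, fixed_p=None, reduced_adult: str = "sex",
                  seed: int = 0, n_starts: int = 1,
                  plausible_delta: float = 7.0) -> _mmi.ModelSet:
    """Fit every candidate model and rank by QAICc."""
    fits = {}
    for terms in term_lists:
        nota = _notation_for(terms, reduced_adult=reduced_adult)
        try:
            fit = _cjs.fit_cjs(data, nota, fixed_p=fixed_p, seed=seed,
                               n_starts=n_starts)
        except Exception:
            continue
        if fit.converged and np.isfinite(fit.deviance):
            fits[nota] = fit
    if not fits:
        raise RuntimeError("no candidate model converged")
    q = {m: _cjs.qaicc(f, c_hat=c_hat) for m, f in fits.items()}
    return _mmi.rank_models(q, k={m: f.k for m, f in fits.items()},
                            deviance={m: f.deviance for m, f in fits.items()},
                            fits=fits, plausible_delta=plausible_delta)


def averaged_table(mset: _mmi.ModelSet, sh_term: str,
                   climate: Sequence[str] = ("SR", "Tsm", "Twt")) -> pd.DataFrame:
    """Table-2-style model-averaged estimates for the standard term list."""
    terms = list(climate) + [sh_term, f"{sh_term}^2"] \
        + [f"{sh_term}*{c}" for c in climate]
    rows = []
    for term in terms:
        # design column name on the cub class
        col = f"phi_cub:{term.replace('*', ':')}"
        try:
            avg = _mmi.model_average(mset, col)
        except ValueError:
            continue
        lo_n, hi_n = avg.ci95("natural")
        lo_z, hi_z = avg.ci95("zero")
        rows.append((term, avg.beta_natural, lo_n, hi_n,
                     avg.beta_zero, lo_z, hi_z, avg.relative_importance))
    return pd.DataFrame(rows, columns=[
        "term", "beta_natural", "nat_ci_lo", "nat_ci_hi",
        "beta_zero", "zero_ci_lo", "zero_ci_hi", "relative_importance"])


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def run_hfc_analysis(genotype_table: "_gt.GenotypeTable",
                     pedigree: "_ped.Pedigree",
                     data: "_cjs.CaptureData",
                     config: RunConfig | None = None,
                     coccidia: pd.DataFrame | None = None,
                     slh_roles: Sequence[str] = ("SH_Ind",),
                     climate: Sequence[str] = ("SR", "Tsm", "Twt")) -> dict:
    """Run the full pipeline; returns a dict of result tables and writes
    CSVs plus a manifest under ``config.out_dir``."""
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # id consistency
    cap_ids = set(data.ids)
    gt_ids = set(genotype_table.individuals)
    orphans = sorted(cap_ids - set(pedigree.records) | (cap_ids - gt_ids))
    if orphans:
        raise ValueError(f"capture ids missing from pedigree/genotypes: "
                         f"{orphans[:10]}{'...' if len(orphans) > 10 else ''}")

    # (a) heterozygosity profiles
    profiles = _gt.het_profiles(genotype_table)
    profiles.to_csv(out / "het_profiles.csv")
    results["profiles"] = profiles
    marker_tab, marker_means = _gt.marker_summary(genotype_table)
    marker_tab.to_csv(out / "marker_summary.csv", index=False)
    results["marker_summary"] = marker_tab

    # (b) inbreeding at the three restriction levels
    inb = {}
    summary_rows = []
    for level in config.restriction_levels:
        tab = _ped.inbreeding_table(pedigree, level=level)
        tab.to_csv(out / f"inbreeding_{level}.csv")
        inb[level] = tab
        joined = tab.join(profiles["sh"], how="inner")
        for flag, name in ((1, "inbred"), (0, "outbred")):
            sub = joined[joined["inbred"] == flag]
            summary_rows.append((level, name, len(sub),
                                 sub["f"].mean(), sub["sh"].mean()))
    results["inbreeding"] = inb
    pd.DataFrame(summary_rows, columns=["level", "class", "n", "mean_f",
                                        "mean_sh"]).to_csv(
        out / "inbreeding_summary.csv", index=False)

    # (c) identity disequilibrium block
    g2res = _id.g2(genotype_table, n_iter=config.n_boot * 10, seed=config.seed)
    hhcres = _id.hhc(genotype_table, seed=config.seed + 1)
    id_block = {
        "g2": g2res.g2, "g2_se": g2res.se, "g2_p": g2res.p_value,
        "g2_p_bootstrap": g2res.p_value_bootstrap, "g2_seed": g2res.seed,
        "hhc_mean": hhcres.mean, "hhc_sd": hhcres.sd,
        "hhc_min": hhcres.min, "hhc_max": hhcres.max,
    }
    rows = []
    for level in config.restriction_levels:
        tab = inb[level].join(profiles["sh"], how="inner")
        if len(tab) < 3 or tab["f"].std() == 0:
            continue
        e_f, sd_f = tab["f"].mean(), tab["f"].std(ddof=1)
        sd_h = tab["sh"].std(ddof=1)
        exp = _id.expected_r_sh_f(e_f, sd_f, sd_h)
        obs_r, obs_p = _id.observed_r_sh_f(tab["sh"].to_numpy(),
                                           tab["f"].to_numpy())
        rows.append((level, len(tab), e_f, sd_f, exp.r_expected, obs_r, obs_p))
    r_table = pd.DataFrame(rows, columns=["level", "n", "e_f", "sd_f",
                                          "r_expected", "r_observed", "p"])
    r_table.to_csv(out / "expected_vs_observed_r.csv", index=False)
    (out / "identity_disequilibrium.json").write_text(json.dumps(id_block,
                                                                 indent=1))
    results["identity"] = id_block
    results["r_table"] = r_table

    # c-hat for the covariate sets
    if config.c_hat is not None:
        c_hat = config.c_hat
    else:
        base = _cjs.fit_cjs(data, "Phi(a2-./sex) p(.)", seed=config.seed,
                            n_starts=config.n_starts, compute_se=False)
        c_hat = _cjs.bootstrap_chat(data, base, n_boot=config.n_boot,
                                    seed=config.seed).for_qaicc
    results["c_hat"] = c_hat

    # (d)-(e) covariate model sets and averaging per SH role
    results["model_sets"] = {}
    results["averaged"] = {}
    for role in ("SH_Ind", "SH_Mat", "SH_Pat"):
        if role not in data.covariates.columns \
                or data.covariates[role].isna().all():
            continue
        sub = _subset_complete(data, [role] + list(climate))
        extra = ("rare_allele_score",) if role == "SH_Pat" and \
            "rare_allele_score" in data.covariates.columns else ()
        cands = candidate_models(role, climate=climate,
                                 max_interactions=config.max_interactions,
                                 extra_terms=extra)
        mset = fit_model_set(sub, cands, c_hat=c_hat, seed=config.seed,
                             n_starts=1, plausible_delta=config.plausible_delta)
        mset.table.to_csv(out / f"model_set_{role}.csv", index=False)
        avg = averaged_table(mset, role, climate=climate)
        avg.to_csv(out / f"averaged_{role}.csv", index=False)
        results["model_sets"][role] = mset
        results["averaged"][role] = avg

    # coccidia-controlled subset
    if coccidia is not None:
        load = _cjs.transform_coccidia(coccidia["count"].to_numpy(),
                                       coccidia["month"].to_numpy())
        cocc = pd.Series(load, index=coccidia["id"]).groupby(level=0).mean()
        keep = [i for i, ind in enumerate(data.ids) if ind in cocc.index]
        if keep:
            subcov = data.covariates.iloc[keep].copy()
            subcov["coccidia"] = cocc.reindex(
                [data.ids[i] for i in keep]).to_numpy()
            subdata = _cjs.CaptureData(
                data.histories[keep], data.age_at_first[keep],
                sex=data.sex[keep], ids=[data.ids[i] for i in keep],
                covariates=subcov, year_covariates=data.year_covariates)
            results["coccidia_subset_n"] = subdata.n_individuals

    # (f) local vs general comparison
    slh_df = pd.DataFrame(
        {f"SLH_{loc}": genotype_table.het[:, j]
         for j, loc in enumerate(genotype_table.loci)},
        index=pd.Index(genotype_table.individuals))
    common = [i for i in data.ids if i in slh_df.index]
    if len(common) == len(data.ids):
        try:
            tab6, screen = _mmi.compare_local_general(
                data, slh_df.loc[data.ids], "SH_Ind",
                climate_terms=("SR", "Twt"), c_hat=c_hat, seed=config.seed)
            tab6.to_csv(out / "local_vs_general.csv", index=False)
            results["local_vs_general"] = tab6
            results["slh_screen"] = screen
        except (ValueError, RuntimeError) as exc:
            results["local_vs_general_error"] = str(exc)

    # manifest
    cfg_json = json.dumps({k: str(v) for k, v in vars(config).items()},
                          sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "c_hat": c_hat,
        "config": vars(config) | {"restriction_levels":
                                  list(config.restriction_levels)},
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_individuals": data.n_individuals,
        "n_occasions": data.n_occasions,
        "note": "candidate model lists are combinatorial approximations",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    results["manifest"] = manifest
    return results


def _subset_complete(data: "_cjs.CaptureData", cols: Sequence[str]
                     ) -> "_cjs.CaptureData":
    """Restrict to individuals with complete covariates in ``cols``
    (individual-level ones only)."""
    icols = [c for c in cols if c in data.covariates.columns]
    ok = ~data.covariates[icols].isna().any(axis=1).to_numpy()
    if ok.all():
        return data
    return _cjs.CaptureData(data.histories[ok], data.age_at_first[ok],
                            sex=data.sex[ok],
                            ids=[i for i, k in zip(data.ids, ok) if k],
                            covariates=data.covariates.loc[ok],
                            year_covariates=data.year_covariates)
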