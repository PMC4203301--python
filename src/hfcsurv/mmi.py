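"""Multimodel inference: QAICc ranking, Akaike weights, evidence ratios,
model averaging (zero and natural methods), relative importance, VIF
collinearity screening, and the single-locus vs multilocus comparison.

Weights are computed over the full considered set
(``w = exp(-delta/2) / sum``); a model is *plausible* when its QAICc sits
within ``plausible_delta`` (default 7) of the best model.  Averaging is
restricted to the plausible set with weights renormalized within it, which
makes the identity ``beta_zero = beta_natural * relative_importance``
exact (relative importance there being the renormalized summed weight of
models containing the term).  Unconditional standard errors follow the
weighted-average form  ``se = sum_i w_i sqrt(var_i + (b_i - bbar)^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cjs as _cjs

__all__ = ["ModelSet", "AveragedEstimate", "rank_models", "evidence_ratio",
           "model_average", "relative_importance", "vif_screen",
           "compare_local_general"]

PLAUSIBLE_DELTA = 7.0


@dataclass(frozen=True)
class AveragedEstimate:
    term: str
    beta_natural: float
    se_natural: float
    beta_zero: float
    se_zero: float
    relative_importance: float

    def ci95(self, method: str = "natural") -> tuple[float, float]:
        b, s = ((self.beta_natural, self.se_natural) if method == "natural"
                else (self.beta_zero, self.se_zero))
        return (b - 1.96 * s, b + 1.96 * s)


class ModelSet:
    """A ranked collection of models with Delta, weights and plausibility.

    ``table`` has columns model, k, deviance, qaicc, delta, weight,
    plausible, sorted by delta then name.  ``fits`` (optional) maps model
    name -> FittedModel for averaging.
    """

    def __init__(self, table: pd.DataFrame,
                 fits: Mapping[str, "_cjs.FittedModel"] | None = None,
                 plausible_delta: float = PLAUSIBLE_DELTA):
        self.table = table
        self.fits = dict(fits) if fits else {}
        self.plausible_delta = plausible_delta

    @property
    def weights(self) -> pd.Series:
        return self.table.set_index("model")["weight"]

    @property
    def deltas(self) -> pd.Series:
        return self.table.set_index("model")["delta"]

    @property
    def plausible_models(self) -> list[str]:
        return self.table.loc[self.table["plausible"], "model"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_models(qaicc: Mapping[str, float],
                k: Mapping[str, float] | None = None,
                deviance: Mapping[str, float] | None = None,
                fits: Mapping[str, "_cjs.FittedModel"] | None = None,
                plausible_delta: float = PLAUSIBLE_DELTA) -> ModelSet:
    """Rank models by QAICc (or directly by printed Delta values, which are
    QAICc up to a shared constant)."""
    names = list(qaicc)
    vals = np.array([qaicc[m] for m in names], dtype=float)
    if np.isnan(vals).any():
        bad = [m for m, v in zip(names, vals) if np.isnan(v)]
        raise ValueError(f"NaN QAICc for model(s): {bad}")
    delta = vals - vals.min()
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    df = pd.DataFrame({
        "model": names,
        "k": [np.nan if k is None else k.get(m, np.nan) for m in names],
        "deviance": [np.nan if deviance is None else deviance.get(m, np.nan)
                     for m in names],
        "qaicc": vals,
        "delta": delta,
        "weight": w,
        "plausible": delta < plausible_delta,
    }).sort_values(["delta", "model"], kind="stable").reset_index(drop=True)
    return ModelSet(df, fits=fits, plausible_delta=plausible_delta)


def evidence_ratio(mset: ModelSet, a: str, b: str) -> float:
    """w_a / w_b, computed as exp(0.5 (delta_b - delta_a)) for stability."""
    d = mset.deltas
    for m in (a, b):
        if m not in d.index:
            raise KeyError(f"model {m!r} not in set")
    return float(np.exp(0.5 * (d[b] - d[a])))


def _term_estimates(mset: ModelSet, term: str) -> pd.DataFrame:
    """Per-plausible-model (estimate, se, present) rows for ``term``."""
    rows = []
    for m in mset.plausible_models:
        fit = mset.fits.get(m)
        if fit is None:
            raise ValueError(f"no fitted model stored for {m!r}")
        present = term in fit.beta.index
        b = float(fit.beta[term]) if present else 0.0
        s = float(fit.se[term]) if present else 0.0
        rows.append((m, present, b, s))
    return pd.DataFrame(rows, columns=["model", "present", "beta", "se"])


def model_average(mset: ModelSet, term: str, method: str = "natural"
                  ) -> AveragedEstimate:
    """Model-averaged estimate of ``term`` over the plausible set.

    natural: average over plausible models containing the term, weighted by
    their renormalized weights.  zero: substitute estimate and SE of 0 in
    plausible models lacking the term.  Both are reported in the returned
    record; ``method`` only selects which is primary for callers using
    ``ci95``.
    """
    if method not in ("natural", "zero"):
        raise ValueError(f"unknown averaging method {method!r}")
    est = _term_estimates(mset, term)
    w_full = mset.weights
    w = np.array([w_full[m] for m in est["model"]])
    w = w / w.sum()  # renormalize within the plausible set
    present = est["present"].to_numpy()
    if not present.any():
        raise ValueError(f"term {term!r} absent from every plausible model")
    b = est["beta"].to_numpy()
    s = est["se"].to_numpy()

    importance = float(w[present].sum())

    wn = w[present] / w[present].sum()
    beta_nat = float(np.sum(wn * b[present]))
    se_nat = float(np.sum(wn * np.sqrt(s[present] ** 2
                                       + (b[present] - beta_nat) ** 2)))

    beta_zero = float(np.sum(w * b))
    se_zero = float(np.sum(w * np.sqrt(s ** 2 + (b - beta_zero) ** 2)))

    return AveragedEstimate(term=term, beta_natural=beta_nat, se_natural=se_nat,
                            beta_zero=beta_zero, se_zero=se_zero,
                            relative_importance=importance)


def relative_importance(mset: ModelSet, term: str,
                        renormalize: bool = False) -> float:
    """Summed Akaike weight of plausible models containing ``term``.

    By default weights are those over the full considered set; with
    ``renormalize`` they are renormalized within the plausible set (the
    convention used internally by :func:`model_average`).
    """
    w_full = mset.weights
    total = 0.0
    plaus_sum = 0.0
    for m in mset.plausible_models:
        fit = mset.fits.get(m)
        if fit is None:
            raise ValueError(f"no fitted model stored for {m!r}")
        plaus_sum += w_full[m]
        if term in fit.beta.index:
            total += w_full[m]
    return float(total / plaus_sum) if renormalize else float(total)


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def vif_screen(X: pd.DataFrame | np.ndarray, threshold: float = 5.0
               ) -> tuple[list, pd.Series]:
    """Iterative variance-inflation-factor screen.

    VIF_j = 1/(1 - R^2_j) from regressing column j (with intercept) on the
    remaining columns; the highest-VIF column above ``threshold`` is dropped
    and VIFs recomputed, until all retained VIFs are below it.  Returns
    (retained column labels, final VIF per retained column).  A perfectly
    collinear column has infinite VIF and is dropped first.
    """
    df = pd.DataFrame(X).copy()
    if df.shape[1] < 2:
        raise ValueError("vif_screen needs at least 2 columns")

    def vifs(d: pd.DataFrame) -> pd.Series:
        out = {}
        M = d.to_numpy(dtype=float)
        n = M.shape[0]
        ones = np.ones((n, 1))
        for j, col in enumerate(d.columns):
            yj = M[:, j]
            Z = np.hstack([ones, np.delete(M, j, axis=1)])
            coef, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
            resid = yj - Z @ coef
            ss_tot = np.sum((yj - yj.mean()) ** 2)
            if ss_tot == 0:
                out[col] = 1.0
                continue
            r2 = 1.0 - np.sum(resid ** 2) / ss_tot
            out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    while df.shape[1] >= 2:
        v = vifs(df)
        worst = v.idxmax()
        if v[worst] > threshold:
            df = df.drop(columns=[worst])
        else:
            break
    final = vifs(df) if df.shape[1] >= 2 else pd.Series({df.columns[0]: 1.0})
    return list(df.columns), final


# ---------------------------------------------------------------------------
# Local vs general effect comparison
# ---------------------------------------------------------------------------

def screen_slh(slh: pd.DataFrame, min_heterozygotes: int = 7,
               vif_threshold: float = 5.0) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion screens to a single-locus heterozygosity matrix:
    drop loci with fewer than ``min_heterozygotes`` heterozygous individuals,
    mean-impute remaining missingness, then VIF-screen.  Returns the screened
    (imputed) matrix and a report of what was dropped."""
    het_counts = (slh == 1).sum()
    few = het_counts[het_counts < min_heterozygotes].index.tolist()
    kept = slh.drop(columns=few)
    if kept.shape[1] < 2:
        raise ValueError("fewer than 2 loci survive the heterozygote screen")
    imputed, _ = _cjs.impute_missing(kept)
    retained, vif = vif_screen(imputed, threshold=vif_threshold)
    dropped_vif = [c for c in kept.columns if c not in retained]
    return imputed[retained], {"dropped_few_hets": few,
                               "dropped_vif": dropped_vif,
                               "vif": vif.to_dict()}


def compare_local_general(data: "_cjs.CaptureData", slh: pd.DataFrame,
                          sh_term: str, climate_terms: Sequence[str] = ("SR", "Twt"),
                          rain_term: str = "SR", c_hat: float = 1.0,
                          min_heterozygotes: int = 7, vif_threshold: float = 5.0,
                          seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Fit the all-single-locus model against the multilocus model.

    The single-locus model puts every screened locus's 0/1 heterozygosity
    (and its interaction with ``rain_term``) on cub survival; the multilocus
    model uses ``sh_term`` (and its interaction) instead.  Both include the
    climate main effects.  Returns a Table-6-style model table and the
    screening report.
    """
    screened, report = screen_slh(slh, min_heterozygotes, vif_threshold)
    data_sl = _cjs.CaptureData(
        data.histories, data.age_at_first, sex=data.sex, ids=data.ids,
        covariates=pd.concat([data.covariates,
                              screened.set_axis(data.covariates.index)], axis=1),
        year_covariates=data.year_covariates)

    climate = " + ".join(climate_terms)
    sl_terms = " + ".join([f"{c} + {c}*{rain_term}" for c in screened.columns])
    notation_sl = f"Phi(a2-{climate} + {sl_terms}/.) p(.)"
    notation_ml = f"Phi(a2-{climate} + {sh_term} + {sh_term}*{rain_term}/.) p(.)"

    fits = {
        "single_locus": _cjs.fit_cjs(data_sl, notation_sl, seed=seed,
                                     compute_se=False),
        "multilocus": _cjs.fit_cjs(data_sl, notation_ml, seed=seed,
                                   compute_se=False),
    }
    q = {m: _cjs.qaicc(f, c_hat=c_hat) for m, f in fits.items()}
    mset = rank_models(q, k={m: f.k for m, f in fits.items()},
                       deviance={m: f.deviance for m, f in fits.items()},
                       fits=fits)
    tab = mset.table.copy()
    tab["minus2lnL"] = tab["deviance"]
    return tab[["model", "minus2lnL", "k", "qaicc", "delta", "weight"]], report
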