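"""Cormack-Jolly-Seber survival/recapture models.

Model structures are written in MARK-style notation, e.g.
``"Phi(a2-t/sex) p(t)"``: the ``a2-`` prefix splits apparent survival into
two age classes, with the pre-slash terms applying to the cub (first-year)
interval and the post-slash terms to adult intervals; ``t`` is a year
factor, ``.`` intercept-only, ``*`` expands to main effects plus
interaction, and any other token names a covariate column (individual- or
year-level).  Recapture probability ``p`` has no age split and may be
fixed at supplied values.

The likelihood conditions on first release: each individual contributes
the probability of its detection pattern after first capture, with the
usual unobserved-fate tail

    chi_t = (1 - phi_t) + phi_t (1 - p_{t+1}) chi_{t+1},  chi_T = 1.

Conventions (documented contracts):

* deviance = -2 log L (saturated-model term taken as zero);
* effective sample size = number of release events, i.e. total detections
  at occasions 1..T-1 (animals caught at the final occasion are not
  released into a modelled interval);
* parameter count k = number of design columns, minus one when recapture
  and the age class active at the final interval are both fully
  time-dependent (the terminal phi*p product is then confounded), minus
  any coefficient pinned at +/-15 on the logit scale (boundary,
  non-estimable);
* QAICc = deviance/c-hat + 2k + 2k(k+1)/(n_eff - k - 1), with c-hat
  truncated below at 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = ["CaptureData", "ModelSpec", "FittedModel", "CHat", "parse_model",
           "standardize", "transform_coccidia", "impute_missing", "fit_cjs",
           "bootstrap_chat", "qaicc", "read_inp", "write_inp",
           "simulate_histories", "n_releases"]

BOUNDARY_LOGIT = 15.0


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

class CaptureData:
    """Capture histories over T occasions plus covariates.

    Parameters
    ----------
    histories : (n, T) 0/1 detection matrix.
    age_at_first : (n,) 0 = first caught as cub, 1 = as adult.
    sex : (n,) 0 = female, 1 = male (coded -0.5/+0.5 in designs).
    covariates : individual-level covariates, indexed like ``ids``.
    year_covariates : per-interval covariates indexed 0..T-2 (a year-level
        covariate attaches to the survival interval starting that year).
    """

    def __init__(self, histories: np.ndarray, age_at_first: np.ndarray,
                 sex: np.ndarray | None = None,
                 ids: Sequence[str] | None = None,
                 covariates: pd.DataFrame | None = None,
                 year_covariates: pd.DataFrame | None = None,
                 groups: np.ndarray | None = None):
        self.histories = np.asarray(histories, dtype=np.int8)
        n, T = self.histories.shape
        if T < 2:
            raise ValueError("need at least two occasions")
        if not self.histories.any(axis=1).all():
            raise ValueError("every individual needs at least one detection")
        self.first = self.histories.argmax(axis=1)
        # last detection occasion
        rev = self.histories[:, ::-1].argmax(axis=1)
        self.last = T - 1 - rev
        self.age_at_first = np.asarray(age_at_first, dtype=np.int8)
        self.sex = (np.zeros(n, dtype=np.int8) if sex is None
                    else np.asarray(sex, dtype=np.int8))
        self.ids = list(ids) if ids is not None else [f"i{k}" for k in range(n)]
        self.covariates = (covariates if covariates is not None
                           else pd.DataFrame(index=pd.Index(self.ids)))
        self.year_covariates = (year_covariates if year_covariates is not None
                                else pd.DataFrame(index=pd.RangeIndex(T - 1)))
        self.groups = groups

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    def cub_interval_mask(self) -> np.ndarray:
        """(n, T-1) True where the cell is a cub (first-year) survival
        interval: the first interval of an individual first caught as a cub."""
        n, T = self.histories.shape
        mask = np.zeros((n, T - 1), dtype=bool)
        cubs = self.age_at_first == 0
        firsts = self.first[cubs]
        ok = firsts < T - 1
        mask[np.nonzero(cubs)[0][ok], firsts[ok]] = True
        return mask


@dataclass(frozen=True)
class ModelSpec:
    """Parsed survival/recapture structure."""

    notation: str
    a2: bool
    phi_cub_terms: tuple[str, ...]    # == phi_terms when not a2
    phi_adult_terms: tuple[str, ...]
    p_terms: tuple[str, ...]
    fixed_p: Optional[tuple[float, ...]] = None

    def with_fixed_p(self, values) -> "ModelSpec":
        vals = tuple(np.atleast_1d(np.asarray(values, dtype=float)).tolist())
        return ModelSpec(self.notation + " [p fixed]", self.a2,
                         self.phi_cub_terms, self.phi_adult_terms,
                         self.p_terms, fixed_p=vals)


@dataclass
class FittedModel:
    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    cov: np.ndarray
    loglik: float
    deviance: float
    k: int
    n_eff: int
    converged: bool
    boundary: np.ndarray
    qaicc: float = np.nan

    def ci95(self) -> pd.DataFrame:
        lo = self.beta - 1.96 * self.se
        hi = self.beta + 1.96 * self.se
        return pd.DataFrame({"beta": self.beta, "se": self.se,
                             "ci_lo": lo, "ci_hi": hi})


@dataclass(frozen=True)
class CHat:
    c_hat: float                  # raw observed/mean-bootstrap ratio
    n_boot: int
    bootstrap_deviances: np.ndarray
    n_failed: int
    seed: int

    @property
    def for_qaicc(self) -> float:
        """c-hat truncated below at 1 for QAICc use."""
        return max(1.0, self.c_hat)


# ---------------------------------------------------------------------------
# Notation parser
# ---------------------------------------------------------------------------

_MODEL_RE = re.compile(
    r"^\s*Phi\s*\(\s*(?P<phi>[^()]*)\s*\)\s*p\s*\(\s*(?P<p>[^()]*)\s*\)\s*$",
    re.IGNORECASE)


def _split_terms(text: str, offset: int) -> list[str]:
    terms = []
    for chunk in text.split("+"):
        token = chunk.strip()
        if not token:
            raise ValueError(f"empty term at position {offset} in model notation")
        terms.append(re.sub(r"\s+", "_", token))
    return terms


def _validate_terms(terms: list[str], notation: str) -> tuple[str, ...]:
    out = []
    for term in terms:
        if term == ".":
            continue  # intercept-only marker adds nothing
        for atom in term.split("*"):
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*(\^2)?|t", atom):
                pos = notation.find(atom.replace("_", " ")) \
                    if atom.replace("_", " ") in notation else notation.find(atom)
                raise ValueError(
                    f"unknown token {atom!r} at position {pos} in {notation!r}")
        out.append(term)
    return tuple(out)


def parse_model(notation: str) -> ModelSpec:
    """Parse MARK-style notation like ``"Phi(a2-t/sex) p(t)"``.

    Raises ``ValueError`` naming the offending token and its position for
    malformed input.
    """
    m = _MODEL_RE.match(notation)
    if m is None:
        raise ValueError(f"cannot parse model notation {notation!r} "
                         "(expected 'Phi(...) p(...)')")
    phi_text = m.group("phi").strip()
    p_text = m.group("p").strip()
    a2 = False
    if phi_text.lower().startswith("a2-"):
        a2 = True
        body = phi_text[3:]
        if "/" not in body:
            raise ValueError(f"a2 split needs '/' in {notation!r}")
        cub_text, adult_text = body.split("/", 1)
        cub = _validate_terms(_split_terms(cub_text, notation.find(cub_text)),
                              notation)
        adult = _validate_terms(_split_terms(adult_text,
                                             notation.find(adult_text)), notation)
    else:
        cub = adult = _validate_terms(
            _split_terms(phi_text, notation.find(phi_text)), notation)
    p_terms = _validate_terms(_split_terms(p_text, notation.find(p_text)),
                              notation)
    return ModelSpec(notation=notation, a2=a2, phi_cub_terms=cub,
                     phi_adult_terms=adult, p_terms=p_terms)


# ---------------------------------------------------------------------------
# Covariate preparation
# ---------------------------------------------------------------------------

def standardize(x: np.ndarray) -> np.ndarray:
    """(x - mean)/(2 SD): mean 0, SD 0.5 (two-SD convention for comparability
    of main effects with binary inputs).  SD uses ddof=1."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - np.nanmean(x)) / (2.0 * sd)


def transform_coccidia(counts: np.ndarray, months: np.ndarray) -> np.ndarray:
    """log(x+1)-transform oocyst counts then standardize within month.

    Months with a single value or zero variance contribute zeros.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("coccidial counts must be nonnegative")
    months = np.asarray(months)
    logged = np.log(counts + 1.0)
    out = np.empty_like(logged)
    for m in np.unique(months):
        sel = months == m
        sd = logged[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        if sd == 0:
            out[sel] = 0.0
        else:
            out[sel] = (logged[sel] - logged[sel].mean()) / (2.0 * sd)
    return out


def impute_missing(x: pd.DataFrame | np.ndarray
                   ) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Column-mean imputation.  Returns (completed, mask) where mask flags
    imputed cells.  A fully missing column is an error."""
    df = pd.DataFrame(x).copy()
    mask = df.isna().to_numpy()
    fully = [c for c in df.columns if df[c].isna().all()]
    if fully:
        raise ValueError(f"cannot impute fully missing column(s): {fully}")
    completed = df.fillna(df.mean())
    if isinstance(x, np.ndarray):
        return completed.to_numpy(), mask
    return completed, mask


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _expand_terms(terms: Sequence[str]) -> list[str]:
    """Expand '*' into mains + interaction, dedupe preserving order."""
    out: list[str] = []

    def push(t):
        if t not in out:
            out.append(t)

    for term in terms:
        if "*" in term:
            a, b = term.split("*", 1)
            push(a)
            push(b)
            push(f"{a}*{b}")
        else:
            push(term)
    return out


def _atom_columns(atom: str, data: CaptureData, class_mask: np.ndarray,
                  prefix: str) -> tuple[list[str], list[np.ndarray]]:
    """Cell-level (n, T-1) value arrays for one atomic term."""
    n, T = data.histories.shape
    nI = T - 1
    if atom == "t":
        # year dummies over the intervals this class actually occupies;
        # earliest occupied interval is the reference level
        occupied = sorted(set(np.nonzero(class_mask.any(axis=0))[0].tolist()))
        names, cols = [], []
        for t in occupied[1:]:
            z = np.zeros((n, nI))
            z[:, t] = 1.0
            names.append(f"{prefix}t{t}")
            cols.append(z)
        return names, cols
    if atom == "sex":
        col = np.repeat((data.sex - 0.5).astype(float)[:, None], nI, axis=1)
        return [f"{prefix}sex"], [col]
    sq = atom.endswith("^2")
    name = atom[:-2] if sq else atom
    if name in data.covariates.columns:
        v = data.covariates[name].to_numpy(dtype=float)
        col = np.repeat(v[:, None], nI, axis=1)
    elif name in data.year_covariates.columns:
        v = data.year_covariates[name].to_numpy(dtype=float)
        col = np.repeat(v[None, :nI], n, axis=0)
    else:
        raise ValueError(f"covariate {name!r} not found in individual or "
                         "year covariates")
    if np.isnan(col[class_mask]).any():
        raise ValueError(f"covariate {name!r} has missing values in active "
                         "cells; impute first")
    if sq:
        col = col ** 2
    return [f"{prefix}{atom}"], [col]


def _class_design(terms: Sequence[str], data: CaptureData,
                  class_mask: np.ndarray, prefix: str
                  ) -> tuple[list[str], np.ndarray]:
    n, T = data.histories.shape
    names = [f"{prefix}int"]
    cols = [np.ones((n, T - 1))]
    for term in _expand_terms(terms):
        atoms = term.split("*")
        sub_names: list[str] = [""]
        sub_cols: list[np.ndarray] = [np.ones((n, T - 1))]
        for atom in atoms:
            a_names, a_cols = _atom_columns(atom, data, class_mask, "")
            new_names, new_cols = [], []
            for sn, sc in zip(sub_names, sub_cols):
                for an, ac in zip(a_names, a_cols):
                    new_names.append(f"{sn}:{an}" if sn else an)
                    new_cols.append(sc * ac)
            sub_names, sub_cols = new_names, new_cols
        for sn, sc in zip(sub_names, sub_cols):
            names.append(f"{prefix}{sn}")
            cols.append(sc)
    X = np.stack(cols, axis=-1)  # (n, T-1, P)
    X = X * class_mask[:, :, None]
    return names, X


def build_design(data: CaptureData, spec: ModelSpec
                 ) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
    """Stacked phi design (n, T-1, P_phi) over age classes and the p design."""
    n, T = data.histories.shape
    active = _active_cells(data)
    cub_mask = data.cub_interval_mask() & active
    adult_mask = active & ~cub_mask
    if spec.a2:
        cn, cX = _class_design(spec.phi_cub_terms, data, cub_mask, "phi_cub:")
        an, aX = _class_design(spec.phi_adult_terms, data, adult_mask,
                               "phi_adult:")
        phi_names = cn + an
        Xphi = np.concatenate([cX, aX], axis=-1)
    else:
        phi_names, Xphi = _class_design(spec.phi_cub_terms, data, active, "phi:")
    if spec.fixed_p is not None:
        p_names: list[str] = []
        Xp = np.zeros((n, T - 1, 0))
    else:
        p_names, Xp = _class_design(spec.p_terms, data, active, "p:")
    return phi_names, Xphi, p_names, Xp


def _active_cells(data: CaptureData) -> np.ndarray:
    n, T = data.histories.shape
    t_idx = np.arange(T - 1)[None, :]
    return t_idx >= data.first[:, None]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class _CJSLikelihood:
    def __init__(self, data: CaptureData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.phi_names, self.Xphi, self.p_names, self.Xp = build_design(data, spec)
        n, T = data.histories.shape
        self.n, self.T = n, T
        t_idx = np.arange(T - 1)[None, :]
        self.obs_mask = ((t_idx >= data.first[:, None])
                         & (t_idx < data.last[:, None]))  # intervals before last
        self.active = _active_cells(data)
        self.y_next = data.histories[:, 1:].astype(float)
        if spec.fixed_p is not None:
            fp = np.asarray(spec.fixed_p, dtype=float)
            if fp.size == 1:
                fp = np.full(T - 1, fp.item())
            if fp.size != T - 1:
                raise ValueError("fixed_p must be scalar or length T-1")
            self.fixed_p = np.clip(fp, 1e-12, 1 - 1e-12)
        else:
            self.fixed_p = None
        self.n_phi = self.Xphi.shape[-1]
        self.n_par = self.n_phi + self.Xp.shape[-1]

    def probs(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bphi = beta[:self.n_phi]
        phi = expit(np.einsum("ntp,p->nt", self.Xphi, bphi))
        if self.fixed_p is not None:
            p = np.broadcast_to(self.fixed_p, phi.shape)
        else:
            p = expit(np.einsum("ntp,p->nt", self.Xp, beta[self.n_phi:]))
        eps = 1e-12
        return np.clip(phi, eps, 1 - eps), np.clip(p, eps, 1 - eps)

    def loglik(self, beta: np.ndarray) -> float:
        phi, p = self.probs(beta)
        n, T = self.n, self.T
        # chi[:, t] = P(never seen after occasion t | alive at t)
        chi = np.ones((n, T))
        for t in range(T - 2, -1, -1):
            chi[:, t] = (1 - phi[:, t]) + phi[:, t] * (1 - p[:, t]) * chi[:, t + 1]
        obs = self.obs_mask * (np.log(phi)
                               + self.y_next * np.log(p)
                               + (1 - self.y_next) * np.log(1 - p))
        ll = obs.sum() + np.log(chi[np.arange(n), self.data.last]).sum()
        return float(ll)

    def __call__(self, beta: np.ndarray) -> float:
        return -self.loglik(beta)

    def negloglik_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        """Value and analytic gradient of the negative log-likelihood.

        The chi-tail derivative uses prefix products of
        ``A_t = phi_t (1 - p_t)``:  d chi_l / d theta_t factors through
        ``prod_{s=l}^{t-1} A_s``.
        """
        phi, p = self.probs(beta)
        n, T = self.n, self.T
        nI = T - 1
        chi = np.ones((n, T))
        A = phi * (1 - p)
        for t in range(nI - 1, -1, -1):
            chi[:, t] = (1 - phi[:, t]) + A[:, t] * chi[:, t + 1]
        last = self.data.last
        obs = self.obs_mask
        y = self.y_next
        ll = (obs * (np.log(phi) + y * np.log(p)
                     + (1 - y) * np.log(1 - p))).sum() \
            + np.log(chi[np.arange(n), last]).sum()

        # dll/d eta_phi and d eta_p per cell
        d_phi = obs * (1 - phi)
        d_p = obs * (y - p)
        # chi-tail region: t >= last (and t >= first implicitly)
        t_idx = np.arange(nI)[None, :]
        tail = t_idx >= last[:, None]
        logB = np.concatenate([np.zeros((n, 1)),
                               np.cumsum(np.log(A), axis=1)], axis=1)
        safe_last = np.minimum(last, nI)
        ratio = np.exp(logB[:, :nI] - logB[np.arange(n), safe_last][:, None])
        chi_l = chi[np.arange(n), last][:, None]
        chi_next = chi[:, 1:]
        d_phi = d_phi + tail * ratio * (-1 + (1 - p) * chi_next) \
            * phi * (1 - phi) / chi_l
        d_p = d_p + tail * ratio * (-phi * chi_next) * p * (1 - p) / chi_l

        g_phi = np.einsum("nt,ntp->p", d_phi, self.Xphi)
        if self.fixed_p is None:
            g_p = np.einsum("nt,ntp->p", d_p, self.Xp)
            grad = np.concatenate([g_phi, g_p])
        else:
            grad = g_phi
        return -ll, -grad


def _num_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / steps[i] ** 2
            else:
                f = (fun(x + ei + ej) - fun(x + ei - ej)
                     - fun(x - ei + ej) + fun(x - ei - ej))
                H[i, j] = H[j, i] = f / (4 * steps[i] * steps[j])
    return H


def n_releases(histories: np.ndarray) -> int:
    """Effective sample size: detections at occasions 1..T-1 (releases)."""
    return int(np.asarray(histories)[:, :-1].sum())


_STRUCTURAL_RE = re.compile(r"^(phi(_cub|_adult)?|p):(int|t\d+|sex)(:t\d+)?$")


def count_parameters(spec: ModelSpec, phi_names: Sequence[str],
                     p_names: Sequence[str], boundary: np.ndarray) -> int:
    names = list(phi_names) + list(p_names)
    k = len(names)
    # terminal phi*p confounding in fully time-dependent models
    last_class_terms = spec.phi_adult_terms if spec.a2 else spec.phi_cub_terms
    if spec.fixed_p is None and "t" in spec.p_terms and "t" in last_class_terms:
        k -= 1
    # structural parameters (intercepts and factor dummies) pinned at the
    # logit boundary are non-estimable and drop from k; covariate slopes at
    # the bound are flagged but still counted (they are fitted dof)
    for name, at_bound in zip(names, boundary):
        if at_bound and _STRUCTURAL_RE.match(name):
            k -= 1
    return k


def fit_cjs(data: CaptureData, spec: ModelSpec | str,
            fixed_p=None, n_starts: int = 5, seed: int = 0,
            compute_se: bool = True) -> FittedModel:
    """Maximize the CJS likelihood conditioned on first release.

    Quasi-Newton (L-BFGS-B) on the logit scale with ``n_starts`` multi-starts
    (the first from zero, the rest random from ``seed``); SEs from a
    numerically differentiated Hessian.  Non-convergence is flagged, not
    raised.
    """
    if isinstance(spec, str):
        spec = parse_model(spec)
    if fixed_p is not None:
        spec = spec.with_fixed_p(fixed_p)
    lik = _CJSLikelihood(data, spec)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        x0 = (np.zeros(lik.n_par) if s == 0
              else rng.normal(0.0, 1.0, size=lik.n_par))
        res = optimize.minimize(lik.negloglik_grad, x0, jac=True,
                                method="L-BFGS-B",
                                bounds=[(-BOUNDARY_LOGIT, BOUNDARY_LOGIT)]
                                       * lik.n_par,
                                options={"maxiter": 2000, "ftol": 1e-10,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    beta = np.clip(best.x, -BOUNDARY_LOGIT, BOUNDARY_LOGIT)
    boundary = np.abs(best.x) >= BOUNDARY_LOGIT
    names = lik.phi_names + lik.p_names
    cov = np.full((lik.n_par, lik.n_par), np.nan)
    se = np.full(lik.n_par, np.nan)
    if compute_se:
        try:
            H = _num_hessian(lik, best.x)
            cov = np.linalg.pinv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
        except Exception:
            pass
    ll = -best.fun
    dev = -2.0 * ll
    k = count_parameters(spec, lik.phi_names, lik.p_names, boundary)
    return FittedModel(spec=spec,
                       beta=pd.Series(beta, index=names),
                       se=pd.Series(se, index=names), cov=cov,
                       loglik=ll, deviance=dev, k=k,
                       n_eff=n_releases(data.histories),
                       converged=bool(best.success), boundary=boundary)


def qaicc(fit_or_dev, c_hat: float = 1.0, n_eff: int | None = None,
          k: int | None = None) -> float:
    """QAICc = deviance/c-hat + 2k + 2k(k+1)/(n_eff - k - 1).

    Accepts either a :class:`FittedModel` or a raw deviance (with ``k`` and
    ``n_eff`` supplied).  ``c_hat`` below 1 is truncated to 1.
    """
    if isinstance(fit_or_dev, FittedModel):
        dev = fit_or_dev.deviance
        k = fit_or_dev.k if k is None else k
        n_eff = fit_or_dev.n_eff if n_eff is None else n_eff
    else:
        dev = float(fit_or_dev)
        if k is None or n_eff is None:
            raise ValueError("k and n_eff required with a raw deviance")
    c = max(1.0, float(c_hat))
    if n_eff <= k + 1:
        raise ValueError(f"effective sample size {n_eff} <= k+1 = {k + 1}")
    return dev / c + 2 * k + 2 * k * (k + 1) / (n_eff - k - 1)


# ---------------------------------------------------------------------------
# Simulation from a (fitted) CJS process and bootstrap goodness of fit
# ---------------------------------------------------------------------------

def simulate_histories(first: np.ndarray, phi: np.ndarray, p: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Simulate (n, T) CJS detection histories.

    ``first`` gives each individual's (conditioned-on) first capture
    occasion; ``phi`` and ``p`` are (n, T-1) per-interval survival and
    per-following-occasion recapture probabilities.
    """
    n, nI = phi.shape
    T = nI + 1
    hist = np.zeros((n, T), dtype=np.int8)
    hist[np.arange(n), first] = 1
    alive = np.ones(n, dtype=bool)
    for t in range(nI):
        started = first <= t
        alive = alive & (~started | (rng.random(n) < phi[:, t]))
        det = started & alive & (rng.random(n) < p[:, t])
        hist[det, t + 1] = 1
    return hist


def saturated_loglik(data: CaptureData) -> float:
    """Log-likelihood of the saturated multinomial: individuals grouped into
    release cohorts (first occasion x age class, covariates ignored), with
    each distinct post-release detection pattern given its empirical
    probability.  Used as the reference for goodness-of-fit deviance."""
    from collections import Counter
    cohorts: dict[tuple, Counter] = {}
    for i in range(data.n_individuals):
        key = (int(data.first[i]), int(data.age_at_first[i]))
        patt = tuple(data.histories[i, data.first[i]:].tolist())
        cohorts.setdefault(key, Counter())[patt] += 1
    ll = 0.0
    for counts in cohorts.values():
        n_c = sum(counts.values())
        for m in counts.values():
            ll += m * np.log(m / n_c)
    return ll


def gof_deviance(data: CaptureData, fit: FittedModel) -> float:
    """-2 (logL_fit - logL_saturated); the deviance actually used for the
    bootstrap variance-inflation ratio."""
    return -2.0 * (fit.loglik - saturated_loglik(data))


def bootstrap_chat(data: CaptureData, fit: FittedModel, n_boot: int = 100,
                   seed: int = 0, n_starts: int = 1) -> CHat:
    """Bootstrap variance-inflation factor.

    Simulates ``n_boot`` datasets from the fitted survival/recapture
    probabilities (same release structure and covariates), refits the same
    model, and divides the observed goodness-of-fit deviance (relative to
    the saturated cohort multinomial, :func:`gof_deviance`) by the mean
    bootstrap value.  Refit failures are excluded (more than 20% is an
    error).
    """
    if not fit.converged:
        raise ValueError("bootstrap_chat requires a converged fit")
    lik = _CJSLikelihood(data, fit.spec)
    phi, p = lik.probs(fit.beta.to_numpy())
    rng = np.random.default_rng(seed)
    obs_dev = gof_deviance(data, fit)
    devs = []
    n_failed = 0
    for b in range(n_boot):
        hist = simulate_histories(data.first, phi, p, rng)
        sim = CaptureData(hist, data.age_at_first, sex=data.sex, ids=data.ids,
                          covariates=data.covariates,
                          year_covariates=data.year_covariates)
        try:
            refit = fit_cjs(sim, fit.spec, n_starts=n_starts,
                            seed=int(rng.integers(2 ** 31)), compute_se=False)
            if not refit.converged or not np.isfinite(refit.deviance):
                raise RuntimeError("refit failed")
            devs.append(gof_deviance(sim, refit))
        except Exception:
            n_failed += 1
    if n_failed > 0.2 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed")
    devs = np.asarray(devs)
    c_hat = float(obs_dev / devs.mean())
    return CHat(c_hat=c_hat, n_boot=n_boot, bootstrap_deviances=devs,
                n_failed=n_failed, seed=seed)


# ---------------------------------------------------------------------------
# MARK .inp and CSV history IO
# ---------------------------------------------------------------------------

def read_inp(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a MARK-style .inp: lines like ``101100 3;``.

    Returns (histories, frequencies); histories are expanded one row per
    line (use the frequency column to weight or replicate).
    """
    hists, freqs = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("/*")[0].strip().rstrip(";").strip()
            if not line:
                continue
            parts = line.split()
            if not set(parts[0]) <= {"0", "1"}:
                raise ValueError(f"line {lineno}: bad capture history {parts[0]!r}")
            hists.append([int(c) for c in parts[0]])
            freqs.append(int(parts[1]) if len(parts) > 1 else 1)
    if not hists:
        raise ValueError("empty .inp file")
    return np.asarray(hists, dtype=np.int8), np.asarray(freqs, dtype=int)


def write_inp(histories: np.ndarray, path, freqs: np.ndarray | None = None
              ) -> None:
    histories = np.asarray(histories, dtype=int)
    if freqs is None:
        freqs = np.ones(len(histories), dtype=int)
    with open(path, "w") as fh:
        for row, f in zip(histories, freqs):
            fh.write("".join(str(int(v)) for v in row) + f" {int(f)};\n")
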