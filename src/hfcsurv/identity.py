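"""Identity-disequilibrium statistics: g2, heterozygosity-heterozygosity
correlations, and the expected correlation between standardized
heterozygosity and the inbreeding coefficient.

g2 measures the excess covariance in heterozygosity across loci generated
by variance in inbreeding.  The point estimate is the multilocus
moment-ratio estimator for data with missing genotypes: with
``h[i,k]`` the 0/1 heterozygosity of individual ``i`` at locus ``k``
(untyped cells excluded), ``n_k`` / ``n_kl`` the counts of individuals
typed at locus ``k`` / at both ``k`` and ``l``, ``H_k = sum_i h[i,k]`` and
``S_kl = sum_i h[i,k] h[i,l]`` over individuals typed at both::

    g2 = [ sum_{k!=l} S_kl / n_kl ]
         / [ sum_{k!=l} (H_k H_l - S_kl) / (n_k n_l - n_kl) ]  -  1

which for complete data reduces to the classical
``(n-1) sum S_kl / sum (H_k H_l - S_kl) - 1``.  The numerator averages the
joint heterozygosity of locus pairs *within* individuals, the denominator
the same quantity *between* individuals; their ratio exceeds one exactly
when heterozygosity is correlated across loci.

Standard errors come from a bootstrap over individuals; p-values from a
permutation null that shuffles each locus's heterozygosity column
independently across individuals (destroying between-locus correlation
while preserving each locus's heterozygosity and missingness profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable

__all__ = ["G2Result", "HHCResult", "ExpectedCorrelation",
           "g2", "g2_point", "hhc", "expected_r_sh_f", "observed_r_sh_f"]


@dataclass(frozen=True)
class G2Result:
    g2: float
    se: float
    p_value: float
    p_value_bootstrap: float
    n_iter: int
    seed: int


@dataclass(frozen=True)
class HHCResult:
    coefficients: np.ndarray
    mean: float
    sd: float
    min: float
    max: float
    seed: int


@dataclass(frozen=True)
class ExpectedCorrelation:
    e_f: float
    sd_f: float
    sd_h: float
    r_expected: float


# ---------------------------------------------------------------------------
# g2
# ---------------------------------------------------------------------------

def _het_matrix(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """(h, typed): h is 0/1 with 0 in untyped cells, typed is the mask."""
    typed = g.typed
    h = ((g.a1 != g.a2) & typed).astype(float)
    return h, typed.astype(float)


def g2_point(h: np.ndarray, typed: np.ndarray) -> float:
    """Moment-ratio g2 from a heterozygosity matrix and typed mask.

    Vectorized over locus pairs; see the module docstring for the formula.
    """
    h = np.asarray(h, dtype=float)
    t = np.asarray(typed, dtype=float)
    S = h.T @ h              # L x L: sum_i h_ik h_il (both typed by construction)
    n_kl = t.T @ t           # individuals typed at both loci
    Hk = h.sum(axis=0)       # het count per locus
    HH = np.outer(Hk, Hk)
    nk = t.sum(axis=0)
    NN = np.outer(nk, nk)
    L = h.shape[1]
    off = ~np.eye(L, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        num_terms = np.where(n_kl > 0, S / n_kl, 0.0)
        den_pairs = NN - n_kl
        den_terms = np.where(den_pairs > 0, (HH - S) / den_pairs, 0.0)
    num = num_terms[off].sum()
    den = den_terms[off].sum()
    if den <= 0:
        return np.nan
    return num / den - 1.0


def g2(g: GenotypeTable, n_iter: int = 1000, seed: int = 0) -> G2Result:
    """g2 with bootstrap SE and permutation p-value.

    The permutation p-value is the fraction of column-shuffled null tables
    with g2 >= the observed value; the bootstrap p-value is the fraction of
    individual-level bootstrap estimates <= 0 (one-sided evidence that
    g2 > 0).  Both resampling schemes use ``n_iter`` draws from ``seed``.
    """
    h, typed = _het_matrix(g)
    n, L = h.shape
    if L < 2:
        raise ValueError("g2 undefined for one locus")
    poly = np.array([(h[typed[:, j] > 0, j].sum() > 0) for j in range(L)])
    if not poly.any():
        raise ValueError("g2 undefined: all loci monomorphic (no heterozygotes)")
    if n < 10:
        warnings.warn(f"g2 on only {n} individuals is unreliable", stacklevel=2)

    point = g2_point(h, typed)
    rng = np.random.default_rng(seed)

    boot = np.empty(n_iter)
    for b in range(n_iter):
        idx = rng.integers(0, n, size=n)
        boot[b] = g2_point(h[idx], typed[idx])
    boot = boot[np.isfinite(boot)]
    se = float(boot.std(ddof=1)) if len(boot) > 1 else np.nan
    p_boot = float((boot <= 0).mean()) if len(boot) else np.nan

    null = np.empty(n_iter)
    for b in range(n_iter):
        hp = np.empty_like(h)
        tp = np.empty_like(typed)
        for j in range(L):
            perm = rng.permutation(n)
            hp[:, j] = h[perm, j]
            tp[:, j] = typed[perm, j]
        null[b] = g2_point(hp, tp)
    null = null[np.isfinite(null)]
    p_perm = float((null >= point).mean()) if len(null) else np.nan

    return G2Result(g2=float(point), se=se, p_value=p_perm,
                    p_value_bootstrap=p_boot, n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# Heterozygosity-heterozygosity correlation
# ---------------------------------------------------------------------------

def hhc(g: GenotypeTable, n_splits: int = 100,
        split_sizes: tuple[int, int] | None = None, seed: int = 0) -> HHCResult:
    """Spearman correlation of per-individual mean heterozygosity between
    random halves of the marker panel, repeated ``n_splits`` times.

    Each half's per-individual statistic is the plain proportion of typed
    loci that are heterozygous (not SH-standardized).
    """
    L = g.n_loci
    if L < 2:
        raise ValueError("hhc requires at least two loci")
    if split_sizes is None:
        split_sizes = (L // 2, L - L // 2)
    if sum(split_sizes) != L:
        raise ValueError(f"split sizes {split_sizes} must sum to {L} loci")
    h = g.het  # 1/0/nan
    rng = np.random.default_rng(seed)
    coeffs = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(L)
        half1, half2 = perm[:split_sizes[0]], perm[split_sizes[0]:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(h[:, half1], axis=1)
            m2 = np.nanmean(h[:, half2], axis=1)
        ok = np.isfinite(m1) & np.isfinite(m2)
        rho, _ = stats.spearmanr(m1[ok], m2[ok])
        coeffs[s] = rho
    return HHCResult(coefficients=coeffs, mean=float(np.mean(coeffs)),
                     sd=float(np.std(coeffs, ddof=1)),
                     min=float(np.min(coeffs)), max=float(np.max(coeffs)),
                     seed=seed)


# ---------------------------------------------------------------------------
# Expected and observed correlation between SH and f
# ---------------------------------------------------------------------------

def expected_r_sh_f(e_f: float, sd_f: float, sd_h: float,
                    e_h: float = 1.0) -> ExpectedCorrelation:
    """Expected correlation between multilocus heterozygosity and f.

    Under the linear-regression model of heterozygosity on inbreeding,
    ``E[H | f] = h0 (1 - f)`` with ``h0 = E(H)/(1 - E(f))``, giving::

        r(H, f) = -h0 * sd_f / sd_h = - sd_f * E(H) / (sd_h * (1 - E(f)))

    ``e_h`` defaults to 1, the mean of standardized heterozygosity (SH) by
    construction.  The result is clamped to [-1, 0].
    """
    if sd_h <= 0:
        raise ValueError("sd_h must be positive")
    if sd_f < 0:
        raise ValueError("sd_f must be nonnegative")
    if sd_f == 0:
        r = 0.0
    else:
        r = -sd_f * e_h / (sd_h * (1.0 - e_f))
        r = max(r, -1.0)
    return ExpectedCorrelation(e_f=e_f, sd_f=sd_f, sd_h=sd_h, r_expected=r)


def expected_sd_h(obs_het: np.ndarray, e_f: float = 0.0, sd_f: float = 0.0,
                  standardized: bool = True) -> float:
    """Expected SD of multilocus heterozygosity over L loci.

    Binomial sampling of per-locus heterozygosity plus the component induced
    by variance in inbreeding: with per-locus outbred heterozygosities
    ``h_l`` and ``hbar`` their mean,

        var(H) = sum h_l (1-h_l) / L^2 * (1 - E f)  +  hbar^2 var(f)

    (the first term evaluated at the f-shrunk heterozygosities).  When
    ``standardized`` the result is scaled to SH units (divided by the mean
    observed heterozygosity).
    """
    h = np.asarray(obs_het, dtype=float)
    L = len(h)
    hf = h * (1.0 - e_f)
    var = float(np.sum(hf * (1.0 - hf))) / L ** 2 + float(np.mean(h)) ** 2 * sd_f ** 2
    sd = np.sqrt(var)
    if standardized:
        sd /= float(np.mean(hf))
    return sd


def observed_r_sh_f(sh: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) between SH and f with a
    two-sided p-value.  Requires >= 3 paired observations; a zero-variance
    input yields (nan, nan)."""
    sh = np.asarray(sh, dtype=float)
    f = np.asarray(f, dtype=float)
    ok = np.isfinite(sh) & np.isfinite(f)
    sh, f = sh[ok], f[ok]
    if len(sh) < 3:
        raise ValueError("observed_r_sh_f requires at least 3 paired observations")
    if np.ptp(sh) == 0 or np.ptp(f) == 0:
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(sh, f)
    return float(rho), float(p)
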