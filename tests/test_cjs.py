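import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from hfcsurv import cjs
from hfcsurv.cjs import (CaptureData, fit_cjs, impute_missing, parse_model,
                         qaicc, read_inp, simulate_histories, standardize,
                         transform_coccidia, write_inp)


# ---------------------------------------------------------------------------
# Notation parsing
# ---------------------------------------------------------------------------

def test_parse_a2_year_constant():
    spec = parse_model("Phi(a2-t/.) p(t)")
    assert spec.a2
    assert spec.phi_cub_terms == ("t",)
    assert spec.phi_adult_terms == ()
    assert spec.p_terms == ("t",)


def test_parse_constant_model_two_params():
    spec = parse_model("Phi(.) p(.)")
    assert not spec.a2
    assert spec.phi_cub_terms == ()
    assert spec.p_terms == ()
    data = _toy_data(np.random.default_rng(0), n=40, T=4)
    fit = fit_cjs(data, spec, n_starts=1)
    assert len(fit.beta) == 2
    assert fit.k == 2


def test_parse_covariate_with_space():
    spec = parse_model("Phi(a2-t/sex + population size) p(t)")
    assert spec.phi_adult_terms == ("sex", "population_size")


def test_parse_interaction_expands():
    spec = parse_model("Phi(a2-t/sex) p(sex*t)")
    assert spec.p_terms == ("sex*t",)


def test_parse_errors():
    with pytest.raises(ValueError, match="cannot parse"):
        parse_model("Phi[t] p(t)")
    with pytest.raises(ValueError, match="position"):
        parse_model("Phi(a2-t/se!x) p(t)")


# ---------------------------------------------------------------------------
# Covariate transforms
# ---------------------------------------------------------------------------

def test_standardize_forced():
    out = standardize(np.array([1.0, 2.0, 3.0]))
    assert out == pytest.approx([-0.5, 0.0, 0.5])


def test_standardize_idempotent_scale():
    x = np.array([0.3, -0.1, 0.4, 0.0, -0.6])
    once = standardize(x)
    twice = standardize(once)
    assert np.allclose(once / np.std(once, ddof=1) / 2,
                       twice / np.std(twice, ddof=1) / 2, atol=1e-12)


def test_standardize_moments():
    rng = np.random.default_rng(3)
    x = rng.normal(10, 7, 100)
    out = standardize(x)
    assert out.mean() == pytest.approx(0.0, abs=1e-12)
    assert out.std(ddof=1) == pytest.approx(0.5, abs=1e-12)


def test_standardize_zero_variance():
    with pytest.raises(ValueError, match="zero-variance"):
        standardize(np.ones(5))


def test_coccidia_zero_count():
    out = transform_coccidia(np.array([0.0, 5.0, 10.0]),
                             np.array(["may", "may", "may"]))
    logged = np.log(np.array([0.0, 5.0, 10.0]) + 1)
    expect = (logged - logged.mean()) / (2 * logged.std(ddof=1))
    assert out == pytest.approx(expect)


def test_coccidia_constant_month_zero():
    out = transform_coccidia(np.array([4.0, 4.0, 7.0, 1.0]),
                             np.array(["jun", "jun", "jul", "jul"]))
    assert out[0] == out[1] == 0.0


def test_coccidia_vs_two_step_oracle():
    rng = np.random.default_rng(5)
    counts = rng.poisson(20, 60).astype(float)
    months = rng.choice(["may", "jun", "jul"], 60)
    out = transform_coccidia(counts, months)
    for m in ["may", "jun", "jul"]:
        sel = months == m
        lg = np.log(counts[sel] + 1)
        assert out[sel] == pytest.approx((lg - lg.mean()) / (2 * lg.std(ddof=1)))


def test_coccidia_negative_error():
    with pytest.raises(ValueError):
        transform_coccidia(np.array([-1.0]), np.array(["may"]))


def test_impute_simple():
    out, mask = impute_missing(pd.DataFrame({"a": [1.0, np.nan, 3.0]}))
    assert out["a"].tolist() == [1.0, 2.0, 3.0]
    assert mask.sum() == 1


def test_impute_identity_and_oracle():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
    out, mask = impute_missing(df)
    assert mask.sum() == 0
    pd.testing.assert_frame_equal(out, df)
    df2 = df.copy()
    hole = rng.random((20, 3)) < 0.3
    df2 = df2.mask(hole)
    out2, mask2 = impute_missing(df2)
    for c in df2.columns:
        col_mean = df2[c].mean()
        assert np.allclose(out2.loc[df2[c].isna(), c], col_mean)
    with pytest.raises(ValueError, match="fully missing"):
        impute_missing(pd.DataFrame({"a": [np.nan, np.nan]}))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _toy_data(rng, n=60, T=5, phi=0.7, p=0.6, stagger=True):
    first = rng.integers(0, T - 2, n) if stagger else np.zeros(n, dtype=int)
    phi_m = np.full((n, T - 1), phi)
    p_m = np.full((n, T - 1), p)
    hist = simulate_histories(first, phi_m, p_m, rng)
    keep = hist.any(axis=1)
    return CaptureData(hist[keep], np.zeros(int(keep.sum()), dtype=np.int8),
                       sex=rng.integers(0, 2, int(keep.sum())))


def test_degenerate_all_detected():
    # every released individual detected at every later occasion
    T = 3
    hist = np.ones((20, T), dtype=int)
    data = CaptureData(hist, np.zeros(20, dtype=int))
    fit = fit_cjs(data, "Phi(.) p(.)", n_starts=1)
    phi = expit(fit.beta["phi:int"])
    p = expit(fit.beta["p:int"])
    assert phi > 0.999 and p > 0.999
    assert fit.deviance == pytest.approx(0.0, abs=1e-4)


def test_mle_vs_grid_oracle():
    rng = np.random.default_rng(42)
    data = _toy_data(rng, n=30, T=5, phi=0.6, p=0.7)
    fit = fit_cjs(data, "Phi(.) p(.)", n_starts=3)
    lik = cjs._CJSLikelihood(data, fit.spec)
    grid = np.linspace(-3, 3, 200)
    vals = np.array([[lik(np.array([a, b])) for b in grid] for a in grid])
    ia, ib = np.unravel_index(vals.argmin(), vals.shape)
    # refine around the best grid node to oracle precision
    assert abs(fit.beta["phi:int"] - grid[ia]) < 3 * (grid[1] - grid[0])
    assert abs(fit.beta["p:int"] - grid[ib]) < 3 * (grid[1] - grid[0])
    ref = optimize.minimize(lik, np.array([grid[ia], grid[ib]]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    assert np.allclose(fit.beta.to_numpy(), ref.x, atol=1e-3)


def test_likelihood_invariant_to_ordering():
    rng = np.random.default_rng(9)
    data = _toy_data(rng, n=50, T=6)
    perm = np.random.default_rng(1).permutation(data.n_individuals)
    data2 = CaptureData(data.histories[perm], data.age_at_first[perm],
                        sex=data.sex[perm])
    f1 = fit_cjs(data, "Phi(.) p(.)", n_starts=1)
    f2 = fit_cjs(data2, "Phi(.) p(.)", n_starts=1)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)


def test_all_zero_tail_individual_adds_chi_term_only():
    rng = np.random.default_rng(11)
    data = _toy_data(rng, n=40, T=5)
    beta = np.array([0.3, -0.2])
    lik1 = cjs._CJSLikelihood(data, parse_model("Phi(.) p(.)"))
    # add one individual first caught at occasion 1, never seen again
    hist = np.vstack([data.histories,
                      np.array([[0, 1, 0, 0, 0]], dtype=np.int8)])
    data2 = CaptureData(hist, np.append(data.age_at_first, 0),
                        sex=np.append(data.sex, 0))
    lik2 = cjs._CJSLikelihood(data2, parse_model("Phi(.) p(.)"))
    phi, p = expit(0.3), expit(-0.2)
    # chi from occasion 1 with T=5: three intervals remain
    chi = 1.0
    for _ in range(3):
        chi = (1 - phi) + phi * (1 - p) * chi
    assert lik2.loglik(beta) - lik1.loglik(beta) == pytest.approx(np.log(chi),
                                                                  abs=1e-10)


def test_nested_model_deviance_never_increases():
    rng = np.random.default_rng(13)
    data = _toy_data(rng, n=120, T=6)
    small = fit_cjs(data, "Phi(.) p(.)", n_starts=2)
    big = fit_cjs(data, "Phi(sex) p(.)", n_starts=2)
    assert big.deviance <= small.deviance + 1e-4


def test_terminal_confounding_profile_flat_and_k():
    rng = np.random.default_rng(15)
    T = 4
    n = 300
    first = rng.integers(0, T - 1, n)
    phi_m = np.full((n, T - 1), 0.7)
    p_m = np.full((n, T - 1), 0.6)
    hist = simulate_histories(first, phi_m, p_m, rng)
    keep = hist.any(axis=1)
    data = CaptureData(hist[keep], np.zeros(int(keep.sum()), dtype=np.int8))
    fit = fit_cjs(data, "Phi(t) p(t)", n_starts=2)
    # k: (1 + T-2) phi + (1 + T-2) p, minus 1 for the confounded pair
    assert fit.k == 2 * (T - 1) - 1
    # profile flatness: shift the terminal phi dummy, re-minimize only the
    # terminal p dummy; deviance must be unchanged
    lik = cjs._CJSLikelihood(data, fit.spec)
    names = lik.phi_names + lik.p_names
    beta0 = fit.beta.to_numpy().copy()
    i_phi = names.index(f"phi:t{T - 2}")
    i_p = names.index(f"p:t{T - 2}")
    beta1 = beta0.copy()
    beta1[i_phi] += 1.0

    def prof(x):
        b = beta1.copy()
        b[i_p] = x
        return lik(b)

    res = optimize.minimize_scalar(prof, bounds=(-15, 15), method="bounded",
                                   options={"xatol": 1e-10})
    assert res.fun == pytest.approx(-fit.loglik, abs=1e-3)


def test_fixed_p_excluded_from_k():
    rng = np.random.default_rng(17)
    data = _toy_data(rng, n=50, T=5)
    fit = fit_cjs(data, "Phi(.) p(.)", fixed_p=0.6, n_starts=1)
    assert fit.k == 1
    assert list(fit.beta.index) == ["phi:int"]


# ---------------------------------------------------------------------------
# QAICc
# ---------------------------------------------------------------------------

def test_qaicc_forced_arithmetic():
    assert qaicc(100.0, 1.0, n_eff=50, k=3) == pytest.approx(100 + 6 + 24 / 46)
    assert qaicc(100.0, 2.0, n_eff=50, k=3) == pytest.approx(50 + 6 + 24 / 46)


def test_qaicc_large_n_limit():
    val = qaicc(100.0, 1.0, n_eff=10 ** 9, k=3)
    assert val == pytest.approx(106.0, abs=1e-6)


def test_qaicc_small_n_error():
    with pytest.raises(ValueError):
        qaicc(100.0, 1.0, n_eff=4, k=3)


def test_chat_truncation():
    ch = cjs.CHat(c_hat=0.8, n_boot=10, bootstrap_deviances=np.ones(10),
                  n_failed=0, seed=0)
    assert ch.for_qaicc == 1.0


def test_n_releases():
    hist = np.array([[1, 0, 1], [0, 1, 1], [0, 0, 1]])
    assert cjs.n_releases(hist) == 2  # final-occasion captures not released


# ---------------------------------------------------------------------------
# Bootstrap c-hat
# ---------------------------------------------------------------------------

def test_chat_deterministic():
    rng = np.random.default_rng(19)
    data = _toy_data(rng, n=80, T=5)
    fit = fit_cjs(data, "Phi(.) p(.)", n_starts=1)
    c1 = cjs.bootstrap_chat(data, fit, n_boot=10, seed=5)
    c2 = cjs.bootstrap_chat(data, fit, n_boot=10, seed=5)
    assert c1.c_hat == c2.c_hat


def test_chat_overdispersed_pairs():
    rng = np.random.default_rng(21)
    n, T = 250, 8
    first = rng.integers(0, T - 2, n)
    phi_m = np.full((n, T - 1), 0.75)
    p_m = np.full((n, T - 1), 0.6)
    hist = simulate_histories(first, phi_m, p_m, rng)
    hist = np.repeat(hist[hist.any(axis=1)], 2, axis=0)
    data = CaptureData(hist, np.zeros(len(hist), dtype=np.int8))
    fit = fit_cjs(data, "Phi(.) p(.)", n_starts=1, compute_se=False)
    ch = cjs.bootstrap_chat(data, fit, n_boot=15, seed=2)
    assert ch.c_hat > 1.0


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def test_inp_round_trip(tmp_path):
    hist = np.array([[1, 0, 1, 1, 0, 0], [0, 1, 1, 0, 0, 1]], dtype=np.int8)
    path = tmp_path / "caps.inp"
    write_inp(hist, path)
    h2, freqs = read_inp(path)
    assert np.array_equal(h2, hist)
    assert freqs.tolist() == [1, 1]


def test_inp_frequencies_and_errors(tmp_path):
    path = tmp_path / "caps.inp"
    path.write_text("101100 3;\n/* comment */\n010010 1;\n")
    h, f = read_inp(path)
    assert f.tolist() == [3, 1]
    bad = tmp_path / "bad.inp"
    bad.write_text("10x100 1;\n")
    with pytest.raises(ValueError, match="line 1"):
        read_inp(bad)


# ---------------------------------------------------------------------------
# Parameter recovery (reduced grid)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", [400, 800])
@pytest.mark.parametrize("beta_true", [0.0, 0.5, 1.0])
def test_covariate_beta_recovery_bias(n, beta_true):
    """Median bias of an individual-covariate slope < 0.05 on the logit scale
    (3 effect sizes x 2 sample sizes, 50 replicates each)."""
    errs = []
    for rep in range(50):
        rng = np.random.default_rng(5000 + rep)
        T = 6
        x = rng.normal(0, 0.5, n)
        first = rng.integers(0, T - 2, n)
        phi_m = expit(0.6 + beta_true * x)[:, None] * np.ones((1, T - 1))
        p_m = np.full((n, T - 1), 0.6)
        hist = simulate_histories(first, phi_m, p_m, rng)
        keep = hist.any(axis=1)
        data = CaptureData(hist[keep], np.zeros(int(keep.sum()), dtype=np.int8),
                           covariates=pd.DataFrame({"x": x[keep]}))
        fit = fit_cjs(data, "Phi(x) p(.)", n_starts=1, compute_se=False)
        errs.append(fit.beta["phi:x"] - beta_true)
    assert abs(np.median(errs)) < 0.05
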