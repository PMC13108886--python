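import numpy as np
import pandas as pd
import pytest

from pombesig.inference import (
    McmcConfig,
    TimeCourseDataset,
    fit_pipeline,
    initial_fit,
    log_likelihood,
    mcmc_fit,
)
from pombesig.parameters import PARAM_NAMES, ParameterSet
from pombesig.simulate import simulate


def make_dataset(rows):
    return TimeCourseDataset(pd.DataFrame(
        rows, columns=["genotype", "observable", "hour", "mean", "sd", "n"]))


@pytest.fixture(scope="module")
def params():
    return ParameterSet.ones().replace(k2=0.2, k20=0.5)


@pytest.fixture(scope="module")
def small_data(params):
    """Noise-free byr1.DD dataset generated from ``params``."""
    hours = [0.0, 4.0, 8.0, 16.0, 24.0]
    tr = simulate(params, "B", "byr1.DD", hours)
    rows = [("byr1.DD", "ppSpk1", h, v, 0.05, 3)
            for h, v in zip(hours, tr.state("ppSpk1"))]
    rows += [("byr1.DD", "tSpk1", h, v, 0.05, 3)
             for h, v in zip(hours, tr.state("tSpk1"))]
    return make_dataset(rows)


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

def test_dataset_requires_columns():
    with pytest.raises(ValueError, match="missing columns"):
        TimeCourseDataset(pd.DataFrame({"genotype": ["WT"]}))


def test_dataset_floors_bad_sds():
    data = make_dataset([
        ("WT", "ppSpk1", 0.0, 2.0, 0.0, 3),
        ("WT", "ppSpk1", 1.0, 4.0, np.nan, 3),
        ("WT", "ppSpk1", 2.0, 1.0, 0.5, 3),
    ])
    floor = 0.05 * 4.0
    assert np.allclose(data.df["sd"], [floor, floor, 0.5])
    # raw values are preserved
    assert data.df["sd_raw"].iloc[2] == 0.5
    assert data.df["sd_raw"].iloc[0] == 0.0


def test_dataset_rejects_unknown_observable_and_genotype():
    with pytest.raises(ValueError, match="unknown observables"):
        make_dataset([("WT", "Ste11", 0.0, 1.0, 0.1, 3)])
    with pytest.raises(Exception):
        make_dataset([("frp1del", "ppSpk1", 0.0, 1.0, 0.1, 3)])


def test_dataset_csv_roundtrip(tmp_path, small_data):
    path = tmp_path / "d.csv"
    small_data.to_csv(path)
    back = TimeCourseDataset.from_csv(path)
    # the six data columns survive; sd is written post-flooring, so the
    # reloaded sd_raw equals the written (floored) sd rather than the original
    cols = ["genotype", "observable", "hour", "mean", "sd", "n"]
    pd.testing.assert_frame_equal(back.df[cols], small_data.df[cols])
    with pytest.raises(ValueError, match="cannot parse"):
        TimeCourseDataset.from_csv(tmp_path / "missing.csv")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_loglik_reorder_invariance(params, small_data):
    df = small_data.df[list(small_data.df.columns[:6])]
    shuffled = TimeCourseDataset(df.sample(frac=1.0, random_state=0))
    a = log_likelihood(params, "B", small_data)
    b = log_likelihood(params, "B", shuffled)
    assert a == pytest.approx(b, rel=1e-12)


def test_loglik_peaks_at_generating_params(params, small_data):
    ll_truth = log_likelihood(params, "B", small_data)
    ll_off = log_likelihood(params.replace(k20=1.0), "B", small_data)
    assert ll_truth > ll_off


def test_loglik_zero_residual_closed_form(params, small_data):
    sigma = small_data.df["sd"].to_numpy()
    expected = float(np.sum(-0.5 * np.log(2 * np.pi * sigma**2)))
    assert log_likelihood(params, "B", small_data) == pytest.approx(expected, rel=1e-8)


# ---------------------------------------------------------------------------
# initial_fit
# ---------------------------------------------------------------------------

def test_initial_fit_recovers_single_parameter(params, small_data):
    start = params.replace(k20=2.0)
    res = initial_fit(small_data, "B", base=start, free_params=["k20"],
                      n_starts=1, seed=0)
    assert res.params.k20 == pytest.approx(params.k20, rel=1e-3)
    # non-free parameters stayed put
    assert res.params.k5 == start.k5
    assert res.cost < 1e-6


def test_initial_fit_respects_box(params, small_data):
    res = initial_fit(small_data, "B", bounds=(0.5, 2.0), base=params,
                      free_params=["k20"], n_starts=1, seed=0, max_nfev=30)
    assert 0.5 <= res.params.k20 <= 2.0


def test_initial_fit_invalid_bounds(small_data):
    with pytest.raises(ValueError):
        initial_fit(small_data, "B", bounds=(2.0, 1.0))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def flat_loglike(_p):
    return 0.0


def test_mcmc_zero_steps_returns_start():
    start = ParameterSet.ones()
    res = mcmc_fit(start, config=McmcConfig(steps=0), loglike=flat_loglike)
    assert res.chain.shape == (1, 29)
    assert np.array_equal(res.best_params.values, start.values)


def test_mcmc_chain_shape_and_determinism():
    cfg = McmcConfig(steps=50, seed=5, log_every=0)
    a = mcmc_fit(ParameterSet.ones(), config=cfg, loglike=flat_loglike)
    b = mcmc_fit(ParameterSet.ones(), config=cfg, loglike=flat_loglike)
    assert a.chain.shape == (51, 29)
    assert a.loglik.shape == (51,)
    assert np.array_equal(a.chain, b.chain)
    # flat target, no bounds: every proposal accepted
    assert a.acceptance_rate == 1.0


def test_mcmc_requires_target():
    with pytest.raises(ValueError):
        mcmc_fit(ParameterSet.ones())


def test_mcmc_free_params_only_move():
    cfg = McmcConfig(steps=100, seed=2, free_params=("k3", "k8"), log_every=0)
    res = mcmc_fit(ParameterSet.ones(), config=cfg, loglike=flat_loglike)
    moved = [n for i, n in enumerate(PARAM_NAMES)
             if np.ptp(res.chain[:, i]) > 0]
    assert set(moved) == {"k3", "k8"}


def test_mcmc_bounds_keep_chain_in_box():
    cfg = McmcConfig(steps=2000, seed=3, proposal_sd=0.1,
                     bounds=(0.5, 2.0), log_every=0)
    res = mcmc_fit(ParameterSet.ones(), config=cfg, loglike=flat_loglike)
    assert res.chain.min() >= 0.5 and res.chain.max() <= 2.0
    assert 0 < res.acceptance_rate < 1


def test_mcmc_single_parameter_update_mode():
    cfg = McmcConfig(steps=50, seed=4, joint_update=False, log_every=0)
    res = mcmc_fit(ParameterSet.ones(), config=cfg, loglike=flat_loglike)
    # each accepted step changes exactly one coordinate
    diffs = res.chain[1:] != res.chain[:-1]
    assert np.all(diffs.sum(axis=1) <= 1)


def test_mcmc_frame_and_csv(tmp_path):
    cfg = McmcConfig(steps=10, seed=0, log_every=0)
    res = mcmc_fit(ParameterSet.ones(), config=cfg, loglike=flat_loglike)
    df = res.to_frame()
    assert list(df.columns[:3]) == ["step", "logL", "accepted"]
    assert len(df) == 11
    path = tmp_path / "chain.csv"
    res.to_csv(path)
    assert len(pd.read_csv(path)) == 11


def test_mcmc_moves_toward_higher_likelihood(params, small_data):
    start = params.replace(k20=0.65)
    cfg = McmcConfig(steps=300, seed=1, proposal_sd=0.02,
                     free_params=("k20",), log_every=0)
    res = mcmc_fit(start, small_data, "B", cfg)
    assert res.best_loglik > res.loglik[0]
    assert abs(res.best_params.k20 - params.k20) < abs(start.k20 - params.k20)


def test_fit_pipeline_noise_free_start_at_truth(params, small_data):
    """Global optimum at the start: the pipeline must not move away."""
    cfg = McmcConfig(steps=50, seed=0, log_every=0)
    res = fit_pipeline(small_data, "B", cfg,
                       init_kwargs=dict(base=params, n_starts=1,
                                        free_params=["k20"], max_nfev=30))
    assert np.allclose(np.log(res.best_params.values),
                       np.log(params.values), atol=1e-6)
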