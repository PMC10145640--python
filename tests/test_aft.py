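"""Profile-likelihood AFT engine: recovery, robustness, sensitivity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from hedgetick.aft import (
    ModelSpec,
    _maximise_beta,
    build_design,
    cell_log_scale_estimates,
    fit_forward_aft,
    fit_report,
    predict_group_means,
    sensitivity_merge_day12,
)
from hedgetick.attachment import ForwardRecurrenceDist, WeibullWholeTime, whole_mean
from hedgetick.simulate import simulate_cohort

from conftest import scaled_config


@pytest.fixture(scope="module")
def recovery_fit():
    """Fit to a study-sized cohort simulated at shape 3 (scales ~4-10 days)."""
    cfg = scaled_config(seed=501, scale=1.0, shape=3.0)
    ticks, _ = simulate_cohort(cfg)
    ticks = ticks[ticks["species"] == "ricinus"]
    fit = fit_forward_aft(ticks, ModelSpec(covariates="stage*season"))
    return cfg, ticks, fit


def test_design_matrix_structure(small_cohort):
    ticks, _ = small_cohort
    X, names, cells, cell_rows = build_design(ticks, ModelSpec("stage*season"))
    assert names[0] == "intercept"
    assert len(names) == 12 and len(cells) == 12
    assert np.linalg.matrix_rank(X) == len(cells)
    # every cell's design row reproduces its own cell mean structure
    for cell, row in cell_rows.items():
        assert row[0] == 1.0

    one = ticks[(ticks["stage"] == "nymph") & (ticks["season"] == "spring")]
    X1, names1, cells1, _ = build_design(one, ModelSpec("1"))
    assert names1 == ["intercept"] and X1.shape[1] == 1

    with pytest.raises(ValueError, match="unknown levels"):
        build_design(pd.DataFrame({"stage": ["pupa"], "season": ["spring"],
                                   "observed_day": [0.5]}),
                     ModelSpec("stage"))


def test_parameter_recovery(recovery_fit):
    cfg, _, fit = recovery_fit
    assert fit.converged
    assert abs(fit.shape_hat - 3.0) / 3.0 < 0.10
    cells, log_means, cov = cell_log_scale_estimates(fit)
    se = np.sqrt(np.diag(cov))
    for j, cell in enumerate(cells):
        true_log_scale = np.log(cfg.whole_time_params[cell].scale)
        assert abs(log_means[j] - true_log_scale) < 3 * se[j], cell


def test_whole_scale_group_means_recovered(recovery_fit):
    cfg, _, fit = recovery_fit
    means = predict_group_means(fit)
    for _, row in means.iterrows():
        d = cfg.whole_time_params[(row["stage"], row["season"])]
        truth = whole_mean(d)
        se_log = (np.log(row["whole_hi"]) - np.log(row["whole_lo"])) / (2 * 1.959964)
        assert abs(np.log(row["whole_mean"]) - np.log(truth)) < 3 * se_log


def test_common_shape_means_ratio_constant(recovery_fit):
    _, _, fit = recovery_fit
    means = predict_group_means(fit)
    ratios = means["whole_mean"] / means["observed_mean"]
    assert np.allclose(ratios, fit.mean_ratio(), rtol=1e-10)


def test_cluster_label_permutation(recovery_fit):
    _, ticks, fit = recovery_fit
    rng = np.random.default_rng(3)
    hosts = pd.unique(ticks["host_id"])
    relabel = dict(zip(hosts, rng.permutation(hosts)))
    shuffled = ticks.assign(host_id=ticks["host_id"].map(relabel))
    refit = fit_forward_aft(shuffled, ModelSpec(covariates="stage*season"))
    assert refit.shape_hat == pytest.approx(fit.shape_hat, abs=1e-8)
    assert np.allclose(refit.beta, fit.beta, atol=1e-8)


def test_cluster_composition_changes_sandwich(recovery_fit):
    """Destroying the host clustering changes the robust (not naive) cov."""
    _, ticks, fit = recovery_fit
    scrambled = ticks.assign(
        host_id=[f"X{i % 200:03d}" for i in range(len(ticks))])
    refit = fit_forward_aft(scrambled, ModelSpec(covariates="stage*season"))
    assert np.allclose(refit.beta, fit.beta, atol=1e-8)
    assert not np.allclose(refit.cov_sandwich, fit.cov_sandwich, rtol=1e-3)
    assert np.allclose(refit.cov_naive, fit.cov_naive, rtol=1e-4)


def test_published_daybin_fit_mean_ratio(daybin_counts):
    """Stage-only fit of the published day-binned counts lands in the
    published interval for the whole/observed mean ratio."""
    fit = fit_forward_aft(daybin_counts, ModelSpec(covariates="stage"),
                          cluster=None, weight="count")
    assert fit.robust == "naive"
    assert 1.80 <= fit.mean_ratio() <= 1.91


def test_aggregated_weights_equal_expanded_rows(daybin_counts):
    expanded = daybin_counts.loc[
        daybin_counts.index.repeat(daybin_counts["count"])].reset_index(drop=True)
    f1 = fit_forward_aft(daybin_counts, ModelSpec("stage"), cluster=None,
                         weight="count")
    f2 = fit_forward_aft(expanded, ModelSpec("stage"), cluster=None)
    assert f1.shape_hat == pytest.approx(f2.shape_hat, abs=1e-6)
    assert np.allclose(f1.beta, f2.beta, atol=1e-6)


def test_merge_day12_examples():
    df = pd.DataFrame({"observed_day": [0.5, 1.5, 2.5, 7.5]})
    out = sensitivity_merge_day12(df)
    assert list(out["observed_day"]) == [1.0, 1.0, 2.5, 7.5]
    assert len(out) == len(df)


def test_merge_refit_changes_whole_means_under_5pct(daybin_counts):
    spec = ModelSpec(covariates="stage")
    base = fit_forward_aft(daybin_counts, spec, cluster=None, weight="count")
    merged = fit_forward_aft(sensitivity_merge_day12(daybin_counts), spec,
                             cluster=None, weight="count")
    m0 = predict_group_means(base).set_index("stage")["whole_mean"]
    m1 = predict_group_means(merged).set_index("stage")["whole_mean"]
    rel = ((m1 - m0) / m0).abs()
    assert (rel < 0.05).all()


def test_midpoint_and_interval_conventions_agree(small_cohort):
    ticks, _ = small_cohort
    ticks = ticks[ticks["species"] == "ricinus"]
    f_mid = fit_forward_aft(ticks, ModelSpec("stage", time_convention="midpoint"))
    f_int = fit_forward_aft(ticks, ModelSpec("stage", time_convention="interval"))
    assert abs(f_mid.shape_hat - f_int.shape_hat) / f_mid.shape_hat < 0.05


def test_profile_unimodal_and_start_invariant(daybin_counts):
    v = daybin_counts["observed_day"].to_numpy(float)
    w = daybin_counts["count"].to_numpy(float)
    X, _, _, _ = build_design(daybin_counts, ModelSpec("stage"))
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(np.average(v, weights=w))

    def nll(logk):
        _, ll = _maximise_beta(v, X, w, float(np.exp(logk)), beta0, "midpoint")
        return -ll

    grid = np.linspace(np.log(0.5), np.log(20.0), 40)
    vals = np.array([nll(g) for g in grid])
    interior_minima = [i for i in range(1, len(grid) - 1)
                       if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]]
    assert len(interior_minima) == 1

    opts = []
    for k0 in (1.0, 4.0, 10.0):
        r = minimize_scalar(nll, bracket=(np.log(k0), np.log(k0) + 0.1),
                            method="brent", options={"xtol": 1e-10})
        opts.append(r.x)
    assert max(opts) - min(opts) < 1e-6


def test_sandwich_at_least_naive_under_host_correlated_durations():
    """Cluster-robust SEs exceed model-based ones when durations share a
    host-level effect.

    Abundance-only frailty leaves durations independent within hosts and
    the two SEs coincide; the sandwich must inflate exactly when the
    attachment times themselves are host-correlated, emulated here with a
    log-normal host multiplier on the Weibull scale.
    """
    violations = 0
    for seed in range(20):
        rng = np.random.default_rng(1200 + seed)
        rows = []
        for h in range(40):
            lam_h = 6.0 * np.exp(rng.normal(0.0, 0.35))
            v = ForwardRecurrenceDist(WeibullWholeTime(3.5, lam_h)).rvs(30, rng)
            rows.append(pd.DataFrame({"observed_day": v, "host_id": f"H{h:02d}"}))
        df = pd.concat(rows, ignore_index=True)
        fit = fit_forward_aft(df, ModelSpec("1"))
        rob = np.sqrt(np.diag(fit.cov_sandwich)[:-1]).mean()
        nai = np.sqrt(np.diag(fit.cov_naive)[:-1]).mean()
        violations += rob < nai
    assert violations <= 2


def test_cell_mean_ci_coverage():
    """Whole-scale cell-mean CIs cover truth at roughly nominal rate."""
    true = WeibullWholeTime(3.5, 6.0)
    target = whole_mean(true)
    fwd = ForwardRecurrenceDist(true)
    rng = np.random.default_rng(777)
    hits, n_rep = 0, 500
    for _ in range(n_rep):
        n_hosts, per_host = 25, 8
        frail = rng.normal(0, 0.0, n_hosts)  # independence: model-correct case
        v = fwd.rvs(n_hosts * per_host, rng)
        df = pd.DataFrame({
            "observed_day": v,
            "host_id": np.repeat([f"H{i}" for i in range(n_hosts)], per_host)})
        fit = fit_forward_aft(df, ModelSpec("1"))
        m = predict_group_means(fit)
        hits += m["whole_lo"][0] <= target <= m["whole_hi"][0]
    assert 0.90 <= hits / n_rep <= 0.98


def test_error_paths(daybin_counts):
    with pytest.raises(ValueError, match="non-empty"):
        fit_forward_aft(daybin_counts.iloc[0:0], ModelSpec("stage"))
    bad = daybin_counts.copy()
    bad.loc[0, "observed_day"] = -0.5
    with pytest.raises(ValueError, match="positive"):
        fit_forward_aft(bad, ModelSpec("stage"), weight="count")
    degenerate = pd.DataFrame({"observed_day": [1.5] * 50, "stage": "nymph"})
    with pytest.raises(ValueError, match="degenerate"):
        fit_forward_aft(degenerate, ModelSpec("stage"))
    with pytest.raises(ValueError):
        ModelSpec(covariates="stage^2")
    with pytest.raises(ValueError):
        ModelSpec(time_convention="exact")


def test_fit_report_roundtrips_to_json(daybin_counts):
    import json
    fit = fit_forward_aft(daybin_counts, ModelSpec("stage"), cluster=None,
                          weight="count")
    rep = fit_report(fit)
    s = json.dumps(rep)
    assert "mean_ratio" in s and "group_means" in s
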