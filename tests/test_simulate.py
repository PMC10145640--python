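"""Synthetic cohort generator: latent structure, sampling laws, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hedgetick import fixtures
from hedgetick.attachment import WeibullWholeTime, forward_cdf, whole_mean
from hedgetick.simulate import (
    SimConfig,
    apply_day1_suppression,
    load_config,
    study_config,
    read_records,
    save_config,
    simulate_cohort,
    write_hosts,
    write_records,
)

from conftest import scaled_config


def one_cell_config(seed, shape=4.5, scale=5.0, per_host=500.0, n_hosts=20,
                    **overrides):
    """Many ticks of a single stage/season cell, for distributional checks."""
    schedule = [(1, "spring")] * n_hosts
    return SimConfig(
        n_hosts=n_hosts, capture_schedule=schedule,
        abundance_mean={("nymph", "spring"): per_host},
        whole_time_params={("nymph", "spring"): WeibullWholeTime(shape, scale)},
        frailty_sd=0.0, hexagonus_fraction=0.0, rng_seed=seed, **overrides)


def test_reproducible_and_seed_sensitive():
    cfg = scaled_config(seed=5, scale=0.1)
    t1, h1 = simulate_cohort(cfg)
    t2, h2 = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(h1, h2)
    t3, _ = simulate_cohort(dataclasses.replace(cfg, rng_seed=6))
    assert not t1.equals(t3)


def test_latent_identity_and_binning():
    ticks, _ = simulate_cohort(one_cell_config(seed=2, per_host=200))
    lat = ticks[["latent_whole_time", "latent_backward_time", "latent_forward_time"]]
    assert np.allclose(lat.iloc[:, 1] + lat.iloc[:, 2], lat.iloc[:, 0], atol=1e-9)
    expected = np.ceil(ticks["latent_forward_time"]) - 0.5
    assert np.array_equal(ticks["observed_day"].to_numpy(), expected.to_numpy())
    assert (ticks["observed_day"] > 0).all()


def test_capture_position_uniform():
    ticks, _ = simulate_cohort(one_cell_config(seed=3, per_host=500))
    u = ticks["latent_forward_time"] / ticks["latent_whole_time"]
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_memoryless_shape_one():
    """With shape 1 the forward law equals the whole-time law itself."""
    cfg = one_cell_config(seed=4, shape=1.0, scale=5.0, per_host=5000)
    ticks, _ = simulate_cohort(cfg)
    fwd = ticks["latent_forward_time"].to_numpy()
    se = fwd.std() / np.sqrt(len(fwd))
    assert abs(fwd.mean() - 5.0) < 4 * se


def test_sampled_whole_times_are_length_biased():
    """Sampled whole mean is E[T^2]/E[T] = 2 E[V], not the unbiased mean."""
    d = WeibullWholeTime(4.5, 5.0)
    ticks, _ = simulate_cohort(one_cell_config(seed=8, per_host=5000))
    w = ticks["latent_whole_time"].to_numpy()
    lb_mean = 2 * whole_mean(d) / 1.880459023826333  # 2 E[V] via R(4.5)
    se = w.std() / np.sqrt(len(w))
    assert abs(w.mean() - lb_mean) < 4 * se


def test_forward_day_bins_match_equilibrium_cdf():
    d = WeibullWholeTime(4.5, 5.0)
    ticks, _ = simulate_cohort(one_cell_config(seed=9, per_host=1000))
    obs = ticks["observed_day"].to_numpy()
    edges = np.arange(0.0, 9.0)
    probs = np.diff(np.append(forward_cdf(edges, d), 1.0))
    counts = np.array([(obs == e + 0.5).sum() for e in edges[:-1]] +
                      [(obs >= edges[-1]).sum()])
    res = stats.chisquare(counts, probs * counts.sum())
    assert res.pvalue > 0.01


def test_stationary_sampler_matches_length_biased():
    c1 = one_cell_config(seed=12, per_host=500)
    c2 = one_cell_config(seed=12, sampler="stationary", per_host=500)
    t1, _ = simulate_cohort(c1)
    t2, _ = simulate_cohort(c2)
    ks = stats.ks_2samp(t1["latent_whole_time"], t2["latent_whole_time"])
    assert ks.pvalue > 0.01
    # the renewal construction also yields a uniform capture position
    u = t2["latent_backward_time"] / t2["latent_whole_time"]
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_cell_counts_match_abundance_without_frailty():
    cfg = scaled_config(seed=21, scale=0.5, frailty_sd=0.0,
                        hexagonus_fraction=0.0)
    ticks, hosts = simulate_cohort(cfg)
    merged = ticks.merge(hosts[["host_id"]], on="host_id")
    for (stage, season), mean in cfg.abundance_mean.items():
        n_hosts = sum(1 for _, s in cfg.capture_schedule if s == season)
        n = len(merged[(merged["stage"] == stage) & (merged["season"] == season) &
                       (merged["species"] == "ricinus")])
        se = np.sqrt(mean * n_hosts)  # Poisson SE of the cell total
        assert abs(n - mean * n_hosts) < 3.5 * se


def test_day1_suppression():
    rng = np.random.default_rng(0)
    base = pd.DataFrame({
        "stage": ["nymph"] * 10**4 + ["male"] * 1000,
        "observed_day": [0.5] * 10**4 + [0.5] * 1000,
        "species": "ricinus",
    })
    same = apply_day1_suppression(base, 0.0, rng)
    pd.testing.assert_frame_equal(same, base)

    allmoved = apply_day1_suppression(base, 1.0, np.random.default_rng(1))
    nymphs = allmoved[allmoved["stage"] == "nymph"]
    males = allmoved[allmoved["stage"] == "male"]
    assert (nymphs["observed_day"] == 1.5).all()
    assert (males["observed_day"] == 0.5).all()  # males unaffected by default

    half = apply_day1_suppression(base, 0.5, np.random.default_rng(2))
    moved = (half.loc[half["stage"] == "nymph", "observed_day"] == 1.5).sum()
    bound = stats.binom.ppf([0.005, 0.995], 10**4, 0.5)
    assert bound[0] <= moved <= bound[1]
    with pytest.raises(ValueError):
        apply_day1_suppression(base, 1.5, rng)


def test_records_roundtrip(tmp_path, small_cohort):
    ticks, hosts = small_cohort
    p = tmp_path / "ticks.csv"
    write_records(ticks, p)
    back = read_records(p)
    pd.testing.assert_frame_equal(back, ticks.reset_index(drop=True),
                                  check_exact=False, rtol=0, atol=1e-12)
    write_hosts(hosts, tmp_path / "hosts.csv")

    empty = ticks.iloc[0:0]
    p2 = tmp_path / "empty.csv"
    write_records(empty, p2)
    assert read_records(p2).empty


def test_read_records_validation(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("host_id,capture_week,season,species,stage,observed_day,status\n"
                 "H000,1,spring,ricinus,nymph,0.5,engorged\n"
                 "H000,1,spring,ricinus,nymph,-1.5,engorged\n")
    with pytest.raises(ValueError, match="line 3"):
        read_records(p)
    p.write_text("host_id,capture_week\nH000,1\n")
    with pytest.raises(ValueError, match="missing required columns"):
        read_records(p)
    p.write_text("host_id,capture_week,season,species,stage,observed_day,status\n"
                 "H000,1,spring,ricinus,pupa,0.5,engorged\n")
    with pytest.raises(ValueError, match="line 2"):
        read_records(p)


def test_config_roundtrip_and_validation(tmp_path):
    cfg = study_config(seed=7)
    path = tmp_path / "cfg.yaml"
    save_config(cfg, path)
    back = load_config(path)
    assert back == cfg

    # seed is mandatory in stored configs
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh)
    del d["rng_seed"]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)
    with pytest.raises(ValueError, match="rng_seed"):
        load_config(path)


def test_invalid_configs():
    good = one_cell_config(seed=0)
    with pytest.raises(ValueError, match="capture_schedule"):
        dataclasses.replace(good, capture_schedule=[])
    with pytest.raises(ValueError, match="season"):
        dataclasses.replace(good, capture_schedule=[(1, "winter")] * good.n_hosts)
    with pytest.raises(ValueError, match="non-negative"):
        dataclasses.replace(good, abundance_mean={("nymph", "spring"): -1.0})
    with pytest.raises(ValueError, match="shared"):
        dataclasses.replace(good, whole_time_params={
            ("nymph", "spring"): WeibullWholeTime(2.0, 5.0),
            ("larva", "spring"): WeibullWholeTime(3.0, 5.0)})
    with pytest.raises(ValueError, match="day1_suppression_prob"):
        dataclasses.replace(good, day1_suppression_prob=1.2)


def test_default_schedule_matches_study_layout():
    sched = fixtures.default_capture_schedule()
    assert len(sched) == 57
    by_season = {s: sum(1 for _, x in sched if x == s)
                 for s in ("spring", "summer", "autumn")}
    assert by_season == {"spring": 18, "summer": 27, "autumn": 12}
    assert max(w for w, _ in sched) == 27


def test_hexagonus_labels_inert():
    cfg = scaled_config(seed=33, scale=1.0, hexagonus_fraction=0.2)
    ticks, _ = simulate_cohort(cfg)
    hexa = ticks[ticks["species"] == "hexagonus"]
    assert len(hexa) > 0
    assert (hexa["stage"] == "nymph").all()
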