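"""Marginal Poisson model of per-host tick burdens by stage and season.

Each host contributes one count per tick life stage (larva, nymph,
female, male) in the season it was captured.  Counts from the same host
are correlated — hosts differ systematically in attractiveness and
exposure — so the model is a GEE: a saturated log-linear Poisson
regression on stage x season with independence working correlation and a
cluster-robust (sandwich) covariance by host.  In the saturated model the
fitted cell mean equals the observed cell mean, total-ticks-in-cell over
hosts-in-season, whatever the working correlation; the sandwich
covariance is what the clustering changes.

The model is fitted through statsmodels' GEE with a cell-indicator
design, so the coefficient vector is directly the vector of log cell
means.  Cells with zero total cannot be represented on the log scale;
they are reported as mean 0 with a boundary profile-likelihood CI and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fixtures import SEASONS, STAGES

__all__ = [
    "AbundanceFit",
    "counts_from_records",
    "fit_poisson_gee",
    "abundance_table",
]

_CHI2_95_HALF = 1.9207  # qchisq(0.95, 1) / 2, boundary profile bound


@dataclass
class AbundanceFit:
    """Saturated stage-by-season marginal Poisson fit."""

    cells: list  # (stage, season) with positive totals, fixed order
    log_means: np.ndarray
    cov: np.ndarray  # sandwich covariance of log cell means
    cov_naive: np.ndarray
    cell_means: dict  # (stage, season) -> fitted ticks per host (all cells)
    n_hosts: dict  # season -> hosts
    zero_cells: list = field(default_factory=list)
    working_correlation: str = "independence"

    @property
    def boundary_flagged(self) -> bool:
        return bool(self.zero_cells)


def counts_from_records(ticks: pd.DataFrame, hosts: pd.DataFrame,
                        species: str | None = "ricinus") -> pd.DataFrame:
    """Per-host per-stage counts (zero-filled) from tick-level records.

    ``species`` keeps only that species (I. hexagonus is excluded from the
    abundance model by default); pass None to count everything.
    """
    t = ticks if species is None else ticks[ticks["species"] == species]
    counts = (t.groupby(["host_id", "stage"], sort=False).size()
              .rename("count").reset_index())
    grid = pd.MultiIndex.from_product(
        [hosts["host_id"], list(STAGES)], names=["host_id", "stage"]
    ).to_frame(index=False)
    out = grid.merge(counts, on=["host_id", "stage"], how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    out = out.merge(hosts[["host_id", "season"]], on="host_id", how="left")
    return out[["host_id", "season", "stage", "count"]]


def fit_poisson_gee(counts: pd.DataFrame, cluster: str = "host_id",
                    working_correlation: str = "independence") -> AbundanceFit:
    """Fit the saturated stage x season Poisson GEE, clustered by host.

    ``counts`` has one row per host x stage with columns
    host_id, season, stage, count.  Every host must carry a count
    (possibly zero) for each of the four stages.
    """
    for col in ("season", "stage", "count", cluster):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    n_hosts = {s: counts.loc[counts["season"] == s, cluster].nunique()
               for s in SEASONS if (counts["season"] == s).any()}
    if not n_hosts:
        raise ValueError("no seasons with hosts in the data")

    cell_totals = counts.groupby(["stage", "season"], sort=False)["count"].sum()
    all_cells = [(st, se) for se in SEASONS for st in STAGES
                 if (st, se) in cell_totals.index]
    zero_cells = [c for c in all_cells if cell_totals[c] == 0]
    cells = [c for c in all_cells if cell_totals[c] > 0]
    if not cells:
        raise ValueError("all cells have zero counts; nothing to fit")

    # cell-indicator design: coefficients are the log cell means
    sub = counts[counts.apply(lambda r: (r["stage"], r["season"]) in set(cells),
                              axis=1)].reset_index(drop=True)
    X = np.zeros((len(sub), len(cells)))
    for j, (st, se) in enumerate(cells):
        X[:, j] = ((sub["stage"] == st) & (sub["season"] == se)).to_numpy(float)
    cov_struct = (sm.cov_struct.Exchangeable()
                  if working_correlation == "exchangeable"
                  else sm.cov_struct.Independence())
    model = sm.GEE(sub["count"].to_numpy(float), X,
                   groups=sub[cluster].to_numpy(),
                   family=sm.families.Poisson(), cov_struct=cov_struct)
    res = model.fit(maxiter=200)
    log_means = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    cov_naive = np.asarray(res.cov_naive)

    cell_means = {c: float(np.exp(log_means[j])) for j, c in enumerate(cells)}
    for c in zero_cells:
        cell_means[c] = 0.0
    return AbundanceFit(
        cells=cells, log_means=log_means, cov=0.5 * (cov + cov.T),
        cov_naive=0.5 * (cov_naive + cov_naive.T), cell_means=cell_means,
        n_hosts=n_hosts, zero_cells=zero_cells,
        working_correlation=working_correlation)


def abundance_table(fit: AbundanceFit, counts: pd.DataFrame | None = None,
                    level: float = 0.95) -> pd.DataFrame:
    """Report per cell: modelled mean, robust CI, observed mean, SD, total.

    In the saturated model modelled and observed means are identical by
    construction; the table shows both for transparency.  Zero cells get
    a one-sided boundary profile-likelihood interval and a flag.
    """
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    idx = {c: j for j, c in enumerate(fit.cells)}
    rows = []
    for se in SEASONS:
        if se not in fit.n_hosts:
            continue
        for st in STAGES:
            cell = (st, se)
            if cell not in fit.cell_means:
                continue
            m = fit.cell_means[cell]
            if cell in idx:
                j = idx[cell]
                se_log = float(np.sqrt(max(fit.cov[j, j], 0.0)))
                lo, hi = m * np.exp(-z * se_log), m * np.exp(z * se_log)
                flagged = False
            else:  # zero-total boundary cell
                lo, hi = 0.0, _CHI2_95_HALF / fit.n_hosts[se]
                flagged = True
            obs_mean = obs_sd = total = np.nan
            if counts is not None:
                sel = counts[(counts["stage"] == st) & (counts["season"] == se)]
                obs_mean = float(sel["count"].mean())
                obs_sd = float(sel["count"].std(ddof=1))
                total = int(sel["count"].sum())
            rows.append({"season": se, "stage": st, "modelled_mean": m,
                         "ci_low": float(lo), "ci_high": float(hi),
                         "observed_mean": obs_mean, "observed_sd": obs_sd,
                         "total": total, "boundary": flagged})
    return pd.DataFrame(rows)
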