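"""Parasitological summaries: prevalence, intensity, composition, peaks.

Conventions follow standard parasitological usage: *prevalence* is the
fraction of examined hosts carrying at least one tick (of a given stage),
*mean intensity* here is the mean number of dropped-off ticks per
examined host.  By default the intensity counts every sampled tick of
both species (I. ricinus and I. hexagonus); a species filter is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .fixtures import STAGES

__all__ = [
    "SummaryReport",
    "summarize",
    "status_fractions",
    "weekly_series",
    "count_peaks",
]


@dataclass
class SummaryReport:
    n_hosts: int
    n_ticks: int
    mean_intensity: float  # ticks per examined host
    prevalence: dict  # stage -> fraction of hosts with >= 1 tick of stage
    prevalence_any: float
    stage_composition: dict  # fractions per stage (I. ricinus)
    species_composition: dict  # fractions per species
    status_props: dict  # stage -> {status: fraction}

    def to_dict(self) -> dict:
        return {
            "n_hosts": self.n_hosts,
            "n_ticks": self.n_ticks,
            "mean_intensity": self.mean_intensity,
            "prevalence": self.prevalence,
            "prevalence_any": self.prevalence_any,
            "stage_composition": self.stage_composition,
            "species_composition": self.species_composition,
            "status_props": self.status_props,
        }


def summarize(records: pd.DataFrame, hosts: pd.DataFrame,
              species: str | None = None) -> SummaryReport:
    """Summary statistics of a tick-drop-off dataset.

    ``species=None`` (default) counts all sampled ticks in the intensity
    and species composition; stage composition and per-stage figures are
    always I. ricinus only, matching how the published totals are broken
    down.
    """
    if hosts.empty:
        raise ValueError("host table must be non-empty")
    unknown = set(records["host_id"]) - set(hosts["host_id"])
    if unknown:
        raise ValueError(f"records reference hosts missing from the host table: "
                         f"{sorted(unknown)[:5]}")
    n_hosts = hosts["host_id"].nunique()
    rec = records if species is None else records[records["species"] == species]

    ric = rec[rec["species"] == "ricinus"] if "species" in rec.columns else rec
    stage_tot = ric.groupby("stage").size()
    n_ric = int(stage_tot.sum())
    prevalence = {}
    for st in STAGES:
        carriers = ric.loc[ric["stage"] == st, "host_id"].nunique()
        prevalence[st] = carriers / n_hosts
    prevalence_any = rec["host_id"].nunique() / n_hosts

    stage_comp = {st: float(stage_tot.get(st, 0)) / n_ric if n_ric else 0.0
                  for st in STAGES}
    if "species" in rec.columns and len(rec):
        sp_tot = rec.groupby("species").size()
        species_comp = {sp: float(n) / len(rec) for sp, n in sp_tot.items()}
    else:
        species_comp = {"ricinus": 1.0} if len(rec) else {}

    status_props = {}
    if "status" in ric.columns:
        for st in STAGES:
            sub = ric[ric["stage"] == st]
            if len(sub) == 0:
                continue
            vc = sub["status"].value_counts()
            status_props[st] = {s: float(n) / len(sub) for s, n in vc.items()}

    return SummaryReport(
        n_hosts=int(n_hosts), n_ticks=int(len(rec)),
        mean_intensity=float(len(rec)) / n_hosts,
        prevalence=prevalence, prevalence_any=float(prevalence_any),
        stage_composition=stage_comp, species_composition=species_comp,
        status_props=status_props)


def status_fractions(counts: dict) -> dict:
    """Condition fractions from published per-stage status counts.

    ``counts`` maps a stage to ``{"total": n, "<status>": m, ...}``;
    returns the same mapping with each status count divided by the total.
    """
    out = {}
    for stage, c in counts.items():
        total = c["total"]
        out[stage] = {k: v / total for k, v in c.items() if k != "total"}
    return out


def weekly_series(records: pd.DataFrame, stage: str | None = None,
                  n_weeks: int | None = None,
                  species: str | None = "ricinus") -> np.ndarray:
    """Dense weekly tick counts (zeros filled) over the study window."""
    rec = records if species is None else records[records["species"] == species]
    if stage is not None:
        rec = rec[rec["stage"] == stage]
    if n_weeks is None:
        n_weeks = int(records["capture_week"].max()) if len(records) else 0
    out = np.zeros(n_weeks, dtype=int)
    if len(rec):
        weeks = rec["capture_week"].astype(int)
        counts = weeks.value_counts()
        for wk, n in counts.items():
            if 1 <= wk <= n_weeks:
                out[wk - 1] = n
    return out


def count_peaks(series, min_prominence: float = 0) -> int:
    """Number of interior activity peaks in a weekly series.

    A peak is a strict local maximum (plateaus count once) whose
    prominence is at least ``min_prominence``; the series endpoints are
    never peaks.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("series must have at least 3 points")
    if min_prominence < 0:
        raise ValueError("min_prominence must be non-negative")
    peaks, _ = find_peaks(series,
                          prominence=min_prominence if min_prominence > 0 else None)
    return int(len(peaks))
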