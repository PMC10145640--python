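"""Published summary tables of the hedgehog–tick field study, as printed.

These are the only data the study released: season-by-stage totals of the
captured hosts and collected ticks, the fitted abundance table, day-binned
drop-off counts, and modelled/observed attachment-time summaries.  They are
bundled so every analysis can be reproduced without network access or the
unpublished per-host records.

The printed tables are not fully consistent with one another (male totals
appear as 75, 76 and 79 in different places; the season totals of nymphs
and larvae differ between tables).  Each table is stored exactly as
printed, and consumers choose the table the corresponding published number
was computed from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STAGES = ("larva", "nymph", "female", "male")
SEASONS = ("spring", "summer", "autumn")

N_HOSTS = 57
HOSTS_BY_SEASON = {"spring": 18, "summer": 27, "autumn": 12}
HEXAGONUS_TOTAL = 31  # I. hexagonus nymphs among all sampled ticks
STUDY_WEEKS = 27

# Season-by-stage I. ricinus totals (seasonality table, as printed;
# ricinus grand total 4714).
SEASON_TOTALS = {
    ("male", "spring"): 49, ("female", "spring"): 213,
    ("nymph", "spring"): 1600, ("larva", "spring"): 300,
    ("male", "summer"): 13, ("female", "summer"): 95,
    ("nymph", "summer"): 804, ("larva", "summer"): 1058,
    ("male", "autumn"): 13, ("female", "autumn"): 67,
    ("nymph", "autumn"): 203, ("larva", "autumn"): 299,
}

# Abundance table: (stage, season) -> (modelled mean/host, CI low, CI high,
# observed mean/host, SD, total ticks).  Saturated Poisson GEE, so
# modelled mean == observed mean == total / hosts-in-season.
ABUNDANCE_TABLE = {
    ("male", "spring"): (2.78, 1.26, 6.14, 2.78, 3.44, 50),
    ("female", "spring"): (12.00, 4.57, 31.49, 12.00, 18.08, 216),
    ("nymph", "spring"): (86.22, 53.78, 138.22, 86.22, 63.55, 1552),
    ("larva", "spring"): (16.89, 7.85, 36.35, 16.89, 20.22, 304),
    ("male", "summer"): (0.52, 0.21, 1.29, 0.52, 0.89, 14),
    ("female", "summer"): (3.81, 2.01, 7.23, 3.81, 4.62, 103),
    ("nymph", "summer"): (31.96, 15.45, 66.12, 31.96, 44.01, 863),
    ("larva", "summer"): (43.85, 25.41, 75.66, 43.85, 45.31, 1184),
    ("male", "autumn"): (1.25, 0.56, 2.77, 1.25, 1.29, 15),
    ("female", "autumn"): (5.08, 2.80, 9.22, 5.08, 3.92, 61),
    ("nymph", "autumn"): (12.33, 6.93, 21.94, 12.33, 9.20, 148),
    ("larva", "autumn"): (15.08, 6.45, 35.29, 15.08, 16.59, 181),
}

# Day-binned drop-off counts: stage -> counts for days 1, 2, 3, ...
# (day d means the tick fell off during the d-th day after capture,
# coded as observed time d - 0.5).
DROPOFF_DAY_COUNTS = {
    "male": [14, 21, 12, 4, 7, 6, 5, 7, 1, 1, 1],
    "female": [17, 55, 47, 46, 52, 47, 41, 31, 15, 18, 2, 2, 4, 2, 1],
    "nymph": [64, 913, 726, 618, 171, 42, 18, 8, 3],
    "larva": [105, 732, 561, 217, 48, 6],
}

# Modelled whole attachment times and experienced (observed) times:
# (stage, season) -> (modelled mean days, CI low, CI high,
#                     experienced mean days, SD, tick abundance).
ATTACHMENT_TIME_TABLE = {
    ("male", "spring"): (7.826, 6.486, 9.442, 3.42, 2.625, 50),
    ("female", "spring"): (10.601, 9.591, 11.718, 5.19, 2.943, 216),
    ("nymph", "spring"): (4.956, 4.567, 5.378, 2.512, 1.257, 1552),
    ("larva", "spring"): (4.586, 3.977, 5.263, 2.717, 1.059, 304),
    ("male", "summer"): (8.749, 7.005, 10.926, 3.071, 3.131, 14),
    ("female", "summer"): (9.044, 8.281, 9.877, 4.267, 2.72, 103),
    ("nymph", "summer"): (4.391, 4.190, 4.601, 2.638, 0.941, 1184),
    ("larva", "summer"): (3.40, 3.207, 3.605, 1.933, 0.784, 863),
    ("male", "autumn"): (6.084, 5.17, 7.16, 3.10, 1.882, 15),
    ("female", "autumn"): (7.665, 6.90, 8.515, 3.992, 2.18, 61),
    ("nymph", "autumn"): (4.826, 4.406, 5.286, 2.75, 1.183, 148),
    ("larva", "autumn"): (4.175, 3.855, 4.522, 2.467, 0.924, 181),
}

# Drop-off condition counts reported in the text: males dead on detachment,
# females with an imperfect (dried/shrunken/dead) blood meal.
STATUS_COUNTS = {
    "male": {"total": 76, "dead": 52},
    "female": {"total": 380, "imperfect": 22},
}
# Subadult "red cuticle" fractions reported in the abstract.
IMPERFECT_FRACTIONS = {"nymph": 0.0156, "larva": 0.114}


def collected_tick_records() -> pd.DataFrame:
    """Expand the season-by-stage totals into one row per tick.

    Host identity and drop-off day are unpublished, so the expansion
    carries only species, stage and season; it supports composition and
    intensity summaries, not model fits.
    """
    rows = []
    for (stage, season), n in SEASON_TOTALS.items():
        rows.extend([("ricinus", stage, season)] * n)
    rows.extend([("hexagonus", "nymph", None)] * HEXAGONUS_TOTAL)
    return pd.DataFrame(rows, columns=["species", "stage", "season"])


def abundance_cells() -> pd.DataFrame:
    """Abundance cell totals with season host counts, one row per cell."""
    rows = [
        (season, stage, ABUNDANCE_TABLE[(stage, season)][5], HOSTS_BY_SEASON[season])
        for season in SEASONS
        for stage in STAGES
    ]
    return pd.DataFrame(rows, columns=["season", "stage", "total", "n_hosts"])


def dropoff_daybins() -> pd.DataFrame:
    """Day-binned drop-off counts, observed time at bin midpoints."""
    rows = []
    for stage, counts in DROPOFF_DAY_COUNTS.items():
        for day, n in enumerate(counts, start=1):
            rows.append((stage, day, day - 0.5, n))
    return pd.DataFrame(rows, columns=["stage", "day_bin", "observed_day", "count"])


def observed_time_means() -> dict:
    """(stage, season) -> printed mean observed attachment time in days."""
    return {cell: vals[3] for cell, vals in ATTACHMENT_TIME_TABLE.items()}


def default_capture_schedule() -> list:
    """Per-host (capture week, season) pairs matching the study layout.

    57 hosts over 27 weekly captures, April through mid-October: two per
    week with three three-host weeks, giving 18 spring, 27 summer and 12
    autumn hosts.  Spring = weeks 1-9, summer = weeks 10-22, autumn =
    weeks 23-27.
    """
    def season_of(week: int) -> str:
        if week <= 9:
            return "spring"
        if week <= 22:
            return "summer"
        return "autumn"

    schedule = []
    triple_weeks = {15, 24, 26}
    for week in range(1, STUDY_WEEKS + 1):
        n = 3 if week in triple_weeks else 2
        schedule.extend([(week, season_of(week))] * n)
    counts = {s: sum(1 for _, ss in schedule if ss == s) for s in SEASONS}
    assert counts == HOSTS_BY_SEASON and len(schedule) == N_HOSTS
    return schedule


def allocate_cell_totals(cells: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Spread published cell totals over synthetic hosts.

    The saturated marginal Poisson model's fitted cell means depend only on
    the totals and host counts, so any allocation reproduces them; a seeded
    random allocation (or the even deterministic one when ``seed`` is
    None) is provided for fitting the published tables without per-host
    data.  Returns a host-by-cell count table with columns
    host_id, season, stage, count.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    rows = []
    host_offset = 0
    for season, grp in cells.groupby("season", sort=False):
        n_hosts = int(grp["n_hosts"].iloc[0])
        hosts = [f"H{host_offset + i:03d}" for i in range(n_hosts)]
        for _, rec in grp.iterrows():
            total = int(rec["total"])
            if rng is None:
                base, extra = divmod(total, n_hosts)
                counts = np.full(n_hosts, base, dtype=int)
                counts[:extra] += 1
            else:
                counts = rng.multinomial(total, np.full(n_hosts, 1.0 / n_hosts))
            for h, c in zip(hosts, counts):
                rows.append((h, season, rec["stage"], int(c)))
        host_offset += n_hosts
    return pd.DataFrame(rows, columns=["host_id", "season", "stage", "count"])
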