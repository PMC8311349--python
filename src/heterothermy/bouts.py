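"""Torpor-bout detection and hibernation summary statistics.

Hourly body-temperature records are labelled euthermic/torpid, maximal runs
of equal labels become bouts (torpor or interbout euthermy, IBE), and the
per-individual hibernation parameters — season duration, bout counts and
durations, minimal T_B — are summarised alongside weekly/monthly torpor
incidence for a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationRule",
    "HibernationSummary",
    "classify_states",
    "segment_bouts",
    "summarize_hibernation",
    "cohort_summary",
    "torpor_incidence",
]

BOUT_COLUMNS = ["id", "kind", "start", "end", "duration_h", "min_tb_c"]


@dataclass(frozen=True)
class ClassificationRule:
    """Operational torpor criterion.

    ``relative`` mode (default): torpid iff T_B falls below
    ``min(ceiling_c, rolling euthermic median - delta_c)``, where the
    rolling median is taken over readings at or above the ceiling within
    ``window_h`` hours.  The margin ``delta_c`` is wide enough that normal
    euthermic variation (a few °C) never triggers false bouts.
    ``absolute`` mode uses ``absolute_threshold_c`` alone, for
    comparability with fixed-threshold studies.
    """

    mode: str = "relative"
    ceiling_c: float = 30.0
    delta_c: float = 5.0
    window_h: float = 168.0
    absolute_threshold_c: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError("mode must be 'relative' or 'absolute'")
        if self.delta_c < 0 or self.window_h <= 0:
            raise ValueError("delta_c >= 0 and window_h > 0 required")


def classify_states(
    records: pd.DataFrame, rule: ClassificationRule = ClassificationRule()
) -> pd.DataFrame:
    """Label each record euthermic / torpid / missing.

    ``records`` needs ``timestamp`` and ``t_b`` columns sorted by time for a
    single individual.  Missing T_B yields the label ``missing``.
    Returns a frame with ``timestamp, t_b, label, threshold``.
    """
    if records.empty or records["t_b"].isna().all():
        raise ValueError("cannot classify an all-missing body-temperature series")
    ts = pd.DatetimeIndex(records["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("records must be sorted by timestamp")
    t_b = records["t_b"].to_numpy(dtype=float)

    if rule.mode == "absolute":
        threshold = np.full(len(t_b), rule.absolute_threshold_c)
    else:
        euth = pd.Series(np.where(t_b >= rule.ceiling_c, t_b, np.nan), index=ts)
        med = euth.rolling(
            pd.Timedelta(hours=rule.window_h), min_periods=1
        ).median()
        med = med.ffill().bfill()
        threshold = np.minimum(rule.ceiling_c, med.to_numpy() - rule.delta_c)
        threshold = np.where(np.isnan(threshold), rule.ceiling_c, threshold)

    label = np.where(np.isnan(t_b), "missing", np.where(t_b < threshold, "torpid", "euthermic"))
    return pd.DataFrame(
        {"timestamp": ts, "t_b": t_b, "label": label, "threshold": threshold}
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of identical labels as (start_idx, stop_idx_excl, label)."""
    out = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((i, j, labels[i]))
        i = j
    return out


def segment_bouts(
    states: pd.DataFrame,
    min_torpor_h: float = 1.0,
    min_ibe_h: float = 1.0,
    max_gap_h: float = 2.0,
    individual_id: str = "",
) -> pd.DataFrame:
    """Segment a labelled series into alternating torpor / IBE bouts.

    Missing gaps no longer than ``max_gap_h`` whose flanks agree inherit
    the flanking label; longer (or disagreeing) gaps split the record.
    Runs shorter than the per-kind minimum that sit between two runs of the
    opposite label are absorbed into them.  Durations count one cadence
    interval per sample; the bout boundary is the first sample of the new
    state.  Returns a frame with columns ``id, kind, start, end,
    duration_h, min_tb_c``.
    """
    ts = pd.DatetimeIndex(states["timestamp"])
    labels = states["label"].to_numpy(dtype=object).copy()
    t_b = states["t_b"].to_numpy(dtype=float)
    if len(ts) == 0:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    if len(ts) > 1:
        cadence_h = float(pd.Series(ts).diff().median() / pd.Timedelta(hours=1))
    else:
        cadence_h = 1.0

    # bridge short missing gaps with agreeing flanks
    for i0, i1, lab in _runs(labels):
        if lab != "missing":
            continue
        gap_h = (i1 - i0) * cadence_h
        if gap_h <= max_gap_h and i0 > 0 and i1 < len(labels):
            left, right = labels[i0 - 1], labels[i1]
            if left == right and left != "missing":
                labels[i0:i1] = left

    # absorb sub-minimum runs sandwiched between opposite-label runs
    min_len = {
        "torpid": max(int(np.ceil(min_torpor_h / cadence_h)), 1),
        "euthermic": max(int(np.ceil(min_ibe_h / cadence_h)), 1),
    }
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        for k, (i0, i1, lab) in enumerate(runs):
            if lab == "missing" or (i1 - i0) >= min_len[lab]:
                continue
            left = runs[k - 1][2] if k > 0 else None
            right = runs[k + 1][2] if k + 1 < len(runs) else None
            if left is not None and left == right and left != "missing":
                labels[i0:i1] = left
                changed = True
                break

    rows = []
    for i0, i1, lab in _runs(labels):
        if lab == "missing":
            continue
        kind = "torpor" if lab == "torpid" else "ibe"
        dur = (i1 - i0) * cadence_h
        seg_tb = t_b[i0:i1]
        rows.append(
            {
                "id": individual_id,
                "kind": kind,
                "start": ts[i0],
                "end": ts[i0] + pd.Timedelta(hours=dur),
                "duration_h": dur,
                "min_tb_c": float(np.nanmin(seg_tb)) if kind == "torpor" and len(seg_tb) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


@dataclass(frozen=True)
class HibernationSummary:
    """Per-individual hibernation parameters (season, bouts, IBE, min T_B)."""

    individual_id: str
    season_duration_h: float
    n_torpor_bouts: int
    mean_bout_h: float
    max_bout_h: float
    min_bout_h: float
    mean_ibe_h: float
    max_ibe_h: float
    min_ibe_h: float
    minimal_t_b: float

    def as_dict(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "season_duration_h": self.season_duration_h,
            "n_torpor_bouts": self.n_torpor_bouts,
            "mean_bout_h": self.mean_bout_h,
            "max_bout_h": self.max_bout_h,
            "min_bout_h": self.min_bout_h,
            "mean_ibe_h": self.mean_ibe_h,
            "max_ibe_h": self.max_ibe_h,
            "min_ibe_h": self.min_ibe_h,
            "minimal_t_b": self.minimal_t_b,
        }


def summarize_hibernation(
    bouts: pd.DataFrame, states: pd.DataFrame, individual_id: str = ""
) -> HibernationSummary:
    """Hibernation parameters for one individual.

    The hibernation season spans the first torpid sample to the end of the
    last torpor bout; IBE statistics use only euthermic intervals strictly
    between torpor bouts.  Zero torpor bouts yields an all-NaN summary with
    ``n_torpor_bouts = 0`` rather than an error.
    """
    if states.empty:
        raise ValueError("empty record span")
    torpor = bouts.loc[bouts["kind"] == "torpor"]
    if torpor.empty:
        return HibernationSummary(
            individual_id, np.nan, 0, *([np.nan] * 7)
        )
    season_start = torpor["start"].min()
    season_end = torpor["end"].max()
    ibe = bouts.loc[
        (bouts["kind"] == "ibe")
        & (bouts["start"] >= season_start)
        & (bouts["end"] <= season_end)
    ]
    torpid_tb = states.loc[states["label"] == "torpid", "t_b"]
    return HibernationSummary(
        individual_id=individual_id,
        season_duration_h=float((season_end - season_start) / pd.Timedelta(hours=1)),
        n_torpor_bouts=int(len(torpor)),
        mean_bout_h=float(torpor["duration_h"].mean()),
        max_bout_h=float(torpor["duration_h"].max()),
        min_bout_h=float(torpor["duration_h"].min()),
        mean_ibe_h=float(ibe["duration_h"].mean()) if len(ibe) else np.nan,
        max_ibe_h=float(ibe["duration_h"].max()) if len(ibe) else np.nan,
        min_ibe_h=float(ibe["duration_h"].min()) if len(ibe) else np.nan,
        minimal_t_b=float(torpid_tb.min()) if len(torpid_tb) else np.nan,
    )


def cohort_summary(summaries: list[HibernationSummary]) -> pd.DataFrame:
    """Across-individual mean ± SE of the five hibernation parameters."""
    frame = pd.DataFrame([s.as_dict() for s in summaries]).set_index("individual_id")
    rows = {
        "hibernation_duration_h": frame["season_duration_h"],
        "n_torpor_bouts": frame["n_torpor_bouts"].astype(float),
        "torpor_bout_duration_h": frame["mean_bout_h"],
        "ibe_duration_h": frame["mean_ibe_h"],
        "minimal_t_b_c": frame["minimal_t_b"],
    }
    out = []
    for name, col in rows.items():
        vals = col.dropna()
        n = len(vals)
        out.append(
            {
                "parameter": name,
                "mean": float(vals.mean()) if n else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "max": float(vals.max()) if n else np.nan,
                "min": float(vals.min()) if n else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(out)


def torpor_incidence(
    states_by_individual: Mapping[str, pd.DataFrame],
    period: str = "week",
    census_hour: int = 12,
) -> pd.DataFrame:
    """Percentage of the cohort found torpid at one census per period.

    Mirrors spot-check field visits: an individual counts as torpid in a
    period iff its label at the census sample (``census_hour`` on the
    period's first day) is torpid.  Individuals without a sample at the
    census are excluded from that period's denominator.
    """
    if period not in ("week", "month"):
        raise ValueError("period must be 'week' or 'month'")
    if not states_by_individual:
        raise ValueError("need at least one individual")

    starts = [pd.DatetimeIndex(df["timestamp"]).min() for df in states_by_individual.values()]
    ends = [pd.DatetimeIndex(df["timestamp"]).max() for df in states_by_individual.values()]
    t0, t1 = min(starts).normalize(), max(ends).normalize()

    if period == "week":
        period_starts = pd.date_range(t0, t1, freq="7D")
    else:
        period_starts = pd.date_range(t0.replace(day=1), t1, freq="MS")

    lookup = {
        ind: df.set_index(pd.DatetimeIndex(df["timestamp"]))["label"]
        for ind, df in states_by_individual.items()
    }
    rows = []
    for p_start in period_starts:
        census = p_start + pd.Timedelta(hours=census_hour)
        n_total = 0
        n_torpid = 0
        for labels in lookup.values():
            lab = labels.get(census)
            if lab is None or lab == "missing":
                continue
            n_total += 1
            n_torpid += int(lab == "torpid")
        rows.append(
            {
                "period_start": p_start,
                "n_torpid": n_torpid,
                "n_total": n_total,
                "incidence_pct": 100.0 * n_torpid / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)
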