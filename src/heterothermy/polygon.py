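"""Thermoregulatory-polygon analysis: T_Bmin and Newton-model RMR.

A torpid thermoconformer keeps a small, roughly constant differential
T_DIFF = T_B − T_A; once T_A falls below the critical region the animal
defends a floor T_B, so T_DIFF rises one-for-one as T_A drops (slope ≈ −1
in the T_DIFF-vs-T_A plane).  The lower-left edge of that plane therefore
identifies torpor thermoregulation, and the defended body temperature
(T_Bmin) is the mean of T_DIFF + T_A over the edge points.  Resting
metabolic rate is reconstructed from Newton's passive-cooling model,
RMR = C_min · M_B · (T_B − T_A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "C_MIN_DEFAULT",
    "EdgePointSet",
    "TbminEstimate",
    "ThermoregRegression",
    "thermal_differential",
    "select_edge_points",
    "estimate_tbmin",
    "rmr_from_newton",
    "thermoreg_regression",
]

C_MIN_DEFAULT = 3.4848  # J g^-1 °C^-1 h^-1


def thermal_differential(records: pd.DataFrame) -> pd.DataFrame:
    """Attach (or refresh) the ``t_diff = t_b - t_a`` column; idempotent."""
    out = records.copy()
    out["t_diff"] = out["t_b"] - out["t_a"]
    return out


@dataclass(frozen=True)
class EdgePointSet:
    """Torpid (T_A, T_DIFF) points selected on the bottom-left edge."""

    individual_id: str
    points: pd.DataFrame  # columns t_a, t_diff
    bin_width: float
    quantile: float
    band_c: float
    bins: tuple[int, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TbminEstimate:
    """Edge-point regression and the derived defended torpid T_B."""

    individual_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    t_bmin: float
    defended_t_b_sd: float


@dataclass(frozen=True)
class ThermoregRegression:
    """OLS of Newton-model total RMR (kJ/h) on T_A during torpor defence."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r_squared: float
    n: int
    pooled: bool


def select_edge_points(
    records: pd.DataFrame,
    torpid: np.ndarray | pd.Series,
    individual_id: str = "",
    bin_width: float = 1.0,
    quantile: float = 0.05,
    band_c: float = 1.0,
    slope_window_bins: int = 3,
    slope_gate: float = -0.7,
    min_bin_count: int = 3,
) -> EdgePointSet:
    """Select the bottom-left edge of the torpid T_DIFF-vs-T_A cloud.

    Torpid points are binned by T_A (``bin_width``); within each bin the
    ``quantile`` of T_DIFF locates the lower edge and points within
    ``band_c`` above it are kept, so the retained defended-floor cluster is
    roughly symmetric about the true floor rather than a truncated lower
    tail.  A rolling OLS over ``slope_window_bins`` consecutive bins gates
    on slope ≤ ``slope_gate`` (the inverse-proportionality signature of
    thermoregulation), and only the maximal contiguous low-T_A range of
    gated bins is returned.  An empty set with a warning means the animal
    never thermoregulated in torpor.
    """
    records = thermal_differential(records)
    mask = np.asarray(torpid, dtype=bool)
    pts = records.loc[mask, ["t_a", "t_diff"]].dropna()
    if len(pts) < 20:
        raise ValueError(f"need >= 20 torpid samples, got {len(pts)}")

    bin_idx = np.floor(pts["t_a"].to_numpy() / bin_width).astype(int)
    kept_parts: dict[int, pd.DataFrame] = {}
    for b in np.unique(bin_idx):
        sub = pts.loc[bin_idx == b]
        if len(sub) < min_bin_count:
            continue
        v_q = float(sub["t_diff"].quantile(quantile))
        kept = sub.loc[sub["t_diff"] <= v_q + band_c]
        if len(kept):
            kept_parts[int(b)] = kept

    ordered = sorted(kept_parts)
    gated: set[int] = set()
    w = max(slope_window_bins, 2)
    for s in range(len(ordered) - w + 1):
        window = ordered[s : s + w]
        if window[-1] - window[0] != w - 1:  # bins must be contiguous
            continue
        wpts = pd.concat([kept_parts[b] for b in window])
        if wpts["t_a"].nunique() < 2:
            continue
        slope = float(
            stats.linregress(wpts["t_a"].to_numpy(), wpts["t_diff"].to_numpy()).slope
        )
        if slope <= slope_gate:
            gated.update(window)

    if not gated:
        warnings.warn(
            f"individual {individual_id!r}: no T_A range with slope <= "
            f"{slope_gate}; animal appears never to thermoregulate in torpor",
            stacklevel=2,
        )
        empty = pd.DataFrame(columns=["t_a", "t_diff"])
        return EdgePointSet(individual_id, empty, bin_width, quantile, band_c)

    # maximal contiguous run containing the lowest gated bin
    low = min(gated)
    run = [low]
    while run[-1] + 1 in gated:
        run.append(run[-1] + 1)
    # the topmost bin straddles the critical ambient region where defended
    # and conforming differentials overlap; keep points strictly below it
    if len(run) > 2:
        run = run[:-1]
    # original record index preserved so callers can join back (e.g. to m_b)
    selected = pd.concat([kept_parts[b] for b in run]).sort_index()
    return EdgePointSet(
        individual_id, selected, bin_width, quantile, band_c, bins=tuple(run)
    )


def estimate_tbmin(edge: EdgePointSet) -> TbminEstimate:
    """Regress T_DIFF on T_A over the edge points and derive T_Bmin.

    T_Bmin is reported as the mean defended body temperature
    (T_DIFF + T_A) over the edge points; with a slope of exactly −1 this
    coincides with the regression intercept, and it remains unbiased when
    the fitted slope wanders slightly from −1.
    """
    pts = edge.points
    if len(pts) < 5:
        raise ValueError(
            f"need >= 5 edge points (got {len(pts)}); widen the selection "
            "(larger band_c or quantile) or check that the animal thermoregulated"
        )
    span = float(pts["t_a"].max() - pts["t_a"].min())
    if span < 2.0:
        raise ValueError(
            f"edge points span only {span:.2f} °C of T_A (< 2 °C); widen the selection"
        )
    res = stats.linregress(pts["t_a"].to_numpy(), pts["t_diff"].to_numpy())
    slope = float(res.slope)
    if not (-1.3 <= slope <= -0.7):
        warnings.warn(
            f"edge slope {slope:.2f} outside [-1.3, -0.7]; selection may include "
            "conforming points",
            stacklevel=2,
        )
    defended = pts["t_diff"].to_numpy() + pts["t_a"].to_numpy()
    return TbminEstimate(
        individual_id=edge.individual_id,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pts),
        t_bmin=float(defended.mean()),
        defended_t_b_sd=float(defended.std(ddof=1)),
    )


def rmr_from_newton(t_b, t_a, m_b, c_min: float = C_MIN_DEFAULT) -> pd.DataFrame:
    """Newton passive-cooling RMR: ``C_min * M_B * (T_B - T_A)``.

    Returns a frame with the mass-specific rate (J g⁻¹ h⁻¹), the total rate
    (kJ h⁻¹), the inputs, and a flag for negative differentials (T_B below
    T_A, possible during rewarming lags or sensor disagreement).
    """
    t_b = np.atleast_1d(np.asarray(t_b, dtype=float))
    t_a = np.atleast_1d(np.asarray(t_a, dtype=float))
    m_b = np.broadcast_to(np.atleast_1d(np.asarray(m_b, dtype=float)), t_b.shape)
    if np.any(m_b <= 0):
        raise ValueError("body mass must be positive")
    diff = t_b - t_a
    mass_specific = c_min * diff
    return pd.DataFrame(
        {
            "t_b": t_b,
            "t_a": t_a,
            "m_b": m_b,
            "c_min": c_min,
            "rmr_mass_specific": mass_specific,
            "rmr_total_kj_h": mass_specific * m_b / 1000.0,
            "negative_differential": diff < 0,
        }
    )


def thermoreg_regression(
    t_b, t_a, m_b, c_min: float = C_MIN_DEFAULT, pooled: bool = False
) -> ThermoregRegression:
    """Torpor-thermoregulation regression: total RMR (kJ/h) against T_A.

    For an individual defending an exactly constant torpid T_B the fit is
    analytic: slope = −C_min·M_B and intercept = C_min·M_B·T_B (in kJ).
    ``pooled=True`` marks a fit over concatenated individuals (pass
    per-record masses).
    """
    rmr = rmr_from_newton(t_b, t_a, m_b, c_min)
    if len(rmr) < 5:
        raise ValueError(f"need >= 5 points for the regression, got {len(rmr)}")
    x = rmr["t_a"].to_numpy()
    y = rmr["rmr_total_kj_h"].to_numpy()
    res = stats.linregress(x, y)
    return ThermoregRegression(
        intercept=float(res.intercept),
        slope=float(res.slope),
        intercept_se=float(res.intercept_stderr),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n=len(rmr),
        pooled=pooled,
    )
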