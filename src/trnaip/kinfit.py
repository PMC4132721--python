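"""Per-position kinetic traces, single-exponential fits and significance profiles.

Turns a time-course band dataset into fraction-unwound traces
``F = I(S1) / (I(S1) + I(S2))`` per modified position, fits each trace with
``F(t) = A * (1 - exp(-k t))``, and classifies amplitude/rate deviations from
a control distribution in SD units.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import CONTROL_POSITION, GelDataset

__all__ = [
    "KineticTrace",
    "ExpFit",
    "LagResult",
    "ControlStats",
    "fraction_unwound",
    "control_trace",
    "fit_single_exponential",
    "detect_lag",
    "control_statistics",
    "classify_positions",
]

log = logging.getLogger(__name__)

#: Fits with A below this are amplitude-dead: k is unidentifiable.
AMPLITUDE_FLOOR = 0.01

LABELS = ("indistinguishable", "slight", "favorable", "detrimental")


@dataclass(frozen=True)
class KineticTrace:
    """Fraction-unwound time course for one modified position.

    Masked points (zero or sub-floor total intensity) are NaN, never zero.
    """

    position: int
    times: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.F, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times and F must have the same length")
        valid = ~np.isnan(f)
        if np.any((f[valid] < 0) | (f[valid] > 1)):
            raise ValueError("F values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "F", f)

    @property
    def n_valid(self) -> int:
        return int((~np.isnan(self.F)).sum())

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~np.isnan(self.F)
        return self.times[keep], self.F[keep]


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential fit result for one trace."""

    A: float
    k: float
    A_se: float
    k_se: float
    rss: float
    n_points: int
    converged: bool
    low_confidence: bool
    message: str = ""


@dataclass(frozen=True)
class LagResult:
    """Model comparison between immediate and lagged single-step kinetics."""

    preferred: str  # "single", "lag", or "undecidable"
    delta_aic: float  # AIC(lag) - AIC(single); positive favours single
    undecidable: bool = False


@dataclass(frozen=True)
class ControlStats:
    """Replicate statistics of the control amplitude and rate."""

    A_mean: float
    A_sd: float
    k_mean: float
    k_sd: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {
            "A_mean": self.A_mean,
            "A_sd": self.A_sd,
            "k_mean": self.k_mean,
            "k_sd": self.k_sd,
            "n_replicates": self.n_replicates,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ControlStats":
        return cls(
            A_mean=float(d["A_mean"]),
            A_sd=float(d["A_sd"]),
            k_mean=float(d["k_mean"]),
            k_sd=float(d["k_sd"]),
            n_replicates=int(d["n_replicates"]),
        )


def _traces_from_pivot(
    pivot_s1: pd.DataFrame, pivot_s2: pd.DataFrame, min_total: float
) -> list[KineticTrace]:
    times = pivot_s1.columns.to_numpy(dtype=float)
    traces = []
    n_masked = 0
    for pos in pivot_s1.index:
        s1 = pivot_s1.loc[pos].to_numpy(dtype=float)
        s2 = pivot_s2.loc[pos].to_numpy(dtype=float)
        total = s1 + s2
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(total > min_total, s1 / total, np.nan)
        n_masked += int(np.isnan(f).sum())
        f = np.clip(f, 0.0, 1.0)
        f[np.isnan(s1 + s2)] = np.nan
        traces.append(KineticTrace(position=int(pos), times=times, F=f))
    if n_masked:
        log.info("masked %d trace points with total intensity <= %g", n_masked, min_total)
    return traces


def fraction_unwound(
    dataset: GelDataset,
    min_total: float = 0.0,
    window: tuple[int, int] | None = None,
) -> list[KineticTrace]:
    """Compute F = S1/(S1+S2) per position and time.

    Points whose total intensity does not exceed ``min_total`` are masked
    (NaN) with a warning count logged.  ``window`` restricts positions to the
    inclusive range (start, end); the control readout row is always excluded.
    """
    df = dataset.frame[dataset.frame["position"] != CONTROL_POSITION]
    if window is not None:
        lo, hi = window
        if lo > hi:
            raise ValueError(f"window start {lo} exceeds end {hi}")
        df = df[(df["position"] >= lo) & (df["position"] <= hi)]
    pivots = {}
    for fraction in ("S1", "S2"):
        sub = df[df["fraction"] == fraction]
        pivots[fraction] = sub.pivot_table(
            index="position", columns="time_s", values="intensity", aggfunc="sum"
        ).sort_index()
    s1, s2 = pivots["S1"], pivots["S2"]
    if not s1.index.equals(s2.index) or not s1.columns.equals(s2.columns):
        raise ValueError("S1 and S2 fractions do not cover the same (time, position) grid")
    return _traces_from_pivot(s1, s2, min_total)


def control_trace(dataset: GelDataset, min_total: float = 0.0) -> KineticTrace:
    """Total-RNA control trace from the reserved control readout rows."""
    df = dataset.frame[dataset.frame["position"] == CONTROL_POSITION]
    if df.empty:
        raise ValueError("dataset carries no control readout rows")
    piv = {
        fr: df[df["fraction"] == fr].set_index("time_s")["intensity"].sort_index()
        for fr in ("S1", "S2")
    }
    times = piv["S1"].index.to_numpy(dtype=float)
    s1 = piv["S1"].to_numpy(dtype=float)
    s2 = piv["S2"].reindex(piv["S1"].index).to_numpy(dtype=float)
    total = s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > min_total, s1 / total, np.nan)
    return KineticTrace(position=CONTROL_POSITION, times=times, F=np.clip(f, 0, 1))


def _single_exp(t: np.ndarray, A: float, k: float) -> np.ndarray:
    return A * (1.0 - np.exp(-k * t))


def _lagged_exp(t: np.ndarray, A: float, k: float) -> np.ndarray:
    # two equal-rate sequential steps: sigmoidal onset with zero initial slope
    return A * (1.0 - (1.0 + k * t) * np.exp(-k * t))


def _init_guess(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    a0 = float(np.nanmax(f))
    a0 = min(max(a0, 1e-3), 1.2)
    above = t[f >= 0.5 * a0]
    t_half = float(above[0]) if above.size else float(t[-1])
    t_half = max(t_half, float(t[t > 0][0]) if np.any(t > 0) else 1.0)
    return a0, math.log(2.0) / t_half


def fit_single_exponential(trace: KineticTrace) -> ExpFit:
    """Unweighted least-squares fit of ``F(t) = A (1 - exp(-k t))``.

    Initialisation: A0 = max observed F; k0 = ln 2 / t_half.  Bounds
    A in [0, 1.2], k > 0.  Degenerate traces (fewer than 4 unmasked points,
    or no signal above the amplitude floor) are flagged low-confidence rather
    than silently propagating NaN.
    """
    t, f = trace.valid_points()
    n = t.size
    if n < 2:
        return ExpFit(
            A=float("nan"), k=float("nan"), A_se=float("nan"), k_se=float("nan"),
            rss=float("nan"), n_points=n, converged=False, low_confidence=True,
            message="fewer than 2 unmasked points",
        )
    if float(np.max(f)) < AMPLITUDE_FLOOR:
        return ExpFit(
            A=0.0, k=float("nan"), A_se=float("nan"), k_se=float("nan"),
            rss=float(np.sum(f**2)), n_points=n, converged=False,
            low_confidence=True, message="no signal above amplitude floor; k unidentifiable",
        )
    a0, k0 = _init_guess(t, f)
    try:
        popt, pcov = curve_fit(
            _single_exp, t, f, p0=[a0, k0],
            bounds=([0.0, 1e-12], [1.2, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        return ExpFit(
            A=float("nan"), k=float("nan"), A_se=float("nan"), k_se=float("nan"),
            rss=float("nan"), n_points=n, converged=False, low_confidence=True,
            message=f"fit failed to converge: {exc}",
        )
    A, k = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    rss = float(np.sum((f - _single_exp(t, A, k)) ** 2))
    low_conf = n < 4 or k * float(t.max()) < 1.0  # no plateau reached
    msg = "" if not low_conf else "sparse or plateau-free sampling"
    return ExpFit(
        A=A, k=k, A_se=float(perr[0]), k_se=float(perr[1]),
        rss=rss, n_points=n, converged=True, low_confidence=low_conf, message=msg,
    )


def detect_lag(trace: KineticTrace) -> LagResult:
    """Compare the immediate exponential against a lagged (sigmoidal) onset.

    Both candidate models have two parameters, so the AIC difference reduces
    to a residual-sum-of-squares comparison; positive ``delta_aic`` favours
    the immediate single exponential (no detectable lag).
    """
    t, f = trace.valid_points()
    if t.size < 4 or float(np.max(f)) < AMPLITUDE_FLOOR:
        return LagResult(preferred="undecidable", delta_aic=float("nan"), undecidable=True)
    a0, k0 = _init_guess(t, f)
    rss = {}
    for name, model in (("single", _single_exp), ("lag", _lagged_exp)):
        try:
            popt, _ = curve_fit(
                model, t, f, p0=[a0, k0],
                bounds=([0.0, 1e-12], [1.2, np.inf]), maxfev=10000,
            )
            rss[name] = float(np.sum((f - model(t, *popt)) ** 2))
        except RuntimeError:
            rss[name] = float("inf")
    n = t.size
    p = 2
    aic = {name: n * math.log(max(r, 1e-300) / n) + 2 * p for name, r in rss.items()}
    delta = aic["lag"] - aic["single"]
    if not math.isfinite(delta):
        return LagResult(preferred="undecidable", delta_aic=float("nan"), undecidable=True)
    return LagResult(preferred="single" if delta >= 0 else "lag", delta_aic=delta)


def control_statistics(fits: Sequence[ExpFit]) -> ControlStats:
    """Mean and SD of amplitude and rate across control replicates."""
    if len(fits) < 2:
        raise ValueError("control statistics require at least 2 replicate fits")
    A = np.array([f.A for f in fits], dtype=float)
    k = np.array([f.k for f in fits], dtype=float)
    return ControlStats(
        A_mean=float(A.mean()), A_sd=float(A.std(ddof=1)),
        k_mean=float(k.mean()), k_sd=float(k.std(ddof=1)),
        n_replicates=len(fits),
    )


def _band(z: float, inner: float, outer: float) -> str:
    az = abs(z)
    if not math.isfinite(az):
        return "masked"
    if az <= inner:
        return "within_1sd"
    if az <= outer:
        return "within_2.5sd"
    return "outside"


def classify_positions(
    fits: Mapping[int, ExpFit],
    control: ControlStats,
    inner_sd: float = 1.0,
    outer_sd: float = 2.5,
) -> pd.DataFrame:
    """Z-score each position's (A, k) against the control distribution.

    Label is driven by the amplitude z-score: ``detrimental`` below
    -``outer_sd``, ``favorable`` above +``outer_sd``, ``slight`` between the
    inner and outer bands, ``indistinguishable`` inside the inner band.  The
    rate is flagged independently.
    """
    if not control.A_sd > 0 or not control.k_sd > 0:
        raise ValueError(
            "control SDs are zero; classification needs >= 2 distinct replicates"
        )
    rows = []
    for pos in sorted(fits):
        fit = fits[pos]
        zA = (fit.A - control.A_mean) / control.A_sd
        zk = (fit.k - control.k_mean) / control.k_sd
        if not math.isfinite(zA):
            label = "unclassified"
        elif abs(zA) <= inner_sd:
            label = "indistinguishable"
        elif abs(zA) <= outer_sd:
            label = "slight"
        elif zA > outer_sd:
            label = "favorable"
        else:
            label = "detrimental"
        rows.append(
            {
                "position": pos,
                "A": fit.A, "A_se": fit.A_se,
                "k": fit.k, "k_se": fit.k_se,
                "zA": zA, "zk": zk,
                "band_A": _band(zA, inner_sd, outer_sd),
                "band_k": _band(zk, inner_sd, outer_sd),
                "label": label,
                "converged": fit.converged,
                "low_confidence": fit.low_confidence,
            }
        )
    n_bad = sum(1 for f in fits.values() if not f.converged)
    if n_bad:
        log.info("%d position fits did not converge", n_bad)
    return pd.DataFrame(rows)
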