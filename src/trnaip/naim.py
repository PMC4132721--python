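"""Endpoint interference statistics: band ratios, normalized factors, periodicity.

Per-position selection ratios (kappa) compare a functionally selected pool
against the input pool after lane-total normalization.  Normalized
interference factors (lambda) are robust z-scores of log2 kappa, so under a
pure-noise profile lambda is approximately standard normal: |lambda| > 2.5
falls outside the two-sided 98.8% interval.  Positive lambda marks depletion
from the selected pool (detrimental); negative marks enrichment (favorable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "InterferenceProfile",
    "CumulativeCurve",
    "Cluster",
    "AutocorrResult",
    "two_sided_coverage_percent",
    "kappa_from_selection",
    "lambda_normalize",
    "cumulative_curve",
    "find_clusters",
    "interference_autocorrelation",
]

log = logging.getLogger(__name__)

#: Robust-scale consistency constant for the normal distribution (1 / Phi^-1(3/4)).
MAD_TO_SD = 1.4826022185056018

DEFAULT_LAMBDA_THRESHOLD = 2.5
DEFAULT_KAPPA_CEILING = 64.0


def two_sided_coverage_percent(z: float, decimals: int = 1) -> float:
    """Coverage of |Z| <= z under a standard normal, in percent.

    z = 2.5 gives 98.8 and z = 1 gives 68.3 — the confidence bands quoted for
    the significance thresholds used throughout this package.
    """
    return round(100.0 * (2.0 * norm.cdf(z) - 1.0), decimals)


@dataclass(frozen=True)
class InterferenceProfile:
    """Per-position normalized interference factors with significance calls."""

    positions: np.ndarray
    kappa: np.ndarray
    lam: np.ndarray
    flagged: np.ndarray
    capped: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        for name in ("kappa", "lam"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != pos.shape:
                raise ValueError(f"{name} length does not match positions")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "flagged", np.asarray(self.flagged, dtype=bool))
        object.__setattr__(self, "capped", np.asarray(self.capped, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "kappa": self.kappa,
                "lambda": self.lam,
                "flagged": self.flagged,
                "capped": self.capped,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, threshold: float = DEFAULT_LAMBDA_THRESHOLD
    ) -> "InterferenceProfile":
        return cls(
            positions=df["position"].to_numpy(),
            kappa=df["kappa"].to_numpy(),
            lam=df["lambda"].to_numpy(),
            flagged=df["flagged"].to_numpy() if "flagged" in df else df["lambda"].abs().to_numpy() > threshold,
            capped=df["capped"].to_numpy() if "capped" in df else np.zeros(len(df), bool),
            threshold=threshold,
        )


@dataclass(frozen=True)
class CumulativeCurve:
    """Running sum of detrimental interference along the track."""

    positions: np.ndarray
    cumulative: np.ndarray


@dataclass(frozen=True)
class Cluster:
    start: int
    end: int
    center: int
    peak: float


@dataclass(frozen=True)
class AutocorrResult:
    """Autocorrelation of the interference profile and its step-size call."""

    lags: np.ndarray
    acf: np.ndarray
    step_size: int | None
    peak_value: float
    significant: bool
    threshold: float
    message: str = ""


def _normalized_share(table: pd.Series) -> pd.Series:
    total = float(table.sum())
    if not total > 0:
        raise ValueError("band table has non-positive lane total")
    return table / total


def kappa_from_selection(
    selected: pd.Series,
    unselected: pd.Series,
    parent_selected: pd.Series | None = None,
    parent_unselected: pd.Series | None = None,
    ceiling: float = DEFAULT_KAPPA_CEILING,
) -> pd.DataFrame:
    """Raw per-position selection ratios.

    kappa_i = (unselected share at i) / (selected share at i), with shares
    normalized by lane totals; kappa > 1 means depletion from the selected
    (unwound) pool.  When parent-tag tables are supplied, the same ratio of
    the parent library divides out tag-only effects.  Zero selected-pool
    bands yield a capped kappa with a flag.
    """
    if not selected.index.equals(unselected.index):
        raise ValueError("selected and unselected tables cover different positions")
    sel = _normalized_share(selected.astype(float))
    unsel = _normalized_share(unselected.astype(float))
    capped = sel.to_numpy() == 0.0
    with np.errstate(divide="ignore"):
        kappa = np.where(capped, ceiling, unsel.to_numpy() / np.where(capped, 1.0, sel.to_numpy()))
    if (parent_selected is None) != (parent_unselected is None):
        raise ValueError("parent correction needs both parent tables")
    if parent_selected is not None:
        parent = kappa_from_selection(
            parent_selected, parent_unselected, ceiling=ceiling
        )
        if not np.array_equal(parent["position"].to_numpy(), selected.index.to_numpy()):
            raise ValueError("parent tables cover different positions")
        kappa = kappa / parent["kappa"].to_numpy()
    kappa = np.minimum(kappa, ceiling)
    n_capped = int(capped.sum())
    if n_capped:
        log.info("capped %d kappa values at ceiling %g", n_capped, ceiling)
    return pd.DataFrame(
        {"position": selected.index.to_numpy(), "kappa": kappa, "capped": capped}
    )


def lambda_normalize(
    kappas: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_LAMBDA_THRESHOLD,
) -> InterferenceProfile:
    """Robust z-score of log2 kappa: median-centred, MAD-scaled.

    Under a pure-noise profile lambda is approximately standard normal, so a
    threshold of 2.5 corresponds to the two-sided 98.8% interval.  Constant
    profiles have no scale and raise.
    """
    if isinstance(kappas, pd.Series):
        df = pd.DataFrame(
            {"position": kappas.index.to_numpy(), "kappa": kappas.to_numpy()}
        )
        df["capped"] = False
    else:
        df = kappas.copy()
        if "capped" not in df:
            df["capped"] = False
    if len(df) < 10:
        raise ValueError("lambda normalization needs >= 10 positions for a robust scale")
    kappa = df["kappa"].to_numpy(dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa values must be > 0")
    logk = np.log2(kappa)
    center = float(np.median(logk))
    mad = float(np.median(np.abs(logk - center)))
    scale = mad * MAD_TO_SD
    if scale == 0.0:
        raise ValueError("constant kappa profile: robust scale is zero")
    lam = (logk - center) / scale
    return InterferenceProfile(
        positions=df["position"].to_numpy(),
        kappa=kappa,
        lam=lam,
        flagged=np.abs(lam) > threshold,
        capped=df["capped"].to_numpy(dtype=bool),
        threshold=threshold,
    )


def cumulative_curve(profile: InterferenceProfile) -> CumulativeCurve:
    """Running sum of positive (detrimental) lambda along the track."""
    order = np.argsort(profile.positions)
    lam = np.maximum(profile.lam[order], 0.0)
    return CumulativeCurve(
        positions=profile.positions[order], cumulative=np.cumsum(lam)
    )


def find_clusters(
    profile: InterferenceProfile,
    threshold: float | None = None,
    gap_tolerance: int = 1,
) -> list[Cluster]:
    """Maximal runs of contiguous above-threshold positions.

    Runs may bridge up to ``gap_tolerance`` sub-threshold positions.  The
    cluster center is the lambda-weighted mean position rounded to the
    nearest integer.
    """
    thr = profile.threshold if threshold is None else threshold
    if thr <= 0:
        raise ValueError("threshold must be > 0")
    order = np.argsort(profile.positions)
    pos = profile.positions[order]
    lam = profile.lam[order]
    hot = np.flatnonzero(lam > thr)
    if hot.size == 0:
        return []
    clusters = []
    run = [hot[0]]
    for i in hot[1:]:
        if pos[i] - pos[run[-1]] <= gap_tolerance + 1:
            run.append(i)
        else:
            clusters.append(run)
            run = [i]
    clusters.append(run)
    out = []
    for run in clusters:
        idx = np.array(run)
        weights = lam[idx]
        center = int(round(float(np.average(pos[idx], weights=weights))))
        out.append(
            Cluster(
                start=int(pos[idx[0]]),
                end=int(pos[idx[-1]]),
                center=center,
                peak=float(weights.max()),
            )
        )
    return out


def _acf(values: np.ndarray, max_lag: int) -> np.ndarray:
    x = values - values.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("constant profile: autocorrelation undefined")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        out[lag] = float(np.dot(x[:-lag], x[lag:])) / denom
    return out


def _first_local_max(acf: np.ndarray, threshold: float) -> tuple[int | None, float]:
    """First lag >= 1 that is a local maximum above ``threshold``."""
    max_lag = acf.size - 1
    for lag in range(1, max_lag + 1):
        left = acf[lag - 1] if lag > 1 else -np.inf  # lag 0 is always 1; ignore it
        right = acf[lag + 1] if lag < max_lag else -np.inf
        if acf[lag] > threshold and acf[lag] >= left and acf[lag] >= right:
            return lag, float(acf[lag])
    return None, float(acf[1:].max()) if max_lag >= 1 else float("nan")


def interference_autocorrelation(
    profile: InterferenceProfile | np.ndarray,
    max_lag: int = 20,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AutocorrResult:
    """Mean-removed, variance-normalized autocorrelation of the lambda profile.

    The step-size estimate is the first off-zero local maximum whose value
    exceeds a significance threshold: the large-sample white-noise band
    1.96/sqrt(n) by default, or the 95th percentile of the maximum
    autocorrelation over ``n_permutations`` profile shuffles when requested.
    Profiles with no qualifying maximum are flagged "no periodicity".
    """
    lam = profile.lam if isinstance(profile, InterferenceProfile) else np.asarray(profile, float)
    if isinstance(profile, InterferenceProfile):
        lam = lam[np.argsort(profile.positions)]
    n = lam.size
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n <= 2 * max_lag:
        raise ValueError(f"profile length {n} must exceed 2 x max_lag = {2 * max_lag}")
    acf = _acf(lam, max_lag)
    threshold = 1.96 / math.sqrt(n)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_permutations)
        for i in range(n_permutations):
            null_max[i] = _acf(rng.permutation(lam), max_lag)[1:].max()
        threshold = max(threshold, float(np.quantile(null_max, 0.95)))
    lag, peak = _first_local_max(acf, threshold)
    if lag is None:
        return AutocorrResult(
            lags=np.arange(max_lag + 1), acf=acf, step_size=None,
            peak_value=peak, significant=False, threshold=threshold,
            message="no periodicity",
        )
    return AutocorrResult(
        lags=np.arange(max_lag + 1), acf=acf, step_size=lag,
        peak_value=peak, significant=True, threshold=threshold,
    )
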