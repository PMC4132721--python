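"""Deterministic kinetics of single-run, sequential-step duplex unwinding.

The model is a linear first-order chain: an irreversible, slow activation
step feeds a series of translocation/unwinding steps.  At every step the
complex either advances (rate ``k_U``) or falls off the track into an
absorbing dissociated state (rate ``k_D``); under single-cycle conditions a
trap prevents re-binding, so dissociation is terminal and the reaction
amplitude reports processivity.  The fraction-unwound progress curve is
obtained from the matrix exponential of the (constant) rate matrix.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PARENT_ANALOG",
    "Step",
    "RateScheme",
    "ModificationPenalty",
    "RegulatoryGeometry",
    "UnwindingCurve",
    "DegenerateStepError",
    "step_processivity",
    "total_amplitude",
    "simulate_progress",
    "apply_penalties",
    "identity_step_map",
    "regulatory_positions",
]

#: Analog identifier for the parent phosphorothioate tag (no sugar change);
#: it carries no kinetic penalty by definition.
PARENT_ANALOG = "parent-aS"

#: Relative tolerance documented for the progress-curve solver (dense matrix
#: exponential of the constant rate matrix; exact to machine precision for
#: well-conditioned chains, comfortably below this bound).
SOLVER_RTOL = 1e-9


class DegenerateStepError(ValueError):
    """Raised when a step has both its forward and dissociation rate at zero."""


@dataclass(frozen=True)
class Step:
    """One translocation/unwinding step: forward rate and dissociation rate."""

    k_U: float
    k_D: float

    def __post_init__(self) -> None:
        if self.k_U < 0 or self.k_D < 0:
            raise ValueError(f"step rates must be >= 0, got ({self.k_U}, {self.k_D})")


@dataclass(frozen=True)
class RateScheme:
    """Rate constants of the activation + sequential unwinding chain.

    Parameters
    ----------
    k_act:
        Rate of the initial, slow activation step (1/s).  Activation has no
        dissociation branch; sub-maximal starting amplitude is carried by
        ``baseline_amplitude`` instead.
    steps:
        Ordered ``Step`` instances, one per consumed track nucleotide.
    baseline_amplitude:
        Fraction of complexes competent at t = 0, in [0, 1].
    """

    k_act: float
    steps: tuple[Step, ...]
    baseline_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.k_act > 0:
            raise ValueError(f"k_act must be > 0, got {self.k_act}")
        steps = tuple(
            s if isinstance(s, Step) else Step(*s) for s in self.steps
        )
        object.__setattr__(self, "steps", steps)
        if len(steps) < 1:
            raise ValueError("scheme needs at least one step")
        if not 0.0 <= self.baseline_amplitude <= 1.0:
            raise ValueError(
                f"baseline_amplitude must be in [0, 1], got {self.baseline_amplitude}"
            )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @classmethod
    def uniform(
        cls,
        n_steps: int,
        k_U: float,
        k_D: float,
        k_act: float,
        baseline_amplitude: float = 1.0,
    ) -> "RateScheme":
        """Chain of ``n_steps`` identical steps."""
        return cls(
            k_act=k_act,
            steps=tuple(Step(k_U, k_D) for _ in range(n_steps)),
            baseline_amplitude=baseline_amplitude,
        )

    def rate_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-step (k_U, k_D) as float arrays."""
        kU = np.array([s.k_U for s in self.steps], dtype=float)
        kD = np.array([s.k_D for s in self.steps], dtype=float)
        return kU, kD

    def to_dict(self) -> dict:
        return {
            "k_act": self.k_act,
            "baseline_amplitude": self.baseline_amplitude,
            "steps": [{"kU": s.k_U, "kD": s.k_D} for s in self.steps],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateScheme":
        """Inverse of :meth:`to_dict`.

        Accepts either an explicit ``steps`` list of ``{kU, kD}`` mappings or
        the uniform shorthand ``{n_steps, kU, kD}``.
        """
        known = {"k_act", "baseline_amplitude", "steps", "n_steps", "kU", "kD"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown scheme keys: {sorted(bad)}")
        if "steps" in d:
            steps = tuple(Step(float(s["kU"]), float(s["kD"])) for s in d["steps"])
        elif "n_steps" in d:
            steps = tuple(
                Step(float(d["kU"]), float(d["kD"])) for _ in range(int(d["n_steps"]))
            )
        else:
            raise ValueError("scheme requires either 'steps' or 'n_steps'/'kU'/'kD'")
        return cls(
            k_act=float(d["k_act"]),
            steps=steps,
            baseline_amplitude=float(d.get("baseline_amplitude", 1.0)),
        )


@dataclass(frozen=True)
class ModificationPenalty:
    """Multiplicative rate perturbation tied to one modified track position."""

    position: int
    analog: str
    kU_factor: float = 1.0
    kD_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kU_factor < 0 or self.kD_factor < 0:
            raise ValueError("penalty factors must be >= 0")
        if self.analog == PARENT_ANALOG and (
            self.kU_factor != 1.0 or self.kD_factor != 1.0
        ):
            raise ValueError(
                f"{PARENT_ANALOG!r} carries no kinetic penalty; factors must be (1, 1)"
            )


@dataclass(frozen=True)
class RegulatoryGeometry:
    """Ring parameters placing periodic checkpoint positions on the track.

    ``period`` is a free parameter and not derived from ``n_subunits``: the
    six-subunit / seven-nucleotide relationship of the default ring model is
    asserted, not computed.
    """

    n_subunits: int = 6
    period: int = 7
    offset: int = 7

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")
        if not 1 <= self.offset <= self.period:
            raise ValueError(
                f"offset must satisfy 1 <= offset <= period, got {self.offset}"
            )
        if self.n_subunits < 1:
            raise ValueError(f"n_subunits must be >= 1, got {self.n_subunits}")

    def to_dict(self) -> dict:
        return {
            "n_subunits": self.n_subunits,
            "period": self.period,
            "offset": self.offset,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegulatoryGeometry":
        bad = set(d) - {"n_subunits", "period", "offset"}
        if bad:
            raise ValueError(f"unknown geometry keys: {sorted(bad)}")
        return cls(**{k: int(v) for k, v in d.items()})


@dataclass(frozen=True)
class UnwindingCurve:
    """Fraction-unwound progress curve F(t)."""

    times: np.ndarray
    fraction_unwound: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_unwound, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fraction_unwound must be 1-D, same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_unwound", f)


def step_processivity(k_U: float, k_D: float) -> float:
    """Probability of completing one step before dissociation: kU/(kU+kD)."""
    if k_U < 0 or k_D < 0:
        raise ValueError("rates must be >= 0")
    if k_U == 0 and k_D == 0:
        raise DegenerateStepError("both k_U and k_D are zero: step never resolves")
    return k_U / (k_U + k_D)


def total_amplitude(scheme: RateScheme) -> float:
    """Asymptotic unwound fraction: baseline x product of step processivities."""
    amp = scheme.baseline_amplitude
    for s in scheme.steps:
        amp *= step_processivity(s.k_U, s.k_D)
    return amp


def _rate_matrix(scheme: RateScheme) -> np.ndarray:
    """Generator of the chain over states [bound, step 1..n, unwound, dissociated].

    Row = from-state; the last two states are absorbing.
    """
    n = scheme.n_steps
    q = np.zeros((n + 3, n + 3))
    unwound, dissociated = n + 1, n + 2
    q[0, 1] = scheme.k_act
    for i, s in enumerate(scheme.steps, start=1):
        target = i + 1 if i < n else unwound
        q[i, target] = s.k_U
        q[i, dissociated] = s.k_D
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def simulate_progress(scheme: RateScheme, times: Sequence[float]) -> UnwindingCurve:
    """Integrate the activation + branching chain; return F(t) at ``times``.

    Exact solution via ``expm`` of the constant rate matrix (handles repeated
    rates, where an eigendecomposition would be defective).  The asymptote
    equals :func:`total_amplitude` and the curve is monotone non-decreasing.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    q = _rate_matrix(scheme)
    unwound = scheme.n_steps + 1
    frac = np.empty(t.size)
    for j, tj in enumerate(t.ravel()):
        if tj == 0.0:
            frac[j] = 0.0
        else:
            frac[j] = expm(q * tj)[0, unwound]
    frac = np.clip(frac * scheme.baseline_amplitude, 0.0, 1.0)
    order = np.argsort(t, kind="stable")
    return UnwindingCurve(times=t[order], fraction_unwound=frac[order])


def unwound_fraction_at(scheme: RateScheme, t: float) -> float:
    """F at a single time (scalar convenience used by root finding)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if t == 0:
        return 0.0
    q = _rate_matrix(scheme)
    return float(
        np.clip(expm(q * t)[0, scheme.n_steps + 1] * scheme.baseline_amplitude, 0, 1)
    )


def identity_step_map(track_length: int, origin: int = 1) -> dict[int, int]:
    """Position -> step mapping with one step per consumed nucleotide.

    ``origin`` is the 1-based track position consumed by step 1; the analysis
    track need not start at nucleotide 1.
    """
    return {origin + i: i + 1 for i in range(track_length)}


def apply_penalties(
    scheme: RateScheme,
    penalties: Iterable[ModificationPenalty],
    position_to_step: Mapping[int, int] | None = None,
) -> RateScheme:
    """Return a new scheme with per-step rates multiplied by penalty factors.

    ``position_to_step`` maps 1-based track positions to 1-based step indices;
    defaults to the identity over ``scheme.n_steps``.  Multiple penalties
    landing on one step combine multiplicatively.  The input scheme is never
    mutated.
    """
    if position_to_step is None:
        position_to_step = identity_step_map(scheme.n_steps)
    kU, kD = scheme.rate_arrays()
    kU, kD = kU.copy(), kD.copy()
    for p in penalties:
        try:
            step = position_to_step[p.position]
        except KeyError:
            raise KeyError(
                f"penalty position {p.position} has no mapped unwinding step"
            ) from None
        if not 1 <= step <= scheme.n_steps:
            raise KeyError(
                f"position {p.position} maps to step {step}, outside 1..{scheme.n_steps}"
            )
        kU[step - 1] *= p.kU_factor
        kD[step - 1] *= p.kD_factor
    return replace(
        scheme, steps=tuple(Step(u, d) for u, d in zip(kU, kD))
    )


def regulatory_positions(
    geometry: RegulatoryGeometry, track_length: int
) -> list[int]:
    """1-based positions of the periodically recurring checkpoint state."""
    if track_length < 1:
        raise ValueError(f"track_length must be >= 1, got {track_length}")
    return list(range(geometry.offset, track_length + 1, geometry.period))
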