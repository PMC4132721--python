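"""Synthetic gel-band datasets from combinatorially modified transcript libraries.

Generates the two experiment styles the analysis stages consume:

* time-course datasets — molecules with random single-analog incorporation are
  partitioned at each sampling time into an unwound supernatant fraction (S1)
  and a bead-retained fraction (S2); backbone-tag cleavage converts each
  fraction into a per-position band ladder;
* endpoint selections — a single partition taken when the control reaction
  reaches a requested extent, yielding a selected (unwound) pool and the
  unselected input pool.

Molecule fates are sampled exactly from the kinetic chain law: conditional on
surviving every step, the completion time is the independent sum of the
activation waiting time and the per-step holding times, so a molecule in an
aliquot taken at time t is unwound with probability
``P(survive all steps) * P(T <= t)`` — identical in distribution to a binomial
draw against the deterministic progress curve of its modified rate scheme.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import (
    PARENT_ANALOG,
    RateScheme,
    identity_step_map,
    total_amplitude,
    unwound_fraction_at,
)

__all__ = [
    "AnalogSpec",
    "LibrarySpec",
    "NoiseModel",
    "NO_NOISE",
    "GelDataset",
    "NaimSelection",
    "CONTROL_POSITION",
    "sample_library",
    "simulate_gel",
    "simulate_naim_selection",
]

#: Reserved position index for the total-RNA ("Control") readout rows.
CONTROL_POSITION = 0

_RNA_BASES = frozenset("ACGU")


@dataclass(frozen=True)
class AnalogSpec:
    """One analog class in the transcription library.

    ``kU_factor``/``kD_factor`` apply at every modified position unless
    overridden per position through ``position_factors`` (1-based position ->
    ``(kU_factor, kD_factor)``).
    """

    analog: str
    incorporation_prob: float = 0.05
    eligible_bases: frozenset[str] | None = None
    kU_factor: float = 1.0
    kD_factor: float = 1.0
    position_factors: Mapping[int, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.incorporation_prob <= 1.0:
            raise ValueError("incorporation_prob must be in [0, 1]")
        if self.kU_factor < 0 or self.kD_factor < 0:
            raise ValueError("penalty factors must be >= 0")
        if self.analog == PARENT_ANALOG and (
            self.kU_factor != 1.0 or self.kD_factor != 1.0 or self.position_factors
        ):
            raise ValueError(f"{PARENT_ANALOG!r} must carry factors (1, 1)")
        if self.eligible_bases is not None:
            bases = frozenset(self.eligible_bases)
            if not bases <= _RNA_BASES:
                raise ValueError(f"eligible_bases must be within {{A,C,G,U}}, got {bases}")
            object.__setattr__(self, "eligible_bases", bases)
        if self.position_factors is not None:
            object.__setattr__(
                self,
                "position_factors",
                {int(k): (float(v[0]), float(v[1])) for k, v in self.position_factors.items()},
            )


@dataclass(frozen=True)
class LibrarySpec:
    """Transcript library: track geometry, analog mix and detection efficiency."""

    track_length: int
    analogs: tuple[AnalogSpec, ...]
    n_molecules: int = 100_000
    sequence: str | None = None
    cleavage_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.track_length < 1:
            raise ValueError("track_length must be >= 1")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 0.0 < self.cleavage_efficiency <= 1.0:
            raise ValueError("cleavage_efficiency must be in (0, 1]")
        object.__setattr__(self, "analogs", tuple(self.analogs))
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.track_length:
                raise ValueError("sequence length must equal track_length")
            extra = set(seq) - _RNA_BASES
            if extra:
                raise ValueError(f"sequence contains non-RNA letters: {sorted(extra)}")
            object.__setattr__(self, "sequence", seq)
        for a in self.analogs:
            if a.eligible_bases is not None and self.sequence is None:
                raise ValueError(
                    f"analog {a.analog!r} is base-restricted but the spec has no sequence"
                )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative densitometry noise: per-band lognormal + per-lane loading."""

    band_cv: float = 0.10
    lane_factor_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.band_cv < 0 or self.lane_factor_sd < 0:
            raise ValueError("noise parameters must be >= 0")


NO_NOISE = NoiseModel(band_cv=0.0, lane_factor_sd=0.0)


@dataclass
class GelDataset:
    """Band intensities in long format plus provenance metadata.

    ``frame`` columns: ``time_s``, ``fraction`` (S1 = unwound supernatant,
    S2 = bead-recovered), ``position`` (1-based; 0 is the total-RNA control
    readout), ``intensity``.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time_s", "fraction", "position", "intensity"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset frame missing columns: {sorted(missing)}")
        if (self.frame["intensity"] < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_s"].unique())

    @property
    def positions(self) -> np.ndarray:
        pos = self.frame["position"].unique()
        return np.sort(pos[pos != CONTROL_POSITION])

    def band_table(self, time_s: float, fraction: str) -> pd.Series:
        """Intensities of one lane, indexed by position (control row excluded)."""
        sel = self.frame[
            (self.frame["time_s"] == time_s)
            & (self.frame["fraction"] == fraction)
            & (self.frame["position"] != CONTROL_POSITION)
        ]
        return sel.set_index("position")["intensity"].sort_index()


@dataclass(frozen=True)
class NaimSelection:
    """Endpoint selection: per-position intensities of both pools."""

    selected: pd.Series
    unselected: pd.Series
    time_s: float
    extent: float


def _spec_hash(*parts) -> str:
    payload = json.dumps(parts, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _eligible_mask(spec: LibrarySpec, analog: AnalogSpec) -> np.ndarray:
    if analog.eligible_bases is None:
        return np.ones(spec.track_length, dtype=bool)
    seq = np.array(list(spec.sequence))
    return np.isin(seq, list(analog.eligible_bases))


def sample_library(
    spec: LibrarySpec, seed: int | np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Draw per-molecule incorporation patterns.

    Returns one boolean matrix of shape ``(n_molecules, track_length)`` per
    analog id; entry (m, p) is True when molecule m carries that analog at
    1-based position p + 1.  Each eligible position is an independent
    Bernoulli draw.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mods: dict[str, np.ndarray] = {}
    for analog in spec.analogs:
        mask = _eligible_mask(spec, analog)
        m = np.zeros((spec.n_molecules, spec.track_length), dtype=bool)
        if analog.incorporation_prob > 0 and mask.any():
            draws = rng.random((spec.n_molecules, int(mask.sum())))
            m[:, mask] = draws < analog.incorporation_prob
        mods[analog.analog] = m
    return mods


class _MoleculeKinetics:
    """Vectorised per-molecule survival probabilities and completion-time sampler."""

    def __init__(
        self,
        spec: LibrarySpec,
        scheme: RateScheme,
        mods: Mapping[str, np.ndarray],
        position_to_step: Mapping[int, int],
    ) -> None:
        self.n_mol = spec.n_molecules
        self.scheme = scheme
        kU, kD = scheme.rate_arrays()
        exit0 = kU + kD
        if np.any(exit0 == 0):
            raise ValueError("base scheme has a degenerate step (k_U = k_D = 0)")
        with np.errstate(divide="ignore"):
            logp0 = np.log(kU / exit0)  # -inf when kU == 0

        # Vectorised 1-based position -> 0-based step lookup table.
        step_of_pos = np.full(spec.track_length + 1, -1, dtype=np.int64)
        for p, s in position_to_step.items():
            if 1 <= p <= spec.track_length and 1 <= s <= scheme.n_steps:
                step_of_pos[p] = s - 1

        # Flatten modified (molecule, step) entries across analogs, then merge
        # duplicates multiplicatively.
        by_analog = {a.analog: a for a in spec.analogs}
        mol_l, step_l, fu_l, fd_l = [], [], [], []
        for name, matrix in mods.items():
            a = by_analog[name]
            mol_idx, pos_idx = np.nonzero(matrix)
            positions = pos_idx + 1
            steps = step_of_pos[positions]
            if np.any(steps < 0):
                bad = np.unique(positions[steps < 0])
                raise KeyError(
                    f"modified positions with no mapped unwinding step: {bad.tolist()}"
                )
            fu = np.full(positions.size, a.kU_factor)
            fd = np.full(positions.size, a.kD_factor)
            if a.position_factors:
                for p, (ou, od) in a.position_factors.items():
                    at_p = positions == p
                    fu[at_p] = ou
                    fd[at_p] = od
            mol_l.append(mol_idx)
            step_l.append(steps)
            fu_l.append(fu)
            fd_l.append(fd)

        if mol_l:
            mol = np.concatenate(mol_l)
            step = np.concatenate(step_l)
            fu = np.concatenate(fu_l)
            fd = np.concatenate(fd_l)
            key = mol * scheme.n_steps + step
            order = np.argsort(key, kind="stable")
            mol, step, fu, fd, key = mol[order], step[order], fu[order], fd[order], key[order]
            uniq, inverse = np.unique(key, return_inverse=True)
            cfu = np.ones(uniq.size)
            cfd = np.ones(uniq.size)
            np.multiply.at(cfu, inverse, fu)
            np.multiply.at(cfd, inverse, fd)
            first = np.searchsorted(key, uniq)
            self.mod_mol = mol[first]
            self.mod_step = step[first]
            kUp = kU[self.mod_step] * cfu
            kDp = kD[self.mod_step] * cfd
            exitp = kUp + kDp
            with np.errstate(divide="ignore", invalid="ignore"):
                logpp = np.where(exitp > 0, np.log(np.where(exitp > 0, kUp / exitp, 1.0)), -np.inf)
            self.mod_exit = exitp
            self._delta_logp = logpp - logp0[self.mod_step]
        else:
            self.mod_mol = np.empty(0, dtype=np.int64)
            self.mod_step = np.empty(0, dtype=np.int64)
            self.mod_exit = np.empty(0)
            self._delta_logp = np.empty(0)

        base_logp_total = logp0.sum()
        log_surv = np.full(self.n_mol, base_logp_total)
        np.add.at(log_surv, self.mod_mol, self._delta_logp)
        self.survival = np.exp(log_surv) * scheme.baseline_amplitude

        # Base holding times grouped by shared exit rate; a molecule skips its
        # modified steps in each group and draws those individually instead.
        self.groups: list[tuple[float, int]] = []
        uniq_rates, grp_of_step = np.unique(exit0, return_inverse=True)
        self._grp_of_step = grp_of_step
        self._grp_rates = uniq_rates
        self._grp_counts = np.bincount(grp_of_step, minlength=uniq_rates.size)
        self._mod_counts_per_grp = np.zeros((self.n_mol, uniq_rates.size), dtype=np.int64)
        if self.mod_mol.size:
            np.add.at(
                self._mod_counts_per_grp,
                (self.mod_mol, grp_of_step[self.mod_step]),
                1,
            )

    def draw_completion_times(self, rng: np.random.Generator) -> np.ndarray:
        """One completion-time draw per molecule (activation + all step holds)."""
        t = rng.exponential(1.0 / self.scheme.k_act, size=self.n_mol)
        for g, rate in enumerate(self._grp_rates):
            shapes = self._grp_counts[g] - self._mod_counts_per_grp[:, g]
            t += rng.gamma(shape=shapes, scale=1.0 / rate)
        if self.mod_mol.size:
            with np.errstate(divide="ignore"):
                scale = np.where(self.mod_exit > 0, 1.0 / self.mod_exit, np.inf)
            finite = np.isfinite(scale)
            holds = np.zeros(self.mod_mol.size)
            holds[finite] = rng.exponential(scale[finite])
            holds[~finite] = np.inf
            np.add.at(t, self.mod_mol, holds)
        return t

    def draw_unwound(self, t: float, rng: np.random.Generator) -> np.ndarray:
        """Boolean unwound-by-time-t indicator per molecule (fresh aliquot)."""
        survived = rng.random(self.n_mol) < self.survival
        return survived & (self.draw_completion_times(rng) <= t)


def _band_counts(mod_any: np.ndarray, selector: np.ndarray) -> np.ndarray:
    return mod_any[selector].sum(axis=0).astype(float)


def _apply_noise(
    values: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    if noise.lane_factor_sd > 0:
        out *= np.exp(rng.normal(0.0, noise.lane_factor_sd))
    if noise.band_cv > 0:
        sigma = np.sqrt(np.log1p(noise.band_cv**2))
        # mean-one lognormal keeps intensities unbiased
        out *= np.exp(rng.normal(-0.5 * sigma**2, sigma, size=out.shape))
    return out


def simulate_gel(
    spec: LibrarySpec,
    base_scheme: RateScheme,
    times: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    position_to_step: Mapping[int, int] | None = None,
) -> GelDataset:
    """Simulate a time-course band dataset.

    Each sampling time is an independent aliquot: every molecule is assigned
    to the unwound (S1) or bead (S2) fraction by sampling its modified kinetic
    chain, band intensity at position i is the count of molecules in that
    fraction modified at i scaled by the cleavage efficiency, and a total-RNA
    control readout (position 0) is emitted per fraction.  ``times`` should
    span the rise and plateau of the control curve so downstream exponential
    fits are identifiable.
    """
    if spec.n_molecules < 1:
        raise ValueError("empty library")
    t_arr = np.asarray(times, dtype=float)
    if t_arr.size == 0 or np.any(t_arr < 0):
        raise ValueError("times must be a non-empty sequence of t >= 0")
    if position_to_step is None:
        position_to_step = identity_step_map(spec.track_length)
    rng = np.random.default_rng(seed)

    mods = sample_library(spec, rng)
    mod_any = np.zeros((spec.n_molecules, spec.track_length), dtype=bool)
    for m in mods.values():
        mod_any |= m
    kin = _MoleculeKinetics(spec, base_scheme, mods, position_to_step)

    positions = np.arange(1, spec.track_length + 1)
    rows = []
    for t in t_arr:
        unwound = kin.draw_unwound(float(t), rng)
        for fraction, selector in (("S1", unwound), ("S2", ~unwound)):
            counts = _band_counts(mod_any, selector) * spec.cleavage_efficiency
            control = float(selector.sum())
            lane = _apply_noise(
                np.concatenate(([control], counts)), noise, rng
            )
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "fraction": fraction,
                        "position": np.concatenate(([CONTROL_POSITION], positions)),
                        "intensity": lane,
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True)
    metadata = {
        "seed": seed,
        "spec_hash": _spec_hash(
            {
                "track_length": spec.track_length,
                "n_molecules": spec.n_molecules,
                "cleavage_efficiency": spec.cleavage_efficiency,
                "analogs": [
                    {
                        "analog": a.analog,
                        "incorporation_prob": a.incorporation_prob,
                        "kU_factor": a.kU_factor,
                        "kD_factor": a.kD_factor,
                        "position_factors": a.position_factors,
                        "eligible_bases": sorted(a.eligible_bases) if a.eligible_bases else None,
                    }
                    for a in spec.analogs
                ],
            },
            base_scheme.to_dict(),
            list(map(float, t_arr)),
        ),
        "noise": {"band_cv": noise.band_cv, "lane_factor_sd": noise.lane_factor_sd},
        "n_molecules": spec.n_molecules,
        "control_position": CONTROL_POSITION,
    }
    return GelDataset(frame=frame, metadata=metadata)


def find_extent_time(scheme: RateScheme, extent: float) -> float:
    """Time at which the control progress curve reaches ``extent`` (absolute F)."""
    if not 0.0 < extent < 1.0:
        raise ValueError("extent must be in (0, 1)")
    asymptote = total_amplitude(scheme)
    if extent >= asymptote:
        raise ValueError(
            f"extent {extent} is at or above the control asymptote {asymptote:.6g}"
        )
    hi = 1.0 / scheme.k_act
    while unwound_fraction_at(scheme, hi) < extent:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the extent time")
    return float(brentq(lambda t: unwound_fraction_at(scheme, t) - extent, 0.0, hi))


def simulate_naim_selection(
    spec: LibrarySpec,
    base_scheme: RateScheme,
    extent: float = 0.2,
    seed: int | None = None,
    noise: NoiseModel = NO_NOISE,
    position_to_step: Mapping[int, int] | None = None,
) -> NaimSelection:
    """Simulate an endpoint selection quenched at a fixed control extent.

    The selected pool is the unwound fraction at the extent time; the
    unselected pool is the input library.  Both are returned as per-position
    band intensities.
    """
    if spec.n_molecules < 1:
        raise ValueError("empty library")
    t_star = find_extent_time(base_scheme, extent)
    if position_to_step is None:
        position_to_step = identity_step_map(spec.track_length)
    rng = np.random.default_rng(seed)
    mods = sample_library(spec, rng)
    mod_any = np.zeros((spec.n_molecules, spec.track_length), dtype=bool)
    for m in mods.values():
        mod_any |= m
    kin = _MoleculeKinetics(spec, base_scheme, mods, position_to_step)
    unwound = kin.draw_unwound(t_star, rng)

    positions = np.arange(1, spec.track_length + 1)
    selected = _band_counts(mod_any, unwound) * spec.cleavage_efficiency
    unselected = mod_any.sum(axis=0).astype(float) * spec.cleavage_efficiency
    selected = _apply_noise(selected, noise, rng)
    unselected = _apply_noise(unselected, noise, rng)
    return NaimSelection(
        selected=pd.Series(selected, index=positions, name="intensity").rename_axis("position"),
        unselected=pd.Series(unselected, index=positions, name="intensity").rename_axis("position"),
        time_s=t_star,
        extent=extent,
    )
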