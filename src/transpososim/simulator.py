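"""Deterministic and stochastic time courses of transpososome state occupancy.

The deterministic route propagates the state distribution with the matrix
exponential of the CTMC generator (the chemical master equation is linear
in the state probabilities, so this is exact).  The stochastic route is an
exact Gillespie simulation of the same generator, used for finite-molecule
noise studies; its binned occupancies converge to the master-equation
solution as the number of molecules grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .kinetic_models import (
    D,
    FREE,
    INTEGRATED,
    N,
    SYNAPSED,
    U,
    KineticModel,
    MoleculeState,
    START_STATE,
    successors,
)

__all__ = [
    "TimeCourse",
    "HalfLifeNotReached",
    "UndefinedDiagnostic",
    "DEFAULT_T_GRID",
    "solve_master",
    "gillespie",
    "half_life",
    "species_half_life",
    "seb_partner_nick_prob",
    "is_seb",
    "has_partner_nick",
]

#: default sampling grid (s), mimicking the time points of a typical
#: kinetics gel: 0, 15 s, 30 s, then 1, 2, 4, 8, 15, 30, 60, 120, 180 min
DEFAULT_T_GRID = (
    0.0,
    15.0,
    30.0,
    60.0,
    120.0,
    240.0,
    480.0,
    900.0,
    1800.0,
    3600.0,
    7200.0,
    10800.0,
)

_MASS_TOL = 1e-9


class HalfLifeNotReached(RuntimeError):
    """The tracked species never fell to half its initial level on the grid."""


class UndefinedDiagnostic(RuntimeError):
    """A conditional diagnostic was requested where its denominator is zero."""


@dataclass(frozen=True)
class TimeCourse:
    """State-occupancy fractions on a time grid.

    ``fractions[i, j]`` is the probability of state ``states[j]`` at
    ``times[i]``; every row sums to one.
    """

    times: np.ndarray
    fractions: np.ndarray
    states: tuple[MoleculeState, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", frac)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if frac.shape != (times.size, len(self.states)):
            raise ValueError("fractions must be (time x state)")
        if np.any(frac < -_MASS_TOL) or np.any(frac > 1 + _MASS_TOL):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.abs(frac.sum(axis=1) - 1.0) > _MASS_TOL):
            raise ValueError("probability mass is not conserved")

    def state_index(self, state: MoleculeState) -> int:
        return self.states.index(state)

    def mask(self, predicate: Callable[[MoleculeState], bool]) -> np.ndarray:
        return np.array([bool(predicate(s)) for s in self.states])

    def species_fraction(
        self, predicate: Callable[[MoleculeState], bool]
    ) -> np.ndarray:
        """Summed fraction of all states satisfying ``predicate``, vs time."""
        return self.fractions[:, self.mask(predicate)].sum(axis=1)

    def at(self, t: float) -> np.ndarray:
        """State distribution at time ``t``, linearly interpolated."""
        t = float(t)
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"t={t} outside the simulated range")
        return np.array(
            [np.interp(t, self.times, self.fractions[:, j]) for j in range(len(self.states))]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: one row per (time_s, state)."""
        rows = []
        for i, t in enumerate(self.times):
            for j, s in enumerate(self.states):
                rows.append({"time_s": t, "state": s.label, "fraction": self.fractions[i, j]})
        return pd.DataFrame(rows)


def solve_master(
    model_or_generator,
    t_grid: Sequence[float],
    states: Sequence[MoleculeState] | None = None,
    p0: Sequence[float] | None = None,
) -> TimeCourse:
    """Solve the master equation on ``t_grid`` by matrix exponentiation.

    Accepts either a :class:`KineticModel` or a raw generator matrix plus
    its state list.  The initial distribution defaults to all mass in FREE.
    """
    if isinstance(model_or_generator, KineticModel):
        q = model_or_generator.generator
        states = tuple(model_or_generator.states)
    else:
        q = np.asarray(model_or_generator, dtype=float)
        if states is None:
            raise ValueError("states must be given with a raw generator matrix")
        states = tuple(states)
    if not np.all(np.isfinite(q)):
        raise ValueError("generator contains non-finite entries")
    if np.any(np.abs(q.sum(axis=1)) > 1e-8 * (1 + np.abs(q).max())):
        raise ValueError("generator rows must sum to zero")
    times = np.asarray(t_grid, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("t_grid must be non-negative and strictly increasing")

    n = len(states)
    p = np.zeros(n)
    if p0 is None:
        p[list(states).index(START_STATE)] = 1.0
    else:
        p = np.asarray(p0, dtype=float).copy()
        if p.shape != (n,) or abs(p.sum() - 1.0) > _MASS_TOL or np.any(p < 0):
            raise ValueError("p0 must be a probability vector over the states")

    out = np.empty((times.size, n))
    prev_t = 0.0
    cur = p
    for i, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            cur = cur @ expm(q * dt)
            # clip the tiny negative round-off the exponential can produce
            cur = np.clip(cur, 0.0, None)
            cur = cur / cur.sum()
            prev_t = t
        out[i] = cur
    return TimeCourse(times, out, states)


def gillespie(
    model: KineticModel,
    n_molecules: int,
    t_max: float,
    seed: int,
    t_grid: Sequence[float] | None = None,
) -> tuple[list[list[tuple[float, MoleculeState]]], TimeCourse]:
    """Exact stochastic simulation of ``n_molecules`` independent molecules.

    Returns per-molecule event trajectories (lists of ``(time, state)``
    starting at ``(0, FREE)``) and the state-occupancy fractions binned on
    ``t_grid`` (default: the part of :data:`DEFAULT_T_GRID` up to
    ``t_max``).  A fixed seed reproduces the trajectories exactly.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if t_grid is None:
        t_grid = [t for t in DEFAULT_T_GRID if t <= t_max]
        if t_grid[-1] < t_max:
            t_grid.append(float(t_max))
    times = np.asarray(t_grid, dtype=float)

    rng = np.random.default_rng(seed)
    states = model.states
    index = model.index
    # precompute successor tables
    succ: dict[MoleculeState, tuple[list[MoleculeState], np.ndarray, float]] = {}
    for s in states:
        edges = successors(s, model.mech)
        targets = [t for t, _ in edges]
        rates = np.array(
            [model.generator[index[s], index[t]] for t in targets], dtype=float
        )
        keep = rates > 0
        targets = [t for t, k in zip(targets, keep) if k]
        rates = rates[keep]
        succ[s] = (targets, np.cumsum(rates), float(rates.sum()))

    trajectories: list[list[tuple[float, MoleculeState]]] = []
    occupancy = np.zeros((times.size, len(states)))
    for _ in range(n_molecules):
        t = 0.0
        s = START_STATE
        traj = [(0.0, s)]
        while True:
            targets, cum, total = succ[s]
            if total == 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > t_max:
                break
            s = targets[int(np.searchsorted(cum, rng.random() * total))]
            traj.append((t, s))
        trajectories.append(traj)
        # bin occupancy: state at each grid time
        ev_times = [et for et, _ in traj]
        for i, gt in enumerate(times):
            k = int(np.searchsorted(ev_times, gt, side="right")) - 1
            occupancy[i, index[traj[k][1]]] += 1.0
    occupancy /= n_molecules
    return trajectories, TimeCourse(times, occupancy, tuple(states))


def trajectories_to_frame(
    trajectories: Iterable[Iterable[tuple[float, MoleculeState]]]
) -> pd.DataFrame:
    """Event-list representation of SSA output (one row per transition)."""
    rows = []
    for mid, traj in enumerate(trajectories):
        traj = list(traj)
        for (t0, a), (t1, b) in zip(traj, traj[1:]):
            rows.append(
                {
                    "molecule_id": mid,
                    "time_s": t1,
                    "from_state": a.label,
                    "to_state": b.label,
                }
            )
    return pd.DataFrame(rows, columns=["molecule_id", "time_s", "from_state", "to_state"])


def half_life(
    tc: TimeCourse, species: Callable[[MoleculeState], bool] | np.ndarray
) -> float:
    """Time at which a decaying species set first reaches half its t=0 level.

    The summed fraction must be monotone non-increasing (checked up to
    numerical tolerance); the crossing is located by linear interpolation
    between grid points.  Raises :class:`HalfLifeNotReached` if the curve
    never falls to half within the grid.
    """
    if callable(species):
        curve = tc.species_fraction(species)
    else:
        curve = tc.fractions[:, np.asarray(species, dtype=bool)].sum(axis=1)
    if np.any(np.diff(curve) > 1e-9):
        raise ValueError("species fraction is not monotone decreasing")
    f0 = curve[0]
    if f0 <= 0:
        raise ValueError("species fraction is zero at t=0")
    target = f0 / 2.0
    below = np.nonzero(curve <= target)[0]
    if below.size == 0:
        raise HalfLifeNotReached(
            f"fraction only fell to {curve[-1] / f0:.3f} of its initial value"
        )
    i = int(below[0])
    if i == 0:
        return float(tc.times[0])
    t0, t1 = tc.times[i - 1], tc.times[i]
    y0, y1 = curve[i - 1], curve[i]
    return float(t0 + (y0 - target) / (y0 - y1) * (t1 - t0))


def species_half_life(
    model: KineticModel,
    species: Callable[[MoleculeState], bool],
    t_upper: float = 1e7,
) -> float:
    """Exact half-life of a decaying species set, by root finding on the CME."""
    mask = model.mask(species)
    p0 = np.zeros(model.n_states)
    p0[model.index[START_STATE]] = 1.0
    f0 = p0[mask].sum()

    def frac(t: float) -> float:
        return float((p0 @ expm(model.generator * t))[mask].sum()) - f0 / 2.0

    if frac(t_upper) > 0:
        raise HalfLifeNotReached("species does not decay to half by t_upper")
    return float(brentq(frac, 0.0, t_upper, xtol=1e-10, rtol=1e-12))


def is_seb(state: MoleculeState) -> bool:
    """True for single-end-break states (exactly one end fully cut)."""
    return state.phase == SYNAPSED and (state.left == D) != (state.right == D)


def has_partner_nick(state: MoleculeState) -> bool:
    """True for SEB states whose uncleaved partner end is NTS-nicked."""
    if not is_seb(state):
        return False
    partner = state.right if state.left == D else state.left
    return partner == N


def seb_partner_nick_prob(tc: TimeCourse, t: float) -> float:
    """P(partner end nicked | molecule is a single-end-break) at time ``t``.

    This is the discriminating statistic of the SEB strand-analysis
    experiment: the constrained mechanism forces it to 1 (an SEB with an
    intact partner NTS is unreachable), the sequential mechanism starts at
    0, and the independent mechanism gives an intermediate, rate-dependent
    value.
    """
    dist = tc.at(t)
    seb_mass = dist[tc.mask(is_seb)].sum()
    if seb_mass <= 1e-12:
        raise UndefinedDiagnostic(f"no single-end-break mass at t={t}")
    nicked = dist[tc.mask(has_partner_nick)].sum()
    return float(nicked / seb_mass)
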