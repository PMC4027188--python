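"""Continuous-time Markov chains for the three transposon-cleavage mechanisms.

A transpososome molecule is tracked by a discrete state: whether the two
ends are synapsed, the cleavage status of each end (U uncut, N NTS-nicked,
D double-strand break) and — for the constrained mechanism — whether the
coordinated conformational transition that licenses TS cleavage has
occurred.  At a given end the NTS is always cleaved before the TS, so a
"TS-only" end state does not exist.

The three candidate mechanisms differ only in which transitions are
allowed:

``independent``
    each end nicks and then cleaves its TS on its own schedule;
``sequential``
    the double-strand break is completed at one end before any chemistry
    starts at the other;
``constrained``
    both NTS must be nicked, and a single coordinated transition (whose
    rate couples the competence of the two half-sites) must occur, before
    either TS is cut.

Synapsis is modelled as committed and pseudo-first-order (transposase in
excess over substrate), integration as a single lumped terminal step that
joins both transposon 3' ends to a target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .substrate_model import Substrate, WT_END

__all__ = [
    "U",
    "N",
    "D",
    "FREE",
    "SYNAPSED",
    "INTEGRATED",
    "MoleculeState",
    "RateSet",
    "MechanismSpec",
    "TransposaseVariant",
    "MECHANISMS",
    "TRANSPOSASE_PRESETS",
    "coupling",
    "enumerate_states",
    "successors",
    "build_generator",
    "KineticModel",
    "chemical_event_count",
    "calibrate_rates",
    "default_rates",
    "wt_substrate",
]

# end cleavage status
U, N, D = "U", "N", "D"
_END_ORDER = {U: 0, N: 1, D: 2}

# molecule phase
FREE, SYNAPSED, INTEGRATED = "FREE", "SYNAPSED", "INTEGRATED"


@dataclass(frozen=True)
class MoleculeState:
    """Discrete state of one substrate molecule."""

    phase: str = FREE
    left: str = U
    right: str = U
    transition_done: bool = False

    def __post_init__(self) -> None:
        if self.phase not in (FREE, SYNAPSED, INTEGRATED):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.left not in _END_ORDER or self.right not in _END_ORDER:
            raise ValueError("end states must be U, N or D")
        if self.phase == FREE and (self.left, self.right) != (U, U):
            raise ValueError("nicking requires synapsis: FREE implies U/U")
        if self.phase == INTEGRATED and (self.left, self.right) != (D, D):
            raise ValueError("integration requires a double-end break")

    @property
    def label(self) -> str:
        if self.phase == FREE:
            return "FREE"
        if self.phase == INTEGRATED:
            return "INTEGRATED"
        body = self.left + self.right
        if (self.left, self.right) == (N, N):
            return body + ("/post" if self.transition_done else "/pre")
        return body

    def end(self, which: str) -> str:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError("end must be 'left' or 'right'")

    def mirrored(self) -> "MoleculeState":
        return replace(self, left=self.right, right=self.left)


START_STATE = MoleculeState()


@dataclass(frozen=True)
class RateSet:
    """First-order rate constants (s^-1) for the cleavage pathway.

    ``k_syn``   pseudo-first-order synapsis (transposase in excess);
    ``k_nts``   NTS nicking, per end;
    ``k_trans`` coordinated conformational transition (constrained only);
    ``k_ts``    TS cleavage chemistry, per end;
    ``k_int``   lumped integration of the double-end-break product.
    """

    k_syn: float
    k_nts: float
    k_trans: float
    k_ts: float
    k_int: float

    def __post_init__(self) -> None:
        for name in ("k_syn", "k_nts", "k_trans", "k_ts", "k_int"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def with_updates(self, **kw: float) -> "RateSet":
        return replace(self, **kw)


_COUPLING_RULES = ("additive", "multiplicative", "min")


@dataclass(frozen=True)
class MechanismSpec:
    """One of the three candidate cleavage mechanisms."""

    kind: str
    coupling_rule: str = "additive"

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "sequential", "constrained"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.coupling_rule not in _COUPLING_RULES:
            raise ValueError(f"coupling_rule must be one of {_COUPLING_RULES}")


MECHANISMS: dict[str, MechanismSpec] = {
    "independent": MechanismSpec("independent"),
    "sequential": MechanismSpec("sequential"),
    "constrained": MechanismSpec("constrained"),
}


@dataclass(frozen=True)
class TransposaseVariant:
    """Transposase protein variant as multiplicative rate modifiers."""

    name: str = "WT"
    syn_multiplier: float = 1.0
    trans_multiplier: float = 1.0
    ts_multiplier: float = 1.0
    coupling_override: str | None = None

    def __post_init__(self) -> None:
        for name in ("syn_multiplier", "trans_multiplier", "ts_multiplier"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.coupling_override is not None and self.coupling_override not in _COUPLING_RULES:
            raise ValueError(f"coupling_override must be one of {_COUPLING_RULES}")


WT_TRANSPOSASE = TransposaseVariant("WT")

# WVPHEL-motif presets.  Both mutants synapse faster than wild type; the
# hyperactive W118R weakens the inter-subunit coupling (a mutant half-site is
# no longer rescued by a wild-type partner, modelled as multiplicative
# coupling), while the hypoactive V119G is strongly defective in the
# coordinated transition itself.
TRANSPOSASE_PRESETS: dict[str, TransposaseVariant] = {
    "WT": WT_TRANSPOSASE,
    "W118R": TransposaseVariant(
        "W118R", syn_multiplier=5.0, trans_multiplier=0.5, coupling_override="multiplicative"
    ),
    "V119G": TransposaseVariant("V119G", syn_multiplier=5.0, trans_multiplier=0.05),
}


def coupling(k_trans: float, c_left: float, c_right: float, rule: str) -> float:
    """Effective coordinated-transition rate for two half-site competences."""
    if not (0.0 <= c_left <= 1.0 and 0.0 <= c_right <= 1.0):
        raise ValueError("competences must lie in [0, 1]")
    if rule == "additive":
        return k_trans * (c_left + c_right) / 2.0
    if rule == "multiplicative":
        return k_trans * c_left * c_right
    if rule == "min":
        return k_trans * min(c_left, c_right)
    raise ValueError(f"unknown coupling rule {rule!r}")


# ---------------------------------------------------------------------------
# transition structure

#: edge kinds: ("syn", None), ("nts", end), ("trans", None), ("ts", end),
#: ("int", None)
Edge = tuple[MoleculeState, tuple[str, str | None]]


def successors(state: MoleculeState, mech: MechanismSpec) -> list[Edge]:
    """Allowed transitions out of ``state`` under mechanism ``mech``.

    Order is deterministic: synapsis; left-end before right-end events and
    nicking before TS cleavage at an end; the coordinated transition; then
    integration.
    """
    kind = mech.kind
    if state.phase == FREE:
        return [(MoleculeState(SYNAPSED, U, U), ("syn", None))]
    if state.phase == INTEGRATED:
        return []
    out: list[Edge] = []
    for end in ("left", "right"):
        mine = state.end(end)
        other = state.end("right" if end == "left" else "left")
        if mine == U:
            # NTS nick. Sequential: allowed from U/U at either end, otherwise
            # only once the partner break is complete.
            if kind != "sequential" or other in (U, D):
                out.append((replace(state, **{end: N}), ("nts", end)))
        elif mine == N:
            if kind == "independent":
                ok = True
            elif kind == "sequential":
                # only the end that initiated (partner still U) or the second
                # end after the partner break is complete
                ok = other in (U, D)
            else:  # constrained: TS requires the coordinated transition
                ok = state.transition_done
            if ok:
                out.append((replace(state, **{end: D}), ("ts", end)))
    if (
        kind == "constrained"
        and (state.left, state.right) == (N, N)
        and not state.transition_done
    ):
        out.append((replace(state, transition_done=True), ("trans", None)))
    if (state.left, state.right) == (D, D):
        out.append(
            (MoleculeState(INTEGRATED, D, D, state.transition_done), ("int", None))
        )
    return out


@lru_cache(maxsize=None)
def _enumerate(kind: str, rule: str) -> tuple[MoleculeState, ...]:
    mech = MechanismSpec(kind, rule)
    order: list[MoleculeState] = [START_STATE]
    seen = {START_STATE}
    frontier = [START_STATE]
    while frontier:
        nxt: list[MoleculeState] = []
        for s in frontier:
            for t, _ in successors(s, mech):
                if t not in seen:
                    seen.add(t)
                    order.append(t)
                    nxt.append(t)
        frontier = nxt
    return tuple(order)


def enumerate_states(mech: MechanismSpec) -> list[MoleculeState]:
    """All states reachable from FREE, in breadth-first order.

    Mirror states (left/right swapped) are distinct; for the constrained
    mechanism the N/N state appears twice (before and after the coordinated
    transition).
    """
    return list(_enumerate(mech.kind, mech.coupling_rule))


def _edge_rate(
    key: tuple[str, str | None],
    mech: MechanismSpec,
    rates: RateSet,
    sub: Substrate,
    tpase: TransposaseVariant,
) -> float:
    what, end = key
    if what == "syn":
        return rates.k_syn * tpase.syn_multiplier
    if what == "nts":
        return rates.k_nts * sub.end(end).nts_factor
    if what == "trans":
        rule = tpase.coupling_override or mech.coupling_rule
        return coupling(
            rates.k_trans * tpase.trans_multiplier,
            sub.left_end.competence,
            sub.right_end.competence,
            rule,
        )
    if what == "ts":
        return rates.k_ts * sub.end(end).ts_factor * tpase.ts_multiplier
    if what == "int":
        return rates.k_int
    raise ValueError(f"unknown edge kind {key!r}")


def build_generator(
    mech: MechanismSpec,
    rates: RateSet,
    sub: Substrate,
    tpase: TransposaseVariant = WT_TRANSPOSASE,
) -> tuple[np.ndarray, list[MoleculeState]]:
    """Infinitesimal generator matrix Q over ``enumerate_states(mech)``.

    Q[i, j] for i != j is the rate of the i -> j transition; diagonals make
    each row sum to zero.  INTEGRATED is absorbing.
    """
    if mech.kind != "constrained" and rates.k_trans > 0:
        warnings.warn(
            f"k_trans is ignored by the {mech.kind} mechanism",
            stacklevel=2,
        )
    states = enumerate_states(mech)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    for i, s in enumerate(states):
        for t, key in successors(s, mech):
            q[i, index[t]] += _edge_rate(key, mech, rates, sub, tpase)
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q, states


class KineticModel:
    """A mechanism + rates + substrate + transposase bundle.

    Caches the state enumeration and generator matrix and provides the
    state-class masks used by the gel and inference layers.
    """

    def __init__(
        self,
        mech: MechanismSpec | str,
        rates: RateSet,
        substrate: Substrate,
        tpase: TransposaseVariant = WT_TRANSPOSASE,
    ) -> None:
        self.mech = MECHANISMS[mech] if isinstance(mech, str) else mech
        self.rates = rates
        self.substrate = substrate
        self.tpase = tpase
        self.generator, self.states = build_generator(
            self.mech, rates, substrate, tpase
        )
        self.index = {s: i for i, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def mask(self, predicate: Callable[[MoleculeState], bool]) -> np.ndarray:
        return np.array([bool(predicate(s)) for s in self.states])

    def replace(self, **kw) -> "KineticModel":
        args = dict(
            mech=self.mech, rates=self.rates, substrate=self.substrate, tpase=self.tpase
        )
        args.update(kw)
        return KineticModel(**args)


def chemical_event_count(trajectory: Sequence[MoleculeState]) -> int:
    """Number of strand breaking/joining events along a state trajectory.

    Each NTS nick and each TS cut is one strand break; integration joins
    both transposon 3' ends to the target and counts as two joining events.
    Synapsis and the coordinated transition are conformational, not
    chemical.  A complete path from intact substrate to integrated product
    therefore records six events.
    """
    count = 0
    for a, b in zip(trajectory, trajectory[1:]):
        changed = [
            end for end in ("left", "right") if a.end(end) != b.end(end)
        ]
        if a.phase == FREE and b.phase == SYNAPSED:
            legal = not changed
            delta = 0
        elif a.phase == SYNAPSED and b.phase == INTEGRATED:
            legal = (a.left, a.right) == (D, D) and not changed
            delta = 2
        elif a.phase == b.phase == SYNAPSED:
            if len(changed) == 1:
                end = changed[0]
                step = (_END_ORDER[b.end(end)] - _END_ORDER[a.end(end)]) == 1
                legal = step
                delta = 1
            elif not changed:
                # coordinated transition only
                legal = b.transition_done and not a.transition_done
                delta = 0
            else:
                legal = False
                delta = 0
        else:
            legal = False
            delta = 0
        if not legal:
            raise ValueError(f"illegal transition {a.label} -> {b.label}")
        count += delta
    return count


# ---------------------------------------------------------------------------
# default-rate calibration


def _hypoexp_survival(stage_rates: Sequence[float], t: float) -> float:
    """P(sum of independent Exp(rate_i) > t), via a linear-chain generator."""
    k = len(stage_rates)
    q = np.zeros((k + 1, k + 1))
    for i, r in enumerate(stage_rates):
        q[i, i] = -r
        q[i, i + 1] = r
    p = expm(q * t)[0]
    return float(p[:k].sum())


def calibrate_rates(
    nts_half_life: float = 30.0,
    ts_half_life: float = 900.0,
    synapsis_share: float = 0.95,
    ts_to_trans_ratio: float = 10.0,
) -> RateSet:
    """Calibrate the default rate constants to the observed half-lives.

    Kinetic studies of this reaction put the half-life of NTS cleavage
    (supercoiled-substrate consumption, which lumps synapsis with the first
    nick) near 30 s and that of TS cleavage near 15 min.  Supercoiled
    consumption is dominated by synapsis — a substrate that pairs a
    wild-type with a nicking-dead end is consumed at the wild-type rate —
    so by default 95% of the mean NTS waiting time is assigned to synapsis.
    The long NTS-to-TS delay is attributed to the coordinated transition,
    so ``k_trans`` is made rate limiting with ``k_ts = 10 * k_trans``;
    integration is not rate-analysed and ``k_int = k_ts``.

    The two half-lives are matched exactly (to solver tolerance) for the
    wild-type constrained pathway.
    """
    if not (0.0 < synapsis_share < 1.0):
        raise ValueError("synapsis_share must lie strictly between 0 and 1")

    # stage means: synapsis = share * m, first nick (rate 2 k_nts) = (1-share) * m
    def sc_gap(m: float) -> float:
        a = 1.0 / (synapsis_share * m)
        b = 1.0 / ((1.0 - synapsis_share) * m)
        return _hypoexp_survival((a, b), nts_half_life) - 0.5

    m = brentq(sc_gap, nts_half_life / 50.0, nts_half_life * 5.0, xtol=1e-12)
    k_syn = 1.0 / (synapsis_share * m)
    k_nts = 0.5 / ((1.0 - synapsis_share) * m)

    # survival of "no TS cut yet" along the wild-type constrained chain:
    # synapsis, first nick (2 k_nts), second nick (k_nts), transition
    # (k_trans), first TS cut (2 k_ts)
    def ts_gap(log_kt: float) -> float:
        kt = math.exp(log_kt)
        chain = (k_syn, 2 * k_nts, k_nts, kt, 2 * ts_to_trans_ratio * kt)
        return _hypoexp_survival(chain, ts_half_life) - 0.5

    log_kt = brentq(ts_gap, math.log(1e-7), math.log(1e2), xtol=1e-13)
    k_trans = math.exp(log_kt)
    k_ts = ts_to_trans_ratio * k_trans
    return RateSet(k_syn=k_syn, k_nts=k_nts, k_trans=k_trans, k_ts=k_ts, k_int=k_ts)


@lru_cache(maxsize=8)
def _default_rates_cached(args: tuple) -> RateSet:
    return calibrate_rates(*args)


def default_rates(
    nts_half_life: float = 30.0,
    ts_half_life: float = 900.0,
    synapsis_share: float = 0.95,
    ts_to_trans_ratio: float = 10.0,
) -> RateSet:
    """Cached :func:`calibrate_rates` with the default calibration targets."""
    return _default_rates_cached(
        (nts_half_life, ts_half_life, synapsis_share, ts_to_trans_ratio)
    )


def wt_substrate() -> Substrate:
    """The default wild-type donor plasmid (WT × WT)."""
    return Substrate("WT × WT", WT_END, WT_END)
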