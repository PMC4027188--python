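"""State spaces, generators and event accounting of the three mechanisms."""

import numpy as np
import pytest

from transpososim.kinetic_models import (
    D,
    FREE,
    INTEGRATED,
    KineticModel,
    MECHANISMS,
    MoleculeState,
    N,
    RateSet,
    SYNAPSED,
    TRANSPOSASE_PRESETS,
    U,
    build_generator,
    chemical_event_count,
    coupling,
    default_rates,
    enumerate_states,
    wt_substrate,
)
from transpososim.simulator import DEFAULT_T_GRID, solve_master
from transpososim.substrate_model import EndVariant, Substrate, five_g_end


# ---------------------------------------------------------------------------
# independent reachability oracle: fixed-point closure over explicitly
# spelled-out transition rules on (phase, left, right, transition_done)
# tuples, written without reference to the package's successor function.


def _oracle_moves(state, kind):
    phase, left, right, td = state
    if phase == "FREE":
        return [("SYN", "U", "U", False)]
    if phase == "INT":
        return []
    moves = []
    ends = {"L": (left, right), "R": (right, left)}
    for side, (mine, other) in ends.items():

        def put(new_mine, new_td=td):
            if side == "L":
                moves.append(("SYN", new_mine, right, new_td))
            else:
                moves.append(("SYN", left, new_mine, new_td))

        if kind == "independent":
            if mine == "U":
                put("N")
            if mine == "N":
                put("D")
        elif kind == "sequential":
            if mine == "U" and (other == "U" or other == "D"):
                put("N")
            if mine == "N" and other != "N":
                put("D")
        else:  # constrained
            if mine == "U":
                put("N")
            if mine == "N" and td:
                put("D")
    if kind == "constrained" and left == right == "N" and not td:
        moves.append(("SYN", "N", "N", True))
    if left == right == "D":
        moves.append(("INT", "D", "D", td))
    return moves


def oracle_reachable(kind):
    seen = {("FREE", "U", "U", False)}
    frontier = list(seen)
    while frontier:
        nxt = []
        for s in frontier:
            for t in _oracle_moves(s, kind):
                if t not in seen:
                    seen.add(t)
                    nxt.append(t)
        frontier = nxt
    return seen


def _as_tuple(state):
    phase = {"FREE": "FREE", "SYNAPSED": "SYN", "INTEGRATED": "INT"}[state.phase]
    return (phase, state.left, state.right, state.transition_done)


class TestEnumeration:
    @pytest.mark.parametrize(
        "kind,expected_count",
        [("independent", 11), ("sequential", 10), ("constrained", 10)],
    )
    def test_state_count_matches_reachability_oracle(self, kind, expected_count):
        states = enumerate_states(MECHANISMS[kind])
        assert len(states) == expected_count
        assert {_as_tuple(s) for s in states} == oracle_reachable(kind)

    def test_sequential_has_no_double_nicked_state(self):
        labels = {s.label for s in enumerate_states(MECHANISMS["sequential"])}
        assert not any(lbl.startswith("NN") for lbl in labels)

    def test_constrained_splits_nn_by_transition(self):
        labels = [s.label for s in enumerate_states(MECHANISMS["constrained"])]
        assert "NN/pre" in labels and "NN/post" in labels

    def test_cleavage_progresses_one_strand_at_a_time(self):
        # the NTS is always cleaved before the TS at a given end: every
        # reachable transition advances at most one end, by exactly one
        # cleavage level (U -> N -> D, never U -> D)
        order = {"U": 0, "N": 1, "D": 2}
        for kind in MECHANISMS:
            for s in oracle_reachable(kind):
                for t in _oracle_moves(s, kind):
                    diffs = sorted(order[t[i]] - order[s[i]] for i in (1, 2))
                    assert diffs in ([0, 0], [0, 1])

    def test_mirror_states_are_distinct(self):
        states = enumerate_states(MECHANISMS["sequential"])
        nu = MoleculeState(SYNAPSED, N, U)
        un = MoleculeState(SYNAPSED, U, N)
        assert nu in states and un in states and nu != un

    def test_constrained_seb_always_has_partner_nick(self):
        for s in enumerate_states(MECHANISMS["constrained"]):
            if (s.left == D) != (s.right == D):
                partner = s.right if s.left == D else s.left
                assert partner in (N, D)


class TestCoupling:
    def test_rules_arithmetic(self):
        assert coupling(1.0, 1.0, 0.05, "additive") == pytest.approx(0.525)
        assert coupling(1.0, 1.0, 0.05, "multiplicative") == pytest.approx(0.05)
        assert coupling(2.0, 1.0, 0.05, "min") == pytest.approx(0.1)

    @pytest.mark.parametrize("rule", ["additive", "multiplicative", "min"])
    def test_wild_type_homodimer_limit(self, rule):
        assert coupling(3.7, 1.0, 1.0, rule) == pytest.approx(3.7)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            coupling(1.0, 1.0, 1.0, "geometric")


class TestGenerator:
    @pytest.mark.parametrize("kind", list(MECHANISMS))
    def test_rows_sum_to_zero_offdiagonals_nonnegative(self, kind, rates, wt_sub):
        r = rates if kind == "constrained" else rates.with_updates(k_trans=0.0)
        q, states = build_generator(MECHANISMS[kind], r, wt_sub)
        off = q - np.diag(q.diagonal())
        assert np.all(off >= 0)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_mutant_end_scales_its_own_nick_rate(self, rates):
        sub = Substrate("5G × WT", five_g_end(), EndVariant("WT"))
        q, states = build_generator(MECHANISMS["constrained"], rates, sub)
        idx = {s.label: i for i, s in enumerate(states)}
        left_nick = q[idx["UU"], idx["NU"]]
        right_nick = q[idx["UU"], idx["UN"]]
        assert left_nick / right_nick == pytest.approx(five_g_end().nts_factor)

    def test_constrained_forbids_ts_before_transition(self, rates, wt_sub):
        q, states = build_generator(MECHANISMS["constrained"], rates, wt_sub)
        idx = {s.label: i for i, s in enumerate(states)}
        assert q[idx["NN/pre"], idx["DN"]] == 0.0
        assert q[idx["NN/pre"], idx["ND"]] == 0.0
        assert q[idx["NN/post"], idx["DN"]] > 0.0

    def test_k_trans_warning_for_non_constrained(self, rates, wt_sub):
        with pytest.warns(UserWarning, match="k_trans"):
            build_generator(MECHANISMS["independent"], rates, wt_sub)

    def test_neutral_heteroduplex_matches_homoduplex_up_to_mirror(self, rates):
        neutral = EndVariant("mut0", (2,), 1.0, 1.0, 1.0)
        homo = Substrate("wt", EndVariant("WT"), EndVariant("WT"))
        hetero = Substrate("h", EndVariant("WT"), neutral)
        for kind in MECHANISMS:
            r = rates if kind == "constrained" else rates.with_updates(k_trans=0.0)
            q1, states = build_generator(MECHANISMS[kind], r, homo)
            q2, states2 = build_generator(MECHANISMS[kind], r, hetero)
            assert states == states2
            assert np.allclose(q1, q2)
            # and mirroring the states permutes the generator onto itself
            mirror = [states.index(s.mirrored()) for s in states]
            assert np.allclose(q2, q2[np.ix_(mirror, mirror)])

    def test_transposase_multipliers_enter_where_expected(self, rates, wt_sub):
        w = TRANSPOSASE_PRESETS["W118R"]
        q0, states = build_generator(MECHANISMS["constrained"], rates, wt_sub)
        q1, _ = build_generator(MECHANISMS["constrained"], rates, wt_sub, w)
        idx = {s.label: i for i, s in enumerate(states)}
        assert q1[idx["FREE"], idx["UU"]] == pytest.approx(
            w.syn_multiplier * q0[idx["FREE"], idx["UU"]]
        )
        assert q1[idx["NN/pre"], idx["NN/post"]] == pytest.approx(
            w.trans_multiplier * q0[idx["NN/pre"], idx["NN/post"]]
        )


class TestRateLimits:
    def test_fast_transition_fast_ts_limits_agree_on_excision(self, rates, wt_sub):
        """Sequential with instantaneous TS chemistry and constrained with an
        instantaneous transition + TS chemistry hit the double-end break
        through the same hypoexponential stage structure, so their excision
        curves coincide in the limit."""
        fast = 1e3
        seq = KineticModel(
            "sequential", rates.with_updates(k_trans=0.0, k_ts=fast), wt_sub
        )
        con = KineticModel(
            "constrained", rates.with_updates(k_trans=fast, k_ts=fast), wt_sub
        )
        grid = np.array([0.0, 5.0, 15.0, 30.0, 60.0, 120.0, 300.0])
        a = solve_master(seq, grid).species_fraction(lambda s: (s.left, s.right) == (D, D))
        b = solve_master(con, grid).species_fraction(lambda s: (s.left, s.right) == (D, D))
        assert np.max(np.abs(a - b)) < 1e-3


class TestCalibration:
    def test_half_lives_match_targets_exactly(self, models):
        from transpososim.simulator import species_half_life

        m = models["constrained"]
        sc = species_half_life(m, lambda s: (s.left, s.right) == (U, U))
        ts = species_half_life(m, lambda s: D not in (s.left, s.right))
        assert sc == pytest.approx(30.0, rel=1e-6)
        assert ts == pytest.approx(900.0, rel=1e-6)

    def test_rateset_validation(self):
        with pytest.raises(ValueError):
            RateSet(-1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            RateSet(float("nan"), 1.0, 1.0, 1.0, 1.0)


class TestEventCount:
    def _constrained_path(self, with_integration=True):
        path = [
            MoleculeState(),
            MoleculeState(SYNAPSED, U, U),
            MoleculeState(SYNAPSED, N, U),
            MoleculeState(SYNAPSED, N, N),
            MoleculeState(SYNAPSED, N, N, True),
            MoleculeState(SYNAPSED, D, N, True),
            MoleculeState(SYNAPSED, D, D, True),
        ]
        if with_integration:
            path.append(MoleculeState(INTEGRATED, D, D, True))
        return path

    def test_complete_pathway_records_six_events(self):
        assert chemical_event_count(self._constrained_path()) == 6

    def test_path_to_double_end_break_records_four(self):
        assert chemical_event_count(self._constrained_path(False)) == 4

    def test_empty_and_singleton_paths(self):
        assert chemical_event_count([]) == 0
        assert chemical_event_count([MoleculeState()]) == 0

    def test_illegal_transitions_rejected(self):
        with pytest.raises(ValueError):
            chemical_event_count(
                [MoleculeState(SYNAPSED, U, U), MoleculeState(SYNAPSED, D, U)]
            )
        with pytest.raises(ValueError):
            chemical_event_count(
                [MoleculeState(SYNAPSED, N, U), MoleculeState(SYNAPSED, U, U)]
            )
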