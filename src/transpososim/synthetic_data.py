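"""Synthetic quantified-gel datasets with known ground truth.

No numerical band quantifications exist for the real gels, so inference is
benchmarked on synthetic data whose statistical structure matches what
densitometry of such gels would produce: per-time-point molar fractions of
the native species classes (and, optionally, the SEB partner-nick
probability from the strand-analysis experiment), corrupted by independent
multiplicative lognormal noise per band, time point and replicate, and
optionally re-normalised within each lane.

The generating truth (mechanism, rates, substrate, transposase, seed) is
stored alongside the observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetic_models import (
    KineticModel,
    MechanismSpec,
    MECHANISMS,
    RateSet,
    TransposaseVariant,
    TRANSPOSASE_PRESETS,
    WT_TRANSPOSASE,
    default_rates,
    wt_substrate,
)
from .simulator import (
    DEFAULT_T_GRID,
    TimeCourse,
    UndefinedDiagnostic,
    gillespie,
    seb_partner_nick_prob,
    solve_master,
)
from .substrate_model import (
    Substrate,
    WT_END,
    five_g_end,
    point_mutant_end,
)
from .virtual_gel import NATIVE_CLASSES, native_species

__all__ = [
    "SyntheticDataset",
    "Scenario",
    "generate",
    "scenario_presets",
    "get_scenario",
    "native_fraction_frame",
    "SEB_OBSERVABLE",
    "DEFAULT_NOISE_SD",
]

SEB_OBSERVABLE = "seb_partner_nick"

#: default lognormal sigma (natural-log scale) mimicking densitometry error
DEFAULT_NOISE_SD = 0.15


@dataclass(frozen=True)
class Scenario:
    """A named experimental configuration (substrate, transposase, mechanism)."""

    name: str
    substrate: Substrate
    tpase: TransposaseVariant = WT_TRANSPOSASE
    mechanism: MechanismSpec = MECHANISMS["constrained"]
    rates: RateSet | None = None

    def model(self, rates: RateSet | None = None, mechanism=None) -> KineticModel:
        mech = mechanism or self.mechanism
        r = rates or self.rates or default_rates()
        if mech.kind != "constrained" and r.k_trans > 0:
            r = r.with_updates(k_trans=0.0)
        return KineticModel(mech, r, self.substrate, self.tpase)


@dataclass
class SyntheticDataset:
    """Tidy noisy observations plus the generating truth."""

    scenario: str
    mechanism: MechanismSpec
    rates: RateSet
    substrate: Substrate
    tpase: TransposaseVariant
    times: tuple[float, ...]
    observables: tuple[str, ...]
    noise_sd: float
    seed: int
    normalization: str
    n_replicates: int
    data: pd.DataFrame = field(repr=False)
    truth: pd.DataFrame = field(repr=False)

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write observations as tidy CSV plus a JSON truth/seed sidecar."""
        self.data.to_csv(path, index=False)
        sidecar = sidecar_path or (str(path) + ".json")
        meta = {
            "scenario": self.scenario,
            "mechanism": {
                "kind": self.mechanism.kind,
                "coupling_rule": self.mechanism.coupling_rule,
            },
            "rates": asdict(self.rates),
            "substrate": {
                "name": self.substrate.name,
                "left": asdict(self.substrate.left_end),
                "right": asdict(self.substrate.right_end),
                "element_length": self.substrate.element_length,
                "backbone_length": self.substrate.backbone_length,
                "digest_site": self.substrate.digest_site,
            },
            "tpase": asdict(self.tpase),
            "times": list(self.times),
            "observables": list(self.observables),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "normalization": self.normalization,
            "n_replicates": self.n_replicates,
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2)


def native_fraction_frame(tc: TimeCourse) -> pd.DataFrame:
    """Native species-class fractions (columns) per time point (rows)."""
    cols = {}
    for cls in NATIVE_CLASSES:
        cols[cls] = tc.species_fraction(lambda s, c=cls: native_species(s) == c)
    return pd.DataFrame(cols, index=pd.Index(tc.times, name="time_s"))


def _true_observables(
    tc: TimeCourse, observables: Sequence[str]
) -> list[tuple[float, str, float]]:
    rows: list[tuple[float, str, float]] = []
    native = native_fraction_frame(tc)
    for t in tc.times:
        for obs in observables:
            if obs == SEB_OBSERVABLE:
                try:
                    rows.append((t, obs, seb_partner_nick_prob(tc, t)))
                except UndefinedDiagnostic:
                    continue  # no SEB mass yet: nothing to quantify
            else:
                rows.append((t, obs, float(native.loc[t, obs])))
    return rows


def generate(
    scenario: "Scenario | str",
    mech: MechanismSpec | None = None,
    rates: RateSet | None = None,
    t_grid: Sequence[float] = DEFAULT_T_GRID,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    n_replicates: int = 3,
    observables: Sequence[str] = NATIVE_CLASSES + (SEB_OBSERVABLE,),
    normalization: str = "per_lane",
    sampling: str = "master",
    n_molecules: int = 10_000,
) -> SyntheticDataset:
    """Generate a noisy quantified-gel dataset for one scenario.

    True fractions come from the master equation (or from a Gillespie run
    of ``n_molecules`` molecules when ``sampling="ssa"``, adding
    finite-count noise).  Each observed value is the truth times
    ``exp(eps)`` with ``eps ~ N(0, noise_sd^2)`` drawn independently per
    observable, time point and replicate; with ``normalization="per_lane"``
    the native-class values of each lane are then rescaled to sum to one
    (the partner-nick probability is a ratio and is never renormalised).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if normalization not in ("per_lane", "none"):
        raise ValueError("normalization must be 'per_lane' or 'none'")
    if len(t_grid) == 0:
        raise ValueError("empty time grid")
    scen = get_scenario(scenario) if isinstance(scenario, str) else scenario
    model = scen.model(rates=rates, mechanism=mech)
    if sampling == "master":
        tc = solve_master(model, t_grid)
    elif sampling == "ssa":
        _, tc = gillespie(
            model, n_molecules, t_max=float(t_grid[-1]) or 1.0, seed=seed, t_grid=t_grid
        )
    else:
        raise ValueError("sampling must be 'master' or 'ssa'")

    truth_rows = _true_observables(tc, observables)
    truth = pd.DataFrame(truth_rows, columns=["time_s", "observable", "value"])

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1CE]))
    rows = []
    for rep in range(n_replicates):
        for t, obs, value in truth_rows:
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "scenario": scen.name,
                    "replicate": rep,
                    "time_s": t,
                    "observable": obs,
                    "value": value * float(np.exp(eps)),
                }
            )
    df = pd.DataFrame(rows)
    if normalization == "per_lane":
        nat = df["observable"].isin(NATIVE_CLASSES)
        sums = df[nat].groupby(["replicate", "time_s"])["value"].transform("sum")
        df.loc[nat, "value"] = df.loc[nat, "value"] / sums
    return SyntheticDataset(
        scenario=scen.name,
        mechanism=model.mech,
        rates=model.rates,
        substrate=scen.substrate,
        tpase=scen.tpase,
        times=tuple(float(t) for t in t_grid),
        observables=tuple(observables),
        noise_sd=noise_sd,
        seed=seed,
        normalization=normalization,
        n_replicates=n_replicates,
        data=df,
        truth=truth,
    )


def _sub(name: str, left, right) -> Substrate:
    return Substrate(name, left, right)


def scenario_presets() -> dict[str, Scenario]:
    """Ready-made configurations matching the experimental panels.

    All presets use the constrained mechanism and the calibrated default
    rates; their noiseless outputs reproduce the qualitative gel
    phenotypes (wild type completes; −1T×−1T stalls at the nicked
    intermediate but is rescued by a wild-type partner end; 5G×5G is
    near-inert; the WVPHEL transposase mutants synapse fast, V119G stalls
    after nicking and W118R fails to rescue a −1T partner).
    """
    wt, g5, m1t = WT_END, five_g_end(), point_mutant_end(-1, "T")
    scen: dict[str, Scenario] = {}

    def add(name, sub, tpase=WT_TRANSPOSASE):
        scen[name] = Scenario(name, sub, tpase)

    add("WT × WT", _sub("WT × WT", wt, wt))
    add("5G × 5G", _sub("5G × 5G", g5, g5))
    add("5G × WT", _sub("5G × WT", g5, wt))
    add("-1T × -1T", _sub("-1T × -1T", m1t, m1t))
    add("-1T × WT", _sub("-1T × WT", m1t, wt))
    for base in ("A", "C", "G"):
        end = point_mutant_end(1, base)
        add(f"+1{base} × WT", _sub(f"+1{base} × WT", end, wt))
    add("W118R", _sub("WT × WT", wt, wt), TRANSPOSASE_PRESETS["W118R"])
    add("V119G", _sub("WT × WT", wt, wt), TRANSPOSASE_PRESETS["V119G"])
    add("W118R -1T × WT", _sub("-1T × WT", m1t, wt), TRANSPOSASE_PRESETS["W118R"])
    return scen


def _normalise_name(name: str) -> str:
    return (
        name.replace("×", "x")
        .replace("−", "-")
        .replace(" ", "")
        .upper()
    )


def get_scenario(name: str) -> Scenario:
    """Look up a preset scenario, tolerant of ×/x and spacing variants."""
    presets = scenario_presets()
    wanted = _normalise_name(name)
    for key, scenario in presets.items():
        if _normalise_name(key) == wanted:
            return scenario
    raise KeyError(
        f"unknown scenario {name!r}; available: {sorted(presets)}"
    )
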