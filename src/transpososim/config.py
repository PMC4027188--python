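"""Scenario/configuration file handling (YAML) and dataset round-tripping.

A scenario file names or describes the substrate, transposase, mechanism
and rates for one reaction.  Ends may be given as preset names ("WT",
"5G", point mutants like "-1T" or "+1C") or as explicit factor dictionaries.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .kinetic_models import (
    MECHANISMS,
    MechanismSpec,
    RateSet,
    TRANSPOSASE_PRESETS,
    TransposaseVariant,
    calibrate_rates,
    default_rates,
)
from .substrate_model import (
    EndVariant,
    Substrate,
    WT_END,
    five_g_end,
    point_mutant_end,
)
from .synthetic_data import Scenario, SyntheticDataset, get_scenario

__all__ = [
    "parse_end",
    "parse_substrate",
    "parse_transposase",
    "parse_rates",
    "load_scenario_file",
    "load_dataset",
]

_POINT_RE = re.compile(r"^([+-])(\d)([ACGT])$")


def parse_end(spec: "str | Mapping[str, Any]") -> EndVariant:
    """An EndVariant from a preset name or an explicit mapping."""
    if isinstance(spec, EndVariant):
        return spec
    if isinstance(spec, str):
        name = spec.replace("−", "-").strip()
        if name.upper() == "WT":
            return WT_END
        if name.upper() == "5G":
            return five_g_end()
        m = _POINT_RE.match(name)
        if m:
            sign, pos, base = m.groups()
            return point_mutant_end(int(pos) * (-1 if sign == "-" else 1), base)
        raise ValueError(f"unknown end variant name {spec!r}")
    d = dict(spec)
    d["mutated_positions"] = tuple(d.get("mutated_positions", ()))
    return EndVariant(**d)


def parse_substrate(spec: Mapping[str, Any]) -> Substrate:
    d = dict(spec)
    left = parse_end(d.pop("left", "WT"))
    right = parse_end(d.pop("right", "WT"))
    d.setdefault("name", f"{left.name} × {right.name}")
    return Substrate(left_end=left, right_end=right, **d)


def parse_transposase(spec: "str | Mapping[str, Any] | None") -> TransposaseVariant:
    if spec is None:
        return TRANSPOSASE_PRESETS["WT"]
    if isinstance(spec, TransposaseVariant):
        return spec
    if isinstance(spec, str):
        try:
            return TRANSPOSASE_PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown transposase preset {spec!r}") from None
    return TransposaseVariant(**dict(spec))


def parse_rates(spec: "Mapping[str, Any] | None") -> RateSet:
    """A RateSet from explicit constants or calibration targets."""
    if spec is None:
        return default_rates()
    d = dict(spec)
    if set(d) <= {"nts_half_life", "ts_half_life", "synapsis_share", "ts_to_trans_ratio"}:
        return calibrate_rates(**d)
    base = default_rates()
    return base.with_updates(**d)


def load_scenario_file(path) -> tuple[Scenario, dict[str, Any]]:
    """Load a YAML scenario file.

    Returns the Scenario plus a dict of the remaining run options
    (``t_grid``, ``noise_sd``, ``n_replicates``, ... as given).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("scenario file must contain a mapping")
    extras = {
        k: raw[k]
        for k in ("t_grid", "noise_sd", "n_replicates", "seed", "normalization")
        if k in raw
    }
    if "scenario" in raw:
        scen = get_scenario(raw["scenario"])
        if "rates" in raw or "mechanism" in raw or "transposase" in raw:
            mech = (
                MechanismSpec(**raw["mechanism"])
                if "mechanism" in raw
                else scen.mechanism
            )
            scen = Scenario(
                scen.name,
                scen.substrate,
                parse_transposase(raw.get("transposase", scen.tpase)),
                mech,
                parse_rates(raw.get("rates")) if "rates" in raw else scen.rates,
            )
        return scen, extras
    substrate = parse_substrate(raw.get("substrate", {"name": "WT × WT"}))
    mech = MechanismSpec(**raw.get("mechanism", {"kind": "constrained"}))
    scen = Scenario(
        raw.get("name", substrate.name),
        substrate,
        parse_transposase(raw.get("transposase")),
        mech,
        parse_rates(raw.get("rates")) if "rates" in raw else None,
    )
    return scen, extras


def load_dataset(csv_path, sidecar_path=None) -> SyntheticDataset:
    """Rebuild a SyntheticDataset from its CSV + JSON-sidecar pair."""
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(csv_path) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"dataset sidecar {sidecar} not found (needed for the generating truth)"
        )
    df = pd.read_csv(csv_path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    sub_meta = meta["substrate"]
    substrate = Substrate(
        sub_meta["name"],
        EndVariant(**{**sub_meta["left"], "mutated_positions": tuple(sub_meta["left"]["mutated_positions"])}),
        EndVariant(**{**sub_meta["right"], "mutated_positions": tuple(sub_meta["right"]["mutated_positions"])}),
        sub_meta["element_length"],
        sub_meta["backbone_length"],
        sub_meta["digest_site"],
    )
    return SyntheticDataset(
        scenario=meta["scenario"],
        mechanism=MechanismSpec(**meta["mechanism"]),
        rates=RateSet(**meta["rates"]),
        substrate=substrate,
        tpase=TransposaseVariant(**meta["tpase"]),
        times=tuple(meta["times"]),
        observables=tuple(meta["observables"]),
        noise_sd=meta["noise_sd"],
        seed=meta["seed"],
        normalization=meta["normalization"],
        n_replicates=meta["n_replicates"],
        data=df,
        truth=df[df["replicate"] == 0][["time_s", "observable", "value"]].copy(),
    )
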