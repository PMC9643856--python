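"""Configuration handling and end-to-end model assembly.

The run configuration is a single YAML document (the packaged default
carries the published base-case parameter set).  Every numeric parameter
that enters the sensitivity analyses is stored as a
``{base, low, high, distribution}`` mapping; plain scalars are structural
constants.  This module turns a configuration into
:class:`~sclcea.costing.StrategyDefinition` objects and runs the two-arm
base case.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
from typing import Any

import yaml

from .costing import (
    AdverseEvent,
    DrugAdministration,
    DrugPrice,
    PatientProfile,
    StrategyDefinition,
    bsa_dose,
    carboplatin_dose,
    weight_dose,
)
from .markov_engine import ArmResult, IcerReport, ModelSettings, compute_icer, run_arm
from .parametric_survival import SurvivalModel

__all__ = [
    "load_config",
    "base_value",
    "build_settings",
    "build_patient",
    "build_strategy",
    "run_base_case",
    "config_hash",
]

ARMS = ("adchm", "plchm")


def load_config(path: str | None = None) -> dict:
    """Load a run configuration; with no path, the packaged base case."""
    if path is None:
        ref = importlib.resources.files("sclcea.data").joinpath("base_config.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def base_value(node: Any) -> Any:
    """Base value of a parameter node (mapping with 'base', or scalar)."""
    if isinstance(node, dict) and "base" in node:
        return node["base"]
    return node


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def build_settings(cfg: dict) -> ModelSettings:
    s = cfg["settings"]
    u = cfg["utilities"]
    return ModelSettings(
        cycle_length_days=s["cycle_length_days"],
        n_cycles=s["n_cycles"],
        annual_discount_rate=base_value(s["annual_discount_rate"]),
        wtp_threshold=s["wtp_threshold"],
        engine_mode=s.get("engine_mode", "state_transition"),
        half_cycle_correction=s.get("half_cycle_correction", False),
        utility_pfs=base_value(u["pfs"]),
        utility_pd=base_value(u["pd"]),
    )


def build_patient(cfg: dict) -> PatientProfile:
    p = cfg["patient"]
    return PatientProfile(
        weight_kg=base_value(p["weight_kg"]),
        height_m=base_value(p["height_m"]),
        bsa_m2=base_value(p["bsa_m2"]),
        crcl_ml_min=base_value(p["crcl_ml_min"]),
    )


def _survival_model(node: dict) -> SurvivalModel:
    return SurvivalModel(
        family=node.get("family", "loglogistic"),
        scale=base_value(node["scale"]),
        shape=base_value(node["shape"]),
    )


def _drug(cfg: dict, name: str) -> DrugPrice:
    d = cfg["drugs"][name]
    return DrugPrice(name=name, vial_mg=d["vial_mg"], price_per_vial=base_value(d["price"]))


def build_strategy(
    cfg: dict,
    arm: str,
    pfs_model=None,
    os_model=None,
) -> StrategyDefinition:
    """Assemble one arm's strategy from the configuration.

    ``pfs_model``/``os_model`` override the configured survival curves
    (used by the subgroup construction, which substitutes hazard-ratio
    adjusted baselines).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    patient = build_patient(cfg)
    reg = cfg["regimen"]
    costs = cfg["costs"]

    surv = cfg["survival"][arm]
    pfs = pfs_model if pfs_model is not None else _survival_model(surv["pfs"])
    os_ = os_model if os_model is not None else _survival_model(surv["os"])

    chemo = (
        DrugAdministration(
            price=_drug(cfg, "carboplatin"),
            dose_mg=carboplatin_dose(reg["carboplatin_auc"], patient.crcl_ml_min),
            times_per_cycle=1,
        ),
        DrugAdministration(
            price=_drug(cfg, "etoposide"),
            dose_mg=bsa_dose(reg["etoposide_mg_per_m2"], patient.bsa_m2),
            times_per_cycle=reg["etoposide_days_per_cycle"],
        ),
    )
    maintenance = None
    if arm == "adchm":
        maintenance = DrugAdministration(
            price=_drug(cfg, "adebrelimab"),
            dose_mg=weight_dose(reg["adebrelimab_mg_per_kg"], patient.weight_kg),
            times_per_cycle=1,
        )
    sl = reg["second_line"]
    second_line = (
        DrugAdministration(
            price=_drug(cfg, "irinotecan"),
            dose_mg=bsa_dose(sl["irinotecan_mg_per_m2"], patient.bsa_m2),
            times_per_cycle=sl["irinotecan_days_per_cycle"],
        ),
        DrugAdministration(
            price=_drug(cfg, "cisplatin"),
            dose_mg=bsa_dose(sl["cisplatin_mg_per_m2"], patient.bsa_m2),
            times_per_cycle=sl["cisplatin_days_per_cycle"],
        ),
    )
    aes = tuple(
        AdverseEvent(
            name=a["name"],
            incidence=base_value(a["incidence"]),
            cost=base_value(a["cost"]),
            disutility=base_value(a["disutility"]),
        )
        for a in cfg["adverse_events"][arm]
    )
    return StrategyDefinition(
        name=arm,
        pfs_model=pfs,
        os_model=os_,
        chemo_drugs=chemo,
        chemo_max_cycles=reg["chemo_max_cycles"],
        maintenance_drug=maintenance,
        maintenance_cap_months=reg["maintenance_cap_months"],
        second_line_drugs=second_line,
        second_line_fraction=base_value(cfg["proportions"]["second_line_chemo"][arm]),
        second_line_duration_cycles=sl["duration_cycles"],
        ae_profile=aes,
        followup_per_cycle=base_value(costs["followup_per_cycle"]),
        tests_per_cycle=base_value(costs["tests_per_cycle"]),
        bsc_per_cycle=base_value(costs["bsc_per_cycle"]),
        end_of_life_cost=base_value(costs["end_of_life"]),
        pd_followup=costs.get("pd_followup", True),
        pd_tests=costs.get("pd_tests", True),
    )


def run_base_case(cfg: dict) -> dict[str, ArmResult | IcerReport]:
    """Run both arms at base values and compare them.

    Returns ``{"adchm": ArmResult, "plchm": ArmResult, "icer": IcerReport}``
    where the ICER is ADCHM versus PLCHM.
    """
    settings = build_settings(cfg)
    results: dict[str, Any] = {}
    for arm in ARMS:
        results[arm] = run_arm(build_strategy(cfg, arm), settings)
    results["icer"] = compute_icer(results["adchm"], results["plchm"])
    return results


def override(cfg: dict, path: tuple, value: Any) -> dict:
    """Return a deep copy of ``cfg`` with the node at ``path`` replaced.

    If the node is a ``{base, ...}`` mapping, only its base value changes.
    """
    new = copy.deepcopy(cfg)
    node = new
    for key in path[:-1]:
        node = node[key]
    leaf = node[path[-1]]
    if isinstance(leaf, dict) and "base" in leaf:
        leaf["base"] = value
    else:
        node[path[-1]] = value
    return new
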