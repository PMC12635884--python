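"""Structured-config serialization (YAML) for rules and calibrations."""

from __future__ import annotations

import dataclasses

import yaml

from .cohort import CohortCalibration, StratumSpec, SurvivalParams, default_calibration
from .eligibility import ScreeningRule

__all__ = [
    "rule_to_yaml",
    "rule_from_yaml",
    "calibration_to_yaml",
    "calibration_from_yaml",
]


def rule_to_yaml(rule: ScreeningRule) -> str:
    return yaml.safe_dump(dataclasses.asdict(rule), sort_keys=False)


def rule_from_yaml(text: str) -> ScreeningRule:
    return ScreeningRule(**yaml.safe_load(text))


def calibration_to_yaml(cal: CohortCalibration) -> str:
    doc = {
        "seed": cal.seed,
        "stratum_specs": [
            {"label": s.label, "count": s.count, "cells": [dict(c) for c in s.cells]}
            for s in cal.stratum_specs
        ],
        "capture_targets": dict(cal.capture_targets),
        "survival_params": dataclasses.asdict(cal.survival_params),
        "group_marginals": cal.group_marginals,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def calibration_from_yaml(text: str) -> CohortCalibration:
    doc = yaml.safe_load(text)
    cal = CohortCalibration(
        stratum_specs=tuple(
            StratumSpec(
                label=s["label"],
                count=s["count"],
                cells=tuple(dict(c) for c in s["cells"]),
            )
            for s in doc["stratum_specs"]
        ),
        capture_targets=doc["capture_targets"],
        survival_params=SurvivalParams(**doc["survival_params"]),
        group_marginals=doc["group_marginals"],
        seed=doc.get("seed", 0),
    )
    cal.validate()
    return cal
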