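"""Pipeline configuration: TOML file with one section per stage, CLI overridable.

All defaults are the tuned operating values of the method (shadow thresholds,
N = 10 descriptor partitions, SVM gamma/cost, the 85%/25-frame fall rules).
Unknown sections or keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from math import pi  # noqa: F401  (handy in configs evaluated by humans)

from .background import DEFAULT_N_TRAIN, DEFAULT_TOLERANCE_FLOOR
from .classifier import ClassifierParams
from .descriptor import FEATURE_N_DEFAULT
from .rules import FallRuleParams
from .shadow import ShadowParams
from .silhouette import MERGE_DISTANCE, MIN_BLOB_AREA

__all__ = ["ExtractionParams", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ExtractionParams:
    n_train: int = DEFAULT_N_TRAIN
    tolerance_floor: float = DEFAULT_TOLERANCE_FLOOR
    min_blob_area: int = MIN_BLOB_AREA
    merge_distance: float = MERGE_DISTANCE


@dataclass
class PipelineConfig:
    shadow: ShadowParams = field(default_factory=ShadowParams)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    descriptor_n: int = FEATURE_N_DEFAULT
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    rules: FallRuleParams = field(default_factory=FallRuleParams)


_SECTIONS = {
    "shadow": ShadowParams,
    "extraction": ExtractionParams,
    "classifier": ClassifierParams,
    "rules": FallRuleParams,
}


def _build(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return cls(**data)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Read a TOML config (all keys optional) and apply flat overrides.

    Overrides use ``section.key`` names, e.g. ``{"shadow.tau_s": 60}`` or
    ``{"descriptor_n": 5}``.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    top_known = set(_SECTIONS) | {"descriptor_n"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
    sections = {name: dict(raw.get(name, {})) for name in _SECTIONS}
    descriptor_n = int(raw.get("descriptor_n", FEATURE_N_DEFAULT))
    for key, value in (overrides or {}).items():
        if key == "descriptor_n":
            descriptor_n = int(value)
        elif "." in key:
            section, sub = key.split(".", 1)
            if section not in sections:
                raise ValueError(f"unknown config section {section!r}")
            sections[section][sub] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return PipelineConfig(
        shadow=_build(ShadowParams, sections["shadow"], "shadow"),
        extraction=_build(ExtractionParams, sections["extraction"], "extraction"),
        descriptor_n=descriptor_n,
        classifier=_build(ClassifierParams, sections["classifier"], "classifier"),
        rules=_build(FallRuleParams, sections["rules"], "rules"),
    )
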