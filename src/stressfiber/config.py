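"""YAML/JSON pipeline configuration with strict key validation.

Unknown keys are errors, not warnings: a typo in a config file must never
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import os

import yaml

from .decomposition import DictionaryConfig
from .enhancement import EnhancementParams
from .segmentation import ExtractionConfig

__all__ = ["build_extraction_config", "load_config_file"]


def _from_mapping(cls, data: dict, context: str):
    valid = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"valid keys: {sorted(valid)}"
        )
    return data


def build_extraction_config(data: dict | None, **overrides) -> ExtractionConfig:
    """Build an ExtractionConfig from a config mapping plus CLI overrides.

    Override values that are ``None`` are ignored; non-None overrides win
    over file values.
    """
    data = dict(data or {})
    # the nested directional/wavelet block is accepted under either name:
    # "decomposition" (config files) or "dictionary" (replayed summaries)
    if "decomposition" in data and "dictionary" in data:
        raise ValueError("give either 'decomposition' or 'dictionary', not both")
    dict_data = dict(data.pop("decomposition", None)
                     or data.pop("dictionary", None) or {})
    enh_data = dict(data.pop("enhancement", {}) or {})
    _from_mapping(ExtractionConfig, data, "extraction config")
    _from_mapping(DictionaryConfig, dict_data, "'decomposition' block")
    _from_mapping(EnhancementParams, enh_data, "'enhancement' block")
    for key, val in overrides.items():
        if val is not None:
            data[key] = val
    if "line_widths" in data:
        data["line_widths"] = tuple(data["line_widths"])
    kwargs = dict(data)
    if dict_data:
        kwargs["dictionary"] = DictionaryConfig(**dict_data)
    if enh_data:
        kwargs["enhancement"] = EnhancementParams(**enh_data)
    return ExtractionConfig(**kwargs)


def load_config_file(path: str | os.PathLike | None) -> dict:
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
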