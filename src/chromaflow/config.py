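"""YAML configuration loading.

One document configures the whole pipeline:

    preprocess:
      target_long_edge: 1000
      white_balance: false
    roi:
      height_px: 50
      width_px: 50
      anchor: center          # or explicit, with origin_row/origin_col
    photometry:
      clip_transmittance: true
      epsilon: 1.0e-6
    calibration:
      water_tolerance: 0.02
      r2_gate: 0.99
    assays:                    # optional registry additions/overrides
      uric_acid:
        channel: green
        units: mg/dL
        standard_concentration: 8.0
        linear_range: [1.0, 30.0]

Unspecified keys fall back to package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import (
    BUILTIN_ASSAYS,
    DEFAULT_R2_GATE,
    DEFAULT_WATER_TOLERANCE,
    AssayDefinition,
)
from .errors import FormatError
from .imaging import Channel, PreprocessConfig, ROIConfig
from .photometry import EPSILON


@dataclass
class RunConfig:
    """Resolved configuration for one CLI invocation."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clip_transmittance: bool = True
    epsilon: float = EPSILON
    water_tolerance: float = DEFAULT_WATER_TOLERANCE
    r2_gate: float = DEFAULT_R2_GATE
    assays: dict[str, AssayDefinition] = field(
        default_factory=lambda: dict(BUILTIN_ASSAYS)
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file; ``None`` gives pure defaults."""
    doc: dict = {}
    if path is not None:
        p = Path(path)
        try:
            doc = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise FormatError(f"invalid YAML config: {p}") from exc
        if not isinstance(doc, dict):
            raise FormatError(f"config root must be a mapping: {p}")

    roi_doc = doc.get("roi", {})
    roi = ROIConfig(
        height_px=int(roi_doc.get("height_px", 50)),
        width_px=int(roi_doc.get("width_px", 50)),
        anchor=roi_doc.get("anchor", "center"),
        origin_row=int(roi_doc.get("origin_row", 0)),
        origin_col=int(roi_doc.get("origin_col", 0)),
    )
    pre_doc = doc.get("preprocess", {})
    pre = PreprocessConfig(
        target_long_edge=int(pre_doc.get("target_long_edge", 1000)),
        white_balance=bool(pre_doc.get("white_balance", False)),
        roi=roi,
    )
    phot = doc.get("photometry", {})
    cal = doc.get("calibration", {})

    assays = dict(BUILTIN_ASSAYS)
    for name, entry in (doc.get("assays") or {}).items():
        base = assays.get(name)
        if base is not None:
            assays[name] = AssayDefinition(
                name=name,
                units=entry.get("units", base.units),
                standard_concentration=float(
                    entry.get("standard_concentration", base.standard_concentration)
                ),
                linear_range=tuple(entry.get("linear_range", base.linear_range)),
                reference_interval=(
                    tuple(entry["reference_interval"])
                    if "reference_interval" in entry
                    else base.reference_interval
                ),
                channel=Channel(entry.get("channel", base.channel.value)),
            )
        else:
            try:
                assays[name] = AssayDefinition(
                    name=name,
                    units=entry["units"],
                    standard_concentration=float(entry["standard_concentration"]),
                    linear_range=tuple(entry["linear_range"]),
                    reference_interval=(
                        tuple(entry["reference_interval"])
                        if entry.get("reference_interval")
                        else None
                    ),
                    channel=Channel(entry["channel"]),
                )
            except KeyError as exc:
                raise FormatError(
                    f"assay {name!r} in config is missing required key {exc}"
                ) from exc

    return RunConfig(
        preprocess=pre,
        clip_transmittance=bool(phot.get("clip_transmittance", True)),
        epsilon=float(phot.get("epsilon", EPSILON)),
        water_tolerance=float(cal.get("water_tolerance", DEFAULT_WATER_TOLERANCE)),
        r2_gate=float(cal.get("r2_gate", DEFAULT_R2_GATE)),
        assays=assays,
    )
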