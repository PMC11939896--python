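"""Adaptive per-session calibration and concentration estimation.

Each measurement session re-derives its own calibration factor:

1. water zero-check — water contains no analyte, so its absorbance against
   the blank baseline must be ~0; a deviation flags contamination or a
   system fault and aborts the session;
2. blank baseline — the reagent-only frame defines the incident intensity
   I0, compensating any intrinsic reagent absorbance;
3. single-standard factor — one frame of a known standard concentration
   C_std gives factor = C_std / A_std (concentration units per AU);
4. unknowns — C = A_test x factor, with linear-range and
   reference-interval flags attached.

Recomputing the factor every session decouples the result from the phone,
the reagent brand and the lighting, because all of those cancel either in
the blank ratio or in the standard ratio.  A multi-point through-origin
fit (slope = sum(c*a)/sum(c^2)) is retained for the one-time linearity
validation; thereafter the single-point factor is exactly 1/slope of the
one-point fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    CalibrationFailureError,
    FormatError,
    MustCalibrateError,
    ParameterError,
    WaterCheckError,
)
from .imaging import (
    Channel,
    ImageSample,
    PreprocessConfig,
    RawRGB,
    process_image,
)
from .photometry import absorbance, normalize, select_channel

#: Default symmetric tolerance (AU) for the water zero-check.
DEFAULT_WATER_TOLERANCE = 0.02

#: R^2 gate for the one-time multi-point linearity validation.
DEFAULT_R2_GATE = 0.99

STORE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Assay definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayDefinition:
    """Per-biomarker constants.

    ``standard_concentration`` is the calibrator shipped with the reagent
    kit; ``linear_range`` is the validated detection range;
    ``reference_interval`` is the normal physiological range in serum
    (``None`` when not defined for the assay).
    """

    name: str
    units: str
    standard_concentration: float
    linear_range: tuple[float, float]
    reference_interval: tuple[float, float] | None
    channel: Channel

    def __post_init__(self) -> None:
        lo, hi = self.linear_range
        if not (0 < lo < hi):
            raise ParameterError(f"invalid linear range [{lo}, {hi}]")
        if self.reference_interval is not None:
            rlo, rhi = self.reference_interval
            if not (0 < rlo < rhi):
                raise ParameterError(f"invalid reference interval [{rlo}, {rhi}]")
        if not (lo <= self.standard_concentration <= hi):
            raise ParameterError(
                "standard concentration must lie inside the linear range"
            )


# Kit standards: uric acid 8 mg/dL, creatinine 2 mg/dL, albumin 4 g/dL.
# Channels by complementary color of each reaction product.
BUILTIN_ASSAYS: dict[str, AssayDefinition] = {
    "uric_acid": AssayDefinition(
        name="uric_acid",
        units="mg/dL",
        standard_concentration=8.0,
        linear_range=(1.0, 30.0),
        reference_interval=None,
        channel=Channel.GREEN,
    ),
    "creatinine": AssayDefinition(
        name="creatinine",
        units="mg/dL",
        standard_concentration=2.0,
        linear_range=(0.1, 20.0),
        reference_interval=(0.6, 1.3),
        channel=Channel.BLUE,
    ),
    "albumin": AssayDefinition(
        name="albumin",
        units="g/dL",
        standard_concentration=4.0,
        linear_range=(0.1, 8.0),
        reference_interval=(3.7, 5.8),
        channel=Channel.RED,
    ),
}


def get_assay(assay_id: str, registry: dict[str, AssayDefinition] | None = None) -> AssayDefinition:
    reg = registry if registry is not None else BUILTIN_ASSAYS
    try:
        return reg[assay_id]
    except KeyError:
        raise ParameterError(
            f"unknown assay {assay_id!r}; registered: {sorted(reg)}"
        ) from None


# ---------------------------------------------------------------------------
# Calibration state
# ---------------------------------------------------------------------------

@dataclass
class CalibrationState:
    """Everything a session derives, persistable between runs."""

    assay_id: str
    water_ok: bool
    blank_rgb: RawRGB
    curve_points: list[tuple[float, float]] = field(default_factory=list)
    slope: float = 0.0  # AU per concentration unit
    factor: float = 0.0  # concentration units per AU
    created_at: str = ""
    session_label: str = ""

    @property
    def valid(self) -> bool:
        return self.water_ok and self.factor > 0


@dataclass(frozen=True)
class ConcentrationResult:
    """An estimated concentration with its clinical-context flags."""

    value: float
    absorbance: float
    inference: str  # below_reference | within_reference | above_reference | no_reference
    in_linear_range: bool


# ---------------------------------------------------------------------------
# Session stages
# ---------------------------------------------------------------------------

def check_water(a, tolerance: float = DEFAULT_WATER_TOLERANCE) -> bool:
    """True iff |A_water| <= tolerance (symmetric band around zero)."""
    if tolerance <= 0:
        raise ParameterError("water tolerance must be > 0")
    value = a.value if hasattr(a, "value") else float(a)
    return abs(value) <= tolerance


def fit_curve(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Least-squares slope of a through-origin line A = slope * C.

    Returns ``(slope, r_squared)`` where R^2 is computed against the
    through-origin fit.  The blank defines A(0) = 0, so no intercept.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ParameterError("need a non-empty list of (concentration, absorbance)")
    c, a = pts[:, 0], pts[:, 1]
    if np.any(c < 0):
        raise ParameterError("concentrations must be non-negative")
    nonzero = c[c > 0]
    if nonzero.size == 0:
        raise ParameterError("degenerate design: all concentrations are zero")
    if nonzero.size != np.unique(nonzero).size:
        raise ParameterError("concentrations must be distinct")
    slope = float(np.sum(c * a) / np.sum(c * c))
    if slope <= 0:
        raise CalibrationFailureError(
            f"calibration slope {slope:g} <= 0: wrong channel or reagent"
        )
    resid = a - slope * c
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(a**2))  # through-origin total sum of squares
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def validate_linearity(
    points: Sequence[tuple[float, float]], r2_gate: float = DEFAULT_R2_GATE
) -> tuple[float, float]:
    """One-time multi-point linearity check; fails below the R^2 gate."""
    slope, r2 = fit_curve(points)
    if r2 < r2_gate:
        raise CalibrationFailureError(
            f"calibration curve R^2 {r2:.4f} below gate {r2_gate}"
        )
    return slope, r2


def adaptive_factor(standard_absorbance: float, assay: AssayDefinition) -> float:
    """Per-session factor C_std / A_std (concentration units per AU)."""
    if standard_absorbance <= 0:
        raise CalibrationFailureError(
            f"standard absorbance {standard_absorbance:g} <= 0; cannot calibrate"
        )
    return assay.standard_concentration / standard_absorbance


def estimate_concentration(
    a_test: float, state: CalibrationState, assay: AssayDefinition
) -> ConcentrationResult:
    """C = A_test x factor, flagged against linear range and reference interval."""
    if not state.valid:
        raise MustCalibrateError(
            f"no valid calibration for assay {assay.name!r}; run a "
            "calibration session first"
        )
    value = a_test * state.factor
    lo, hi = assay.linear_range
    in_range = lo <= value <= hi
    if assay.reference_interval is None:
        inference = "no_reference"
    else:
        rlo, rhi = assay.reference_interval
        if value < rlo:
            inference = "below_reference"
        elif value > rhi:
            inference = "above_reference"
        else:
            inference = "within_reference"
    return ConcentrationResult(
        value=value, absorbance=a_test, inference=inference, in_linear_range=in_range
    )


def run_session(
    water: ImageSample,
    blank: ImageSample,
    standard: ImageSample,
    assay: AssayDefinition,
    cfg: PreprocessConfig = PreprocessConfig(),
    water_tolerance: float = DEFAULT_WATER_TOLERANCE,
    session_label: str = "",
) -> CalibrationState:
    """Execute one adaptive calibration session.

    Stages run in order — water check, blank baseline, standard factor —
    and the session aborts at the first failing stage.  The water check
    uses unclipped (signed) absorbance so negative deviations are visible.
    """
    channel = select_channel(assay)
    blank_rgb = process_image(blank, cfg)
    water_rgb = process_image(water, cfg)

    a_water = absorbance(
        normalize(water_rgb, blank_rgb, clip_transmittance=False), channel
    )
    water_ok = check_water(a_water, water_tolerance)
    if not water_ok:
        raise WaterCheckError(
            f"water absorbance {a_water.value:+.4f} AU exceeds tolerance "
            f"{water_tolerance} AU: check for contamination or interference"
        )

    std_rgb = process_image(standard, cfg)
    a_std = absorbance(normalize(std_rgb, blank_rgb), channel).value
    factor = adaptive_factor(a_std, assay)
    slope = 1.0 / factor
    return CalibrationState(
        assay_id=assay.name,
        water_ok=True,
        blank_rgb=blank_rgb,
        curve_points=[(assay.standard_concentration, a_std)],
        slope=slope,
        factor=factor,
        created_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        session_label=session_label,
    )


def measure_sample(
    test: ImageSample,
    state: CalibrationState,
    assay: AssayDefinition,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> ConcentrationResult:
    """Measure one test frame against a session's blank and factor."""
    channel = select_channel(assay)
    test_rgb = process_image(test, cfg)
    a = absorbance(normalize(test_rgb, state.blank_rgb), channel).value
    return estimate_concentration(a, state, assay)


# ---------------------------------------------------------------------------
# State persistence (JSON store, one document per file, keyed by assay)
# ---------------------------------------------------------------------------

def save_state(state: CalibrationState, store: str | Path) -> None:
    """Persist a calibration state into a JSON store file."""
    path = Path(store)
    doc: dict = {"schema_version": STORE_SCHEMA_VERSION, "assays": {}}
    if path.exists():
        doc = _read_store(path)
    doc["assays"][state.assay_id] = {
        **asdict(state),
        "blank_rgb": [state.blank_rgb.r, state.blank_rgb.g, state.blank_rgb.b],
        "curve_points": [list(p) for p in state.curve_points],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_state(assay_id: str, store: str | Path) -> CalibrationState:
    """Load the stored calibration for an assay; error if never calibrated."""
    path = Path(store)
    if not path.exists():
        raise MustCalibrateError(
            f"calibration store {path} does not exist; calibrate {assay_id!r} first"
        )
    doc = _read_store(path)
    try:
        raw = doc["assays"][assay_id]
    except KeyError:
        raise MustCalibrateError(
            f"assay {assay_id!r} has never been calibrated in {path}"
        ) from None
    return CalibrationState(
        assay_id=raw["assay_id"],
        water_ok=bool(raw["water_ok"]),
        blank_rgb=RawRGB(*raw["blank_rgb"]),
        curve_points=[tuple(p) for p in raw["curve_points"]],
        slope=float(raw["slope"]),
        factor=float(raw["factor"]),
        created_at=raw.get("created_at", ""),
        session_label=raw.get("session_label", ""),
    )


def _read_store(path: Path) -> dict:
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"corrupted calibration store: {path}") from exc
    if not isinstance(doc, dict) or "assays" not in doc:
        raise FormatError(f"calibration store {path} missing 'assays' key")
    return doc
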