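"""Synthetic flow-cell image generator (forward model).

No public dataset of flow-cell photographs exists for this kind of
platform, so every pipeline stage is exercised against images synthesized
from the same physics the analysis inverts.  Per channel c the rendered
mean intensity is

    I_c = clip(base_c * gain_c * illum * 10^(-k_c * C) + ramp + noise, 0, 255)

where ``base_c`` is the blank intensity under diffused LED light,
``gain_c`` a device-specific channel gain, ``illum`` a global illumination
scale (lighting condition), ``k_c`` the effective absorptivity of the
reaction product (AU per concentration unit at the fixed flow-cell path
length), ``ramp`` an optional zero-mean linear illumination gradient
across the frame, and ``noise`` additive Gaussian sensor noise per pixel.

Water and blank frames are rendered at concentration 0.  Scene grids over
devices x reagent brands x lighting emulate the cross-condition
variability study: brand variation perturbs the absorptivity by +/-10%,
lighting scales illumination over {0.8, 1.0, 1.2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import AssayDefinition, BUILTIN_ASSAYS
from .errors import ParameterError
from .imaging import Channel, ImageSample, Role, save_image

#: Default blank intensity: near-white under the diffused LED.
DEFAULT_BASE = (210.0, 215.0, 205.0)

#: Fraction of the measurement-channel absorptivity leaking into the
#: other channels (broad dye spectra); set to 0 for idealized tests.
OFF_CHANNEL_FRACTION = 0.2


def default_absorptivity(assay: AssayDefinition) -> tuple[float, float, float]:
    """Per-channel absorptivity giving A = 0.4 at the standard concentration.

    0.4 AU sits mid-range: well above noise yet clip-safe across the
    assay's linear range.  Off-channel constants are a fixed fraction of
    the measurement channel.
    """
    k_meas = 0.4 / assay.standard_concentration
    k = [k_meas * OFF_CHANNEL_FRACTION] * 3
    k[assay.channel.index] = k_meas
    return tuple(k)


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Forward-model parameters for one acquisition condition."""

    base_intensity: tuple[float, float, float] = DEFAULT_BASE
    absorptivity: tuple[float, float, float] = (0.01, 0.05, 0.01)
    device_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    illumination_scale: float = 1.0
    illumination_gradient: float = 0.0  # peak-to-peak ramp, intensity units
    noise_sd: float = 0.0
    seed: int = 0
    image_size: tuple[int, int] = (100, 100)
    device_label: str = "synthetic"
    lighting_label: str = "reference"

    def __post_init__(self) -> None:
        if any(not (0 < b <= 255) for b in self.base_intensity):
            raise ParameterError("base_intensity channels must be in (0, 255]")
        if any(k < 0 for k in self.absorptivity):
            raise ParameterError("absorptivity must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        h, w = self.image_size
        if h < 50 or w < 50:
            raise ParameterError("image_size must be at least 50 x 50")


def scene_for_assay(assay_id: str, **overrides) -> SyntheticSceneConfig:
    """A reference scene with the assay's default absorptivity."""
    assay = BUILTIN_ASSAYS[assay_id]
    return SyntheticSceneConfig(
        absorptivity=default_absorptivity(assay), **overrides
    )


def render_sample(
    concentration: float,
    role: Role,
    scene: SyntheticSceneConfig,
    assay_id: str = "",
) -> ImageSample:
    """Render one flow-cell frame; deterministic given the scene's seed."""
    if concentration < 0:
        raise ParameterError("concentration must be >= 0")
    if role in (Role.WATER, Role.BLANK) and concentration != 0:
        raise ParameterError(f"{role.value} frames imply concentration 0")
    h, w = scene.image_size
    base = np.asarray(scene.base_intensity)
    gain = np.asarray(scene.device_gain)
    k = np.asarray(scene.absorptivity)
    mean = base * gain * scene.illumination_scale * 10.0 ** (-k * concentration)
    px = np.broadcast_to(mean, (h, w, 3)).copy()
    if scene.illumination_gradient != 0.0:
        # zero-mean linear ramp across columns, same in every channel
        ramp = np.linspace(-0.5, 0.5, w) * scene.illumination_gradient
        px += ramp[None, :, None]
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        px = px + rng.normal(0.0, scene.noise_sd, size=px.shape)
    px = np.clip(px, 0.0, 255.0)
    return ImageSample(
        pixels=px,
        role=role,
        assay_id=assay_id,
        device_label=scene.device_label,
        lighting_label=scene.lighting_label,
    )


def is_saturated(scene: SyntheticSceneConfig, channel: Channel,
                 concentration: float = 0.0) -> bool:
    """True when the noise-free mean on ``channel`` hits 0 or 255."""
    base = scene.base_intensity[channel.index]
    gain = scene.device_gain[channel.index]
    k = scene.absorptivity[channel.index]
    mean = base * gain * scene.illumination_scale * 10.0 ** (-k * concentration)
    return mean <= 0.0 or mean >= 255.0


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Index of a generated dataset: one row per written image."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "file_path", "assay_id", "role", "true_concentration",
                "device_label", "lighting_label", "seed", "saturated",
            ]
        )
    )

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        return cls(rows=pd.read_csv(Path(path), keep_default_na=False))


def make_dataset(
    concentrations: Sequence[float],
    replicates: int,
    scenes: Sequence[SyntheticSceneConfig],
    out_dir: str | Path,
    assay_id: str = "uric_acid",
    base_seed: int = 0,
) -> DatasetManifest:
    """Render a grid of test images plus per-scene water/blank/standard.

    Writes ``|concentrations| * replicates * |scenes|`` test PNGs and one
    water, blank and standard control triplet per scene, plus a CSV
    manifest.  Seeds are derived deterministically from ``base_seed`` so
    a rerun reproduces identical files.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    assay = BUILTIN_ASSAYS[assay_id]
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable") from exc

    records = []
    counter = 0

    def emit(conc: float, role: Role, scene: SyntheticSceneConfig, name: str):
        nonlocal counter
        seed = (base_seed * 1_000_003 + counter) % (2**31)
        counter += 1
        sc = replace(scene, seed=seed)
        img = render_sample(conc, role, sc, assay_id=assay_id)
        path = out / f"{name}.png"
        save_image(img, path)
        records.append(
            {
                "file_path": str(path),
                "assay_id": assay_id,
                "role": role.value,
                "true_concentration": conc,
                "device_label": sc.device_label,
                "lighting_label": sc.lighting_label,
                "seed": seed,
                "saturated": is_saturated(sc, assay.channel, conc),
            }
        )

    for si, scene in enumerate(scenes):
        emit(0.0, Role.WATER, scene, f"s{si:02d}_water")
        emit(0.0, Role.BLANK, scene, f"s{si:02d}_blank")
        emit(assay.standard_concentration, Role.STANDARD, scene, f"s{si:02d}_standard")
        for ci, conc in enumerate(concentrations):
            for rep in range(replicates):
                emit(conc, Role.TEST, scene, f"s{si:02d}_c{ci:02d}_r{rep:02d}")

    manifest = DatasetManifest(rows=pd.DataFrame(records))
    manifest.to_csv(out / "manifest.csv")
    return manifest


def condition_grid(
    assay_id: str = "uric_acid",
    devices: Sequence[tuple[str, tuple[float, float, float]]] = (
        ("deviceA", (1.00, 1.00, 1.00)),
        ("deviceB", (1.06, 0.97, 1.02)),
        ("deviceC", (0.94, 1.03, 0.99)),
    ),
    brand_perturbation: Sequence[float] = (1.0, 1.1, 0.9),
    lighting: Sequence[tuple[str, float]] = (
        ("morning", 0.8),
        ("afternoon", 1.0),
        ("evening", 1.2),
    ),
    noise_sd: float = 1.0,
) -> list[SyntheticSceneConfig]:
    """Device x reagent-brand x lighting grid (diagonal pairing).

    Pairs device i with brand i and sweeps lighting, giving one scene per
    device/lighting combination — the synthetic analogue of measuring the
    same sample on several phones with several reagent brands at several
    times of day.
    """
    assay = BUILTIN_ASSAYS[assay_id]
    k0 = np.asarray(default_absorptivity(assay))
    scenes = []
    for (dev, gains), brand in zip(devices, brand_perturbation):
        for light, scale in lighting:
            scenes.append(
                SyntheticSceneConfig(
                    absorptivity=tuple(k0 * brand),
                    device_gain=gains,
                    illumination_scale=scale,
                    noise_sd=noise_sd,
                    device_label=dev,
                    lighting_label=light,
                )
            )
    return scenes
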