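"""Synthetic transmitted-light capsule images and study-shaped datasets.

The renderer is a deliberately simple optical stand-in for a transmitted
light microscope viewing a spherical capsule whose shell is stained with
iron-oxide nanoparticles (the core is optically clear agarose/water):

* light crossing the shell is attenuated per channel by the Beer-Lambert
  law, ``I = I0 * exp(-mu_c * L)``, where ``L`` is the local chord length
  through the shell material;
* over the capsule centre the chord is twice the shell thickness (the ray
  crosses the shell front and back), so the centre colour has the closed
  form ``I_c = background_c * exp(-mu_c * 2h)``;
* the attenuation coefficients are ordered ``mu_R < mu_G < mu_B`` - the
  stained shell transmits red preferentially, so thicker shells look
  redder against the neutral background;
* a narrow darkened rim at the capsule boundary stands in for the
  refraction halo seen at a hydrogel/water interface; it is what keeps a
  zero-thickness (shell-less) capsule visible to the segmenter, exactly as
  real bare cores remain visible under the microscope;
* Gaussian read-out noise is added per pixel and channel, then values are
  clipped and quantised to the bit depth.

Datasets mirror the shape of the soaking experiment: a grid of CaCl2
concentrations, a few replicate capsules per concentration with core radii
drawn uniformly from a range, shell thickness following the volumetric
growth law above a formation threshold and zero at or below it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .colorimetry import CapsuleImage
from .errors import DomainError, GeometryError
from .geometry import predict_thickness

__all__ = [
    "OpticsParams",
    "ScenarioSpec",
    "render_capsule",
    "generate_dataset",
    "centre_intensity",
    "STUDY_CONCENTRATIONS_MM",
]

#: The soaking-concentration grid of the experiment, mM.
STUDY_CONCENTRATIONS_MM: tuple[float, ...] = (0.1, 1, 2, 5, 10, 15, 20, 30, 50, 100)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class OpticsParams:
    """Optical model of the synthetic microscope.

    ``mu`` are per-channel attenuation coefficients in um^-1 with
    ``mu_R < mu_G < mu_B`` (iron-oxide staining transmits red
    preferentially); ``noise_sigma`` is Gaussian read-out noise in intensity
    units.  ``edge_width_um``/``edge_transmittance`` parameterise the
    refraction rim at the capsule boundary (transmittance 1 disables it).
    """

    background_rgb: tuple[float, float, float] = (240.0, 238.0, 235.0)
    mu: tuple[float, float, float] = (0.001, 0.004, 0.010)
    noise_sigma: float = 2.0
    bit_depth: int = 8
    edge_width_um: float = 2.0
    edge_transmittance: float = 0.7

    def __post_init__(self) -> None:
        mu_r, mu_g, mu_b = self.mu
        if not 0 < mu_r < mu_g < mu_b:
            raise DomainError(
                f"attenuation must satisfy 0 < mu_R < mu_G < mu_B, got {self.mu}"
            )
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be non-negative")
        if not 1 <= self.bit_depth <= 16:
            raise DomainError("bit_depth must be in [1, 16]")
        if not 0 < self.edge_transmittance <= 1:
            raise DomainError("edge_transmittance must lie in (0, 1]")
        if self.edge_width_um < 0:
            raise DomainError("edge_width_um must be non-negative")
        for v in self.background_rgb:
            if not 0 <= v <= 2**self.bit_depth - 1:
                raise DomainError("background intensities must fit the bit depth")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def saturation_thickness(self) -> float:
        """Thickness (um) at which the centre R-B metric peaks.

        Below this the centre R-B is strictly increasing in shell thickness;
        beyond it the red channel's own decay dominates and R-B declines.
        """
        bg_r, _, bg_b = self.background_rgb
        mu_r, _, mu_b = self.mu
        return float(np.log((mu_b * bg_b) / (mu_r * bg_r)) / (2 * (mu_b - mu_r)))


def centre_intensity(optics: OpticsParams, h: float) -> np.ndarray:
    """Closed-form noiseless centre colour for shell thickness ``h`` (um).

    The chord through the shell at the capsule centre is 2h, so
    ``I_c = background_c * exp(-mu_c * 2h)`` per channel.
    """
    if h < 0:
        raise DomainError("shell thickness must be non-negative")
    bg = np.asarray(optics.background_rgb, dtype=float)
    mu = np.asarray(optics.mu, dtype=float)
    return bg * np.exp(-mu * 2.0 * h)


@dataclass(frozen=True)
class ScenarioSpec:
    """Shape and ground truth of a synthetic soaking experiment.

    Defaults reproduce the study conditions: the ten-concentration grid,
    growth constant alpha = 0.033 mM^-1, no shell at or below 2 mM.  Core
    radii (40-60 um) and the 0.5 um/px scale are chosen so the realised
    thicknesses stay within the strictly increasing, near-linear range of
    the default optics' R-B response.
    """

    alpha_true: float = 0.033
    concentrations: tuple[float, ...] = STUDY_CONCENTRATIONS_MM
    replicates_per_conc: int = 4
    R_c_range: tuple[float, float] = (40.0, 60.0)
    formation_threshold: float = 2.0
    seed: int = 0
    scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.alpha_true > 0:
            raise DomainError("alpha_true must be positive")
        if self.replicates_per_conc < 1:
            raise DomainError("replicates_per_conc must be >= 1")
        if any(c < 0 for c in self.concentrations):
            raise DomainError("concentrations must be non-negative")
        if self.formation_threshold < 0:
            raise DomainError("formation_threshold must be non-negative")
        lo, hi = self.R_c_range
        if not 0 < lo <= hi:
            raise DomainError(f"invalid R_c_range {self.R_c_range}")
        if not self.scale > 0:
            raise DomainError("scale must be positive um/px")


def _image_seed(root_seed: int, index: int) -> int:
    """Deterministic per-image seed derived from the root seed by counter."""
    return (root_seed * 100_003 + index) % _SEED_MOD


def render_capsule(
    R_c: float,
    h: float,
    optics: OpticsParams = OpticsParams(),
    scale: float = 0.5,
    seed: int = 0,
    canvas: Optional[tuple[int, int]] = None,
    sample_id: str = "",
    conc: float = float("nan"),
    margin: float = 1.3,
) -> CapsuleImage:
    """Render one capsule (core radius ``R_c``, shell thickness ``h``, um).

    The canvas defaults to a square sized ``margin`` times the capsule
    diameter (minimum 64 px).  Rendering is deterministic for a fixed seed.
    Raises :class:`GeometryError` when an explicit canvas cannot contain the
    capsule.
    """
    if not R_c > 0:
        raise DomainError("core radius must be positive")
    if h < 0:
        raise DomainError("shell thickness must be non-negative")
    if not scale > 0:
        raise DomainError("scale must be positive um/px")
    R_o = R_c + h
    diameter_px = 2.0 * R_o / scale
    if canvas is None:
        side = max(64, int(np.ceil(diameter_px * margin)))
        canvas = (side, side)
    H, W = canvas
    if diameter_px > min(H, W):
        raise GeometryError(
            f"capsule diameter {diameter_px:.0f} px exceeds canvas {canvas}"
        )

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    d = np.hypot(yy - cy, xx - cx) * scale  # um from capsule axis

    # chord length through the shell material for a ray at lateral distance d
    outer = 2.0 * np.sqrt(np.clip(R_o**2 - d**2, 0.0, None))
    inner = 2.0 * np.sqrt(np.clip(R_c**2 - d**2, 0.0, None))
    L = outer - inner

    bg = np.asarray(optics.background_rgb, dtype=float)
    mu = np.asarray(optics.mu, dtype=float)
    img = bg[None, None, :] * np.exp(-L[..., None] * mu[None, None, :])

    if optics.edge_transmittance < 1.0 and optics.edge_width_um > 0:
        rim = (d <= R_o) & (d >= R_o - optics.edge_width_um)
        img[rim] *= optics.edge_transmittance

    if optics.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, optics.noise_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, optics.max_value).astype(np.uint8)
    return CapsuleImage(pixels=img, sample_id=sample_id, conc=conc, scale=scale)


def generate_dataset(
    spec: ScenarioSpec,
    optics: OpticsParams = OpticsParams(),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic experiment: images, manifest, ground truth.

    For every concentration and replicate a core radius is drawn uniformly
    from ``spec.R_c_range``; the true thickness is the growth-law prediction
    when the concentration exceeds the formation threshold and 0 otherwise.
    Returns ``(manifest, ground_truth)`` DataFrames; when ``out_dir`` is
    given, PNG images, ``manifest.csv``, ``ground_truth.csv`` and
    ``scenario.yaml`` are written there.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed % _SEED_MOD)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        try:
            out_path.mkdir(parents=True, exist_ok=True)
            (out_path / "images").mkdir(exist_ok=True)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"cannot create output directory {out_path}: {exc}") from exc

    manifest_rows, truth_rows, images = [], [], []
    idx = 0
    for conc in spec.concentrations:
        for rep in range(spec.replicates_per_conc):
            R_c = float(rng.uniform(*spec.R_c_range))
            if conc > spec.formation_threshold:
                h = float(predict_thickness(spec.alpha_true, conc, R_c))
            else:
                h = 0.0
            sample_id = f"s{idx:03d}_c{conc:g}mM_r{rep}"
            image = render_capsule(
                R_c,
                h,
                optics=optics,
                scale=spec.scale,
                seed=_image_seed(spec.seed, idx),
                sample_id=sample_id,
                conc=conc,
            )
            rel = f"images/{sample_id}.png"
            manifest_rows.append(
                {
                    "image_path": rel,
                    "sample_id": sample_id,
                    "conc_mM": conc,
                    "scale_um_per_px": spec.scale,
                }
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "conc_mM": conc,
                    "R_c_um": R_c,
                    "h_true_um": h,
                }
            )
            images.append(image)
            idx += 1

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)

    if out_path is not None:
        for row, image in zip(manifest_rows, images):
            iio.imwrite(out_path / row["image_path"], image.pixels)
        manifest.to_csv(out_path / "manifest.csv", index=False)
        truth.to_csv(out_path / "ground_truth.csv", index=False)
        scenario = {"scenario": asdict(spec), "optics": asdict(optics)}
        # YAML-friendly plain types
        scenario["scenario"]["concentrations"] = [float(c) for c in spec.concentrations]
        scenario["scenario"]["R_c_range"] = [float(v) for v in spec.R_c_range]
        scenario["optics"]["background_rgb"] = [float(v) for v in optics.background_rgb]
        scenario["optics"]["mu"] = [float(v) for v in optics.mu]
        with open(out_path / "scenario.yaml", "w") as fh:
            yaml.safe_dump(scenario, fh, sort_keys=False)

    return manifest, truth
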