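"""Synthetic data with known ground truth for both pipeline arms.

Expression side: a compendium of tissue transcriptomes with disjoint planted
marker-gene sets. Every gene has a common baseline expectation (on the RPM
scale); a tissue's markers are elevated ``marker_elevation``-fold. Realised
values multiply the expectation by lognormal noise exp(N(0, noise_sd)) — the
simplest positive-support model with the heavy right tail of RPM data. Query
samples perturb a chosen profile the same way.

Imaging side: five-plane focal stacks of a disc-shaped lens over a uniform
background. At z=0 the lens disc attenuates the background to
``transmittance`` x background; below the lens a Gaussian focal spot appears
whose amplitude peaks at the focal distance f and decays axially as a
Gaussian of width f/2 (only the ordering of plane intensities matters for the
downstream measurements, not optical realism). Additive Gaussian pixel noise,
8-bit quantisation.

All randomness flows from the explicit per-call seed; there is no global
random state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LookupError_
from .matrix import ExpressionMatrix
from .optics import FocalStack, disc_mask


# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

@dataclass
class CompendiumSimConfig:
    """Study conditions for the synthetic tissue compendium.

    Defaults emulate a modest multi-tissue compendium: 20 tissues over a
    5000-gene universe, 100 disjoint markers per tissue elevated 10-fold over
    a ~100 RPM baseline, with dataset-level lognormal noise of sd 0.5 on the
    natural-log scale (a typical cross-laboratory spread).
    """

    n_tissues: int = 20
    n_genes: int = 5000
    markers_per_tissue: int = 100
    marker_elevation: float = 10.0
    baseline_log_mean: float = float(np.log(100.0))
    noise_sd: float = 0.5
    n_query_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 1 or self.n_genes < 1 or self.markers_per_tissue < 0:
            raise ConfigurationError("counts must be positive")
        if self.n_tissues * self.markers_per_tissue > self.n_genes:
            raise ConfigurationError(
                "n_tissues * markers_per_tissue exceeds n_genes; planted marker sets must be disjoint"
            )
        if self.marker_elevation <= 1:
            raise ConfigurationError("marker_elevation must exceed 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class CompendiumSim:
    """Simulated compendium: realised matrix, noiseless expectation, truth."""

    matrix: ExpressionMatrix
    expected: ExpressionMatrix
    planted_markers: dict[str, frozenset[str]]


def _gene_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _tissue_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"tissue{i:0{width}d}" for i in range(1, n + 1)]


def simulate_compendium(config: CompendiumSimConfig) -> CompendiumSim:
    """Generate a tissue compendium with disjoint planted marker sets."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_labels(config.n_genes)
    tissues = _tissue_labels(config.n_tissues)
    baseline = float(np.exp(config.baseline_log_mean))
    expected = np.full((config.n_genes, config.n_tissues), baseline)
    planted: dict[str, frozenset[str]] = {}
    for t, tissue in enumerate(tissues):
        lo = t * config.markers_per_tissue
        hi = lo + config.markers_per_tissue
        expected[lo:hi, t] *= config.marker_elevation
        planted[tissue] = frozenset(genes[lo:hi])
    noise = np.exp(rng.normal(0.0, config.noise_sd, size=expected.shape)) if config.noise_sd > 0 else 1.0
    realised = expected * noise
    index = pd.Index(genes, name="gene")
    return CompendiumSim(
        matrix=ExpressionMatrix(pd.DataFrame(realised, index=index, columns=tissues)),
        expected=ExpressionMatrix(pd.DataFrame(expected, index=index, columns=tissues)),
        planted_markers=planted,
    )


def simulate_query(
    source: ExpressionMatrix,
    tissue_id: str,
    noise_sd: float,
    n_replicates: int = 2,
    seed: int = 0,
) -> ExpressionMatrix:
    """Replicate query samples: a source column under fresh lognormal noise.

    Pass the noiseless expected matrix for independent-measurement queries, or
    the realised matrix for technical replicates of one concrete sample.
    """
    if tissue_id not in source.samples:
        raise LookupError_(f"unknown tissue {tissue_id!r}")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if n_replicates < 1:
        raise ConfigurationError("need at least one replicate")
    rng = np.random.default_rng(seed)
    profile = source.data[tissue_id].to_numpy()
    cols = {}
    for r in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(0.0, noise_sd, size=profile.shape)) if noise_sd > 0 else 1.0
        cols[f"{tissue_id}_query{r}"] = profile * noise
    return ExpressionMatrix(pd.DataFrame(cols, index=source.genes))


# ---------------------------------------------------------------------------
# focal stacks
# ---------------------------------------------------------------------------

@dataclass
class LensSimConfig:
    """Study conditions for a synthetic micro-lens focal stack.

    Defaults mimic phase imaging of a ~80 µm lens (1 µm/pixel) against a
    medium of grey 100, leaving 8-bit headroom for a focal spot up to ~1.5x
    the background before clipping. The focal distance default follows the
    paraxial ball-lens formula for a lens-like refractive index (~1.42):
    f ~ 1.06 x diameter, rounded to 85 µm.
    """

    image_size: int = 192
    background_grey: float = 100.0
    lens_diameter: float = 80.0
    lens_center: tuple[float, float] | None = None  # defaults to image centre
    transmittance: float = 1.0
    focus_gain: float = 1.0
    focal_distance: float = 85.0
    spot_sigma: float = 10.0
    noise_sd: float = 2.0
    pixel_scale: float = 1.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.lens_center is not None:
            return self.lens_center
        c = (self.image_size - 1) / 2
        return (c, c)

    def validate(self) -> None:
        if not 0 <= self.transmittance <= 1:
            raise ConfigurationError("transmittance must lie in [0, 1]")
        if self.focus_gain < 0 or self.noise_sd < 0:
            raise ConfigurationError("focus_gain and noise_sd must be non-negative")
        if self.focal_distance <= 0 or self.spot_sigma <= 0:
            raise ConfigurationError("focal_distance and spot_sigma must be positive")
        r0, c0 = self.resolved_center()
        radius = self.lens_diameter / 2
        if min(r0, c0) - radius < 0 or max(r0, c0) + radius > self.image_size - 1:
            raise ConfigurationError("lens disc does not fit inside the image")


def default_background_region(config: LensSimConfig) -> tuple[float, float]:
    """Annulus just outside the lens disc, clipped to the image."""
    inner = config.lens_diameter / 2 * 1.25
    outer = inner + max(8.0, config.lens_diameter / 8)
    return (inner, outer)


def axial_amplitude(z: float, focal_distance: float, background_grey: float, focus_gain: float) -> float:
    """Focal-spot peak amplitude at axial offset z (Gaussian in z, width f/2)."""
    f = focal_distance
    return background_grey * focus_gain * float(np.exp(-((z - f) ** 2) / (2 * (f / 2) ** 2)))


def simulate_focal_stack(config: LensSimConfig, quantise: bool = True) -> FocalStack:
    """Generate a five-plane focal stack at z in {0, f/2, f, 3f/2, 2f}."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    center = config.resolved_center()
    f = config.focal_distance
    z_offsets = np.array([0.0, f / 2, f, 1.5 * f, 2 * f])
    lens = disc_mask((size, size), center, config.lens_diameter)
    rr, cc = np.ogrid[:size, :size]
    r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    spot = np.exp(-r2 / (2 * config.spot_sigma**2))
    planes = np.empty((5, size, size))
    for i, z in enumerate(z_offsets):
        plane = np.full((size, size), config.background_grey)
        if i == 0:
            plane[lens] *= config.transmittance
        else:
            plane = plane + axial_amplitude(z, f, config.background_grey, config.focus_gain) * spot
        if config.noise_sd > 0:
            plane = plane + rng.normal(0.0, config.noise_sd, size=plane.shape)
        planes[i] = plane
    if quantise:
        planes = np.clip(np.rint(planes), 0, 255).astype(np.uint8)
    else:
        planes = np.clip(planes, 0, 255)
    return FocalStack(
        planes=planes,
        z_offsets=z_offsets,
        lens_center=center,
        lens_diameter=config.lens_diameter,
        background_region=default_background_region(config),
        pixel_scale=config.pixel_scale,
    )


def ball_lens_focal_length(refractive_index: float, diameter: float) -> float:
    """Paraxial effective focal length of a ball lens, from the lens centre.

    f = n * D / (4 * (n - 1)); at n=2 the focus sits on the back surface.
    """
    if refractive_index <= 1:
        raise ConfigurationError("refractive index must exceed 1")
    if diameter <= 0:
        raise ConfigurationError("diameter must be positive")
    n = refractive_index
    return n * diameter / (4 * (n - 1))
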