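"""Synthetic measurement sets and AFM-like images with known ground truth.

The study this package supports measured virus-like particles (VLPs,
~50-100 nm self-assembled capsids) in 1 µm x 1 µm tapping-mode AFM fields
and summarized each aging condition as a fitted Gaussian mixture of
per-particle areas (nm²) or widths (nm). The raw images and measurement
tables are not public, so this module emulates them:

* :func:`sample_mixture` draws measurement sets from a mixture
  specification, keeping the latent component label of every draw;
* :func:`preset_spec` exposes the published fitted mixtures (fractions,
  means, sigmas and total particle counts per condition) as generator
  truth, which is the only faithful emulation available;
* :func:`make_afm_image` renders bright, dome-like particles on a noisy
  background with a pixel calibration in the instrument's printed range
  (103-125 pixels per 200 nm), so the image-processing chain can be tested
  against analytic particle areas.

Everything is a pure function of (spec, n, seed); there is no hidden
global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .measurements import AREA_NM2, WIDTH_NM, MeasurementSet

#: midpoint of the instrument's printed calibration range
DEFAULT_CALIBRATION = 115.0
CALIBRATION_RANGE = (103.0, 125.0)


@dataclass(frozen=True)
class ComponentSpec:
    """Generator truth for one mixture component.

    Unlike a fitted component, a spec may be degenerate (sigma == 0) to
    express an exact point mass; such specs are only legal inside the
    generator and are flagged via :attr:`degenerate`.
    """

    weight: float
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValidationError(f"weight must be in (0, 1], got {self.weight}")
        if self.sigma < 0.0:
            raise ValidationError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass
class SyntheticTruth:
    """Latent component labels (1..K) and the generating spec."""

    labels: np.ndarray
    spec: tuple[ComponentSpec, ...]
    seed: int


def validate_spec(spec) -> tuple[ComponentSpec, ...]:
    comps = tuple(
        c if isinstance(c, ComponentSpec) else ComponentSpec(*c) for c in spec
    )
    if not comps:
        raise ValidationError("empty mixture spec")
    total = sum(c.weight for c in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"spec weights sum to {total!r}, not 1")
    return comps


# ---------------------------------------------------------------------------
# published fitted mixtures, used as generator presets
# ---------------------------------------------------------------------------

def _preset(unit, n, condition, rows):
    return {
        "unit": unit,
        "n_total": n,
        "condition": condition,
        "components": tuple(ComponentSpec(w, m, s) for (w, m, s) in rows),
    }


#: Fitted mixtures per condition: per-particle areas (single AFM pass),
#: widths after a single pass, and widths after a double pass, plus the
#: ensemble-of-all-conditions fits. ``n_total`` is the number of particles
#: the condition contributed.
PRESETS: dict[str, dict] = {
    # areas (nm²), single pass
    "area_2h": _preset(AREA_NM2, 36, "2h", [(0.15, 1184, 103), (0.85, 1566, 120)]),
    "area_3h": _preset(
        AREA_NM2, 33, "3h", [(0.12, 1331, 27), (0.60, 1585, 69), (0.28, 1993, 185)]
    ),
    "area_4h": _preset(
        AREA_NM2,
        23,
        "4h",
        [(0.41, 1107, 85), (0.20, 1351, 35), (0.30, 1639, 71), (0.09, 2011, 59)],
    ),
    "area_all_3": _preset(
        AREA_NM2, 92, "all", [(0.66, 1450, 241), (0.27, 1613, 56), (0.07, 2093, 128)]
    ),
    "area_all_4": _preset(
        AREA_NM2,
        92,
        "all",
        [(0.07, 1054, 48), (0.59, 1479, 194), (0.25, 1617, 54), (0.09, 2045, 150)],
    ),
    # widths (nm), single pass
    "width_singlepass_2h": _preset(
        WIDTH_NM, 54, "2h", [(0.10, 73.6, 0.83), (0.46, 80.3, 6.22), (0.44, 81.4, 3.28)]
    ),
    "width_singlepass_3h": _preset(WIDTH_NM, 33, "3h", [(1.00, 74.1, 8.47)]),
    "width_singlepass_4h": _preset(
        WIDTH_NM, 42, "4h", [(0.50, 60.8, 3.24), (0.43, 71.2, 3.92), (0.07, 81.0, 0.70)]
    ),
    "width_singlepass_all": _preset(
        WIDTH_NM, 129, "all", [(0.23, 61.8, 3.60), (0.77, 78.0, 6.25)]
    ),
    # widths (nm), double pass
    "width_doublepass_0h": _preset(
        WIDTH_NM, 19, "0h", [(0.62, 98.1, 5.11), (0.38, 112.7, 2.81)]
    ),
    "width_doublepass_1h": _preset(
        WIDTH_NM, 25, "1h", [(0.62, 98.5, 7.05), (0.38, 113.3, 8.27)]
    ),
    "width_doublepass_2h": _preset(
        WIDTH_NM, 23, "2h", [(0.33, 109.9, 10.8), (0.67, 123.0, 8.98)]
    ),
    "width_doublepass_3h": _preset(WIDTH_NM, 31, "3h", [(1.00, 106.2, 7.08)]),
    "width_doublepass_all": _preset(
        WIDTH_NM,
        98,
        "all",
        [(0.23, 96.8, 5.6), (0.46, 106.3, 6.9), (0.22, 114.8, 5.5), (0.09, 129.6, 5.6)],
    ),
}


def preset_spec(name: str) -> tuple[ComponentSpec, ...]:
    """The mixture spec for a documented preset condition."""
    info = preset_info(name)
    return info["components"]


def preset_info(name: str) -> dict:
    """Full preset record: unit, condition label, total n, components."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None


def sample_mixture(
    spec,
    n: int,
    seed: int,
    *,
    unit: str = AREA_NM2,
    condition: str = "",
) -> tuple[MeasurementSet, SyntheticTruth]:
    """Draw ``n`` values from a mixture spec, keeping latent labels.

    Draw i comes from the component named by ``truth.labels[i]`` (1-based).
    Identical ``(spec, n, seed)`` give identical output.
    """
    comps = validate_spec(spec)
    if n < 1:
        raise ValidationError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in comps])
    means = np.array([c.mean for c in comps])
    sigmas = np.array([c.sigma for c in comps])
    labels0 = rng.choice(len(comps), size=n, p=weights / weights.sum())
    values = rng.normal(means[labels0], sigmas[labels0])
    data = MeasurementSet(values, unit=unit, condition=condition)
    truth = SyntheticTruth(labels=labels0 + 1, spec=comps, seed=seed)
    return data, truth


def sample_preset(name: str, n: int | None = None, seed: int = 0):
    """Draw from a named preset; ``n`` defaults to the condition's own count."""
    info = preset_info(name)
    n = info["n_total"] if n is None else n
    return sample_mixture(
        info["components"], n, seed, unit=info["unit"], condition=info["condition"]
    )


# ---------------------------------------------------------------------------
# AFM-like images
# ---------------------------------------------------------------------------

@dataclass
class ImageTruth:
    """Ground truth for one synthetic AFM field.

    ``radii_px`` are half-maximum radii: the rendered radial profile of a
    particle crosses half its peak height exactly at its radius, so the
    analytic particle area is pi r² pixels.
    """

    centers: list[tuple[float, float]]  # (row, col) pixels
    radii_px: list[float]
    pixels_per_200nm: float = DEFAULT_CALIBRATION
    noise_sd: float = 6.0
    background: float = 30.0
    peak: float = 180.0
    overlapping: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii_px):
            raise ValidationError("one radius per center required")
        if any(r <= 0 for r in self.radii_px):
            raise ValidationError("particle radii must be positive")
        if not self.pixels_per_200nm > 0:
            raise ValidationError("calibration must be positive")

    @property
    def n_particles(self) -> int:
        return len(self.centers)

    def analytic_areas_px(self) -> np.ndarray:
        return math.pi * np.asarray(self.radii_px, dtype=float) ** 2

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)

    @classmethod
    def from_json(cls, path) -> "ImageTruth":
        with open(path) as handle:
            payload = json.load(handle)
        payload["centers"] = [tuple(c) for c in payload["centers"]]
        return cls(**payload)


def random_image_truth(
    n_particles: int,
    size: int = 512,
    seed: int = 0,
    *,
    radius_range: tuple[float, float] = (17.0, 30.0),
    pixels_per_200nm: float = DEFAULT_CALIBRATION,
    noise_sd: float = 6.0,
    separation_factor: float = 3.0,
) -> ImageTruth:
    """Place well-separated particles uniformly in a square field.

    Radii are uniform over ``radius_range`` (the default spans the 60-130 nm
    particle widths seen in this kind of data at the default calibration).
    Centers are rejection-sampled so that every pair is at least
    ``separation_factor`` times the larger radius apart and no particle
    approaches the border.
    """
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = 10000
    for _ in range(max_tries):
        if len(centers) == n_particles:
            break
        r = float(rng.uniform(*radius_range))
        margin = r + 12.0
        if 2 * margin >= size:
            raise ValidationError("image too small for requested particle radii")
        c = (float(rng.uniform(margin, size - margin)),
             float(rng.uniform(margin, size - margin)))
        ok = all(
            math.hypot(c[0] - c2[0], c[1] - c2[1]) >= separation_factor * max(r, r2)
            for c2, r2 in zip(centers, radii)
        )
        if ok:
            centers.append(c)
            radii.append(r)
    if len(centers) < n_particles:
        raise ValidationError(
            f"could not place {n_particles} separated particles in a {size}px field"
        )
    return ImageTruth(
        centers=centers,
        radii_px=radii,
        pixels_per_200nm=pixels_per_200nm,
        noise_sd=noise_sd,
    )


def make_afm_image(
    truth: ImageTruth,
    size: int = 512,
    seed: int = 0,
    *,
    edge_width_px: float = 1.0,
) -> np.ndarray:
    """Render an 8-bit grayscale AFM-like field from ground truth.

    Each particle is a radially symmetric dome: a flat top with a smooth
    sigmoidal shoulder of scale ``edge_width_px`` centered on the half-max
    radius. Additive Gaussian intensity noise of ``truth.noise_sd`` is
    applied and the result clipped to [0, 255]. Overlapping particle pairs
    (shoulder regions within touching distance) are flagged in
    ``truth.overlapping``; they emulate the contiguous-particle failure mode
    of edge-based segmentation rather than being an error.
    """
    if size < 4:
        raise ValidationError("image size must be at least 4 pixels")
    for (row, col), r in zip(truth.centers, truth.radii_px):
        if not (0 <= row < size and 0 <= col < size):
            raise ValidationError(f"particle center {(row, col)} outside the image")
    img = np.full((size, size), truth.background, dtype=float)
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    amplitude = truth.peak - truth.background
    for (crow, ccol), r in zip(truth.centers, truth.radii_px):
        dist = np.hypot(rows - crow, cols - ccol)
        img += amplitude / (1.0 + np.exp((dist - r) / edge_width_px))
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, truth.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255)

    flags = []
    n = truth.n_particles
    for i in range(n):
        touching = False
        for j in range(n):
            if i == j:
                continue
            gap = math.hypot(
                truth.centers[i][0] - truth.centers[j][0],
                truth.centers[i][1] - truth.centers[j][1],
            )
            if gap < truth.radii_px[i] + truth.radii_px[j] + 6 * edge_width_px:
                touching = True
        flags.append(touching)
    truth.overlapping = flags
    return img.astype(np.uint8)


def write_image(path, img: np.ndarray) -> None:
    """Write an 8-bit grayscale raster (PNG or TIFF chosen by suffix)."""
    from PIL import Image

    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)
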