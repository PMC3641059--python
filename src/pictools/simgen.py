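"""Synthetic two-channel translocation microscopy and FRAP traces.

Emulates a yeast anchor/prey recruitment assay: cells carry discrete,
static cortical anchor puncta (eisosome-like sites on the plasma membrane,
red channel) and a GFP prey that is cytosolic and/or natively punctate
(green channel). Under rapamycin, an interacting prey is co-recruited to the
anchor sites: a configurable fraction of its fluorescence is relocated from
the cytosol (and native puncta) onto the anchor coordinates. Images are
rendered as point/area photon sources convolved with a Gaussian PSF, then
passed through a standard CCD model: Poisson shot noise, linear gain, a
camera offset, and Gaussian read noise.

Relocation conserves photons: recruitment moves signal to anchor sites, it
does not create signal, so the expected green photon total per cell is
invariant to the recruitment efficiency.

The generator also produces single-spot bleach-recovery (FRAP) traces with
an exponential exchange model and a whole-field acquisition-bleaching
envelope, plus a pixel-level rendering of such a movie for round-trip tests
of trace extraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imgproc import Field2C

__all__ = [
    "SimFieldConfig",
    "FieldTruth",
    "ScreenSimConfig",
    "FrapSimConfig",
    "FrapTrace",
    "EXOCYST_PREYS",
    "simulate_field",
    "simulate_screen",
    "simulate_frap_trace",
    "simulate_frap_stack",
]

# Known exocyst subunits included as preys in the screened GFP collection;
# these are the planted interactors of the default synthetic screen.
EXOCYST_PREYS = ("Sec3", "Sec5", "Sec6", "Sec8", "Sec15", "Exo84")

CONDITIONS = ("minusRAP", "plusRAP")


def _check_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class SimFieldConfig:
    """Parameters of one synthetic field of view.

    Amplitudes are photon counts: ``anchor_amplitude`` and
    ``prey_puncta_photons`` are total photons per punctum,
    ``prey_expression`` is the mean cytosolic photon emission per interior
    pixel. ``recruitment_efficiency`` is the fraction of a cell's prey
    signal relocated to its anchor sites in a +RAP interactor field.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_cells: int = 10
    cell_radius_px: tuple[float, float] = (18.0, 2.0)  # (mean, sd)
    anchors_per_cell: float = 4.0  # Poisson mean, at least 1 drawn
    anchor_amplitude: float = 2000.0
    prey_expression: float = 5.0
    prey_native_puncta: int = 0
    prey_puncta_photons: float = 1200.0
    recruitment_efficiency: float = 0.8
    psf_sigma_px: float = 1.2
    read_noise_sd: float = 3.0
    gain: float = 2.0
    background_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_shape
        if h < 64 or w < 64:
            raise ValueError("field_shape must be at least 64x64")
        if not 0.0 <= self.recruitment_efficiency <= 1.0:
            raise ValueError("recruitment_efficiency must lie in [0, 1]")
        for name in (
            "anchor_amplitude",
            "prey_expression",
            "prey_puncta_photons",
            "psf_sigma_px",
            "read_noise_sd",
            "gain",
            "background_level",
            "anchors_per_cell",
        ):
            _check_nonneg(name, getattr(self, name))
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        mean_r, sd_r = self.cell_radius_px
        _check_nonneg("cell_radius_px mean", mean_r)
        _check_nonneg("cell_radius_px sd", sd_r)


@dataclass(frozen=True)
class FieldTruth:
    """Ground truth of a simulated field, for parameter-recovery tests."""

    anchor_coordinates: tuple[tuple[int, int], ...]
    cell_centers: tuple[tuple[int, int], ...]
    is_interactor: bool
    condition: str


@dataclass(frozen=True)
class ScreenSimConfig:
    """Layout of a full synthetic recruitment screen.

    227 prey strains by default, of which the six exocyst subunits are the
    planted interactors; 9 fields of view per strain and condition. Per-strain
    overrides replace any subset of ``field_config`` parameters.
    """

    n_strains: int = 227
    interactor_ids: tuple[str, ...] = EXOCYST_PREYS
    fields_per_condition: int = 9
    field_config: SimFieldConfig = dc_field(
        default_factory=lambda: SimFieldConfig(prey_native_puncta=3)
    )
    overrides: dict = dc_field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.fields_per_condition < 2:
            raise ValueError("fields_per_condition must be >= 2 (t-test needs variance)")
        labels = self.strain_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate strain labels")
        missing = set(self.interactor_ids) - set(labels)
        if missing:
            raise ValueError(f"interactor_ids not among strain labels: {sorted(missing)}")
        unknown = set(self.overrides) - set(labels)
        if unknown:
            raise ValueError(f"overrides for unknown strains: {sorted(unknown)}")

    def strain_labels(self) -> list[str]:
        """Interactor labels first, then numbered non-interactor preys."""
        labels = list(self.interactor_ids)[: self.n_strains]
        i = 1
        while len(labels) < self.n_strains:
            labels.append(f"prey{i:03d}")
            i += 1
        return labels


def _derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-(strain, condition, field) seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _place_cells(
    cfg: SimFieldConfig, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    """Random non-overlapping-ish cell centers kept away from the border."""
    h, w = cfg.field_shape
    mean_r, sd_r = cfg.cell_radius_px
    margin = mean_r + 3 * sd_r + 4 * cfg.psf_sigma_px + 2
    cells: list[tuple[int, int, float]] = []
    for _ in range(cfg.n_cells):
        radius = float(np.clip(rng.normal(mean_r, sd_r), 6.0, min(h, w) / 4))
        placed = False
        for _attempt in range(40):
            r = int(rng.uniform(margin, h - margin))
            c = int(rng.uniform(margin, w - margin))
            if all(
                (r - r0) ** 2 + (c - c0) ** 2 >= (radius + rad0) ** 2
                for r0, c0, rad0 in cells
            ):
                placed = True
                break
        if not placed:  # crowded field: accept the last draw (cells may touch)
            r = int(rng.uniform(margin, h - margin))
            c = int(rng.uniform(margin, w - margin))
        cells.append((r, c, radius))
    return cells


def simulate_field(
    config: SimFieldConfig,
    condition: str = "minusRAP",
    interactor: bool = False,
    apply_noise: bool = True,
) -> tuple[Field2C, FieldTruth]:
    """Render one two-channel field and its ground truth.

    The red channel holds anchor puncta on cell perimeters; the green channel
    holds cytosolic prey plus optional native membrane puncta. In a +RAP
    interactor field, ``recruitment_efficiency`` of each cell's prey photons
    (cytosolic and native-punctum) is relocated onto that cell's anchor
    coordinates. With ``apply_noise=False`` the noise-free expected ADU image
    is returned (for photon-conservation and truth-recovery tests).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(config.seed)
    h, w = config.field_shape
    red = np.zeros((h, w))
    green = np.zeros((h, w))

    recruit = config.recruitment_efficiency if (condition == "plusRAP" and interactor) else 0.0

    cells = _place_cells(config, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    anchor_coords: list[tuple[int, int]] = []

    for r0, c0, radius in cells:
        n_anchors = max(1, int(rng.poisson(config.anchors_per_cell)))
        angles = rng.uniform(0, 2 * np.pi, size=n_anchors)
        coords = [
            (
                int(np.clip(round(r0 + radius * np.sin(a)), 0, h - 1)),
                int(np.clip(round(c0 + radius * np.cos(a)), 0, w - 1)),
            )
            for a in angles
        ]
        anchor_coords.extend(coords)
        for ar, ac in coords:
            red[ar, ac] += config.anchor_amplitude

        interior = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
        area = int(interior.sum())
        cyto_total = config.prey_expression * area

        n_native = int(config.prey_native_puncta)
        native_angles = rng.uniform(0, 2 * np.pi, size=n_native)
        native_total = config.prey_puncta_photons * n_native

        # relocation conserves photons: the recruited fraction of this
        # cell's prey signal is split equally over its anchor sites
        green[interior] += (1.0 - recruit) * config.prey_expression
        for a in native_angles:
            nr = int(np.clip(round(r0 + radius * np.sin(a)), 0, h - 1))
            nc = int(np.clip(round(c0 + radius * np.cos(a)), 0, w - 1))
            green[nr, nc] += (1.0 - recruit) * config.prey_puncta_photons
        if recruit > 0:
            per_anchor = recruit * (cyto_total + native_total) / n_anchors
            for ar, ac in coords:
                green[ar, ac] += per_anchor

    sigma = config.psf_sigma_px
    if sigma > 0:
        red = gaussian_filter(red, sigma, mode="reflect")
        green = gaussian_filter(green, sigma, mode="reflect")

    if apply_noise:
        red = rng.poisson(red).astype(float) * config.gain
        green = rng.poisson(green).astype(float) * config.gain
        red += config.background_level + rng.normal(0, config.read_noise_sd, (h, w))
        green += config.background_level + rng.normal(0, config.read_noise_sd, (h, w))
    else:
        red = red * config.gain + config.background_level
        green = green * config.gain + config.background_level

    field = Field2C(
        red=np.clip(red, 0, None),
        green=np.clip(green, 0, None),
        condition=condition,
        field_index=0,
    )
    truth = FieldTruth(
        anchor_coordinates=tuple(anchor_coords),
        cell_centers=tuple((r, c) for r, c, _ in cells),
        is_interactor=bool(interactor),
        condition=condition,
    )
    return field, truth


def simulate_screen(
    config: ScreenSimConfig,
) -> Iterator[tuple[str, str, int, Field2C, FieldTruth]]:
    """Lazily generate every field of a synthetic screen.

    Yields (strain, condition, field_index, field, truth) in a fixed order;
    identical ``master_seed`` gives bit-identical pixel data. Each field's
    RNG stream is derived from (master_seed, strain index, condition index,
    field index), so any subset regenerates reproducibly.
    """
    labels = config.strain_labels()
    for si, strain in enumerate(labels):
        base = config.field_config
        if strain in config.overrides:
            base = dataclasses.replace(base, **config.overrides[strain])
        interactor = strain in config.interactor_ids
        for ci, condition in enumerate(CONDITIONS):
            for fi in range(config.fields_per_condition):
                seed = _derive_seed(config.master_seed, si, ci, fi)
                cfg = dataclasses.replace(base, seed=seed)
                fld, truth = simulate_field(cfg, condition=condition, interactor=interactor)
                fld.strain = strain
                fld.field_index = fi
                yield strain, condition, fi, fld, truth


# ---------------------------------------------------------------------------
# FRAP simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapSimConfig:
    """Generative parameters of a single-spot bleach-recovery trace.

    ``k_off`` is the exchange (dissociation) rate of the prey at the anchor
    site in 1/s; ``immobile_fraction`` the fraction of spot fluorescence that
    never exchanges; ``bleach_depth`` the fraction of spot intensity removed
    by the bleach pulse at ``bleach_frame``; ``acquisition_bleach_rate`` the
    whole-field photobleaching rate. Amplitudes are in ADU.
    """

    k_off: float = 0.02
    immobile_fraction: float = 0.0
    bleach_depth: float = 0.9
    acquisition_bleach_rate: float = 0.001
    frame_interval: float = 2.0
    n_frames: int = 240
    bleach_frame: int = 5
    noise_sd: float = 5.0
    spot_amplitude: float = 1000.0
    field_level: float = 300.0
    background_offset: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in [0, 1]")
        for name in ("k_off", "acquisition_bleach_rate", "noise_sd", "spot_amplitude",
                     "field_level", "background_offset"):
            _check_nonneg(name, getattr(self, name))
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.bleach_frame < 2:
            raise ValueError("need at least 2 pre-bleach frames")
        if self.n_frames < self.bleach_frame + 5:
            raise ValueError("n_frames too small to contain the bleach and recovery")


@dataclass
class FrapTrace:
    """Raw single-spot FRAP time series (spot, local background, whole field)."""

    times: np.ndarray
    spot_intensity: np.ndarray
    background_intensity: np.ndarray
    whole_field_intensity: np.ndarray
    bleach_frame: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("spot_intensity", "background_intensity", "whole_field_intensity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValueError("all series must have the same length as times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.bleach_frame < self.times.size:
            raise ValueError("bleach_frame out of range")


def _frap_relative_intensity(cfg: FrapSimConfig, times: np.ndarray) -> np.ndarray:
    """Spot intensity relative to the pre-bleach plateau, before the
    whole-field bleaching envelope.

    Post-bleach: 1 − bleach_depth·(immobile + mobile·exp(−k_off·(t − t_b))).
    The bleach removes ``bleach_depth`` of the spot; the mobile part
    re-exchanges with the unbleached pool at rate ``k_off`` while the
    immobile bleached part never recovers.
    """
    t_b = cfg.bleach_frame * cfg.frame_interval
    mobile = 1.0 - cfg.immobile_fraction
    rel = np.ones_like(times)
    post = times >= t_b
    rel[post] = 1.0 - cfg.bleach_depth * (
        cfg.immobile_fraction + mobile * np.exp(-cfg.k_off * (times[post] - t_b))
    )
    return rel


def simulate_frap_trace(config: FrapSimConfig) -> FrapTrace:
    """Generate a noisy FRAP trace with its reference series.

    The spot trace is the relative-recovery curve scaled by
    ``spot_amplitude``, multiplied by the acquisition-bleaching envelope
    B(t) = exp(−acquisition_bleach_rate·t), offset by the camera background;
    the whole-field trace is ``field_level``·B(t) plus background and is
    returned for bleach correction.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(config.n_frames) * config.frame_interval
    envelope = np.exp(-config.acquisition_bleach_rate * times)
    rel = _frap_relative_intensity(config, times)

    spot = config.spot_amplitude * rel * envelope + config.background_offset
    whole = config.field_level * envelope + config.background_offset
    background = np.full_like(times, config.background_offset)
    if config.noise_sd > 0:
        spot = spot + rng.normal(0, config.noise_sd, times.shape)
        whole = whole + rng.normal(0, config.noise_sd / 4, times.shape)
        background = background + rng.normal(0, config.noise_sd / 4, times.shape)
    return FrapTrace(
        times=times,
        spot_intensity=spot,
        background_intensity=background,
        whole_field_intensity=whole,
        bleach_frame=config.bleach_frame,
    )


def simulate_frap_stack(
    config: FrapSimConfig,
    shape: tuple[int, int] = (64, 64),
    spot_sigma_px: float = 1.5,
) -> np.ndarray:
    """Render the FRAP trace as a pixel movie (T, H, W).

    A Gaussian spot sits at the center of a circular cell region of uniform
    fluorescence; both decay with the acquisition-bleaching envelope and the
    spot additionally follows the bleach-recovery curve. The frame corners
    carry only the camera offset, so a corner ROI measures the true
    background. Used to round-trip trace extraction.
    """
    rng = np.random.default_rng(config.seed)
    h, w = shape
    times = np.arange(config.n_frames) * config.frame_interval
    envelope = np.exp(-config.acquisition_bleach_rate * times)
    rel = _frap_relative_intensity(config, times)

    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - h / 2) ** 2 + (xx - w / 2) ** 2
    cell = (d2 <= (min(h, w) / 3) ** 2).astype(float)
    spot_profile = np.exp(-d2 / (2 * spot_sigma_px**2))
    stack = (
        config.field_level * envelope[:, None, None] * cell[None]
        + config.spot_amplitude * (rel * envelope)[:, None, None] * spot_profile
        + config.background_offset
    )
    if config.noise_sd > 0:
        stack = stack + rng.normal(0, config.noise_sd, stack.shape)
    return np.clip(stack, 0, None)
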