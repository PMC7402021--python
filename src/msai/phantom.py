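"""Synthetic phantoms for end-to-end testing of the pipeline.

The phantom stands in for an in-vivo multi-orientation gradient-echo study:
a small voxel grid partitioned into tissue classes with known orientation
distributions, a ground-truth microscopic frequency shift curve per class,
per-(position, echo) global frequency offsets, smooth polynomial background
fields, and i.i.d. Gaussian frequency noise of equal level across field
directions.

Default tissue classes mirror the orientation contrasts found in brain
white matter: a coherent fiber parallel to the standard field direction, a
coherent fiber perpendicular to it, a dispersed fiber (Watson κ = 5), a
50/50 orthogonal crossing, an oblique dispersed fiber that breaks the
up/down acquisition symmetry, and an isotropic ("gray-matter-like") region.
The default truth curves ramp the microscopic shift linearly from 0 at the
reference echo to −3 Hz·2π at the last selected echo in fiber classes and
keep it at 0 in the isotropic class; white matter's microscopic shift grows
more negative with echo time in vivo, but the defaults are illustrative and
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .fdm import AcquisitionScheme, FrequencyShiftData, _poly_design
from .forward import MicroShiftCurve, ensemble_signal_sh, sh_projection_at
from .odf import ODF, WATSON_KAPPA_CAP, mixture_odf, uniform_odf, watson_odf

__all__ = [
    "TISSUE_CLASSES",
    "PhantomConfig",
    "Phantom",
    "build_phantom",
    "default_scheme",
    "simulate_measurements",
]

TISSUE_CLASSES = (
    "parallel", "perpendicular", "dispersed", "crossing", "oblique", "isotropic"
)

#: Standard (untilted) field direction in the image frame.
B0_STANDARD = np.array([0.0, 0.0, 1.0])

#: Half-angle of the head tilt about the left-right axis; the angle between
#: the extreme (upward/downward) positions is then 59.8°.
TILT_DEG = 29.9


@dataclass(frozen=True)
class PhantomConfig:
    """Tissue layout and ground-truth settings for :func:`build_phantom`."""

    grid_shape: tuple[int, int, int] = (10, 10, 5)
    classes: tuple[str, ...] = TISSUE_CLASSES
    kappa_coherent: float = WATSON_KAPPA_CAP
    kappa_dispersed: float = 5.0
    #: peak microscopic shift (Hz) reached at the last selected echo in
    #: fiber classes; illustrative default, not a literature value.
    wm_peak_shift_hz: float = -3.0
    #: uniform-random global offset amplitude (rad/s) per (position, echo).
    offset_amplitude: float = 0.0
    #: smooth background field amplitude (rad/s).
    background_amplitude: float = 1.0
    background_order: int = 2
    seed: int = 0


@dataclass(frozen=True)
class Phantom:
    """A voxel grid with known ODFs, truth curves, offsets and backgrounds."""

    grid_shape: tuple[int, int, int]
    tissue_labels: np.ndarray  # (V,) indices into class_names
    class_names: tuple[str, ...]
    class_odfs: dict[str, ODF]
    truth_curves: dict[str, MicroShiftCurve]
    offsets_true: np.ndarray  # (P, E) rad/s
    background_coeffs: np.ndarray  # (P, E, n_terms) rad/s
    background_order: int
    seed: int

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def odf_for_voxel(self, v: int) -> ODF:
        return self.class_odfs[self.class_names[self.tissue_labels[v]]]

    @property
    def voxel_odfs(self) -> list[ODF]:
        return [self.odf_for_voxel(v) for v in range(self.n_voxels)]


def default_scheme(n_positions: int) -> AcquisitionScheme:
    """The reference acquisition: 11 echoes at 4.5 ms spacing, odd selected.

    Echo train starts at 4.5 ms; the odd-numbered echoes (4.5, 13.5, 22.5,
    31.5, 40.5, 49.5 ms) are selected and the first is the reference.  Head
    positions tilt about the left-right (x) axis: 1 → standard; 2 → downward
    and upward (±29.9°, 59.8° apart); 3 → downward, standard, upward.
    """
    if n_positions not in (1, 2, 3):
        raise ValueError(f"n_positions must be 1, 2 or 3, got {n_positions}")
    echo_times = 4.5 * np.arange(1, 12)
    alpha = np.deg2rad(TILT_DEG)
    tilt_down = np.array([0.0, -np.sin(alpha), np.cos(alpha)])
    tilt_up = np.array([0.0, np.sin(alpha), np.cos(alpha)])
    positions = {
        1: [B0_STANDARD],
        2: [tilt_down, tilt_up],
        3: [tilt_down, B0_STANDARD, tilt_up],
    }[n_positions]
    return AcquisitionScheme(
        b0_directions=np.array(positions),
        echo_times_ms=echo_times,
        reference_time_ms=4.5,
    )


def _class_odf(name: str, config: PhantomConfig) -> ODF:
    x = np.array([1.0, 0.0, 0.0])
    if name == "parallel":
        return watson_odf(B0_STANDARD, config.kappa_coherent)
    if name == "perpendicular":
        return watson_odf(x, config.kappa_coherent)
    if name == "dispersed":
        return watson_odf(B0_STANDARD, config.kappa_dispersed)
    if name == "crossing":
        return mixture_odf([
            (0.5, watson_odf(B0_STANDARD, config.kappa_coherent)),
            (0.5, watson_odf(x, config.kappa_coherent)),
        ])
    if name == "oblique":
        # fiber at 45° in the tilt plane: breaks the up/down acquisition
        # symmetry, which the joint offset estimation relies on
        mu = np.array([0.0, np.sin(np.pi / 4), np.cos(np.pi / 4)])
        return watson_odf(mu, config.kappa_dispersed)
    if name == "isotropic":
        return uniform_odf()
    raise ValueError(f"unknown tissue class {name!r}")


def build_phantom(
    config: PhantomConfig | None = None,
    scheme: AcquisitionScheme | None = None,
) -> Phantom:
    """Deterministically construct a phantom for the given scheme.

    Voxels are partitioned into contiguous equal blocks, one per tissue
    class.  Truth curves are defined at every fitted echo of the scheme.
    Offsets and background coefficients are drawn reproducibly from the
    config seed (zero offsets when ``offset_amplitude`` is 0).
    """
    if config is None:
        config = PhantomConfig()
    if scheme is None:
        scheme = default_scheme(3)
    n_vox = int(np.prod(config.grid_shape))
    n_classes = len(config.classes)
    if n_classes < 1:
        raise ValueError("need at least one tissue class")
    labels = np.minimum(
        (np.arange(n_vox) * n_classes) // n_vox, n_classes - 1
    )
    class_odfs = {name: _class_odf(name, config) for name in config.classes}

    times = scheme.fitted_echo_times_ms
    t0 = scheme.reference_time_ms
    ramp = (times - t0) / (times[-1] - t0)
    peak = 2.0 * np.pi * config.wm_peak_shift_hz
    curves = {}
    for name in config.classes:
        omega = np.zeros_like(times) if name == "isotropic" else peak * ramp
        curves[name] = MicroShiftCurve(echo_times_ms=times, omega_A=omega)

    rng = np.random.default_rng(config.seed)
    shape_pe = (scheme.n_positions, times.size)
    if config.offset_amplitude > 0:
        offsets = rng.uniform(-config.offset_amplitude, config.offset_amplitude,
                              size=shape_pe)
    else:
        offsets = np.zeros(shape_pe)
    n_terms = _poly_design((2, 2, 2), config.background_order).shape[1]
    bg = rng.uniform(-1.0, 1.0, size=shape_pe + (n_terms,))
    bg *= config.background_amplitude
    return Phantom(
        grid_shape=config.grid_shape,
        tissue_labels=labels,
        class_names=tuple(config.classes),
        class_odfs=class_odfs,
        truth_curves=curves,
        offsets_true=offsets,
        background_coeffs=bg,
        background_order=config.background_order,
        seed=config.seed,
    )


def simulate_measurements(
    phantom: Phantom,
    scheme: AcquisitionScheme,
    sigma_y: float = 0.0,
    with_background: bool = False,
    seed: int = 0,
) -> FrequencyShiftData:
    """Forward-simulate frequency-shift measurements for a phantom.

    Per voxel, position and fitted echo:
    ``y = arg(δE)/(t − t₀) + φ_true + background + N(0, σ_y)``, with the
    noise i.i.d. across voxels, positions and echoes and seeded.
    """
    if sigma_y < 0:
        raise ValueError(f"sigma_y must be >= 0, got {sigma_y}")
    times = scheme.fitted_echo_times_ms
    if phantom.offsets_true.shape != (scheme.n_positions, times.size):
        raise ValueError("phantom offsets do not match the scheme")
    t0 = scheme.reference_time_ms * 1e-3
    dts = times * 1e-3 - t0
    n_vox = phantom.n_voxels

    # model-implied frequency per (class, position, echo)
    class_y = {}
    for name in phantom.class_names:
        odf = phantom.class_odfs[name]
        omega = phantom.truth_curves[name].omega_A
        y_pe = np.empty((scheme.n_positions, times.size))
        for p, b in enumerate(scheme.b0_directions):
            q = sh_projection_at(odf, b)
            delta_e = ensemble_signal_sh(q, omega * dts)
            y_pe[p] = np.angle(delta_e) / dts
        class_y[name] = y_pe

    values = np.empty((n_vox, scheme.n_positions, times.size))
    for idx, name in enumerate(phantom.class_names):
        sel = phantom.tissue_labels == idx
        values[sel] = class_y[name][None, :, :]
    values += phantom.offsets_true[None, :, :]
    if with_background:
        design = _poly_design(phantom.grid_shape, phantom.background_order)
        bg = np.einsum("vk,pek->vpe", design, phantom.background_coeffs)
        values += bg
    if sigma_y > 0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, sigma_y, size=values.shape)
    return FrequencyShiftData(
        values=values,
        scheme=scheme,
        noise_sigma=sigma_y or None,
        meta={"phantom_seed": phantom.seed, "noise_seed": seed},
    )
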