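"""Synthetic data generators: embryo-scale edge tracks, single-junction
traces, and rendered junction images.

The embryo generator emulates the statistical structure of tracked cell edges
in the germband during ventral-furrow formation:

* a dorsoventrally graded, anisotropic strain-rate field — strongest on
  DV-parallel edges next to the furrow, decaying linearly with DV distance,
  ramping up and down in time (trapezoidal window);
* myosin produced by driving the junction model kinematically along the
  imposed length history, with an edge-specific feedback coefficient
  interpolated linearly between a ventral and a dorsal endpoint, plus
  turnover and density noise — so generated tracks embody the ground-truth
  feedback power law with oscillator-style fluctuations on top;
* a mutant condition obtained by uniformly attenuating the strain field
  (``mutant_scale``), leaving the feedback machinery untouched.

Every generated dataset is accompanied by its :class:`GroundTruth`, enabling
parameter-recovery tests of the downstream inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.morphology import disk

from .model import JunctionState, ModelParams, TensionProtocol, simulate
from .tracks import EdgeTrack

__all__ = [
    "EmbryoSpec",
    "GroundTruth",
    "generate_embryo_tracks",
    "generate_single_junction_trace",
    "render_junction_image",
    "trapezoid_ramp",
]


def _default_oscillator() -> ModelParams:
    # coarser step than the free-running oscillator: the embryo drive is
    # kinematic (no fast length dynamics to resolve), only turnover/noise
    return ModelParams(dt=0.5)


@dataclass(frozen=True)
class EmbryoSpec:
    """Full parameterization of a synthetic embryo.

    Lengths in µm, durations in minutes, rates per minute.  ``strain_peak_rate``
    is the plateau strain rate of a perfectly DV-parallel edge at the ventral
    midline; the field decays linearly with DV distance (clamped at zero) and
    is weighted by ``|sin(orientation)|**anisotropy_exponent``.
    """

    ap_length: float = 400.0
    dv_halfcircumference: float = 280.0
    n_edges: int = 2000
    edge_orientation_mix: float = 0.5     # fraction of DV-parallel edges
    orientation_spread: float = 10.0      # degrees, cone width around 0/90
    strain_peak_rate: float = 0.12        # per minute at the ventral midline
    strain_gradient: float = 0.0027       # per µm of DV distance
    anisotropy_exponent: float = 2.0
    ramp_window: tuple[float, float] = (2.0, 22.0)  # minutes
    ramp_rise: float = 3.0                # minutes, trapezoid rise/fall time
    feedback_c_ventral: float = 1.0
    feedback_c_dorsal: float = 0.5
    oscillator: ModelParams = field(default_factory=_default_oscillator)
    sampling_dt: float = 30.0             # seconds
    duration: float = 25.0                # minutes
    mutant_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ap_length", "dv_halfcircumference", "sampling_dt",
                     "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_edges < 1:
            raise ValueError("n_edges must be >= 1")
        if not 0.0 <= self.edge_orientation_mix <= 1.0:
            raise ValueError("edge_orientation_mix must be in [0, 1]")
        if not 0.0 <= self.mutant_scale <= 1.0:
            raise ValueError("mutant_scale must be in [0, 1]")
        if self.feedback_c_ventral < 0 or self.feedback_c_dorsal < 0:
            raise ValueError("feedback coefficients must be >= 0")
        if self.strain_peak_rate < 0 or self.strain_gradient < 0:
            raise ValueError("strain field parameters must be >= 0")
        t0, t1 = self.ramp_window
        if not (0 <= t0 < t1):
            raise ValueError("ramp_window must satisfy 0 <= start < end")
        if self.sampling_dt < self.oscillator.dt:
            raise ValueError("sampling_dt must be >= oscillator dt")


@dataclass(frozen=True)
class GroundTruth:
    """Imposed quantities behind a generated embryo, for recovery tests.

    ``strain_rate`` holds the imposed (noise-free) strain rate per minute at
    the sampled timepoints, one row per edge, aligned with the track order.
    """

    times: np.ndarray
    strain_rate: np.ndarray          # (n_edges, n_times), per minute
    feedback_c: np.ndarray           # (n_edges,)
    dv_position: np.ndarray          # (n_edges,)
    orientation: np.ndarray          # (n_edges,)
    baseline_density: float
    spec: EmbryoSpec


def trapezoid_ramp(t_min: np.ndarray, window: tuple[float, float],
                   rise: float) -> np.ndarray:
    """Trapezoidal time profile in [0, 1] over ``window`` (minutes).

    Linear rise over ``rise`` minutes after the window opens, plateau, then a
    symmetric fall ending when the window closes.
    """
    t0, t1 = window
    rise = min(rise, 0.5 * (t1 - t0))
    t = np.asarray(t_min, dtype=float)
    up = np.clip((t - t0) / rise, 0.0, 1.0) if rise > 0 else (t >= t0).astype(float)
    down = np.clip((t1 - t) / rise, 0.0, 1.0) if rise > 0 else (t <= t1).astype(float)
    return np.where((t >= t0) & (t <= t1), np.minimum(up, down), 0.0)


def _draw_orientations(rng: np.random.Generator, spec: EmbryoSpec) -> np.ndarray:
    """Two cones of orientations around the AP (0°) and DV (90°) axes."""
    n = spec.n_edges
    is_dv = rng.random(n) < spec.edge_orientation_mix
    dev = np.abs(rng.normal(0.0, spec.orientation_spread, size=n))
    dev = np.clip(dev, 0.0, 90.0)
    return np.where(is_dv, 90.0 - dev, dev)


def generate_embryo_tracks(spec: EmbryoSpec) -> tuple[list[EdgeTrack], GroundTruth]:
    """Generate ``spec.n_edges`` edge tracks plus their ground truth.

    Edge lengths integrate the imposed strain-rate field exactly
    (``L(t) = L(0) * exp(int eps_dot dt)``); myosin densities come from the
    junction model driven along that length history (exact dilution, Euler
    turnover, exact feedback log-increment, Euler–Maruyama noise), using an
    edge-specific feedback coefficient interpolated linearly in DV position.
    Deterministic given ``spec.seed``; per-edge noise streams are derived
    from spawned child seeds, so edge ``i`` is unaffected by ``n_edges``.
    """
    osc = spec.oscillator
    root = np.random.SeedSequence(spec.seed)
    geom_rng = np.random.default_rng(root.spawn(1)[0])
    edge_seeds = root.spawn(spec.n_edges + 1)[1:]

    n = spec.n_edges
    dv = geom_rng.uniform(0.0, spec.dv_halfcircumference, size=n)
    ap = geom_rng.uniform(0.0, spec.ap_length, size=n)
    theta = _draw_orientations(geom_rng, spec)
    L0 = geom_rng.lognormal(mean=math.log(5.0), sigma=0.2, size=n)
    c_edge = (spec.feedback_c_ventral
              + (spec.feedback_c_dorsal - spec.feedback_c_ventral)
              * dv / spec.dv_halfcircumference)

    # per-edge strain-rate amplitude (per minute, before the time ramp)
    dv_factor = np.maximum(0.0, 1.0 - spec.strain_gradient * dv)
    ani = np.abs(np.sin(np.radians(theta))) ** spec.anisotropy_exponent
    amp = spec.strain_peak_rate * dv_factor * ani * spec.mutant_scale

    dt = osc.dt
    n_steps = int(round(spec.duration * 60.0 / dt))
    stride = int(round(spec.sampling_dt / dt))
    if abs(stride * dt - spec.sampling_dt) > 1e-9:
        raise ValueError("sampling_dt must be a multiple of the oscillator dt")
    n_samp = n_steps // stride
    times = np.arange(n_samp + 1) * stride * dt

    # per-edge density noise, one stream per edge (reproducible under subsetting)
    if osc.noise_sigma > 0:
        noise = np.empty((n, n_steps))
        for i, ss in enumerate(edge_seeds):
            noise[i] = np.random.default_rng(ss).standard_normal(n_steps)
    else:
        noise = None

    L = L0.copy()
    m = np.full(n, osc.baseline_density)
    m0t = np.full(n, osc.baseline_density)
    L_out = np.empty((n, n_samp + 1))
    m_out = np.empty((n, n_samp + 1))
    gt_rate = np.empty((n, n_samp + 1))
    # time ramp evaluated at step midpoints (for integration) and at the
    # sampled timepoints (for the ground-truth table)
    ramp_mid = trapezoid_ramp((np.arange(n_steps) + 0.5) * dt / 60.0,
                              spec.ramp_window, spec.ramp_rise)
    ramp_samp = trapezoid_ramp(times / 60.0, spec.ramp_window, spec.ramp_rise)

    L_out[:, 0] = L
    m_out[:, 0] = m
    gt_rate[:] = amp[:, None] * ramp_samp[None, :]

    inv_tau = (dt / osc.turnover_tau) if math.isfinite(osc.turnover_tau) else 0.0
    sig = osc.noise_sigma * math.sqrt(dt)
    j = 0
    for i in range(n_steps):
        # per-second imposed rate over this step; exact exponential update
        ratio = np.exp(amp * (ramp_mid[i] / 60.0 * dt))
        L *= ratio
        m /= ratio                      # exact dilution/concentration
        if inv_tau:
            m += inv_tau * (m0t - m)
        if noise is not None:
            m += sig * noise[:, i]
            np.maximum(m, 0.0, out=m)
        np.power(ratio, c_edge, out=ratio)   # reuse buffer: ratio**c
        m0t *= ratio                    # exact feedback law
        if (i + 1) % stride == 0:
            j += 1
            L_out[:, j] = L
            m_out[:, j] = m

    tracks = [
        EdgeTrack(edge_id=i, times=times, lengths=L_out[i],
                  myosin_density=m_out[i], dv_position=float(dv[i]),
                  ap_position=float(ap[i]), orientation=float(theta[i]))
        for i in range(n)
    ]
    truth = GroundTruth(times=times, strain_rate=gt_rate, feedback_c=c_edge,
                        dv_position=dv, orientation=theta,
                        baseline_density=osc.baseline_density, spec=spec)
    return tracks, truth


def generate_single_junction_trace(params: ModelParams,
                                   protocol: TensionProtocol,
                                   duration: float,
                                   sampling_dt: float = 4.7,
                                   seed: int = 0,
                                   initial: JunctionState | None = None,
                                   edge_id: int = 0) -> EdgeTrack:
    """Free-running junction simulation down-sampled to a confocal-like rate.

    The model is integrated at ``params.dt`` and sampled every
    ``sampling_dt`` seconds (default 4.7 s, a typical high-speed confocal
    frame interval).  ``sampling_dt`` is rounded to the nearest multiple of
    the model step.
    """
    if sampling_dt < params.dt:
        raise ValueError("sampling_dt must be >= model dt")
    stride = max(1, int(round(sampling_dt / params.dt)))
    trace = simulate(params, protocol, duration, initial=initial, seed=seed)
    return EdgeTrack(edge_id=edge_id,
                     times=trace.times[::stride],
                     lengths=trace.length[::stride],
                     myosin_density=np.maximum(trace.myosin_density[::stride],
                                               1e-12),
                     dv_position=0.0, ap_position=0.0, orientation=90.0)


def render_junction_image(shape: tuple[int, int],
                          edges: Sequence[np.ndarray],
                          junction_density: float,
                          cytoplasm_density: float,
                          psf_sigma: float = 0.0,
                          noise_sigma: float = 0.0,
                          seed: int = 0,
                          junction_halfwidth: int = 0,
                          border: int = 3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a synthetic junction image plus labeled masks.

    Each entry of ``edges`` is an (n, 2) array of (row, col) polyline
    vertices.  The tissue interior (everything except a dark ``border``
    frame) is filled with ``cytoplasm_density``; edge pixels (optionally
    thickened by ``junction_halfwidth``) are set to ``junction_density``.
    The image is then Gaussian-blurred with ``psf_sigma`` pixels and Gaussian
    noise of SD ``noise_sigma`` is added.  Returns ``(image, edge_labels,
    cytoplasm_mask)`` with the masks unblurred; labels are 1-based in input
    order.
    """
    if junction_density < 0 or cytoplasm_density < 0:
        raise ValueError("densities must be >= 0")
    if not edges:
        raise ValueError("no edge geometry given")
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    selem = disk(junction_halfwidth) if junction_halfwidth > 0 else None
    for i, poly in enumerate(edges):
        poly = np.asarray(poly)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
            raise ValueError(f"edge {i}: polyline needs >= 2 (row, col) points")
        if np.all(np.ptp(poly, axis=0) == 0):
            raise ValueError(f"edge {i}: zero-length polyline")
        mask = np.zeros(shape, dtype=bool)
        for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
            rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[keep], cc[keep]] = True
        if selem is not None:
            mask = ndimage.binary_dilation(mask, structure=selem)
        labels[mask] = i + 1

    interior = np.zeros(shape, dtype=bool)
    interior[border:h - border, border:w - border] = True
    # keep the cytoplasm mask clear of the dark frame by a PSF-sized guard so
    # border bleed does not depress the cytoplasmic reference level
    guard = int(math.ceil(3.0 * psf_sigma)) if psf_sigma > 0 else 0
    pure = np.zeros(shape, dtype=bool)
    pure[border + guard:h - border - guard, border + guard:w - border - guard] = True
    cytoplasm_mask = pure & (labels == 0)

    image = np.zeros(shape, dtype=float)
    image[interior] = cytoplasm_density
    image[(labels > 0) & interior] = junction_density
    if psf_sigma > 0:
        image = ndimage.gaussian_filter(image, psf_sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=shape)
    return image, labels, cytoplasm_mask
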