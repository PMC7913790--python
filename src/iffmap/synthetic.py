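"""Forward simulation of contrast transport and synthetic cohort generation.

The tracer model is the 2D diffusion–advection equation

    dphi/dt = div(D grad phi) - div(phi u)

for contrast concentration ``phi`` with isotropic diffusion coefficient
``D(x)`` and interstitial velocity ``u(x)``, both held constant over the
(short) analysis window.  Two explicit time-stepping schemes are provided:

``"conservative"`` (default)
    Finite-volume flux form with zero-flux (Neumann) boundaries.  Without a
    source it conserves total tracer to rounding error and is the scheme used
    for physically realistic phantoms; an internal micro-timestep keeps the
    explicit update inside its stability bound even when frame intervals are
    long.

``"gradient"``
    Forward-time central-space update
    ``phi <- phi + dt * (D * lap(phi) - ux * gx(phi) - uy * gy(phi))``,
    the exact discrete model inverted by :mod:`iffmap.estimation`.  With one
    step per frame interval this produces *matched-discretization* stacks on
    which parameter recovery is exact up to solver rounding — the key
    self-consistency check of the whole pipeline.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np

from .types import ConcentrationStack, RegionMask, TransportField

__all__ = [
    "SourceSpec",
    "PhantomSpec",
    "SyntheticCohortSpec",
    "simulate_stack",
    "make_phantom",
    "phantom_region_masks",
    "simulate_cohort",
    "gaussian_blob",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SourceSpec:
    """Additive per-pixel enhancement source, active on [t_on, t_off).

    Represents vascular gadolinium entry as a constant influx ``rate``
    (concentration units per second, scalar or per-pixel map) switched on and
    off at configurable times.  Default phantoms use no source and a nonzero
    initial blob instead.
    """

    rate: float | np.ndarray = 0.0
    t_on: float = 0.0
    t_off: float = math.inf


@dataclass
class PhantomSpec:
    """Recipe for a ground-truth transport field plus initial condition.

    Kinds
    -----
    ``uniform``
        Constant D and u everywhere.
    ``gaussian_blob``
        Constant D; velocity is the uniform direction modulated by a Gaussian
        envelope around the grid centre (a localized flow jet).
    ``tumor_ring``
        A central disk (``tumor``) with one (D, |u|) regime and a surrounding
        annulus (``parenchyma``) with another; velocity points radially
        outward, emulating pressure-driven efflux from a tumor core.
    """

    grid_shape: tuple[int, int] = (64, 64)
    kind: Literal["uniform", "gaussian_blob", "tumor_ring"] = "uniform"
    pixel_spacing: float = 1.0
    diffusion: float = 0.2
    velocity: tuple[float, float] = (0.4, -0.2)
    # tumor_ring regime parameters
    inner_speed: float = 0.05
    outer_speed: float = 0.15
    inner_diffusion: float = 0.1
    outer_diffusion: float = 0.2
    inner_radius: float = 10.0
    outer_radius: float = 20.0
    # initial condition: list of (cx, cy, sigma, amplitude) Gaussian blobs
    blobs: Sequence[tuple[float, float, float, float]] | None = None
    baseline: float = 0.0
    noise_sigma: float = 0.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        ny, nx = self.grid_shape
        if ny < 16 or nx < 16:
            raise ValueError("phantom grid must be at least 16x16")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


@dataclass
class SyntheticCohortSpec:
    """Generator settings for a synthetic patient cohort.

    Draws (velocity, age, survival) from a trivariate Gaussian with the
    requested pairwise correlations, then attaches uncorrelated weight, sex
    and molecular covariates.  Defaults encode the qualitative pattern seen
    clinically: faster tumor interstitial flow in younger patients who
    survive longer.
    """

    n_patients: int = 14
    velocity_mean: float = 0.5  # mean tumor |u| per patient (um/s scale)
    velocity_sd: float = 0.15
    age_mean: float = 60.0  # years
    age_sd: float = 10.0
    survival_mean: float = 400.0  # days
    survival_sd: float = 150.0
    r_velocity_survival: float = 0.6
    r_velocity_age: float = -0.6
    r_age_survival: float = -0.6
    weight_mean: float = 80.0  # kg, uncorrelated
    weight_sd: float = 12.0
    seed: int | None = 0

    def correlation_matrix(self) -> np.ndarray:
        """Correlation of (velocity, age, survival); must be PSD to sample."""
        for r in (self.r_velocity_survival, self.r_velocity_age, self.r_age_survival):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlation targets must lie in [-1, 1]")
        return np.array(
            [
                [1.0, self.r_velocity_age, self.r_velocity_survival],
                [self.r_velocity_age, 1.0, self.r_age_survival],
                [self.r_velocity_survival, self.r_age_survival, 1.0],
            ]
        )


# ---------------------------------------------------------------------------
# stepping kernels
# ---------------------------------------------------------------------------


def _edge_pad(a: np.ndarray) -> np.ndarray:
    return np.pad(a, 1, mode="edge")


def gradient_stencils(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """5-point Laplacian and central first differences, pixel units (h = 1).

    Edge-replicated padding supplies boundary neighbours; interior pixels are
    exact central stencils.  x is the column axis, y the row axis.
    """
    p = _edge_pad(phi)
    c = p[1:-1, 1:-1]
    up, down = p[:-2, 1:-1], p[2:, 1:-1]
    left, right = p[1:-1, :-2], p[1:-1, 2:]
    lap = up + down + left + right - 4.0 * c
    gx = 0.5 * (right - left)
    gy = 0.5 * (down - up)
    return lap, gx, gy


def _step_gradient(phi, D, ux, uy, h, dt):
    lap, gx, gy = gradient_stencils(phi)
    return phi + dt * (D * lap / h**2 - ux * gx / h - uy * gy / h)


def _step_conservative(phi, D, ux, uy, h, dt, upwind: bool):
    # fluxes on cell faces; boundary faces carry zero flux (Neumann)
    dphi = np.zeros_like(phi)
    # x faces between columns j and j+1
    Df = 0.5 * (D[:, 1:] + D[:, :-1])
    Uf = 0.5 * (ux[:, 1:] + ux[:, :-1])
    if upwind:
        phif = np.where(Uf > 0, phi[:, :-1], phi[:, 1:])
    else:
        phif = 0.5 * (phi[:, 1:] + phi[:, :-1])
    Fx = -Df * (phi[:, 1:] - phi[:, :-1]) / h + Uf * phif
    dphi[:, :-1] -= Fx / h
    dphi[:, 1:] += Fx / h
    # y faces between rows i and i+1
    Df = 0.5 * (D[1:, :] + D[:-1, :])
    Vf = 0.5 * (uy[1:, :] + uy[:-1, :])
    if upwind:
        phif = np.where(Vf > 0, phi[:-1, :], phi[1:, :])
    else:
        phif = 0.5 * (phi[1:, :] + phi[:-1, :])
    Fy = -Df * (phi[1:, :] - phi[:-1, :]) / h + Vf * phif
    dphi[:-1, :] -= Fy / h
    dphi[1:, :] += Fy / h
    return phi + dt * dphi


def _stability_limit(D: np.ndarray, ux: np.ndarray, uy: np.ndarray, h: float) -> tuple[float, str]:
    """Most restrictive explicit-step bound and the constraint that sets it."""
    dmax = float(np.nanmax(D)) if D.size else 0.0
    umax = float(np.nanmax(np.hypot(ux, uy))) if ux.size else 0.0
    dt_diff = h**2 / (4.0 * dmax) if dmax > 0 else math.inf
    dt_adv = h / (2.0 * umax) if umax > 0 else math.inf
    if dt_diff <= dt_adv:
        return dt_diff, f"diffusion (dt <= h^2/(4 max D) = {dt_diff:.3g})"
    return dt_adv, f"advection (dt <= h/(2 max |u|) = {dt_adv:.3g})"


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def simulate_stack(
    field: TransportField,
    initial: np.ndarray,
    frame_times: Sequence[float],
    *,
    pre_contrast_count: int = 1,
    baseline: float = 0.0,
    source: SourceSpec | None = None,
    noise_sigma: float = 0.0,
    noise_model: Literal["gaussian", "rician"] = "gaussian",
    seed: int | None = None,
    scheme: Literal["conservative", "gradient"] = "conservative",
    upwind: bool = False,
    cfl_factor: float = 0.25,
    dt_micro: float | None = None,
) -> ConcentrationStack:
    """Evolve ``initial`` under ``field`` and sample frames at ``frame_times``.

    The first ``pre_contrast_count`` entries of ``frame_times`` are
    pre-contrast frames containing only ``baseline`` (+ noise); the tracer
    field starts as ``initial`` at the first post-contrast time and is
    integrated between successive post-contrast times.

    ``dt_micro`` fixes the internal micro-timestep explicitly; it must satisfy
    the explicit-scheme stability bound (error otherwise, naming the limiting
    constraint).  By default the step is ``cfl_factor`` times that bound,
    rounded so each frame interval holds an integer number of micro-steps.
    With ``scheme="gradient"`` and ``dt_micro`` equal to the frame spacing,
    one update per interval yields a matched-discretization stack for exact
    inverse recovery.

    Raises
    ------
    ValueError
        On negative diffusion anywhere, or a requested micro-step violating
        the stability bound.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if initial.shape != field.grid_shape:
        raise ValueError("initial condition and transport field shapes differ")
    D, ux, uy = field.diffusion, field.velocity_x, field.velocity_y
    if np.any(D < 0) or not np.all(np.isfinite(D)):
        raise ValueError("diffusion map must be finite and nonnegative everywhere")
    h = field.pixel_spacing
    n_post = len(frame_times) - pre_contrast_count
    if n_post < 1:
        raise ValueError("need at least one post-contrast frame time")

    dt_limit, constraint = _stability_limit(D, ux, uy, h)
    if dt_micro is not None:
        if dt_micro > dt_limit * (1 + 1e-12):
            raise ValueError(
                f"micro-timestep {dt_micro:.3g} violates the stability bound set by {constraint}"
            )
        base_dt = dt_micro
    else:
        base_dt = cfl_factor * dt_limit

    source = source or SourceSpec()
    rate = np.broadcast_to(np.asarray(source.rate, dtype=float), initial.shape)

    step = (
        (lambda p, dt: _step_gradient(p, D, ux, uy, h, dt))
        if scheme == "gradient"
        else (lambda p, dt: _step_conservative(p, D, ux, uy, h, dt, upwind))
    )

    post_times = frame_times[pre_contrast_count:]
    frames = np.empty((len(frame_times),) + initial.shape, dtype=float)
    frames[:pre_contrast_count] = baseline

    phi = initial.copy()
    t = post_times[0]
    frames[pre_contrast_count] = baseline + phi
    for k, t_next in enumerate(post_times[1:], start=1):
        span = t_next - t
        n_sub = max(1, math.ceil(span / base_dt - 1e-12)) if math.isfinite(base_dt) else 1
        dt = span / n_sub
        for _ in range(n_sub):
            phi = step(phi, dt)
            if source.t_on <= t < source.t_off or (
                source.t_on < t + dt <= source.t_off
            ):  # source active during (part of) this micro-step
                on = max(t, source.t_on)
                off = min(t + dt, source.t_off)
                if off > on:
                    phi = phi + rate * (off - on)
            t += dt
        t = t_next  # absorb rounding
        frames[pre_contrast_count + k] = baseline + phi

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
        elif noise_model == "rician":
            n1 = rng.normal(0.0, noise_sigma, size=frames.shape)
            n2 = rng.normal(0.0, noise_sigma, size=frames.shape)
            frames = np.hypot(frames + n1, n2)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    # magnitude images are nonnegative
    np.clip(frames, 0.0, None, out=frames)

    return ConcentrationStack(
        frames=frames,
        frame_times=frame_times,
        pixel_spacing=h,
        pre_contrast_count=pre_contrast_count,
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def gaussian_blob(
    grid_shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    sigma: float = 8.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Isotropic Gaussian concentration bump; center in (x, y) pixel coords."""
    ny, nx = grid_shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))


def _radial_unit(grid_shape, center):
    ny, nx = grid_shape
    cx, cy = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(r > 0, dx / r, 1.0)  # center pixel points +x by convention
        ey = np.where(r > 0, dy / r, 0.0)
    return ex, ey, r


def make_phantom(spec: PhantomSpec) -> tuple[TransportField, np.ndarray]:
    """Build the ground-truth transport field and initial concentration.

    Returns the true :class:`TransportField` (all pixels valid) and the
    initial condition used as the first post-contrast frame, so downstream
    parameter-recovery tests can compare estimates against exact truth.
    """
    ny, nx = spec.grid_shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    if spec.kind == "uniform":
        D = np.full(spec.grid_shape, spec.diffusion)
        ux = np.full(spec.grid_shape, spec.velocity[0])
        uy = np.full(spec.grid_shape, spec.velocity[1])
    elif spec.kind == "gaussian_blob":
        D = np.full(spec.grid_shape, spec.diffusion)
        envelope = gaussian_blob(spec.grid_shape, center, sigma=min(ny, nx) / 6.0)
        ux = spec.velocity[0] * envelope
        uy = spec.velocity[1] * envelope
    elif spec.kind == "tumor_ring":
        ex, ey, r = _radial_unit(spec.grid_shape, center)
        inner = r <= spec.inner_radius
        outer = (r > spec.inner_radius) & (r <= spec.outer_radius)
        speed = np.zeros(spec.grid_shape)
        speed[inner] = spec.inner_speed
        speed[outer] = spec.outer_speed
        D = np.full(spec.grid_shape, spec.outer_diffusion)
        D[inner] = spec.inner_diffusion
        ux, uy = speed * ex, speed * ey
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    field = TransportField(
        diffusion=D,
        velocity_x=ux,
        velocity_y=uy,
        valid_mask=np.ones(spec.grid_shape, dtype=bool),
        pixel_spacing=spec.pixel_spacing,
        units="pixel-frame",
    )

    blobs = spec.blobs
    if blobs is None:
        blobs = [(center[0], center[1], min(ny, nx) / 8.0, 1.0)]
    initial = np.zeros(spec.grid_shape)
    for cx, cy, sigma, amp in blobs:
        initial += gaussian_blob(spec.grid_shape, (cx, cy), sigma, amp)
    return field, initial


def phantom_region_masks(spec: PhantomSpec) -> tuple[RegionMask, RegionMask]:
    """Tumor-disk and parenchyma-annulus masks matching a tumor_ring phantom."""
    if spec.kind != "tumor_ring":
        raise ValueError("region masks are defined for the tumor_ring kind")
    ny, nx = spec.grid_shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    _, _, r = _radial_unit(spec.grid_shape, center)
    tumor = RegionMask(r <= spec.inner_radius, label="tumor")
    ring = RegionMask((r > spec.inner_radius) & (r <= spec.outer_radius), label="parenchyma")
    return tumor, ring


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(spec: SyntheticCohortSpec):
    """Sample a synthetic patient cohort with a built-in correlation structure.

    Returns a :class:`pandas.DataFrame` with one row per patient: a true mean
    tumor velocity magnitude plus clinical covariates (age, survival, weight,
    sex, MGMT methylation, EGFR amplification).  Velocity, age and survival
    follow a trivariate Gaussian with the spec's target correlations; at
    n >= 500 the sample Pearson correlations land within ~0.05 of the
    targets.

    Raises
    ------
    ValueError
        If the target correlation matrix is not positive semi-definite.
    """
    import pandas as pd

    corr = spec.correlation_matrix()
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "target correlations are jointly infeasible (matrix not positive semi-definite)"
        )
    rng = np.random.default_rng(spec.seed)
    # eigendecomposition square root tolerates the semi-definite edge cases
    w, V = np.linalg.eigh(corr)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_patients, 3)) @ L.T

    velocity = spec.velocity_mean + spec.velocity_sd * z[:, 0]
    age = spec.age_mean + spec.age_sd * z[:, 1]
    survival = spec.survival_mean + spec.survival_sd * z[:, 2]
    velocity = np.clip(velocity, 1e-6, None)
    age = np.clip(age, 18.0, None)
    survival = np.clip(survival, 1.0, None)

    weight = rng.normal(spec.weight_mean, spec.weight_sd, size=spec.n_patients)
    sex = rng.choice(["F", "M"], size=spec.n_patients)
    mgmt = rng.choice(["methylated", "unmethylated"], size=spec.n_patients)
    egfr = rng.choice([True, False], size=spec.n_patients)

    return pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:02d}" for i in range(spec.n_patients)],
            "true_velocity": velocity,
            "age_years": age,
            "survival_days": survival,
            "weight_kg": weight,
            "sex": sex,
            "mgmt_status": mgmt,
            "egfr_amplified": egfr,
        }
    )
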