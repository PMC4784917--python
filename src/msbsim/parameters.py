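"""Physical-to-dimensionless conversions for Brownian magnetic nanoparticles.

A rigid single-domain nanoparticle suspended in fluid rotates mechanically
(Brownian rotation) under an oscillating magnetic field.  Its mean dynamics
are controlled by three dimensionless groups:

* the unitless field ``xi0 = mu * B0 / (k_B * T)`` — Zeeman over thermal
  energy at peak drive,
* the unitless frequency ``Omega = f * tau_B`` with the zero-field Brownian
  relaxation time ``tau_B = 3 * eta * V / (k_B * T)``,
* the master variable ``A = xi0 / Omega``, which alone parameterizes the
  noise-free dynamics and dominates the mean response whenever xi0 > Omega.

This module holds the domain containers (fluid environment, drive field,
particle size specification, sampled polydisperse ensembles) and the
conversion functions between physical (SI) and dimensionless descriptions,
including lognormal size sampling and the rotational Reynolds-number check
that justifies dropping inertia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import K_B, ROOM_TEMPERATURE

__all__ = [
    "Environment",
    "DriveField",
    "ParticleSpec",
    "ParticleEnsemble",
    "DimensionlessParams",
    "brownian_relaxation_time",
    "unitless_field",
    "unitless_frequency",
    "master_variable",
    "ensemble_master_variable",
    "reynolds_number",
    "sample_lognormal_radii",
    "moment_from_core",
    "lognormal_sigma",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) >= 0):
            raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class Environment:
    """Suspending-fluid environment.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity eta, Pa*s.  Water at room temperature is ~1e-3.
    temperature : float
        Absolute temperature T, K.
    density : float
        Fluid mass density rho, kg/m^3.  Used only for the Reynolds-number
        estimate.
    """

    viscosity: float = 1.0e-3
    temperature: float = ROOM_TEMPERATURE
    density: float = 1.0e3

    def __post_init__(self) -> None:
        _require_positive(
            viscosity=self.viscosity,
            temperature=self.temperature,
            density=self.density,
        )


@dataclass(frozen=True)
class DriveField:
    """Sinusoidal drive field B(t) = B0 cos(2 pi f t) along +z.

    ``amplitude`` is the flux-density amplitude B0 in tesla (i.e. mu_0 H0);
    ``frequency`` is f in Hz.
    """

    amplitude: float
    frequency: float

    def __post_init__(self) -> None:
        _require_nonnegative(amplitude=self.amplitude)
        _require_positive(frequency=self.frequency)


@dataclass(frozen=True)
class ParticleSpec:
    """Lognormal size specification of a nanoparticle population.

    Radii are stored (not diameters); hydrodynamic volume uses d = 2r in
    V = pi d^3 / 6.  Defaults describe the typical MSB tracer: 20 nm core
    radius, 50 nm hydrodynamic radius, size sd 10% of the mean, saturation
    magnetization 250 kA/m.
    """

    mean_core_radius: float = 20e-9
    mean_hydro_radius: float = 50e-9
    std_core_radius: float | None = None
    std_hydro_radius: float | None = None
    saturation_magnetization: float = 250e3

    #: default coefficient of variation s_r / m_r when stds are not given
    DEFAULT_CV = 0.10

    def __post_init__(self) -> None:
        _require_positive(
            mean_core_radius=self.mean_core_radius,
            mean_hydro_radius=self.mean_hydro_radius,
            saturation_magnetization=self.saturation_magnetization,
        )
        if self.std_core_radius is None:
            object.__setattr__(
                self, "std_core_radius", self.DEFAULT_CV * self.mean_core_radius
            )
        if self.std_hydro_radius is None:
            object.__setattr__(
                self, "std_hydro_radius", self.DEFAULT_CV * self.mean_hydro_radius
            )
        _require_nonnegative(
            std_core_radius=self.std_core_radius,
            std_hydro_radius=self.std_hydro_radius,
        )


def brownian_relaxation_time(
    viscosity: float, hydro_diameter, temperature: float
):
    """Zero-field Brownian rotational relaxation time tau_B = 3 eta V / (k_B T).

    ``hydro_diameter`` is the hydrodynamic diameter d (m); V = pi d^3 / 6.
    Accepts arrays of diameters.
    """
    if viscosity <= 0 or temperature <= 0:
        raise ValueError("viscosity and temperature must be positive")
    d = np.asarray(hydro_diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("hydro_diameter must be non-negative")
    volume = np.pi * d**3 / 6.0
    tau = 3.0 * viscosity * volume / (K_B * temperature)
    return float(tau) if np.ndim(hydro_diameter) == 0 else tau


def unitless_field(moment, b0: float, temperature: float):
    """Unitless field amplitude xi0 = mu B0 / (k_B T).

    Ratio of peak Zeeman energy to thermal energy; ``b0`` is the flux-density
    amplitude mu_0 H0 in tesla.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    mu = np.asarray(moment, dtype=float)
    if np.any(mu < 0) or b0 < 0:
        raise ValueError("moment and b0 must be non-negative")
    xi0 = mu * b0 / (K_B * temperature)
    return float(xi0) if np.ndim(moment) == 0 else xi0


def unitless_frequency(frequency: float, tau_b):
    """Unitless frequency Omega = f * tau_B (drive periods per relaxation)."""
    tau = np.asarray(tau_b, dtype=float)
    if frequency <= 0 or np.any(tau <= 0):
        raise ValueError("frequency and tau_b must be positive")
    omega = frequency * tau
    return float(omega) if np.ndim(tau_b) == 0 else omega


def master_variable(xi0, omega):
    """Master variable A = xi0 / Omega.

    Invariant under joint rescaling (xi0, Omega) -> (c xi0, c Omega): doubling
    the drive amplitude is equivalent to halving frequency (or relaxation
    time).  A alone parameterizes the noise-free dynamics.
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om <= 0):
        raise ValueError("omega must be positive")
    a = np.asarray(xi0, dtype=float) / om
    return float(a) if np.ndim(xi0) == 0 and np.ndim(omega) == 0 else a


def reynolds_number(density: float, frequency: float, diameter: float, viscosity: float) -> float:
    """Rotational Reynolds number Re = rho f d^2 / eta.

    For typical MSB conditions (rho ~ 1e3 kg/m^3, f ~ 1 kHz, d ~ 100 nm,
    eta ~ 1 mPa*s) Re ~ 1e-5, so angular accelerations are negligible and the
    rotational Langevin equation is first order in time.
    """
    if viscosity <= 0 or density <= 0 or diameter <= 0:
        raise ValueError("density, diameter and viscosity must be positive")
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    return density * frequency * diameter**2 / viscosity


def lognormal_sigma(mean: float, std: float) -> float:
    """Lognormal shape parameter sigma_r = sqrt(ln(1 + s^2/m^2))."""
    return float(np.sqrt(np.log1p((std / mean) ** 2)))


def sample_lognormal_radii(
    mean: float, std: float, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Sample ``n`` radii from a lognormal with given arithmetic mean and sd.

    The distribution is moment-matched: scale = mean / sqrt(1 + cv^2),
    shape sigma_r = sqrt(ln(1 + cv^2)), so the sample mean -> ``mean`` and
    sample sd -> ``std`` as n grows.  ``std = 0`` degenerates to a point mass.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if std < 0:
        raise ValueError("std must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if std == 0:
        return np.full(n, float(mean))
    rng = np.random.default_rng(rng)
    sigma = lognormal_sigma(mean, std)
    mu_log = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mean=mu_log, sigma=sigma, size=n)


def moment_from_core(core_radius, saturation_magnetization: float):
    """Magnetic moment magnitude mu = M_s * (4/3) pi r_core^3 (A*m^2)."""
    if saturation_magnetization <= 0:
        raise ValueError("saturation_magnetization must be positive")
    r = np.asarray(core_radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("core_radius must be non-negative")
    mu = saturation_magnetization * (4.0 / 3.0) * np.pi * r**3
    return float(mu) if np.ndim(core_radius) == 0 else mu


@dataclass
class ParticleEnsemble:
    """A sampled polydisperse particle population.

    Per-particle arrays of core volume, hydrodynamic volume (both m^3),
    magnetic moment magnitude (A*m^2) and Brownian relaxation time (s).
    Core and hydrodynamic radii are drawn independently, each lognormal.
    """

    core_volume: np.ndarray
    hydro_volume: np.ndarray
    moment: np.ndarray
    tau_b: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.core_volume)
        for name in ("core_volume", "hydro_volume", "moment", "tau_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError("ensemble arrays must share one length")
            if n == 0:
                raise ValueError("ensemble must be non-empty")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be strictly positive")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.core_volume)

    @classmethod
    def from_spec(
        cls,
        spec: ParticleSpec,
        env: Environment,
        n: int,
        rng: np.random.Generator | int | None = None,
    ) -> "ParticleEnsemble":
        """Sample an ensemble of ``n`` particles.

        Draw order is fixed: core radii first, hydrodynamic radii second,
        so a seeded generator reproduces the population exactly.
        """
        rng = np.random.default_rng(rng)
        r_core = sample_lognormal_radii(
            spec.mean_core_radius, spec.std_core_radius, n, rng
        )
        r_hyd = sample_lognormal_radii(
            spec.mean_hydro_radius, spec.std_hydro_radius, n, rng
        )
        v_core = (4.0 / 3.0) * np.pi * r_core**3
        v_hyd = np.pi * (2.0 * r_hyd) ** 3 / 6.0
        mu = moment_from_core(r_core, spec.saturation_magnetization)
        tau = brownian_relaxation_time(env.viscosity, 2.0 * r_hyd, env.temperature)
        return cls(core_volume=v_core, hydro_volume=v_hyd, moment=mu, tau_b=tau)

    def unitless_fields(self, field: DriveField, env: Environment) -> np.ndarray:
        """Per-particle xi0 array."""
        return unitless_field(self.moment, field.amplitude, env.temperature)

    def unitless_frequencies(self, field: DriveField) -> np.ndarray:
        """Per-particle Omega array."""
        return unitless_frequency(field.frequency, self.tau_b)


@dataclass(frozen=True)
class DimensionlessParams:
    """The (xi0, Omega, A) triple for a particle or an ensemble mean."""

    xi0: float
    omega: float
    a: float = field(init=False)

    def __post_init__(self) -> None:
        if self.xi0 < 0:
            raise ValueError("xi0 must be non-negative")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        object.__setattr__(self, "a", self.xi0 / self.omega)

    @classmethod
    def from_physical(
        cls,
        moment: float,
        tau_b: float,
        field_: DriveField,
        env: Environment,
    ) -> "DimensionlessParams":
        return cls(
            xi0=unitless_field(moment, field_.amplitude, env.temperature),
            omega=unitless_frequency(field_.frequency, tau_b),
        )


def ensemble_master_variable(
    ensemble: ParticleEnsemble, field_: DriveField, env: Environment
) -> float:
    """Master variable of the mean parameters, A = <xi0> / <Omega>.

    For a polydisperse population the single-particle A is replaced by the
    ratio of the ensemble-mean unitless field (moment averaged over the core
    size distribution) to the ensemble-mean unitless frequency (relaxation
    time averaged over the hydrodynamic size distribution).
    """
    xi0 = ensemble.unitless_fields(field_, env)
    omega = ensemble.unitless_frequencies(field_)
    return float(np.mean(xi0) / np.mean(omega))
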