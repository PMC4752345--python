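"""Physical parameters and nondimensionalization for the NICD sensing model.

The model describes a neural progenitor cell (NPC) of the pseudostratified
neuroepithelium as a thin elongated cell of length ``L`` with its apical
surface at ``z = 0`` and basal surface at ``z = L``.  The Notch intracellular
domain (NICD) is produced at the apical surface at a constant areal rate
``R``, diffuses through the cytoplasm with diffusivity ``D``, is degraded at
first-order rate ``k`` and exchanges with the (moving) nucleus through
import/export mass-transfer coefficients ``K_i`` and ``K_e``.

All quantities are nondimensionalized with the cell length ``L`` as length
scale, ``t_d = L^2/D`` as time scale and ``C_0 = R/(k L)`` as concentration
scale.  The resulting dimensionless groups are

* the Thiele modulus squared ``phi^2 = k L^2 / D`` (reaction vs diffusion;
  large ``phi`` means a steep apico-basal gradient),
* import/export numbers ``alpha_i = K_i L / D`` and ``alpha_e = K_e L / D``,
* the Peclet number ``Pe = v L / D`` per migration phase (convective vs
  diffusive transport; small here, which justifies dropping convection), and
* the dimensionless nuclear drift speeds and positional diffusivity used by
  the trajectory simulator.

Units: inputs are accepted in the mixed units in which they are commonly
reported (speeds and mass-transfer coefficients in μm/h, molecular
diffusivity in μm²/s, nuclear positional diffusivity in μm²/h) and converted
to a single (μm, s) system at this boundary, once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "H_TO_S",
    "CellGeometry",
    "TransportParameters",
    "MotionParameters",
    "DimensionlessGroups",
    "derive_dimensionless",
    "phi_from_k",
    "k_from_phi",
    "ellipsoid_surface_area",
]

H_TO_S = 3600.0  # seconds per hour


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0.0) or not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")


def _require_nonnegative(**fields: float) -> None:
    for name, value in fields.items():
        if value < 0.0 or not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be non-negative, got {value!r}")


def ellipsoid_surface_area(a: float, b: float) -> float:
    """Surface area of a prolate spheroid with polar semi-axis ``a`` and
    equatorial semi-axes ``b`` (μm², for ``a >= b``); exact for the sphere."""
    _require_positive(a=a, b=b)
    if a < b:
        raise ValueError("expected a prolate spheroid with a >= b")
    if math.isclose(a, b, rel_tol=1e-12):
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - (b * b) / (a * a))
    return 2.0 * math.pi * b * b * (1.0 + (a / (b * e)) * math.asin(e))


@dataclass(frozen=True)
class CellGeometry:
    """Geometry of the progenitor cell and its nucleus (all lengths in μm).

    ``length`` is the apico-basal cell length L; ``width`` the diameter of the
    thin cytoplasmic process; the nucleus is an ellipsoid with semi-axis
    ``nuclear_semi_major`` (a, along the cell axis) and ``nuclear_semi_minor``
    (b, the two transverse semi-axes); ``apical_gap`` is the distance between
    the apical nuclear membrane and the apical cell membrane at the start of a
    trajectory.  The nucleus may be wider than the process (it sits in the
    dilated cell body), so ``2 b <= width`` is deliberately not required.
    """

    length: float
    width: float
    nuclear_semi_major: float
    nuclear_semi_minor: float
    apical_gap: float

    def __post_init__(self) -> None:
        _require_positive(
            length=self.length,
            width=self.width,
            nuclear_semi_major=self.nuclear_semi_major,
            nuclear_semi_minor=self.nuclear_semi_minor,
        )
        _require_nonnegative(apical_gap=self.apical_gap)
        if not 2.0 * self.nuclear_semi_major < self.length:
            raise ValueError("nucleus (2a) must fit inside the cell length")
        if not 2.0 * self.nuclear_semi_major + self.apical_gap < self.length:
            raise ValueError("nucleus plus apical gap must fit inside the cell length")

    @property
    def nuclear_extent(self) -> float:
        """Dimensionless axial half-length of the nucleus, a/L."""
        return self.nuclear_semi_major / self.length

    @property
    def xi_min(self) -> float:
        """Apical-most admissible centroid position (nucleus fully inside)."""
        return (self.apical_gap + self.nuclear_semi_major) / self.length

    @property
    def xi_max(self) -> float:
        """Basal-most admissible centroid position."""
        return 1.0 - self.nuclear_semi_major / self.length

    @property
    def nuclear_volume(self) -> float:
        """Ellipsoid volume, μm³."""
        return (4.0 / 3.0) * math.pi * self.nuclear_semi_major * self.nuclear_semi_minor**2

    @property
    def nuclear_surface_area(self) -> float:
        """Ellipsoid surface area, μm²."""
        return ellipsoid_surface_area(self.nuclear_semi_major, self.nuclear_semi_minor)

    @property
    def sv_ratio(self) -> float:
        """Nuclear surface-to-volume ratio, 1/μm; sets the import/export
        equilibration time V_n/(A_n K_e)."""
        return self.nuclear_surface_area / self.nuclear_volume

    @property
    def cyto_cross_section(self) -> float:
        """Cross-sectional area of the cytoplasmic process (circular), μm²."""
        return math.pi * (self.width / 2.0) ** 2


@dataclass(frozen=True)
class TransportParameters:
    """Cytoplasmic transport and nuclear exchange parameters.

    ``diffusivity`` D in μm²/s, ``degradation`` k in 1/s, apical production
    rate ``production`` R in concentration·μm/s (defaults to 1 in arbitrary
    units — every reported quantity is a dimensionless θ = C/C0 in which R
    cancels), import/export mass-transfer coefficients ``import_rate`` K_i and
    ``export_rate`` K_e in μm/h.
    """

    diffusivity: float
    degradation: float
    import_rate: float
    export_rate: float
    production: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            diffusivity=self.diffusivity,
            degradation=self.degradation,
            import_rate=self.import_rate,
            export_rate=self.export_rate,
            production=self.production,
        )

    def with_phi(self, phi: float, length: float) -> "TransportParameters":
        """Return a copy with the degradation constant set so the Thiele
        modulus equals ``phi`` for a cell of the given length."""
        return TransportParameters(
            diffusivity=self.diffusivity,
            degradation=k_from_phi(phi, length, self.diffusivity),
            import_rate=self.import_rate,
            export_rate=self.export_rate,
            production=self.production,
        )


@dataclass(frozen=True)
class MotionParameters:
    """Nuclear drift speeds (magnitudes, μm/h) and positional diffusivity of
    the Wiener process (μm²/h).  The sign convention (basalward positive,
    apicalward negative) is applied by the trajectory simulator."""

    v_basal: float
    v_apical: float
    d_n: float

    def __post_init__(self) -> None:
        _require_positive(v_basal=self.v_basal, v_apical=self.v_apical)
        _require_nonnegative(d_n=self.d_n)


@dataclass(frozen=True)
class DimensionlessGroups:
    """Derived dimensionless groups and characteristic scales.

    ``pe_basal``/``pe_apical`` are the Peclet numbers of the two drift phases;
    they coincide with the dimensionless drift speeds ``v_basal_nd`` /
    ``v_apical_nd`` (both are v·L/D) but are carried separately because they
    play different roles: the Peclet numbers justify dropping convection from
    the concentration equation, the nondimensional speeds drive the nuclear
    trajectory.  ``c0`` is the concentration scale R/(kL) and ``t_d`` the
    diffusion time L²/D in seconds.
    """

    phi_sq: float
    alpha_i: float
    alpha_e: float
    pe_basal: float
    pe_apical: float
    c0: float
    t_d: float
    v_basal_nd: float
    v_apical_nd: float
    dn_nd: float

    @property
    def phi(self) -> float:
        return math.sqrt(self.phi_sq)


def phi_from_k(k: float, length: float, diffusivity: float) -> float:
    """Thiele modulus φ = sqrt(k L² / D)."""
    _require_positive(k=k, length=length, diffusivity=diffusivity)
    return math.sqrt(k * length * length / diffusivity)


def k_from_phi(phi: float, length: float, diffusivity: float) -> float:
    """Degradation constant k = φ² D / L² (inverse of :func:`phi_from_k`)."""
    _require_positive(phi=phi, length=length, diffusivity=diffusivity)
    return phi * phi * diffusivity / (length * length)


def derive_dimensionless(
    geometry: CellGeometry,
    transport: TransportParameters,
    motion: MotionParameters,
) -> DimensionlessGroups:
    """Compute all dimensionless groups from the dimensional parameter sets.

    Pure arithmetic; μm/h and μm²/h inputs are converted to seconds here.
    """
    L = geometry.length
    D = transport.diffusivity
    k = transport.degradation
    ki = transport.import_rate / H_TO_S  # μm/s
    ke = transport.export_rate / H_TO_S
    vb = motion.v_basal / H_TO_S
    va = motion.v_apical / H_TO_S
    dn = motion.d_n / H_TO_S  # μm²/s

    return DimensionlessGroups(
        phi_sq=k * L * L / D,
        alpha_i=ki * L / D,
        alpha_e=ke * L / D,
        pe_basal=vb * L / D,
        pe_apical=va * L / D,
        c0=transport.production / (k * L),
        t_d=L * L / D,
        v_basal_nd=vb * L / D,
        v_apical_nd=va * L / D,
        dn_nd=dn / D,
    )
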