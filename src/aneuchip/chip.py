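"""Microfluidic-chip translation of wall shear stress.

A wide, shallow rectangular channel (height h much smaller than width w)
behaves like a parallel-plate flow chamber: the wall shear rate at the
channel floor is

    gamma = 6 Q / (h^2 w)           [1/s]
    tau   = gamma * mu              [Pa]

with Q the volumetric flow rate and mu the dynamic viscosity of the
perfusate (water at 37 C, ~7e-4 Pa s, as a culture-medium surrogate —
deliberately different from the blood viscosity used in the CFD stage).
These printed formulas are implemented verbatim as the primary mapping;
an optional rectangular-duct series correction (exact for laminar duct
flow) is available behind a flag but OFF by default so outputs match the
parallel-plate design convention.

Default channel: 56 x 1.2 x 0.1 mm (length x width x height), for which
the approximation error of the parallel-plate formula at h/w = 1/12 is
below ~10%.

Note: the published operating pair (0.03 Pa, 8.67e-10 m^3/s) for the
default chip is internally inconsistent by exactly 10x — the formula
gives 0.30 Pa for that flow rate, while (1.5 Pa, 4.33e-9 m^3/s) is
self-consistent to ~1%.  This module never silently "fixes" supplied
numbers; :func:`validate_operating_pair` surfaces the disagreement as a
warning whenever both tau and Q are given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError

__all__ = [
    "ChipSpec",
    "OperatingPoint",
    "shear_rate_from_flow",
    "shear_stress_from_flow",
    "flow_for_target_shear",
    "map_sites",
    "operating_point",
    "validate_operating_pair",
    "M3S_TO_UL_MIN",
]

#: exact conversion 1 m^3/s = 6e10 uL/min
M3S_TO_UL_MIN = 6.0e10

#: laminar-turbulent transition bound for the channel Reynolds number
RE_LAMINAR_LIMIT = 2000.0

#: aspect ratio above which the parallel-plate formula degrades badly
ASPECT_RATIO_LIMIT = 0.25


@dataclass(frozen=True)
class ChipSpec:
    """Microfluidic channel geometry and perfusate properties.

    ``density`` (water at 37 C) enters only the laminarity check, never
    the shear formulas.
    """

    length: float = 56.0e-3
    width: float = 1.2e-3
    height: float = 0.1e-3
    viscosity: float = 7.0e-4
    density: float = 993.0

    def __post_init__(self) -> None:
        for name in ("length", "width", "height", "viscosity", "density"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")
        if self.height > self.width:
            raise UsageError(
                "the parallel-plate formula assumes a wide shallow channel: "
                f"height ({self.height}) must not exceed width ({self.width})"
            )

    @property
    def aspect_ratio(self) -> float:
        return self.height / self.width

    @property
    def hydraulic_diameter(self) -> float:
        return 2.0 * self.height * self.width / (self.height + self.width)


@dataclass
class OperatingPoint:
    """One culture condition: the (tau, gamma, Q) triple for a chip.

    The algebraic identities tau = gamma * mu and gamma = 6 Q / (h^2 w)
    hold exactly by construction.
    """

    tau: float                 # Pa
    gamma: float               # 1/s
    flow_rate: float           # m^3/s
    chip: ChipSpec
    reynolds_chip: float
    site_label: str | None = None
    warnings: list = field(default_factory=list)

    @property
    def flow_rate_ul_min(self) -> float:
        return self.flow_rate * M3S_TO_UL_MIN

    def to_dict(self) -> dict:
        return {
            "site": self.site_label,
            "tau_Pa": self.tau,
            "gamma_per_s": self.gamma,
            "Q_m3_per_s": self.flow_rate,
            "Q_uL_per_min": self.flow_rate_ul_min,
            "Re_chip": self.reynolds_chip,
            "warnings": list(self.warnings),
        }


def _duct_correction_factor(aspect: float, n_terms: int = 50) -> float:
    """Ratio Q_true/Q_parallel_plate for a rectangular duct at equal
    pressure gradient (classical odd-n tanh series)."""
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    s = np.sum(np.tanh(n * np.pi / (2.0 * aspect)) / n**5)
    return 1.0 - (192.0 * aspect / np.pi**5) * s


def shear_rate_from_flow(Q: float, chip: ChipSpec, *, rectangular_correction: bool = False) -> float:
    """Wall shear rate gamma = 6 Q / (h^2 w) for a flow rate Q >= 0.

    With ``rectangular_correction`` the finite-width duct solution is
    used instead of the parallel-plate approximation (shear at the
    center of the wide wall)."""
    if Q < 0:
        raise UsageError("flow rate must be non-negative")
    gamma = 6.0 * Q / (chip.height**2 * chip.width)
    if rectangular_correction:
        gamma /= _duct_correction_factor(chip.aspect_ratio)
    return gamma


def shear_stress_from_flow(Q: float, chip: ChipSpec, *, rectangular_correction: bool = False) -> float:
    """Wall shear stress tau = mu * gamma for a flow rate Q >= 0."""
    return chip.viscosity * shear_rate_from_flow(
        Q, chip, rectangular_correction=rectangular_correction
    )


def flow_for_target_shear(tau: float, chip: ChipSpec, *, rectangular_correction: bool = False) -> float:
    """Flow rate producing a target wall shear stress: Q = tau h^2 w / (6 mu).

    Exact algebraic inverse of :func:`shear_stress_from_flow` (round
    trips to machine precision)."""
    if tau < 0:
        raise UsageError("target shear stress must be non-negative")
    Q = tau * chip.height**2 * chip.width / (6.0 * chip.viscosity)
    if rectangular_correction:
        Q *= _duct_correction_factor(chip.aspect_ratio)
    return Q


def operating_point(
    tau: float, chip: ChipSpec, *, site_label: str | None = None,
    rectangular_correction: bool = False,
) -> OperatingPoint:
    """Build the full (tau, gamma, Q) triple for a target stress, with
    laminarity and aspect-ratio warnings."""
    Q = flow_for_target_shear(tau, chip, rectangular_correction=rectangular_correction)
    gamma = tau / chip.viscosity
    mean_speed = Q / (chip.height * chip.width)
    re_chip = chip.density * mean_speed * chip.hydraulic_diameter / chip.viscosity
    warnings = []
    if re_chip >= RE_LAMINAR_LIMIT:
        warnings.append(
            f"channel Reynolds number {re_chip:.0f} >= {RE_LAMINAR_LIMIT:.0f}: "
            "flow may not be laminar"
        )
    if chip.aspect_ratio > ASPECT_RATIO_LIMIT:
        warnings.append(
            f"aspect ratio h/w = {chip.aspect_ratio:.2f} > {ASPECT_RATIO_LIMIT}: "
            "parallel-plate approximation is inaccurate"
        )
    return OperatingPoint(tau, gamma, Q, chip, re_chip, site_label, warnings)


def map_sites(sites, chip: ChipSpec) -> list[tuple[object, OperatingPoint]]:
    """One operating point per shear site, using the site's
    representative (median) stress in Pa.

    Sites must carry dimensional values — produce the WSS field with a
    :class:`~aneuchip.wss.DimensionalScaling`."""
    pairs = []
    for site in list(sites.low_sites) + list(sites.high_sites):
        if site.tau_median_pa is None:
            raise UsageError(
                "site carries no dimensional stress; supply a "
                "DimensionalScaling to compute_wss so tau is available in Pa"
            )
        pairs.append(
            (site, operating_point(site.tau_median_pa, chip, site_label=site.label))
        )
    return pairs


def validate_operating_pair(tau: float, Q: float, chip: ChipSpec, rel_tol: float = 0.05) -> list[str]:
    """Check a user-supplied (tau, Q) pair against the chip formula;
    returns a list of warning strings (empty when consistent within
    ``rel_tol``).  Published pairs are reported, never corrected."""
    if tau < 0 or Q < 0:
        raise UsageError("tau and Q must be non-negative")
    tau_formula = shear_stress_from_flow(Q, chip)
    if tau == 0 and tau_formula == 0:
        return []
    ref = max(abs(tau), abs(tau_formula))
    rel = abs(tau - tau_formula) / ref
    if rel > rel_tol:
        return [
            f"supplied tau = {tau:g} Pa disagrees with the value "
            f"{tau_formula:.3g} Pa implied by Q = {Q:g} m^3/s "
            f"({100 * rel:.0f}% relative); check for a transcription error"
        ]
    return []
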