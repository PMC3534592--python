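"""Synthetic conductivity phantoms on the unit disk."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "make_chest_phantom",
    "make_rotating_target",
    "make_smooth_phantom",
]


@dataclass
class Inclusion:
    """One elliptical or circular inclusion.

    ``semi_axes`` is ``(a, b)`` for ellipses and ``(radius, radius)`` for
    circles; ``angle`` is the CCW rotation of the major axis (radians);
    ``sigma`` the conductivity inside (mS/m).
    """

    shape: str  # "ellipse" | "circle"
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    sigma: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "circle"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if self.sigma <= 0:
            raise ValueError("inclusion conductivity must be positive")
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("inclusion semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d = pts - np.asarray(self.center)
        c, s = np.cos(-self.angle), np.sin(-self.angle)
        x = c * d[:, 0] - s * d[:, 1]
        y = s * d[:, 0] + c * d[:, 1]
        a, b = self.semi_axes
        return (x / a) ** 2 + (y / b) ** 2 <= 1.0

    def max_extent(self) -> float:
        """Largest distance from the origin to any point of the inclusion."""
        return float(np.hypot(*self.center) + max(self.semi_axes))


@dataclass
class PhantomSpec:
    """Piecewise-constant conductivity: a background plus inclusions.

    An optional ``smooth`` callable (vectorized ``(n,2) -> (n,)`` conductivity
    in mS/m) overrides the piecewise description; it is used by the
    convergence studies that need infinitely differentiable targets.
    """

    background_sigma: float
    inclusions: list[Inclusion] = field(default_factory=list)
    domain_radius: float = 1.0
    smooth: object | None = None

    def __post_init__(self) -> None:
        if self.background_sigma <= 0:
            raise ValueError("background conductivity must be positive")
        for inc in self.inclusions:
            if inc.max_extent() >= self.domain_radius:
                raise ValueError(
                    f"inclusion at {inc.center} is not strictly inside the disk"
                )

    def sigma_at(self, points: np.ndarray) -> np.ndarray:
        """Conductivity sampled at the given (n, 2) points (mS/m)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.smooth is not None:
            return np.asarray(self.smooth(pts), dtype=float)
        sig = np.full(pts.shape[0], float(self.background_sigma))
        for inc in self.inclusions:
            sig[inc.contains(pts)] = inc.sigma
        return sig

    def scaled_to(self, radius: float) -> "PhantomSpec":
        """Same phantom on a disk of a different radius."""
        f = radius / self.domain_radius
        incs = [
            Inclusion(
                shape=i.shape,
                center=(i.center[0] * f, i.center[1] * f),
                semi_axes=(i.semi_axes[0] * f, i.semi_axes[1] * f),
                sigma=i.sigma,
                angle=i.angle,
            )
            for i in self.inclusions
        ]
        return PhantomSpec(
            background_sigma=self.background_sigma,
            inclusions=incs,
            domain_radius=radius,
            smooth=None if self.smooth is None else (lambda p: self.smooth(p / f)),
        )


#: conductivities (mS/m): background, heart, lungs
CHEST_CONDUCTIVITIES = {
    "simulated": (1000.0, 1500.0, 500.0),
    "experimental": (424.0, 750.0, 240.0),
}


def make_chest_phantom(variant: str = "simulated") -> PhantomSpec:
    """Two elliptical lungs and one circular heart on the unit disk.

    The conductivities are fixed per variant; the geometry (not standardized
    anywhere) is chosen to resemble a thoracic cross-section and
    can be overridden through configuration.
    """
    if variant not in CHEST_CONDUCTIVITIES:
        raise ValueError(f"variant must be 'simulated' or 'experimental', got {variant!r}")
    bg, heart, lung = CHEST_CONDUCTIVITIES[variant]
    inclusions = [
        Inclusion("circle", (0.1, 0.45), (0.2, 0.2), heart),
        Inclusion("ellipse", (-0.48, -0.1), (0.35, 0.22), lung, angle=np.deg2rad(75)),
        Inclusion("ellipse", (0.48, -0.1), (0.35, 0.22), lung, angle=np.deg2rad(105)),
    ]
    return PhantomSpec(background_sigma=bg, inclusions=inclusions)


def make_rotating_target(
    position_index: int,
    domain_radius: float = 1.0,
    background_sigma: float = 1000.0,
    diameter_ratio: float = 0.05,
    contrast: float = 2.0,
    n_positions: int = 9,
) -> PhantomSpec:
    """Small circular target at one of nine radial displacements.

    The target has diameter ``diameter_ratio`` times the tank diameter and
    conductivity ``contrast`` times the background.  Position 0 is the medium
    center; the outermost position keeps a boundary clearance of one target
    radius.  The displacement ray is theta = 0.
    """
    if not 0 <= position_index < n_positions:
        raise ValueError(
            f"position_index must be in 0..{n_positions - 1}, got {position_index}"
        )
    rho = diameter_ratio * domain_radius  # radius = ratio * diameter / 2
    r_max = domain_radius - 2.0 * rho
    d = r_max * position_index / (n_positions - 1)
    target = Inclusion("circle", (d, 0.0), (rho, rho), contrast * background_sigma)
    return PhantomSpec(
        background_sigma=background_sigma,
        inclusions=[target],
        domain_radius=domain_radius,
    )


def make_smooth_phantom(
    background_sigma: float = 1000.0,
    amplitude: float = 300.0,
    center: tuple[float, float] = (0.3, 0.1),
    width: float = 0.35,
) -> PhantomSpec:
    """Infinitely smooth Gaussian bump phantom for convergence studies."""

    cx, cy = center

    def smooth(pts: np.ndarray) -> np.ndarray:
        r2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        return background_sigma + amplitude * np.exp(-r2 / (2.0 * width**2))

    return PhantomSpec(background_sigma=background_sigma, smooth=smooth)
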