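"""Quantitative evaluation of reconstructions.

Implements the GREIT-style figures of merit (amplitude response, position
error, ringing, resolution, shape deformation) on difference images, plus
sup-norm convergence tables, degree of truth and relative extremum errors.

All measures operate on 2D images sampled on a Cartesian grid over the unit
disk with NaN outside; radii are normalized to the medium radius 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dbareit.sinc_dbar import ConductivityImage

__all__ = [
    "QuarterAmplitudeSet",
    "TargetTruth",
    "MetricsReport",
    "difference_image",
    "quarter_amplitude",
    "amplitude_response",
    "position_error",
    "ringing",
    "resolution",
    "shape_deformation",
    "convergence_table",
    "degree_of_truth",
    "rel_extremum_errors",
    "evaluate_target_image",
]


@dataclass
class QuarterAmplitudeSet:
    """Pixels at or above one fourth of the image maximum."""

    mask: np.ndarray          # boolean image
    cog: complex              # amplitude-weighted centroid (image coords)
    r_q: float                # |cog|, radius-normalized
    A_q: int                  # pixel count

    def __post_init__(self) -> None:
        if self.A_q <= 0:
            raise ValueError("quarter-amplitude set is empty")


@dataclass
class TargetTruth:
    """The simulated circular target and its background."""

    center: complex
    radius: float
    sigma_t: float
    sigma_r: float

    def __post_init__(self) -> None:
        if self.sigma_t <= 0 or self.sigma_r <= 0:
            raise ValueError("conductivities must be positive")

    @property
    def r_t(self) -> float:
        return abs(self.center)

    def pixel_area(self, points: np.ndarray) -> float:
        """Target area in pixel units of the given image grid."""
        px = _pixel_size(points)
        return np.pi * self.radius**2 / px**2


def _pixel_size(points: np.ndarray) -> float:
    return float(np.abs(points[1, 0] - points[0, 0]))


def difference_image(img: ConductivityImage, background: float | None = None) -> np.ndarray:
    """Reconstruction minus its homogeneous background (gamma_best)."""
    bg = img.meta.get("gamma_best", 0.0) if background is None else background
    return img.gamma - bg


def quarter_amplitude(
    img: np.ndarray, points: np.ndarray | None = None
) -> QuarterAmplitudeSet:
    """Binary set of pixels >= max/4 with its amplitude-weighted centroid."""
    vals = np.asarray(img, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any() or np.nanmax(vals) <= 0:
        raise ValueError("image has no positive values; quarter set undefined")
    peak = np.nanmax(vals)
    mask = finite & (vals >= peak / 4.0)
    if points is None:
        n = vals.shape[0]
        ax = np.linspace(-1, 1, n)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        points = X + 1j * Y
    w = vals[mask]
    cog = complex(np.sum(w * points[mask]) / np.sum(w))
    return QuarterAmplitudeSet(
        mask=mask, cog=cog, r_q=abs(cog), A_q=int(mask.sum())
    )


def amplitude_response(
    img: np.ndarray, truth: TargetTruth, points: np.ndarray, norm_const: float = 1.0
) -> float:
    """Ratio of summed image amplitude to the ideal target amplitude.

    ``AR = sum_k [gamma]_k / (A_t (sigma_t - sigma_r) / sigma_r)`` divided by
    ``norm_const``; calibrate ``norm_const`` once per pipeline configuration
    so that the centered contrast-2 target gives AR = 1.
    """
    if truth.sigma_t == truth.sigma_r:
        raise ValueError("undefined contrast: sigma_t == sigma_r")
    if norm_const == 0:
        raise ValueError("norm_const must be nonzero")
    total = float(np.nansum(img))
    ideal = truth.pixel_area(points) * (truth.sigma_t - truth.sigma_r) / truth.sigma_r
    return total / ideal / norm_const


def position_error(qset: QuarterAmplitudeSet, truth: TargetTruth) -> float:
    """Signed ``r_t - r_q`` in units of the medium radius."""
    return truth.r_t - qset.r_q


def _equal_area_circle(qset: QuarterAmplitudeSet, points: np.ndarray) -> np.ndarray:
    """Pixels inside the circle centered at the COG with area A_q."""
    px = _pixel_size(points)
    radius = np.sqrt(qset.A_q * px**2 / np.pi)
    return np.abs(points - qset.cog) <= radius


def ringing(
    img: np.ndarray, qset: QuarterAmplitudeSet, points: np.ndarray
) -> float:
    """Opposite-sign amplitude outside the main lobe over in-lobe amplitude.

    The main lobe is the equal-area circle C at the quarter-set COG;
    ``A_out`` sums |amplitude| of opposite-sign pixels outside C, ``A_in``
    sums same-sign amplitude inside C.
    """
    vals = np.asarray(img, dtype=float)
    finite = np.isfinite(vals)
    C = _equal_area_circle(qset, points)
    main_sign = 1.0 if np.nanmax(vals) >= 0 else -1.0
    inside = finite & C
    a_in = float(np.sum(np.clip(main_sign * vals[inside], 0.0, None)))
    if a_in == 0:
        raise ValueError("degenerate main lobe: no in-lobe amplitude")
    outside = finite & ~C
    opp = np.clip(-main_sign * vals[outside], 0.0, None)
    return float(np.sum(opp)) / a_in


def resolution(qset: QuarterAmplitudeSet, domain_mask: np.ndarray) -> float:
    """Pixel-count ratio ``A_q / A_0`` (no square root)."""
    a0 = int(np.asarray(domain_mask, dtype=bool).sum())
    if a0 == 0:
        raise ValueError("empty image domain")
    return qset.A_q / a0


def shape_deformation(qset: QuarterAmplitudeSet, points: np.ndarray) -> float:
    """Fraction of the quarter set outside its own equal-area circle."""
    C = _equal_area_circle(qset, points)
    outside = qset.mask & ~C
    return int(outside.sum()) / qset.A_q


def convergence_table(
    images: list[np.ndarray],
    truth_img: np.ndarray,
    domain_mask: np.ndarray | None = None,
    rim_exclude: int = 2,
) -> tuple[list[float], list[float]]:
    """Sup-norm errors E_i against the truth image and ratios CR_i = E_i/E_{i+1}.

    The supremum runs over disk pixels, excluding a ``rim_exclude``-pixel
    band at the boundary where the constant-near-boundary normalization makes
    the error uninformative.
    """
    if len(images) < 2:
        raise ValueError("need at least two images for a convergence table")
    truth = np.asarray(truth_img, dtype=float)
    n = truth.shape[0]
    ax = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    px = ax[1] - ax[0]
    rad = np.hypot(X, Y)
    mask = rad <= 1.0 - rim_exclude * px
    if domain_mask is not None:
        mask &= np.asarray(domain_mask, dtype=bool)
    E = []
    for img in images:
        if img.shape != truth.shape:
            raise ValueError("image/truth grid mismatch")
        E.append(float(np.nanmax(np.abs(truth - img)[mask])))
    CR = [
        (E[i] / E[i + 1]) if E[i + 1] != 0 else np.inf
        for i in range(len(E) - 1)
    ]
    return E, CR


def degree_of_truth(img: np.ndarray, truth_img: np.ndarray) -> float:
    """Range of the reconstruction over the range of the truth."""
    tmax, tmin = np.nanmax(truth_img), np.nanmin(truth_img)
    if tmax == tmin:
        raise ValueError("constant truth image: degree of truth undefined")
    return (np.nanmax(img) - np.nanmin(img)) / (tmax - tmin)


def rel_extremum_errors(img: np.ndarray, truth_img: np.ndarray) -> tuple[float, float]:
    """Relative errors of max and min, in percent."""
    tmax, tmin = np.nanmax(truth_img), np.nanmin(truth_img)
    err_max = abs(np.nanmax(img) - tmax) / abs(tmax) * 100.0
    err_min = abs(np.nanmin(img) - tmin) / abs(tmin) * 100.0
    return float(err_max), float(err_min)


@dataclass
class MetricsReport:
    """Per-image figures of merit and optional convergence diagnostics."""

    AR: float
    PE: float
    RNG: float
    RES: float
    SD: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.RES <= 1.0:
            raise ValueError(f"RES out of [0, 1]: {self.RES}")
        if self.RNG < 0:
            raise ValueError(f"RNG negative: {self.RNG}")
        if not 0.0 <= self.SD <= 1.0:
            raise ValueError(f"SD out of [0, 1]: {self.SD}")

    def as_dict(self) -> dict:
        d = {"AR": self.AR, "PE": self.PE, "RNG": self.RNG,
             "RES": self.RES, "SD": self.SD}
        d.update(self.extra)
        return d


def evaluate_target_image(
    img: ConductivityImage,
    truth: TargetTruth,
    norm_const: float = 1.0,
) -> MetricsReport:
    """All five figures of merit for one reconstruction of a circular target."""
    diff = difference_image(img)
    qset = quarter_amplitude(diff, img.points)
    return MetricsReport(
        AR=amplitude_response(diff, truth, img.points, norm_const=norm_const),
        PE=position_error(qset, truth),
        RNG=ringing(diff, qset, img.points),
        RES=resolution(qset, img.mask),
        SD=shape_deformation(qset, img.points),
        extra={"r_q": qset.r_q, "r_t": truth.r_t, "A_q": qset.A_q},
    )
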