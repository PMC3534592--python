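"""Discrete Neumann-to-Dirichlet / Dirichlet-to-Neumann maps.

Given normalized current columns ``t^j`` and voltage columns ``v^j`` the
discrete ND map is ``R(m, n) = (t^m / A, v^n)_L`` with the L-point inner
product ``(u, w)_L = sum_l conj(u_l) w_l``; the DN map is its matrix inverse,
and the data object of the inverse problem is ``dL = L_gamma - L_1`` together
with the best homogeneous conductivity fit.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from dbareit.forward_sim.cem import ElectrodeLayout
from dbareit.forward_sim.patterns import normalize_patterns

__all__ = [
    "NDMap",
    "DeltaDNMap",
    "build_nd_map",
    "homogeneous_nd",
    "dn_from_nd",
    "delta_dn",
    "gamma_best",
]

#: condition-number thresholds for inverting the ND map
COND_WARN = 1e8
COND_FAIL = 1e12


@dataclass
class NDMap:
    """(L-1) x (L-1) discrete Neumann-to-Dirichlet matrix."""

    R: np.ndarray
    layout: ElectrodeLayout | None = None

    @property
    def L(self) -> int:
        return self.R.shape[0] + 1


@dataclass
class DeltaDNMap:
    """Difference DN matrix ``dL`` plus the best homogeneous conductivity.

    ``gamma_best`` is in the units of the simulated conductivities (mS/m when
    the phantom tables are used); ``dL`` is the DN difference of the
    *gamma_best-normalized* data against the unit reference.
    """

    dL: np.ndarray
    gamma_best: float
    layout: ElectrodeLayout | None = None
    #: DN matrix of the homogeneous reference frame, kept for per-mode
    #: calibration of the scattering series (optional provenance).
    L1: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.dL.shape[0] + 1


def build_nd_map(
    t: np.ndarray, v: np.ndarray, A: float, layout: ElectrodeLayout | None = None
) -> NDMap:
    """ND matrix ``R(m, n) = (t^m / A, v^n)_L`` from normalized data."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.shape[1] != t.shape[0] - 1:
        raise ValueError(f"expected L x (L-1) matrices, got {t.shape} and {v.shape}")
    col_sums = np.abs(v.sum(axis=0))
    if np.max(col_sums) > 1e-8 * max(1.0, np.abs(v).max()):
        raise ValueError("voltage columns must sum to zero; normalize first")
    R = (t.T @ v) / A
    return NDMap(R=R, layout=layout)


def homogeneous_nd(L: int, A: float, layout: ElectrodeLayout | None = None) -> NDMap:
    """Diagonal ND map of the homogeneous unit-conductivity disk.

    Entry ``1/(A*m)`` for m <= L/2 and ``1/(A*(m - L/2))`` for m > L/2.
    """
    if L < 4 or L % 2 != 0:
        raise ValueError(f"electrode count must be even and >= 4, got {L}")
    m = np.arange(1, L)
    freq = np.where(m <= L // 2, m, m - L // 2)
    return NDMap(R=np.diag(1.0 / (A * freq)), layout=layout)


def dn_from_nd(nd: NDMap) -> np.ndarray:
    """DN matrix = inverse of the ND matrix, with a conditioning guard."""
    R = nd.R
    cond = np.linalg.cond(R)
    if cond > COND_FAIL:
        raise np.linalg.LinAlgError(
            f"ND map numerically singular (cond={cond:.3g} > {COND_FAIL:.0e})"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"ND map badly conditioned (cond={cond:.3g}); DN entries may be "
            "noise-amplified",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.linalg.inv(R)


def delta_dn(
    L_gamma: np.ndarray,
    L_1: np.ndarray,
    gamma_best_value: float = 1.0,
    layout: ElectrodeLayout | None = None,
) -> DeltaDNMap:
    """Elementwise DN difference ``dL = L_gamma - L_1``."""
    L_gamma = np.asarray(L_gamma, dtype=float)
    L_1 = np.asarray(L_1, dtype=float)
    if L_gamma.shape != L_1.shape:
        raise ValueError(f"shape mismatch: {L_gamma.shape} vs {L_1.shape}")
    return DeltaDNMap(
        dL=L_gamma - L_1, gamma_best=gamma_best_value, layout=layout, L1=L_1
    )


def gamma_best(U: np.ndarray, V1: np.ndarray) -> float:
    """Best homogeneous conductivity from measured vs unit-reference voltages.

    Solves ``min_rho sum (rho*V1 - U)^2`` exactly (least squares through the
    origin): ``rho_best = sum(V1*U) / sum(V1^2)`` and ``gamma = 1/rho_best``.
    """
    U = np.asarray(U, dtype=float)
    V1 = np.asarray(V1, dtype=float)
    if U.shape != V1.shape:
        raise ValueError(f"shape mismatch: {U.shape} vs {V1.shape}")
    denom = float(np.sum(V1 * V1))
    if denom == 0.0:
        raise ValueError("degenerate reference: sum(V1^2) is zero")
    rho = float(np.sum(V1 * U)) / denom
    if rho <= 0:
        raise ValueError(f"non-positive resistivity fit rho={rho}")
    return 1.0 / rho


def delta_dn_from_data(
    T: np.ndarray,
    V: np.ndarray,
    T_ref: np.ndarray,
    V_ref: np.ndarray,
    A: float,
    layout: ElectrodeLayout | None = None,
) -> DeltaDNMap:
    """Full data-to-dL chain: normalize, fit gamma_best, scale, difference.

    ``(T, V)`` is the measurement frame and ``(T_ref, V_ref)`` the
    unit-conductivity reference frame.  The measured voltages are scaled by
    ``gamma_best`` so the effective medium is ~1 near the boundary, then both
    frames are turned into DN matrices and differenced.
    """
    g_best = gamma_best(V, V_ref)
    t, v = normalize_patterns(T, np.asarray(V) * g_best)
    t1, v1 = normalize_patterns(T_ref, V_ref)
    L_g = dn_from_nd(build_nd_map(t, v, A, layout))
    L_1 = dn_from_nd(build_nd_map(t1, v1, A, layout))
    return delta_dn(L_g, L_1, gamma_best_value=g_best, layout=layout)
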