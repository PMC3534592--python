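"""Trigonometric current patterns and current/voltage normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CurrentPatternSet", "trig_patterns", "normalize_patterns", "electrode_angles"]


def electrode_angles(L: int) -> np.ndarray:
    """Angular centers theta_l = 2*pi*l/L for electrodes l = 1..L.

    Electrode 1 sits one step past 3 o'clock; electrode L closes the circle
    at angle 2*pi (== 0, the 3 o'clock position), matching a counter-clockwise
    layout whose first electrode index is 1.
    """
    return 2.0 * np.pi * np.arange(1, L + 1) / L


@dataclass
class CurrentPatternSet:
    """An L x (L-1) matrix of applied currents, one pattern per column.

    ``T[l, j]`` is the current on electrode ``l+1`` for pattern ``j+1`` (mA).
    """

    T: np.ndarray
    M: float
    normalized: bool = False

    @property
    def L(self) -> int:
        return self.T.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.T.shape[1]

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.T, axis=0)


def trig_patterns(L: int, M: float) -> CurrentPatternSet:
    """Build the L-1 trigonometric patterns of amplitude M.

    Pattern j on electrode l (l = 1..L, theta_l = 2*pi*l/L):

    * ``M*cos(j*theta_l)``            for j = 1..L/2-1,
    * ``M*cos(pi*l)``                 for j = L/2,
    * ``M*sin((j-L/2)*theta_l)``      for j = L/2+1..L-1.
    """
    if L < 4 or L % 2 != 0:
        raise ValueError(f"electrode count must be even and >= 4, got {L}")
    if M <= 0:
        raise ValueError(f"current amplitude must be positive, got {M}")
    theta = electrode_angles(L)
    l_idx = np.arange(1, L + 1)
    cols = []
    for j in range(1, L):
        if j < L // 2:
            cols.append(M * np.cos(j * theta))
        elif j == L // 2:
            cols.append(M * np.cos(np.pi * l_idx))
        else:
            cols.append(M * np.sin((j - L // 2) * theta))
    T = np.column_stack(cols)
    return CurrentPatternSet(T=T, M=M)


def normalize_patterns(T: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize currents to unit Euclidean norm and voltages accordingly.

    ``t^j = T^j / ||T^j||`` and ``v^j = (V^j - mean(V^j)) / ||T^j||`` so every
    voltage column sums to zero.  Accepts raw L x (L-1) matrices.
    """
    T = np.asarray(T, dtype=float)
    V = np.asarray(V, dtype=float)
    if T.shape != V.shape:
        raise ValueError(f"current/voltage shape mismatch: {T.shape} vs {V.shape}")
    norms = np.linalg.norm(T, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate current pattern with zero norm")
    t = T / norms
    v = (V - V.mean(axis=0)) / norms
    return t, v
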