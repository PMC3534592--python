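"""Complete-electrode-model FEM forward solver on disk meshes.

The weak form couples interior potential ``u`` with per-electrode potentials
``U_l`` through the contact impedance ``z``:

    int gamma grad(u).grad(w) dx
      + sum_l (1/z_l) int_{e_l} (u - U_l)(w - W_l) ds  =  sum_l I_l W_l

Linear (P1) elements are used on triangles; electrode arcs are unions of
boundary edges.  The singular constant mode is removed with a Lagrange
multiplier enforcing sum_l U_l = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from dbareit.forward_sim.mesh import Mesh2D, make_disk_mesh
from dbareit.forward_sim.patterns import CurrentPatternSet, electrode_angles
from dbareit.forward_sim.phantoms import PhantomSpec

__all__ = [
    "ElectrodeLayout",
    "VoltageDataset",
    "solve_forward_cem",
    "add_noise",
    "default_layout",
    "mesh_for_layout",
]


@dataclass
class ElectrodeLayout:
    """Ring of L equally spaced electrodes on a disk of radius r.

    ``A`` is the electrode area (m^2); with the model's unit out-of-plane
    depth the electrode arc width is ``A / height``.  ``z_contact`` is the
    contact impedance (Ohm m^2).
    """

    L: int
    r: float = 1.0
    A: float | None = None
    height: float = 1.0
    z_contact: float = 1e-4

    def __post_init__(self) -> None:
        if self.L < 4 or self.L % 2 != 0:
            raise ValueError(f"electrode count must be even and >= 4, got {self.L}")
        if self.r <= 0:
            raise ValueError("domain radius must be positive")
        if self.A is None:
            # default: 85% of the boundary covered by electrodes (ACT3-like
            # tanks have 2.5 cm electrodes at 2.94 cm spacing)
            self.A = 0.85 * 2.0 * np.pi * self.r / self.L * self.height
        if self.width * self.L >= 2.0 * np.pi * self.r:
            raise ValueError("electrodes overlap: width * L must be < 2*pi*r")
        if self.z_contact <= 0:
            raise ValueError("contact impedance must be positive")

    @property
    def theta(self) -> np.ndarray:
        """Electrode angular centers, l = 1..L."""
        return electrode_angles(self.L)

    @property
    def width(self) -> float:
        """Electrode arc width (length units of r)."""
        return self.A / self.height

    @property
    def delta_theta(self) -> float:
        return 2.0 * np.pi / self.L


def default_layout(L: int = 32, r: float = 1.0, **kw) -> ElectrodeLayout:
    return ElectrodeLayout(L=L, r=r, **kw)


@dataclass
class VoltageDataset:
    """Paired injected currents and measured electrode voltages.

    ``V[l, j]`` is the voltage on electrode ``l+1`` under pattern ``j+1``,
    mean-shifted so each column sums to zero.  ``patterns.T`` holds the
    currents actually injected (they carry the noise when current-side noise
    is configured).
    """

    V: np.ndarray
    patterns: CurrentPatternSet
    layout: ElectrodeLayout
    noise_seed: int | None = None
    noise_amplitude: float = 0.0
    noise_target: str = "currents"

    def __post_init__(self) -> None:
        if self.V.shape != self.patterns.T.shape:
            raise ValueError(
                f"voltage shape {self.V.shape} does not match patterns "
                f"{self.patterns.T.shape}"
            )


def mesh_for_layout(
    layout: ElectrodeLayout, target_elements: int, edges_per_electrode: int = 4
) -> Mesh2D:
    """Disk mesh whose boundary nodes align with the electrode arcs."""
    per = max(2, edges_per_electrode)
    n_boundary = layout.L * 2 * per  # even multiple of L: arcs align with edges
    n_boundary = max(n_boundary, int(round(2 * np.pi * np.sqrt(target_elements / (2 * np.pi)))))
    n_boundary += (-n_boundary) % (2 * layout.L)
    return make_disk_mesh(layout.r, target_elements, n_boundary=n_boundary)


def _electrode_edges(mesh: Mesh2D, layout: ElectrodeLayout) -> list[np.ndarray]:
    """Boundary-edge index lists, one per electrode (midpoint-in-arc rule)."""
    pts = mesh.nodes
    be = mesh.boundary_edges
    mid = 0.5 * (pts[be[:, 0]] + pts[be[:, 1]])
    ang = np.mod(np.arctan2(mid[:, 1], mid[:, 0]), 2.0 * np.pi)
    half = 0.5 * layout.width / layout.r  # half arc angle
    groups: list[np.ndarray] = []
    for th in layout.theta:
        d = np.mod(ang - th + np.pi, 2.0 * np.pi) - np.pi
        sel = np.flatnonzero(np.abs(d) <= half + 1e-12)
        if sel.size == 0:
            raise RuntimeError(
                "electrode arc covers no boundary edge; refine the mesh or "
                "use mesh_for_layout()"
            )
        groups.append(sel)
    return groups


def _stiffness(mesh: Mesh2D, sigma_elem: np.ndarray) -> sp.csr_matrix:
    nodes, elems = mesh.nodes, mesh.elements
    p = nodes[elems]  # (E,3,2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0]  # = 2*area * 2? (see below)
    area = 0.5 * np.abs(
        (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
        - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    )
    coef = sigma_elem / (4.0 * area)
    Ke = coef[:, None, None] * (
        b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
    )
    rows = np.repeat(elems, 3, axis=1).ravel()
    cols = np.tile(elems, (1, 3)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def solve_forward_cem(
    mesh: Mesh2D,
    phantom: PhantomSpec,
    layout: ElectrodeLayout,
    patterns: CurrentPatternSet,
) -> VoltageDataset:
    """Solve the CEM for every current pattern and return electrode voltages.

    Conductivity is sampled per element at the centroid.  Returned voltages
    are mean-shifted to sum to zero over electrodes.
    """
    if patterns.L != layout.L:
        raise ValueError("pattern electrode count does not match layout")
    col_sums = patterns.T.sum(axis=0)
    if np.max(np.abs(col_sums)) > 1e-9 * max(patterns.M, 1.0):
        raise ValueError("current patterns do not conserve current")

    sigma = phantom.sigma_at(mesh.element_centroids())
    if np.any(sigma <= 0):
        raise ValueError("phantom conductivity must be positive on all elements")

    N, L = mesh.n_nodes, layout.L
    K = _stiffness(mesh, sigma)
    groups = _electrode_edges(mesh, layout)
    z = layout.z_contact / layout.height  # per-unit-depth contact impedance

    # boundary edge lengths
    be = mesh.boundary_edges
    elen = np.linalg.norm(mesh.nodes[be[:, 1]] - mesh.nodes[be[:, 0]], axis=1)

    rows_b, cols_b, vals_b = [], [], []
    rows_c, cols_c, vals_c = [], [], []
    D = np.zeros(L)
    for l, sel in enumerate(groups):
        for e in sel:
            n0, n1 = be[e]
            le = elen[e]
            # edge mass matrix le/6 * [[2,1],[1,2]]
            m00 = m11 = le / 3.0 / z
            m01 = le / 6.0 / z
            rows_b += [n0, n1, n0, n1]
            cols_b += [n0, n1, n1, n0]
            vals_b += [m00, m11, m01, m01]
            # int over edge of basis fn = le/2
            rows_c += [n0, n1]
            cols_c += [l, l]
            vals_c += [le / 2.0 / z, le / 2.0 / z]
            D[l] += le / z
    B = sp.coo_matrix((vals_b, (rows_b, cols_b)), shape=(N, N))
    C = sp.coo_matrix((vals_c, (rows_c, cols_c)), shape=(N, L))

    ones = np.ones((L, 1))
    top = sp.hstack([K + B, -C, sp.csr_matrix((N, 1))])
    midrow = sp.hstack([-C.T, sp.diags(D), sp.csr_matrix(ones)])
    bottom = sp.hstack([sp.csr_matrix((1, N)), sp.csr_matrix(ones.T), sp.csr_matrix((1, 1))])
    Asys = sp.vstack([top, midrow, bottom]).tocsc()

    rhs = np.zeros((N + L + 1, patterns.n_patterns))
    rhs[N : N + L, :] = patterns.T

    try:
        lu = spla.splu(Asys)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"CEM system is singular: {exc}") from exc
    sol = lu.solve(rhs)
    U = sol[N : N + L, :]
    U = U - U.mean(axis=0)
    return VoltageDataset(V=U, patterns=patterns, layout=layout)


def add_noise(
    dataset: VoltageDataset,
    amplitude: float,
    seed: int,
    target: str = "currents",
) -> VoltageDataset:
    """Add i.i.d. uniform noise on [-amplitude, amplitude].

    ``target='currents'`` perturbs the injected-current matrix (the recorded
    patterns are updated so downstream normalization uses the currents
    actually applied); ``target='voltages'`` perturbs the measured voltages.
    """
    if amplitude < 0:
        raise ValueError("noise amplitude must be >= 0")
    if target not in ("currents", "voltages"):
        raise ValueError(f"noise target must be 'currents' or 'voltages', got {target!r}")
    if amplitude == 0:
        return dataset
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-amplitude, amplitude, size=dataset.V.shape)
    if target == "voltages":
        V = dataset.V + noise
        patterns = dataset.patterns
    else:
        V = dataset.V
        patterns = CurrentPatternSet(
            T=dataset.patterns.T + noise,
            M=dataset.patterns.M,
            normalized=False,
        )
    return replace(
        dataset,
        V=V,
        patterns=patterns,
        noise_seed=seed,
        noise_amplitude=amplitude,
        noise_target=target,
    )
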