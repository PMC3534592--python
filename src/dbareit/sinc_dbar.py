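"""Sinc-convolution solution of the 2D D-bar integral equation.

The solution matrix ``mu`` at sinc points of the square [-2R, 2R]^2 obeys the
fixed-point form ``mu = 1 + r / pi`` where ``r`` is the convolution of the
Cauchy kernel ``g(k) = 1/k`` with the density
``t_R(k) e_{-k}(x) conj(mu(x, k)) / (4 conj(k))``.

The convolution is decomposed into four one-sided pieces (lower/upper
integration limit per axis).  Each piece is evaluated by the separation of
variables: one-dimensional sinc integration operators ``A1`` (lower) and
``A2`` (upper) are eigendecomposed once, and the kernel enters only through
its "Laplace transform" evaluated at eigenvalue pairs.  The transform
convention is ``F(lam) = \\int f(t) e^{-t/lam} dt`` (reciprocal eigenvalue in
the exponent), which is what makes plugging eigenvalues of the integration
operators legitimate; the four pieces use the four axis-reflected variants of
the kernel transform.

Because the fixed-point map conjugates ``mu`` it is real-linear but not
complex-linear, so GMRES operates on stacked real/imaginary parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla
from scipy.special import sici

from dbareit.scattering import ScatteringTransform

__all__ = [
    "SincGrid",
    "SincOperators",
    "MuSolution",
    "ConductivityImage",
    "build_sinc_grid",
    "build_Im1",
    "build_operators",
    "laplace_kernel_G",
    "separate_convolve",
    "dbar_apply",
    "solve_dbar_at",
    "reconstruct_image",
    "disk_image_grid",
]


# --------------------------------------------------------------------------
# sinc grid


@dataclass
class SincGrid:
    """One-dimensional sinc points of the interval (-2R, 2R).

    ``z_pts[l + M_idx] = 2R(e^{lh} - 1)/(e^{lh} + 1)`` for l = -M_idx..N_idx,
    the conformal image of the uniform grid ``l*h`` under the inverse of
    ``phi(z) = ln((2R + z)/(2R - z))``.
    """

    R: float
    M_idx: int
    N_idx: int
    h: float
    z_pts: np.ndarray
    phi_prime: np.ndarray

    @property
    def m(self) -> int:
        return self.M_idx + self.N_idx + 1

    @property
    def origin_index(self) -> int:
        """Index of the sinc point z = 0 (l = 0)."""
        return self.M_idx

    def phi(self, z: np.ndarray) -> np.ndarray:
        return np.log((2.0 * self.R + z) / (2.0 * self.R - z))

    def complex_points(self) -> np.ndarray:
        """(m, m) complex grid k = z_i + i z_j (axis 0 = real part)."""
        Z1, Z2 = np.meshgrid(self.z_pts, self.z_pts, indexing="ij")
        return Z1 + 1j * Z2


def default_step(m_lo: int, coverage: float = 1.4) -> float:
    """Step size placing the outermost sinc point at ``coverage * R``.

    The D-bar density vanishes outside the truncation disk |k| <= R, so
    endpoint clustering of the tanh map is wasted there; choosing
    ``h = 2 artanh(coverage/2) / M`` spreads the points nearly uniformly
    across the support with a modest margin.  (The textbook balance
    ``h ~ pi/sqrt(m/2)`` targets endpoint-singular integrands and leaves the
    interior catastrophically under-resolved for this equation.)
    """
    if not 0 < coverage < 2:
        raise ValueError("coverage must be in (0, 2)")
    return 2.0 * np.arctanh(coverage / 2.0) / m_lo


def build_sinc_grid(
    R: float, m_lo: int, m_hi: int | None = None, h: float | None = None
) -> SincGrid:
    """Sinc points and map derivatives on (-2R, 2R).

    ``phi'(z) = 4R / ((2R + z)(2R - z))``, the (positive) derivative of the
    tanh-type map.  (A variant sometimes written with ``(z - 2R)`` in the
    denominator is negative on the whole interval; the positive form is the
    actual derivative.)
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if m_hi is None:
        m_hi = m_lo
    if m_lo < 1 or m_hi < 1:
        raise ValueError("sinc index counts must be >= 1")
    m = m_lo + m_hi + 1
    if h is None:
        h = default_step(m_lo)
    if h <= 0:
        raise ValueError("step h must be positive")
    ls = np.arange(-m_lo, m_hi + 1)
    elh = np.exp(ls * h)
    z = 2.0 * R * (elh - 1.0) / (elh + 1.0)
    if np.any(2.0 * R - np.abs(z) < 1e-13 * R):
        raise ValueError(
            f"h={h} is too large: sinc points collide with the interval ends"
        )
    phi_prime = 4.0 * R / ((2.0 * R + z) * (2.0 * R - z))
    return SincGrid(R=R, M_idx=m_lo, N_idx=m_hi, h=h, z_pts=z, phi_prime=phi_prime)


# --------------------------------------------------------------------------
# sinc matrices and kernel transform


def build_Im1(m: int) -> np.ndarray:
    """Toeplitz matrix with entries ``Si(pi (i - j)) / pi + 1/2``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    idx = np.arange(m)
    diff = idx[:, None] - idx[None, :]
    si, _ = sici(np.pi * diff)
    return si / np.pi + 0.5


def laplace_kernel_G(
    u: complex | np.ndarray,
    v: complex | np.ndarray,
    signs: tuple[int, int] = (1, 1),
) -> complex | np.ndarray:
    """Closed form of ``\\int_0^inf \\int_0^inf g(s1*k1, s2*k2) e^{-k1 u - k2 v} dk``
    for the Cauchy kernel ``g(k) = 1/(k1 + i k2)`` and axis signs ``s1, s2``.

    For the base quadrant ``(+1, +1)`` the closed form is
    ``-i (Log u - Log(-iv)) / (u + iv)``, which reduces to the ratio form
    ``(pi/2 + i ln(v/u)) / (u + iv)`` when ``|arg(v/u)| < pi/2`` but keeps
    the correct branch on the whole product of right half planes.
    Reflecting an axis flips the corresponding sign of the kernel argument;
    the two reflected-in-one-axis variants differ only by a global sign, as
    do the two reflected-in-both variants:

    * ``(+1, +1)`` ->  ``-i (Log u - Log(-iv)) / (u + iv)``
    * ``(+1, -1)`` ->  ``+i (Log u - Log(+iv)) / (u - iv)``
    * ``(-1, +1)`` ->  minus the ``(+1, -1)`` form
    * ``(-1, -1)`` ->  minus the ``(+1, +1)`` form

    Valid for ``Re(u) > 0`` and ``Re(v) > 0`` (where the defining integral
    converges; this covers the ``Re(u/v), Re(v/u) > 0`` ratio condition of
    interest for integration-operator eigenvalues).
    """
    u = np.asarray(u, dtype=complex)
    v = np.asarray(v, dtype=complex)
    if not (np.all(u.real > 0) and np.all(v.real > 0)):
        raise ValueError("kernel domain violated: need Re(u) > 0 and Re(v) > 0")
    s1, s2 = signs

    def base(uu, vv, rot):
        # -i * (Log(uu) - Log(rot*vv)) / (uu - rot*vv) with rot = -i or +i;
        # confluent case uu == rot*vv handled by the limit 1/uu.
        denom = uu - rot * vv
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (np.log(uu) - np.log(rot * vv)) / denom
        tiny = np.abs(denom) <= 1e-14 * (np.abs(uu) + np.abs(vv))
        if np.any(tiny):
            out = np.where(tiny, 1.0 / uu, out)
        return -1j * out if rot == -1j else 1j * out

    if (s1, s2) == (1, 1):
        out = base(u, v, -1j)
    elif (s1, s2) == (1, -1):
        out = base(u, v, 1j)
    elif (s1, s2) == (-1, 1):
        out = -base(u, v, 1j)
    elif (s1, s2) == (-1, -1):
        out = -base(u, v, -1j)
    else:
        raise ValueError(f"signs must be (+-1, +-1), got {signs}")
    return out[()] if out.ndim == 0 else out


#: axis-sign pattern of the kernel argument per convolution piece:
#: piece 1 = (lower, lower), 2 = (lower, upper), 3 = (upper, lower),
#: 4 = (upper, upper); "upper" integration reflects that axis of the kernel.
QUADRANT_SIGNS = {1: (1, 1), 2: (1, -1), 3: (-1, 1), 4: (-1, -1)}


@dataclass
class SincOperators:
    """Eigendecomposed 1D integration operators and kernel transform tables.

    ``A1 = h * Im1 * D(1/phi')`` collocates integration from the lower end,
    ``A2 = h * Im1^T * D(1/phi')`` from the upper end.  ``Gq[q]`` holds the
    kernel transform at eigenvalue pairs for convolution piece ``q``; the
    first factor of the pair comes from the axis-0 operator, the second from
    the axis-1 operator (A1 for "lower", A2 for "upper").
    """

    grid: SincGrid
    Im1: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    S1: np.ndarray
    X1: np.ndarray
    X1inv: np.ndarray
    S2: np.ndarray
    X2: np.ndarray
    X2inv: np.ndarray
    Gq: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.grid.m


#: which (axis0, axis1) operator pair each piece uses: 1 = A1/X1, 2 = A2/X2
QUADRANT_OPS = {1: (1, 1), 2: (1, 2), 3: (2, 1), 4: (2, 2)}


def build_operators(grid: SincGrid, recon_tol: float = 1e-6) -> SincOperators:
    """Assemble and eigendecompose the sinc integration operators."""
    m = grid.m
    Im1 = build_Im1(m)
    Dinv = np.diag(1.0 / grid.phi_prime)
    A1 = grid.h * Im1 @ Dinv
    A2 = grid.h * Im1.T @ Dinv
    S1, X1 = np.linalg.eig(A1)
    S2, X2 = np.linalg.eig(A2)
    X1inv = np.linalg.inv(X1)
    X2inv = np.linalg.inv(X2)
    for name, A, S, X, Xi in (("A1", A1, S1, X1, X1inv), ("A2", A2, S2, X2, X2inv)):
        err = np.abs(X @ np.diag(S) @ Xi - A).max() / np.abs(A).max()
        if err > recon_tol:
            raise np.linalg.LinAlgError(
                f"eigendecomposition of {name} reconstitutes poorly "
                f"(rel err {err:.2e}); try a different h or m"
            )
    if np.any(S1.real <= 0) or np.any(S2.real <= 0):
        raise np.linalg.LinAlgError(
            "integration-operator eigenvalues left the right half plane; "
            "kernel transform undefined (try different h or m)"
        )
    ops = SincOperators(
        grid=grid, Im1=Im1, A1=A1, A2=A2,
        S1=S1, X1=X1, X1inv=X1inv, S2=S2, X2=X2, X2inv=X2inv,
    )
    eigs = {1: S1, 2: S2}
    for q, (p_ax0, p_ax1) in QUADRANT_OPS.items():
        # transform arguments are reciprocal eigenvalues (e^{-t/lam} convention)
        U, V = np.meshgrid(1.0 / eigs[p_ax0], 1.0 / eigs[p_ax1], indexing="ij")
        ops.Gq[q] = laplace_kernel_G(U, V, signs=QUADRANT_SIGNS[q])
    return ops


# --------------------------------------------------------------------------
# convolution pieces and the D-bar operator


def separate_convolve(U: np.ndarray, ops: SincOperators, quadrant: int) -> np.ndarray:
    """One convolution piece by separation of variables.

    Steps: transform columns (axis 0), transform rows (axis 1), Hadamard with
    the kernel-transform table, then back-transform rows and columns.
    """
    if quadrant not in QUADRANT_OPS:
        raise ValueError(f"quadrant must be 1..4, got {quadrant}")
    m = ops.m
    if U.shape != (m, m):
        raise ValueError(f"integrand array must be {m}x{m}, got {U.shape}")
    p_ax0, p_ax1 = QUADRANT_OPS[quadrant]
    X_a, Xi_a = (ops.X1, ops.X1inv) if p_ax0 == 1 else (ops.X2, ops.X2inv)
    X_b, Xi_b = (ops.X1, ops.X1inv) if p_ax1 == 1 else (ops.X2, ops.X2inv)
    b_plus = Xi_a @ U          # columns
    t_plus = b_plus @ Xi_b.T   # rows
    t_minus = ops.Gq[quadrant] * t_plus
    b_minus = t_minus @ X_b.T  # rows back
    return X_a @ b_minus       # columns back


def convolve_cauchy(U: np.ndarray, ops: SincOperators) -> np.ndarray:
    """Full convolution ``r = sum_q r_q`` of the Cauchy kernel with U."""
    r = np.zeros_like(U, dtype=complex)
    for q in QUADRANT_OPS:
        r = r + separate_convolve(U, ops, q)
    return r


def _density_prefactor(
    t: ScatteringTransform, grid: SincGrid, x: complex
) -> np.ndarray:
    """``t_R(k) e_{-k}(x) / (4 pi conj(k))`` on the sinc grid, 0 at k = 0.

    ``e_{-k}(x) = exp(-i(kx + conj(k) conj(x))) = exp(-2i Re(kx))``.

    Together with the outer ``1/pi`` of the fixed-point form this realizes
    the Cauchy-transform constant ``1/(4 pi^2)`` of the D-bar equation (the
    inverse of ``dbar`` is ``(1/pi) int f(k)/(z - k) dA``); reconstruction
    amplitudes are wrong by a factor ~pi without it.
    """
    K = grid.complex_points()
    if t.values.shape != K.shape:
        raise ValueError(
            f"scattering transform shape {t.values.shape} does not match the "
            f"sinc grid ({K.shape}); evaluate it on KGrid.from_sinc_points"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = t.values / (4.0 * np.pi * np.conj(K))
    C[K == 0] = 0.0
    phase = np.exp(-2j * (K * x).real)
    return C * phase


def dbar_apply(
    mu_vec: np.ndarray,
    x: complex,
    t: ScatteringTransform,
    grid: SincGrid,
    ops: SincOperators,
    _C: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the real-linear fixed-point operator to a stacked vector.

    ``mu_vec`` stacks ``[Re(mu).ravel(), Im(mu).ravel()]``; the image is
    ``mu - (1/pi) * conv(C * conj(mu))`` in the same stacking.  The complex
    conjugation of ``mu`` is what breaks complex linearity and forces the
    stacked-real representation.
    """
    m = grid.m
    if mu_vec.size != 2 * m * m:
        raise ValueError(f"expected stacked vector of length {2 * m * m}")
    C = _density_prefactor(t, grid, x) if _C is None else _C
    mu = (mu_vec[: m * m] + 1j * mu_vec[m * m :]).reshape(m, m)
    r = convolve_cauchy(C * np.conj(mu), ops)
    out = mu - r / np.pi
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values produced by the D-bar operator")
    return np.concatenate([out.real.ravel(), out.imag.ravel()])


# --------------------------------------------------------------------------
# GMRES solve and image reconstruction


@dataclass
class MuSolution:
    """mu(x, .) at sinc points for one image point x."""

    mu: np.ndarray
    x: complex
    converged: bool
    iterations: int
    residual: float

    def at_origin(self, grid: SincGrid) -> complex:
        i0 = grid.origin_index
        return self.mu[i0, i0]


def solve_dbar_at(
    x: complex,
    t: ScatteringTransform,
    grid: SincGrid,
    ops: SincOperators,
    tol: float = 1e-5,
    maxit: int = 200,
    restart: int = 30,
    method: str = "gmres",
) -> MuSolution:
    """Solve the discretized D-bar equation at one image point.

    ``method='direct'`` assembles the dense real-linear system by applying
    the operator to coordinate vectors and solves it with LU; it is the
    (slow) reference used to validate the GMRES path.
    """
    m = grid.m
    n = 2 * m * m
    C = _density_prefactor(t, grid, x)
    rhs = np.concatenate([np.ones(m * m), np.zeros(m * m)])

    if np.abs(t.values).max() == 0.0:
        return MuSolution(
            mu=np.ones((m, m), complex), x=x, converged=True, iterations=0,
            residual=0.0,
        )

    if method == "direct":
        M = np.empty((n, n))
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            M[:, j] = dbar_apply(e, x, t, grid, ops, _C=C)
            e[j] = 0.0
        sol = np.linalg.solve(M, rhs)
        res = np.linalg.norm(M @ sol - rhs) / np.linalg.norm(rhs)
        mu = (sol[: m * m] + 1j * sol[m * m :]).reshape(m, m)
        return MuSolution(mu=mu, x=x, converged=True, iterations=0, residual=res)
    if method != "gmres":
        raise ValueError(f"unknown method {method!r}")

    count = {"n": 0}

    def matvec(vec: np.ndarray) -> np.ndarray:
        count["n"] += 1
        return dbar_apply(vec, x, t, grid, ops, _C=C)

    op = spla.LinearOperator((n, n), matvec=matvec, dtype=float)
    sol, info = spla.gmres(
        op, rhs, x0=rhs.copy(), rtol=tol, atol=0.0, restart=restart, maxiter=maxit
    )
    residual = float(np.linalg.norm(matvec(sol) - rhs) / np.linalg.norm(rhs))
    mu = (sol[: m * m] + 1j * sol[m * m :]).reshape(m, m)
    return MuSolution(
        mu=mu, x=x, converged=(info == 0), iterations=count["n"], residual=residual
    )


def disk_image_grid(n: int, radius: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """n x n Cartesian points over [-radius, radius]^2 and the disk mask."""
    ax = np.linspace(-radius, radius, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    pts = X + 1j * Y
    return pts, np.abs(pts) <= radius


@dataclass
class ConductivityImage:
    """Reconstructed conductivity on an image grid.

    ``gamma`` is NaN outside the disk; ``converged`` flags each solved pixel;
    ``meta`` records solver provenance.
    """

    points: np.ndarray
    mask: np.ndarray
    gamma: np.ndarray
    converged: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_unconverged(self) -> int:
        return int(self.mask.sum() - self.converged[self.mask].sum())


def reconstruct_image(
    t: ScatteringTransform,
    xgrid: np.ndarray | int,
    grid: SincGrid,
    ops: SincOperators | None = None,
    gamma_best: float | None = None,
    tol: float = 1e-5,
    maxit: int = 200,
    apply_gamma_best: bool = True,
    mask: np.ndarray | None = None,
) -> ConductivityImage:
    """Reconstruct conductivity at every image point inside the unit disk.

    Per pixel: solve the D-bar system, read ``mu`` at the k = 0 sinc point
    and set ``gamma(x) = gamma_best * mu(x, 0)^2`` (the D-bar output is
    normalized to ~1 near the boundary; ``apply_gamma_best=False`` returns
    the normalized image).  Pixels are independent; non-converged pixels are
    kept but flagged.
    """
    if isinstance(xgrid, int):
        points, mask = disk_image_grid(xgrid)
    else:
        points = np.asarray(xgrid, dtype=complex)
        if mask is None:
            mask = np.abs(points) <= 1.0
    if ops is None:
        ops = build_operators(grid)
    gb = t.gamma_best if gamma_best is None else gamma_best
    scale = gb if apply_gamma_best else 1.0

    gamma = np.full(points.shape, np.nan)
    conv = np.zeros(points.shape, dtype=bool)
    imag_mag = 0.0
    iters = []
    i0 = grid.origin_index
    for idx in np.ndindex(points.shape):
        if not mask[idx]:
            continue
        sol = solve_dbar_at(points[idx], t, grid, ops, tol=tol, maxit=maxit)
        mu0 = sol.mu[i0, i0]
        g = mu0 * mu0
        gamma[idx] = scale * g.real
        conv[idx] = sol.converged
        imag_mag = max(imag_mag, abs(g.imag) / max(abs(g.real), 1e-30))
        iters.append(sol.iterations)
    meta = {
        "R": grid.R,
        "h": grid.h,
        "m": grid.m,
        "tol": tol,
        "maxit": maxit,
        "gamma_best": gb,
        "apply_gamma_best": apply_gamma_best,
        "max_rel_imag_mu0_sq": imag_mag,
        "mean_gmres_applies": float(np.mean(iters)) if iters else 0.0,
        "n_unconverged": int(mask.sum() - conv[mask].sum()),
    }
    return ConductivityImage(
        points=points, mask=mask, gamma=gamma, converged=conv, meta=meta
    )
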