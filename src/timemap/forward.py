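"""Spherical head model and analytic dipole lead field.

The head is modelled as three concentric spherical shells (brain, skull,
scalp) with piecewise-constant conductivity, and the solution space is a
regular lattice of source nodes inside the brain sphere.  The scalp
potential of a current dipole is computed from the exact spherical-harmonic
series: per Legendre degree ``n`` the potential in each shell is
``A r^n + B r^-(n+1)``; the coefficients follow from continuity of potential
and radial current at each interface and a no-current condition at the outer
surface (solved as a small linear system per degree, in radii normalized by
the scalp radius for conditioning).

For an electrode in direction ``u`` and a dipole with moment ``q`` at radius
``b`` along ``r0``::

    V(u) = sum_n c_n(b) * [ n (q . r0) P_n(x) + (q . t_e) sqrt(1-x^2) P_n'(x) ]

with ``x = u . r0`` and ``t_e`` the tangent-plane direction from the dipole
axis toward the electrode.  For a homogeneous sphere the shell solve reduces
to the classical closed form ``c_n = (2n+1)/n * (b/R)^(n-1) / (4 pi sigma
R^2)``, which serves as an independent check.

Units: radii in meters, conductivities in S/m, dipole moments in A*m,
potentials in volts (callers typically rescale to uV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeadModel", "SourceGrid", "lead_field", "dipole_potential"]


@dataclass(frozen=True)
class HeadModel:
    """Concentric-spheres conductor, innermost shell first.

    Defaults: brain/skull/scalp radii 87/92/100 mm, conductivities
    0.33/0.0042/0.33 S/m (the standard 1:1/80:1 skull contrast).
    """

    radii: tuple[float, ...] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        s = np.asarray(self.conductivities, dtype=float)
        if r.size != s.size or r.size < 1:
            raise ValueError("radii and conductivities must have equal length >= 1")
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if np.any(s <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


@dataclass(frozen=True)
class SourceGrid:
    """Regular lattice of source nodes strictly inside the brain sphere."""

    nodes: np.ndarray  # (n_nodes, 3) meters
    spacing: float  # meters

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        object.__setattr__(self, "nodes", nodes)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @classmethod
    def from_spacing(
        cls,
        head: HeadModel,
        spacing_mm: float = 12.0,
        max_radius_fraction: float = 0.95,
    ) -> "SourceGrid":
        """Cubic lattice clipped to ``max_radius_fraction`` of the brain
        radius (default 12 mm spacing: ~1400 nodes)."""
        if not 0 < max_radius_fraction < 1:
            raise ValueError("max_radius_fraction must be in (0, 1)")
        spacing = spacing_mm / 1000.0
        rmax = head.brain_radius * max_radius_fraction
        ax = np.arange(-rmax, rmax + spacing / 2, spacing)
        ax = ax - ax.mean()  # symmetric about the origin
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        nodes = nodes[np.linalg.norm(nodes, axis=1) <= rmax]
        return cls(nodes, spacing)


def _shell_transfer(head: HeadModel, n_terms: int) -> np.ndarray:
    """Surface coefficient t_n for a unit singular source term.

    Radii are normalized by the scalp radius R.  In shell k the degree-n
    potential is ``A_k rho^n + B_k rho^-(n+1)``; with B_1 = 1 fixed by the
    source, continuity of potential and sigma*dPhi/drho at each interface
    plus zero radial current at rho = 1 determine the rest.  Returns
    ``t_n = A_K + B_K`` (the potential at rho = 1) for n = 1..n_terms.
    """
    rho = np.asarray(head.radii, dtype=float) / head.scalp_radius
    sig = np.asarray(head.conductivities, dtype=float)
    K = rho.size
    t = np.empty(n_terms)
    for i, n in enumerate(range(1, n_terms + 1)):
        # unknowns: A_1, (A_k, B_k for k=2..K)
        m = 2 * K - 1
        A = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_A(k):  # index of A_k
            return 0 if k == 1 else 2 * k - 3

        def col_B(k):  # index of B_k (k >= 2)
            return 2 * k - 2

        row = 0
        for k in range(1, K):
            r = rho[k - 1]
            rn, rm = r**n, r ** -(n + 1)
            drn, drm = n * r ** (n - 1), -(n + 1) * r ** -(n + 2)
            # potential continuity at interface k
            A[row, col_A(k)] = rn
            if k >= 2:
                A[row, col_B(k)] = rm
            A[row, col_A(k + 1)] = -rn
            A[row, col_B(k + 1)] = -rm
            if k == 1:
                rhs[row] = -rm  # B_1 = 1 contribution
            row += 1
            # radial current continuity
            A[row, col_A(k)] = sig[k - 1] * drn
            if k >= 2:
                A[row, col_B(k)] = sig[k - 1] * drm
            A[row, col_A(k + 1)] = -sig[k] * drn
            A[row, col_B(k + 1)] = -sig[k] * drm
            if k == 1:
                rhs[row] = -sig[0] * drm
            row += 1
        # insulating outer boundary at rho = 1
        A[row, col_A(K)] = n
        if K >= 2:
            A[row, col_B(K)] = -(n + 1)
        else:
            rhs[row] = n + 1  # B_1 = 1
        sol = np.linalg.solve(A, rhs)
        if K >= 2:
            t[i] = sol[col_A(K)] + sol[col_B(K)]
        else:
            t[i] = sol[col_A(1)] + 1.0
    return t


def dipole_potential(
    head: HeadModel,
    positions: np.ndarray,
    moments: np.ndarray,
    electrode_units: np.ndarray,
    n_terms: int = 100,
    average_reference: bool = True,
) -> np.ndarray:
    """Scalp potentials of dipoles in a concentric-spheres conductor.

    positions: (n_dip, 3) m inside the brain sphere; moments: (n_dip, 3)
    A*m; electrode_units: (n_e, 3) unit vectors (electrodes on the scalp
    sphere).  Returns (n_e, n_dip) potentials in volts.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    mom = np.atleast_2d(np.asarray(moments, dtype=float))
    eu = np.asarray(electrode_units, dtype=float)
    eu = eu / np.linalg.norm(eu, axis=1, keepdims=True)
    R = head.scalp_radius
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= head.brain_radius):
        raise ValueError("dipole outside the innermost (brain) sphere")

    # dipole radial frame; arbitrary axis for a central dipole (the n=1
    # term is frame-independent)
    r0 = np.where(b[:, None] > 0, pos / np.maximum(b, 1e-300)[:, None], [0.0, 0.0, 1.0])
    x = np.clip(r0 @ eu.T, -1.0, 1.0)  # (n_dip, n_e) cos(gamma)
    tang = eu[None, :, :] - x[:, :, None] * r0[:, None, :]
    tnorm = np.linalg.norm(tang, axis=2, keepdims=True)
    t_e = np.where(tnorm > 1e-12, tang / np.where(tnorm == 0, 1, tnorm), 0.0)

    q_r = np.sum(mom * r0, axis=1)  # (n_dip,)
    q_te = np.einsum("dec,dc->de", t_e, mom)  # (n_dip, n_e)
    sin_g = np.sqrt(np.clip(1.0 - x**2, 0.0, None))

    tn = _shell_transfer(head, n_terms)
    sigma1 = head.conductivities[0]
    base = 1.0 / (4.0 * np.pi * sigma1 * R**2)
    ratio = b / R

    v = np.zeros_like(x)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    dp_prev = np.zeros_like(x)  # P_0'
    dp_cur = np.ones_like(x)  # P_1'
    # (b/R)^(n-1) accumulated multiplicatively; 0^0 = 1 handles b = 0
    pow_b = np.ones_like(b)
    for n in range(1, n_terms + 1):
        w = (tn[n - 1] * base) * pow_b  # (n_dip,)
        v += w[:, None] * (n * q_r[:, None] * p_cur + q_te * sin_g * dp_cur)
        # advance Legendre recurrences to degree n+1
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        pow_b = pow_b * ratio

    out = v.T  # (n_e, n_dip)
    if average_reference:
        out = out - out.mean(axis=0, keepdims=True)
    return out


def lead_field(
    head: HeadModel,
    grid: SourceGrid,
    montage,
    n_terms: int = 100,
) -> np.ndarray:
    """Forward matrix (n_electrodes, 3 * n_nodes), node-major columns
    (x, y, z moment per node), average-referenced rows."""
    eu = montage.positions
    n_nodes = grid.n_nodes
    L = np.empty((eu.shape[0], 3 * n_nodes))
    # three unit moments per node, computed in one vectorized sweep per axis
    for axis in range(3):
        mom = np.zeros((n_nodes, 3))
        mom[:, axis] = 1.0
        L[:, axis::3] = dipole_potential(head, grid.nodes, mom, eu, n_terms)
    return L
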