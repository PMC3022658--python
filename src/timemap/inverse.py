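"""LAURA-style distributed linear inverse solution.

Estimates distributed dipole currents on the source grid from a scalp map.
The prior follows the local autoregressive average (LAURA) idea: the current
at a node should resemble a distance-weighted average of its neighbors
(weights proportional to ``distance**exponent``; the default exponent -2
mimics the fall-off of electric vector fields).  Writing that local
regression as a sparse operator ``A = I - alpha * W`` (W row-normalized
neighbor weights, ``alpha`` slightly below 1 so A stays invertible), the
source metric is ``M = A' A`` and the estimate is the Tikhonov-regularized
weighted minimum-norm solution

    J = M^-1 L' (L M^-1 L' + lambda I)^-1 v

applied independently to the three moment components of every node.  With
``A = I`` (no neighborhood) this reduces to the classical minimum-norm
inverse, which serves as an oracle in tests.

``DistributedInverse`` (model) / ``InverseResults`` (fitted operator) follow
the model/results split; ``InverseResults.apply`` yields a
``SourceEstimate`` with per-node current magnitudes and local peaks.
Lambda is either fixed or chosen per input map by an L-curve corner scan
over a log grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import factorized
from scipy.spatial import cKDTree

from .forward import HeadModel, SourceGrid, lead_field

__all__ = [
    "DistributedInverse",
    "InverseResults",
    "SourceEstimate",
    "localization_error_benchmark",
]


def _neighbor_operator(
    grid: SourceGrid, radius: float, exponent: float, alpha: float
) -> sparse.csr_matrix:
    """A = I - alpha * W with W the row-normalized distance**exponent
    weights of neighbors within ``radius``."""
    tree = cKDTree(grid.nodes)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    n = grid.n_nodes
    if pairs.size == 0:
        raise ValueError(
            "no neighboring nodes within the radius; increase the "
            "neighborhood radius"
        )
    d = np.linalg.norm(grid.nodes[pairs[:, 0]] - grid.nodes[pairs[:, 1]], axis=1)
    w = d**exponent
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    vals = np.concatenate([w, w])
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    if np.any(rowsum == 0):
        isolated = np.where(rowsum == 0)[0]
        raise ValueError(
            f"isolated nodes with no neighbors: {isolated[:5].tolist()}...; "
            "increase the neighborhood radius"
        )
    W = sparse.diags(1.0 / rowsum) @ W
    return (sparse.identity(n) - alpha * W).tocsr()


class DistributedInverse:
    """Distributed inverse model for one head model + source grid + montage.

    Parameters
    ----------
    leadfield : (n_electrodes, 3 * n_nodes) array, node-major columns.
    grid : SourceGrid
    neighborhood_radius : float or None
        Meters; default 2.1 x grid spacing (the 26-neighbor cube plus a
        small tolerance).
    exponent : float
        Distance-law exponent of the neighbor weights; 0 gives uniform
        weights, ``None`` neighborhood -> identity prior (minimum norm).
    alpha : float
        Autoregressive damping, 0 <= alpha < 1; 0 disables the neighborhood
        term entirely (pure weighted minimum norm).
    depth_weight : float
        Depth-compensation exponent ``gamma``: the prior current variance of
        node i scales as ``||L_i||_F**(-2 gamma)``, counteracting the
        superficial bias of minimum-norm estimates; 0 disables.
    """

    def __init__(
        self,
        leadfield: np.ndarray,
        grid: SourceGrid,
        neighborhood_radius: float | None = None,
        exponent: float = -2.0,
        alpha: float = 0.5,
        depth_weight: float = 1.0,
    ):
        L = np.asarray(leadfield, dtype=float)
        if L.ndim != 2 or L.shape[1] != 3 * grid.n_nodes:
            raise ValueError("lead field shape inconsistent with grid")
        if not 0 <= alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if depth_weight < 0:
            raise ValueError("depth_weight must be >= 0")
        self.leadfield = L
        self.grid = grid
        self.exponent = float(exponent)
        self.alpha = float(alpha)
        self.depth_weight = float(depth_weight)
        self.neighborhood_radius = (
            2.1 * grid.spacing if neighborhood_radius is None else float(neighborhood_radius)
        )

    @classmethod
    def from_head_model(
        cls,
        head: HeadModel,
        grid: SourceGrid,
        montage,
        **kwargs,
    ) -> "DistributedInverse":
        return cls(lead_field(head, grid, montage), grid, **kwargs)

    def fit(self, lam: float | None = None) -> "InverseResults":
        """Precompute the inverse operator ingredients.

        ``lam`` is the Tikhonov parameter relative to the mean eigenvalue of
        the data-space Gram matrix; ``None`` defers the choice to an L-curve
        scan at apply time.
        """
        n = self.grid.n_nodes
        if self.alpha > 0:
            A = _neighbor_operator(
                self.grid, self.neighborhood_radius, self.exponent, self.alpha
            )
            M = (A.T @ A).tocsc()
            solve = factorized(M)
        else:
            solve = lambda b: b  # identity metric -> minimum norm

        n_e = self.leadfield.shape[0]
        if self.depth_weight > 0:
            colnorm2 = np.array(
                [np.sum(self.leadfield[:, 3 * i : 3 * i + 3] ** 2) for i in range(n)]
            )
            d = colnorm2 ** (-self.depth_weight / 2.0)
        else:
            d = np.ones(n)
        # K_c = D M^-1 D L_c' per moment component, Gram = sum_c L_c K_c
        K = np.empty((3, n, n_e))
        gram = np.zeros((n_e, n_e))
        for c in range(3):
            Lc = self.leadfield[:, c::3]
            Kc = d[:, None] * solve((Lc * d[None, :]).T)
            K[c] = Kc
            gram += Lc @ Kc
        evals, evecs = np.linalg.eigh(gram)
        KV = np.einsum("cne,ef->cnf", K, evecs)
        return InverseResults(
            model=self, K=K, gram=gram, evals=evals, evecs=evecs, KV=KV, lam=lam
        )


class SourceEstimate(NamedTuple):
    currents: np.ndarray  # (n_nodes, 3)
    magnitude: np.ndarray  # (n_nodes,) |J| current-density magnitude
    power: np.ndarray  # (n_nodes,) standardized (resolution-normalized) power
    peaks: tuple[int, ...]  # node indices of local maxima
    lam: float

    @property
    def peak_node(self) -> int:
        return int(np.argmax(self.power))


@dataclass
class InverseResults:
    """Fitted inverse operator; apply to scalp maps to localize sources."""

    model: DistributedInverse
    K: np.ndarray  # (3, n_nodes, n_electrodes)
    gram: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray
    KV: np.ndarray  # K rotated into the Gram eigenbasis
    lam: float | None

    def _lcurve_lambda(self, v: np.ndarray) -> float:
        """Corner of the L-curve over a log grid of relative lambdas."""
        scale = float(self.evals.mean())
        lams = scale * np.logspace(-8, 2, 41)
        beta = self.evecs.T @ v
        res, sol = [], []
        for lam in lams:
            f = beta / (self.evals + lam)
            res.append(np.linalg.norm(lam * f))  # residual ||v - G w||
            sol.append(np.linalg.norm(f))  # proxy for solution size
        lr = np.log10(np.maximum(res, 1e-300))
        ls = np.log10(np.maximum(sol, 1e-300))
        # discrete curvature of (lr, ls)
        d1r, d1s = np.gradient(lr), np.gradient(ls)
        d2r, d2s = np.gradient(d1r), np.gradient(d1s)
        curv = (d1r * d2s - d1s * d2r) / np.maximum(
            (d1r**2 + d1s**2) ** 1.5, 1e-300
        )
        return float(lams[int(np.argmax(curv))])

    def apply(
        self,
        scalp_map: np.ndarray,
        lam: float | None = None,
        peak_fraction: float = 0.5,
    ) -> SourceEstimate:
        """Invert one average-referenced scalp map.

        ``lam`` overrides the fitted/auto lambda (absolute Tikhonov value;
        the automatic L-curve choice scales by the Gram spectrum).  Peaks
        are grid-local maxima, above ``peak_fraction`` of the global
        maximum, of the *standardized* power: the current estimate at each
        node normalized by its model resolution covariance.  The
        standardization removes the location bias linear inverses show on
        the raw current magnitude.
        """
        v = np.asarray(scalp_map, dtype=float)
        if v.shape != (self.K.shape[2],):
            raise ValueError("scalp map length does not match electrode count")
        if lam is None:
            lam = self.lam
        if lam is None:
            lam = self._lcurve_lambda(v) if np.any(v) else float(self.evals.mean())
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        f = 1.0 / (self.evals + lam)
        beta = (self.evecs.T @ v) * f
        J = np.einsum("cne,e->nc", self.KV, beta)
        mag = np.linalg.norm(J, axis=1)
        # per-node 3x3 resolution covariance S_ii = (K G K')_ii
        S = np.einsum("cne,dne,e->ncd", self.KV, self.KV, f)
        power = np.einsum("nc,ncd,nd->n", J, np.linalg.pinv(S, hermitian=True), J)
        power = np.maximum(power, 0.0)
        peaks = self._local_maxima(power, peak_fraction)
        return SourceEstimate(J, mag, power, peaks, float(lam))

    def _local_maxima(self, mag: np.ndarray, frac: float) -> tuple[int, ...]:
        if not np.any(mag > 0):
            return ()
        grid = self.model.grid
        tree = cKDTree(grid.nodes)
        thresh = frac * mag.max()
        peaks = []
        for i in np.where(mag >= thresh)[0]:
            nb = tree.query_ball_point(grid.nodes[i], r=1.5 * grid.spacing)
            if mag[i] >= mag[nb].max():
                peaks.append(int(i))
        return tuple(sorted(peaks, key=lambda i: -mag[i]))


def localization_error_benchmark(
    head: HeadModel,
    grid: SourceGrid,
    montage,
    n_sources: int = 20,
    seed: int | None = 0,
    noise_sd: float = 0.0,
    lam: float | None = 1e-8,
    min_radius_fraction: float = 0.7,
    leadfield: np.ndarray | None = None,
    inverse: "InverseResults | None" = None,
) -> pd.DataFrame:
    """Forward-simulate random superficial dipoles and measure how far the
    estimated magnitude peak lands from the true node.

    ``noise_sd`` is additive sensor noise relative to the RMS of the clean
    map; ``lam`` is the regularization relative to the mean Gram eigenvalue
    (``None`` -> per-map L-curve, appropriate when noise is present).
    Returns one row per source with the true node, estimated peak and error
    in meters.
    """
    rng = np.random.default_rng(seed)
    L = lead_field(head, grid, montage) if leadfield is None else leadfield
    if inverse is None:
        inverse = DistributedInverse(L, grid).fit(lam=None)
    radii = np.linalg.norm(grid.nodes, axis=1)
    superficial = np.where(radii >= min_radius_fraction * radii.max())[0]
    rows = []
    scale = float(np.mean(inverse.evals))
    for k in range(n_sources):
        node = int(rng.choice(superficial))
        q = rng.standard_normal(3)
        q /= np.linalg.norm(q)
        v = L[:, 3 * node : 3 * node + 3] @ q
        if noise_sd > 0:
            v = v + rng.standard_normal(v.size) * noise_sd * v.std()
        v = v - v.mean()
        est = inverse.apply(v, lam=None if lam is None else lam * scale)
        peak = est.peak_node
        err = float(np.linalg.norm(grid.nodes[peak] - grid.nodes[node]))
        rows.append(
            {"source": k, "true_node": node, "peak_node": peak,
             "error_m": err, "noise_sd": noise_sd}
        )
    return pd.DataFrame(rows)
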