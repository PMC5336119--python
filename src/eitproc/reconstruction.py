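"""Desk-scale EIT image reconstruction on 2D triangular finite-element meshes.

The forward problem solves the continuum conduction equation
``div(sigma grad u) = 0`` with point current sources on boundary electrodes
(linear P1 elements); the sensitivity (Jacobian) matrix comes from the
adjoint-field identity ``J[m, e] = -int_e grad(u_drive) . grad(u_meas) dA``,
the standard result that the change in a four-terminal transfer voltage per
unit conductivity change in element e is minus the dot product of the drive
and measurement lead fields over the element. Conductivity-change images are
the zeroth-order Tikhonov estimate
``argmin ||J ds - dv||^2 + lambda ||ds||^2`` with the hyperparameter chosen
by k-fold cross-validation over measurement rows, followed by a noise-based
post-correction: each element's value is divided by the standard deviation
of reconstructions of pure measurement noise (propagated through the linear
inverse), and elements whose |z| falls below a threshold are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized

from .protocol import InjectionProtocol

__all__ = [
    "Mesh2D",
    "ForwardModel",
    "ReconResult",
    "disc_mesh",
    "tikhonov_inverse",
    "select_lambda_cv",
    "noise_correction",
]


@dataclass
class Mesh2D:
    """Triangular mesh with point electrodes on boundary nodes."""

    nodes: np.ndarray  # (n_nodes, 2), metres
    triangles: np.ndarray  # (n_elements, 3) node indices, counter-clockwise
    electrode_nodes: np.ndarray  # (n_electrodes,) node index per electrode
    conductivity: np.ndarray = None  # (n_elements,), S/m

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.electrode_nodes = np.asarray(self.electrode_nodes, dtype=int)
        if self.conductivity is None:
            self.conductivity = np.ones(len(self.triangles))
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        if np.any(self.conductivity <= 0):
            raise ValueError("conductivity must be positive")
        areas = self.areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise ValueError(
                f"triangle {bad} is degenerate or clockwise (area {areas[bad]:.3g})"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def element_diameter(self) -> float:
        """Median circumscribing diameter, the mesh's native length scale."""
        p = self.nodes[self.triangles]
        edges = np.stack(
            [
                np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
                np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
                np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
            ]
        )
        return float(np.median(edges.max(axis=0)))

    # plain-text I/O: node and element files --------------------------------
    def write(self, node_path, ele_path) -> None:
        with open(node_path, "w") as fh:
            fh.write(f"{self.n_nodes} 2\n")
            for i, (x, y) in enumerate(self.nodes):
                fh.write(f"{i} {x:.12g} {y:.12g}\n")
        with open(ele_path, "w") as fh:
            fh.write(f"{self.n_elements} 3\n")
            for i, (a, b, c) in enumerate(self.triangles):
                fh.write(f"{i} {a} {b} {c} {self.conductivity[i]:.12g}\n")

    @classmethod
    def read(cls, node_path, ele_path, electrode_nodes) -> "Mesh2D":
        with open(node_path) as fh:
            n, _ = map(int, fh.readline().split())
            nodes = np.array([list(map(float, fh.readline().split()[1:3])) for _ in range(n)])
        with open(ele_path) as fh:
            m, _ = map(int, fh.readline().split())
            tris, sigma = [], []
            for _ in range(m):
                parts = fh.readline().split()
                tris.append([int(x) for x in parts[1:4]])
                sigma.append(float(parts[4]) if len(parts) > 4 else 1.0)
        return cls(nodes, np.array(tris), np.asarray(electrode_nodes), np.array(sigma))


def disc_mesh(
    n_rings: int = 8, n_sectors: int = 16, radius: float = 0.1, n_electrodes: int = 16
) -> Mesh2D:
    """Structured triangulation of a disc with equally spaced boundary
    electrodes. ``n_sectors`` must be a multiple of ``n_electrodes``."""
    if n_sectors % n_electrodes:
        raise ValueError("n_sectors must be a multiple of n_electrodes")
    nodes = [(0.0, 0.0)]
    ring_start = [0]
    for r in range(1, n_rings + 1):
        ring_start.append(len(nodes))
        rho = radius * r / n_rings
        for s in range(n_sectors):
            th = 2 * np.pi * s / n_sectors
            nodes.append((rho * np.cos(th), rho * np.sin(th)))
    tris = []
    # innermost fan
    first = ring_start[1]
    for s in range(n_sectors):
        tris.append((0, first + s, first + (s + 1) % n_sectors))
    # ring bands
    for r in range(1, n_rings):
        a0, b0 = ring_start[r], ring_start[r + 1]
        for s in range(n_sectors):
            s1 = (s + 1) % n_sectors
            tris.append((a0 + s, b0 + s, b0 + s1))
            tris.append((a0 + s, b0 + s1, a0 + s1))
    outer = ring_start[n_rings]
    step = n_sectors // n_electrodes
    electrodes = np.array([outer + step * e for e in range(n_electrodes)])
    mesh = Mesh2D(np.array(nodes), np.array(tris), electrodes)
    return mesh


def _gradients(mesh: Mesh2D) -> tuple[np.ndarray, np.ndarray]:
    """P1 shape-function gradients: (n_elements, 3, 2) and element areas."""
    p = mesh.nodes[mesh.triangles]
    areas = mesh.areas()
    # grad of barycentric coordinate i is perpendicular to the opposite edge
    g = np.empty((mesh.n_elements, 3, 2))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        edge = p[:, k] - p[:, j]
        g[:, i, 0] = -edge[:, 1]
        g[:, i, 1] = edge[:, 0]
    g /= (2 * areas)[:, None, None]
    return g, areas


class ForwardModel:
    """Assembled FEM forward operator for a mesh and injection protocol."""

    def __init__(self, mesh: Mesh2D, protocol: InjectionProtocol):
        if protocol.n_electrodes != mesh.n_electrodes:
            raise ValueError("protocol and mesh electrode counts differ")
        self.mesh = mesh
        self.protocol = protocol
        self._grads, self._areas = _gradients(mesh)
        self._solve = None

    def _stiffness(self, conductivity: np.ndarray) -> sparse.csc_matrix:
        g, areas = self._grads, self._areas
        n = self.mesh.n_nodes
        tri = self.mesh.triangles
        rows, cols, vals = [], [], []
        coeff = conductivity * areas
        for i in range(3):
            for j in range(3):
                rows.append(tri[:, i])
                cols.append(tri[:, j])
                vals.append(coeff * np.einsum("ek,ek->e", g[:, i], g[:, j]))
        K = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsc()
        return K

    def factorize(self, conductivity: np.ndarray | None = None) -> None:
        sigma = self.mesh.conductivity if conductivity is None else np.asarray(conductivity)
        K = self._stiffness(sigma).tolil()
        # ground node 0 to remove the constant-potential null space
        K[0, :] = 0.0
        K[:, 0] = 0.0
        K[0, 0] = 1.0
        self._solve = factorized(K.tocsc())

    def _solve_current(self, rhs: np.ndarray) -> np.ndarray:
        if self._solve is None:
            self.factorize()
        rhs = rhs.copy()
        rhs[0] = 0.0
        return self._solve(rhs)

    def forward_solve(self, pair: tuple[int, int], current_a: float = 1.0) -> np.ndarray:
        """Electrode voltages (mean-zero referenced) for one injection pair.

        Kirchhoff holds by construction: +I at the source node, -I at the
        sink node, zero elsewhere.
        """
        src, sink = pair
        rhs = np.zeros(self.mesh.n_nodes)
        rhs[self.mesh.electrode_nodes[src - 1]] += current_a
        rhs[self.mesh.electrode_nodes[sink - 1]] -= current_a
        u = self._solve_current(rhs)
        v = u[self.mesh.electrode_nodes]
        return v - v.mean()

    def boundary_voltages(self, current_a: float | None = None) -> np.ndarray:
        """(n_pairs, n_electrodes) mean-zero electrode voltages for the full
        protocol at the protocol's current amplitude (or an override)."""
        amp = self.protocol.current_amplitude_a if current_a is None else current_a
        return np.stack([self.forward_solve(p, amp) for p in self.protocol.pairs])

    def measurement_fields(self) -> np.ndarray:
        """Adjoint (lead) field per electrode for the mean-zero measurement
        operator: unit current at the electrode, balanced by -1/n at all
        electrodes."""
        n_e = self.mesh.n_electrodes
        fields = np.empty((n_e, self.mesh.n_nodes))
        for e in range(n_e):
            rhs = np.zeros(self.mesh.n_nodes)
            rhs[self.mesh.electrode_nodes[e]] += 1.0
            rhs[self.mesh.electrode_nodes] -= 1.0 / n_e
            fields[e] = self._solve_current(rhs)
        return fields

    def jacobian(self, current_a: float | None = None) -> np.ndarray:
        """Sensitivity matrix (pairs*electrodes, elements), rows pair-major.

        ``J[m, e] = -int_e grad(u_drive) . grad(u_meas) dA`` so that
        ``dV_m = sum_e J[m, e] dsigma_e`` to first order.
        """
        amp = self.protocol.current_amplitude_a if current_a is None else current_a
        g, areas = self._grads, self._areas
        tri = self.mesh.triangles
        meas = self.measurement_fields()

        def elem_grad(u: np.ndarray) -> np.ndarray:
            # (n_elements, 2) gradient of a nodal field
            return np.einsum("eiv,ei->ev", g, u[tri])

        meas_grads = np.stack([elem_grad(meas[e]) for e in range(self.mesh.n_electrodes)])
        rows = []
        for pair in self.protocol.pairs:
            src, sink = pair
            rhs = np.zeros(self.mesh.n_nodes)
            rhs[self.mesh.electrode_nodes[src - 1]] += amp
            rhs[self.mesh.electrode_nodes[sink - 1]] -= amp
            u_d = self._solve_current(rhs)
            gd = elem_grad(u_d)
            for e in range(self.mesh.n_electrodes):
                rows.append(-areas * np.einsum("ev,ev->e", gd, meas_grads[e]))
        return np.stack(rows)


@dataclass
class ReconResult:
    """Tikhonov reconstruction with its hyperparameter trace and the
    noise-corrected image."""

    delta_sigma: np.ndarray
    lambda_used: float
    cv_curve: list[tuple[float, float]] = field(default_factory=list)
    corrected_delta_sigma: np.ndarray | None = None
    z_scores: np.ndarray | None = None


def tikhonov_inverse(J: np.ndarray, dv: np.ndarray, lam: float) -> np.ndarray:
    """Zeroth-order Tikhonov estimate via the regularised normal equations."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    J = np.asarray(J, dtype=float)
    A = J.T @ J + lam * np.eye(J.shape[1])
    return np.linalg.solve(A, J.T @ np.asarray(dv, dtype=float))


def default_lambda_grid(J: np.ndarray, n: int = 20) -> np.ndarray:
    scale = np.trace(J.T @ J) / J.shape[1]
    return scale * np.logspace(-8, 0, n)


def select_lambda_cv(
    J: np.ndarray,
    dv: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[float, list[tuple[float, float]]]:
    """k-fold cross-validation over measurement rows.

    For each fold the image is fitted on the training rows and scored by the
    held-out residual ``||J_test ds_train - dv_test||^2``; the lambda with
    the lowest mean score wins, ties broken towards stronger regularisation.
    Returns (lambda, cv_curve).
    """
    J = np.asarray(J, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(J)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = J.shape[0]
    if n < k_folds:
        raise ValueError(f"{n} measurements is fewer than {k_folds} folds")
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % k_folds
    scores = np.zeros(len(lambda_grid))
    for f in range(k_folds):
        test = fold == f
        Jtr, Jte = J[~test], J[test]
        dtr, dte = dv[~test], dv[test]
        JtJ = Jtr.T @ Jtr
        Jtd = Jtr.T @ dtr
        for i, lam in enumerate(lambda_grid):
            ds = np.linalg.solve(JtJ + lam * np.eye(J.shape[1]), Jtd)
            r = Jte @ ds - dte
            scores[i] += r @ r
    scores /= k_folds
    best = np.flatnonzero(scores <= scores.min() * (1 + 1e-12)).max()
    return float(lambda_grid[best]), list(zip(lambda_grid.tolist(), scores.tolist()))


def noise_correction(
    delta_sigma: np.ndarray,
    J: np.ndarray,
    noise_sd: np.ndarray,
    lam: float,
    threshold: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-based post-correction of a Tikhonov image.

    The per-measurement noise SDs are propagated through the linear inverse
    operator ``B = (J'J + lam I)^-1 J'`` to give each element's
    reconstruction-noise SD; the image is expressed as a z-score map and
    elements with |z| below the threshold are zeroed. Returns
    (corrected_delta_sigma, z_scores).
    """
    noise_sd = np.asarray(noise_sd, dtype=float)
    if np.any(noise_sd <= 0):
        raise ValueError("noise SDs must be positive for noise-based correction")
    J = np.asarray(J, dtype=float)
    if len(noise_sd) != J.shape[0]:
        raise ValueError("one noise SD per measurement is required")
    B = np.linalg.solve(J.T @ J + lam * np.eye(J.shape[1]), J.T)
    elem_sd = np.sqrt((B**2) @ noise_sd**2)
    z = delta_sigma / elem_sd
    corrected = np.where(np.abs(z) >= threshold, delta_sigma, 0.0)
    return corrected, z


def reconstruct(
    J: np.ndarray,
    dv: np.ndarray,
    noise_sd: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 10,
    seed: int = 0,
    z_threshold: float = 3.0,
) -> ReconResult:
    """Convenience wrapper: cross-validate lambda, invert, and (when noise
    estimates are available) apply the noise-based correction."""
    lam, curve = select_lambda_cv(J, dv, lambda_grid, k_folds, seed)
    ds = tikhonov_inverse(J, dv, lam)
    result = ReconResult(ds, lam, curve)
    if noise_sd is not None:
        result.corrected_delta_sigma, result.z_scores = noise_correction(
            ds, J, noise_sd, lam, z_threshold
        )
    return result


def export_element_values(mesh: Mesh2D, values: np.ndarray, path) -> None:
    """Element-value CSV: centroid coordinates and the value per element."""
    cent = mesh.centroids()
    with open(path, "w") as fh:
        fh.write("element,x,y,value\n")
        for i, ((x, y), v) in enumerate(zip(cent, values)):
            fh.write(f"{i},{x:.8g},{y:.8g},{v:.8g}\n")
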