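"""Generalized Procrustes analysis with sliding semilandmarks.

Implements partial Procrustes superimposition (translation, unit centroid
size, optimal rotation with det +1) with optional orthogonal tangent-space
projection, the thin-plate-spline bending-energy matrix, and the classic
minimum-bending-energy sliding of semilandmarks along outline tangents.

Reflections are never produced by the alignment itself; right-side
configurations must be mirrored beforehand with ``landmark_io.reflect``,
mirroring the workflow in which right opercle images are reflected prior
to digitizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkConfiguration

__all__ = [
    "BendingEnergyModel",
    "AlignedDataset",
    "centroid_size",
    "bending_energy_model",
    "gpa",
    "slide_and_align",
    "procrustes_distance",
    "average_sides",
]


def centroid_size(config) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 points")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BendingEnergyModel:
    """Bending-energy quadratic form of a 2D reference configuration.

    ``energy_matrix`` is the k x k symmetric positive-semidefinite matrix B
    such that the bending energy of a target with coordinate columns
    (tx, ty) is tx' B tx + ty' B ty. B annihilates affine terms
    (B 1 = B x_ref = B y_ref = 0), so affine deformations cost nothing.
    """

    reference: np.ndarray
    energy_matrix: np.ndarray

    def energy(self, target: np.ndarray) -> float:
        t = np.asarray(target, float)
        B = self.energy_matrix
        return float(t[:, 0] @ B @ t[:, 0] + t[:, 1] @ B @ t[:, 1])


def bending_energy_model(reference) -> BendingEnergyModel:
    """Assemble the thin-plate-spline bending-energy matrix of a reference.

    Uses the kernel U(r) = r^2 log r (with U(0) = 0), augments with the
    affine block Q = [1 | x | y], inverts the bordered system and returns
    the upper-left k x k block.
    """
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    k = ref.shape[0]
    if k < 3:
        raise ValueError("bending energy needs at least 3 landmarks")
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    off = d.copy()
    np.fill_diagonal(off, np.inf)
    if off.min() == 0.0:
        raise ValueError("duplicate landmarks: singular thin-plate-spline kernel")
    K = d**2 * np.log(d + np.eye(k))  # U(r) = r^2 log r, U(0) = 0
    np.fill_diagonal(K, 0.0)
    Q = np.column_stack([np.ones(k), ref[:, 0], ref[:, 1]])
    if np.linalg.matrix_rank(Q, tol=1e-10 * max(1.0, np.abs(ref).max())) < 3:
        raise ValueError("collinear reference: thin-plate spline undefined")
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        L_inv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular bordered thin-plate-spline system") from exc
    B = L_inv[:k, :k]
    B = 0.5 * (B + B.T)
    return BendingEnergyModel(reference=ref.copy(), energy_matrix=B)


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignedDataset:
    """Jointly superimposed configurations in a common shape space.

    ``shapes`` holds the aligned (n, k, 2) coordinates; ``centroid_sizes``
    the sizes of the original configurations; ``consensus`` the unit-size
    mean shape the dataset converged to.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    converged: bool
    slid: bool = False
    fixed_index: int = 0
    closed: bool = True

    @property
    def n(self) -> int:
        return int(self.shapes.shape[0])

    @property
    def k(self) -> int:
        return int(self.shapes.shape[1])

    def flat(self) -> np.ndarray:
        """Shapes as an (n, 2k) matrix, x-coordinates then y-coordinates."""
        return np.concatenate([self.shapes[:, :, 0], self.shapes[:, :, 1]], axis=1)


def _preshape(coords: np.ndarray) -> np.ndarray:
    """Center and scale a configuration to unit centroid size."""
    c = coords - coords.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1 only) minimizing ||source @ R - target||_F.

    Both inputs are centered (k, 2) configurations.
    """
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, sign])
    return U @ D @ Vt


def _tangent_project(shapes: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent space at the consensus."""
    c = consensus.ravel()
    c = c / np.linalg.norm(c)
    flat = shapes.reshape(shapes.shape[0], -1)
    coeff = flat @ c - 1.0
    return (flat - coeff[:, None] * c).reshape(shapes.shape)


def _extract(configs):
    coords = []
    fixed_index = None
    closed = None
    for cfg in configs:
        if isinstance(cfg, LandmarkConfiguration):
            coords.append(cfg.coords)
            fi, cl = cfg.fixed_index, cfg.closed
        else:
            coords.append(np.asarray(cfg, float))
            fi, cl = 0, True
        if fixed_index is None:
            fixed_index, closed = fi, cl
        elif fi != fixed_index:
            raise ValueError("all configurations must share fixed_index")
    ks = {c.shape[0] for c in coords}
    if len(ks) != 1:
        raise ValueError(f"mixed landmark counts: {sorted(ks)}")
    return np.stack(coords), fixed_index, closed


def gpa(
    configs,
    *,
    project_tangent: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes analysis: remove translation, scale, rotation.

    Iteratively rotates unit-size centered configurations onto the running
    consensus (mean shape, re-scaled to unit centroid size) until the
    consensus moves less than ``tol`` (root summed squared difference).
    With ``project_tangent`` the aligned shapes are finally projected
    orthogonally into the tangent space at the consensus.
    """
    coords, fixed_index, closed = _extract(configs)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in coords])
    shapes = np.stack([_preshape(c) for c in coords])

    consensus = shapes[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus = _preshape(new_consensus)
        # align consensus orientation to previous to measure drift only
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    aligned = shapes
    if project_tangent:
        aligned = _tangent_project(aligned, consensus)
    return AlignedDataset(
        shapes=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=iterations,
        converged=converged,
        slid=False,
        fixed_index=fixed_index,
        closed=closed,
    )


# ---------------------------------------------------------------------------
# Sliding semilandmarks (minimum bending energy)
# ---------------------------------------------------------------------------

def _tangent_directions(shape: np.ndarray, sliders: np.ndarray, closed: bool):
    """Unit tangent at each slider from its outline neighbors i-1, i+1.

    Returns (directions, frozen_mask); a slider whose neighbors coincide has
    no defined tangent and is frozen for the iteration.
    """
    k = shape.shape[0]
    prev_idx = (sliders - 1) % k
    next_idx = (sliders + 1) % k
    if not closed:
        prev_idx = np.clip(sliders - 1, 0, k - 1)
        next_idx = np.clip(sliders + 1, 0, k - 1)
    tangents = shape[next_idx] - shape[prev_idx]
    norms = np.linalg.norm(tangents, axis=1)
    frozen = norms < 1e-12
    safe = np.where(frozen, 1.0, norms)
    return tangents / safe[:, None], frozen


def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    B: np.ndarray,
    sliders: np.ndarray,
    closed: bool,
) -> np.ndarray:
    """One minimum-bending-energy sliding step of a single specimen.

    Moves each slider along its outline tangent so that the bending energy
    of the deviation from the consensus is minimized:
    t* = -(T'ET)^{-1} T'E (y - ybar) with E = blockdiag(B, B).
    """
    k = shape.shape[0]
    directions, frozen = _tangent_directions(shape, sliders, closed)
    active = sliders[~frozen]
    if frozen.any():
        warnings.warn(
            f"{int(frozen.sum())} slider(s) frozen: coincident neighbors",
            stacklevel=2,
        )
    if active.size == 0:
        return shape
    u = directions[~frozen]
    m = active.size
    y = np.concatenate([shape[:, 0], shape[:, 1]])
    ybar = np.concatenate([consensus[:, 0], consensus[:, 1]])
    # T is 2k x m with disjoint support: column j has u_x at row active_j,
    # u_y at row k + active_j.  Form T'E and T'ET without materializing T.
    # (T'E)_{j,:} = u_x_j * E[active_j,:] + u_y_j * E[k+active_j,:]
    TtE = u[:, 0:1] * np.concatenate([B[active], np.zeros((m, k))], axis=1) + \
        u[:, 1:2] * np.concatenate([np.zeros((m, k)), B[active]], axis=1)
    TtET = (u[:, 0:1] * B[np.ix_(active, active)] * u[:, 0][None, :]) + \
        (u[:, 1:2] * B[np.ix_(active, active)] * u[:, 1][None, :])
    rhs = TtE @ (y - ybar)
    try:
        t_star = -np.linalg.solve(TtET, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular sliding system; using pseudoinverse", stacklevel=2)
        t_star = -np.linalg.pinv(TtET) @ rhs
    out = shape.copy()
    out[active, 0] += t_star * u[:, 0]
    out[active, 1] += t_star * u[:, 1]
    return out


def slide_and_align(
    configs,
    fixed_indices=None,
    closed: bool | None = None,
    *,
    project_tangent: bool = True,
    tol: float = 1e-8,
    max_outer: int = 10,
    gpa_tol: float = 1e-10,
) -> AlignedDataset:
    """GPA with semilandmarks sliding to minimize bending energy.

    Outer loop: run GPA; build the bending-energy model from the current
    consensus; slide every specimen's semilandmarks along their outline
    tangents toward minimum bending energy relative to the consensus;
    re-run GPA. Stops when the consensus moves less than ``tol`` or after
    ``max_outer`` iterations. The fixed landmark(s) never move.
    """
    coords, default_fixed, default_closed = _extract(configs)
    if fixed_indices is None:
        fixed_indices = {default_fixed}
    fixed_indices = set(int(i) for i in fixed_indices)
    if closed is None:
        closed = default_closed
    k = coords.shape[1]
    sliders = np.array([i for i in range(k) if i not in fixed_indices], dtype=int)

    aligned = gpa(coords, project_tangent=False, tol=gpa_tol)
    consensus = aligned.consensus
    outer = 0
    converged = False
    for outer in range(1, max_outer + 1):
        model = bending_energy_model(consensus)
        B = model.energy_matrix
        slid = np.stack(
            [
                _slide_one(aligned.shapes[i], consensus, B, sliders, closed)
                for i in range(aligned.n)
            ]
        )
        aligned = gpa(slid, project_tangent=False, tol=gpa_tol)
        # keep original sizes: sliding operates on unit-size aligned shapes
        delta = float(np.sqrt(np.sum((aligned.consensus - consensus) ** 2)))
        consensus = aligned.consensus
        if delta < tol:
            converged = True
            break

    shapes = aligned.shapes
    if project_tangent:
        shapes = _tangent_project(shapes, consensus)
    sizes = np.array([centroid_size(c) for c in coords])
    return AlignedDataset(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=outer,
        converged=converged,
        slid=True,
        fixed_index=default_fixed,
        closed=closed,
    )


# ---------------------------------------------------------------------------
# Distances and side averaging
# ---------------------------------------------------------------------------

def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the aligned coordinate-vector difference.

    The partial Procrustes distance in the common aligned frame; the unit
    of shape change used for axis visualizations and group contrasts.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def average_sides(aligned: AlignedDataset, specimen_ids, sides):
    """Average left/right aligned shapes and centroid sizes per specimen.

    Specimens with both sides get the arithmetic mean of aligned coordinates
    and of centroid sizes; one-sided specimens pass through. Returns
    ``(shapes, sizes, specimen_order)`` with one entry per specimen, in
    first-appearance order.
    """
    specimen_ids = list(specimen_ids)
    if len(specimen_ids) != aligned.n or len(list(sides)) != aligned.n:
        raise ValueError("specimen_ids/sides length must match dataset size")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, sid in enumerate(specimen_ids):
        if sid not in members:
            members[sid] = []
            order.append(sid)
        members[sid].append(i)
    shapes = np.empty((len(order), aligned.k, 2))
    sizes = np.empty(len(order))
    for j, sid in enumerate(order):
        idx = members[sid]
        if len(idx) == 0:
            raise ValueError(f"specimen {sid} has no sides")
        shapes[j] = aligned.shapes[idx].mean(axis=0)
        sizes[j] = aligned.centroid_sizes[idx].mean()
    return shapes, sizes, order
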