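"""Rotation/translation-invariant pair featurization of 3D molecules.

A molecule's Cartesian coordinates are converted into two pairwise views that
are invariant under any rigid motion of the whole structure:

* a **distance matrix** ``D`` with ``D[i, j] = ||x_i - x_j||``;
* a **spatial position matrix** ``P`` where ``P[i, j]`` gives the coordinates
  of atom *j* expressed in an orthonormal local frame attached to atom *i*.

The local frame of atom *i* is built from its chain neighbours
``(i-1, i, i+1)``: difference vectors ``v1 = x_i - x_{i-1}`` and
``v2 = x_{i+1} - x_i`` are orthogonalized by Gram–Schmidt.  The third stencil
difference ``v3 = x_{i+1} - x_{i-1}`` equals ``v1 + v2`` identically, so its
Gram–Schmidt residual vanishes; a full right-handed frame therefore needs the
cross product ``u1 × u2`` as its third axis (see :func:`build_local_frame`).

Both matrices are discretized into integer bins and embedded into the initial
pair representation that seeds the attention bias of the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vocab import CLS

__all__ = [
    "Molecule",
    "PairFeatures",
    "BinningScheme",
    "compute_distance_matrix",
    "build_local_frame",
    "gram_schmidt_stencil",
    "compute_spatial_position_matrix",
    "discretize_pair_features",
    "featurize",
]

#: frames whose first two stencil vectors are this close to collinear
#: (by sine of the enclosed angle) fall back to the canonical world frame
COLLINEAR_TOL = 1e-6

CANONICAL_FRAME = np.eye(3)


@dataclass
class Molecule:
    """A small molecule: typed atoms with 3D coordinates in Å.

    ``atom_types`` holds vocabulary tokens (element symbols, possibly
    ``[UNK]``/``[MASK]``); ``coords`` is an ``(m, 3)`` float array.  The atom
    order of the input file is kept and acts as the chain along which local
    frames are built, so featurization is reproducible for a given file.
    """

    atom_types: list[str]
    coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (m, 3), got {self.coords.shape}")
        if len(self.atom_types) != self.coords.shape[0]:
            raise ValueError("atom_types and coords length mismatch")
        if self.coords.shape[0] < 1:
            raise ValueError("molecule must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def validate_geometry(self, min_dist: float = 0.5) -> None:
        """Raise if two atoms sit closer than ``min_dist`` Å (clashed input)."""
        if self.n_atoms > 1:
            d = compute_distance_matrix(self.coords)
            off = d[~np.eye(self.n_atoms, dtype=bool)]
            if off.min() < min_dist:
                raise ValueError(f"atoms closer than {min_dist} Å: {off.min():.3f}")


@dataclass
class BinningScheme:
    """Discretization grid for distances and signed local-frame positions.

    Distances use uniform ``dist_width`` Å bins over ``[0, dist_max)`` plus one
    overflow bin.  Each signed position axis uses uniform ``pos_width`` Å bins
    over ``[-pos_max, pos_max)`` plus an underflow and an overflow bin.  The
    defaults (0.5 Å / 16 Å and 1 Å / 10 Å) cover drug-like molecular extents.
    """

    dist_width: float = 0.5
    dist_max: float = 16.0
    pos_width: float = 1.0
    pos_max: float = 10.0

    @property
    def n_dist_bins(self) -> int:
        # interior bins + overflow
        return int(round(self.dist_max / self.dist_width)) + 1

    @property
    def n_pos_bins(self) -> int:
        # underflow + interior + overflow
        return 2 * int(round(self.pos_max / self.pos_width)) + 2

    def to_dict(self) -> dict:
        return {
            "dist_width": self.dist_width,
            "dist_max": self.dist_max,
            "pos_width": self.pos_width,
            "pos_max": self.pos_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(**d)


@dataclass
class PairFeatures:
    """Invariant pair features of one (optionally [CLS]-prefixed) molecule."""

    D: np.ndarray  # (m', m') distances, Å
    P: np.ndarray  # (m', m', 3) local-frame positions, Å
    D_bins: np.ndarray  # (m', m') int
    P_bins: np.ndarray  # (m', m', 3) int
    degenerate_frames: np.ndarray = field(default=None)  # (m',) bool
    has_cls: bool = False

    @property
    def n_tokens(self) -> int:
        return self.D.shape[0]


def compute_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix of an ``(m, 3)`` coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be (m, 3), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    # enforce exact symmetry and zero diagonal against fp noise
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def _stencil_indices(i: int, m: int) -> tuple[int, int, int]:
    """Neighbour stencil (prev, i, next) with mirrored ends.

    Interior atoms use ``(i-1, i, i+1)``.  Atom 0 borrows the forward pair
    ``(0, 1, 2)`` and the last atom the backward pair, so every atom of a
    molecule with at least three atoms gets a well-defined stencil.
    """
    if m < 3:
        raise ValueError("stencil needs at least 3 atoms")
    if i == 0:
        return 0, 1, 2
    if i == m - 1:
        return m - 3, m - 2, m - 1
    return i - 1, i, i + 1


def gram_schmidt_stencil(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray):
    """Literal Gram–Schmidt of the stencil vectors ``(v1, v2, v3)``.

    Returns ``(u1, u2, u3)`` *unnormalized*.  Because ``v3 = v1 + v2`` by
    construction, ``u3`` is analytically zero; it is returned so callers (and
    tests) can verify the identity numerically.
    """
    u1 = np.asarray(v1, dtype=float)
    u2 = v2 - (v2 @ u1) / (u1 @ u1) * u1
    n2 = u2 @ u2
    if n2 < 1e-300:
        u3 = v3 - (v3 @ u1) / (u1 @ u1) * u1
    else:
        u3 = v3 - (v3 @ u1) / (u1 @ u1) * u1 - (v3 @ u2) / n2 * u2
    return u1, u2, u3


def build_local_frame(coords: np.ndarray, i: int) -> tuple[np.ndarray, bool]:
    """Orthonormal right-handed frame for atom ``i``.

    Rows are the frame axes: ``u1/|u1|``, ``u2/|u2|`` from Gram–Schmidt of the
    neighbour differences, and their cross product.  Returns
    ``(frame, degenerate)`` where ``degenerate`` flags collinear stencils (and
    molecules with fewer than three atoms) that fall back to the canonical
    world frame.
    """
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    if m < 2:
        raise ValueError("frames need at least 2 atoms")
    if m < 3:
        return CANONICAL_FRAME.copy(), True
    a, b, c = _stencil_indices(i, m)
    v1 = coords[b] - coords[a]
    v2 = coords[c] - coords[b]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return CANONICAL_FRAME.copy(), True
    # sine of the angle between v1 and v2 detects collinearity
    cross = np.cross(v1, v2)
    if np.linalg.norm(cross) / (n1 * n2) < COLLINEAR_TOL:
        return CANONICAL_FRAME.copy(), True
    u1, u2, _ = gram_schmidt_stencil(v1, v2, v1 + v2)
    e1 = u1 / np.linalg.norm(u1)
    e2 = u2 / np.linalg.norm(u2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3]), False


def compute_spatial_position_matrix(coords: np.ndarray):
    """Positions of every atom in every other atom's local frame.

    Returns ``(P, degenerate)`` where ``P[i, j] = frame_i @ (x_j - x_i)`` and
    ``degenerate[i]`` marks atoms whose frame fell back to the world frame.
    ``P`` is rigid-motion invariant wherever the frame is non-degenerate, and
    ``||P[i, j]|| == D[i, j]`` always (frames are orthonormal).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be (m, 3), got {coords.shape}")
    m = coords.shape[0]
    P = np.zeros((m, m, 3))
    degenerate = np.zeros(m, dtype=bool)
    if m == 1:
        return P, degenerate
    for i in range(m):
        frame, degenerate[i] = build_local_frame(coords, i)
        P[i] = (coords - coords[i]) @ frame.T
        P[i, i] = 0.0
    return P, degenerate


def discretize_pair_features(
    D: np.ndarray, P: np.ndarray, scheme: BinningScheme | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Map distances and signed positions onto integer bin grids.

    Distance ``d`` goes to ``floor(d / width)`` clamped to the overflow bin;
    position component ``p`` goes to ``floor((p + pos_max) / width) + 1`` with
    bin 0 reserved for underflow and the last bin for overflow.
    """
    scheme = scheme or BinningScheme()
    D = np.asarray(D, dtype=float)
    P = np.asarray(P, dtype=float)
    # tiny epsilon inside the floor: values analytically *on* an edge (e.g.
    # the identically-zero in-plane components of stencil neighbours) must
    # bin identically under floating-point jitter from rigid motions
    eps = 1e-9
    n_interior_d = scheme.n_dist_bins - 1
    D_bins = np.floor(D / scheme.dist_width + eps).astype(int)
    D_bins = np.clip(D_bins, 0, n_interior_d)
    n_interior_p = scheme.n_pos_bins - 2
    P_bins = np.floor((P + scheme.pos_max) / scheme.pos_width + eps).astype(int) + 1
    P_bins = np.clip(P_bins, 0, n_interior_p + 1)
    return D_bins, P_bins


def featurize(
    molecule: Molecule,
    scheme: BinningScheme | None = None,
    include_cls: bool = True,
) -> PairFeatures:
    """Full invariant featurization of one molecule.

    With ``include_cls`` a summary token is prepended whose coordinates are
    the centroid of all atoms; distances to and from it are computed like any
    other atom's.  Rows whose frame is degenerate (collinear stencil, tiny
    molecules, and the [CLS] token itself, which has no chain neighbours)
    would otherwise express positions in the world frame and leak the global
    orientation, so their position vectors are zeroed here: the feature
    tensor stays rigid-motion invariant and the pairwise geometry of such
    rows is still fully described by the distance matrix.
    """
    scheme = scheme or BinningScheme()
    coords = molecule.coords
    if include_cls:
        centroid = coords.mean(axis=0, keepdims=True)
        ext = np.concatenate([centroid, coords], axis=0)
    else:
        ext = coords
    m = ext.shape[0]
    D = compute_distance_matrix(ext)
    if m == 1:
        P = np.zeros((1, 1, 3))
        degenerate = np.ones(1, dtype=bool)
    elif include_cls:
        # atom frames are built on the *atom* chain only; [CLS] (row 0) uses
        # the canonical frame
        P = np.zeros((m, m, 3))
        degenerate = np.zeros(m, dtype=bool)
        degenerate[0] = True
        P[0] = ext - ext[0]
        P[0, 0] = 0.0
        n_atoms = molecule.n_atoms
        if n_atoms == 1:
            degenerate[1] = True
            P[1] = ext - ext[1]
            P[1, 1] = 0.0
        else:
            for a in range(n_atoms):
                frame, deg = build_local_frame(coords, a)
                degenerate[a + 1] = deg
                P[a + 1] = (ext - ext[a + 1]) @ frame.T
                P[a + 1, a + 1] = 0.0
    else:
        if molecule.n_atoms == 1:
            P = np.zeros((1, 1, 3))
            degenerate = np.ones(1, dtype=bool)
        else:
            P, degenerate = compute_spatial_position_matrix(coords)
    P[degenerate] = 0.0
    D_bins, P_bins = discretize_pair_features(D, P, scheme)
    return PairFeatures(
        D=D, P=P, D_bins=D_bins, P_bins=P_bins,
        degenerate_frames=degenerate, has_cls=include_cls,
    )
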