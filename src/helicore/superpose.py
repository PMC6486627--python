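"""Weighted least-squares rigid superposition and transform decomposition.

The superposition is the classical Kabsch solution: translate both point
sets to their (weighted) centroids, take the SVD of the weighted covariance
matrix, and correct an improper rotation by flipping the sign of the
smallest singular direction so that only proper rotations (det = +1) are
ever returned.

The decomposition recovers the axis-angle form of a rotation matrix (angle
from the trace, axis as the unit eigenvector for eigenvalue 1, sign fixed so
the angle lies in [0, 180] degrees) and the displacement of a named
reference point, e.g. a domain centre of mass, under the full transform.
This is the machinery behind statements like "the mobile domain is rotated
by 19 degrees about an axis close to its centre of mass, which is displaced
by only 1.8 A".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AtomSet

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "TransformDecomposition",
    "pair_common_atoms",
    "kabsch_fit",
    "center_of_mass",
    "decompose_transform",
    "rotation_from_axis_angle",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with R a proper rotation."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det < 0) is not allowed")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    pairing: list[tuple]      # matched (seqid, icode, atom name) keys


@dataclass(frozen=True)
class TransformDecomposition:
    angle_deg: float          # in [0, 180]
    axis: np.ndarray          # unit vector
    point_displacement: float # |T(p) - p| in Angstrom


def pair_common_atoms(a: AtomSet, b: AtomSet,
                      mode: str = "by-residue-number",
                      equivalence: dict[int, int] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, list[tuple], np.ndarray]:
    """Match atoms present in both sets and return paired coordinate arrays.

    ``by-residue-number`` pairs on identical (seqid, icode, atom name) keys.
    ``by-alignment`` first maps A's residue numbers through ``equivalence``
    (a -> b residue-number table, for cross-protein comparisons).

    Returns (coords_a, coords_b, keys, masses) with deterministic order
    (sorted by residue number then atom name).  Raises if fewer than 3
    atoms match.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot pair empty atom sets")
    if mode == "by-alignment":
        if equivalence is None:
            raise ValueError("by-alignment mode needs an equivalence table")
        a_keys = {}
        for i, (seq, ic, name) in enumerate(a.keys):
            if seq in equivalence:
                a_keys[(equivalence[seq], ic, name)] = i
    elif mode == "by-residue-number":
        a_keys = {k: i for i, k in enumerate(a.keys)}
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")

    b_keys = {k: i for i, k in enumerate(b.keys)}
    common = sorted(set(a_keys) & set(b_keys))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common atoms between "
            f"{a.structure_id}/{a.chain_id} and {b.structure_id}/{b.chain_id}"
            " (need >= 3)")
    ia = [a_keys[k] for k in common]
    ib = [b_keys[k] for k in common]
    masses = a.masses[ia]
    return a.coords[ia], b.coords[ib], common, masses


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray,
               weights: np.ndarray | None = None,
               pairing: list[tuple] | None = None) -> SuperpositionResult:
    """Least-squares fit of A onto B: find the rigid T minimising
    sum_i w_i |T(a_i) - b_i|^2.

    Degenerate inputs (all pairs collinear) raise rather than silently
    returning a reflection or an ill-conditioned rotation.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("paired coordinate arrays must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    ca = w @ A
    cb = w @ B
    A0 = A - ca
    B0 = B - cb
    H = (A0 * w[:, None]).T @ B0
    U, S, Vt = np.linalg.svd(H)
    # collinearity: at most one significant singular value
    scale = max(S[0], 1e-30)
    if S[1] / scale < 1e-9:
        raise ValueError("degenerate (collinear) atom pairs: "
                         "rotation is not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    resid = transform.apply(A) - B
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", resid, resid))))
    return SuperpositionResult(transform, rmsd, n, list(pairing or []))


def center_of_mass(atoms: AtomSet | np.ndarray,
                   weighting: str = "uniform") -> np.ndarray:
    """Weighted mean position; ``weighting`` is 'uniform' or 'atomic-mass'."""
    if isinstance(atoms, AtomSet):
        coords = atoms.coords
        masses = atoms.masses
    else:
        coords = np.asarray(atoms, dtype=float)
        masses = np.ones(len(coords))
    if len(coords) == 0:
        raise ValueError("centre of mass of an empty atom set")
    if weighting == "uniform":
        return coords.mean(axis=0)
    if weighting == "atomic-mass":
        return (masses[:, None] * coords).sum(axis=0) / masses.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def rotation_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle in degrees."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]],
                  [k[2], 0, -k[0]],
                  [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def decompose_transform(t: RigidTransform,
                        reference_point: np.ndarray) -> TransformDecomposition:
    """Axis-angle decomposition plus displacement of a reference point.

    The angle comes from the rotation-matrix trace (clipped into [-1, 1]
    against round-off); the axis is the eigenvector for eigenvalue 1 of R,
    with its sign fixed from the antisymmetric part so the angle is
    reported in [0, 180] degrees.  For angles near 0 the axis is
    ill-defined and a unit z vector is returned by convention.
    """
    R = t.rotation
    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_th)))

    if angle < 1e-7:
        axis = np.array([0.0, 0.0, 1.0])
    elif angle > 180.0 - 1e-7:
        # axis from the symmetric part: R = 2 a a^T - I
        M = (R + np.eye(3)) / 2.0
        axis = M[:, int(np.argmax(np.diag(M)))]
        axis = axis / np.linalg.norm(axis)
    else:
        v = np.array([R[2, 1] - R[1, 2],
                      R[0, 2] - R[2, 0],
                      R[1, 0] - R[0, 1]])
        axis = v / np.linalg.norm(v)

    p = np.asarray(reference_point, dtype=float)
    disp = float(np.linalg.norm(t.apply(p) - p))
    return TransformDecomposition(angle, axis, disp)
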