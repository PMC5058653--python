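"""Optimal rigid-body superposition (Kabsch) and RMSD.

Fit and measure selections are deliberately separate: clustering uses a
backbone fit with a backbone measure, while cross-ensemble comparison
superposes on the mapped backbone and measures over all mapped heavy
atoms.  No mass or occupancy weighting; every atom counts equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Conformer, Ensemble, StructureError, select_atoms


class DegenerateInputError(StructureError):
    """Too few or collinear points: the rotation is not determined."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares optimal proper rotation+translation mapping mobile onto
    target (SVD of the covariance; reflections corrected by a sign flip)."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise StructureError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError("need at least 3 points")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    a = mobile - cm
    b = target - ct
    # collinear points leave a rotation degree of freedom undetermined
    if (np.linalg.svd(a, compute_uv=False)[1] < 1e-8
            or np.linalg.svd(b, compute_uv=False)[1] < 1e-8):
        raise DegenerateInputError("points are (near-)collinear")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ct - rotation @ cm
    return RigidTransform(rotation, translation)


def rmsd_coords(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD of two already-superposed coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray,
                    fit_idx: np.ndarray, measure_idx: np.ndarray) -> float:
    """Superpose on ``fit_idx``, measure RMSD over ``measure_idx``."""
    transform = kabsch(mobile[fit_idx], target[fit_idx])
    return rmsd_coords(transform.apply(mobile[measure_idx]),
                       target[measure_idx])


def rmsd(a: Conformer, b: Conformer, fit_selection: np.ndarray,
         measure_selection: np.ndarray) -> float:
    """RMSD (A) between two conformers after optimal superposition.

    ``fit_selection`` and ``measure_selection`` are index arrays referring
    to corresponding atoms in both conformers.
    """
    fit_idx = np.asarray(fit_selection, dtype=int)
    measure_idx = np.asarray(measure_selection, dtype=int)
    if fit_idx.size == 0 or measure_idx.size == 0:
        raise StructureError("fit and measure selections must be non-empty")
    for idx in (fit_idx, measure_idx):
        if idx.max() >= a.n_atoms or idx.max() >= b.n_atoms:
            raise StructureError("selection index out of range")
    return superposed_rmsd(a.coords, b.coords, fit_idx, measure_idx)


def batched_rmsd_matrix(coords_a: np.ndarray, coords_b: np.ndarray,
                        fit_idx: np.ndarray,
                        measure_idx: np.ndarray) -> np.ndarray:
    """All-against-all superposed RMSD between two coordinate stacks.

    ``coords_a`` is (P, n, 3), ``coords_b`` is (Q, n, 3); the same index
    arrays apply to both (shared topology).  Kabsch rotations for all P*Q
    pairs are obtained from a batched 3x3 SVD; the measured RMSD uses the
    closed form |A|^2 + |B|^2 - 2 tr(R H) on fit-centred coordinates.
    """
    fa = coords_a[:, fit_idx, :]
    fb = coords_b[:, fit_idx, :]
    cm_a = fa.mean(axis=1)
    cm_b = fb.mean(axis=1)
    fa = fa - cm_a[:, None, :]
    fb = fb - cm_b[:, None, :]
    ma = coords_a[:, measure_idx, :] - cm_a[:, None, :]
    mb = coords_b[:, measure_idx, :] - cm_b[:, None, :]

    # covariance H = A^T B of the fit selections for every (p, q) pair
    h = np.einsum("pai,qaj->pqij", fa, fb)
    u, _, vt = np.linalg.svd(h)
    # rotation R = V diag(1,1,d) U^T, d = sign(det(V U^T))
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    flip = np.broadcast_to(np.eye(3), u.shape).copy()
    flip[..., 2, 2] = d
    r = np.einsum("pqji,pqjk,pqlk->pqil", vt, flip, u)

    hm = np.einsum("pai,qaj->pqij", ma, mb)
    n_m = measure_idx.size
    sq_a = np.sum(ma ** 2, axis=(1, 2))
    sq_b = np.sum(mb ** 2, axis=(1, 2))
    # sum_a B_a . (R A_a) = sum_ij R_ij (Hm)_ji = tr(R Hm)
    cross = np.einsum("pqij,pqji->pq", r, hm)
    msd = (sq_a[:, None] + sq_b[None, :] - 2.0 * cross) / n_m
    return np.sqrt(np.clip(msd, 0.0, None))


def align_ensemble(ensemble: Ensemble, fit_selection: str = "backbone"):
    """Iteratively superpose all frames onto a converged mean structure.

    The mean is initialised to frame 1; frames are superposed onto it and
    the mean recomputed until the maximum mean-coordinate shift drops
    below 1e-6 A or 10 iterations are reached.  Returns the aligned
    ensemble and the mean conformer.
    """
    if ensemble.n_frames < 2:
        raise StructureError("alignment needs at least 2 frames")
    template = ensemble.frames[0]
    fit_idx = select_atoms(template, fit_selection)
    coords = ensemble.coords.copy()
    mean = coords[0].copy()
    for _ in range(10):
        for f in range(coords.shape[0]):
            transform = kabsch(coords[f][fit_idx], mean[fit_idx])
            coords[f] = transform.apply(coords[f])
        new_mean = coords.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < 1e-6:
            break
    aligned = ensemble.with_coords(coords, label=f"{ensemble.label}|aligned")
    return aligned, template.with_coords(mean)
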