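"""Trajectory analyses: residue fluctuation, RMSD matrices, clustering.

Residue fluctuation analysis (RFA) is the per-residue RMSF of an ensemble
aligned to its converged mean (backbone fit); the default basis is the CA
atom, with a residue-heavy-atom option.  Conformers are clustered by
average-linkage agglomeration on the backbone RMSD matrix with a merge
cutoff (default 2.0 A); each cluster is represented by its medoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    Conformer,
    Ensemble,
    ResidueRange,
    StructureError,
    select_atoms,
)
from .superposition import align_ensemble, batched_rmsd_matrix


@dataclass
class FluctuationProfile:
    """Per-residue RMSF (A) of an aligned ensemble."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray
    atom_basis: str = "calpha"

    def as_dict(self) -> dict:
        return {int(r): float(v)
                for r, v in zip(self.residue_numbers, self.rmsf)}

    def mean_over(self, residues: ResidueRange) -> float:
        mask = np.array([int(r) in residues for r in self.residue_numbers])
        if not mask.any():
            raise StructureError(f"no residues in range {residues}")
        return float(self.rmsf[mask].mean())


@dataclass
class RmsdMatrix:
    """RMSD values (A) between frames of one or two ensembles."""

    values: np.ndarray
    labels_a: list
    labels_b: list
    fit: str = "backbone"
    measure: str = "backbone"

    @property
    def is_self(self) -> bool:
        return self.labels_a == self.labels_b

    @property
    def n_entries(self) -> int:
        return int(self.values.size)


@dataclass
class Clustering:
    """Flat partition of frames with medoid representatives."""

    assignment: dict
    cutoff: float
    linkage: str = "average"
    representatives: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list:
        return sorted(f for f, c in self.assignment.items()
                      if c == cluster_id)


def residue_fluctuation(ensemble: Ensemble, atom_basis: str = "calpha",
                        align: bool = True) -> FluctuationProfile:
    """RMSF per residue: sqrt of the mean (over frames and basis atoms) of
    the squared displacement from the mean structure.

    The ensemble is aligned to its converged mean with a backbone fit
    first (disable with ``align=False`` for pre-aligned input).
    """
    if ensemble.n_frames < 2:
        raise StructureError("residue fluctuation needs at least 2 frames")
    if atom_basis not in ("calpha", "residue-heavy"):
        raise StructureError(f"unknown atom basis {atom_basis!r}")
    if align:
        ensemble, _ = align_ensemble(ensemble, "backbone")
    template = ensemble.frames[0]
    coords = ensemble.coords
    mean = coords.mean(axis=0)
    sq = np.sum((coords - mean[None]) ** 2, axis=2)  # (frames, atoms)
    msd_atom = sq.mean(axis=0)

    residues = template.residue_number_list()
    rmsf = np.empty(len(residues))
    for k, rnum in enumerate(residues):
        if atom_basis == "calpha":
            idx = [i for i in range(template.n_atoms)
                   if int(template.residue_numbers[i]) == rnum
                   and template.atom_names[i] == "CA"]
        else:
            idx = [i for i in range(template.n_atoms)
                   if int(template.residue_numbers[i]) == rnum]
        if not idx:
            raise StructureError(f"residue {rnum} lacks basis atoms")
        rmsf[k] = np.sqrt(msd_atom[idx].mean())
    return FluctuationProfile(np.asarray(residues), rmsf, atom_basis)


def pairwise_rmsd_matrix(ensemble: Ensemble,
                         fit: str = "backbone",
                         measure: str | None = None) -> RmsdMatrix:
    """Symmetric zero-diagonal frame-vs-frame RMSD matrix of one ensemble."""
    if ensemble.n_frames < 2:
        raise StructureError("need at least 2 frames")
    measure = fit if measure is None else measure
    template = ensemble.frames[0]
    fit_idx = select_atoms(template, fit)
    measure_idx = select_atoms(template, measure)
    coords = ensemble.coords
    values = batched_rmsd_matrix(coords, coords, fit_idx, measure_idx)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    labels = [f"frame{i + 1}" for i in range(ensemble.n_frames)]
    return RmsdMatrix(values, labels, labels, fit, measure)


def _mapped_atom_indices(fragment: Conformer, protein: Conformer, mapping):
    """Corresponding (fragment, protein) atom indices over mapped residues.

    Within each mapped residue the atom-name sequences must agree 1:1.
    """
    frag_fit, prot_fit, frag_all, prot_all = [], [], [], []
    frag_by_res = {}
    prot_by_res = {}
    for i in range(fragment.n_atoms):
        frag_by_res.setdefault(int(fragment.residue_numbers[i]), []).append(i)
    for i in range(protein.n_atoms):
        prot_by_res.setdefault(int(protein.residue_numbers[i]), []).append(i)
    for f_res, p_res in mapping.pairs:
        fi = frag_by_res.get(f_res)
        pi = prot_by_res.get(p_res)
        if fi is None or pi is None:
            raise StructureError(
                f"mapped residue pair ({f_res}, {p_res}) absent from input")
        f_names = [fragment.atom_names[i] for i in fi]
        p_names = [protein.atom_names[i] for i in pi]
        if f_names != p_names:
            raise StructureError(
                f"atom mismatch at mapped residues ({f_res}, {p_res}): "
                f"{f_names} vs {p_names}")
        for i, j in zip(fi, pi):
            frag_all.append(i)
            prot_all.append(j)
            if fragment.atom_names[i] in ("N", "CA", "C", "O"):
                frag_fit.append(i)
                prot_fit.append(j)
    return (np.asarray(frag_fit), np.asarray(prot_fit),
            np.asarray(frag_all), np.asarray(prot_all))


def cross_rmsd_matrix(fragment: Ensemble, protein: Ensemble,
                      mapping) -> RmsdMatrix:
    """Every fragment frame against every protein frame over mapped residues.

    Frames are superposed on the mapped backbone and measured over all
    mapped heavy atoms (150 x 150 frames gives 22500 values).
    """
    ff, pf, fa, pa = _mapped_atom_indices(
        fragment.frames[0], protein.frames[0], mapping)
    if ff.size == 0:
        raise StructureError("mapped backbone selection is empty")
    coords_f = fragment.coords[:, np.concatenate([ff, fa]), :]
    coords_p = protein.coords[:, np.concatenate([pf, pa]), :]
    fit_idx = np.arange(ff.size)
    measure_idx = np.arange(ff.size, ff.size + fa.size)
    values = batched_rmsd_matrix(coords_f, coords_p, fit_idx, measure_idx)
    return RmsdMatrix(
        values,
        [f"frag{i + 1}" for i in range(fragment.n_frames)],
        [f"prot{i + 1}" for i in range(protein.n_frames)],
        fit="backbone-of-mapped", measure="all-heavy-of-mapped",
    )


def fraction_in_range(matrix: RmsdMatrix, lo: float = 2.0, hi: float = 4.0,
                      per_frame: bool = False) -> float:
    """Fraction of matrix entries with lo <= RMSD <= hi (closed interval).

    With ``per_frame=True`` the statistic is computed over rows instead:
    the fraction of row (fragment-frame) mean RMSDs inside the interval.
    """
    if lo >= hi:
        raise StructureError("require lo < hi")
    values = matrix.values
    if values.size == 0:
        raise StructureError("empty matrix")
    if per_frame:
        values = values.mean(axis=1)
    return float(np.mean((values >= lo) & (values <= hi)))


def average_linkage_cluster(matrix: RmsdMatrix,
                            cutoff: float = 2.0) -> Clustering:
    """Agglomerative average-linkage clustering with a merge cutoff.

    Repeatedly merges the pair of clusters with the smallest average
    inter-cluster RMSD (Lance-Williams update) until that minimum exceeds
    ``cutoff``; ties are broken by the smallest index pair.  Cluster ids
    are assigned 0..K-1 in order of each cluster's lowest frame index,
    and medoid representatives are attached.
    """
    d = np.asarray(matrix.values, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise StructureError("self-matrix required")
    if not np.allclose(d, d.T, atol=1e-9):
        raise StructureError("matrix is not symmetric")
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}  # key = lowest original index
    dist = {}
    keys = sorted(clusters)
    for ai in range(len(keys)):
        for bi in range(ai + 1, len(keys)):
            dist[(keys[ai], keys[bi])] = d[keys[ai], keys[bi]]

    while len(clusters) > 1:
        (a, b), best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        if best > cutoff:
            break
        lo_key, hi_key = min(a, b), max(a, b)
        na, nb = len(clusters[a]), len(clusters[b])
        updated = {}
        for k in clusters:
            if k in (a, b):
                continue
            dka = dist[(min(k, a), max(k, a))]
            dkb = dist[(min(k, b), max(k, b))]
            updated[(min(k, lo_key), max(k, lo_key))] = \
                (na * dka + nb * dkb) / (na + nb)
        dist = {pair: v for pair, v in dist.items()
                if lo_key not in pair and hi_key not in pair}
        dist.update(updated)
        clusters[lo_key] = sorted(clusters[a] + clusters[b])
        del clusters[hi_key]

    ordered = sorted(clusters.values(), key=lambda m: m[0])
    assignment = {}
    for cid, members in enumerate(ordered):
        for f in members:
            assignment[f] = cid
    clustering = Clustering(assignment, cutoff)
    clustering.representatives = cluster_representatives(clustering, matrix)
    return clustering


def cluster_representatives(clustering: Clustering,
                            matrix: RmsdMatrix) -> dict:
    """Medoid of each cluster: the member frame minimising the mean RMSD to
    the other members (singletons represent themselves; ties go to the
    lowest frame index)."""
    d = matrix.values
    reps = {}
    for cid in sorted(set(clustering.assignment.values())):
        members = clustering.members(cid)
        if len(members) == 1:
            reps[cid] = members[0]
            continue
        best, best_mean = None, np.inf
        for f in members:
            others = [g for g in members if g != f]
            mean = float(np.mean([d[f, g] for g in others]))
            if mean < best_mean - 1e-12:
                best, best_mean = f, mean
        reps[cid] = best
    return reps
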