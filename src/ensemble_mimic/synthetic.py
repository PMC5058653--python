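"""Seeded synthetic conformational ensembles.

Two samplers stand in for molecular-dynamics trajectories:

* a **gaussian** sampler with exact per-residue amplitude control — each
  residue is displaced rigidly by an isotropic normal deviate, so the
  expected unaligned CA RMSF of residue *r* equals ``a_r * sqrt(3)``;
* an **elastic-network** (ENM) sampler — overdamped Langevin dynamics on
  CA beads joined by harmonic springs between all reference-structure CA
  pairs within a contact cutoff, with the other atoms riding rigidly on
  their CA.  A chain region built with locally stretched backbone rise has
  fewer contacts and therefore fluctuates more, emulating a flexible loop.

All randomness is drawn from ``numpy.random.default_rng(seed)``; identical
spec + seed reproduces ensembles bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import (
    Conformer,
    Ensemble,
    ONE_TO_THREE,
    ResidueRange,
    StructureError,
)

#: Human Fhit (UniProt P49789) residues 1-38 — the ANXA4-binding N-terminus.
#: Contains the QHLIKPS heptapeptide at positions 7-13 and Lys at 11, 18, 29.
FHIT_NTERM_SEQ = "MSFRFGQHLIKPSVVFLKTELSFALVNRKPVVPGHVLV"

#: Synthetic C-terminal segment (positions 39-147 of the default fixture).
#: This is NOT the native Fhit sequence: it is a fixed synthetic stand-in
#: giving the default chain its full ~147-residue length.
SYNTHETIC_TAIL_39_147 = (
    "TTYTVPCSMYEGCLNDNVHNGMLWTVRDEITFRLTWTIQPKPQRTRKWWARPYFHFVMEL"
    "DMPCTDKCCADPNTERKGWNFYCWQVDNKVWECCRHSICHLGWPCMHSR"
)

#: Default 147-residue chain: real Fhit 1-38 + synthetic tail.
DEFAULT_PROTEIN_SEQUENCE = FHIT_NTERM_SEQ + SYNTHETIC_TAIL_39_147

#: Default elevated-flexibility loop of the 147-residue fixture.
DEFAULT_LOOP = ResidueRange(108, 127)

# Coil geometry: ideal-helix-like parameters with exact 3.8 A CA-CA spacing.
_CA_CA = 3.8
_RESIDUES_PER_TURN = 3.6
_RISE = 1.5
_LOOP_RISE = 3.7  # locally stretched rise -> low-contact loop
_HELIX_RADIUS = np.sqrt(_CA_CA**2 - _RISE**2) / (
    2.0 * np.sin(np.pi / _RESIDUES_PER_TURN)
)
_CB_OFFSET = 1.5


class StabilityError(RuntimeError):
    """The Langevin integration diverged; reduce the step size."""


@dataclass(frozen=True)
class EnmParams:
    """Elastic-network Langevin parameters.

    ``spring_k`` in energy/A^2, ``cutoff`` in A, ``kT`` in the same energy
    unit, ``dt``/``friction`` set the overdamped mobility dt/friction.
    """

    spring_k: float = 10.0
    cutoff: float = 10.0
    kT: float = 0.6
    dt: float = 0.005
    friction: float = 1.0
    n_equilibration: int = 2000
    stride: int = 20


@dataclass
class EnsembleSpec:
    """Recipe for one synthetic ensemble (the sampling contract: 150 frames)."""

    sequence: str
    seed: int
    n_frames: int = 150
    sampler: str = "gaussian"
    amplitude_profile: np.ndarray | None = None
    base_amplitude: float = 0.3
    loop_range: ResidueRange | None = None
    loop_multiplier: float = 3.0
    enm: EnmParams = field(default_factory=EnmParams)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise StructureError("sequence must be non-empty")
        bad = set(self.sequence) - set(ONE_TO_THREE)
        if bad:
            raise StructureError(f"invalid one-letter codes: {sorted(bad)}")
        if self.n_frames < 2:
            raise StructureError("n_frames must be >= 2")
        if self.sampler not in ("gaussian", "enm"):
            raise StructureError(f"unknown sampler {self.sampler!r}")
        if self.amplitude_profile is not None:
            prof = np.asarray(self.amplitude_profile, dtype=float)
            if prof.size != len(self.sequence):
                raise StructureError("amplitude_profile length != sequence length")
            if np.any(prof <= 0):
                raise StructureError("amplitudes must be > 0")
            self.amplitude_profile = prof
        if self.loop_range is not None:
            if self.loop_range.end > len(self.sequence):
                raise StructureError("loop_range outside sequence")
            if self.loop_multiplier <= 1:
                raise StructureError("loop_multiplier must be > 1")

    def resolved_amplitudes(self) -> np.ndarray:
        """Per-residue per-axis displacement SD (A) for the gaussian sampler."""
        if self.amplitude_profile is not None:
            return self.amplitude_profile.copy()
        amp = np.full(len(self.sequence), self.base_amplitude, dtype=float)
        if self.loop_range is not None:
            amp[self.loop_range.start - 1:self.loop_range.end] *= self.loop_multiplier
        return amp


@dataclass
class MimicrySpec:
    """Planted-mimicry recipe for a protein / N-terminal-fragment pair."""

    planted_window: ResidueRange
    seed: int
    fragment_range: ResidueRange = ResidueRange(1, 38)
    outside_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.fragment_range.start != 1:
            raise StructureError("fragment must be N-terminal (range starts at 1)")
        if not (self.planted_window.start in self.fragment_range
                and self.planted_window.end in self.fragment_range):
            raise StructureError("planted_window must lie inside fragment_range")
        if self.outside_scale <= 0:
            raise StructureError("outside_scale must be > 0")


def build_reference_chain(sequence: str,
                          loop_range: ResidueRange | None = None) -> Conformer:
    """Deterministic idealized backbone for a one-letter sequence.

    CA atoms lie on a regular coil (3.6 residues/turn, 1.5 A rise) with
    exact 3.8 A CA-CA spacing; inside ``loop_range`` the per-residue rise is
    stretched to 3.7 A (turn angle adjusted so spacing stays 3.8 A), which
    thins out non-sequential contacts there.  Each residue gets backbone
    N, CA, C, O plus one CB pseudo-sidechain atom 1.5 A from the CA,
    perpendicular to the local chain direction (glycine has no CB).
    """
    if not sequence:
        raise StructureError("sequence must be non-empty")
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise StructureError(f"invalid one-letter codes: {sorted(bad)}")
    n = len(sequence)

    rise = np.full(n, _RISE)
    if loop_range is not None:
        rise[loop_range.start - 1:loop_range.end] = _LOOP_RISE
    chord = np.sqrt(_CA_CA**2 - rise**2)
    dphi = 2.0 * np.arcsin(chord / (2.0 * _HELIX_RADIUS))
    # residue i sits after i steps of (dphi, rise) taken at the step's values
    phi = np.concatenate([[0.0], np.cumsum(dphi[1:])])
    z = np.concatenate([[0.0], np.cumsum(rise[1:])])
    ca = np.stack([_HELIX_RADIUS * np.cos(phi),
                   _HELIX_RADIUS * np.sin(phi), z], axis=1)

    # local frames: tangent along the chain, radial outward, normal = t x r
    tangent = np.empty_like(ca)
    tangent[1:-1] = ca[2:] - ca[:-2]
    tangent[0] = ca[1] - ca[0] if n > 1 else np.array([0.0, 0.0, 1.0])
    tangent[-1] = ca[-1] - ca[-2] if n > 1 else tangent[0]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    radial = ca.copy()
    radial[:, 2] = 0.0
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    radial -= np.sum(radial * tangent, axis=1, keepdims=True) * tangent
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    normal = np.cross(tangent, radial)

    names, elements, res_names, res_numbers, coords = [], [], [], [], []
    for i, letter in enumerate(sequence):
        res3 = ONE_TO_THREE[letter]
        atoms = [
            ("N", "N", ca[i] - 1.2 * tangent[i] + 0.5 * normal[i]),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + 1.2 * tangent[i] + 0.5 * normal[i]),
            ("O", "O", ca[i] + 1.2 * tangent[i] + 1.7 * normal[i]),
        ]
        if letter != "G":
            atoms.append(("CB", "C", ca[i] + _CB_OFFSET * radial[i]))
        for name, element, xyz in atoms:
            names.append(name)
            elements.append(element)
            res_names.append(res3)
            res_numbers.append(i + 1)
            coords.append(xyz)
    from .structure_io import VDW_RADII
    radii = [VDW_RADII[e] for e in elements]
    return Conformer(names, elements, res_names, res_numbers, coords, radii)


def _residue_index(conformer: Conformer) -> np.ndarray:
    """0-based residue position for every atom."""
    order = conformer.residue_number_list()
    pos = {r: i for i, r in enumerate(order)}
    return np.array([pos[int(r)] for r in conformer.residue_numbers], dtype=int)


def sample_gaussian_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Rigid-per-residue isotropic normal displacements about the reference.

    Expected unaligned CA RMSF of residue r = a_r * sqrt(3).
    """
    reference = build_reference_chain(spec.sequence)
    amp = spec.resolved_amplitudes()
    res_idx = _residue_index(reference)
    rng = np.random.default_rng(spec.seed)
    disp = rng.standard_normal((spec.n_frames, len(spec.sequence), 3))
    disp *= amp[None, :, None]
    coords = reference.coords[None, :, :] + disp[:, res_idx, :]
    frames = [reference.with_coords(c) for c in coords]
    return Ensemble(frames, label=f"gaussian-seed{spec.seed}")


def enm_spring_network(ca_coords: np.ndarray, cutoff: float):
    """Spring pairs (i, j), i<j, within ``cutoff`` A, and their rest lengths."""
    dist = squareform(pdist(ca_coords))
    ii, jj = np.where(np.triu(dist <= cutoff, k=1))
    return np.stack([ii, jj], axis=1), dist[ii, jj]


def elastic_energy(ca_coords: np.ndarray, pairs: np.ndarray,
                   rest_lengths: np.ndarray, spring_k: float) -> float:
    """Total harmonic network energy 0.5 k sum (r - r0)^2."""
    d = ca_coords[pairs[:, 0]] - ca_coords[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return 0.5 * spring_k * float(np.sum((r - rest_lengths) ** 2))


def sample_enm_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Overdamped Langevin (Euler-Maruyama) on the CA elastic network.

    Update: x <- x - (dt/friction) * grad U + sqrt(2 kT dt / friction) * xi.
    Frames are recorded every ``stride`` steps after ``n_equilibration``
    steps; backbone and CB atoms ride rigidly with their CA.
    """
    if spec.sampler != "enm":
        raise StructureError("spec.sampler must be 'enm'")
    p = spec.enm
    reference = build_reference_chain(spec.sequence, loop_range=spec.loop_range)
    from .structure_io import select_atoms
    ca_idx = select_atoms(reference, "calpha")
    ca_ref = reference.coords[ca_idx]
    pairs, r0 = enm_spring_network(ca_ref, p.cutoff)
    i_idx, j_idx = pairs[:, 0], pairs[:, 1]
    res_idx = _residue_index(reference)

    rng = np.random.default_rng(spec.seed)
    mobility = p.dt / p.friction
    noise_scale = np.sqrt(2.0 * p.kT * p.dt / p.friction)
    x = ca_ref.copy()
    n_res = len(spec.sequence)
    frames_coords = []
    total_steps = p.n_equilibration + spec.n_frames * p.stride
    for step in range(1, total_steps + 1):
        d = x[i_idx] - x[j_idx]
        r = np.linalg.norm(d, axis=1)
        f = (-p.spring_k * (r - r0) / r)[:, None] * d
        force = np.zeros_like(x)
        np.add.at(force, i_idx, f)
        np.add.at(force, j_idx, -f)
        x = x + mobility * force
        if p.kT > 0:
            x = x + noise_scale * rng.standard_normal((n_res, 3))
        if np.abs(x).max() > 1e3:
            raise StabilityError(
                f"coordinate blow-up at step {step}; reduce dt "
                f"(dt={p.dt}, spring_k={p.spring_k})"
            )
        after_eq = step - p.n_equilibration
        if after_eq > 0 and after_eq % p.stride == 0:
            frames_coords.append(x.copy())
            if len(frames_coords) == spec.n_frames:
                break
    # every atom follows its residue's CA displacement rigidly
    frames = []
    for xc in frames_coords:
        disp = xc - ca_ref
        frames.append(reference.with_coords(
            reference.coords + disp[res_idx]))
    return Ensemble(frames, label=f"enm-seed{spec.seed}")


def sample_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Dispatch on ``spec.sampler``."""
    if spec.sampler == "gaussian":
        return sample_gaussian_ensemble(spec)
    return sample_enm_ensemble(spec)


def sample_fragment_pair(protein_spec: EnsembleSpec,
                         mimicry: MimicrySpec):
    """Protein ensemble plus an N-terminal fragment ensemble with a planted
    mimetic window.

    The fragment's gaussian amplitude profile equals the protein's inside
    ``planted_window`` and is multiplied by ``outside_scale`` elsewhere, so
    the fragment's dynamics match the protein's only inside the window.
    The two ensembles use independent seeds.
    """
    if protein_spec.sampler != "gaussian":
        raise StructureError(
            "fragment-pair planting is defined for the gaussian sampler"
        )
    if mimicry.fragment_range.end > len(protein_spec.sequence):
        raise StructureError("fragment_range outside protein sequence")
    protein = sample_gaussian_ensemble(protein_spec)
    amp = protein_spec.resolved_amplitudes()
    lo, hi = mimicry.fragment_range.start, mimicry.fragment_range.end
    frag_amp = amp[lo - 1:hi].copy()
    for pos in range(lo, hi + 1):
        if pos not in mimicry.planted_window:
            frag_amp[pos - lo] *= mimicry.outside_scale
    frag_spec = EnsembleSpec(
        sequence=protein_spec.sequence[lo - 1:hi],
        seed=mimicry.seed,
        n_frames=protein_spec.n_frames,
        sampler="gaussian",
        amplitude_profile=frag_amp,
    )
    fragment = sample_gaussian_ensemble(frag_spec)
    fragment.label = f"fragment-{mimicry.fragment_range}-seed{mimicry.seed}"
    return protein, fragment
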