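"""Mimetic-window selection and peptide construction.

Compares the residue-fluctuation profiles of an N-terminal fragment and
the full-length protein over a positional residue mapping, selects the
contiguous window with the smallest mean |RMSF difference|, extends it
with hydrophilic flanks (Kyte-Doolittle hydropathy < 0), and builds the
Tat-fusion and scrambled-control peptide strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import ONE_TO_THREE, ResidueRange, StructureError
from .trajectory import FluctuationProfile

#: HIV-1 Tat 47-58 cell-penetrating peptide, fused N-terminal of cargo.
TAT_PEPTIDE = "YGRKKRRQRRR"

#: Kyte-Doolittle hydropathy scale; negative = hydrophilic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class ResidueMapping:
    """1:1 correspondence (fragment residue, protein residue), both strictly
    increasing.  N-terminal fragments use the identity mapping."""

    pairs: tuple

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise StructureError("mapping must be non-empty")
        frag = [a for a, _ in pairs]
        prot = [b for _, b in pairs]
        if sorted(set(frag)) != frag or sorted(set(prot)) != prot:
            raise StructureError("mapping sides must be strictly increasing")

    @classmethod
    def identity(cls, residues: ResidueRange) -> "ResidueMapping":
        return cls(tuple((r, r) for r in residues))

    @property
    def fragment_residues(self):
        return [a for a, _ in self.pairs]


@dataclass
class MimicryReport:
    """Window-selection outcome plus the designed peptide strings."""

    residue_numbers: np.ndarray
    diff_profile: np.ndarray
    window_scores: dict
    core_window: ResidueRange
    core_score: float
    extended_window: ResidueRange
    core_peptide: str
    extended_peptide: str
    tat_construct: str
    scrambled_control: str
    extras: dict = field(default_factory=dict)


def rfa_difference_profile(frag: FluctuationProfile,
                           prot: FluctuationProfile,
                           mapping: ResidueMapping) -> np.ndarray:
    """|RMSF_frag(i) - RMSF_prot(map(i))| per mapped residue, in order."""
    frag_d = frag.as_dict()
    prot_d = prot.as_dict()
    out = np.empty(len(mapping.pairs))
    for k, (f_res, p_res) in enumerate(mapping.pairs):
        if f_res not in frag_d or p_res not in prot_d:
            raise StructureError(
                f"mapped pair ({f_res}, {p_res}) missing from profiles")
        out[k] = abs(frag_d[f_res] - prot_d[p_res])
    return out


def select_mimetic_window(diff: np.ndarray, residue_numbers,
                          window_len: int = 5):
    """Contiguous window of ``window_len`` residues minimising mean |dRMSF|.

    Ties go to the smallest start position.  Returns (window, score,
    all window scores keyed by start residue).
    """
    diff = np.asarray(diff, dtype=float)
    residue_numbers = [int(r) for r in residue_numbers]
    if window_len < 1:
        raise StructureError("window_len must be >= 1")
    if window_len > diff.size:
        raise StructureError("window_len exceeds number of mapped residues")
    scores = {}
    best_start, best_score = None, np.inf
    for s in range(diff.size - window_len + 1):
        score = float(diff[s:s + window_len].mean())
        scores[residue_numbers[s]] = score
        if score < best_score - 1e-15:
            best_start, best_score = s, score
    window = ResidueRange(residue_numbers[best_start],
                          residue_numbers[best_start + window_len - 1])
    return window, best_score, scores


def extend_window_hydrophilic(core: ResidueRange, sequence: str,
                              max_extension: int = 1) -> ResidueRange:
    """Grow the core on each side with up to ``max_extension`` hydrophilic
    flanking residues (Kyte-Doolittle < 0), stopping at the first
    hydrophobic residue or chain end."""
    if core.start < 1 or core.end > len(sequence):
        raise StructureError("core window outside sequence bounds")
    start = core.start
    for _ in range(max_extension):
        pos = start - 1
        if pos < 1 or KYTE_DOOLITTLE[sequence[pos - 1]] >= 0:
            break
        start = pos
    end = core.end
    for _ in range(max_extension):
        pos = end + 1
        if pos > len(sequence) or KYTE_DOOLITTLE[sequence[pos - 1]] >= 0:
            break
        end = pos
    return ResidueRange(start, end)


def build_tat_construct(peptide: str) -> str:
    """Tat(47-58) + Gly linker + cargo, e.g. QHLIKPS -> Tat-G-QHLIKPS."""
    if not peptide:
        raise StructureError("peptide must be non-empty")
    bad = set(peptide) - set(ONE_TO_THREE)
    if bad:
        raise StructureError(f"invalid one-letter codes: {sorted(bad)}")
    return TAT_PEPTIDE + "G" + peptide


def scramble_peptide(peptide: str, seed: int) -> str:
    """Seeded Fisher-Yates scramble, re-drawn until it differs from the
    input; the residue multiset is preserved."""
    if len(peptide) < 2 or len(set(peptide)) < 2:
        raise StructureError("peptide cannot be scrambled "
                             "(needs >= 2 distinct residues)")
    rng = np.random.default_rng(seed)
    letters = list(peptide)
    while True:
        shuffled = letters.copy()
        for i in range(len(shuffled) - 1, 0, -1):
            j = int(rng.integers(0, i + 1))
            shuffled[i], shuffled[j] = shuffled[j], shuffled[i]
        candidate = "".join(shuffled)
        if candidate != peptide:
            return candidate


def build_mimicry_report(frag_profile: FluctuationProfile,
                         prot_profile: FluctuationProfile,
                         mapping: ResidueMapping,
                         fragment_sequence: str,
                         window_len: int = 5,
                         max_extension: int = 1,
                         scramble_seed: int = 0) -> MimicryReport:
    """Full mimetic-design chain: difference profile, window selection,
    hydrophilic extension, Tat fusion, scrambled control."""
    diff = rfa_difference_profile(frag_profile, prot_profile, mapping)
    residues = mapping.fragment_residues
    core, score, scores = select_mimetic_window(diff, residues, window_len)
    extended = extend_window_hydrophilic(core, fragment_sequence,
                                         max_extension)
    core_pep = fragment_sequence[core.start - 1:core.end]
    ext_pep = fragment_sequence[extended.start - 1:extended.end]
    return MimicryReport(
        residue_numbers=np.asarray(residues),
        diff_profile=diff,
        window_scores=scores,
        core_window=core,
        core_score=score,
        extended_window=extended,
        core_peptide=core_pep,
        extended_peptide=ext_pep,
        tat_construct=build_tat_construct(ext_pep),
        scrambled_control=scramble_peptide(ext_pep, scramble_seed),
    )
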