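import numpy as np
import pytest

import ensemble_mimic as em


@pytest.fixture
def toy_conformer():
    """Three-residue chain (Gln-Gly-Lys) with hand-placed heavy atoms."""
    names = ["N", "CA", "C", "O", "CB",
             "N", "CA", "C", "O",
             "N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C",
                "N", "C", "C", "O",
                "N", "C", "C", "O", "C"]
    res_names = ["GLN"] * 5 + ["GLY"] * 4 + ["LYS"] * 5
    res_numbers = [1] * 5 + [2] * 4 + [3] * 5
    rng = np.random.default_rng(42)
    coords = rng.normal(scale=3.0, size=(14, 3))
    radii = [em.structure_io.VDW_RADII[e] for e in elements]
    return em.Conformer(names, elements, res_names, res_numbers,
                        coords, radii)


@pytest.fixture
def small_ensemble():
    """Seeded 8-frame gaussian ensemble over a 10-residue chain."""
    spec = em.EnsembleSpec(sequence="QHLIKPSVVF", seed=7, n_frames=8)
    return em.sample_gaussian_ensemble(spec)


def random_ensemble(seed: int, n_res: int = 5, n_frames: int = 3):
    """Small random ensemble for round-trip / property tests."""
    rng = np.random.default_rng(seed)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    sequence = "".join(rng.choice(list(letters), size=n_res))
    spec = em.EnsembleSpec(sequence=sequence, seed=seed + 1,
                           n_frames=max(2, n_frames))
    return em.sample_gaussian_ensemble(spec)
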