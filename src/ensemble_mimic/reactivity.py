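"""Lysine cross-linker-reactivity ranking.

Amine-reactive NHS-ester cross-linkers (e.g. DSP) favour lysines that are
(a) solvent exposed and (b) carry an electron-rich primary amine.  The
exposure descriptor is the trajectory-averaged sidechain SASA (ASASA);
the nucleophilicity descriptor comes from an externally supplied partial
charge per lysine (more negative charge = more electron-available amine).
Both are min-max normalised over the lysine set and combined as a
weighted mean (default equal weights).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .structure_io import StructureError

logger = logging.getLogger("ensemble_mimic")


class ChargeTableError(StructureError):
    """Malformed charge-table input."""


def load_charge_table(path) -> dict:
    """Parse a TSV of ``residue_number<TAB>charge`` (header required).

    Returns {residue_number: charge}.  Duplicate residue numbers and
    malformed rows raise, with the offending line number.
    """
    charges: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        logger.warning("charge table %s is empty", path)
        return {}
    header = lines[0].split("\t")
    if [h.strip() for h in header[:2]] != ["residue_number", "charge"]:
        raise ChargeTableError(
            f"{path}:1: expected header 'residue_number<TAB>charge'")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ChargeTableError(f"{path}:{lineno}: expected 2 columns")
        try:
            rnum = int(parts[0])
            charge = float(parts[1].replace("−", "-"))
        except ValueError as exc:
            raise ChargeTableError(f"{path}:{lineno}: {exc}") from exc
        if rnum in charges:
            raise ChargeTableError(
                f"{path}:{lineno}: duplicate residue number {rnum}")
        charges[rnum] = charge
    return charges


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def rank_lysines(asasa: dict, charges: dict | None = None,
                 exposure_weight: float = 0.5) -> pd.DataFrame:
    """Rank lysines by combined exposure/nucleophilicity score.

    ``asasa`` maps residue number to mean sidechain SASA (A^2); optional
    ``charges`` maps residue number to amine partial charge.  Scores are
    min-max normalised (a single lysine scores 1.0); the combined score is
    ``w * exposure + (1 - w) * nucleophilicity`` (exposure alone when no
    charges are given).  Rank 1 is the predicted most reactive lysine;
    ties go to the lower residue number.
    """
    if not asasa:
        raise StructureError("asasa table is empty")
    if not 0.0 <= exposure_weight <= 1.0:
        raise StructureError("exposure_weight must be in [0, 1]")
    residues = sorted(asasa)
    area = np.array([asasa[r] for r in residues], dtype=float)
    exposure = _minmax(area)
    if charges is not None:
        missing = [r for r in residues if r not in charges]
        if missing:
            raise StructureError(f"charges missing for lysines {missing}")
        charge = np.array([charges[r] for r in residues], dtype=float)
        nucleophilicity = _minmax(-charge)
        combined = (exposure_weight * exposure
                    + (1.0 - exposure_weight) * nucleophilicity)
    else:
        charge = np.full(len(residues), np.nan)
        nucleophilicity = np.full(len(residues), np.nan)
        combined = exposure

    table = pd.DataFrame({
        "residue_number": residues,
        "asasa": area,
        "amine_charge": charge,
        "exposure_score": exposure,
        "nucleophilicity_score": nucleophilicity,
        "combined_score": combined,
    })
    table = table.sort_values(
        ["combined_score", "residue_number"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
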