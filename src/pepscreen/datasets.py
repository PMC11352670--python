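"""Loaders for the small datasets bundled with the package.

``reported_candidates`` and ``reported_poses`` transcribe the published
candidate-peptide listings of the tomato-peel case study (lead peptides per
bioactivity class with their parent proteins, and the externally computed
MM-PBSA pose energies against each docking target).  They serve as
worked-example inputs for the filter cascade and the table-backed
predictor; the package does not recompute any of the energies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .filtering import PoseEnergy


def _bundled_frame(filename: str) -> pd.DataFrame:
    ref = resources.files("pepscreen.data") / filename
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reported_candidates() -> pd.DataFrame:
    """Lead candidate peptides per class (sequence, class, residues, parent
    protein, and an always-positive call for the table-backed predictor)."""
    return _bundled_frame("reported_candidates.tsv")


def reported_poses() -> list[PoseEnergy]:
    """Externally supplied MM-PBSA pose energies for the lead candidates."""
    df = _bundled_frame("reported_poses.tsv")
    return [
        PoseEnergy(
            sequence=str(r.sequence),
            target=str(r.target),
            pose=int(r.pose),
            energy_mean=float(r.energy_mean),
            energy_sd=float(r.energy_sd),
        )
        for r in df.itertuples(index=False)
    ]


def reported_poses_frame() -> pd.DataFrame:
    return _bundled_frame("reported_poses.tsv")
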