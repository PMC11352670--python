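"""Workflow configuration: every published cutoff as an overridable key.

The defaults encode the workflow's numbers — peptide length window 5..30
residues, bitterness cutoff 333, plasma half-life 800 s, intestinal
half-life 1.0 s, pose-energy cutoff -30 kcal/mol, top-50 substrates from a
triplicate expression table — so nothing is a buried constant.  A YAML file
with any subset of these keys overrides the defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import SchemaError
from .filtering import Thresholds


@dataclass(frozen=True)
class WorkflowConfig:
    min_len: int = 5
    max_len: int = 30
    top_n: int = 50
    n_replicates: int = 3
    bitterness_max: float = 333.0
    plasma_min_s: float = 800.0
    intestinal_min_s: float = 1.0
    energy_cutoff_kcal: float = -30.0

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(
            bitterness_max=self.bitterness_max,
            plasma_min_s=self.plasma_min_s,
            intestinal_min_s=self.intestinal_min_s,
            energy_cutoff_kcal=self.energy_cutoff_kcal,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None) -> WorkflowConfig:
    """Defaults, optionally overridden by a YAML mapping of known keys."""
    if path is None:
        return WorkflowConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(WorkflowConfig)}
    unknown = set(doc) - known
    if unknown:
        raise SchemaError(f"unknown config keys {sorted(unknown)} in {path}")
    return WorkflowConfig(**doc)
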