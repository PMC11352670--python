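"""Pluggable multi-label bioactivity predictor backends.

The screening stage only needs a ``BioactivityPredictor``: an object with a
``name``/``version`` and a pure ``predict(peptides)`` method returning one
:class:`BioactivityPrediction` per input peptide, covering the five classes
ACP (anticancer), ADP (antidiabetic), AHP (antihypertensive), AIP
(anti-inflammatory) and AMP (antimicrobial).  Three backends ship here:

* :class:`TableBackedPredictor` — replays calls from a delimited score
  table, as exported from an external prediction server.
* :class:`SeededRandomPredictor` — deterministic pseudo-random calls keyed
  by (seed, class, sequence); for tests and synthetic fixtures.
* :class:`CompositionHeuristicPredictor` — a transparent amino-acid
  composition baseline.  It is a stand-in that makes the pipeline runnable
  end to end offline; it is not equivalent to any trained deep-learning
  model and supports no claim about real peptide bioactivity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import pandas as pd

from .errors import PredictionError, SchemaError

BIOACTIVITY_CLASSES = ("ACP", "ADP", "AHP", "AIP", "AMP")


@dataclass(frozen=True)
class BioactivityPrediction:
    """Per-class scores in [0, 1] and boolean calls for one peptide."""

    sequence: str
    scores: Mapping[str, float]
    calls: Mapping[str, bool]
    predictor: str
    version: str

    def __post_init__(self) -> None:
        missing = set(BIOACTIVITY_CLASSES) - set(self.scores) | (
            set(BIOACTIVITY_CLASSES) - set(self.calls)
        )
        if missing:
            raise PredictionError(
                f"prediction for {self.sequence!r} lacks classes {sorted(missing)}"
            )

    @property
    def positive_classes(self) -> tuple[str, ...]:
        return tuple(c for c in BIOACTIVITY_CLASSES if self.calls[c])


@runtime_checkable
class BioactivityPredictor(Protocol):
    """Contract every predictor backend satisfies."""

    name: str
    version: str

    def predict(self, peptides: Sequence[str]) -> list[BioactivityPrediction]:
        """Return exactly one prediction per input peptide, in order."""
        ...


def unit_float(*keys) -> float:
    """Deterministic uniform-[0,1) value derived from hashing the keys.

    Stable across processes and across call order, which gives seeded
    backends purity: the prediction for a sequence never depends on which
    other sequences were predicted before it.
    """
    digest = hashlib.sha256(":".join(str(k) for k in keys).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class TableBackedPredictor:
    """Replay predictions from a long-format score table.

    Expected columns: ``sequence``, ``class``, ``score``, ``call`` (one row
    per peptide x class).  In strict mode a peptide/class absent from the
    table raises :class:`PredictionError`; otherwise missing entries
    default to a negative call with score 0.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        *,
        name: str = "table",
        version: str = "0",
        strict: bool = True,
    ):
        required = {"sequence", "class", "score", "call"}
        missing = required - set(table.columns)
        if missing:
            raise SchemaError(f"score table lacks columns {sorted(missing)}")
        self.name = name
        self.version = version
        self.strict = strict
        self._scores: dict[tuple[str, str], tuple[float, bool]] = {}
        for row in table.itertuples(index=False):
            cls = str(row[table.columns.get_loc("class")])
            if cls not in BIOACTIVITY_CLASSES:
                raise SchemaError(f"unknown bioactivity class {cls!r} in score table")
            seq = str(getattr(row, "sequence"))
            score = float(getattr(row, "score"))
            call = bool(int(getattr(row, "call")))
            self._scores[(seq, cls)] = (score, call)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "TableBackedPredictor":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def predict(self, peptides: Sequence[str]) -> list[BioactivityPrediction]:
        out = []
        for pep in peptides:
            scores: dict[str, float] = {}
            calls: dict[str, bool] = {}
            for cls in BIOACTIVITY_CLASSES:
                entry = self._scores.get((pep, cls))
                if entry is None:
                    if self.strict and not any(
                        (pep, c) in self._scores for c in BIOACTIVITY_CLASSES
                    ):
                        raise PredictionError(
                            f"no table entry for peptide {pep!r} (strict mode)"
                        )
                    entry = (0.0, False)
                scores[cls], calls[cls] = entry
            out.append(
                BioactivityPrediction(
                    sequence=pep,
                    scores=scores,
                    calls=calls,
                    predictor=self.name,
                    version=self.version,
                )
            )
        return out


class SeededRandomPredictor:
    """Deterministic pseudo-random predictor for tests and simulations.

    ``positive_rate`` sets the marginal probability of a positive call per
    class; the call threshold is ``1 - positive_rate`` on the hashed score,
    so calls are always consistent with scores.
    """

    def __init__(self, seed: int, positive_rate: float = 0.1):
        if not 0.0 <= positive_rate <= 1.0:
            raise PredictionError("positive_rate must lie in [0, 1]")
        self.seed = int(seed)
        self.positive_rate = float(positive_rate)
        self.name = "seeded-random"
        self.version = "1"

    def predict(self, peptides: Sequence[str]) -> list[BioactivityPrediction]:
        threshold = 1.0 - self.positive_rate
        out = []
        for pep in peptides:
            scores = {
                cls: unit_float(self.seed, cls, pep) for cls in BIOACTIVITY_CLASSES
            }
            calls = {cls: scores[cls] >= threshold for cls in BIOACTIVITY_CLASSES}
            out.append(
                BioactivityPrediction(
                    sequence=pep,
                    scores=scores,
                    calls=calls,
                    predictor=self.name,
                    version=self.version,
                )
            )
        return out


# Crude physicochemical residue groups used by the composition baseline.
_CATIONIC = set("KRH")
_HYDROPHOBIC = set("AVLIMFWY")
_AROMATIC = set("FWY")
_SMALL = set("AGSTP")
_ACIDIC = set("DE")


class CompositionHeuristicPredictor:
    """Amino-acid-composition baseline with fixed, documented weights.

    Each class score is a clipped linear function of residue-group
    fractions loosely reflecting published composition biases (cationic and
    hydrophobic residues for antimicrobial peptides, proline/aromatic
    content for antihypertensive ones, and so on).  Threshold 0.5.  This is
    a transparent baseline, not a trained model.
    """

    THRESHOLD = 0.5

    def __init__(self):
        self.name = "composition-heuristic"
        self.version = "1"

    @staticmethod
    def _fractions(pep: str) -> dict[str, float]:
        n = len(pep)
        return {
            "cationic": sum(c in _CATIONIC for c in pep) / n,
            "hydrophobic": sum(c in _HYDROPHOBIC for c in pep) / n,
            "aromatic": sum(c in _AROMATIC for c in pep) / n,
            "small": sum(c in _SMALL for c in pep) / n,
            "acidic": sum(c in _ACIDIC for c in pep) / n,
            "proline": pep.count("P") / n,
            "short": 1.0 if n <= 10 else 0.0,
        }

    def predict(self, peptides: Sequence[str]) -> list[BioactivityPrediction]:
        out = []
        for pep in peptides:
            if not pep:
                raise PredictionError("cannot predict an empty peptide")
            f = self._fractions(pep)
            raw = {
                "ACP": 0.9 * f["cationic"] + 0.5 * f["hydrophobic"] - 0.4 * f["acidic"],
                "ADP": 0.8 * f["proline"] + 0.5 * f["small"] + 0.3 * f["short"],
                "AHP": 0.7 * f["aromatic"] + 0.6 * f["proline"] + 0.3 * f["short"],
                "AIP": 0.6 * f["small"] + 0.4 * f["acidic"],
                "AMP": 1.0 * f["cationic"] + 0.6 * f["hydrophobic"] - 0.5 * f["acidic"],
            }
            scores = {cls: min(max(v, 0.0), 1.0) for cls, v in raw.items()}
            calls = {cls: scores[cls] >= self.THRESHOLD for cls in BIOACTIVITY_CLASSES}
            out.append(
                BioactivityPrediction(
                    sequence=pep,
                    scores=scores,
                    calls=calls,
                    predictor=self.name,
                    version=self.version,
                )
            )
        return out


def predict_bioactivity(
    peptides: Sequence[str], predictor: BioactivityPredictor
) -> list[BioactivityPrediction]:
    """Run ``predictor`` on ``peptides`` and enforce the totality contract."""
    predictions = predictor.predict(list(peptides))
    if len(predictions) != len(peptides):
        raise PredictionError(
            f"predictor {predictor.name!r} returned {len(predictions)} predictions "
            f"for {len(peptides)} peptides"
        )
    return predictions
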