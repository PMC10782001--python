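"""Core domain types shared across the pipeline.

Conventions
-----------
* Residue coordinates are 1-based and inclusive everywhere in the public
  interface, matching the CAID per-residue file dialect.
* Per-residue label series are numpy integer arrays over {0, 1}; score
  series are float arrays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class ReferenceEntry:
    """One benchmark protein: sequence plus per-residue annotations.

    Parameters
    ----------
    id : str
        Accession (header token before the first whitespace).
    sequence : str
        Amino-acid sequence, length ``L >= 1``.
    disorder : numpy.ndarray
        Per-residue disorder labels over {0, 1}, length ``L``.
    binding : numpy.ndarray, optional
        Per-residue binding labels over {0, 1}, length ``L``.  Binding is
        annotated at the region level: an entire disordered region is
        flagged even if only some of its residues contact the partner.
    """

    id: str
    sequence: str
    disorder: np.ndarray
    binding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=np.int8)
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if self.disorder.shape[0] != len(self.sequence):
            raise ValueError(
                f"{self.id}: disorder length {self.disorder.shape[0]} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.binding is not None:
            self.binding = np.asarray(self.binding, dtype=np.int8)
            if self.binding.shape[0] != len(self.sequence):
                raise ValueError(f"{self.id}: binding length mismatch")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def disorder_content(self) -> float:
        return float(np.mean(self.disorder))


@dataclass
class ScoreProfile:
    """Per-residue disorder propensities for one protein from one method."""

    id: str
    method: str
    scores: np.ndarray
    binary: Optional[np.ndarray] = None
    residues: Optional[str] = None  # residue letters, when known

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.binary is not None:
            self.binary = np.asarray(self.binary, dtype=np.int8)
            if self.binary.shape[0] != self.scores.shape[0]:
                raise ValueError(f"{self.id}: binary/scores length mismatch")

    def __len__(self) -> int:
        return int(self.scores.shape[0])


#: Allowed kinds for a ResidueSeries and their value ranges.
SERIES_KINDS = ("plddt", "asa", "rsa")


@dataclass
class ResidueSeries:
    """A per-residue real series: pLDDT in [0,100], ASA in A^2, or RSA in [0,1]."""

    id: str
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class IdrSegment:
    """A maximal run of disorder-labelled residues (1-based inclusive)."""

    start: int
    end: int
    at_terminus: bool = False
    binding: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; disorder is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class BinaryMetrics:
    """MCC, F1 and sensitivity with a degenerate-denominator flag."""

    mcc: float
    f1: float
    sensitivity: float
    degenerate: bool = False


@dataclass(frozen=True)
class CalibratedThreshold:
    """A dataset-wide binarization cut-off.

    ``achieved_count`` is the number of pooled scores strictly above
    ``threshold``; calibration aims it at ``target_count``, the number of
    natively disordered residues in the pool.
    """

    method: str
    threshold: float
    target_count: int
    achieved_count: int


@dataclass
class EvalRecord:
    """Metric values for one method on one dataset."""

    method: str
    dataset: str
    threshold: Optional[float] = None
    coverage: Optional[float] = None
    auc: Optional[float] = None
    auprc: Optional[float] = None
    mcc: Optional[float] = None
    f1: Optional[float] = None
    sensitivity: Optional[float] = None
    mae: Optional[float] = None
    scc: Optional[float] = None
    verdicts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Verdict:
    """Outcome of one paired significance comparison.

    ``symbol`` is '+' when method A is significantly better than method B
    on the metric's natural orientation, '-' when significantly worse, and
    '=' otherwise (p >= alpha).
    """

    method_a: str
    method_b: str
    symbol: str
    p_value: float
    test_used: str


@dataclass
class SubsetPlan:
    """A resampling plan: 20 protein-id subsets plus provenance."""

    mode: str
    subsets: list
    seed: int


@dataclass(frozen=True)
class MarkerVector:
    """The eight per-protein sequence-derived markers.

    ``composite`` is the sum of the distances of predicted-disordered
    residues to the nearest terminus, divided by sequence length; low
    values indicate little predicted disorder and/or terminal disorder.
    ``min_terminus_distance`` uses the sentinel ``seq_length + 1`` when the
    protein has no putative IDR (no run of >= 4 predicted residues).
    """

    seq_length: int
    putative_content: float
    binding_content: float
    n_putative_idrs: int
    max_idr_len: int
    coil_content: float
    min_terminus_distance: int
    composite: float

    FIELDS = (
        "seq_length",
        "putative_content",
        "binding_content",
        "n_putative_idrs",
        "max_idr_len",
        "coil_content",
        "min_terminus_distance",
        "composite",
    )


@dataclass
class CompetitiveSplit:
    """Partition of evaluable proteins by whether the AF2-derived
    predictor is competitive with the field of disorder predictors."""

    competitive: set
    rest: set
    auc_floor: float
    excluded: set = field(default_factory=set)
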