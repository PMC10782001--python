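"""Sequence-derived markers for where an AF2-derived predictor is competitive.

Eight per-protein markers are computed from binary prediction profiles
(disorder, binding-region, coiled-coil): sequence length, putative
disorder content, putative binding-region content, number and maximal
length of putative IDRs (runs of >= 4 predicted disordered residues),
putative coiled-coil content, the distance of putative IDRs to the
closest terminus, and a composite score — the sum of terminus distances
of all predicted disordered residues divided by sequence length.  Low
composite values indicate little predicted disorder and/or disorder at
the termini.

Proteins are split into a *competitive* set — those where the
AF2-derived predictor's per-protein AUC clears a floor (the dataset-level
AUC of the best disorder predictor) and is statistically comparable to
the field of disorder predictors — and the rest.  Marker distributions
between the two groups are compared with a two-sided rank-sum test, and
the below-median selection rule picks proteins whose significant markers
all fall strictly below the competitive group's medians.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedMetricError
from .stratify import extract_idrs
from .types import CompetitiveSplit, MarkerVector, ScoreProfile

logger = logging.getLogger(__name__)

#: Minimum run length for a putative IDR.
PUTATIVE_MIN_LEN = 4

#: Markers the below-median selection rule uses by default.
DEFAULT_ACTIVE_MARKERS = (
    "seq_length", "binding_content", "n_putative_idrs", "composite",
)


def _binary_of(profile) -> np.ndarray:
    if isinstance(profile, ScoreProfile):
        if profile.binary is None:
            raise ParameterError(f"{profile.id}: profile has no binary calls")
        return np.asarray(profile.binary)
    return np.asarray(profile)


def terminus_distances(length: int) -> np.ndarray:
    """Distance of each residue to the nearest terminus: min(i-1, L-i),
    1-based, so terminal residues score 0."""
    i = np.arange(1, length + 1)
    return np.minimum(i - 1, length - i)


def compute_markers(disorder_profile, binding_profile=None,
                    coil_profile=None) -> MarkerVector:
    """Compute the eight markers from binary per-residue profiles.

    The composite score sums terminus distances over *all* predicted
    disordered residues (runs shorter than 4 still contribute), while the
    IDR count, maximal length and terminus distance use only putative
    IDRs (runs of >= 4).  Missing binding/coil profiles give content 0.
    """
    disorder = _binary_of(disorder_profile)
    length = disorder.size
    if length == 0:
        raise ParameterError("empty profile")
    for other in (binding_profile, coil_profile):
        if other is not None and _binary_of(other).size != length:
            raise ParameterError("profile length mismatch")
    distances = terminus_distances(length)
    composite = float(distances[disorder == 1].sum() / length)
    idrs = extract_idrs(disorder, min_len=PUTATIVE_MIN_LEN)
    if idrs:
        max_len = max(s.length for s in idrs)
        min_dist = min(
            int(distances[s.start - 1:s.end].min()) for s in idrs
        )
    else:
        max_len = 0
        min_dist = length + 1  # sentinel: no putative IDR
    return MarkerVector(
        seq_length=length,
        putative_content=float(disorder.mean()),
        binding_content=float(_binary_of(binding_profile).mean())
        if binding_profile is not None else 0.0,
        n_putative_idrs=len(idrs),
        max_idr_len=max_len,
        coil_content=float(_binary_of(coil_profile).mean())
        if coil_profile is not None else 0.0,
        min_terminus_distance=min_dist,
        composite=composite,
    )


def competitive_split(af2_auc: Mapping[str, float], auc_floor: float,
                      predictor_aucs: Mapping[str, Sequence[float]]) -> CompetitiveSplit:
    """Split proteins by whether the AF2-derived predictor is competitive.

    A protein is competitive iff its AF2 AUC strictly exceeds
    ``auc_floor`` *and* is at or above the lower bound of the 95%
    normal-approximation interval (mean - 1.96 sd / sqrt(k)) of its k
    per-protein AUCs from the field of disorder predictors.  Proteins
    with a missing AF2 AUC are excluded with a logged flag.
    """
    competitive: Set[str] = set()
    rest: Set[str] = set()
    excluded: Set[str] = set()
    for pid, aucs in predictor_aucs.items():
        if pid not in af2_auc:
            excluded.add(pid)
            continue
        aucs = np.asarray(aucs, dtype=np.float64)
        if aucs.size < 2:
            raise ParameterError(f"{pid}: need >= 2 predictor AUCs")
        lower = aucs.mean() - 1.96 * aucs.std(ddof=1) / np.sqrt(aucs.size)
        if af2_auc[pid] > auc_floor and af2_auc[pid] >= lower:
            competitive.add(pid)
        else:
            rest.add(pid)
    if excluded:
        logger.warning("%d protein(s) lack an AF2 AUC and were excluded", len(excluded))
    return CompetitiveSplit(competitive=competitive, rest=rest,
                            auc_floor=auc_floor, excluded=excluded)


def compare_marker_distributions(split: CompetitiveSplit,
                                 markers: Mapping[str, MarkerVector]) -> Dict[str, float]:
    """Two-sided rank-sum (Mann-Whitney) p-value per marker between the
    competitive group and the rest; degenerate markers get p = 1."""
    if not split.competitive or not split.rest:
        raise ParameterError("both groups must be non-empty")
    p_values: Dict[str, float] = {}
    for name in MarkerVector.FIELDS:
        x = np.array([getattr(markers[pid], name) for pid in sorted(split.competitive)
                      if pid in markers], dtype=np.float64)
        y = np.array([getattr(markers[pid], name) for pid in sorted(split.rest)
                      if pid in markers], dtype=np.float64)
        if x.size == 0 or y.size == 0:
            raise ParameterError(f"marker {name}: empty group")
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            p_values[name] = 1.0
            continue
        p_values[name] = float(
            stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        )
    return p_values


def group_medians(markers: Mapping[str, MarkerVector],
                  ids: Iterable[str]) -> Dict[str, float]:
    """Per-marker medians over the given protein ids."""
    ids = [pid for pid in ids if pid in markers]
    if not ids:
        raise ParameterError("no markers for the given ids")
    return {
        name: float(np.median([getattr(markers[pid], name) for pid in ids]))
        for name in MarkerVector.FIELDS
    }


def marker_select(markers: Mapping[str, MarkerVector],
                  medians: Mapping[str, float],
                  active: Sequence[str] = DEFAULT_ACTIVE_MARKERS) -> Set[str]:
    """Proteins whose active markers are all strictly below the medians."""
    unknown = set(active) - set(MarkerVector.FIELDS)
    if unknown:
        raise ParameterError(f"unknown markers: {sorted(unknown)}")
    return {
        pid for pid, vec in markers.items()
        if all(getattr(vec, name) < medians[name] for name in active)
    }
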