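"""Transforms from AlphaFold2 outputs to disorder propensity profiles.

Two routes are supported:

* **pLDDT route** — AF2's per-residue confidence is mapped to a disorder
  propensity as ``1 - pLDDT/100``: low structural confidence is read as
  high disorder.
* **RSA route** — DSSP-style accessible surface area is normalized by the
  residue's maximum accessibility in an extended Gly-X-Gly tripeptide,
  then smoothed with a sliding window (default 25 residues).  Unusually
  high solvent accessibility over a window is read as lack of structure.

AF2 emits five ranked models per protein; :func:`select_best_model`
implements the optimized-rank scenario, picking the model whose derived
profile scores the highest per-protein ROC AUC against the reference.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, UndefinedMetricError
from .types import ReferenceEntry, ResidueSeries, ScoreProfile

logger = logging.getLogger(__name__)


def load_max_asa(path=None) -> Dict[str, float]:
    """Load a Gly-X-Gly maximum-ASA table (all 20 standard letters).

    The packaged table ships theoretical values; pass ``path`` to swap in
    another normalization table.
    """
    if path is None:
        source = resources.files("idrbench.data").joinpath("max_asa.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        letter, value = line.split()
        table[letter] = float(value)
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(table)
    if missing:
        raise ValueError(f"max-ASA table missing letters: {sorted(missing)}")
    if any(v <= 0 for v in table.values()):
        raise ValueError("max-ASA values must be strictly positive")
    return table


def plddt_to_disorder(plddt: ResidueSeries, method: str = "af2-plddt") -> ScoreProfile:
    """Map pLDDT (0-100) to disorder propensity ``1 - pLDDT/100``."""
    if plddt.kind != "plddt":
        raise ParameterError(f"expected a plddt series, got {plddt.kind!r}")
    values = plddt.values
    if values.size and (values.min() < 0 or values.max() > 100):
        raise DomainError(f"{plddt.id}: pLDDT values outside [0,100]")
    return ScoreProfile(id=plddt.id, method=method, scores=1.0 - values / 100.0)


def asa_to_rsa(asa: ResidueSeries, sequence: str,
               max_asa: Optional[Dict[str, float]] = None) -> ResidueSeries:
    """Normalize ASA to relative solvent accessibility, capped at 1.

    Unknown residue letter 'X' is normalized by the mean of the 20 table
    values (logged); any other letter outside the table is an error.
    """
    if asa.kind != "asa":
        raise ParameterError(f"expected an asa series, got {asa.kind!r}")
    if len(asa) != len(sequence):
        raise ParameterError(
            f"{asa.id}: ASA length {len(asa)} != sequence length {len(sequence)}"
        )
    table = max_asa if max_asa is not None else load_max_asa()
    mean_max = float(np.mean(list(table.values())))
    denominators = np.empty(len(sequence))
    for i, letter in enumerate(sequence):
        if letter in table:
            denominators[i] = table[letter]
        elif letter == "X":
            logger.warning("%s: unknown residue X at %d; using mean max-ASA", asa.id, i + 1)
            denominators[i] = mean_max
        else:
            raise DomainError(f"{asa.id}: residue {letter!r} not in max-ASA table")
    rsa = np.minimum(1.0, asa.values / denominators)
    return ResidueSeries(id=asa.id, values=rsa, kind="rsa")


def smooth_rsa(rsa: ResidueSeries, window: int = 25,
               method: str = "af2-rsa") -> ScoreProfile:
    """Smooth an RSA series with a centred moving average of odd width.

    The window is truncated at the termini (mean over the in-range part),
    so outputs stay within [min(series), max(series)].
    """
    if rsa.kind != "rsa":
        raise ParameterError(f"expected an rsa series, got {rsa.kind!r}")
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    smoothed = (
        pd.Series(rsa.values)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ScoreProfile(id=rsa.id, method=method, scores=smoothed)


def select_best_model(profiles: Sequence[ScoreProfile],
                      reference: ReferenceEntry) -> ScoreProfile:
    """Pick the ranked model whose profile maximizes per-protein ROC AUC.

    Ties are broken toward AF2's native rank order (earliest profile
    wins).  Degenerate references (single-class labels) raise
    :class:`UndefinedMetricError`; callers exclude such proteins, as is
    done for fully disordered proteins throughout the evaluation.
    """
    from .metrics import roc_auc

    if not 1 <= len(profiles) <= 5:
        raise ParameterError(f"expected 1-5 ranked profiles, got {len(profiles)}")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ParameterError(f"{reference.id}: ranked profiles differ in length")
    labels = reference.disorder
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            f"{reference.id}: single-class labels; exclude this protein"
        )
    best_idx = 0
    best_auc = -np.inf
    for idx, profile in enumerate(profiles):
        auc = roc_auc(profile.scores, labels)
        if auc > best_auc:
            best_auc = auc
            best_idx = idx
    return profiles[best_idx]
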