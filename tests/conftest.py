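"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from idrbench import synthgen


def auc_pairwise(scores, labels) -> float:
    """Brute-force ROC AUC: enumerate every positive-negative pair,
    counting ties as 1/2.  Independent of the library implementation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def make_pdb(residues, missing_ca=()) -> str:
    """Build a minimal single-chain PDB text.

    ``residues`` is a list of (resname, bfactor); indices in
    ``missing_ca`` (0-based) get an N atom instead of a CA.
    """
    lines = []
    serial = 1
    for i, (resname, bfactor) in enumerate(residues):
        name = "N" if i in missing_ca else "CA"
        elem = name[0]
        lines.append(
            f"ATOM  {serial:>5d}  {name:<3s}{resname:>3s} A{i + 1:>4d}    "
            f"{1.0 * i:>8.3f}{0.0:>8.3f}{0.0:>8.3f}{1.00:>6.2f}{bfactor:>6.2f}"
            f"          {elem:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_reference_text() -> str:
    return ">P1\nMKKL\n0110\n>P2\nAAAA\n0000\n"


@pytest.fixture
def small_benchmark():
    """A small synthetic benchmark: entries plus two predictors of
    different strength, reused across integration tests."""
    cfg = synthgen.GenConfig(n_proteins=120, seed=11)
    entries = synthgen.gen_reference(cfg)
    strong = synthgen.gen_predictor(entries, (0.0, 1.5, 1.0), seed=11, method="strong")
    weak = synthgen.gen_predictor(entries, (0.0, 0.5, 1.0), seed=11, method="weak")
    return entries, strong, weak
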