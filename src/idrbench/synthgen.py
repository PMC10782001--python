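"""Synthetic benchmark generator.

Emulates the three kinds of inputs the evaluation consumes — annotated
reference proteins, per-residue predictor score profiles, and AF2-style
pLDDT/RSA series — with controllable statistical structure, so every
pipeline stage is testable without external downloads.

Reference proteins alternate ordered and disordered runs with geometric
run lengths; binding labels are painted on whole disordered runs
(region-level annotation).  Defaults approximate the composition of the
CAID DisProt benchmark: ~650 proteins, mean length ~520, disorder
prevalence ~16%, ~1.3 IDRs per protein, ~30% of IDRs binding.

Predictor scores follow a binormal model: a latent class-conditional
normal (mean ``mu0`` on ordered residues, ``mu1`` on disordered, common
``sigma``) squashed to [0,1] by a logistic.  Because ROC AUC is invariant
under the monotone squash, the expected dataset AUC is exactly
``Phi((mu1 - mu0) / (sigma * sqrt(2)))``, which gives the test suite a
closed-form target.

Randomness is threaded through a single master seed: each protein's
stream is derived by stable hashing of (seed, protein id, stream tag),
so generation is reproducible independent of iteration order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .types import ReferenceEntry, ResidueSeries, ScoreProfile

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class GenConfig:
    """Generator parameters; defaults approximate the CAID benchmark."""

    n_proteins: int = 646
    length_log_mean: float = 6.0   # lognormal: median ~400, mean ~520
    length_log_sd: float = 0.7
    min_length: int = 30
    mean_idr_len: float = 65.0     # geometric mean run lengths
    mean_ordered_len: float = 340.0  # -> prevalence ~ 65/405 ~ 0.16
    p_terminus: float = 0.3        # P(a sequence end falls in an IDR)
    p_binding: float = 0.31        # P(a disordered run is binding)
    p_fdp: float = 0.07            # P(protein is fully disordered)
    fdp_length_log_mean: float = 4.9  # FDPs are short: median ~134 residues
    fdp_length_log_sd: float = 0.5
    score_law: Tuple[float, float, float] = (0.0, 1.0, 1.0)  # mu0, mu1, sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score_law[2] <= 0:
            raise ValueError("sigma must be > 0")
        for p in (self.p_terminus, self.p_binding, self.p_fdp):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if min(self.mean_idr_len, self.mean_ordered_len) < 1:
            raise ValueError("mean run lengths must be >= 1")


def _rng_for(seed: int, *tags: str) -> np.random.Generator:
    """Per-stream RNG keyed by stable CRC32 hashes of the tags."""
    entropy = [seed] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def binormal_auc(mu0: float, mu1: float, sigma: float) -> float:
    """Closed-form expected ROC AUC of the binormal score model."""
    from scipy.stats import norm

    return float(norm.cdf((mu1 - mu0) / (sigma * math.sqrt(2.0))))


def _gen_labels(rng: np.random.Generator, length: int, cfg: GenConfig):
    """Alternating geometric runs; returns (disorder, binding) arrays."""
    disorder = np.zeros(length, dtype=np.int8)
    binding = np.zeros(length, dtype=np.int8)
    start_disordered = rng.random() < cfg.p_terminus
    end_disordered = rng.random() < cfg.p_terminus
    pos = 0
    is_disordered = start_disordered
    runs: List[Tuple[int, int, bool]] = []
    while pos < length:
        mean = cfg.mean_idr_len if is_disordered else cfg.mean_ordered_len
        run = int(rng.geometric(1.0 / mean))
        end = min(pos + run, length)
        runs.append((pos, end, is_disordered))
        pos = end
        is_disordered = not is_disordered
    # honour the end-terminus draw: a disordered run truncated by the
    # sequence end is re-typed ordered unless the end was drawn disordered
    if runs and runs[-1][2] and not end_disordered:
        start, end, _ = runs[-1]
        runs[-1] = (start, end, False)
    for start, end, dis in runs:
        if dis:
            disorder[start:end] = 1
            if rng.random() < cfg.p_binding:
                binding[start:end] = 1
    return disorder, binding


def gen_reference(cfg: GenConfig) -> List[ReferenceEntry]:
    """Generate annotated reference proteins; deterministic under seed."""
    entries = []
    for i in range(cfg.n_proteins):
        pid = f"SYN{i:05d}"
        rng = _rng_for(cfg.seed, pid, "reference")
        if rng.random() < cfg.p_fdp:
            # fully disordered protein: one IDR spanning a short chain
            length = max(
                cfg.min_length,
                int(round(rng.lognormal(cfg.fdp_length_log_mean,
                                        cfg.fdp_length_log_sd))),
            )
            disorder = np.ones(length, dtype=np.int8)
            binding = np.zeros(length, dtype=np.int8)
            if rng.random() < cfg.p_binding:
                binding[:] = 1
        else:
            length = max(
                cfg.min_length,
                int(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd))),
            )
            disorder, binding = _gen_labels(rng, length, cfg)
        sequence = "".join(rng.choice(AMINO_ACIDS, size=length))
        entries.append(
            ReferenceEntry(id=pid, sequence=sequence, disorder=disorder,
                           binding=binding)
        )
    return entries


def gen_predictor(entries: Sequence[ReferenceEntry],
                  score_law: Tuple[float, float, float],
                  seed: int, method: str = "synth") -> List[ScoreProfile]:
    """Binormal score profiles for each entry (see module docstring)."""
    mu0, mu1, sigma = score_law
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    profiles = []
    for entry in entries:
        rng = _rng_for(seed, entry.id, f"predictor:{method}")
        latent = np.where(entry.disorder == 1, mu1, mu0) + sigma * rng.standard_normal(
            entry.length
        )
        profiles.append(
            ScoreProfile(id=entry.id, method=method, scores=logistic(latent),
                         residues=entry.sequence)
        )
    return profiles


def _smoothed_noise(rng: np.random.Generator, length: int, window: int) -> np.ndarray:
    """Unit-variance noise with short-range autocorrelation."""
    raw = rng.standard_normal(length + window - 1)
    kernel = np.ones(window) / window
    smooth = np.convolve(raw, kernel, mode="valid")
    return smooth * math.sqrt(window)  # restore unit variance


def gen_af2_series(entries: Sequence[ReferenceEntry], quality: float = 1.0,
                   autocorr_window: int = 9, seed: int = 0,
                   ) -> Tuple[List[ResidueSeries], List[ResidueSeries]]:
    """Paired pLDDT and RSA series per entry.

    pLDDT is anti-correlated with disorder and RSA elevated in disordered
    runs; ``quality`` scales the class separation (0 = uninformative) and
    the noise carries moving-average autocorrelation, mimicking the
    spatial smoothness of structure-derived signals.
    """
    if quality < 0:
        raise ValueError("quality must be >= 0")
    plddt_series = []
    rsa_series = []
    for entry in entries:
        signed = quality * (entry.disorder.astype(np.float64) - 0.5)
        rng_p = _rng_for(seed, entry.id, "af2:plddt")
        rng_r = _rng_for(seed, entry.id, "af2:rsa")
        latent_p = signed + _smoothed_noise(rng_p, entry.length, autocorr_window)
        latent_r = signed + _smoothed_noise(rng_r, entry.length, autocorr_window)
        plddt = np.clip(100.0 * (1.0 - logistic(latent_p)), 0.0, 100.0)
        rsa = np.clip(logistic(latent_r), 0.0, 1.0)
        plddt_series.append(ResidueSeries(id=entry.id, values=plddt, kind="plddt"))
        rsa_series.append(ResidueSeries(id=entry.id, values=rsa, kind="rsa"))
    return plddt_series, rsa_series


def gen_model_ranks(entries: Sequence[ReferenceEntry], qualities: Sequence[float],
                    seed: int = 0) -> List[List[ResidueSeries]]:
    """Per-entry ranked pLDDT series of varying quality (one per rank)."""
    per_rank = [
        gen_af2_series(entries, quality=q, seed=seed + 1000 * (k + 1))[0]
        for k, q in enumerate(qualities)
    ]
    return [[per_rank[k][i] for k in range(len(qualities))]
            for i in range(len(entries))]
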