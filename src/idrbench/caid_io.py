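"""Readers and writers for the external formats the pipeline touches.

Dialects
--------
* CAID reference file: FASTA-like records — a ``>`` header, one or more
  sequence lines, then a single annotation line of identical total length
  over ``{0,1}``.  Other annotation characters (masks such as ``-``) are
  rejected.
* CAID prediction file: per-protein ``>`` header followed by tab- or
  whitespace-separated data lines ``position  residue  score  [binary]``
  with contiguous 1-based positions.
* AF2 model: PDB coordinate format with per-residue pLDDT stored in the
  temperature-factor column.
* ASA table: per-residue TSV ``position  residue  ASA`` in square angstroms.

Identifier matching between files is exact string equality on the header
token before the first whitespace.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import FormatError
from .types import ReferenceEntry, ResidueSeries, ScoreProfile

logger = logging.getLogger(__name__)

#: Scores may overshoot [0,1] by at most this much before parsing fails.
SCORE_CLAMP_TOLERANCE = 0.05


def _header_token(line: str) -> str:
    return line[1:].strip().split()[0]


def _split_records(lines: Sequence[str]) -> List[tuple]:
    """Group stripped, non-empty lines into (id, body_lines) records."""
    records = []
    current_id = None
    body: List[str] = []
    for line in lines:
        line = line.rstrip("\n").strip()
        if not line:
            continue
        if line.startswith(">"):
            if current_id is not None:
                records.append((current_id, body))
            current_id = _header_token(line)
            body = []
        else:
            if current_id is None:
                raise FormatError("data line before the first '>' header")
            body.append(line)
    if current_id is not None:
        records.append((current_id, body))
    return records


def _parse_annotated_records(path) -> Dict[str, tuple]:
    """Parse a FASTA-like annotated file into ``id -> (sequence, labels)``."""
    with open(path) as fh:
        records = _split_records(fh.readlines())
    out: Dict[str, tuple] = {}
    for rec_id, body in records:
        if len(body) < 2:
            raise FormatError(
                f"record {rec_id}: expected sequence line(s) plus an annotation line"
            )
        annotation = body[-1]
        sequence = "".join(body[:-1])
        if set(annotation) - {"0", "1"}:
            bad = sorted(set(annotation) - {"0", "1"})
            raise FormatError(
                f"record {rec_id}: annotation characters outside {{0,1}}: {bad}"
            )
        if len(annotation) != len(sequence):
            raise FormatError(
                f"record {rec_id}: annotation length {len(annotation)} "
                f"!= sequence length {len(sequence)}"
            )
        if rec_id in out:
            raise FormatError(f"duplicate identifier {rec_id}")
        labels = np.frombuffer(annotation.encode(), dtype=np.uint8) - ord("0")
        out[rec_id] = (sequence, labels.astype(np.int8))
    return out


def read_reference(path, binding_path=None) -> List[ReferenceEntry]:
    """Read a CAID-style disorder reference file.

    When ``binding_path`` is given, binding labels are joined onto matching
    identifiers; records present only in the binding file are ignored with
    a logged warning.  Joining never alters disorder labels.
    """
    disorder = _parse_annotated_records(path)
    binding: Dict[str, tuple] = {}
    if binding_path is not None:
        binding = _parse_annotated_records(binding_path)
        orphan = set(binding) - set(disorder)
        if orphan:
            logger.warning(
                "%d binding-file record(s) have no disorder record and are "
                "ignored: %s", len(orphan), sorted(orphan)[:5],
            )
    entries = []
    for rec_id, (sequence, labels) in disorder.items():
        bind = None
        if rec_id in binding:
            bseq, blab = binding[rec_id]
            if len(blab) != len(labels):
                raise FormatError(
                    f"record {rec_id}: binding annotation length {len(blab)} "
                    f"!= disorder annotation length {len(labels)}"
                )
            bind = blab
        entries.append(
            ReferenceEntry(id=rec_id, sequence=sequence, disorder=labels, binding=bind)
        )
    return entries


def _parse_score(token: str, rec_id: str, pos: int) -> float:
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(
            f"record {rec_id}, position {pos}: unparseable score {token!r}"
        ) from exc
    if value < 0.0 or value > 1.0:
        excess = max(-value, value - 1.0)
        if excess > SCORE_CLAMP_TOLERANCE + 1e-9:  # guard float rounding
            raise FormatError(
                f"record {rec_id}, position {pos}: score {value} outside [0,1] "
                f"by more than {SCORE_CLAMP_TOLERANCE}"
            )
        clamped = min(1.0, max(0.0, value))
        logger.warning(
            "record %s, position %d: score %s clamped to %s", rec_id, pos, value, clamped
        )
        value = clamped
    return value


def read_prediction(path, method: Optional[str] = None) -> List[ScoreProfile]:
    """Read a CAID-style per-residue prediction file.

    Each record is a ``>`` header followed by lines of
    ``position residue score [binary]``.  Positions must be contiguous
    from 1.  Scores marginally outside [0,1] are clamped with a warning.
    The method name defaults to the file stem.
    """
    path = Path(path)
    if method is None:
        method = path.stem
    with open(path) as fh:
        records = _split_records(fh.readlines())
    profiles = []
    seen = set()
    for rec_id, body in records:
        if rec_id in seen:
            raise FormatError(f"duplicate identifier {rec_id}")
        seen.add(rec_id)
        scores: List[float] = []
        binaries: List[int] = []
        letters: List[str] = []
        has_binary = None
        for expected_pos, line in enumerate(body, start=1):
            fields = line.split()
            if len(fields) not in (3, 4):
                raise FormatError(
                    f"record {rec_id}: expected 3 or 4 fields, got {len(fields)}: {line!r}"
                )
            try:
                pos = int(fields[0])
            except ValueError as exc:
                raise FormatError(
                    f"record {rec_id}: unparseable position {fields[0]!r}"
                ) from exc
            if pos != expected_pos:
                raise FormatError(
                    f"record {rec_id}: non-contiguous positions "
                    f"(expected {expected_pos}, got {pos})"
                )
            letters.append(fields[1])
            scores.append(_parse_score(fields[2], rec_id, pos))
            row_has_binary = len(fields) == 4
            if has_binary is None:
                has_binary = row_has_binary
            elif has_binary != row_has_binary:
                raise FormatError(f"record {rec_id}: inconsistent binary column")
            if row_has_binary:
                if fields[3] not in ("0", "1"):
                    raise FormatError(
                        f"record {rec_id}: binary value {fields[3]!r} not in {{0,1}}"
                    )
                binaries.append(int(fields[3]))
        profiles.append(
            ScoreProfile(
                id=rec_id,
                method=method,
                scores=np.asarray(scores, dtype=np.float64),
                binary=np.asarray(binaries, dtype=np.int8) if has_binary else None,
                residues="".join(letters),
            )
        )
    return profiles


def write_prediction(profiles: Sequence[ScoreProfile], path) -> None:
    """Write profiles in the CAID prediction dialect (round-trips with
    :func:`read_prediction` to 3 decimals on scores, exactly on binary)."""
    with open(path, "w") as fh:
        for profile in profiles:
            fh.write(f">{profile.id}\n")
            residues = profile.residues or "X" * len(profile)
            for i, score in enumerate(profile.scores):
                row = f"{i + 1}\t{residues[i]}\t{score:.3f}"
                if profile.binary is not None:
                    row += f"\t{int(profile.binary[i])}"
                fh.write(row + "\n")


def read_plddt_from_model(path, chain: Optional[str] = None,
                          model: Optional[int] = None) -> ResidueSeries:
    """Extract per-residue pLDDT from an AF2 model in PDB format.

    pLDDT is stored in the temperature-factor column; the value is taken
    from the alpha-carbon record of each residue, falling back (with a
    logged warning) to the residue's first atom when no CA is present.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure("af2", str(path))
        except Exception as exc:
            raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no ATOM records")
    if len(models) > 1 and model is None:
        raise FormatError(
            f"{path}: {len(models)} models present; pass model= to select one"
        )
    mdl = models[0] if model is None else structure[model]
    chains = [c for c in mdl]
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise FormatError(f"{path}: chain {chain!r} not found")
    elif len(chains) > 1:
        raise FormatError(
            f"{path}: {len(chains)} chains present; pass chain= to select one"
        )
    if not chains:
        raise FormatError(f"{path}: no chains with ATOM records")
    values = []
    for residue in chains[0]:
        if residue.id[0] != " ":  # skip HETATM / water
            continue
        if "CA" in residue:
            values.append(residue["CA"].get_bfactor())
        else:
            first = next(iter(residue))
            logger.warning(
                "%s: residue %s lacks CA; using atom %s",
                path, residue.id[1], first.get_name(),
            )
            values.append(first.get_bfactor())
    if not values:
        raise FormatError(f"{path}: no standard-residue ATOM records")
    return ResidueSeries(id=Path(path).stem, values=np.asarray(values), kind="plddt")


def read_asa_table(path) -> ResidueSeries:
    """Read a per-residue ASA table (``position residue ASA`` per line).

    Header lines starting with ``>`` or ``#`` are skipped; the first
    ``>`` header, when present, names the series.
    """
    path = Path(path)
    series_id = path.stem
    values: List[float] = []
    expected_pos = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                series_id = _header_token(line)
                continue
            if line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: expected 3 fields, got {line!r}")
            try:
                pos = int(fields[0])
                asa = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable line {line!r}") from exc
            if pos != expected_pos:
                raise FormatError(
                    f"{path}: non-contiguous positions (expected {expected_pos}, got {pos})"
                )
            if asa < 0:
                raise FormatError(f"{path}: negative ASA {asa} at position {pos}")
            values.append(asa)
            expected_pos += 1
    if not values:
        logger.warning("%s: empty ASA table", path)
    return ResidueSeries(id=series_id, values=np.asarray(values), kind="asa")


def write_reference(entries: Sequence[ReferenceEntry], path,
                    labels: str = "disorder") -> None:
    """Write entries in the CAID reference dialect.

    ``labels`` selects which label series goes on the annotation line
    ('disorder' or 'binding'); entries lacking binding labels are skipped
    when writing a binding file.
    """
    with open(path, "w") as fh:
        for entry in entries:
            series = entry.disorder if labels == "disorder" else entry.binding
            if series is None:
                continue
            fh.write(f">{entry.id}\n{entry.sequence}\n")
            fh.write("".join(str(int(v)) for v in series) + "\n")
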