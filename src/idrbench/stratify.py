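"""IDR segmentation and benchmark dataset construction.

Native IDRs are maximal runs of disorder-labelled residues.  Proteins are
stratified into overlapping subsets by the size, location and function of
their IDRs:

* ``shortIDR`` — at least one IDR and all IDRs of length <= 30;
* ``longIDR`` — at least one IDR of length > 30;
* ``bindingIDR`` — at least one binding-annotated IDR;
* ``non-terminusIDR`` — at least one IDR, none touching residue 1 or L;
* ``FDP99``/``FDP90``/``FDP80`` — disorder content strictly above the
  cut-off (nested sets of fully disordered proteins).

The >30 threshold separates domain-sized disordered regions from shorter
linkers and loops.  Binding is annotated at the region level: one binding
residue flags the whole IDR.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import IdrSegment, ReferenceEntry

LONG_IDR_THRESHOLD = 30

DATASET_ORDER = (
    "CAID", "shortIDR", "longIDR", "bindingIDR", "non-terminusIDR",
    "FDP99", "FDP90", "FDP80",
)


def extract_idrs(labels: Sequence[int], min_len: int = 1) -> List[IdrSegment]:
    """Maximal runs of 1s with length >= ``min_len``, in ascending order.

    ``at_terminus`` is true iff the run includes residue 1 or residue L.
    Native IDRs use ``min_len=1``; putative IDRs in the marker analysis
    use ``min_len=4``.
    """
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise ParameterError("labels must be over {0,1}")
    length = labels.size
    if length == 0:
        return []
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0] + 1  # 1-based
    ends = np.nonzero(diff == -1)[0]
    segments = []
    for start, end in zip(starts, ends):
        if end - start + 1 < min_len:
            continue
        segments.append(
            IdrSegment(
                start=int(start),
                end=int(end),
                at_terminus=(start == 1 or end == length),
            )
        )
    return segments


def paint_segments(segments: Iterable[IdrSegment], length: int) -> np.ndarray:
    """Inverse of :func:`extract_idrs`: paint segments back to a 0/1 series."""
    labels = np.zeros(length, dtype=np.int8)
    for seg in segments:
        labels[seg.start - 1:seg.end] = 1
    return labels


def flag_binding(segments: Sequence[IdrSegment],
                 binding: Sequence[int]) -> List[IdrSegment]:
    """Set ``binding`` on each segment iff any of its residues is binding."""
    binding = np.asarray(binding)
    out = []
    for seg in segments:
        flag = bool(binding[seg.start - 1:seg.end].any())
        out.append(IdrSegment(start=seg.start, end=seg.end,
                              at_terminus=seg.at_terminus, binding=flag))
    return out


def entry_idrs(entry: ReferenceEntry, min_len: int = 1) -> List[IdrSegment]:
    """Native IDRs of one entry, with binding flags when labels exist."""
    segments = extract_idrs(entry.disorder, min_len=min_len)
    if entry.binding is not None:
        segments = flag_binding(segments, entry.binding)
    return segments


def build_datasets(entries: Sequence[ReferenceEntry]) -> Dict[str, Set[str]]:
    """Assign every protein to its benchmark datasets (id -> tag set)."""
    membership: Dict[str, Set[str]] = {}
    for entry in entries:
        tags = {"CAID"}
        segments = entry_idrs(entry)
        if segments:
            lengths = [s.length for s in segments]
            if max(lengths) > LONG_IDR_THRESHOLD:
                tags.add("longIDR")
            else:
                tags.add("shortIDR")
            if any(s.binding for s in segments):
                tags.add("bindingIDR")
            if not any(s.at_terminus for s in segments):
                tags.add("non-terminusIDR")
        content = entry.disorder_content
        for cutoff, tag in ((0.99, "FDP99"), (0.90, "FDP90"), (0.80, "FDP80")):
            if content > cutoff:
                tags.add(tag)
        if entry.id in membership:
            raise ParameterError(f"duplicate entry id {entry.id}")
        membership[entry.id] = tags
    return membership


def dataset_members(membership: Dict[str, Set[str]], dataset: str) -> Set[str]:
    return {pid for pid, tags in membership.items() if dataset in tags}


def _qualifying_idrs(dataset: str, segments: Sequence[IdrSegment]) -> List[IdrSegment]:
    """The IDR population a dataset's median length is computed over."""
    if dataset == "bindingIDR":
        return [s for s in segments if s.binding]
    if dataset == "shortIDR":
        return [s for s in segments if s.length <= LONG_IDR_THRESHOLD]
    return list(segments)


def dataset_summary(membership: Dict[str, Set[str]],
                    entries: Sequence[ReferenceEntry]) -> pd.DataFrame:
    """Per-dataset counts of proteins, IDRs, disordered residues, and the
    median length of the dataset's qualifying IDRs."""
    by_id = {e.id: e for e in entries}
    rows = []
    for dataset in DATASET_ORDER:
        members = dataset_members(membership, dataset)
        n_idrs = 0
        n_res = 0
        qualifying_lengths: List[int] = []
        for pid in members:
            entry = by_id[pid]
            segments = entry_idrs(entry)
            n_idrs += len(segments)
            n_res += int(entry.disorder.sum())
            qualifying_lengths.extend(
                s.length for s in _qualifying_idrs(dataset, segments)
            )
        rows.append({
            "dataset": dataset,
            "n_proteins": len(members),
            "n_idrs": n_idrs,
            "n_disordered_residues": n_res,
            "median_idr_length": float(np.median(qualifying_lengths))
            if qualifying_lengths else float("nan"),
        })
    return pd.DataFrame(rows)


def write_membership(membership: Dict[str, Set[str]], path) -> None:
    """Emit membership as a two-column TSV (id, comma-joined tags)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tdatasets\n")
        for pid in sorted(membership):
            tags = [t for t in DATASET_ORDER if t in membership[pid]]
            fh.write(f"{pid}\t{','.join(tags)}\n")
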