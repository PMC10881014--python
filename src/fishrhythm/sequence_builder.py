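"""Grouping annotated elements into call sequences and presumed individuals.

A call sequence is a temporally ordered run of at least three elements from
one recording, terminated by a prolonged silence (10 s by convention for long
files; for 1-minute excerpts the whole excerpt is one sequence).  In long
recordings, sequences whose elements share a very similar signal-to-noise
ratio are attributed to the same presumed (stationary) individual, which is
what makes intra- vs inter-individual beat variability measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .selection_io import ElementRecord, RecordingMeta

__all__ = [
    "CallSequence",
    "segment_sequences",
    "split_runs",
    "assign_individuals",
    "beat_range_size",
]


@dataclass(frozen=True)
class CallSequence:
    """An ordered run of >= 3 elements attributed to one presumed individual."""

    elements: tuple[ElementRecord, ...]
    source_id: str
    individual_id: str | None = None
    meta: RecordingMeta | None = None
    max_silence_s: float = math.inf

    def __post_init__(self) -> None:
        if len(self.elements) < 3:
            raise ValueError(
                f"a call sequence needs at least 3 elements, got {len(self.elements)}"
            )
        onsets = [e.begin_s for e in self.elements]
        if any(b >= a for a, b in zip(onsets[1:], onsets[:-1])):
            raise ValueError("element onsets must be strictly increasing")
        for prev, nxt in zip(self.elements[:-1], self.elements[1:]):
            if nxt.begin_s - prev.end_s >= self.max_silence_s:
                raise ValueError(
                    f"internal silence between selections {prev.selection_id} and "
                    f"{nxt.selection_id} exceeds the termination threshold"
                )

    @property
    def onsets_s(self) -> np.ndarray:
        """Element onset times in seconds, strictly increasing."""
        return np.array([e.begin_s for e in self.elements], dtype=float)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def _check_stream(elements: Sequence[ElementRecord]) -> None:
    sources = {e.source_id for e in elements}
    if len(sources) > 1:
        raise ValueError(f"elements come from multiple recordings: {sorted(sources)}")
    for prev, nxt in zip(elements[:-1], elements[1:]):
        if nxt.begin_s < prev.begin_s:
            raise ValueError(
                f"elements are not sorted by onset (selection {prev.selection_id} "
                f"before {nxt.selection_id})"
            )
        if nxt.begin_s < prev.end_s:
            raise ValueError(
                f"selections {prev.selection_id} and {nxt.selection_id} overlap in time; "
                "overlapping annotations indicate an annotation error in a "
                "single-caller sequence"
            )


def split_runs(
    elements: Sequence[ElementRecord],
    max_silence_s: float = 10.0,
) -> list[list[ElementRecord]]:
    """Split a sorted element stream into maximal runs separated by silence.

    Silence is the gap between the *offset* of one element and the *onset* of
    the next; a run ends as soon as that gap reaches ``max_silence_s``.
    """
    if max_silence_s <= 0:
        raise ValueError(f"max_silence_s must be positive, got {max_silence_s}")
    _check_stream(elements)
    runs: list[list[ElementRecord]] = []
    current: list[ElementRecord] = []
    for element in elements:
        if current and element.begin_s - current[-1].end_s >= max_silence_s:
            runs.append(current)
            current = []
        current.append(element)
    if current:
        runs.append(current)
    return runs


def segment_sequences(
    elements: Sequence[ElementRecord],
    max_silence_s: float = 10.0,
    min_elements: int = 3,
    meta: RecordingMeta | None = None,
) -> list[CallSequence]:
    """Build call sequences from one recording's sorted element stream.

    Runs shorter than ``min_elements`` are discarded (a "sequence" requires a
    repetition of at least three elements).  Pass ``max_silence_s=math.inf``
    for the 1-minute-excerpt protocol, where the whole excerpt is one
    sequence regardless of internal gaps.
    """
    if min_elements < 3:
        raise ValueError(f"min_elements must be >= 3, got {min_elements}")
    if not elements:
        return []
    runs = split_runs(elements, max_silence_s=max_silence_s)
    source_id = elements[0].source_id
    return [
        CallSequence(
            elements=tuple(run),
            source_id=source_id,
            meta=meta,
            max_silence_s=max_silence_s,
        )
        for run in runs
        if len(run) >= min_elements
    ]


def _median_snr(sequence: CallSequence) -> float | None:
    snrs = [e.snr_db for e in sequence.elements]
    if any(s is None for s in snrs):
        if any(s is not None for s in snrs):
            raise ValueError(
                f"{sequence.source_id}: mixed presence/absence of SNR within one "
                "sequence; individual attribution is ambiguous"
            )
        return None
    return float(np.median([float(s) for s in snrs]))


def assign_individuals(
    sequences: Sequence[CallSequence],
    snr_tolerance_db: float = 1.0,
    one_per_file: bool = False,
) -> list[CallSequence]:
    """Attribute sequences from one recording to presumed individuals.

    Two sequences are attributed to the same individual when their median
    element SNRs differ by at most ``snr_tolerance_db``, chained transitively
    in time order (a stationary fish keeps a near-constant SNR).  Sequences
    without SNR each get a fresh identifier.  With ``one_per_file=True`` every
    sequence in the recording is attributed to the same individual — the
    convention for 1-minute excerpts, where excerpts (files) rather than
    SNR carry the individual attribution.
    """
    if not sequences:
        return []
    sources = {s.source_id for s in sequences}
    if len(sources) > 1:
        raise ValueError(f"sequences come from multiple recordings: {sorted(sources)}")
    source_id = sequences[0].source_id

    if one_per_file:
        return [replace(s, individual_id=f"{source_id}:ind1") for s in sequences]

    medians = [_median_snr(s) for s in sequences]
    with_snr = [m is not None for m in medians]
    if any(with_snr) and not all(with_snr):
        raise ValueError(
            f"{source_id}: some sequences have SNR and some do not; "
            "individual attribution is ambiguous"
        )

    labels: list[int] = []
    if not any(with_snr):
        labels = list(range(len(sequences)))
    else:
        # Transitive chaining in time order: join the cluster of the earliest
        # previous sequence within tolerance, else start a new one.
        next_label = 0
        for i, med in enumerate(medians):
            assigned = None
            for j in range(i):
                if abs(med - medians[j]) <= snr_tolerance_db:  # type: ignore[operator]
                    assigned = labels[j]
                    break
            if assigned is None:
                assigned = next_label
                next_label += 1
            labels.append(assigned)

    return [
        replace(s, individual_id=f"{source_id}:ind{label + 1}")
        for s, label in zip(sequences, labels)
    ]


def beat_range_size(beats_hz: Sequence[float]) -> float:
    """Difference between the fastest and slowest beat (Hz) in a collection.

    Computed per individual it measures intra-individual beat variability;
    computed over a whole dataset it measures the inter-individual spread.
    """
    if len(beats_hz) == 0:
        raise ValueError("beat_range_size needs at least one beat estimate")
    beats = np.asarray(beats_hz, dtype=float)
    return float(beats.max() - beats.min())
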