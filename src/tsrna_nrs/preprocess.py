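"""Adapter trimming and read collapsing.

Small-RNA inserts are shorter than the read, so the 3' sequencing adapter
(or a prefix of it, when the read ends inside the adapter) must be removed
before counting. Collapsing then reduces each sample to unique sequences
with counts; a feature is only considered supported when it is seen more
than once across all samples.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .seq import normalize


def trim_adapters(
    reads: Iterable[str],
    adapter: str,
    min_length: int = 18,
    min_partial_overlap: int = 3,
) -> list[str]:
    """Trim the 3' adapter from each read and drop short inserts.

    The earliest occurrence of the full adapter truncates the read there;
    otherwise the longest adapter *prefix* of length >= ``min_partial_overlap``
    that is a suffix of the read is removed (partial adapter at the read end).
    Reads shorter than ``min_length`` after trimming are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = normalize(adapter)
    if len(adapter) < min_partial_overlap:
        raise ValueError("adapter shorter than min_partial_overlap")
    out: list[str] = []
    for read in reads:
        read = normalize(read)
        idx = read.find(adapter)
        if idx >= 0:
            trimmed = read[:idx]
        else:
            trimmed = read
            for k in range(min(len(adapter) - 1, len(read)), min_partial_overlap - 1, -1):
                if read.endswith(adapter[:k]):
                    trimmed = read[: len(read) - k]
                    break
        if len(trimmed) >= min_length:
            out.append(trimmed)
    return out


def collapse_reads(reads_per_sample: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Collapse trimmed reads to unique sequences with per-sample counts.

    Returns a DataFrame with columns ``sequence``, one count column per
    sample, ``total`` and ``feature_flag`` (total > 1), sorted
    lexicographically by sequence so output files are reproducible.
    """
    samples = list(reads_per_sample)
    counts: dict[str, dict[str, int]] = {}
    for sample in samples:
        for read in reads_per_sample[sample]:
            row = counts.setdefault(read, dict.fromkeys(samples, 0))
            row[sample] += 1
    df = pd.DataFrame(
        [{"sequence": seq, **row} for seq, row in counts.items()],
        columns=["sequence", *samples],
    )
    if df.empty:
        df = pd.DataFrame(columns=["sequence", *samples])
    df = df.sort_values("sequence", kind="mergesort").reset_index(drop=True)
    df["total"] = df[samples].sum(axis=1) if samples else 0
    df["feature_flag"] = df["total"] > 1
    return df
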