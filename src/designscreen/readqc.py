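"""Quality control of selection-pool sequencing reads.

Turns FASTQ pools from a selection experiment (phage rounds, yeast
two-hybrid pools) into per-variant read-count tables: Phred-quality read
filtering with an optional low-quality-position exemption, extraction and
translation of the designed variant window between fixed flanking anchors,
and thresholded tallying into a :class:`ReadCountTable`.

The default thresholds mirror common deep-sequencing practice for selection
pools: a minimum Phred of 30 across the read (with an optional allowance of
a few positions down to Phred 20), and per-variant count minima of 2 for
phage pools and 5 for Y2H pools.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .codons import NT_ALPHABET, STOP_CHAR, translate

__all__ = [
    "ReadCountTable",
    "ReadTemplate",
    "parse_fastq",
    "filter_reads",
    "extract_variant_window",
    "tally_variants",
    "PHAGE_MIN_COUNT",
    "Y2H_MIN_COUNT",
]

PHAGE_MIN_COUNT = 2
Y2H_MIN_COUNT = 5


@dataclass
class ReadCountTable:
    """Variant-by-channel integer read counts with per-channel thresholds.

    Rows are amino-acid window sequences; columns are channel identifiers
    (e.g. ``phage_r4``, ``y2h``). ``thresholds`` records the minimum count
    applied to each channel; after thresholding every retained non-zero
    entry meets its channel's minimum.
    """

    df: pd.DataFrame
    thresholds: dict[str, int] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "ReadCountTable":
        return cls(pd.DataFrame(dtype=np.int64))

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], channel: str, min_count: int = 0
    ) -> "ReadCountTable":
        kept = {k: int(v) for k, v in counts.items() if v >= min_count}
        df = pd.DataFrame({channel: pd.Series(kept, dtype=np.int64)})
        df.index.name = "window_seq"
        return cls(df.sort_index(), {channel: min_count})

    @property
    def channels(self) -> list[str]:
        return list(self.df.columns)

    def counts(self, channel: str) -> pd.Series:
        col = self.df[channel].fillna(0).astype(np.int64)
        return col[col > 0]

    def merge(self, other: "ReadCountTable") -> "ReadCountTable":
        df = self.df.join(other.df, how="outer").fillna(0).astype(np.int64)
        return ReadCountTable(df.sort_index(), {**self.thresholds, **other.thresholds})

    def total(self, channel: str) -> int:
        return int(self.df[channel].fillna(0).sum())

    def to_tsv(self, handle: IO[str] | str) -> None:
        """Write counts as TSV with a header block recording the thresholds."""
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            for ch in self.channels:
                handle.write(f"# min_count\t{ch}\t{self.thresholds.get(ch, 0)}\n")
            self.df.fillna(0).astype(np.int64).to_csv(handle, sep="\t")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_tsv(cls, handle: IO[str] | str) -> "ReadCountTable":
        close = False
        if isinstance(handle, str):
            handle, close = open(handle), True
        try:
            thresholds: dict[str, int] = {}
            lines = []
            for line in handle:
                if line.startswith("# min_count\t"):
                    _, ch, val = line.rstrip("\n").split("\t")
                    thresholds[ch] = int(val)
                else:
                    lines.append(line)
            df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
            return cls(df.astype(np.int64), thresholds)
        finally:
            if close:
                handle.close()


@dataclass(frozen=True)
class ReadTemplate:
    """Layout of a read: fixed 5'/3' anchors flanking the in-frame window."""

    left_anchor: str = "GCTAGCACTAGT"
    right_anchor: str = "GGATCCGAATTC"
    window_length: int = 18  # residues


DEFAULT_TEMPLATE = ReadTemplate()


def parse_fastq(handle: IO[str] | str) -> Iterator[SeqRecord]:
    """Iterate FASTQ records (Phred+33), raising on malformed records.

    Accepts an open text handle or a path (``.gz`` paths are decompressed
    transparently). Errors are re-raised as ``ValueError`` carrying the
    index of the offending record.
    """
    close = False
    if isinstance(handle, str):
        if handle.endswith(".gz"):
            import gzip

            handle = gzip.open(handle, "rt")
        else:
            handle = open(handle)
        close = True
    idx = 0
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec
            idx += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {idx}: {exc}") from exc
    finally:
        if close:
            handle.close()


def filter_reads(
    reads: Iterable[SeqRecord],
    min_phred: int = 30,
    n_exempt: int = 0,
    exempt_min: int = 20,
    strict: bool = False,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Quality-filter reads on their per-base Phred scores.

    A read passes iff at most ``n_exempt`` positions fall below ``min_phred``
    and every such position still has quality >= ``exempt_min``. The
    threshold is inclusive by default (quality >= ``min_phred`` passes);
    ``strict=True`` requires quality strictly greater than ``min_phred``.
    Returns the passing reads and a tally ``{"pass": ..., "low_quality": ...}``.
    """
    passing: list[SeqRecord] = []
    tally = {"pass": 0, "low_quality": 0}
    for rec in reads:
        quals = np.asarray(rec.letter_annotations["phred_quality"])
        low = quals <= min_phred if strict else quals < min_phred
        n_low = int(low.sum())
        ok = n_low <= n_exempt and (n_low == 0 or quals[low].min() >= exempt_min)
        if ok:
            passing.append(rec)
            tally["pass"] += 1
        else:
            tally["low_quality"] += 1
    return passing, tally


def extract_variant_window(
    read_seq: str, template: ReadTemplate = DEFAULT_TEMPLATE
) -> tuple[str | None, str]:
    """Locate, excise and translate the designed window from one read.

    Returns ``(window_aa, "ok")`` on success, else ``(None, category)`` with
    category one of ``anchor`` (an anchor not found), ``length`` (excised
    segment is not 3 x window_length), ``ambiguous`` (non-ACGT base) or
    ``stop`` (internal stop codon).
    """
    read_seq = str(read_seq).upper()
    start = read_seq.find(template.left_anchor)
    if start < 0:
        return None, "anchor"
    start += len(template.left_anchor)
    end = read_seq.find(template.right_anchor, start)
    if end < 0:
        return None, "anchor"
    window_nt = read_seq[start:end]
    if len(window_nt) != 3 * template.window_length:
        return None, "length"
    if not set(window_nt) <= set(NT_ALPHABET):
        return None, "ambiguous"
    aa = translate(window_nt)
    if STOP_CHAR in aa:
        return None, "stop"
    return aa, "ok"


def tally_variants(
    windows: Iterable[str], channel: str, min_count: int
) -> tuple[ReadCountTable, dict[str, int]]:
    """Count window sequences into one channel, dropping rare variants.

    Variants observed fewer than ``min_count`` times (threshold inclusive:
    a count equal to ``min_count`` is retained) are dropped and reported in
    the returned ``dropped`` map.
    """
    counts = Counter(windows)
    dropped = {k: v for k, v in counts.items() if v < min_count}
    table = ReadCountTable.from_counts(dict(counts), channel, min_count)
    return table, dropped
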