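"""Overlap-merging of paired-end reads via adapter read-through.

When a cDNA fragment is shorter than the read length, each mate sequences
through the fragment into the ligated adapter; the adapter's position in
the read therefore *is* the fragment length. Pairs detected this way are
merged into single-end reads (disagreements resolved by base quality) and
the library is bipartitioned into a merged single-end part and an
untouched paired-end part. Fragments shorter than 20 bases, and pairs
whose mates disagree at more than ten overlapping bases, are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import encode, revcomp

MIN_FRAGMENT = 20
MAX_DISAGREEMENTS = 10


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: matching-length sequence and quality per mate."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.name}")


@dataclass(frozen=True)
class MergeOutcome:
    status: str  # merged, kept_pair, discarded_short, discarded_mismatch
    merged_sequence: str | None = None
    merged_quality: str | None = None
    n_disagreements: int = 0
    n_overlap: int = 0
    fragment_length: int | None = None


def find_adapter(
    sequence: str,
    adapter: str,
    max_adapter_mismatch: int = 0,
    truncated_mismatch: int = 1,
    min_truncated: int = 5,
) -> int | None:
    """Leftmost position of the adapter (or its prefix at the read end).

    A full-length adapter match tolerates ``max_adapter_mismatch``
    substitutions. A truncated match — only a prefix of the adapter fits
    before the read ends — must show at least ``min_truncated`` adapter
    bases (very short prefixes match random sequence far too often) and
    tolerates ``truncated_mismatch`` substitutions when at least 8 bases
    are visible, none below that. Returns None when no position qualifies.
    """
    if len(adapter) < 13:
        raise ValueError("adapter must be at least 13 bases")
    n, k = len(sequence), len(adapter)
    seq = encode(sequence)
    ad = encode(adapter)
    if n >= k:
        windows = np.lib.stride_tricks.sliding_window_view(seq, k)
        mm = (windows != ad).sum(axis=1)
        full = np.flatnonzero(mm <= max_adapter_mismatch)
        if len(full):
            return int(full[0])
    # truncated prefix matches hanging off the read end
    for pos in range(max(n - k + 1, 0), n - min_truncated + 1):
        piece = seq[pos:]
        mm = int((piece != ad[: len(piece)]).sum())
        allowed = truncated_mismatch if len(piece) >= 8 else 0
        if mm <= allowed:
            return pos
    return None


def merge_pair(
    pair: ReadPair,
    adapter: str,
    min_fragment: int = MIN_FRAGMENT,
    max_disagreements: int = MAX_DISAGREEMENTS,
    max_adapter_mismatch: int = 0,
) -> MergeOutcome:
    """Merge one pair if both mates reveal the same adapter position.

    The adapter position, located independently in each mate's own
    orientation, gives the fragment length. The second mate is
    reverse-complemented onto the first over the fragment; at each
    disagreeing base the higher-quality call wins (ties go to mate 1) and
    the merged quality is the per-position maximum. Output is reported in
    mate-1 (transcript-sense) orientation.
    """
    pos1 = find_adapter(pair.seq1, adapter, max_adapter_mismatch)
    pos2 = find_adapter(pair.seq2, adapter, max_adapter_mismatch)
    if pos1 is None or pos2 is None or pos1 != pos2:
        return MergeOutcome("kept_pair")
    flen = pos1
    if flen < min_fragment:
        return MergeOutcome("discarded_short", fragment_length=flen)
    f1 = pair.seq1[:flen]
    q1 = pair.qual1[:flen]
    f2 = revcomp(pair.seq2[:flen])
    q2 = pair.qual2[:flen][::-1]
    a1, a2 = encode(f1), encode(f2)
    disagree = np.flatnonzero(a1 != a2)
    n_dis = len(disagree)
    if n_dis > max_disagreements:
        return MergeOutcome("discarded_mismatch",
                            n_disagreements=n_dis, n_overlap=flen,
                            fragment_length=flen)
    merged = list(f1)
    for i in disagree:
        if ord(q2[i]) > ord(q1[i]):
            merged[i] = f2[i]
    quality = "".join(max(a, b) for a, b in zip(q1, q2))
    return MergeOutcome("merged",
                        merged_sequence="".join(merged),
                        merged_quality=quality,
                        n_disagreements=n_dis, n_overlap=flen,
                        fragment_length=flen)


@dataclass
class MergeStats:
    n_input: int = 0
    n_merged: int = 0
    n_kept_pairs: int = 0
    n_discarded_short: int = 0
    n_discarded_mismatch: int = 0
    overlap_bases: int = 0
    disagreeing_bases: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_discarded_short + self.n_discarded_mismatch

    @property
    def disagreement_rate(self) -> float:
        """Fraction of overlapping bases at which the mates disagreed."""
        if self.overlap_bases == 0:
            return 0.0
        return self.disagreeing_bases / self.overlap_bases

    def as_table(self) -> str:
        rows = [
            ("input_pairs", self.n_input),
            ("merged", self.n_merged),
            ("kept_pairs", self.n_kept_pairs),
            ("discarded_short", self.n_discarded_short),
            ("discarded_mismatch", self.n_discarded_mismatch),
            ("overlap_bases", self.overlap_bases),
            ("disagreeing_bases", self.disagreeing_bases),
            ("disagreement_rate", f"{self.disagreement_rate:.6f}"),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows)


@dataclass
class LibraryBipartition:
    """Single-end (merged) and paired-end halves of one input library."""

    merged: list[tuple[str, str, str]]  # (name, sequence, quality)
    pairs: list[ReadPair]
    stats: MergeStats


def partition_library(
    pairs: list[ReadPair],
    adapter: str,
    min_fragment: int = MIN_FRAGMENT,
    max_disagreements: int = MAX_DISAGREEMENTS,
    max_adapter_mismatch: int = 0,
) -> LibraryBipartition:
    """Bipartition a paired library into merged single-end reads and pairs.

    Counts are conserved: merged + kept + discarded = input pairs.
    """
    stats = MergeStats(n_input=len(pairs))
    merged: list[tuple[str, str, str]] = []
    kept: list[ReadPair] = []
    for pair in pairs:
        out = merge_pair(pair, adapter, min_fragment,
                         max_disagreements, max_adapter_mismatch)
        if out.status in ("merged", "discarded_mismatch"):
            stats.overlap_bases += out.n_overlap
            stats.disagreeing_bases += out.n_disagreements
        if out.status == "merged":
            stats.n_merged += 1
            merged.append((pair.name, out.merged_sequence, out.merged_quality))
        elif out.status == "kept_pair":
            stats.n_kept_pairs += 1
            kept.append(pair)
        elif out.status == "discarded_short":
            stats.n_discarded_short += 1
        else:
            stats.n_discarded_mismatch += 1
    return LibraryBipartition(merged, kept, stats)
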