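"""Core domain model: annotation, phased variants, aligned fragments.

Coordinates are 0-based half-open throughout the in-memory model; the
file writers emit 1-based GTF/VCF/SAM coordinates.

The atomic unit of every analysis stage is the :class:`AlignedFragment`:
one sequenced cDNA fragment (a read pair, or a merged overlapping pair)
reduced to the reference intervals it covers, the base called at every
covered reference position (reference-strand oriented), and the splice
junctions its alignment asserts.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """One mRNA isoform: ordered, disjoint exon intervals on the genome."""

    id: str
    gene_id: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"exons of {self.id} not sorted/disjoint")
        if self.exons and not self.exons[0][0] < self.exons[0][1]:
            raise ValueError(f"empty exon in {self.id}")

    @property
    def length(self) -> int:
        """Mature-mRNA length (sum of exon lengths)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def junctions(self) -> frozenset[Interval]:
        """Intron intervals (donor end, acceptor start) of this isoform."""
        return frozenset(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class Gene:
    id: str
    name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def exonic_union(self) -> tuple[Interval, ...]:
        """Merged union of all isoform exons, sorted."""
        return merge_intervals(
            iv for t in self.transcripts for iv in t.exons
        )


@dataclass
class Annotation:
    """Genes → transcripts → exons, with id lookup helpers."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id}")
        self.genes[gene.id] = gene

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self:
            yield from g.transcripts

    def transcript(self, tid: str) -> Transcript:
        for g in self:
            for t in g.transcripts:
                if t.id == tid:
                    return t
        raise KeyError(tid)

    def gene_of(self, tid: str) -> Gene:
        for g in self:
            if any(t.id == tid for t in g.transcripts):
                return g
        raise KeyError(tid)


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


# ---------------------------------------------------------------------------
# Transcript <-> reference coordinate mapping
# ---------------------------------------------------------------------------

def tx_window_to_blocks(
    transcript: Transcript, strand: str, start: int, end: int
) -> list[Interval]:
    """Map a mature-mRNA window [start, end) to reference intervals.

    mRNA coordinates run 5'→3'; for a minus-strand transcript coordinate 0
    is the *rightmost* exonic base. Blocks are returned in reference order.
    """
    if not 0 <= start <= end <= transcript.length:
        raise ValueError("window outside transcript")
    if strand == "-":
        start, end = transcript.length - end, transcript.length - start
    blocks: list[Interval] = []
    off = 0
    for s, e in transcript.exons:
        elen = e - s
        lo, hi = max(start - off, 0), min(end - off, elen)
        if lo < hi:
            blocks.append((s + lo, s + hi))
        off += elen
    return blocks


def tx_pos_to_ref(transcript: Transcript, strand: str, pos: int) -> int:
    """Reference position of mature-mRNA coordinate `pos`."""
    ((s, _e),) = tx_window_to_blocks(transcript, strand, pos, pos + 1)
    return s


class TranscriptMap:
    """Vectorized mature-mRNA -> reference coordinate mapping."""

    def __init__(self, transcript: Transcript):
        import numpy as np

        self._starts = np.array([s for s, _ in transcript.exons])
        lens = np.array([e - s for s, e in transcript.exons])
        self._cum = np.concatenate([[0], np.cumsum(lens)])
        self.length = int(self._cum[-1])

    def to_ref(self, tx_positions, strand: str):
        """Reference positions of an array of mRNA coordinates."""
        import numpy as np

        q = np.asarray(tx_positions)
        if strand == "-":
            q = self.length - 1 - q
        idx = np.searchsorted(self._cum, q, side="right") - 1
        return self._starts[idx] + (q - self._cum[idx])


# ---------------------------------------------------------------------------
# Phased variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasedSite:
    """A phased heterozygous single-base variant."""

    chrom: str
    pos: int
    ref: str
    maternal: str
    paternal: str

    def __post_init__(self) -> None:
        if self.maternal == self.paternal:
            raise ValueError("site is not heterozygous")
        if len(self.maternal) != 1 or len(self.paternal) != 1:
            raise ValueError("only single-base sites are phased here")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.maternal, self.paternal))

    def other(self, allele: str) -> str:
        if allele == self.maternal:
            return self.paternal
        if allele == self.paternal:
            return self.maternal
        raise ValueError(f"{allele} is not an allele of this site")


class SiteIndex:
    """Position-sorted index of phased sites for one chromosome set."""

    def __init__(self, sites: Iterable[PhasedSite]):
        self._by_chrom: dict[str, tuple[list[int], list[PhasedSite]]] = {}
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            pos, rec = self._by_chrom.setdefault(site.chrom, ([], []))
            pos.append(site.pos)
            rec.append(site)

    def overlapping(self, chrom: str, start: int, end: int) -> list[PhasedSite]:
        if chrom not in self._by_chrom:
            return []
        pos, rec = self._by_chrom[chrom]
        return rec[bisect_left(pos, start):bisect_left(pos, end)]

    def __len__(self) -> int:
        return sum(len(p) for p, _ in self._by_chrom.values())


# ---------------------------------------------------------------------------
# Aligned fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedFragment:
    """One fragment's alignment: covered blocks, called bases, junctions.

    `blocks` are disjoint sorted reference intervals; `block_seqs[i]` holds
    the base called at every position of `blocks[i]`, oriented to the
    reference strand. `junctions` are the intron intervals asserted by
    spliced alignment (a gap between blocks that is *not* listed here is an
    unsequenced inner-mate gap, not a splice).
    """

    name: str
    chrom: str
    blocks: tuple[Interval, ...]
    block_seqs: tuple[str, ...]
    junctions: frozenset[Interval] = frozenset()
    strand: str | None = None

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.block_seqs):
            raise ValueError("blocks and block_seqs differ in length")
        for (s, e), seq in zip(self.blocks, self.block_seqs):
            if e - s != len(seq):
                raise ValueError("block length does not match its sequence")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not e1 <= s2:
                raise ValueError("blocks overlap or are unsorted")

    @property
    def effective_length(self) -> int:
        """Distinct reference bases covered (the fragment's information span)."""
        return sum(e - s for s, e in self.blocks)

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.blocks)

    def base_at(self, pos: int) -> str | None:
        """Called base (reference orientation) at `pos`, or None if uncovered."""
        for (s, e), seq in zip(self.blocks, self.block_seqs):
            if s <= pos < e:
                return seq[pos - s]
        return None

    def overlaps(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.blocks)

    def positions(self) -> Iterator[int]:
        for s, e in self.blocks:
            yield from range(s, e)

    def with_base(self, substitutions: Mapping[int, str]) -> "AlignedFragment":
        """Copy of the fragment with bases replaced at given reference positions."""
        seqs = []
        for (s, e), seq in zip(self.blocks, self.block_seqs):
            chars = list(seq)
            for pos, base in substitutions.items():
                if s <= pos < e:
                    chars[pos - s] = base
            seqs.append("".join(chars))
        return replace(self, block_seqs=tuple(seqs))

    def segments(self) -> list[str]:
        """Contiguously sequenced stretches, concatenated across splice gaps.

        Consecutive blocks separated by a recorded junction belong to one
        sequenced read; any other gap (inner-mate distance) splits segments.
        These are the strings a re-aligner should be given.
        """
        out: list[str] = []
        cur = self.block_seqs[0]
        for (b1, b2), seq in zip(
            zip(self.blocks, self.blocks[1:]), self.block_seqs[1:]
        ):
            if (b1[1], b2[0]) in self.junctions or b1[1] == b2[0]:
                cur += seq
            else:
                out.append(cur)
                cur = seq
        out.append(cur)
        return out


def fragment_from_positions(
    name: str,
    chrom: str,
    calls: Mapping[int, str],
    junctions: Iterable[Interval] = (),
    strand: str | None = None,
) -> AlignedFragment:
    """Build a fragment from a {reference position: called base} mapping."""
    if not calls:
        raise ValueError("fragment covers no positions")
    positions = sorted(calls)
    blocks: list[Interval] = []
    seqs: list[str] = []
    run_start = positions[0]
    run = [calls[positions[0]]]
    for prev, pos in zip(positions, positions[1:]):
        if pos == prev + 1:
            run.append(calls[pos])
        else:
            blocks.append((run_start, prev + 1))
            seqs.append("".join(run))
            run_start, run = pos, [calls[pos]]
    blocks.append((run_start, positions[-1] + 1))
    seqs.append("".join(run))
    return AlignedFragment(
        name=name,
        chrom=chrom,
        blocks=tuple(blocks),
        block_seqs=tuple(seqs),
        junctions=frozenset(junctions),
        strand=strand,
    )
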