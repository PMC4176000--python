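"""Sequencing-cost model and library subsampling.

Costs are unit-agnostic: a library is a price, a pair count and the
bases per pair (twice the read length); the derived quantities are cost
per million bases, the per-read cost ratio between two libraries, and
the fraction of the pricier library that matches the cheaper one's
budget. Subsampling draws without replacement by read count, base count
(accumulating until the target, overshooting by at most one fragment)
or cost fraction, with replicate seeds derived deterministically from
one master seed. Library preparation cost is excluded by default; a
constant can be added per library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, TypeVar

import numpy as np

from .read_merge import ReadPair

T = TypeVar("T")


@dataclass(frozen=True)
class LibraryCostSpec:
    price: float
    n_pairs: int
    bases_per_pair: int  # 2 x read length
    prep_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.price <= 0 or self.n_pairs <= 0 or self.bases_per_pair <= 0:
            raise ValueError("price, n_pairs and bases_per_pair must be positive")

    @property
    def total_price(self) -> float:
        return self.price + self.prep_cost

    @property
    def total_bases(self) -> int:
        return self.n_pairs * self.bases_per_pair


def cost_per_million_bases(spec: LibraryCostSpec) -> float:
    """Price per megabase sequenced, reported at 3 decimals."""
    return round(spec.total_price / (spec.total_bases / 1e6), 3)


def per_read_cost_ratio(spec_a: LibraryCostSpec, spec_b: LibraryCostSpec) -> float:
    """How many of B's read pairs cost the same as one of A's."""
    return (spec_a.total_price / spec_a.n_pairs) / (
        spec_b.total_price / spec_b.n_pairs
    )


def cost_matched_fraction(spec_a: LibraryCostSpec, spec_b: LibraryCostSpec) -> float:
    """Fraction of library A whose cost equals all of library B."""
    frac = spec_b.total_price / spec_a.total_price
    if frac > 1:
        raise ValueError("library B costs more than library A")
    return frac


@dataclass(frozen=True)
class SubsampleSpec:
    mode: str  # by_reads, by_bases, by_cost
    target: float  # read count, base count, or cost fraction
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("by_reads", "by_bases", "by_cost"):
            raise ValueError("mode must be by_reads, by_bases or by_cost")
        if self.target <= 0:
            raise ValueError("target must be positive")
        if self.mode == "by_cost" and self.target > 1:
            raise ValueError("by_cost target is a fraction in (0, 1]")


def _pair_bases(pair: ReadPair) -> int:
    return len(pair.seq1) + len(pair.seq2)


def subsample(
    library: Sequence[T],
    spec: SubsampleSpec,
    bases_of: Callable[[T], int] | None = None,
) -> list[list[T]]:
    """Replicate subsamples of a library, drawn without replacement.

    by_reads / by_cost pick a fixed number of fragments; by_bases walks a
    random permutation accumulating bases until the target is reached,
    including the fragment that crosses it. Each replicate is
    deterministic in (seed, replicate index).
    """
    n = len(library)
    if bases_of is None:
        bases_of = _pair_bases  # type: ignore[assignment]
    if spec.mode == "by_reads":
        k = int(spec.target)
        if k > n:
            raise ValueError("target exceeds library size")
    elif spec.mode == "by_cost":
        k = int(round(spec.target * n))
    else:
        total = sum(bases_of(item) for item in library)
        if spec.target > total:
            raise ValueError("target exceeds library bases")
        k = None
    out: list[list[T]] = []
    for child in np.random.SeedSequence(spec.seed).spawn(spec.n_replicates):
        rng = np.random.Generator(np.random.PCG64(child))
        perm = rng.permutation(n)
        if k is not None:
            out.append([library[i] for i in perm[:k]])
        else:
            picked: list[T] = []
            acc = 0
            for i in perm:
                picked.append(library[i])
                acc += bases_of(library[i])
                if acc >= spec.target:
                    break
            out.append(picked)
    return out


def truncate_reads(pairs: Sequence[ReadPair], new_length: int) -> list[ReadPair]:
    """Truncate each mate (sequence and quality) to its first bases.

    Emulates a shorter-read library from a longer-read one.
    """
    out = []
    for p in pairs:
        if new_length > len(p.seq1) or new_length > len(p.seq2):
            raise ValueError("new_length exceeds read length")
        out.append(ReadPair(
            p.name,
            p.seq1[:new_length], p.qual1[:new_length],
            p.seq2[:new_length], p.qual2[:new_length],
        ))
    return out
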