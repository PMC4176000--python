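"""Allele-specific expression (ASE) and alternative splicing (ASAS).

A fragment that covers one or more phased heterozygous sites, all of
which show the same parental haplotype's alleles, is assigned to that
haplotype. Gene-level ASE is an exact two-sided binomial test of the
maternal/paternal fragment counts against a balanced null; ASAS tests
each *exon block* (an atomic exonic interval free of any isoform's
internal exon boundary) with a 1-df Pearson chi-square on the 2x2 table
haplotype x block-overlap. Discoveries are controlled by
Benjamini-Hochberg at 10% FDR.

Reference-allele mapping bias is diagnosed with the *mapping retention
rate*: every haplotype-assigned fragment has its het-site bases flipped
to the other haplotype and is realigned; genes where fewer than 90% of
flipped reads return to the same location are untestable.

The haplotype-assignable fraction grows with the covered reference span
L as 1 - exp(-lambda * L) when het sites fall as a Poisson process with
rate lambda; fitting lambda to per-fragment (length, assigned) data
extrapolates assignability to arbitrary read lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    AlignedFragment,
    Annotation,
    Gene,
    Interval,
    PhasedSite,
    SiteIndex,
)

MIN_ASE_READS = 20
MIN_ASAS_READS = 40
RETENTION_MIN = 0.9
FDR_Q = 0.10


# ---------------------------------------------------------------------------
# Haplotype assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeCall:
    status: str  # maternal, paternal, no_site, conflicting
    n_sites: int = 0

    @property
    def assigned(self) -> bool:
        return self.status in ("maternal", "paternal")


def assign_haplotype(
    fragment: AlignedFragment, sites: SiteIndex
) -> HaplotypeCall:
    """Assign a fragment to a parental haplotype via its het-site bases.

    Assignment requires every covered het site to carry the same
    haplotype's allele; a mixture, or a base that is neither allele,
    is conflicting.
    """
    covered = [
        s for s in sites.overlapping(fragment.chrom, *fragment.span)
        if fragment.covers(s.pos)
    ]
    if not covered:
        return HaplotypeCall("no_site")
    votes = set()
    for site in covered:
        base = fragment.base_at(site.pos)
        if base == site.maternal:
            votes.add("maternal")
        elif base == site.paternal:
            votes.add("paternal")
        else:
            return HaplotypeCall("conflicting", len(covered))
    if len(votes) == 1:
        return HaplotypeCall(votes.pop(), len(covered))
    return HaplotypeCall("conflicting", len(covered))


def assignable_fraction(
    fragments: Sequence[AlignedFragment],
    sites: SiteIndex,
    strata_edges: Sequence[int] = (),
) -> pd.DataFrame:
    """Haplotype-assignable fraction, optionally by effective-length stratum.

    Returns columns (stratum, n, fraction); empty strata are skipped.
    """
    edges = sorted(strata_edges)
    bounds = list(zip((0, *edges), (*edges, np.inf))) if edges else [(0, np.inf)]
    labels = [
        f"[{lo},{hi})" if np.isfinite(hi) else f">={lo}" for lo, hi in bounds
    ]
    tallies = {lab: [0, 0] for lab in labels}
    for frag in fragments:
        L = frag.effective_length
        call = assign_haplotype(frag, sites)
        for (lo, hi), lab in zip(bounds, labels):
            if lo <= L < hi:
                tallies[lab][0] += 1
                tallies[lab][1] += call.assigned
                break
    rows = [
        {"stratum": lab, "n": n, "fraction": k / n}
        for lab, (n, k) in tallies.items() if n > 0
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Poisson read-length extrapolation
# ---------------------------------------------------------------------------

class PoissonAssignmentModel:
    """p(L) = 1 - exp(-lambda * L): chance a length-L alignment is assignable.

    Fit by maximum likelihood on per-fragment Bernoulli outcomes; the
    fitted rate ``lambda_`` is the effective density of usable
    heterozygous sites per covered base.
    """

    def __init__(self) -> None:
        self.lambda_: float | None = None
        self.boundary_: bool = False

    def fit(
        self,
        lengths: Sequence[int],
        assigned: Sequence[bool],
    ) -> "PoissonAssignmentModel":
        L = np.asarray(lengths, dtype=float)
        y = np.asarray(assigned, dtype=bool)
        if len(L) < 100:
            raise ValueError("need at least 100 fragments to fit")
        if (L <= 0).any():
            raise ValueError("lengths must be positive")
        if y.all() or not y.any():
            # degenerate input: the MLE sits on the boundary
            self.boundary_ = True
            self.lambda_ = math.inf if y.all() else 0.0
            return self

        def nll(log_lam: float) -> float:
            lam = math.exp(log_lam)
            p = -np.expm1(-lam * L)
            return -(np.log(p[y]).sum() + (-lam * L[~y]).sum())

        res = optimize.minimize_scalar(
            nll, bounds=(math.log(1e-10), math.log(1.0)), method="bounded",
            options={"xatol": 1e-8},
        )
        self.lambda_ = math.exp(res.x)
        self.boundary_ = False
        return self

    def predict(self, length: float | np.ndarray) -> float | np.ndarray:
        """Expected assignable fraction at covered length `length`."""
        if self.lambda_ is None:
            raise ValueError("model not fitted")
        return -np.expm1(-self.lambda_ * np.asarray(length, dtype=float))


def fit_poisson_model(
    lengths: Sequence[int], assigned: Sequence[bool]
) -> PoissonAssignmentModel:
    return PoissonAssignmentModel().fit(lengths, assigned)


# ---------------------------------------------------------------------------
# ASE tests
# ---------------------------------------------------------------------------

def ase_test(
    n_maternal: int, n_paternal: int, min_total: int = MIN_ASE_READS
) -> float | None:
    """Two-sided exact binomial test of allelic balance for one gene.

    Returns None (excluded) when the haplotype-assigned total is below
    ``min_total``.
    """
    total = n_maternal + n_paternal
    if total < min_total:
        return None
    return float(stats.binomtest(n_maternal, total, 0.5).pvalue)


def per_locus_ase_test(
    site_counts: Mapping[tuple[str, int], tuple[int, int]]
) -> pd.DataFrame:
    """Two-sided binomial at p=0.5 per heterozygous site.

    ``site_counts`` maps (chrom, pos) to (maternal, paternal) read counts.
    Returns columns (chrom, pos, maternal, paternal, p).
    """
    rows = []
    for (chrom, pos), (m, p) in sorted(site_counts.items()):
        if m + p == 0:
            continue
        rows.append({
            "chrom": chrom, "pos": pos, "maternal": m, "paternal": p,
            "p": float(stats.binomtest(m, m + p, 0.5).pvalue),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exon blocks and the ASAS test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonBlock:
    gene_id: str
    index: int
    start: int
    end: int


def exon_blocks(gene: Gene) -> list[ExonBlock]:
    """Atomic exonic intervals free of any isoform's exon boundaries.

    The union of all isoform exons is cut at every exon start/end of
    every isoform; the resulting disjoint intervals tile the exonic union
    and none contains an internal boundary.
    """
    boundaries = sorted({
        b for t in gene.transcripts for s, e in t.exons for b in (s, e)
    })
    exonic = gene.exonic_union
    blocks: list[ExonBlock] = []
    idx = 0
    for lo, hi in zip(boundaries, boundaries[1:]):
        if any(s <= lo and hi <= e for s, e in exonic):
            blocks.append(ExonBlock(gene.id, idx, lo, hi))
            idx += 1
    return blocks


@dataclass(frozen=True)
class AsasTable:
    """2x2 contingency table: haplotype (rows) x block overlap (columns)."""

    a: int  # maternal, overlapping the block
    b: int  # maternal, not overlapping
    c: int  # paternal, overlapping
    d: int  # paternal, not overlapping

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def zero_margin(self) -> bool:
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)

    @property
    def min_expected(self) -> float:
        n = self.total
        return min(
            (self.a + self.b) * (self.a + self.c) / n,
            (self.a + self.b) * (self.b + self.d) / n,
            (self.c + self.d) * (self.a + self.c) / n,
            (self.c + self.d) * (self.b + self.d) / n,
        )


def asas_table(
    block: ExonBlock,
    fragments: Sequence[AlignedFragment],
    calls: Sequence[HaplotypeCall],
) -> AsasTable:
    """Count the gene's haplotype-assigned fragments into the 2x2 table.

    A fragment overlaps the block when any covered base (either mate)
    falls inside it; each fragment is counted once.
    """
    a = b = c = d = 0
    for frag, call in zip(fragments, calls):
        if not call.assigned:
            continue
        ov = frag.overlaps(block.start, block.end)
        if call.status == "maternal":
            a, b = (a + 1, b) if ov else (a, b + 1)
        else:
            c, d = (c + 1, d) if ov else (c, d + 1)
    return AsasTable(a, b, c, d)


def asas_test(
    block: ExonBlock,
    fragments: Sequence[AlignedFragment],
    calls: Sequence[HaplotypeCall],
    min_total: int = MIN_ASAS_READS,
) -> tuple[AsasTable, float | None]:
    """Pearson chi-square (1 df, no continuity correction) on the block.

    Returns (table, p); p is None when the gene's assigned total is below
    ``min_total`` or a table margin is zero (test undefined).
    """
    t = asas_table(block, fragments, calls)
    if t.total < min_total or t.zero_margin:
        return t, None
    num = t.total * (t.a * t.d - t.b * t.c) ** 2
    den = ((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d))
    chi2 = num / den
    return t, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float], q: float = FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean significance per input p-value.

    Largest k with p_(k) <= k*q/m is found; every p-value of rank <= k is
    significant. Empty input gives an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = np.flatnonzero(ranked <= (np.arange(1, m + 1) * q / m))
    out = np.zeros(m, dtype=bool)
    if passing.size:
        out[order[: passing[-1] + 1]] = True
    return out


# ---------------------------------------------------------------------------
# Mapping-bias diagnostics
# ---------------------------------------------------------------------------

def allele_flip(
    fragment: AlignedFragment,
    sites: SiteIndex,
    haplotype: str | None = None,
) -> tuple[AlignedFragment, tuple[int, ...]]:
    """Swap the base at every covered het site to the other allele.

    A base that matches neither allele (a sequencing error on the site)
    cannot be flipped symmetrically; when the fragment's assigned
    ``haplotype`` is given, such bases are set to the opposite
    haplotype's allele and their positions reported as flagged.
    Flipping twice restores the original fragment (involution) whenever
    no base was flagged.
    """
    covered = [
        s for s in sites.overlapping(fragment.chrom, *fragment.span)
        if fragment.covers(s.pos)
    ]
    if not covered:
        raise ValueError("fragment covers no heterozygous site")
    subs: dict[int, str] = {}
    flagged: list[int] = []
    for site in covered:
        base = fragment.base_at(site.pos)
        if base in site.alleles:
            subs[site.pos] = site.other(base)
        elif haplotype in ("maternal", "paternal"):
            other = "paternal" if haplotype == "maternal" else "maternal"
            subs[site.pos] = getattr(site, other)
            flagged.append(site.pos)
        else:
            flagged.append(site.pos)
    return fragment.with_base(subs), tuple(flagged)


@dataclass(frozen=True)
class RetentionResult:
    gene_id: str
    n_flipped: int
    n_retained: int

    @property
    def rate(self) -> float:
        return self.n_retained / self.n_flipped if self.n_flipped else float("nan")

    @property
    def testable(self) -> bool:
        return self.n_flipped > 0 and self.rate >= RETENTION_MIN


def retention_rate(
    gene: Gene,
    fragments: Sequence[AlignedFragment],
    calls: Sequence[HaplotypeCall],
    sites: SiteIndex,
    aligner: Callable[[str], "object"],
) -> RetentionResult:
    """Fraction of flipped haplotype-assigned fragments that map back.

    Each assigned fragment's het-site bases are flipped to the other
    haplotype and its sequenced segments are realigned with ``aligner``
    (any callable returning an object with .status/.chrom/.blocks, e.g.
    ``ToyAligner.align``). A fragment is retained only if every segment
    maps uniquely to its original location with the identical block
    structure.
    """
    n_flipped = n_retained = 0
    for frag, call in zip(fragments, calls):
        if not call.assigned:
            continue
        flipped, _flags = allele_flip(frag, sites, call.status)
        n_flipped += 1
        # segment boundaries in the flipped fragment mirror the original
        seg_blocks: list[list[Interval]] = [[flipped.blocks[0]]]
        for b1, b2 in zip(flipped.blocks, flipped.blocks[1:]):
            if (b1[1], b2[0]) in flipped.junctions or b1[1] == b2[0]:
                seg_blocks[-1].append(b2)
            else:
                seg_blocks.append([b2])
        retained = True
        for seq, blocks in zip(flipped.segments(), seg_blocks):
            merged = []
            for s, e in blocks:
                if merged and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            hit = aligner(seq)
            if (hit.status != "mapped" or hit.chrom != frag.chrom
                    or tuple(hit.blocks) != tuple(merged)):
                retained = False
                break
        n_retained += retained
    return RetentionResult(gene.id, n_flipped, n_retained)


# ---------------------------------------------------------------------------
# Gene filters and enrichment
# ---------------------------------------------------------------------------

def exclusion_filters(
    gene_read_counts: Mapping[str, int],
    gene_names: Mapping[str, str],
    min_reads: int,
    retention: Mapping[str, float] | None = None,
    retention_min: float = RETENTION_MIN,
    excluded_prefixes: Sequence[str] = ("HLA-",),
) -> tuple[set[str], pd.DataFrame]:
    """Testable gene set after name, count and retention filters.

    Returns (testable gene ids, log of removals with reasons).
    """
    testable: set[str] = set()
    log_rows = []
    for gid, count in gene_read_counts.items():
        name = gene_names.get(gid, gid)
        reasons = []
        if any(name.startswith(p) for p in excluded_prefixes):
            reasons.append("excluded_name")
        if count < min_reads:
            reasons.append("low_count")
        if retention is not None:
            r = retention.get(gid)
            if r is None or r < retention_min:
                reasons.append("low_retention")
        if reasons:
            log_rows.append({"gene_id": gid, "reasons": ",".join(reasons)})
        else:
            testable.add(gid)
    return testable, pd.DataFrame(log_rows, columns=["gene_id", "reasons"])


def enrichment_test(
    k_overlap: int, n_eqtl_het: int, n_significant: int, n_tested: int
) -> float:
    """Hypergeometric upper tail P(X >= k) for eQTL overlap enrichment.

    Population ``n_tested`` genes, of which ``n_eqtl_het`` carry a het
    eQTL site; ``n_significant`` genes were called, ``k_overlap`` of them
    in the eQTL set.
    """
    if not (0 <= k_overlap <= min(n_eqtl_het, n_significant) <= n_tested):
        raise ValueError("inconsistent counts")
    if k_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_overlap - 1, n_tested,
                                    n_eqtl_het, n_significant))


# ---------------------------------------------------------------------------
# Convenience pipelines over a set of fragments
# ---------------------------------------------------------------------------

def gene_haplotype_counts(
    fragments: Sequence[AlignedFragment],
    calls: Sequence[HaplotypeCall],
    gene_ids: Sequence[str | None],
) -> pd.DataFrame:
    """Per-gene maternal/paternal fragment counts.

    ``gene_ids[i]`` is the gene each fragment was (unambiguously)
    assigned to, or None. Returns columns (gene_id, maternal, paternal).
    """
    tally: dict[str, list[int]] = {}
    for call, gid in zip(calls, gene_ids):
        if gid is None or not call.assigned:
            continue
        m_p = tally.setdefault(gid, [0, 0])
        m_p[0 if call.status == "maternal" else 1] += 1
    rows = [
        {"gene_id": gid, "maternal": m, "paternal": p}
        for gid, (m, p) in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "maternal", "paternal"])


def ase_scan(
    counts: pd.DataFrame,
    min_total: int = MIN_ASE_READS,
    q: float = FDR_Q,
) -> pd.DataFrame:
    """ASE test per gene plus BH significance over the tested pool."""
    tested = counts[
        counts["maternal"] + counts["paternal"] >= min_total
    ].copy()
    tested["p"] = [
        ase_test(int(r.maternal), int(r.paternal), min_total)
        for r in tested.itertuples()
    ]
    if len(tested):
        tested["significant"] = bh_fdr(tested["p"].to_numpy(), q)
    else:
        tested["significant"] = pd.Series(dtype=bool)
    return tested.reset_index(drop=True)


def asas_scan(
    annotation: Annotation,
    fragments_by_gene: Mapping[str, Sequence[AlignedFragment]],
    calls_by_gene: Mapping[str, Sequence[HaplotypeCall]],
    min_total: int = MIN_ASAS_READS,
    q: float = FDR_Q,
) -> pd.DataFrame:
    """ASAS chi-square over every exon block of every eligible gene.

    All blocks of all testable genes enter one BH pool. Returns columns
    (gene_id, block, start, end, a, b, c, d, chi2_ok, p, low_expected,
    significant).
    """
    rows = []
    for gid, frags in fragments_by_gene.items():
        gene = annotation.genes[gid]
        calls = calls_by_gene[gid]
        for block in exon_blocks(gene):
            table, p = asas_test(block, frags, calls, min_total)
            if p is None:
                continue
            rows.append({
                "gene_id": gid, "block": block.index,
                "start": block.start, "end": block.end,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "p": p, "low_expected": table.min_expected < 5,
            })
    df = pd.DataFrame(rows, columns=["gene_id", "block", "start", "end",
                                     "a", "b", "c", "d", "p", "low_expected"])
    df["significant"] = bh_fdr(df["p"].to_numpy(), q) if len(df) else False
    return df
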