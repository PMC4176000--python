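"""RNA/DNA genotype concordance as a mapping-error diagnostic.

At every genotyped SNP covered deeply enough by RNA-seq, the reads'
bases are compared with the DNA-derived genotype: a read is *mismatched*
when it carries an allele the genotype does not support. Under a
sequencing-error-only null the mismatch count at a site of depth ``n``
is Binomial(n, eps), with eps the per-base sequencing error rate
estimated from the same data; the upper-tail probability is the site's
discordance p-value. Libraries are compared bin-by-bin after depth
stratification, with a one-sided Wilcoxon rank-sum test per bin.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignedFragment

MIN_DEPTH = 10
DEPTH_BIN_EDGES = (10, 100, 500, 1000)
DEPTH_BIN_LABELS = ("10-99", "100-499", "500-999", ">=1000")


@dataclass(frozen=True)
class GenotypedSite:
    """A DNA-genotyped SNP: position plus the supported allele set."""

    chrom: str
    pos: int
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("biallelic SNP genotypes only")


@dataclass(frozen=True)
class ErrorRateEstimate:
    epsilon: float
    n_mismatches: int
    n_aligned_bases: int


def site_mismatch_counts(
    fragments: Iterable[AlignedFragment],
    sites: Sequence[GenotypedSite],
    min_depth: int = MIN_DEPTH,
) -> pd.DataFrame:
    """Per-site depth ``n`` and mismatched-read count ``x``.

    Each fragment contributes at most one base per site (overlapping
    mates were already collapsed into the fragment). Sites with depth
    below ``min_depth`` are dropped. Returns columns
    (chrom, pos, n, x).
    """
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for i in order:
        pos_list, idx_list = by_chrom.setdefault(sites[i].chrom, ([], []))
        pos_list.append(sites[i].pos)
        idx_list.append(i)
    n = np.zeros(len(sites), dtype=np.int64)
    x = np.zeros(len(sites), dtype=np.int64)
    for frag in fragments:
        if frag.chrom not in by_chrom:
            continue
        pos_list, idx_list = by_chrom[frag.chrom]
        for s, e in frag.blocks:
            lo = bisect_left(pos_list, s)
            hi = bisect_left(pos_list, e)
            for j in range(lo, hi):
                i = idx_list[j]
                base = frag.base_at(sites[i].pos)
                if base is None:
                    continue  # deletion over the site: no base contributed
                n[i] += 1
                if base not in sites[i].alleles:
                    x[i] += 1
    df = pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "n": n,
        "x": x,
    })
    return df[df["n"] >= min_depth].reset_index(drop=True)


def estimate_error_rate(sites: pd.DataFrame) -> ErrorRateEstimate:
    """Per-base error rate: total mismatches over total aligned bases.

    Estimated per dataset, over the analyzed genotyped sites.
    """
    n_bases = int(sites["n"].sum())
    if n_bases == 0:
        raise ValueError("no aligned bases at genotyped sites")
    n_mm = int(sites["x"].sum())
    return ErrorRateEstimate(n_mm / n_bases, n_mm, n_bases)


def discordance_pvalue(n: int, x: int, epsilon: float) -> float:
    """Upper-tail P(X >= x) for X ~ Binomial(n, epsilon); 1.0 when x = 0."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, epsilon))


def add_discordance_pvalues(
    sites: pd.DataFrame, epsilon: float
) -> pd.DataFrame:
    out = sites.copy()
    out["p"] = [
        discordance_pvalue(int(r.n), int(r.x), epsilon)
        for r in sites.itertuples()
    ]
    return out


def depth_bin(n: int) -> str | None:
    """Label of the read-depth bin containing depth ``n``."""
    if n < DEPTH_BIN_EDGES[0]:
        return None
    for lo, hi, label in zip(
        DEPTH_BIN_EDGES, DEPTH_BIN_EDGES[1:] + (np.inf,), DEPTH_BIN_LABELS
    ):
        if lo <= n < hi:
            return label
    return None


def stratify_and_compare(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-depth-bin one-sided Wilcoxon rank-sum comparison of p-values.

    Tests, per bin, whether library A's discordance p-values are
    stochastically larger (A more concordant) than library B's. Each
    library is binned by its own depth. Bins with fewer than two sites in
    either library are skipped (reported with NaN). Returns columns
    (bin, n_a, n_b, statistic, pvalue, significant).
    """
    rows = []
    for df in (sites_a, sites_b):
        if "p" not in df.columns:
            raise ValueError("sites need a 'p' column; "
                             "run add_discordance_pvalues first")
    bins_a = sites_a["n"].map(depth_bin)
    bins_b = sites_b["n"].map(depth_bin)
    for label in DEPTH_BIN_LABELS:
        pa = sites_a.loc[bins_a == label, "p"].to_numpy()
        pb = sites_b.loc[bins_b == label, "p"].to_numpy()
        if len(pa) < 2 or len(pb) < 2:
            rows.append({"bin": label, "n_a": len(pa), "n_b": len(pb),
                         "statistic": np.nan, "pvalue": np.nan,
                         "significant": False})
            continue
        res = stats.mannwhitneyu(pa, pb, alternative="greater")
        rows.append({"bin": label, "n_a": len(pa), "n_b": len(pb),
                     "statistic": float(res.statistic),
                     "pvalue": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha)})
    return pd.DataFrame(rows)


def modal_indel_size(
    observations: Mapping[tuple[str, int], Sequence[int]],
    expected: Mapping[tuple[str, int], int],
) -> pd.DataFrame:
    """Most frequent observed indel size per genotyped indel site.

    ``observations`` maps (chrom, pos) to the signed indel sizes seen in
    reads spanning the site (insertions positive, deletions negative);
    ``expected`` holds the DNA-genotyped size. Sites without spanning
    observations are omitted. Plurality wins; on a tied count the size of
    smaller magnitude is reported and the site flagged. Returns columns
    (chrom, pos, expected, modal, tie, agree) plus a
    ``.attrs['agreement']`` diagonal-agreement fraction.
    """
    rows = []
    for key, exp_size in expected.items():
        obs = observations.get(key)
        if not obs:
            continue
        counts = Counter(obs)
        top = max(counts.values())
        modal_candidates = sorted(
            (size for size, c in counts.items() if c == top),
            key=lambda s: (abs(s), s),
        )
        modal = modal_candidates[0]
        rows.append({
            "chrom": key[0], "pos": key[1],
            "expected": exp_size, "modal": modal,
            "tie": len(modal_candidates) > 1,
            "agree": modal == exp_size,
        })
    df = pd.DataFrame(rows)
    df.attrs["agreement"] = float(df["agree"].mean()) if len(df) else float("nan")
    return df


def homozygous_background_sites(
    genome_sequences: Mapping[str, str],
    het_positions: Iterable[tuple[str, int]],
    n_sites: int,
    rng: np.random.Generator,
) -> list[GenotypedSite]:
    """Sample homozygous-reference genotyped sites away from het positions.

    Convenience for building a concordance panel on synthetic data, where
    the DNA genotype at any non-variant position is hom-ref.
    """
    taken = set(het_positions)
    out: list[GenotypedSite] = []
    chroms = sorted(genome_sequences)
    lengths = np.array([len(genome_sequences[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    while len(out) < n_sites:
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(0, len(genome_sequences[chrom])))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        out.append(GenotypedSite(chrom, pos,
                                 frozenset(genome_sequences[chrom][pos])))
    return sorted(out, key=lambda s: (s.chrom, s.pos))
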