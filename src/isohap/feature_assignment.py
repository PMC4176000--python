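"""Assigning aligned fragments to genes and isoforms, and quantifying them.

The assignment rule is per-base feature-set intersection: every covered
reference base carries the set of features (genes, or isoforms) whose
footprint contains it, and a fragment's *consistent features* are the
intersection of its non-empty per-base sets — empty sets are ignored so
that bases outside the annotation do not veto an otherwise informative
fragment. At isoform level the consistent set is further restricted to
isoforms whose intron chain contains every splice junction the fragment's
alignment asserts.

Downstream quantities: per-gene read fractions and fold-change flags,
mappability-stratified library comparison, biotype breakdown, and a
transcript abundance estimate that divides a transcript's unambiguous
read count by the number of exonic bases unique to it within its gene.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignedFragment, Annotation, Gene, Interval, Transcript


# ---------------------------------------------------------------------------
# Base-level feature index
# ---------------------------------------------------------------------------

@dataclass
class BaseFeatureIndex:
    """Map genomic base -> feature-id set, at gene or isoform level."""

    level: str
    by_chrom: dict[str, dict[int, frozenset[str]]]

    def features_at(self, chrom: str, pos: int) -> frozenset[str]:
        return self.by_chrom.get(chrom, {}).get(pos, frozenset())


def build_base_index(annotation: Annotation, level: str) -> BaseFeatureIndex:
    """Index exonic (isoform level) or genic (gene level) bases.

    Gene level uses the gene's full genomic footprint (introns included),
    so intronic bases still vote for their gene; isoform level covers
    exactly the annotated exonic bases of each transcript.
    """
    if level not in ("gene", "isoform"):
        raise ValueError("level must be 'gene' or 'isoform'")
    tmp: dict[str, dict[int, set[str]]] = {}

    def paint(chrom: str, iv: Interval, fid: str) -> None:
        d = tmp.setdefault(chrom, {})
        for pos in range(*iv):
            d.setdefault(pos, set()).add(fid)

    for gene in annotation:
        if level == "gene":
            paint(gene.chrom, gene.span, gene.id)
        else:
            for t in gene.transcripts:
                for ex in t.exons:
                    paint(gene.chrom, ex, t.id)
    frozen = {
        chrom: {pos: frozenset(s) for pos, s in d.items()}
        for chrom, d in tmp.items()
    }
    return BaseFeatureIndex(level, frozen)


@dataclass(frozen=True)
class FeatureAssignment:
    consistent_features: frozenset[str]

    @property
    def unambiguous(self) -> bool:
        return len(self.consistent_features) == 1

    @property
    def unassigned(self) -> bool:
        return len(self.consistent_features) == 0


def consistent_features(
    fragment: AlignedFragment,
    index: BaseFeatureIndex,
    annotation: Annotation | None = None,
) -> FeatureAssignment:
    """Consistent feature set of one fragment.

    Intersects the non-empty per-base sets over all covered positions;
    at isoform level, also drops isoforms whose intron chain does not
    contain every junction of the fragment. A fragment asserting a
    junction unknown to every base-consistent isoform is unassigned.
    """
    result: frozenset[str] | None = None
    chrom_index = index.by_chrom.get(fragment.chrom, {})
    for pos in fragment.positions():
        feats = chrom_index.get(pos)
        if not feats:
            continue
        result = feats if result is None else (result & feats)
        if not result:
            return FeatureAssignment(frozenset())
    if result is None:
        return FeatureAssignment(frozenset())
    if index.level == "isoform" and fragment.junctions:
        if annotation is None:
            raise ValueError("isoform-level junction filtering needs the annotation")
        jset = fragment.junctions
        result = frozenset(
            tid for tid in result
            if jset <= annotation.transcript(tid).junctions
        )
    return FeatureAssignment(result)


def assign_fragments(
    fragments: Sequence[AlignedFragment],
    index: BaseFeatureIndex,
    annotation: Annotation | None = None,
) -> list[FeatureAssignment]:
    return [consistent_features(f, index, annotation) for f in fragments]


# ---------------------------------------------------------------------------
# Consistency distribution (isoform ambiguity)
# ---------------------------------------------------------------------------

def consistency_distribution(
    fragments: Sequence[AlignedFragment],
    assignments: Sequence[FeatureAssignment],
    strata_edges: Sequence[int] = (),
) -> pd.DataFrame:
    """Cumulative distribution of consistent-set size, per length stratum.

    Fragments assigned to at least one feature enter the distribution;
    ``strata_edges`` split them by effective alignment length. Returns
    columns (stratum, size, cum_fraction, n) where ``cum_fraction`` at
    size k is the fraction of fragments with |consistent set| <= k; the
    row at size 1 is the unambiguous rate.
    """
    edges = sorted(strata_edges)

    def stratum(L: int) -> str:
        if not edges:
            return "all"
        for lo, hi in zip((0, *edges), (*edges, np.inf)):
            if lo <= L < hi:
                return f"[{lo},{hi})" if np.isfinite(hi) else f">={lo}"
        raise AssertionError

    sizes: dict[str, list[int]] = {}
    for frag, a in zip(fragments, assignments):
        if a.unassigned:
            continue
        sizes.setdefault(stratum(frag.effective_length), []).append(
            len(a.consistent_features)
        )
    rows = []
    for label, vals in sizes.items():
        arr = np.asarray(vals)
        for k in range(1, arr.max() + 1):
            rows.append({
                "stratum": label, "size": k,
                "cum_fraction": float((arr <= k).mean()),
                "n": len(arr),
            })
    return pd.DataFrame(rows)


def unambiguous_rate(assignments: Sequence[FeatureAssignment]) -> float:
    """Fraction of assigned fragments whose consistent set is a singleton."""
    assigned = [a for a in assignments if not a.unassigned]
    if not assigned:
        return float("nan")
    return sum(a.unambiguous for a in assigned) / len(assigned)


# ---------------------------------------------------------------------------
# Gene-level quantification
# ---------------------------------------------------------------------------

def gene_read_fractions(
    assignments: Sequence[FeatureAssignment],
    min_fraction: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene fraction of unambiguously assigned reads.

    Returns columns (gene_id, count, fraction, observed); genes with a
    fraction below ``min_fraction`` are flagged unobserved.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        if a.unambiguous:
            (gid,) = a.consistent_features
            counts[gid] = counts.get(gid, 0) + 1
    total = sum(counts.values())
    rows = [
        {"gene_id": gid, "count": c, "fraction": c / total,
         "observed": c / total >= min_fraction}
        for gid, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "count", "fraction", "observed"])


def fold_change_flags(
    frac_a: Mapping[str, float],
    frac_b: Mapping[str, float],
    fold: float = 10.0,
) -> pd.DataFrame:
    """Flag genes as A-enriched / B-enriched / neither by fraction ratio.

    Only genes observed (fraction > 0) in at least one library enter;
    zero in one library with signal in the other counts as enrichment.
    """
    rows = []
    for gid in sorted(set(frac_a) | set(frac_b)):
        fa, fb = frac_a.get(gid, 0.0), frac_b.get(gid, 0.0)
        if fa == 0.0 and fb == 0.0:
            continue
        if fb == 0.0 or (fb > 0 and fa / fb > fold):
            flag = "A-enriched"
        elif fa == 0.0 or fb / fa > fold:
            flag = "B-enriched"
        else:
            flag = "neither"
        rows.append({"gene_id": gid, "fraction_a": fa, "fraction_b": fb,
                     "flag": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mappability stratification
# ---------------------------------------------------------------------------

def gene_mean_mappability(
    genes: Iterable[Gene],
    track: Sequence[tuple[str, int, int, float]],
) -> pd.Series:
    """Length-weighted mean mappability over each gene's genomic footprint."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, s, e, score in track:
        by_chrom.setdefault(chrom, []).append((s, e, score))
    for ivs in by_chrom.values():
        ivs.sort()
    out = {}
    for gene in genes:
        lo, hi = gene.span
        total = weighted = 0.0
        for s, e, score in by_chrom.get(gene.chrom, []):
            ov = min(e, hi) - max(s, lo)
            if ov > 0:
                total += ov
                weighted += ov * score
        out[gene.id] = weighted / total if total else 0.0
    return pd.Series(out, name="mean_mappability")


def mappability_stratify(
    genes: Sequence[Gene],
    scores: Mapping[str, float],
    frac_a: Mapping[str, float],
    frac_b: Mapping[str, float],
    n_groups: int = 5,
    min_length: int = 500,
    biotype: str | None = None,
) -> pd.DataFrame:
    """Fraction of genes better represented in library A, per score group.

    Genes at least ``min_length`` long (genomic span) and observed in both
    libraries are sorted by mean mappability and split into ``n_groups``
    near-equal groups (sizes differ by at most one). Optionally restricted
    to one biotype. Returns columns
    (group, n_genes, mean_score, frac_a_higher).
    """
    eligible = [
        g for g in genes
        if g.span[1] - g.span[0] >= min_length
        and g.id in frac_a and g.id in frac_b
        and (biotype is None or g.biotype == biotype)
    ]
    eligible.sort(key=lambda g: (scores.get(g.id, 0.0), g.id))
    if len(eligible) < n_groups:
        raise ValueError("fewer eligible genes than groups")
    rows = []
    for group_idx, chunk in enumerate(
        np.array_split(np.arange(len(eligible)), n_groups)
    ):
        members = [eligible[i] for i in chunk]
        higher = [frac_a[g.id] > frac_b[g.id] for g in members]
        rows.append({
            "group": group_idx,
            "n_genes": len(members),
            "mean_score": float(np.mean([scores.get(g.id, 0.0)
                                         for g in members])),
            "frac_a_higher": float(np.mean(higher)),
        })
    return pd.DataFrame(rows)


def biotype_breakdown(
    assignments: Sequence[FeatureAssignment], annotation: Annotation
) -> pd.Series:
    """Fraction of unambiguously assigned reads per gene biotype (sums to 1)."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.unambiguous:
            (gid,) = a.consistent_features
            bt = annotation.genes[gid].biotype
            counts[bt] = counts.get(bt, 0) + 1
    total = sum(counts.values())
    return pd.Series({k: v / total for k, v in sorted(counts.items())},
                     name="fraction")


# ---------------------------------------------------------------------------
# Transcript-level quantification
# ---------------------------------------------------------------------------

def unique_bases(transcript: Transcript, gene: Gene) -> int:
    """Exonic bases belonging to this isoform and to no sibling isoform."""
    own = {p for s, e in transcript.exons for p in range(s, e)}
    for sib in gene.transcripts:
        if sib.id == transcript.id:
            continue
        own -= {p for s, e in sib.exons for p in range(s, e)}
    return len(own)


def transcript_abundance(
    assignments: Sequence[FeatureAssignment],
    annotation: Annotation,
    min_unique: int = 10,
    multi_isoform_coding_only: bool = True,
) -> pd.DataFrame:
    """Unambiguous-read transcript abundance, unique-base normalized.

    abundance(t) = (# fragments whose consistent set is exactly {t})
    / unique_bases(t). Transcripts with fewer than ``min_unique`` unique
    bases are excluded; by default the analysis set is multi-isoform
    protein-coding genes. Returns columns
    (transcript_id, gene_id, count, unique_bases, abundance).
    """
    counts: dict[str, int] = {}
    for a in assignments:
        if a.unambiguous:
            (tid,) = a.consistent_features
            counts[tid] = counts.get(tid, 0) + 1
    rows = []
    for gene in annotation:
        if multi_isoform_coding_only and (
            gene.biotype != "protein_coding" or len(gene.transcripts) < 2
        ):
            continue
        for t in gene.transcripts:
            ub = unique_bases(t, gene)
            if ub < min_unique:
                continue
            c = counts.get(t.id, 0)
            rows.append({
                "transcript_id": t.id, "gene_id": gene.id,
                "count": c, "unique_bases": ub, "abundance": c / ub,
            })
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "count",
                       "unique_bases", "abundance"]
    )


def ambiguity_rate(
    gene: Gene,
    assignments: Sequence[FeatureAssignment],
    annotation: Annotation,
) -> float | None:
    """Fraction of the gene's isoform-level reads that are ambiguous.

    A fragment counts toward the gene when every isoform in its consistent
    set belongs to the gene; it is ambiguous when that set has >1 element.
    Returns None for genes with no reads.
    """
    own = {t.id for t in gene.transcripts}
    total = ambiguous = 0
    for a in assignments:
        if a.unassigned or not (a.consistent_features <= own):
            continue
        total += 1
        if not a.unambiguous:
            ambiguous += 1
    if total == 0:
        return None
    return ambiguous / total


def compare_abundance_estimates(
    external: Mapping[str, float],
    internal: Mapping[str, float],
    gene_of: Mapping[str, str],
    gene_ambiguity: Mapping[str, float],
    thresholds: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Spearman correlation of an external estimator against direct counts.

    For each ambiguity threshold, correlates over the transcripts whose
    gene's ambiguity rate is below the threshold. Fewer than 3 shared
    transcripts gives NaN. Returns columns (threshold, n, rho).
    """
    shared = sorted(set(external) & set(internal))
    rows = []
    for thr in thresholds:
        ids = [
            t for t in shared
            if gene_ambiguity.get(gene_of.get(t, ""), np.inf) < thr
        ]
        if len(ids) < 3:
            rows.append({"threshold": thr, "n": len(ids), "rho": np.nan})
            continue
        rho = stats.spearmanr(
            [external[t] for t in ids], [internal[t] for t in ids]
        ).statistic
        rows.append({"threshold": thr, "n": len(ids), "rho": float(rho)})
    return pd.DataFrame(rows)


def correlation_difference_test(
    estimates_a: Mapping[str, float],
    estimates_b: Mapping[str, float],
    internal: Mapping[str, float],
    gene_of: Mapping[str, str],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap test that estimator A correlates better than estimator B.

    Resamples genes (not transcripts, which co-vary within a gene) and
    recomputes the Spearman-correlation difference. Returns
    (observed difference, one-sided p-value for A > B).
    """
    shared = sorted(set(estimates_a) & set(estimates_b) & set(internal))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared transcripts")
    genes: dict[str, list[str]] = {}
    for t in shared:
        genes.setdefault(gene_of[t], []).append(t)
    gene_ids = sorted(genes)

    def diff(tids: list[str]) -> float:
        truth = [internal[t] for t in tids]
        ra = stats.spearmanr([estimates_a[t] for t in tids], truth).statistic
        rb = stats.spearmanr([estimates_b[t] for t in tids], truth).statistic
        return float(ra - rb)

    observed = diff(shared)
    rng = np.random.default_rng(seed)
    worse = 0
    for _ in range(n_boot):
        sample = rng.integers(0, len(gene_ids), size=len(gene_ids))
        tids = [t for i in sample for t in genes[gene_ids[i]]]
        if len(set(tids)) < 3:
            continue
        if diff(tids) <= 0:
            worse += 1
    return observed, (worse + 1) / (n_boot + 1)
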