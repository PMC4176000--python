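"""Reusable synthetic-benchmark workflows.

Each function stands up a seeded synthetic study and runs one of the
package's comparative analyses end to end: read-length effects on
isoform ambiguity and haplotype assignability, mappability-stratified
library comparison, null-calibration and power of the allele-specific
tests, and the base-matched long- vs short-read ASE comparison with the
mapping-retention filter. They are the workloads behind the validation
suite and the reproduction script; problem sizes default to desk scale.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_specific import (
    ase_scan,
    asas_scan,
    assign_haplotype,
    exon_blocks,
    gene_haplotype_counts,
    retention_rate,
)
from .feature_assignment import (
    BaseFeatureIndex,
    assign_fragments,
    build_base_index,
    consistent_features,
    gene_mean_mappability,
    gene_read_fractions,
    mappability_stratify,
    unambiguous_rate,
)
from .model import AlignedFragment, Annotation, SiteIndex
from .synthetic_data import (
    ReferenceGenome,
    SimulationConfig,
    ToyAligner,
    compute_mappability,
    generate_annotation,
    generate_diplotype,
    generate_genome,
    simulate_library,
)


# ---------------------------------------------------------------------------
# Independent reference implementation of the assignment rule
# ---------------------------------------------------------------------------

def brute_force_consistent(
    fragment: AlignedFragment, annotation: Annotation, level: str
) -> frozenset[str]:
    """Direct per-base implementation of the consistent-feature rule.

    Recomputes, without any index, the intersection of non-empty
    per-base feature sets (plus the junction filter at isoform level) by
    scanning every gene and transcript for every covered base. Used as
    the slow reference the indexed path is validated against.
    """
    per_base_sets = []
    for pos in fragment.positions():
        feats = set()
        for gene in annotation:
            if gene.chrom != fragment.chrom:
                continue
            if level == "gene":
                lo, hi = gene.span
                if lo <= pos < hi:
                    feats.add(gene.id)
            else:
                for t in gene.transcripts:
                    if any(s <= pos < e for s, e in t.exons):
                        feats.add(t.id)
        if feats:
            per_base_sets.append(feats)
    if not per_base_sets:
        return frozenset()
    result = set.intersection(*per_base_sets)
    if level == "isoform" and fragment.junctions:
        result = {
            tid for tid in result
            if fragment.junctions <= annotation.transcript(tid).junctions
        }
    return frozenset(result)


# ---------------------------------------------------------------------------
# Read-length effect experiments
# ---------------------------------------------------------------------------

def _uniform_coding_expression(annotation: Annotation) -> dict[str, float]:
    coding = [g.id for g in annotation if g.biotype != "pseudogene"]
    return {gid: 1.0 for gid in coding}


def truncated_fragment(
    full: AlignedFragment,
    transcript,
    strand: str,
    tx_start: int,
    fragment_length: int,
    read_length: int,
) -> AlignedFragment:
    """The alignment the same fragment would give with shorter reads.

    Rebuilds the two mate windows of length ``read_length`` over the
    fragment's mRNA interval and keeps only the bases of ``full`` those
    windows cover — i.e. per-fragment read truncation.
    """
    from .model import fragment_from_positions, tx_window_to_blocks

    c = min(fragment_length, read_length)
    calls: dict[int, str] = {}
    junctions: set[tuple[int, int]] = set()
    for ws, we in ((tx_start, tx_start + c),
                   (tx_start + fragment_length - c,
                    tx_start + fragment_length)):
        blocks = tx_window_to_blocks(transcript, strand, ws, we)
        junctions |= {
            (b1[1], b2[0]) for b1, b2 in zip(blocks, blocks[1:])
        }
        for s, e in blocks:
            for pos in range(s, e):
                calls[pos] = full.base_at(pos)
    return fragment_from_positions(
        full.name, full.chrom, calls, junctions, strand
    )


def read_length_sweep(
    read_lengths: Sequence[int] = (75, 150, 262, 524),
    n_fragments: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Isoform ambiguity and haplotype assignability versus read length.

    One library is simulated at the longest read length; every shorter
    read length sees the *same fragments* through truncated reads, so
    the comparison is paired: with fewer covered bases a fragment's
    consistent-isoform set can only grow and its chance of covering a
    het site can only fall. Returns columns (read_length,
    unambiguous_isoform_rate, assignable_fraction,
    mean_effective_length).
    """
    base = SimulationConfig(
        genome_length=120_000,
        n_genes=18,
        isoforms_per_gene=(2, 3),
        duplicate_locus_fraction=0.0,
        het_density=2e-3,
        fragment_mean=450.0,
        fragment_sd=120.0,
        read_length=max(read_lengths),
        error_rate=5e-3,
        n_fragments=n_fragments,
        seed=seed,
    )
    genome = generate_genome(base)
    annotation = generate_annotation(genome, base)
    sites = generate_diplotype(genome, base)
    base = replace(base, expression=_uniform_coding_expression(annotation))
    lib = simulate_library(genome, annotation, sites, base)
    tx_by_id = {t.id: t for t in annotation.transcripts()}
    index = build_base_index(annotation, "isoform")
    site_index = SiteIndex(sites)
    rows = []
    for rl in sorted(read_lengths):
        if rl == max(read_lengths):
            fragments = lib.fragments
        else:
            fragments = [
                truncated_fragment(
                    f, tx_by_id[row.transcript_id], row.strand,
                    int(row.tx_start), int(row.fragment_length), rl,
                )
                for f, row in zip(lib.fragments, lib.truth.itertuples())
            ]
        assignments = assign_fragments(fragments, index, annotation)
        calls = [assign_haplotype(f, site_index) for f in fragments]
        rows.append({
            "read_length": rl,
            "unambiguous_isoform_rate": unambiguous_rate(assignments),
            "assignable_fraction": float(np.mean([c.assigned for c in calls])),
            "mean_effective_length": float(np.mean(
                [f.effective_length for f in fragments]
            )),
        })
    return pd.DataFrame(rows)


def mappability_enrichment(
    seed: int = 0,
    n_fragments: int = 1500,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Long- vs short-read gene quantification across mappability groups.

    A genome with diverged duplicate loci is sequenced at 262 bp and
    75 bp; reads are aligned with the exhaustive toy aligner (so short
    reads from duplicated genes genuinely multimap and are lost), genes
    are quantified from uniquely mapped reads, and genes are stratified
    by mean 75-mer mappability. The lowest-mappability group should show
    the largest excess of long-read representation.
    """
    cfg = SimulationConfig(
        genome_length=42_000,
        n_genes=12,
        isoforms_per_gene=(1, 1),
        duplicate_locus_fraction=1 / 3,
        duplicate_divergence=0.01,
        het_density=0.0,
        fragment_mean=300.0,
        fragment_sd=60.0,
        read_length=262,
        error_rate=0.0,
        pseudogene_expression=0.0,
        n_fragments=n_fragments,
        seed=seed,
    )
    genome = generate_genome(cfg)
    annotation = generate_annotation(genome, cfg)
    cfg = replace(cfg, expression=_uniform_coding_expression(annotation))
    lib = simulate_library(genome, annotation, [], cfg)
    aligner = ToyAligner(genome, annotation, max_mismatches=4)
    gene_by_tid = {
        t.id: g.id for g in annotation for t in g.transcripts
    }
    index = build_base_index(annotation, "gene")

    def quantify(read_cores: list[str]) -> dict[str, float]:
        counts: dict[str, int] = {}
        for core in read_cores:
            hit = aligner.align(core)
            if hit.status != "mapped":
                continue
            feats = None
            for s, e in hit.blocks:
                for pos in range(s, e):
                    fs = index.features_at(hit.chrom, pos)
                    if fs:
                        feats = fs if feats is None else feats & fs
            if feats and len(feats) == 1:
                gid = next(iter(feats))
                counts[gid] = counts.get(gid, 0) + 1
        total = sum(counts.values())
        return {g: c / total for g, c in counts.items()}

    def cores(rl: int) -> list[str]:
        return [
            p.seq1[:min(rl, int(row.fragment_length))]
            for p, row in zip(lib.pairs, lib.truth.itertuples())
        ]

    frac_long = quantify(cores(262))
    frac_short = quantify(cores(75))
    track = compute_mappability(genome, k=75)
    scores = gene_mean_mappability(list(annotation), track)
    coding = [g for g in annotation if g.biotype != "pseudogene"]
    return mappability_stratify(
        coding, scores.to_dict(), frac_long, frac_short,
        n_groups=n_groups, min_length=500,
    )


# ---------------------------------------------------------------------------
# ASE calibration, power, and the base-matched comparison
# ---------------------------------------------------------------------------

def _ase_inputs(genome, annotation, sites, cfg, index=None, site_index=None):
    lib = simulate_library(genome, annotation, sites, cfg)
    if index is None:
        index = build_base_index(annotation, "gene")
    assignments = assign_fragments(lib.fragments, index)
    if site_index is None:
        site_index = SiteIndex(sites)
    calls = [assign_haplotype(f, site_index) for f in lib.fragments]
    gene_ids = [
        next(iter(a.consistent_features)) if a.unambiguous else None
        for a in assignments
    ]
    return lib, calls, gene_ids, site_index


def ase_null_calibration(
    n_replicates: int = 100,
    n_genes: int = 50,
    n_fragments: int = 3000,
    seed: int = 0,
    q: float = 0.10,
) -> pd.DataFrame:
    """False-positive rate of the ASE scan on balanced (null) genes.

    One fixed genome; ``n_replicates`` independent libraries at
    allelic_ratio 0.5. Returns per-replicate columns
    (replicate, n_tested, n_significant, fp_fraction).
    """
    cfg = SimulationConfig(
        genome_length=n_genes * 2400,
        n_genes=n_genes,
        isoforms_per_gene=(1, 1),
        duplicate_locus_fraction=0.0,
        het_density=2e-3,
        fragment_mean=250.0,
        fragment_sd=60.0,
        read_length=262,
        error_rate=5e-3,
        allelic_ratio=0.5,
        n_fragments=n_fragments,
        seed=seed,
    )
    genome = generate_genome(cfg)
    annotation = generate_annotation(genome, cfg)
    sites = generate_diplotype(genome, cfg)
    cfg = replace(cfg, expression=_uniform_coding_expression(annotation))
    index = build_base_index(annotation, "gene")
    site_index = SiteIndex(sites)
    rows = []
    for rep in range(n_replicates):
        rep_cfg = replace(cfg, seed=seed + 1000 + rep)
        lib, calls, gene_ids, _ = _ase_inputs(
            genome, annotation, sites, rep_cfg, index, site_index
        )
        counts = gene_haplotype_counts(lib.fragments, calls, gene_ids)
        result = ase_scan(counts, q=q)
        n_tested = len(result)
        n_sig = int(result["significant"].sum()) if n_tested else 0
        rows.append({
            "replicate": rep, "n_tested": n_tested, "n_significant": n_sig,
            "fp_fraction": n_sig / n_tested if n_tested else 0.0,
        })
    return pd.DataFrame(rows)


def ase_power(
    allelic_ratio: float = 0.8,
    n_genes: int = 20,
    n_fragments: int = 3000,
    seed: int = 0,
    q: float = 0.10,
) -> dict[str, float]:
    """Detection power for a planted allelic imbalance.

    Every gene expresses the maternal haplotype at ``allelic_ratio``;
    power is the fraction of tested genes called significant at FDR q.
    Also reports the mean absolute error of the per-gene maternal
    fraction estimate and its expected binomial 3-sigma bound.
    """
    cfg = SimulationConfig(
        genome_length=n_genes * 2400,
        n_genes=n_genes,
        isoforms_per_gene=(1, 1),
        duplicate_locus_fraction=0.0,
        het_density=2e-3,
        fragment_mean=250.0,
        fragment_sd=60.0,
        read_length=262,
        error_rate=5e-3,
        allelic_ratio=allelic_ratio,
        n_fragments=n_fragments,
        seed=seed,
    )
    genome = generate_genome(cfg)
    annotation = generate_annotation(genome, cfg)
    sites = generate_diplotype(genome, cfg)
    cfg = replace(cfg, expression=_uniform_coding_expression(annotation))
    lib, calls, gene_ids, _ = _ase_inputs(genome, annotation, sites, cfg)
    counts = gene_haplotype_counts(lib.fragments, calls, gene_ids)
    result = ase_scan(counts, q=q)
    if not len(result):
        return {"power": 0.0, "n_tested": 0,
                "mean_abs_error": float("nan"), "max_3sigma": float("nan")}
    totals = result["maternal"] + result["paternal"]
    est = result["maternal"] / totals
    sigma = np.sqrt(allelic_ratio * (1 - allelic_ratio) / totals)
    return {
        "power": float(result["significant"].mean()),
        "n_tested": int(len(result)),
        "mean_abs_error": float((est - allelic_ratio).abs().mean()),
        "frac_within_3sigma": float(
            ((est - allelic_ratio).abs() <= 3 * sigma).mean()
        ),
    }


def asas_planted_skipping(
    inclusion: tuple[float, float] = (0.9, 0.1),
    n_fragments: int = 4000,
    seed: int = 0,
    q: float = 0.10,
) -> dict[str, object]:
    """Detection of haplotype-specific exon skipping at the right block.

    One target gene expresses its exon-inclusion isoform at
    ``inclusion[0]`` on the maternal haplotype and ``inclusion[1]`` on
    the paternal one; the remaining genes splice identically on both
    haplotypes. Reports the ASAS scan result, the skipped-exon interval
    and whether the top significant block lies inside it. Layouts
    without a usable target (a skipping isoform plus a het site on a
    shared exon) are re-drawn from the next seed.
    """
    target = None
    for attempt in range(10):
        cfg = SimulationConfig(
            genome_length=8 * 3000,
            n_genes=8,
            isoforms_per_gene=(2, 2),
            duplicate_locus_fraction=0.0,
            het_density=0.01,
            fragment_mean=250.0,
            fragment_sd=60.0,
            read_length=262,
            error_rate=5e-3,
            n_fragments=n_fragments,
            seed=seed + attempt,
        )
        genome = generate_genome(cfg)
        annotation = generate_annotation(genome, cfg)
        sites = generate_diplotype(genome, cfg)
        # target: first gene whose second isoform skips an internal exon
        # and that carries at least one het site on a shared exon
        site_positions = [s.pos for s in sites]
        for gene in annotation:
            if len(gene.transcripts) < 2:
                continue
            full, alt = gene.transcripts[0], gene.transcripts[1]
            skipped = set(full.exons) - set(alt.exons)
            shared = set(full.exons) & set(alt.exons)
            has_shared_het = any(
                s <= p < e for s, e in shared for p in site_positions
            )
            if skipped and has_shared_het:
                target = (gene, next(iter(skipped)))
                break
        if target is not None:
            break
    if target is None:
        raise RuntimeError("no usable target gene in any attempted layout")
    gene, skipped_exon = target
    expression = _uniform_coding_expression(annotation)
    expression[gene.id] = len(expression)  # ~half the library
    usage = {gene.id: {
        "maternal": [inclusion[0], 1 - inclusion[0]],
        "paternal": [inclusion[1], 1 - inclusion[1]],
    }}
    cfg = replace(cfg, expression=expression, isoform_usage=usage)
    lib, calls, gene_ids, _ = _ase_inputs(genome, annotation, sites, cfg)
    frag_by_gene: dict[str, list] = {}
    call_by_gene: dict[str, list] = {}
    for f, c, gid in zip(lib.fragments, calls, gene_ids):
        if gid is None:
            continue
        frag_by_gene.setdefault(gid, []).append(f)
        call_by_gene.setdefault(gid, []).append(c)
    result = asas_scan(annotation, frag_by_gene, call_by_gene, q=q)
    sig = result[result["significant"]]
    top_in_skipped = False
    if len(sig):
        top = sig.loc[sig["p"].idxmin()]
        top_in_skipped = (
            top.gene_id == gene.id
            and skipped_exon[0] <= top.start and top.end <= skipped_exon[1]
        )
    return {
        "result": result,
        "target_gene": gene.id,
        "skipped_exon": skipped_exon,
        "n_significant": int(len(sig)),
        "top_block_in_skipped_exon": bool(top_in_skipped),
    }


def base_matched_ase_comparison(
    seed: int = 0,
    n_long: int = 2200,
    long_read_length: int = 262,
    short_read_length: int = 75,
    q: float = 0.10,
) -> dict[str, object]:
    """Base-matched ASE discovery: long reads vs short reads.

    Both libraries sequence the same diploid genome, which includes
    diverged duplicate loci, with the same total raw base budget (the
    short library gets proportionally more fragments). The ASE pipeline
    runs with the mapping-retention filter: flipped haplotype-assigned
    reads are realigned with the exhaustive aligner, and genes retaining
    fewer than 90% are untestable. Short reads fail retention at the
    duplicated loci, so the long-read library should call at least as
    many ASE genes.
    """
    cfg = SimulationConfig(
        genome_length=35_000,
        n_genes=10,
        isoforms_per_gene=(1, 1),
        duplicate_locus_fraction=0.4,
        duplicate_divergence=0.02,
        het_density=2.5e-3,
        fragment_mean=300.0,
        fragment_sd=80.0,
        read_length=long_read_length,
        error_rate=2e-3,
        pseudogene_expression=0.0,
        allelic_ratio=0.8,
        n_fragments=n_long,
        seed=seed,
    )
    genome = generate_genome(cfg)
    annotation = generate_annotation(genome, cfg)
    sites = generate_diplotype(genome, cfg)
    cfg = replace(cfg, expression=_uniform_coding_expression(annotation))
    aligner = ToyAligner(genome, annotation, max_mismatches=4)
    site_index = SiteIndex(sites)

    def run(read_length: int, n_fragments: int, lib_seed: int):
        lib_cfg = replace(cfg, read_length=read_length,
                          n_fragments=n_fragments, seed=lib_seed)
        lib, calls, gene_ids, _ = _ase_inputs(
            genome, annotation, sites, lib_cfg
        )
        retention = {}
        for gid in sorted({g for g in gene_ids if g}):
            sub = [(f, c) for f, c, g in zip(lib.fragments, calls, gene_ids)
                   if g == gid and c.assigned]
            if not sub:
                continue
            res = retention_rate(
                annotation.genes[gid],
                [f for f, _ in sub], [c for _, c in sub],
                site_index, aligner.align,
            )
            retention[gid] = res.rate
        counts = gene_haplotype_counts(lib.fragments, calls, gene_ids)
        kept = counts[counts["gene_id"].map(
            lambda g: retention.get(g, 0.0) >= 0.9
        )]
        scan = ase_scan(kept.reset_index(drop=True), q=q)
        return {
            "n_tested": len(scan),
            "n_significant": int(scan["significant"].sum()) if len(scan) else 0,
            "retention": retention,
        }

    n_short = int(round(n_long * long_read_length / short_read_length))
    long_res = run(long_read_length, n_long, seed + 11)
    short_res = run(short_read_length, n_short, seed + 12)
    return {"long": long_res, "short": short_res,
            "n_long_fragments": n_long, "n_short_fragments": n_short}
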