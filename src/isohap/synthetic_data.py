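"""Synthetic diploid transcriptome and sequencing-library generator.

Produces, from one seeded configuration, everything the comparative
read-length analysis consumes: a reference genome with optional
pseudogene-like duplicated loci (the low-mappability regime), a
multi-isoform annotation, phased heterozygous SNPs laid down as a Poisson
process, strand-specific poly-A-style paired-end reads with adapter
read-through for fragments shorter than the read length, per-read truth
records, and a brute-force spliced aligner to close the loop.

All randomness flows from ``SimulationConfig.seed`` through fixed spawned
streams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AlignedFragment,
    TranscriptMap,
    Annotation,
    Gene,
    Interval,
    PhasedSite,
    Transcript,
    fragment_from_positions,
    tx_window_to_blocks,
)
from .read_merge import ReadPair
from .seq import ALPHABET, complement, encode, random_seq, revcomp

_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# 13-base Illumina TruSeq read-through prefix
DEFAULT_ADAPTER = "AGATCGGAAGAGC"

_MIN_FOOTPRINT = 700  # smallest locus that can host an exon chain


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale version of a deeply sequenced human
    LCL poly-A library: heterozygous sites at ~3 per 10 kb (the regime in
    which roughly a quarter of 1 kb alignments cover at least one het
    site), 262 bp reads over fragments that are frequently shorter than
    the read length, ~0.5% substitution error, and a few percent of reads
    arising from pseudogene-like duplicated loci.
    """

    genome_length: int = 150_000
    n_genes: int = 24
    isoforms_per_gene: tuple[int, int] = (1, 3)
    duplicate_locus_fraction: float = 0.125
    duplicate_divergence: float = 0.01
    het_density: float = 3e-4
    fragment_mean: float = 220.0
    fragment_sd: float = 80.0
    fragment_min: int = 20
    read_length: int = 262
    error_rate: float = 5e-3
    adapter: str = DEFAULT_ADAPTER
    n_fragments: int = 10_000
    expression: Mapping[str, float] | None = None
    pseudogene_expression: float = 0.03
    allelic_ratio: float | Mapping[str, float] = 0.5
    isoform_usage: Mapping[str, Mapping[str, Sequence[float]]] | None = None
    quality_profile: str = "constant"  # or "decay"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_locus_fraction", "duplicate_divergence",
                     "het_density", "error_rate", "pseudogene_expression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_min < 1:
            raise ValueError("fragment_min must be >= 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if len(self.adapter) < 13:
            raise ValueError("adapter must be at least 13 bases")
        lo, hi = self.isoforms_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("isoforms_per_gene range invalid")
        if isinstance(self.allelic_ratio, (int, float)):
            if not 0.0 <= self.allelic_ratio <= 1.0:
                raise ValueError("allelic_ratio must be in [0, 1]")
        if self.quality_profile not in ("constant", "decay"):
            raise ValueError("quality_profile must be 'constant' or 'decay'")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named, independent RNG streams derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genome", "annotation", "diplotype", "library")
        return {n: np.random.Generator(np.random.PCG64(c))
                for n, c in zip(names, children)}


@dataclass(frozen=True)
class Locus:
    """One gene-sized slot of the synthetic genome."""

    index: int
    kind: str  # "coding" or "pseudogene"
    start: int
    end: int
    source: int | None = None  # index of the copied coding locus


@dataclass
class ReferenceGenome:
    """Named nucleotide sequences plus the locus layout they were built on."""

    sequences: dict[str, str]
    loci: tuple[Locus, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequence names must be unique")
        for name, seq in self.sequences.items():
            if set(seq) - set(ALPHABET):
                raise ValueError(f"{name} contains non-ACGT characters")


CHROM = "chr1"


def _layout(config: SimulationConfig) -> tuple[Locus, ...]:
    n_dup = int(round(config.duplicate_locus_fraction * config.n_genes))
    n_slots = config.n_genes + n_dup
    slot = config.genome_length // n_slots
    flank = max(slot // 12, 20)
    if slot - 2 * flank < _MIN_FOOTPRINT:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{n_slots} loci of usable size >= {_MIN_FOOTPRINT}"
        )
    loci = [
        Locus(i, "coding", i * slot + flank, (i + 1) * slot - flank)
        for i in range(config.n_genes)
    ]
    loci += [
        Locus(config.n_genes + j, "pseudogene",
              (config.n_genes + j) * slot + flank,
              (config.n_genes + j + 1) * slot - flank,
              source=j)
        for j in range(n_dup)
    ]
    return tuple(loci)


def generate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Random genome with `duplicate_locus_fraction` of loci copied elsewhere.

    Each duplicated locus is a full copy of its source gene's footprint with
    independent per-base substitutions at rate ``duplicate_divergence``.
    """
    rng = config.streams()["genome"]
    loci = _layout(config)
    seq = list(random_seq(rng, config.genome_length))
    for locus in loci:
        if locus.kind != "pseudogene":
            continue
        src = loci[locus.source]
        copy = seq[src.start:src.end]
        hits = np.flatnonzero(
            rng.random(len(copy)) < config.duplicate_divergence
        )
        for i in hits:
            others = [b for b in ALPHABET if b != copy[i]]
            copy[i] = others[rng.integers(0, 3)]
        seq[locus.start:locus.start + len(copy)] = copy
    return ReferenceGenome({CHROM: "".join(seq)}, loci)


def _exon_chain(
    rng: np.random.Generator, start: int, end: int
) -> tuple[Interval, ...]:
    """Random exon chain filling part of [start, end)."""
    footprint = end - start
    for n_exons in range(min(8, footprint // 260), 1, -1):
        exon_lens = rng.integers(80, 261, size=n_exons)
        intron_lens = rng.integers(60, 201, size=n_exons - 1)
        if exon_lens.sum() + intron_lens.sum() <= footprint:
            break
    else:
        n_exons = 2
        exon_lens = np.full(2, max((footprint - 80) // 2, 60))
        intron_lens = np.array([80])
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos = exons[-1][1] + (int(intron_lens[i]) if i < n_exons - 1 else 0)
    return tuple(exons)


def _isoforms(
    rng: np.random.Generator,
    gene_id: str,
    exons: tuple[Interval, ...],
    k: int,
) -> tuple[Transcript, ...]:
    """Up to k isoforms: the full chain plus skipped-exon variants.

    Every isoform shares the first exon with the others and differs from
    the full chain by exactly one skipped internal exon.
    """
    txs = [Transcript(f"{gene_id}.1", gene_id, exons)]
    internal = list(range(1, len(exons) - 1))
    rng.shuffle(internal)
    for j, skip in enumerate(internal[: k - 1], start=2):
        kept = tuple(ex for i, ex in enumerate(exons) if i != skip)
        txs.append(Transcript(f"{gene_id}.{j}", gene_id, kept))
    return tuple(txs)


def generate_annotation(
    genome: ReferenceGenome, config: SimulationConfig
) -> Annotation:
    """Gene models over the genome's loci.

    Coding loci get 1..k isoforms built by internal-exon skipping; each
    duplicated locus carries the source gene's exon chain (shifted) as a
    single-isoform gene of biotype ``pseudogene``.
    """
    rng = config.streams()["annotation"]
    ann = Annotation()
    chains: dict[int, tuple[Interval, ...]] = {}
    lo, hi = config.isoforms_per_gene
    for locus in genome.loci:
        if locus.kind != "coding":
            continue
        exons = _exon_chain(rng, locus.start, locus.end)
        chains[locus.index] = exons
        gid = f"G{locus.index:04d}"
        k = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(Gene(gid, gid, CHROM, strand, "protein_coding",
                     _isoforms(rng, gid, exons, k)))
    for locus in genome.loci:
        if locus.kind != "pseudogene":
            continue
        src = next(l for l in genome.loci if l.index == locus.source)
        shift = locus.start - src.start
        exons = tuple((s + shift, e + shift) for s, e in chains[src.index])
        gid = f"PG{locus.source:04d}"
        strand = ann.genes[f"G{locus.source:04d}"].strand
        ann.add(Gene(gid, gid, CHROM, strand, "pseudogene",
                     (Transcript(f"{gid}.1", gid, exons),)))
    return ann


def generate_diplotype(
    genome: ReferenceGenome, config: SimulationConfig
) -> list[PhasedSite]:
    """Phased heterozygous SNPs from a Poisson process at `het_density`."""
    rng = config.streams()["diplotype"]
    sites: list[PhasedSite] = []
    for chrom, seq in genome.sequences.items():
        n = rng.poisson(config.het_density * len(seq))
        n = min(n, len(seq))
        positions = np.sort(rng.choice(len(seq), size=n, replace=False))
        for pos in positions:
            ref = seq[pos]
            others = [b for b in ALPHABET if b != ref]
            alt = others[rng.integers(0, 3)]
            if rng.random() < 0.5:
                mat, pat = ref, alt
            else:
                mat, pat = alt, ref
            sites.append(PhasedSite(chrom, int(pos), ref, mat, pat))
    return sites


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MateAlignment:
    """True alignment of one mate, in reference coordinates."""

    name: str
    mate: int  # 1 or 2
    chrom: str
    blocks: tuple[Interval, ...]
    junctions: frozenset[Interval]
    reverse: bool  # read aligns as reverse complement of the reference
    aligned_read_bases: int  # leading read bases that align (rest is adapter)


@dataclass
class SimulatedLibrary:
    """Reads, true alignments and truth tables for one simulated run."""

    pairs: list[ReadPair]
    fragments: list[AlignedFragment]
    mate_alignments: list[MateAlignment]
    truth: pd.DataFrame
    n_resampled: int
    config: SimulationConfig


def haplotype_mrna(
    genome: ReferenceGenome,
    gene: Gene,
    transcript: Transcript,
    sites: Sequence[PhasedSite],
    haplotype: str,
) -> str:
    """Mature mRNA (5'->3') of one haplotype of a transcript."""
    chrom_seq = genome.sequences[gene.chrom]
    parts = []
    for s, e in transcript.exons:
        seg = list(chrom_seq[s:e])
        for site in sites:
            if s <= site.pos < e:
                seg[site.pos - s] = getattr(site, haplotype)
        parts.append("".join(seg))
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def _quality_string(config: SimulationConfig) -> str:
    if config.quality_profile == "constant":
        return chr(37 + 33) * config.read_length
    quals = np.linspace(37, 20, config.read_length).astype(int)
    return "".join(chr(q + 33) for q in quals)


def _apply_errors(
    rng: np.random.Generator, read: str, rate: float
) -> str:
    if rate <= 0:
        return read
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if len(hits) == 0:
        return read
    chars = list(read)
    for i in hits:
        others = [b for b in ALPHABET if b != chars[i]]
        chars[i] = others[rng.integers(0, 3)]
    return "".join(chars)


def _gene_weights(
    annotation: Annotation, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[Gene], np.ndarray]:
    genes = list(annotation)
    if config.expression is not None:
        w = np.array([config.expression.get(g.id, 0.0) for g in genes])
    else:
        w = np.zeros(len(genes))
        coding = [i for i, g in enumerate(genes) if g.biotype != "pseudogene"]
        pseudo = [i for i, g in enumerate(genes) if g.biotype == "pseudogene"]
        w[coding] = rng.lognormal(0.0, 1.0, size=len(coding))
        w[coding] *= (1.0 - (config.pseudogene_expression if pseudo else 0.0)
                      ) / w[coding].sum()
        if pseudo:
            w[pseudo] = config.pseudogene_expression / len(pseudo)
    if w.sum() <= 0:
        raise ValueError("all expression weights are zero")
    return genes, w / w.sum()


def _maternal_fraction(config: SimulationConfig, gene_id: str) -> float:
    if isinstance(config.allelic_ratio, Mapping):
        return float(config.allelic_ratio.get(gene_id, 0.5))
    return float(config.allelic_ratio)


def _usage_weights(
    config: SimulationConfig, gene: Gene, haplotype: str
) -> np.ndarray:
    k = len(gene.transcripts)
    if config.isoform_usage and gene.id in config.isoform_usage:
        w = np.asarray(config.isoform_usage[gene.id][haplotype], dtype=float)
        if len(w) != k or w.sum() <= 0:
            raise ValueError(f"bad isoform_usage for {gene.id}")
        return w / w.sum()
    return np.full(k, 1.0 / k)


def simulate_library(
    genome: ReferenceGenome,
    annotation: Annotation,
    sites: Sequence[PhasedSite],
    config: SimulationConfig,
) -> SimulatedLibrary:
    """Draw `config.n_fragments` strand-specific read pairs with truth.

    Fragments are sampled per gene-expression weight, haplotype (per-gene
    maternal fraction) and per-haplotype isoform usage; fragment lengths
    follow a normal law truncated below at ``fragment_min`` and above at
    the transcript length. When the fragment is shorter than the read
    length each mate reads through into the adapter and is padded with
    random bases — the structure the merge stage detects.
    """
    rng = config.streams()["library"]
    genes, gene_w = _gene_weights(annotation, config, rng)
    rl = config.read_length
    qual = _quality_string(config)
    site_by_gene: dict[str, list[PhasedSite]] = {}
    for g in genes:
        lo, hi = g.span
        site_by_gene[g.id] = [
            s for s in sites if s.chrom == g.chrom and lo <= s.pos < hi
        ]
    mrna_cache: dict[tuple[str, str], str] = {}
    txmap_cache: dict[str, TranscriptMap] = {}

    pairs: list[ReadPair] = []
    fragments: list[AlignedFragment] = []
    mates: list[MateAlignment] = []
    truth_rows = []
    n_resampled = 0

    for idx in range(config.n_fragments):
        for _attempt in range(1000):
            gene = genes[rng.choice(len(genes), p=gene_w)]
            hap = ("maternal"
                   if rng.random() < _maternal_fraction(config, gene.id)
                   else "paternal")
            usage = _usage_weights(config, gene, hap)
            t = gene.transcripts[rng.choice(len(gene.transcripts), p=usage)]
            if t.length >= config.fragment_min:
                break
            n_resampled += 1
        else:
            raise RuntimeError(f"no transcript of length >= fragment_min")

        key = (t.id, hap)
        if key not in mrna_cache:
            mrna_cache[key] = haplotype_mrna(
                genome, gene, t, site_by_gene[gene.id], hap
            )
        mrna = mrna_cache[key]
        flen = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
        flen = max(config.fragment_min, min(flen, t.length))
        start = int(rng.integers(0, t.length - flen + 1))
        frag = mrna[start:start + flen]

        def _read_through(core: str) -> str:
            if len(core) >= rl:
                return core[:rl]
            tail = core + config.adapter
            if len(tail) < rl:
                tail += random_seq(rng, rl - len(tail))
            return tail[:rl]

        read1 = _apply_errors(rng, _read_through(frag), config.error_rate)
        read2 = _apply_errors(rng, _read_through(revcomp(frag)),
                              config.error_rate)
        name = f"frag{idx:07d}"
        pairs.append(ReadPair(name, read1, qual, read2, qual))

        c1 = min(flen, rl)
        c2 = min(flen, rl)
        strand = gene.strand
        if key not in txmap_cache:
            txmap_cache[key[0]] = TranscriptMap(t)
        txmap = txmap_cache[key[0]]
        # mate2 reads the fragment 3'->5', so revcomp of its aligned part
        # lines up with ascending fragment coordinates
        mate2_seg = revcomp(read2[:c2])
        tx_pos: list[int] = []
        bases: list[str] = []
        m2_from = start + flen - c2
        for p in range(m2_from, start + flen):
            if p >= start + c1:  # mate1 wins where both cover
                tx_pos.append(p)
                bases.append(mate2_seg[p - m2_from])
        tx_pos.extend(range(start, start + c1))
        bases.extend(read1[:c1])
        ref_pos = txmap.to_ref(np.array(tx_pos), strand)
        base_str = "".join(bases)
        if strand == "-":
            base_str = base_str.translate(_COMP_TABLE)
        ref_calls = dict(zip(ref_pos.tolist(), base_str))

        junctions: set[Interval] = set()
        mate_windows = [(1, start, start + c1),
                        (2, start + flen - c2, start + flen)]
        for mate_no, ws, we in mate_windows:
            blocks = tx_window_to_blocks(t, strand, ws, we)
            jx = frozenset(
                (b1[1], b2[0]) for b1, b2 in zip(blocks, blocks[1:])
            )
            junctions |= jx
            # reverse flag: mate1 is transcript-sense, so it is reversed
            # on the reference exactly when the gene is minus-strand
            reverse = (strand == "-") == (mate_no == 1)
            mates.append(MateAlignment(
                name, mate_no, gene.chrom, tuple(blocks), jx,
                reverse, we - ws,
            ))

        fragment = fragment_from_positions(
            name, gene.chrom, ref_calls, junctions, strand
        )
        fragments.append(fragment)
        covered_sites = [
            s for s in site_by_gene[gene.id] if fragment.covers(s.pos)
        ]
        truth_rows.append({
            "name": name,
            "gene_id": gene.id,
            "transcript_id": t.id,
            "haplotype": hap,
            "strand": strand,
            "tx_start": start,
            "fragment_length": flen,
            "effective_length": fragment.effective_length,
            "chrom": gene.chrom,
            "ref_start": fragment.span[0],
            "ref_end": fragment.span[1],
            "n_het_sites": len(covered_sites),
        })

    truth = pd.DataFrame(truth_rows)
    return SimulatedLibrary(pairs, fragments, mates, truth,
                            n_resampled, config)


def simulate(config: SimulationConfig) -> tuple[
    ReferenceGenome, Annotation, list[PhasedSite], SimulatedLibrary
]:
    """End-to-end convenience wrapper: genome, annotation, sites, library."""
    genome = generate_genome(config)
    annotation = generate_annotation(genome, config)
    sites = generate_diplotype(genome, config)
    library = simulate_library(genome, annotation, sites, config)
    return genome, annotation, sites, library


# ---------------------------------------------------------------------------
# Toy aligner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyAlignment:
    status: str  # "mapped", "multimapped", "unmapped"
    chrom: str | None = None
    blocks: tuple[Interval, ...] = ()
    strand: str | None = None
    mismatches: int | None = None

    @property
    def start(self) -> int | None:
        return self.blocks[0][0] if self.blocks else None


class ToyAligner:
    """Exhaustive substring aligner with a bounded mismatch budget.

    Searches both strands of the genome for contiguous hits and, when an
    annotation is supplied, every isoform's spliced exonic sequence for
    junction-crossing hits. A unique best hit maps the read; two or more
    equally good hits multimap it. Seed-and-extend (pigeonhole over
    ``max_mismatches + 1`` read chunks) keeps the scan exact but fast.
    """

    def __init__(
        self,
        genome: ReferenceGenome,
        annotation: Annotation | None = None,
        max_mismatches: int = 4,
    ):
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.genome = genome
        self.max_mismatches = max_mismatches
        self._chroms = {
            name: (seq, encode(seq)) for name, seq in genome.sequences.items()
        }
        self._tx: list[tuple[str, Transcript, str, np.ndarray]] = []
        if annotation is not None:
            for g in annotation:
                chrom_seq = genome.sequences[g.chrom]
                for t in g.transcripts:
                    if len(t.exons) < 2:
                        continue  # contiguous; the genome scan covers it
                    cat = "".join(chrom_seq[s:e] for s, e in t.exons)
                    self._tx.append((g.chrom, t, cat, encode(cat)))

    def _candidates(self, text: str, read: str) -> set[int]:
        """Candidate start offsets via exact-seed pigeonhole."""
        m = self.max_mismatches
        k = len(read)
        n_chunks = m + 1
        chunk = max(k // n_chunks, 1)
        out: set[int] = set()
        for c in range(n_chunks):
            off = c * chunk
            piece = read[off:off + chunk] if c < n_chunks - 1 else read[off:]
            if not piece:
                continue
            i = text.find(piece)
            while i != -1:
                cand = i - off
                if 0 <= cand <= len(text) - k:
                    out.add(cand)
                i = text.find(piece, i + 1)
        return out

    def _scan(
        self, text: str, arr: np.ndarray, read: str
    ) -> list[tuple[int, int]]:
        """(offset, mismatches) of every hit within the budget."""
        r = encode(read)
        hits = []
        for cand in self._candidates(text, read):
            mm = int((arr[cand:cand + len(r)] != r).sum())
            if mm <= self.max_mismatches:
                hits.append((cand, mm))
        return hits

    def align(self, read: str) -> ToyAlignment:
        best: dict[tuple, tuple[int, str, tuple[Interval, ...]]] = {}

        def record(chrom: str, blocks: tuple[Interval, ...],
                   strand: str, mm: int) -> None:
            key = (chrom, blocks)
            if key not in best or mm < best[key][0]:
                best[key] = (mm, strand, blocks)

        rc = revcomp(read)
        for chrom, (text, arr) in self._chroms.items():
            for strand, r in (("+", read), ("-", rc)):
                for off, mm in self._scan(text, arr, r):
                    record(chrom, ((off, off + len(read)),), strand, mm)
        for chrom, t, cat, arr in self._tx:
            for strand, r in (("+", read), ("-", rc)):
                for off, mm in self._scan(cat, arr, r):
                    blocks = tuple(tx_window_to_blocks(
                        t, "+", off, off + len(read)
                    ))
                    record(chrom, blocks, strand, mm)

        if not best:
            return ToyAlignment("unmapped")
        top = min(mm for mm, _, _ in best.values())
        winners = [(key, v) for key, v in best.items() if v[0] == top]
        if len(winners) > 1:
            return ToyAlignment("multimapped", mismatches=top)
        (chrom, blocks), (mm, strand, _) = winners[0]
        return ToyAlignment("mapped", chrom, blocks, strand, mm)


def toy_align(
    read: str,
    genome: ReferenceGenome,
    annotation: Annotation | None = None,
    max_mismatches: int = 4,
) -> ToyAlignment:
    """One-shot wrapper over :class:`ToyAligner` (index built per call)."""
    return ToyAligner(genome, annotation, max_mismatches).align(read)


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------

def compute_mappability(
    genome: ReferenceGenome, k: int = 75
) -> list[tuple[str, int, int, float]]:
    """Per-base k-mer uniqueness track, run-length encoded.

    The score at position p is 1 / (number of occurrences of the k-mer
    starting at p, counting both strands), mirroring alignability tracks:
    1.0 marks uniquely mappable sequence.
    """
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            counts[km] = counts.get(km, 0) + 1
    out: list[tuple[str, int, int, float]] = []
    for chrom, seq in genome.sequences.items():
        scores = []
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            occ = counts.get(km, 0) + counts.get(revcomp(km), 0)
            scores.append(1.0 / occ if occ else 0.0)
        run_start, run_val = 0, scores[0]
        for i, v in enumerate(scores[1:], start=1):
            if v != run_val:
                out.append((chrom, run_start, i, run_val))
                run_start, run_val = i, v
        out.append((chrom, run_start, len(scores), run_val))
    return out
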