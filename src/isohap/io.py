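"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open; GTF and VCF are emitted
1-based per their conventions. SAM traffic goes through pysam; the
text formats (FASTA/FASTQ/GTF/VCF) are emitted directly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .model import (
    AlignedFragment,
    Annotation,
    Gene,
    PhasedSite,
    Transcript,
    fragment_from_positions,
)
from .read_merge import ReadPair
from .synthetic_data import (
    MateAlignment,
    ReferenceGenome,
    SimulatedLibrary,
)
from .seq import revcomp


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> ReferenceGenome:
    sequences: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        sequences[name] = "".join(chunks)
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(path: str | Path, annotation: Annotation, source: str = "isohap") -> None:
    """GENCODE-style GTF: gene/transcript/exon rows, 1-based inclusive."""
    with open(path, "w") as fh:
        for gene in annotation:
            attrs = (f'gene_id "{gene.id}"; gene_name "{gene.name}"; '
                     f'gene_type "{gene.biotype}";')
            s, e = gene.span
            fh.write("\t".join([gene.chrom, source, "gene", str(s + 1),
                                str(e), ".", gene.strand, ".", attrs]) + "\n")
            for t in gene.transcripts:
                tattrs = attrs + f' transcript_id "{t.id}";'
                ts, te = t.span
                fh.write("\t".join([gene.chrom, source, "transcript",
                                    str(ts + 1), str(te), ".", gene.strand,
                                    ".", tattrs]) + "\n")
                for xs, xe in t.exons:
                    fh.write("\t".join([gene.chrom, source, "exon",
                                        str(xs + 1), str(xe), ".",
                                        gene.strand, ".", tattrs]) + "\n")


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> Annotation:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feature, start, end, _sc, strand, _fr, attr_col = \
                line.rstrip("\n").split("\t")
            attrs = dict(_ATTR_RE.findall(attr_col))
            gid = attrs["gene_id"]
            g = genes.setdefault(gid, {
                "chrom": chrom, "strand": strand,
                "name": attrs.get("gene_name", gid),
                "biotype": attrs.get("gene_type", "protein_coding"),
                "tx": {},
            })
            if feature == "exon":
                tid = attrs["transcript_id"]
                g["tx"].setdefault(tid, []).append((int(start) - 1, int(end)))
    ann = Annotation()
    for gid, g in genes.items():
        txs = tuple(
            Transcript(tid, gid, tuple(sorted(exons)))
            for tid, exons in sorted(g["tx"].items())
        )
        ann.add(Gene(gid, g["name"], g["chrom"], g["strand"], g["biotype"], txs))
    return ann


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path: str | Path, sites: Sequence[PhasedSite],
              sample: str = "sample") -> None:
    """Phased genotypes, GT written maternal|paternal relative to REF/ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            alt = s.maternal if s.maternal != s.ref else s.paternal
            gm = "0" if s.maternal == s.ref else "1"
            gp = "0" if s.paternal == s.ref else "1"
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{alt}\t.\tPASS\t"
                     f".\tGT\t{gm}|{gp}\n")


def read_phased_vcf(path: str | Path) -> tuple[list[PhasedSite], int]:
    """Phased heterozygous SNPs from a VCF; unphased/hom records are dropped.

    Returns (sites, number of dropped records).
    """
    sites: list[PhasedSite] = []
    dropped = 0
    vcf = pysam.VariantFile(str(path))
    for rec in vcf:
        sample = rec.samples[next(iter(rec.samples))]
        gt = sample.get("GT")
        if (gt is None or None in gt or len(gt) != 2
                or not sample.phased or gt[0] == gt[1]):
            dropped += 1
            continue
        alleles = [rec.ref, *(rec.alts or ())]
        mat, pat = alleles[gt[0]], alleles[gt[1]]
        if len(mat) != 1 or len(pat) != 1 or len(rec.ref) != 1:
            dropped += 1
            continue
        sites.append(PhasedSite(rec.chrom, rec.pos - 1, rec.ref, mat, pat))
    return sites, dropped


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq_pairs(
    prefix: str | Path, pairs: Iterable[ReadPair]
) -> tuple[Path, Path]:
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.name}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.name}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
    return p1, p2


def write_fastq_single(
    path: str | Path, reads: Iterable[tuple[str, str, str]]
) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    def records(path):
        with pysam.FastxFile(str(path)) as fh:
            return [(r.name, r.sequence, r.quality) for r in fh]

    out = []
    for (n1, s1, q1), (n2, s2, q2) in zip(records(path1), records(path2)):
        name = n1.removesuffix("/1")
        if n2.removesuffix("/2") != name:
            raise ValueError(f"mate names do not match: {n1} vs {n2}")
        out.append(ReadPair(name, s1, q1, s2, q2))
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in genome.sequences.items()],
    })


def _cigar_for(mate: MateAlignment, read_len: int) -> list[tuple[int, int]]:
    ops: list[tuple[int, int]] = []
    for (s1, e1), (s2, _e2) in zip(mate.blocks, mate.blocks[1:]):
        ops.append((0, e1 - s1))      # M
        ops.append((3, s2 - e1))      # N
    last = mate.blocks[-1]
    ops.append((0, last[1] - last[0]))
    clip = read_len - mate.aligned_read_bases
    if clip > 0:
        # adapter/pad at the read 3' end: rightmost in reference
        # orientation for a forward read, leftmost for a reverse one
        if mate.reverse:
            ops.insert(0, (4, clip))  # S
        else:
            ops.append((4, clip))
    return ops


def write_true_sam(
    path: str | Path, genome: ReferenceGenome, library: SimulatedLibrary
) -> None:
    """True alignments of a simulated library as a SAM file (N for introns)."""
    header = _sam_header(genome)
    reads = {(p.name, 1): (p.seq1, p.qual1) for p in library.pairs}
    reads.update({(p.name, 2): (p.seq2, p.qual2) for p in library.pairs})
    by_name: dict[str, list[MateAlignment]] = {}
    for m in library.mate_alignments:
        by_name.setdefault(m.name, []).append(m)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in library.mate_alignments:
            seq, qual = reads[(m.name, m.mate)]
            a = pysam.AlignedSegment(header)
            a.query_name = m.name
            a.reference_name = m.chrom
            a.reference_start = m.blocks[0][0]
            a.mapping_quality = 60
            a.cigartuples = _cigar_for(m, len(seq))
            a.flag = (0x1 | 0x2
                      | (0x10 if m.reverse else 0)
                      | (0x40 if m.mate == 1 else 0x80))
            other = next(x for x in by_name[m.name] if x.mate != m.mate)
            a.flag |= 0x20 if other.reverse else 0
            a.next_reference_name = other.chrom
            a.next_reference_start = other.blocks[0][0]
            if m.reverse:
                a.query_sequence = revcomp(seq)
                a.query_qualities = pysam.qualitystring_to_array(qual[::-1])
            else:
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qual)
            out.write(a)


def fragments_from_sam(path: str | Path) -> list[AlignedFragment]:
    """Rebuild per-fragment alignments from a SAM/BAM of aligned pairs.

    Mates sharing a query name are pooled into one fragment: covered
    blocks are unioned (the first mate's base wins where they overlap)
    and splice junctions are taken from N CIGAR operations.
    """
    grouped: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            grouped.setdefault(rec.query_name, []).append(rec)
    fragments = []
    for name, recs in grouped.items():
        recs.sort(key=lambda r: (not r.is_read1, r.reference_start))
        calls: dict[int, str] = {}
        junctions: set[tuple[int, int]] = set()
        chrom = recs[0].reference_name
        for rec in recs:
            seq = rec.query_sequence
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                calls.setdefault(rpos, seq[qpos])
            pos = rec.reference_start
            for op, ln in rec.cigartuples:
                if op == 3:
                    junctions.add((pos, pos + ln))
                if op in (0, 2, 3, 7, 8):
                    pos += ln
        fragments.append(
            fragment_from_positions(name, chrom, calls, junctions)
        )
    return fragments
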