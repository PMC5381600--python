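"""Extraction of 4-fold degenerate and short-intron (SI) sites.

Input is a bundle of per-gene alignments: three reference sequences (focal,
second ingroup, outgroup) plus N population haplotypes, gap-aware and
strand-normalized to the coding strand, together with GFF3 annotation.  Two
site classes are produced:

* 4-fold sites: third codon positions whose codon family is fully
  degenerate (prefixes TC, CT, GT, CC, CG, AC, GC, GG) in all three
  references and every sample haplotype, with at most one segregating site
  in the codon; genes contributing fewer than 10 qualifying sites are
  dropped entirely.
* SI sites: positions 8-30 (1-based, inclusive, counted on the gap-stripped
  focal reference) of introns whose focal-reference length is < 66 bp — the
  standard putatively neutral reference class in Drosophila.

Genes are then stratified into GC-content bins (computed from the focal
reference at qualifying sites only) with approximately equal numbers of
genes per bin, separately for autosomes and the X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FOURFOLD_PREFIXES",
    "ExtractionError",
    "IntronAlignment",
    "GeneAlignment",
    "AlignmentBundle",
    "GcBin",
    "load_bundle",
    "extract_fourfold_sites",
    "extract_si_sites",
    "assign_gc_bins",
]

#: codon prefixes whose third position is fourfold degenerate (standard code)
FOURFOLD_PREFIXES = frozenset(
    {"TC", "CT", "GT", "CC", "CG", "AC", "GC", "GG"})

SITE_COLUMNS = ["gene_id", "chrom", "site_class", "column",
                "ref_focal", "ref_second", "ref_outgroup",
                "A", "C", "G", "T", "N"]


class ExtractionError(ValueError):
    """Structured parse/validation error for alignment bundles."""


@dataclass
class IntronAlignment:
    intron_id: str
    rows: dict  # name -> aligned sequence (coding strand)


@dataclass
class GeneAlignment:
    gene_id: str
    chrom: str
    strand: str
    cds: dict  # name -> aligned in-frame CDS (coding strand)
    introns: list = field(default_factory=list)


@dataclass
class AlignmentBundle:
    """Per-gene CDS and intron alignments for three references plus a
    population sample."""

    genes: dict  # gene_id -> GeneAlignment
    reference_names: tuple  # (focal, second, outgroup)
    sample_names: list

    def row_names(self) -> list:
        return list(self.reference_names) + list(self.sample_names)


@dataclass
class GcBin:
    """A GC-content stratum of genes used as the unit of analysis."""

    bin_id: str
    gene_ids: list
    gc_content: float
    chromosome_set: str  # "autosomal" | "X"


def _read_fasta(path: str | Path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _slice(seq: str, start: int, end: int, strand: str, contig: str) -> str:
    """1-based closed-interval slice, reverse-complemented for minus strand."""
    if start < 1 or end > len(seq):
        raise ExtractionError(
            f"feature {start}-{end} overflows contig {contig!r} "
            f"(length {len(seq)})")
    piece = seq[start - 1:end]
    if strand == "-":
        piece = str(Seq(piece).reverse_complement())
    return piece


def load_bundle(
    genomes: dict,
    annotation: str | Path,
    samples: dict,
    reference_names: tuple = ("mel", "sim", "yak"),
) -> AlignmentBundle:
    """Assemble per-gene alignments from genome FASTAs and a GFF3.

    ``genomes`` maps the three reference names to FASTA paths and
    ``samples`` maps haplotype names to FASTA paths; all sequences are
    assumed to share the focal coordinate system (pre-aligned, as produced
    by the synthetic generator or by a consensus-calling pipeline).  CDS
    parts are spliced in coding order; introns come from explicit ``intron``
    features, or are inferred between consecutive CDS parts.
    """
    missing = [r for r in reference_names if r not in genomes]
    if missing:
        raise ExtractionError(f"missing reference genomes: {missing}")
    seqs = {name: _read_fasta(path) for name, path in genomes.items()}
    sample_seqs = {name: _read_fasta(path) for name, path in samples.items()}
    all_rows = {**seqs, **sample_seqs}

    db = gffutils.create_db(str(annotation), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    genes = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        chrom, strand = gene.seqid, gene.strand
        cds_parts = sorted(db.children(gene, featuretype="CDS"),
                           key=lambda f: f.start)
        if not cds_parts:
            continue
        intron_feats = sorted(db.children(gene, featuretype="intron"),
                              key=lambda f: f.start)
        if not intron_feats:
            intron_feats = []
            for left, right in zip(cds_parts[:-1], cds_parts[1:]):
                if right.start - left.end > 1:
                    intron_feats.append((left.end + 1, right.start - 1))
        else:
            intron_feats = [(f.start, f.end) for f in intron_feats]

        def rows_for(start_end_list):
            rows = {}
            for name, contigs in all_rows.items():
                if chrom not in contigs:
                    raise ExtractionError(
                        f"contig {chrom!r} absent from sequence set {name!r}")
                parts = [_slice(contigs[chrom], s, e, "+", chrom)
                         for s, e in start_end_list]
                joined = "".join(parts)
                if strand == "-":
                    joined = str(Seq(joined).reverse_complement())
                rows[name] = joined
            return rows

        cds_rows = rows_for([(f.start, f.end) for f in cds_parts])
        lengths = {len(v) for v in cds_rows.values()}
        if len(lengths) != 1:
            raise ExtractionError(f"unequal CDS row lengths in gene {gid}")
        if lengths.pop() % 3 != 0:
            raise ExtractionError(f"CDS length not divisible by 3 in gene {gid}")

        introns = []
        for k, (s, e) in enumerate(intron_feats):
            introns.append(IntronAlignment(
                intron_id=f"{gid}.i{k}", rows=rows_for([(s, e)])))
        if strand == "-":
            introns = introns[::-1]
        genes[gid] = GeneAlignment(gene_id=gid, chrom=chrom, strand=strand,
                                   cds=cds_rows, introns=introns)
    return AlignmentBundle(genes=genes, reference_names=tuple(reference_names),
                           sample_names=sorted(sample_seqs))


def _allele_counts(bases: list) -> dict:
    counts = {b: 0 for b in "ACGTN"}
    for b in bases:
        counts[b if b in "ACGT" else "N"] += 1
    return counts


def _is_fourfold_prefix(prefix: str) -> bool:
    return prefix in FOURFOLD_PREFIXES


def extract_fourfold_sites(b: AlignmentBundle, min_sites: int = 10) -> pd.DataFrame:
    """Site table of qualifying 4-fold degenerate third positions.

    A column qualifies if the codon prefix is a 4-fold family in all three
    references and in every sample row (sample prefixes containing N are
    treated as uninformative rather than disqualifying), the codon has at
    most one segregating site among the samples, and at most two distinct
    non-N bases segregate at the focal column.  Genes with fewer than
    ``min_sites`` qualifying columns are dropped.
    """
    focal, second, outgroup = b.reference_names
    records = []
    for gid, gene in b.genes.items():
        ref_rows = [gene.cds[focal], gene.cds[second], gene.cds[outgroup]]
        sample_rows = [gene.cds[s] for s in b.sample_names]
        n_codons = len(ref_rows[0]) // 3
        gene_records = []
        for c in range(n_codons):
            i0, i2 = 3 * c, 3 * c + 2
            prefixes = [row[i0:i0 + 2] for row in ref_rows]
            if not all(_is_fourfold_prefix(p) for p in prefixes):
                continue
            ok = True
            for row in sample_rows:
                p = row[i0:i0 + 2]
                if "N" in p or "-" in p:
                    continue
                if not _is_fourfold_prefix(p):
                    ok = False
                    break
            if not ok:
                continue
            # at most one segregating codon position among the samples
            seg = 0
            for pos in range(3):
                col = {row[i0 + pos] for row in sample_rows} - {"N", "-"}
                if len(col) > 1:
                    seg += 1
            if seg >= 2:
                continue
            counts = _allele_counts([row[i2] for row in sample_rows])
            non_n = sum(1 for base in "ACGT" if counts[base] > 0)
            if non_n > 2 or non_n == 0:
                continue
            gene_records.append({
                "gene_id": gid, "chrom": gene.chrom, "site_class": "4fold",
                "column": i2,
                "ref_focal": ref_rows[0][i2],
                "ref_second": ref_rows[1][i2],
                "ref_outgroup": ref_rows[2][i2],
                **counts,
            })
        if len(gene_records) >= min_sites:
            records.extend(gene_records)
    return pd.DataFrame(records, columns=SITE_COLUMNS)


def extract_si_sites(
    b: AlignmentBundle,
    max_intron_len: int = 66,
    first: int = 8,
    last: int = 30,
) -> pd.DataFrame:
    """Site table of short-intron positions ``first``..``last``.

    Intron length and positions are measured on the gap-stripped focal
    reference; alignment columns where the focal reference has a gap carry
    no focal coordinate and are skipped.  Introns of length >=
    ``max_intron_len`` are excluded (strict inequality, per the < 66 bp
    convention).
    """
    focal = b.reference_names[0]
    records = []
    for gid, gene in b.genes.items():
        for intron in gene.introns:
            focal_row = intron.rows[focal]
            ungapped = focal_row.replace("-", "")
            if len(ungapped) >= max_intron_len:
                continue
            pos = 0
            for col, base in enumerate(focal_row):
                if base == "-":
                    continue
                pos += 1
                if pos < first or pos > last:
                    continue
                sample_bases = [intron.rows[s][col] for s in b.sample_names]
                counts = _allele_counts(sample_bases)
                non_n = sum(1 for x in "ACGT" if counts[x] > 0)
                if non_n > 2 or non_n == 0:
                    continue
                records.append({
                    "gene_id": gid, "chrom": gene.chrom, "site_class": "SI",
                    "column": col,
                    "ref_focal": base,
                    "ref_second": intron.rows[b.reference_names[1]][col],
                    "ref_outgroup": intron.rows[b.reference_names[2]][col],
                    **counts,
                })
    return pd.DataFrame(records, columns=SITE_COLUMNS)


def assign_gc_bins(
    t: pd.DataFrame,
    n_auto: int = 20,
    n_x: int = 4,
    x_chroms: tuple = ("X",),
) -> list:
    """Partition genes into GC-content bins of near-equal gene counts.

    GC content is the fraction of G/C focal-reference bases at a gene's
    qualifying sites.  Genes are ranked by (GC, gene id) — the id breaks
    ties deterministically — and split into ``n_auto`` autosomal and
    ``n_x`` X-linked bins whose sizes differ by at most one.
    """
    if t.empty:
        raise ValueError("empty site table")
    per_gene = (
        t.assign(is_gc=t["ref_focal"].isin(["G", "C"]))
        .groupby(["gene_id", "chrom"])["is_gc"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "gc", "count": "n_sites"})
    )
    bins = []
    for chrom_set, n_bins in (("autosomal", n_auto), ("X", n_x)):
        if chrom_set == "X":
            sub = per_gene[per_gene["chrom"].isin(x_chroms)]
        else:
            sub = per_gene[~per_gene["chrom"].isin(x_chroms)]
        if sub.empty:
            continue
        if len(sub) < n_bins:
            raise ValueError(
                f"{len(sub)} {chrom_set} genes cannot fill {n_bins} bins")
        sub = sub.sort_values(["gc", "gene_id"], kind="mergesort")
        chunks = (sub.iloc[idx] for idx in
                  np.array_split(np.arange(len(sub)), n_bins))
        for k, chunk in enumerate(chunks):
            total = (chunk["gc"] * chunk["n_sites"]).sum()
            bins.append(GcBin(
                bin_id=f"{chrom_set[0].upper()}{k}",
                gene_ids=chunk["gene_id"].tolist(),
                gc_content=float(total / chunk["n_sites"].sum()),
                chromosome_set=chrom_set,
            ))
    return bins
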