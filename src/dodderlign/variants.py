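"""Resistance-specific SNP filtering, promoter windows and W-box scanning.

The resistance filter keeps biallelic SNPs whose genotype calls are
identical in the two resistant cultivars (H9553, H9492) and differ from
the susceptible comparator (H9775) — calls are compared as unordered
allele sets, so "different from H9775" covers both the
H9775-equals-reference and the third-allele case.

Promoter windows span up to 5 kb upstream of the annotated gene 5' end,
strand-aware and clipped at chromosome ends.  The W-box WRKY-binding
cis-element is scanned as the IUPAC pattern TTGACY (Y = C or T) on both
strands; N never matches.  All coordinates are 1-based inclusive
(VCF/GFF3 convention); BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

RESISTANT = ("H9553", "H9492")
SUSCEPTIBLE = "H9775"
WBOX = "TTGACY"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]
MOTIF_COLUMNS = ["chrom", "start", "strand", "hexamer"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _call_alleles(call: str | None) -> frozenset | None:
    """Genotype call string ('A/G', 'C|C', or a bare base) -> allele set."""
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return None
    alleles = [a for a in str(call).replace("|", "/").split("/") if a]
    if not alleles or any(a not in "ACGT" for a in alleles):
        return None
    return frozenset(alleles)


def resistance_specific_snps(
    variants: pd.DataFrame,
    resistant: tuple[str, str] = RESISTANT,
    susceptible: str = SUSCEPTIBLE,
) -> tuple[pd.DataFrame, int]:
    """Keep SNPs shared by both resistant cultivars and differing from the
    susceptible one.

    Expects columns chrom, pos, ref, alt plus one call column per
    genotype.  Non-biallelic-SNP rows and rows with missing calls are
    skipped; the skip count is returned alongside the filtered frame.
    """
    for col in VARIANT_COLUMNS + [*resistant, susceptible]:
        if col not in variants.columns:
            raise ValueError(f"variant table lacks column {col!r}")
    keep, skipped = [], 0
    for idx, row in variants.iterrows():
        if (
            row["ref"] not in IUPAC
            or len(str(row["ref"])) != 1
            or len(str(row["alt"])) != 1
            or str(row["ref"]) not in "ACGT"
            or str(row["alt"]) not in "ACGT"
        ):
            skipped += 1
            continue
        calls = [_call_alleles(row[g]) for g in (*resistant, susceptible)]
        if any(c is None for c in calls):
            skipped += 1
            continue
        r1, r2, s = calls
        if r1 == r2 and r1 != s:
            keep.append(idx)
    return variants.loc[keep], skipped


def promoter_windows(
    genes: pd.DataFrame,
    window: int = 5000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware upstream windows, 1-based inclusive, clipped at ends.

    + strand gene starting at S -> [max(1, S-window), S-1];
    - strand gene ending at E -> [E+1, min(E+window, chrom length)].
    Genes whose window is empty (TSS at a chromosome edge) are dropped.
    """
    rows = []
    for _, g in genes.iterrows():
        strand = g["strand"]
        if strand == "+":
            start, end = max(1, int(g["start"]) - window), int(g["start"]) - 1
        elif strand == "-":
            start = int(g["end"]) + 1
            end = int(g["end"]) + window
            if chrom_lengths and g["chrom"] in chrom_lengths:
                end = min(end, chrom_lengths[g["chrom"]])
        else:
            raise ValueError(f"unknown strand {strand!r} for gene {g['gene_id']}")
        if end >= start:
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "chrom": g["chrom"],
                    "start": start,
                    "end": end,
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        base in IUPAC[p] for base, p in zip(window, pattern)
    )


def scan_motif(
    seq: str,
    pattern: str = WBOX,
    both_strands: bool = True,
    chrom: str = "chr1",
    offset: int = 0,
) -> pd.DataFrame:
    """All IUPAC-pattern matches; reverse-strand hits in forward coordinates.

    ``start`` is the 1-based leftmost base of the match on the forward
    strand (plus ``offset``); ``hexamer`` is the matching sequence read
    on the reported strand.
    """
    pattern = pattern.upper()
    bad = [p for p in pattern if p not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad} in pattern {pattern!r}")
    seq = seq.upper()
    k = len(pattern)
    rc_pattern = reverse_complement(pattern)
    rows = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if _matches(window, pattern):
            rows.append(
                {"chrom": chrom, "start": offset + i + 1, "strand": "+", "hexamer": window}
            )
        if both_strands and _matches(window, rc_pattern):
            rows.append(
                {
                    "chrom": chrom,
                    "start": offset + i + 1,
                    "strand": "-",
                    "hexamer": reverse_complement(window),
                }
            )
    return pd.DataFrame(rows, columns=MOTIF_COLUMNS)


def scan_promoters(
    sequences: dict[str, str],
    promoters: pd.DataFrame,
    pattern: str = WBOX,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Motif scan restricted to promoter windows; coordinates stay genomic."""
    frames = []
    for _, p in promoters.iterrows():
        seq = sequences[p["chrom"]][p["start"] - 1 : p["end"]]
        hits = scan_motif(
            seq, pattern, both_strands, chrom=p["chrom"], offset=p["start"] - 1
        )
        if len(hits):
            hits = hits.assign(gene_id=p["gene_id"])
            frames.append(hits)
    if not frames:
        return pd.DataFrame(columns=MOTIF_COLUMNS + ["gene_id"])
    return pd.concat(frames, ignore_index=True)


def snp_motif_overlap(
    snps: pd.DataFrame,
    hits: pd.DataFrame,
    promoters: pd.DataFrame,
    pattern: str = WBOX,
) -> pd.DataFrame:
    """Resistance-specific SNPs inside promoter windows that fall within a
    motif hit's span, annotated with whether the alt allele breaks the match."""
    k = len(pattern)
    rc_pattern = reverse_complement(pattern)
    rows = []
    for _, snp in snps.iterrows():
        in_prom = promoters[
            (promoters["chrom"] == snp["chrom"])
            & (promoters["start"] <= snp["pos"])
            & (snp["pos"] <= promoters["end"])
        ]
        if in_prom.empty:
            continue
        span = hits[
            (hits["chrom"] == snp["chrom"])
            & (hits["start"] <= snp["pos"])
            & (snp["pos"] <= hits["start"] + k - 1)
        ]
        for _, hit in span.iterrows():
            fwd = (
                hit["hexamer"]
                if hit["strand"] == "+"
                else reverse_complement(hit["hexamer"])
            )
            i = int(snp["pos"] - hit["start"])
            mutated = fwd[:i] + str(snp["alt"]) + fwd[i + 1 :]
            still = _matches(mutated, pattern) or _matches(mutated, rc_pattern)
            rows.append(
                {
                    "chrom": snp["chrom"],
                    "pos": int(snp["pos"]),
                    "ref": snp["ref"],
                    "alt": snp["alt"],
                    "gene_id": ",".join(in_prom["gene_id"]),
                    "motif_start": int(hit["start"]),
                    "motif_strand": hit["strand"],
                    "hexamer": hit["hexamer"],
                    "breaks_motif": not still,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id",
            "motif_start", "motif_strand", "hexamer", "breaks_motif",
        ],
    )


# ---------------------------------------------------------------------------
# file I/O


def read_vcf(path: str, genotypes: list[str] | None = None) -> pd.DataFrame:
    """Read a (possibly multi-sample) VCF into the variant-table frame."""
    rows = []
    with pysam.VariantFile(path) as vf:
        names = genotypes or list(vf.header.samples)
        for rec in vf:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
            for g in names:
                alleles = rec.samples[g].alleles
                row[g] = (
                    "/".join(a for a in alleles if a is not None) if alleles else None
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS + list(names))


def write_vcf(
    variants: pd.DataFrame,
    path: str,
    genotypes: list[str],
    chrom_lengths: dict[str, int],
) -> None:
    """Write the variant-table frame as an uncompressed multi-sample VCF."""
    header = pysam.VariantHeader()
    header.add_meta("source", "dodderlign")
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for g in genotypes:
        header.add_sample(g)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for _, row in variants.iterrows():
            rec = vf.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            alleles = (str(row["ref"]), str(row["alt"]))
            for g in genotypes:
                call = _call_alleles(row[g])
                if call is None:
                    rec.samples[g]["GT"] = (None, None)
                else:
                    gt = sorted(alleles.index(a) for a in str(row[g]).split("/"))
                    if len(gt) == 1:
                        gt = gt * 2
                    rec.samples[g]["GT"] = tuple(gt)
            vf.write(rec)


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene records from a GFF3 file -> frame with gene_id/chrom/start/end/strand."""
    names = [
        "chrom", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    df = df[df["type"] == "gene"].copy()
    df["gene_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    return df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)


def write_gff3_genes(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tdodderlign\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Promoter intervals as BED (0-based half-open on export)."""
    out = intervals.assign(bed_start=intervals["start"] - 1)[
        ["chrom", "bed_start", "end", "gene_id", "strand"]
    ]
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)
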