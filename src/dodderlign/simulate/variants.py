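"""Synthetic variant tables, reference sequence and gene annotations.

Emulates the four-cultivar DNA-seq comparison: three genotypes (two
resistant, one susceptible) called against a shared reference, with a
planted subset of sites satisfying the resistance-specific rule by
construction — the two resistant cultivars share a call that differs
from the susceptible one.  Every non-planted site is constructed to
violate the rule (resistant cultivars disagree, or all three agree).

W-box hexamers (TTGACY, either strand) are planted at requested
positions in the reference, and a chosen number of resistance-specific
SNPs are placed inside planted W-boxes that fall within promoter
windows, giving a known SNP-in-motif overlap count.  Remaining
resistance-specific sites are kept out of promoter windows so the
planted overlap count is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..variants import (
    RESISTANT,
    SUSCEPTIBLE,
    WBOX,
    promoter_windows,
    reverse_complement,
    write_gff3_genes,
    write_vcf,
)

_Y = "CT"


@dataclass
class VariantSimSpec:
    """Parameters for one simulated variant data set."""

    genotypes: tuple[str, str, str] = (*RESISTANT, SUSCEPTIBLE)
    reference_name: str = "H1706"
    n_sites: int = 1000
    resistance_specific_fraction: float = 0.1
    chrom: str = "SL_chr1"
    chrom_length: int = 100_000
    promoter_genes: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("LIF1", "+", 60_000)]
    )  # (gene id, strand, TSS position)
    gene_length: int = 3000
    promoter_window: int = 5000
    planted_wbox_positions: list[int] = field(default_factory=lambda: [57_000])
    planted_wbox_snps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype names must be unique")
        if not 0.0 <= self.resistance_specific_fraction <= 1.0:
            raise ValueError("resistance_specific_fraction must lie in [0, 1]")
        for pos in self.planted_wbox_positions:
            if not 1 <= pos <= self.chrom_length - len(WBOX) + 1:
                raise ValueError(f"planted W-box at {pos} outside chromosome")
        for name, strand, tss in self.promoter_genes:
            if not 1 <= tss <= self.chrom_length:
                raise ValueError(f"TSS of {name} outside chromosome")
            if strand not in "+-":
                raise ValueError(f"unknown strand {strand!r} for {name}")
        if self.planted_wbox_snps > len(self.planted_wbox_positions):
            raise ValueError("more W-box SNPs requested than planted W-boxes")


@dataclass
class VariantSimResult:
    variants: pd.DataFrame  # chrom,pos,ref,alt + genotype call columns
    reference: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    truth: dict


def _gene_table(spec: VariantSimSpec) -> pd.DataFrame:
    rows = []
    for name, strand, tss in spec.promoter_genes:
        if strand == "+":
            start, end = tss, min(tss + spec.gene_length - 1, spec.chrom_length)
        else:
            start, end = max(1, tss - spec.gene_length + 1), tss
        rows.append(
            {"gene_id": name, "chrom": spec.chrom, "start": start, "end": end,
             "strand": strand}
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def simulate_variants(spec: VariantSimSpec) -> VariantSimResult:
    """Draw one variant data set; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=spec.chrom_length)

    # plant W-box hexamers (random strand and Y base per site)
    for pos in spec.planted_wbox_positions:
        hexamer = WBOX[:-1] + rng.choice(list(_Y))
        if rng.random() < 0.5:
            hexamer = reverse_complement(hexamer)
        seq[pos - 1 : pos - 1 + len(hexamer)] = list(hexamer)

    genes = _gene_table(spec)
    promoters = promoter_windows(
        genes, spec.promoter_window, {spec.chrom: spec.chrom_length}
    )
    in_promoter = np.zeros(spec.chrom_length, dtype=bool)
    for _, p in promoters.iterrows():
        in_promoter[p["start"] - 1 : p["end"]] = True

    n_res = int(round(spec.n_sites * spec.resistance_specific_fraction))
    n_res_in_wbox = min(spec.planted_wbox_snps, n_res)

    taken: set[int] = set()

    def sample_positions(n: int, admissible: np.ndarray) -> list[int]:
        pool = np.flatnonzero(admissible) + 1
        pool = np.array([p for p in pool if p not in taken])
        if len(pool) < n:
            raise ValueError("chromosome too short for requested site count")
        chosen = rng.choice(pool, size=n, replace=False)
        taken.update(int(c) for c in chosen)
        return sorted(int(c) for c in chosen)

    # resistance SNPs planted inside promoter W-boxes (one per planted box)
    wbox_snp_pos: list[int] = []
    boxes_in_promoters = [
        p
        for p in spec.planted_wbox_positions
        if in_promoter[p - 1 : p - 1 + len(WBOX)].any()
    ]
    if n_res_in_wbox > len(boxes_in_promoters):
        raise ValueError(
            "not enough planted W-boxes inside promoter windows for the "
            "requested in-motif SNP count"
        )
    for box in boxes_in_promoters[:n_res_in_wbox]:
        offsets = [
            o for o in range(len(WBOX)) if in_promoter[box - 1 + o] and (box + o) not in taken
        ]
        pos = box + offsets[int(rng.integers(len(offsets)))]
        wbox_snp_pos.append(pos)
        taken.add(pos)

    # remaining resistance SNPs: outside promoter windows
    res_pos = wbox_snp_pos + sample_positions(n_res - len(wbox_snp_pos), ~in_promoter)
    # non-qualifying sites: anywhere not yet taken
    other_pos = sample_positions(
        spec.n_sites - n_res, np.ones(spec.chrom_length, dtype=bool)
    )

    r1, r2 = spec.genotypes[0], spec.genotypes[1]
    sus = spec.genotypes[2]
    rows = []
    for pos in sorted(res_pos):
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        # qualifying: both resistant share the alt call, susceptible differs
        sus_call = f"{ref}/{ref}" if rng.random() < 0.8 else f"{ref}/{alt}"
        res_call = f"{alt}/{alt}"
        if sus_call == res_call:  # pragma: no cover - cannot happen (ref!=alt)
            sus_call = f"{ref}/{ref}"
        rows.append(
            {"chrom": spec.chrom, "pos": pos, "ref": ref, "alt": alt,
             r1: res_call, r2: res_call, sus: sus_call, "resistance_specific": True}
        )
    for pos in sorted(other_pos):
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        if rng.random() < 0.5:
            # resistant cultivars disagree with each other
            calls = {r1: f"{alt}/{alt}", r2: f"{ref}/{ref}", sus: f"{ref}/{alt}"}
        else:
            # all three agree
            shared = f"{alt}/{alt}" if rng.random() < 0.5 else f"{ref}/{alt}"
            calls = {r1: shared, r2: shared, sus: shared}
        rows.append(
            {"chrom": spec.chrom, "pos": pos, "ref": ref, "alt": alt,
             **calls, "resistance_specific": False}
        )
    variants = (
        pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", r1, r2, sus, "resistance_specific"],
        )
        .sort_values("pos")
        .reset_index(drop=True)
    )

    truth = {
        "resistance_positions": sorted(res_pos),
        "wbox_snp_positions": sorted(wbox_snp_pos),
        "planted_wbox_positions": list(spec.planted_wbox_positions),
        "n_resistance_specific": n_res,
    }
    return VariantSimResult(
        variants=variants,
        reference={spec.chrom: "".join(seq)},
        genes=genes,
        truth=truth,
    )


def write_variant_files(
    result: VariantSimResult, vcf_path: str, fasta_path: str, gff_path: str
) -> None:
    """Write VCF + FASTA + GFF3 for one simulated data set."""
    spec_cols = [c for c in result.variants.columns if c != "resistance_specific"]
    genotypes = spec_cols[4:]
    chrom_lengths = {c: len(s) for c, s in result.reference.items()}
    write_vcf(result.variants[spec_cols], vcf_path, genotypes, chrom_lengths)
    with open(fasta_path, "w") as fh:
        for chrom, s in result.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    write_gff3_genes(result.genes, gff_path)
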