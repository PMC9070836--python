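"""Resistance-SNP set logic, promoter windows, W-box scanning, overlap."""

import numpy as np
import pandas as pd
import pytest

from dodderlign.simulate.variants import (
    VariantSimSpec,
    simulate_variants,
    write_variant_files,
)
from dodderlign.variants import (
    IUPAC,
    promoter_windows,
    read_fasta,
    read_gff3_genes,
    read_vcf,
    resistance_specific_snps,
    reverse_complement,
    scan_motif,
    scan_promoters,
    snp_motif_overlap,
    write_bed,
)


def variant_row(r1, r2, sus, ref="A", alt="G", pos=100):
    return {
        "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
        "H9553": r1, "H9492": r2, "H9775": sus,
    }


class TestResistanceFilter:
    def test_shared_resistant_alt_kept(self):
        table = pd.DataFrame([variant_row("A/G", "A/G", "A/A")])
        kept, skipped = resistance_specific_snps(table)
        assert len(kept) == 1 and skipped == 0

    def test_all_three_sharing_alt_dropped(self):
        table = pd.DataFrame([variant_row("G/G", "G/G", "G/G")])
        kept, _ = resistance_specific_snps(table)
        assert len(kept) == 0

    def test_resistant_disagreement_dropped(self):
        table = pd.DataFrame([variant_row("G/G", "A/A", "A/A")])
        kept, _ = resistance_specific_snps(table)
        assert len(kept) == 0

    def test_het_calls_compared_as_unordered_sets(self):
        table = pd.DataFrame([variant_row("A/G", "G/A", "A/A")])
        kept, _ = resistance_specific_snps(table)
        assert len(kept) == 1

    def test_missing_call_skipped_and_counted(self):
        table = pd.DataFrame(
            [variant_row(None, "G/G", "A/A"), variant_row("G/G", "G/G", "A/A")]
        )
        kept, skipped = resistance_specific_snps(table)
        assert len(kept) == 1 and skipped == 1

    def test_simulated_table_matches_exhaustive_scan(self):
        sim = simulate_variants(VariantSimSpec(n_sites=1000, seed=3))
        kept, _ = resistance_specific_snps(sim.variants)
        assert len(kept) == 100  # round(1000 * 0.1) by construction
        # exhaustive truth-table scan, written independently
        expected = []
        for _, row in sim.variants.iterrows():
            c1 = frozenset(row["H9553"].split("/"))
            c2 = frozenset(row["H9492"].split("/"))
            cs = frozenset(row["H9775"].split("/"))
            if c1 == c2 and c1 != cs:
                expected.append(row["pos"])
        assert sorted(kept["pos"]) == sorted(expected)
        assert sorted(kept["pos"]) == sim.truth["resistance_positions"]

    def test_zero_fraction_yields_empty_set(self):
        sim = simulate_variants(
            VariantSimSpec(
                n_sites=100, resistance_specific_fraction=0.0,
                planted_wbox_snps=0, seed=4,
            )
        )
        kept, _ = resistance_specific_snps(sim.variants)
        assert kept.empty

    def test_filter_is_idempotent(self):
        sim = simulate_variants(VariantSimSpec(n_sites=200, seed=5))
        once, _ = resistance_specific_snps(sim.variants)
        twice, skipped = resistance_specific_snps(once)
        assert skipped == 0
        pd.testing.assert_frame_equal(once, twice)


class TestPromoterWindows:
    def gene(self, strand, start, end):
        return pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "start": start, "end": end,
              "strand": strand}]
        )

    def test_plus_strand_window(self):
        w = promoter_windows(self.gene("+", 10_000, 12_000))
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (5000, 9999)
        assert w.iloc[0]["end"] - w.iloc[0]["start"] + 1 == 5000

    def test_plus_strand_clipped_at_origin(self):
        w = promoter_windows(self.gene("+", 3, 500))
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (1, 2)

    def test_minus_strand_clipped_at_chromosome_end(self):
        w = promoter_windows(
            self.gene("-", 8_000, 10_000), chrom_lengths={"c": 12_000}
        )
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (10_001, 12_000)

    def test_window_never_overlaps_gene_body(self):
        for strand, start, end in (("+", 7_000, 9_000), ("-", 2_000, 4_000)):
            w = promoter_windows(self.gene(strand, start, end))
            assert w.iloc[0]["end"] < start or w.iloc[0]["start"] > end

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            promoter_windows(self.gene(".", 10, 20))


def brute_force_scan(seq, pattern="TTGACY"):
    """Sliding-window IUPAC match on both strands, written independently."""
    hits = []
    rc = reverse_complement(pattern)
    for i in range(len(seq) - len(pattern) + 1):
        window = seq[i : i + len(pattern)]
        if all(b in IUPAC[p] for b, p in zip(window, pattern)):
            hits.append((i + 1, "+"))
        if all(b in IUPAC[p] for b, p in zip(window, rc)):
            hits.append((i + 1, "-"))
    return sorted(hits)


class TestMotifScan:
    @pytest.mark.parametrize(
        "seq,n_fwd", [("TTGACC", 1), ("TTGACT", 1), ("TTGACA", 0)]
    )
    def test_wbox_y_degeneracy(self, seq, n_fwd):
        hits = scan_motif(seq, both_strands=False)
        assert len(hits) == n_fwd

    def test_reverse_strand_hit_reported_forward(self):
        hits = scan_motif("AAGGTCAAAA")
        assert len(hits) == 1
        hit = hits.iloc[0]
        assert (hit["start"], hit["strand"], hit["hexamer"]) == (3, "-", "TTGACC")

    def test_n_never_matches(self):
        assert scan_motif("TTGACNTTNACC").empty

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            hits = scan_motif(seq)
            got = sorted(zip(hits["start"], hits["strand"]))
            assert got == brute_force_scan(seq)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = scan_motif(seq)
        rev = scan_motif(reverse_complement(seq))
        k = 6
        mirrored = sorted(
            (len(seq) - (s + k - 1) + 1, {"+": "-", "-": "+"}[st])
            for s, st in zip(fwd["start"], fwd["strand"])
        )
        assert mirrored == sorted(zip(rev["start"], rev["strand"]))

    def test_invalid_iupac_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGT", pattern="TTGAXY")


class TestOverlap:
    def fixtures(self):
        snps = pd.DataFrame([variant_row("G/G", "G/G", "A/A", pos=5)])
        promoters = pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "start": 1, "end": 100,
              "strand": "+"}]
        )
        return snps, promoters

    def test_snp_inside_hit_span_reported(self):
        snps, promoters = self.fixtures()
        hits = pd.DataFrame(
            [{"chrom": "chr1", "start": 3, "strand": "+", "hexamer": "TTGACC"}]
        )
        report = snp_motif_overlap(snps, hits, promoters)
        assert len(report) == 1

    def test_snp_past_hit_end_not_reported(self):
        snps, promoters = self.fixtures()
        hits = pd.DataFrame(
            [{"chrom": "chr1", "start": 3, "strand": "+", "hexamer": "TTGACC"}]
        )
        snps["pos"] = 9  # hit spans 3..8
        assert snp_motif_overlap(snps, hits, promoters).empty

    def test_breaking_and_silent_substitutions_annotated(self):
        snps, promoters = self.fixtures()
        hits = pd.DataFrame(
            [{"chrom": "chr1", "start": 5, "strand": "+", "hexamer": "TTGACC"}]
        )
        # SNP at pos 5 = first T of the hexamer; T>G destroys the W-box
        snps.loc[0, ["ref", "alt"]] = ["T", "G"]
        assert bool(snp_motif_overlap(snps, hits, promoters)["breaks_motif"].iloc[0])
        # C>T at the degenerate Y position keeps it
        snps.loc[0, "pos"] = 10
        snps.loc[0, ["ref", "alt"]] = ["C", "T"]
        report = snp_motif_overlap(snps, hits, promoters)
        assert not bool(report["breaks_motif"].iloc[0])

    def test_planted_fixture_count_recovered(self):
        sim = simulate_variants(VariantSimSpec(seed=8))
        kept, _ = resistance_specific_snps(sim.variants)
        promoters = promoter_windows(
            sim.genes, 5000, {c: len(s) for c, s in sim.reference.items()}
        )
        hits = scan_promoters(sim.reference, promoters)
        report = snp_motif_overlap(kept, hits, promoters)
        assert len(report) == len(sim.truth["wbox_snp_positions"]) == 1
        assert report["pos"].iloc[0] in sim.truth["wbox_snp_positions"]


class TestFileRoundTrips:
    def test_vcf_fasta_gff_round_trip(self, tmp_path):
        sim = simulate_variants(VariantSimSpec(n_sites=50, seed=9))
        vcf, fa, gff = (
            str(tmp_path / "v.vcf"), str(tmp_path / "r.fa"), str(tmp_path / "g.gff3")
        )
        write_variant_files(sim, vcf, fa, gff)
        table = read_vcf(vcf)
        assert len(table) == 50
        kept_disk, _ = resistance_specific_snps(table)
        kept_mem, _ = resistance_specific_snps(sim.variants)
        assert sorted(kept_disk["pos"]) == sorted(kept_mem["pos"])
        ref = read_fasta(fa)
        assert ref == sim.reference
        genes = read_gff3_genes(gff)
        pd.testing.assert_frame_equal(genes, sim.genes)

    def test_bed_export_is_half_open(self, tmp_path):
        promoters = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "start": 5000, "end": 9999,
              "strand": "+"}]
        )
        path = tmp_path / "p.bed"
        write_bed(promoters, str(path))
        fields = path.read_text().split()
        assert (fields[1], fields[2]) == ("4999", "9999")


class TestSimSpecValidation:
    def test_wbox_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="W-box"):
            VariantSimSpec(planted_wbox_positions=[200_000])

    def test_duplicate_genotypes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            VariantSimSpec(genotypes=("a", "a", "b"))

    def test_fixed_seed_reproduces_tables(self):
        a = simulate_variants(VariantSimSpec(n_sites=100, seed=10))
        b = simulate_variants(VariantSimSpec(n_sites=100, seed=10))
        pd.testing.assert_frame_equal(a.variants, b.variants)
        assert a.reference == b.reference
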