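from math import comb

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from hvrkit import annotation as ann
from hvrkit.ssv import SSVSet

BASES = "ACGT"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def gene(gene_id="G1", chrom="chr1", strand="+", start=100, cds_seq="ATGTAA",
         tss=None):
    end = start + len(cds_seq)
    if tss is None:
        tss = start if strand == "+" else end - 1
    return ann.GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, start=start, end=end,
        transcripts=[ann.Transcript(
            transcript_id=f"{gene_id}.t1", exons=[(start, end)],
            cds=[(start, end)], cds_seq=cds_seq)])


class TestExpressedGenes:
    def test_strict_inequality_at_threshold(self):
        table = pd.DataFrame({"gene_id": ["a", "b", "c"], "fpkm": [1.0, 1.01, 0.2]})
        assert ann.expressed_genes(table) == {"b"}

    def test_empty_table(self):
        assert ann.expressed_genes(pd.DataFrame()) == set()


class TestPromoterAssignment:
    def _promoter(self, start=10_000, end=11_000, pid="P1", chrom="chr1"):
        return pd.DataFrame([{"chrom": chrom, "start": start, "end": end,
                              "promoter_id": pid}])

    def _gene(self, tss, strand="+", gid="G1", chrom="chr1"):
        return pd.DataFrame([{"gene_id": gid, "chrom": chrom, "strand": strand,
                              "tss": tss}])

    def test_plus_strand_boundary_enumeration(self):
        # oracle: overlap for tss in [10000, 11000); downstream for [11000, 16000)
        for tss, expected in [(9_999, False), (10_000, True), (10_999, True),
                              (11_000, True), (11_000 + 4_999, True),
                              (11_000 + 5_000, False)]:
            out = ann.assign_promoters(self._promoter(), self._gene(tss, "+"))
            assert (len(out) == 1) == expected, tss

    def test_minus_strand_boundary_enumeration(self):
        # mirrored: overlap in [10000, 11000); downstream (5' shift) in [5000, 10000)
        for tss, expected in [(10_000 - 5_001, False), (10_000 - 5_000, True),
                              (9_999, True), (10_000, True), (10_999, True),
                              (11_000, False)]:
            out = ann.assign_promoters(self._promoter(), self._gene(tss, "-"))
            assert (len(out) == 1) == expected, tss

    def test_one_promoter_two_genes_dropped(self):
        genes = pd.DataFrame([
            {"gene_id": "G1", "chrom": "chr1", "strand": "+", "tss": 11_100},
            {"gene_id": "G2", "chrom": "chr1", "strand": "+", "tss": 11_200}])
        assert len(ann.assign_promoters(self._promoter(), genes)) == 0

    def test_two_promoters_one_gene_dropped(self):
        proms = pd.concat([self._promoter(), self._promoter(12_000, 13_000, "P2")],
                          ignore_index=True)
        out = ann.assign_promoters(proms, self._gene(13_500, "+"))
        assert len(out) == 0

    def test_distance_class_labels(self):
        assert ann.assign_promoters(
            self._promoter(), self._gene(10_500))["distance_class"].iloc[0] == "overlap"
        assert ann.assign_promoters(
            self._promoter(), self._gene(12_000))["distance_class"].iloc[0] == "downstream"

    def test_zero_length_promoter_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            ann.assign_promoters(self._promoter(10_000, 10_000), self._gene(10_000))

    def test_unstranded_option_accepts_both_sides(self):
        out = ann.assign_promoters(self._promoter(), self._gene(9_000, "+"),
                                   stranded=False)
        assert len(out) == 1

    def test_strand_symmetry_under_reflection(self, rng):
        R = 1_000_000
        proms = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.choice(900_000, size=15, replace=False),
        })
        proms["end"] = proms["start"] + 1_000
        proms["promoter_id"] = [f"P{i}" for i in range(15)]
        genes = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(20)],
            "chrom": "chr1",
            "strand": rng.choice(["+", "-"], size=20),
            "tss": rng.choice(990_000, size=20, replace=False),
        })
        forward = ann.assign_promoters(proms, genes)

        proms_r = proms.assign(start=R - proms["end"], end=R - proms["start"])
        genes_r = genes.assign(
            tss=R - 1 - genes["tss"],
            strand=genes["strand"].map({"+": "-", "-": "+"}))
        mirrored = ann.assign_promoters(proms_r, genes_r)
        key = lambda df: sorted(zip(df["promoter_id"], df["gene_id"]))
        assert key(forward) == key(mirrored)


def consequence_oracle(codon, pos, alt):
    """Independent single-codon classifier via Bio.Seq translation."""
    alt_codon = codon[:pos] + alt + codon[pos + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous_variant"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    return "missense_variant"


class TestConsequences:
    def test_all_576_codon_substitutions_match_oracle(self):
        for codon in CODONS:
            g = gene(cds_seq=codon, start=100)
            for pos in range(3):
                for alt in BASES:
                    if alt == codon[pos]:
                        continue
                    call = ann.classify_consequence("chr1", 100 + pos, alt, [g],
                                                    ref=codon[pos])
                    assert call["term"] == consequence_oracle(codon, pos, alt), \
                        (codon, pos, alt)

    def test_tac_to_taa_is_stop_gained(self):
        g = gene(cds_seq="TAC")
        assert ann.classify_consequence("chr1", 102, "A", [g])["term"] == "stop_gained"

    def test_ctt_to_ctc_is_synonymous(self):
        g = gene(cds_seq="CTT")
        assert ann.classify_consequence("chr1", 102, "C", [g])["term"] == \
            "synonymous_variant"

    def test_intronic_variant_is_non_coding(self):
        g = ann.GeneModel(
            gene_id="G1", chrom="chr1", strand="+", tss=100, start=100, end=220,
            transcripts=[ann.Transcript(
                transcript_id="t1", exons=[(100, 103), (200, 203)],
                cds=[(100, 103), (200, 203)], cds_seq="ATGTAA")])
        assert ann.classify_consequence("chr1", 150, "G", [g])["term"] == "non_coding"

    def test_minus_strand_substitution(self):
        # genomic TAC at [100,103) on '-' strand reads GTA (Val);
        # genomic C>T at pos 102 flips sense G>A -> ATA (Ile): missense
        g = gene(cds_seq="GTA", strand="-")
        call = ann.classify_consequence("chr1", 102, "T", [g], ref="C")
        assert call["term"] == "missense_variant"

    def test_most_severe_across_transcripts(self):
        shared = dict(gene_id="G1", chrom="chr1", strand="+", tss=100,
                      start=100, end=103)
        g = ann.GeneModel(**shared, transcripts=[
            ann.Transcript("t1", [(100, 103)], [(100, 103)], "CTT"),  # L -> L syn
            ann.Transcript("t2", [(101, 104)], [(101, 104)], "TTC"),  # offset frame
        ])
        call = ann.classify_consequence("chr1", 102, "C", [g])
        terms = {c["transcript_id"]: c["term"] for c in call["calls"]}
        assert terms["t1"] == "synonymous_variant"
        assert ann.SEVERITY[call["term"]] == max(ann.SEVERITY[t] for t in terms.values())

    def test_reference_mismatch_raises(self):
        g = gene(cds_seq="ATG")
        with pytest.raises(ValueError, match="disagrees"):
            ann.classify_consequence("chr1", 100, "C", [g], ref="G")

    def test_cds_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            ann.Transcript("t1", [(0, 4)], [(0, 4)], "ATGT")


class TestCandidateGenes:
    def _scenario(self):
        # gene A inside the HVR with a missense SSV; gene B outside; gene C's
        # promoter holds SSVs inside the HVR
        cds = "ATG" + "AAA" * 198 + "TAA"
        a = gene("GA", start=100_000, cds_seq=cds)
        b = gene("GB", start=500_000, cds_seq=cds)
        c = gene("GC", start=130_000, cds_seq=cds)
        hvrs = pd.DataFrame([("chr1", 90_000, 140_000, "HVR", 5, 0)],
                            columns=["chrom", "start", "end", "region_type",
                                     "n_windows", "n_ssvs"])
        # AAA -> GAA (missense) at the first base of codon 2
        ssv_rows = [
            ("chr1", 100_003, "G", "hom"),   # NSC in gene A, inside HVR
            ("chr1", 500_003, "G", "hom"),   # NSC in gene B, outside HVR
            ("chr1", 128_600, "T", "hom"),   # in gene C's promoter, inside HVR
            ("chr1", 128_700, "T", "hom"),
        ]
        ssvs = SSVSet("t", pd.DataFrame(
            ssv_rows, columns=["chrom", "pos", "novel", "zygosity"]))
        promoters = pd.DataFrame([
            {"chrom": "chr1", "start": 128_500, "end": 129_500, "promoter_id": "P1"}])
        assignments = ann.assign_promoters(
            promoters, pd.DataFrame([{"gene_id": "GC", "chrom": "chr1",
                                      "strand": "+", "tss": 130_000}]))
        return hvrs, ssvs, [a, b, c], assignments, promoters

    def test_selection(self):
        hvrs, ssvs, genes, assignments, promoters = self._scenario()
        out = ann.select_candidate_genes(
            hvrs, ssvs, genes, assignments, promoters,
            expressed={"GA", "GB", "GC"})
        assert out["coding"]["gene_id"].tolist() == ["GA"]
        assert out["coding"]["n_nsc_ssvs"].tolist() == [1]
        assert out["promoter"].iloc[0].tolist() == ["GC", "P1", 2]

    def test_unexpressed_genes_excluded(self):
        hvrs, ssvs, genes, assignments, promoters = self._scenario()
        out = ann.select_candidate_genes(
            hvrs, ssvs, genes, assignments, promoters, expressed={"GB"})
        assert len(out["coding"]) == 0 and len(out["promoter"]) == 0


class TestOrthology:
    def _table(self):
        return pd.DataFrame([
            ("r1", "h1", "one2one"),
            ("r2", "h2", "apparently_one2one"),
            ("r3", "h3", "other"),
            ("r4", "h4", "one2one"),
            ("r4", "h5", "one2one"),      # many-to-many rat
            ("r5", "h6", "one2one"),
            ("r6", "h6", "one2one"),      # many-to-many human
        ], columns=["rat_id", "human_id", "class"])

    def test_classes_and_multimaps(self):
        mapping = ann.orthologue_filter(["r1", "r2", "r3", "r4", "r5", "r6", "r9"],
                                        self._table())
        assert mapping == {"r1": "h1", "r2": "h2"}


def fisher_oracle_two_sided(a, b, c, d):
    """Exact hypergeometric enumeration of the two-sided p-value."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_small_table_matches_hypergeometric_enumeration(self):
        odds, p_two, _ = ann.fisher_2x2(2, 3, 4, 6)
        assert p_two == pytest.approx(fisher_oracle_two_sided(2, 3, 4, 6))

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 15, size=4)
            _, p_two, _ = ann.fisher_2x2(int(a), int(b), int(c), int(d))
            assert p_two == pytest.approx(
                fisher_oracle_two_sided(int(a), int(b), int(c), int(d)))
            assert 0 <= p_two <= 1

    def test_proportional_table_is_null(self):
        odds, p_two, _ = ann.fisher_2x2(10, 20, 30, 60)
        assert odds == 1.0 and p_two == 1.0

    def test_transpose_invariance(self, rng):
        for _ in range(10):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            assert ann.fisher_2x2(a, b, c, d)[1] == \
                pytest.approx(ann.fisher_2x2(a, c, b, d)[1])

    def test_degenerate_odds_flagged(self):
        odds, _, _ = ann.fisher_2x2(5, 0, 3, 7)
        assert np.isinf(odds)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            ann.fisher_2x2(-1, 2, 3, 4)


class TestDiseaseEnrichment:
    def _map(self):
        return pd.DataFrame({
            "disease_id": ["dx"] * 4 + ["other"] * 2,
            "human_id": ["h1", "h2", "h3", "h4", "h1", "h9"]})

    def test_counts_and_marginals(self):
        res = ann.disease_enrichment(
            {"h1", "h2", "h5"}, {f"h{i}" for i in range(1, 9)}, self._map(), "dx")
        assert (res.a, res.b, res.c, res.d) == (2, 1, 2, 3)
        assert res.a + res.b + res.c + res.d == 8

    def test_candidates_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            ann.disease_enrichment({"zzz"}, {"h1"}, self._map(), "dx")

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="background"):
            ann.disease_enrichment(set(), set(), self._map(), "dx")

    def test_term_enrichment_wrapper(self):
        terms = pd.DataFrame({"term": ["liver", "liver"], "gene_id": ["h1", "h2"]})
        res = ann.term_enrichment({"h1"}, {"h1", "h2", "h3"}, terms, "liver")
        assert res.a == 1 and res.disease_id == "liver"

    def test_planted_enrichment_single_seed(self, rng):
        from hvrkit.simulate import simulate_disease_map

        human = [f"h{i}" for i in range(3_800)]
        candidates = set(human[:200])
        dmap = simulate_disease_map(human, candidates, 0.11, 2.5, rng)
        res = ann.disease_enrichment(candidates, set(human), dmap, "D:planted")
        assert res.p_two_sided < 0.05
        assert res.odds_ratio > 1
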