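"""Candidate intervals, GFF3 gene overlap, and genotype stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budmetrics.imaging import InputError, ValidationError
from budmetrics.intervals import (
    IntervalConfig,
    annotate_genes,
    build_intervals,
    candidate_snps,
    merge_interval_records,
    read_bed,
    read_gff_genes,
    stratification_table,
    stratify_by_genotype,
    write_bed,
)
from budmetrics.synthetic import AssocSimSpec, PlantedPeak, simulate_association


def _snps(positions, chrom="Chr1", traits=("length", "width")):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "traits": [list(traits)] * len(positions)}
    )


def brute_force_merge(positions, flank, length, bookended=True):
    """Per-bp union-then-scan oracle for interval merging."""
    covered = np.zeros(length + 2, dtype=bool)  # 1-based; +1 sentinel
    for pos in positions:
        covered[max(1, pos - flank) : min(length, pos + flank) + 1] = True
    runs = []
    start = None
    for bp in range(1, length + 2):
        if covered[bp] and start is None:
            start = bp
        elif not covered[bp] and start is not None:
            runs.append((start, bp - 1))
            start = None
    if not bookended:
        return runs
    merged = []
    for s, e in runs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class TestCandidateSnps:
    def _scans(self, sig_traits, pos=5_000_000, chrom="Chr1"):
        traits = ["length", "width", "perimeter", "area"]
        scans = {}
        for t in traits:
            p = 1e-8 if t in sig_traits else 0.5
            scans[t] = pd.DataFrame({"chrom": [chrom], "pos": [pos], "p": [p]})
        return scans

    def test_two_trait_support_retained(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 10_000_000})
        out = candidate_snps(self._scans({"length", "area"}), cfg)
        assert len(out) == 1 and out.loc[0, "traits"] == ["area", "length"]

    def test_single_trait_dropped(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 10_000_000})
        assert candidate_snps(self._scans({"length"}), cfg).empty

    def test_missing_p_nonsignificant(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 10_000_000})
        scans = self._scans({"length", "width"})
        scans["length"].loc[0, "p"] = np.nan
        assert candidate_snps(scans, cfg).empty


class TestBuildIntervals:
    def test_lead_snp_worked_example(self):
        # 100-kb flank around Chr10:14322573 spans 14.22-14.42 Mb.
        cfg = IntervalConfig(chrom_lengths={"Chr10": 20_000_000})
        out = build_intervals(_snps([14322573], chrom="Chr10"), cfg)
        assert out.loc[0, "start"] == 14_222_573
        assert out.loc[0, "end"] == 14_422_573

    def test_start_clipped_to_one(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 10_000_000})
        out = build_intervals(_snps([50_000]), cfg)
        assert out.loc[0, "start"] == 1 and out.loc[0, "end"] == 150_000

    def test_snp_beyond_chromosome_rejected(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 100})
        with pytest.raises(ValidationError):
            build_intervals(_snps([200]), cfg)

    def test_traits_and_snps_unioned_on_merge(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 10_000_000}, flank=1000)
        snps = pd.DataFrame(
            {
                "chrom": ["Chr1", "Chr1"],
                "pos": [5000, 6000],
                "traits": [["length", "width"], ["width", "area"]],
            }
        )
        out = build_intervals(snps, cfg)
        assert len(out) == 1
        assert out.loc[0, "snps"] == [5000, 6000]
        assert out.loc[0, "traits"] == ["area", "length", "width"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        positions=st.lists(st.integers(1, 50_000), min_size=1, max_size=12),
        flank=st.integers(0, 4000),
    )
    def test_matches_bruteforce_oracle(self, positions, flank):
        length = 50_000
        cfg = IntervalConfig(chrom_lengths={"Chr1": length}, flank=flank)
        out = build_intervals(_snps(sorted(positions)), cfg)
        expected = brute_force_merge(positions, flank, length)
        assert list(zip(out["start"], out["end"])) == expected

    def test_idempotent_on_merged_output(self):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 1_000_000}, flank=20_000)
        once = build_intervals(_snps([100_000, 130_000, 600_000]), cfg)
        records = once[["chrom", "start", "end"]].to_dict("records")
        again = merge_interval_records(records)
        assert [(r["start"], r["end"]) for r in again] == list(zip(once["start"], once["end"]))

    def test_monotone_in_flank_and_min_traits(self):
        positions = [100_000, 400_000, 401_000, 900_000]
        length = 1_000_000
        spans = []
        for flank in (1000, 10_000, 100_000):
            cfg = IntervalConfig(chrom_lengths={"Chr1": length}, flank=flank)
            out = build_intervals(_snps(positions), cfg)
            spans.append((out["end"] - out["start"] + 1).sum())
        assert spans == sorted(spans)

        scans = {
            t: pd.DataFrame({"chrom": "Chr1", "pos": positions, "p": ps})
            for t, ps in {
                "length": [1e-8, 1e-8, 0.5, 1e-8],
                "width": [1e-8, 0.5, 0.5, 1e-8],
                "area": [0.5, 0.5, 0.5, 1e-8],
            }.items()
        }
        counts = [
            len(candidate_snps(scans, IntervalConfig(chrom_lengths={"Chr1": length}, min_traits=k)))
            for k in (1, 2, 3)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_bed_round_trip(self, tmp_path):
        cfg = IntervalConfig(chrom_lengths={"Chr1": 1_000_000}, flank=25_000)
        out = build_intervals(_snps([100_000, 120_000, 800_000]), cfg)
        path = tmp_path / "iv.bed"
        write_bed(out, path)
        back = read_bed(path)
        assert back[["chrom", "start", "end"]].equals(out[["chrom", "start", "end"]])


GFF_10_GENES = "##gff-version 3\n" + "".join(
    f"Chr1\tsrc\tgene\t{1 + i * 1000}\t{500 + i * 1000}\t.\t+\t.\tID=g{i + 1}\n"
    for i in range(10)
)


class TestAnnotateGenes:
    def test_tiled_fixture_counts(self):
        genes = read_gff_genes(GFF_10_GENES)
        assert len(genes) == 10
        iv = pd.DataFrame({"chrom": ["Chr1"], "start": [1], "end": [2500], "traits": [[]]})
        annotated, summary = annotate_genes(iv, genes)
        assert annotated.loc[0, "genes"] == ["g1", "g2", "g3"]
        assert summary == {"n_intervals": 1, "total_span_bp": 2500, "n_genes": 3}

    def test_inclusive_abutment(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["Chr1"], "start": [2000], "end": [2400]}
        )
        iv = pd.DataFrame({"chrom": ["Chr1"], "start": [1000], "end": [2000]})
        annotated, _ = annotate_genes(iv, genes)
        assert annotated.loc[0, "genes"] == ["g"]  # gene.start == interval.end
        iv2 = iv.assign(end=[1999])
        annotated2, _ = annotate_genes(iv2, genes)
        assert annotated2.loc[0, "genes"] == []  # one bp short

    def test_malformed_gff_line_number(self):
        bad = "##gff-version 3\nChr1\tsrc\tgene\t1\t100\n"
        with pytest.raises(InputError, match="line 2"):
            read_gff_genes(bad)


class TestStratify:
    @pytest.fixture()
    def assoc_fixture(self, tmp_path):
        spec = AssocSimSpec(
            peaks=[PlantedPeak("Chr10", 14322573, ["length", "width", "perimeter", "area"])],
            seed=0,
        )
        _, _, vcf, pheno = simulate_association(spec)
        vcf_path = tmp_path / "geno.vcf"
        vcf_path.write_text(vcf)
        return vcf_path, pheno

    def test_additive_effect_separates_all_classes(self, assoc_fixture):
        vcf_path, pheno = assoc_fixture
        strat = stratify_by_genotype(vcf_path, "Chr10:14322573", pheno)
        res = strat["length"]
        assert res.anova_p < 1e-6
        assert (res.tukey["p"] < 0.05).all()
        assert len(set(res.letters.values())) == 3
        means = [np.mean(v) for v in res.group_values.values()]
        assert means == sorted(means)  # monotone in alt dosage

    def test_null_trait_shares_a_letter(self, assoc_fixture, tmp_path):
        vcf_path, pheno = assoc_fixture
        rng = np.random.default_rng(1)
        null = pheno.copy()
        null["length"] = rng.normal(size=len(null))  # unrelated to genotype
        strat = stratify_by_genotype(vcf_path, "Chr10:14322573", null)
        letters = strat["length"].letters
        assert len(set(letters.values())) < 3 or any(len(v) > 1 for v in letters.values())

    def test_missing_snp_and_samples_rejected(self, assoc_fixture):
        vcf_path, pheno = assoc_fixture
        with pytest.raises(ValidationError):
            stratify_by_genotype(vcf_path, "Chr10:1", pheno)
        with pytest.raises(ValidationError):
            stratify_by_genotype(vcf_path, "Chr10:14322573", pheno.iloc[:10])

    def test_table_export(self, assoc_fixture):
        vcf_path, pheno = assoc_fixture
        strat = stratify_by_genotype(vcf_path, "Chr10:14322573", pheno)
        table = stratification_table(strat)
        assert set(table.columns) == {"trait", "genotype", "n", "mean", "sd", "anova_p", "letters"}
        assert table["n"].sum() == len(pheno) * pheno.shape[1]


class TestEndToEnd:
    def test_planted_peak_becomes_single_interval(self, tmp_path):
        spec = AssocSimSpec(
            peaks=[PlantedPeak("Chr10", 14322573, ["length", "width"])], seed=0
        )
        scans, gff, _, _ = simulate_association(spec)
        cfg = IntervalConfig(chrom_lengths=dict(spec.chrom_lengths))
        ivs = build_intervals(candidate_snps(scans, cfg), cfg)
        assert len(ivs) == 1
        assert ivs.loc[0, "start"] <= 14322573 <= ivs.loc[0, "end"]
        annotated, summary = annotate_genes(ivs, gff)
        assert summary["n_genes"] == len(annotated.loc[0, "genes"]) > 0
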