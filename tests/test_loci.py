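"""Complex-locus identification: hand-traced fixtures and randomized oracles."""

import numpy as np
import pandas as pd
import pytest

from relocus import sim
from relocus.elements import RegulatoryElement
from relocus.intervals import GenomicInterval
from relocus.loci import (
    ComplexLocus,
    density_rank,
    expand_to_stat5,
    finalize,
    find_complex_loci,
    stitch_genes,
    validate_domains,
)


def toy_annotation(n=6, chrom="chr9", gene_len=500, pitch=1000):
    rows = [
        (f"g{i + 1}", chrom, i * pitch, i * pitch + gene_len, "+",
         "protein_coding", "none", "toy")
        for i in range(n)
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "biotype", "tissue_spec", "group"]
    )


def element(start, end, chrom="chr9", name="el"):
    return RegulatoryElement(GenomicInterval(chrom, start, end), name=name)


class TestStitchGenes:
    def test_consecutive_run_forms_locus(self):
        ann = toy_annotation()
        loci = stitch_genes({"g1", "g2", "g3"}, ann)
        assert len(loci) == 1
        assert loci[0].member_genes == ["g1", "g2", "g3"]
        assert (loci[0].interval.start, loci[0].interval.end) == (0, 2500)

    def test_interloper_breaks_run(self):
        ann = toy_annotation()
        assert stitch_genes({"g1", "g3"}, ann) == []  # two singletons

    def test_unknown_gene_errors(self):
        with pytest.raises(ValueError, match="ghost"):
            stitch_genes({"g1", "ghost"}, toy_annotation())

    def test_non_protein_coding_ignored(self):
        ann = toy_annotation()
        ann.loc[ann["gene_id"] == "g2", "biotype"] = "lncRNA"
        # g2 is not protein coding: it neither joins nor breaks the run
        loci = stitch_genes({"g1", "g3"}, ann)
        assert len(loci) == 1 and loci[0].member_genes == ["g1", "g3"]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_run_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ann = toy_annotation(n=n)
        induced = {f"g{i + 1}" for i in np.flatnonzero(rng.random(n) < 0.4)}
        got = [tuple(l.member_genes) for l in stitch_genes(induced, ann)]
        # exhaustive scan over gene order
        order = [f"g{i + 1}" for i in range(n)]
        runs, cur = [], []
        for g in order:
            if g in induced:
                cur.append(g)
            else:
                if len(cur) >= 2:
                    runs.append(tuple(cur))
                cur = []
        if len(cur) >= 2:
            runs.append(tuple(cur))
        assert got == runs


class TestValidateDomains:
    def test_two_gene_crossing_locus_discarded(self):
        ann = toy_annotation()
        loci = stitch_genes({"g1", "g2"}, ann)
        doms = [GenomicInterval("chr9", 0, 700), GenomicInterval("chr9", 700, 9000)]
        assert validate_domains(loci, doms, ann) == []

    def test_non_crossing_locus_unchanged(self):
        ann = toy_annotation()
        loci = stitch_genes({"g1", "g2", "g3"}, ann)
        doms = [GenomicInterval("chr9", 0, 9000)]
        out = validate_domains(loci, doms, ann)
        assert out == loci  # idempotent identity on valid loci

    def test_six_gene_3_3_split(self):
        ann = toy_annotation()
        loci = stitch_genes(set(ann["gene_id"]), ann)
        doms = [GenomicInterval("chr9", 0, 2700), GenomicInterval("chr9", 2700, 9000)]
        out = validate_domains(loci, doms, ann)
        assert [l.member_genes for l in out] == [["g1", "g2", "g3"],
                                                 ["g4", "g5", "g6"]]
        # shrunk to the span of the remaining genes
        assert (out[0].interval.start, out[0].interval.end) == (0, 2500)
        assert (out[1].interval.start, out[1].interval.end) == (3000, 5500)
        assert "shrunk_to_genes" in out[0].provenance

    def test_six_gene_4_2_split_keeps_only_big_side(self):
        ann = toy_annotation()
        loci = stitch_genes(set(ann["gene_id"]), ann)
        doms = [GenomicInterval("chr9", 0, 3700), GenomicInterval("chr9", 3700, 9000)]
        out = validate_domains(loci, doms, ann)
        assert len(out) == 1
        assert out[0].member_genes == ["g1", "g2", "g3", "g4"]
        assert (out[0].interval.start, out[0].interval.end) == (0, 3500)

    def test_straddling_gene_dropped(self):
        ann = toy_annotation()
        loci = stitch_genes(set(ann["gene_id"]), ann)
        # border inside g4 (3000-3500): g4 belongs to neither side
        doms = [GenomicInterval("chr9", 0, 3200), GenomicInterval("chr9", 3200, 9000)]
        out = validate_domains(loci, doms, ann)
        assert [l.member_genes for l in out] == [["g1", "g2", "g3"]]

    def test_gene_partition_property(self):
        ann = toy_annotation(n=12)
        loci = stitch_genes(set(ann["gene_id"]), ann)
        doms = [
            GenomicInterval("chr9", 0, 3700),
            GenomicInterval("chr9", 3700, 7700),
            GenomicInterval("chr9", 7700, 20_000),
        ]
        out = validate_domains(loci, doms, ann)
        all_members = [g for l in out for g in l.member_genes]
        assert len(all_members) == len(set(all_members))


class TestExpansion:
    def test_extends_to_intergenic_site_same_domain(self):
        ann = toy_annotation()
        locus = stitch_genes({"g1", "g2", "g3"}, ann)[0]
        els = [element(2600, 2650, name="s1")]
        doms = [GenomicInterval("chr9", 0, 9000)]
        out = expand_to_stat5(locus, els, ann, doms)
        assert out.interval.end == 2650
        assert out.included_elements == ["s1"]
        assert any(e.startswith("expanded_to") for e in out.provenance)

    def test_no_sites_identity(self):
        ann = toy_annotation()
        locus = stitch_genes({"g1", "g2", "g3"}, ann)[0]
        out = expand_to_stat5(locus, [], ann, [GenomicInterval("chr9", 0, 9000)])
        assert out is locus

    def test_site_beyond_next_gene_not_used(self):
        ann = toy_annotation()
        locus = stitch_genes({"g1", "g2", "g3"}, ann)[0]
        # site inside the intergenic region beyond g4: not adjacent
        els = [element(3600, 3650, name="far")]
        out = expand_to_stat5(locus, els, ann, [GenomicInterval("chr9", 0, 9000)])
        assert out is locus

    def test_trimmed_to_last_element_before_boundary(self):
        ann = toy_annotation()
        locus = stitch_genes({"g1", "g2", "g3"}, ann)[0]
        els = [element(2550, 2570, name="near"), element(2800, 2820, name="beyond")]
        doms = [GenomicInterval("chr9", 0, 2700), GenomicInterval("chr9", 2700, 9000)]
        out = expand_to_stat5(locus, els, ann, doms)
        assert out.interval.end == 2570
        assert out.included_elements == ["near"]
        assert "trimmed_to_last_element" in out.provenance

    def test_all_sites_beyond_boundary_identity(self):
        ann = toy_annotation()
        locus = stitch_genes({"g1", "g2", "g3"}, ann)[0]
        els = [element(2800, 2820, name="beyond")]
        doms = [GenomicInterval("chr9", 0, 2700), GenomicInterval("chr9", 2700, 9000)]
        out = expand_to_stat5(locus, els, ann, doms)
        assert out is locus

    def test_left_border_expansion(self):
        ann = toy_annotation()
        locus = stitch_genes({"g2", "g3", "g4"}, ann)[0]
        els = [element(700, 750, name="up")]  # between g1 end (500) and g2
        out = expand_to_stat5(locus, els, ann, [GenomicInterval("chr9", 0, 9000)])
        assert out.interval.start == 700


class TestFinalizeAndRank:
    def test_three_gene_kept_two_gene_dropped(self):
        ann = toy_annotation()
        keep = stitch_genes({"g1", "g2", "g3"}, ann)[0]
        drop = ComplexLocus(GenomicInterval("chr9", 7000, 8000), ["a", "b"])
        out = finalize([keep, drop])
        assert out == [keep]
        assert finalize([]) == []

    def test_density_arithmetic_on_toy(self):
        l1 = ComplexLocus(GenomicInterval("chr9", 0, 100_000), ["a", "b", "c"])
        l2 = ComplexLocus(GenomicInterval("chr9", 200_000, 250_000), ["d", "e", "f"])
        els = [element(10, 50), element(300, 350), element(201_000, 201_050)]
        table = density_rank([l1, l2], els).set_index("start")
        # l1: 2 elements over 100 kb; l2: 1 element over 50 kb -> both 2.0
        assert table.loc[0, "n_elements"] == 2
        assert np.isclose(table.loc[0, "elements_per_100kb"], 2.0)
        assert np.isclose(table.loc[200_000, "elements_per_100kb"], 2.0)
        # tie on element density broken by gene density (6 vs 3 per 100 kb)
        assert table.index[0] == 200_000
        assert np.isclose(table.loc[200_000, "genes_per_100kb"], 6.0)

    def test_zero_element_locus_density_zero(self):
        l1 = ComplexLocus(GenomicInterval("chr9", 0, 50_000), ["a", "b", "c"])
        table = density_rank([l1], [])
        assert table.iloc[0]["n_elements"] == 0
        assert table.iloc[0]["elements_per_100kb"] == 0.0


class TestPipelineOnFixture:
    def test_focal_locus_recovered_and_ranked_first(self, fixture_full):
        from relocus import elements as el_mod
        from relocus.expression import induced_genes

        els = el_mod.identify_elements(
            fixture_full.peaks["STAT5A_rep1"],
            fixture_full.peaks["STAT5A_rep2"],
            fixture_full.peaks["H3K27ac"],
        )
        induced = induced_genes(fixture_full.counts, fixture_full.meta)
        final = find_complex_loci(
            induced, fixture_full.annotation, fixture_full.domains, els
        )
        focal = [l for l in final if l.interval.chrom == "chr5"]
        assert len(focal) == 1
        assert set(sim.CASEIN_GENES) <= set(focal[0].member_genes)
        assert all(l.n_genes >= 3 for l in final)
        # density ranking puts the casein-like locus first
        table = density_rank(final, els)
        assert table.iloc[0]["chrom"] == "chr5"
        # cluster B (2 genes over a boundary) eliminated
        members = {g for l in final for g in l.member_genes}
        assert not members & {"bgB1", "bgB2"}
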