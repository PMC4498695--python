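"""Panel loading and flat-file round trips (TSV, PED, VCF)."""

import textwrap

import pytest

from mendelsieve import io as msio
from mendelsieve.model import GenotypeCall
from mendelsieve.panel import PanelError, load_builtin_panel, load_panel


class TestPanel:
    def test_builtin_stgd_panel(self, stgd_panel):
        assert stgd_panel["ABCA4"].inheritance_mode == "AR"
        assert stgd_panel["PROM1"].inheritance_mode == "AR"
        assert stgd_panel["PRPH2"].inheritance_mode == "AD"
        assert len(stgd_panel) == 5

    def test_builtin_full_panel_size(self, full_panel):
        assert len(full_panel) == 214
        stgd = [e for e in full_panel.values() if e.phenotype_group == "STGD"]
        assert len(stgd) == 5
        assert full_panel["ABCA4"].recessive

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "panel.yaml"
        p.write_text(
            "panel:\n"
            "  - {gene: ABCA4, inheritance_mode: AR}\n"
            "  - {gene: ABCA4, inheritance_mode: AD}\n"
        )
        with pytest.raises(PanelError, match="duplicate"):
            load_panel(p)

    def test_unknown_mode_rejected(self, tmp_path):
        p = tmp_path / "panel.yaml"
        p.write_text("panel:\n  - {gene: ABCA4, inheritance_mode: dominantish}\n")
        with pytest.raises(PanelError):
            load_panel(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "panel.yaml"
        p.write_text("")
        with pytest.raises(PanelError, match="empty"):
            load_panel(p)


class TestVariantTableRoundTrip:
    def test_write_then_read_is_identity(self, table1, tmp_path):
        path = tmp_path / "variants.tsv"
        msio.write_variant_table(table1.variants, path)
        assert msio.read_variant_table(path) == table1.variants

    def test_packaged_cohort_tables(self):
        from importlib import resources

        data = resources.files("mendelsieve.data")
        variants = msio.read_variant_table(data / "table1_variants.tsv")
        calls = msio.read_genotype_table(data / "table1_genotypes.tsv")
        assert len(variants) == 28
        assert len(calls) == 37
        zygosities = [c.zygosity for c in calls]
        assert zygosities.count("hom") == 1
        assert zygosities.count("het") == 36
        hom = next(c for c in calls if c.zygosity == "hom")
        assert hom.proband_id == "QT1182"

    def test_malformed_row_reports_line_number(self, tmp_path, table1):
        path = tmp_path / "variants.tsv"
        msio.write_variant_table(table1.variants, path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        cells = lines[3].split("\t")
        cells[header.index("consequence")] = "bogus"
        lines[3] = "\t".join(cells)
        path.write_text("\n".join(lines))
        with pytest.raises(msio.TableFormatError, match=":4:"):
            msio.read_variant_table(path)

    def test_allele_count_above_number_rejected(self, tmp_path):
        header = "\t".join(
            "variant_id gene chrom pos ref alt cdna_name protein_name consequence "
            "splice_flag polyphen sift provean reported_status ExAC_ac ExAC_an".split()
        )
        row = "\t".join(
            "G:c.1A>G G 1 100 A G c.1A>G p.X1Y missense False PrD D D novel 10 5".split()
        )
        path = tmp_path / "bad.tsv"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(msio.TableFormatError, match="exceeds"):
            msio.read_variant_table(path)

    def test_empty_table_reads_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        header = "\t".join(
            "variant_id gene chrom pos ref alt cdna_name protein_name consequence "
            "splice_flag polyphen sift provean reported_status".split()
        )
        path.write_text(header + "\n")
        assert msio.read_variant_table(path) == {}


class TestGenotypeTable:
    def test_round_trip(self, table1, tmp_path):
        path = tmp_path / "gt.tsv"
        msio.write_genotype_table(table1.genotypes, path)
        assert msio.read_genotype_table(path) == table1.genotypes

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "gt.tsv"
        path.write_text(
            "proband_id\tvariant_id\tzygosity\nP1\tV1\thet\nP1\tV1\thom\n"
        )
        with pytest.raises(msio.TableFormatError, match="duplicate"):
            msio.read_genotype_table(path)

    def test_read_cohort_flags_off_panel_genes(self, tmp_path, table1, stgd_panel):
        vpath, gpath = tmp_path / "v.tsv", tmp_path / "g.tsv"
        import dataclasses

        variants = dict(table1.variants)
        rogue = next(iter(variants.values()))
        variants["ZZZ9:c.1A>G"] = dataclasses.replace(
            rogue,
            variant_id="ZZZ9:c.1A>G",
            gene="ZZZ9",
            cdna_name="c.1A>G",
            freq_evidence=(),
        )
        msio.write_variant_table(variants, vpath)
        msio.write_genotype_table(
            list(table1.genotypes) + [GenotypeCall("QT058", "ZZZ9:c.1A>G", "het")], gpath
        )
        _, _, off_panel = msio.read_cohort(vpath, gpath, stgd_panel)
        assert off_panel == {"ZZZ9"}


class TestPed:
    def test_round_trip(self, tmp_path):
        ped_text = textwrap.dedent(
            """\
            FAM1\tdad\t0\t0\t1\t1
            FAM1\tmom\t0\t0\t2\t1
            FAM1\tkid\tdad\tmom\t2\t2
            """
        )
        path = tmp_path / "fam.ped"
        path.write_text(ped_text)
        pedigrees = msio.read_ped(path)
        assert set(pedigrees) == {"FAM1"}
        kid = pedigrees["FAM1"].individuals["kid"]
        assert kid.affected == "affected"
        assert kid.father_id == "dad"
        out = tmp_path / "out.ped"
        msio.write_ped(pedigrees, out)
        assert msio.read_ped(out) == pedigrees

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text("FAM1\tkid\t0\t0\n")
        with pytest.raises(msio.TableFormatError, match="6 columns"):
            msio.read_ped(path)


class TestVcf:
    VCF = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##INFO=<ID=GENE,Number=1,Type=String,Description="gene">
        ##INFO=<ID=CDNA,Number=1,Type=String,Description="hgvs c.">
        ##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="consequence">
        ##INFO=<ID=EXAC_AC,Number=1,Type=Integer,Description="ac">
        ##INFO=<ID=EXAC_AN,Number=1,Type=Integer,Description="an">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2
        1\t100\t.\tA\tG\t50\tPASS\tGENE=ABCA4;CDNA=c.2894A>G;CSQCLASS=missense;EXAC_AC=21;EXAC_AN=121302\tGT\t0/1\t1/1
        1\t200\t.\tC\tT\t50\tPASS\tGENE=ABCA4;CDNA=c.22C>T;CSQCLASS=nonsense\tGT\t0/0\t0/1
        """
    )

    MAPPING = {
        "gene": "GENE",
        "cdna_name": "CDNA",
        "consequence": "CSQCLASS",
        "frequencies": {"ExAC": {"ac": "EXAC_AC", "an": "EXAC_AN"}},
    }

    def test_vcf_ingestion(self, tmp_path):
        path = tmp_path / "cohort.vcf"
        path.write_text(self.VCF)
        variants, calls = msio.read_vcf(path, self.MAPPING)
        assert set(variants) == {"ABCA4:c.2894A>G", "ABCA4:c.22C>T"}
        v = variants["ABCA4:c.2894A>G"]
        assert v.freq_evidence[0].allele_count == 21
        assert sorted((c.proband_id, c.variant_id, c.zygosity) for c in calls) == [
            ("P1", "ABCA4:c.2894A>G", "het"),
            ("P2", "ABCA4:c.22C>T", "het"),
            ("P2", "ABCA4:c.2894A>G", "hom"),
        ]
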