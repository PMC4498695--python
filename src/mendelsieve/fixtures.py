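"""Packaged cohort fixture: 33 Stargardt probands, ABCA4 candidate variants.

The fixture encodes a published per-proband variant table for a 33-proband
Stargardt cohort: 28 distinct ABCA4 variants (13 novel, 15 previously
reported) observed as 37 proband-variant genotype calls — 36 heterozygous
plus one homozygous splice variant — across the 19 probands whose disease
the variants explain.  Fourteen further probands carry only deterministic
decoy variants, one decoy class per exclusion step of the cascade, so the
full cohort exercises every removal path and both partial states.

Synthetic elements, clearly not measured data:

* genomic coordinates (``chrom``/``pos``/``ref``/``alt``) are placeholder
  positions inside ABCA4's locus on chromosome 1 derived from the cDNA
  position — the source table prints HGVS names only;
* the decoy variants and the ids of the 14 unexplained probands
  (``QTX01``..``QTX14``) are constructed here;
* where the source table prints conflicting PolyPhen calls for the same
  variant in different probands (p.M1882I: PoD vs B; p.R602W: PoD vs B),
  the fixture stores the damaging call once per variant;
* predictor tokens outside the controlled vocabulary (PolyPhen "D",
  SIFT "N") are stored as NA, per the reader's normalization rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    FrequencyEvidence,
    GenePanelEntry,
    GenotypeCall,
    PredictorCalls,
    VariantRecord,
)

__all__ = ["Table1Fixture", "make_table1_fixture"]

_GENE = "ABCA4"
_CHROM = "1"
_POS_ANCHOR = 94_600_000  # synthetic anchor near the ABCA4 locus (hg19 scale)

# cdna, protein ('' = splicing defect), consequence, polyphen, provean, sift,
# evs_maf (None = no observation), exac (ac, an) or None, NC screen, RC screen,
# reported status
_TABLE1_VARIANTS = [
    ("c.6173T>G", "p.L2058R", "missense", "PrD", "D", "D", None, None, "0/192", "0/456", "novel"),
    ("c.4773+1G>T", "", "splice_site", "NA", "NA", "NA", None, None, "-", "0/456", "known"),
    ("c.5932delA", "p.K1978Qfs*13", "frameshift", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.6389T>A", "p.M2130K", "missense", "PoD", "D", "D", None, None, "-", "0/456", "known"),
    ("c.6118C>T", "p.R2040*", "nonsense", "NA", "NA", "NA", None, (2, 121394), "0/192", "0/456", "known"),
    ("c.6816+1G>A", "", "splice_site", "NA", "NA", "NA", None, None, "-", "0/456", "known"),
    ("c.4555delA", "p.T1519Rfs*7", "frameshift", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.4352+1G>A", "", "splice_site", "NA", "NA", "NA", None, (1, 121268), "-", "0/456", "known"),
    ("c.1804C>T", "p.R602W", "missense", "PoD", "D", "D", None, (6, 119038), "-", "2/456", "known"),
    ("c.5646G>A", "p.M1882I", "missense", "PoD", "D", "D", None, (3, 121340), "-", "0/456", "known"),
    ("c.164A>G", "p.H55R", "missense", "PoD", "D", "D", None, None, "-", "0/456", "known"),
    ("c.161-2A>G", "", "splice_site", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.101_106del", "p.S34_L35del", "inframe_indel", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.2424C>G", "p.Y808*", "nonsense", "NA", "NA", "NA", None, None, "-", "0/456", "known"),
    ("c.1560delG", "p.V521Sfs*47", "frameshift", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.6284A>T", "p.D2095V", "missense", "PrD", "D", "D", None, None, "0/192", "0/456", "novel"),
    ("c.22C>T", "p.Q8*", "nonsense", "NA", "NA", "NA", 0.0001, None, "0/192", "0/456", "novel"),
    ("c.240_241del", "p.C81Ffs*17", "frameshift", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.4195G>T", "p.E1399*", "nonsense", "NA", "NA", "NA", None, (2, 120596), "0/192", "0/456", "novel"),
    ("c.2894A>G", "p.N965S", "missense", "PrD", "D", "D", 0.0001, (21, 121302), "-", "0/456", "known"),
    ("c.6317G>C", "p.R2106P", "missense", "PrD", "D", "D", None, None, "0/192", "0/456", "novel"),
    ("c.6479+2T>C", "", "splice_site", "NA", "NA", "NA", None, None, "0/192", "0/456", "novel"),
    ("c.5196+1G>A", "", "splice_site", "NA", "NA", "NA", None, (3, 49858), "-", "0/456", "known"),
    ("c.4622T>C", "p.L1541P", "missense", "PrD", "D", "D", None, None, "0/192", "0/456", "novel"),
    ("c.6563T>C", "p.F2188S", "missense", "B", "D", "D", 0.0005, (2, 121380), "-", "1/456", "known"),
    ("c.858+2T>A", "", "splice_site", "NA", "NA", "NA", None, None, "-", "0/456", "known"),
    ("c.4793C>G", "p.A1598G", "missense", "PoD", "D", "NA", 0.0001, None, "-", "0/456", "known"),
    ("c.634C>T", "p.R212C", "missense", "NA", "D", "D", 0.0002, (14, 120056), "-", "0/456", "known"),
]

# proband -> [(cdna, zygosity), ...]; one row per observed genotype call
_TABLE1_GENOTYPES = {
    "QT058": [("c.6173T>G", "het"), ("c.4773+1G>T", "het")],
    "QT085": [("c.6173T>G", "het"), ("c.5932delA", "het")],
    "QT292": [("c.6389T>A", "het"), ("c.6118C>T", "het")],
    "QT302": [("c.6816+1G>A", "het"), ("c.4555delA", "het")],
    "QT398": [("c.4352+1G>A", "het"), ("c.1804C>T", "het")],
    "QT431": [("c.5646G>A", "het"), ("c.1804C>T", "het")],
    "QT458": [("c.4555delA", "het"), ("c.164A>G", "het")],
    "QT727": [("c.161-2A>G", "het"), ("c.101_106del", "het")],
    "QT833": [("c.2424C>G", "het"), ("c.1560delG", "het")],
    "QT1137": [("c.6284A>T", "het"), ("c.22C>T", "het")],
    "QT1160": [("c.240_241del", "het"), ("c.101_106del", "het")],
    "QT1175": [("c.4195G>T", "het"), ("c.2894A>G", "het")],
    "QT1182": [("c.4773+1G>T", "hom")],
    "QT1198": [("c.5646G>A", "het"), ("c.2894A>G", "het")],
    "QT1200": [("c.6563T>C", "het"), ("c.858+2T>A", "het")],
    "QT1230": [("c.6317G>C", "het"), ("c.101_106del", "het")],
    "QT1277": [("c.6479+2T>C", "het"), ("c.5196+1G>A", "het")],
    "QT1317": [("c.5646G>A", "het"), ("c.4622T>C", "het")],
    "MD19": [("c.4793C>G", "het"), ("c.634C>T", "het")],
}

# Decoys: each class is constructed to fail exactly one exclusion step.
# cdna, protein, consequence, polyphen, provean, sift, exac, target step
_DECOYS = [
    ("c.5814A>G", "p.=", "synonymous", "NA", "NA", "NA", None, "removed_step1"),
    ("c.1268A>G", "p.H423R", "missense", "PoD", "D", "D", (12000, 120000), "removed_step2"),
    ("c.71G>A", "p.R24H", "missense", "PrD", "D", "D", None, "removed_step3"),
    ("c.3899G>A", "p.R1300Q", "missense", "B", "N", "T", None, "removed_step4"),
]

# The 14 probands without a causative genotype, mirroring the published
# split: 4 with a lone pathogenic het, 4 with >=2 hets of which one
# pathogenic, 6 with nothing surviving the first two steps.
_EXTRA_PROBANDS = {
    **{f"QTX{i:02d}": ["c.71G>A"] for i in (1, 2, 3, 4)},
    **{f"QTX{i:02d}": ["c.71G>A", "c.3899G>A"] for i in (5, 6, 7, 8)},
    **{f"QTX{i:02d}": ["c.5814A>G", "c.1268A>G"] for i in (9, 10, 11, 12, 13, 14)},
}


@dataclass
class Table1Fixture:
    """In-memory packaged cohort (variants include the decoys)."""

    variants: dict[str, VariantRecord]
    genotypes: list[GenotypeCall]
    control_screens: dict[str, dict[str, str]]
    decoy_expected_step: dict[str, str]
    solved_probands: tuple[str, ...]
    extra_probands: tuple[str, ...]

    @property
    def probands(self) -> tuple[str, ...]:
        return self.solved_probands + self.extra_probands

    @property
    def table1_pairs(self) -> set[tuple[str, str]]:
        """The published (proband, variant) pairs, i.e. the non-decoy calls."""
        decoys = set(self.decoy_expected_step)
        return {
            (c.proband_id, c.variant_id)
            for c in self.genotypes
            if c.variant_id not in decoys
        }

    @property
    def zygosities(self) -> dict[tuple[str, str], str]:
        return {(c.proband_id, c.variant_id): c.zygosity for c in self.genotypes}


def _synthetic_locus(cdna: str, consequence: str) -> tuple[int, str, str]:
    from .hgvs import parse_hgvs_c

    change = parse_hgvs_c(cdna)
    pos = _POS_ANCHOR - change.coding_position
    if change.change_kind == "substitution":
        return pos, change.ref, change.alt
    if change.change_kind == "deletion":
        length = (
            len(change.ref)
            if change.ref
            else (change.end_position or change.coding_position) - change.coding_position + 1
        )
        return pos, "N" + (change.ref or "N" * length), "N"
    return pos, "N", "N" + (change.alt or "N")


def _record(
    cdna: str,
    protein: str,
    consequence: str,
    polyphen: str,
    provean: str,
    sift: str,
    evs_maf: float | None,
    exac: tuple[int, int] | None,
    reported: str,
) -> VariantRecord:
    pos, ref, alt = _synthetic_locus(cdna, consequence)
    evidence = []
    if evs_maf is not None:
        evidence.append(FrequencyEvidence(source="EVS", maf=evs_maf))
    if exac is not None:
        evidence.append(
            FrequencyEvidence(source="ExAC", allele_count=exac[0], allele_number=exac[1])
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # vocabulary coercion is documented above
        calls = PredictorCalls(polyphen=polyphen, sift=sift, provean=provean)
    return VariantRecord(
        variant_id=f"{_GENE}:{cdna}",
        gene=_GENE,
        chrom=_CHROM,
        pos=pos,
        ref=ref,
        alt=alt,
        cdna_name=cdna,
        protein_name="" if not protein or protein == "p.=" else protein,
        consequence=consequence,
        splice_flag=consequence == "splice_site",
        freq_evidence=tuple(evidence),
        predictor_calls=calls,
        reported_status=reported,
    )


def make_table1_fixture() -> Table1Fixture:
    """Build the packaged 33-proband cohort fixture.

    Deterministic: no randomness, byte-identical on every call.
    """
    variants: dict[str, VariantRecord] = {}
    control_screens: dict[str, dict[str, str]] = {}
    for cdna, protein, csq, pp, prov, sift, evs, exac, nc, rc, reported in _TABLE1_VARIANTS:
        rec = _record(cdna, protein, csq, pp, prov, sift, evs, exac, reported)
        variants[rec.variant_id] = rec
        control_screens[rec.variant_id] = {"NC": nc, "RC": rc}

    decoy_expected_step: dict[str, str] = {}
    for cdna, protein, csq, pp, prov, sift, exac, step in _DECOYS:
        rec = _record(cdna, protein, csq, pp, prov, sift, None, exac, "novel")
        variants[rec.variant_id] = rec
        decoy_expected_step[rec.variant_id] = step

    genotypes: list[GenotypeCall] = []
    for proband, calls in _TABLE1_GENOTYPES.items():
        for cdna, zygosity in calls:
            genotypes.append(GenotypeCall(proband, f"{_GENE}:{cdna}", zygosity))
    for proband, cdnas in _EXTRA_PROBANDS.items():
        for cdna in cdnas:
            genotypes.append(GenotypeCall(proband, f"{_GENE}:{cdna}", "het"))

    return Table1Fixture(
        variants=variants,
        genotypes=genotypes,
        control_screens=control_screens,
        decoy_expected_step=decoy_expected_step,
        solved_probands=tuple(_TABLE1_GENOTYPES),
        extra_probands=tuple(_EXTRA_PROBANDS),
    )


def fixture_panel_entry() -> GenePanelEntry:
    """The panel entry the fixture's causal gene relies on."""
    return GenePanelEntry(gene=_GENE, inheritance_mode="AR", phenotype_group="STGD")
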