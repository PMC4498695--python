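"""Synthetic cohort generator.

Generates annotated-variant-level cohorts with the statistical structure the
prioritization pipeline assumes: each *solved* proband carries a planted
biallelic genotype (homozygous or compound heterozygous, trans in the
generated trio) in a recessive panel gene, hidden among per-proband decoys
constructed to fail exactly one exclusion step each — common polymorphisms
(MAF above the 0.01 cutoff), synonymous/intronic/UTR changes, unanimously
benign missense variants, and lone pathogenic heterozygotes in other
recessive genes.  A truth table records the planted status per proband and
the class of every variant, so recovery can be scored exactly.

Simulation starts at the annotated-variant level (no reads, no alignment),
mirroring where panel-based exome interpretation actually begins.  MAF
mixtures deliberately exclude the 0.01 boundary (common decoys sample
uniform(0.011, 0.5); rare variants uniform(0, 0.009)): boundary behaviour
is a fixed unit-test concern, not a sampling one.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import write_genotype_table, write_ped, write_variant_table
from .model import (
    FrequencyEvidence,
    GenePanelEntry,
    GenotypeCall,
    Individual,
    Pedigree,
    PredictorCalls,
    VariantRecord,
)
from .panel import load_builtin_panel

__all__ = ["DecoyCounts", "SimulationConfig", "SimulatedCohort", "simulate_cohort"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class DecoyCounts:
    """Per-proband decoy load by class (defaults emulate a pre-filter exome
    funnel of a few hundred panel variants over a small cohort)."""

    common: int = 10
    noncoding: int = 8
    benign_missense: int = 3
    lone_het: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the reference cohort's shape: 33 probands, 19 of
    them solvable (one homozygous, the rest compound heterozygous).
    ``seed`` is mandatory — reproducibility is part of the contract.
    """

    seed: int
    n_probands: int = 33
    solved_fraction: float = 19 / 33
    hom_vs_comphet_ratio: float = 1 / 19  # fraction of solved probands homozygous
    decoys: DecoyCounts = field(default_factory=DecoyCounts)
    n_cis_control_families: int = 0
    panel: Mapping[str, GenePanelEntry] | None = None  # default: builtin 'full'

    def __post_init__(self) -> None:
        if self.n_probands < 0:
            raise ValueError("n_probands must be >= 0")
        for name in ("solved_fraction", "hom_vs_comphet_ratio"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ProbandTruth:
    proband_id: str
    planted_status: str  # solved_homozygous | solved_compound_het | unsolved | cis_control
    causal_gene: str | None
    planted_variant_ids: tuple[str, ...]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    variants: dict[str, VariantRecord]
    genotypes: list[GenotypeCall]
    pedigrees: dict[str, Pedigree]
    family_genotypes: dict[str, dict[str, str]]  # individual -> {variant: zygosity}
    proband_truth: dict[str, ProbandTruth]
    variant_truth: dict[str, str]  # variant_id -> causal | decoy_step1..4
    cis_controls: dict[str, ProbandTruth] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write variants/genotypes/pedigrees/truth as the flat dialects the
        readers consume; byte-identical across runs with the same config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.variants, outdir / "variants.tsv")
        write_genotype_table(self.genotypes, outdir / "genotypes.tsv")
        write_ped(self.pedigrees, outdir / "families.ped")
        lines = ["proband_id\tplanted_status\tcausal_gene\tplanted_variant_ids"]
        for pid in sorted(self.proband_truth):
            t = self.proband_truth[pid]
            lines.append(
                "\t".join(
                    [
                        pid,
                        t.planted_status,
                        t.causal_gene or "NA",
                        ",".join(t.planted_variant_ids) or "NA",
                    ]
                )
            )
        (outdir / "truth_probands.tsv").write_text("\n".join(lines) + "\n")
        vlines = ["variant_id\tclass"]
        for vid in sorted(self.variant_truth):
            vlines.append(f"{vid}\t{self.variant_truth[vid]}")
        (outdir / "truth_variants.tsv").write_text("\n".join(vlines) + "\n")


class _VariantFactory:
    """Mints unique variants; errors when a gene's position pool runs dry."""

    _POOL = 5000  # distinct cDNA positions per gene

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._used: dict[str, set[int]] = {}
        self._gene_pos: dict[str, int] = {}

    def _position(self, gene: str) -> int:
        used = self._used.setdefault(gene, set())
        if len(used) >= self._POOL:
            raise ValueError(
                f"variant pool exhausted for gene {gene}: the configuration "
                f"demands more than {self._POOL} distinct variants"
            )
        while True:
            pos = int(self.rng.integers(1, self._POOL + 1))
            if pos not in used:
                used.add(pos)
                return pos

    def _locus(self, gene: str) -> int:
        if gene not in self._gene_pos:
            self._gene_pos[gene] = 1_000_000 * (len(self._gene_pos) + 1)
        return self._gene_pos[gene]

    def mint(
        self,
        gene: str,
        consequence: str,
        predictor_calls: PredictorCalls,
        maf: float | None,
        intron_offset: int = 0,
    ) -> VariantRecord:
        cpos = self._position(gene)
        ref, alt = self.rng.choice(_BASES, size=2, replace=False)
        offset = f"{intron_offset:+d}" if intron_offset else ""
        cdna = f"c.{cpos}{offset}{ref}>{alt}"
        evidence = ()
        if maf is not None:
            an = 120_000
            ac = max(0, int(round(maf * an)))
            evidence = (FrequencyEvidence(source="ExAC", allele_count=ac, allele_number=an),)
        protein = f"p.X{cpos}Y" if consequence == "missense" else ""
        return VariantRecord(
            variant_id=f"{gene}:{cdna}",
            gene=gene,
            chrom="1",
            pos=self._locus(gene) + cpos,
            ref=str(ref),
            alt=str(alt),
            cdna_name=cdna,
            protein_name=protein,
            consequence=consequence,
            splice_flag=False,
            freq_evidence=evidence,
            predictor_calls=predictor_calls,
            reported_status="novel",
        )


_DAMAGING = PredictorCalls(polyphen="PrD", sift="D", provean="D")
_BENIGN = PredictorCalls(polyphen="B", sift="T", provean="N")
_NOT_APPLICABLE = PredictorCalls()


def _rare_maf(rng: np.random.Generator) -> float | None:
    # half the rare variants have no population observation at all
    if rng.random() < 0.5:
        return None
    return float(rng.uniform(0.0, 0.009))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort under ``config``; see the module docstring.

    Solved probands come first in the id sequence (``SIMxxxx``); each gets a
    trio pedigree with unaffected carrier parents arranged in trans.
    ``n_cis_control_families`` adds extra families *outside* the cohort
    count whose proband carries both heterozygotes inherited in cis from one
    parent — a negative control for the segregation checker.
    """
    rng = np.random.default_rng(config.seed)
    panel = dict(config.panel) if config.panel is not None else load_builtin_panel("full")
    ar_genes = sorted(g for g, e in panel.items() if e.recessive)
    if not ar_genes and config.n_probands and config.solved_fraction > 0:
        raise ValueError("panel has no recessive gene to plant causal genotypes in")

    factory = _VariantFactory(rng)
    variants: dict[str, VariantRecord] = {}
    genotypes: list[GenotypeCall] = []
    pedigrees: dict[str, Pedigree] = {}
    family_genotypes: dict[str, dict[str, str]] = {}
    proband_truth: dict[str, ProbandTruth] = {}
    variant_truth: dict[str, str] = {}

    n_solved = int(round(config.n_probands * config.solved_fraction))
    n_hom = int(round(n_solved * config.hom_vs_comphet_ratio))

    def add_variant(record: VariantRecord, truth_class: str) -> str:
        variants[record.variant_id] = record
        variant_truth[record.variant_id] = truth_class
        return record.variant_id

    def plant_decoys(pid: str, causal_gene: str | None) -> None:
        d = config.decoys
        for _ in range(d.noncoding):
            csq = str(rng.choice(["synonymous", "intronic", "utr"]))
            offset = int(rng.integers(10, 300)) if csq == "intronic" else 0
            vid = add_variant(
                factory.mint(
                    str(rng.choice(ar_genes)), csq, _NOT_APPLICABLE,
                    _rare_maf(rng), intron_offset=offset,
                ),
                "decoy_step1",
            )
            genotypes.append(GenotypeCall(pid, vid, "het"))
        for _ in range(d.common):
            vid = add_variant(
                factory.mint(
                    str(rng.choice(ar_genes)), "missense", _DAMAGING,
                    float(rng.uniform(0.011, 0.5)),
                ),
                "decoy_step2",
            )
            genotypes.append(GenotypeCall(pid, vid, "het"))
        for _ in range(d.benign_missense):
            vid = add_variant(
                factory.mint(str(rng.choice(ar_genes)), "missense", _BENIGN, _rare_maf(rng)),
                "decoy_step4",
            )
            genotypes.append(GenotypeCall(pid, vid, "het"))
        # lone pathogenic hets go in distinct recessive genes, never the causal one
        eligible = [g for g in ar_genes if g != causal_gene]
        if d.lone_het > len(eligible):
            raise ValueError("more lone-het decoys requested than recessive genes available")
        if d.lone_het == 0:
            return
        lone_genes = rng.choice(len(eligible), size=d.lone_het, replace=False)
        for gi in lone_genes:
            vid = add_variant(
                factory.mint(eligible[int(gi)], "missense", _DAMAGING, _rare_maf(rng)),
                "decoy_step3",
            )
            genotypes.append(GenotypeCall(pid, vid, "het"))

    def make_trio(pid: str, carried: dict[str, dict[str, str]]) -> None:
        """carried: parent role -> {variant_id: zygosity}."""
        father, mother = f"{pid}-F", f"{pid}-M"
        pedigrees[pid] = Pedigree(
            family_id=pid,
            individuals={
                father: Individual(father, sex="male", affected="unaffected"),
                mother: Individual(mother, sex="female", affected="unaffected"),
                pid: Individual(
                    pid, sex=str(rng.choice(["male", "female"])),
                    affected="affected", father_id=father, mother_id=mother,
                ),
            },
        )
        family_genotypes[father] = carried["father"]
        family_genotypes[mother] = carried["mother"]

    for i in range(config.n_probands):
        pid = f"SIM{i:04d}"
        if i < n_hom:
            gene = str(rng.choice(ar_genes))
            vid = add_variant(
                factory.mint(gene, "missense", _DAMAGING, _rare_maf(rng)), "causal"
            )
            genotypes.append(GenotypeCall(pid, vid, "hom"))
            proband_truth[pid] = ProbandTruth(pid, "solved_homozygous", gene, (vid,))
            make_trio(pid, {"father": {vid: "het"}, "mother": {vid: "het"}})
            family_genotypes[pid] = {vid: "hom"}
            plant_decoys(pid, gene)
        elif i < n_solved:
            gene = str(rng.choice(ar_genes))
            vid_a = add_variant(
                factory.mint(gene, "missense", _DAMAGING, _rare_maf(rng)), "causal"
            )
            vid_b = add_variant(
                factory.mint(gene, "nonsense", _NOT_APPLICABLE, _rare_maf(rng)), "causal"
            )
            genotypes.append(GenotypeCall(pid, vid_a, "het"))
            genotypes.append(GenotypeCall(pid, vid_b, "het"))
            proband_truth[pid] = ProbandTruth(
                pid, "solved_compound_het", gene, (vid_a, vid_b)
            )
            make_trio(pid, {"father": {vid_a: "het"}, "mother": {vid_b: "het"}})
            family_genotypes[pid] = {vid_a: "het", vid_b: "het"}
            plant_decoys(pid, gene)
        else:
            proband_truth[pid] = ProbandTruth(pid, "unsolved", None, ())
            plant_decoys(pid, None)

    cis_controls: dict[str, ProbandTruth] = {}
    for i in range(config.n_cis_control_families):
        pid = f"CIS{i:04d}"
        gene = str(rng.choice(ar_genes))
        vid_a = add_variant(factory.mint(gene, "missense", _DAMAGING, None), "causal")
        vid_b = add_variant(factory.mint(gene, "missense", _DAMAGING, None), "causal")
        # both candidates on one parental haplotype: the proband genotype
        # looks compound het but transmission is cis
        make_trio(pid, {"father": {vid_a: "het", vid_b: "het"}, "mother": {}})
        family_genotypes[pid] = {vid_a: "het", vid_b: "het"}
        cis_controls[pid] = ProbandTruth(pid, "cis_control", gene, (vid_a, vid_b))

    return SimulatedCohort(
        config=config,
        variants=variants,
        genotypes=genotypes,
        pedigrees=pedigrees,
        family_genotypes=family_genotypes,
        proband_truth=proband_truth,
        variant_truth=variant_truth,
        cis_controls=cis_controls,
    )
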