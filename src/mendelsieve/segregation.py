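"""Pedigree co-segregation checks for recessive candidate genotypes.

Given a proband whose diagnosis hypothesis is a homozygote or a compound
heterozygote (two variants presumed trans) in a recessive gene, genotyped
relatives either support, contradict or fail to constrain the hypothesis:

(a) each genotyped *unaffected parent* must carry exactly one of the two
    candidate alleles (which simultaneously establishes the trans phase) —
    a parent carrying both places them cis, a parent carrying neither would
    require a de novo event;
(b) each genotyped *affected relative* must carry the full candidate
    genotype;
(c) each genotyped *unaffected relative* must not — complete penetrance is
    assumed, as appropriate for juvenile-onset macular dystrophy.

Relative genotypes follow the cohort convention: an individual present in
the genotype mapping is considered genotyped, and any candidate variant
missing from that individual's entry is reference.  Individuals absent from
the mapping are ungenotyped and never influence the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import Pedigree

__all__ = ["SegregationVerdict", "check_recessive_segregation"]

#: individual_id -> {variant_id: "het" | "hom"}
GenotypeMap = Mapping[str, Mapping[str, str]]


@dataclass(frozen=True)
class SegregationVerdict:
    verdict: str  # consistent | inconsistent | uninformative
    violated_rule: str | None = None
    notes: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()
    phase_established: bool = False

    def __post_init__(self) -> None:
        if self.verdict not in ("consistent", "inconsistent", "uninformative"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "inconsistent" and self.violated_rule is None:
            raise ValueError("inconsistent verdict must name the violated rule")


def _carried(genotypes: GenotypeMap, individual_id: str, variant_ids: Sequence[str]) -> set[str]:
    entry = genotypes.get(individual_id, {})
    return {v for v in variant_ids if entry.get(v) in ("het", "hom")}


def _carries_full_genotype(
    genotypes: GenotypeMap, individual_id: str, variant_ids: Sequence[str]
) -> bool:
    entry = genotypes.get(individual_id, {})
    if len(variant_ids) == 1:  # homozygous hypothesis
        return entry.get(variant_ids[0]) == "hom"
    return all(entry.get(v) in ("het", "hom") for v in variant_ids)


def check_recessive_segregation(
    pedigree: Pedigree,
    genotypes: GenotypeMap,
    proband_id: str,
    candidate_variant_ids: Sequence[str],
    allow_denovo: bool = False,
) -> SegregationVerdict:
    """Test a biallelic candidate genotype against genotyped relatives.

    ``candidate_variant_ids`` holds two variant ids (compound-het
    hypothesis) or one (homozygous hypothesis).  ``allow_denovo`` downgrades
    a parent carrying neither allele from a violation to a warning.
    Raises ``KeyError`` if the proband is not in the pedigree.
    """
    candidates = list(dict.fromkeys(candidate_variant_ids))
    if len(candidates) not in (1, 2):
        raise ValueError("expected one (hom) or two (compound het) candidate variants")
    relatives = pedigree.relatives_of(proband_id)  # raises if proband absent
    genotyped = [r for r in relatives if r.individual_id in genotypes]

    notes: list[str] = []
    warnings: list[str] = []
    phase_established = False

    if not genotyped:
        return SegregationVerdict(
            "uninformative", notes=("no genotyped relative constrains the hypothesis",)
        )

    if proband_id in genotypes and not _carries_full_genotype(genotypes, proband_id, candidates):
        return SegregationVerdict(
            "inconsistent",
            violated_rule="proband",
            notes=("proband's own genotype lacks the candidate alleles",),
        )

    parent_ids = {p.individual_id for p in pedigree.parents_of(proband_id)}
    hom_hypothesis = len(candidates) == 1
    parental_origins: set[frozenset[str]] = set()
    n_informative = 0

    for rel in genotyped:
        rid = rel.individual_id
        carried = _carried(genotypes, rid, candidates)
        is_parent = rid in parent_ids

        if is_parent and rel.affected != "affected":
            n_informative += 1
            if hom_hypothesis:
                if genotypes.get(rid, {}).get(candidates[0]) == "hom":
                    return SegregationVerdict(
                        "inconsistent",
                        violated_rule="c",
                        notes=(f"unaffected parent {rid} is homozygous for the candidate",),
                    )
                if not carried:
                    if allow_denovo:
                        warnings.append(f"parent {rid} carries no candidate allele (de novo?)")
                    else:
                        return SegregationVerdict(
                            "inconsistent",
                            violated_rule="a",
                            notes=(f"parent {rid} carries neither candidate allele",),
                        )
                else:
                    notes.append(f"parent {rid} is a heterozygous carrier")
            else:
                if len(carried) == 2:
                    return SegregationVerdict(
                        "inconsistent",
                        violated_rule="a",
                        notes=(
                            f"unaffected parent {rid} carries both candidates: "
                            "cis configuration",
                        ),
                    )
                if len(carried) == 0:
                    if allow_denovo:
                        warnings.append(f"parent {rid} carries no candidate allele (de novo?)")
                    else:
                        return SegregationVerdict(
                            "inconsistent",
                            violated_rule="a",
                            notes=(f"parent {rid} carries neither candidate allele",),
                        )
                else:
                    parental_origins.add(frozenset(carried))
                    notes.append(f"parent {rid} carries only {next(iter(carried))}")
            continue

        if rel.affected == "affected":
            n_informative += 1
            if not _carries_full_genotype(genotypes, rid, candidates):
                return SegregationVerdict(
                    "inconsistent",
                    violated_rule="b",
                    notes=(f"affected relative {rid} lacks the candidate genotype",),
                )
            notes.append(f"affected relative {rid} carries the full candidate genotype")
        elif rel.affected == "unaffected":
            n_informative += 1
            if _carries_full_genotype(genotypes, rid, candidates):
                return SegregationVerdict(
                    "inconsistent",
                    violated_rule="c",
                    notes=(f"unaffected relative {rid} carries the full candidate genotype",),
                )
            notes.append(f"unaffected relative {rid} does not carry both alleles")
        else:
            notes.append(f"relative {rid} of unknown affection status: not constraining")

    if n_informative == 0:
        return SegregationVerdict(
            "uninformative",
            notes=tuple(notes) + ("no genotyped relative constrains the hypothesis",),
        )

    if not hom_hypothesis and len(parental_origins) == 2:
        phase_established = True
        notes.append("parents carry one candidate each: trans phase established")
    if hom_hypothesis and len([r for r in genotyped if r.individual_id in parent_ids]) == 2:
        phase_established = True

    return SegregationVerdict(
        "consistent",
        notes=tuple(notes),
        warnings=tuple(warnings),
        phase_established=phase_established,
    )
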