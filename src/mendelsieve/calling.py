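"""Diagnosis calling from the cascade's surviving candidates.

A proband is *solved* when a panel gene explains the phenotype under its
inheritance mode: a homozygous candidate or two distinct heterozygous
candidates in a recessive gene (presumed trans until pedigree evidence says
otherwise), or any candidate in a dominant gene.  Probands that narrowly
miss are graded into the two *partial* states clinicians distinguish:

* ``partial_one_pathogenic`` — the gene had two or more rare heterozygous
  variants, but only one survived the pathogenicity consensus;
* ``partial_single_het`` — only a single rare heterozygous variant was ever
  seen in the gene.

Both read the filter trace: the lone het itself is removed at step 3, so the
distinction is whether its gene group also lost variants at step 4.
Everything else is ``unsolved``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .filters import CascadeResult
from .model import GenePanelEntry, GenotypeCall, VariantRecord

__all__ = ["SOLVED_STATUSES", "ProbandClassification", "call_proband", "classify_cohort"]

SOLVED_STATUSES = ("solved_homozygous", "solved_compound_het", "solved_dominant")
PARTIAL_STATUSES = ("partial_one_pathogenic", "partial_single_het")
ALL_STATUSES = SOLVED_STATUSES + PARTIAL_STATUSES + ("unsolved",)


@dataclass(frozen=True)
class ProbandClassification:
    proband_id: str
    status: str
    causal_gene: str | None = None
    candidate_variant_ids: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ALL_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status in SOLVED_STATUSES:
            if self.causal_gene is None:
                raise ValueError(f"{self.proband_id}: solved call needs a causal gene")
            n = len(set(self.candidate_variant_ids))
            if self.status == "solved_homozygous" and n < 1:
                raise ValueError(f"{self.proband_id}: homozygous call needs >= 1 variant")
            if self.status == "solved_compound_het" and n < 2:
                raise ValueError(
                    f"{self.proband_id}: compound het call needs >= 2 distinct variants"
                )
        if self.status == "unsolved" and self.candidate_variant_ids:
            raise ValueError(f"{self.proband_id}: unsolved call must have no candidates")

    @property
    def solved(self) -> bool:
        return self.status in SOLVED_STATUSES


def _gene_rank_key(panel: Mapping[str, GenePanelEntry]):
    def key(gene: str) -> tuple[int, str]:
        entry = panel.get(gene)
        stgd_first = 0 if entry is not None and entry.phenotype_group == "STGD" else 1
        return (stgd_first, gene)

    return key


def _gene_verdict(
    entry: GenePanelEntry, calls: list[GenotypeCall]
) -> tuple[str, list[str]] | None:
    """Solved status for one on-panel gene group of surviving candidates."""
    homs = sorted({c.variant_id for c in calls if c.zygosity == "hom"})
    hets = sorted({c.variant_id for c in calls if c.zygosity == "het"})
    if entry.inheritance_mode in ("AR", "AR_AD"):
        if homs:
            return "solved_homozygous", homs + hets
        if len(hets) >= 2:
            return "solved_compound_het", hets
    if entry.inheritance_mode in ("AD", "AR_AD") and (homs or hets):
        return "solved_dominant", homs + hets
    return None


def call_proband(
    proband_id: str,
    survivors: Iterable[GenotypeCall],
    variants: Mapping[str, VariantRecord],
    panel: Mapping[str, GenePanelEntry],
    trace_statuses: Mapping[tuple[str, str], str] | None = None,
) -> ProbandClassification:
    """Classify one proband from its surviving candidate genotypes.

    ``trace_statuses`` (pair -> filter-trace status) enables the partial
    states; without it a candidate-free proband is simply unsolved.  When
    several genes qualify, all their candidates are reported, the status
    comes from the best-ranked gene (STGD phenotype-group genes first, then
    alphabetically) and a ``multi-gene`` flag is raised.
    """
    by_gene: dict[str, list[GenotypeCall]] = defaultdict(list)
    flags: list[str] = []
    for call in survivors:
        if call.proband_id != proband_id:
            raise ValueError(f"call for {call.proband_id!r} passed to {proband_id!r}")
        gene = variants[call.variant_id].gene
        if gene not in panel:
            if "off-panel-candidates" not in flags:
                flags.append("off-panel-candidates")
            continue
        by_gene[gene].append(call)

    rank = _gene_rank_key(panel)
    verdicts: dict[str, tuple[str, list[str]]] = {}
    for gene, calls in by_gene.items():
        verdict = _gene_verdict(panel[gene], calls)
        if verdict is not None:
            verdicts[gene] = verdict

    if verdicts:
        ordered = sorted(verdicts, key=rank)
        best = ordered[0]
        status, _ = verdicts[best]
        if status == "solved_dominant":
            flags.append("dominant")
        if len(ordered) > 1:
            flags.append("multi-gene")
        candidates = [vid for gene in ordered for vid in verdicts[gene][1]]
        return ProbandClassification(
            proband_id=proband_id,
            status=status,
            causal_gene=best,
            candidate_variant_ids=tuple(candidates),
            flags=tuple(flags),
        )

    # no solved gene: grade near-misses (lone hets in recessive genes)
    lone_het_by_gene: dict[str, list[str]] = defaultdict(list)
    step4_genes: set[str] = set()
    for gene, calls in by_gene.items():
        hets = sorted({c.variant_id for c in calls if c.zygosity == "het"})
        if panel[gene].recessive and len(hets) == 1:
            lone_het_by_gene[gene] = hets
    if trace_statuses:
        for (pid, vid), status in trace_statuses.items():
            if pid != proband_id or vid not in variants:
                continue
            gene = variants[vid].gene
            if status == "removed_step3":
                lone_het_by_gene.setdefault(gene, []).append(vid)
            elif status == "removed_step4":
                step4_genes.add(gene)
    partial: list[tuple[str, str, list[str]]] = []
    for gene, vids in lone_het_by_gene.items():
        kind = "partial_one_pathogenic" if gene in step4_genes else "partial_single_het"
        partial.append((kind, gene, vids))
    if partial:
        partial.sort(key=lambda t: (PARTIAL_STATUSES.index(t[0]), rank(t[1])))
        kind, gene, vids = partial[0]
        return ProbandClassification(
            proband_id=proband_id,
            status=kind,
            causal_gene=gene,
            candidate_variant_ids=tuple(sorted(set(vids))),
            flags=tuple(flags),
        )

    return ProbandClassification(proband_id=proband_id, status="unsolved", flags=tuple(flags))


def classify_cohort(
    cascade: CascadeResult,
    variants: Mapping[str, VariantRecord],
    genotypes: Iterable[GenotypeCall],
    panel: Mapping[str, GenePanelEntry],
) -> list[ProbandClassification]:
    """One classification per proband appearing in the genotype table.

    Probands whose every variant was filtered away are classified too
    (partial or unsolved), so cohort denominators match the genotype table.
    Output is sorted by proband id.
    """
    probands = sorted({c.proband_id for c in genotypes})
    by_proband: dict[str, list[GenotypeCall]] = defaultdict(list)
    for call in cascade.survivors:
        by_proband[call.proband_id].append(call)
    trace_statuses = {k: d.status for k, d in cascade.trace.decisions.items()}
    return [
        call_proband(pid, by_proband.get(pid, []), variants, panel, trace_statuses)
        for pid in probands
    ]
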