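"""The four-step exclusion cascade.

Exome variants restricted to the virtual panel are whittled down by four
rules, each mirroring a step a diagnostic analyst applies by hand:

1. drop non-coding or synonymous variants unless a splice site is affected;
2. drop variants with minor allele frequency > 0.01 in any population source;
3. drop *single* heterozygous variants in genes inherited recessively;
4. drop missense/in-frame variants unanimously called benign by all three
   in-silico predictors.

Steps 1, 2 and 4 are per-variant predicates and commute; step 3 depends on
which variants of a proband-gene group are still standing, so it is applied
to the group surviving steps 1/2/4 (a lone het accompanied only by
later-excluded variants is still a lone het in the final accounting).
Removal labels keep the analyst-facing step numbers.

Every (proband, variant) input pair receives exactly one trace entry, either
``retained`` or ``removed_stepK`` with a human-readable reason.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .hgvs import HgvsParseError, is_canonical_splice, parse_hgvs_c
from .model import (
    NONCODING_OR_SILENT,
    TRUNCATING,
    GenePanelEntry,
    GenotypeCall,
    VariantRecord,
    max_allele_frequency,
)

__all__ = [
    "DEFAULT_MAF_THRESHOLD",
    "FilterDecision",
    "FilterTrace",
    "CascadeResult",
    "step1_consequence",
    "step2_frequency",
    "step3_recessive_zygosity",
    "step4_benign_consensus",
    "run_cascade",
]

DEFAULT_MAF_THRESHOLD = 0.01

STATUSES = (
    "retained",
    "removed_step1",
    "removed_step2",
    "removed_step3",
    "removed_step4",
)


@dataclass(frozen=True)
class FilterDecision:
    status: str
    reason: str


@dataclass
class FilterTrace:
    """Audit trail: one decision per (proband_id, variant_id) input pair."""

    decisions: dict[tuple[str, str], FilterDecision] = field(default_factory=dict)

    def record(self, proband_id: str, variant_id: str, status: str, reason: str) -> None:
        key = (proband_id, variant_id)
        if key in self.decisions:
            raise ValueError(f"duplicate trace entry for {key}")
        if status not in STATUSES:
            raise ValueError(f"unknown trace status {status!r}")
        self.decisions[key] = FilterDecision(status, reason)

    def status_of(self, proband_id: str, variant_id: str) -> str:
        return self.decisions[(proband_id, variant_id)].status

    def pairs_with_status(self, status: str) -> set[tuple[str, str]]:
        return {k for k, d in self.decisions.items() if d.status == status}

    @property
    def retained_pairs(self) -> set[tuple[str, str]]:
        return self.pairs_with_status("retained")

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for d in self.decisions.values():
            out[d.status] += 1
        return out


@dataclass
class CascadeResult:
    trace: FilterTrace
    survivors: list[GenotypeCall]
    off_panel_genes: set[str] = field(default_factory=set)

    @property
    def survivor_pairs(self) -> set[tuple[str, str]]:
        return {(c.proband_id, c.variant_id) for c in self.survivors}


def _splice_rescued(variant: VariantRecord) -> bool:
    if variant.splice_flag:
        return True
    try:
        return is_canonical_splice(parse_hgvs_c(variant.cdna_name))
    except HgvsParseError:
        warnings.warn(
            f"{variant.variant_id}: unparseable cDNA name {variant.cdna_name!r}; "
            "no splice rescue applied"
        )
        return False


def step1_consequence(variant: VariantRecord) -> bool:
    """Keep unless non-coding/synonymous without any splice-site effect."""
    if variant.consequence not in NONCODING_OR_SILENT:
        return True
    return _splice_rescued(variant)


def step2_frequency(variant: VariantRecord, threshold: float = DEFAULT_MAF_THRESHOLD) -> bool:
    """Keep unless any population source shows MAF strictly above threshold.

    A variant with no frequency observation anywhere is kept: rare until
    proven common.  MAF exactly at the threshold is kept (the exclusion rule
    is a strict inequality).
    """
    maf = max_allele_frequency(variant)
    return maf is None or maf <= threshold


def step4_benign_consensus(variant: VariantRecord) -> bool:
    """Keep unless all three predictors agree the variant is benign.

    Applies only to missense and in-frame indels: truncating and
    splice-affecting variants are damaging by mechanism and bypass the
    predictors (they are typically 'not applicable' there anyway).  An NA
    never counts toward the benign consensus — a variant cannot be excluded
    on missing evidence.
    """
    if variant.consequence in TRUNCATING or variant.consequence == "splice_site":
        return True
    if variant.consequence not in ("missense", "inframe_indel"):
        return True
    return not variant.predictor_calls.unanimously_benign


def step3_recessive_zygosity(
    gene_entry: GenePanelEntry | None, calls: Iterable[GenotypeCall]
) -> dict[tuple[str, str], bool]:
    """Apply the single-heterozygote exclusion to one proband-gene group.

    For a strictly recessive gene the whole group is dropped when it carries
    exactly one heterozygous variant and no homozygote; two or more distinct
    heterozygotes (a potential compound heterozygote) or any homozygote keep
    the group.  Dominant and dual-mode genes always keep.  Returns keep/drop
    per (proband_id, variant_id) pair.
    """
    calls = list(calls)
    keep_group = True
    if gene_entry is not None and gene_entry.recessive:
        n_hom = sum(1 for c in calls if c.zygosity == "hom")
        distinct_het = {c.variant_id for c in calls if c.zygosity == "het"}
        if n_hom == 0 and len(distinct_het) == 1:
            keep_group = False
    return {(c.proband_id, c.variant_id): keep_group for c in calls}


def run_cascade(
    variants: Mapping[str, VariantRecord],
    genotypes: Iterable[GenotypeCall],
    panel: Mapping[str, GenePanelEntry],
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> CascadeResult:
    """Run the four exclusion steps over a cohort.

    Per-variant steps run in the order 1, 2, 4 (first failing step is the
    one recorded); the group-level step 3 runs on the per-proband-per-gene
    survivors.  Variants in genes absent from the panel pass through steps
    1/2/4 but are exempt from step 3 and reported in ``off_panel_genes``.
    """
    trace = FilterTrace()
    genotypes = list(genotypes)
    off_panel: set[str] = set()

    # per-variant verdicts, computed once per distinct variant
    variant_fate: dict[str, FilterDecision | None] = {}
    for vid in {c.variant_id for c in genotypes}:
        v = variants[vid]
        if not step1_consequence(v):
            variant_fate[vid] = FilterDecision(
                "removed_step1", f"{v.consequence} without splice-site effect"
            )
        elif not step2_frequency(v, maf_threshold):
            variant_fate[vid] = FilterDecision(
                "removed_step2",
                f"minor allele frequency {max_allele_frequency(v):.4g} > {maf_threshold:g}",
            )
        elif not step4_benign_consensus(v):
            variant_fate[vid] = FilterDecision(
                "removed_step4", "predicted benign by all three tools"
            )
        else:
            variant_fate[vid] = None  # survives per-variant steps

    groups: dict[tuple[str, str], list[GenotypeCall]] = defaultdict(list)
    for call in genotypes:
        fate = variant_fate[call.variant_id]
        if fate is not None:
            trace.record(call.proband_id, call.variant_id, fate.status, fate.reason)
            continue
        gene = variants[call.variant_id].gene
        if gene not in panel:
            off_panel.add(gene)
        groups[(call.proband_id, gene)].append(call)

    survivors: list[GenotypeCall] = []
    for (proband_id, gene), calls in groups.items():
        entry = panel.get(gene)
        verdicts = step3_recessive_zygosity(entry, calls)
        for call in calls:
            if verdicts[(call.proband_id, call.variant_id)]:
                reason = "passed all four steps"
                if entry is None:
                    reason += " (off-panel gene, recessive rule not applied)"
                trace.record(call.proband_id, call.variant_id, "retained", reason)
                survivors.append(call)
            else:
                trace.record(
                    call.proband_id,
                    call.variant_id,
                    "removed_step3",
                    f"single heterozygous variant in recessive gene {gene}",
                )
    return CascadeResult(trace=trace, survivors=survivors, off_panel_genes=off_panel)
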