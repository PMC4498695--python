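"""Cohort-level tallies and the per-variant report table.

``summarize`` produces the numbers a cohort study quotes in its results:
solved counts and percentage, the homozygous vs compound-het split,
and distinct / novel / known variant tallies over solved probands'
candidates.  ``write_variant_report`` renders a per-(proband, variant)
table with predictor calls, per-source frequencies and control-screen
counts, in the style of a published variant table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from .calling import ProbandClassification
from .model import VariantRecord

__all__ = ["CohortSummary", "summarize", "write_variant_report"]


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    n_probands: int
    n_solved: int
    pct_solved: float
    n_hom_probands: int
    n_comphet_probands: int
    n_dominant_probands: int
    n_partial_one_pathogenic: int
    n_partial_single_het: int
    n_unsolved: int
    n_distinct_variants: int
    n_novel: int
    n_known: int
    per_gene_solved: dict[str, int] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_solved != (
            self.n_hom_probands + self.n_comphet_probands + self.n_dominant_probands
        ):
            raise ValueError("solved count does not equal sum of its parts")
        if self.n_novel + self.n_known != self.n_distinct_variants:
            raise ValueError("novel + known must equal distinct variants")
        if not 0.0 <= self.pct_solved <= 100.0:
            raise ValueError("pct_solved outside [0, 100]")

    def to_dict(self) -> dict:
        return {
            "n_probands": self.n_probands,
            "n_solved": self.n_solved,
            "pct_solved": self.pct_solved,
            "n_hom_probands": self.n_hom_probands,
            "n_comphet_probands": self.n_comphet_probands,
            "n_dominant_probands": self.n_dominant_probands,
            "n_partial_one_pathogenic": self.n_partial_one_pathogenic,
            "n_partial_single_het": self.n_partial_single_het,
            "n_unsolved": self.n_unsolved,
            "n_distinct_variants": self.n_distinct_variants,
            "n_novel": self.n_novel,
            "n_known": self.n_known,
            "per_gene_solved": dict(sorted(self.per_gene_solved.items())),
            "flags": list(self.flags),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize(
    classifications: Iterable[ProbandClassification],
    variants: Mapping[str, VariantRecord],
) -> CohortSummary:
    """Tally a classified cohort.

    Distinct variants are counted by variant id over *solved* probands'
    candidate sets (an allele shared by several solved probands counts
    once).  The solved percentage is rounded half-up to one decimal.  An
    empty cohort yields all-zero tallies with an ``empty-cohort`` flag.
    """
    classifications = list(classifications)
    n = len(classifications)
    status_counts = {s: 0 for s in (
        "solved_homozygous", "solved_compound_het", "solved_dominant",
        "partial_one_pathogenic", "partial_single_het", "unsolved",
    )}
    solved_variant_ids: set[str] = set()
    per_gene: dict[str, int] = {}
    for c in classifications:
        status_counts[c.status] += 1
        if c.solved:
            solved_variant_ids.update(c.candidate_variant_ids)
            if c.causal_gene:
                per_gene[c.causal_gene] = per_gene.get(c.causal_gene, 0) + 1
    n_solved = (
        status_counts["solved_homozygous"]
        + status_counts["solved_compound_het"]
        + status_counts["solved_dominant"]
    )
    n_novel = sum(1 for v in solved_variant_ids if variants[v].reported_status == "novel")
    flags: tuple[str, ...] = ()
    if n == 0:
        pct = 0.0
        flags = ("empty-cohort",)
    else:
        pct = _round_half_up_1dp(100.0 * n_solved / n)
    return CohortSummary(
        n_probands=n,
        n_solved=n_solved,
        pct_solved=pct,
        n_hom_probands=status_counts["solved_homozygous"],
        n_comphet_probands=status_counts["solved_compound_het"],
        n_dominant_probands=status_counts["solved_dominant"],
        n_partial_one_pathogenic=status_counts["partial_one_pathogenic"],
        n_partial_single_het=status_counts["partial_single_het"],
        n_unsolved=status_counts["unsolved"],
        n_distinct_variants=len(solved_variant_ids),
        n_novel=n_novel,
        n_known=len(solved_variant_ids) - n_novel,
        per_gene_solved=per_gene,
        flags=flags,
    )


_REPORT_COLUMNS = [
    "proband_id",
    "gene",
    "nucleotide_change",
    "amino_acid_change",
    "state",
    "polyphen",
    "provean",
    "sift",
]


def _render_frequency(variant: VariantRecord, source: str) -> str:
    for ev in variant.freq_evidence:
        if ev.source == source:
            if ev.maf is not None:
                return f"{ev.maf:g}"
            return f"{ev.allele_count}/{ev.allele_number}"
    return "NA"


def write_variant_report(
    variants: Mapping[str, VariantRecord],
    classifications: Iterable[ProbandClassification],
    path: str | Path,
    control_screens: Mapping[str, Mapping[str, str]] | None = None,
    zygosities: Mapping[tuple[str, str], str] | None = None,
) -> None:
    """Write the per-variant candidate table as TSV.

    One row per (solved proband, candidate variant), ordered by proband id
    then variant id (partial probands' near-miss candidates belong in a
    separate supplement, not the causative-variant table).  Frequency columns are derived from the
    union of sources present; counts render as ``ac/an`` and mafs as plain
    numbers.  ``control_screens`` maps variant_id -> {column: rendered
    count}, e.g. ``{"NC": "0/192", "RC": "0/456"}``, written verbatim.
    ``zygosities`` maps (proband_id, variant_id) -> het/hom for the state
    column (NA when absent).
    """
    classifications = sorted(classifications, key=lambda c: c.proband_id)
    rows = [
        (c.proband_id, vid)
        for c in classifications
        if c.solved
        for vid in sorted(set(c.candidate_variant_ids))
    ]
    sources = sorted({ev.source for (_, vid) in rows for ev in variants[vid].freq_evidence})
    screen_cols: list[str] = []
    if control_screens:
        seen: set[str] = set()
        for cols in control_screens.values():
            seen.update(cols)
        screen_cols = sorted(seen)
    header = _REPORT_COLUMNS + sources + screen_cols + ["reported"]
    lines = ["\t".join(header)]
    for proband_id, vid in rows:
        v = variants[vid]
        state = (zygosities or {}).get((proband_id, vid), "NA")
        cells = [
            proband_id,
            v.gene,
            v.cdna_name,
            v.protein_name or ("Splicing defect" if v.consequence == "splice_site" else "NA"),
            state,
            v.predictor_calls.polyphen if not v.splice_flag else "SSA",
            v.predictor_calls.provean,
            v.predictor_calls.sift,
        ]
        cells += [_render_frequency(v, s) for s in sources]
        screens = (control_screens or {}).get(vid, {})
        cells += [screens.get(col, "-") for col in screen_cols]
        cells.append(v.reported_status)
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
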