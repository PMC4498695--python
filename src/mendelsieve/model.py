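"""Domain types for panel-based variant prioritization.

The central objects are annotated variant alleles (:class:`VariantRecord`),
per-proband genotype observations (:class:`GenotypeCall`), the virtual gene
panel (:class:`GenePanelEntry`) and family structure (:class:`Pedigree`).
Everything downstream (filtering, diagnosis calling, segregation, reporting)
consumes these.

Conventions
-----------
* Genomic coordinates are 1-based, VCF-style.
* A (proband, variant) pair absent from the genotype table means the proband
  is homozygous reference for that variant.
* A frequency source that reports nothing is *no observation*, never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "CONSEQUENCES",
    "NONCODING_OR_SILENT",
    "TRUNCATING",
    "EvidenceError",
    "FrequencyEvidence",
    "PredictorCalls",
    "VariantRecord",
    "GenotypeCall",
    "GenePanelEntry",
    "Individual",
    "Pedigree",
    "max_allele_frequency",
]

#: Exactly one of these per variant.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "synonymous",
        "splice_site",
        "intronic",
        "utr",
        "other_noncoding",
    }
)

#: Classes that do not alter the protein unless a splice site is hit.
NONCODING_OR_SILENT = frozenset({"synonymous", "intronic", "utr", "other_noncoding"})

#: Protein-truncating classes; these bypass the in-silico benign consensus.
TRUNCATING = frozenset({"nonsense", "frameshift"})

POLYPHEN_TOKENS = frozenset({"PrD", "PoD", "B", "NA"})
SIFT_TOKENS = frozenset({"D", "T", "NA"})
PROVEAN_TOKENS = frozenset({"D", "N", "NA"})

INHERITANCE_MODES = frozenset({"AR", "AD", "AR_AD"})
ZYGOSITIES = frozenset({"het", "hom"})
REPORTED_STATUSES = frozenset({"novel", "known"})


class EvidenceError(ValueError):
    """Malformed population-frequency evidence (e.g. allele_number of 0)."""


def _normalize_token(value: str, vocabulary: frozenset[str], predictor: str) -> str:
    if value in vocabulary:
        return value
    warnings.warn(
        f"unrecognized {predictor} call {value!r}: stored as NA",
        stacklevel=3,
    )
    return "NA"


@dataclass(frozen=True)
class PredictorCalls:
    """Categorical calls from the three missense predictors.

    PolyPhen-2: PrD (probably damaging) / PoD (possibly damaging) / B (benign);
    SIFT: D (damaging) / T (tolerated); PROVEAN: D (damaging) / N (neutral).
    NA means the tool was not applicable or not run.  Any token outside the
    vocabulary is coerced to NA with a warning.
    """

    polyphen: str = "NA"
    sift: str = "NA"
    provean: str = "NA"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "polyphen", _normalize_token(self.polyphen, POLYPHEN_TOKENS, "PolyPhen")
        )
        object.__setattr__(self, "sift", _normalize_token(self.sift, SIFT_TOKENS, "SIFT"))
        object.__setattr__(
            self, "provean", _normalize_token(self.provean, PROVEAN_TOKENS, "PROVEAN")
        )

    @property
    def unanimously_benign(self) -> bool:
        """True iff all three calls are present and benign-class."""
        return self.polyphen == "B" and self.sift == "T" and self.provean == "N"

    @property
    def any_damaging(self) -> bool:
        return self.polyphen in ("PrD", "PoD") or self.sift == "D" or self.provean == "D"


@dataclass(frozen=True)
class FrequencyEvidence:
    """One population source's allele-frequency observation.

    Either allele counts (``allele_count``/``allele_number``) or a
    pre-computed ``maf`` is given, never both.
    """

    source: str
    allele_count: int | None = None
    allele_number: int | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        has_counts = self.allele_count is not None or self.allele_number is not None
        if has_counts and self.maf is not None:
            raise EvidenceError(f"{self.source}: give counts or maf, not both")
        if not has_counts and self.maf is None:
            raise EvidenceError(f"{self.source}: empty evidence entry")
        if has_counts:
            if self.allele_count is None or self.allele_number is None:
                raise EvidenceError(f"{self.source}: allele_count and allele_number go together")
            if self.allele_number == 0:
                raise EvidenceError(f"{self.source}: allele_number is 0")
            if self.allele_count < 0 or self.allele_number < 0:
                raise EvidenceError(f"{self.source}: negative allele counts")
            if self.allele_count > self.allele_number:
                raise EvidenceError(
                    f"{self.source}: allele_count {self.allele_count} exceeds "
                    f"allele_number {self.allele_number}"
                )
        elif not 0.0 <= float(self.maf) <= 1.0:  # type: ignore[arg-type]
            raise EvidenceError(f"{self.source}: maf {self.maf} outside [0, 1]")

    @property
    def frequency(self) -> float:
        if self.maf is not None:
            return float(self.maf)
        return self.allele_count / self.allele_number  # type: ignore[operator]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant allele.

    ``variant_id`` is the dataset-wide key, conventionally ``gene:cdna_name``.
    ``protein_name`` is carried through verbatim, never computed.
    ``splice_flag`` records an external splice-site predictor's verdict;
    canonical +/-1,2 offsets are additionally recognized from the cDNA name.
    """

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cdna_name: str
    protein_name: str
    consequence: str
    splice_flag: bool = False
    freq_evidence: tuple[FrequencyEvidence, ...] = ()
    predictor_calls: PredictorCalls = field(default_factory=PredictorCalls)
    reported_status: str = "novel"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt ({self.ref!r})")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.reported_status not in REPORTED_STATUSES:
            raise ValueError(
                f"{self.variant_id}: reported_status must be novel|known, "
                f"got {self.reported_status!r}"
            )
        sources = [e.source for e in self.freq_evidence]
        if len(sources) != len(set(sources)):
            raise ValueError(f"{self.variant_id}: duplicate frequency source")


def max_allele_frequency(variant: VariantRecord) -> float | None:
    """Maximum allele frequency across all population sources.

    Counts-based sources contribute allele_count/allele_number; maf-based
    sources contribute their maf.  Sources with no observation contribute
    nothing; returns ``None`` when no source has data.
    """
    freqs = [e.frequency for e in variant.freq_evidence]
    return max(freqs) if freqs else None


@dataclass(frozen=True)
class GenotypeCall:
    """Observed non-reference genotype of one proband at one variant."""

    proband_id: str
    variant_id: str
    zygosity: str

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(
                f"{self.proband_id}/{self.variant_id}: zygosity must be het|hom, "
                f"got {self.zygosity!r}"
            )


@dataclass(frozen=True)
class GenePanelEntry:
    """One virtual-panel gene with its inheritance mode."""

    gene: str
    inheritance_mode: str
    phenotype_group: str = ""

    def __post_init__(self) -> None:
        if self.inheritance_mode not in INHERITANCE_MODES:
            raise ValueError(
                f"{self.gene}: inheritance mode must be one of "
                f"{sorted(INHERITANCE_MODES)}, got {self.inheritance_mode!r}"
            )

    @property
    def recessive(self) -> bool:
        """True iff biallelic genotypes are required (strict AR)."""
        return self.inheritance_mode == "AR"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    sex: str = "unknown"  # male | female | unknown
    affected: str = "unknown"  # affected | unaffected | unknown
    father_id: str | None = None
    mother_id: str | None = None


@dataclass
class Pedigree:
    """A family: individuals plus parent links.

    Validates referential integrity (named parents exist) and acyclicity
    (nobody is their own ancestor).
    """

    family_id: str
    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.individuals.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in self.individuals:
                    raise ValueError(
                        f"{self.family_id}/{ind.individual_id}: parent {parent!r} "
                        "not in pedigree"
                    )
        for start in self.individuals:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                ind = self.individuals[cur]
                for parent in (ind.father_id, ind.mother_id):
                    if parent is None:
                        continue
                    if parent == start:
                        raise ValueError(
                            f"{self.family_id}/{start}: is its own ancestor"
                        )
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)

    def parents_of(self, individual_id: str) -> list[Individual]:
        ind = self.individuals[individual_id]
        return [
            self.individuals[p]
            for p in (ind.father_id, ind.mother_id)
            if p is not None
        ]

    def relatives_of(self, individual_id: str) -> list[Individual]:
        if individual_id not in self.individuals:
            raise KeyError(f"{individual_id!r} not in family {self.family_id}")
        return [i for k, i in self.individuals.items() if k != individual_id]
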