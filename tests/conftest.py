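"""Shared fixtures: the packaged cohort, panels, and independent oracles.

The brute-force filter here is deliberately written from scratch (flat
predicate evaluation + set subtraction, no shared helpers) so it can serve
as an independent oracle for the cascade implementation.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from mendelsieve.calling import classify_cohort
from mendelsieve.filters import run_cascade
from mendelsieve.fixtures import make_table1_fixture
from mendelsieve.model import (
    FrequencyEvidence,
    GenePanelEntry,
    GenotypeCall,
    PredictorCalls,
    VariantRecord,
)
from mendelsieve.panel import load_builtin_panel


@pytest.fixture(scope="session")
def full_panel():
    return load_builtin_panel("full")


@pytest.fixture(scope="session")
def stgd_panel():
    return load_builtin_panel("stgd")


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()


@pytest.fixture(scope="session")
def table1_pipeline(table1, full_panel):
    """Cascade + classification on the packaged cohort, run once."""
    cascade = run_cascade(table1.variants, table1.genotypes, full_panel)
    classifications = classify_cohort(cascade, table1.variants, table1.genotypes, full_panel)
    return cascade, classifications


# ---------------------------------------------------------------------------
# independent brute-force oracle for the exclusion cascade

_OFFSET_RE = re.compile(r"^c\.\d+(?:_\d+)?([+-]\d+)?")


def _oracle_splice_hit(variant: VariantRecord) -> bool:
    if variant.splice_flag:
        return True
    m = _OFFSET_RE.match(variant.cdna_name)
    if not m or m.group(1) is None:
        return False
    return abs(int(m.group(1))) in (1, 2)


def brute_force_survivors(variants, genotypes, panel, threshold=0.01):
    """Re-evaluate every exclusion predicate per pair; subtract sets."""
    pairs = {(c.proband_id, c.variant_id): c for c in genotypes}
    removed = set()
    for key, call in pairs.items():
        v = variants[call.variant_id]
        if v.consequence in ("synonymous", "intronic", "utr", "other_noncoding"):
            if not _oracle_splice_hit(v):
                removed.add(key)
                continue
        freqs = []
        for ev in v.freq_evidence:
            freqs.append(ev.maf if ev.maf is not None else ev.allele_count / ev.allele_number)
        if freqs and max(freqs) > threshold:
            removed.add(key)
            continue
        if v.consequence in ("missense", "inframe_indel"):
            p = v.predictor_calls
            if p.polyphen == "B" and p.sift == "T" and p.provean == "N":
                removed.add(key)
    survivors = {k for k in pairs if k not in removed}
    # recessive single-het rule on the surviving proband-gene groups
    groups = {}
    for pid, vid in survivors:
        groups.setdefault((pid, variants[vid].gene), []).append((pid, vid))
    for (pid, gene), members in groups.items():
        entry = panel.get(gene)
        if entry is None or entry.inheritance_mode != "AR":
            continue
        homs = [m for m in members if pairs[m].zygosity == "hom"]
        het_vids = {m[1] for m in members if pairs[m].zygosity == "het"}
        if not homs and len(het_vids) == 1:
            survivors -= set(members)
    return survivors


# ---------------------------------------------------------------------------
# random cohort generator for oracle-equivalence and property tests

_RAND_PANEL = {
    "GENEA": GenePanelEntry("GENEA", "AR", "STGD"),
    "GENEB": GenePanelEntry("GENEB", "AR"),
    "GENEC": GenePanelEntry("GENEC", "AD"),
    "GENED": GenePanelEntry("GENED", "AR_AD"),
}

_CSQ = [
    "missense", "nonsense", "frameshift", "inframe_indel",
    "synonymous", "splice_site", "intronic", "utr", "other_noncoding",
]


def random_cohort(seed: int, max_variants: int = 200):
    """An adversarial random cohort: boundary MAFs, NA-laden predictors,
    random zygosities, genes from a 4-gene panel mixing all modes."""
    rng = np.random.default_rng(seed)
    n_var = int(rng.integers(1, max_variants + 1))
    variants = {}
    for i in range(n_var):
        gene = str(rng.choice(list(_RAND_PANEL)))
        csq = str(rng.choice(_CSQ))
        offset = int(rng.choice([0, 1, 2, -1, -2, 5, -40])) if csq in ("intronic", "splice_site") else 0
        cdna = f"c.{i + 1}{offset:+d}A>G" if offset else f"c.{i + 1}A>G"
        evidence = []
        if rng.random() < 0.6:
            maf = float(rng.choice([0.0, 0.001, 0.0099, 0.01, 0.0101, 0.02, 0.3]))
            if rng.random() < 0.5:
                evidence.append(FrequencyEvidence(source="S1", maf=maf))
            else:
                an = 10_000
                evidence.append(
                    FrequencyEvidence(source="S2", allele_count=int(round(maf * an)), allele_number=an)
                )
        calls = PredictorCalls(
            polyphen=str(rng.choice(["PrD", "PoD", "B", "NA"])),
            sift=str(rng.choice(["D", "T", "NA"])),
            provean=str(rng.choice(["D", "N", "NA"])),
        )
        vid = f"{gene}:{cdna}"
        variants[vid] = VariantRecord(
            variant_id=vid,
            gene=gene,
            chrom="1",
            pos=i + 1,
            ref="A",
            alt="G",
            cdna_name=cdna,
            protein_name="",
            consequence=csq,
            splice_flag=bool(rng.random() < 0.15),
            freq_evidence=tuple(evidence),
            predictor_calls=calls,
            reported_status=str(rng.choice(["novel", "known"])),
        )
    n_probands = int(rng.integers(1, 12))
    genotypes = []
    vids = list(variants)
    for p in range(n_probands):
        pid = f"P{p:02d}"
        k = int(rng.integers(0, min(len(vids), 12) + 1))
        chosen = rng.choice(len(vids), size=k, replace=False)
        for ci in chosen:
            genotypes.append(
                GenotypeCall(pid, vids[int(ci)], str(rng.choice(["het", "het", "hom"])))
            )
    return variants, genotypes, dict(_RAND_PANEL)
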