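"""Readers and writers for the flat formats the pipeline touches.

Variant table (TSV)
    Fixed columns ``variant_id, gene, chrom, pos, ref, alt, cdna_name,
    protein_name, consequence, splice_flag, polyphen, sift, provean,
    reported_status`` plus any number of frequency columns named
    ``<source>_ac`` / ``<source>_an`` (paired) or ``<source>_maf``.
    Empty cells / ``NA`` mean "no observation".

Genotype table (TSV)
    ``proband_id, variant_id, zygosity`` with zygosity ``het`` or ``hom``;
    pairs absent from the table are reference genotypes.

Pedigree (PED)
    The classic 6-column dialect: family, individual, father, mother,
    sex (1=male, 2=female, 0=unknown), affected (2=affected, 1=unaffected,
    0/-9=unknown).  ``0`` parent means founder.

VCF
    Standard VCF 4.x via cyvcf2; the mapping from INFO fields to annotation
    columns is declared in a YAML config (see :func:`read_vcf`).
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .model import (
    FrequencyEvidence,
    GenotypeCall,
    Individual,
    Pedigree,
    PredictorCalls,
    VariantRecord,
)

__all__ = [
    "TableFormatError",
    "read_variant_table",
    "write_variant_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_cohort",
    "read_ped",
    "write_ped",
    "read_vcf",
]

_FIXED_COLUMNS = [
    "variant_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "cdna_name",
    "protein_name",
    "consequence",
    "splice_flag",
    "polyphen",
    "sift",
    "provean",
    "reported_status",
]

_FREQ_COL_RE = re.compile(r"^(?P<source>.+)_(?P<kind>ac|an|maf)$")
_MISSING = {"", "NA", "na", ".", "-"}


class TableFormatError(ValueError):
    """A table row or header violates the documented schema."""


def _is_missing(cell: str | None) -> bool:
    return cell is None or cell.strip() in _MISSING


def _freq_sources(fieldnames: Iterable[str]) -> dict[str, str]:
    """Map source name -> 'counts' or 'maf' from the header's freq columns."""
    sources: dict[str, set[str]] = {}
    for col in fieldnames:
        m = _FREQ_COL_RE.match(col)
        if m and col not in _FIXED_COLUMNS:
            sources.setdefault(m.group("source"), set()).add(m.group("kind"))
    out: dict[str, str] = {}
    for source, kinds in sources.items():
        if "maf" in kinds and kinds & {"ac", "an"}:
            raise TableFormatError(f"source {source!r} declares both counts and maf columns")
        if kinds == {"maf"}:
            out[source] = "maf"
        elif kinds == {"ac", "an"}:
            out[source] = "counts"
        else:
            raise TableFormatError(
                f"source {source!r} needs paired _ac/_an columns or a _maf column"
            )
    return out


def read_variant_table(path: str | Path, strict: bool = True) -> dict[str, VariantRecord]:
    """Read a variant TSV into ``{variant_id: VariantRecord}``.

    Malformed rows raise :class:`TableFormatError` naming the line number;
    with ``strict=False`` they are skipped with a warning-style note attached
    to the raised-at-the-end error only if *all* rows fail.
    """
    import warnings

    path = Path(path)
    records: dict[str, VariantRecord] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return records
        missing = [c for c in _FIXED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TableFormatError(f"{path}: missing columns {missing}")
        sources = _freq_sources(reader.fieldnames)
        for lineno, row in enumerate(reader, start=2):
            try:
                record = _row_to_record(row, sources)
                if record.variant_id in records:
                    raise TableFormatError(f"duplicate variant_id {record.variant_id!r}")
                records[record.variant_id] = record
            except (ValueError, KeyError) as exc:
                msg = f"{path}:{lineno}: {exc}"
                if strict:
                    raise TableFormatError(msg) from exc
                warnings.warn(f"skipping malformed row — {msg}")
    return records


def _row_to_record(row: Mapping[str, str], sources: Mapping[str, str]) -> VariantRecord:
    evidence = []
    for source, kind in sources.items():
        if kind == "maf":
            cell = row.get(f"{source}_maf")
            if not _is_missing(cell):
                evidence.append(FrequencyEvidence(source=source, maf=float(cell)))
        else:
            ac, an = row.get(f"{source}_ac"), row.get(f"{source}_an")
            if not _is_missing(ac) and not _is_missing(an):
                evidence.append(
                    FrequencyEvidence(source=source, allele_count=int(ac), allele_number=int(an))
                )
    return VariantRecord(
        variant_id=row["variant_id"],
        gene=row["gene"],
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        cdna_name=row["cdna_name"],
        protein_name="" if _is_missing(row.get("protein_name")) else row["protein_name"],
        consequence=row["consequence"],
        splice_flag=str(row["splice_flag"]).strip().lower() in ("true", "1", "yes"),
        freq_evidence=tuple(sorted(evidence, key=lambda e: e.source)),
        predictor_calls=PredictorCalls(
            polyphen="NA" if _is_missing(row.get("polyphen")) else row["polyphen"].strip(),
            sift="NA" if _is_missing(row.get("sift")) else row["sift"].strip(),
            provean="NA" if _is_missing(row.get("provean")) else row["provean"].strip(),
        ),
        reported_status=row["reported_status"].strip(),
    )


def write_variant_table(records: Mapping[str, VariantRecord], path: str | Path) -> None:
    """Write records to TSV; inverse of :func:`read_variant_table`."""
    path = Path(path)
    sources: dict[str, str] = {}
    for rec in records.values():
        for ev in rec.freq_evidence:
            sources[ev.source] = "maf" if ev.maf is not None else "counts"
    freq_cols: list[str] = []
    for source in sorted(sources):
        if sources[source] == "maf":
            freq_cols.append(f"{source}_maf")
        else:
            freq_cols.extend([f"{source}_ac", f"{source}_an"])
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_FIXED_COLUMNS + freq_cols)
        for rec in sorted(records.values(), key=lambda r: r.variant_id):
            ev_by_source = {e.source: e for e in rec.freq_evidence}
            freq_cells = []
            for source in sorted(sources):
                ev = ev_by_source.get(source)
                if sources[source] == "maf":
                    freq_cells.append("NA" if ev is None or ev.maf is None else repr(ev.maf))
                else:
                    if ev is None or ev.allele_count is None:
                        freq_cells.extend(["NA", "NA"])
                    else:
                        freq_cells.extend([str(ev.allele_count), str(ev.allele_number)])
            writer.writerow(
                [
                    rec.variant_id,
                    rec.gene,
                    rec.chrom,
                    str(rec.pos),
                    rec.ref,
                    rec.alt,
                    rec.cdna_name,
                    rec.protein_name or "NA",
                    rec.consequence,
                    str(rec.splice_flag),
                    rec.predictor_calls.polyphen,
                    rec.predictor_calls.sift,
                    rec.predictor_calls.provean,
                    rec.reported_status,
                ]
                + freq_cells
            )


def read_genotype_table(path: str | Path) -> list[GenotypeCall]:
    path = Path(path)
    calls: list[GenotypeCall] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return calls
        for col in ("proband_id", "variant_id", "zygosity"):
            if col not in reader.fieldnames:
                raise TableFormatError(f"{path}: missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            key = (row["proband_id"], row["variant_id"])
            if key in seen:
                raise TableFormatError(f"{path}:{lineno}: duplicate call for {key}")
            seen.add(key)
            try:
                calls.append(GenotypeCall(*key, zygosity=row["zygosity"].strip()))
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_genotype_table(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["proband_id", "variant_id", "zygosity"])
        for call in calls:
            writer.writerow([call.proband_id, call.variant_id, call.zygosity])


def read_cohort(
    variant_table: str | Path,
    genotype_table: str | Path,
    panel: Mapping[str, object] | None = None,
    strict: bool = True,
) -> tuple[dict[str, VariantRecord], list[GenotypeCall], set[str]]:
    """Read a (variant table, genotype table) pair.

    Returns ``(variants, genotype_calls, off_panel_genes)``; variants in
    genes absent from ``panel`` are retained but their genes are reported in
    the third element so callers can flag them.
    """
    variants = read_variant_table(variant_table, strict=strict)
    calls = read_genotype_table(genotype_table)
    for call in calls:
        if call.variant_id not in variants:
            msg = f"genotype call references unknown variant {call.variant_id!r}"
            if strict:
                raise TableFormatError(msg)
    off_panel: set[str] = set()
    if panel is not None:
        off_panel = {v.gene for v in variants.values() if v.gene not in panel}
    return variants, calls, off_panel


_SEX = {"1": "male", "2": "female"}
_AFFECTED = {"2": "affected", "1": "unaffected"}


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Read a 6-column PED file into ``{family_id: Pedigree}``."""
    path = Path(path)
    rows: dict[str, dict[str, Individual]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise TableFormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        fam, ind, father, mother, sex, affected = parts[:6]
        rows.setdefault(fam, {})[ind] = Individual(
            individual_id=ind,
            sex=_SEX.get(sex, "unknown"),
            affected=_AFFECTED.get(affected, "unknown"),
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
        )
    return {fam: Pedigree(family_id=fam, individuals=inds) for fam, inds in rows.items()}


def write_ped(pedigrees: Mapping[str, Pedigree], path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    lines = []
    for fam_id in sorted(pedigrees):
        ped = pedigrees[fam_id]
        for ind_id in sorted(ped.individuals):
            ind = ped.individuals[ind_id]
            lines.append(
                "\t".join(
                    [
                        fam_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_code[ind.sex],
                        aff_code[ind.affected],
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_vcf(
    vcf_path: str | Path, mapping_config: str | Path | Mapping
) -> tuple[dict[str, VariantRecord], list[GenotypeCall]]:
    """Ingest an annotated VCF using a YAML field-mapping config.

    The config declares which INFO fields carry each annotation::

        gene: GENE            # INFO field with the gene symbol
        cdna_name: CDNA       # HGVS c. name
        protein_name: PROT    # optional
        consequence: CSQCLASS # one of this package's consequence categories
        splice_flag: SPLICE   # optional; truthy INFO flag/value
        polyphen: PP2         # optional predictor fields
        sift: SIFT
        provean: PROVEAN
        reported_status: KNOWN   # optional; value 'known'/'novel' (default novel)
        frequencies:             # optional, per population source
          ExAC: {ac: EXAC_AC, an: EXAC_AN}
          EVS: {maf: EVS_MAF}

    Sample genotypes become :class:`GenotypeCall` objects (0/1 -> het,
    1/1 -> hom); reference and missing genotypes produce no call.
    """
    from cyvcf2 import VCF

    if isinstance(mapping_config, (str, Path)):
        cfg = yaml.safe_load(Path(mapping_config).read_text())
    else:
        cfg = dict(mapping_config)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variants: dict[str, VariantRecord] = {}
    calls: list[GenotypeCall] = []
    freq_cfg = cfg.get("frequencies", {}) or {}
    for var in vcf:
        gene = str(var.INFO.get(cfg["gene"], ""))
        cdna = str(var.INFO.get(cfg["cdna_name"], ""))
        variant_id = f"{gene}:{cdna}" if gene and cdna else f"{var.CHROM}:{var.POS}:{var.REF}>{var.ALT[0]}"
        evidence = []
        for source, fields in freq_cfg.items():
            if "maf" in fields:
                maf = var.INFO.get(fields["maf"])
                if maf is not None:
                    evidence.append(FrequencyEvidence(source=source, maf=float(maf)))
            else:
                ac = var.INFO.get(fields["ac"])
                an = var.INFO.get(fields["an"])
                if ac is not None and an is not None:
                    evidence.append(
                        FrequencyEvidence(source=source, allele_count=int(ac), allele_number=int(an))
                    )
        splice_field = cfg.get("splice_flag")
        splice_flag = bool(var.INFO.get(splice_field)) if splice_field else False

        def _info_str(key_name: str, default: str = "NA") -> str:
            field = cfg.get(key_name)
            if field is None:
                return default
            value = var.INFO.get(field)
            return default if value is None else str(value)

        variants[variant_id] = VariantRecord(
            variant_id=variant_id,
            gene=gene,
            chrom=str(var.CHROM),
            pos=int(var.POS),
            ref=str(var.REF),
            alt=str(var.ALT[0]),
            cdna_name=cdna,
            protein_name=_info_str("protein_name", ""),
            consequence=str(var.INFO.get(cfg["consequence"])),
            splice_flag=splice_flag,
            freq_evidence=tuple(evidence),
            predictor_calls=PredictorCalls(
                polyphen=_info_str("polyphen"),
                sift=_info_str("sift"),
                provean=_info_str("provean"),
            ),
            reported_status=_info_str("reported_status", "novel"),
        )
        for sample, gt in zip(samples, var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt == 0:
                continue
            zygosity = "hom" if len(alleles) > 1 and all(a > 0 for a in alleles) else "het"
            calls.append(GenotypeCall(sample, variant_id, zygosity))
    return variants, calls
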