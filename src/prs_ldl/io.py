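"""Reading and writing genotypes, phenotypes, scores, and weight files.

Genotypes come in as VCFv4.2 (records matched to the panel by the ID column,
GT field only, phase ignored) or as a wide TSV (``sample_id`` plus one
``X/Y`` column per rsID). Emitted VCFs carry the panel's GRCh38 metadata
coordinates; all matching is rsID-based.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .variant_model import (
    ApoeWeightTable,
    GenotypeCall,
    GenotypeError,
    PanelError,
    SampleGenotypes,
    VariantDef,
    VariantPanel,
    validate_call,
)

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["sample_id", "group", "sex", "age", "ldl_c", "smoking", "statin", "hypertension"]

WEIGHT_FILE_VERSION = "1"


# ---------------------------------------------------------------------------
# Weight files


def write_weight_file(panel: VariantPanel, path: str | Path) -> None:
    """Serialise a panel to the versioned two-section TSV weight format."""
    lines = [
        f"# prs-ldl weight file v{WEIGHT_FILE_VERSION}",
        f"# panel: {panel.name}",
        "[variants]",
        "rsid\tgene\treference_allele\trisk_allele\tweight",
    ]
    for v in panel.variants:
        lines.append(f"{v.rsid}\t{v.gene}\t{v.reference_allele}\t{v.risk_allele}\t{v.weight!r}")
    lines.append("[apoe_diplotypes]")
    lines.append("diplotype\tweight")
    for d, w in panel.apoe_weights.weights.items():
        lines.append(f"{d}\t{w!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_weight_file(path: str | Path, template: VariantPanel) -> VariantPanel:
    """Load a weight file; locus metadata (allele sets, coordinates) is
    taken from the template panel. Round-trips losslessly with
    :func:`write_weight_file` (weights written via repr)."""
    section = None
    variants: list[VariantDef] = []
    apoe: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        fields = line.split("\t")
        if section == "variants":
            if fields[0] == "rsid":
                continue
            if len(fields) != 5:
                raise PanelError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            variants.append(VariantDef(fields[0], fields[1], fields[2], fields[3], float(fields[4])))
        elif section == "apoe_diplotypes":
            if fields[0] == "diplotype":
                continue
            apoe[fields[0]] = float(fields[1])
        else:
            raise PanelError(f"{path}:{lineno}: content outside a known section")
    return VariantPanel(
        name=Path(path).stem,
        version=WEIGHT_FILE_VERSION,
        variants=tuple(variants),
        apoe_weights=ApoeWeightTable(apoe),
        loci=template.loci,
    )


# ---------------------------------------------------------------------------
# VCF


_VCF_HEADER = """##fileformat=VCFv4.2
##source=prs-ldl
##reference=GRCh38
##INFO=<ID=GENE,Number=1,Type=String,Description="Nearest gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(samples: Sequence[SampleGenotypes], panel: VariantPanel, path: str | Path) -> None:
    """Write the seven panel loci as a VCFv4.2 file with one GT column per
    sample. Unphased notation; missing genotypes as ``./.``."""
    specs = sorted(panel.loci.values(), key=lambda s: (int(s.chrom), s.pos))
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in dict.fromkeys(spec.chrom for spec in specs):
        lines.append(f"##contig=<ID={chrom}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header_cols += [s.sample_id for s in samples]
    lines.append("\t".join(header_cols))
    for spec in specs:
        row = [spec.chrom, str(spec.pos), spec.rsid, spec.ref, spec.alt, ".", "PASS", ".", "GT"]
        for sample in samples:
            call = sample.get(spec.rsid)
            if call.is_missing:
                row.append("./.")
            else:
                idx = sorted(0 if a == spec.ref else 1 for a in call.alleles)
                row.append(f"{idx[0]}/{idx[1]}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path: str | Path, panel: VariantPanel) -> list[SampleGenotypes]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    samples = {sid: SampleGenotypes(sid) for sid in sample_ids}
    seen: set[str] = set()
    wanted = set(panel.all_rsids)
    for record in vcf:
        rsid = record.ID
        if rsid not in wanted:
            continue
        if rsid in seen:
            raise GenotypeError(f"{path}: duplicate VCF record for {rsid}")
        seen.add(rsid)
        alleles = [record.REF] + list(record.ALT)
        declared = panel.allele_set(rsid)
        for a in alleles:
            if a not in declared:
                raise GenotypeError(
                    f"{path}: {rsid} allele {a!r} does not match panel set "
                    f"{{{'/'.join(sorted(declared))}}}"
                )
        for sid, gt in zip(sample_ids, record.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                call = GenotypeCall.missing(rsid)
            else:
                call = GenotypeCall(rsid, alleles[a1], alleles[a2])
            samples[sid].add(call)
    absent = wanted - seen
    if absent:
        logger.info("%s: no VCF record for %s; calls left missing", path, sorted(absent))
    return [samples[sid] for sid in sample_ids]


# ---------------------------------------------------------------------------
# Wide genotype TSV


def write_genotype_tsv(samples: Sequence[SampleGenotypes], panel: VariantPanel, path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id}
        for rsid in panel.all_rsids:
            call = s.get(rsid)
            row[rsid] = "./." if call.is_missing else "/".join(call.alleles)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_genotype_tsv(path: str | Path, panel: VariantPanel) -> list[SampleGenotypes]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise GenotypeError(f"{path}: genotype TSV must have a sample_id column")
    rsids = [c for c in df.columns if c != "sample_id"]
    unknown = [r for r in rsids if r not in panel.all_rsids]
    if unknown:
        raise GenotypeError(f"{path}: unknown rsID column(s) {unknown}")
    samples = []
    for i, row in df.iterrows():
        sg = SampleGenotypes(str(row["sample_id"]))
        for rsid in rsids:
            value = row[rsid]
            if pd.isna(value) or value in ("./.", "."):
                call = GenotypeCall.missing(rsid)
            else:
                parts = str(value).split("/")
                if len(parts) != 2:
                    raise GenotypeError(
                        f"{path} row {i + 2}: genotype {value!r} for {rsid} is not 'X/Y'"
                    )
                try:
                    call = GenotypeCall(rsid, parts[0], parts[1])
                    validate_call(call, panel, sg.sample_id)
                except GenotypeError as exc:
                    raise GenotypeError(f"{path} row {i + 2}: {exc}") from None
            sg.add(call)
        samples.append(sg)
    return samples


def read_genotypes(path: str | Path, panel: VariantPanel, fmt: str | None = None) -> list[SampleGenotypes]:
    """Load genotypes from VCF or wide TSV (auto-detected from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        samples = _read_vcf(path, panel)
    elif fmt == "tsv":
        samples = _read_genotype_tsv(path, panel)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    logger.info("read %d samples from %s (%s)", len(samples), path, fmt)
    return samples


# ---------------------------------------------------------------------------
# Phenotypes and scores


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype TSV missing column(s) {missing}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out["prs"] = out["prs"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
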