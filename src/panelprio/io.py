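"""Readers and writers for the standard formats the toolkit touches.

VCF 4.2 is read through cyvcf2 and decomposed per ALT allele; annotation
travels in a sidecar TSV keyed by chrom/pos/ref/alt (header:
``chrom pos ref alt gene consequence clin_class cip_has_plp maf_<source>...
score_<predictor>... hgvs``). BED is 0-based half-open on disk and converted
to the internal 1-based inclusive convention at this boundary. All text
outputs are UTF-8, tab-separated, with a header line.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    AnnotatedVariant,
    ClinClass,
    CoverageMatrix,
    CtRole,
    CtRow,
    CtTable,
    GenomicInterval,
    PedMember,
    Pedigree,
    Sex,
    Zygosity,
    norm_chrom,
)

logger = logging.getLogger(__name__)

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


class FormatError(ValueError):
    """A file violates its declared format; the message names the line."""


def read_annotation_table(path: str | Path) -> dict[tuple, dict]:
    """Load the sidecar annotation TSV into a dict keyed by variant key.

    Columns ``maf_<source>`` populate the per-source frequency map and
    ``score_<predictor>`` the in-silico score map; other columns map 1:1
    onto :class:`AnnotatedVariant` fields.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    score_cols = [c for c in df.columns if c.startswith("score_")]
    out: dict[tuple, dict] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict()
        key = (norm_chrom(rec["chrom"]), int(rec["pos"]), rec["ref"], rec["alt"])
        maf = {
            c[len("maf_"):]: float(rec[c]) for c in maf_cols if rec[c] != ""
        }
        scores = {
            c[len("score_"):]: rec[c] for c in score_cols if rec[c] != ""
        }
        out[key] = {
            "gene": rec.get("gene", ""),
            "consequence": rec.get("consequence", ""),
            "clin_class": ClinClass(rec.get("clin_class") or "NONE"),
            "cip_has_plp": str(rec.get("cip_has_plp", "")).lower()
            in ("1", "true", "yes"),
            "maf": maf,
            "scores": scores,
            "hgvs": rec.get("hgvs", ""),
        }
    return out


def _genotype_calls(gt_alleles: list[int]) -> dict[int, Zygosity]:
    """Map ALT allele index (1-based) -> zygosity from one GT's alleles."""
    called = [a for a in gt_alleles if a >= 0]
    out: dict[int, Zygosity] = {}
    for alt_idx in set(a for a in called if a > 0):
        n = called.count(alt_idx)
        if len(called) == 1:
            out[alt_idx] = Zygosity.HEM
        elif n >= 2:
            out[alt_idx] = Zygosity.HOM
        else:
            out[alt_idx] = Zygosity.HET
    return out


def read_vcf_with_annotations(
    vcf_path: str | Path, ann_path: str | Path, sample_id: str
) -> list[AnnotatedVariant]:
    """Read one sample's non-reference calls, joined to the annotation table.

    Emits one :class:`AnnotatedVariant` per ALT allele genotyped non-reference
    in ``sample_id`` (multiallelic records are decomposed; GT 1/2 yields two
    HET variants). Variants lacking an annotation row get ``clin_class=NONE``
    and an empty frequency map; annotation rows that match no emitted variant
    are ignored with a logged count.
    """
    annotations = read_annotation_table(ann_path)
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise FormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    if sample_id not in vcf.samples:
        raise KeyError(
            f"sample {sample_id!r} absent from VCF (has {vcf.samples})"
        )
    sidx = vcf.samples.index(sample_id)

    variants: list[AnnotatedVariant] = []
    used_keys: set[tuple] = set()
    for rec in vcf:
        gt = rec.genotypes[sidx]
        alleles = [a for a in gt[:-1]]  # last element is the phased flag
        calls = _genotype_calls(alleles)
        if not calls:
            continue
        depth = None
        if rec.format("DP") is not None:
            depth = int(rec.format("DP")[sidx][0])
        ad = rec.format("AD")
        for alt_idx, zyg in sorted(calls.items()):
            alt = rec.ALT[alt_idx - 1]
            vaf = None
            if ad is not None:
                counts = ad[sidx]
                total = int(np.sum(np.clip(counts, 0, None)))
                if total > 0:
                    vaf = float(counts[alt_idx]) / total
                if depth is None:
                    depth = total
            key = (norm_chrom(rec.CHROM), rec.POS, rec.REF, alt)
            ann = annotations.get(key)
            if ann is not None:
                used_keys.add(key)
            v = AnnotatedVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                zygosity=zyg,
                vaf=vaf,
                depth=depth,
                **(ann or {}),
            )
            variants.append(v)
    unmatched = len(annotations) - len(used_keys)
    if unmatched:
        logger.info(
            "%d annotation rows matched no emitted variant for %s",
            unmatched,
            sample_id,
        )
    return variants


def read_bed_targets(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open) into 1-based inclusive intervals."""
    out: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise FormatError(
                    f"line {lineno}: BED end ({end0}) <= start ({start0})"
                )
            label = parts[3] if len(parts) > 3 else ""
            out.append(
                GenomicInterval(chrom=chrom, start=start0 + 1, end=end0, label=label)
            )
    return out


def write_bed_targets(
    intervals: list[GenomicInterval], path: str | Path
) -> None:
    """Write intervals back to BED (0-based half-open); round-trip exact."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")


def read_ped(path: str | Path) -> Pedigree:
    """Read a standard 6-column PED file (unknown parents coded 0)."""
    members: list[PedMember] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"line {lineno}: expected 6 PED columns")
            _fam, sid, fid, mid, sex, pheno = parts[:6]
            if sid in seen:
                raise FormatError(f"line {lineno}: duplicate sample id {sid!r}")
            seen.add(sid)
            members.append(
                PedMember(
                    sample_id=sid,
                    father_id=None if fid in ("0", ".") else fid,
                    mother_id=None if mid in ("0", ".") else mid,
                    sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                    affected=pheno == "2",
                )
            )
    return Pedigree(members=members)


def read_depth_table(path: str | Path) -> CoverageMatrix:
    """Read a per-target depth TSV: chrom, start, end, gene, then samples."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "start", "end", "gene"]:
            raise FormatError(
                "depth table must start with columns chrom, start, end, gene"
            )
        samples = header[4:]
        targets: list[GenomicInterval] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"line {lineno}: {len(parts)} fields, expected {len(header)}"
                )
            targets.append(
                GenomicInterval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    label=parts[3],
                )
            )
            vals = [float(x) for x in parts[4:]]
            if any(v < 0 for v in vals):
                raise FormatError(f"line {lineno}: negative depth value")
            rows.append(vals)
    return CoverageMatrix(
        targets=targets, samples=samples, depth=np.array(rows, dtype=float)
    )


def write_depth_table(m: CoverageMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\tgene\t" + "\t".join(m.samples) + "\n")
        for iv, row in zip(m.targets, m.depth):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{vals}\n")


def read_ct_table(path: str | Path) -> CtTable:
    """Read a qPCR Ct CSV: sample_id, assay_id, role, calibrator, replicate, ct."""
    rows: list[CtRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                CtRow(
                    sample_id=rec["sample_id"],
                    assay_id=rec["assay_id"],
                    role=CtRole(rec["role"].upper()),
                    calibrator=rec["calibrator"].strip().lower()
                    in ("1", "true", "yes"),
                    ct=float(rec["ct"]),
                    replicate=int(rec.get("replicate", 1) or 1),
                )
            )
    return CtTable(rows=rows)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "assay_id", "role", "calibrator", "replicate", "ct"])
        for r in table.rows:
            w.writerow(
                [
                    r.sample_id,
                    r.assay_id,
                    r.role.value,
                    int(r.calibrator),
                    r.replicate,
                    repr(r.ct),
                ]
            )
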