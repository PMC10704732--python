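"""File formats: SV VCFs, PAV tables, presence matrices, GFF3, reports.

The in-memory data model is 1-based inclusive; BED export converts to
0-based half-open at this boundary. VCF I/O goes through pysam.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .core import (
    ALT,
    DEL,
    GeneModels,
    INS,
    MIN_SV_LENGTH,
    MISSING,
    PavRecord,
    PresenceMatrix,
    REF,
    SvCall,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# SV call VCFs (one file per sample per caller)
# --------------------------------------------------------------------------

def read_sv_vcf(path, sample: str, caller: str) -> Tuple[List[SvCall], Dict[str, int]]:
    """Read one caller's calls for one sample from a VCF.

    SVTYPE must be DEL or INS; the length comes from |SVLEN| when present,
    else END - POS + 1 for deletions. Records without SVTYPE are skipped
    with a warning; calls shorter than 20 bp are dropped and counted.
    Returns (calls, counters).
    """
    counters = {"kept": 0, "short": 0, "no_svtype": 0, "bad_type": 0}
    calls: List[SvCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            if "SVTYPE" not in info:
                warnings.warn(f"{path}: record at {rec.chrom}:{rec.pos} lacks SVTYPE; skipped")
                counters["no_svtype"] += 1
                continue
            svtype = str(info["SVTYPE"])
            if svtype not in (DEL, INS):
                counters["bad_type"] += 1
                continue
            pos = rec.pos  # pysam .pos is 1-based
            svlen = info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is not None:
                length = abs(int(svlen))
            elif svtype == DEL:
                length = rec.stop - pos + 1  # rec.stop is the 1-based inclusive END
            else:
                counters["no_svtype"] += 1
                continue
            if length < MIN_SV_LENGTH:
                counters["short"] += 1
                continue
            end = pos + length - 1 if svtype == DEL else pos
            calls.append(SvCall(sample, caller, rec.chrom, pos, end, svtype, length))
            counters["kept"] += 1
    calls.sort(key=lambda c: (c.chrom, c.pos, c.end))
    return calls, counters


def write_sv_vcf(calls: Sequence[SvCall], path, contigs: Mapping[str, int]) -> None:
    """Write calls as a minimal VCF 4.2 with SVTYPE/SVLEN/END INFO keys."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=int(length))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("END", 1, "Integer", "1-based inclusive end position")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.end)):
            # htslib emits END one past our inclusive end for deletions;
            # pass stop = end - 1 so the file carries the inclusive end
            # (insertions are points: stop = pos keeps END = POS)
            stop = c.end - 1 if c.svtype == DEL else c.pos
            rec = vf.new_record(
                contig=c.chrom, start=c.pos - 1, stop=stop,
                alleles=("N", f"<{c.svtype}>"),
            )
            rec.info["SVTYPE"] = c.svtype
            rec.info["SVLEN"] = -c.length if c.svtype == DEL else c.length
            vf.write(rec)


# --------------------------------------------------------------------------
# PAV records (VCF with per-sample GT, and TSV)
# --------------------------------------------------------------------------

_GT_CODE = {REF: (0, 0), ALT: (1, 1), MISSING: (None, None)}


def write_pav_vcf(records: Sequence[PavRecord], path, contigs: Mapping[str, int]) -> None:
    """Merged PAV map as a multi-sample VCF; GT 0/0 = carries the reference
    segment, 1/1 = carries the variation, ./. = missing."""
    samples = sorted({s for r in records for s in r.alleles})
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=int(length))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("END", 1, "Integer", "1-based inclusive end position")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.end)):
            stop = r.end - 1 if r.svtype == DEL else r.pos
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=stop,
                alleles=("N", f"<{r.svtype}>"), id=r.id,
            )
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = -r.length if r.svtype == DEL else r.length
            for s in samples:
                rec.samples[s]["GT"] = _GT_CODE[r.alleles.get(s, MISSING)]
            vf.write(rec)


def read_pav_vcf(path) -> List[PavRecord]:
    records: List[PavRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            svtype = str(rec.info["SVTYPE"])
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            length = abs(int(svlen))
            pos = rec.pos
            end = pos + length - 1 if svtype == DEL else pos
            alleles = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or gt[0] is None:
                    alleles[s] = MISSING
                else:
                    alleles[s] = ALT if gt[0] == 1 else REF
            records.append(
                PavRecord(rec.id, rec.chrom, pos, end, svtype, length, alleles)
            )
    return records


def write_pav_tsv(records: Sequence[PavRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id, "chrom": r.chrom, "pos": r.pos, "end": r.end,
                "svtype": r.svtype, "length": r.length,
                **{f"allele:{s}": a for s, a in sorted(r.alleles.items())},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pav_tsv(path) -> List[PavRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    allele_cols = [c for c in df.columns if c.startswith("allele:")]
    records = []
    for _, row in df.iterrows():
        alleles = {c[len("allele:"):]: row[c] for c in allele_cols}
        records.append(
            PavRecord(
                id=row["id"], chrom=row["chrom"], pos=int(row["pos"]),
                end=int(row["end"]), svtype=row["svtype"],
                length=int(row["length"]), alleles=alleles,
            )
        )
    return records


def write_bed(records: Sequence[PavRecord], path) -> None:
    """0-based half-open BED export of the reference loci."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.end)):
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.end}\t{r.id}\n")


# --------------------------------------------------------------------------
# presence matrix (TSV pair: genotypes + sample metadata)
# --------------------------------------------------------------------------

def write_matrix_tsv(matrix: PresenceMatrix, matrix_path, samples_path) -> None:
    out = matrix.data.copy()
    out.index.name = "segment_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.0f")
    meta = pd.DataFrame(
        {
            "sample": list(matrix.data.columns),
            "role": [matrix.roles[s] for s in matrix.data.columns],
            "region": [
                matrix.regions.get(s) if matrix.regions is not None else None
                for s in matrix.data.columns
            ],
            "foreign": [s in matrix.foreign for s in matrix.data.columns],
        }
    )
    meta.to_csv(samples_path, sep="\t", index=False, na_rep="NA")


def read_matrix_tsv(matrix_path, samples_path) -> PresenceMatrix:
    data = pd.read_csv(matrix_path, sep="\t", index_col="segment_id", na_values=["NA"])
    data.index.name = None
    meta = pd.read_csv(samples_path, sep="\t", na_values=["NA"])
    roles = dict(zip(meta["sample"], meta["role"]))
    regions = {
        s: r for s, r in zip(meta["sample"], meta["region"]) if isinstance(r, str)
    }
    foreign = set(meta.loc[meta["foreign"] == True, "sample"])  # noqa: E712
    return PresenceMatrix(data, roles, regions=regions or None, foreign=foreign)


def read_table_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


# --------------------------------------------------------------------------
# gene models (GFF3)
# --------------------------------------------------------------------------

def write_gff3(models: GeneModels, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exons = models.exons.groupby("gene_id")
        for _, g in models.genes.sort_values(["chrom", "start"]).iterrows():
            gid = g["gene_id"]
            fh.write(
                f"{g['chrom']}\tpavpedigree\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g['chrom']}\tpavpedigree\tmRNA\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={gid}.t1;Parent={gid}\n"
            )
            if gid in exons.groups:
                for k, (_, e) in enumerate(exons.get_group(gid).iterrows()):
                    fh.write(
                        f"{e['chrom']}\tpavpedigree\texon\t{e['start']}\t{e['end']}\t.\t"
                        f"{g['strand']}\t.\tID={gid}.e{k + 1};Parent={gid}.t1\n"
                    )


def _gff_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.strip().split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def read_gff3(path) -> GeneModels:
    """Parse gene and exon features from a GFF3 file.

    Exons are attached to their gene through the Parent chain
    (exon -> mRNA -> gene); malformed rows raise.
    """
    gene_rows, exon_rows, mrna_parent = [], [], {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{line_no}: malformed GFF3 row")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype == "gene":
                gid = _gff_attr(attrs, "ID")
                if gid is None:
                    raise ValueError(f"{path}:{line_no}: gene without ID")
                gene_rows.append((gid, chrom, int(start), int(end), strand))
            elif ftype in ("mRNA", "transcript"):
                tid, parent = _gff_attr(attrs, "ID"), _gff_attr(attrs, "Parent")
                if tid and parent:
                    mrna_parent[tid] = parent
            elif ftype == "exon":
                parent = _gff_attr(attrs, "Parent")
                exon_rows.append((parent, chrom, int(start), int(end)))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons = pd.DataFrame(exon_rows, columns=["parent", "chrom", "start", "end"])
    exons["gene_id"] = exons["parent"].map(lambda p: mrna_parent.get(p, p))
    exons = exons[["gene_id", "chrom", "start", "end"]]
    return GeneModels(genes, exons)


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

REPORT_SCHEMA = {
    "required": {
        "pipeline": str,
        "seed": int,
        "parameters": dict,
        "stages": dict,
    },
    "stage_required": {"status": str},
}


def validate_report(report: dict) -> None:
    """Check a run manifest against the shipped schema; raises ValueError."""
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for name, stage in report["stages"].items():
        for key, typ in REPORT_SCHEMA["stage_required"].items():
            if key not in stage or not isinstance(stage[key], typ):
                raise ValueError(f"stage {name!r} missing valid key {key!r}")


def write_report(report: dict, path) -> None:
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
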