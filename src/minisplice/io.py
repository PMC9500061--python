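"""Reading and writing the pipeline's file formats.

Text formats only: FASTA (reference), FASTQ (reads), TSV (library, counts,
frequency and association tables), a VCF-like per-variant table with an AF
penetrance field, and JSON (ground truth, fitted models).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .isoforms import IsoformFrequencyTable
from .reference import MinigeneReference
from .simulate import GroundTruth
from .variants import MinigeneVariant, Mutation


# ----------------------------------------------------------------- reference

def write_reference_fasta(ref: MinigeneReference, path) -> None:
    desc = "exons=" + ";".join(f"{a}-{b}" for a, b in ref.exons) + f" orf_start={ref.orf_start}"
    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.name, description=desc)], path, "fasta")


def read_reference_fasta(path) -> MinigeneReference:
    rec = next(SeqIO.parse(path, "fasta"))
    fields = dict(kv.split("=") for kv in rec.description.split()[1:] if "=" in kv)
    exons = tuple(
        tuple(int(x) for x in span.split("-")) for span in fields["exons"].split(";")
    )
    return MinigeneReference(str(rec.seq), exons, int(fields["orf_start"]), name=rec.id)


def read_fastq(path) -> Iterable[str]:
    for rec in SeqIO.parse(path, "fastq"):
        yield str(rec.seq)


def read_sam_pairs(path) -> dict[str, list]:
    """Read pair alignments from a SAM file, grouped by barcode.

    Expects read names of the form ``<barcode>|<read id>``; mates are paired
    by full read name. Only M (or =/X) and N operations are accepted —
    soft-clipped or indel-containing alignments are rejected, matching a
    mapping configuration that prohibits clipping.
    """
    import pysam

    from .isoforms import ReadPairAlignment

    op_map = {0: "M", 7: "M", 8: "M", 3: "N"}
    pending: dict[str, tuple] = {}
    out: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            ops = []
            for code, length in aln.cigartuples:
                if code not in op_map:
                    raise ValueError(
                        f"unsupported CIGAR operation in {aln.query_name}: "
                        f"only M/N alignments are accepted"
                    )
                ops.append((op_map[code], length))
            rec = (aln.reference_start + 1, tuple(ops), "-" if aln.is_reverse else "+")
            name = aln.query_name
            if name in pending:
                first = pending.pop(name)
                barcode = name.split("|", 1)[0]
                out.setdefault(barcode, []).append(
                    ReadPairAlignment(first[0], first[1], first[2], *rec)
                )
            else:
                pending[name] = rec
    return out


# ------------------------------------------------------------------- library

def write_library_tsv(variants: Sequence[MinigeneVariant], path) -> None:
    rows = [
        {
            "barcode": v.barcode,
            "mutations": ",".join(m.label for m in v.mutations),
            "ccs_support": v.ccs_support,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> list[MinigeneVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"mutations": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        muts = tuple(
            Mutation.from_label(tok) for tok in str(row["mutations"]).split(",") if tok
        )
        out.append(
            MinigeneVariant(row["barcode"], muts, ccs_support=int(row.get("ccs_support", 0)))
        )
    return out


def write_variant_vcf(variants: Sequence[MinigeneVariant], ref: MinigeneReference, path) -> None:
    """VCF-like per-variant table: one record per (barcode, mutation) with AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={ref.length}>\n")
        fh.write('##INFO=<ID=BC,Number=1,Type=String,Description="Minigene barcode">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Penetrance (allele frequency)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            for m in v.mutations:
                af = v.penetrances.get(m, 1.0) if v.penetrances else 1.0
                fh.write(
                    f"{ref.name}\t{m.position}\t.\t{m.ref}\t{m.alt}\t.\tPASS\t"
                    f"BC={v.barcode};AF={af:g}\n"
                )


def read_variant_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref_a, alt_a, _, _, info = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=") for kv in info.split(";"))
            rows.append(
                {
                    "barcode": fields["BC"],
                    "position": int(pos),
                    "ref": ref_a,
                    "alt": alt_a,
                    "af": float(fields.get("AF", 1.0)),
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- tables

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("barcode").to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_frequency_table(table: IsoformFrequencyTable, path) -> None:
    out = table.counts.copy()
    out.columns = [str(c) for c in out.columns]
    out["total_pairs"] = table.total_pairs
    out.rename_axis("barcode").to_csv(path, sep="\t")


def read_frequency_table(path) -> IsoformFrequencyTable:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    total = df.pop("total_pairs")
    return IsoformFrequencyTable(df, total)


# ---------------------------------------------------------------------- JSON

def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "isoform_labels": list(truth.isoform_labels),
        "intercepts": list(map(float, truth.intercepts)),
        "effects": {m.label: list(map(float, v)) for m, v in truth.effects.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        intercepts=np.asarray(payload["intercepts"], dtype=float),
        effects={
            Mutation.from_label(k): np.asarray(v, dtype=float)
            for k, v in payload["effects"].items()
        },
        isoform_labels=tuple(payload["isoform_labels"]),
    )
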