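"""On-disk formats: TSV matrices, BED annotations, JSON reports.

Matrices are probes x samples TSV with "NA" as the missing sentinel.
Interval annotations are BED (0-based, half-open): islands as 3-column
BED, chromatin segments with the state in column 4, genes as 6-column BED
(name = gene id, strand in column 6).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GenomeAnnotation
from .preprocess import IntensityMatrix

NA = "NA"

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_intensities",
    "read_intensities",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_annotation",
    "read_annotation",
    "write_bed",
    "read_bed",
    "write_json",
    "read_json",
]


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id", na_values=[NA])


def write_intensities(intensities: IntensityMatrix, prefix) -> None:
    """Write M/U/detection-p companions as <prefix>.{meth,unmeth,detection}.tsv."""
    prefix = str(prefix)
    write_matrix(intensities.M, prefix + ".meth.tsv")
    write_matrix(intensities.U, prefix + ".unmeth.tsv")
    write_matrix(intensities.detection_p, prefix + ".detection.tsv")


def read_intensities(prefix) -> IntensityMatrix:
    prefix = str(prefix)
    return IntensityMatrix(
        M=read_matrix(prefix + ".meth.tsv"),
        U=read_matrix(prefix + ".unmeth.tsv"),
        detection_p=read_matrix(prefix + ".detection.tsv"),
    )


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end")) -> None:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, columns=("chrom", "start", "end")) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=list(columns))


def write_annotation(annotation: GenomeAnnotation, outdir) -> None:
    """Islands as 3-col BED, chromatin as 4-col BED, genes as 6-col BED."""
    outdir = Path(outdir)
    write_bed(annotation.cgi, outdir / "cgi.bed")
    write_bed(annotation.chromatin, outdir / "chromatin.bed", ("chrom", "start", "end", "state"))
    genes = annotation.genes.copy()
    # BED interval of a gene spans min/max of TSS and TES; name carries the id
    genes["start"] = genes[["tss", "tes"]].min(axis=1)
    genes["end"] = genes[["tss", "tes"]].max(axis=1)
    genes["score"] = 0
    write_bed(genes, outdir / "genes.bed", ("chrom", "start", "end", "gene_id", "score", "strand"))


def read_annotation(outdir) -> GenomeAnnotation:
    outdir = Path(outdir)
    cgi = read_bed(outdir / "cgi.bed")
    chromatin = read_bed(outdir / "chromatin.bed", ("chrom", "start", "end", "state"))
    genes = read_bed(
        outdir / "genes.bed", ("chrom", "start", "end", "gene_id", "score", "strand")
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    genes["tes"] = np.where(genes["strand"] == "+", genes["end"], genes["start"])
    return GenomeAnnotation(
        cgi=cgi, genes=genes[["chrom", "tss", "tes", "strand", "gene_id"]], chromatin=chromatin
    )


class _Encoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Encoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
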