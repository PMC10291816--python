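"""Plain-text readers and writers for every pipeline artifact.

All tabular formats are TSV. Count matrices carry ``v_index``/``j_index``
key columns followed by one column per sample; barcode libraries carry the
universal barcode on a ``#universal_barcode=`` header line. Clonotype
tables use the native dialect (``cdr3_nt``, ``v_gene``, ``j_gene``,
``count``); a reader adapter accepts MiXCR-style exports (``cloneCount``,
``allVHitsWithScore``, ``allJHitsWithScore``, ``nSeqCDR3``), taking the top
hit and stripping scores/alleles.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import MergedRead, STBarcodeLibrary
from .normalize import PrimerMap
from .scaling import ScalingFactorSet


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTQ -------------------------------------------------------------------

def read_fastq(path) -> list[MergedRead]:
    with _open_text(path) as handle:
        return [MergedRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fastq")]


def write_fastq(reads: Iterable[MergedRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fastq")


# -- ST count matrices -------------------------------------------------------

def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.reset_index().to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["v_index", "j_index"])


# -- barcode libraries -------------------------------------------------------

def write_barcode_library(library: STBarcodeLibrary, path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"#universal_barcode={library.universal_barcode}\n")
        fh.write("v_index\tj_index\tunique_barcode\n")
        for v, j, bc in library.entries:
            fh.write(f"{v}\t{j}\t{bc}\n")


def read_barcode_library(path) -> STBarcodeLibrary:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#universal_barcode="):
            raise ValueError("library file must start with #universal_barcode=")
        universal = header.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t")
    entries = tuple(
        (int(r.v_index), int(r.j_index), str(r.unique_barcode))
        for r in df.itertuples()
    )
    n_v = max(e[0] for e in entries)
    n_j = max(e[1] for e in entries)
    return STBarcodeLibrary(universal, entries, n_v=n_v, n_j=n_j)


# -- scaling factors ---------------------------------------------------------

def write_scaling_factors(factors: ScalingFactorSet, path) -> None:
    df = factors.factors.rename("factor").reset_index()
    df["method"] = factors.method
    df.to_csv(path, sep="\t", index=False)


def read_scaling_factors(path) -> ScalingFactorSet:
    df = pd.read_csv(path, sep="\t")
    s = df.set_index(["v_index", "j_index"])["factor"]
    method = str(df["method"].iloc[0]) if "method" in df.columns else "unknown"
    return ScalingFactorSet(s, method=method)


# -- NB fits ----------------------------------------------------------------

def write_fits(fits: pd.DataFrame, path) -> None:
    fits.reset_index().to_csv(path, sep="\t", index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index(["v_index", "j_index"])


# -- clonotype tables --------------------------------------------------------

def _strip_hit(hit: str) -> str:
    """'TRBV12-1*00(957.1)' or comma-separated list -> 'TRBV12-1'."""
    first = str(hit).split(",")[0]
    return first.split("*")[0].split("(")[0].strip()


def read_clonotypes(path) -> pd.DataFrame:
    """Read a clonotype TSV, accepting either the native dialect or a
    MiXCR-style export."""
    df = pd.read_csv(path, sep="\t")
    if {"cdr3_nt", "v_gene", "j_gene", "count"}.issubset(df.columns):
        return df
    mixcr = {"cloneCount", "allVHitsWithScore", "allJHitsWithScore", "nSeqCDR3"}
    if mixcr.issubset(df.columns):
        out = pd.DataFrame(
            {
                "cdr3_nt": df["nSeqCDR3"],
                "v_gene": df["allVHitsWithScore"].map(_strip_hit),
                "j_gene": df["allJHitsWithScore"].map(_strip_hit),
                "count": df["cloneCount"],
            }
        )
        if "cloneId" in df.columns:
            out.insert(0, "clonotype_id", df["cloneId"].astype(str))
        return out
    raise ValueError(
        "unrecognized clonotype table: need cdr3_nt/v_gene/j_gene/count "
        "or a MiXCR-style export"
    )


def write_clonotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- primer maps -------------------------------------------------------------

def write_primer_map(pmap: PrimerMap, path) -> None:
    rows = [("V", g, i) for g, i in pmap.v_map.items()] + [
        ("J", g, i) for g, i in pmap.j_map.items()
    ]
    pd.DataFrame(rows, columns=["segment", "gene", "primer_index"]).to_csv(
        path, sep="\t", index=False
    )


def read_primer_map(path, n_v: int = 20, n_j: int = 13) -> PrimerMap:
    df = pd.read_csv(path, sep="\t")
    v = {
        str(r.gene): int(r.primer_index)
        for r in df.itertuples()
        if str(r.segment).upper() == "V"
    }
    j = {
        str(r.gene): int(r.primer_index)
        for r in df.itertuples()
        if str(r.segment).upper() == "J"
    }
    return PrimerMap(v_map=v, j_map=j, n_v=n_v, n_j=n_j)
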