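"""Format adapters: SAM, BED, TSV tables, variant specs and model bundles.

Every dialect written by the simulators round-trips losslessly through the
corresponding reader. Malformed records are rejected with the offending
line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .reads import AlignedRead
from .variants import VariantSpec

_CIGAR_CODE = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S"}
_CIGAR_NUM = {v: k for k, v in _CIGAR_CODE.items()}


# ---------------------------------------------------------------------------
# SAM


def write_sam(path, reads: Sequence[AlignedRead], reference_name: str,
              reference_length: int) -> None:
    """Write reads as plain-text SAM with a single-reference header.

    Simulation truth tags (allelic origin ``XO``, duplicate group ``XD``)
    are carried as string/int auxiliary tags.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference_name, "LN": int(reference_length)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.name
            a.query_sequence = read.bases
            a.flag = 0
            a.reference_id = 0
            a.reference_start = read.start - 1          # SAM text is 1-based; API 0-based
            a.mapping_quality = read.mapq
            a.cigartuples = [(_CIGAR_NUM[op], ln) for op, ln in read.cigar]
            for tag, value in read.tags.items():
                a.set_tag(tag, value)
            out.write(a)


def read_sam(path) -> List[AlignedRead]:
    """Read a SAM file into :class:`AlignedRead` records (mapped reads only)."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = tuple(
                (_CIGAR_CODE[op], ln) for op, ln in (a.cigartuples or ())
                if op in _CIGAR_CODE
            )
            reads.append(AlignedRead(
                name=a.query_name,
                chrom=a.reference_name,
                start=a.reference_start + 1,
                cigar=cigar,
                bases=a.query_sequence or "",
                mapq=a.mapping_quality,
                tags=dict(a.get_tags()),
            ))
    return reads


# ---------------------------------------------------------------------------
# variant specs (minimal VCF-like TSV)

_VARIANT_COLS = ["chrom", "pos", "id", "ref", "alt", "var_class",
                 "cdna_name", "intron_start", "intron_end",
                 "downstream_exon_start", "flank_left", "flank_right"]


def write_variants(path, variants: Sequence[VariantSpec]) -> None:
    rows = []
    for v in variants:
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "id": v.id, "ref": v.ref_allele,
            "alt": v.alt_allele, "var_class": v.var_class,
            "cdna_name": v.cdna_name,
            "intron_start": v.intron_start if v.intron_start is not None else ".",
            "intron_end": v.intron_end if v.intron_end is not None else ".",
            "downstream_exon_start": (v.downstream_exon_start
                                      if v.downstream_exon_start is not None else "."),
            "flank_left": v.flank_left or ".",
            "flank_right": v.flank_right or ".",
        })
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


def read_variants(path) -> List[VariantSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _VARIANT_COLS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table lacks required columns: {missing}")

    def opt_int(x):
        return None if pd.isna(x) or x == "." else int(x)

    def opt_str(x):
        return None if pd.isna(x) or x == "." else str(x)

    out = []
    for i, r in df.iterrows():
        try:
            out.append(VariantSpec(
                id=r["id"], cdna_name=r.get("cdna_name", r["id"]),
                var_class=r["var_class"], chrom=r["chrom"], pos=int(r["pos"]),
                ref_allele=r["ref"], alt_allele=r["alt"],
                flank_left=opt_str(r.get("flank_left")),
                flank_right=opt_str(r.get("flank_right")),
                intron_start=opt_int(r.get("intron_start")),
                intron_end=opt_int(r.get("intron_end")),
                downstream_exon_start=opt_int(r.get("downstream_exon_start")),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"variant table line {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# matrices and tables


def write_count_matrix(path, matrix: pd.DataFrame) -> None:
    """Write a samples x features matrix as TSV, features in rows.

    First column ``feature``, one column per sample — the compact layout
    when features outnumber samples a thousandfold.
    """
    matrix.T.rename_axis("feature").to_csv(path, sep="\t")


def read_count_matrix(path) -> pd.DataFrame:
    """Read a feature-rows TSV back into samples x features orientation."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated feature id {dup!r} in {path}")
    return df.T


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    """A differential table: feature, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    for col in ("feature", "log2fc", "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: differential table lacks column {col!r}")
    if df["feature"].duplicated().any():
        dup = df.loc[df["feature"].duplicated(), "feature"].iloc[0]
        raise ValueError(f"{path}: duplicated feature id {dup!r}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError(f"{path}: adjusted p outside [0, 1]")
    return df


def read_bed_regions(path) -> pd.DataFrame:
    """BED-style regions (0-based half-open) with optional extra columns.

    The first three columns are chrom/start/end; named extra columns
    (e.g. log2fc, padj, feature) are taken from the header if present.
    """
    with open(path) as fh:
        first = fh.readline()
    has_header = not first.split("\t")[1].strip().lstrip("-").isdigit()
    if has_header:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={df.columns[0]: "chrom",
                                df.columns[1]: "start", df.columns[2]: "end"})
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        names = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
        df.columns = names
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at line {bad[0] + (2 if has_header else 1)}")
    return df


def read_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "chrom", "tss"):
        if col not in df.columns:
            raise ValueError(f"{path}: TSS table lacks column {col!r}")
    df["tss"] = df["tss"].astype(int)
    return df


def read_panels(path) -> Dict[str, List[str]]:
    """Marker panels as TSV with columns cell_type, marker."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_type", "marker"):
        if col not in df.columns:
            raise ValueError(f"{path}: panel table lacks column {col!r}")
    return {ct: sub["marker"].tolist() for ct, sub in df.groupby("cell_type")}


# ---------------------------------------------------------------------------
# model bundle (JSON metadata + TSV components)


def save_o2pls(results, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_joint": int(results.n_joint),
        "n_x_specific": int(results.T_x_specific.shape[1]),
        "n_y_specific": int(results.T_y_specific.shape[1]),
        "singular_values": [float(s) for s in results.singular_values],
        "n_samples": int(results.T.shape[0]),
        "n_x_features": int(results.W.shape[0]),
        "n_y_features": int(results.C.shape[0]),
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    for name in ("W", "C", "T", "U", "T_x_specific", "P_x_specific",
                 "T_y_specific", "P_y_specific"):
        getattr(results, name).rename_axis("id").to_csv(d / f"{name}.tsv", sep="\t")


def load_o2pls_components(directory) -> Dict[str, pd.DataFrame]:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    out = {"meta": meta}
    for name in ("W", "C", "T", "U"):
        out[name] = pd.read_csv(d / f"{name}.tsv", sep="\t", index_col=0)
    return out
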