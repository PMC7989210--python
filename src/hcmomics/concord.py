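"""Region annotation, multi-omics overlaps and direction concordance.

This module carries the bookkeeping half of the integrative analysis:

* map differentially acetylated regions (DARs) to genes whose TSS lies
  within +/- 5 kb or +/- 50 kb, flagging the nearest gene;
* intersect the top-k O2PLS-ranked genes with the differential-expression
  table, split by direction;
* keep the genes whose protein change is significant and sign-matches the
  RNA change (the protein-coding candidate lists);
* assemble the per-gene concordance table — O2PLS rank, RNA and protein
  log2FC, per-window acetylome direction match, plasma detectability,
  external cardiomyocyte log2FC — and count plasma-detectable candidates;
* aggregate cell-type marker panels (mean signal per marker) and compare
  the cardiomyocyte panel against each non-myocyte panel with a one-way
  ANOVA over marker-level means.

Coordinate conventions: regions are BED-style 0-based half-open; TSS
coordinates are compared directly on the same coordinate line (a TSS
inside ``[start, end)`` has distance 0; otherwise the distance is the gap
to the nearer region edge, boundary inclusive against the window).
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

WINDOWS = (5_000, 50_000)


# ---------------------------------------------------------------------------
# region -> TSS annotation


def annotate_regions(
    regions: pd.DataFrame, tss: pd.DataFrame, window: int
) -> pd.DataFrame:
    """Map regions to genes whose TSS lies within ``window`` bases.

    ``regions`` needs columns chrom/start/end (0-based half-open; extra
    columns such as log2fc/padj are carried through); ``tss`` needs
    gene/chrom/tss (strand, if present, is informational — the window is
    symmetric). Returns one row per (region, in-window gene) with the
    distance and a ``nearest`` flag (ties broken by smaller gene id).
    Regions with no gene in the window are absent from the output.
    """
    if (regions["start"] >= regions["end"]).any():
        bad = regions.index[regions["start"] >= regions["end"]][0]
        raise ValueError(f"region with start >= end at row {bad}")
    region_chroms = set(regions["chrom"])
    tss_chroms = set(tss["chrom"])
    if region_chroms and tss_chroms and not (region_chroms & tss_chroms):
        raise ValueError(
            "no shared chromosome names between regions and TSS table "
            f"(regions use e.g. {sorted(region_chroms)[:3]}, TSS uses "
            f"{sorted(tss_chroms)[:3]}); harmonize naming first"
        )

    out_rows: List[dict] = []
    extra_cols = [c for c in regions.columns if c not in ("chrom", "start", "end")]
    for chrom, regs in regions.groupby("chrom", sort=False):
        sub = tss[tss["chrom"] == chrom]
        if sub.empty:
            continue
        order = np.argsort(sub["tss"].to_numpy(), kind="mergesort")
        positions = sub["tss"].to_numpy()[order]
        genes = sub["gene"].to_numpy()[order]
        starts = regs["start"].to_numpy()
        ends = regs["end"].to_numpy()
        lo = np.searchsorted(positions, starts - window, side="left")
        hi = np.searchsorted(positions, ends - 1 + window, side="right")
        for row_i, (ridx, s, e, a, b) in enumerate(zip(regs.index, starts, ends, lo, hi)):
            hits = []
            for j in range(a, b):
                t = positions[j]
                if s <= t < e:
                    d = 0
                elif t < s:
                    d = int(s - t)
                else:
                    d = int(t - (e - 1))
                if d <= window:
                    hits.append((d, genes[j]))
            if not hits:
                continue
            d_min = min(h[0] for h in hits)
            nearest_gene = min(g for d, g in hits if d == d_min)
            for d, g in sorted(hits, key=lambda h: (h[0], h[1])):
                rec = {
                    "chrom": chrom, "start": int(s), "end": int(e),
                    "gene": g, "distance": d,
                    "nearest": bool(g == nearest_gene and d == d_min),
                }
                for c in extra_cols:
                    rec[c] = regs.at[ridx, c]
                out_rows.append(rec)
    cols = ["chrom", "start", "end", "gene", "distance", "nearest"] + extra_cols
    return pd.DataFrame(out_rows, columns=cols)


# ---------------------------------------------------------------------------
# overlaps


def intersect_ranked_de(
    ranked: pd.DataFrame, de: pd.DataFrame, alpha: float = 0.05
) -> Dict[str, pd.DataFrame]:
    """Intersect the ranked gene list with significant DE genes, by direction.

    ``ranked`` has columns feature/rank (output of the O2PLS feature
    ranking); ``de`` has feature/log2fc/padj. Returns ``{"up": ..., "down":
    ...}``, each sorted by O2PLS rank and carrying the DE statistics.
    """
    if de["feature"].duplicated().any():
        dup = de.loc[de["feature"].duplicated(), "feature"].iloc[0]
        raise ValueError(f"duplicate feature id in DE table: {dup!r}")
    merged = ranked.merge(de, on="feature", how="inner")
    sig = merged[merged["padj"] < alpha]
    up = sig[sig["log2fc"] > 0].sort_values("rank").reset_index(drop=True)
    down = sig[sig["log2fc"] < 0].sort_values("rank").reset_index(drop=True)
    return {"up": up, "down": down}


def overlap_proteome(
    up: pd.DataFrame,
    down: pd.DataFrame,
    proteome: pd.DataFrame,
    alpha: float = 0.05,
    id_map: Optional[Mapping[str, str]] = None,
) -> Dict[str, pd.DataFrame]:
    """Retain genes whose protein change is significant and sign-concordant.

    ``up``/``down`` are the RNA-direction gene lists (columns feature/rank/
    log2fc/...); ``proteome`` has feature/log2fc/padj keyed by protein ids
    (``id_map`` translates gene id -> protein id when the namespaces
    differ; identity by default). Returns concordant ``up``/``down`` lists
    (with a ``protein_log2fc`` column) plus ``discordant``: genes whose
    protein is significant but changes in the opposite direction.
    """
    if proteome["feature"].duplicated().any():
        raise ValueError("duplicate feature id in proteome table")
    prot = proteome.set_index("feature")

    def _lookup(gene):
        pid = id_map.get(gene, gene) if id_map else gene
        if pid in prot.index:
            return prot.loc[pid]
        return None

    out = {"up": [], "down": [], "discordant": []}
    for direction, table in (("up", up), ("down", down)):
        sign = 1.0 if direction == "up" else -1.0
        for _, row in table.iterrows():
            p = _lookup(row["feature"])
            if p is None or p["padj"] >= alpha:
                continue
            rec = dict(row)
            rec["protein_log2fc"] = float(p["log2fc"])
            rec["protein_padj"] = float(p["padj"])
            if np.sign(p["log2fc"]) == sign:
                out[direction].append(rec)
            else:
                rec["rna_direction"] = direction
                out["discordant"].append(rec)
    return {
        k: pd.DataFrame(v) if v else pd.DataFrame(
            columns=list(up.columns) + ["protein_log2fc", "protein_padj"])
        for k, v in out.items()
    }


# ---------------------------------------------------------------------------
# concordance table


def acetylome_direction_by_gene(
    annotated: pd.DataFrame, strict: bool = False
) -> Dict[str, int]:
    """Per-gene acetylome direction from annotated differential regions.

    ``annotated`` is the output of :func:`annotate_regions` on regions that
    carry a ``log2fc`` column. A gene's direction is +1/-1 when some
    region in its window changes in that direction (disjunctive rule, the
    default: a single yes/no per gene is reported downstream); with
    ``strict=True`` the direction is only set when *all* regions in the
    window agree. Genes whose regions disagree get 0 under strict mode,
    and both directions are representable under the default by the
    special value 2 (any-direction present both ways).
    """
    out: Dict[str, int] = {}
    for gene, sub in annotated.groupby("gene"):
        signs = set(int(np.sign(v)) for v in sub["log2fc"] if v != 0)
        if not signs:
            continue
        if strict:
            out[gene] = signs.pop() if len(signs) == 1 else 0
        else:
            out[gene] = 2 if len(signs) == 2 else signs.pop()
    return out


def _matches(gene_sign: int, acet_sign: Optional[int]) -> bool:
    if acet_sign is None:
        return False
    return acet_sign == 2 or acet_sign == gene_sign


def build_concordance_table(
    up: pd.DataFrame,
    down: pd.DataFrame,
    acetylome_by_window: Mapping[int, Mapping[str, int]],
    plasma: Optional[Mapping[str, str]] = None,
    cm_expression: Optional[Mapping[str, str]] = None,
    external_cm: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """One row per candidate gene mirroring the study's multi-level table.

    ``up``/``down`` are the proteome-concordant gene lists (must carry
    feature/rank/log2fc/protein_log2fc). ``acetylome_by_window`` maps
    window size -> per-gene acetylome direction (see
    :func:`acetylome_direction_by_gene`); a gene absent from a window's
    mapping is a no-match. ``plasma`` maps gene -> {detected,
    not_detected, no_data}; missing genes get no_data. ``external_cm``
    supplies log2FC in an external mutant-vs-control cardiomyocyte data
    set (absent -> NaN). The ``fully_concordant_<w>`` flag is true iff the
    RNA and protein signs agree and the window's acetylome direction
    matches.
    """
    rows = []
    for direction, table in (("up", up), ("down", down)):
        sign = 1 if direction == "up" else -1
        for _, r in table.iterrows():
            gene = r["feature"]
            rec = {
                "gene": gene,
                "o2pls_rank": int(r["rank"]),
                "rna_log2fc": float(r["log2fc"]),
                "protein_log2fc": float(r["protein_log2fc"]),
                "rna_direction": direction,
            }
            protein_concordant = np.sign(rec["protein_log2fc"]) == sign
            for w, mapping in acetylome_by_window.items():
                match = _matches(sign, mapping.get(gene))
                rec[f"acetylome_match_{_kb(w)}"] = "yes" if match else "no"
                rec[f"fully_concordant_{_kb(w)}"] = bool(protein_concordant and match)
            rec["plasma_detectable"] = (plasma or {}).get(gene, "no_data")
            if cm_expression is not None:
                rec["cm_expression"] = cm_expression.get(gene, "No data")
            rec["external_cm_log2fc"] = (
                float(external_cm[gene]) if external_cm and gene in external_cm
                else np.nan
            )
            rows.append(rec)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("gene", kind="mergesort").reset_index(drop=True)
    return df


def _kb(window: int) -> str:
    return f"{window // 1000}kb"


def count_plasma_detectable(rows: pd.DataFrame) -> int:
    """Number of candidate genes whose protein is detectable in plasma/serum."""
    if "plasma_detectable" not in rows.columns:
        raise ValueError("concordance table lacks a plasma_detectable column")
    flags = rows["plasma_detectable"].astype(str).str.lower()
    return int(flags.isin(["detected", "yes"]).sum())


# ---------------------------------------------------------------------------
# marker panels


def marker_panel_summary(
    matrix: pd.DataFrame,
    panels: Mapping[str, Sequence[str]],
    groups: Optional[Sequence[str]] = None,
    reference_panel: str = "cardiomyocyte",
) -> Dict[str, pd.DataFrame]:
    """Aggregate cell-type marker panels and compare them to the reference.

    ``matrix`` is samples x features (normalized signal). Every marker's
    mean across all samples — and, when ``groups`` is given, across cases
    and controls separately — is reported; each dot of the corresponding
    figure is one such marker mean. For every non-reference panel a
    one-way ANOVA compares the reference panel's marker means with that
    panel's marker means (two groups of marker-level values). Markers
    absent from the matrix are excluded with a warning; a panel with fewer
    than two present markers gets no F statistic.
    """
    if reference_panel not in panels:
        raise ValueError(f"reference panel {reference_panel!r} not among panels")
    group_arr = np.asarray(list(groups)) if groups is not None else None

    marker_rows = []
    panel_means: Dict[str, np.ndarray] = {}
    missing: Dict[str, List[str]] = {}
    for panel, markers in panels.items():
        present = [m for m in markers if m in matrix.columns]
        absent = [m for m in markers if m not in matrix.columns]
        if absent:
            missing[panel] = absent
            warnings.warn(
                f"panel {panel!r}: {len(absent)} marker(s) absent from the "
                f"matrix and excluded: {', '.join(absent[:5])}",
                stacklevel=2,
            )
        means = []
        for m in present:
            col = matrix[m]
            rec = {"panel": panel, "marker": m, "mean_all": float(col.mean())}
            if group_arr is not None:
                for level in sorted(set(group_arr)):
                    rec[f"mean_{level}"] = float(col[group_arr == level].mean())
            marker_rows.append(rec)
            means.append(rec["mean_all"])
        panel_means[panel] = np.asarray(means)

    ref = panel_means[reference_panel]
    panel_rows = []
    for panel, means in panel_means.items():
        rec = {
            "panel": panel,
            "n_markers": len(means),
            "n_missing": len(missing.get(panel, [])),
            "panel_mean": float(means.mean()) if len(means) else np.nan,
        }
        if panel != reference_panel:
            if len(means) >= 2 and len(ref) >= 2:
                f, p = f_oneway(ref, means)
                rec["anova_F"], rec["anova_p"] = float(f), float(p)
            else:
                rec["anova_F"], rec["anova_p"] = np.nan, np.nan
        panel_rows.append(rec)
    return {
        "markers": pd.DataFrame(marker_rows),
        "panels": pd.DataFrame(panel_rows),
    }


# ---------------------------------------------------------------------------
# shipped candidate table


def load_candidate_table() -> pd.DataFrame:
    """The curated 53-gene multi-omics candidate table shipped with the package.

    Columns: symbol, cardiomyocyte expression class, plasma detectability,
    O2PLS rank, RNA and protein log2FC, 50 kb acetylome direction match,
    and log2FC in external mutant-vs-control cardiomyocytes (NaN when not
    significant/matching).
    """
    with resources.files("hcmomics.data").joinpath("hcm_candidates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def candidate_table_as_concordance(df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Recast the curated candidate table into concordance-table form."""
    if df is None:
        df = load_candidate_table()
    out = pd.DataFrame({
        "gene": df["symbol"],
        "o2pls_rank": df["o2pls_rank"],
        "rna_log2fc": df["rna_log2fc"],
        "protein_log2fc": df["protein_log2fc"],
        "rna_direction": np.where(df["rna_log2fc"] > 0, "up", "down"),
        "acetylome_match_50kb": df["acetylome_match_50kb"],
        "plasma_detectable": df["plasma"].str.lower().str.replace(" ", "_"),
        "cm_expression": df["cm_expression"],
        "external_cm_log2fc": df["external_cm_log2fc"],
    })
    concordant = (
        (np.sign(out["rna_log2fc"]) == np.sign(out["protein_log2fc"]))
        & (out["acetylome_match_50kb"] == "yes")
    )
    out["fully_concordant_50kb"] = concordant
    return out
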