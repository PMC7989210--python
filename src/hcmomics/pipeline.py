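"""Orchestration: the integrative analysis as one reproducible run.

``integrate`` executes the in-memory stage chain
normalize -> O2PLS -> rank -> intersect with RNA DE -> proteome overlap ->
DAR-to-TSS annotation -> concordance table; ``run_pipeline`` wraps it with
file I/O, configuration validation and a manifest (config echo, seed,
input checksums, package version) so identical config + inputs give
identical outputs. Allele-specific quantification runs independently per
assay via :func:`run_ase`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import allelic, concord, io as hio, o2pls

_PARAM_DEFAULTS = {
    "alpha": 0.05,
    "windows": [5000, 50000],
    "top_k": 2000,
    "min_aligned_frac": 0.9,
    "r": 1,
    "nx": 0,
    "ny": 0,
    "min_count": 10,
    "min_failing_samples": 22,
    "rank_side": "Y",
    "rank_component": 1,
    "seed": 0,
    "log_level": "info",
}

_INPUT_KEYS = {
    "x_matrix", "y_matrix", "groups", "rna_de", "protein_de",
    "acetylome_regions", "tss", "plasma", "external_cm",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    inputs: Dict[str, str]
    output_dir: str
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        merged = dict(_PARAM_DEFAULTS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - {"inputs", "output_dir", "params"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(inputs=raw.get("inputs", {}),
                   output_dir=raw["output_dir"],
                   params=raw.get("params", {}))


def integrate(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    rna_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    acetylome_regions: pd.DataFrame,
    tss: pd.DataFrame,
    groups: Optional[Sequence[str]] = None,
    plasma: Optional[Dict[str, str]] = None,
    external_cm: Optional[Dict[str, float]] = None,
    *,
    r: int = 1,
    nx: int = 0,
    ny: int = 0,
    top_k: int = 2000,
    alpha: float = 0.05,
    windows: Sequence[int] = (5000, 50000),
    min_count: int = 10,
    min_failing_samples: int = 22,
    rank_side: str = "Y",
    rank_component: int = 1,
) -> Dict[str, object]:
    """Run the full integrative chain in memory; returns every stage output."""
    Xf = o2pls.filter_low_counts(X, min_count, min_failing_samples)
    Yf = o2pls.filter_low_counts(Y, min_count, min_failing_samples)
    Xm, Ym = o2pls.match_samples(Xf, Yf)
    Xn = o2pls.log_quantile_normalize(Xm)
    Yn = o2pls.log_quantile_normalize(Ym)
    results = o2pls.fit_o2pls(Xn, Yn, r=r, nx=nx, ny=ny)
    ranked = results.rank_features(side=rank_side, component=rank_component, k=top_k)
    separation = results.separation(groups) if groups is not None else None

    inter = concord.intersect_ranked_de(ranked, rna_de, alpha)
    prot = concord.overlap_proteome(inter["up"], inter["down"], protein_de, alpha)

    dars = acetylome_regions[acetylome_regions["padj"] < alpha]
    acet_by_window = {}
    annotations = {}
    for w in windows:
        ann = concord.annotate_regions(
            dars[["chrom", "start", "end", "log2fc", "padj"]], tss, w)
        annotations[w] = ann
        acet_by_window[w] = concord.acetylome_direction_by_gene(ann)

    table = concord.build_concordance_table(
        prot["up"], prot["down"], acet_by_window,
        plasma=plasma, external_cm=external_cm)
    n_plasma = concord.count_plasma_detectable(table) if len(table) else 0

    return {
        "o2pls": results,
        "ranked": ranked,
        "separation": separation,
        "intersect": inter,
        "proteome": prot,
        "annotations": annotations,
        "concordance": table,
        "n_plasma_detectable": n_plasma,
        "shapes": {
            "X_filtered": Xf.shape, "Y_filtered": Yf.shape,
            "X_matched": Xm.shape, "Y_matched": Ym.shape,
        },
    }


def run_ase(
    sam_path,
    variants_path,
    assay: str,
    min_aligned_frac: float = 0.9,
    dedup: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-specific quantification of one SAM against a variant table.

    Returns (per-variant counts table, per-read calls table). The
    aligned-fraction gate applies to ChIP reads by default; for RNA it is
    off unless explicitly requested via ``min_aligned_frac``.
    """
    reads = hio.read_sam(sam_path)
    variants = hio.read_variants(variants_path)
    counts_rows, call_rows = [], []
    for variant in variants:
        frac = min_aligned_frac if assay == "chip" else None
        counts, calls = allelic.quantify_locus(
            reads, variant, assay, dedup_variants=variants,
            min_aligned_frac=frac, dedup=dedup)
        counts_rows.append({
            "variant": variant.id, "assay": assay,
            "n_wildtype": counts.n_wildtype, "n_mutant": counts.n_mutant,
            "n_unassigned": counts.n_unassigned,
            "n_duplicates_removed": counts.n_duplicates_removed,
            "ratio_percent": counts.ratio_percent,
        })
        for c in calls:
            call_rows.append(dataclasses.asdict(c))
    return pd.DataFrame(counts_rows), pd.DataFrame(call_rows)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the configured integrative run and write the artifact bundle."""
    paths = {k: Path(v) for k, v in config.inputs.items()}
    for key, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"input {key!r}: no such file {p}")

    stage = "load"
    try:
        X = hio.read_count_matrix(paths["x_matrix"])
        Y = hio.read_count_matrix(paths["y_matrix"])
        rna_de = hio.read_de_table(paths["rna_de"])
        protein_de = hio.read_de_table(paths["protein_de"])
        regions = hio.read_bed_regions(paths["acetylome_regions"])
        tss = hio.read_tss_table(paths["tss"])
        groups = None
        if "groups" in paths:
            gdf = pd.read_csv(paths["groups"], sep="\t")
            groups = gdf.set_index("sample")["group"]
        plasma = None
        if "plasma" in paths:
            pdf = pd.read_csv(paths["plasma"], sep="\t")
            plasma = dict(zip(pdf["gene"], pdf["status"]))
        external_cm = None
        if "external_cm" in paths:
            edf = pd.read_csv(paths["external_cm"], sep="\t")
            external_cm = dict(zip(edf["gene"], edf["log2fc"]))

        stage = "integrate"
        p = config.params
        group_list = None
        if groups is not None:
            group_list = [groups[s] for s in X.index if s in groups.index]
        out = integrate(
            X, Y, rna_de, protein_de, regions, tss,
            groups=group_list, plasma=plasma, external_cm=external_cm,
            r=int(p["r"]), nx=int(p["nx"]), ny=int(p["ny"]),
            top_k=int(p["top_k"]), alpha=float(p["alpha"]),
            windows=[int(w) for w in p["windows"]],
            min_count=int(p["min_count"]),
            min_failing_samples=int(p["min_failing_samples"]),
            rank_side=str(p["rank_side"]),
            rank_component=int(p["rank_component"]),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "write"
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.save_o2pls(out["o2pls"], outdir / "o2pls_model")
    hio.write_table(outdir / "ranked_features.tsv", out["ranked"])
    if out["separation"] is not None:
        hio.write_table(outdir / "separation.tsv", out["separation"])
    hio.write_table(outdir / "overlap_up.tsv", out["intersect"]["up"])
    hio.write_table(outdir / "overlap_down.tsv", out["intersect"]["down"])
    hio.write_table(outdir / "proteome_up.tsv", out["proteome"]["up"])
    hio.write_table(outdir / "proteome_down.tsv", out["proteome"]["down"])
    hio.write_table(outdir / "proteome_discordant.tsv", out["proteome"]["discordant"])
    for w, ann in out["annotations"].items():
        hio.write_table(outdir / f"annotation_{w // 1000}kb.tsv", ann)
    hio.write_table(outdir / "concordance.tsv", out["concordance"])

    manifest = {
        "package_version": __version__,
        "config": {"inputs": {k: str(v) for k, v in config.inputs.items()},
                   "output_dir": str(config.output_dir),
                   "params": config.params},
        "input_sha256": {k: _sha256(v) for k, v in paths.items()},
        "n_plasma_detectable": out["n_plasma_detectable"],
        "shapes": {k: list(v) for k, v in out["shapes"].items()},
        "coordinate_conventions": {
            "regions": "0-based half-open (BED)",
            "variants_and_reads": "1-based closed (SAM/VCF)",
            "fold_changes": "log2, case vs control",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
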