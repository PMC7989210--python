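"""Validation studies: parameter recovery, oracles and null behaviour.

These functions re-run the package's own machinery on synthetic data at
stated problem sizes and measure how well ground truth is recovered. They
back both the test suite and the reproduction script; each returns plain
numbers/dicts so callers can assert or report them.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import allelic, concord, o2pls, synthio
from .reads import ref_blocks, base_at

VAR_CLASSES = ("snv", "duplication", "splice_acceptor_snv")
ASSAYS = ("chip", "rna")


# ---------------------------------------------------------------------------
# allele-specific classification recovery


def ase_recovery_study(
    fractions: Sequence[float] = (0.05, 0.25, 0.5),
    depth: int = 5000,
    n_replicates: int = 200,
    seed: int = 0,
    var_classes: Sequence[str] = VAR_CLASSES,
    assays: Sequence[str] = ASSAYS,
) -> Dict[str, object]:
    """Recovery of the planted mutant fraction by the classification rules.

    For every (variant class, assay, fraction) combination and replicate,
    ``depth`` error-free reads are simulated and classified (duplicate
    simulation and removal off: at saturating single-locus depth the
    interval-based duplicate identity cannot distinguish distinct
    molecules, so it is validated separately). Reports the share of
    replicates whose recovered mutant/(mutant+wildtype) fraction falls
    inside the exact central 99 % binomial interval of the planted value,
    and the total number of cross-allele misclassifications (expected 0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_cross = 0
    templates = {vc: synthio.make_locus_template(vc) for vc in var_classes}
    for vc in var_classes:
        template = templates[vc]
        for assay in assays:
            for f in fractions:
                inside = 0
                for _ in range(n_replicates):
                    rep_seed = int(rng.integers(2**31 - 1))
                    reads, truth = synthio.simulate_locus_reads(
                        template, assay, f, depth, seed=rep_seed)
                    counts, calls = allelic.quantify_locus(
                        reads, template.variant, assay, dedup=False)
                    for c in calls:
                        true_origin = truth.origins[c.read_name]
                        if c.call != "unassigned" and c.call != true_origin:
                            n_cross += 1
                    n = counts.n_mutant + counts.n_wildtype
                    lo, hi = binom.ppf([0.005, 0.995], n, f)
                    if lo <= counts.n_mutant <= hi:
                        inside += 1
                rows.append({
                    "var_class": vc, "assay": assay, "fraction": f,
                    "coverage": inside / n_replicates,
                })
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "min_coverage": float(table["coverage"].min()),
        "mean_coverage": float(table["coverage"].mean()),
        "cross_misclassifications": n_cross,
        "n_conditions": len(rows),
    }


# ---------------------------------------------------------------------------
# deduplication vs brute-force oracle


def dedup_bruteforce_oracle(
    n_reads: int = 1000, seed: int = 0, var_class: str = "snv", assay: str = "chip"
) -> Dict[str, int]:
    """Keyed deduplication against a quadratic all-pairs oracle.

    Simulates reads with planted duplicate groups, then counts distinct
    reads by comparing every pair on (reference blocks, bases at the
    non-indel variant positions) — O(n^2) — and checks the keyed
    implementation retains exactly that many reads.
    """
    template = synthio.make_locus_template(var_class)
    # depth chosen so duplicates bring the emitted total near n_reads
    reads, truth = synthio.simulate_locus_reads(
        template, assay, 0.5, depth=int(n_reads * 0.7),
        duplicate_rate=0.3, seed=seed)
    reads = reads[:n_reads]
    variants = [template.variant]
    anchors = [v.pos for v in variants if not v.is_indel]

    def identity(r):
        return (r.chrom, ref_blocks(r), tuple(base_at(r, p) for p in anchors))

    # quadratic oracle: group by pairwise identity
    groups: List[List[int]] = []
    for i, r in enumerate(reads):
        placed = False
        for grp in groups:
            q = reads[grp[0]]
            if identity(r) == identity(q):
                grp.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])

    retained, n_removed = allelic.deduplicate(reads, variants)
    return {
        "oracle_groups": len(groups),
        "retained": len(retained),
        "n_removed": n_removed,
        "n_input": len(reads),
        "agreement": int(len(groups) == len(retained)),
    }


# ---------------------------------------------------------------------------
# O2PLS against a direct SVD oracle


def o2pls_svd_oracle(
    n: int = 24, p: int = 200, q: int = 300, r: int = 3, seed: int = 0
) -> Dict[str, float]:
    """Joint loadings vs truncated SVD of the explicitly formed cross-covariance.

    With no omic-specific components the joint loadings must equal the
    top-r singular-vector pairs of X'Y (up to sign). Also reports the
    orthonormality and reconstruction-identity defects.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     index=[f"S{i}" for i in range(n)],
                     columns=[f"R{j}" for j in range(p)])
    Y = pd.DataFrame(rng.normal(size=(n, q)),
                     index=[f"S{i}" for i in range(n)],
                     columns=[f"G{j}" for j in range(q)])
    res = o2pls.fit_o2pls(X, Y, r=r)

    Xc = X.to_numpy() - X.to_numpy().mean(0)
    Yc = Y.to_numpy() - Y.to_numpy().mean(0)
    M = Xc.T @ Yc
    Uo, so, Vto = np.linalg.svd(M, full_matrices=False)

    W = res.W.to_numpy()
    C = res.C.to_numpy()
    dev = 0.0
    for k in range(r):
        wk, ck = Uo[:, k], Vto[k]
        # each side carries its own largest-entry sign convention, so the
        # oracle vectors are aligned per side
        if np.dot(wk, W[:, k]) < 0:
            wk = -wk
        if np.dot(ck, C[:, k]) < 0:
            ck = -ck
        dev = max(dev, float(np.max(np.abs(wk - W[:, k]))))
        dev = max(dev, float(np.max(np.abs(ck - C[:, k]))))

    ortho = max(
        float(np.max(np.abs(W.T @ W - np.eye(r)))),
        float(np.max(np.abs(C.T @ C - np.eye(r)))),
    )
    recon_x = Xc - (res.T.to_numpy() @ W.T
                    + res.T_x_specific.to_numpy() @ res.P_x_specific.to_numpy().T
                    + res.residual_x.to_numpy())
    recon_y = Yc - (res.U.to_numpy() @ C.T
                    + res.T_y_specific.to_numpy() @ res.P_y_specific.to_numpy().T
                    + res.residual_y.to_numpy())
    recon = max(float(np.max(np.abs(recon_x))), float(np.max(np.abs(recon_y))))
    return {"max_loading_dev": dev, "orthonormality_defect": ortho,
            "reconstruction_defect": recon}


# ---------------------------------------------------------------------------
# joint-component group separation


def separation_study(
    n_seeds: int = 100,
    group_effect: float = 2.0,
    n_samples: int = 24,
    p_regions: int = 300,
    q_genes: int = 200,
    seed: int = 0,
) -> Dict[str, object]:
    """How often the first joint component linearly separates the groups.

    Each replicate simulates a fresh study at the given effect size,
    preprocesses (log + quantile normalization) and fits a one-component
    O2PLS; reported are the share of replicates with perfect linear
    separation on joint component 1 (X side) and the distribution of the
    raw rank AUC (which should centre on 0.5 when the effect is zero).
    """
    rng = np.random.default_rng(seed)
    n_sep = 0
    aucs = []
    for _ in range(n_seeds):
        rep_seed = int(rng.integers(2**31 - 1))
        X, Y, truth = synthio.simulate_multiomics(
            n_samples=n_samples, p_regions=p_regions, q_genes=q_genes,
            joint_rank=1, group_effect=group_effect, n_de=0, seed=rep_seed)
        Xn = o2pls.log_quantile_normalize(X)
        Yn = o2pls.log_quantile_normalize(Y)
        res = o2pls.fit_o2pls(Xn, Yn, r=1)
        rep = res.separation(truth.group_labels)
        row = rep[(rep["side"] == "T") & (rep["component"] == "joint1")].iloc[0]
        n_sep += int(row["separable"])
        aucs.append(float(row["auc"]))
    aucs = np.asarray(aucs)
    return {
        "separation_rate": n_sep / n_seeds,
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std()),
        "aucs": aucs,
    }


# ---------------------------------------------------------------------------
# annotation vs brute force


def annotation_bruteforce_oracle(
    n_regions: int = 500,
    n_tss: int = 50,
    windows: Sequence[int] = concord.WINDOWS,
    seed: int = 0,
) -> Dict[int, int]:
    """Windowed TSS annotation against an all-pairs distance oracle.

    Random regions and TSS (including exact-boundary placements) are
    annotated at each window size; returns, per window, 1 when the
    implementation's (region, gene, distance, nearest) mapping equals the
    brute-force one exactly.
    """
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 2_000_000, size=n_regions)
    lengths = rng.integers(200, 3000, size=n_regions)
    regions = pd.DataFrame({
        "chrom": "chrT", "start": starts, "end": starts + lengths,
        "log2fc": rng.normal(size=n_regions), "padj": rng.random(n_regions),
    })
    tss_pos = rng.integers(0, 2_000_000, size=n_tss - 2)
    # pin two TSS exactly on a window boundary to exercise inclusivity
    boundary = [int(regions.at[0, "start"]) - windows[0],
                int(regions.at[1, "end"]) - 1 + windows[0]]
    tss = pd.DataFrame({
        "gene": [f"g{i:03d}" for i in range(n_tss)],
        "chrom": "chrT",
        "tss": np.concatenate([tss_pos, boundary]),
        "strand": "+",
    })

    results = {}
    for window in windows:
        got = concord.annotate_regions(regions, tss, window)
        got_set = set(zip(got["start"], got["end"], got["gene"], got["distance"], got["nearest"]))
        expected = set()
        for _, reg in regions.iterrows():
            hits = []
            for _, t in tss.iterrows():
                if reg["start"] <= t["tss"] < reg["end"]:
                    d = 0
                elif t["tss"] < reg["start"]:
                    d = int(reg["start"] - t["tss"])
                else:
                    d = int(t["tss"] - (reg["end"] - 1))
                if d <= window:
                    hits.append((d, t["gene"]))
            if not hits:
                continue
            dmin = min(d for d, _ in hits)
            nearest = min(g for d, g in hits if d == dmin)
            for d, g in hits:
                expected.add((reg["start"], reg["end"], g, d,
                              bool(g == nearest and d == dmin)))
        results[window] = int(got_set == expected)
    return results
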