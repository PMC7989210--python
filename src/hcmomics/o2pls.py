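"""Two-way orthogonal partial least squares (O2PLS) for paired omics matrices.

O2PLS decomposes two matrices measured on the same samples — here H3K27ac
region counts and gene expression counts — into *joint*, *omic-specific*
and *residual* parts::

    X = T W' + T_x P_x' + E_x
    Y = U C' + T_y P_y' + E_y

The joint loadings (W, C) are the top singular-vector pairs of the
cross-covariance X'Y, i.e. the linear combinations of regions and genes
that maximise covariation between the two data sets; the joint scores
(T = XW, U = YC) place each heart sample in the shared subspace, where the
first joint component is the axis expected to separate disease from
control without using the labels. Omic-specific components absorb
structured variation present in only one matrix so that it does not leak
into the joint part.

Preprocessing mirrors a count-based two-omics study: a low-count feature
filter, sample matching between the two matrices, then log(1 + x) and
quantile normalization across samples. Columns are mean-centered inside
the fit; no unit-variance scaling is applied.

The module follows the model/results idiom: ``O2PLS(X, Y, ...)`` holds the
data and the component counts, ``fit()`` returns an :class:`O2PLSResults`
carrying loadings, scores, diagnostics, feature ranking and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "filter_low_counts",
    "match_samples",
    "log_quantile_normalize",
    "O2PLS",
    "O2PLSResults",
    "fit_o2pls",
    "joint_scores_separation",
    "rank_features",
]


# ---------------------------------------------------------------------------
# preprocessing


def filter_low_counts(
    matrix: pd.DataFrame, min_count: int = 10, min_failing_samples: int = 22
) -> pd.DataFrame:
    """Drop features with count below ``min_count`` in at least ``min_failing_samples`` samples.

    ``matrix`` is samples x features, raw counts. The defaults express the
    study rule "lower than 10 counts in at least 22 (of 23) samples".
    """
    if min_failing_samples > matrix.shape[0]:
        raise ValueError(
            f"min_failing_samples={min_failing_samples} exceeds the "
            f"{matrix.shape[0]} samples present"
        )
    failing = (matrix < min_count).sum(axis=0)
    return matrix.loc[:, failing < min_failing_samples]


def match_samples(X: pd.DataFrame, Y: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their shared samples, in identical row order.

    Order follows X's ordering of the shared sample ids.
    """
    shared = [s for s in X.index if s in set(Y.index)]
    if not shared:
        raise ValueError("no overlapping samples between the two matrices")
    return X.loc[shared], Y.loc[shared]


def log_quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log(1 + x) then quantile normalization across samples.

    After the quantile step every sample (row) has the identical sorted
    value vector — the mean of the per-rank sorted values — while each
    sample's internal rank order is preserved (ties keep their original
    relative order).
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values: expected non-negative counts")
    logged = np.log1p(values)
    order = np.argsort(logged, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1, kind="stable")
    mean_sorted = np.sort(logged, axis=1).mean(axis=0)
    out = mean_sorted[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# model


def _cross_cov_svd(Xc: np.ndarray, Yc: np.ndarray, r: int):
    """Top-r singular triplets of X'Y without forming the p x q matrix.

    Uses thin SVDs of the (few-sample) matrices: with X = Px Dx Qx' and
    Y = Py Dy Qy', X'Y = Qx (Dx Px'Py Dy) Qy' and the inner n x n matrix
    carries all the singular structure.
    """
    Px, dx, Qxt = np.linalg.svd(Xc, full_matrices=False)
    Py, dy, Qyt = np.linalg.svd(Yc, full_matrices=False)
    B = (dx[:, None] * (Px.T @ Py)) * dy[None, :]
    F, s, Ht = np.linalg.svd(B)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if r > rank:
        raise ValueError(f"r={r} exceeds the rank {rank} of the cross-covariance")
    W = Qxt.T @ F[:, :r]
    C = Qyt.T @ Ht.T[:, :r]
    return W, C, s[:r]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Make the largest-|entry| element of each loading column positive (in place)."""
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0


def _specific_part(M: np.ndarray, T: np.ndarray, W: np.ndarray, n_comp: int):
    """Omic-specific scores/loadings from the joint-fit residual.

    The residual after removing the joint fit is projected orthogonal to
    the joint scores; its dominant singular directions define the specific
    subspace.
    """
    E = M - T @ W.T
    # remove any component of the residual along the joint scores
    Q, _ = np.linalg.qr(T)
    E_perp = E - Q @ (Q.T @ E)
    P_, s_, Vt_ = np.linalg.svd(E_perp, full_matrices=False)
    k = min(n_comp, int(np.sum(s_ > (s_[0] * 1e-12 if s_.size and s_[0] > 0 else 0))))
    T_spec = P_[:, :k] * s_[:k]
    P_spec = Vt_[:k].T
    _fix_signs(P_spec, T_spec)
    return T_spec, P_spec


class O2PLS:
    """O2PLS model for two samples-by-features matrices.

    Parameters
    ----------
    X, Y : DataFrame
        Samples x features, already preprocessed (the class does its own
        column mean-centering but no other normalization). Row indices
        must agree element-wise — run :func:`match_samples` first.
    n_joint : int
        Number of joint components r (the study interprets the first).
    n_x_specific, n_y_specific : int
        Omic-specific component counts nx, ny.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        Y: pd.DataFrame,
        n_joint: int = 1,
        n_x_specific: int = 0,
        n_y_specific: int = 0,
    ) -> None:
        if list(X.index) != list(Y.index):
            raise ValueError("X and Y must contain the same samples in the same order")
        if n_joint < 1:
            raise ValueError("n_joint must be >= 1")
        if n_x_specific < 0 or n_y_specific < 0:
            raise ValueError("specific component counts must be non-negative")
        n = X.shape[0]
        if n_joint + max(n_x_specific, n_y_specific) >= n:
            raise ValueError("n_joint + max(nx, ny) must be smaller than the sample count")
        self.X = X
        self.Y = Y
        self.n_joint = n_joint
        self.n_x_specific = n_x_specific
        self.n_y_specific = n_y_specific

    def fit(self) -> "O2PLSResults":
        Xc = self.X.to_numpy(dtype=float)
        Yc = self.Y.to_numpy(dtype=float)
        x_mean = Xc.mean(axis=0)
        y_mean = Yc.mean(axis=0)
        Xc = Xc - x_mean
        Yc = Yc - y_mean
        r, nx, ny = self.n_joint, self.n_x_specific, self.n_y_specific

        W, C, sv = _cross_cov_svd(Xc, Yc, r)
        T = Xc @ W
        U = Yc @ C

        if nx > 0:
            T_xs, P_xs = _specific_part(Xc, T, W, nx)
        else:
            T_xs = np.zeros((Xc.shape[0], 0))
            P_xs = np.zeros((Xc.shape[1], 0))
        if ny > 0:
            T_ys, P_ys = _specific_part(Yc, U, C, ny)
        else:
            T_ys = np.zeros((Yc.shape[0], 0))
            P_ys = np.zeros((Yc.shape[1], 0))

        if nx > 0 or ny > 0:
            # one deflation pass: re-estimate the joint part on the matrices
            # with the specific structure removed
            Xd = Xc - T_xs @ P_xs.T
            Yd = Yc - T_ys @ P_ys.T
            W, C, sv = _cross_cov_svd(Xd, Yd, r)
            T = Xd @ W
            U = Yd @ C
        else:
            Xd, Yd = Xc, Yc

        _fix_signs(W, T)
        _fix_signs(C, U)

        E_x = Xc - T @ W.T - T_xs @ P_xs.T
        E_y = Yc - U @ C.T - T_ys @ P_ys.T

        comp = [f"joint{k + 1}" for k in range(r)]
        sidx, xf, yf = self.X.index, self.X.columns, self.Y.columns
        return O2PLSResults(
            model=self,
            W=pd.DataFrame(W, index=xf, columns=comp),
            C=pd.DataFrame(C, index=yf, columns=comp),
            T=pd.DataFrame(T, index=sidx, columns=comp),
            U=pd.DataFrame(U, index=sidx, columns=comp),
            singular_values=np.asarray(sv),
            T_x_specific=pd.DataFrame(T_xs, index=sidx,
                                      columns=[f"xspec{k+1}" for k in range(T_xs.shape[1])]),
            P_x_specific=pd.DataFrame(P_xs, index=xf,
                                      columns=[f"xspec{k+1}" for k in range(P_xs.shape[1])]),
            T_y_specific=pd.DataFrame(T_ys, index=sidx,
                                      columns=[f"yspec{k+1}" for k in range(T_ys.shape[1])]),
            P_y_specific=pd.DataFrame(P_ys, index=yf,
                                      columns=[f"yspec{k+1}" for k in range(P_ys.shape[1])]),
            residual_x=pd.DataFrame(E_x, index=sidx, columns=xf),
            residual_y=pd.DataFrame(E_y, index=sidx, columns=yf),
            x_mean=pd.Series(x_mean, index=xf),
            y_mean=pd.Series(y_mean, index=yf),
        )


@dataclass
class O2PLSResults:
    """Fitted O2PLS decomposition.

    ``W``/``C`` are the joint loadings (orthonormal columns), ``T``/``U``
    the joint scores of the X and Y side, plus the omic-specific parts and
    residual matrices; ``X_centered = T W' + T_x_specific P_x_specific' +
    residual_x`` holds exactly (analogously for Y).
    """

    model: O2PLS
    W: pd.DataFrame
    C: pd.DataFrame
    T: pd.DataFrame
    U: pd.DataFrame
    singular_values: np.ndarray
    T_x_specific: pd.DataFrame
    P_x_specific: pd.DataFrame
    T_y_specific: pd.DataFrame
    P_y_specific: pd.DataFrame
    residual_x: pd.DataFrame
    residual_y: pd.DataFrame
    x_mean: pd.Series
    y_mean: pd.Series
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_joint(self) -> int:
        return self.W.shape[1]

    def rank_features(
        self,
        side: str = "Y",
        component: int = 1,
        k: int = 2000,
        across_components: bool = False,
    ) -> pd.DataFrame:
        """Features ranked by joint-loading magnitude, rank 1 = largest.

        By default the ranking uses |loading| on the chosen joint component;
        ``across_components=True`` ranks by the Euclidean norm across all
        joint components instead. Ties break lexicographically by feature
        id. Returns the top ``k`` with columns feature / loading / rank.
        """
        loadings = {"X": self.W, "Y": self.C}[side.upper()]
        if not across_components:
            if not 1 <= component <= loadings.shape[1]:
                raise ValueError(f"component {component} not in 1..{loadings.shape[1]}")
            vals = loadings.iloc[:, component - 1]
        else:
            vals = pd.Series(np.linalg.norm(loadings.to_numpy(), axis=1),
                             index=loadings.index)
        if k > len(vals):
            warnings.warn(
                f"k={k} exceeds the {len(vals)} features; returning all",
                stacklevel=2,
            )
            k = len(vals)
        df = pd.DataFrame({"feature": vals.index, "loading": vals.to_numpy()})
        df["absload"] = df["loading"].abs()
        df = df.sort_values(["absload", "feature"], ascending=[False, True],
                            kind="mergesort").head(k)
        df["rank"] = np.arange(1, len(df) + 1)
        return df[["feature", "loading", "rank"]].reset_index(drop=True)

    def separation(self, groups: Sequence[str]) -> pd.DataFrame:
        """Per-component group separation of the joint scores.

        Reports, per joint component and per side (T = X scores, U = Y
        scores): group score means, the rank-based AUC of scores against
        the binary labels (ties contribute 1/2), the orientation-free AUC
        max(a, 1 - a), and whether the two groups are linearly separable
        (score ranges do not overlap). The statistic is descriptive — the
        underlying claim is about score plots, so no p-value is attached.
        """
        groups = list(groups)
        if len(groups) != self.T.shape[0]:
            raise ValueError("one group label per sample required")
        levels = sorted(set(groups))
        if len(levels) != 2:
            raise ValueError(f"exactly two group levels required, got {levels}")
        pos = np.array([g == levels[1] for g in groups])
        rows = []
        for side, scores in (("T", self.T), ("U", self.U)):
            for comp in scores.columns:
                s = scores[comp].to_numpy()
                auc = _rank_auc(s, pos)
                sep = (s[pos].min() > s[~pos].max()) or (s[~pos].min() > s[pos].max())
                rows.append({
                    "side": side, "component": comp,
                    f"mean_{levels[0]}": float(s[~pos].mean()),
                    f"mean_{levels[1]}": float(s[pos].mean()),
                    "auc": auc, "auc_oriented": max(auc, 1.0 - auc),
                    "separable": bool(sep),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """A compact textual report of the decomposition."""
        m = self.model
        n, p = m.X.shape
        q = m.Y.shape[1]
        lines = [
            "O2PLS decomposition",
            "===================",
            f"samples: {n}   X features: {p}   Y features: {q}",
            f"components: joint={self.n_joint}  x-specific={self.T_x_specific.shape[1]}"
            f"  y-specific={self.T_y_specific.shape[1]}",
            "",
            "joint component   singular value   cov(T, U)",
        ]
        for k in range(self.n_joint):
            cov = float(np.mean(self.T.iloc[:, k] * self.U.iloc[:, k]))
            lines.append(f"  joint{k + 1:<14d}{self.singular_values[k]:>14.4g}{cov:>12.4g}")
        rx = float(np.linalg.norm(self.residual_x.to_numpy()))
        ry = float(np.linalg.norm(self.residual_y.to_numpy()))
        lines += ["", f"residual Frobenius norm: X {rx:.4g}   Y {ry:.4g}"]
        return "\n".join(lines)

    def plot_scores(self, groups: Optional[Sequence[str]] = None, component: int = 1, ax=None):
        """Scatter of the component's X-side vs Y-side joint scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.T.iloc[:, component - 1]
        u = self.U.iloc[:, component - 1]
        if groups is None:
            ax.scatter(t, u)
        else:
            for level in sorted(set(groups)):
                mask = [g == level for g in groups]
                ax.scatter(t[mask], u[mask], label=level)
            ax.legend()
        ax.set_xlabel(f"X joint score {component}")
        ax.set_ylabel(f"Y joint score {component}")
        return ax


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC from average ranks; constant scores give exactly 0.5."""
    n_pos = int(positive.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# functional wrappers mirroring the pipeline vocabulary


def fit_o2pls(X, Y, r: int = 1, nx: int = 0, ny: int = 0) -> O2PLSResults:
    """Fit an O2PLS model; convenience wrapper over :class:`O2PLS`."""
    return O2PLS(X, Y, n_joint=r, n_x_specific=nx, n_y_specific=ny).fit()


def joint_scores_separation(results: O2PLSResults, groups: Sequence[str]) -> pd.DataFrame:
    return results.separation(groups)


def rank_features(results: O2PLSResults, side: str = "Y", component: int = 1,
                  k: int = 2000, across_components: bool = False) -> pd.DataFrame:
    return results.rank_features(side, component, k, across_components)
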