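"""qPCR relative quantification and rank-based validation statistics.

Relative expression is the classic 2^-ddCt: dCt = Ct(target) - Ct(reference),
ddCt = dCt - calibrator, calibrator = mean normal dCt (or the matched
normal of the same animal in paired mode). One PCR cycle is a doubling,
so a ddCt of -k is a 2^k-fold up-regulation.

Group separation is assessed with the exact Mann-Whitney U test: the null
distribution of U for tie-free data is enumerated by dynamic programming
(the count of n1-subsets of ranks 1..n1+n2 attaining each rank sum), the
reported U is min(U1, U2), and the two-sided p doubles the lower tail
(the null is symmetric), capped at 1. The same U yields the empirical
ROC area through AUC = 1 - U/(n1*n2), reported on the >= 0.5 side.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

QPCR_COLUMNS = ["sample_id", "condition", "gene", "ct_target", "ct_reference"]


# ---------------------------------------------------------------------------
# 2^-ddCt


def ddct(
    records: pd.DataFrame,
    calibrator: str = "normal-mean",
) -> pd.DataFrame:
    """Per-sample relative expression 2^-ddCt for each gene.

    ``records`` columns: sample_id, condition (tumor|normal), gene,
    ct_target, ct_reference. ``calibrator="normal-mean"`` subtracts the
    mean normal dCt of the gene; ``"paired"`` subtracts the matched
    normal sample's dCt, pairing tumour and normal rows by sample_id.
    Returns the records plus dct, ddct and rel_expr columns.
    """
    rec = records.copy()
    missing = rec["ct_reference"].isna() | rec["ct_target"].isna()
    if missing.any():
        bad = rec.loc[missing, "sample_id"].iloc[0]
        raise ValueError(f"sample {bad!r} lacks a Ct value")
    rec["dct"] = rec["ct_target"] - rec["ct_reference"]
    out = []
    for gene, grp in rec.groupby("gene", sort=False):
        normals = grp[grp["condition"] == "normal"]
        if normals.empty:
            raise ValueError(f"gene {gene!r} has no normal (calibrator) samples")
        g = grp.copy()
        if calibrator == "normal-mean":
            g["ddct"] = g["dct"] - normals["dct"].mean()
        elif calibrator == "paired":
            cal = normals.set_index("sample_id")["dct"]
            g["ddct"] = g["dct"] - g["sample_id"].map(cal)
            if g["ddct"].isna().any():
                unmatched = g.loc[g["ddct"].isna(), "sample_id"].iloc[0]
                raise ValueError(f"sample {unmatched!r} has no matched normal for pairing")
        else:
            raise ValueError(f"unknown calibrator {calibrator!r}")
        g["rel_expr"] = 2.0 ** (-g["ddct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# exact Mann-Whitney


def u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of subsets giving each U value under the tie-free null.

    ``counts[u]`` is the number of n1-subsets of ranks 1..n1+n2 whose
    Mann-Whitney statistic equals u, for u = 0..n1*n2; the counts sum to
    C(n1+n2, n1). Computed by the standard DP over the recursion
    f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u), carried iteratively with
    exact integer arithmetic (this is the Gaussian binomial coefficient
    expansion).
    """
    umax = n1 * n2
    # table[a][u] for current b; iterate b upward
    prev = [[0] * (umax + 1) for _ in range(n1 + 1)]
    for a in range(n1 + 1):
        prev[a][0] = 1  # b = 0: only u = 0
    for b in range(1, n2 + 1):
        cur = [[0] * (umax + 1) for _ in range(n1 + 1)]
        cur[0][0] = 1
        for a in range(1, n1 + 1):
            for u in range(umax + 1):
                val = prev[a][u]  # last y-element contributes nothing new
                if u >= b:
                    val += cur[a - 1][u - b]
                cur[a][u] = val
        prev = cur
    return np.array(prev[n1], dtype=float)


def exact_u_pvalue(u: int, n1: int, n2: int) -> float:
    """Two-sided exact p at min-orientation U: 2 x P(U <= u), capped at 1."""
    if not 0 <= u <= n1 * n2:
        raise ValueError("U out of range")
    counts = u_null_counts(n1, n2)
    total = comb(n1 + n2, n1)
    p = 2.0 * counts[: u + 1].sum() / total
    return min(p, 1.0)


@dataclass
class TestResult:
    """Mann-Whitney outcome with the derived ROC area."""

    U: float
    n1: int
    n2: int
    p_two_sided: float
    auc: float
    auc_ci: tuple[float, float] | None = None
    method: str = "exact"


def mann_whitney_exact(x, y, seed: int = 0, n_mc: int = 20_000) -> TestResult:
    """Exact Mann-Whitney U test, min-U orientation.

    Ranks use mid-ranks. With no ties the p-value is exact, from the DP
    null distribution of U; with ties the exact tie-free null no longer
    applies and a seeded Monte-Carlo permutation of the group labels is
    used instead (two-sided, via min-U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)

    def min_u(a, b):
        ranks = stats.rankdata(np.concatenate([a, b]))
        r1 = ranks[: len(a)].sum()
        u1 = r1 - len(a) * (len(a) + 1) / 2
        return min(u1, len(a) * len(b) - u1)

    u = min_u(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties:
        p = exact_u_pvalue(int(round(u)), n1, n2)
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        hits = 1
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            if min_u(perm[:n1], perm[n1:]) <= u + 1e-9:
                hits += 1
        p = min(1.0, hits / (n_mc + 1))
        method = "permutation"
    return TestResult(U=float(u), n1=n1, n2=n2, p_two_sided=float(p),
                      auc=auc_from_u(u, n1, n2), method=method)


def auc_from_u(u: float, n1: int, n2: int) -> float:
    """ROC area from the min-orientation U: AUC = 1 - U/(n1*n2), always >= 0.5."""
    if not 0 <= u <= n1 * n2:
        raise ValueError("U out of range")
    return 1.0 - u / (n1 * n2)


# ---------------------------------------------------------------------------
# ROC


def hanley_mcneil_ci(auc: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation confidence interval for an AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    flipped: bool  # True when scores were negated to keep AUC >= 0.5


def roc_curve(values, labels) -> ROCResult:
    """Empirical ROC of a score against binary labels (1 = positive class).

    The AUC is the tie-corrected rank statistic (equal to the Mann-Whitney
    identity on tie-free data); when the raw direction gives AUC < 0.5 the
    score is negated so the reported curve and area sit on the >= 0.5 side,
    matching the min-U convention. CI: Hanley-McNeil.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = values[labels == classes.max()]
    neg = values[labels == classes.min()]
    # rank-statistic AUC with mid-rank tie correction
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    auc = (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    flipped = auc < 0.5
    if flipped:
        auc = 1.0 - auc
        values = -values
    fpr, tpr, thr = _sk_roc_curve((labels == classes.max()).astype(int), values)
    ci = hanley_mcneil_ci(auc, len(pos), len(neg))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc), auc_ci=ci, flipped=flipped)


# ---------------------------------------------------------------------------
# qPCR panel driver


def validate_genes(
    qpcr: pd.DataFrame,
    genes: list[str] | None = None,
    calibrator: str = "normal-mean",
    seed: int = 0,
) -> pd.DataFrame:
    """Run 2^-ddCt + Mann-Whitney + ROC for each target gene in a qPCR table."""
    rel = ddct(qpcr, calibrator=calibrator)
    if genes is None:
        genes = sorted(rel["gene"].unique())
    rows = []
    for gene in genes:
        g = rel[rel["gene"] == gene]
        t = g.loc[g["condition"] == "tumor", "rel_expr"].to_numpy()
        n = g.loc[g["condition"] == "normal", "rel_expr"].to_numpy()
        res = mann_whitney_exact(t, n, seed=seed)
        roc = roc_curve(g["rel_expr"].to_numpy(), (g["condition"] == "tumor").to_numpy().astype(int))
        rows.append({
            "gene": gene, "n_tumor": res.n1, "n_normal": res.n2,
            "U": res.U, "p_two_sided": res.p_two_sided, "method": res.method,
            "auc": roc.auc, "auc_ci_low": roc.auc_ci[0], "auc_ci_high": roc.auc_ci[1],
            "median_rel_expr_tumor": float(np.median(t)),
            "median_rel_expr_normal": float(np.median(n)),
        })
    return pd.DataFrame(rows)
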