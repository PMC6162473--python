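"""Differential expression at fixed fold-change and p-value thresholds.

A gene is a DEG when |log2 fold change| >= 1 (a 2-fold increase or
decrease, inclusive) AND p < 0.01 (strict). The fold change is
log2((mean tumor FPKM + eps) / (mean normal FPKM + eps)) with a small
pseudocount eps guarding near-zero denominators.

Three tests are offered on log2(FPKM + eps):

- ``moderated`` (default): a moderated t with the per-gene pooled
  variance shrunk toward the across-gene mean variance (prior df 4).
  At 2-3 samples per group a per-gene variance estimate has so few
  degrees of freedom that no purely per-gene test can reliably call a
  4-fold effect at p < 0.01; pooling variance information across genes
  is how the standard bulk RNA-seq tools (Cuffdiff's pooled dispersion,
  limma, DESeq2) make this regime workable, and the moderated t is the
  simplest member of that family.
- ``welch``: Welch's unequal-variance t test, per gene only.
- ``permutation``: exact label-permutation test on the difference of
  group means — full enumeration when the number of labelings is at most
  C(10,5) = 252, Monte-Carlo otherwise. Distribution-free, but its p
  cannot go below 2/C(n, n1), so at 3v3 (min p = 0.1) it can never pass
  the p < 0.01 gate; use it for comparisons with 6+ per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

COMPARISONS = ("overall", "complex", "ductal", "simple")

DEG_COLUMNS = ["gene_id", "comparison", "log2fc", "p_value", "direction", "passes"]

MAX_EXACT_LABELINGS = comb(10, 5)


def _permutation_pvalues(
    x: np.ndarray, n1: int, n_mc: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Two-sided permutation p per row for the difference of group means.

    ``x`` is genes x samples with the first ``n1`` columns being group 1.
    Full enumeration of column relabelings when feasible, else Monte-Carlo
    (the observed labeling is always included, so p >= 1/(n_mc+1)).
    """
    n = x.shape[1]
    obs = x[:, :n1].mean(axis=1) - x[:, n1:].mean(axis=1)
    tol = 1e-12
    n_label = comb(n, n1)
    if n_label <= MAX_EXACT_LABELINGS:
        hits = np.zeros(x.shape[0], dtype=np.int64)
        for idx in combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            stat = x[:, sel].mean(axis=1) - x[:, ~sel].mean(axis=1)
            hits += np.abs(stat) >= np.abs(obs) - tol
        return hits / n_label
    rng = np.random.default_rng(seed)
    hits = np.ones(x.shape[0], dtype=np.int64)  # observed labeling counts
    for _ in range(n_mc):
        perm = rng.permutation(n)
        stat = x[:, perm[:n1]].mean(axis=1) - x[:, perm[n1:]].mean(axis=1)
        hits += np.abs(stat) >= np.abs(obs) - tol
    return hits / (n_mc + 1)


def _moderated_pvalues(lt: np.ndarray, ln: np.ndarray, prior_df: float = 4.0) -> np.ndarray:
    """Two-sided moderated t per row on two log-scale groups.

    The pooled per-gene variance (df = n1+n2-2) is shrunk toward the
    across-gene mean pooled variance with ``prior_df`` pseudo-degrees of
    freedom; the t statistic is referred to t(prior_df + n1 + n2 - 2).
    """
    n1, n2 = lt.shape[1], ln.shape[1]
    df_res = n1 + n2 - 2
    v1 = lt.var(axis=1, ddof=1)
    v2 = ln.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_res
    s0 = pooled.mean()
    shrunk = (prior_df * s0 + df_res * pooled) / (prior_df + df_res)
    diff = lt.mean(axis=1) - ln.mean(axis=1)
    se = np.sqrt(shrunk * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2 * stats.t.sf(np.abs(t), prior_df + df_res)
    # degenerate all-zero-variance input: the t is +-inf or 0/0
    p = np.where(np.isnan(t), np.where(np.isclose(diff, 0), 1.0, 0.0), p)
    p = np.where(np.isinf(t), 0.0, p)
    return p


def test_differential(
    matrix: ExpressionMatrix,
    comparison: str = "overall",
    test: Literal["moderated", "welch", "permutation"] = "moderated",
    eps: float = 0.1,
    fc: float = 2.0,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Tumor-vs-normal differential test for one comparison.

    ``comparison`` is ``overall`` (all samples) or a histological subtype
    (that subtype's samples only). Returns one row per gene with columns
    gene_id, comparison, log2fc, p_value, direction (up|down|none), passes.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
    subtype = None if comparison == "overall" else comparison
    tumor = matrix.samples(condition="tumor", subtype=subtype)
    normal = matrix.samples(condition="normal", subtype=subtype)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"comparison {comparison!r} needs >= 2 samples per group "
            f"(tumor n={len(tumor)}, normal n={len(normal)})"
        )
    vt = matrix.values[tumor].to_numpy(dtype=float)
    vn = matrix.values[normal].to_numpy(dtype=float)
    log2fc = np.log2(vt.mean(axis=1) + eps) - np.log2(vn.mean(axis=1) + eps)

    lt = np.log2(vt + eps)
    ln = np.log2(vn + eps)
    if test == "moderated":
        p = _moderated_pvalues(lt, ln)
    elif test == "welch":
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # zero-variance groups trip a scipy precision warning; handled below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(lt, ln, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        # zero-variance rows with equal means are no-signal, not NaN
        same = np.isclose(lt.mean(axis=1), ln.mean(axis=1))
        p = np.where(np.isnan(res.statistic) & same, 1.0, p)
    elif test == "permutation":
        p = _permutation_pvalues(np.hstack([lt, ln]), n1=lt.shape[1], seed=seed)
    else:
        raise ValueError(f"unknown test {test!r}")

    lfc_gate = np.abs(log2fc) >= np.log2(fc)
    passes = lfc_gate & (p < alpha)
    direction = np.where(passes, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "comparison": comparison,
            "log2fc": log2fc,
            "p_value": p,
            "direction": direction,
            "passes": passes,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Venn partition across subtypes


@dataclass
class SubtypePartition:
    """Up/down DEG sets per subtype plus all Venn cells per direction."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]

    def venn_cells(self, direction: Literal["up", "down"]) -> dict[str, set[str]]:
        """All 7 cells of the 3-set Venn diagram, keyed by '+'-joined subtype names.

        A cell key like ``complex`` is the exclusive cell; ``complex+ductal``
        the pairwise-only cell; ``complex+ductal+simple`` the triple cell.
        """
        sets = self.up if direction == "up" else self.down
        names = sorted(sets)
        if len(names) != 3:
            raise ValueError("Venn partition is defined for exactly three subtypes")
        a, b, c = (sets[n] for n in names)
        triple = a & b & c
        cells = {
            "+".join(names): triple,
            f"{names[0]}+{names[1]}": (a & b) - triple,
            f"{names[0]}+{names[2]}": (a & c) - triple,
            f"{names[1]}+{names[2]}": (b & c) - triple,
            names[0]: a - b - c,
            names[1]: b - a - c,
            names[2]: c - a - b,
        }
        return cells

    def exclusive(self, subtype: str, direction: str | None = None) -> set[str]:
        """Genes passing in ``subtype`` and in no other subtype."""
        def excl(sets: Mapping[str, set[str]]) -> set[str]:
            others = set().union(*(v for k, v in sets.items() if k != subtype))
            return sets[subtype] - others
        if direction == "up":
            return excl(self.up)
        if direction == "down":
            return excl(self.down)
        both = {k: self.up[k] | self.down[k] for k in self.up}
        return excl(both)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction in ("up", "down"):
            for cell, genes in self.venn_cells(direction).items():
                rows.append({"direction": direction, "cell": cell, "n": len(genes),
                             "genes": ",".join(sorted(genes))})
        return pd.DataFrame(rows)


def partition_subtypes(records_by_subtype: Mapping[str, pd.DataFrame]) -> SubtypePartition:
    """Set algebra over passing gene_ids of the three subtype comparisons."""
    up, down = {}, {}
    for subtype, rec in records_by_subtype.items():
        passing = rec[rec["passes"]]
        up[subtype] = set(passing.loc[passing["direction"] == "up", "gene_id"])
        down[subtype] = set(passing.loc[passing["direction"] == "down", "gene_id"])
    return SubtypePartition(up=up, down=down)


def summarize_degs(records: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Top-n up- and down-regulated passing DEGs by fold change.

    Sorted by signed log2fc (ties broken lexicographically by gene_id);
    adds a -log10(p) column. Mirrors a top-DEG table.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    passing = records[records["passes"]].copy()
    passing["neg_log10_p"] = -np.log10(passing["p_value"].clip(lower=np.finfo(float).tiny))
    up = passing[passing["log2fc"] > 0].sort_values(
        ["log2fc", "gene_id"], ascending=[False, True]).head(n)
    down = passing[passing["log2fc"] < 0].sort_values(
        ["log2fc", "gene_id"], ascending=[True, True]).head(n)
    up = up.assign(rank=np.arange(1, len(up) + 1), which="up")
    down = down.assign(rank=np.arange(1, len(down) + 1), which="down")
    cols = ["which", "rank", "gene_id", "comparison", "log2fc", "p_value", "neg_log10_p"]
    return pd.concat([up, down], ignore_index=True)[cols]
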