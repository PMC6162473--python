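"""Cross-species comparison of tumour subtype signatures.

Canine subtype-specific DEGs (genes passing in exactly one histological
subtype) are summarised as mean log2(FPKM + eps) over that subtype's
tumour samples, mapped to human genes through a one-to-one ortholog map,
and correlated (Spearman) against each column of a human molecular-subtype
expression panel. The human subtype with the highest correlation is the
candidate counterpart of the canine subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import SubtypePartition
from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """One-to-one canine-to-human gene pairs.

    Built from a possibly redundant two-column table; any canine or human
    gene appearing more than once is dropped entirely (conservative
    one-to-one filtering).
    """

    pairs: pd.DataFrame  # columns: canine_gene_id, human_gene_id

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "OrthologMap":
        t = table.rename(columns=dict(zip(table.columns, ["canine_gene_id", "human_gene_id"])))
        t = t.drop_duplicates()
        multi_c = t["canine_gene_id"].duplicated(keep=False)
        multi_h = t["human_gene_id"].duplicated(keep=False)
        kept = t[~(multi_c | multi_h)].reset_index(drop=True)
        dropped = len(t) - len(kept)
        if dropped:
            logger.info("dropped %d many-to-many ortholog pair(s)", dropped)
        return cls(pairs=kept)

    @classmethod
    def read(cls, path) -> "OrthologMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_human(self) -> pd.Series:
        return self.pairs.set_index("canine_gene_id")["human_gene_id"]


@dataclass
class SubtypeSignature:
    """Subtype-exclusive DEG set with a per-gene canine expression summary."""

    subtype: str
    expression: pd.Series  # index: canine gene_id; mean log2(FPKM+eps), tumour samples

    @property
    def genes(self) -> set[str]:
        return set(self.expression.index)

    @property
    def size(self) -> int:
        return len(self.expression)


def build_signatures(
    partition: SubtypePartition,
    matrix: ExpressionMatrix,
    eps: float = 0.1,
    mode: str = "tumor-mean",
) -> dict[str, SubtypeSignature]:
    """One signature per subtype from the exclusive Venn cells.

    ``mode="tumor-mean"`` (default) summarises each signature gene as the
    mean log2(FPKM+eps) over that subtype's tumour samples;
    ``mode="fold-change"`` uses log2 tumour/normal mean ratio instead.
    Empty signatures are kept (size 0) with a warning so the caller can
    skip their correlations.
    """
    out = {}
    for subtype in sorted(partition.up):
        genes = sorted(partition.exclusive(subtype))
        tumor = matrix.samples(condition="tumor", subtype=subtype)
        if mode == "tumor-mean":
            summary = np.log2(matrix.values.loc[genes, tumor].mean(axis=1) + eps)
        elif mode == "fold-change":
            normal = matrix.samples(condition="normal", subtype=subtype)
            summary = np.log2(matrix.values.loc[genes, tumor].mean(axis=1) + eps) - np.log2(
                matrix.values.loc[genes, normal].mean(axis=1) + eps)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if not genes:
            logger.warning("subtype %s has an empty exclusive signature", subtype)
        out[subtype] = SubtypeSignature(subtype=subtype, expression=summary)
    return out


def _spearman_perm_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact permutation two-sided p for Spearman r (n small).

    All n! orderings of one side are scored at once: Spearman r is the
    Pearson correlation of the rank vectors, so each permuted r is a dot
    product of standardised ranks.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def standardise(v):
        v = v - v.mean()
        norm = np.sqrt((v**2).sum())
        return v / norm if norm else v

    zx = standardise(rx)
    zy = standardise(ry)
    perms = np.array(list(permutations(range(n))))
    rs = zy[perms] @ zx
    return float((np.abs(rs) >= abs(r_obs) - 1e-12).mean())


def correlate_with_panel(
    signature: SubtypeSignature,
    ortholog_map: OrthologMap,
    human_panel: pd.DataFrame,
    eps: float = 0.1,
    log_panel: bool = True,
) -> pd.DataFrame:
    """Spearman correlation of a canine signature against each human subtype.

    ``human_panel`` is human_gene_id x human subtype expression (linear
    scale unless ``log_panel=False``). Returns one row per human subtype
    with r, p and n (mapped genes); a signature mapping to fewer than 3
    panel genes yields an empty frame with a logged reason. p is an exact
    permutation p for n <= 8, otherwise the t approximation.
    """
    mapping = ortholog_map.to_human()
    mapped = signature.expression.rename(index=mapping.to_dict())
    shared = mapped.index.intersection(human_panel.index)
    shared = shared[~shared.isna()] if shared.hasnans else shared
    if len(shared) < 3:
        logger.warning("signature %s: only %d mapped genes; correlation skipped",
                       signature.subtype, len(shared))
        return pd.DataFrame(columns=["canine_subtype", "human_subtype", "r", "p", "n"])
    x = mapped.loc[shared].to_numpy(dtype=float)
    rows = []
    for hs in human_panel.columns:
        y = human_panel.loc[shared, hs].to_numpy(dtype=float)
        if log_panel:
            y = np.log2(y + eps)
        res = stats.spearmanr(x, y)
        r = float(res.statistic)
        p = _spearman_perm_p(x, y, r) if len(shared) <= 8 else float(res.pvalue)
        rows.append({"canine_subtype": signature.subtype, "human_subtype": hs,
                     "r": r, "p": p, "n": len(shared)})
    return pd.DataFrame(rows)


def best_match(correlations: pd.DataFrame) -> str:
    """Human subtype with the highest r (ties broken alphabetically)."""
    if correlations.empty:
        raise ValueError("no correlations computed")
    ordered = correlations.sort_values(["r", "human_subtype"], ascending=[False, True])
    return str(ordered.iloc[0]["human_subtype"])
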