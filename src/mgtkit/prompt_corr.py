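"""Gene-PROMPT concordance: join DEG calls with PROMPT-window fold changes.

A gene and its upstream window form a classified pair when the gene is a
DEG (p < 0.01, |log2FC| >= 1) and the window's own tumour/normal fold
change also clears the 2-fold gate. The pair is *positive* when both fold
changes share a sign (gene up & PROMPT up, or gene down & PROMPT down),
*negative* when they oppose, and *excluded* otherwise. Because a single
fold change is available per gene and per window, concordance of signs is
the per-pair correlation notion; an overall Pearson r across pairs'
(gene log2FC, PROMPT log2FC) quantifies the trend.

Windows with low mean fragment counts are flagged: sign calls from a
handful of fragments are unreliable, which is the practical reason
negative pairs tend to evaporate on inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["gene_id", "gene_log2fc", "gene_p", "prompt_log2fc",
                "prompt_mean_count", "class", "low_count_flag"]


def prompt_fold_changes(
    prompt_counts: pd.DataFrame,
    meta: pd.DataFrame,
    eps: float = 0.1,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-window tumour/normal log2 fold change on CPM-normalised counts.

    ``prompt_counts`` is regions x samples raw fragment counts; ``meta``
    maps sample_id to condition. Counts are scaled per million mapped
    fragments per sample (``library_sizes`` defaults to the column totals)
    before group means, so library-size imbalance cancels. The raw mean
    count is retained for downstream low-count flagging.
    """
    tumor = [s for s in prompt_counts.columns if meta.loc[s, "condition"] == "tumor"]
    normal = [s for s in prompt_counts.columns if meta.loc[s, "condition"] == "normal"]
    if not tumor or not normal:
        raise ValueError("both tumour and normal samples are required")
    if library_sizes is None:
        library_sizes = prompt_counts.sum(axis=0)
    libs = pd.Series(library_sizes).reindex(prompt_counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = prompt_counts.div(libs, axis=1) * 1e6
    log2fc = np.log2(cpm[tumor].mean(axis=1) + eps) - np.log2(cpm[normal].mean(axis=1) + eps)
    return pd.DataFrame({
        "prompt_log2fc": log2fc,
        "prompt_mean_count": prompt_counts.mean(axis=1),
    })


def classify_pairs(
    deg_records: pd.DataFrame,
    prompt_fcs: pd.DataFrame,
    min_mean_count: float = 5.0,
    fc: float = 2.0,
    alpha: float = 0.01,
    prompt_fc: float = 2.0,
    overall_r_over: str = "positive",
) -> tuple[pd.DataFrame, dict]:
    """Join DEGs with PROMPT fold changes and classify each pair.

    Classes: ``positive``/``negative`` when the gene passes its DEG gate
    AND |PROMPT log2FC| >= log2(prompt_fc), by fold-change sign
    concordance; ``excluded`` otherwise. Pairs whose window mean count is
    below ``min_mean_count`` carry ``low_count_flag`` (their sign is
    suspect) but are not re-classified.

    Returns (pairs table, summary). The summary's ``overall_r`` is the
    Pearson correlation of (gene log2FC, PROMPT log2FC) over the
    positive-class pairs by default (``overall_r_over="all-classified"``
    uses positives and negatives together); NaN when fewer than 2 pairs
    qualify. ``overall_r_all_classified`` is always reported alongside.
    """
    degs = deg_records.set_index("gene_id")
    joined = prompt_fcs.join(degs[["log2fc", "p_value", "passes"]], how="inner")
    missing = len(deg_records) - len(joined)
    if missing:
        logger.warning("%d DEG record(s) had no quantified PROMPT window", missing)

    gene_ok = joined["passes"].astype(bool)
    prompt_ok = joined["prompt_log2fc"].abs() >= np.log2(prompt_fc)
    concordant = np.sign(joined["log2fc"]) == np.sign(joined["prompt_log2fc"])
    cls = np.where(gene_ok & prompt_ok, np.where(concordant, "positive", "negative"), "excluded")

    pairs = pd.DataFrame({
        "gene_id": joined.index,
        "gene_log2fc": joined["log2fc"].to_numpy(),
        "gene_p": joined["p_value"].to_numpy(),
        "prompt_log2fc": joined["prompt_log2fc"].to_numpy(),
        "prompt_mean_count": joined["prompt_mean_count"].to_numpy(),
        "class": cls,
        "low_count_flag": (joined["prompt_mean_count"] < min_mean_count).to_numpy(),
    }).reset_index(drop=True)

    def _pearson(sub: pd.DataFrame) -> float:
        if len(sub) < 2 or sub["gene_log2fc"].std() == 0 or sub["prompt_log2fc"].std() == 0:
            return float("nan")
        return float(np.corrcoef(sub["gene_log2fc"], sub["prompt_log2fc"])[0, 1])

    pos = pairs[pairs["class"] == "positive"]
    classified = pairs[pairs["class"] != "excluded"]
    r_pos = _pearson(pos)
    r_all = _pearson(classified)
    summary = {
        "n_positive": int((pairs["class"] == "positive").sum()),
        "n_negative": int((pairs["class"] == "negative").sum()),
        "n_excluded": int((pairs["class"] == "excluded").sum()),
        "n_low_count": int(pairs["low_count_flag"].sum()),
        "overall_r": r_pos if overall_r_over == "positive" else r_all,
        "overall_r_positive": r_pos,
        "overall_r_all_classified": r_all,
    }
    return pairs, summary
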