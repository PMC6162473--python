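"""Stranded fragment counting over genomic features and FPKM conversion.

Fragments are pre-aligned intervals (BED6: chrom, start, end, sample_id,
score, strand), the abstraction of a paired-end, strand-specific library
after alignment. A fragment is counted into every feature it overlaps by
at least ``min_overlap`` bp, subject to the strand mode:

- ``ignore``: strands are not compared (used for PROMPT windows, where
  all mapped signal in the upstream region counts);
- ``same``: fragment strand must equal the feature strand (stranded
  gene-level counting);
- ``opposite``: fragment strand must differ (antisense counting).

FPKM = count x 10^9 / (feature_length x library_size), with library_size
the total mapped fragments of the sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, Interval, PromptRegion

logger = logging.getLogger(__name__)

StrandMode = Literal["ignore", "same", "opposite"]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "sample_id", "score", "strand"]


@dataclass
class Feature:
    """A countable feature: one or more disjoint intervals on one chromosome."""

    feature_id: str
    chrom: str
    strand: str
    intervals: list[Interval]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


def features_from_genes(genes: Sequence[GeneModel]) -> list[Feature]:
    return [Feature(g.gene_id, g.chrom, g.strand, [(g.start, g.end)]) for g in genes]


def features_from_regions(regions: Sequence[PromptRegion]) -> list[Feature]:
    return [Feature(r.gene_id, r.chrom, r.strand, list(r.intervals)) for r in regions]


# ---------------------------------------------------------------------------
# fragment I/O


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read fragments from BED6; the name column holds the sample_id."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "sample_id": str, "strand": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("empty or inverted fragment interval in BED input")
    return df


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.to_csv(path, sep="\t", header=False, index=False, columns=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# counting


def _strand_ok(frag_strand: str, feat_strand: str, mode: StrandMode) -> bool:
    if mode == "ignore":
        return True
    if mode == "same":
        return frag_strand == feat_strand
    return frag_strand != feat_strand


def count_fragments(
    features: Sequence[Feature],
    fragments: pd.DataFrame,
    strand_mode: StrandMode = "same",
    min_overlap: int = 1,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count fragments into features; returns a features x samples integer matrix.

    A fragment overlapping k features increments all k (multi-assignment).
    Overlap of a fragment with a multi-interval feature is the summed
    overlap across the feature's intervals, compared against ``min_overlap``.
    Fragments on chromosomes absent from the features are skipped with a
    logged summary.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if samples is None:
        samples = sorted(fragments["sample_id"].unique())
    sample_idx = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(features), len(samples)), dtype=np.int64)

    by_chrom: dict[str, list[tuple[int, Feature]]] = {}
    for i, f in enumerate(features):
        by_chrom.setdefault(f.chrom, []).append((i, f))

    known = fragments["chrom"].isin(by_chrom)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning("%d fragment(s) on chromosomes absent from the features were skipped", n_skipped)
    frs = fragments.loc[known]

    for chrom, group in frs.groupby("chrom", sort=False):
        feats = by_chrom[chrom]
        fs = group["start"].to_numpy()
        fe = group["end"].to_numpy()
        fstrand = group["strand"].to_numpy()
        fsample = group["sample_id"].to_numpy()
        for i, feat in feats:
            ov = np.zeros(len(group), dtype=np.int64)
            for s, e in feat.intervals:
                ov += np.maximum(0, np.minimum(fe, e) - np.maximum(fs, s))
            hit = ov >= min_overlap
            if strand_mode != "ignore":
                strand_hit = (fstrand == feat.strand) if strand_mode == "same" else (fstrand != feat.strand)
                hit &= strand_hit
            for samp in fsample[hit]:
                j = sample_idx.get(samp)
                if j is not None:
                    counts[i, j] += 1
    return pd.DataFrame(counts, index=[f.feature_id for f in features], columns=list(samples))


# ---------------------------------------------------------------------------
# FPKM


def fpkm(count, feature_length, library_size):
    """Fragments per kilobase of feature per million mapped fragments.

    ``count * 1e9 / (feature_length * library_size)``; scalar or array.
    """
    feature_length = np.asarray(feature_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(feature_length <= 0):
        raise ValueError("feature_length must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    out = np.asarray(count, dtype=float) * 1e9 / (feature_length * library_size)
    return out if out.ndim else float(out)


def fpkm_matrix(
    counts: pd.DataFrame,
    feature_lengths: Mapping[str, int] | pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Convert a features x samples count matrix to FPKM.

    ``library_sizes`` defaults to the column totals of ``counts``; pass the
    true per-sample mapped-fragment totals when the matrix is a subset of
    the library (e.g. PROMPT windows only).
    """
    lengths = pd.Series(feature_lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every counted feature needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths, axis=0).div(libs, axis=1) * 1e9


# ---------------------------------------------------------------------------
# expression container


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    ``values`` holds FPKM (or counts — stated by ``unit``); ``meta`` is
    indexed by sample_id with columns ``animal_id``, ``condition``
    (tumor|normal) and ``subtype`` (complex|ductal|simple).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    feature_lengths: pd.Series | None = None
    unit: str = "fpkm"

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [c for c in ("animal_id", "condition", "subtype") if c not in self.meta.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        unmatched = [s for s in self.values.columns if s not in self.meta.index]
        if unmatched:
            raise ValueError(f"samples without metadata: {unmatched}")
        bad = set(self.meta["condition"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown condition values: {sorted(bad)}")

    def samples(self, condition: str | None = None, subtype: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if condition is not None:
            mask &= self.meta["condition"] == condition
        if subtype is not None:
            mask &= self.meta["subtype"] == subtype
        return [s for s in self.values.columns if mask.get(s, False)]

    def write(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.rename_axis("gene_id").to_csv(values_path, sep="\t")
        self.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")

    @classmethod
    def read(cls, values_path: str | Path, meta_path: str | Path, unit: str = "fpkm") -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, meta=meta, unit=unit)
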