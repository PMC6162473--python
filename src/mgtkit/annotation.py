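"""Gene models, GTF/BED input-output, and promoter-upstream (PROMPT) windows.

Coordinates are 0-based half-open internally. GTF I/O converts to the
format's 1-based inclusive convention; BED I/O is 0-based half-open.

The central operation is :func:`build_prompt_regions`: for every gene the
1500 bp immediately upstream of its transcription start site (TSS), taken
on the gene's own orientation, minus any position covered by a different
gene's transcript span. What remains — possibly several disjoint intervals,
possibly nothing — is the window in which promoter upstream transcripts
(PROMPTs) are quantified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

Interval = tuple[int, int]

ExclusionPolicy = Literal["both-strands", "same-strand", "exons-only"]


class GTFParseError(ValueError):
    """Raised on a malformed GTF line; message carries the line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene: span, strand, exons, and the derived TSS.

    ``start``/``end`` are the 0-based half-open span; ``exons`` are
    non-overlapping, sorted sub-intervals of the span. The TSS is the
    5'-most position on the gene's own strand: ``start`` on ``+``,
    ``end`` on ``-`` (the half-open boundary just past the last base).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start},{self.end}) for {self.gene_id}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s},{e}) outside span of {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def exonic_length(self) -> int:
        if not self.exons:
            return self.end - self.start
        return sum(e - s for s, e in merge_intervals(self.exons))


@dataclass
class PromptRegion:
    """The upstream window of one gene after exclusion of foreign transcript spans.

    ``intervals`` are disjoint, sorted, and contained in the nominal
    window ``[tss-window, tss)`` (transcription-direction coordinates);
    ``effective_length`` is their total span and is 0 for a fully
    excluded (flagged) window.
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: list[Interval]
    window_length: int = 1500

    @property
    def effective_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def empty(self) -> bool:
        return self.effective_length == 0


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/touching intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(window: Interval, blockers: Iterable[Interval]) -> list[Interval]:
    """Positions of ``window`` not covered by any blocker, as sorted disjoint intervals."""
    ws, we = window
    if ws >= we:
        return []
    pieces: list[Interval] = []
    cursor = ws
    for bs, be in merge_intervals(blockers):
        if be <= cursor:
            continue
        if bs >= we:
            break
        if bs > cursor:
            pieces.append((cursor, bs))
        cursor = max(cursor, be)
        if cursor >= we:
            break
    if cursor < we:
        pieces.append((cursor, we))
    return pieces


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect, 1-based inclusive coordinates on disk)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into gene models.

    Exon lines are grouped by ``gene_id``; a gene's span is the envelope
    of its gene line (if present) and its exons. Raises
    :class:`GTFParseError` with the offending line number on malformed input.
    """
    spans: dict[str, list] = {}  # gene_id -> [chrom, strand, start, end, exons]
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise GTFParseError(f"line {lineno}: unknown strand {strand!r}")
            if start1 < 1 or end1 < start1:
                raise GTFParseError(f"line {lineno}: invalid coordinates {start1}-{end1}")
            attrs = _parse_attributes(attr_field)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GTFParseError(f"line {lineno}: missing gene_id attribute")
            start, end = start1 - 1, end1  # to 0-based half-open
            rec = spans.get(gene_id)
            if rec is None:
                spans[gene_id] = rec = [chrom, strand, start, end, []]
                order.append(gene_id)
            else:
                if rec[0] != chrom or rec[1] != strand:
                    raise GTFParseError(f"line {lineno}: gene {gene_id} changes chromosome or strand")
                rec[2] = min(rec[2], start)
                rec[3] = max(rec[3], end)
            if feature == "exon":
                rec[4].append((start, end))
    genes = []
    for gid in order:
        chrom, strand, start, end, exons = spans[gid]
        genes.append(GeneModel(gid, chrom, strand, start, end, tuple(merge_intervals(exons)) if exons else ()))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "mgtkit") -> None:
    """Write gene models as Ensembl-dialect GTF (gene + exon rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "protein_coding";'
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            exons = g.exons or ((g.start, g.end),)
            for i, (s, e) in enumerate(exons, start=1):
                ex_attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; exon_number "{i}";'
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{ex_attrs}\n")


# ---------------------------------------------------------------------------
# PROMPT window construction


def nominal_window(gene: GeneModel, window: int = 1500) -> Interval:
    """The un-excluded upstream window, clipped at chromosome start (position 0)."""
    if gene.strand == "+":
        return (max(0, gene.tss - window), gene.tss)
    return (gene.tss, gene.tss + window)


def build_prompt_regions(
    genes: Sequence[GeneModel],
    window: int = 1500,
    exclusion: ExclusionPolicy = "both-strands",
) -> list[PromptRegion]:
    """Construct the PROMPT window for every gene.

    The nominal window is the ``window`` bp immediately upstream of the
    TSS on the gene's own orientation (clipped at position 0 on ``+``).
    Every position overlapping another gene's transcript span is removed;
    which spans count is set by ``exclusion``:

    - ``both-strands`` (default): any other gene's full span, either strand;
    - ``same-strand``: only other genes on the same strand;
    - ``exons-only``: only other genes' exons (either strand).

    Genes whose window is entirely excluded are retained with
    ``effective_length`` 0 rather than dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    regions = []
    for g in genes:
        win = nominal_window(g, window)
        blockers: list[Interval] = []
        for other in by_chrom[g.chrom]:
            if other.gene_id == g.gene_id:
                continue
            if exclusion == "same-strand" and other.strand != g.strand:
                continue
            if exclusion == "exons-only":
                blockers.extend(other.exons or ((other.start, other.end),))
            else:
                blockers.append((other.start, other.end))
        pieces = subtract_intervals(win, blockers)
        regions.append(PromptRegion(g.gene_id, g.chrom, g.strand, pieces, window_length=window))
    n_empty = sum(r.empty for r in regions)
    if n_empty:
        warnings.warn(f"{n_empty} PROMPT window(s) fully excluded by neighbouring transcripts", stacklevel=2)
    return regions


# ---------------------------------------------------------------------------
# region I/O


def write_regions(regions: Sequence[PromptRegion], path: str | Path) -> None:
    """Write PROMPT intervals as BED6 (0-based half-open), name = gene_id."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in regions:
            for s, e in r.intervals:
                fh.write(f"{r.chrom}\t{s}\t{e}\t{r.gene_id}\t0\t{r.strand}\n")


def read_regions(path: str | Path) -> list[PromptRegion]:
    """Read a BED6 written by :func:`write_regions` back into regions."""
    rows: dict[str, PromptRegion] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, s, e, name, _score, strand = line.rstrip("\n").split("\t")
            if name not in rows:
                rows[name] = PromptRegion(name, chrom, strand, [])
            rows[name].intervals.append((int(s), int(e)))
    for r in rows.values():
        r.intervals.sort()
    return list(rows.values())


def write_modified_gtf(regions: Sequence[PromptRegion], path: str | Path) -> None:
    """Write PROMPT intervals as a GTF (1-based inclusive) of promoter_upstream features."""
    with open(path, "w") as fh:
        fh.write("#!promoter-upstream windows\n")
        for r in regions:
            for i, (s, e) in enumerate(r.intervals, start=1):
                attrs = f'gene_id "{r.gene_id}"; region_part "{i}";'
                fh.write(f"{r.chrom}\tmgtkit\tpromoter_upstream\t{s + 1}\t{e}\t.\t{r.strand}\t.\t{attrs}\n")
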