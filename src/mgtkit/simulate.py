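"""Synthetic study generator: a paired tumour/normal canine mammary-tumour
design with planted, recoverable structure.

Everything the analysis pipeline consumes can be generated here, with no
external download: a gene annotation (GTF), strand-specific fragment
records over promoter-upstream windows (BED), tumour/normal count and
FPKM matrices with sample metadata, an ortholog map plus human
molecular-subtype panel, and qPCR Ct tables.

The default configuration mirrors the emulated study design: eight
animals in three histological subtypes (3 complex, 3 ductal, 2 simple),
one tumour and one matched normal sample per animal; planted
differential effects of at least 2-fold so they clear the DEG gate by
construction; negative-binomial count noise whose dispersion can be sent
to zero for sharp tests; PROMPT windows with >= 4-fold planted
tumour/normal signal on a subset of the planted DEGs; and Ct tables for
12 tumour/normal pairs.

Every generator is a pure function of (config, seed): the same seed
yields byte-identical output files. Each operation draws from its own
seed stream so adding one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, PromptRegion, write_gtf

HUMAN_SUBTYPES = ("ER+", "ER+HER2+", "HER2+", "TNBC")

# per-operation seed stream tags (spawned as default_rng([seed, tag]))
_TAG_ANNOT, _TAG_EXPR, _TAG_FRAG, _TAG_QPCR, _TAG_PANEL = 11, 22, 33, 44, 55


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated design."""

    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (800, 3000)
    intergenic_gap_range: tuple[int, int] = (300, 4000)
    n_animals_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"complex": 3, "ductal": 3, "simple": 2})
    n_planted_degs_overall: int = 10
    n_planted_degs_per_subtype: int = 6
    planted_log2fc_range: tuple[float, float] = (2.0, 4.0)
    nb_dispersion: float = 0.05
    library_size: int = 300_000
    baseline_mean_range: tuple[float, float] = (50.0, 2000.0)
    planted_mass_fraction: float = 0.05  # library share of all planted genes at baseline
    animal_sigma: float = 0.15          # log-normal sd of per-animal baselines
    normal_extra_sigma: float = 0.15    # extra log-normal spread of normal samples
    n_prompt_positive: int = 6
    n_prompt_negative: int = 3
    prompt_fragment_rate: float = 20.0  # expected fragments per active window/sample
    prompt_background_rate: float = 1.0
    prompt_planted_fold: float = 4.0
    fragment_length: int = 80
    qpcr_n_pairs: int = 12
    qpcr_sd_ct: float = 0.8
    ortholog_fraction: float = 0.9
    panel_noise_sd: float = 0.25
    matched_canine_subtype: str = "complex"
    matched_human_subtype: str = "TNBC"

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_chromosomes < 0:
            raise ConfigError("counts must be non-negative")
        if self.n_genes > 0 and self.n_chromosomes == 0:
            raise ConfigError("genes need at least one chromosome")
        for name in ("gene_length_range", "intergenic_gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        lo, hi = self.planted_log2fc_range
        if not 1.0 <= lo <= hi:
            raise ConfigError("planted log2fc magnitudes must be >= 1 (the 2-fold gate)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if not 0 < self.planted_mass_fraction < 1:
            raise ConfigError("planted_mass_fraction must be in (0, 1)")
        if any(v < 0 for v in self.n_animals_per_subtype.values()):
            raise ConfigError("animal counts must be non-negative")
        n_planted = self.n_planted_degs_overall + \
            self.n_planted_degs_per_subtype * len(self.n_animals_per_subtype)
        if n_planted > self.n_genes:
            raise ConfigError(f"{n_planted} planted DEGs exceed {self.n_genes} genes")
        if self.n_prompt_positive + self.n_prompt_negative > self.n_planted_degs_overall:
            raise ConfigError("PROMPT-planted pairs exceed the overall planted DEGs")
        if self.qpcr_n_pairs < 2:
            raise ConfigError("qpcr_n_pairs must be >= 2")
        if self.matched_canine_subtype not in self.n_animals_per_subtype:
            raise ConfigError(f"unknown subtype {self.matched_canine_subtype!r}")
        if self.matched_human_subtype not in HUMAN_SUBTYPES:
            raise ConfigError(f"unknown human subtype {self.matched_human_subtype!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Lay out non-overlapping genes along each chromosome.

    Genes are placed sequentially with intergenic gaps drawn from
    ``intergenic_gap_range`` (so gaps below 1500 bp occur whenever the
    range allows, exercising window exclusion), random strand, and one or
    two exons. Genes never nest or overlap by construction. A divergent
    "- then +" neighbour pair would put both upstream windows into the
    same gap, so that configuration alone gets the gap widened by 3 kb,
    keeping upstream windows essentially non-overlapping while leaving
    window-vs-gene-span collisions (the exclusion case) frequent.
    """
    config.validate()
    rng = _rng(config, _TAG_ANNOT)
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes if config.n_chromosomes else []
    for c in range(config.n_genes % config.n_chromosomes if config.n_chromosomes else 0):
        per_chrom[c] += 1
    gid = 0
    for c, n_here in enumerate(per_chrom, start=1):
        chrom = f"chr{c}"
        cursor = 2000  # leave room for the first gene's upstream window
        prev_strand = None
        for _ in range(n_here):
            gap = int(rng.integers(config.intergenic_gap_range[0], config.intergenic_gap_range[1] + 1))
            length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if prev_strand == "-" and strand == "+":
                gap += 3000  # two upstream windows would meet in this gap
            prev_strand = strand
            start = cursor + gap
            end = start + length
            if length >= 400 and rng.random() < 0.5:
                e1 = int(rng.integers(100, length // 2))
                intron = int(rng.integers(50, max(51, length // 4)))
                exons = ((start, start + e1), (min(start + e1 + intron, end - 50), end))
            else:
                exons = ((start, end),)
            gid += 1
            genes.append(GeneModel(f"GENE{gid:04d}", chrom, strand, start, end, exons))
            cursor = end
    return genes


def chromosome_lengths(genes: list[GeneModel], margin: int = 2000) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in genes:
        out[g.chrom] = max(out.get(g.chrom, 0), g.end + margin)
    return out


# ---------------------------------------------------------------------------
# expression


def sample_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata for the paired design: one tumour + one normal per animal."""
    rows = []
    for subtype in sorted(config.n_animals_per_subtype):
        for i in range(1, config.n_animals_per_subtype[subtype] + 1):
            animal = f"{subtype}_{i}"
            for cond, suffix in (("tumor", "T"), ("normal", "N")):
                rows.append({"sample_id": f"{animal}_{suffix}", "animal_id": animal,
                             "condition": cond, "subtype": subtype})
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class SimulatedExpression:
    counts: pd.DataFrame      # genes x samples
    fpkm: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame       # gene_id, comparison, log2fc
    gene_lengths: pd.Series


def simulate_expression(genes: list[GeneModel], config: SimulationConfig) -> SimulatedExpression:
    """Negative-binomial counts around per-gene baselines with planted effects.

    Per-gene baselines are log-uniform over ``baseline_mean_range`` and
    scaled once (globally) so the expected baseline library is
    ``library_size`` fragments. The planted genes are then jointly
    rescaled to hold ``planted_mass_fraction`` of that library at
    baseline: differential genes are a small share of the transcriptome's
    mass in real libraries, and keeping that share small keeps the
    FPKM composition bias (planted up-regulation inflating tumour library
    totals and deflating every measured fold change) realistically minor. Each animal carries a log-normal baseline
    factor shared by its tumour and normal sample; normal samples get
    extra log-normal spread (normal tissue is the more heterogeneous
    compartment — tumours share a common expression shift).

    Planted effects multiply the tumour mean by 2^log2fc: overall-planted
    genes in every tumour sample, subtype-planted genes only in that
    subtype's tumours. The truth table records gene, comparison, signed
    log2fc. Counts are NB(mean, dispersion); dispersion 0 degenerates to
    Poisson.
    """
    config.validate()
    if not genes:
        raise ValueError("annotation is empty")
    rng = _rng(config, _TAG_EXPR)
    meta = sample_table(config)
    gene_ids = [g.gene_id for g in genes]
    n_g = len(gene_ids)

    lo, hi = config.baseline_mean_range
    baseline = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_g)
    baseline *= config.library_size / baseline.sum()

    # planted assignment: disjoint gene sets, signed magnitudes
    order = rng.permutation(n_g)
    cursor = 0
    truth_rows = []
    lfc = {}  # (comparison) -> array of per-gene log2fc, 0 if unplanted

    def draw_signed(k):
        mags = rng.uniform(*config.planted_log2fc_range, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        return mags * signs

    comparisons = ["overall"] + sorted(config.n_animals_per_subtype)
    counts_planted = {"overall": config.n_planted_degs_overall}
    for s in sorted(config.n_animals_per_subtype):
        counts_planted[s] = config.n_planted_degs_per_subtype
    for comp in comparisons:
        k = counts_planted[comp]
        idx = order[cursor:cursor + k]
        cursor += k
        effects = draw_signed(k)
        arr = np.zeros(n_g)
        arr[idx] = effects
        lfc[comp] = arr
        for i, e in zip(idx, effects):
            truth_rows.append({"gene_id": gene_ids[i], "comparison": comp, "log2fc": float(e)})

    planted_idx = np.flatnonzero(sum(np.abs(v) for v in lfc.values()))
    if 0 < len(planted_idx) < n_g:
        unplanted = np.setdiff1d(np.arange(n_g), planted_idx)
        target = config.planted_mass_fraction * config.library_size
        baseline[planted_idx] *= target / baseline[planted_idx].sum()
        baseline[unplanted] *= (config.library_size - target) / baseline[unplanted].sum()

    animals = meta["animal_id"].unique()
    animal_factor = {
        a: np.exp(rng.normal(0.0, config.animal_sigma, size=n_g)) for a in animals
    }

    counts = pd.DataFrame(0, index=gene_ids, columns=meta.index, dtype=np.int64)
    for sample_id, row in meta.iterrows():
        mean = baseline * animal_factor[row["animal_id"]]
        if row["condition"] == "normal":
            mean = mean * np.exp(rng.normal(0.0, config.normal_extra_sigma, size=n_g))
        else:
            mean = mean * 2.0 ** lfc["overall"] * 2.0 ** lfc[row["subtype"]]
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mean)
            draw = rng.negative_binomial(r, p)
        else:
            draw = rng.poisson(mean)
        counts[sample_id] = draw

    lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
    lib = counts.sum(axis=0).astype(float)
    fpkm = counts.div(lengths, axis=0).div(lib, axis=1) * 1e9
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "comparison", "log2fc"])
    return SimulatedExpression(counts=counts, fpkm=fpkm, meta=meta, truth=truth,
                               gene_lengths=lengths)


# ---------------------------------------------------------------------------
# PROMPT fragments


def _isolated_window_genes(regions: list[PromptRegion]) -> set[str]:
    """Genes whose surviving window shares no base with any other window."""
    events: dict[str, list[tuple[int, int, str]]] = {}
    for r in regions:
        for s, e in r.intervals:
            events.setdefault(r.chrom, []).append((s, e, r.gene_id))
    clashing: set[str] = set()
    for ivs in events.values():
        ivs.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
            if s2 < e1 and g1 != g2:
                clashing.update((g1, g2))
    return {r.gene_id for r in regions} - clashing


def choose_prompt_pairs(
    truth: pd.DataFrame, regions: list[PromptRegion], config: SimulationConfig
) -> tuple[list[str], list[str]]:
    """Pick positive/negative PROMPT-planted genes among overall-planted DEGs.

    Only genes whose window is non-empty and overlaps no other gene's
    window are eligible, so the planted signal is attributable to exactly
    one window (fragments multi-assign across overlapping windows).
    Deterministic: the first usable overall-planted genes in truth order
    become positives, the next ones negatives.
    """
    usable = {r.gene_id for r in regions if not r.empty} & _isolated_window_genes(regions)
    pool = [g for g in truth.loc[truth["comparison"] == "overall", "gene_id"] if g in usable]
    need = config.n_prompt_positive + config.n_prompt_negative
    if len(pool) < need:
        raise ConfigError(f"only {len(pool)} overall-planted genes have usable windows; need {need}")
    return pool[: config.n_prompt_positive], pool[config.n_prompt_positive: need]


def simulate_prompt_fragments(
    regions: list[PromptRegion],
    meta: pd.DataFrame,
    planted_positive: list[str],
    planted_negative: list[str],
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stranded BED-like fragments over PROMPT windows.

    Positive-planted windows move with their gene (window rate is
    ``prompt_planted_fold`` higher in the condition where the gene is
    higher); negative-planted windows move against it. All other windows
    receive the background rate in every sample. Fragment counts per
    window/sample are Poisson; fragments are placed uniformly inside the
    window's surviving intervals, so they never leave chromosome bounds.

    Returns (fragments, prompt_truth) where prompt_truth records
    gene_id, class (positive|negative) and the planted window log2fc per
    condition contrast. Planted genes whose window is fully excluded are
    skipped with a warning row in prompt_truth (class 'skipped').
    """
    import warnings as _warnings

    rng = _rng(config, _TAG_FRAG)
    by_gene = {r.gene_id: r for r in regions}
    gene_sign = truth.set_index("gene_id")["log2fc"].apply(np.sign).to_dict()
    fold = config.prompt_planted_fold
    rows = []
    truth_rows = []

    plan: dict[str, tuple[float, float]] = {}  # gene -> (tumor_rate, normal_rate)
    for gene in planted_positive:
        up = gene_sign.get(gene, 1.0) > 0
        hi_t = config.prompt_fragment_rate
        plan[gene] = (hi_t, hi_t / fold) if up else (hi_t / fold, hi_t)
        truth_rows.append({"gene_id": gene, "class": "positive",
                           "planted_log2fc": float(np.log2(fold) * (1 if up else -1))})
    for gene in planted_negative:
        up = gene_sign.get(gene, 1.0) > 0
        hi_t = config.prompt_fragment_rate
        plan[gene] = (hi_t / fold, hi_t) if up else (hi_t, hi_t / fold)
        truth_rows.append({"gene_id": gene, "class": "negative",
                           "planted_log2fc": float(np.log2(fold) * (-1 if up else 1))})

    for gene in list(plan):
        region = by_gene.get(gene)
        if region is None or region.empty:
            _warnings.warn(f"planted gene {gene} has a fully excluded window; skipped", stacklevel=2)
            for tr in truth_rows:
                if tr["gene_id"] == gene:
                    tr["class"] = "skipped"
            del plan[gene]

    for region in regions:
        if region.empty:
            continue
        starts = np.array([s for s, _ in region.intervals])
        widths = np.array([e - s for s, e in region.intervals], dtype=float)
        cum = np.cumsum(widths)
        total = cum[-1]
        frag_strand = "-" if region.strand == "+" else "+"  # PROMPTs run antisense
        for sample_id, srow in meta.iterrows():
            if region.gene_id in plan:
                t_rate, n_rate = plan[region.gene_id]
                rate = t_rate if srow["condition"] == "tumor" else n_rate
            else:
                rate = config.prompt_background_rate
            k = rng.poisson(rate)
            if k == 0:
                continue
            offs = rng.uniform(0, total, size=k)
            piece = np.searchsorted(cum, offs, side="right")
            for j in range(k):
                i = piece[j]
                within = offs[j] - (cum[i - 1] if i else 0.0)
                s0 = int(starts[i] + within)
                flen = min(config.fragment_length, int(widths[i]))
                s0 = min(s0, int(starts[i] + widths[i]) - flen)
                rows.append((region.chrom, s0, s0 + flen, sample_id, 0, frag_strand))

    fragments = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id", "score", "strand"])
    fragments = fragments.sort_values(["chrom", "start", "end", "sample_id"], kind="stable").reset_index(drop=True)
    prompt_truth = pd.DataFrame(truth_rows, columns=["gene_id", "class", "planted_log2fc"])
    return fragments, prompt_truth


# ---------------------------------------------------------------------------
# ortholog map + human panel


def generate_ortholog_panel(
    fpkm: pd.DataFrame, meta: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-to-one ortholog map plus a human molecular-subtype panel.

    A random ``ortholog_fraction`` of canine genes get a human ortholog.
    The ``matched_human_subtype`` panel column is a noisy monotone
    transform (power 1.3 on the linear scale, log-normal noise of sd
    ``panel_noise_sd``) of the canine tumour-mean profile of
    ``matched_canine_subtype``; the remaining human subtypes are
    independent log-uniform profiles, so only the planted column should
    correlate with that canine subtype's signature.
    """
    rng = _rng(config, _TAG_PANEL)
    canine = list(fpkm.index)
    n_map = int(round(config.ortholog_fraction * len(canine)))
    mapped = sorted(rng.choice(canine, size=n_map, replace=False))
    human_ids = [f"HS_{g}" for g in mapped]
    orthologs = pd.DataFrame({"canine_gene_id": mapped, "human_gene_id": human_ids})

    tumor_cols = [s for s in fpkm.columns
                  if meta.loc[s, "condition"] == "tumor"
                  and meta.loc[s, "subtype"] == config.matched_canine_subtype]
    profile = fpkm.loc[mapped, tumor_cols].mean(axis=1).to_numpy()
    panel = {}
    for hs in HUMAN_SUBTYPES:
        if hs == config.matched_human_subtype:
            vals = (profile + 0.1) ** 1.3 * np.exp(rng.normal(0, config.panel_noise_sd, len(mapped)))
        else:
            vals = 10 ** rng.uniform(0, 3, size=len(mapped))
        panel[hs] = vals
    panel_df = pd.DataFrame(panel, index=pd.Index(human_ids, name="human_gene_id"))
    return orthologs, panel_df


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    config: SimulationConfig,
    planted_fold_changes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Ct table for paired tumour/normal qPCR of target genes vs a reference.

    The reference gene's Ct is condition-independent in expectation; a
    target's tumour Ct is shifted by -log2(fold change) relative to its
    normal baseline. Gaussian measurement noise of sd ``qpcr_sd_ct``
    applies independently to every Ct read-out (target and reference), so
    sd 0 makes the ddCt arithmetic exact. One tumour and one normal row
    per pair per gene: 2 * qpcr_n_pairs rows per gene.
    """
    config.validate()
    if planted_fold_changes is None:
        planted_fold_changes = {"FN1": 6.0, "BGN": 4.0, "SCD": 0.25}
    rng = _rng(config, _TAG_QPCR)
    ref_base = 18.0
    rows = []
    for gi, (gene, fold) in enumerate(sorted(planted_fold_changes.items())):
        if fold <= 0:
            raise ConfigError(f"fold change for {gene} must be positive")
        base = 23.0 + gi
        for p in range(1, config.qpcr_n_pairs + 1):
            for cond in ("tumor", "normal"):
                shift = -np.log2(fold) if cond == "tumor" else 0.0
                rows.append({
                    "sample_id": f"pair{p:02d}",
                    "condition": cond,
                    "gene": gene,
                    "ct_target": base + shift + rng.normal(0, config.qpcr_sd_ct),
                    "ct_reference": ref_base + rng.normal(0, config.qpcr_sd_ct),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call writer


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns name -> path."""
    from .annotation import build_prompt_regions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = generate_annotation(config)
    paths["annotation_gtf"] = outdir / "annotation.gtf"
    write_gtf(genes, paths["annotation_gtf"])

    expr = simulate_expression(genes, config)
    paths["counts_tsv"] = outdir / "counts.tsv"
    paths["fpkm_tsv"] = outdir / "fpkm.tsv"
    paths["meta_tsv"] = outdir / "samples.tsv"
    paths["truth_tsv"] = outdir / "deg_truth.tsv"
    expr.counts.rename_axis("gene_id").to_csv(paths["counts_tsv"], sep="\t")
    expr.fpkm.rename_axis("gene_id").to_csv(paths["fpkm_tsv"], sep="\t")
    expr.meta.rename_axis("sample_id").to_csv(paths["meta_tsv"], sep="\t")
    expr.truth.to_csv(paths["truth_tsv"], sep="\t", index=False)

    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        regions = build_prompt_regions(genes)
    pos, neg = choose_prompt_pairs(expr.truth, regions, config)
    fragments, prompt_truth = simulate_prompt_fragments(regions, expr.meta, pos, neg, expr.truth, config)
    paths["fragments_bed"] = outdir / "prompt_fragments.bed"
    paths["prompt_truth_tsv"] = outdir / "prompt_truth.tsv"
    fragments.to_csv(paths["fragments_bed"], sep="\t", header=False, index=False)
    prompt_truth.to_csv(paths["prompt_truth_tsv"], sep="\t", index=False)

    orthologs, panel = generate_ortholog_panel(expr.fpkm, expr.meta, config)
    paths["orthologs_tsv"] = outdir / "orthologs.tsv"
    paths["human_panel_tsv"] = outdir / "human_panel.tsv"
    orthologs.to_csv(paths["orthologs_tsv"], sep="\t", index=False)
    panel.to_csv(paths["human_panel_tsv"], sep="\t")

    qpcr = simulate_qpcr(config)
    paths["qpcr_tsv"] = outdir / "qpcr_ct.tsv"
    qpcr.to_csv(paths["qpcr_tsv"], sep="\t", index=False)
    return paths
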