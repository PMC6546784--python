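"""Synthetic study-input generator with planted ground truths.

Generates every input the pipeline consumes — a genome with a varying GC
landscape, conservation islands, gene models, element sets, regulatory
annotation peaks with a planted odds ratio, distance-decaying 10 kb contact
maps with planted element-to-promoter loops, two-species staged expression
atlases with planted stage-matched shifts and breakpoint shifts, cell-type
matrices with planted markers, dN/dS tables and module memberships — as pure
functions of (config, seed).  The planted truths are returned in a
:class:`GroundTruth` record so recovery can be scored without re-deriving
randomness.

The background contact model is a Weibull whose scale follows a power-law
distance decay, so the interaction caller's parametric family is
well-specified by default; a log-normal background (``background_family =
"lognormal"``) provides a misspecification mode for robustness reporting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationTrack
from .crossspecies import DEFAULT_STAGE_PAIRS, StagePairTable
from .expression import CellExpression, StagedExpression
from .genome import GenomeSequence
from .hic import ContactMatrix, bin_anchor
from .intervals import GeneModel, IntervalSet, classify_elements

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthStudy",
    "ExpressionBundle",
    "make_genome_and_annotation",
    "make_contact_map",
    "make_expression_atlases",
    "write_study",
]

ELEMENT_CLASSES = ("HAR", "HGE_FB", "HGE_AB", "HLE")


def _field(obj):
    return field(default_factory=lambda: dict(obj) if isinstance(obj, dict) else list(obj))


@dataclass
class SynthConfig:
    """All generator knobs; defaults are the study conditions.

    Element counts follow the four element classes (2737 sequence-accelerated
    regions, 2104 fetal-brain and 1518 adult-brain gained enhancers, 1779
    lost enhancers) placed on a two-chromosome 2 x 20 Mb genome.
    """

    seed: int = 0
    chrom_lengths: dict = _field({"chr1": 20_000_000, "chr2": 20_000_000})
    # GC landscape: per-block GC probability, sinusoidal isochore-like drift
    gc_block: int = 1000
    gc_mean: float = 0.41
    gc_amplitude: float = 0.08
    gc_noise: float = 0.02
    # elements: counts per class; lognormal length parameters (median bp, sigma)
    n_elements: dict = _field(
        {"HAR": 2737, "HGE_FB": 2104, "HGE_AB": 1518, "HLE": 1779}
    )
    element_len_median: dict = _field(
        {"HAR": 230.0, "HGE_FB": 900.0, "HGE_AB": 900.0, "HLE": 900.0}
    )
    element_len_sigma: float = 0.5
    element_min_len: int = 16
    # genes
    n_genes: int = 700
    # conservation islands
    island_fraction: float = 0.05
    island_len: tuple = (200, 800)
    island_score: tuple = (0.55, 0.95)
    background_score_max: float = 0.25
    # regulatory annotation
    annotation_bg_rate: float = 0.15  # fraction of islands carrying a peak
    planted_annotation_or: float = 3.0
    n_neutral_peaks: int = 1500
    neutral_peak_len: int = 500
    # contact model
    bin_size: int = 10_000
    decay_alpha: float = 1.0
    contact_scale: float = 10.0  # Weibull scale at one-bin distance
    contact_shape: float = 4.0
    zero_frac: float = 0.10
    loop_fold: float = 3.0
    n_loops: int = 100
    loop_min_offset: int = 5
    background_family: str = "weibull"  # or "lognormal" (misspecification mode)
    # expression model
    n_orthologs: int = 4125
    human_event_scores: list = _field(
        [0.12, 0.20, 0.28, 0.35, 0.40, 0.46, 0.54, 0.62, 0.70, 0.76, 0.82, 0.88]
    )
    # the macaque grid mirrors the human grid except at the matched stages,
    # whose event scores differ slightly between species by construction
    macaque_event_scores: list = _field(
        [0.12, 0.20, 0.28, 0.35, 0.40, 0.48, 0.51, 0.62, 0.70, 0.77, 0.82, 0.88]
    )
    stage_noise_sd: float = 0.2
    traj_min_amplitude: float = 2.0
    dz_set_size: int = 500
    dz_shift: float = 0.128
    bp_set_size: int = 200
    bp_shift: float = -0.05
    bp_sd: float = 0.10
    # bulk developmental samples
    n_prenatal_stages: int = 6
    n_postnatal_stages: int = 6
    samples_per_stage: int = 5
    bulk_noise_sd: float = 1.0
    prenatal_set_size: int = 400
    prenatal_shift_sd: float = 1.0  # planted shift, in units of sample noise SD
    # cells
    n_clusters: int = 8
    cells_per_cluster: int = 30
    marker_set_size: int = 120
    marker_fold: float = 5.0
    # modules / constraint
    n_modules: int = 100
    module_size: int = 40
    module_or: float = 7.0
    module_set_size: int = 400
    dnds_sigma: float = 0.6
    dnds_background_median: float = 0.5
    dnds_planted_median: float = 0.2
    dnds_set_size: int = 400

    def validate(self) -> None:
        for cls_, n in self.n_elements.items():
            if n < 1:
                raise ValueError(f"n_elements[{cls_}] must be >= 1")
        if self.loop_fold <= 0 or self.marker_fold <= 0:
            raise ValueError("folds must be positive")
        max_len = max(self.chrom_lengths.values())
        if self.island_len[1] >= max_len:
            raise ValueError("elements/islands longer than chromosome")
        if self.background_family not in ("weibull", "lognormal"):
            raise ValueError("background_family must be weibull or lognormal")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw = {k: tuple(v) if isinstance(getattr(cls, k, None), tuple) else v
               for k, v in raw.items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted truths sufficient to score every recovery check."""

    planted_annotation_or: float = float("nan")
    planted_annotation: str = "planted_dhs"
    neutral_annotation: str = "neutral_dhs"
    loops: list = field(default_factory=list)  # dicts with chrom/anchor/target_bin/element/gene
    loop_fold: float = float("nan")
    dz_genes: list = field(default_factory=list)
    dz_shift: float = float("nan")
    bp_genes: list = field(default_factory=list)
    bp_shift: float = float("nan")
    prenatal_genes: list = field(default_factory=list)
    marker_genes: list = field(default_factory=list)
    marker_cluster: str = ""
    module_id: str = ""
    module_set_genes: list = field(default_factory=list)
    module_or: float = float("nan")
    dnds_genes: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    return np.random.Generator(np.random.PCG64(ss))


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------


@dataclass
class SynthStudy:
    config: SynthConfig
    genome: GenomeSequence
    conservation: ConservationTrack
    genes: list
    elements: dict  # class -> IntervalSet
    annotations: dict  # name -> IntervalSet
    truth: GroundTruth


def _make_sequence(config: SynthConfig, rng: np.random.Generator) -> GenomeSequence:
    seqs = {}
    bases_gc = np.frombuffer(b"GC", dtype=np.uint8)
    bases_at = np.frombuffer(b"AT", dtype=np.uint8)
    for chrom, L in config.chrom_lengths.items():
        n_blocks = -(-L // config.gc_block)
        t = np.arange(n_blocks)
        phase = rng.uniform(0, 2 * np.pi)
        p_blocks = (
            config.gc_mean
            + config.gc_amplitude * np.sin(2 * np.pi * t / 400 + phase)
            + rng.normal(0, config.gc_noise, n_blocks)
        )
        p_blocks = np.clip(p_blocks, 0.25, 0.65).astype(np.float32)
        p = np.repeat(p_blocks, config.gc_block)[:L]
        r = rng.random(L, dtype=np.float32)
        is_gc = r < p
        sub = rng.integers(0, 2, size=L).astype(np.uint8)
        arr = np.where(is_gc, bases_gc[sub], bases_at[sub])
        seqs[chrom] = arr
    return GenomeSequence(seqs)


def _make_conservation(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[ConservationTrack, dict[str, np.ndarray]]:
    """Two-level track: low-score background blocks + high-score islands.

    Returns the track and, per chromosome, the island (start, end) arrays.
    """
    pieces = {}
    islands: dict[str, np.ndarray] = {}
    mean_len = sum(config.island_len) / 2
    for chrom, L in config.chrom_lengths.items():
        n_isl = int(config.island_fraction * L / mean_len)
        slot = L // n_isl
        lens = rng.integers(config.island_len[0], config.island_len[1] + 1, n_isl)
        offs = rng.integers(0, np.maximum(slot - lens, 1))
        starts = np.arange(n_isl) * slot + offs
        ends = starts + lens
        islands[chrom] = np.column_stack((starts, ends))
        # background: piecewise-constant low scores on 5 kb blocks
        n_bg = -(-L // 5000)
        bg_scores = rng.uniform(0.0, config.background_score_max, n_bg)
        isl_scores = rng.uniform(*config.island_score, n_isl)
        b: list[int] = [0]
        v: list[float] = []
        pos = 0
        for i in range(n_isl):
            s, e = int(starts[i]), int(ends[i])
            while pos < s:
                nxt = min((pos // 5000 + 1) * 5000, s)
                v.append(float(bg_scores[pos // 5000]))
                b.append(nxt)
                pos = nxt
            v.append(float(isl_scores[i]))
            b.append(e)
            pos = e
        while pos < L:
            nxt = min((pos // 5000 + 1) * 5000, L)
            v.append(float(bg_scores[pos // 5000]))
            b.append(nxt)
            pos = nxt
        pieces[chrom] = (np.array(b), np.array(v))
    return ConservationTrack(pieces), islands


def _make_genes(config: SynthConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], float)
    per_chrom = np.round(weights / weights.sum() * config.n_genes).astype(int)
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        L = config.chrom_lengths[chrom]
        slot = L // n
        for k in range(n):
            span = int(rng.integers(5000, min(30000, slot - 2000)))
            start = k * slot + int(rng.integers(1000, max(slot - span - 1000, 1001)))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(3, 9))
            exons = []
            pos = start
            # n_ex exons of 100-300 bp spread over the span
            ex_lens = rng.integers(100, 301, n_ex)
            gap = (span - int(ex_lens.sum())) // max(n_ex - 1, 1)
            for i in range(n_ex):
                s_ = pos
                e_ = s_ + int(ex_lens[i])
                exons.append((s_, e_))
                pos = e_ + max(gap, 50)
            exons = [(s_, min(e_, end)) for s_, e_ in exons if s_ < end]
            five_first = exons[0] if strand == "+" else exons[-1]
            three_last = exons[-1] if strand == "+" else exons[0]
            if strand == "+":
                utr5 = [(five_first[0], min(five_first[0] + 100, five_first[1]))]
                utr3 = [(max(three_last[1] - 150, three_last[0]), three_last[1])]
            else:
                utr5 = [(max(five_first[1] - 100, five_first[0]), five_first[1])]
                utr3 = [(three_last[0], min(three_last[0] + 150, three_last[1]))]
            total_ex = sum(e_ - s_ for s_, e_ in exons)
            cds_length = max(total_ex - 250, 0)
            tss, tes = (exons[0][0], exons[-1][1]) if strand == "+" else (
                exons[-1][1], exons[0][0]
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                    cds_length=int(cds_length),
                )
            )
            gid += 1
    return genes


def make_genome_and_annotation(config: SynthConfig) -> SynthStudy:
    """Genome, conservation, genes, element classes and annotation peaks.

    Sequence-accelerated elements ("HAR" class) are placed on conservation
    islands, with a configurable fraction landing on islands that carry an
    annotation peak so that the element-vs-conserved-background odds ratio
    equals ``planted_annotation_or`` in expectation.  Enhancer-change classes
    are placed uniformly.  A neutral annotation placed independently of all
    elements supports null calibration.
    """
    config.validate()
    genome = _make_sequence(config, _rng(config, 0))
    track, islands = _make_conservation(config, _rng(config, 1))
    genes = _make_genes(config, _rng(config, 2))
    rng = _rng(config, 3)

    chroms = list(config.chrom_lengths)
    # annotation peaks on a random subset of islands
    peak_recs = []
    peak_flags: dict[str, np.ndarray] = {}
    for chrom in chroms:
        isl = islands[chrom]
        flags = rng.random(len(isl)) < config.annotation_bg_rate
        peak_flags[chrom] = flags
        for s, e in isl[flags]:
            peak_recs.append((chrom, max(int(s) - 100, 0), int(e) + 100))
    planted_annot = IntervalSet.from_records(peak_recs)

    # element placement
    p_b = config.annotation_bg_rate
    odds_e = config.planted_annotation_or * p_b / (1 - p_b)
    p_e = odds_e / (1 + odds_e)
    elements: dict[str, IntervalSet] = {}
    for cls_ in config.n_elements:
        n = config.n_elements[cls_]
        med = config.element_len_median[cls_]
        lens = np.exp(rng.normal(np.log(med), config.element_len_sigma, n))
        lens = np.maximum(lens.astype(int), config.element_min_len)
        recs = []
        if cls_ == "HAR":
            # on islands; peak islands with probability p_e
            all_isl = []
            for chrom in chroms:
                for j, (s, e) in enumerate(islands[chrom]):
                    all_isl.append((chrom, int(s), int(e), bool(peak_flags[chrom][j])))
            on_peak = [x for x in all_isl if x[3]]
            off_peak = [x for x in all_isl if not x[3]]
            choose_peak = rng.random(n) < p_e
            for i in range(n):
                pool = on_peak if choose_peak[i] and on_peak else off_peak
                chrom, s, e, _ = pool[int(rng.integers(0, len(pool)))]
                L = min(int(lens[i]), e - s)
                start = s + int(rng.integers(0, e - s - L + 1))
                recs.append((chrom, start, start + L, f"{cls_}-{i:05d}"))
        else:
            weights = np.array([config.chrom_lengths[c] for c in chroms], float)
            p_chrom = weights / weights.sum()
            ci = rng.choice(len(chroms), size=n, p=p_chrom)
            for i in range(n):
                chrom = chroms[int(ci[i])]
                L = int(lens[i])
                start = int(rng.integers(0, config.chrom_lengths[chrom] - L))
                recs.append((chrom, start, start + L, f"{cls_}-{i:05d}"))
        elements[cls_] = IntervalSet.from_records(recs)

    # neutral annotation, independent of everything
    recs = []
    weights = np.array([config.chrom_lengths[c] for c in chroms], float)
    p_chrom = weights / weights.sum()
    ci = rng.choice(len(chroms), size=config.n_neutral_peaks, p=p_chrom)
    for i in range(config.n_neutral_peaks):
        chrom = chroms[int(ci[i])]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - config.neutral_peak_len))
        recs.append((chrom, start, start + config.neutral_peak_len))
    neutral_annot = IntervalSet.from_records(recs)

    truth = GroundTruth(
        planted_annotation_or=config.planted_annotation_or,
        loop_fold=config.loop_fold,
    )
    return SynthStudy(
        config=config,
        genome=genome,
        conservation=track,
        genes=genes,
        elements=elements,
        annotations={"planted_dhs": planted_annot, "neutral_dhs": neutral_annot},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# contact map
# ---------------------------------------------------------------------------


def decay_scale(config: SynthConfig, offset_bins: np.ndarray) -> np.ndarray:
    """Weibull scale at a given bin offset: power-law distance decay."""
    return config.contact_scale * np.asarray(offset_bins, float) ** (-config.decay_alpha)


def make_contact_map(
    config: SynthConfig,
    study: SynthStudy,
    loop_class: str = "HAR",
) -> tuple[ContactMatrix, list[dict]]:
    """Distance-decaying contact map with planted element-to-promoter loops.

    Background contacts at offset o are Weibull(shape, scale * o^-alpha)
    draws (or log-normal with the same mean in misspecification mode), zeroed
    with probability ``zero_frac``.  ``n_loops`` intergenic single-bin
    elements of ``loop_class`` with interior anchors are paired with gene
    promoter bins 5-99 bins away and their contact is drawn with the scale
    multiplied by ``loop_fold``.  Updates ``study.truth.loops`` and returns
    (matrix, loops).
    """
    rng = _rng(config, 4)
    bin_size = config.bin_size
    n_flank = 99
    n_bins = {c: -(-L // bin_size) for c, L in config.chrom_lengths.items()}
    for c, n in n_bins.items():
        if n < 200:
            raise ValueError(f"{c}: need >= 200 bins for full interior windows")

    # candidate loop elements: intergenic, single-bin, interior anchors
    elems = study.elements[loop_class]
    cats = classify_elements(elems, study.genes)
    from .intervals import promoter_regions

    proms = promoter_regions(study.genes, 2000, config.chrom_lengths)
    prom_bins: dict[str, list[tuple[int, str]]] = {}
    for iv in proms:
        for b in range(iv.start // bin_size, (iv.end - 1) // bin_size + 1):
            prom_bins.setdefault(iv.chrom, []).append((b, iv.name))

    candidates = []
    for i, (iv, cat) in enumerate(zip(elems, cats)):
        bins = bin_anchor(iv, bin_size)
        if cat.category != "intergenic" or len(bins) != 1:
            continue
        a = bins[0]
        if n_flank <= a < n_bins[iv.chrom] - n_flank:
            candidates.append((iv.chrom, a, iv.name))
    rng.shuffle(candidates)

    loops: list[dict] = []
    used_anchor: set[tuple[str, int]] = set()
    for chrom, a, name in candidates:
        if len(loops) >= config.n_loops:
            break
        if (chrom, a) in used_anchor:
            continue
        near = [
            (b, g) for b, g in prom_bins.get(chrom, [])
            if config.loop_min_offset <= abs(b - a) <= n_flank and b != a
        ]
        if not near:
            continue
        b, g = near[int(rng.integers(0, len(near)))]
        used_anchor.add((chrom, a))
        loops.append(
            {
                "chrom": chrom, "anchor": int(a), "target_bin": int(b),
                "element": name, "gene": g,
                "distance": int(abs(b - a)) * bin_size,
            }
        )
    if len(loops) < config.n_loops:
        raise ValueError(
            f"only {len(loops)} plantable loops available (requested {config.n_loops})"
        )

    planted: dict[str, dict[int, list[tuple[int, int]]]] = {}
    for lp in loops:
        lo = min(lp["anchor"], lp["target_bin"])
        hi = max(lp["anchor"], lp["target_bin"])
        planted.setdefault(lp["chrom"], {}).setdefault(hi - lo, []).append((lo, hi))

    def draw(scale: np.ndarray, size: int) -> np.ndarray:
        if config.background_family == "weibull":
            return scale * rng.weibull(config.contact_shape, size)
        # log-normal with the same mean as the Weibull cell
        from scipy.special import gamma as _gamma

        mean = scale * _gamma(1 + 1 / config.contact_shape)
        sigma = 0.35
        return rng.lognormal(np.log(mean) - sigma**2 / 2, sigma, size)

    triplets: dict[str, np.ndarray] = {}
    for chrom, n in n_bins.items():
        ii, jj, vv = [], [], []
        for o in range(1, n_flank + 1):
            m = n - o
            scale = float(decay_scale(config, np.array([o]))[0])
            vals = draw(np.full(m, scale), m)
            vals[rng.random(m) < config.zero_frac] = 0.0
            for lo, hi in planted.get(chrom, {}).get(o, []):
                vals[lo] = float(draw(np.array([scale * config.loop_fold]), 1)[0])
                while vals[lo] <= 0:
                    vals[lo] = float(draw(np.array([scale * config.loop_fold]), 1)[0])
            keep = vals > 0
            ii.append(np.arange(m)[keep])
            jj.append(np.arange(o, n)[keep])
            vv.append(vals[keep])
        triplets[chrom] = np.column_stack(
            (np.concatenate(ii), np.concatenate(jj), np.concatenate(vv))
        )
    matrix = ContactMatrix.from_coo(triplets, n_bins, bin_size)
    study.truth.loops = loops
    return matrix, loops


# ---------------------------------------------------------------------------
# expression atlases
# ---------------------------------------------------------------------------


@dataclass
class ExpressionBundle:
    ortholog_ids: list
    human_stages: pd.DataFrame  # genes x stage labels (event-score strings)
    macaque_stages: pd.DataFrame
    stage_pairs: StagePairTable
    bulk: StagedExpression
    cells: CellExpression
    breakpoints: pd.Series
    dnds: pd.DataFrame
    modules: pd.Series
    gene_sets: dict
    cds_length: pd.Series
    truth: GroundTruth


def make_expression_atlases(
    config: SynthConfig,
    gene_ids: Sequence[str] | None = None,
    dz_genes: Sequence[str] | None = None,
    truth: GroundTruth | None = None,
) -> ExpressionBundle:
    """Two-species staged atlases, bulk samples, cells, and gene tables.

    Ortholog trajectories are smooth logistic ramps of the developmental
    event score, shared between species, plus independent stage noise.  The
    planted stage-shift set receives, at the event-score-matched human
    stages, an additive shift equal to ``dz_shift`` times the gene's
    across-stage SD (mean-compensated at the remaining stages), so its
    post-normalisation delta expression Z equals ``dz_shift`` up to noise.
    ``gene_ids`` optionally names the first orthologs (to share ids with a
    generated genome); ``dz_genes`` optionally pins the planted set.
    """
    rng = _rng(config, 5)
    n = config.n_orthologs
    ids = [f"G{k:05d}" for k in range(n)]
    if gene_ids is not None:
        if len(gene_ids) > n:
            raise ValueError("gene_ids longer than n_orthologs")
        ids[: len(gene_ids)] = list(gene_ids)
    truth = truth if truth is not None else GroundTruth()

    h_scores = list(config.human_event_scores)
    m_scores = list(config.macaque_event_scores)
    # one set of ramp parameters shared by both species (orthologous
    # trajectories), drawn from a dedicated stream
    rng2 = _rng(config, 6)
    base = rng2.normal(8.0, 1.0, n)
    # every gene carries a real developmental ramp (minimum amplitude), so
    # stage Z-scores reflect trajectory shape rather than measurement noise
    amp = rng2.choice([-1.0, 1.0], n) * (
        config.traj_min_amplitude + np.abs(rng2.normal(0.0, 1.5, n))
    )
    mid = rng2.uniform(0.2, 0.8, n)
    width = rng2.uniform(0.05, 0.2, n)

    def ramp(scores):
        e = np.asarray(scores)[None, :]
        return base[:, None] + amp[:, None] / (
            1 + np.exp(-(e - mid[:, None]) / width[:, None])
        )

    H = ramp(h_scores) + rng.normal(0, config.stage_noise_sd, (n, len(h_scores)))
    M = ramp(m_scores) + rng.normal(0, config.stage_noise_sd, (n, len(m_scores)))

    # planted stage-matched shift
    pairs = DEFAULT_STAGE_PAIRS
    h_labels = [f"{s:g}" for s in h_scores]
    m_labels = [f"{s:g}" for s in m_scores]
    matched_idx = [h_labels.index(p.human_stage) for p in pairs]
    if dz_genes is None:
        dz_idx = rng.choice(n, size=config.dz_set_size, replace=False)
        dz_genes = [ids[k] for k in dz_idx]
    else:
        pos = {g: k for k, g in enumerate(ids)}
        dz_idx = np.array([pos[g] for g in dz_genes])
    k = len(matched_idx)
    n_st = len(h_scores)
    sd = H[dz_idx].std(axis=1, ddof=1)
    shift = config.dz_shift * sd
    H[np.ix_(dz_idx, matched_idx)] += shift[:, None]
    others = [i for i in range(n_st) if i not in matched_idx]
    H[np.ix_(dz_idx, others)] -= (shift * k / (n_st - k))[:, None]

    human_stages = pd.DataFrame(H, index=ids, columns=h_labels)
    macaque_stages = pd.DataFrame(M, index=ids, columns=m_labels)

    # breakpoints
    bp = rng.normal(0, config.bp_sd, n)
    bp_idx = rng.choice(n, size=config.bp_set_size, replace=False)
    bp[bp_idx] += config.bp_shift
    breakpoints = pd.Series(bp, index=ids, name="delta_breakpoint")
    bp_genes = [ids[k_] for k_ in bp_idx]

    # bulk developmental samples (prenatal / postnatal periods)
    n_stages = config.n_prenatal_stages + config.n_postnatal_stages
    samples, stage_lab, period_lab, ages = [], [], [], []
    for si in range(n_stages):
        period = "prenatal" if si < config.n_prenatal_stages else "postnatal"
        for r in range(config.samples_per_stage):
            samples.append(f"s{si:02d}_{r}")
            stage_lab.append(f"stage{si:02d}")
            period_lab.append(period)
            ages.append(float(si))
    mu = rng.uniform(3, 10, n)
    bulk_vals = mu[:, None] + rng.normal(
        0, config.bulk_noise_sd, (n, len(samples))
    )
    pre_idx = rng.choice(n, size=config.prenatal_set_size, replace=False)
    prenatal_genes = [ids[k_] for k_ in pre_idx]
    pre_cols = [i for i, p in enumerate(period_lab) if p == "prenatal"]
    bulk_vals[np.ix_(pre_idx, pre_cols)] += (
        config.prenatal_shift_sd * config.bulk_noise_sd
    )
    bulk_expr = np.maximum(np.power(2.0, bulk_vals) - 1, 0.0)  # counts-like, >= 0
    bulk = StagedExpression(
        values=pd.DataFrame(bulk_expr, index=ids, columns=samples),
        metadata=pd.DataFrame(
            {"stage": stage_lab, "age": ages, "period": period_lab}, index=samples
        ),
    )

    # single cells with one planted marker cluster
    clusters = [f"cluster{c}" for c in range(config.n_clusters)]
    cell_ids, cell_lab = [], []
    for c in clusters:
        for r in range(config.cells_per_cluster):
            cell_ids.append(f"{c}_cell{r}")
            cell_lab.append(c)
    cell_mu = rng.uniform(1, 6, n)
    cell_vals = cell_mu[:, None] + rng.normal(0, 0.5, (n, len(cell_ids)))
    marker_idx = rng.choice(n, size=config.marker_set_size, replace=False)
    marker_genes = [ids[k_] for k_ in marker_idx]
    marker_cluster = clusters[int(rng.integers(0, len(clusters)))]
    mc_cols = [i for i, lab in enumerate(cell_lab) if lab == marker_cluster]
    cell_expr = np.power(2.0, cell_vals)
    cell_expr[np.ix_(marker_idx, mc_cols)] *= config.marker_fold
    cells = CellExpression(
        values=pd.DataFrame(cell_expr, index=ids, columns=cell_ids),
        clusters=pd.Series(cell_lab, index=cell_ids),
    )

    # dN/dS per species pair; planted purifying set
    dnds_idx = rng.choice(n, size=config.dnds_set_size, replace=False)
    dnds_genes = [ids[k_] for k_ in dnds_idx]
    rows = []
    for pair in ("mouse", "macaque", "chimpanzee"):
        med = np.full(n, config.dnds_background_median)
        med[dnds_idx] = config.dnds_planted_median
        ratio = np.exp(rng.normal(np.log(med), config.dnds_sigma))
        ds = np.exp(rng.normal(np.log(0.2), 0.3, n))
        rows.append(
            pd.DataFrame(
                {"gene": ids, "dN": ratio * ds, "dS": ds, "species_pair": pair}
            )
        )
    dnds = pd.concat(rows, ignore_index=True)

    # modules: uniform assignment, then a planted module overlapping a set
    module_of = np.array(
        [f"M{rng.integers(0, config.n_modules):03d}" for _ in range(n)], dtype=object
    )
    set_idx = rng.choice(n, size=config.module_set_size, replace=False)
    module_set_genes = [ids[k_] for k_ in set_idx]
    m_size, s_size = config.module_size, config.module_set_size
    # overlap achieving the target odds ratio in expectation
    best_o, best_err = 1, np.inf
    for o in range(1, min(m_size, s_size)):
        d_ = n - s_size - m_size + o
        if d_ <= 0 or (s_size - o) <= 0 or (m_size - o) <= 0:
            continue
        or_ = o * d_ / ((s_size - o) * (m_size - o))
        err = abs(np.log(or_) - np.log(config.module_or))
        if err < best_err:
            best_o, best_err = o, err
    in_set = set_idx[: best_o]
    outside = np.setdiff1d(np.arange(n), set_idx)
    rest = rng.choice(outside, size=m_size - best_o, replace=False)
    module_of[np.concatenate((in_set, rest))] = "M_PLANTED"
    modules = pd.Series(module_of, index=ids, name="module")

    cds_length = pd.Series(
        np.exp(rng.normal(np.log(1500), 0.6, n)).astype(int), index=ids,
        name="cds_length",
    )

    gene_sets = {
        "dz_set": list(dz_genes),
        "breakpoint_set": bp_genes,
        "prenatal_set": prenatal_genes,
        "marker_set": marker_genes,
        "module_set": module_set_genes,
        "dnds_set": dnds_genes,
    }
    truth.dz_genes = list(dz_genes)
    truth.dz_shift = config.dz_shift
    truth.bp_genes = bp_genes
    truth.bp_shift = config.bp_shift
    truth.prenatal_genes = prenatal_genes
    truth.marker_genes = marker_genes
    truth.marker_cluster = marker_cluster
    truth.module_id = "M_PLANTED"
    truth.module_set_genes = module_set_genes
    truth.module_or = config.module_or
    truth.dnds_genes = dnds_genes

    return ExpressionBundle(
        ortholog_ids=ids,
        human_stages=human_stages,
        macaque_stages=macaque_stages,
        stage_pairs=pairs,
        bulk=bulk,
        cells=cells,
        breakpoints=breakpoints,
        dnds=dnds,
        modules=modules,
        gene_sets=gene_sets,
        cds_length=cds_length,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_study(
    study: SynthStudy,
    outdir: str | Path,
    contacts: ContactMatrix | None = None,
    expression: ExpressionBundle | None = None,
    write_fasta: bool = True,
) -> None:
    """Write every generated input in the formats the readers consume."""
    from .intervals import write_gene_models, write_intervals

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if write_fasta:
        study.genome.write_fasta(out / "genome.fa")
    with open(out / "chrom.sizes", "w") as fh:
        for c, L in study.config.chrom_lengths.items():
            fh.write(f"{c}\t{L}\n")
    study.conservation.to_bedgraph(out / "conservation.bedGraph")
    write_gene_models(study.genes, out / "genes.gtf")
    for cls_, ivs in study.elements.items():
        write_intervals(ivs, out / f"elements_{cls_}.bed")
    for name, ivs in study.annotations.items():
        write_intervals(ivs, out / f"annotation_{name}.bed")
    if contacts is not None:
        contacts.write_coo(out / "contacts.coo.tsv")
    if expression is not None:
        e = expression
        e.human_stages.to_csv(out / "expr_human_stages.tsv", sep="\t", float_format="%.6g")
        e.macaque_stages.to_csv(out / "expr_macaque_stages.tsv", sep="\t", float_format="%.6g")
        e.bulk.values.to_csv(out / "expr_bulk.tsv", sep="\t", float_format="%.6g")
        e.bulk.metadata.to_csv(out / "expr_bulk_metadata.tsv", sep="\t")
        e.cells.values.to_csv(out / "expr_cells.tsv", sep="\t", float_format="%.6g")
        e.cells.clusters.rename("cluster").to_csv(out / "expr_cell_clusters.tsv", sep="\t")
        e.breakpoints.to_csv(out / "breakpoints.tsv", sep="\t", float_format="%.6g")
        e.dnds.to_csv(out / "dnds.tsv", sep="\t", index=False, float_format="%.6g")
        e.modules.to_csv(out / "modules.tsv", sep="\t")
        e.cds_length.to_csv(out / "cds_length.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "human_score": p.human_score, "macaque_score": p.macaque_score,
                    "human_stage": p.human_stage, "macaque_stage": p.macaque_stage,
                }
                for p in e.stage_pairs
            ]
        ).to_csv(out / "stage_pairs.tsv", sep="\t", index=False)
        with open(out / "gene_sets.tsv", "w") as fh:
            fh.write("gene\tset_name\n")
            for name, genes_ in e.gene_sets.items():
                for g in genes_:
                    fh.write(f"{g}\t{name}\n")
    study.truth.to_json(out / "ground_truth.json")
    study.config.to_yaml(out / "config.yaml")
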