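"""Synthetic Hi-C / ChIP / expression / dSTORM data with recorded ground truth.

Every downstream stage of the package is exercised on data from this
module, so each generator records exactly what it planted
(:class:`SyntheticTruth`) and is deterministic given ``(config, seed)``.

The contact-map model: expected counts decay with genomic distance as
``(d_bins + 1) ** -decay_exponent``, modulated multiplicatively by a
compartment plaid (same-label bin pairs up, cross-label down), by
per-boundary depletion of boundary-crossing pairs, and by focal loop
enrichments at chosen anchor pixels.  Each replicate is an independent
Poisson draw around that structured expectation — the same background
model the loop caller assumes.  Replicate noise of real proximity-ligation
libraries is plausibly over-dispersed; Poisson is an explicit modelling
choice here, not a claim about the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic import ContactMatrix

__all__ = [
    "LoopSpec",
    "SynthConfig",
    "PlantedLoop",
    "PeakPlacement",
    "GeneAssignment",
    "SyntheticTruth",
    "generate_hic_experiment",
    "generate_peak_tracks",
    "generate_expression",
    "generate_storm_pair",
    "generate_sequences",
]


@dataclass
class LoopSpec:
    """One planted loop: two on-bin anchors and its enrichment.

    ``condition_factors`` multiplies the base enrichment per condition,
    e.g. ``{"WT": 1.0, "MKO": 3.0}`` plants a loop three-fold stronger in
    the MKO maps.  ``myod`` / ``ctcf`` say which anchors carry a binding
    site ("both", "left", "right", "none"); ``myod_dynamic`` is the
    ChIP dynamic label planted for the MyoD peaks and ``gene_log2fc``
    the expression effect planted for the gene assigned to this loop
    (None = no gene).
    """

    anchor1: int  # bp
    anchor2: int  # bp
    enrichment: float = 5.0
    condition_factors: dict[str, float] | None = None
    myod: str = "none"
    ctcf: str = "none"
    myod_dynamic: str = "static"
    gene_log2fc: float | None = None


@dataclass
class SynthConfig:
    n_chroms: int = 1
    chrom_length: int = 3_000_000
    resolution: int = 10_000
    depth: float = 800_000.0
    decay_exponent: float = 1.0
    compartment_block_size: int = 0  # 0 disables the plaid
    plaid_strength: float = 1.0
    boundary_positions: list[tuple[int, float]] = field(default_factory=list)
    loop_specs: list[LoopSpec] = field(default_factory=list)
    conditions: tuple[str, ...] = ("WT", "MKO")
    replicates_per_condition: int = 2
    peak_width: int = 2_000
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length % self.resolution:
            raise ValueError("resolution must divide chrom_length")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.compartment_block_size % max(self.resolution, 1):
            if self.compartment_block_size:
                raise ValueError("compartment_block_size must be a bin multiple")
        if self.plaid_strength < 1:
            raise ValueError("plaid_strength must be >= 1")
        for pos, f in self.boundary_positions:
            if not (0 < f <= 1):
                raise ValueError(f"boundary depletion factor {f} outside (0, 1]")
            if pos % self.resolution:
                raise ValueError(f"boundary position {pos} is off-bin")
        for spec in self.loop_specs:
            if spec.anchor1 % self.resolution or spec.anchor2 % self.resolution:
                raise ValueError(f"loop anchor off-bin: {spec.anchor1}, {spec.anchor2}")
            if spec.enrichment < 1:
                raise ValueError("loop enrichment factors must be >= 1")
            for f in (spec.condition_factors or {}).values():
                if f <= 0:
                    raise ValueError("condition factors must be positive")

    @property
    def n_bins(self) -> int:
        return self.chrom_length // self.resolution


@dataclass
class PlantedLoop:
    chrom: str
    bin1: int
    bin2: int
    enrichment: float
    condition_factors: dict[str, float]
    background_lambda: dict[str, float]  # expectation at the pixel without the loop factor
    spec: LoopSpec


@dataclass
class PeakPlacement:
    chrom: str
    start: int
    end: int
    factor: str  # MyoD / CTCF / H3K27ac
    dynamic: str  # static / enhanced / reduced
    loop_index: int | None = None


@dataclass
class GeneAssignment:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    loop_index: int | None
    log2fc: float  # planted second-condition / first-condition effect


@dataclass
class SyntheticTruth:
    """Everything the generators planted, for downstream recovery checks."""

    chrom_names: list[str]
    n_bins: int
    resolution: int
    compartment_labels: dict[str, np.ndarray]  # per chrom, 'A'/'B' per bin
    boundary_bins: dict[str, list[tuple[int, float]]]
    loops: list[PlantedLoop] = field(default_factory=list)
    peak_placements: list[PeakPlacement] = field(default_factory=list)
    gene_assignments: list[GeneAssignment] = field(default_factory=list)
    storm_overlap_fraction: float | None = None
    rigid_shift: tuple[int, int] | None = None


def _structured_expectation(config: SynthConfig, condition: str, chrom_idx: int):
    """Dense expectation matrix for one chromosome plus per-loop backgrounds."""
    n = config.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = (d + 1.0) ** (-config.decay_exponent)

    labels = np.full(n, "A", dtype="<U1")
    if config.compartment_block_size and config.plaid_strength > 1:
        block = config.compartment_block_size // config.resolution
        labels = np.where((idx // block) % 2 == 0, "A", "B")
        same = labels[:, None] == labels[None, :]
        lam = np.where(same, lam * config.plaid_strength, lam / config.plaid_strength)

    for pos, f in config.boundary_positions:
        b = pos // config.resolution
        cross = (idx[:, None] < b) & (idx[None, :] >= b)
        lam = np.where(cross | cross.T, lam * f, lam)

    # scale the background so each replicate's expected cis total is `depth`
    upper_total = np.triu(lam).sum()
    lam *= config.depth / upper_total

    chrom = f"chr{chrom_idx + 1}"
    backgrounds = []
    for spec in config.loop_specs:
        b1 = spec.anchor1 // config.resolution
        b2 = spec.anchor2 // config.resolution
        backgrounds.append(float(lam[b1, b2]))
        factor = spec.enrichment * (spec.condition_factors or {}).get(condition, 1.0)
        lam[b1, b2] *= factor
        lam[b2, b1] = lam[b1, b2]
    return lam, labels, chrom, backgrounds


def generate_hic_experiment(config: SynthConfig, seed: int | None = None):
    """Poisson-sampled contact maps per condition x replicate, plus truth.

    Returns ``(matrices, truth)`` where ``matrices[condition][rep]`` is a
    list of per-chromosome :class:`ContactMatrix`.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(config.n_chroms * len(config.conditions) * config.replicates_per_condition))

    matrices: dict[str, list[list[ContactMatrix]]] = {c: [] for c in config.conditions}
    comp_labels: dict[str, np.ndarray] = {}
    boundary_bins: dict[str, list[tuple[int, float]]] = {}
    loops: list[PlantedLoop] = []
    placements: list[PeakPlacement] = []
    genes: list[GeneAssignment] = []

    for ci in range(config.n_chroms):
        per_cond_bg: dict[str, list[float]] = {}
        chrom = f"chr{ci + 1}"
        for cond in config.conditions:
            lam, labels, chrom, bgs = _structured_expectation(config, cond, ci)
            per_cond_bg[cond] = bgs
            comp_labels[chrom] = labels
            boundary_bins[chrom] = [(pos // config.resolution, f) for pos, f in config.boundary_positions]
            upper = np.triu(lam)
            for rep in range(config.replicates_per_condition):
                rng = np.random.default_rng(next(streams))
                draw = rng.poisson(upper).astype(float)
                full = draw + np.triu(draw, k=1).T
                mat = ContactMatrix.from_dense(full, chrom=chrom, resolution=config.resolution)
                while len(matrices[cond]) <= rep:
                    matrices[cond].append([])
                matrices[cond][rep].append(mat)

        if ci == 0:  # loops/peaks/genes are planted on the first chromosome
            for li, spec in enumerate(config.loop_specs):
                loops.append(
                    PlantedLoop(
                        chrom=chrom,
                        bin1=spec.anchor1 // config.resolution,
                        bin2=spec.anchor2 // config.resolution,
                        enrichment=spec.enrichment,
                        condition_factors=dict(spec.condition_factors or {}),
                        background_lambda={c: per_cond_bg[c][li] for c in config.conditions},
                        spec=spec,
                    )
                )
                half = config.peak_width // 2
                for factor, where, dyn in (("MyoD", spec.myod, spec.myod_dynamic), ("CTCF", spec.ctcf, "static")):
                    anchors = {"both": (spec.anchor1, spec.anchor2), "left": (spec.anchor1,),
                               "right": (spec.anchor2,), "none": ()}[where]
                    for a in anchors:
                        mid = a + config.resolution // 2
                        placements.append(
                            PeakPlacement(chrom=chrom, start=mid - half, end=mid + half,
                                          factor=factor, dynamic=dyn, loop_index=li)
                        )
                if spec.gene_log2fc is not None:
                    genes.append(
                        GeneAssignment(gene_id=f"gene_loop{li}", chrom=chrom,
                                       tss=spec.anchor1 + config.resolution // 2,
                                       strand="+", loop_index=li, log2fc=spec.gene_log2fc)
                    )

    truth = SyntheticTruth(
        chrom_names=[f"chr{i + 1}" for i in range(config.n_chroms)],
        n_bins=config.n_bins,
        resolution=config.resolution,
        compartment_labels=comp_labels,
        boundary_bins=boundary_bins,
        loops=loops,
        peak_placements=placements,
        gene_assignments=genes,
    )
    return matrices, truth


_KNOWN_FACTORS = ("MyoD", "CTCF", "H3K27ac")


def generate_peak_tracks(
    truth: SyntheticTruth,
    config: SynthConfig,
    seed: int,
    base_mean: float = 100.0,
    fold: float = 4.0,
    nb_dispersion: float = 0.05,
):
    """Per-factor peak intervals with NB replicate counts per condition.

    The dynamic label of a placement sets the condition means: ``static``
    -> (m, m); ``enhanced`` -> (m, fold*m); ``reduced`` -> (fold*m, m),
    conditions taken in ``config.conditions`` order.  Counts are negative
    binomial with gamma-Poisson dispersion ``nb_dispersion``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: dict[str, "pd.DataFrame"] = {}
    import pandas as pd

    for factor in _KNOWN_FACTORS:
        rows = []
        for pi, p in enumerate(pl for pl in truth.peak_placements if pl.factor == factor):
            means = {
                "static": (base_mean, base_mean),
                "enhanced": (base_mean, base_mean * fold),
                "reduced": (base_mean * fold, base_mean),
            }[p.dynamic]
            rec = {"chrom": p.chrom, "start": p.start, "end": p.end,
                   "name": f"{factor}_{pi}", "true_dynamic": p.dynamic}
            for cond, m in zip(config.conditions, means):
                for rep in range(config.replicates_per_condition):
                    # NB as gamma-Poisson: shape r = 1/dispersion, p = r/(r+m)
                    r = 1.0 / nb_dispersion
                    rec[f"{cond}_rep{rep + 1}"] = int(rng.negative_binomial(r, r / (r + m)))
            rows.append(rec)
        out[factor] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "true_dynamic"]
                                   + [f"{c}_rep{r + 1}" for c in config.conditions
                                      for r in range(config.replicates_per_condition)])
    return out


def generate_expression(
    truth: SyntheticTruth,
    config: SynthConfig,
    seed: int,
    n_background_genes: int = 400,
    base_mean: float = 200.0,
    nb_dispersion: float = 0.05,
):
    """NB count table tied to the planted gene-loop effects.

    Background genes are unchanged between conditions; each planted gene
    assignment gets the log2 fold change recorded in the truth (second
    condition relative to the first).
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cond_a, cond_b = config.conditions[0], config.conditions[1]
    reps = config.replicates_per_condition
    rows = []
    gene_meta = []

    def nb_draw(mean):
        r = 1.0 / nb_dispersion
        return int(rng.negative_binomial(r, r / (r + mean)))

    for g in truth.gene_assignments:
        means = {cond_a: base_mean, cond_b: base_mean * 2.0 ** g.log2fc}
        rec = {"gene_id": g.gene_id}
        for cond in (cond_a, cond_b):
            for rep in range(reps):
                rec[f"{cond}_rep{rep + 1}"] = nb_draw(means[cond])
        rows.append(rec)
        gene_meta.append({"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
                          "strand": g.strand, "true_log2fc": g.log2fc})
    span = truth.n_bins * truth.resolution
    for i in range(n_background_genes):
        mean = base_mean * float(rng.uniform(0.5, 2.0))
        rec = {"gene_id": f"bg_{i}"}
        for cond in (cond_a, cond_b):
            for rep in range(reps):
                rec[f"{cond}_rep{rep + 1}"] = nb_draw(mean)
        rows.append(rec)
        gene_meta.append({"gene_id": f"bg_{i}", "chrom": truth.chrom_names[0],
                          "tss": int(rng.integers(0, span)), "strand": "+" if rng.random() < 0.5 else "-",
                          "true_log2fc": 0.0})
    counts = pd.DataFrame(rows).set_index("gene_id")
    genes = pd.DataFrame(gene_meta).set_index("gene_id")
    return counts, genes


def generate_storm_pair(
    overlap_fraction: float,
    density: float,
    shape: tuple[int, int] = (512, 512),
    shift: tuple[int, int] = (0, 0),
    n_beads: int = 5,
    seed: int = 0,
):
    """Binary image pair with a planted on-pixel overlap and rigid shift.

    The second image shares ``overlap_fraction`` of the first image's
    on-pixels (before shifting) and draws the remainder of its signal
    from the off-pixels, so both channels have the same density.  The
    second image and its bead coordinates are then translated by
    ``shift`` (rows, cols), zero-filled at the edges.
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if not (0 < density < 1):
        raise ValueError("density must lie in (0, 1)")
    if abs(shift[0]) >= shape[0] or abs(shift[1]) >= shape[1]:
        raise ValueError("shift exceeds image size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_pix = shape[0] * shape[1]
    n_on = max(1, int(round(density * n_pix)))

    flat_a = rng.choice(n_pix, size=n_on, replace=False)
    n_shared = int(round(overlap_fraction * n_on))
    shared = rng.choice(flat_a, size=n_shared, replace=False)
    off = np.setdiff1d(np.arange(n_pix), flat_a, assume_unique=False)
    extra = rng.choice(off, size=n_on - n_shared, replace=False)
    flat_b = np.concatenate([shared, extra])

    img_a = np.zeros(n_pix, dtype=np.uint8)
    img_a[flat_a] = 1
    img_a = img_a.reshape(shape)
    img_b = np.zeros(n_pix, dtype=np.uint8)
    img_b[flat_b] = 1
    img_b = img_b.reshape(shape)

    beads_a = np.column_stack([
        rng.integers(max(0, -shift[0]) + 2, shape[0] - max(0, shift[0]) - 2, size=n_beads),
        rng.integers(max(0, -shift[1]) + 2, shape[1] - max(0, shift[1]) - 2, size=n_beads),
    ]).astype(float)

    shifted = np.zeros_like(img_b)
    r0, c0 = shift
    src = shifted  # noqa: F841  (clarity: translation below fills `shifted`)
    rs_src = slice(max(0, -r0), shape[0] - max(0, r0))
    cs_src = slice(max(0, -c0), shape[1] - max(0, c0))
    rs_dst = slice(max(0, r0), shape[0] - max(0, -r0))
    cs_dst = slice(max(0, c0), shape[1] - max(0, -c0))
    shifted[rs_dst, cs_dst] = img_b[rs_src, cs_src]
    beads_b = beads_a + np.array(shift, dtype=float)

    return img_a, shifted, beads_a, beads_b


_BASES = np.array(list("ACGT"))


def generate_sequences(
    n_fg: int,
    n_bg: int,
    length: int,
    seed: int,
    fg_motif_rate: float = 0.8,
    motif: str = "CAGCTG",
):
    """Random DNA with the motif planted in a fraction of foreground sequences.

    Background sequences are purely random (the consensus still occurs by
    chance at roughly ``length / 512`` per strand for CANNTG-class motifs).
    Returns ``(foreground, background)`` lists of strings.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def rand_seq():
        return "".join(_BASES[rng.integers(0, 4, size=length)])

    fg = []
    for _ in range(n_fg):
        s = rand_seq()
        if rng.random() < fg_motif_rate:
            pos = int(rng.integers(0, length - len(motif)))
            s = s[:pos] + motif + s[pos + len(motif):]
        fg.append(s)
    bg = [rand_seq() for _ in range(n_bg)]
    return fg, bg
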