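"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data the pipeline consumes, so each stage can be
exercised and benchmarked without any external download:

* :func:`generate_screen_plates` — duplicate-run 96-well viability plates
  with on-plate no-siRNA controls and planted commitment-resistant genes;
* :func:`generate_genome` — a toy genome with gene models, per-factor peaks
  placed at controlled summit-to-TSS distances, reads piled under summits
  with a configurable PCR-duplicate fraction, and a uniform IgG background;
* :func:`generate_ranked_expression` — a ranked differential-expression
  table with a planted over-representation of bound genes at the top;
* :func:`generate_cell_image` — multi-channel cell images of disk nuclei
  inside larger disk cell bodies with configurable nuclear/cytoplasmic
  target intensities.

All randomness flows through one seeded :class:`numpy.random.Generator` per
call: identical configs (seed included) give identical outputs.

The screen noise model is an explicit stand-in — no empirical noise model
is attached to this assay — so wells get multiplicative log-normal noise
(positive, right-skewed, as plate-reader viability readouts are) with a
gene-level shared latent term inducing the requested between-replicate
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pluriexit.screen import CONTROL_LABEL

PLATE_WELLS = 96
_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class ScreenSimConfig:
    """Duplicate-run arrayed screen simulation.

    ``planted_hits`` maps gene ids to viability effect sizes (fold over the
    control mean); ``replicate_correlation`` is the correlation of the
    gene-level log-viability between the two runs; ``noise_cv`` the
    coefficient of variation of the multiplicative readout noise;
    ``control_level`` the expected raw viability of control wells (a.u.).
    """

    n_genes: int
    controls_per_plate: int = 11
    n_replicates: int = 2
    planted_hits: tuple[tuple[str, float], ...] = ()
    replicate_correlation: float = 0.5
    noise_cv: float = 0.15
    control_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 1 <= self.controls_per_plate < PLATE_WELLS:
            raise ValueError(
                f"controls_per_plate must be in [1, {PLATE_WELLS - 1}]; "
                f"{self.controls_per_plate} controls leave no gene wells on a {PLATE_WELLS}-well plate"
            )
        if not 0.0 <= self.replicate_correlation <= 1.0:
            raise ValueError("replicate_correlation must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(e <= 0 for _, e in self.planted_hits):
            raise ValueError("planted effect sizes must be > 0")
        if self.control_level <= 0:
            raise ValueError("control_level must be > 0")

    @property
    def genes_per_plate(self) -> int:
        return PLATE_WELLS - self.controls_per_plate

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_genes / self.genes_per_plate)


def _well_names() -> list[str]:
    return [f"{r}{c:02d}" for r in _ROWS for c in range(1, 13)]


def generate_screen_plates(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Simulate the raw viability table of a duplicate-run arrayed screen.

    Plates are filled row-wise with one siRNA pool per gene; every plate
    carries exactly ``cfg.controls_per_plate`` no-siRNA control wells at
    evenly spread positions, used downstream for percent-of-control
    normalization.  Gene wells have expected raw viability
    ``control_level x effect`` (effect 1 unless planted); the log-normal
    noise has CV ``noise_cv`` and its gene-level component is shared
    between replicates with weight ``replicate_correlation``.

    Returns a ScreenTable DataFrame (``plate``, ``well``, ``replicate``,
    ``sirna_id``, ``gene_id``, ``raw``).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    effects = {g: 1.0 for g in genes}
    for g, e in cfg.planted_hits:
        if g not in effects:
            raise ValueError(f"planted hit {g!r} is not among the simulated genes")
        effects[g] = float(e)

    sigma2 = math.log1p(cfg.noise_cv**2)
    sigma = math.sqrt(sigma2)
    rho = cfg.replicate_correlation
    # gene-level latent shared across replicates; the residual is per
    # replicate, so corr(log-value rep1, log-value rep2) = rho
    shared = rng.standard_normal(cfg.n_genes) * math.sqrt(rho)
    resid = rng.standard_normal((cfg.n_replicates, cfg.n_genes)) * math.sqrt(1.0 - rho)

    ctrl_pos = np.unique(np.linspace(0, PLATE_WELLS - 1, cfg.controls_per_plate).round().astype(int))
    assert len(ctrl_pos) == cfg.controls_per_plate
    wells = _well_names()
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        gi = 0
        for plate_idx in range(cfg.n_plates):
            plate = f"P{plate_idx + 1:03d}"
            ctrl_set = set(ctrl_pos.tolist())
            for w in range(PLATE_WELLS):
                if w in ctrl_set:
                    noise = math.exp(sigma * rng.standard_normal() - sigma2 / 2)
                    rows.append((plate, wells[w], rep, CONTROL_LABEL, "", cfg.control_level * noise))
                elif gi < cfg.n_genes:
                    g = genes[gi]
                    z = shared[gi] + resid[rep - 1, gi]
                    noise = math.exp(sigma * z - sigma2 / 2)
                    rows.append((plate, wells[w], rep, f"si_{g}", g, cfg.control_level * effects[g] * noise))
                    gi += 1
                # trailing wells of a partially filled last plate stay empty
    return pd.DataFrame(rows, columns=["plate", "well", "replicate", "sirna_id", "gene_id", "raw"])


@dataclass(frozen=True)
class GenomeSimConfig:
    """Toy genome with planted factor binding.

    Genes are evenly spaced along each chromosome (alternating strand);
    each factor gets ``peaks_per_factor`` peaks whose summits sit at the
    ``planted_distances`` offsets (bp, signed) from the TSSs of successive
    genes.  Per-factor reads pile under summits; a ``duplicate_fraction``
    of each read set are exact copies (same chrom, start, strand)
    mimicking PCR duplicates, and an IgG sample is uniform background at
    ``igg_background_rate`` reads per bp.
    """

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 10
    factors: tuple[str, ...] = ("tfe3",)
    peaks_per_factor: int = 10
    planted_distances: tuple[int, ...] = (0,)
    peak_width: int = 600
    reads_per_peak: int = 50
    duplicate_fraction: float = 0.0
    igg_background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_genes, self.peaks_per_factor, self.reads_per_peak) < 1:
            raise ValueError("n_chroms, n_genes, peaks_per_factor and reads_per_peak must be >= 1")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.igg_background_rate < 0:
            raise ValueError("igg_background_rate must be >= 0")
        if self.peak_width < 2:
            raise ValueError("peak_width must be >= 2")
        if not self.factors:
            raise ValueError("need at least one factor")


GENE_BODY = 2_000  # bp; fixed toy gene length


def _gene_table(cfg: GenomeSimConfig) -> pd.DataFrame:
    margin = max((abs(d) for d in cfg.planted_distances), default=0) + cfg.peak_width + GENE_BODY
    if 2 * margin >= cfg.chrom_length:
        raise ValueError(
            f"planted distances/peaks (margin {margin} bp) exceed chromosome bounds ({cfg.chrom_length} bp)"
        )
    per_chrom = [cfg.n_genes // cfg.n_chroms + (1 if c < cfg.n_genes % cfg.n_chroms else 0) for c in range(cfg.n_chroms)]
    rows = []
    gid = 0
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        tss_positions = np.linspace(margin, cfg.chrom_length - margin, max(n, 1)).round().astype(int)[:n]
        for t in tss_positions:
            strand = "+" if gid % 2 == 0 else "-"
            if strand == "+":
                start, end = int(t), int(t) + GENE_BODY
            else:
                start, end = int(t) - GENE_BODY + 1, int(t) + 1
            rows.append({"gene_id": f"g{gid:04d}", "chrom": chrom, "start": start, "end": end, "strand": strand, "tss": int(t)})
            gid += 1
    return pd.DataFrame(rows)


def generate_genome(
    cfg: GenomeSimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate gene models, per-factor peaks, per-sample reads and ground truth.

    Returns ``(genes, peaks_by_factor, reads_by_sample, truth)``.
    ``reads_by_sample`` has one entry per factor plus ``"IgG"``.  ``truth``
    lists one row per planted peak: factor, peak name, target gene, signed
    summit offset from the TSS and the absolute distance the association
    score sees.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg)
    half = cfg.peak_width // 2
    peaks_by_factor: dict[str, pd.DataFrame] = {}
    reads_by_sample: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for factor in cfg.factors:
        peak_rows = []
        read_frames = []
        for j in range(cfg.peaks_per_factor):
            gene = genes.iloc[j % len(genes)]
            offset = cfg.planted_distances[j % len(cfg.planted_distances)]
            summit = int(gene["tss"]) + int(offset)
            start, end = summit - half, summit + half
            if start < 0 or end > cfg.chrom_length:
                raise ValueError(
                    f"peak {factor}:{j} at summit {summit} exceeds chromosome bounds [0, {cfg.chrom_length})"
                )
            name = f"{factor}_peak{j:04d}"
            fold = float(rng.uniform(120.0, 400.0))
            peak_rows.append(
                {"chrom": gene["chrom"], "start": start, "end": end, "name": name,
                 "summit": summit, "fold_enrichment": fold, "score": fold}
            )
            truth_rows.append(
                {"factor": factor, "peak": name, "gene_id": gene["gene_id"],
                 "offset": int(offset), "distance": abs(int(offset))}
            )
            # distinct start positions under the peak -> no accidental duplicates
            span = np.arange(start, end)
            starts = rng.choice(span, size=min(cfg.reads_per_peak, len(span)), replace=False)
            read_frames.append(
                pd.DataFrame(
                    {"chrom": gene["chrom"], "start": np.sort(starts),
                     "strand": rng.choice(["+", "-"], size=len(starts))}
                )
            )
        peaks_by_factor[factor] = pd.DataFrame(peak_rows)
        reads = pd.concat(read_frames, ignore_index=True)
        if cfg.duplicate_fraction > 0:
            n_dup = round(len(reads) * cfg.duplicate_fraction / (1.0 - cfg.duplicate_fraction))
            dup_idx = rng.choice(len(reads), size=n_dup, replace=True)
            reads = pd.concat([reads, reads.iloc[dup_idx]], ignore_index=True)
        reads_by_sample[factor] = reads.reset_index(drop=True)

    igg_frames = []
    n_igg_per_chrom = round(cfg.igg_background_rate * cfg.chrom_length)
    for ci in range(cfg.n_chroms):
        if n_igg_per_chrom > 0:
            igg_frames.append(
                pd.DataFrame(
                    {"chrom": f"chr{ci + 1}",
                     "start": np.sort(rng.integers(0, cfg.chrom_length, size=n_igg_per_chrom)),
                     "strand": rng.choice(["+", "-"], size=n_igg_per_chrom)}
                )
            )
    reads_by_sample["IgG"] = (
        pd.concat(igg_frames, ignore_index=True)
        if igg_frames
        else pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int), "strand": pd.Series(dtype=str)})
    )
    truth = pd.DataFrame(truth_rows)
    return genes, peaks_by_factor, reads_by_sample, truth


def generate_ranked_expression(
    n_genes: int,
    bound_set: Sequence[str] | set[str],
    enrichment: float = 1.0,
    seed: int | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ranked differential-expression table with planted bound-gene enrichment.

    Ranks follow a Plackett–Luce model: each gene gets weight ``enrichment``
    if bound, 1 otherwise, and the ranking is sampled by perturbing
    ``log(weight)`` with Gumbel noise and sorting in decreasing order.
    ``enrichment=1`` makes all orderings exchangeable; in the limit of very
    large enrichment every bound gene precedes every unbound one.

    Returns a DataFrame ordered by rank with ``rank`` (1-based),
    ``gene_id``, ``stat`` (the sorting key, a ranking statistic) and
    ``bound``.
    """
    if n_genes < 1:
        raise ValueError("empty gene universe")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    bound = set(bound_set)
    extra = bound - set(gene_ids)
    if extra:
        raise ValueError(f"bound_set contains unknown genes: {sorted(extra)[:5]}")
    rng = np.random.default_rng(seed)
    w = np.array([enrichment if g in bound else 1.0 for g in gene_ids])
    key = np.log(w) + rng.gumbel(size=n_genes)
    order = np.argsort(-key, kind="stable")
    out = pd.DataFrame(
        {
            "rank": np.arange(1, n_genes + 1),
            "gene_id": np.asarray(gene_ids, dtype=object)[order],
            "stat": key[order],
            "bound": np.isin(np.asarray(gene_ids, dtype=object)[order], list(bound)),
        }
    )
    return out


@dataclass(frozen=True)
class ImageSimConfig:
    """Multi-channel cell-image simulation: disk nuclei inside disk cells.

    The target channel is ``nuclear_intensity`` over each nucleus,
    ``cytoplasmic_intensity`` over the surrounding cytoplasmic ring and
    ``background`` elsewhere, before additive Gaussian noise of standard
    deviation ``noise_sd`` (all a.u., clipped at 0).  The ground-truth
    nuclear/cytoplasmic ratio of every cell is therefore
    ``nuclear_intensity / cytoplasmic_intensity``.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 10
    nucleus_radius: int = 8
    cell_radius: int = 18
    nuclear_intensity: float = 300.0
    cytoplasmic_intensity: float = 100.0
    background: float = 10.0
    noise_sd: float = 0.0
    dna_level: float = 500.0
    cell_level: float = 400.0
    seed: int = 0
    max_placement_tries: int = 10_000

    def __post_init__(self) -> None:
        if self.cell_radius <= self.nucleus_radius:
            raise ValueError("cell_radius must exceed nucleus_radius")
        if min(self.nuclear_intensity, self.cytoplasmic_intensity, self.background) < 0:
            raise ValueError("intensities must be >= 0")
        if self.cytoplasmic_intensity == 0:
            raise ValueError("cytoplasmic_intensity must be > 0 for a defined N/C ratio")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _place_cells(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_size
    margin = cfg.cell_radius + 2
    if 2 * margin >= min(h, w):
        raise ValueError("image too small for the requested cell radius")
    centers: list[tuple[int, int]] = []
    tries = 0
    min_sep = 2 * cfg.cell_radius + 3
    while len(centers) < cfg.n_cells:
        if tries >= cfg.max_placement_tries:
            raise ValueError(
                f"could not place {cfg.n_cells} non-overlapping cells in {cfg.image_size} "
                f"after {cfg.max_placement_tries} tries"
            )
        tries += 1
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    return np.array(centers, dtype=int)


def generate_cell_image(
    cfg: ImageSimConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render DNA, whole-cell and target channels plus per-cell ground truth.

    Returns ``(channels, truth)`` where ``channels`` maps ``"dna"``,
    ``"cell"``, ``"target"`` to equal-sized float arrays and ``truth`` has
    one row per cell (``cell_id``, center, radii, ``ratio``); the ratio is
    nuclear over cytoplasmic target intensity before noise.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = _place_cells(cfg, rng)
    h, w = cfg.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    dna = np.full((h, w), cfg.background, dtype=float)
    cell = np.full((h, w), cfg.background, dtype=float)
    target = np.full((h, w), cfg.background, dtype=float)
    truth_rows = []
    for i, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuc = d2 <= cfg.nucleus_radius**2
        body = d2 <= cfg.cell_radius**2
        dna[nuc] = cfg.dna_level
        cell[body] = cfg.cell_level
        target[body] = cfg.cytoplasmic_intensity
        target[nuc] = cfg.nuclear_intensity
        truth_rows.append(
            {"cell_id": i, "y": int(cy), "x": int(cx),
             "nucleus_radius": cfg.nucleus_radius, "cell_radius": cfg.cell_radius,
             "ratio": cfg.nuclear_intensity / cfg.cytoplasmic_intensity}
        )
    if cfg.noise_sd > 0:
        for img in (dna, cell, target):
            img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)
    channels = {"dna": dna, "cell": cell, "target": target}
    return channels, pd.DataFrame(truth_rows)
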