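"""ChIP-seq downstream analysis: peak filtering, TSS association, co-occupancy.

Consumes aligned read positions and called peaks (alignment and peak calling
are upstream tools, out of scope here) and implements the comparative steps:
PCR-duplicate removal, equal-depth subsampling across samples (IgG included),
retention of peaks with high fold enrichment over the IgG isotype control,
per-peak read densities, binary factor x bin binding matrices over gene
windows, an exponential-decay summit-to-TSS gene association score,
hierarchical clustering of binding profiles under Pearson-correlation
distance, nearest-factor distances between peak summits, and hypergeometric
enrichment of bound genes at the top of ranked expression tables.

Containers are plain :class:`pandas.DataFrame` tables in BED convention
(0-based, half-open):

* reads    — ``chrom``, ``start``, ``strand``
* peaks    — ``chrom``, ``start``, ``end``, ``name``, ``summit`` (absolute
  bp of maximal pile-up), ``fold_enrichment``, ``score``
* genes    — ``gene_id``, ``chrom``, ``start``, ``end``, ``strand``,
  ``tss`` (``start`` on +, ``end - 1`` on -)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

READ_COLUMNS = ["chrom", "start", "strand"]
PEAK_COLUMNS = ["chrom", "start", "end", "name", "summit", "fold_enrichment", "score"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


@dataclass(frozen=True)
class AssocConfig:
    """Parameters of the peak-to-gene association machinery.

    window : bp half-width of the region around a gene (or its TSS) inside
        which peaks are considered; default 25 kb.
    bin_size : bp width of the tiling bins of the binary matrix; default 1 kb.
    decay : bp length scale of the exponential distance decay
        ``exp(-d / decay)``; default 5 kb.
    top_quantiles : quantiles of a ranked gene list inspected for
        bound-gene enrichment; default top 2% and 5%.
    anchor : ``"tss"`` windows are ``TSS +/- window``; ``"gene"`` windows
        span ``[gene.start - window, gene.end + window)``.
    """

    window: int = 25_000
    bin_size: int = 1_000
    decay: float = 5_000.0
    top_quantiles: tuple[float, ...] = (0.02, 0.05)
    anchor: str = "tss"

    def __post_init__(self) -> None:
        if min(self.window, self.bin_size) <= 0 or self.decay <= 0:
            raise ValueError("window, bin_size and decay must be positive")
        if self.bin_size > self.window:
            raise ValueError("bin_size must not exceed window")
        if any(not 0 < q < 1 for q in self.top_quantiles):
            raise ValueError("top_quantiles must lie in (0, 1)")
        if self.anchor not in ("tss", "gene"):
            raise ValueError(f"anchor must be 'tss' or 'gene', got {self.anchor!r}")


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware TSS: ``start`` for + genes, ``end - 1`` for - genes."""
    return pd.Series(
        np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1),
        index=genes.index,
        name="tss",
    )


def dedup_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Remove potential PCR duplicates: keep one read per (chrom, start, strand).

    Idempotent; first occurrence kept, order preserved.
    """
    return reads.drop_duplicates(subset=READ_COLUMNS, keep="first").reset_index(drop=True)


def subsample_equal(
    samples: Sequence[pd.DataFrame], seed: int | None = None
) -> list[pd.DataFrame]:
    """Randomly subsample every read set to the size of the smallest one.

    Uniform draws without replacement, one seeded generator per call, so a
    fixed seed reproduces the selection exactly.  Input row order is
    preserved within each output.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    sizes = [len(s) for s in samples]
    if min(sizes) == 0:
        raise ValueError("cannot subsample an empty read set")
    target = min(sizes)
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        idx = np.sort(rng.choice(len(s), size=target, replace=False))
        out.append(s.iloc[idx].reset_index(drop=True))
    return out


def filter_peaks(peaks: pd.DataFrame, min_fold: float = 100.0) -> pd.DataFrame:
    """Retain peaks with at least ``min_fold`` enrichment over IgG (inclusive)."""
    if "fold_enrichment" not in peaks.columns:
        raise ValueError("peaks lack a fold_enrichment column")
    return peaks[peaks["fold_enrichment"] >= min_fold].reset_index(drop=True)


def peak_stats(peaks: pd.DataFrame) -> dict[str, float]:
    """Peak count and mean width (``end - start``) in bp."""
    widths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    return {"count": int(len(peaks)), "mean_width": float(widths.mean()) if len(widths) else float("nan")}


def read_density(peaks: pd.DataFrame, reads: pd.DataFrame) -> pd.Series:
    """Reads per kilobase for each peak region.

    Counts reads whose start lies in ``[peak.start, peak.end)`` and divides
    by the peak width in kb.  Reads are expected deduplicated and
    depth-matched upstream when densities are compared across samples.
    """
    dens = np.zeros(len(peaks), dtype=float)
    starts_by_chrom = {c: np.sort(g["start"].to_numpy()) for c, g in reads.groupby("chrom")}
    for i, p in enumerate(peaks.itertuples(index=False)):
        s = starts_by_chrom.get(p.chrom)
        n = 0 if s is None else np.searchsorted(s, p.end, "left") - np.searchsorted(s, p.start, "left")
        dens[i] = n / ((p.end - p.start) / 1000.0)
    return pd.Series(dens, index=peaks.index, name="reads_per_kb")


@dataclass
class BinMatrix:
    """Binary factor x genomic-bin binding matrix.

    ``matrix`` is a 0/1 DataFrame with factor rows; ``bins`` maps each
    column to its genomic interval (``chrom``, ``start``, ``end``).
    """

    matrix: pd.DataFrame
    bins: pd.DataFrame


def gene_windows(genes: pd.DataFrame, cfg: AssocConfig) -> pd.DataFrame:
    """Per-gene analysis window, anchored per ``cfg.anchor``, clipped at 0."""
    if cfg.anchor == "gene":
        lo = genes["start"] - cfg.window
        hi = genes["end"] + cfg.window
    else:
        tss = gene_tss(genes)
        lo = tss - cfg.window
        hi = tss + cfg.window
    return pd.DataFrame(
        {"gene_id": genes["gene_id"], "chrom": genes["chrom"], "start": lo.clip(lower=0), "end": hi}
    )


def build_bin_matrix(
    peaks_by_factor: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    cfg: AssocConfig | None = None,
) -> BinMatrix:
    """Tile gene windows into fixed-width bins and mark factor occupancy.

    Each gene window (gene body, or TSS, +/- ``cfg.window``; see
    ``cfg.anchor``) is split into consecutive ``cfg.bin_size``-bp bins
    starting at the window start; bins duplicated between genes are kept
    once.  Entry (factor, bin) is 1 iff any peak *interval* of that factor
    overlaps the bin (a peak spanning a bin boundary marks both bins).
    """
    cfg = cfg or AssocConfig(anchor="gene")
    windows = gene_windows(genes, cfg)
    seen: dict[tuple, None] = {}
    for w in windows.itertuples(index=False):
        for b0 in range(int(w.start), int(w.end), cfg.bin_size):
            seen.setdefault((w.chrom, b0, b0 + cfg.bin_size), None)
    bins = pd.DataFrame(list(seen), columns=["chrom", "start", "end"])
    bins = bins.sort_values(["chrom", "start"]).reset_index(drop=True)
    names = [f"{c}:{s}-{e}" for c, s, e in bins.itertuples(index=False)]
    mat = np.zeros((len(peaks_by_factor), len(bins)), dtype=int)
    col_by_chrom = {c: g for c, g in bins.groupby("chrom")}
    for fi, (_, peaks) in enumerate(peaks_by_factor.items()):
        for p in peaks.itertuples(index=False):
            g = col_by_chrom.get(p.chrom)
            if g is None:
                continue
            starts = g["start"].to_numpy()
            # bin overlaps peak iff bin.start < peak.end and bin.end > peak.start
            j0 = np.searchsorted(starts, p.start - cfg.bin_size, "right")
            j1 = np.searchsorted(starts, p.end, "left")
            sel = g.iloc[j0:j1]
            hit = (sel["start"] < p.end) & (sel["end"] > p.start)
            mat[fi, sel.index[hit.to_numpy()]] = 1
    matrix = pd.DataFrame(mat, index=list(peaks_by_factor), columns=names)
    return BinMatrix(matrix=matrix, bins=bins)


def association_score(
    peaks: pd.DataFrame,
    tss: int,
    chrom: str,
    cfg: AssocConfig | None = None,
    *,
    restrict_to_window: bool = True,
) -> float:
    """Distance-decay association of one factor's peaks with one gene.

    ``score = sum_i exp(-d_i / decay)`` over peak summits, with
    ``d_i = |summit_i - TSS|`` in bp.  By default only peaks whose summit
    lies within ``+/- window`` of the TSS contribute (more distant peaks
    would each add less than ``exp(-window/decay)``, i.e. < e^-5 at the
    defaults); ``restrict_to_window=False`` sums genome-wide on the chrom.
    Additive over peaks and strictly decreasing in every distance.
    """
    cfg = cfg or AssocConfig()
    p = peaks[peaks["chrom"] == chrom]
    summits = summit_positions(p).to_numpy(dtype=float)
    d = np.abs(summits - tss)
    if restrict_to_window:
        d = d[d <= cfg.window]
    return float(np.exp(-d / cfg.decay).sum())


def summit_positions(peaks: pd.DataFrame) -> pd.Series:
    """Absolute summit per peak; interval midpoint where the summit is missing."""
    mid = (peaks["start"] + peaks["end"]) // 2
    if "summit" not in peaks.columns:
        return mid.rename("summit")
    s = peaks["summit"]
    return s.where(s.notna(), mid).astype(int).rename("summit")


def association_table(
    peaks_by_factor: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    cfg: AssocConfig | None = None,
    *,
    restrict_to_window: bool = True,
) -> pd.DataFrame:
    """Factor x gene table of association scores plus bound indicators.

    Long format: ``factor``, ``gene_id``, ``score``, ``bound``.  A gene is
    bound by a factor iff at least one peak summit lies within
    ``+/- window`` of its TSS (presence-based, not score-thresholded), so
    ``bound`` implies ``score > 0``.
    """
    cfg = cfg or AssocConfig()
    tss = gene_tss(genes)
    rows = []
    for factor, peaks in peaks_by_factor.items():
        by_chrom = {c: np.sort(summit_positions(g).to_numpy()) for c, g in peaks.groupby("chrom")}
        for (_, gene), t in zip(genes.iterrows(), tss):
            s = by_chrom.get(gene["chrom"], np.empty(0, dtype=int))
            n_within = int(np.searchsorted(s, t + cfg.window, "right") - np.searchsorted(s, t - cfg.window, "left"))
            score = association_score(peaks, int(t), gene["chrom"], cfg, restrict_to_window=restrict_to_window)
            rows.append({"factor": factor, "gene_id": gene["gene_id"], "score": score, "bound": n_within > 0})
    return pd.DataFrame(rows, columns=["factor", "gene_id", "score", "bound"])


def bound_genes(assoc: pd.DataFrame) -> dict[str, set[str]]:
    """Per-factor sets of bound genes from an :func:`association_table`."""
    return {
        f: set(g.loc[g["bound"], "gene_id"])
        for f, g in assoc.groupby("factor")
    }


@dataclass
class ClusterResult:
    """Hierarchical clustering of factor binding profiles.

    ``linkage`` is a scipy linkage matrix over ``labels``;
    ``distances`` the symmetric Pearson-correlation distance table
    (``1 - r``) used to build it; ``dropped`` lists zero-variance rows
    removed before clustering.
    """

    linkage: np.ndarray
    labels: list[str]
    distances: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    def newick(self) -> str:
        """Dendrogram in Newick format, branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            return f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});" if not tree.is_leaf() else f"({self.labels[tree.id]});"


def cluster_profiles(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering under 1 − Pearson r distance.

    Rows are factors (binary bin occupancies or per-gene scores).  Rows
    with zero variance carry no correlation signal and are dropped with a
    warning.  Requires >= 2 usable rows.
    """
    X = matrix.to_numpy(dtype=float)
    variances = X.var(axis=1)
    keep = variances > 0
    dropped = [str(l) for l, k in zip(matrix.index, keep) if not k]
    if dropped:
        warnings.warn(f"zero-variance rows dropped before clustering: {dropped}", stacklevel=2)
    X = X[keep]
    labels = [str(l) for l, k in zip(matrix.index, keep) if k]
    if len(labels) < 2:
        raise ValueError("need at least 2 factors with nonzero variance to cluster")
    r = np.corrcoef(X)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    table = pd.DataFrame(dist, index=labels, columns=labels)
    return ClusterResult(linkage=Z, labels=labels, distances=table, dropped=dropped)


def nearest_factor_distance(query_peaks: pd.DataFrame, other_peaks: pd.DataFrame) -> pd.Series:
    """Distance from each query peak summit to the nearest summit of another factor.

    Same-chromosome distances only; queries on chromosomes absent from the
    other factor get ``NaN``.
    """
    out = np.full(len(query_peaks), np.nan)
    qs = summit_positions(query_peaks).to_numpy()
    others = {c: np.sort(summit_positions(g).to_numpy()) for c, g in other_peaks.groupby("chrom")}
    chroms = query_peaks["chrom"].to_numpy()
    for i, (c, s) in enumerate(zip(chroms, qs)):
        o = others.get(c)
        if o is None or len(o) == 0:
            continue
        j = np.searchsorted(o, s)
        cand = []
        if j > 0:
            cand.append(abs(s - o[j - 1]))
        if j < len(o):
            cand.append(abs(o[j] - s))
        out[i] = min(cand)
    return pd.Series(out, index=query_peaks.index, name="nearest_bp")


def rank_enrichment(
    ranked_genes: Sequence[str],
    bound: Iterable[str],
    q: float,
) -> dict[str, float]:
    """Over-representation of bound genes in the top quantile of a ranking.

    The top slice holds the first ``floor(q * N)`` genes of the ranked list
    (e.g. the most up- or downregulated).  Enrichment is the bound fraction
    in the slice over the bound fraction in the universe; the p-value is
    the hypergeometric upper tail ``P(X >= observed)`` of bound genes in a
    slice-sized draw.
    """
    genes = list(ranked_genes)
    N = len(genes)
    if N == 0:
        raise ValueError("empty ranked gene list")
    bound_set = set(bound)
    extra = bound_set - set(genes)
    if extra:
        raise ValueError(f"bound genes absent from the ranked universe: {sorted(extra)[:5]}")
    k = int(np.floor(q * N))
    if k < 1:
        raise ValueError(f"top {q:.1%} of {N} genes is an empty slice")
    K = len(bound_set)
    x = sum(g in bound_set for g in genes[:k])
    universe_frac = K / N
    slice_frac = x / k
    enr = slice_frac / universe_frac if universe_frac > 0 else float("nan")
    p = float(stats.hypergeom.sf(x - 1, N, K, k))
    return {
        "n_universe": N,
        "n_bound": K,
        "slice_size": k,
        "bound_in_slice": x,
        "enrichment": float(enr),
        "p_value": p,
    }
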