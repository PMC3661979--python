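"""File formats shared by all stages: BED, TSV, Newick, images, manifests.

Conventions: all genomic intervals are BED-style 0-based half-open.
Coordinates are validated on read (``0 <= start < end``, valid strand);
violations are hard errors naming the file, line and rule — never silently
clamped.  Peak BED files are BED6 plus two extra columns: the summit offset
relative to ``start`` (column 7) and the fold enrichment over IgG
(column 8).  Read BED files carry the aligned 5' position as a 1-bp
interval.  Every writer has a reader that recovers its fields losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from pluriexit.chip import GENE_COLUMNS, PEAK_COLUMNS, READ_COLUMNS
from pluriexit.screen import SCREEN_COLUMNS


class FormatError(ValueError):
    """A malformed input file; the message names file, line and violated rule."""


def _check_bed_fields(path, lineno: int, chrom: str, start: int, end: int, strand: str | None) -> None:
    if start < 0:
        raise FormatError(f"{path}:{lineno}: start {start} is negative")
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end {end} must exceed start {start} (half-open interval)")
    if strand is not None and strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
    if not chrom:
        raise FormatError(f"{path}:{lineno}: empty chrom name")


def _bed_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            yield lineno, fields


def read_reads_bed(path) -> pd.DataFrame:
    """Aligned read 5' positions from a BED6 file (name/score ignored)."""
    rows = []
    for lineno, f in _bed_rows(path):
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: read BED needs 6 columns, got {len(f)}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
        _check_bed_fields(path, lineno, f[0], start, end, f[5])
        rows.append((f[0], start, f[5]))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads.itertuples(index=False)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.start + 1}\tread{i}\t0\t{r.strand}\n")


def read_peaks_bed(path) -> pd.DataFrame:
    """Peaks from BED6+2 (summit offset from start in col 7, fold enrichment in col 8)."""
    rows = []
    for lineno, f in _bed_rows(path):
        if len(f) < 8:
            raise FormatError(f"{path}:{lineno}: peak BED needs 8 columns (BED6 + summit offset + fold), got {len(f)}")
        try:
            start, end, summit_off = int(f[1]), int(f[2]), int(f[6])
            score, fold = float(f[4]), float(f[7])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: malformed numeric field") from e
        _check_bed_fields(path, lineno, f[0], start, end, f[5] if f[5] in ("+", "-") else None)
        summit = start + summit_off
        if not start <= summit < end:
            raise FormatError(f"{path}:{lineno}: summit {summit} outside peak [{start}, {end})")
        if fold < 0:
            raise FormatError(f"{path}:{lineno}: fold_enrichment must be >= 0, got {fold}")
        rows.append((f[0], start, end, f[3], summit, fold, score))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for p in peaks.itertuples(index=False):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t"
                f"{int(p.summit) - int(p.start)}\t{p.fold_enrichment:g}\n"
            )


def read_genes_bed(path) -> pd.DataFrame:
    """Gene models from BED6; TSS derived from strand (start on +, end-1 on -)."""
    rows = []
    for lineno, f in _bed_rows(path):
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: gene BED needs 6 columns, got {len(f)}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
        _check_bed_fields(path, lineno, f[0], start, end, f[5])
        tss = start if f[5] == "+" else end - 1
        rows.append((f[3], f[0], start, end, f[5], tss))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_screen_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plate": str, "well": str, "sirna_id": str, "gene_id": str})
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: screen table lacks columns {missing}")
    df["gene_id"] = df["gene_id"].fillna("")
    if (df["raw"] < 0).any():
        bad = int((df["raw"] < 0).sum())
        raise FormatError(f"{path}: {bad} wells have negative raw viability")
    return df


def write_screen_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Generic TSV writer for result tables (z-scores, associations, measurements)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_image(img: np.ndarray, path) -> None:
    """16-bit grayscale TIFF, values clipped to the uint16 range."""
    arr = np.clip(np.asarray(img, dtype=float), 0, np.iinfo(np.uint16).max).round().astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    *,
    stage: str,
    params: Mapping,
    inputs: Mapping[str, str] | None = None,
    outputs: Mapping[str, str] | None = None,
    seed: int | None = None,
    counts: Mapping[str, int] | None = None,
) -> None:
    """JSON provenance sidecar: stage, parameters, seed, checksums, filter counts."""
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": dict(params),
        "inputs": dict(inputs or {}),
        "outputs": {k: sha256_of(v) for k, v in (outputs or {}).items()},
        "counts": dict(counts or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
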