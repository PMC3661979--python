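import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_screen_table() -> pd.DataFrame:
    """One plate, one replicate: three gene wells {1, 2, 3} and two controls at 2."""
    rows = [
        ("P1", "A01", 1, "CONTROL", "", 2.0),
        ("P1", "A02", 1, "CONTROL", "", 2.0),
        ("P1", "B01", 1, "si_a", "a", 1.0),
        ("P1", "B02", 1, "si_b", "b", 2.0),
        ("P1", "B03", 1, "si_c", "c", 3.0),
    ]
    return pd.DataFrame(rows, columns=["plate", "well", "replicate", "sirna_id", "gene_id", "raw"])


@pytest.fixture
def toy_genes() -> pd.DataFrame:
    """Two genes on a 100 kb toy chromosome, one per strand."""
    return pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "start": 30_000, "end": 32_000, "strand": "+", "tss": 30_000},
            {"gene_id": "gB", "chrom": "chr1", "start": 60_000, "end": 62_000, "strand": "-", "tss": 61_999},
        ]
    )


def make_peaks(rows) -> pd.DataFrame:
    """Peak table from (chrom, start, end, summit, fold) tuples."""
    return pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "name": f"p{i}", "summit": m, "fold_enrichment": f, "score": f}
            for i, (c, s, e, m, f) in enumerate(rows)
        ],
        columns=["chrom", "start", "end", "name", "summit", "fold_enrichment", "score"],
    )


def make_reads(rows) -> pd.DataFrame:
    """Read table from (chrom, start, strand) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "strand"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
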