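"""siRNA-screen analysis: plate normalization, Z-scores, dual-replicate hit calling.

The screen measures cell viability after puromycin selection for retained
naive-pluripotency reporter expression: genes whose knockdown blocks
commitment leave resistant (viable) cells, so hits are high-viability
outliers.  Each 96-well plate carries on-plate no-siRNA control wells used
for percent-of-control normalization; the screen is run in experimental
duplicate and Z-scores are computed per run across the gene population.
A gene is screen-positive when its two replicate Z-scores clear a dual
threshold (one run above ``z_hi``, the other above ``z_lo``); under
independent standard-normal null scores this rule has a closed-form
false-positive probability.  Screen positives are then whittled down by an
expression filter and a manual exclusion list into primary hits, and primary
hits are validated when at least ``min_validating_sirnas`` independent
siRNAs raise viability more than ``validation_fold``-fold over control.

A ``ScreenTable`` is a tidy :class:`pandas.DataFrame` with columns
``plate``, ``well``, ``replicate``, ``sirna_id``, ``gene_id``, ``raw``;
control wells carry ``sirna_id == "CONTROL"`` and an empty ``gene_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTROL_LABEL = "CONTROL"

SCREEN_COLUMNS = ["plate", "well", "replicate", "sirna_id", "gene_id", "raw"]


class DegenerateRunError(ValueError):
    """Raised when a replicate has zero dispersion and Z-scores are undefined."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the hit-calling and validation rules.

    Parameters
    ----------
    z_hi, z_lo : float
        Dual Z thresholds; a gene is positive when one replicate exceeds
        ``z_hi`` and the other exceeds ``z_lo``.
    order_agnostic : bool
        If True (default) the rule is ``max(z1, z2) > z_hi and
        min(z1, z2) > z_lo``; if False, replicate 1 must exceed ``z_hi``
        and replicate 2 must exceed ``z_lo``.
    validation_fold : float
        Fold viability increase over no-siRNA control counted as a
        significant validation (strictly greater).
    min_validating_sirnas : int
        Number of independent siRNAs that must clear ``validation_fold``
        for a gene to be called validated.
    """

    z_hi: float = 3.0
    z_lo: float = 2.5
    order_agnostic: bool = True
    validation_fold: float = 2.0
    min_validating_sirnas: int = 2

    def __post_init__(self) -> None:
        if not (self.z_hi >= self.z_lo > 0):
            raise ValueError(f"require z_hi >= z_lo > 0, got z_hi={self.z_hi}, z_lo={self.z_lo}")
        if self.validation_fold <= 1:
            raise ValueError(f"validation_fold must exceed 1, got {self.validation_fold}")
        if self.min_validating_sirnas < 1:
            raise ValueError("min_validating_sirnas must be >= 1")


def _require_screen_columns(table: pd.DataFrame) -> None:
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screen table lacks required columns: {missing}")


def is_control(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of no-siRNA control wells."""
    return table["sirna_id"] == CONTROL_LABEL


def normalize_plates(table: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-control normalization within each (plate, replicate).

    Adds a ``normalized`` column: raw viability divided by the mean raw
    viability of the control wells on the same plate and replicate, so
    control wells average to 1 on every plate.

    Raises
    ------
    ValueError
        If a (plate, replicate) has no control wells (the plate is named).
        Plates whose control mean is <= 0 are flagged invalid: their wells
        get ``normalized = NaN`` and a warning names the plate.
    """
    _require_screen_columns(table)
    if (table["raw"] < 0).any():
        raise ValueError("raw viabilities must be non-negative")
    out = table.copy()
    ctrl = table[is_control(table)]
    ctrl_means = ctrl.groupby(["plate", "replicate"])["raw"].mean()
    all_plates = out[["plate", "replicate"]].drop_duplicates()
    for plate, replicate in all_plates.itertuples(index=False):
        if (plate, replicate) not in ctrl_means.index:
            raise ValueError(f"plate {plate!r} replicate {replicate!r} has no control wells")
    denom = out.set_index(["plate", "replicate"]).index.map(ctrl_means)
    denom = np.asarray(denom, dtype=float)
    bad = denom <= 0
    if bad.any():
        invalid = sorted(set(map(tuple, out.loc[bad, ["plate", "replicate"]].itertuples(index=False))))
        warnings.warn(f"control mean <= 0; plates flagged invalid: {invalid}", stacklevel=2)
        denom = np.where(bad, np.nan, denom)
    out["normalized"] = out["raw"].to_numpy(dtype=float) / denom
    return out


def gene_values(table: pd.DataFrame, on: str = "normalized") -> pd.DataFrame:
    """Collapse wells to one value per (replicate, gene): the well mean.

    Control wells are excluded.  Duplicated library entries for a gene are
    averaged here; :func:`compute_z` operates on these gene-level values.
    """
    genes = table[~is_control(table)]
    out = genes.groupby(["replicate", "gene_id"], sort=True)[on].mean().reset_index()
    return out.rename(columns={on: "value"})


def compute_z(table: pd.DataFrame, on: str = "normalized") -> pd.DataFrame:
    """Per-gene, per-replicate Z-scores across the gene population of a run.

    ``z = (x_g - mean_g(x)) / sd_g(x)`` within each replicate, on gene-level
    values of column ``on`` (plate-normalized by default; pass ``on="raw"``
    to standardize raw readouts).  Sample standard deviation (ddof=1);
    control wells never enter.

    Raises
    ------
    DegenerateRunError
        If a replicate has zero dispersion.
    ValueError
        If a replicate has fewer than 3 genes.
    """
    if on not in table.columns:
        raise ValueError(f"column {on!r} not present; run normalize_plates first?")
    vals = gene_values(table, on=on)
    out = []
    for replicate, grp in vals.groupby("replicate"):
        x = grp["value"].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"replicate {replicate!r} has {len(x)} genes; need >= 3")
        sd = np.std(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateRunError(f"degenerate run: replicate {replicate!r} has zero dispersion")
        g = grp.copy()
        g["z"] = (x - np.mean(x)) / sd
        out.append(g)
    return pd.concat(out, ignore_index=True)[["replicate", "gene_id", "z"]]


def call_hits(zscores: pd.DataFrame, cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Dual-replicate threshold hit calling.

    Parameters
    ----------
    zscores : DataFrame
        Long table from :func:`compute_z` (``replicate``, ``gene_id``,
        ``z``) with exactly two replicates.
    cfg : ScreenConfig
        Thresholds; default Z > 3 in one run and Z > 2.5 in the other.

    Returns
    -------
    DataFrame
        One row per gene: ``gene_id``, ``z1``, ``z2``, ``scorable``,
        ``screen_positive``.  Genes missing a replicate are unscorable
        (flagged False, warned about), never imputed.
    """
    cfg = cfg or ScreenConfig()
    reps = sorted(zscores["replicate"].unique())
    if len(reps) != 2:
        raise ValueError(f"need exactly 2 replicates, found {reps}")
    wide = zscores.pivot_table(index="gene_id", columns="replicate", values="z", aggfunc="mean")
    wide = wide.reindex(columns=reps)
    wide.columns = ["z1", "z2"]
    wide = wide.reset_index()
    scorable = wide[["z1", "z2"]].notna().all(axis=1)
    if (~scorable).any():
        missing = wide.loc[~scorable, "gene_id"].tolist()
        warnings.warn(f"{len(missing)} gene(s) missing a replicate are unscorable: {missing[:10]}", stacklevel=2)
    z1 = wide["z1"].to_numpy(dtype=float)
    z2 = wide["z2"].to_numpy(dtype=float)
    if cfg.order_agnostic:
        pos = (np.fmax(z1, z2) > cfg.z_hi) & (np.fmin(z1, z2) > cfg.z_lo)
    else:
        pos = (z1 > cfg.z_hi) & (z2 > cfg.z_lo)
    wide["scorable"] = scorable.to_numpy()
    wide["screen_positive"] = np.where(scorable, pos, False)
    return wide


def false_positive_probability(
    cfg: ScreenConfig | None = None,
    *,
    rho: float = 0.0,
    method: str = "closed_form",
    n_draws: int = 10_000_000,
    seed: int | None = None,
) -> float:
    """Null probability that the dual-threshold rule calls a gene positive.

    The null gene has standard-normal Z in each replicate, with correlation
    ``rho`` between replicates (0 = independent).  With survival function
    Φ̄ and thresholds (h, l) = (z_hi, z_lo), the independent order-agnostic
    probability is ``2 Φ̄(h) Φ̄(l) − Φ̄(h)²``; at the defaults (3, 2.5) this
    is ≈ 1.494e-5, comfortably below the 1% design bound of the screen.
    For ``rho != 0`` rectangle probabilities of the bivariate normal are
    used.  ``method="mc"`` estimates the same probability by Monte Carlo
    (``n_draws`` gene pairs, seeded), as an independent cross-check.
    """
    cfg = cfg or ScreenConfig()
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if method == "mc":
        rng = np.random.default_rng(seed)
        hits = 0
        cov = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        remaining = int(n_draws)
        while remaining > 0:
            m = min(remaining, 2_000_000)
            z = rng.standard_normal((m, 2)) @ chol.T
            if cfg.order_agnostic:
                hits += int(np.count_nonzero((np.max(z, 1) > cfg.z_hi) & (np.min(z, 1) > cfg.z_lo)))
            else:
                hits += int(np.count_nonzero((z[:, 0] > cfg.z_hi) & (z[:, 1] > cfg.z_lo)))
            remaining -= m
        return hits / n_draws
    if method != "closed_form":
        raise ValueError(f"unknown method {method!r}")
    h, lo = cfg.z_hi, cfg.z_lo
    if rho == 0.0:
        ph = stats.norm.sf(h)
        pl = stats.norm.sf(lo)
        if cfg.order_agnostic:
            return 2 * ph * pl - ph * ph
        return ph * pl
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True)

    def joint_sf(a: float, b: float) -> float:
        # P(Z1 > a, Z2 > b) by inclusion-exclusion on the joint CDF
        return float(1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + mvn.cdf([a, b]))

    if cfg.order_agnostic:
        # both above lo, minus both inside (lo, hi]
        both_lo = joint_sf(lo, lo)
        inside = both_lo - joint_sf(lo, h) - joint_sf(h, lo) + joint_sf(h, h)
        return both_lo - inside
    return joint_sf(h, lo)


@dataclass
class HitLedger:
    """Per-gene bookkeeping of the screen filters, with step counts.

    ``table`` has one row per screen-positive gene with flags
    ``screen_positive``, ``expressed``, ``manual_excluded``,
    ``primary_hit`` and, once :func:`call_validation` results are merged,
    ``validated``.  ``counts`` records the size of every filter step for
    the provenance log.
    """

    table: pd.DataFrame
    counts: dict = field(default_factory=dict)


def apply_ledger(
    positives: Iterable[str],
    expressed_set: Iterable[str],
    manual_exclusions: Iterable[str],
) -> HitLedger:
    """Reduce screen positives to primary hits via the exclusion ledger.

    ``primary_hit = screen_positive ∧ expressed ∧ ¬manually excluded``.
    Exclusions naming genes that never scored positive are warned about and
    ignored.  ``counts`` reports positives, expression-excluded,
    manually-excluded (among expressed positives) and primary hits; when
    the exclusion sets are disjoint subsets of the positives these satisfy
    ``positives = primary + excluded_expression + excluded_manual``.
    """
    pos = list(dict.fromkeys(positives))
    expressed = set(expressed_set)
    manual = set(manual_exclusions)
    stray = manual - set(pos)
    if stray:
        warnings.warn(f"manual exclusions never scored positive (ignored): {sorted(stray)}", stacklevel=2)
    rows = []
    for g in pos:
        is_expr = g in expressed
        is_manual = g in manual
        rows.append(
            {
                "gene_id": g,
                "screen_positive": True,
                "expressed": is_expr,
                "manual_excluded": is_manual,
                "primary_hit": is_expr and not is_manual,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "screen_positive", "expressed", "manual_excluded", "primary_hit"])
    n_pos = len(table)
    n_not_expr = int((~table["expressed"]).sum()) if n_pos else 0
    n_manual = int((table["expressed"] & table["manual_excluded"]).sum()) if n_pos else 0
    n_primary = int(table["primary_hit"].sum()) if n_pos else 0
    counts = {
        "screen_positive": n_pos,
        "excluded_not_expressed": n_not_expr,
        "excluded_manual": n_manual,
        "primary_hits": n_primary,
    }
    return HitLedger(table=table, counts=counts)


def call_validation(
    fold_changes: Mapping[str, Sequence[float]],
    cfg: ScreenConfig | None = None,
) -> dict[str, bool]:
    """Validated iff >= ``min_validating_sirnas`` siRNAs give a fold increase
    strictly above ``validation_fold`` (fold viability over no-siRNA control)."""
    cfg = cfg or ScreenConfig()
    out = {}
    for gene, folds in fold_changes.items():
        folds = np.asarray(list(folds), dtype=float)
        if folds.size == 0:
            raise ValueError(f"gene {gene!r} has no validation fold-changes")
        out[gene] = int(np.count_nonzero(folds > cfg.validation_fold)) >= cfg.min_validating_sirnas
    return out
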