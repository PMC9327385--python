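"""SpliceAI delta-score aggregation and per-position summaries.

SpliceAI reports four delta scores per variant — acceptor gain (AG),
acceptor loss (AL), donor gain (DG), donor loss (DL) — each the probability
of one splicing change. Treating the four events as independent, the
probability that a variant disrupts splicing at all is

    P = 1 - (1 - DS_AG)(1 - DS_AL)(1 - DS_DG)(1 - DS_DL)

Per-position summaries are the arithmetic mean of P (or of a conservation
track value) over all variants sharing a (site, offset) label, with a 95%
confidence interval. Variants with no SpliceAI record are excluded from
numerator and denominator rather than zero-filled, which would bias means
downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DELTA_COLS = ["ds_ag", "ds_al", "ds_dg", "ds_dl"]


@dataclass(frozen=True)
class SpliceAiDelta:
    """Delta scores for one (variant, gene) record."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    gene: str = ""

    @property
    def deltas(self) -> tuple[float, float, float, float]:
        return (self.ds_ag, self.ds_al, self.ds_dg, self.ds_dl)


def combine_delta_scores(*deltas) -> float | np.ndarray:
    """Probability of at least one predicted splicing event.

    Accepts a single :class:`SpliceAiDelta`, four scalars, or four arrays.
    Raises ``ValueError`` on missing values or values outside [0, 1]:
    a missing annotation must be represented as an absent record, never as
    zeros.
    """
    if len(deltas) == 1 and isinstance(deltas[0], SpliceAiDelta):
        deltas = deltas[0].deltas
    if len(deltas) != 4:
        raise ValueError(f"expected four delta scores, got {len(deltas)}")
    arrs = [np.asarray(d, dtype=float) for d in deltas]
    for a in arrs:
        if np.any(np.isnan(a)) or np.any(a < 0) or np.any(a > 1):
            raise ValueError("delta scores must be present and within [0, 1]")
    p = 1.0 - (1 - arrs[0]) * (1 - arrs[1]) * (1 - arrs[2]) * (1 - arrs[3])
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# Input parsing


def read_spliceai_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with columns chrom, pos, ref, alt, gene, ds_ag, ds_al, ds_dg, ds_dl."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt", *DELTA_COLS} - set(df.columns)
    if missing:
        raise ValueError(f"SpliceAI TSV missing columns: {sorted(missing)}")
    return df


def read_spliceai_vcf(path: str | Path) -> pd.DataFrame:
    """Parse the SpliceAI VCF INFO dialect.

    ``SpliceAI=ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL``
    with comma-separated entries for multi-gene annotations. The DP_*
    position fields are parsed but not used. Records without a SpliceAI
    INFO field are omitted (absent, not zero).
    """
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        info = v.INFO.get("SpliceAI")
        if info is None:
            continue
        for entry in str(info).split(","):
            parts = entry.split("|")
            if len(parts) < 6:
                logger.warning("malformed SpliceAI entry at %s:%d: %r", v.CHROM, v.POS, entry)
                continue
            rows.append(
                (v.CHROM, v.POS - 1, v.REF, parts[0], parts[1],
                 float(parts[2]), float(parts[3]), float(parts[4]), float(parts[5]))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", *DELTA_COLS]
    )


def attach_spliceai(
    variants: pd.DataFrame,
    spliceai: pd.DataFrame,
    gene_col: str = "gene_name",
) -> pd.DataFrame:
    """Left-join aggregate disruption probability ``ds_any`` onto variants.

    When a variant carries multiple SpliceAI records (multi-gene), the
    record whose gene matches the variant's annotated gene is used;
    otherwise the maximum-probability record. Variants without any record
    get NaN.
    """
    sa = spliceai.copy()
    sa["ds_any"] = combine_delta_scores(*(sa[c].to_numpy() for c in DELTA_COLS))
    key = ["chrom", "pos", "ref", "alt"]
    merged = variants[key + ([gene_col] if gene_col in variants else [])].merge(
        sa, on=key, how="left"
    )
    if gene_col in variants.columns and "gene" in sa.columns:
        # prefer gene-matched records, then the highest-probability one
        merged = (
            merged.assign(_match=merged["gene"] == merged[gene_col])
            .sort_values(["_match", "ds_any"], ascending=[False, False], kind="stable")
            .drop_duplicates(subset=key, keep="first")
            .drop(columns="_match")
        )
    else:
        merged = (
            merged.sort_values("ds_any", ascending=False, kind="stable")
            .drop_duplicates(subset=key, keep="first")
        )
    out = variants.merge(merged[key + ["ds_any"]], on=key, how="left")
    return out


# ---------------------------------------------------------------------------
# Per-position summaries


def _ci_normal(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = float(np.mean(x))
    if len(x) < 2:
        return m, m
    se = float(np.std(x, ddof=1) / np.sqrt(len(x)))
    z = stats.norm.ppf(0.5 + level / 2)
    return m - z * se, m + z * se


def _ci_bootstrap(
    x: np.ndarray, level: float = 0.95, n_boot: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 0.5 + level / 2])
    return float(lo), float(hi)


def summarise_positions(
    df: pd.DataFrame,
    value_col: str = "ds_any",
    ci: str = "normal",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean of ``value_col`` per (site, offset) with a confidence interval.

    Rows with missing values (e.g. variants lacking a SpliceAI record) are
    excluded from both numerator and denominator. Offsets left with zero
    values are omitted with a warning. A single-value group gets a
    degenerate CI equal to its mean (flagged by ``n_variants == 1``).
    """
    rows = []
    for (site, offset), grp in df.groupby(["site", "offset"], sort=True):
        x = grp[value_col].dropna().to_numpy(dtype=float)
        if len(x) == 0:
            logger.warning("no %s values at %s %+d; omitted", value_col, site, offset)
            continue
        if ci == "bootstrap":
            lo, hi = _ci_bootstrap(x, level, n_boot, seed)
        else:
            lo, hi = _ci_normal(x, level)
        m = float(np.mean(x))
        rows.append((site, offset, len(x), m, min(lo, m), max(hi, m)))
    return pd.DataFrame(
        rows, columns=["site", "offset", "n_variants", "mean_value", "ci95_low", "ci95_high"]
    )


# ---------------------------------------------------------------------------
# Conservation tracks


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph (0-based half-open) -> frame of chrom, start, end, value."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )


def track_values(
    track: str | Path | pd.DataFrame, positions: pd.DataFrame
) -> pd.Series:
    """Per-base track value at each position (NaN where the track is silent).

    ``track`` is a bigWig path, a bedGraph path, or an interval frame.
    A position beyond the end of a bigWig chromosome raises a ``ValueError``
    naming the chromosome (track/assembly mismatch).
    """
    if isinstance(track, (str, Path)) and str(track).endswith((".bw", ".bigwig", ".bigWig")):
        import pyBigWig

        bw = pyBigWig.open(str(track))
        vals = np.full(len(positions), np.nan)
        lengths = bw.chroms()
        for i, (chrom, pos) in enumerate(zip(positions["chrom"], positions["pos"])):
            if chrom not in lengths or pos >= lengths[chrom]:
                raise ValueError(
                    f"position {chrom}:{pos} beyond track chromosome bounds "
                    f"(chromosome {chrom}): track/assembly mismatch?"
                )
            v = bw.values(chrom, pos, pos + 1)[0]
            vals[i] = v if v is not None else np.nan
        bw.close()
        return pd.Series(vals, index=positions.index)

    intervals = track if isinstance(track, pd.DataFrame) else read_bedgraph(track)
    vals = np.full(len(positions), np.nan)
    for chrom, grp in intervals.groupby("chrom"):
        grp = grp.sort_values("start")
        mask = (positions["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = positions.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(grp["start"].to_numpy(), pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < grp["end"].to_numpy()[idx[ok]]
        sub = np.full(len(pos), np.nan)
        sub[ok] = grp["value"].to_numpy()[idx[ok]]
        vals[mask] = sub
    return pd.Series(vals, index=positions.index)


def summarise_conservation(
    track: str | Path | pd.DataFrame,
    positions: pd.DataFrame,
    ci: str = "normal",
    **kwargs,
) -> pd.DataFrame:
    """Per-(site, offset) mean conservation score with 95% CI.

    Bases missing from the track are excluded.
    """
    df = positions.copy()
    df["phylop"] = track_values(track, positions)
    return summarise_positions(df, value_col="phylop", ci=ci, **kwargs)
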