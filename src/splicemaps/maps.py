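"""Mutability-adjusted proportion of singletons (MAPS).

The raw proportion of singletons (variants seen exactly once in a cohort)
in a variant class mixes two signals: purifying selection, which keeps
deleterious variants rare, and mutability, since highly mutable contexts
recur and are therefore less often singletons. MAPS removes the mutability
component by calibrating the expected singleton proportion on synonymous
variants:

1. Synonymous variants are aggregated by (trinucleotide context, alt) and
   a weighted least-squares line of singleton proportion on the context's
   relative mutation rate is fitted (weights = group variant counts).
2. For any variant class, expected singletons = sum of the per-variant
   model predictions (clamped to [0, 1]);
   MAPS = (observed singletons - expected singletons) / n.

By construction MAPS is ~0 for synonymous variants and positive for
classes under purifying selection. Significance against the synonymous
baseline uses the corrected two-cell chi-squared recipe: every MAPS score
is shifted by the synonymous unadjusted proportion of singletons so the
baseline expectation is a real count, observed = n * (MAPS_class + c) is
compared with expected = n * (MAPS_synonymous + c) on the
{singleton, non-singleton} table with 1 df, two-sided. Family-wise error
is controlled by Bonferroni.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .regions import reverse_complement

logger = logging.getLogger(__name__)

CODING_CONSEQUENCES = frozenset({"synonymous", "missense", "nonsense"})

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Mutability table


class MutabilityTable:
    """Map (trinucleotide context, alt base) -> relative mutation rate.

    Rates are unitless relative mutabilities in the style of per-context
    mutation-rate tables estimated from intergenic variation. The table is
    strand-collapsed: a context and its reverse complement (with the
    complementary alt) share one rate.
    """

    def __init__(self, rates: Mapping[tuple[str, str], float]):
        self._rates: dict[tuple[str, str], float] = {}
        for (context, alt), rate in rates.items():
            if not rate > 0:
                raise ValueError(f"rate for {context}>{alt} must be positive, got {rate}")
            self._rates[(context, alt)] = float(rate)
            rc = (reverse_complement(context), _COMP[alt])
            existing = self._rates.get(rc)
            if existing is not None and not np.isclose(existing, rate):
                raise ValueError(f"strand-complement rates disagree for {context}>{alt}")
            self._rates[rc] = float(rate)

    def get(self, context: str, alt: str) -> float | None:
        return self._rates.get((context, alt))

    def lookup(self, contexts: Iterable[str], alts: Iterable[str]) -> np.ndarray:
        """Vector lookup; NaN where the (context, alt) pair is unknown."""
        return np.array(
            [self._rates.get((c, a), np.nan) for c, a in zip(contexts, alts)], dtype=float
        )

    def __len__(self) -> int:
        return len(self._rates)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutabilityTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls({(r.context, r.alt): r.rate for r in df.itertuples()})

    @classmethod
    def default(cls) -> "MutabilityTable":
        """The packaged synthetic placeholder table (96 strand-collapsed rows).

        Published per-context rate tables are distribution-restricted, so
        the packaged default is a synthetic table with a realistic spread
        (CpG transitions elevated); swap in a real table via from_tsv for
        real-data work. MAPS is invariant to the table's overall scale.
        """
        from importlib.resources import files

        return cls.from_tsv(str(files("splicemaps") / "data" / "mutation_rates_synthetic.tsv"))


# ---------------------------------------------------------------------------
# Class assignment


def assign_class(
    consequence: str | None,
    near_splice: tuple[str, int] | None = None,
    branchpoint: int | None = None,
) -> str | None:
    """One class label per variant, or None if excluded.

    Positional precedence: a variant with both near-splice and branchpoint
    labels keeps only the near-splice one. Coding/positional interaction:
    synonymous variants inside a positional window take the positional
    class (and leave the synonymous calibration set); missense ones are
    excluded altogether; nonsense ones stay nonsense. Unknown consequence
    strings are excluded with a logged reason.
    """
    if consequence is not None and consequence not in CODING_CONSEQUENCES:
        logger.info("unknown consequence %r: variant excluded", consequence)
        return None
    positional = None
    if near_splice is not None:
        site, offset = near_splice
        positional = f"near_splice:{site}:{offset}"
    elif branchpoint is not None:
        positional = f"branchpoint:{branchpoint}"
    if positional is not None:
        if consequence == "missense":
            return None
        if consequence == "nonsense":
            return "nonsense"
        return positional  # synonymous or purely intronic
    return consequence


def label_variants(variants: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`assign_class` over a variant frame.

    Expects columns ``consequence`` (NaN for non-coding), ``ns_site``/
    ``ns_offset`` (NaN if outside near-splice windows) and ``bp_offset``
    (NaN if outside branchpoint windows).
    """
    labels = []
    for rec in variants.itertuples(index=False):
        cons = getattr(rec, "consequence", None)
        cons = None if (cons is None or (isinstance(cons, float) and np.isnan(cons))) else cons
        ns = None
        if getattr(rec, "ns_site", None) is not None and pd.notna(rec.ns_site):
            ns = (rec.ns_site, int(rec.ns_offset))
        bp = None
        if hasattr(rec, "bp_offset") and pd.notna(rec.bp_offset):
            bp = int(rec.bp_offset)
        labels.append(assign_class(cons, ns, bp))
    return pd.Series(labels, index=variants.index, dtype=object)


def branchpoint_hiconf_classes(variants: pd.DataFrame) -> pd.DataFrame:
    """Relabel branchpoint variants at high-confidence branchpoints.

    Returns a copy in which ``branchpoint:<o>`` becomes
    ``branchpoint_hiconf:<o>`` wherever ``bp_hiconf`` is set, supporting the
    parallel constraint analysis restricted to confident branchpoints. With
    the full window sizes this completes the 79-class positional family
    (57 near-splice offsets + 11 branchpoint + 11 high-confidence
    branchpoint offsets).
    """
    df = variants.copy()
    if "bp_hiconf" not in df.columns:
        return df
    mask = (
        df["class_label"].astype("string").str.startswith("branchpoint:").fillna(False)
        & df["bp_hiconf"].eq(True)
    ).to_numpy(dtype=bool)
    df.loc[mask, "class_label"] = df.loc[mask, "class_label"].str.replace(
        "branchpoint:", "branchpoint_hiconf:", regex=False
    )
    return df


# ---------------------------------------------------------------------------
# Calibration model


class SingletonCalibration:
    """Linear model of singleton proportion on context mutability.

    Fitted on synonymous variants only, by weighted least squares on
    per-(context, alt) aggregates with weights equal to group variant
    counts. Predictions are clamped to [0, 1].

    Attributes (after fit): ``slope_``, ``intercept_``,
    ``slope_identifiable_``, ``training_`` (the aggregate table).
    """

    def __init__(self, rate_table: MutabilityTable | None = None):
        self.rate_table = rate_table

    def get_params(self) -> dict:
        return {"rate_table": self.rate_table}

    def set_params(self, **params) -> "SingletonCalibration":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, synonymous: pd.DataFrame) -> "SingletonCalibration":
        """Fit on a frame of synonymous variants.

        Needs ``is_singleton`` plus either a ``rate`` column or
        ``context``/``alt`` columns resolvable through ``rate_table``.
        """
        df = synonymous.copy()
        if "rate" not in df.columns:
            if self.rate_table is None:
                raise ValueError("need a rate column or a rate_table")
            df["rate"] = self.rate_table.lookup(df["context"], df["alt"])
        n_missing = int(df["rate"].isna().sum())
        if n_missing:
            logger.warning("%d training variants lack a context rate; dropped", n_missing)
            df = df.dropna(subset=["rate"])
        if {"context", "alt"} <= set(df.columns):
            groups = (
                df.groupby(["context", "alt"], sort=True)
                .agg(rate=("rate", "first"), n=("rate", "size"),
                     proportion=("is_singleton", "mean"))
                .reset_index()
            )
        else:
            groups = (
                df.groupby("rate", sort=True)
                .agg(n=("is_singleton", "size"), proportion=("is_singleton", "mean"))
                .reset_index()
            )
        if len(df) == 0:
            raise ValueError("no usable synonymous training variants")
        if "context" in df.columns and df["context"].nunique() < 2:
            raise ValueError("all training variants share one context: fit unidentifiable")
        rates = groups["rate"].to_numpy()
        props = groups["proportion"].to_numpy()
        weights = groups["n"].to_numpy(dtype=float)
        if np.ptp(rates) == 0:
            # degenerate design: slope unidentifiable, fall back to pooled mean
            self.slope_ = 0.0
            self.intercept_ = float(np.average(props, weights=weights))
            self.slope_identifiable_ = False
        else:
            X = sm.add_constant(rates)
            res = sm.WLS(props, X, weights=weights).fit()
            self.intercept_, self.slope_ = float(res.params[0]), float(res.params[1])
            self.slope_identifiable_ = True
        self.training_ = groups
        return self

    def predict(self, rates: np.ndarray | Iterable[float]) -> np.ndarray:
        """Expected singleton proportion per variant, clamped to [0, 1]."""
        if not hasattr(self, "slope_"):
            raise ValueError("calibration not fitted")
        rates = np.asarray(list(rates) if not isinstance(rates, np.ndarray) else rates, float)
        return np.clip(self.intercept_ + self.slope_ * rates, 0.0, 1.0)


def fit_calibration(
    synonymous: pd.DataFrame, rates: MutabilityTable | None = None
) -> SingletonCalibration:
    return SingletonCalibration(rate_table=rates).fit(synonymous)


# ---------------------------------------------------------------------------
# MAPS


@dataclass
class MapsResult:
    class_label: str
    n_variants: int
    n_singletons: int
    expected_singletons: float
    ps_raw: float
    maps: float
    ci95_low: float = np.nan
    ci95_high: float = np.nan
    chi2_stat: float = np.nan
    p_value: float = np.nan
    significant_after_bonferroni: bool | None = None
    n_dropped: int = 0


def compute_maps(
    variants: pd.DataFrame,
    model: SingletonCalibration,
    class_label: str = "",
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> MapsResult:
    """MAPS for one variant class with a nonparametric bootstrap CI.

    ``variants`` needs ``is_singleton`` and either ``rate`` or
    ``context``/``alt``. Variants whose context is absent from the rate
    table are dropped and counted in ``n_dropped``. Raises on an empty
    class.
    """
    df = variants.copy()
    if "rate" not in df.columns:
        if model.rate_table is None:
            raise ValueError("need a rate column or a fitted rate_table")
        df["rate"] = model.rate_table.lookup(df["context"], df["alt"])
    n_dropped = int(df["rate"].isna().sum())
    if n_dropped:
        logger.warning("%s: %d variants lack a context rate; dropped", class_label, n_dropped)
        df = df.dropna(subset=["rate"])
    n = len(df)
    if n == 0:
        raise ValueError(f"class {class_label!r} has no variants")
    singleton = df["is_singleton"].to_numpy(dtype=float)
    pred = model.predict(df["rate"].to_numpy())
    observed = float(singleton.sum())
    expected = float(pred.sum())
    maps = (observed - expected) / n
    ci_low = ci_high = np.nan
    if n_boot and n > 1:
        rng = np.random.default_rng(seed)
        diff = singleton - pred
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = diff[idx].mean(axis=1)
        ci_low, ci_high = np.quantile(boot, [(1 - ci_level) / 2, 0.5 + ci_level / 2])
    return MapsResult(
        class_label=class_label,
        n_variants=n,
        n_singletons=int(observed),
        expected_singletons=expected,
        ps_raw=observed / n,
        maps=maps,
        ci95_low=float(ci_low),
        ci95_high=float(ci_high),
        n_dropped=n_dropped,
    )


def _joint_bootstrap_cis(
    syn_singleton: np.ndarray,
    syn_rate: np.ndarray,
    class_arrays: dict[str, tuple[np.ndarray, np.ndarray]],
    synonymous_label: str,
    n_boot: int,
    seed: int | None,
    ci_level: float,
) -> dict[str, tuple[float, float]]:
    """Bootstrap CIs that propagate calibration uncertainty.

    Each replicate resamples the synonymous training variants, refits the
    calibration line, then resamples each class and recomputes MAPS under
    the refitted line. The WLS fit on per-context aggregates weighted by
    group counts has the same normal equations as variant-level least
    squares of the 0/1 singleton indicator on rate, so the refit reduces
    to moment arrays. The synonymous class is evaluated on its own
    training resample, preserving the MAPS = 0 identity per replicate.
    """
    rng = np.random.default_rng(seed)
    n_syn = len(syn_singleton)
    idx = rng.integers(0, n_syn, size=(n_boot, n_syn))
    x = syn_rate[idx]
    y = syn_singleton[idx]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    var = (x * x).mean(axis=1) - mx**2
    cov = (x * y).mean(axis=1) - mx * my
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    intercept = my - slope * mx
    q = [(1 - ci_level) / 2, 0.5 + ci_level / 2]
    out: dict[str, tuple[float, float]] = {}
    for lab, (singleton, rate) in class_arrays.items():
        if lab == synonymous_label:
            pred = np.clip(intercept[:, None] + slope[:, None] * x, 0.0, 1.0)
            boots = y.mean(axis=1) - pred.mean(axis=1)
        else:
            cidx = rng.integers(0, len(singleton), size=(n_boot, len(singleton)))
            xr = rate[cidx]
            pred = np.clip(intercept[:, None] + slope[:, None] * xr, 0.0, 1.0)
            boots = singleton[cidx].mean(axis=1) - pred.mean(axis=1)
        lo, hi = np.quantile(boots, q)
        out[lab] = (float(lo), float(hi))
    return out


def test_constraint(
    class_result: MapsResult, synonymous_result: MapsResult
) -> tuple[float, float]:
    """Corrected two-cell chi-squared test of a class against synonymous.

    The correction constant c is the synonymous raw proportion of
    singletons, so that observed = n * (MAPS_class + c) and
    expected = n * (MAPS_synonymous + c) are genuine counts. The
    {singleton, non-singleton} goodness-of-fit statistic has 1 df; the
    returned p-value is two-sided.
    """
    c = synonymous_result.ps_raw
    n = class_result.n_variants
    obs1 = n * (class_result.maps + c)
    exp1 = n * (synonymous_result.maps + c)
    obs = np.array([obs1, n - obs1])
    exp = np.array([exp1, n - exp1])
    if np.any(exp < 1):
        warnings.warn(
            f"expected cell below 1 for {class_result.class_label}: chi-squared unreliable",
            stacklevel=2,
        )
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def maps_table(
    variants: pd.DataFrame,
    rate_table: MutabilityTable | None = None,
    class_col: str = "class_label",
    synonymous_label: str = "synonymous",
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_class_size: int = 1,
) -> pd.DataFrame:
    """Full MAPS analysis: calibrate, score every class, test, correct.

    Fits the calibration on the synonymous class, computes MAPS for every
    class, attaches joint-bootstrap CIs that propagate calibration
    uncertainty (see :func:`_joint_bootstrap_cis`), tests each
    non-synonymous class against the synonymous baseline with the
    corrected chi-squared, and applies a Bonferroni threshold over the
    number of tests performed.
    """
    df = variants.dropna(subset=[class_col])
    syn = df[df[class_col] == synonymous_label]
    if syn.empty:
        raise ValueError("no synonymous variants to calibrate on")
    model = fit_calibration(syn, rate_table)
    labels = sorted(df[class_col].unique())
    results: dict[str, MapsResult] = {}
    class_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lab in labels:
        sub = df[df[class_col] == lab]
        if len(sub) < min_class_size:
            logger.warning("class %s below min size (%d); skipped", lab, len(sub))
            continue
        results[lab] = compute_maps(sub, model, class_label=lab, n_boot=0)
        rates = (
            sub["rate"].to_numpy(dtype=float)
            if "rate" in sub.columns
            else model.rate_table.lookup(sub["context"], sub["alt"])
        )
        ok = ~np.isnan(rates)
        class_arrays[lab] = (
            sub["is_singleton"].to_numpy(dtype=float)[ok], rates[ok],
        )
    if n_boot:
        syn_singleton, syn_rate = class_arrays[synonymous_label]
        cis = _joint_bootstrap_cis(
            syn_singleton, syn_rate, class_arrays, synonymous_label,
            n_boot=n_boot, seed=seed, ci_level=0.95,
        )
        for lab, (lo, hi) in cis.items():
            results[lab].ci95_low = lo
            results[lab].ci95_high = hi
    syn_res = results[synonymous_label]
    tested = [lab for lab in results if lab != synonymous_label]
    threshold = bonferroni_threshold(len(tested), alpha) if tested else np.nan
    for lab in tested:
        chi2, p = test_constraint(results[lab], syn_res)
        results[lab].chi2_stat = chi2
        results[lab].p_value = p
        results[lab].significant_after_bonferroni = bool(p < threshold)
    out = pd.DataFrame([vars(results[lab]) for lab in results])
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["calibration"] = model
    return out
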