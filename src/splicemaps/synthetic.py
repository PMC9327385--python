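"""Synthetic cohort generator.

Emits every input the pipeline consumes — reference FASTA, GENCODE-style
GTF (with planted decoy transcripts that must fail the CDS filter),
branchpoint score tracks, a trinucleotide mutability table, cohort variant
calls with allele counts, SpliceAI-like delta scores, a per-base
conservation track, trio de novo variants with known filter outcomes, a
disease gene panel, and a toy phenotype ontology — so the whole analysis is
exercisable without any access-controlled data.

The observation model is deliberately matched to the calibration model's
functional form: each possible SNV is observed with probability
proportional to its context mutation rate, and an observed variant is a
singleton with probability ``a + b * rate + s_class``, where ``s_class`` is
a configured selection effect. MAPS on such a cohort has expectation
``s_class``, which makes parameter recovery a sharp end-to-end test. The
allele-count distribution for non-singletons (shifted geometric) is
arbitrary: MAPS depends only on the singleton indicator.

Everything is driven by one numpy Generator, so a fixed seed yields
byte-identical files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from gffutils.feature import feature_from_line
import numpy as np
import pandas as pd

from . import maps as maps_mod
from . import regions

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def default_selection_effects() -> dict[str, float]:
    """Class-specific selection effects mirroring the qualitative ordering
    seen in large cohorts: canonical splice sites and nonsense strongest,
    donor +5 and donor 0 intermediate, missense mild."""
    s = {
        "nonsense": 0.12,
        "missense": 0.04,
        "near_splice:donor:1": 0.13,
        "near_splice:donor:2": 0.13,
        "near_splice:acceptor:-1": 0.12,
        "near_splice:acceptor:-2": 0.12,
        "near_splice:donor:0": 0.05,
        "near_splice:donor:5": 0.06,
        "branchpoint:0": 0.04,
        "branchpoint:-2": 0.03,
    }
    return s


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Scale defaults (about 100 genes, ~5e4 near-splice SNVs, 50 trios) keep
    a full pipeline run in seconds while leaving every class large enough
    for constraint estimation.
    """

    seed: int = 0
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (60, 120)
    intron_length: tuple[int, int] = (120, 300)
    intergenic: tuple[int, int] = (300, 600)
    n_chroms: int = 4
    n_decoy_genes: int = 9
    n_sex_chrom_genes: int = 2
    rate_sigma: float = 0.4  # log-normal spread of context rates
    cpg_boost: float = 6.0  # CpG transition elevation before renormalising
    obs_scale: float = 0.35  # P(observe) = clip(obs_scale * rate, 0, 1)
    singleton_intercept: float = 0.55  # a
    singleton_slope: float = -0.05  # b
    selection_effects: dict = field(default_factory=default_selection_effects)
    consequence_probs: tuple[float, float, float] = (0.25, 0.70, 0.05)  # syn/mis/non
    branchpoint_cutoff: float = 0.85
    spliceai_missing_fraction: float = 0.018
    n_trios: int = 50
    n_candidate_dnvs: int = 24
    n_background_dnvs_per_trio: int = 3

    def validate(self) -> None:
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length,
                       self.intergenic):
            if lo > hi or lo < 1:
                raise ValueError(f"infeasible length range ({lo}, {hi})")
        if self.intron_length[0] < 80:
            raise ValueError("introns must be >= 80 bp to carry a 70 bp branchpoint track")
        if not 0 <= self.spliceai_missing_fraction <= 1:
            raise ValueError("spliceai_missing_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Mutability table


def generate_rate_table(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """96-row strand-collapsed context -> rate table (mean rate 1).

    Contexts with an A or C middle base represent both strands; CpG
    transitions (xCG -> xTG) are boosted to mimic the dominant feature of
    real trinucleotide mutability."""
    rows = []
    for mid in "AC":
        for left in "ACGT":
            for right in "ACGT":
                ctx = left + mid + right
                for alt in "ACGT":
                    if alt == mid:
                        continue
                    rate = float(np.exp(rng.normal(0.0, config.rate_sigma)))
                    if mid == "C" and right == "G" and alt == "T":
                        rate *= config.cpg_boost
                    rows.append((ctx, alt, rate))
    df = pd.DataFrame(rows, columns=["context", "alt", "rate"])
    df["rate"] /= df["rate"].mean()
    return df


# ---------------------------------------------------------------------------
# Reference + annotation


@dataclass
class SyntheticAnnotation:
    genome: dict[str, str]
    gtf_lines: list[str]
    introns: pd.DataFrame  # chrom,start,end,strand,intron_id,transcript_id,gene_name
    gene_names: list[str]


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def generate_reference_and_annotation(config: GeneratorConfig) -> SyntheticAnnotation:
    """Multi-exon protein-coding genes on both strands with canonical GT/AG
    intron ends (in transcript orientation), plus decoy transcripts planted
    to violate the CDS filter (level 3, unaccepted tags, non-coding
    biotypes) and a couple of sex-chromosome genes for the autosome flag."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_seq: dict[str, list[str]] = {c: _random_seq(rng, 200) for c in chrom_names}
    chrom_seq["chrX"] = _random_seq(rng, 200)

    gtf: list[str] = []
    introns = []
    gene_names: list[str] = []
    decoy_kinds = ["level3", "badtag", "noncoding"]

    total = config.n_genes + config.n_sex_chrom_genes
    for g in range(total):
        on_x = g >= config.n_genes
        chrom = "chrX" if on_x else chrom_names[g % config.n_chroms]
        seq = chrom_seq[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SYNG{g:04d}"
        gene_name = f"GENE{g:04d}"
        tx_id = f"SYNT{g:04d}"
        gene_names.append(gene_name)

        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=k)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=k - 1)

        start = len(seq) + int(rng.integers(*config.intergenic))
        seq.extend(_random_seq(rng, start - len(seq)))
        exons = []  # 0-based half-open
        cur = start
        for i in range(k):
            exons.append((cur, cur + int(exon_lens[i])))
            cur += int(exon_lens[i])
            if i < k - 1:
                i_start, i_end = cur, cur + int(intron_lens[i])
                introns.append((chrom, i_start, i_end, strand,
                                f"{tx_id}_i{i + 1}", tx_id, gene_name))
                cur = i_end
        seq.extend(_random_seq(rng, cur - len(seq) + 10))
        # canonical splice dinucleotides, transcript orientation
        for (_, i_start, i_end, s, *_rest) in [t for t in introns if t[5] == tx_id]:
            if s == "+":
                seq[i_start], seq[i_start + 1] = "G", "T"
                seq[i_end - 2], seq[i_end - 1] = "A", "G"
            else:
                seq[i_end - 2], seq[i_end - 1] = "A", "C"  # revcomp GT
                seq[i_start], seq[i_start + 1] = "C", "T"  # revcomp AG

        def _lines(txid, ttype, level, tag):
            attrs_base = (
                f'gene_id "{gene_id}"; transcript_id "{txid}"; '
                f'gene_type "protein_coding"; transcript_type "{ttype}"; '
                f'gene_name "{gene_name}"; level {level}; tag "{tag}";'
            )
            out = []
            for (s0, e0) in exons:
                for ftype in ("exon", "CDS"):
                    out.append(
                        "\t".join(
                            [chrom, "synthetic", ftype, str(s0 + 1), str(e0), ".",
                             strand, "0" if ftype == "CDS" else ".", attrs_base]
                        )
                    )
            return out

        gtf.extend(_lines(tx_id, "protein_coding", 2, "CCDS"))
        if g < config.n_decoy_genes:
            kind = decoy_kinds[g % len(decoy_kinds)]
            if kind == "level3":
                gtf.extend(_lines(f"DECOY{g:04d}", "protein_coding", 3, "CCDS"))
            elif kind == "badtag":
                gtf.extend(_lines(f"DECOY{g:04d}", "protein_coding", 2, "basic"))
            else:
                gtf.extend(_lines(f"DECOY{g:04d}", "retained_intron", 2, "CCDS"))

    genome = {c: "".join(s) for c, s in chrom_seq.items()}
    introns_df = pd.DataFrame(
        introns,
        columns=["chrom", "start", "end", "strand", "intron_id", "transcript_id", "gene_name"],
    )
    return SyntheticAnnotation(genome, gtf, introns_df, gene_names)


def features_from_lines(lines) -> list[gffutils.Feature]:
    return [feature_from_line(line, dialect=None) for line in lines]


# ---------------------------------------------------------------------------
# Branchpoint scores


def generate_branchpoint_scores(
    config: GeneratorConfig, annotation: SyntheticAnnotation
) -> pd.DataFrame:
    """Per-intron scores at every position 1-70 bp upstream of the acceptor,
    with one planted high-scoring peak 20-40 bp out (the true branchpoint)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    rows = []
    for it in annotation.introns.itertuples(index=False):
        peak = int(rng.integers(20, 41))
        background = rng.beta(1.0, 30.0, size=70)
        peak_score = float(rng.beta(8.0, 2.5))
        for d in range(1, 71):
            if it.strand == "+":
                pos = it.end - d
            else:
                pos = it.start - 1 + d
            score = peak_score if d == peak else float(background[d - 1])
            rows.append((it.chrom, pos, it.strand, it.intron_id, it.gene_name, score))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "intron_id", "gene_name", "score"]
    )


# ---------------------------------------------------------------------------
# SNV universe with positional + coding labels


def build_position_universe(
    config: GeneratorConfig, annotation: SyntheticAnnotation, bp_scores: pd.DataFrame
) -> dict:
    """Run the real region pipeline over the synthetic annotation and join
    coding bases, near-splice labels, and branchpoint labels into one
    per-base table."""
    exons = regions.filter_cds(features_from_lines(annotation.gtf_lines))
    ns_positions = regions.resolve_conflicts(regions.annotate_near_splice(exons))
    ns_df = regions.positions_frame(ns_positions)

    branchpoints = regions.select_branchpoints(bp_scores, config.branchpoint_cutoff)
    bp_windows = regions.resolve_conflicts(regions.branchpoint_windows(branchpoints))
    bp_df = regions.positions_frame(bp_windows).rename(columns={"offset": "bp_offset"})
    hiconf = {bp.intron_id for bp in branchpoints if bp.high_confidence}
    bp_df["bp_hiconf"] = bp_df["transcript_id"].isin(hiconf)
    bp_df = bp_df.drop(columns=["site"])

    unique_exons = regions.filter_cds(features_from_lines(annotation.gtf_lines), unique=True)
    coding = pd.DataFrame(
        [
            (e.chrom, p, e.strand, e.gene_name, e.transcript_id)
            for e in unique_exons
            for p in range(e.start, e.end)
        ],
        columns=["chrom", "pos", "strand", "gene_name", "transcript_id"],
    ).drop_duplicates(subset=["chrom", "pos"])

    uni = coding.assign(is_coding=True).merge(
        ns_df.rename(columns={"site": "ns_site", "offset": "ns_offset"})[
            ["chrom", "pos", "strand", "gene_name", "transcript_id", "ns_site", "ns_offset"]
        ],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("", "_ns"),
    )
    for col in ("strand", "gene_name", "transcript_id"):
        uni[col] = uni[col].fillna(uni[f"{col}_ns"])
    uni = uni.drop(columns=[c for c in uni.columns if c.endswith("_ns")])
    uni = uni.merge(
        bp_df[["chrom", "pos", "strand", "gene_name", "bp_offset", "bp_hiconf"]],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("", "_bp"),
    )
    for col in ("strand", "gene_name"):
        uni[col] = uni[col].fillna(uni[f"{col}_bp"])
    uni = uni.drop(columns=[c for c in uni.columns if c.endswith("_bp")])
    uni["is_coding"] = uni["is_coding"].eq(True)
    uni["pos"] = uni["pos"].astype(int)
    uni = uni.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return {
        "universe": uni,
        "exons": exons,
        "ns_positions": ns_df,
        "branchpoints": branchpoints,
        "bp_positions": bp_df,
    }


def generate_possible_snvs(
    config: GeneratorConfig,
    annotation: SyntheticAnnotation,
    universe: pd.DataFrame,
    rate_table: maps_mod.MutabilityTable,
) -> pd.DataFrame:
    """Enumerate all three alternates per base; attach context rate,
    a drawn coding consequence, and the MAPS class label."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 103]))
    snvs = regions.enumerate_snvs(universe, annotation.genome)
    snvs["rate"] = rate_table.lookup(snvs["context"], snvs["alt"])

    cons = np.full(len(snvs), None, dtype=object)
    coding_idx = np.flatnonzero(snvs["is_coding"].to_numpy())
    draws = rng.choice(
        ["synonymous", "missense", "nonsense"], size=len(coding_idx),
        p=config.consequence_probs,
    )
    cons[coding_idx] = draws
    snvs["consequence"] = cons
    snvs["class_label"] = maps_mod.label_variants(snvs)
    return snvs


# ---------------------------------------------------------------------------
# Cohort variants


def generate_cohort_variants(
    config: GeneratorConfig,
    snvs: pd.DataFrame,
    partition: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observe possible SNVs and draw allele counts with the configured
    singleton structure.

    With ``partition`` (name -> selection effect), intronic SNVs are
    instead assigned uniformly at random to the partition classes — a
    controlled design for parameter-recovery experiments; coding SNVs keep
    their ordinary labels so the synonymous calibration set is untouched.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104]))
    df = snvs.copy()
    if partition:
        names = sorted(partition)
        intronic = df["consequence"].isna() & df["class_label"].notna()
        assigned = rng.choice(names, size=int(intronic.sum()))
        df.loc[intronic, "class_label"] = assigned
    sel = df["class_label"].map(
        {**config.selection_effects, **(partition or {})}
    ).fillna(0.0).astype(float)
    df["true_s"] = sel

    rate = df["rate"].to_numpy(dtype=float)
    p_obs = np.clip(config.obs_scale * rate, 0.0, 1.0)
    observed = rng.random(len(df)) < p_obs
    p_single = (
        config.singleton_intercept + config.singleton_slope * rate + sel.to_numpy()
    )
    clipped = np.mean((p_single < 0) | (p_single > 1))
    if clipped > 0.2:
        warnings.warn(
            f"{clipped:.0%} of singleton probabilities clamped: parameters implausible",
            stacklevel=2,
        )
    p_single = np.clip(p_single, 0.0, 1.0)
    singleton = rng.random(len(df)) < p_single
    ac = np.where(singleton, 1, 2 + rng.geometric(0.35, size=len(df)) - 1)

    out = df.loc[observed].copy()
    out["allele_count"] = ac[observed]
    out["is_singleton"] = out["allele_count"] == 1
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# SpliceAI-like scores and conservation


def _elevated_delta_column(site, offset) -> str | None:
    if site == "donor" and offset in (1, 2):
        return "ds_dl"
    if site == "acceptor" and offset in (-1, -2):
        return "ds_al"
    if site == "donor" and offset == 5:
        return "ds_dl"
    return None


def generate_spliceai(
    config: GeneratorConfig, snvs: pd.DataFrame
) -> pd.DataFrame:
    """Beta-distributed delta scores with class-dependent means: high loss
    scores at canonical sites, moderate at donor +5, mild at branchpoint 0
    and -2, near-zero background. A configured fraction of SNVs has no
    record at all (absent, not zero)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 105]))
    n = len(snvs)
    deltas = {c: rng.beta(0.5, 40.0, size=n) for c in aggregate_delta_cols()}
    site = snvs["ns_site"] if "ns_site" in snvs else pd.Series([None] * n)
    offset = snvs["ns_offset"] if "ns_offset" in snvs else pd.Series([np.nan] * n)
    bp_off = snvs["bp_offset"] if "bp_offset" in snvs else pd.Series([np.nan] * n)

    css = (
        ((site == "donor") & offset.isin([1, 2]))
        | ((site == "acceptor") & offset.isin([-1, -2]))
    ).to_numpy()
    d5 = ((site == "donor") & (offset == 5)).to_numpy()
    bp = (site.isna() & bp_off.isin([0, -2])).to_numpy()
    donor_like = (site == "donor").to_numpy()

    for mask, col_sel, a, b in (
        (css & donor_like, "ds_dl", 10.0, 3.0),
        (css & ~donor_like, "ds_al", 10.0, 3.0),
        (d5, "ds_dl", 3.0, 6.0),
        (bp, "ds_al", 2.0, 10.0),
    ):
        k = int(mask.sum())
        if k:
            deltas[col_sel][mask] = rng.beta(a, b, size=k)

    out = snvs[["chrom", "pos", "ref", "alt", "gene_name"]].copy()
    out = out.rename(columns={"gene_name": "gene"})
    for c, v in deltas.items():
        out[c] = v
    if config.spliceai_missing_fraction > 0:
        keep = rng.random(n) >= config.spliceai_missing_fraction
        out = out.loc[keep]
    return out.reset_index(drop=True)


def aggregate_delta_cols() -> list[str]:
    from .aggregate import DELTA_COLS

    return list(DELTA_COLS)


#: mean conservation by (site, offset); canonical sites dominate, donor 0
#: conserved despite being exonic, acceptor -4 deliberately weak.
CONSERVATION_MEANS = {
    ("donor", 1): 6.3, ("donor", 2): 6.3,
    ("acceptor", -1): 6.3, ("acceptor", -2): 6.3,
    ("donor", 5): 3.4, ("donor", 4): 2.4, ("donor", 3): 2.0,
    ("acceptor", -3): 1.7, ("donor", 6): 1.3, ("acceptor", -4): 0.1,
    ("donor", 0): 5.0,
}


def generate_conservation(
    config: GeneratorConfig, universe: pd.DataFrame
) -> pd.DataFrame:
    """Per-base bedGraph-style track: background ~N(0, 0.3), exonic bases
    ~N(1.5, 0.3), designated splice offsets spiked per CONSERVATION_MEANS."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 106]))
    vals = rng.normal(0.0, 0.3, size=len(universe))
    vals = np.where(universe["is_coding"].to_numpy(), vals + 1.5, vals)
    site = universe["ns_site"]
    offset = universe["ns_offset"]
    for (s, o), mean in CONSERVATION_MEANS.items():
        mask = ((site == s) & (offset == o)).to_numpy()
        vals[mask] = rng.normal(mean, 0.3, size=int(mask.sum()))
    track = universe[["chrom", "pos"]].copy()
    track["start"] = track["pos"]
    track["end"] = track["pos"] + 1
    track["value"] = vals
    return track[["chrom", "start", "end", "value"]].sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trio DNVs


def generate_trios(
    config: GeneratorConfig,
    annotation: SyntheticAnnotation,
    universe: pd.DataFrame,
    panel: pd.DataFrame,
) -> pd.DataFrame:
    """Trio DNV table with planted truth.

    Plants clean passing DNVs (a subset on near-splice/branchpoint
    positions of panel genes, so prioritisation has work to do) plus one
    dedicated violator per stringent rule. ``should_pass`` records the
    generator's intent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 107]))
    individuals = [f"P{i:04d}" for i in range(1, config.n_trios + 1)]
    genome = annotation.genome

    def base_row(chrom, pos, individual):
        ref = genome[chrom][pos].upper()
        alt = rng.choice([b for b in "ACGT" if b != ref])
        depth = int(rng.integers(30, 60))
        alt_reads = int(np.clip(rng.binomial(depth, 0.5), round(0.31 * depth),
                                round(0.69 * depth)))
        return {
            "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
            "individual_id": individual, "child_gt": "0/1", "father_gt": "0/0",
            "mother_gt": "0/0", "child_alt_reads": alt_reads, "child_depth": depth,
            "father_alt_reads": int(rng.integers(0, 2)), "father_depth": int(rng.integers(30, 60)),
            "mother_alt_reads": int(rng.integers(0, 2)), "mother_depth": int(rng.integers(30, 60)),
            "lcr_overlap": False, "patch_overlap": False,
            "should_pass": True, "planted_rule": "", "is_candidate": False,
        }

    rows: list[dict] = []
    from . import dnv as dnv_mod

    norm = panel.copy()
    norm.columns = [c.strip().lower().replace(" ", "_") for c in norm.columns]
    # plant candidates only in genes that survive the panel filter, so the
    # planted set is exactly what prioritisation should recover
    panel_genes = set(dnv_mod.filter_panel(norm)["gene_symbol"])
    splice_pool = universe[
        (universe["ns_site"].notna() | universe["bp_offset"].notna())
        & universe["gene_name"].isin(panel_genes)
    ]
    picks = splice_pool.sample(
        n=min(config.n_candidate_dnvs, len(splice_pool)), random_state=int(rng.integers(2**31))
    )
    for i, rec in enumerate(picks.itertuples(index=False)):
        row = base_row(rec.chrom, rec.pos, individuals[i % len(individuals)])
        row["is_candidate"] = True
        rows.append(row)

    chroms = [c for c in genome if c != "chrX"]
    for ind in individuals:
        for _ in range(config.n_background_dnvs_per_trio):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(100, len(genome[chrom]) - 100))
            rows.append(base_row(chrom, pos, ind))

    def violator(rule, **mut):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(100, len(genome[chrom]) - 100))
        row = base_row(chrom, pos, individuals[int(rng.integers(len(individuals)))])
        row.update(mut)
        row["should_pass"] = False
        row["planted_rule"] = rule
        return row

    rows.append(violator("vaf_out_of_range", child_alt_reads=10, child_depth=35))
    rows.append(violator("parent_alt_reads", father_alt_reads=2))
    rows.append(violator("offspring_depth_high", child_depth=98, child_alt_reads=49))
    rows.append(violator("offspring_depth_low", child_depth=20, child_alt_reads=10))
    rows.append(violator("parent_depth_low", mother_depth=15))
    rows.append(violator("lcr_overlap", lcr_overlap=True))
    rows.append(violator("patch_region_overlap", patch_overlap=True))
    rows.append(violator("offspring_not_het", child_gt="1/1"))
    rows.append(violator("parent_not_homref", father_gt="0/1"))
    rows.append(violator("incomplete_evidence", child_alt_reads=None, child_depth=None))
    pair = violator("nearby_dnv")
    twin = dict(pair)
    twin["pos"] = pair["pos"] + 15
    twin["ref"] = genome[pair["chrom"]][twin["pos"]].upper()
    twin["alt"] = "A" if twin["ref"] != "A" else "G"
    rows.extend([pair, twin])

    df = pd.DataFrame(rows)
    # planted passes must not collide with the proximity rule by accident;
    # relocate the non-candidate member of any accidental pair
    for _ in range(5):
        bad = set()
        key = df.sort_values(["individual_id", "chrom", "pos"]).reset_index()
        for a, b in zip(key.itertuples(), key.iloc[1:].itertuples()):
            if (
                a.individual_id == b.individual_id and a.chrom == b.chrom
                and abs(a.pos - b.pos) <= 20 and "nearby" not in (a.planted_rule + b.planted_rule)
            ):
                bad.add(a.index if (b.is_candidate and not a.is_candidate) else b.index)
        if not bad:
            break
        for i in bad:
            chrom = df.at[i, "chrom"]
            df.at[i, "pos"] = int(rng.integers(100, len(genome[chrom]) - 100))
            df.at[i, "ref"] = genome[chrom][df.at[i, "pos"]].upper()
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Panel and ontology


def generate_panel(config: GeneratorConfig, gene_names: list[str],
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """G2P-style panel: half the genes monoallelic loss-of-function
    confirmed/probable, plus decoy entries that the panel filter must drop."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 108]))
    rows = []
    for i, gene in enumerate(gene_names):
        if i % 2 == 0:
            rows.append((gene, "monoallelic_autosomal", "absent gene product",
                         "confirmed" if i % 4 == 0 else "probable"))
        elif i % 5 == 1:
            rows.append((gene, "biallelic_autosomal", "absent gene product", "confirmed"))
        elif i % 5 == 3:
            rows.append((gene, "monoallelic_autosomal", "altered gene product structure",
                         "confirmed"))
        elif i % 7 == 4:
            rows.append((gene, "monoallelic_autosomal", "absent gene product", "possible"))
    return pd.DataFrame(
        rows,
        columns=["gene symbol", "allelic requirement", "mutation consequence", "confidence"],
    )


TOY_HPO_OBO = """\
format-version: 1.2
ontology: hp-toy

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0001626
name: Abnormality of the cardiovascular system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001627
name: Abnormal heart morphology
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0001710
name: Conotruncal defect
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0001636
name: Tetralogy of Fallot
is_a: HP:0001710 ! Conotruncal defect

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001250
name: Seizure
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0100022
name: Abnormality of movement
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0002197
name: Generalized-onset seizure
is_a: HP:0001250 ! Seizure
is_a: HP:0100022 ! Abnormality of movement
"""


# ---------------------------------------------------------------------------
# Top-level dataset


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    annotation: SyntheticAnnotation
    rate_frame: pd.DataFrame
    rate_table: maps_mod.MutabilityTable
    bp_scores: pd.DataFrame
    branchpoints: list
    ns_positions: pd.DataFrame
    bp_positions: pd.DataFrame
    universe: pd.DataFrame
    snvs: pd.DataFrame
    cohort: pd.DataFrame
    spliceai: pd.DataFrame
    conservation: pd.DataFrame
    panel: pd.DataFrame
    trios: pd.DataFrame
    hpo_obo: str = TOY_HPO_OBO


def generate_dataset(
    config: GeneratorConfig | None = None,
    partition: dict[str, float] | None = None,
) -> SyntheticDataset:
    """Generate every pipeline input for one seed."""
    config = config or GeneratorConfig()
    annotation = generate_reference_and_annotation(config)
    rate_frame = generate_rate_table(
        config, np.random.default_rng(np.random.SeedSequence([config.seed, 100]))
    )
    rate_table = maps_mod.MutabilityTable(
        {(r.context, r.alt): r.rate for r in rate_frame.itertuples()}
    )
    bp_scores = generate_branchpoint_scores(config, annotation)
    parts = build_position_universe(config, annotation, bp_scores)
    snvs = generate_possible_snvs(config, annotation, parts["universe"], rate_table)
    cohort = generate_cohort_variants(config, snvs, partition=partition)
    spliceai = generate_spliceai(config, snvs)
    conservation = generate_conservation(config, parts["universe"])
    panel = generate_panel(config, annotation.gene_names)
    trios = generate_trios(config, annotation, parts["universe"], panel)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        rate_frame=rate_frame,
        rate_table=rate_table,
        bp_scores=bp_scores,
        branchpoints=parts["branchpoints"],
        ns_positions=parts["ns_positions"],
        bp_positions=parts["bp_positions"],
        universe=parts["universe"],
        snvs=snvs,
        cohort=cohort,
        spliceai=spliceai,
        conservation=conservation,
        panel=panel,
        trios=trios,
    )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the file formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["fasta"] = outdir / "genome.fa"
    write_fasta(ds.annotation.genome, paths["fasta"])
    paths["gtf"] = outdir / "annotation.gtf"
    paths["gtf"].write_text("\n".join(ds.annotation.gtf_lines) + "\n")
    paths["hpo"] = outdir / "hpo.obo"
    paths["hpo"].write_text(ds.hpo_obo)
    paths["panel"] = outdir / "panel.csv"
    ds.panel.to_csv(paths["panel"], index=False)

    for name, df in [
        ("rates", ds.rate_frame), ("branchpoint_scores", ds.bp_scores),
        ("positions", ds.ns_positions), ("branchpoint_positions", ds.bp_positions),
        ("possible_snvs", ds.snvs), ("cohort_variants", ds.cohort),
        ("spliceai", ds.spliceai), ("trios", ds.trios),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    paths["conservation"] = outdir / "conservation.bedgraph"
    ds.conservation.to_csv(paths["conservation"], sep="\t", index=False, header=False)
    return paths
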