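"""Trio de novo variant filtering and candidate prioritisation.

Implements the stringent post-processing filters applied to candidate de
novo SNVs called in parent-offspring trios — heterozygous offspring,
homozygous-reference parents, at most one alternate read in each parent,
offspring allele balance in [0.3, 0.7], depth > 20 in all three samples,
offspring depth < 98, no overlap with locus-control or assembly-patch
regions, and no other DNV within 20 bp in the same individual — and the
prioritisation of surviving variants against near-splice/branchpoint
positions of monoallelic loss-of-function disease-panel genes.

Upstream "global" and "base" calling filters are an input contract: the
table handed to :func:`filter_dnvs` is assumed to contain putative DNVs
that already passed them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from . import aggregate

logger = logging.getLogger(__name__)

SITE_PRECEDENCE = {"acceptor": 0, "donor": 0, "branchpoint": 1}  # near-splice wins

#: Boundary semantics, literal reading of the filter wording:
#: VAF "between 0.3 and 0.7" inclusive; depth "greater than 20" and
#: "fewer than 98" strict; proximity "within 20 bp" inclusive.
VAF_MIN, VAF_MAX = 0.3, 0.7
MIN_DEPTH = 20
MAX_OFFSPRING_DEPTH = 98
MAX_PARENT_ALT_READS = 1
PROXIMITY_BP = 20

HET_GENOTYPES = {"0/1", "1/0", "0|1", "1|0"}
HOMREF_GENOTYPES = {"0/0", "0|0"}


@dataclass(frozen=True)
class TrioDnv:
    chrom: str
    pos: int
    ref: str
    alt: str
    individual_id: str
    child_gt: str
    father_gt: str
    mother_gt: str
    child_alt_reads: int | None
    child_depth: int | None
    father_alt_reads: int | None
    father_depth: int | None
    mother_alt_reads: int | None
    mother_depth: int | None
    lcr_overlap: bool = False
    patch_overlap: bool = False

    @property
    def vaf(self) -> float | None:
        if self.child_alt_reads is None or not self.child_depth:
            return None
        return self.child_alt_reads / self.child_depth


@dataclass
class FilterVerdict:
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and pd.isna(x))


def stringent_filter(
    dnv: TrioDnv, all_dnvs_for_individual: Sequence[TrioDnv] = ()
) -> FilterVerdict:
    """Evaluate every stringent rule; no short-circuiting.

    The proximity rule counts any *other* DNV of the same individual on the
    same chromosome within 20 bp, regardless of that neighbour's own
    verdict, so the rule is symmetric between the pair.
    """
    failed: list[str] = []
    counts = [
        dnv.child_alt_reads, dnv.child_depth,
        dnv.father_alt_reads, dnv.father_depth,
        dnv.mother_alt_reads, dnv.mother_depth,
    ]
    if any(_is_missing(c) for c in counts):
        failed.append("incomplete_evidence")
    if dnv.child_gt not in HET_GENOTYPES:
        failed.append("offspring_not_het")
    if dnv.father_gt not in HOMREF_GENOTYPES or dnv.mother_gt not in HOMREF_GENOTYPES:
        failed.append("parent_not_homref")
    if not _is_missing(dnv.father_alt_reads) and dnv.father_alt_reads > MAX_PARENT_ALT_READS:
        failed.append("parent_alt_reads")
    if (
        not _is_missing(dnv.mother_alt_reads)
        and dnv.mother_alt_reads > MAX_PARENT_ALT_READS
        and "parent_alt_reads" not in failed
    ):
        failed.append("parent_alt_reads")
    vaf = dnv.vaf
    if vaf is not None and not (VAF_MIN <= vaf <= VAF_MAX):
        failed.append("vaf_out_of_range")
    if not _is_missing(dnv.child_depth) and dnv.child_depth <= MIN_DEPTH:
        failed.append("offspring_depth_low")
    if (not _is_missing(dnv.father_depth) and dnv.father_depth <= MIN_DEPTH) or (
        not _is_missing(dnv.mother_depth) and dnv.mother_depth <= MIN_DEPTH
    ):
        failed.append("parent_depth_low")
    if not _is_missing(dnv.child_depth) and dnv.child_depth >= MAX_OFFSPRING_DEPTH:
        failed.append("offspring_depth_high")
    if dnv.lcr_overlap:
        failed.append("lcr_overlap")
    if dnv.patch_overlap:
        failed.append("patch_region_overlap")
    for other in all_dnvs_for_individual:
        if other is dnv or (
            other.chrom == dnv.chrom
            and other.pos == dnv.pos
            and other.ref == dnv.ref
            and other.alt == dnv.alt
        ):
            continue
        if other.chrom == dnv.chrom and abs(other.pos - dnv.pos) <= PROXIMITY_BP:
            failed.append("nearby_dnv")
            break
    return FilterVerdict(failed_rules=failed)


_DNV_COLS = [
    "chrom", "pos", "ref", "alt", "individual_id", "child_gt", "father_gt",
    "mother_gt", "child_alt_reads", "child_depth", "father_alt_reads",
    "father_depth", "mother_alt_reads", "mother_depth", "lcr_overlap",
    "patch_overlap",
]


def _row_to_dnv(rec) -> TrioDnv:
    def num(x):
        return None if _is_missing(x) else int(x)

    return TrioDnv(
        chrom=str(rec.chrom), pos=int(rec.pos), ref=rec.ref, alt=rec.alt,
        individual_id=str(rec.individual_id), child_gt=str(rec.child_gt),
        father_gt=str(rec.father_gt), mother_gt=str(rec.mother_gt),
        child_alt_reads=num(rec.child_alt_reads), child_depth=num(rec.child_depth),
        father_alt_reads=num(rec.father_alt_reads), father_depth=num(rec.father_depth),
        mother_alt_reads=num(rec.mother_alt_reads), mother_depth=num(rec.mother_depth),
        lcr_overlap=bool(rec.lcr_overlap), patch_overlap=bool(rec.patch_overlap),
    )


def filter_dnvs(dnvs: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`stringent_filter` to a DNV table.

    Returns a copy with ``filter_pass`` (bool) and ``failed_rules``
    (comma-joined string, empty on pass) columns.
    """
    records = [_row_to_dnv(rec) for rec in dnvs.itertuples(index=False)]
    by_ind: dict[str, list[TrioDnv]] = {}
    for d in records:
        by_ind.setdefault(d.individual_id, []).append(d)
    verdicts = [stringent_filter(d, by_ind[d.individual_id]) for d in records]
    out = dnvs.copy()
    out["filter_pass"] = [v.passed for v in verdicts]
    out["failed_rules"] = [",".join(v.failed_rules) for v in verdicts]
    return out


# ---------------------------------------------------------------------------
# Gene panel


def load_g2p(path: str | Path) -> pd.DataFrame:
    """Read a G2P-style CSV (gene symbol, allelic requirement, mutation
    consequence, confidence); column names are normalised to snake_case."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    required = {"gene_symbol", "allelic_requirement", "mutation_consequence", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    return df


def filter_panel(
    panel: pd.DataFrame,
    confidences: frozenset = frozenset({"confirmed", "probable", "definitive", "strong"}),
) -> pd.DataFrame:
    """Keep monoallelic, loss-of-function, confirmed/probable panel entries."""
    allelic = panel["allelic_requirement"].str.lower().str.contains("monoallelic")
    mech = panel["mutation_consequence"].str.lower().str.contains(
        "loss of function|loss-of-function|absent gene product"
    )
    conf = panel["confidence"].str.lower().isin(confidences)
    return panel[allelic & mech & conf]


# ---------------------------------------------------------------------------
# Prioritisation


def prioritise(
    dnvs: pd.DataFrame,
    positions: pd.DataFrame,
    panel: pd.DataFrame,
    spliceai: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate diagnostic splicing DNVs.

    Keeps filter-passing SNVs that land on a near-splice or branchpoint
    position of a gene in the (already filtered) panel. A variant with
    both annotations keeps only the near-splice one; at most one candidate
    row is emitted per (individual, variant). The aggregate SpliceAI
    probability is attached for reporting but no score cut-off is applied —
    prediction scores do not gate candidacy.
    """
    df = dnvs[dnvs["filter_pass"]] if "filter_pass" in dnvs.columns else dnvs
    n_in = len(df)
    hits = df.merge(
        positions[["chrom", "pos", "strand", "site", "offset", "transcript_id", "gene_name"]],
        on=["chrom", "pos"],
        how="inner",
    )
    panel_genes = set(panel["gene_symbol"])
    hits = hits[hits["gene_name"].isin(panel_genes)]
    hits = hits.assign(_prec=hits["site"].map(SITE_PRECEDENCE))
    hits = (
        hits.sort_values(["_prec", "site", "offset"], kind="stable")
        .drop_duplicates(subset=["individual_id", "chrom", "pos", "ref", "alt"], keep="first")
        .drop(columns="_prec")
    )
    if spliceai is not None:
        hits = aggregate.attach_spliceai(hits, spliceai)
    logger.info("prioritise: %d/%d filter-passing DNVs are panel-gene splicing candidates",
                len(hits), n_in)
    return hits.reset_index(drop=True)


# ---------------------------------------------------------------------------
# HPO abstraction


def load_hpo(path: str | Path) -> nx.MultiDiGraph:
    import obonet

    return obonet.read_obo(str(path))


def hpo_name_to_id(graph: nx.MultiDiGraph, name: str) -> str:
    for node, data in graph.nodes(data=True):
        if data.get("name") == name:
            return node
    raise KeyError(f"no HPO term named {name!r}")


def abstract_hpo(term: str, graph: nx.MultiDiGraph) -> str:
    """Replace a term by one direct is-a parent (one step up the hierarchy).

    With multiple parents the lexicographically smallest parent ID is
    chosen for determinism. The root is returned unchanged with a warning;
    an unknown term raises ``KeyError``.
    """
    if term not in graph:
        raise KeyError(f"unknown HPO term {term!r}")
    parents = sorted(v for _, v, k in graph.out_edges(term, keys=True) if k == "is_a")
    if not parents:
        logger.warning("HPO term %s has no parent (root); returned unchanged", term)
        return term
    return parents[0]
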