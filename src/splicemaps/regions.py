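"""Positional model of splicing-relevant genomic regions.

Builds the universe the constraint analysis runs over: high-confidence CDS
exons from a GENCODE-style GTF, near-splice windows around every internal
exon-intron junction (acceptor -25..+10, donor -10..+10, position 0 being
the first / last exonic base), per-intron branchpoints chosen as the
highest-scoring position of a precomputed track, and every possible SNV at
those positions with its trinucleotide reference context.

Coordinates are 0-based half-open internally; GTF I/O converts from the
1-based closed convention explicitly. Offsets are defined in transcript
orientation (5'->3'): on the minus strand "donor +1" is the base with the
lower genomic coordinate than donor 0.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
from gffutils.feature import feature_from_line
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

#: GENCODE tags accepted as evidence of a high-confidence transcript.
ACCEPTED_TAGS = frozenset(
    {"CCDS", "appris_principal_1", "appris_candidate_longest", "appris_candidate", "exp_conf"}
)

AUTOSOMES = frozenset({f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)})

#: Default window extents (intronic/exonic bases, position 0 counted as exonic).
ACCEPTOR_INTRONIC = 25
ACCEPTOR_EXONIC = 10
DONOR_EXONIC = 10
DONOR_INTRONIC = 10
BRANCHPOINT_FLANK = 5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdsExon:
    """A coding exon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    gene_name: str = ""
    tags: frozenset = field(default_factory=frozenset)
    level: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty/inverted exon {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_gtf_coords(self) -> tuple[int, int]:
        """Back to 1-based closed (start+1, end)."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class SplicePosition:
    """One genomic base labelled with a splice-site type and signed offset.

    Offset 0 is the first exonic base (acceptor), the last exonic base
    (donor), or the predicted branchpoint base. Positive offsets run
    downstream in transcript orientation.
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    site: str  # donor | acceptor | branchpoint
    offset: int
    transcript_id: str = ""
    gene_name: str = ""

    _RANGES = {
        "acceptor": (-ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC),
        "donor": (-DONOR_EXONIC, DONOR_INTRONIC),
        "branchpoint": (-BRANCHPOINT_FLANK, BRANCHPOINT_FLANK),
    }

    def __post_init__(self):
        lo, hi = self._RANGES[self.site]
        if not lo <= self.offset <= hi:
            raise ValueError(f"offset {self.offset} out of range for {self.site}")


@dataclass(frozen=True)
class Branchpoint:
    chrom: str
    pos: int
    strand: str
    intron_id: str
    score: float
    high_confidence: bool = False
    gene_name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"branchpoint score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class PossibleSnv:
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if self.context[1] != self.ref:
            raise ValueError("context centre must equal ref")


# ---------------------------------------------------------------------------
# GTF parsing / CDS filtering


def iter_gtf_features(path: str | Path) -> Iterator[gffutils.Feature]:
    """Yield GTF records, skipping malformed lines with a logged warning."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                logger.warning("skipping malformed GTF line %d: expected 9 fields", i)
                continue
            try:
                yield feature_from_line(line, dialect=None)
            except Exception as exc:  # malformed attribute string etc.
                logger.warning("skipping malformed GTF line %d: %s", i, exc)


def _attr(feature: gffutils.Feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def filter_cds(
    records: Iterable[gffutils.Feature],
    accepted_tags: frozenset = ACCEPTED_TAGS,
    autosomes_only: bool = True,
    unique: bool = False,
) -> list[CdsExon]:
    """Select high-confidence protein-coding CDS features.

    Keeps records with feature type ``CDS``, ``gene_type`` and
    ``transcript_type`` both ``protein_coding``, annotation level other than
    3, and at least one accepted tag. ``unique=True`` collapses features
    sharing (chrom, start, end, strand) to one representative.
    """
    kept: list[CdsExon] = []
    for f in records:
        if f.featuretype != "CDS":
            continue
        if autosomes_only and f.seqid not in AUTOSOMES:
            continue
        if _attr(f, "gene_type") != "protein_coding":
            continue
        if _attr(f, "transcript_type") != "protein_coding":
            continue
        level = _attr(f, "level")
        if level is not None and level.strip() in ("3", "level 3"):
            continue
        tags = frozenset(f.attributes.get("tag", []))
        if not tags & accepted_tags:
            continue
        try:
            kept.append(
                CdsExon(
                    chrom=f.seqid,
                    start=f.start - 1,  # GTF 1-based closed -> 0-based half-open
                    end=f.end,
                    strand=f.strand,
                    gene_id=_attr(f, "gene_id") or "",
                    transcript_id=_attr(f, "transcript_id") or "",
                    gene_name=_attr(f, "gene_name") or "",
                    tags=tags,
                    level=level,
                )
            )
        except ValueError as exc:
            logger.warning("skipping invalid CDS record: %s", exc)
    if unique:
        seen: dict[tuple, CdsExon] = {}
        for e in kept:
            seen.setdefault((e.chrom, e.start, e.end, e.strand), e)
        kept = list(seen.values())
    return kept


def load_cds(gtf_path: str | Path, **kwargs) -> list[CdsExon]:
    return filter_cds(iter_gtf_features(gtf_path), **kwargs)


# ---------------------------------------------------------------------------
# Near-splice windows


def annotate_near_splice(
    exons: Sequence[CdsExon],
    acceptor_intronic: int = ACCEPTOR_INTRONIC,
    acceptor_exonic: int = ACCEPTOR_EXONIC,
    donor_exonic: int = DONOR_EXONIC,
    donor_intronic: int = DONOR_INTRONIC,
) -> list[SplicePosition]:
    """Emit near-splice positions around every internal junction.

    An exon end that abuts a UTR-only boundary (the transcript's first or
    last CDS edge, where there is no intron) receives no window. Exonic
    offsets are truncated so they never extend past the exon's other end;
    overlapping labels in short exons are left for :func:`resolve_conflicts`.
    """
    by_tx: dict[str, list[CdsExon]] = defaultdict(list)
    for e in exons:
        if e.strand not in ("+", "-"):
            raise ValueError(f"exon on unknown strand: {e}")
        by_tx[e.transcript_id].append(e)

    out: list[SplicePosition] = []
    for tx, tx_exons in by_tx.items():
        tx_exons = sorted(tx_exons, key=lambda e: e.start)
        k = len(tx_exons)
        for i, e in enumerate(tx_exons):
            if e.strand == "+":
                has_acceptor, has_donor = i > 0, i < k - 1
            else:
                has_acceptor, has_donor = i < k - 1, i > 0
            if has_acceptor:
                anchor = e.start if e.strand == "+" else e.end - 1
                sign = 1 if e.strand == "+" else -1
                for off in range(-acceptor_intronic, acceptor_exonic + 1):
                    pos = anchor + sign * off
                    if off >= 0 and not (e.start <= pos < e.end):
                        continue  # exonic window truncated at the far junction
                    out.append(
                        SplicePosition(e.chrom, pos, e.strand, "acceptor", off, tx, e.gene_name)
                    )
            if has_donor:
                anchor = e.end - 1 if e.strand == "+" else e.start
                sign = 1 if e.strand == "+" else -1
                for off in range(-donor_exonic, donor_intronic + 1):
                    pos = anchor + sign * off
                    if off <= 0 and not (e.start <= pos < e.end):
                        continue
                    out.append(
                        SplicePosition(e.chrom, pos, e.strand, "donor", off, tx, e.gene_name)
                    )
    return out


def resolve_conflicts(positions: Iterable[SplicePosition]) -> list[SplicePosition]:
    """Drop genomic bases carrying more than one distinct (site, offset, strand)
    label; deduplicate identical labels from multiple transcripts.

    Idempotent. The representative of a deduplicated base is the one with
    the lexicographically smallest transcript_id, for determinism.
    """
    by_base: dict[tuple, dict[tuple, SplicePosition]] = defaultdict(dict)
    for p in positions:
        label = (p.site, p.offset, p.strand)
        prev = by_base[(p.chrom, p.pos)].get(label)
        if prev is None or p.transcript_id < prev.transcript_id:
            by_base[(p.chrom, p.pos)][label] = p
    out = []
    for labels in by_base.values():
        if len(labels) == 1:
            out.append(next(iter(labels.values())))
    out.sort(key=lambda p: (p.chrom, p.pos, p.site, p.offset))
    return out


# ---------------------------------------------------------------------------
# Branchpoints


def select_branchpoints(
    scores: pd.DataFrame,
    high_confidence_cutoff: float = 0.85,
) -> list[Branchpoint]:
    """Pick one branchpoint per intron: the highest-scoring position.

    ``scores`` needs columns chrom, pos (0-based), strand, intron_id, score
    (optionally gene_name). Ties are broken toward the 5'-most position
    (furthest from the acceptor). Introns with no scored positions are
    skipped with a warning (empty groups cannot occur with a frame input,
    but all-NaN scores are treated the same way).
    """
    out: list[Branchpoint] = []
    for intron_id, grp in scores.groupby("intron_id", sort=True):
        grp = grp.dropna(subset=["score"])
        if grp.empty:
            logger.warning("intron %s has no scored positions; skipped", intron_id)
            continue
        best = grp["score"].max()
        top = grp[grp["score"] == best]
        strand = top["strand"].iloc[0]
        # 5'-most = lowest genomic coordinate on +, highest on -
        row = top.loc[top["pos"].idxmin() if strand == "+" else top["pos"].idxmax()]
        out.append(
            Branchpoint(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                strand=strand,
                intron_id=intron_id,
                score=float(best),
                high_confidence=bool(best > high_confidence_cutoff),
                gene_name=str(row["gene_name"]) if "gene_name" in row else "",
            )
        )
    return out


def branchpoint_windows(
    branchpoints: Iterable[Branchpoint], flank: int = BRANCHPOINT_FLANK
) -> list[SplicePosition]:
    """Positions -flank..+flank around each branchpoint, transcript-oriented
    (+1 is one base toward the acceptor)."""
    out = []
    for bp in branchpoints:
        sign = 1 if bp.strand == "+" else -1
        for off in range(-flank, flank + 1):
            out.append(
                SplicePosition(
                    bp.chrom, bp.pos + sign * off, bp.strand, "branchpoint", off,
                    bp.intron_id, bp.gene_name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# SNV enumeration and PWMs


def positions_frame(positions: Iterable[SplicePosition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.chrom, p.pos, p.strand, p.site, p.offset, p.transcript_id, p.gene_name)
            for p in positions
        ],
        columns=["chrom", "pos", "strand", "site", "offset", "transcript_id", "gene_name"],
    )


def _chrom_seqs(reference: str | Path | Fasta | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(reference, (str, Path)):
        reference = Fasta(str(reference))
    if isinstance(reference, Fasta):
        return {name: str(reference[name][:]) for name in reference.keys()}
    return reference


def enumerate_snvs(
    positions: pd.DataFrame | Iterable[SplicePosition],
    reference: str | Path | Fasta | Mapping[str, str],
) -> pd.DataFrame:
    """All three possible single-base changes at each position.

    Returns one row per SNV with the reference-strand trinucleotide context
    (bases pos-1..pos+1). Positions whose reference base is not A/C/G/T are
    skipped; the count is in ``result.attrs["n_skipped"]``.
    """
    if not isinstance(positions, pd.DataFrame):
        positions = positions_frame(positions)
    seqs = _chrom_seqs(reference)
    rows = []
    n_skipped = 0
    for rec in positions.itertuples(index=False):
        seq = seqs[rec.chrom]
        ref = seq[rec.pos].upper()
        if ref not in "ACGT":
            n_skipped += 1
            continue
        context = seq[rec.pos - 1 : rec.pos + 2].upper() if rec.pos >= 1 else ""
        for alt in "ACGT":
            if alt == ref:
                continue
            rows.append((*rec, ref, alt, context))
    out = pd.DataFrame(rows, columns=[*positions.columns, "ref", "alt", "context"])
    out.attrs["n_skipped"] = n_skipped
    if n_skipped:
        logger.info("enumerate_snvs: skipped %d positions with ambiguous reference", n_skipped)
    return out


def build_pwm(
    positions: pd.DataFrame | Iterable[SplicePosition],
    reference: str | Path | Fasta | Mapping[str, str],
) -> pd.DataFrame:
    """Per-(site, offset) base frequencies from the reference sequence.

    Strand-aware: bases at minus-strand positions are complemented so each
    column describes the transcript-orientation motif. Rows sum to 1;
    offsets with zero usable positions are omitted.
    """
    if not isinstance(positions, pd.DataFrame):
        positions = positions_frame(positions)
    seqs = _chrom_seqs(reference)
    counts: dict[tuple, dict[str, int]] = defaultdict(lambda: {b: 0 for b in "ACGT"})
    for rec in positions.itertuples(index=False):
        base = seqs[rec.chrom][rec.pos].upper()
        if rec.strand == "-":
            base = base.translate(_COMPLEMENT)
        if base in "ACGT":
            counts[(rec.site, rec.offset)][base] += 1
    rows = {}
    for key in sorted(counts):
        total = sum(counts[key].values())
        if total == 0:
            continue
        rows[key] = {b: counts[key][b] / total for b in "ACGT"}
    pwm = pd.DataFrame.from_dict(rows, orient="index")
    pwm.index.names = ["site", "offset"]
    return pwm
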