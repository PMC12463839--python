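"""ASV-to-isolate matching by ungapped local alignment and best-hit collation.

A culture collection is typically sequenced in several 16S regions
(a merged paired-read product plus single reads named by primer: 27F,
515F, 515R).  Field-derived amplicon sequence variants (ASVs) are aligned
against each region database with an ungapped local aligner, the best
alignment per subject is kept, hits whose alignment length differs from
the ASV length by more than a small slop are discarded, and — when one
isolate is hit in several regions — the hit from the highest-preference
region (merged > 27F > 515F > 515R) represents the isolate.  Isolates are
then summarized with their matched ASVs and best percent identity above a
configurable identity floor.

The aligner searches every diagonal on both query strands, so on
desk-scale inputs it is exact rather than heuristic; scoring defaults to
the classic blastn reward/penalty of +2/-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from rhizoscreen._align_core import best_segment, encode
from rhizoscreen.simdata.sequences import reverse_complement

logger = logging.getLogger(__name__)

REGIONS = ("merged", "27F", "515F", "515R")
DEFAULT_PREFERENCE = REGIONS
DEFAULT_REWARD = 2
DEFAULT_PENALTY = -3

_ALPHABET = set("ACGTNRYSWKMBVDH")


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence with identity, optional region tag and isolate group."""

    id: str
    residues: str
    region: str | None = None
    isolate_id: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues.upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-DNA symbols {sorted(bad)}")


@dataclass(frozen=True)
class AlignmentHit:
    """One scored ungapped local alignment of an ASV against a subject."""

    asv_id: str
    subject_id: str
    isolate_id: str
    region: str
    strand: str
    query_start: int  # offset in the query as aligned (revcomp for '-')
    subject_start: int
    alignment_length: int
    matches: int
    score: int

    @property
    def percent_identity(self) -> float:
        return round(100.0 * self.matches / self.alignment_length, 3)


class ReferenceIndex:
    """Region-keyed reference sequences with a subject -> isolate map."""

    def __init__(self) -> None:
        self.by_region: dict[str, dict[str, SequenceRecord]] = {}
        self.isolate_of: dict[str, str] = {}

    def subjects(self, region: str) -> dict[str, SequenceRecord]:
        return self.by_region.get(region, {})

    @property
    def regions(self) -> list[str]:
        return list(self.by_region)

    @property
    def isolates(self) -> set[str]:
        return set(self.isolate_of.values())


def build_reference_index(records: Iterable[SequenceRecord]) -> ReferenceIndex:
    """Index reference records by region; ids must be unique per region.

    Isolates missing a region are tolerated (that region's sub-index is
    simply smaller); a warning is logged when region counts are uneven.
    """
    index = ReferenceIndex()
    for rec in records:
        if not rec.region:
            raise ValueError(f"reference record {rec.id!r} has no region tag")
        sub = index.by_region.setdefault(rec.region, {})
        if rec.id in sub:
            raise ValueError(
                f"duplicate subject id {rec.id!r} in region {rec.region!r}")
        sub[rec.id] = rec
        index.isolate_of[rec.id] = rec.isolate_id or rec.id
    counts = {r: len(s) for r, s in index.by_region.items()}
    if len(set(counts.values())) > 1:
        logger.warning("uneven region coverage in reference index: %s", counts)
    return index


def read_reference_fasta(path: str | Path,
                         region: str | None = None) -> list[SequenceRecord]:
    """Read reference FASTA; region/isolate parsed from ``key=value`` tags
    in the description line unless ``region`` is forced."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(part.split("=", 1) for part in rec.description.split()
                    if "=" in part)
        records.append(SequenceRecord(
            id=rec.id, residues=str(rec.seq).upper(),
            region=region or tags.get("region"),
            isolate_id=tags.get("isolate"),
        ))
    return records


def read_asv_fasta(path: str | Path) -> dict[str, str]:
    """Read ASV FASTA into ``{asv_id: sequence}``."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _hit_sort_key(hit: AlignmentHit) -> tuple:
    # larger score/length/matches first; '+' strand before '-'; then
    # smaller subject_start, query_start; subject id last for total order
    return (-hit.score, -hit.alignment_length, -hit.matches,
            hit.strand != "+", hit.subject_start, hit.query_start,
            hit.subject_id)


def ungapped_local_align(query: str, subject: str, *,
                         reward: int = DEFAULT_REWARD,
                         penalty: int = DEFAULT_PENALTY,
                         asv_id: str = "query", subject_id: str = "subject",
                         isolate_id: str = "", region: str = "",
                         ) -> AlignmentHit | None:
    """Best ungapped local alignment over both query strands, or ``None``.

    The optimum is the maximum-score contiguous single-diagonal segment;
    ties resolve to the longer segment, then more matches, then the '+'
    strand, then the smaller subject start.  A best score <= 0 is a
    no-hit.  For '-' strand hits ``query_start`` indexes the
    reverse-complemented query.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if not (reward > 0 > penalty):
        raise ValueError("require reward > 0 > penalty")
    for seq, name in ((query, asv_id), (subject, subject_id)):
        bad = set(seq.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{name!r} contains non-DNA symbols {sorted(bad)}")
    q_fwd = encode(query)
    s_enc = encode(subject)
    q_rev = encode(reverse_complement(query))

    candidates = []
    for strand, q_enc in (("+", q_fwd), ("-", q_rev)):
        sc, ln, mat, qs, ss = best_segment(q_enc, s_enc, reward, penalty)
        if sc > 0:
            candidates.append(AlignmentHit(
                asv_id=asv_id, subject_id=subject_id, isolate_id=isolate_id,
                region=region, strand=strand, query_start=int(qs),
                subject_start=int(ss), alignment_length=int(ln),
                matches=int(mat), score=int(sc)))
    if not candidates:
        return None
    return min(candidates, key=_hit_sort_key)


def match_asvs(asvs: Mapping[str, str], index: ReferenceIndex, *,
               reward: int = DEFAULT_REWARD,
               penalty: int = DEFAULT_PENALTY) -> list[AlignmentHit]:
    """Align every ASV against every subject of every region database."""
    hits: list[AlignmentHit] = []
    for asv_id in sorted(asvs):
        query = asvs[asv_id]
        for region in REGIONS:
            for subject_id in sorted(index.subjects(region)):
                rec = index.subjects(region)[subject_id]
                hit = ungapped_local_align(
                    query, rec.residues, reward=reward, penalty=penalty,
                    asv_id=asv_id, subject_id=subject_id,
                    isolate_id=index.isolate_of[subject_id], region=region)
                if hit is not None:
                    hits.append(hit)
    return hits


@dataclass
class MatchTable:
    """Collated best hits: one retained hit per (ASV, subject).

    ``hits`` carries a ``preferred`` flag marking, per (ASV, isolate), the
    hit from the highest-preference region — the hit that represents the
    isolate match; ``winning_region`` gives the preference-resolved region
    of each ASV's top hit.
    """

    hits: pd.DataFrame
    query_lengths: dict[str, int]
    max_len_diff: int = 2
    preference: tuple[str, ...] = DEFAULT_PREFERENCE
    winning_region: dict[str, str] = field(default_factory=dict)

    COLUMNS = ("asv_id", "subject_id", "isolate_id", "region", "strand",
               "query_start", "subject_start", "alignment_length", "matches",
               "score", "percent_identity", "preferred")

    def to_tsv(self, path: str | Path) -> None:
        self.hits.to_csv(path, sep="\t", index=False,
                         float_format="%.3f")


def collate_matches(hits: Iterable[AlignmentHit] | pd.DataFrame,
                    query_lengths: Mapping[str, int], *,
                    max_len_diff: int = 2,
                    preference: Sequence[str] = DEFAULT_PREFERENCE,
                    one_per_asv: bool = False) -> MatchTable:
    """Collate raw hits into per-ASV best matches.

    Applies the length rule ``|alignment_length - query_length| <=
    max_len_diff``, keeps the single best hit per (ASV, subject), and
    resolves multi-region hits of one isolate by region preference.  With
    ``one_per_asv`` only each ASV's single preference-resolved winner is
    retained (the alternative reading of one-hit-per-ASV collation).
    Collation is idempotent: re-collating a collated table is a no-op.
    """
    if isinstance(hits, pd.DataFrame):
        records = [AlignmentHit(
            asv_id=r.asv_id, subject_id=r.subject_id, isolate_id=r.isolate_id,
            region=r.region, strand=r.strand, query_start=int(r.query_start),
            subject_start=int(r.subject_start),
            alignment_length=int(r.alignment_length), matches=int(r.matches),
            score=int(r.score)) for r in hits.itertuples()]
    else:
        records = list(hits)
    pref_rank = {r: k for k, r in enumerate(preference)}

    filtered: list[AlignmentHit] = []
    for hit in records:
        if hit.asv_id not in query_lengths:
            raise KeyError(f"hit references unknown asv_id {hit.asv_id!r}")
        if abs(hit.alignment_length - query_lengths[hit.asv_id]) \
                <= max_len_diff:
            filtered.append(hit)

    best_per_subject: dict[tuple[str, str], AlignmentHit] = {}
    for hit in filtered:
        key = (hit.asv_id, hit.subject_id)
        prev = best_per_subject.get(key)
        if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
            best_per_subject[key] = hit

    # region preference resolves which hit represents each (asv, isolate)
    preferred: set[tuple[str, str]] = set()
    by_isolate: dict[tuple[str, str], list[AlignmentHit]] = {}
    for hit in best_per_subject.values():
        by_isolate.setdefault((hit.asv_id, hit.isolate_id), []).append(hit)
    winners: dict[str, list[AlignmentHit]] = {}
    for (asv_id, _), group in by_isolate.items():
        top = min(group, key=lambda h: (pref_rank.get(h.region, len(pref_rank)),
                                        _hit_sort_key(h)))
        preferred.add((top.asv_id, top.subject_id))
        winners.setdefault(asv_id, []).append(top)

    winning_region: dict[str, str] = {}
    overall: dict[str, AlignmentHit] = {}
    for asv_id, group in winners.items():
        top = min(group, key=lambda h: (pref_rank.get(h.region, len(pref_rank)),
                                        _hit_sort_key(h)))
        winning_region[asv_id] = top.region
        overall[asv_id] = top

    retained = list(best_per_subject.values())
    if one_per_asv:
        retained = list(overall.values())
        preferred = {(h.asv_id, h.subject_id) for h in retained}

    rows = [{
        "asv_id": h.asv_id, "subject_id": h.subject_id,
        "isolate_id": h.isolate_id, "region": h.region, "strand": h.strand,
        "query_start": h.query_start, "subject_start": h.subject_start,
        "alignment_length": h.alignment_length, "matches": h.matches,
        "score": h.score, "percent_identity": h.percent_identity,
        "preferred": (h.asv_id, h.subject_id) in preferred,
    } for h in retained]
    df = pd.DataFrame(rows, columns=list(MatchTable.COLUMNS))
    if len(df):
        df["_pref"] = df["region"].map(lambda r: pref_rank.get(r, len(pref_rank)))
        df = df.sort_values(
            ["asv_id", "_pref", "score", "alignment_length", "matches",
             "subject_id"],
            ascending=[True, True, False, False, False, True],
        ).drop(columns="_pref").reset_index(drop=True)
    return MatchTable(hits=df, query_lengths=dict(query_lengths),
                      max_len_diff=max_len_diff,
                      preference=tuple(preference),
                      winning_region=winning_region)


@dataclass(frozen=True)
class IsolateMatchSummary:
    """Per-isolate match summary above the identity floor."""

    isolate_id: str
    matched_asv_ids: frozenset[str]
    best_percent_identity: float
    n_regions_supporting: int


def summarize_isolates(table: MatchTable, *, min_identity: float = 95.0,
                       ) -> tuple[list[IsolateMatchSummary], dict]:
    """Summarize matched isolates and report the ASV match rate.

    Only preference-resolved hits at ``percent_identity >= min_identity``
    count an ASV as matched; ``n_regions_supporting`` counts the distinct
    regions of all retained per-subject hits passing the floor.
    """
    if not 0.0 < min_identity <= 100.0:
        raise ValueError("min_identity must be in (0, 100]")
    df = table.hits
    passing = df[df["percent_identity"] >= min_identity] if len(df) else df
    summaries: list[IsolateMatchSummary] = []
    if len(passing):
        for isolate_id, grp in passing.groupby("isolate_id", sort=True):
            pref = grp[grp["preferred"]]
            if not len(pref):
                continue
            summaries.append(IsolateMatchSummary(
                isolate_id=str(isolate_id),
                matched_asv_ids=frozenset(pref["asv_id"]),
                best_percent_identity=float(pref["percent_identity"].max()),
                n_regions_supporting=int(grp["region"].nunique())))
    matched_asvs = (set(passing[passing["preferred"]]["asv_id"])
                    if len(passing) else set())
    n_total = len(table.query_lengths)
    report = {
        "n_matched_asvs": len(matched_asvs),
        "n_total_asvs": n_total,
        "fraction_matched": len(matched_asvs) / n_total if n_total else 0.0,
        "n_matched_isolates": len(summaries),
        "min_identity": min_identity,
    }
    return summaries, report


def summaries_to_frame(summaries: list[IsolateMatchSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "isolate_id": s.isolate_id,
        "n_matched_asvs": len(s.matched_asv_ids),
        "matched_asv_ids": ",".join(sorted(s.matched_asv_ids)),
        "best_percent_identity": s.best_percent_identity,
        "n_regions_supporting": s.n_regions_supporting,
    } for s in summaries])
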