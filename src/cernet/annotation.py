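"""Transcript filtering, positional lncRNA classification, and the
small-RNA annotation cascade.

lncRNA categories (precedence order, first match wins):

1. ``sense``        -- exonic overlap with a coding gene's exons, same strand
2. ``antisense``    -- any overlap with a coding gene span, opposite strand
3. ``intronic``     -- span fully inside one intron of a same-strand gene
4. ``bidirectional``-- no overlap, TSS within a window of a coding TSS,
   divergent (opposite) strands
5. ``intergenic``   -- otherwise

Precedence is a pipeline choice (physical overlap beats proximity,
strandedness disambiguates overlap) and is fixed here; the bidirectional
window is configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .models import GeneModel, SmallRNATag, TranscriptModel

LNC_CATEGORIES = ("sense", "antisense", "intronic", "bidirectional", "intergenic")

DEFAULT_BIDIRECTIONAL_WINDOW = 1000

# Small-RNA annotation priority, highest first.  The structural-RNA block
# outranks everything; unannotated is the fallback, never listed.
SRNA_PRIORITY = (
    "rRNA",
    "scRNA",
    "snoRNA",
    "snRNA",
    "tRNA",
    "existing_miRNA",
    "existing_miRNA_edit",
    "known_miRNA",
    "repeat",
    "exon",
    "novel_miRNA",
    "intron",
)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def filter_novel_transcripts(
    transcripts: Iterable[TranscriptModel], min_exons: int = 2
) -> list[TranscriptModel]:
    """Keep transcripts with spliced length > 200 nt and >= ``min_exons`` exons.

    The length cut is strict.  ``min_exons`` defaults to 2 (the common
    pipeline convention); pass 3 for the literal 'above 2' reading.
    """
    return [
        t
        for t in transcripts
        if t.spliced_length > 200 and t.exon_count >= min_exons
    ]


def classify_lncrna(
    lnc: TranscriptModel,
    coding_genes: Sequence[GeneModel],
    bidirectional_window: int = DEFAULT_BIDIRECTIONAL_WINDOW,
) -> str:
    """Positional category of a lncRNA relative to protein-coding genes."""
    if lnc.strand not in ("+", "-"):
        raise ValueError(f"{lnc.id}: bad strand")
    genes = [g for g in coding_genes if g.chromosome == lnc.chromosome]
    if coding_genes and not genes:
        raise ValueError(f"{lnc.id}: unknown chromosome {lnc.chromosome!r}")

    span = lnc.span

    # 1. sense: exon-level overlap, same strand
    for g in genes:
        if g.strand != lnc.strand:
            continue
        for ls, le in lnc.exons:
            if any(_overlaps((ls, le), ex) for ex in g.exons):
                return "sense"

    # 2. antisense: span-level overlap, opposite strand
    for g in genes:
        if g.strand != lnc.strand and _overlaps(span, g.span):
            return "antisense"

    # 3. intronic: span fully inside one intron, same strand
    for g in genes:
        if g.strand != lnc.strand:
            continue
        for is_, ie in g.introns:
            if is_ <= span[0] and span[1] <= ie:
                return "intronic"

    # 4. bidirectional: no overlap anywhere, divergent promoter within window
    overlapping = any(_overlaps(span, g.span) for g in genes)
    if not overlapping:
        for g in genes:
            if g.strand != lnc.strand and abs(lnc.tss - g.tss) <= bidirectional_window:
                return "bidirectional"

    return "intergenic"


def classify_all(
    lncrnas: Iterable[TranscriptModel],
    coding_genes: Sequence[GeneModel],
    bidirectional_window: int = DEFAULT_BIDIRECTIONAL_WINDOW,
) -> dict[str, str]:
    return {
        t.id: classify_lncrna(t, coding_genes, bidirectional_window) for t in lncrnas
    }


# --- small-RNA annotation cascade -----------------------------------------


class TrackError(ValueError):
    pass


@dataclass
class SequenceTrack:
    """Matches a tag by exact sequence membership."""

    sequences: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        try:
            self.sequences = frozenset(
                s.upper().replace("T", "U") for s in self.sequences
            )
        except AttributeError as exc:
            raise TrackError("sequence track entries must be strings") from exc

    def matches(self, tag: SmallRNATag) -> bool:
        return tag.sequence in self.sequences


@dataclass
class EditTrack:
    """Matches single-substitution variants of known mature miRNAs.

    A tag matches if some reference of identical length differs at exactly
    one internal position (neither terminal base).  Exact equals do NOT
    match here -- they belong to the exact-sequence track upstream.
    """

    references: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.references = frozenset(
            s.upper().replace("T", "U") for s in self.references
        )

    def matches(self, tag: SmallRNATag) -> bool:
        seq = tag.sequence
        for ref in self.references:
            if len(ref) != len(seq) or ref == seq:
                continue
            diffs = [i for i, (a, b) in enumerate(zip(seq, ref)) if a != b]
            if len(diffs) == 1 and 0 < diffs[0] < len(seq) - 1:
                return True
        return False


@dataclass
class IntervalTrack:
    """Matches a tag whose genomic placement overlaps a track interval."""

    intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if len(iv) != 3 or iv[2] <= iv[1]:
                raise TrackError(f"malformed interval {iv!r}")

    def matches(self, tag: SmallRNATag) -> bool:
        for chrom, s, e in tag.genomic_matches:
            for tchrom, ts, te in self.intervals:
                if chrom == tchrom and s < te and ts < e:
                    return True
        return False


def annotate_srna(
    tag: SmallRNATag,
    tracks: Mapping[str, object],
    priority: Sequence[str] = SRNA_PRIORITY,
) -> str:
    """First category in priority order whose track matches, else 'unannotated'."""
    for category in priority:
        track = tracks.get(category)
        if track is None:
            continue
        if not hasattr(track, "matches"):
            raise TrackError(f"track {category!r} lacks a matches() method")
        if track.matches(tag):
            return category
    return "unannotated"


def length_distribution(tags: Sequence[SmallRNATag]) -> tuple[Counter, int]:
    """Count-weighted length histogram and modal length (ties -> smaller)."""
    if not tags:
        raise ValueError("no tags provided")
    hist: Counter = Counter()
    for tag in tags:
        hist[len(tag.sequence)] += tag.count
    top = max(hist.values())
    mode = min(length for length, c in hist.items() if c == top)
    return hist, mode
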