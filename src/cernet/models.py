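"""Shared domain types.

Coordinate convention: all in-memory intervals are 0-based half-open
``[start, end)`` on the forward genome strand.  GTF I/O converts to/from
1-based inclusive, BED I/O stays 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

VALID_CONDITIONS = ("BN", "BH")


class ModelError(ValueError):
    """Raised for malformed domain objects."""


def _check_exons(exons: Sequence[Interval]) -> tuple[Interval, ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ModelError("at least one exon required")
    for s, e in exons:
        if e <= s or s < 0:
            raise ModelError(f"bad exon interval ({s}, {e})")
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        if s1 < e0:
            raise ModelError("exons must be sorted and non-overlapping")
    return exons


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on a chromosome."""

    id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = "lncRNA"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", _check_exons(self.exons))

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Position of the first transcribed base (strand-aware)."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: union exon structure of its transcripts."""

    id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.id}: strand must be '+' or '-'")
        object.__setattr__(self, "exons", _check_exons(self.exons))

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1] - 1

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts plus a design map.

    ``counts`` is a pandas DataFrame indexed by feature id with sample-id
    columns.  ``design`` maps every sample to a condition ("BN" or "BH").
    ``lengths`` (nt per feature) is required only for FPKM.
    """

    counts: pd.DataFrame
    design: Mapping[str, str]
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ModelError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ModelError("duplicate sample ids")
        missing = [s for s in self.counts.columns if s not in self.design]
        if missing:
            raise ModelError(f"samples without condition: {missing}")
        bad = {c for c in self.design.values()} - set(VALID_CONDITIONS)
        if bad:
            raise ModelError(f"unknown conditions: {sorted(bad)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ModelError("negative counts")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ModelError("feature lengths must be present and > 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression result (BH over BN)."""

    feature_id: str
    log2fc: float
    p_value: float
    fdr: float
    call: str  # up | down | null

    def __post_init__(self) -> None:
        if self.call not in ("up", "down", "null"):
            raise ModelError(f"bad call {self.call!r}")
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise ModelError("p-value and FDR must lie in [0, 1]")
        if self.call == "up" and not self.log2fc > 0:
            raise ModelError("up call with non-positive log2fc")
        if self.call == "down" and not self.log2fc < 0:
            raise ModelError("down call with non-negative log2fc")


@dataclass(frozen=True)
class SeedSite:
    """A seed-match site on a target, sense strand, 0-based start."""

    mirna_id: str
    target_id: str
    start: int
    site_type: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer

    SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

    def __post_init__(self) -> None:
        if self.site_type not in self.SITE_TYPES:
            raise ModelError(f"bad site type {self.site_type!r}")
        if self.start < 0:
            raise ModelError("negative site start")


@dataclass(frozen=True)
class CorrelationPair:
    id_a: str
    id_b: str
    method: str  # spearman | pearson
    coefficient: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ModelError(f"bad method {self.method!r}")
        if not -1.0 <= self.coefficient <= 1.0 + 1e-12:
            raise ModelError(f"coefficient {self.coefficient} outside [-1, 1]")
        if self.n_samples < 3:
            raise ModelError("n_samples must be >= 3")


@dataclass(frozen=True)
class CeRNATriad:
    """A lncRNA--mRNA pair with its shared miRNAs and sponge-test counts."""

    lncrna_id: str
    mrna_id: str
    shared_mirna_ids: tuple[str, ...]
    K: int  # miRNAs targeting the lncRNA
    n: int  # miRNAs targeting the mRNA
    N: int  # universe size
    p_value: float

    def __post_init__(self) -> None:
        k = len(self.shared_mirna_ids)
        if k > min(self.K, self.n):
            raise ModelError("shared set larger than either margin")
        if max(self.K, self.n) > self.N:
            raise ModelError("margin exceeds universe")
        if not 0.0 < self.p_value <= 1.0:
            raise ModelError("p-value must lie in (0, 1]")

    @property
    def k(self) -> int:
        return len(self.shared_mirna_ids)


@dataclass
class SmallRNATag:
    """A collapsed small-RNA read with genomic match positions."""

    sequence: str
    count: int = 1
    genomic_matches: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if len(self.sequence) < 15:
            raise ModelError("tag shorter than 15 nt")
        if self.count < 1:
            raise ModelError("tag count must be >= 1")


@dataclass(frozen=True)
class TermMap:
    """One annotation term and its member genes."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ModelError(f"term {self.term_id} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k_study: int
    n_study: int
    K_pop: int
    N_pop: int
    p_value: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if self.k_study > min(self.n_study, self.K_pop):
            raise ModelError("k exceeds a margin")
        if self.adjusted_p + 1e-12 < self.p_value:
            raise ModelError("adjusted p below raw p")


@dataclass
class TruthTable:
    """Planted ground truth for recovery scoring of the synthetic data."""

    de_flags: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    planted_lnc_categories: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        site_pairs = {(m, t) for m, t, _, _ in self.planted_sites}
        for lnc, mir, mrna in self.planted_triads:
            for cls, fid in (("lncrna", lnc), ("mirna", mir), ("mrna", mrna)):
                if self.de_flags.get(cls, {}).get(fid, "null") == "null":
                    raise ModelError(f"triad member {fid} not flagged DE")
            if (mir, mrna) not in site_pairs or (mir, lnc) not in site_pairs:
                raise ModelError(f"triad ({lnc},{mir},{mrna}) missing planted sites")


def rng_from_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
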