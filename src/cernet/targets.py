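"""Seed-match miRNA target prediction.

Deterministic stand-in for heuristic target predictors: scans a target
sequence for exact reverse-complement matches to the miRNA seed (positions
2-7) and classifies each hit into the canonical site taxonomy
(6mer, 7mer-A1, 7mer-m8, 8mer).  No free-energy scoring, no conservation.

Orientation: miRNA and target are both read 5'->3'; pairing is antiparallel,
so miRNA position 8 pairs with the target base immediately 5' of the 6mer
core match, and the target base opposite miRNA position 1 (the canonical
'A') sits immediately 3' of the core.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, NamedTuple

from .models import SeedSite

_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}
_ALLOWED = frozenset("ACGUTN")

# 7mer-A1 and 7mer-m8 share a rank: either one satisfies a "7mer" bar.
SITE_RANK: Mapping[str, int] = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 1, "8mer": 2}
_MIN_RANK = {"6mer": 0, "7mer": 1, "7mer-A1": 1, "7mer-m8": 1, "8mer": 2}


def normalize_rna(sequence: str, what: str = "sequence") -> str:
    """Uppercase, map T to U, reject characters outside {A,C,G,U,T,N}."""
    seq = sequence.upper()
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
    return seq.replace("T", "U")


def reverse_complement(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


def find_seed_sites(
    mirna_sequence: str,
    target_sequence: str,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[SeedSite]:
    """All seed-match sites of ``mirna_sequence`` on ``target_sequence``.

    Every position whose 6 nt window is the exact reverse complement of
    miRNA positions 2-7 yields one site, typed by the two optional
    extensions: a match to position 8 (on the 5' side of the core) and a
    target 'A' opposite position 1 (on the 3' side).  ``start`` is the
    0-based offset of the full site sequence; 8mer and 7mer-m8 sites start
    one base 5' of the core.  'N' never matches anything.
    """
    m = normalize_rna(mirna_sequence, "miRNA sequence")
    t = normalize_rna(target_sequence, "target sequence")
    if len(m) < 8:
        raise ValueError(f"miRNA length {len(m)} < 8")

    core = reverse_complement(m[1:7])  # pairs miRNA positions 2-7
    if "N" in core:
        return []
    m8_pair = _RNA_COMPLEMENT[m[7]]  # target base pairing miRNA position 8

    sites: list[SeedSite] = []
    for p in range(len(t) - 5):
        if t[p : p + 6] != core:
            continue
        has_m8 = p >= 1 and m8_pair != "N" and t[p - 1] == m8_pair
        has_a1 = p + 6 < len(t) and t[p + 6] == "A"
        if has_m8 and has_a1:
            site_type, start = "8mer", p - 1
        elif has_m8:
            site_type, start = "7mer-m8", p - 1
        elif has_a1:
            site_type, start = "7mer-A1", p
        else:
            site_type, start = "6mer", p
        sites.append(SeedSite(mirna_id, target_id, start, site_type))
    return sites


class TargetPair(NamedTuple):
    mirna_id: str
    target_id: str
    n_sites: int
    best_site_type: str


def predict_targets(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    min_site_type: str = "7mer",
) -> list[TargetPair]:
    """Candidate (miRNA, target) pairs with at least one qualifying site.

    A pair qualifies if it carries >= 1 site whose rank is at least that of
    ``min_site_type`` (6mer < 7mer-A1 = 7mer-m8 < 8mer).  Output is sorted
    by (miRNA id, target id) for determinism; ``n_sites`` counts only
    qualifying sites.
    """
    if min_site_type not in _MIN_RANK:
        raise ValueError(f"unknown min_site_type {min_site_type!r}")
    bar = _MIN_RANK[min_site_type]
    pairs: list[TargetPair] = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            sites = [
                s
                for s in find_seed_sites(mirnas[mid], targets[tid], mid, tid)
                if SITE_RANK[s.site_type] >= bar
            ]
            if sites:
                best = max(sites, key=lambda s: SITE_RANK[s.site_type])
                pairs.append(TargetPair(mid, tid, len(sites), best.site_type))
    return pairs


def site_type_histogram(sites: Iterable[SeedSite]) -> Counter:
    return Counter(s.site_type for s in sites)
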