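"""Correlation-filtered pair selection, the hypergeometric shared-sponge
test, triad assembly, and network export.

Thresholds are strict exactly as printed in the pipeline contract:
Spearman < -0.7 for miRNA-target pairs, Pearson > 0.9 for lncRNA-mRNA
co-expression, sponge-test p < 0.05.  Correlations are computed across all
samples pooled over conditions.  Constant expression vectors cannot be
ranked; those pairs are excluded and logged, never assigned a coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .models import CeRNATriad, CorrelationPair
from .stats import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

DEFAULT_SPEARMAN_THRESHOLD = -0.7
DEFAULT_PEARSON_THRESHOLD = 0.9
DEFAULT_SPONGE_P_THRESHOLD = 0.05

Edge = tuple[str, str, str]  # (source, interaction, target)


class ConstantVectorError(ValueError):
    """Correlation undefined: one of the vectors is constant."""


def _check_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("constant input vector")
    return x, y


def spearman(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson of average ranks)."""
    x, y = _check_vectors(x, y)
    return float(_st.spearmanr(x, y).statistic)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _check_vectors(x, y)
    return float(_st.pearsonr(x, y).statistic)


def negative_pairs(
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    candidate_pairs: Iterable[tuple[str, str]],
    rho_threshold: float = DEFAULT_SPEARMAN_THRESHOLD,
) -> list[CorrelationPair]:
    """Candidate (miRNA, target) pairs with Spearman < ``rho_threshold``.

    Expression frames are features x samples and must share sample columns.
    Pairs with a constant vector are skipped with a log record.
    """
    samples = list(mirna_expr.columns)
    if list(target_expr.columns) != samples:
        raise ValueError("expression matrices must share identical sample columns")
    kept: list[CorrelationPair] = []
    for mid, tid in candidate_pairs:
        if mid not in mirna_expr.index:
            raise KeyError(f"miRNA {mid!r} missing from expression matrix")
        if tid not in target_expr.index:
            raise KeyError(f"target {tid!r} missing from expression matrix")
        try:
            rho = spearman(mirna_expr.loc[mid], target_expr.loc[tid])
        except ConstantVectorError:
            logger.info("pair (%s, %s) skipped: constant expression", mid, tid)
            continue
        if rho < rho_threshold:
            kept.append(CorrelationPair(mid, tid, "spearman", rho, len(samples)))
    return kept


def coexpressed_pairs(
    lncrna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_threshold: float = DEFAULT_PEARSON_THRESHOLD,
) -> list[CorrelationPair]:
    """All lncRNA x mRNA pairs with Pearson > ``r_threshold`` (strict)."""
    samples = list(lncrna_expr.columns)
    if list(mrna_expr.columns) != samples:
        raise ValueError("expression matrices must share identical sample columns")
    kept: list[CorrelationPair] = []
    for lnc in lncrna_expr.index:
        for mrna in mrna_expr.index:
            try:
                r = pearson(lncrna_expr.loc[lnc], mrna_expr.loc[mrna])
            except ConstantVectorError:
                logger.info("pair (%s, %s) skipped: constant expression", lnc, mrna)
                continue
            if r > r_threshold:
                kept.append(CorrelationPair(str(lnc), str(mrna), "pearson", r, len(samples)))
    return kept


def sponge_test(lnc_mirnas: set, mrna_mirnas: set, universe_size: int) -> float:
    """Upper-tail hypergeometric p for the shared-miRNA overlap.

    k = |intersection|, K = |lnc_mirnas|, n = |mrna_mirnas|, N = universe.
    """
    K, n = len(lnc_mirnas), len(mrna_mirnas)
    if max(K, n) > universe_size:
        raise ValueError(
            f"universe N={universe_size} smaller than a miRNA set (K={K}, n={n})"
        )
    k = len(set(lnc_mirnas) & set(mrna_mirnas))
    return hypergeom_upper_tail(k, universe_size, K, n)


def sponge_universe(neg_pairs: Iterable[CorrelationPair]) -> set[str]:
    """Default universe: miRNAs participating in >= 1 negative pair."""
    return {p.id_a for p in neg_pairs}


@dataclass
class CeRNANetwork:
    triads: list[CeRNATriad] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)


def build_cerna_network(
    neg_pairs_lnc: Sequence[CorrelationPair],
    neg_pairs_mrna: Sequence[CorrelationPair],
    coexp_pairs: Sequence[CorrelationPair],
    universe: set[str] | None = None,
    p_threshold: float = DEFAULT_SPONGE_P_THRESHOLD,
    adjust: bool = False,
) -> CeRNANetwork:
    """Assemble ceRNA triads from the two filtered pair sets.

    For each co-expressed (lncRNA, mRNA) pair, the shared miRNAs are those
    negatively paired with BOTH members; pairs with >= 1 shared miRNA are
    sponge-tested and kept at p < ``p_threshold``.  ``universe`` defaults to
    all miRNAs appearing in either negative pair list.  ``adjust=True``
    applies Benjamini-Hochberg across tested pairs before thresholding
    (off by default: the contract uses raw p).
    """
    if universe is None:
        universe = sponge_universe(neg_pairs_lnc) | sponge_universe(neg_pairs_mrna)
    if not universe:
        raise ValueError("empty miRNA universe")

    lnc_map: dict[str, set[str]] = {}
    for p in neg_pairs_lnc:
        lnc_map.setdefault(p.id_b, set()).add(p.id_a)
    mrna_map: dict[str, set[str]] = {}
    for p in neg_pairs_mrna:
        mrna_map.setdefault(p.id_b, set()).add(p.id_a)

    candidates = []
    for pair in coexp_pairs:
        lnc, mrna = pair.id_a, pair.id_b
        lnc_set = lnc_map.get(lnc, set()) & universe
        mrna_set = mrna_map.get(mrna, set()) & universe
        shared = lnc_set & mrna_set
        if not shared:
            continue
        p_val = sponge_test(lnc_set, mrna_set, len(universe))
        candidates.append((lnc, mrna, shared, lnc_set, mrna_set, p_val))

    p_final = (
        bh_adjust([c[5] for c in candidates]) if (adjust and candidates) else [c[5] for c in candidates]
    )

    network = CeRNANetwork()
    edge_set: set[Edge] = set()
    for (lnc, mrna, shared, lnc_set, mrna_set, _), p_val in zip(candidates, p_final):
        if not p_val < p_threshold:
            continue
        network.triads.append(
            CeRNATriad(
                lncrna_id=lnc,
                mrna_id=mrna,
                shared_mirna_ids=tuple(sorted(shared)),
                K=len(lnc_set),
                n=len(mrna_set),
                N=len(universe),
                p_value=float(p_val),
            )
        )
        for mir in shared:
            edge_set.add((lnc, "lncRNA-miRNA", mir))
            edge_set.add((mir, "miRNA-mRNA", mrna))
    network.triads.sort(key=lambda t: (t.p_value, t.lncrna_id, t.mrna_id))
    network.edges = sorted(edge_set)
    return network


def export_network(
    triads: Sequence[CeRNATriad],
    edges: Sequence[Edge],
    node_attributes: Mapping[str, Mapping[str, str]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write SIF, node-attribute TSV, and triad TSV for network viewers.

    ``node_attributes`` maps node id -> {"type": ..., "de": ...}.
    """
    if not triads and not edges:
        raise ValueError("refusing to export an empty network")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": out / "network.sif",
        "nodes": out / "nodes.tsv",
        "triads": out / "triads.tsv",
    }
    with paths["sif"].open("w") as fh:
        for src, interaction, dst in edges:
            fh.write(f"{src}\t{interaction}\t{dst}\n")
    nodes = sorted({e[0] for e in edges} | {e[2] for e in edges})
    with paths["nodes"].open("w") as fh:
        fh.write("node_id\ttype\tde\n")
        for node in nodes:
            attrs = node_attributes.get(node, {})
            fh.write(f"{node}\t{attrs.get('type', 'NA')}\t{attrs.get('de', 'NA')}\n")
    rows = [
        {
            "lncrna_id": t.lncrna_id,
            "mrna_id": t.mrna_id,
            "shared_mirnas": ",".join(t.shared_mirna_ids),
            "k": t.k,
            "K": t.K,
            "n": t.n,
            "N": t.N,
            "p_value": t.p_value,
        }
        for t in triads
    ]
    pd.DataFrame(
        rows,
        columns=["lncrna_id", "mrna_id", "shared_mirnas", "k", "K", "n", "N", "p_value"],
    ).to_csv(paths["triads"], sep="\t", index=False)
    return paths


def parse_sif(path: str | Path) -> list[Edge]:
    edges: list[Edge] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        src, interaction, dst = line.split("\t")
        edges.append((src, interaction, dst))
    return edges
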