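"""Synthetic-data generator with planted ground truth.

Emulates a 2-condition x 3-replicate skin-transcriptome design (samples
BH-1..3, BN-1..3): miniature gene models on one chromosome, miRNA/UTR/lncRNA
sequences with planted seed sites, and negative-binomial count matrices with
planted differential expression and planted ceRNA triads.

Key constructions
-----------------
* lncRNA placement is stratified over the five positional categories and is
  the exact inverse of the classifier's rules, so category round-trip is
  deterministic.
* Planted (miRNA, target) pairs carry one exact 8mer seed site at a recorded
  position; all other (miRNA, target) pairs are rejection-sampled/repaired
  to contain no 7mer-or-better site.
* Each planted triad shares a per-sample latent factor added to the lncRNA
  and mRNA log2-means and subtracted from the miRNA log2-mean, scaled by
  ``triad_correlation_strength``, yielding strong positive lncRNA-mRNA and
  negative miRNA-x correlations at strength 1.
* Decoys make both ceRNA filters individually falsifiable: one DE miRNA with
  planted sites but independent expression, and one DE miRNA sharing the
  latent factor but carrying no sites.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .models import (
    CountMatrix,
    GeneModel,
    TermMap,
    TranscriptModel,
    TruthTable,
    rng_from_seed,
)
from .targets import SITE_RANK, find_seed_sites, reverse_complement

MARGIN = 2_000
CASSETTE = 8_000
MAX_JITTER = 80  # placement offset budget inside a cassette, nt
CATEGORY_CYCLE = ("sense", "antisense", "intronic", "bidirectional", "intergenic")
# Half-range (log2 units) of the per-sample latent factor shared by a
# triad's members.  The factor takes equally spaced values within each
# condition group (randomly assigned to samples), so it is balanced across
# conditions (true log2FC stays exactly +/- planted_de_lfc), has a fixed
# within-group variance (stable DE power), and orders the samples
# consistently for the rank-correlation filter.
TRIAD_LATENT_SPREAD = 0.25
MIRNA_LENGTH_CHOICES = (21, 22, 23)
MIRNA_LENGTH_WEIGHTS = (0.2, 0.6, 0.2)  # mode 22 by construction
_NT = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    pass


class SequenceDesignError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_mrna: int = 40
    n_lncrna: int = 16
    n_mirna: int = 36
    n_replicates_per_group: int = 3
    nb_dispersion: float = 0.02
    base_mean_log_range: tuple[float, float] = (1.5, 2.5)  # log10 of base mean
    planted_de_lfc: float = 2.0
    n_planted_triads: int = 3
    mirnas_per_triad: int = 3
    triad_correlation_strength: float = 1.0
    utr_length: int = 300
    genome_length: int | None = None  # None -> smallest length that fits
    de_fraction: float = 0.2
    library_size_cv: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "seed",
            "n_mrna",
            "n_lncrna",
            "n_mirna",
            "n_replicates_per_group",
            "n_planted_triads",
            "utr_length",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_mrna < 1 or self.n_mirna < 1 or self.n_replicates_per_group < 2:
            raise ValueError("need n_mrna >= 1, n_mirna >= 1, replicates >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.triad_correlation_strength <= 1.0:
            raise ValueError("triad_correlation_strength must lie in [0, 1]")
        if self.n_planted_triads > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError(
                "n_planted_triads exceeds min(n_mrna, n_lncrna, n_mirna)"
            )
        if self.mirnas_per_triad < 1:
            raise ValueError("mirnas_per_triad must be >= 1")
        if self.n_planted_triads * self.mirnas_per_triad > self.n_mirna:
            raise ValueError(
                "n_planted_triads * mirnas_per_triad exceeds n_mirna"
            )
        if self.utr_length < 80:
            raise ValueError("utr_length must be >= 80 nt")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")

    @property
    def required_genome_length(self) -> int:
        return 2 * MARGIN + self.n_mrna * CASSETTE

    @property
    def mrna_ids(self) -> list[str]:
        return [f"mrna_{i:04d}" for i in range(self.n_mrna)]

    @property
    def lncrna_ids(self) -> list[str]:
        return [f"lnc_{i:04d}" for i in range(self.n_lncrna)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"mir_{i:04d}" for i in range(self.n_mirna)]

    @property
    def samples(self) -> list[str]:
        r = self.n_replicates_per_group
        return [f"BH-{i + 1}" for i in range(r)] + [f"BN-{i + 1}" for i in range(r)]

    @property
    def design(self) -> dict[str, str]:
        return {s: s.split("-")[0] for s in self.samples}


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    lncrnas: list[TranscriptModel]
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    lnc_seqs: dict[str, str]
    counts: dict[str, CountMatrix]
    truth: TruthTable
    term_maps: list[TermMap] = field(default_factory=list)


# --------------------------------------------------------------------------
# gene models


def _opp(strand: str) -> str:
    return "-" if strand == "+" else "+"


def generate_gene_models(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[TranscriptModel], dict[str, str]]:
    """Protein-coding cassettes plus stratified lncRNAs of all 5 categories.

    One coding gene (3 exons) per 8 kb cassette; each lncRNA is placed
    relative to a host gene so that exactly one classification rule fires.
    """
    glen = config.genome_length or config.required_genome_length
    if glen < config.required_genome_length:
        raise PlacementError(
            f"genome_length {glen} cannot fit {config.n_mrna} gene cassettes "
            f"on chr1 (requires >= {config.required_genome_length})"
        )

    genes = []
    for i, gid in enumerate(config.mrna_ids):
        o = MARGIN + i * CASSETTE
        strand = "+" if i % 2 == 0 else "-"
        exons = ((o, o + 200), (o + 600, o + 800), (o + 1200, o + 1400))
        genes.append(GeneModel(gid, "chr1", strand, exons))

    lncrnas: list[TranscriptModel] = []
    categories: dict[str, str] = {}
    for j, lid in enumerate(config.lncrna_ids):
        category = CATEGORY_CYCLE[j % len(CATEGORY_CYCLE)]
        host = genes[j % config.n_mrna]
        d = (j // config.n_mrna) * 17
        if d > MAX_JITTER:
            raise PlacementError(
                f"cassette of gene {host.id} is crowded: cannot place {lid} "
                f"({category}) without overlap"
            )
        o = host.span[0]
        hs = host.strand
        if category == "sense":
            strand = hs
            exons = ((o + 100 + d, o + 260 + d), (o + 900 + d, o + 1000 + d))
        elif category == "antisense":
            strand = _opp(hs)
            exons = ((o + 820 + d, o + 940 + d), (o + 1000 + d, o + 1120 + d))
        elif category == "intronic":
            strand = hs
            exons = ((o + 205 + d, o + 330 + d), (o + 380 + d, o + 490 + d))
        elif category == "bidirectional":
            strand = _opp(hs)
            if hs == "+":
                exons = ((o - 700 - d, o - 560 - d), (o - 500 - d, o - 350 - d))
            else:
                exons = ((o + 1750 + d, o + 1890 + d), (o + 1950 + d, o + 2100 + d))
        else:  # intergenic
            strand = hs
            exons = ((o + 4000 + d, o + 4150 + d), (o + 4200 + d, o + 4350 + d))
        lncrnas.append(
            TranscriptModel(lid, "chr1", strand, exons, "lncRNA", gene_id=lid)
        )
        categories[lid] = category
    return genes, lncrnas, categories


# --------------------------------------------------------------------------
# truth planning


def plan_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    """Assign planted triads, decoys, and DE flags before any sampling."""
    truth = TruthTable()
    mrnas, lncs, mirs = config.mrna_ids, config.lncrna_ids, config.mirna_ids
    flags = {
        "mrna": {f: "null" for f in mrnas},
        "lncrna": {f: "null" for f in lncs},
        "mirna": {f: "null" for f in mirs},
    }

    mpt = config.mirnas_per_triad
    for t in range(config.n_planted_triads):
        lnc, mrna = lncs[t], mrnas[t]
        duplex, mono = ("up", "down") if t % 2 == 0 else ("down", "up")
        flags["lncrna"][lnc] = duplex
        flags["mrna"][mrna] = duplex
        for mir in mirs[t * mpt : (t + 1) * mpt]:
            flags["mirna"][mir] = mono
            truth.planted_triads.append((lnc, mir, mrna))

    # decoy with sites but independent expression
    used = config.n_planted_triads * mpt
    if config.n_mirna > used and config.n_planted_triads > 0:
        flags["mirna"][mirs[used]] = "up"
    # decoy correlated with triad 0's factor but without sites
    if config.n_mirna > used + 1 and config.n_planted_triads > 0:
        flags["mirna"][mirs[used + 1]] = "down"

    # extra planted DE among the remainder
    for cls, ids in (("mrna", mrnas), ("lncrna", lncs), ("mirna", mirs)):
        for fid in ids:
            if flags[cls][fid] == "null" and rng.random() < config.de_fraction:
                flags[cls][fid] = "up" if rng.random() < 0.5 else "down"

    truth.de_flags = flags
    for lid, cat in zip(lncs, [CATEGORY_CYCLE[j % 5] for j in range(config.n_lncrna)]):
        truth.planted_lnc_categories[lid] = cat
    return truth


def planted_site_plan(config: SimulationConfig, truth: TruthTable) -> list[tuple[str, str]]:
    """(miRNA, target) pairs that must carry a planted 8mer site."""
    plan: list[tuple[str, str]] = []
    for lnc, mir, mrna in truth.planted_triads:
        plan.append((mir, mrna))
        plan.append((mir, lnc))
    used = config.n_planted_triads * config.mirnas_per_triad
    if config.n_mirna > used and config.n_planted_triads > 0:
        decoy = config.mirna_ids[used]
        lnc0, _, mrna0 = truth.planted_triads[0]
        plan.append((decoy, mrna0))
        plan.append((decoy, lnc0))
    return plan


# --------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, length: int, alphabet=_NT) -> str:
    return "".join(rng.choice(alphabet, size=length))


def _draw_mirnas(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """miRNA sequences with pairwise-compatible seeds.

    Constraints (resampled until satisfied): all 6mer seed cores distinct,
    and no miRNA's core occurs inside another miRNA's planted 8mer site
    sequence -- this guarantees background repair around planted sites can
    always succeed.
    """
    rna = np.array(list("ACGU"))
    seqs: dict[str, str] = {}
    cores: dict[str, str] = {}
    sites: dict[str, str] = {}
    for mid in config.mirna_ids:
        for _ in range(500):
            length = rng.choice(MIRNA_LENGTH_CHOICES, p=MIRNA_LENGTH_WEIGHTS)
            cand = _random_seq(rng, int(length), rna)
            core = reverse_complement(cand[1:7])
            site = reverse_complement(cand[1:8]) + "A"
            self_hits = [i for i in range(3) if site[i : i + 6] == core]
            ok = (
                core not in cores.values()
                and all(core not in s for s in sites.values())
                and all(c not in site for c in cores.values())
                and self_hits == [1]  # own core only at its canonical offset
            )
            if ok:
                seqs[mid] = cand
                cores[mid] = core
                sites[mid] = site
                break
        else:
            raise SequenceDesignError(
                f"could not draw a compatible sequence for {mid}"
            )
    return seqs


def _plant_and_clean(
    target_len: int,
    planted_mirs: list[str],
    mirna_seqs: dict[str, str],
    rng: np.random.Generator,
    max_redraws: int = 20,
    max_repairs: int = 300,
) -> tuple[str, list[tuple[str, int]]]:
    """One target sequence: planted 8mer per miRNA in ``planted_mirs``,
    no 7mer-or-better site for any other miRNA (nor stray >=7mer sites of
    the planted miRNAs outside their recorded positions).

    Returns (sequence, [(mirna_id, site_start), ...]).
    """
    n_slots = len(planted_mirs)
    if n_slots * 25 + 10 > target_len:
        raise SequenceDesignError(
            f"target length {target_len} too short for {n_slots} planted sites"
        )
    site_seqs = {
        mid: reverse_complement(mirna_seqs[mid][1:8]) + "A" for mid in planted_mirs
    }

    for _ in range(max_redraws):
        seq = list(_random_seq(rng, target_len))
        placements: list[tuple[str, int]] = []
        protected: set[int] = set()
        for slot, mid in enumerate(planted_mirs):
            start = 5 + slot * 25
            seq[start : start + 8] = site_seqs[mid]
            placements.append((mid, start))
            protected.update(range(start, start + 8))

        ok = False
        for _ in range(max_repairs):
            offending: list[tuple[int, int]] = []
            text = "".join(seq)
            allowed = {(mid, pos) for mid, pos in placements}
            for mid, mseq in mirna_seqs.items():
                for site in find_seed_sites(mseq, text, mid, "t"):
                    if SITE_RANK[site.site_type] < 1:
                        continue
                    span_len = {"7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[site.site_type]
                    if (mid, site.start) in allowed and site.site_type == "8mer":
                        continue
                    # a planted 8mer also scans as nothing else at that start
                    offending.append((site.start, site.start + span_len))
            if not offending:
                ok = True
                break
            repaired_any = False
            for s, e in offending:
                mutable = [p for p in range(s, e) if p not in protected and p < target_len]
                if not mutable:
                    continue
                pos = int(rng.choice(mutable))
                current = seq[pos]
                seq[pos] = str(rng.choice(_NT[_NT != current]))
                repaired_any = True
            if not repaired_any:
                break  # unrepairable with this background; redraw
        if ok:
            return "".join(seq), placements
    raise SequenceDesignError(
        "could not build a seed-site-free background after bounded retries"
    )


def generate_sequences(
    config: SimulationConfig,
    lncrnas: list[TranscriptModel],
    site_plan: list[tuple[str, str]],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], list[tuple[str, str, int, str]]]:
    """miRNA, mRNA-3'UTR, and lncRNA sequences plus recorded planted sites."""
    mirna_seqs = _draw_mirnas(config, rng)
    by_target: dict[str, list[str]] = {}
    for mid, tid in site_plan:
        by_target.setdefault(tid, []).append(mid)

    lnc_lengths = {t.id: t.spliced_length for t in lncrnas}
    sites: list[tuple[str, str, int, str]] = []
    utr_seqs: dict[str, str] = {}
    lnc_seqs: dict[str, str] = {}
    for tid in config.mrna_ids:
        seq, placed = _plant_and_clean(
            config.utr_length, by_target.get(tid, []), mirna_seqs, rng
        )
        utr_seqs[tid] = seq
        sites.extend((mid, tid, pos, "8mer") for mid, pos in placed)
    for tid in config.lncrna_ids:
        seq, placed = _plant_and_clean(
            lnc_lengths.get(tid, config.utr_length), by_target.get(tid, []), mirna_seqs, rng
        )
        lnc_seqs[tid] = seq
        sites.extend((mid, tid, pos, "8mer") for mid, pos in placed)
    return mirna_seqs, utr_seqs, lnc_seqs, sites


# --------------------------------------------------------------------------
# counts


def _latent_assignments(
    config: SimulationConfig, truth: TruthTable
) -> dict[str, list[tuple[int, float]]]:
    """feature id -> [(triad index, sign), ...] latent-factor loadings."""
    loadings: dict[str, list[tuple[int, float]]] = {}
    mpt = config.mirnas_per_triad
    for t in range(config.n_planted_triads):
        lnc, mrna = config.lncrna_ids[t], config.mrna_ids[t]
        loadings.setdefault(lnc, []).append((t, +1.0))
        loadings.setdefault(mrna, []).append((t, +1.0))
        for mir in config.mirna_ids[t * mpt : (t + 1) * mpt]:
            loadings.setdefault(mir, []).append((t, -1.0))
    used = config.n_planted_triads * mpt
    if config.n_mirna > used + 1 and config.n_planted_triads > 0:
        # decoy miRNA: correlated with triad 0's factor, no sites
        loadings.setdefault(config.mirna_ids[used + 1], []).append((0, -1.0))
    return loadings


def generate_counts(
    config: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> dict[str, CountMatrix]:
    """Negative-binomial count matrices per RNA class.

    Mean model, on log2 scale per feature f and sample s:
    ``log2 mu = log2(base) + lfc * [DE shift] + strength * sign * z``
    with one balanced latent z vector per planted triad (+1 loading for the
    lncRNA and mRNA, -1 for the shared miRNAs); a per-sample log-normal
    library-size factor (CV ``library_size_cv``) multiplies all classes.
    """
    samples = config.samples
    n_s = len(samples)
    is_bh = np.array([config.design[s] == "BH" for s in samples])

    r_g = config.n_replicates_per_group
    pattern = np.linspace(-1.0, 1.0, r_g) if r_g > 1 else np.zeros(1)
    z = TRIAD_LATENT_SPREAD * np.stack(
        [
            np.concatenate([rng.permutation(pattern), rng.permutation(pattern)])
            for _ in range(max(config.n_planted_triads, 1))
        ]
    )
    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    lib = np.exp(rng.normal(0.0, sigma, size=n_s)) if config.library_size_cv > 0 else np.ones(n_s)
    loadings = _latent_assignments(config, truth)
    amp = config.triad_correlation_strength
    r = 1.0 / config.nb_dispersion

    matrices: dict[str, CountMatrix] = {}
    lo, hi = config.base_mean_log_range
    for cls, ids in (
        ("mrna", config.mrna_ids),
        ("lncrna", config.lncrna_ids),
        ("mirna", config.mirna_ids),
    ):
        rows = []
        for fid in ids:
            base = 10.0 ** rng.uniform(lo, hi)
            log2mu = np.full(n_s, np.log2(base))
            flag = truth.de_flags[cls][fid]
            if flag == "up":
                log2mu = log2mu + config.planted_de_lfc * is_bh
            elif flag == "down":
                log2mu = log2mu + config.planted_de_lfc * (~is_bh)
            for t_idx, sign in loadings.get(fid, []):
                log2mu = log2mu + amp * sign * z[t_idx]
            mu = (2.0**log2mu) * lib
            p = r / (r + mu)
            rows.append(rng.negative_binomial(r, p))
        df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n_s), int),
                          index=ids, columns=samples)
        matrices[cls] = CountMatrix(df, config.design)
    return matrices


def generate_term_map(
    config: SimulationConfig,
    truth: TruthTable,
    rng: np.random.Generator,
    n_terms: int = 12,
    term_size: int = 8,
) -> list[TermMap]:
    """Random terms over the mRNA universe plus one term planted on the
    triad mRNAs (enriched in any study set that recovers the triads)."""
    mrnas = config.mrna_ids
    terms: list[TermMap] = []
    triad_mrnas = {m for _, _, m in truth.planted_triads}
    if triad_mrnas:
        pad = [m for m in mrnas if m not in triad_mrnas]
        extra = list(rng.choice(pad, size=min(2, len(pad)), replace=False)) if pad else []
        terms.append(
            TermMap("term_0000", "planted_triad_program", frozenset(triad_mrnas | set(extra)))
        )
    for i in range(1, n_terms):
        size = min(term_size, len(mrnas))
        members = rng.choice(mrnas, size=size, replace=False)
        terms.append(TermMap(f"term_{i:04d}", f"random_term_{i}", frozenset(members)))
    return terms


# --------------------------------------------------------------------------
# orchestration and fixture I/O


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset deterministically from ``config.seed``."""
    rng = rng_from_seed(config.seed)
    genes, lncrnas, categories = generate_gene_models(config)
    truth = plan_truth(config, rng)
    truth.planted_lnc_categories = categories
    plan = planted_site_plan(config, truth)
    mirna_seqs, utr_seqs, lnc_seqs, sites = generate_sequences(
        config, lncrnas, plan, rng
    )
    truth.planted_sites = sites
    counts = generate_counts(config, truth, rng)
    truth.validate()
    terms = generate_term_map(config, truth, rng)
    return SyntheticDataset(
        config, genes, lncrnas, mirna_seqs, utr_seqs, lnc_seqs, counts, truth, terms
    )


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files plus a manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    paths: dict[str, Path] = {}
    for cls, cm in dataset.counts.items():
        paths[f"counts_{cls}"] = out / f"counts_{cls}.tsv"
        _io.write_counts(cm, paths[f"counts_{cls}"])
    paths["design"] = out / "design.tsv"
    _io.write_design(dataset.config.design, paths["design"])
    paths["gtf"] = out / "models.gtf"
    _io.write_gtf(dataset.genes, dataset.lncrnas, paths["gtf"])
    for name, seqs in (
        ("mirna", dataset.mirna_seqs),
        ("mrna_utr", dataset.utr_seqs),
        ("lncrna", dataset.lnc_seqs),
    ):
        paths[name] = out / f"{name}.fa"
        _io.write_fasta(seqs, paths[name])
    paths["terms"] = out / "terms.tsv"
    _io.write_term_map(dataset.term_maps, paths["terms"])

    truth = dataset.truth
    paths["truth_de"] = out / "truth_de.tsv"
    with paths["truth_de"].open("w") as fh:
        fh.write("rna_class\tfeature_id\tflag\n")
        for cls in ("mrna", "lncrna", "mirna"):
            for fid, flag in truth.de_flags[cls].items():
                fh.write(f"{cls}\t{fid}\t{flag}\n")
    paths["truth_sites"] = out / "truth_sites.tsv"
    with paths["truth_sites"].open("w") as fh:
        fh.write("mirna_id\ttarget_id\tposition\tsite_type\n")
        for mid, tid, pos, st in truth.planted_sites:
            fh.write(f"{mid}\t{tid}\t{pos}\t{st}\n")
    paths["truth_triads"] = out / "truth_triads.tsv"
    with paths["truth_triads"].open("w") as fh:
        fh.write("lncrna_id\tmirna_id\tmrna_id\n")
        for lnc, mir, mrna in truth.planted_triads:
            fh.write(f"{lnc}\t{mir}\t{mrna}\n")
    paths["truth_categories"] = out / "truth_lnc_categories.tsv"
    with paths["truth_categories"].open("w") as fh:
        fh.write("transcript_id\tcategory\n")
        for lid, cat in truth.planted_lnc_categories.items():
            fh.write(f"{lid}\t{cat}\n")

    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "seed": dataset.config.seed,
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def load_fixture_config(fixture_dir: str | Path) -> SimulationConfig:
    manifest = json.loads((Path(fixture_dir) / "manifest.json").read_text())
    cfg = dict(manifest["config"])
    cfg["base_mean_log_range"] = tuple(cfg["base_mean_log_range"])
    return SimulationConfig(**cfg)
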