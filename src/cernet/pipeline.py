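"""Stage orchestration over a single structured config.

Every stage reads its thresholds from :class:`PipelineConfig` only, writes
its outputs plus a ``manifest.json`` (config hash, thresholds applied,
seed) into its own subdirectory of the working directory, and refuses to
start if a required upstream output is missing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, cerna, enrichment, expression, io as _io, targets
from .simulate import SimulationConfig, simulate, write_fixture

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "classify", "targets", "network", "enrich")


class MissingInputError(FileNotFoundError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    work_dir: str = "cernet_run"
    seed: int = 0
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    spearman_threshold: float = -0.7
    pearson_threshold: float = 0.9
    sponge_p_threshold: float = 0.05
    enrichment_threshold: float = 0.05
    bidirectional_window: int = 1000
    min_site_type: str = "7mer"
    min_exons: int = 2
    simulate_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1 or not 0 < self.sponge_p_threshold <= 1:
            raise ValueError("p-value thresholds must lie in (0, 1]")
        if not 0 < self.enrichment_threshold <= 1:
            raise ValueError("enrichment threshold must lie in (0, 1]")
        if not -1 <= self.spearman_threshold <= 0:
            raise ValueError("spearman threshold must lie in [-1, 0]")
        if not 0 <= self.pearson_threshold <= 1:
            raise ValueError("pearson threshold must lie in [0, 1]")
        if self.lfc_threshold < 0:
            raise ValueError("lfc threshold must be >= 0")
        if self.bidirectional_window < 0:
            raise ValueError("bidirectional window must be >= 0")
        if self.min_site_type not in ("6mer", "7mer", "7mer-A1", "7mer-m8", "8mer"):
            raise ValueError(f"bad min_site_type {self.min_site_type!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def fixture_dir(self) -> Path:
        return Path(self.work_dir) / "fixture"

    def stage_dir(self, stage: str) -> Path:
        return Path(self.work_dir) / stage


def _require(stage: str, *paths: Path) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise MissingInputError(
            f"stage '{stage}' is missing required inputs: {missing} "
            "(run the upstream stage first)"
        )


def _write_manifest(cfg: PipelineConfig, stage: str, thresholds: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "thresholds": thresholds,
    }
    path = cfg.stage_dir(stage) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    for key, value in thresholds.items():
        logger.info("stage %s: %s = %r", stage, key, value)


def run_simulate(cfg: PipelineConfig) -> Path:
    sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulate_params)
    dataset = simulate(sim_cfg)
    write_fixture(dataset, cfg.fixture_dir)
    logger.info("fixture written to %s", cfg.fixture_dir)
    return cfg.fixture_dir


def _load_counts(cfg: PipelineConfig, cls: str):
    fx = cfg.fixture_dir
    design = _io.read_design(fx / "design.tsv")
    return _io.read_counts(fx / f"counts_{cls}.tsv", design)


def run_de(cfg: PipelineConfig) -> Path:
    fx = cfg.fixture_dir
    _require("de", fx / "design.tsv", *(fx / f"counts_{c}.tsv" for c in ("mrna", "lncrna", "mirna")))
    out = cfg.stage_dir("de")
    out.mkdir(parents=True, exist_ok=True)
    for cls in ("mrna", "lncrna", "mirna"):
        cm = _load_counts(cfg, cls)
        table = expression.de_analysis(
            cm, fdr_threshold=cfg.fdr_threshold, lfc_threshold=cfg.lfc_threshold
        )
        table.to_csv(out / f"de_{cls}.tsv", sep="\t", index_label="feature_id")
    _write_manifest(cfg, "de", {"fdr": cfg.fdr_threshold, "lfc": cfg.lfc_threshold})
    return out


def run_classify(cfg: PipelineConfig) -> Path:
    gtf = cfg.fixture_dir / "models.gtf"
    _require("classify", gtf)
    out = cfg.stage_dir("classify")
    out.mkdir(parents=True, exist_ok=True)
    genes, transcripts = _io.read_gtf(gtf)
    lncs = annotation.filter_novel_transcripts(
        (t for t in transcripts if t.biotype == "lncRNA"), cfg.min_exons
    )
    categories = annotation.classify_all(lncs, genes, cfg.bidirectional_window)
    with (out / "lncrna_categories.tsv").open("w") as fh:
        fh.write("transcript_id\tcategory\n")
        for tid in sorted(categories):
            fh.write(f"{tid}\t{categories[tid]}\n")
    _io.write_bed(lncs, categories, out / "lncrna.bed")
    _write_manifest(
        cfg,
        "classify",
        {"bidirectional_window": cfg.bidirectional_window, "min_exons": cfg.min_exons},
    )
    return out


def _read_de(de_path: Path) -> pd.DataFrame:
    # keep_default_na: the literal call value "null" must survive the round trip
    return pd.read_csv(
        de_path, sep="\t", index_col="feature_id", keep_default_na=False, na_values=[]
    )


def _de_features(de_path: Path) -> list[str]:
    df = _read_de(de_path)
    return list(df.index[df["call"] != "null"])


def run_targets(cfg: PipelineConfig) -> Path:
    fx = cfg.fixture_dir
    de_dir = cfg.stage_dir("de")
    _require(
        "targets",
        fx / "mirna.fa",
        fx / "mrna_utr.fa",
        fx / "lncrna.fa",
        *(de_dir / f"de_{c}.tsv" for c in ("mrna", "lncrna", "mirna")),
    )
    out = cfg.stage_dir("targets")
    out.mkdir(parents=True, exist_ok=True)

    mirna_seqs = _io.read_fasta(fx / "mirna.fa")
    utr_seqs = _io.read_fasta(fx / "mrna_utr.fa")
    lnc_seqs = _io.read_fasta(fx / "lncrna.fa")
    de_mir = set(_de_features(de_dir / "de_mirna.tsv"))
    de_mrna = set(_de_features(de_dir / "de_mrna.tsv"))
    de_lnc = set(_de_features(de_dir / "de_lncrna.tsv"))

    mirnas = {m: s for m, s in mirna_seqs.items() if m in de_mir}
    rows = []
    for cls, pool in (
        ("mrna", {t: s for t, s in utr_seqs.items() if t in de_mrna}),
        ("lncrna", {t: s for t, s in lnc_seqs.items() if t in de_lnc}),
    ):
        for pair in targets.predict_targets(mirnas, pool, cfg.min_site_type):
            rows.append(
                {
                    "mirna_id": pair.mirna_id,
                    "target_id": pair.target_id,
                    "target_class": cls,
                    "n_sites": pair.n_sites,
                    "best_site_type": pair.best_site_type,
                }
            )
    pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "target_class", "n_sites", "best_site_type"]
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)
    _write_manifest(cfg, "targets", {"min_site_type": cfg.min_site_type})
    return out


def run_network(cfg: PipelineConfig) -> Path:
    fx = cfg.fixture_dir
    de_dir, tg_dir = cfg.stage_dir("de"), cfg.stage_dir("targets")
    _require(
        "network",
        tg_dir / "pairs.tsv",
        *(de_dir / f"de_{c}.tsv" for c in ("mrna", "lncrna", "mirna")),
        *(fx / f"counts_{c}.tsv" for c in ("mrna", "lncrna", "mirna")),
    )
    out = cfg.stage_dir("network")
    out.mkdir(parents=True, exist_ok=True)

    expr = {
        cls: expression.normalize_median_ratio(_load_counts(cfg, cls))
        for cls in ("mrna", "lncrna", "mirna")
    }
    de_calls = {cls: _read_de(de_dir / f"de_{cls}.tsv") for cls in ("mrna", "lncrna", "mirna")}
    de_sets = {cls: set(df.index[df["call"] != "null"]) for cls, df in de_calls.items()}

    pairs = pd.read_csv(tg_dir / "pairs.tsv", sep="\t")
    mrna_candidates = [
        (r.mirna_id, r.target_id)
        for r in pairs.itertuples()
        if r.target_class == "mrna"
    ]
    lnc_candidates = [
        (r.mirna_id, r.target_id)
        for r in pairs.itertuples()
        if r.target_class == "lncrna"
    ]
    neg_mrna = cerna.negative_pairs(
        expr["mirna"], expr["mrna"], mrna_candidates, cfg.spearman_threshold
    )
    neg_lnc = cerna.negative_pairs(
        expr["mirna"], expr["lncrna"], lnc_candidates, cfg.spearman_threshold
    )
    # co-expression on log2(normalized + 1): Pearson on the log scale is the
    # usual choice for heavy-tailed expression data; Spearman above is
    # unaffected by the transform.
    log_lnc = np.log2(expr["lncrna"].loc[sorted(de_sets["lncrna"])] + 1.0)
    log_mrna = np.log2(expr["mrna"].loc[sorted(de_sets["mrna"])] + 1.0)
    coexp = cerna.coexpressed_pairs(log_lnc, log_mrna, cfg.pearson_threshold)
    if neg_lnc or neg_mrna:
        network = cerna.build_cerna_network(
            neg_lnc, neg_mrna, coexp, p_threshold=cfg.sponge_p_threshold
        )
    else:
        logger.warning("no negative miRNA pairs survived filtering; empty network")
        network = cerna.CeRNANetwork()

    node_attrs: dict[str, dict[str, str]] = {}
    for cls, kind in (("mrna", "mRNA"), ("lncrna", "lncRNA"), ("mirna", "miRNA")):
        for fid, row in de_calls[cls].iterrows():
            node_attrs[str(fid)] = {"type": kind, "de": row["call"]}

    if network.triads or network.edges:
        cerna.export_network(network.triads, network.edges, node_attrs, out)
    else:
        # still emit an empty triad table so downstream stages can proceed
        pd.DataFrame(
            columns=["lncrna_id", "mrna_id", "shared_mirnas", "k", "K", "n", "N", "p_value"]
        ).to_csv(out / "triads.tsv", sep="\t", index=False)
        (out / "network.sif").write_text("")
    _write_manifest(
        cfg,
        "network",
        {
            "spearman": cfg.spearman_threshold,
            "pearson": cfg.pearson_threshold,
            "sponge_p": cfg.sponge_p_threshold,
        },
    )
    return out


def run_enrich(cfg: PipelineConfig) -> Path:
    fx = cfg.fixture_dir
    net_dir, de_dir = cfg.stage_dir("network"), cfg.stage_dir("de")
    _require("enrich", net_dir / "triads.tsv", fx / "terms.tsv", de_dir / "de_mrna.tsv")
    out = cfg.stage_dir("enrich")
    out.mkdir(parents=True, exist_ok=True)

    triads = pd.read_csv(net_dir / "triads.tsv", sep="\t")
    study = sorted(set(triads["mrna_id"])) if len(triads) else []
    population = list(
        pd.read_csv(de_dir / "de_mrna.tsv", sep="\t", index_col="feature_id").index
    )
    terms = _io.read_term_map(fx / "terms.tsv")
    results = enrichment.enrich(study, population, terms) if study else []
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=[f.name for f in dataclasses.fields(enrichment.EnrichmentResult)],
    )
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for mode in ("go", "kegg"):
        sig = enrichment.filter_enrichment(results, mode, cfg.enrichment_threshold)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in sig],
            columns=[f.name for f in dataclasses.fields(enrichment.EnrichmentResult)],
        ).to_csv(out / f"{mode}_significant.tsv", sep="\t", index=False)
    _write_manifest(cfg, "enrich", {"threshold": cfg.enrichment_threshold})
    return out


_RUNNERS = {
    "simulate": run_simulate,
    "de": run_de,
    "classify": run_classify,
    "targets": run_targets,
    "network": run_network,
    "enrich": run_enrich,
}


def run_stage(cfg: PipelineConfig, stage: str) -> Path:
    if stage == "all":
        last = None
        for name in STAGES:
            last = _RUNNERS[name](cfg)
        return last
    try:
        runner = _RUNNERS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}") from None
    return runner(cfg)
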