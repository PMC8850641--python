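"""Readers/writers for the pipeline's plain-text formats.

GTF is written 1-based inclusive with ``gene_id``/``transcript_id``/
``gene_biotype`` attributes; BED is 0-based half-open.  FASTA goes through
Biopython.  Count matrices and design tables are TSV via pandas.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CountMatrix, GeneModel, TermMap, TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(
    genes: Sequence[GeneModel],
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
    source: str = "cernet",
) -> None:
    """Write gene/transcript/exon rows, 1-based inclusive coordinates."""
    path = Path(path)
    lines: list[str] = []

    def _row(chrom, feature, start, end, strand, attrs) -> str:
        attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
        return "\t".join(
            [chrom, source, feature, str(start + 1), str(end), ".", strand, ".", attr_str]
        )

    for g in genes:
        gs, ge = g.span
        lines.append(
            _row(g.chromosome, "gene", gs, ge, g.strand, [("gene_id", g.id), ("gene_biotype", g.biotype)])
        )
        attrs = [("gene_id", g.id), ("transcript_id", f"{g.id}.t1"), ("gene_biotype", g.biotype)]
        lines.append(_row(g.chromosome, "transcript", gs, ge, g.strand, attrs))
        for es, ee in g.exons:
            lines.append(_row(g.chromosome, "exon", es, ee, g.strand, attrs))
    for t in transcripts:
        ts, te = t.span
        gene_id = t.gene_id or t.id
        attrs = [("gene_id", gene_id), ("transcript_id", t.id), ("gene_biotype", t.biotype)]
        lines.append(_row(t.chromosome, "transcript", ts, te, t.strand, attrs))
        for es, ee in t.exons:
            lines.append(_row(t.chromosome, "exon", es, ee, t.strand, attrs))
    path.write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> tuple[list[GeneModel], list[TranscriptModel]]:
    """Parse exon rows back into gene and transcript models.

    Transcripts with ``gene_biotype protein_coding`` are merged per gene id
    into GeneModels (union of exons); everything else becomes a
    TranscriptModel.
    """
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF row: {line!r}")
        chrom, _, feature, start, end, _, strand, _, attr_str = fields
        if feature != "exon":
            continue
        attrs = dict(_ATTR_RE.findall(attr_str))
        tid = attrs.get("transcript_id")
        if tid is None:
            raise ValueError(f"exon row without transcript_id: {line!r}")
        meta[tid] = (
            chrom,
            strand,
            attrs.get("gene_id", tid),
            attrs.get("gene_biotype", "lncRNA"),
        )
        exons.setdefault(tid, []).append((int(start) - 1, int(end)))

    genes: dict[str, dict] = {}
    transcripts: list[TranscriptModel] = []
    for tid, (chrom, strand, gene_id, biotype) in meta.items():
        ivs = sorted(exons[tid])
        if biotype == "protein_coding":
            rec = genes.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "exons": []}
            )
            rec["exons"].extend(ivs)
        else:
            transcripts.append(
                TranscriptModel(tid, chrom, strand, tuple(ivs), biotype, gene_id)
            )
    gene_models = [
        GeneModel(gid, rec["chrom"], rec["strand"], tuple(sorted(set(rec["exons"]))))
        for gid, rec in genes.items()
    ]
    gene_models.sort(key=lambda g: g.id)
    transcripts.sort(key=lambda t: t.id)
    return gene_models, transcripts


def write_bed(transcripts: Iterable[TranscriptModel], categories: Mapping[str, str], path: str | Path) -> None:
    """BED6 of classified transcripts; the name column is id|category."""
    with Path(path).open("w") as fh:
        for t in transcripts:
            s, e = t.span
            name = f"{t.id}|{categories.get(t.id, 'NA')}"
            fh.write(f"{t.chromosome}\t{s}\t{e}\t{name}\t0\t{t.strand}\n")


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(
    counts_path: str | Path,
    design: Mapping[str, str],
    lengths: pd.Series | None = None,
) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    return CountMatrix(df, dict(design), lengths)


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tcondition\n")
        for sample, condition in design.items():
            fh.write(f"{sample}\t{condition}\n")


def read_design(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["condition"]))


def write_term_map(terms: Sequence[TermMap], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_id\tname\tgene_id\n")
        for term in terms:
            for gene in sorted(term.genes):
                fh.write(f"{term.term_id}\t{term.name}\t{gene}\n")


def read_term_map(path: str | Path) -> list[TermMap]:
    df = pd.read_csv(path, sep="\t")
    terms = []
    for (term_id, name), group in df.groupby(["term_id", "name"], sort=True):
        terms.append(TermMap(str(term_id), str(name), frozenset(group["gene_id"])))
    return terms
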