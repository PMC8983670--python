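"""File-format adapters: TSV/MTX count matrices, GTF/SAM, run manifests.

Conventions: GTF coordinates are 1-based closed on disk and converted to
0-based half-open internally; the read-record adapter assumes a single-end
reverse-stranded protocol (a read matches a gene's strand when it aligns
antisense to it).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam
import yaml
from scipy import io as spio
from scipy import sparse

from .simulate import GeneModel

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "write_gtf",
    "read_gene_models_gtf",
    "write_sam",
    "records_from_sam",
    "write_manifest",
    "read_manifest",
]


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, prefix: str) -> None:
    """MatrixMarket matrix with row/column sidecar files (``<prefix>.mtx``,
    ``<prefix>.rows.tsv``, ``<prefix>.cols.tsv``)."""
    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(f"{prefix}.rows.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(f"{prefix}.cols.tsv", sep="\t", index=False, header=False)


def write_gtf(models: list[GeneModel], path: str, source: str = "stresswaves") -> None:
    """Write gene/transcript/exon features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f'gene_id "{m.gene_id}";\n'
            )
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gene_models_gtf(path: str) -> list[GeneModel]:
    """Parse exon features of a GTF back into gene models (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes["gene_id"][0]
        g = genes.setdefault(gid, {"chrom": ex.seqid, "strand": ex.strand, "exons": []})
        g["exons"].append((ex.start - 1, ex.end))  # to 0-based half-open
    return [
        GeneModel(gid, g["chrom"], g["strand"], sorted(g["exons"]))
        for gid, g in sorted(genes.items())
    ]


def _parse_blocks(s: str) -> list[tuple[int, int]]:
    return [tuple(map(int, part.split("-"))) for part in s.split(";")]


def write_sam(records: pd.DataFrame, models: list[GeneModel], path: str) -> None:
    """Write simulated reads as SAM using their genomic blocks.

    Strand-discordant reads are written on the wrong strand for a
    reverse-stranded protocol; secondary alignments get the secondary flag.
    """
    by_chrom: dict[str, int] = {}
    strand = {m.gene_id: m.strand for m in models}
    for m in models:
        by_chrom[m.chrom] = max(by_chrom.get(m.chrom, 0), m.end + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(by_chrom.items())],
    }
    chrom_id = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for row in records.itertuples():
            blocks = _parse_blocks(row.blocks)
            a = pysam.AlignedSegment()
            a.query_name = row.read_id
            a.reference_id = chrom_id[row.chrom]
            a.reference_start = blocks[0][0]
            a.mapping_quality = 255
            cig = []
            for i, (s, e) in enumerate(blocks):
                if i:
                    gap = s - blocks[i - 1][1]
                    cig.append((3, gap))  # N
                cig.append((0, e - s))  # M
            a.cigartuples = cig
            length = sum(e - s for s, e in blocks)
            a.query_sequence = "N" * length
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            # reverse-stranded protocol: a concordant read aligns antisense
            gene_plus = strand[row.gene_id] == "+"
            concordant = bool(row.strand_match)
            a.is_reverse = gene_plus == concordant
            a.is_secondary = not bool(row.primary)
            out.write(a)


def records_from_sam(sam_path: str, gtf_path: str) -> pd.DataFrame:
    """Canonical read-record table from a SAM and its GTF annotation.

    For every alignment and every candidate gene its blocks overlap, the
    exon and transcript-span overlap fractions, unmatched bases relative to
    that gene, the split flag, primary flag and strand concordance
    (reverse-stranded, single-end) are computed.
    """
    models = read_gene_models_gtf(gtf_path)
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    rows = []
    with pysam.AlignmentFile(sam_path, "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            blocks = aln.get_blocks()
            length = sum(e - s for s, e in blocks)
            split = any(op == 3 for op, _ in (aln.cigartuples or []))
            chrom = aln.reference_name
            for m in by_chrom.get(chrom, []):
                span_bp = sum(max(0, min(e, m.end) - max(s, m.start)) for s, e in blocks)
                if span_bp == 0:
                    continue
                exon_bp = sum(
                    max(0, min(e, eb) - max(s, ea))
                    for s, e in blocks
                    for ea, eb in m.exons
                )
                strand_match = aln.is_reverse == (m.strand == "+")
                rows.append(
                    {
                        "read_id": aln.query_name,
                        "gene_id": m.gene_id,
                        "split": split,
                        "exon_overlap_fraction": exon_bp / length,
                        "transcript_overlap_fraction": span_bp / length,
                        "unmatched_bases": length - span_bp,
                        "primary": not aln.is_secondary,
                        "strand_match": strand_match,
                        "chrom": chrom,
                    }
                )
    return pd.DataFrame(rows)


def write_manifest(path: str, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_manifest(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_run(outdir: str, config: dict, tables: dict[str, pd.DataFrame]) -> None:
    """Emit a run directory: manifest plus named TSV tables."""
    os.makedirs(outdir, exist_ok=True)
    write_manifest(os.path.join(outdir, "manifest.yaml"), config)
    for name, df in tables.items():
        df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t")
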