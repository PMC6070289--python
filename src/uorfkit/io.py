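"""Readers and writers for the package's file formats.

Transcript models travel as FASTA (spliced transcript sequences, via
Biopython) plus either GFF3 (five_prime_UTR/CDS features in transcript
coordinates, 1-based at the file boundary) or a CDS-coordinate TSV.
Counts, uORF annotations, and population site tables are plain TSVs read
and written with pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from uorfkit.models import TranscriptModel, UORF


def write_transcripts_fasta(transcripts: Iterable[TranscriptModel], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=f"gene={t.gene_id}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_transcripts_gff3(transcripts: Iterable[TranscriptModel], path) -> None:
    """GFF3 in transcript coordinates (seqid = transcript id, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            n = len(t.sequence)
            attrs = f"ID={t.transcript_id};gene_id={t.gene_id}"
            rows = [
                (t.transcript_id, "uorfkit", "mRNA", 1, n, attrs),
                (t.transcript_id, "uorfkit", "five_prime_UTR", 1, t.cds_start, attrs),
                (t.transcript_id, "uorfkit", "CDS", t.cds_start + 1, t.cds_end, attrs),
            ]
            if t.cds_end < n:
                rows.append((t.transcript_id, "uorfkit", "three_prime_UTR", t.cds_end + 1, n, attrs))
            for seqid, src, ftype, start, end, a in rows:
                if end < start:
                    continue
                fh.write(f"{seqid}\t{src}\t{ftype}\t{start}\t{end}\t.\t+\t.\t{a}\n")


def read_transcripts(fasta_path, gff3_path) -> list[TranscriptModel]:
    """Rebuild transcript models from a FASTA + transcript-coordinate GFF3."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    gff = pd.read_csv(
        gff3_path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    cds = gff[gff["type"] == "CDS"]
    out = []
    for _, row in cds.iterrows():
        tid = row["seqid"]
        gene = dict(kv.split("=") for kv in row["attrs"].split(";")).get("gene_id", tid)
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                sequence=seqs[tid],
                cds_start=int(row["start"]) - 1,
                cds_end=int(row["end"]),
            )
        )
    return out


def write_uorf_table(uorfs: Iterable[UORF], path) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": u.feature_id,
                "transcript_id": u.transcript_id,
                "start": u.start,
                "end": u.end,
                "overlap_class": u.overlap_class,
                "kozak_score": u.kozak_score,
                "distance_uaug_to_caug": u.distance_uaug_to_caug,
                "distance_cap_to_uaug": u.distance_cap_to_uaug,
                "distance_stop_to_caug": u.distance_stop_to_caug,
            }
            for u in uorfs
        ]
    ).to_csv(path, sep="\t", index=False)


def write_uorf_bed(uorfs: Iterable[UORF], path) -> None:
    """Transcript-relative BED12 (one block per uORF)."""
    with open(path, "w") as fh:
        for u in uorfs:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            u.transcript_id, u.start, u.end, u.feature_id, 0, "+",
                            u.start, u.end, "0,0,0", 1, u.end - u.start, 0,
                        ],
                    )
                )
                + "\n"
            )


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sites(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_coverage_tsv(path) -> dict[str, "pd.DataFrame"]:
    """Per-position coverage TSV (transcript_id, pos, count) grouped by transcript."""
    df = pd.read_csv(path, sep="\t")
    return {tid: g[["pos", "count"]] for tid, g in df.groupby("transcript_id")}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
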