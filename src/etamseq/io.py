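"""Readers and writers for the on-disk formats the pipeline touches.

All tabular formats are UTF-8, tab-separated with a header line, LF line
endings.  Coordinates are 0-based half-open throughout; BED output follows
the BED convention.  Motif strings use the RNA alphabet (U, not T).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .model import (
    BoundaryError,
    GenomicSite,
    MethylCall,
    ParseError,
    ReadObservation,
    ReferenceMismatchError,
    SampleTable,
    SiteCount,
    TranscriptAnnotation,
    ValidationError,
)

SITE_COLUMNS = ["contig", "pos", "strand", "a_count", "g_count", "other_count"]
READ_COLUMNS = ["read_id", "umi", "contig", "strand", "ref_a_positions", "observed"]

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def _require_columns(path, header: List[str], wanted: List[str]) -> None:
    missing = [c for c in wanted if c not in header]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header was {header}")


def read_site_counts(path, role: str, label: Optional[str] = None) -> SampleTable:
    """Parse a per-site A/G count TSV into a :class:`SampleTable`.

    Expected columns: contig, pos, strand, a_count, g_count, other_count.
    Duplicate (contig, pos, strand) rows and negative counts are rejected.
    """
    path = Path(path)
    table = SampleTable(label=label or path.stem, role=role)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, expected a header line")
        _require_columns(path, reader.fieldnames, SITE_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                site = GenomicSite(row["contig"].strip(), int(row["pos"]), row["strand"].strip())
                count = SiteCount(
                    site,
                    a_count=int(row["a_count"]),
                    g_count=int(row["g_count"]),
                    other_count=int(row["other_count"]),
                )
            except (TypeError, KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if site in table:
                raise ValidationError(f"{path}:{lineno}: duplicate site {site}")
            table.add(count)
    return table


def write_site_counts(table: SampleTable, path) -> None:
    rows = sorted(table, key=lambda sc: sc.site)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for sc in rows:
            fh.write(
                f"{sc.site.contig}\t{sc.site.pos}\t{sc.site.strand}\t"
                f"{sc.a_count}\t{sc.g_count}\t{sc.other_count}\n"
            )


def _split_field(text: str) -> List[str]:
    text = text.strip()
    return [] if text in ("", "-") else text.split(",")


def read_reads(path) -> List[ReadObservation]:
    """Parse the simplified aligned-read TSV.

    ``ref_a_positions`` and ``observed`` are comma-joined and must align
    1:1; a ``umi`` field of "-" records an absent UMI.
    """
    path = Path(path)
    out: List[ReadObservation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, expected a header line")
        _require_columns(path, reader.fieldnames, READ_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            umi = row["umi"].strip()
            try:
                positions = [int(p) for p in _split_field(row["ref_a_positions"])]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed position list: {exc}") from exc
            try:
                obs = ReadObservation(
                    read_id=row["read_id"].strip(),
                    umi=None if umi in ("", "-") else umi,
                    contig=row["contig"].strip(),
                    strand=row["strand"].strip(),
                    ref_a_positions=positions,
                    observed=_split_field(row["observed"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            out.append(obs)
    return out


def write_reads(reads: Iterable[ReadObservation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(READ_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.umi or '-'}\t{r.contig}\t{r.strand}\t"
                f"{','.join(str(p) for p in r.ref_a_positions)}\t{','.join(r.observed)}\n"
            )


def fetch_motif(site: GenomicSite, reference: Mapping[str, object]) -> str:
    """5-mer centred on an A site, in RNA alphabet, strand-resolved.

    ``reference`` is any mapping from contig name to a sliceable sequence
    (a ``pyfaidx.Fasta`` or a plain dict of strings).  Minus-strand sites
    return the reverse complement, so the centre is always A.
    """
    if site.contig not in reference:
        raise ParseError(f"contig {site.contig!r} not in reference")
    seq = reference[site.contig]
    if site.pos < 2 or site.pos + 3 > len(seq):
        raise BoundaryError(f"site {site} within 2 nt of a contig end")
    window = str(seq[site.pos - 2 : site.pos + 3]).upper()
    if site.strand == "-":
        window = window.translate(_COMPLEMENT)[::-1]
    window = window.replace("T", "U")
    if window[2] != "A":
        raise ReferenceMismatchError(
            f"reference base at {site} is {window[2]!r} on strand {site.strand}, expected A"
        )
    return window


CALL_COLUMNS = [
    "contig",
    "pos",
    "strand",
    "apparent_m",
    "accessibility",
    "true_m",
    "exposed_m",
    "p_value",
    "q_value",
    "treated_a",
    "treated_g",
    "control_a",
    "control_g",
    "motif5",
    "passed",
]


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.6g}"


def write_calls(calls: Iterable[MethylCall], path, format: str = "tsv") -> None:
    """Write a call set, sorted by (contig, pos, strand).

    ``tsv`` emits every field; ``bed`` emits BED6 with name "m6A" and
    score = round(1000 x true_m).
    """
    if format not in ("tsv", "bed"):
        raise ValueError(f"format must be 'tsv' or 'bed', got {format!r}")
    calls = sorted(calls, key=lambda c: (c.site.contig, c.site.pos, c.site.strand))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if format == "tsv":
            fh.write("\t".join(CALL_COLUMNS) + "\n")
            for c in calls:
                fh.write(
                    "\t".join(
                        [
                            c.site.contig,
                            str(c.site.pos),
                            c.site.strand,
                            _fmt(c.apparent_m),
                            _fmt(c.accessibility),
                            _fmt(c.true_m),
                            _fmt(c.exposed_m),
                            _fmt(c.p_value),
                            _fmt(c.q_value),
                            str(c.treated_counts[0]),
                            str(c.treated_counts[1]),
                            str(c.control_counts[0]),
                            str(c.control_counts[1]),
                            c.motif5 or "NA",
                            str(c.passed),
                        ]
                    )
                    + "\n"
                )
        else:
            for c in calls:
                score = 0 if c.true_m is None else int(round(1000 * c.true_m))
                fh.write(
                    f"{c.site.contig}\t{c.site.pos}\t{c.site.pos + 1}\tm6A\t{score}\t{c.site.strand}\n"
                )


def read_calls(path) -> pd.DataFrame:
    """Read a call TSV back as a DataFrame (NA-aware)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_exclusion_sites(path) -> Set[GenomicSite]:
    """Sites to exclude from calling (e.g. known A-to-I editing positions).

    TSV with columns contig, pos, strand.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(path, list(df.columns), ["contig", "pos", "strand"])
    return {
        GenomicSite(str(r.contig), int(r.pos), str(r.strand))
        for r in df.itertuples(index=False)
    }


def read_half_lives(path) -> Dict[str, float]:
    """transcript_id -> half-life in hours."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(path, list(df.columns), ["transcript_id", "half_life_hours"])
    return dict(zip(df["transcript_id"].astype(str), df["half_life_hours"].astype(float)))


def read_annotation(path) -> Dict[str, TranscriptAnnotation]:
    """Transcript exon structures from a TSV with comma-joined exon bounds."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        path, list(df.columns), ["transcript_id", "contig", "strand", "exon_starts", "exon_ends"]
    )
    out: Dict[str, TranscriptAnnotation] = {}
    for r in df.itertuples(index=False):
        starts = [int(x) for x in str(r.exon_starts).split(",") if x != ""]
        ends = [int(x) for x in str(r.exon_ends).split(",") if x != ""]
        if len(starts) != len(ends):
            raise ParseError(f"{path}: transcript {r.transcript_id}: exon_starts/exon_ends length mismatch")
        ann = TranscriptAnnotation(
            transcript_id=str(r.transcript_id),
            contig=str(r.contig),
            strand=str(r.strand),
            exons=list(zip(starts, ends)),
        )
        out[ann.transcript_id] = ann
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sequences:
            seq = sequences[name]
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
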