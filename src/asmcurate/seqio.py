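"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; the three alignment-table dialects
(PAF, MUMmer ``show-coords -T -H``, BLAST outfmt 6) are converted to a
single internal convention — 0-based half-open coordinates on the forward
strand of both sequences — at this boundary and nowhere else.
"""

from __future__ import annotations

import gzip
import io
from typing import Optional

from Bio import SeqIO as _BioSeqIO

from .core import AlignmentBlock, Interval, SeqRecord
from .errors import ParseError, ValidationError

DIALECTS = ("paf", "coords", "blast6")


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: Optional[str] = None) -> list[SeqRecord]:
    """Read FASTA or FASTQ (optionally gzipped) into SeqRecords.

    Sequences are uppercased; FASTQ qualities are Phred+33-decoded by
    Biopython. Duplicate record ids are rejected.
    """
    fmt = format or _sniff_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValidationError(f"unsupported sequence format {fmt!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        try:
            for rec in _BioSeqIO.parse(fh, fmt):
                if rec.id in seen:
                    raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
                seen.add(rec.id)
                qual = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
                records.append(SeqRecord(rec.id, str(rec.seq), qual))
        except ValueError as exc:  # Biopython's malformed-record errors
            raise ParseError(f"malformed {fmt}: {exc}", path) from exc
    return records


def _sniff_format(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def write_sequences(records, path, format: str = "fasta") -> None:
    if format not in ("fasta", "fastq"):
        raise ValidationError(f"unsupported sequence format {format!r}")
    with _open_text(path, "wt") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                if rec.quality is None:
                    raise ValidationError(f"record {rec.id!r} lacks qualities for FASTQ")
                qstr = "".join(chr(q + 33) for q in rec.quality)
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")


def softmask_intervals(path) -> list[Interval]:
    """Lowercase (soft-masked) spans of a FASTA, as repeat-mask intervals.

    Masked FASTAs are a common carrier of repeat annotation; this recovers
    it even though sequences are uppercased on read.
    """
    out: list[Interval] = []
    with _open_text(path) as fh:
        seq_id = None
        pos = 0
        run_start = None

        def close_run():
            nonlocal run_start
            if run_start is not None:
                out.append(Interval(seq_id, run_start, pos))
                run_start = None

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                close_run()
                seq_id = line[1:].split()[0]
                pos = 0
                continue
            for ch in line:
                if ch.islower():
                    if run_start is None:
                        run_start = pos
                else:
                    close_run()
                pos += 1
        close_run()
    return out


# ---------------------------------------------------------------------------
# alignment tables


def parse_alignment_table(
    path, dialect: str, lengths: Optional[dict[str, int]] = None
) -> list[AlignmentBlock]:
    """Parse PAF / show-coords tabular / BLAST outfmt-6 into AlignmentBlocks.

    coords and blast6 are 1-based inclusive on input; PAF is already
    0-based half-open. Minus-strand blocks come out with both coordinate
    pairs on the forward strand and ``strand == "-"``. When ``lengths``
    is given, coordinates are validated against it.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown alignment dialect {dialect!r}")
    parser = {"paf": _parse_paf_line, "coords": _parse_coords_line, "blast6": _parse_blast6_line}[dialect]
    blocks: list[AlignmentBlock] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                block = parser(line.split("\t"))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"bad {dialect} record: {exc}", path, lineno) from exc
            if block is None:
                raise ParseError(f"wrong column count for {dialect}", path, lineno)
            if lengths is not None:
                _check_lengths(block, lengths, path, lineno)
            blocks.append(block)
    return blocks


def _check_lengths(block, lengths, path, lineno):
    for sid, end in ((block.query_id, block.q_end), (block.target_id, block.t_end)):
        if sid in lengths and end > lengths[sid]:
            raise ValidationError(
                f"{path}:{lineno}: coordinate {end} exceeds length "
                f"{lengths[sid]} of {sid}"
            )


def _parse_paf_line(cols) -> Optional[AlignmentBlock]:
    if len(cols) < 12:
        return None
    qname, _qlen, qs, qe, strand, tname, _tlen, ts, te, nmatch, alen = (
        cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4],
        cols[5], int(cols[6]), int(cols[7]), int(cols[8]), int(cols[9]), int(cols[10]),
    )
    strand = "-" if strand == "-" else "+"
    identity = nmatch / alen if alen else 0.0
    nmatch = min(nmatch, qe - qs, te - ts)
    return AlignmentBlock(qname, tname, qs, qe, ts, te, strand,
                          nmatch, min(identity, 1.0), float(nmatch), None, "paf")


def _parse_coords_line(cols) -> Optional[AlignmentBlock]:
    # show-coords -T -H: S1 E1 S2 E2 LEN1 LEN2 %IDY [LENR LENQ] REF QRY
    if len(cols) < 9:
        return None
    s1, e1, s2, e2 = (int(cols[i]) for i in range(4))
    idy = float(cols[6])
    ref, qry = cols[-2], cols[-1]
    t_start, t_end = s1 - 1, e1  # reference coords are always forward
    if s2 <= e2:
        strand, q_start, q_end = "+", s2 - 1, e2
    else:
        strand, q_start, q_end = "-", e2 - 1, s2
    identity = idy / 100.0
    matched = min(round(identity * min(q_end - q_start, t_end - t_start)),
                  q_end - q_start, t_end - t_start)
    return AlignmentBlock(qry, ref, q_start, q_end, t_start, t_end, strand,
                          matched, min(identity, 1.0), float(matched), None, "coords")


def _parse_blast6_line(cols) -> Optional[AlignmentBlock]:
    if len(cols) != 12:
        return None
    qseqid, sseqid, pident, length = cols[0], cols[1], float(cols[2]), int(cols[3])
    qs, qe, ss, se = int(cols[6]), int(cols[7]), int(cols[8]), int(cols[9])
    evalue, bitscore = float(cols[10]), float(cols[11])
    q_start, q_end = qs - 1, qe
    if ss <= se:
        strand, t_start, t_end = "+", ss - 1, se
    else:
        strand, t_start, t_end = "-", se - 1, ss
    identity = pident / 100.0
    matched = min(round(identity * min(q_end - q_start, t_end - t_start)),
                  q_end - q_start, t_end - t_start)
    return AlignmentBlock(qseqid, sseqid, q_start, q_end, t_start, t_end, strand,
                          matched, min(identity, 1.0), bitscore, evalue, "blast6")


def write_alignment_table(
    blocks, path, dialect: str, lengths: Optional[dict[str, int]] = None
) -> None:
    """Write AlignmentBlocks in one of the three dialects.

    PAF needs sequence lengths; unknown lengths fall back to the block's
    end coordinate (a lower bound).
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown alignment dialect {dialect!r}")
    lengths = lengths or {}
    with _open_text(path, "wt") as fh:
        for b in blocks:
            fh.write(_format_block(b, dialect, lengths) + "\n")


def _format_block(b: AlignmentBlock, dialect: str, lengths) -> str:
    if dialect == "paf":
        qlen = lengths.get(b.query_id, b.q_end)
        tlen = lengths.get(b.target_id, b.t_end)
        alen = max(b.q_span, b.t_span)
        return "\t".join(map(str, (
            b.query_id, qlen, b.q_start, b.q_end, b.strand,
            b.target_id, tlen, b.t_start, b.t_end, b.matched_bases, alen, 255,
        )))
    if dialect == "coords":
        s1, e1 = b.t_start + 1, b.t_end
        if b.strand == "+":
            s2, e2 = b.q_start + 1, b.q_end
        else:
            s2, e2 = b.q_end, b.q_start + 1
        return "\t".join(map(str, (
            s1, e1, s2, e2, b.t_span, b.q_span,
            f"{b.identity * 100:.6f}", b.target_id, b.query_id,
        )))
    # blast6
    qs, qe = b.q_start + 1, b.q_end
    if b.strand == "+":
        ss, se = b.t_start + 1, b.t_end
    else:
        ss, se = b.t_end, b.t_start + 1
    length = max(b.q_span, b.t_span)
    mismatch = max(0, length - b.matched_bases)
    ev = b.evalue if b.evalue is not None else 0.0
    return "\t".join(map(str, (
        b.query_id, b.target_id, f"{b.identity * 100:.6f}", length, mismatch, 0,
        qs, qe, ss, se, f"{ev:.3g}", f"{b.score:.6g}",
    )))


# ---------------------------------------------------------------------------
# BED masks


def read_bed(path) -> list[Interval]:
    """Read BED3+ into intervals (strand from column 6 when present)."""
    out: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError("BED needs at least 3 columns", path, lineno)
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "+"
            try:
                out.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad BED interval: {exc}", path, lineno) from exc
    return out


def write_bed(intervals, path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
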