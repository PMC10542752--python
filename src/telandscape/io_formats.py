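"""Readers and writers for the external formats the pipeline touches.

Dialects handled
----------------
* RepeatMasker ``.out`` hit tables (3 header lines, whitespace-separated
  columns, ``C`` for minus strand, consensus coordinates mirrored on minus
  strand, optional trailing ``*`` marking a hit overlapped by a higher
  scoring one).
* RepeatMasker-style ``.align`` files carrying one pairwise copy-versus-
  consensus alignment per hit.  The canonical dialect written here is a
  header line with the same fields as the ``.out`` row followed by
  interleaved wrapped sequence lines (query first, consensus second).
* GFF3 (1-based inclusive), BED (0-based half-open), chromosome-size TSV
  and recombination-map TSV.

Coordinate convention: everything in memory is 0-based half-open; each
reader/writer converts at the boundary.  Consensus coordinates are the one
exception — they live in consensus space and stay 1-based inclusive, as in
the dialect itself.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

logger = logging.getLogger("telandscape")

CLASS_LABELS = ("LTR", "LINE", "SINE", "DNA", "Unclassified")

_ALIGN_WRAP = 60  # residues per wrapped sequence line in .align blocks


def classify_label(class_family: str) -> str:
    """Map a RepeatMasker ``class/family`` string to one of the five labels.

    The text before the first ``/`` or ``?`` decides: ``LTR*`` -> LTR,
    ``LINE*`` -> LINE, ``SINE*`` -> SINE, ``DNA*`` or ``RC*`` -> DNA,
    anything else -> Unclassified.
    """
    head = re.split(r"[/?]", class_family, maxsplit=1)[0].strip()
    if head.startswith("LTR"):
        return "LTR"
    if head.startswith("LINE"):
        return "LINE"
    if head.startswith("SINE"):
        return "SINE"
    if head.startswith("DNA") or head.startswith("RC"):
        return "DNA"
    return "Unclassified"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RepeatHit:
    """One masked fragment from a ``.out`` table.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``cons_start``/``cons_end`` are 1-based inclusive positions in the
    consensus and always satisfy ``cons_start <= cons_end`` (minus-strand
    rows are normalised on parse).  ``run_id`` is RepeatMasker's per-element
    ID (last column) which groups fragments of one interrupted element.
    """

    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    class_family: str
    score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    cons_start: int
    cons_end: int
    cons_left: int
    run_id: int
    overlapped: bool = False  # trailing "*" in the .out row

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty genomic interval {self.start}:{self.end}")
        if not (1 <= self.cons_start <= self.cons_end):
            raise ValueError(
                f"bad consensus interval {self.cons_start}..{self.cons_end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if min(self.pct_div, self.pct_del, self.pct_ins) < 0:
            raise ValueError("negative percentage field")

    @property
    def class_label(self) -> str:
        return classify_label(self.class_family)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def consensus_length(self) -> int:
        """Consensus length implied by the row itself (end + remaining)."""
        return self.cons_end + self.cons_left

    @property
    def key(self) -> tuple:
        """Coordinate key used to join .align blocks to .out rows."""
        return (self.chrom, self.start, self.end, self.family_name)


@dataclass
class AlignmentBlock:
    """One pairwise copy-vs-consensus alignment.

    ``query_seq`` and ``cons_seq`` are equal-length aligned strings with
    ``-`` gaps.  ``cpg_mask`` flags, per column, whether the consensus base
    is the C or the G of a CpG dinucleotide in the ungapped consensus
    (gap columns are always False).
    """

    hit: RepeatHit
    query_seq: str
    cons_seq: str
    cpg_mask: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.query_seq) != len(self.cons_seq):
            raise ValueError("aligned sequence lengths differ")
        if not self.cpg_mask:
            self.cpg_mask = compute_cpg_mask(self.cons_seq)
        if len(self.cpg_mask) != len(self.cons_seq):
            raise ValueError("cpg_mask length differs from alignment length")

    @property
    def hit_key(self) -> tuple:
        return self.hit.key


def compute_cpg_mask(cons_seq: str) -> list:
    """Mark alignment columns in CpG context of the ungapped consensus.

    A column is CpG-context when its consensus base is the C of a CG
    dinucleotide or the G of one, adjacency taken across gap columns.
    """
    n = len(cons_seq)
    mask = [False] * n
    upper = cons_seq.upper()
    nongap = [i for i in range(n) if upper[i] != "-"]
    for a, b in zip(nongap, nongap[1:]):
        if upper[a] == "C" and upper[b] == "G":
            mask[a] = True
            mask[b] = True
    return mask


@dataclass
class ConsensusRecord:
    """A TE consensus library entry.

    ``ltr_role`` links the two halves of an LTR retrotransposon model:
    names ``X_LTR`` / ``X_I`` share the stem ``X`` and get roles
    ``ltr_part`` / ``internal_part``; other names get ``none``.
    """

    name: str
    class_family: str
    sequence: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.sequence:
            if self.length and self.length != len(self.sequence):
                raise ValueError(f"declared length != |sequence| for {self.name}")
            self.length = len(self.sequence)

    @property
    def class_label(self) -> str:
        return classify_label(self.class_family)

    @property
    def ltr_role(self) -> str:
        if self.name.endswith("_LTR"):
            return "ltr_part"
        if self.name.endswith("_I"):
            return "internal_part"
        return "none"

    @property
    def stem(self) -> str:
        if self.ltr_role == "ltr_part":
            return self.name[: -len("_LTR")]
        if self.ltr_role == "internal_part":
            return self.name[: -len("_I")]
        return self.name


@dataclass
class IntervalTrack:
    """A half-open genomic interval with an optional numeric value."""

    chrom: str
    start: int
    end: int
    value: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"inverted/empty interval {self.chrom}:{self.start}-{self.end}"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_OUT_HEADER = (
    "   SW   perc perc perc  query      position in query           matching"
    "       repeat              position in repeat\n"
    "score   div. del. ins.  sequence    begin end          (left)   repeat"
    "         class/family         begin  end    (left)     ID\n"
    "\n"
)


def _paren_int(tok: str) -> int:
    if not (tok.startswith("(") and tok.endswith(")")):
        raise ValueError(f"expected parenthesised field, got {tok!r}")
    return int(tok[1:-1])


def parse_rm_out(stream: TextIO) -> list:
    """Parse a RepeatMasker ``.out`` table into :class:`RepeatHit` rows.

    Minus-strand rows (strand column ``C``) are normalised: strand becomes
    ``-`` and the mirrored consensus coordinates ``(left) end begin`` are
    reordered so ``cons_start <= cons_end``.  Rows carrying a trailing
    ``*`` are retained with ``overlapped=True``.
    """
    hits = []
    for lineno, line in enumerate(stream, start=1):
        if lineno <= 3 or not line.strip():
            continue
        tok = line.split()
        try:
            if len(tok) not in (15, 16):
                raise ValueError(f"expected 15 or 16 fields, got {len(tok)}")
            strand = tok[8]
            if strand == "+":
                cons_start, cons_end, cons_left = (
                    int(tok[11]),
                    int(tok[12]),
                    _paren_int(tok[13]),
                )
            elif strand == "C":
                strand = "-"
                cons_left, cons_end, cons_start = (
                    _paren_int(tok[11]),
                    int(tok[12]),
                    int(tok[13]),
                )
            else:
                raise ValueError(f"unknown strand symbol {tok[8]!r}")
            hit = RepeatHit(
                chrom=tok[4],
                start=int(tok[5]) - 1,
                end=int(tok[6]),
                strand=strand,
                family_name=tok[9],
                class_family=tok[10],
                score=int(tok[0]),
                pct_div=float(tok[1]),
                pct_del=float(tok[2]),
                pct_ins=float(tok[3]),
                cons_start=cons_start,
                cons_end=cons_end,
                cons_left=cons_left,
                run_id=int(tok[14]),
                overlapped=len(tok) == 16 and tok[15] == "*",
            )
        except ValueError as exc:
            raise ValueError(f".out line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def _out_row(hit: RepeatHit, chrom_len: int | None) -> str:
    qleft = (chrom_len - hit.end) if chrom_len is not None else 0
    if hit.strand == "+":
        strand = "+"
        c1, c2, c3 = str(hit.cons_start), str(hit.cons_end), f"({hit.cons_left})"
    else:
        strand = "C"
        c1, c2, c3 = f"({hit.cons_left})", str(hit.cons_end), str(hit.cons_start)
    cols = [
        f"{hit.score:>5d}",
        f"{hit.pct_div:5.1f}",
        f"{hit.pct_del:4.1f}",
        f"{hit.pct_ins:4.1f}",
        f"{hit.chrom:<10s}",
        f"{hit.start + 1:>9d}",
        f"{hit.end:>9d}",
        f"({qleft})",
        strand,
        f"{hit.family_name:<20s}",
        f"{hit.class_family:<18s}",
        f"{c1:>7s}",
        f"{c2:>7s}",
        f"{c3:>9s}",
        f"{hit.run_id:>6d}",
    ]
    if hit.overlapped:
        cols.append("*")
    return " ".join(cols) + "\n"


def write_rm_out(
    hits: Iterable[RepeatHit],
    stream: TextIO,
    chrom_sizes: dict | None = None,
) -> None:
    """Write hits in the ``.out`` dialect (inverse of :func:`parse_rm_out`)."""
    stream.write(_OUT_HEADER)
    for hit in hits:
        size = chrom_sizes.get(hit.chrom) if chrom_sizes else None
        stream.write(_out_row(hit, size))


# ---------------------------------------------------------------------------
# RepeatMasker-style .align
# ---------------------------------------------------------------------------


def write_rm_align(
    blocks: Iterable[AlignmentBlock],
    stream: TextIO,
    chrom_sizes: dict | None = None,
) -> None:
    """Write alignment blocks in the canonical ``.align`` dialect.

    Each block is the hit's ``.out`` row followed by interleaved wrapped
    query/consensus lines and a blank separator line::

        <out row fields ...>
        chr1            101 ACGT... 160
        TE_fam#LTR/ERVK   1 ACGT... 60
    """
    for block in blocks:
        hit = block.hit
        size = chrom_sizes.get(hit.chrom) if chrom_sizes else None
        stream.write(_out_row(hit, size))
        qpos = hit.start + 1
        cpos = hit.cons_start if hit.strand == "+" else hit.cons_end
        qname = hit.chrom[:24]
        cname = hit.family_name[:24]
        for off in range(0, len(block.query_seq), _ALIGN_WRAP):
            qchunk = block.query_seq[off : off + _ALIGN_WRAP]
            cchunk = block.cons_seq[off : off + _ALIGN_WRAP]
            qn = sum(c != "-" for c in qchunk)
            cn = sum(c != "-" for c in cchunk)
            qend = qpos + qn - 1
            cend = cpos + cn - 1 if hit.strand == "+" else cpos - cn + 1
            stream.write(f"{qname:<24s} {qpos:>9d} {qchunk} {qend:>9d}\n")
            stream.write(f"{cname:<24s} {cpos:>9d} {cchunk} {cend:>9d}\n")
            qpos = qend + 1
            cpos = cend + 1 if hit.strand == "+" else cend - 1
        stream.write("\n")


def parse_rm_align(
    stream: TextIO,
    consensus_library: dict | None = None,
    hits: Sequence[RepeatHit] | None = None,
) -> list:
    """Parse the canonical ``.align`` dialect into :class:`AlignmentBlock`.

    When ``consensus_library`` (name -> :class:`ConsensusRecord`) is given,
    blocks referencing a consensus absent from it raise an error.  When
    ``hits`` is given, parsed blocks are joined to those hits by coordinate
    key; blocks without a matching ``.out`` row are kept with the hit
    reconstructed from the block header, and a warning is logged.
    """
    by_key = {h.key: h for h in hits} if hits is not None else None
    blocks = []
    lines = stream.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header_line = lines[i]
        lineno = i + 1
        try:
            hit = parse_rm_out_row(header_line)
        except ValueError as exc:
            raise ValueError(f".align line {lineno}: {exc}") from exc
        i += 1
        qparts, cparts = [], []
        while i < len(lines) and lines[i].strip():
            qtok = lines[i].split()
            ctok = lines[i + 1].split() if i + 1 < len(lines) else []
            if len(qtok) != 4 or len(ctok) != 4:
                raise ValueError(f".align line {i + 1}: malformed sequence line")
            if len(qtok[2]) != len(ctok[2]):
                raise ValueError(
                    f".align line {i + 1}: interleaved line length mismatch"
                )
            qparts.append(qtok[2])
            cparts.append(ctok[2])
            i += 2
        if consensus_library is not None and hit.family_name not in consensus_library:
            raise ValueError(
                f".align line {lineno}: unknown consensus {hit.family_name!r}"
            )
        if by_key is not None:
            matched = by_key.get(hit.key)
            if matched is not None:
                hit = matched
            else:
                logger.warning(
                    "alignment block %s:%d-%d (%s) has no .out row; kept",
                    hit.chrom,
                    hit.start,
                    hit.end,
                    hit.family_name,
                )
        blocks.append(
            AlignmentBlock(hit=hit, query_seq="".join(qparts), cons_seq="".join(cparts))
        )
    return blocks


def parse_rm_out_row(line: str) -> RepeatHit:
    """Parse a single ``.out``-dialect data row (used for .align headers)."""
    import io

    fake = io.StringIO("\n\n\n" + line + "\n")
    hits = parse_rm_out(fake)
    if len(hits) != 1:
        raise ValueError("not a single .out row")
    return hits[0]


# ---------------------------------------------------------------------------
# consensus library FASTA
# ---------------------------------------------------------------------------


def read_library(path) -> dict:
    """Read a TE consensus FASTA with ``name#class/family`` headers."""
    lib = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "#" in rec.id:
            name, class_family = rec.id.split("#", 1)
        else:
            name, class_family = rec.id, "Unknown"
        if name in lib:
            raise ValueError(f"duplicate consensus name {name!r}")
        lib[name] = ConsensusRecord(
            name=name, class_family=class_family, sequence=str(rec.seq).upper()
        )
    return lib


def write_library(library: dict, stream: TextIO) -> None:
    for rec in library.values():
        stream.write(f">{rec.name}#{rec.class_family}\n")
        for off in range(0, len(rec.sequence), 70):
            stream.write(rec.sequence[off : off + 70] + "\n")


# ---------------------------------------------------------------------------
# interval tracks: BED / GFF3 / TSV map
# ---------------------------------------------------------------------------


def read_tracks(path, format: str, chrom_sizes: dict | None = None) -> list:
    """Read genomic intervals from BED, GFF3 or a recombination-map TSV.

    Output is normalised to 0-based half-open coordinates and sorted per
    chromosome.  GFF3 keeps only ``gene``-type features.  The TSV map has
    columns ``chrom  start  end  rate`` (0-based half-open) and stores the
    rate in ``value``.
    """
    tracks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            tok = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "BED":
                    chrom, start, end = tok[0], int(tok[1]), int(tok[2])
                    value = None
                elif format == "GFF3":
                    if tok[2] != "gene":
                        continue
                    chrom, start, end = tok[0], int(tok[3]) - 1, int(tok[4])
                    value = None
                elif format == "TSV-map":
                    if tok[0].lower() in ("chrom", "chr", "chromosome"):
                        continue
                    chrom, start, end = tok[0], int(tok[1]), int(tok[2])
                    value = float(tok[3])
                else:
                    raise ValueError(f"unknown track format {format!r}")
                if start >= end:
                    raise ValueError(f"inverted interval {start}:{end}")
                if chrom_sizes is not None and chrom not in chrom_sizes:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                tracks.append(IntervalTrack(chrom, start, end, value))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    tracks.sort(key=lambda t: (t.chrom, t.start, t.end))
    return tracks


def write_bed(tracks: Iterable[IntervalTrack], stream: TextIO) -> None:
    for t in tracks:
        if t.value is None:
            stream.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
        else:
            stream.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.value:.6g}\n")


def write_recmap(tracks: Iterable[IntervalTrack], stream: TextIO) -> None:
    stream.write("chrom\tstart\tend\trate\n")
    for t in tracks:
        stream.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.value:.6g}\n")


def write_genes_gff3(tracks: Iterable[IntervalTrack], stream: TextIO) -> None:
    """Write gene intervals as minimal GFF3 (1-based inclusive columns)."""
    stream.write("##gff-version 3\n")
    for i, t in enumerate(tracks):
        stream.write(
            f"{t.chrom}\tsim\tgene\t{t.start + 1}\t{t.end}\t.\t+\t.\tID=gene{i:05d}\n"
        )


# ---------------------------------------------------------------------------
# chromosome-size table
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> "dict[str, dict]":
    """Read a chromosome-size TSV: ``chrom  length  [autosome|Z|W]``.

    Returns ``{chrom: {"length": int, "is_autosome": bool}}``; the third
    column defaults to autosome when absent.
    """
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].lower() in ("chrom", "chromosome"):
                continue
            try:
                label = tok[2] if len(tok) > 2 else "autosome"
                sizes[tok[0]] = {
                    "length": int(tok[1]),
                    "is_autosome": label == "autosome",
                }
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: "dict[str, dict]", stream: TextIO) -> None:
    for chrom, meta in sizes.items():
        label = "autosome" if meta["is_autosome"] else "sex"
        stream.write(f"{chrom}\t{meta['length']}\t{label}\n")


# ---------------------------------------------------------------------------
# final annotation GFF3
# ---------------------------------------------------------------------------


def write_annotation_gff3(copies, stream: TextIO) -> None:
    """Write defragmented TE copies as GFF3, one feature per copy.

    Attributes carry family, class, kimura (2 decimals), age_class and
    n_fragments.  Rows are ordered by (chrom, start, family) so output is
    deterministic.
    """
    stream.write("##gff-version 3\n")
    ordered = sorted(copies, key=lambda c: (c.chrom, c.start, c.family_name))
    for i, c in enumerate(ordered):
        attrs = (
            f"ID=te_copy_{i:06d};family={c.family_name};te_class={c.class_label};"
            f"kimura={c.K:.2f};age_class={c.age_class};n_fragments={len(c.fragments)}"
        )
        stream.write(
            f"{c.chrom}\ttelandscape\ttransposable_element\t{c.start + 1}\t{c.end}"
            f"\t{c.score}\t{c.strand}\t.\t{attrs}\n"
        )


def read_annotation_gff3(stream: TextIO) -> list:
    """Read back :func:`write_annotation_gff3` output (round-trip support).

    Returns a list of lightweight records with the same public fields a
    TECopy exposes (chrom, start, end, strand, family_name, class_label,
    K, age_class, n_fragments).
    """
    out = []
    for line in stream:
        if line.startswith("#") or not line.strip():
            continue
        tok = line.rstrip("\n").split("\t")
        attrs = dict(kv.split("=", 1) for kv in tok[8].split(";") if "=" in kv)
        out.append(
            AnnotationFeature(
                chrom=tok[0],
                start=int(tok[3]) - 1,
                end=int(tok[4]),
                strand=tok[6],
                family_name=attrs["family"],
                class_label=attrs["te_class"],
                K=float(attrs["kimura"]),
                age_class=attrs["age_class"],
                n_fragments=int(attrs["n_fragments"]),
                score=int(tok[5]) if tok[5] != "." else 0,
            )
        )
    return out


@dataclass
class AnnotationFeature:
    """A TE copy as read back from an annotation GFF3."""

    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    class_label: str
    K: float
    age_class: str
    n_fragments: int
    score: int = 0
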