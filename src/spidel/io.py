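"""Input/output for Spi- deletion spectrum analysis.

Reads the reference (FASTA), mutant-record tables (TSV) and per-animal assay
count tables, parses the breakpoint notation used to report sequenced Spi-
deletion junctions, and optionally exports normalized deletion calls as VCF.

Coordinate conventions
----------------------
The published notation is 1-based and reports the *last retained* and *first
retained* base around a deletion, e.g. ``182–184 → 187–189`` for a 4-bp
deletion whose breakpoints can be placed in three equivalent ways because the
flanks share a 2-bp microhomology (range span = MH + 1).  Everything internal
to this package is 0-based half-open; the conversion happens only here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceSeq",
    "MutantRecord",
    "RawDescriptor",
    "DescriptorForm",
    "AnimalAssay",
    "ParseError",
    "DescriptorError",
    "SchemaError",
    "read_reference",
    "read_mutant_table",
    "read_assay_table",
    "parse_breakpoint_notation",
    "format_position",
    "write_vcf",
]

_ALPHABET = set("ACGTN")
_DNA = set("ACGT")


class ParseError(ValueError):
    """A file could not be parsed (malformed FASTA/TSV content)."""


class DescriptorError(ValueError):
    """A mutation descriptor string could not be interpreted.

    Carries the offending text in ``args[0]``.
    """


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


class DescriptorForm(str, Enum):
    COORDINATE = "COORDINATE"
    CONTEXT = "CONTEXT"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class ReferenceSeq:
    """A reference sequence against which deletions are placed.

    ``features`` maps names (e.g. the *gam* / *red* selection targets) to
    0-based half-open intervals.
    """

    id: str
    sequence: str
    features: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"reference contains non-nucleotide characters: {sorted(bad)}")
        for name, (start, end) in self.features.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"feature {name!r} interval ({start}, {end}) outside reference")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RawDescriptor:
    """A raw mutation descriptor as printed in a mutant table.

    COORDINATE form carries the 1-based inclusive last-retained and
    first-retained ranges; CONTEXT form carries short before/after sequence
    strings (capital letters mark the deleted or inserted bases); COMPLEX
    preserves anything that is neither, verbatim.
    """

    form: DescriptorForm
    last_retained_range: Optional[tuple[int, int]] = None
    first_retained_range: Optional[tuple[int, int]] = None
    context_before: Optional[str] = None
    context_after: Optional[str] = None
    context_position: Optional[tuple[int, int]] = None  # 1-based inclusive locus of context_before
    inserted_seq: str = ""  # junction insertion sequence, "" if none
    inserted_len: int = 0  # declared junction insertion length
    mh_annotation: Optional[str] = None  # junction homology bases, when annotated
    flanks: Optional[tuple[str, str]] = None  # retained sequence printed around the junction
    note: str = ""
    raw_position: str = ""
    raw_change: str = ""

    def __post_init__(self) -> None:
        if self.form is DescriptorForm.COORDINATE:
            lo, hi = self.last_retained_range, self.first_retained_range
            if lo is None or hi is None:
                raise DescriptorError(f"{self.raw_position!r}: coordinate form requires both ranges")
            if lo[1] < lo[0] or hi[1] < hi[0]:
                raise DescriptorError(f"{self.raw_position!r}: reversed range")
            if (lo[1] - lo[0]) != (hi[1] - hi[0]):
                raise DescriptorError(f"{self.raw_position!r}: unequal range spans")
            if hi[0] <= lo[0]:
                raise DescriptorError(f"{self.raw_position!r}: reversed coordinates")
        if self.inserted_seq and self.inserted_len == 0:
            object.__setattr__(self, "inserted_len", len(self.inserted_seq))

    # ----- derived quantities (1-based printed convention) -----

    @property
    def span(self) -> Optional[int]:
        """Number of alternative breakpoint placements printed (range span)."""
        if self.last_retained_range is None:
            return None
        lo = self.last_retained_range
        return lo[1] - lo[0] + 1

    @property
    def implied_size(self) -> Optional[int]:
        """Deleted-base count implied by the coordinates (gross of insertions)."""
        if self.form is not DescriptorForm.COORDINATE:
            return None
        return self.first_retained_range[0] - self.last_retained_range[0] - 1

    @property
    def implied_mh_len(self) -> Optional[int]:
        span = self.span
        return None if span is None else span - 1

    @property
    def mh_len(self) -> Optional[int]:
        """Best available microhomology length.

        The junction-sequence annotation is authoritative when present;
        otherwise the placement-range span is used.
        """
        if self.mh_annotation is not None:
            return len(self.mh_annotation)
        return self.implied_mh_len


@dataclass(frozen=True)
class MutantRecord:
    """One sequenced Spi- mutant with its group metadata."""

    mutant_id: str
    strain: str
    dose_gy: float
    organ: str
    animal_id: str
    descriptor: RawDescriptor
    printed_size: Optional[int] = None
    class_hint: Optional[str] = None
    flag: str = ""

    @property
    def group(self) -> tuple[str, float, str]:
        return (self.strain, self.dose_gy, self.organ)


@dataclass(frozen=True)
class AnimalAssay:
    """Confirmed-mutant and rescued-phage counts for one animal/organ."""

    strain: str
    dose_gy: float
    organ: str
    animal_id: str
    confirmed_mutants: int
    rescued_pfu: int

    def __post_init__(self) -> None:
        if self.confirmed_mutants < 0:
            raise ValueError("confirmed_mutants must be non-negative")
        if self.rescued_pfu <= 0:
            raise ValueError("rescued_pfu must be positive")
        if self.confirmed_mutants > self.rescued_pfu:
            raise ValueError("confirmed_mutants cannot exceed rescued_pfu")

    @property
    def group(self) -> tuple[str, float, str]:
        return (self.strain, self.dose_gy, self.organ)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> ReferenceSeq:
    """Read the first record of a FASTA file as the reference.

    The sequence is uppercased; ``N`` is allowed but counted in a warning.
    Additional records are ignored with a warning.  Non-nucleotide characters
    raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records found; using the first ({records[0].id})",
            stacklevel=2,
        )
    seq = str(records[0].seq).upper()
    bad = set(seq) - _ALPHABET
    if bad:
        line_no = _find_line(path, bad)
        raise ParseError(
            f"{path}:{line_no}: non-nucleotide characters in sequence: {sorted(bad)}"
        )
    n_count = seq.count("N")
    if n_count:
        warnings.warn(f"{path}: reference contains {n_count} N bases", stacklevel=2)
    return ReferenceSeq(id=records[0].id, sequence=seq)


def _find_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


# ---------------------------------------------------------------------------
# Breakpoint / junction notation
# ---------------------------------------------------------------------------

_DASHES = "‐‑‒–—―-"
_INS_SUFFIX = re.compile(r"\(\s*(\d+)\s*bps?\.?\s*ins\.?\s*\)\s*$", re.IGNORECASE)
_THOUSANDS = re.compile(r",(?=\d{3}(?!\d))")


def _normalize_position(text: str) -> str:
    text = text.strip()
    for d in _DASHES[:-1]:
        text = text.replace(d, "-")
    text = text.replace("→", "->")
    return _THOUSANDS.sub("", text)


def _parse_range(text: str) -> tuple[int, int]:
    parts = text.split("-")
    if len(parts) == 1:
        v = int(parts[0])
        return (v, v)
    if len(parts) == 2:
        return (int(parts[0]), int(parts[1]))
    raise DescriptorError(f"unparseable range: {text!r}")


def _parse_junction_text(change: str) -> tuple[tuple[str, str], Optional[str], str]:
    """Split a printed junction sequence into flanks, homology and insertion.

    Uppercase letters mark the junction microhomology; a segment wrapped in
    ``<...>`` marks bases inserted at the junction.  Returns
    ``((left_flank, right_flank), mh_annotation_or_None, inserted_seq)``.
    """
    inserted = ""
    m = re.search(r"<([ACGTacgt]+)>", change)
    if m:
        inserted = m.group(1).upper()
        change = change[: m.start()] + " " + change[m.end():]
    compact = change.replace(" ", "")
    if not re.fullmatch(r"[ACGTacgt]*", compact):
        raise DescriptorError(f"unparseable junction text: {change!r}")
    upper_runs = re.findall(r"[ACGT]+", compact)
    if len(upper_runs) > 1:
        raise DescriptorError(f"multiple homology segments in junction text: {change!r}")
    mh = upper_runs[0] if upper_runs else None
    if mh:
        left, right = compact.split(mh, 1)
    else:
        parts = change.split()
        left = parts[0] if parts else ""
        right = parts[1] if len(parts) > 1 else ""
    return (left.upper(), right.upper()), mh, inserted


def _diff_contexts(before: str, after: str) -> tuple[int, str, str]:
    """Locate the single contiguous difference between two context strings.

    Returns ``(offset_in_before, deleted, inserted)`` comparing
    case-insensitively.  Raises :class:`DescriptorError` if the strings do not
    differ by exactly one contiguous deletion/insertion.
    """
    b, a = before.upper(), after.upper()
    if b == a:
        raise DescriptorError(f"contexts identical: {before!r} -> {after!r}")
    p = 0
    while p < min(len(b), len(a)) and b[p] == a[p]:
        p += 1
    s = 0
    while (
        s < min(len(b), len(a)) - p
        and b[len(b) - 1 - s] == a[len(a) - 1 - s]
    ):
        s += 1
    deleted = b[p: len(b) - s]
    inserted = a[p: len(a) - s]
    if deleted and inserted:
        raise DescriptorError(
            f"contexts differ by substitution, not a pure indel: {before!r} -> {after!r}"
        )
    return p, deleted, inserted


def parse_breakpoint_notation(
    position_text: str,
    sequence_change_text: str = "",
    printed_size: Optional[int] = None,
) -> RawDescriptor:
    """Parse the printed position/sequence-change notation of one mutant.

    Supported position forms (1-based, thousands separators and any dash
    accepted):

    * ``"A → B"`` — unique breakpoints, last retained A, first retained B;
    * ``"A–B → C–D"`` — equivalent placements, span = microhomology + 1;
    * ``"A → B (k bp ins.)"`` — junction insertion of k bases;
    * ``"A–B (k bps ins.)"`` — no arrow printed; read as ``A → B``;
    * ``"A–B"`` with a sequence change (``AAAAA→AAAA``) — a slippage event
      inside the printed repeat, or, with a junction sequence and a declared
      size, the union of the equivalent deleted segments;
    * ``"A"`` with a context change (``ttAtt→tttt``).

    Anything else (``N.D.``, reversed or multi-segment coordinates) raises
    :class:`DescriptorError`; table readers downgrade such rows to COMPLEX.
    """
    raw_pos, raw_change = position_text, sequence_change_text
    pos = _normalize_position(position_text)
    change = sequence_change_text.strip()

    ins_len = 0
    m = _INS_SUFFIX.search(pos)
    if m:
        ins_len = int(m.group(1))
        pos = pos[: m.start()].strip()

    if "," in pos or pos.upper().startswith("N.D") or pos == "":
        raise DescriptorError(f"unparseable position: {position_text!r}")

    arrow_context = "→" in change or "->" in change
    flanks = mh_annotation = None
    inserted_seq = ""
    if change and not arrow_context:
        flanks, mh_annotation, inserted_seq = _parse_junction_text(change)

    if "->" in pos:
        left, _, right = pos.partition("->")
        lo = _parse_range(left.strip())
        hi = _parse_range(right.strip())
        return RawDescriptor(
            form=DescriptorForm.COORDINATE,
            last_retained_range=lo,
            first_retained_range=hi,
            inserted_seq=inserted_seq,
            inserted_len=ins_len or len(inserted_seq),
            mh_annotation=mh_annotation,
            flanks=flanks,
            raw_position=raw_pos,
            raw_change=raw_change,
        )

    region = _parse_range(pos)
    if ins_len and not arrow_context and region[1] > region[0]:
        # "A–B (k bps ins.)": arrow dropped in print; read as A -> B.
        return RawDescriptor(
            form=DescriptorForm.COORDINATE,
            last_retained_range=(region[0], region[0]),
            first_retained_range=(region[1], region[1]),
            inserted_seq=inserted_seq,
            inserted_len=ins_len or len(inserted_seq),
            mh_annotation=mh_annotation,
            flanks=flanks,
            note="arrow inferred from insertion suffix",
            raw_position=raw_pos,
            raw_change=raw_change,
        )

    if arrow_context:
        before, _, after = change.replace("->", "→").partition("→")
        before, after = before.strip(), after.strip()
        if not re.fullmatch(r"[ACGTacgt]+", before) or not re.fullmatch(r"[ACGTacgt]+", after):
            raise DescriptorError(f"unparseable context change: {sequence_change_text!r}")
        _diff_contexts(before, after)  # validates exactly-one-indel
        return RawDescriptor(
            form=DescriptorForm.CONTEXT,
            context_before=before,
            context_after=after,
            context_position=region,
            raw_position=raw_pos,
            raw_change=raw_change,
        )

    if flanks is not None and printed_size is not None and region[1] > region[0]:
        # Deleted-region form "A–B": the union of the equivalent deleted
        # segments; reconstruct retained ranges from size + homology length.
        region_len = region[1] - region[0] + 1
        mh = len(mh_annotation) if mh_annotation else region_len - printed_size
        if mh < 0 or printed_size + mh != region_len:
            raise DescriptorError(
                f"region {position_text!r} inconsistent with size {printed_size} and homology"
            )
        lo = (region[0] - 1, region[0] - 1 + mh)
        hi = (region[0] + printed_size, region[0] + printed_size + mh)
        return RawDescriptor(
            form=DescriptorForm.COORDINATE,
            last_retained_range=lo,
            first_retained_range=hi,
            inserted_seq=inserted_seq,
            inserted_len=ins_len or len(inserted_seq),
            mh_annotation=mh_annotation,
            flanks=flanks,
            note="retained ranges reconstructed from deleted-region notation",
            raw_position=raw_pos,
            raw_change=raw_change,
        )

    raise DescriptorError(f"unparseable position: {position_text!r}")


def format_position(d: RawDescriptor) -> str:
    """Format a COORDINATE descriptor back to the printed notation."""
    if d.form is not DescriptorForm.COORDINATE:
        raise ValueError("only COORDINATE descriptors have a position notation")

    def fmt_range(r: tuple[int, int]) -> str:
        if r[0] == r[1]:
            return f"{r[0]:,}"
        return f"{r[0]:,}–{r[1]:,}"

    text = f"{fmt_range(d.last_retained_range)} → {fmt_range(d.first_retained_range)}"
    if d.inserted_len:
        unit = "bp" if d.inserted_len == 1 else "bps"
        text += f" ({d.inserted_len} {unit} ins.)"
    return text


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_MUTANT_COLUMNS = [
    "mutant_id",
    "strain",
    "dose_gy",
    "organ",
    "animal_id",
    "position",
    "sequence_change",
]


def read_mutant_table(path: str | Path) -> list[MutantRecord]:
    """Read a TSV of sequenced mutants, one row per mutant.

    Mandatory columns: mutant_id, strain, dose_gy, organ, animal_id,
    position, sequence_change.  Optional: size, class_hint, flag.  Rows whose
    descriptor parses as neither COORDINATE nor CONTEXT are loaded with
    form=COMPLEX, preserving the raw text.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MUTANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")
    records: list[MutantRecord] = []
    for row in df.itertuples(index=False):
        printed_size = None
        size_text = getattr(row, "size", "")
        if size_text not in ("", "N.D."):
            printed_size = int(str(size_text).replace(",", ""))
        try:
            descriptor = parse_breakpoint_notation(
                row.position, row.sequence_change, printed_size=printed_size
            )
        except DescriptorError as exc:
            descriptor = RawDescriptor(
                form=DescriptorForm.COMPLEX,
                note=str(exc),
                raw_position=row.position,
                raw_change=row.sequence_change,
            )
        records.append(
            MutantRecord(
                mutant_id=row.mutant_id,
                strain=row.strain,
                dose_gy=float(row.dose_gy),
                organ=row.organ,
                animal_id=row.animal_id,
                descriptor=descriptor,
                printed_size=printed_size,
                class_hint=getattr(row, "class_hint", "") or None,
                flag=getattr(row, "flag", ""),
            )
        )
    return records


def write_mutant_table(records: Iterable[MutantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = r.descriptor
        rows.append(
            {
                "mutant_id": r.mutant_id,
                "strain": r.strain,
                "dose_gy": r.dose_gy,
                "organ": r.organ,
                "animal_id": r.animal_id,
                "size": "" if r.printed_size is None else r.printed_size,
                "position": d.raw_position,
                "sequence_change": d.raw_change,
                "class_hint": r.class_hint or "",
                "flag": r.flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_ASSAY_COLUMNS = ["strain", "dose_gy", "organ", "animal_id", "confirmed_mutants", "rescued_pfu"]


def read_assay_table(path: str | Path) -> list[AnimalAssay]:
    """Read a TSV of per-animal assay counts (one MF observation per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")
    return [
        AnimalAssay(
            strain=row.strain,
            dose_gy=float(row.dose_gy),
            organ=row.organ,
            animal_id=row.animal_id,
            confirmed_mutants=int(row.confirmed_mutants),
            rescued_pfu=int(row.rescued_pfu),
        )
        for row in df.itertuples(index=False)
    ]


def write_assay_table(assays: Iterable[AnimalAssay], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "strain": a.strain,
                "dose_gy": a.dose_gy,
                "organ": a.organ,
                "animal_id": a.animal_id,
                "confirmed_mutants": a.confirmed_mutants,
                "rescued_pfu": a.rescued_pfu,
            }
            for a in assays
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(calls: Sequence, ref: ReferenceSeq, path: str | Path) -> None:
    """Write normalized deletion calls as VCF 4.x (anchor-base convention).

    Calls must be left-aligned (:func:`spidel.caller.call_deletion` output).
    Microhomology and junction-insertion information goes to INFO so records
    round-trip through :func:`spidel.caller.call_from_mutant_sequence`.
    """
    import pysam

    for call in calls:
        if call.canonical_start + call.size > len(ref):
            raise ValueError(f"call outside reference: {call}")

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.id},length={len(ref)}>")
    header.add_line(
        '##INFO=<ID=MHLEN,Number=1,Type=Integer,Description="Junction microhomology length">'
    )
    header.add_line(
        '##INFO=<ID=MHSEQ,Number=1,Type=String,Description="Junction microhomology sequence">'
    )
    header.add_line(
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Sequence inserted at the junction">'
    )
    header.add_line(
        '##INFO=<ID=PLACEMENTS,Number=1,Type=Integer,Description="Equivalent breakpoint placements">'
    )

    seq = ref.sequence
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            start0 = call.canonical_start
            end0 = start0 + call.size
            if start0 > 0:
                pos0 = start0 - 1  # anchor base before the deletion
                ref_allele = seq[pos0:end0]
                alt_allele = seq[pos0] + call.inserted_seq
            else:
                pos0 = 0  # deletion at position 1: anchor on the following base
                ref_allele = seq[:end0 + 1]
                alt_allele = call.inserted_seq + seq[end0]
            rec = vcf.new_record(
                contig=ref.id,
                start=pos0,
                alleles=(ref_allele, alt_allele),
            )
            rec.info["MHLEN"] = call.mh_len
            if call.mh_seq:
                rec.info["MHSEQ"] = call.mh_seq
            if call.inserted_seq:
                rec.info["INSSEQ"] = call.inserted_seq
            rec.info["PLACEMENTS"] = call.placement_count
            vcf.write(rec)
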