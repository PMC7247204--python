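"""Mutation spectrum classification for Spi- deletion mutants.

Every sequenced mutant is assigned to exactly one of seven classes:

* ``DEL1_RUN``    — 1-bp deletion inside a mononucleotide run (slippage
  signature);
* ``DEL1_OTHER``  — 1-bp deletion of a non-repeated base;
* ``DELGT2_MH``   — deletion of >= 2 bp with junction microhomology;
* ``DELGT2_NOMH`` — deletion of >= 2 bp with blunt (no-homology) junction;
* ``DELGT2_INS``  — deletion of >= 2 bp carrying extra bases at the junction
  (classified apart from the homology split);
* ``INSERTION``   — pure insertion, no deleted bases;
* ``COMPLEX``     — multi-segment or otherwise uncallable rearrangement.

The ">= 2 bp" boundary follows the published table contents (2- and 3-bp
deletions are grouped with the larger NHEJ-type deletions, not with the
slippage classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from .caller import DeletionCall
from .io import DescriptorForm, MutantRecord, RawDescriptor

__all__ = [
    "SpectrumClass",
    "SpectrumSummary",
    "JunctionStatistics",
    "classify",
    "classify_record",
    "notation_call",
    "summarize_group",
    "junction_statistics",
    "UndefinedStatisticError",
    "InvalidCallError",
]


class UndefinedStatisticError(ValueError):
    """A junction statistic has an empty denominator (no qualifying records)."""


class InvalidCallError(ValueError):
    """A call describes no mutation (size 0 with no insertion)."""


class SpectrumClass(str, Enum):
    """Spectrum classes, in report row order."""

    DEL1_RUN = "DEL1_RUN"
    DEL1_OTHER = "DEL1_OTHER"
    DELGT2_MH = "DELGT2_MH"
    DELGT2_NOMH = "DELGT2_NOMH"
    DELGT2_INS = "DELGT2_INS"
    INSERTION = "INSERTION"
    COMPLEX = "COMPLEX"


CLASS_ORDER = list(SpectrumClass)

#: Deletions strictly larger than this (bp) count as "large" in junction stats.
DEFAULT_LARGE_THRESHOLD = 1000


@dataclass(frozen=True)
class ClassifiedRecord:
    """A mutant record together with its call-level quantities."""

    record: Optional[MutantRecord]
    spectrum_class: SpectrumClass
    size: int = 0
    mh_len: int = 0
    inserted_len: int = 0

    @property
    def group(self):
        return None if self.record is None else self.record.group


def classify(call: Union[DeletionCall, MutantRecord, None], *, is_complex: bool = False) -> SpectrumClass:
    """Assign one spectrum class to a call (or a COMPLEX record)."""
    if is_complex or call is None:
        return SpectrumClass.COMPLEX
    if isinstance(call, MutantRecord):
        return classify_record(call).spectrum_class
    if call.size == 0 and not call.inserted_seq:
        raise InvalidCallError("size 0 with empty insertion")
    if call.size == 0:
        return SpectrumClass.INSERTION
    if call.size == 1 and not call.inserted_seq:
        return SpectrumClass.DEL1_RUN if call.in_run else SpectrumClass.DEL1_OTHER
    if call.size >= 2 and call.inserted_seq:
        return SpectrumClass.DELGT2_INS
    if call.size >= 2 and call.mh_len >= 1:
        return SpectrumClass.DELGT2_MH
    if call.size >= 2:
        return SpectrumClass.DELGT2_NOMH
    return SpectrumClass.COMPLEX  # e.g. 1-bp deletion plus insertion


@dataclass(frozen=True)
class NotationCall:
    """Call-level quantities derived from printed notation alone.

    Stands in for a reference-based :class:`~spidel.caller.DeletionCall`
    when only the published coordinates/junction annotations are available
    (the transgene sequence itself is not bundled).
    """

    size: int
    mh_len: int
    inserted_len: int
    in_run: bool

    @property
    def inserted_seq(self) -> str:  # duck-types DeletionCall for classify()
        return "N" * self.inserted_len


def notation_call(d: RawDescriptor, printed_size: Optional[int] = None) -> Optional[NotationCall]:
    """Derive size / microhomology / insertion / run-context from a descriptor.

    Returns ``None`` for COMPLEX descriptors.  The printed size, when given,
    is authoritative for reporting (a handful of published rows are
    arithmetically inconsistent with their own coordinates; they are carried
    flagged rather than silently corrected).
    """
    if d.form is DescriptorForm.COMPLEX:
        return None
    if d.form is DescriptorForm.COORDINATE:
        size = printed_size if printed_size is not None else d.implied_size
        mh = d.mh_len or 0
        if d.inserted_len:
            mh = len(d.mh_annotation) if d.mh_annotation else 0
        in_run = size == 1 and mh >= 1
        return NotationCall(size=size, mh_len=mh, inserted_len=d.inserted_len, in_run=in_run)
    # CONTEXT form: a short before/after pair around a 1-bp event.
    from .io import _diff_contexts

    p, deleted, inserted = _diff_contexts(d.context_before, d.context_after)
    before = d.context_before.upper()
    if inserted and not deleted:
        return NotationCall(size=0, mh_len=0, inserted_len=len(inserted), in_run=False)
    base = deleted[0]
    neighbours = []
    if p > 0:
        neighbours.append(before[p - 1])
    if p + len(deleted) < len(before):
        neighbours.append(before[p + len(deleted)])
    in_run = base in neighbours
    return NotationCall(size=len(deleted), mh_len=int(in_run), inserted_len=0, in_run=in_run)


def classify_record(
    record: MutantRecord, call: Optional[DeletionCall] = None
) -> ClassifiedRecord:
    """Classify one mutant record, from a reference-based call if supplied,
    otherwise from its printed notation."""
    if call is None:
        ncall = notation_call(record.descriptor, record.printed_size)
        if ncall is None:
            return ClassifiedRecord(record, SpectrumClass.COMPLEX)
        cls = classify(ncall)  # type: ignore[arg-type]
        return ClassifiedRecord(
            record, cls, size=ncall.size, mh_len=ncall.mh_len, inserted_len=ncall.inserted_len
        )
    cls = classify(call)
    return ClassifiedRecord(
        record, cls, size=call.size, mh_len=call.mh_len, inserted_len=len(call.inserted_seq)
    )


@dataclass(frozen=True)
class SpectrumSummary:
    """Per-group class counts and ratios (one report column)."""

    group: tuple[str, float, str]
    counts: dict[SpectrumClass, int]
    total: int

    @property
    def ratios(self) -> dict[SpectrumClass, float]:
        return {c: self.counts[c] / self.total for c in CLASS_ORDER}


def summarize_group(records: Sequence[ClassifiedRecord]) -> SpectrumSummary:
    """Aggregate classified records of one group into counts and ratios."""
    if not records:
        raise UndefinedStatisticError("cannot summarize an empty group")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError(f"records span multiple groups: {groups}")
    counts = {c: 0 for c in CLASS_ORDER}
    for r in records:
        counts[r.spectrum_class] += 1
    return SpectrumSummary(group=groups.pop(), counts=counts, total=len(records))


@dataclass(frozen=True)
class JunctionStatistics:
    """Junction-level statistics over the >= 2-bp deletions of one group."""

    mh_count: int
    gt2bp_total: int  # DELGT2_MH + DELGT2_NOMH + DELGT2_INS
    mean_mh_len: float
    n_mh_used: int  # records entering the mean (after optional exclusion)
    large_count: int
    insertion_count: int  # DELGT2_INS + INSERTION records
    total_records: int

    @property
    def mh_fraction(self) -> float:
        return self.mh_count / self.gt2bp_total

    @property
    def large_fraction(self) -> float:
        return self.large_count / self.gt2bp_total

    @property
    def insertion_fraction(self) -> float:
        return self.insertion_count / self.total_records


def junction_statistics(
    records: Sequence[ClassifiedRecord],
    exclude_mh_above: Optional[int] = None,
    large_threshold: int = DEFAULT_LARGE_THRESHOLD,
) -> JunctionStatistics:
    """Compute microhomology / size / insertion statistics for one group.

    * ``mh_fraction``: share of >= 2-bp deletions with junction homology,
      over *all* >= 2-bp deletions (including junction-insertion ones);
    * ``mean_mh_len``: mean homology length over the homology-bearing
      deletions, optionally excluding records with ``mh_len >
      exclude_mh_above`` (reported alongside as an explicit exception);
    * ``large_fraction``: share of >= 2-bp deletions larger than
      ``large_threshold`` bp (default 1 kb);
    * ``insertion_fraction``: share of *all* records carrying inserted bases
      (junction insertions plus pure insertions).

    Raises :class:`UndefinedStatisticError` when the group has no >= 2-bp
    deletions rather than returning a silent zero.
    """
    gt2 = [
        r
        for r in records
        if r.spectrum_class
        in (SpectrumClass.DELGT2_MH, SpectrumClass.DELGT2_NOMH, SpectrumClass.DELGT2_INS)
    ]
    if not gt2:
        raise UndefinedStatisticError("no >= 2-bp deletions in this group")
    mh_records = [r for r in gt2 if r.spectrum_class is SpectrumClass.DELGT2_MH]
    used = mh_records
    if exclude_mh_above is not None:
        used = [r for r in mh_records if r.mh_len <= exclude_mh_above]
    mean_mh = math.nan if not used else sum(r.mh_len for r in used) / len(used)
    large = sum(1 for r in gt2 if r.size > large_threshold)
    ins = sum(
        1
        for r in records
        if r.spectrum_class in (SpectrumClass.DELGT2_INS, SpectrumClass.INSERTION)
    )
    return JunctionStatistics(
        mh_count=len(mh_records),
        gt2bp_total=len(gt2),
        mean_mh_len=mean_mh,
        n_mh_used=len(used),
        large_count=large,
        insertion_count=ins,
        total_records=len(records),
    )


def group_records(
    classified: Iterable[ClassifiedRecord],
) -> dict[tuple[str, float, str], list[ClassifiedRecord]]:
    """Bucket classified records by (strain, dose_gy, organ)."""
    out: dict[tuple[str, float, str], list[ClassifiedRecord]] = {}
    for r in classified:
        out.setdefault(r.group, []).append(r)
    return out
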