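"""Deletion junction calling: canonical placement and microhomology.

Microhomology is defined operationally by *placement equivalence*: the
number of distinct deletions of the reference that yield the identical
mutant sequence.  A deletion flanked by a k-bp microhomology can be placed
in k+1 equivalent ways, which is exactly what the published range notation
("182–184 → 187–189", span 3 = 2-bp homology + 1) encodes.  The canonical
placement is the left-most one, matching VCF left-alignment.

For deletions carrying a junction insertion, homology is computed between
the retained flanks, ignoring the inserted bases; such events form their
own spectrum class regardless of flank homology.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import DescriptorForm, RawDescriptor, ReferenceSeq

__all__ = [
    "DeletionCall",
    "call_deletion",
    "call_insertion",
    "call_from_descriptor",
    "call_from_mutant_sequence",
    "NonIndelError",
    "ResolutionError",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NonIndelError(ValueError):
    """Two sequences do not differ by one contiguous deletion/insertion."""


class ResolutionError(ValueError):
    """A context descriptor could not be located uniquely in the reference."""


@dataclass(frozen=True)
class DeletionCall:
    """A normalized (left-aligned) deletion, with optional junction insertion.

    ``size`` counts deleted reference bases (0 for a pure insertion);
    junction insertions are reported separately in ``inserted_seq``, never
    netted into the size.  ``placement_count`` is the number of equivalent
    breakpoint placements and always equals ``mh_len + 1``.  ``in_run`` is
    meaningful for 1-bp deletions: the deleted base sits in a mononucleotide
    run of length >= 2 (the slippage signature).
    """

    ref_id: str
    canonical_start: int  # 0-based index of the first deleted base
    size: int
    placement_count: int
    mh_len: int
    mh_seq: str
    inserted_seq: str = ""
    in_run: bool = False

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if self.size == 0 and not self.inserted_seq:
            raise ValueError("a call must delete or insert at least one base")
        if self.mh_len != self.placement_count - 1:
            raise ValueError("mh_len must equal placement_count - 1")
        if len(self.mh_seq) != self.mh_len:
            raise ValueError("mh_seq length must equal mh_len")

    @property
    def end(self) -> int:
        """0-based exclusive end of the deleted segment (canonical placement)."""
        return self.canonical_start + self.size

    def apply(self, ref: ReferenceSeq) -> str:
        """Reconstruct the mutant sequence this call describes."""
        s = ref.sequence
        return s[: self.canonical_start] + self.inserted_seq + s[self.end:]


def call_deletion(
    ref: ReferenceSeq, start: int, end: int, inserted_seq: str = ""
) -> DeletionCall:
    """Call the deletion of ``ref[start:end)`` with an optional junction insertion.

    Finds the left-most equivalent placement, counts all equivalent
    placements, and extracts the junction microhomology.  ``start``/``end``
    are 0-based half-open; ``end == start`` is allowed only with a non-empty
    insertion (pure insertion).
    """
    seq = ref.sequence
    if not (0 <= start <= end <= len(seq)):
        raise IndexError(f"deletion [{start}, {end}) outside reference of length {len(seq)}")
    if start == end:
        if not inserted_seq:
            raise ValueError("empty deletion with no insertion")
        return call_insertion(ref, start, inserted_seq)
    if set(inserted_seq) - set("ACGT"):
        raise ValueError(f"inserted sequence contains non-DNA characters: {inserted_seq!r}")

    # Shifting the deleted window left by s preserves the mutant sequence iff
    # ref[start-i] == ref[end-i] for i = 1..s; symmetrically to the right.
    left = 0
    while start - left - 1 >= 0 and seq[start - left - 1] == seq[end - left - 1]:
        left += 1
    right = 0
    while end + right < len(seq) and seq[start + right] == seq[end + right]:
        right += 1

    canonical_start = start - left
    size = end - start
    placement_count = left + right + 1
    mh_len = placement_count - 1
    end0 = canonical_start + size
    mh_seq = seq[end0: end0 + mh_len]
    in_run = size == 1 and mh_len >= 1  # run length = placements for 1-bp deletions
    return DeletionCall(
        ref_id=ref.id,
        canonical_start=canonical_start,
        size=size,
        placement_count=placement_count,
        mh_len=mh_len,
        mh_seq=mh_seq,
        inserted_seq=inserted_seq,
        in_run=in_run,
    )


def call_insertion(ref: ReferenceSeq, position: int, inserted_seq: str) -> DeletionCall:
    """Call a pure insertion before 0-based ``position``, left-aligned.

    ``placement_count`` counts the equivalent insertion points (an extra copy
    of a run base can be credited to any position along the run).
    """
    seq = ref.sequence
    if not (0 <= position <= len(seq)):
        raise IndexError(f"insertion point {position} outside reference")
    if not inserted_seq or set(inserted_seq) - set("ACGT"):
        raise ValueError(f"invalid inserted sequence: {inserted_seq!r}")
    ins = inserted_seq
    pos = position
    while pos > 0 and seq[pos - 1] == ins[-1]:
        ins = seq[pos - 1] + ins[:-1]
        pos -= 1
    # count equivalent placements to the right of the canonical one
    count = 1
    probe_ins, probe_pos = ins, pos
    while probe_pos < len(seq) and seq[probe_pos] == probe_ins[0]:
        probe_ins = probe_ins[1:] + seq[probe_pos]
        probe_pos += 1
        count += 1
    mh_len = count - 1
    mh_seq = seq[pos: pos + mh_len]
    return DeletionCall(
        ref_id=ref.id,
        canonical_start=pos,
        size=0,
        placement_count=count,
        mh_len=mh_len,
        mh_seq=mh_seq,
        inserted_seq=ins,
        in_run=False,
    )


def call_from_descriptor(ref: ReferenceSeq, d: RawDescriptor) -> DeletionCall:
    """Resolve a parsed descriptor against a reference and call it.

    COORDINATE descriptors use the left-most printed placement (1-based last
    retained L, first retained F -> 0-based [L, F-1)).  CONTEXT descriptors
    locate ``context_before`` in the reference; an ambiguous or absent match
    raises :class:`ResolutionError` with the match count.
    """
    if d.form is DescriptorForm.COORDINATE:
        lo = d.last_retained_range[0]
        hi = d.first_retained_range[0]
        return call_deletion(ref, lo, hi - 1, d.inserted_seq)
    if d.form is DescriptorForm.CONTEXT:
        before = d.context_before.upper()
        after = d.context_after.upper()
        n = ref.sequence.count(before)
        if n != 1:
            raise ResolutionError(
                f"context {before!r} found {n} times in reference {ref.id!r}"
            )
        offset = ref.sequence.index(before)
        from .io import _diff_contexts  # shared exact-one-indel diff

        p, deleted, inserted = _diff_contexts(before, after)
        if deleted:
            return call_deletion(ref, offset + p, offset + p + len(deleted))
        return call_insertion(ref, offset + p, inserted)
    raise ValueError("COMPLEX descriptors cannot be called against a reference")


def call_from_mutant_sequence(ref: ReferenceSeq, mutant: str) -> DeletionCall:
    """Recover the deletion (with optional junction insertion) behind a mutant.

    The mutant must differ from the reference by exactly one contiguous
    deletion and/or insertion; anything else raises :class:`NonIndelError`.
    The recovered call, applied to the reference, reproduces the mutant
    exactly.
    """
    seq = ref.sequence
    mutant = mutant.upper()
    if mutant == seq:
        raise NonIndelError("sequences are identical")
    p = 0
    limit = min(len(seq), len(mutant))
    while p < limit and seq[p] == mutant[p]:
        p += 1
    s = 0
    while s < limit - p and seq[len(seq) - 1 - s] == mutant[len(mutant) - 1 - s]:
        s += 1
    deleted_len = len(seq) - p - s
    inserted = mutant[p: len(mutant) - s]
    if deleted_len == 0 and not inserted:
        raise NonIndelError("sequences differ by a non-indel pattern")
    if deleted_len == 0:
        call = call_insertion(ref, p, inserted)
    else:
        call = call_deletion(ref, p, p + deleted_len, inserted)
    if call.apply(ref) != mutant:
        raise NonIndelError("sequences differ by a non-indel pattern")
    return call


def reverse_complement_call(ref: ReferenceSeq, call: DeletionCall) -> DeletionCall:
    """Re-call the same event on the reverse-complemented reference.

    Used to check strand symmetry of the microhomology definition.
    """
    rc = ReferenceSeq(id=ref.id + "_rc", sequence=ref.sequence.translate(_COMPLEMENT)[::-1])
    start = len(ref) - call.end
    end = len(ref) - call.canonical_start
    ins_rc = call.inserted_seq.translate(_COMPLEMENT)[::-1]
    if call.size == 0:
        return call_insertion(rc, start, ins_rc)
    return call_deletion(rc, start, end, ins_rc)
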