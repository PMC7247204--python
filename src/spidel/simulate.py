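"""Synthetic data generator for the Spi- deletion analysis.

Emulates the statistical structure the analysis assumes, providing ground
truth for every other module:

* a reference sequence with planted homopolymer runs (slippage substrate);
* spontaneous 1-bp slippage deletions concentrated in runs;
* radiation-type double-strand-break (DSB) deletions with a log-uniform size
  distribution, junctions biased toward flanking microhomology, and
  occasional junction insertions;
* per-animal Poisson mutant counts at group-level mean mutant frequencies,
  with rescued-phage totals drawn per animal.

The generative model is deliberately minimal — a breakpoint pair plus
optional homology weighting and insertion — because it exists to test the
analysis, not to model radiobiology.  Mutant counts are Poisson (rare-event
limit of the plaque assay).  All randomness derives from one integer seed
through a spawned-substream scheme, so every fixture is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .caller import DeletionCall, call_deletion, call_insertion
from .io import (
    AnimalAssay,
    MutantRecord,
    ReferenceSeq,
    parse_breakpoint_notation,
    write_assay_table,
    write_mutant_table,
)
from .spectrum import SpectrumClass

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "GroundTruthEntry",
    "SimulatedExperiment",
    "simulate_reference",
    "simulate_mutant",
    "simulate_experiment",
]

_BASES = np.array(list("ACGT"))

#: Event-type probabilities mirroring the irradiated wild-type spectrum
#: (slippage-dominated 1-bp deletions plus a large DSB-deletion component).
IRRADIATED_SPECTRUM = {
    "slippage_1bp": 0.42,
    "other_1bp": 0.08,
    "dsb_deletion": 0.49,
    "pure_insertion": 0.0,
    "complex": 0.01,
}

#: Event-type probabilities mirroring the unirradiated spectrum
#: (almost entirely replication slippage in runs).
SPONTANEOUS_SPECTRUM = {
    "slippage_1bp": 0.72,
    "other_1bp": 0.08,
    "dsb_deletion": 0.12,
    "pure_insertion": 0.08,
    "complex": 0.0,
}

_EVENT_KEYS = ["slippage_1bp", "other_1bp", "dsb_deletion", "pure_insertion", "complex"]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: strain x dose x organ."""

    strain: str
    dose_gy: float
    organ: str
    n_animals: int
    pfu_per_animal_range: tuple[int, int] = (300_000, 500_000)
    true_total_mf: float = 5e-6
    spectrum_params: dict[str, float] = field(
        default_factory=lambda: dict(IRRADIATED_SPECTRUM)
    )

    def __post_init__(self) -> None:
        total = sum(self.spectrum_params.get(k, 0.0) for k in _EVENT_KEYS)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"spectrum probabilities must sum to 1, got {total}")
        if any(v < 0 for v in self.spectrum_params.values()):
            raise ValueError("spectrum probabilities must be non-negative")


def _default_groups() -> tuple[GroupSpec, ...]:
    # Mirrors the brain arm of the study: wild-type and scid mice, sham or a
    # single 10 Gy dose, 10/8/6/7 animals, group mean MFs on the 1e-6 scale.
    return (
        GroupSpec("WT", 0.0, "brain", 10, true_total_mf=1.03e-6,
                  spectrum_params=dict(SPONTANEOUS_SPECTRUM)),
        GroupSpec("WT", 10.0, "brain", 8, true_total_mf=5.00e-6,
                  spectrum_params=dict(IRRADIATED_SPECTRUM)),
        GroupSpec("scid", 0.0, "brain", 6, true_total_mf=0.85e-6,
                  spectrum_params=dict(SPONTANEOUS_SPECTRUM)),
        GroupSpec("scid", 10.0, "brain", 7, true_total_mf=2.89e-6,
                  spectrum_params=dict(IRRADIATED_SPECTRUM)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults reproduce the study's design scale."""

    seed: int = 0
    ref_length: int = 6_000
    run_enrichment: float = 2.0  # expected planted 4-6-mer runs per kb
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    min_size: int = 2  # smallest DSB-deletion size
    max_size: int = 10_000  # clipped to the reference
    mh_bias: float = 2.0  # >= 0; weight (placements)^bias on breakpoint pairs
    junction_insertion_prob: float = 0.06
    insertion_geom_p: float = 0.5  # insertion length ~ 1 + Geometric, truncated
    insertion_max_len: int = 22  # largest junction insertion observed in vivo

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.mh_bias < 0:
            raise ValueError("mh_bias must be non-negative")
        if self.ref_length < 100:
            raise ValueError("ref_length must be >= 100")


@dataclass(frozen=True)
class GroundTruthEntry:
    """The generative truth for one simulated mutant."""

    mutant_id: str
    strain: str
    dose_gy: float
    organ: str
    animal_id: str
    true_class: SpectrumClass
    canonical_start: Optional[int]
    size: Optional[int]
    mh_len: Optional[int]
    inserted_seq: str
    mutant_sequence: Optional[str]


@dataclass
class SimulatedExperiment:
    reference: ReferenceSeq
    records: list[MutantRecord]
    assays: list[AnimalAssay]
    truth: list[GroundTruthEntry]
    config: SimulationConfig

    def true_class_ratios(self, group: tuple[str, float, str]) -> dict[SpectrumClass, float]:
        entries = [t for t in self.truth if (t.strain, t.dose_gy, t.organ) == group]
        out = {c: 0 for c in SpectrumClass}
        for t in entries:
            out[t.true_class] += 1
        n = max(len(entries), 1)
        return {c: v / n for c, v in out.items()}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize mutant/assay/ground-truth tables and the reference."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "reference.fasta",
            "mutants": out / "mutants.tsv",
            "assays": out / "assays.tsv",
            "truth": out / "ground_truth.tsv",
        }
        with open(paths["reference"], "w") as fh:
            fh.write(f">{self.reference.id}\n")
            seq = self.reference.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
        write_mutant_table(self.records, paths["mutants"])
        write_assay_table(self.assays, paths["assays"])
        pd.DataFrame(
            [
                {
                    "mutant_id": t.mutant_id,
                    "strain": t.strain,
                    "dose_gy": t.dose_gy,
                    "organ": t.organ,
                    "animal_id": t.animal_id,
                    "true_class": t.true_class.value,
                    "canonical_start": "" if t.canonical_start is None else t.canonical_start,
                    "size": "" if t.size is None else t.size,
                    "mh_len": "" if t.mh_len is None else t.mh_len,
                    "inserted_seq": t.inserted_seq,
                }
                for t in self.truth
            ]
        ).to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> ReferenceSeq:
    """Uniform random reference with planted homopolymer runs.

    The planted run intervals (length 4-6) are recorded as features named
    ``run_<i>``; their expected number is ``run_enrichment`` per kb.
    Deterministic given the config seed.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n = cfg.ref_length
    seq = rng.choice(_BASES, size=n)
    n_runs = rng.poisson(cfg.run_enrichment * n / 1000.0)
    features: dict[str, tuple[int, int]] = {}
    for i in range(n_runs):
        length = int(rng.integers(4, 7))
        start = int(rng.integers(0, n - length))
        base = str(rng.choice(_BASES))
        seq[start: start + length] = base
        features[f"run_{i}"] = (start, start + length)
    return ReferenceSeq(id="synthetic_ref", sequence="".join(seq), features=features)


# ---------------------------------------------------------------------------
# Per-mutant events
# ---------------------------------------------------------------------------

class _RefIndex:
    """Precomputed lookups for event placement on one reference."""

    def __init__(self, ref: ReferenceSeq):
        self.ref = ref
        seq = ref.sequence
        self.codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        run_positions: list[int] = []
        lone_positions: list[int] = []
        i, n = 0, len(seq)
        while i < n:
            j = i
            while j < n and seq[j] == seq[i]:
                j += 1
            if j - i >= 2:
                run_positions.extend(range(i, j))
            elif 0 < i < n - 1:
                lone_positions.append(i)
            i = j
        self.run_positions = np.array(run_positions, dtype=np.int64)
        self.lone_positions = np.array(lone_positions, dtype=np.int64)


def _forward_runs(flags: np.ndarray) -> np.ndarray:
    """Length of the True-run starting at each index (0 where False)."""
    n = flags.size
    false_idx = np.flatnonzero(~flags)
    nxt = np.full(n, n, dtype=np.int64)
    if false_idx.size:
        pos = np.searchsorted(false_idx, np.arange(n), side="left")
        has = pos < false_idx.size
        nxt[has] = false_idx[pos[has]]
    return nxt - np.arange(n)


def _placement_counts(codes: np.ndarray, size: int) -> np.ndarray:
    """Equivalent-placement count for a size-bp deletion at every start.

    ``eq[j] = (ref[j] == ref[j+size])`` encodes both shift directions: the
    right extension at start s is the True-run of ``eq`` starting at s, the
    left extension the True-run ending at s-1.
    """
    eq = codes[:-size] == codes[size:]
    fwd = _forward_runs(eq)
    bwd = _forward_runs(eq[::-1])[::-1]
    counts = np.ones(eq.size, dtype=np.int64) + fwd
    counts[1:] += bwd[:-1]
    return counts  # index s in [0, L-size)


def _draw_insertion(
    rng: np.random.Generator, cfg: SimulationConfig, first_del: str, last_del: str
) -> str:
    """Random junction insertion that cannot be absorbed into the flanks.

    Requires ins[0] != first deleted base and ins[-1] != last deleted base so
    the (deletion, insertion) decomposition of the mutant is unique.
    """
    length = min(int(rng.geometric(cfg.insertion_geom_p)), cfg.insertion_max_len)
    ins = rng.choice(_BASES, size=length)
    choices_first = [b for b in "ACGT" if b != first_del]
    choices_last = [b for b in "ACGT" if b != last_del]
    if ins[0] == first_del:
        ins[0] = rng.choice(np.array(choices_first))
    if ins[-1] == last_del:
        ins[-1] = rng.choice(np.array(choices_last))
    if length == 1 and (ins[0] == first_del or ins[0] == last_del):
        both = [b for b in "ACGT" if b not in (first_del, last_del)]
        ins[0] = rng.choice(np.array(both))
    return "".join(ins)


def simulate_mutant(
    ref: ReferenceSeq,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    spectrum_params: Optional[dict[str, float]] = None,
    index: Optional[_RefIndex] = None,
) -> tuple[Optional[str], SpectrumClass, Optional[DeletionCall]]:
    """Draw one mutation event.

    Returns ``(mutant_sequence, true_class, call)``; COMPLEX events carry no
    sequence-level representation (``(None, COMPLEX, None)``).  The call's
    microhomology is the realized one, computed by the same placement-
    equivalence definition the junction caller uses.
    """
    params = spectrum_params or dict(IRRADIATED_SPECTRUM)
    index = index or _RefIndex(ref)
    probs = np.array([params.get(k, 0.0) for k in _EVENT_KEYS])
    event = _EVENT_KEYS[int(rng.choice(len(_EVENT_KEYS), p=probs))]
    seq = ref.sequence
    n = len(seq)

    if event == "complex":
        return None, SpectrumClass.COMPLEX, None

    if event == "slippage_1bp":
        pos = int(rng.choice(index.run_positions))
        call = call_deletion(ref, pos, pos + 1)
        return call.apply(ref), SpectrumClass.DEL1_RUN, call

    if event == "other_1bp":
        pos = int(rng.choice(index.lone_positions))
        call = call_deletion(ref, pos, pos + 1)
        return call.apply(ref), SpectrumClass.DEL1_OTHER, call

    if event == "pure_insertion":
        pos = int(rng.choice(index.run_positions))
        call = call_insertion(ref, pos, seq[pos])
        return call.apply(ref), SpectrumClass.INSERTION, call

    # DSB deletion: log-uniform size, homology-weighted breakpoints.
    hi = min(cfg.max_size, n - 2)
    size = int(
        math.floor(math.exp(rng.uniform(math.log(cfg.min_size), math.log(hi + 1))))
    )
    size = max(cfg.min_size, min(size, hi))
    counts = _placement_counts(index.codes, size)
    starts = np.arange(1, n - size)  # keep >= 1 retained base on each side
    weights = counts[starts].astype(float) ** cfg.mh_bias
    start = int(rng.choice(starts, p=weights / weights.sum()))
    base = call_deletion(ref, start, start + size)  # canonical window
    inserted = ""
    if rng.random() < cfg.junction_insertion_prob:
        # guard against the canonical flanks so the (deletion, insertion)
        # decomposition of the mutant sequence stays unique
        inserted = _draw_insertion(
            rng, cfg, seq[base.canonical_start], seq[base.end - 1]
        )
    call = call_deletion(ref, base.canonical_start, base.end, inserted)
    cls = (
        SpectrumClass.DELGT2_INS
        if inserted
        else (SpectrumClass.DELGT2_MH if call.mh_len >= 1 else SpectrumClass.DELGT2_NOMH)
    )
    return call.apply(ref), cls, call


# ---------------------------------------------------------------------------
# Notation emission (so simulated tables flow through the same readers)
# ---------------------------------------------------------------------------

def _call_to_notation(ref: ReferenceSeq, call: DeletionCall) -> tuple[str, str]:
    """Render a call in the published position / junction-sequence notation."""
    seq = ref.sequence
    cs, size, mh = call.canonical_start, call.size, call.mh_len
    if size == 0:
        # Pure insertion: context notation, expanded until unique.
        half = max(4, call.placement_count + 2)
        while True:
            lo = max(0, cs - half)
            hi = min(len(seq), cs + mh + half)
            before = seq[lo:hi]
            if seq.count(before) == 1 or (lo == 0 and hi == len(seq)):
                break
            half += 4
        after = before[: cs - lo] + call.inserted_seq + before[cs - lo:]
        after = after[: cs - lo].lower() + call.inserted_seq.upper() + before[cs - lo:].lower()
        position = f"{lo + 1}–{hi}"
        return position, f"{before.lower()}→{after}"
    last = (cs, cs + mh)  # 1-based last-retained range (cs 0-based => cs 1-based is the base before)
    first = (cs + size + 1, cs + size + 1 + mh)
    if last[0] == last[1]:
        position = f"{last[0]:,} → {first[0]:,}"
    else:
        position = f"{last[0]:,}–{last[1]:,} → {first[0]:,}–{first[1]:,}"
    end0 = cs + size
    flank_l = seq[max(0, cs - 4): cs].lower()
    flank_r = seq[end0 + mh: end0 + mh + 4].lower()
    if call.inserted_seq:
        unit = "bp" if len(call.inserted_seq) == 1 else "bps"
        position += f" ({len(call.inserted_seq)} {unit} ins.)"
        change = f"{flank_l} <{call.inserted_seq}> {seq[end0: end0 + 4].lower()}"
    elif mh:
        change = f"{flank_l}{seq[end0: end0 + mh].upper()}{flank_r}"
    else:
        change = f"{flank_l} {seq[end0: end0 + 4].lower()}"
    return position, change


# ---------------------------------------------------------------------------
# Whole experiment
# ---------------------------------------------------------------------------

def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Simulate the full assay: animals, counts, and sequenced mutants.

    Per animal, rescued pfu is uniform over the configured range and the
    confirmed mutant count is Poisson(true MF x pfu); each mutant receives a
    mutation event.  One :class:`numpy.random.SeedSequence` spawns one
    substream for the reference and one per animal, so results are fully
    deterministic given the seed and invariant to group order changes
    elsewhere in the pipeline.
    """
    root = np.random.SeedSequence(cfg.seed)
    ref_ss, *animal_ss = root.spawn(1 + sum(g.n_animals for g in cfg.groups))
    ref = simulate_reference(cfg, np.random.default_rng(ref_ss))
    index = _RefIndex(ref)

    records: list[MutantRecord] = []
    assays: list[AnimalAssay] = []
    truth: list[GroundTruthEntry] = []
    stream = iter(animal_ss)
    for group in cfg.groups:
        for j in range(group.n_animals):
            rng = np.random.default_rng(next(stream))
            animal_id = f"{group.strain}-{group.dose_gy:g}Gy-{group.organ}-{j + 1}"
            lo, hi = group.pfu_per_animal_range
            pfu = int(rng.integers(lo, hi + 1))
            n_mutants = int(rng.poisson(group.true_total_mf * pfu))
            n_mutants = min(n_mutants, pfu)
            assays.append(
                AnimalAssay(
                    strain=group.strain,
                    dose_gy=group.dose_gy,
                    organ=group.organ,
                    animal_id=animal_id,
                    confirmed_mutants=n_mutants,
                    rescued_pfu=pfu,
                )
            )
            for m in range(n_mutants):
                mutant_id = f"{animal_id}-m{m + 1:03d}"
                mutant_seq, cls, call = simulate_mutant(
                    ref, cfg, rng, group.spectrum_params, index
                )
                if call is None:
                    position, change = "N.D.", ""
                    printed_size = None
                else:
                    position, change = _call_to_notation(ref, call)
                    printed_size = call.size if call.size else None
                descriptor = _parse_or_complex(position, change, printed_size)
                records.append(
                    MutantRecord(
                        mutant_id=mutant_id,
                        strain=group.strain,
                        dose_gy=group.dose_gy,
                        organ=group.organ,
                        animal_id=animal_id,
                        descriptor=descriptor,
                        printed_size=printed_size,
                    )
                )
                truth.append(
                    GroundTruthEntry(
                        mutant_id=mutant_id,
                        strain=group.strain,
                        dose_gy=group.dose_gy,
                        organ=group.organ,
                        animal_id=animal_id,
                        true_class=cls,
                        canonical_start=None if call is None else call.canonical_start,
                        size=None if call is None else call.size,
                        mh_len=None if call is None else call.mh_len,
                        inserted_seq="" if call is None else call.inserted_seq,
                        mutant_sequence=mutant_seq,
                    )
                )
    return SimulatedExperiment(
        reference=ref, records=records, assays=assays, truth=truth, config=cfg
    )


def _parse_or_complex(position: str, change: str, printed_size: Optional[int]):
    from .io import DescriptorError, DescriptorForm, RawDescriptor

    try:
        return parse_breakpoint_notation(position, change, printed_size=printed_size)
    except DescriptorError as exc:
        return RawDescriptor(
            form=DescriptorForm.COMPLEX, note=str(exc), raw_position=position, raw_change=change
        )
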