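"""End-to-end report generation.

Chains descriptor parsing / junction calling, spectrum classification and
frequency statistics into a deterministic report bundle of TSV tables:

* ``calls.tsv``           — per-mutant class, size, microhomology, insertion;
* ``spectrum.tsv``        — per-group class counts, percentages and specific
  MFs (one row per class x group);
* ``junction_stats.tsv``  — microhomology / large-deletion / insertion
  statistics per group;
* ``mf_summary.tsv``      — per-group mean +/- SD mutant frequencies;
* ``tukey.tsv``           — all-pairs Tukey comparisons (when per-animal
  assay counts are available);
* ``fold_changes.tsv``    — dose-response fold changes of the 1-bp and
  >= 2-bp deletion specific MFs.

Mutant frequencies are reported both at full precision and rounded the way
such results are conventionally printed (2 decimals in units of 1e-6,
percentages to whole numbers); fold changes are quoted from the rounded
specific MFs, matching that printed-arithmetic convention, with the
full-precision ratio alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .caller import call_from_descriptor
from .io import (
    DescriptorForm,
    MutantRecord,
    read_assay_table,
    read_mutant_table,
    read_reference,
    write_vcf,
)
from .spectrum import (
    CLASS_ORDER,
    ClassifiedRecord,
    SpectrumClass,
    UndefinedStatisticError,
    classify_record,
    group_records,
    junction_statistics,
    summarize_group,
)
from .stats import fold_change, group_frequencies, specific_mf, tukey_hsd

log = logging.getLogger("spidel")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    mutants: Path
    out_dir: Path
    reference: Optional[Path] = None
    assays: Optional[Path] = None
    group_mf: Optional[Path] = None  # TSV of printed group mean MFs (x1e-6)
    large_del_threshold: int = 1000
    mh_exclude_above: Optional[int] = None
    alpha: float = 0.05
    seed: Optional[int] = None
    clonal_correction: bool = False
    emit_vcf: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError(f"config: alpha must be in (0, 1), got {self.alpha}")
        for name in ("mutants", "reference", "assays", "group_mf"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {name} path does not exist: {p}")


def _group_label(group: tuple[str, float, str]) -> str:
    strain, dose, organ = group
    return f"{strain} {dose:g} Gy {organ}"


def _clonal_collapse(records: list[MutantRecord]) -> list[MutantRecord]:
    seen = set()
    out = []
    for r in records:
        key = (r.group, r.animal_id, r.descriptor.raw_position, r.descriptor.raw_change)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run all stages and write the report bundle to ``config.out_dir``.

    Returns the report tables as DataFrames keyed by file stem.  Re-running
    with identical inputs yields byte-identical tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        records = read_mutant_table(config.mutants)
    except Exception as exc:
        raise PipelineError(f"read mutants: {exc}") from exc
    if config.clonal_correction:
        records = _clonal_collapse(records)

    ref = None
    if config.reference is not None:
        try:
            ref = read_reference(config.reference)
        except Exception as exc:
            raise PipelineError(f"read reference: {exc}") from exc

    classified: list[ClassifiedRecord] = []
    calls = []
    for r in records:
        call = None
        if ref is not None and r.descriptor.form is not DescriptorForm.COMPLEX:
            try:
                call = call_from_descriptor(ref, r.descriptor)
                calls.append(call)
            except Exception as exc:
                raise PipelineError(f"junction calling: {r.mutant_id}: {exc}") from exc
        classified.append(classify_record(r, call))

    if config.emit_vcf and ref is not None:
        write_vcf(calls, ref, out / "calls.vcf")

    calls_df = pd.DataFrame(
        [
            {
                "mutant_id": c.record.mutant_id,
                "strain": c.record.strain,
                "dose_gy": c.record.dose_gy,
                "organ": c.record.organ,
                "animal_id": c.record.animal_id,
                "class": c.spectrum_class.value,
                "size_bp": c.size,
                "mh_len": c.mh_len,
                "inserted_len": c.inserted_len,
            }
            for c in classified
        ]
    )

    by_group = group_records(classified)
    group_keys = sorted(by_group, key=lambda g: (g[2], g[0], g[1]))

    mean_mf = {}  # group -> mean MF in 1e-6 units
    mf_rows = []
    tukey_df = pd.DataFrame()
    if config.assays is not None:
        try:
            assays = read_assay_table(config.assays)
        except Exception as exc:
            raise PipelineError(f"read assays: {exc}") from exc
        freqs = group_frequencies(assays)
        for g, fr in sorted(freqs.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1])):
            mean_mf[g] = fr.mean_mf * 1e6
            mf_rows.append(
                {
                    "group": _group_label(g),
                    "n_animals": fr.n_animals,
                    "mean_mf_e6": fr.mean_mf * 1e6,
                    "sd_mf_e6": fr.sd_mf * 1e6,
                    "mean_mf_e6_printed": round(fr.mean_mf * 1e6, 2),
                }
            )
        organs = {g[2] for g in freqs}
        comparisons = []
        for organ in sorted(organs):
            sub = [fr for g, fr in freqs.items() if g[2] == organ]
            if len(sub) >= 2 and all(fr.n_animals >= 2 for fr in sub):
                comparisons.extend(tukey_hsd(sub, alpha=config.alpha))
        tukey_df = pd.DataFrame(
            [
                {
                    "group_a": _group_label(c.group_a),
                    "group_b": _group_label(c.group_b),
                    "mean_diff_e6": c.mean_diff * 1e6,
                    "q_statistic": c.q_statistic,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in comparisons
            ]
        )
    elif config.group_mf is not None:
        gmf = pd.read_csv(config.group_mf, sep="\t")
        for row in gmf.itertuples(index=False):
            g = (row.strain, float(row.dose_gy), row.organ)
            mean_mf[g] = float(row.mean_mf_e6)
            mf_rows.append(
                {
                    "group": _group_label(g),
                    "n_animals": getattr(row, "n_animals", ""),
                    "mean_mf_e6": float(row.mean_mf_e6),
                    "sd_mf_e6": float(getattr(row, "sd_mf_e6", float("nan"))),
                    "mean_mf_e6_printed": round(float(row.mean_mf_e6), 2),
                }
            )
    mf_df = pd.DataFrame(mf_rows)

    spectrum_rows = []
    for g in group_keys:
        summary = summarize_group(by_group[g])
        for cls in CLASS_ORDER:
            row = {
                "group": _group_label(g),
                "class": cls.value,
                "count": summary.counts[cls],
                "percent": 100.0 * summary.ratios[cls],
                "percent_printed": round(100.0 * summary.ratios[cls]),
            }
            if g in mean_mf:
                smf = specific_mf(mean_mf[g], summary.counts[cls], summary.total)
                row["specific_mf_e6"] = smf
                row["specific_mf_e6_printed"] = round(smf, 2)
            spectrum_rows.append(row)
        spectrum_rows.append(
            {
                "group": _group_label(g),
                "class": "Total",
                "count": summary.total,
                "percent": 100.0,
                "percent_printed": 100,
                **(
                    {"specific_mf_e6": mean_mf[g], "specific_mf_e6_printed": round(mean_mf[g], 2)}
                    if g in mean_mf
                    else {}
                ),
            }
        )
    spectrum_df = pd.DataFrame(spectrum_rows)

    junction_rows = []
    for g in group_keys:
        try:
            js = junction_statistics(
                by_group[g],
                exclude_mh_above=config.mh_exclude_above,
                large_threshold=config.large_del_threshold,
            )
        except UndefinedStatisticError:
            continue
        junction_rows.append(
            {
                "group": _group_label(g),
                "gt2bp_deletions": js.gt2bp_total,
                "with_mh": js.mh_count,
                "mh_fraction_pct": 100.0 * js.mh_fraction,
                "mean_mh_len_bp": js.mean_mh_len,
                "n_mh_in_mean": js.n_mh_used,
                "large_count": js.large_count,
                "large_fraction_pct": 100.0 * js.large_fraction,
                "insertion_records": js.insertion_count,
                "insertion_fraction_pct": 100.0 * js.insertion_fraction,
            }
        )
    junction_df = pd.DataFrame(junction_rows)

    fold_rows = []
    strains_organs = {(g[0], g[2]) for g in group_keys}
    for strain, organ in sorted(strains_organs):
        doses = sorted(g[1] for g in group_keys if (g[0], g[2]) == (strain, organ))
        if len(doses) < 2:
            continue
        pre, post = (strain, doses[0], organ), (strain, doses[-1], organ)
        if pre not in mean_mf or post not in mean_mf:
            continue
        for label, classes in (
            ("1bp_deletion", (SpectrumClass.DEL1_RUN, SpectrumClass.DEL1_OTHER)),
            (
                "gt2bp_deletion",
                (SpectrumClass.DELGT2_MH, SpectrumClass.DELGT2_NOMH, SpectrumClass.DELGT2_INS),
            ),
        ):
            s_pre = summarize_group(by_group[pre])
            s_post = summarize_group(by_group[post])
            mf_pre = specific_mf(
                mean_mf[pre], sum(s_pre.counts[c] for c in classes), s_pre.total
            )
            mf_post = specific_mf(
                mean_mf[post], sum(s_post.counts[c] for c in classes), s_post.total
            )
            fold_rows.append(
                {
                    "strain": strain,
                    "organ": organ,
                    "class": label,
                    "pre_mf_e6_printed": round(mf_pre, 2),
                    "post_mf_e6_printed": round(mf_post, 2),
                    "fold_change_printed": round(
                        fold_change(round(mf_post, 2), round(mf_pre, 2)), 1
                    ),
                    "fold_change_full": fold_change(mf_post, mf_pre),
                }
            )
    fold_df = pd.DataFrame(fold_rows)

    tables = {
        "calls": calls_df,
        "spectrum": spectrum_df,
        "junction_stats": junction_df,
        "mf_summary": mf_df,
        "tukey": tukey_df,
        "fold_changes": fold_df,
    }
    for stem, df in tables.items():
        df.to_csv(out / f"{stem}.tsv", sep="\t", index=False)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"spidel {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config: {config}\n")
        fh.write(f"records: {len(records)}\n")
    log.info("report written to %s", out)
    return tables
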