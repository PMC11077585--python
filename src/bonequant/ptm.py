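"""Peptide modification-occupancy (PTM ratio) computation.

For a peptide sequence in one sample, the occupancy of a modification class
is the summed abundance of the sequence forms carrying at least one
modification of that class divided by the summed abundance of all forms of
the sequence.  A form carrying both a deamidation and an oxidation counts in
the numerator of both classes, which keeps each class's conservation law
(modified + complement = total) exact.  Ratios are computed from raw
(pre-log) abundances; cells whose total abundance is unobserved are missing,
never zero.

N-terminal acetylation and fixed carbamidomethylation never form a ratio
row: they are search-engine bookkeeping, not degradation markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PrecursorRecord, QuantMatrix

__all__ = ["PTMRatioTable", "ptm_ratio", "build_ptm_table", "class_summary"]

PTM_CLASSES = ("deamidation", "oxidation")
_SITE_LETTERS = {"deamidation": set("NQ"), "oxidation": {"M"}}


@dataclass
class PTMRatioTable:
    """Per-(sequence, class) occupancy fractions across samples.

    ``ratios`` is indexed by (stripped_sequence, ptm_class) with one column
    per sample; values lie in [0, 1], NaN where the total abundance is
    unobserved.  ``modified`` and ``total`` retain the abundances the ratios
    were computed from.
    """

    ratios: pd.DataFrame
    modified: pd.DataFrame
    total: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.columns)

    def to_tsv(self, path) -> None:
        out = self.ratios * 100.0
        out.to_csv(path, sep="\t", na_rep="", index_label=["stripped_sequence", "ptm_class"])


def ptm_ratio(records: list[PrecursorRecord], ptm_class: str) -> float:
    """Occupancy of one modification class for one sequence in one sample.

    All records must share the stripped sequence and run.  Returns the
    modified-over-total abundance fraction; raises if the total is zero
    (an undefined ratio is a missing cell, decided by the caller).
    """
    if ptm_class not in PTM_CLASSES:
        raise ValueError(f"unknown ptm_class {ptm_class!r}")
    if not records:
        raise ValueError("no records")
    seqs = {r.stripped_sequence for r in records}
    runs = {r.run_id for r in records}
    if len(seqs) > 1 or len(runs) > 1:
        raise ValueError(f"records span sequences {seqs} and runs {runs}")
    total = sum(r.abundance for r in records)
    if total <= 0:
        raise ValueError("total abundance is zero; ratio undefined")
    modified = sum(
        r.abundance
        for r in records
        if any(ev.kind.value == ptm_class for ev in r.modifications)
    )
    return modified / total


def build_ptm_table(m: QuantMatrix, retained_peptides: set[str]) -> PTMRatioTable:
    """Build the occupancy table from a modified-sequence matrix.

    Only peptides that passed the all-sequences missingness filter should be
    passed in: a ratio over a partial set of forms is biased.  One
    deamidation row is emitted per retained sequence containing N or Q and
    one oxidation row per sequence containing M, whether or not the modified
    form was ever observed.  Within a cell the ratio uses the observed forms
    only; if every form is missing the cell is missing.
    """
    if m.level != "modified_sequence":
        raise ValueError("PTM ratios require a modified_sequence matrix")
    if m.scale != "raw":
        raise ValueError("PTM ratios are computed from raw abundances")
    if m.feature_meta is None:
        raise ValueError("matrix lacks feature metadata")

    meta = m.feature_meta
    vals = m.values
    idx_rows = []
    mod_rows = []
    tot_rows = []
    for seq in sorted(retained_peptides):
        sel = meta["stripped_sequence"] == seq
        if not sel.any():
            continue
        sub = vals.loc[sel.to_numpy()]
        sub_meta = meta.loc[sel.to_numpy()]
        total = sub.sum(axis=0, min_count=1)
        for cls in PTM_CLASSES:
            if not (_SITE_LETTERS[cls] & set(seq)):
                continue
            carries = (sub_meta[f"n_{cls}"] > 0).to_numpy()
            modified = sub.loc[carries].sum(axis=0, min_count=1) if carries.any() else None
            if modified is None:
                modified = pd.Series(0.0, index=sub.columns).where(total.notna())
            else:
                # a sequence with an observed total but no observed modified
                # form has occupancy 0 there, not missing
                modified = modified.where(total.isna() | modified.notna(), 0.0)
            idx_rows.append((seq, cls))
            mod_rows.append(modified)
            tot_rows.append(total)

    index = pd.MultiIndex.from_tuples(idx_rows, names=["stripped_sequence", "ptm_class"]) \
        if idx_rows else pd.MultiIndex.from_arrays([[], []], names=["stripped_sequence", "ptm_class"])
    modified_df = pd.DataFrame(mod_rows, index=index, columns=vals.columns)
    total_df = pd.DataFrame(tot_rows, index=index, columns=vals.columns)
    ratios = modified_df / total_df
    return PTMRatioTable(ratios=ratios, modified=modified_df, total=total_df)


def class_summary(table: PTMRatioTable, design: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Unweighted mean occupancy per (ptm_class, group), in percent.

    Every defined (sequence, sample) cell contributes equally.  Groups with
    no defined cell yield NaN with a warning.
    """
    run_group = design.set_index("run_id")[by]
    long = table.ratios.stack(future_stack=True).rename("ratio").reset_index()
    long.columns = ["stripped_sequence", "ptm_class", "run_id", "ratio"]
    long[by] = long["run_id"].map(run_group)
    out = (
        long.groupby(["ptm_class", by])["ratio"]
        .mean()
        .mul(100.0)
        .rename("mean_ratio_pct")
        .reset_index()
    )
    for row in out.itertuples(index=False):
        if np.isnan(row.mean_ratio_pct):
            warnings.warn(
                f"no defined {row.ptm_class} cells for {by}={getattr(row, by)}",
                stacklevel=2,
            )
    return out
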