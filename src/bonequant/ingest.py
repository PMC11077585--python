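"""Parsers for DIA-NN and MaxQuant quantification reports.

Both engines are mapped onto the same :class:`~bonequant.types.PrecursorRecord`
vocabulary so everything downstream is engine-agnostic.  Only the reported
quantities are consumed; identification and FDR control are the engines' job
and are never recomputed here.

Conventions
-----------
* Zero or blank intensities are missing observations, never numeric zeros.
* Rows flagged as decoys ("Reverse") or potential contaminants are dropped
  from MaxQuant evidence.
* A precursor mapping to several protein groups is counted only toward the
  first listed group (razor-style assignment), with a log notice.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .types import (
    DesignError,
    FormatError,
    ModificationEvent,
    ModKind,
    PrecursorRecord,
    QuantMatrix,
    validate_design,
)

logger = logging.getLogger(__name__)

__all__ = [
    "parse_diann_report",
    "parse_maxquant_evidence",
    "build_quant_matrix",
    "canonical_feature_id",
    "records_to_frame",
]

DIANN_COLUMNS = [
    "Run",
    "Protein.Group",
    "Stripped.Sequence",
    "Modified.Sequence",
    "Precursor.Charge",
    "Precursor.Quantity",
]

MAXQUANT_COLUMNS = [
    "Sequence",
    "Modified sequence",
    "Modifications",
    "Proteins",
    "Charge",
    "Intensity",
    "Raw file",
]

# UniMod accessions used by DIA-NN for the modifications searched here
_UNIMOD_MAP = {
    "UniMod:7": ModKind.DEAMIDATION,
    "UniMod:35": ModKind.OXIDATION,
    "UniMod:1": ModKind.ACETYL_NTERM,
    "UniMod:4": ModKind.CARBAMIDOMETHYL,
}

# MaxQuant in-sequence annotation names (long form) and legacy short codes
_MAXQUANT_TOKEN_MAP = [
    ("deamidation", ModKind.DEAMIDATION),
    ("de", ModKind.DEAMIDATION),
    ("oxidation", ModKind.OXIDATION),
    ("ox", ModKind.OXIDATION),
    ("acetyl", ModKind.ACETYL_NTERM),
    ("ac", ModKind.ACETYL_NTERM),
    ("carbamidomethyl", ModKind.CARBAMIDOMETHYL),
    ("ca", ModKind.CARBAMIDOMETHYL),
]


def _classify_token(token: str, residue: str, position: int) -> ModificationEvent:
    """Map one engine annotation token to a ModificationEvent.

    Unknown tokens become kind=other with a logged warning rather than an
    error: search configurations vary and an unrecognized modification must
    not abort ingestion.
    """
    low = token.strip().lower()
    kind = None
    if token in _UNIMOD_MAP:
        kind = _UNIMOD_MAP[token]
    else:
        for prefix, k in _MAXQUANT_TOKEN_MAP:
            if low == prefix or low.startswith(prefix + " ") or low.startswith(prefix + "("):
                kind = k
                break
    if kind is None:
        logger.warning("unknown modification token %r; recording as kind=other", token)
        return ModificationEvent(ModKind.OTHER, residue, position)
    if kind is ModKind.ACETYL_NTERM:
        return ModificationEvent(kind, residue="-", position=0)
    try:
        return ModificationEvent(kind, residue, position)
    except ValueError:
        logger.warning(
            "token %r maps to %s but sits on residue %r; recording as kind=other",
            token,
            kind.value,
            residue,
        )
        return ModificationEvent(ModKind.OTHER, residue, position)


def _parse_annotated_sequence(seq: str) -> tuple[str, tuple[ModificationEvent, ...]]:
    """Parse a sequence with parenthesized annotations after residues.

    Handles both DIA-NN (``AGN(UniMod:7)K``) and MaxQuant
    (``_AGN(Deamidation (NQ))K_``) notation, including nested parentheses in
    MaxQuant's long modification names.  An annotation before any residue
    applies to the N-terminus (position 0).
    """
    seq = seq.strip().strip("_")
    stripped: list[str] = []
    events: list[ModificationEvent] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch == "(":
            depth = 1
            j = i + 1
            while j < len(seq) and depth:
                if seq[j] == "(":
                    depth += 1
                elif seq[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise FormatError(f"unbalanced parentheses in {seq!r}")
            token = seq[i + 1 : j - 1]
            pos = len(stripped)
            residue = stripped[-1] if stripped else "-"
            events.append(_classify_token(token, residue, pos))
            i = j
        elif ch.isalpha():
            stripped.append(ch.upper())
            i += 1
        else:
            i += 1  # tolerate stray separators
    return "".join(stripped), tuple(events)


def _leading_accession(group: str, engine: str) -> str:
    parts = [p for p in re.split(r"[;,]", str(group)) if p]
    if len(parts) > 1:
        logger.info(
            "%s precursor maps to %d protein groups; assigned to first (%s)",
            engine,
            len(parts),
            parts[0],
        )
    return parts[0] if parts else str(group)


def _read_tsv(path, mandatory: list[str], engine: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"{engine} report {path} is missing column {col!r}")
    return df


def _exact_float(series: pd.Series) -> pd.Series:
    """Parse numeric strings with correctly-rounded float conversion.

    ``pd.to_numeric`` can be off by one ulp on long decimal strings, which
    would break exact round-trips through emitted reports.
    """

    def conv(s):
        if s is None or (isinstance(s, float) and np.isnan(s)):
            return np.nan
        s = str(s).strip()
        if not s:
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    return series.map(conv)


def _check_runs(runs, design: pd.DataFrame) -> None:
    known = set(design["run_id"])
    unknown = sorted(set(runs) - known)
    if unknown:
        raise DesignError(f"runs absent from design table: {unknown}")


def parse_diann_report(path, design: pd.DataFrame) -> list[PrecursorRecord]:
    """Parse a DIA-NN ``report.tsv`` into precursor records.

    One record is produced per report row with a positive quantity; blank or
    zero quantities yield no record (missing, not zero).
    """
    design = validate_design(design)
    df = _read_tsv(path, DIANN_COLUMNS, "DIA-NN")
    if df.empty:
        logger.warning("DIA-NN report %s contains no data rows", path)
        return []
    _check_runs(df["Run"].unique(), design)

    records: list[PrecursorRecord] = []
    quantities = _exact_float(df["Precursor.Quantity"])
    for idx in range(len(df)):
        qty = quantities.iloc[idx]
        if not np.isfinite(qty) or qty <= 0:
            continue
        stripped, events = _parse_annotated_sequence(df["Modified.Sequence"].iloc[idx])
        declared = str(df["Stripped.Sequence"].iloc[idx]).upper()
        if stripped != declared:
            raise FormatError(
                f"Modified.Sequence {df['Modified.Sequence'].iloc[idx]!r} strips to "
                f"{stripped!r}, not declared {declared!r}"
            )
        records.append(
            PrecursorRecord(
                run_id=str(df["Run"].iloc[idx]),
                protein_group=_leading_accession(df["Protein.Group"].iloc[idx], "diann"),
                stripped_sequence=stripped,
                modified_sequence=str(df["Modified.Sequence"].iloc[idx]),
                modifications=events,
                charge=int(float(df["Precursor.Charge"].iloc[idx])),
                abundance=float(qty),
                engine="diann",
            )
        )
    return records


def parse_maxquant_evidence(path, design: pd.DataFrame) -> list[PrecursorRecord]:
    """Parse a MaxQuant ``evidence.txt`` into precursor records.

    Decoy ("Reverse" == "+") and potential-contaminant rows are excluded.
    Duplicate (run, modified sequence, charge) rows — e.g. separate elution
    peaks of the same precursor — are summed with a log notice.
    """
    design = validate_design(design)
    df = _read_tsv(path, MAXQUANT_COLUMNS, "MaxQuant")
    if df.empty:
        logger.warning("MaxQuant evidence %s contains no data rows", path)
        return []
    for flag in ("Reverse", "Potential contaminant"):
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]
    _check_runs(df["Raw file"].unique(), design)

    merged: dict[tuple[str, str, int], dict] = {}
    dup_count = 0
    intensities = _exact_float(df["Intensity"])
    for idx in range(len(df)):
        inten = intensities.iloc[idx]
        if not np.isfinite(inten) or inten <= 0:
            continue
        modseq = str(df["Modified sequence"].iloc[idx])
        stripped, events = _parse_annotated_sequence(modseq)
        declared = str(df["Sequence"].iloc[idx]).upper()
        if stripped != declared:
            raise FormatError(
                f"Modified sequence {modseq!r} strips to {stripped!r}, "
                f"not declared {declared!r}"
            )
        run = str(df["Raw file"].iloc[idx])
        charge = int(float(df["Charge"].iloc[idx]))
        key = (run, modseq, charge)
        if key in merged:
            merged[key]["abundance"] += float(inten)
            dup_count += 1
        else:
            merged[key] = {
                "run_id": run,
                "protein_group": _leading_accession(df["Proteins"].iloc[idx], "maxquant"),
                "stripped_sequence": stripped,
                "modified_sequence": modseq,
                "modifications": events,
                "charge": charge,
                "abundance": float(inten),
            }
    if dup_count:
        logger.info(
            "summed %d duplicated (run, modified sequence, charge) evidence rows",
            dup_count,
        )
    return [PrecursorRecord(engine="maxquant", **rec) for rec in merged.values()]


# ---------------------------------------------------------------------------
# aggregation into matrices
# ---------------------------------------------------------------------------

# PTM classes that define a distinct quantified form of a peptide.  Fixed-
# modification carbamidomethylation and default N-terminal acetylation are
# engine bookkeeping, not analytes, and are excluded from the feature key so
# that both engine dialects of the same observation land on the same feature.
_KEY_KINDS = (ModKind.DEAMIDATION, ModKind.OXIDATION)


def canonical_feature_id(stripped: str, modifications) -> str:
    """Canonical modified-sequence feature id: sequence + PTM-class counts.

    Counts (not site positions) are used so that positional isomers — which
    engines may localize differently — pool into one form, matching the
    form-level occupancy definition used by the PTM module.
    """
    counts = {}
    for ev in modifications:
        if ev.kind in _KEY_KINDS:
            counts[ev.kind.value] = counts.get(ev.kind.value, 0) + 1
    if not counts:
        return stripped
    tag = ";".join(f"{k}:{counts[k]}" for k in sorted(counts))
    return f"{stripped}[{tag}]"


def _feature_key(record: PrecursorRecord, level: str) -> str:
    if level == "protein":
        return record.protein_group
    if level == "peptide_sequence":
        return record.stripped_sequence
    if level == "modified_sequence":
        return canonical_feature_id(record.stripped_sequence, record.modifications)
    raise ValueError(f"unknown level {level!r}")


def build_quant_matrix(
    records: list[PrecursorRecord], level: str, design: pd.DataFrame
) -> QuantMatrix:
    """Aggregate precursor records into a features x samples QuantMatrix.

    Abundance is summed over all records sharing (feature key, run): protein
    rows pool peptides, peptide rows pool charge and modification states,
    modified-sequence rows pool charges only.  Cells with no record stay
    missing; features observed in no run never appear.  Columns are the runs
    of the design table, in design order.
    """
    if level not in ("protein", "peptide_sequence", "modified_sequence"):
        raise ValueError(f"unknown level {level!r}")
    if not records:
        raise ValueError("no records to aggregate")
    design = validate_design(design)

    meta: dict[str, dict] = {}
    long_rows = []
    for rec in records:
        key = _feature_key(rec, level)
        long_rows.append({"feature": key, "run_id": rec.run_id, "abundance": rec.abundance})
        if level == "modified_sequence" and key not in meta:
            counts = {k: 0 for k in ("deamidation", "oxidation")}
            for ev in rec.modifications:
                if ev.kind in _KEY_KINDS:
                    counts[ev.kind.value] += 1
            meta[key] = {
                "stripped_sequence": rec.stripped_sequence,
                "n_deamidation": counts["deamidation"],
                "n_oxidation": counts["oxidation"],
            }

    long = pd.DataFrame(long_rows)
    values = long.pivot_table(index="feature", columns="run_id", values="abundance",
                              aggfunc="sum")
    values = values.reindex(columns=list(design["run_id"])).sort_index()
    values.index.name = None
    values.columns.name = None

    feature_meta = None
    if level == "modified_sequence":
        feature_meta = pd.DataFrame.from_dict(meta, orient="index").loc[values.index]
    return QuantMatrix(values=values, level=level, scale="raw", feature_meta=feature_meta)


def records_to_frame(records: list[PrecursorRecord]) -> pd.DataFrame:
    """Flatten records into a unified long observation table."""
    rows = []
    for r in records:
        rows.append(
            {
                "run_id": r.run_id,
                "protein_group": r.protein_group,
                "stripped_sequence": r.stripped_sequence,
                "modified_sequence": r.modified_sequence,
                "feature_id": canonical_feature_id(r.stripped_sequence, r.modifications),
                "charge": r.charge,
                "abundance": r.abundance,
                "engine": r.engine,
            }
        )
    return pd.DataFrame(rows)
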