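"""Core domain types shared across the pipeline.

The central container is :class:`QuantMatrix`, a features x samples abundance
grid backed by a pandas DataFrame in which ``NaN`` marks a missing observation.
Zero and blank intensities are converted to missing at ingest and never reach
a matrix: downstream log2 transformation must not see zeros, and absence of a
precursor in a run is treated as missingness to (potentially) impute rather
than as a measured zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModKind",
    "ModificationEvent",
    "PrecursorRecord",
    "QuantMatrix",
    "Level",
    "Scale",
    "read_design",
    "validate_design",
    "BoneQuantError",
    "FormatError",
    "DesignError",
    "ConfigError",
    "MaskingError",
    "DataError",
]


class BoneQuantError(Exception):
    """Base class for package errors."""


class FormatError(BoneQuantError):
    """A search-engine report does not have the expected shape."""


class DesignError(BoneQuantError):
    """Sample design table inconsistent with the data."""


class ConfigError(BoneQuantError):
    """Invalid or infeasible configuration."""


class MaskingError(BoneQuantError):
    """An artificial-masking request cannot be satisfied."""


class DataError(BoneQuantError):
    """Data violate a numeric precondition (e.g. non-positive values at log2)."""


class ModKind(str, enum.Enum):
    """Vocabulary of peptide modifications the pipeline understands."""

    DEAMIDATION = "deamidation"
    OXIDATION = "oxidation"
    ACETYL_NTERM = "acetyl_nterm"
    CARBAMIDOMETHYL = "carbamidomethyl"
    OTHER = "other"


# residues on which each modification class is chemically possible
_ALLOWED_RESIDUES = {
    ModKind.DEAMIDATION: {"N", "Q"},
    ModKind.OXIDATION: {"M"},
    ModKind.CARBAMIDOMETHYL: {"C"},
}


@dataclass(frozen=True, order=True)
class ModificationEvent:
    """One modification on one residue of a peptide.

    ``position`` is the 1-based index into the stripped sequence; 0 is
    reserved for the peptide/protein N-terminus (acetylation).
    """

    kind: ModKind
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        allowed = _ALLOWED_RESIDUES.get(self.kind)
        if allowed is not None and self.residue not in allowed:
            raise ValueError(
                f"{self.kind.value} not chemically possible on residue "
                f"{self.residue!r} (allowed: {sorted(allowed)})"
            )


@dataclass(frozen=True)
class PrecursorRecord:
    """One quantified (modified) peptide observation from a search report."""

    run_id: str
    protein_group: str
    stripped_sequence: str
    modified_sequence: str
    modifications: tuple[ModificationEvent, ...]
    charge: int
    abundance: float
    engine: str  # "diann" | "maxquant"

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be nonnegative")
        if self.charge <= 0:
            raise ValueError("charge must be positive")
        for ev in self.modifications:
            if ev.position > len(self.stripped_sequence):
                raise ValueError(
                    f"modification position {ev.position} beyond sequence "
                    f"{self.stripped_sequence!r}"
                )


Level = ("protein", "peptide_sequence", "modified_sequence")
Scale = ("raw", "log2", "zscored")


@dataclass
class QuantMatrix:
    """Features x samples abundance matrix with explicit missing markers.

    Attributes
    ----------
    values
        DataFrame indexed by feature id, columns = sample (run) ids,
        ``NaN`` = missing.
    level
        One of ``protein``, ``peptide_sequence``, ``modified_sequence``.
    scale
        One of ``raw``, ``log2``, ``zscored``.
    feature_meta
        Optional per-feature metadata; for the ``modified_sequence`` level it
        carries ``stripped_sequence`` and the deamidation/oxidation counts of
        the form, which the PTM module relies on.
    """

    values: pd.DataFrame
    level: str
    scale: str = "raw"
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in Level:
            raise ValueError(f"unknown level {self.level!r}; expected one of {Level}")
        if self.scale not in Scale:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {Scale}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative abundance at raw scale")
        if self.feature_meta is not None and not self.feature_meta.index.equals(
            self.values.index
        ):
            raise ValueError("feature_meta index must match values index")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean grid, True where a cell is missing."""
        return self.values.isna()

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            values=self.values.copy(),
            level=self.level,
            scale=self.scale,
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "QuantMatrix":
        keep = [f for f in feature_ids if f in self.values.index]
        return QuantMatrix(
            values=self.values.loc[keep],
            level=self.level,
            scale=self.scale,
            feature_meta=None if self.feature_meta is None else self.feature_meta.loc[keep],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantMatrix":
        keep = [s for s in sample_ids if s in self.values.columns]
        return QuantMatrix(
            values=self.values[keep],
            level=self.level,
            scale=self.scale,
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
        )

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write features x samples TSV; missing cells are left empty."""
        self.values.to_csv(path, sep="\t", na_rep="", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, level: str, scale: str = "raw") -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        df.index = df.index.astype(str)
        return cls(values=df.astype(float), level=level, scale=scale)


DESIGN_COLUMNS = ["run_id", "donor_id", "replicate_set", "group", "acquisition"]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design table mapping runs to donor / set / group.

    Required columns: run_id, donor_id, replicate_set, group, acquisition.
    (donor_id, replicate_set) pairs must be unique, as must run ids.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    design = design[DESIGN_COLUMNS].astype(str)
    if design["run_id"].duplicated().any():
        raise DesignError("duplicate run_id in design")
    dupes = design.duplicated(subset=["donor_id", "replicate_set"])
    if dupes.any():
        bad = design.loc[dupes, ["donor_id", "replicate_set"]].values.tolist()
        raise DesignError(f"duplicate (donor_id, replicate_set): {bad}")
    bad_acq = set(design["acquisition"]) - {"DDA", "DIA"}
    if bad_acq:
        raise DesignError(f"acquisition must be DDA or DIA, got {sorted(bad_acq)}")
    return design.reset_index(drop=True)


def read_design(path) -> pd.DataFrame:
    """Read a design table from CSV or TSV (sniffed on the header line)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return validate_design(pd.read_csv(path, sep=sep, dtype=str))
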