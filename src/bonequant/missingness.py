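"""Missingness quantification, cutoff calibration and exclusion rules.

The calibration procedure artificially removes observed values — 30% to 50%
in 5% steps by default — re-imputes them, and scores the concordance between
true and imputed values (RMSE and Pearson r on the log2 scale).  The largest
masking fraction still meeting a Pearson floor becomes the missingness
cutoff used by the protein and peptide exclusion rules:

* proteins with missingness above the cutoff are removed;
* a peptide is analyzed only if *every* one of its modified/unmodified
  sequence forms is at or below the cutoff — an occupancy ratio computed
  from a partial set of forms would be biased, so exclusion is
  all-or-nothing per peptide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MaskingError, QuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MaskingExperiment",
    "CalibrationResult",
    "feature_missingness",
    "dataset_missingness",
    "mask_completely_at_random",
    "calibrate_cutoff",
    "filter_proteins",
    "filter_peptides",
]

DEFAULT_FRACTIONS = (0.30, 0.35, 0.40, 0.45, 0.50)


@dataclass
class MaskingExperiment:
    """Grid definition for the mask-and-score calibration."""

    masking_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    n_repeats: int = 5
    seed: int = 17
    imputer_id: str = "missforest"

    def __post_init__(self) -> None:
        fr = tuple(self.masking_fractions)
        if not fr or any(not (0.0 < f < 1.0) for f in fr):
            raise ValueError("masking fractions must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("masking fractions must be strictly increasing")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        self.masking_fractions = fr


@dataclass
class CalibrationResult:
    """Per-run metrics, per-fraction summaries and the selected cutoff."""

    per_run: pd.DataFrame      # fraction, repeat, rmse, pearson_r, failed
    summary: pd.DataFrame      # fraction, rmse_mean, rmse_sd, r_mean, r_sd, n_ok
    selected_cutoff: float
    r_min: float
    imputer_id: str

    def to_dict(self) -> dict:
        return {
            "imputer_id": self.imputer_id,
            "r_min": self.r_min,
            "selected_cutoff": self.selected_cutoff,
            "summary": self.summary.to_dict(orient="records"),
            "per_run": self.per_run.to_dict(orient="records"),
        }


def feature_missingness(m: QuantMatrix) -> pd.Series:
    """Fraction of samples missing per feature, in [0, 1]."""
    if m.values.empty:
        raise ValueError("empty matrix")
    return m.values.isna().mean(axis=1)


def dataset_missingness(m: QuantMatrix) -> float:
    """Mean missing fraction over all cells of the matrix."""
    if m.values.empty:
        raise ValueError("empty matrix")
    return float(m.values.isna().to_numpy().mean())


def mask_completely_at_random(
    m: QuantMatrix, fraction: float, seed: int
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Mask ``round(fraction * n_observed)`` observed cells uniformly.

    Cells are drawn without replacement among observed cells, subject to
    every feature keeping at least one observation (a fully masked feature
    could not be re-imputed or scored).  Returns the masked matrix and a
    boolean grid marking the newly masked cells; the input is untouched, so
    the original values remain available for scoring.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    obs = ~m.values.isna().to_numpy()
    n_obs = int(obs.sum())
    target = int(round(fraction * n_obs))
    mask = pd.DataFrame(False, index=m.values.index, columns=m.values.columns)
    if target == 0:
        return m.copy(), mask

    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(obs)
    order = rng.permutation(len(rows))
    remaining = obs.sum(axis=1).astype(int)
    mask_arr = np.zeros_like(obs, dtype=bool)
    taken = 0
    for k in order:
        i, j = rows[k], cols[k]
        if remaining[i] <= 1:
            continue
        mask_arr[i, j] = True
        remaining[i] -= 1
        taken += 1
        if taken == target:
            break
    if taken < target:
        raise MaskingError(
            f"cannot mask {target} cells while keeping >=1 observation per "
            f"feature (only {taken} maskable)"
        )
    new_vals = m.values.to_numpy(dtype=float, copy=True)
    new_vals[mask_arr] = np.nan
    masked = QuantMatrix(
        values=pd.DataFrame(new_vals, index=m.values.index, columns=m.values.columns),
        level=m.level,
        scale=m.scale,
        feature_meta=None if m.feature_meta is None else m.feature_meta.copy(),
    )
    mask = pd.DataFrame(mask_arr, index=m.values.index, columns=m.values.columns)
    return masked, mask


def _run_seed(base: int, fraction_idx: int, repeat: int) -> int:
    return int(np.random.SeedSequence([base, fraction_idx, repeat]).generate_state(1)[0] % (2**31))


def calibrate_cutoff(
    m: QuantMatrix,
    exp: MaskingExperiment,
    imputer=None,
    r_min: float = 0.7,
) -> CalibrationResult:
    """Mask-and-score calibration of the acceptable missingness cutoff.

    For each masking fraction and repeat: mask observed cells, impute with
    the requested imputer, and score RMSE / Pearson r between the true and
    imputed values over the masked cells only.  The selected cutoff is the
    largest fraction whose mean Pearson r is at least ``r_min``; if none
    qualifies the smallest fraction is returned with a warning.
    """
    from .imputation import ImputerSpec, get_imputer, score_imputation

    if m.scale != "log2":
        raise ValueError("calibration expects a log2-scale matrix")
    if imputer is None:
        imputer = get_imputer(exp.imputer_id)

    records = []
    for fi, frac in enumerate(exp.masking_fractions):
        for rep in range(exp.n_repeats):
            run_seed = _run_seed(exp.seed, fi, rep)
            masked, mask = mask_completely_at_random(m, frac, run_seed)
            try:
                spec = ImputerSpec(id=exp.imputer_id, seed=run_seed)
                result = imputer(masked, spec)
                scores = score_imputation(m, result.matrix, mask)
                records.append({"fraction": frac, "repeat": rep, "failed": False, **scores})
            except Exception as err:  # noqa: BLE001 - recorded, not fatal
                logger.warning(
                    "imputation failed at fraction %.2f repeat %d: %s", frac, rep, err
                )
                records.append({
                    "fraction": frac, "repeat": rep, "failed": True,
                    "rmse": np.nan, "pearson_r": np.nan,
                })
    per_run = pd.DataFrame(records)
    ok = per_run[~per_run["failed"]]
    summary = (
        ok.groupby("fraction")
        .agg(
            rmse_mean=("rmse", "mean"),
            rmse_sd=("rmse", "std"),
            r_mean=("pearson_r", "mean"),
            r_sd=("pearson_r", "std"),
            n_ok=("rmse", "count"),
        )
        .reindex(list(exp.masking_fractions))
        .reset_index()
    )

    qualifying = summary.loc[summary["r_mean"] >= r_min, "fraction"]
    if len(qualifying):
        selected = float(qualifying.max())
    else:
        selected = float(exp.masking_fractions[0])
        warnings.warn(
            f"no masking fraction reached mean Pearson r >= {r_min}; "
            f"falling back to the smallest fraction {selected}",
            stacklevel=2,
        )
    return CalibrationResult(
        per_run=per_run,
        summary=summary,
        selected_cutoff=selected,
        r_min=r_min,
        imputer_id=exp.imputer_id,
    )


def filter_proteins(m: QuantMatrix, cutoff: float) -> QuantMatrix:
    """Retain proteins with missingness at or below the cutoff."""
    if m.level != "protein":
        raise ValueError(f"expected a protein-level matrix, got {m.level}")
    keep = feature_missingness(m) <= cutoff + 1e-12
    return m.subset_features(list(m.values.index[keep]))


def filter_peptides(m: QuantMatrix, cutoff: float) -> set[str]:
    """All-or-nothing peptide retention over modified/unmodified forms.

    A peptide (stripped sequence) is retained iff every one of its sequence
    forms in the matrix has missingness at or below the cutoff.
    """
    if m.level != "modified_sequence":
        raise ValueError("peptide filtering operates on a modified_sequence matrix")
    if m.feature_meta is None or "stripped_sequence" not in m.feature_meta.columns:
        raise ValueError("matrix lacks stripped_sequence feature metadata")
    miss = feature_missingness(m)
    ok_per_form = miss <= cutoff + 1e-12
    by_pep = ok_per_form.groupby(m.feature_meta["stripped_sequence"]).all()
    return set(by_pep.index[by_pep])
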