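"""Normalization, standardization and paired workflow comparison.

Abundance matrices are log2-transformed; z-score standardization per sample
is applied only when arms from different analytical runs or acquisition
modes are compared (matrices from one run share a scale already).  The
primary inferential tool is the paired Wilcoxon signed-rank test on
donor-paired values: exact two-sided p-values by enumeration of all sign
assignments for n <= 12 usable pairs, a tie-corrected normal approximation
with continuity correction beyond that.  Zero differences are dropped
(classic Wilcoxon; Pratt's method is available via ``zero_method``).

Raw p-values are reported by default; Benjamini-Hochberg adjustment is
available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .types import DataError, QuantMatrix

__all__ = [
    "WilcoxonResult",
    "ComparisonReport",
    "log2_transform",
    "zscore_per_sample",
    "paired_wilcoxon",
    "compare_groups",
    "compare_ptm",
    "pca_embed",
    "hclust_order",
    "proteome_coverage",
]

EXACT_LIMIT = 12  # enumerate 2^n sign assignments up to this many pairs


def log2_transform(m: QuantMatrix) -> QuantMatrix:
    """Elementwise log2; missing markers are preserved."""
    if m.scale != "raw":
        raise ValueError(f"log2_transform expects raw scale, got {m.scale}")
    vals = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if (vals[obs] <= 0).any():
        raise DataError(
            "non-positive observed abundance; zeros must be converted to "
            "missing at ingest"
        )
    out = np.full_like(vals, np.nan)
    out[obs] = np.log2(vals[obs])
    return QuantMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        level=m.level,
        scale="log2",
        feature_meta=None if m.feature_meta is None else m.feature_meta.copy(),
    )


def zscore_per_sample(m: QuantMatrix, ddof: int = 1) -> QuantMatrix:
    """Center and scale each sample column over its observed cells.

    Sample standard deviation (n−1 denominator) by convention.
    """
    if m.scale != "log2":
        raise ValueError(f"zscore_per_sample expects log2 scale, got {m.scale}")
    vals = m.values.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    for j, col in enumerate(m.values.columns):
        x = vals[:, j]
        obs = ~np.isnan(x)
        if obs.sum() < 2 or np.unique(x[obs]).size < 2:
            raise DataError(f"sample {col!r} has no within-sample variance to scale")
        mu = x[obs].mean()
        sd = x[obs].std(ddof=ddof)
        out[obs, j] = (x[obs] - mu) / sd
    return QuantMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        level=m.level,
        scale="zscored",
        feature_meta=None if m.feature_meta is None else m.feature_meta.copy(),
    )


@dataclass
class WilcoxonResult:
    w: float  # sum of ranks of positive differences
    p: float | None
    n_used: int
    tested: bool
    reason: str = ""


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating every sign assignment.

    The null distribution of W+ over the 2^n assignments is symmetric about
    mu = sum(ranks)/2 (also with tied ranks); the two-sided p-value is the
    probability of a W+ at least as far from mu as observed.
    """
    n = len(ranks)
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    w_all = bits @ ranks
    mu = ranks.sum() / 2.0
    return float(np.mean(np.abs(w_all - mu) >= abs(w_plus - mu) - 1e-9))


def paired_wilcoxon(
    x, y, zero_method: str = "drop", exact_limit: int = EXACT_LIMIT
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on x − y.

    Pairs with a missing member are removed; zero differences are dropped
    (``zero_method='pratt'`` keeps them in the ranking).  Fewer than 3
    usable pairs → untested result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    if zero_method == "drop":
        d_ranked = d[d != 0]
    elif zero_method == "pratt":
        d_ranked = d
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = len(d_ranked)
    nonzero = d_ranked != 0
    if int(nonzero.sum()) == 0 or n < 3:
        return WilcoxonResult(w=np.nan, p=None, n_used=n, tested=False,
                              reason="fewer than 3 usable pairs")
    ranks = sps.rankdata(np.abs(d_ranked))
    if zero_method == "pratt":
        ranks = ranks[nonzero]
        d_used = d_ranked[nonzero]
    else:
        d_used = d_ranked
    w_plus = float(ranks[d_used > 0].sum())
    if len(d_used) <= exact_limit:
        p = _exact_two_sided_p(np.asarray(ranks, dtype=float), w_plus)
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)  # tie-aware by construction
        z = (abs(w_plus - mu) - 0.5) / sigma     # continuity correction
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return WilcoxonResult(w=w_plus, p=p, n_used=len(d_used), tested=True)


@dataclass
class ComparisonReport:
    """Per-feature paired-test results and dataset summary for two arms."""

    per_feature: pd.DataFrame
    summary: dict
    group_a: str
    group_b: str


def _paired_columns(design: pd.DataFrame, group_a: str, group_b: str):
    """Donor-paired (run_a, run_b) column pairs from the design table."""
    by_group = {g: design[design["group"] == g].set_index("donor_id")["run_id"]
                for g in (group_a, group_b)}
    donors = [d for d in by_group[group_a].index if d in by_group[group_b].index]
    if not donors:
        raise ValueError(f"no donors paired across groups {group_a!r}/{group_b!r}")
    return donors, [by_group[group_a][d] for d in donors], [by_group[group_b][d] for d in donors]


def compare_groups(
    mA: QuantMatrix,
    mB: QuantMatrix,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> ComparisonReport:
    """Feature-by-feature paired comparison of two workflow arms.

    Shared features (the intersection of the two matrices' post-filter
    feature sets) are tested with the paired Wilcoxon signed-rank test on
    donor-paired values.  Direction is the sign of the median paired
    difference.  ``adjust=True`` applies Benjamini-Hochberg and flags
    significance on the adjusted values.
    """
    shared = [f for f in mA.feature_ids if f in set(mB.feature_ids)]
    if not shared:
        raise ValueError("no shared features between the two matrices")
    donors, runs_a, runs_b = _paired_columns(design, group_a, group_b)
    a = mA.values.loc[shared, [r for r in runs_a if r in mA.values.columns]]
    b = mB.values.loc[shared, [r for r in runs_b if r in mB.values.columns]]
    if a.shape[1] != len(donors) or b.shape[1] != len(donors):
        raise ValueError("design lists runs absent from the matrices")

    rows = []
    for f in shared:
        res = paired_wilcoxon(a.loc[f].to_numpy(), b.loc[f].to_numpy())
        diffs = a.loc[f].to_numpy() - b.loc[f].to_numpy()
        med = float(np.nanmedian(diffs)) if np.isfinite(diffs).any() else np.nan
        direction = group_a if med > 0 else (group_b if med < 0 else "tie")
        rows.append({
            "feature_id": f, "w": res.w, "p": res.p, "n_pairs": res.n_used,
            "tested": res.tested, "median_log2_diff": med, "direction": direction,
        })
    per_feature = pd.DataFrame(rows).set_index("feature_id")
    tested = per_feature["tested"]
    if adjust:
        pvals = per_feature.loc[tested, "p"].astype(float)
        per_feature["q"] = np.nan
        per_feature.loc[tested, "q"] = sps.false_discovery_control(pvals, method="bh")
        sig = per_feature["q"] < alpha
    else:
        sig = per_feature["p"].astype(float) < alpha
    per_feature["significant"] = sig.fillna(False) & tested

    sigset = per_feature[per_feature["significant"]]
    summary = {
        "group_a": group_a,
        "group_b": group_b,
        "n_shared": len(shared),
        "n_tested": int(tested.sum()),
        "n_significant": int(len(sigset)),
        "higher_in_a": int((sigset["direction"] == group_a).sum()),
        "higher_in_b": int((sigset["direction"] == group_b).sum()),
        "alpha": alpha,
        "adjusted": adjust,
    }
    return ComparisonReport(per_feature=per_feature, summary=summary,
                            group_a=group_a, group_b=group_b)


def compare_ptm(tableA, tableB, design: pd.DataFrame, group_a: str, group_b: str,
                alpha: float = 0.05) -> dict:
    """Compare PTM occupancy between arms, per peptide and pooled per class.

    Per-peptide: each shared (sequence, class) row is tested like a feature.
    Pooled: all (sequence, donor) paired occupancy cells of one class are
    pooled into a single signed-rank test per class.  Both views are
    reported.
    """
    donors, runs_a, runs_b = _paired_columns(design, group_a, group_b)
    shared = tableA.ratios.index.intersection(tableB.ratios.index)
    rows = []
    pooled: dict[str, list[tuple[float, float]]] = {}
    for key in shared:
        xa = tableA.ratios.loc[key, [r for r in runs_a if r in tableA.ratios.columns]].to_numpy()
        xb = tableB.ratios.loc[key, [r for r in runs_b if r in tableB.ratios.columns]].to_numpy()
        res = paired_wilcoxon(xa, xb)
        med = float(np.nanmedian(xa - xb))
        rows.append({
            "stripped_sequence": key[0], "ptm_class": key[1], "w": res.w,
            "p": res.p, "tested": res.tested, "median_diff": med,
            "direction": group_a if med > 0 else (group_b if med < 0 else "tie"),
            "significant": bool(res.tested and res.p is not None and res.p < alpha),
        })
        pooled.setdefault(key[1], []).extend(
            (va, vb) for va, vb in zip(xa, xb)
            if not (np.isnan(va) or np.isnan(vb))
        )
    per_peptide = pd.DataFrame(rows)
    class_tests = {}
    for cls, pairs in pooled.items():
        va = np.array([p[0] for p in pairs])
        vb = np.array([p[1] for p in pairs])
        res = paired_wilcoxon(va, vb)
        class_tests[cls] = {
            "w": res.w, "p": res.p, "n_pairs": res.n_used, "tested": res.tested,
            "median_diff": float(np.nanmedian(va - vb)) if len(va) else np.nan,
        }
    return {"per_peptide": per_peptide, "class_tests": class_tests}


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_explained_pct: np.ndarray

    def top2_pct(self) -> float:
        return float(self.variance_explained_pct[:2].sum())


def pca_embed(m: QuantMatrix, n_components: int | None = None) -> PCAResult:
    """PCA with samples as observations on a complete matrix."""
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("PCA requires a complete (post-imputation) matrix")
    X = vals.T  # samples x features
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    k = n_components or min(X.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.values.columns, columns=cols),
        variance_explained_pct=pca.explained_variance_ratio_ * 100.0,
    )


def hclust_order(m: QuantMatrix) -> tuple[list[str], list[str]]:
    """Euclidean average-linkage dendrogram leaf orders.

    Features and samples are pre-sorted by id so equal-distance merges break
    ties deterministically.
    """
    vals = m.values.sort_index()
    vals = vals[sorted(vals.columns)]
    if vals.isna().to_numpy().any():
        raise ValueError("hierarchical clustering requires a complete matrix")
    f_order = [vals.index[i] for i in hierarchy.leaves_list(
        hierarchy.linkage(vals.to_numpy(), method="average", metric="euclidean"))]
    s_order = [vals.columns[i] for i in hierarchy.leaves_list(
        hierarchy.linkage(vals.to_numpy().T, method="average", metric="euclidean"))]
    return f_order, s_order


def proteome_coverage(mA: QuantMatrix, mB: QuantMatrix, design: pd.DataFrame,
                      group_a: str, group_b: str) -> dict:
    """Per-sample observed-protein counts and their paired group test.

    Coverage is operationalized as the number of proteins observed
    (non-missing) in a sample of the pre-imputation matrix; the definition
    is a declared surrogate and is labeled as such in the output.
    """
    cov_a = (~mA.values.isna()).sum(axis=0)
    cov_b = (~mB.values.isna()).sum(axis=0)
    donors, runs_a, runs_b = _paired_columns(design, group_a, group_b)
    xa = np.array([cov_a.get(r, np.nan) for r in runs_a], dtype=float)
    xb = np.array([cov_b.get(r, np.nan) for r in runs_b], dtype=float)
    res = paired_wilcoxon(xa, xb)
    return {
        "definition": "observed_protein_count_per_sample (surrogate)",
        "coverage_a": cov_a,
        "coverage_b": cov_b,
        "w": res.w,
        "p": res.p,
        "tested": res.tested,
    }
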