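"""Synthetic bone-proteome quantification data with known ground truth.

The generator stands in for deposited raw mass-spectrometry data so that
every downstream stage — ingestion, filtering, imputation, PTM ratios,
paired comparison — can be exercised offline against an exact truth.

What is emulated
----------------
* A collagen-dominated abundance profile: a small high-abundance protein
  class (collagens and other structural proteins dominate bone extracts)
  over a larger low-abundance class, on the log2-intensity scale.
* Paired biological replicates: each donor contributes one run per workflow
  arm (replicate sets A/B), with a donor-level global intensity shift shared
  across arms.  That shift both induces the strong inter-feature correlation
  typical of label-free data and cancels in paired within-donor contrasts.
* Peptide modification states: per-peptide deamidation (N/Q) and methionine
  oxidation occupancies; each peptide's total abundance is partitioned
  exactly across its modified/unmodified forms, so realized occupancy equals
  the configured truth before masking.
* Missingness: an MCAR floor plus a logistic missing-not-at-random component
  whose probability rises as latent abundance falls, with the intercept
  calibrated so the marginal missing fraction hits a configured target.

Not emulated: chromatography, spectra, retention time, m/z, interference,
or engine scoring — reports are written directly in each engine's table
dialect.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import ConfigError, QuantMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_bone_proteome", "emit_search_report", "write_truth"]

_AA_POOL = list("ADEFGHIKLPSTVWY")  # N, Q, M, C, R inserted deliberately


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for one synthetic dataset.

    Defaults describe a two-arm paired design of 30 donors (60 runs) over
    150 proteins, ~10% of them in the high-abundance collagen class, with
    occupancies around 50% and a dataset missingness target of 18%.
    """

    n_donors: int = 30
    n_proteins: int = 150
    collagen_fraction: float = 0.10
    peptides_per_protein: tuple[int, int] = (2, 6)

    # log2 abundance model
    mu_collagen: float = 24.0
    sigma_collagen: float = 1.5
    mu_noncollagen: float = 17.5
    sigma_noncollagen: float = 1.8
    donor_shift_sd: float = 1.0   # global per-donor shift, shared across arms
    protein_donor_sd: float = 0.3  # biological protein x donor effect, shared across arms
    run_shift_sd: float = 0.15     # technical per-run loading shift
    noise_sd: float = 0.3          # residual per protein x run
    peptide_offset_sd: float = 0.8  # fixed per-peptide ionization offset

    # group structure
    groups: tuple[str, str] = ("arm_a", "arm_b")
    n_differential: int = 0
    log2_fc: float = 1.0
    acquisition_by_group: dict | None = None  # default: DIA for every arm

    # PTM structure
    prob_deamidation_site: float = 0.6
    prob_oxidation_site: float = 0.35
    prob_cys_site: float = 0.10
    occupancy_range: tuple[float, float] = (0.2, 0.8)
    deamidation_drift: float = 0.0  # occupancy shift added in the second arm

    # missingness
    mcar_rate: float = 0.02
    mnar_slope: float = 1.0  # logistic slope per log2 unit; 0 disables MNAR
    target_missingness: float = 0.18
    mode_missingness: dict | None = None  # per-group overrides of the target
    missing_unit: str = "form"  # "form" (per precursor cell) or "protein"

    seed: int = 0

    def validate(self) -> None:
        for name in ("collagen_fraction", "prob_deamidation_site", "prob_oxidation_site",
                     "prob_cys_site", "mcar_rate", "target_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        lo, hi = self.occupancy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"occupancy_range {self.occupancy_range} invalid")
        targets = [self.target_missingness]
        if self.mode_missingness:
            targets += list(self.mode_missingness.values())
        for t in targets:
            if t > 0.95:
                raise ConfigError(f"missingness target {t} > 0.95 is infeasible")
        if self.missing_unit not in ("form", "protein"):
            raise ConfigError(f"missing_unit must be 'form' or 'protein', got {self.missing_unit!r}")
        if self.n_differential > self.n_proteins:
            raise ConfigError("n_differential exceeds n_proteins")
        if len(self.groups) != 2:
            raise ConfigError("exactly two workflow arms are supported")


@dataclass
class GroundTruth:
    """Complete latent dataset plus the missingness mask and all truths."""

    config: SimulationConfig
    design: pd.DataFrame
    # one row per (modified form, run): latent abundance + missing flag
    table: pd.DataFrame
    # per-peptide catalog with modification site positions
    peptides: pd.DataFrame
    # (stripped_sequence, ptm_class) x run true occupancies
    occupancy: pd.DataFrame
    differential: dict

    def _aggregate(self, rows: pd.DataFrame, level: str) -> QuantMatrix:
        key = {
            "protein": "protein",
            "peptide_sequence": "stripped_sequence",
            "modified_sequence": "feature_id",
        }[level]
        wide = rows.pivot_table(index=key, columns="run_id", values="abundance",
                                aggfunc="sum")
        wide = wide.reindex(columns=list(self.design["run_id"]))
        wide = wide.sort_index()
        wide.index.name = None
        wide.columns.name = None
        meta = None
        if level == "modified_sequence":
            meta = (
                rows.drop_duplicates("feature_id")
                .set_index("feature_id")[["stripped_sequence", "n_deamidation", "n_oxidation"]]
                .reindex(wide.index)
            )
        return QuantMatrix(values=wide, level=level, scale="raw", feature_meta=meta)

    def latent_matrix(self, level: str) -> QuantMatrix:
        """Complete (pre-masking) abundance matrix at the requested level."""
        return self._aggregate(self.table, level)

    def observed_matrix(self, level: str) -> QuantMatrix:
        """Post-masking matrix: what a search report of this dataset yields."""
        return self._aggregate(self.table[~self.table["missing"]], level)

    def realized_missingness(self) -> float:
        """Realized marginal missing fraction over the configured unit."""
        if self.config.missing_unit == "protein":
            per = self.table.groupby(["protein", "run_id"])["missing"].all()
            return float(per.mean())
        return float(self.table["missing"].mean())


# ---------------------------------------------------------------------------


def _random_peptide(rng: np.random.Generator, cfg: SimulationConfig):
    """One tryptic-like peptide with optional N/Q, M and C sites."""
    length = int(rng.integers(7, 15))
    letters = [str(rng.choice(_AA_POOL)) for _ in range(length - 1)]
    deam_site = ox_site = None
    interior = list(range(1, length - 1))  # keep termini plain
    rng.shuffle(interior)
    slots = list(interior)
    if rng.random() < cfg.prob_deamidation_site and slots:
        pos = slots.pop()
        letters[pos - 1] = "N" if rng.random() < 0.5 else "Q"
        deam_site = pos
    if rng.random() < cfg.prob_oxidation_site and slots:
        pos = slots.pop()
        letters[pos - 1] = "M"
        ox_site = pos
    cys_sites = ()
    if rng.random() < cfg.prob_cys_site and slots:
        pos = slots.pop()
        letters[pos - 1] = "C"
        cys_sites = (pos,)
    letters.append("K" if rng.random() < 0.5 else "R")
    return "".join(letters), deam_site, ox_site, cys_sites


def _calibrate_intercept(x: np.ndarray, target: float, mcar: float, slope: float) -> float | None:
    """Find the logistic intercept so the marginal missing fraction hits target.

    Returns None when the MNAR component is disabled (slope 0) or unneeded
    (the MCAR floor already reaches the target).
    """
    if slope <= 0:
        return None
    need = (target - mcar) / (1.0 - mcar)
    if need <= 0:
        return None
    lo, hi = x.min() - 60.0, x.max() + 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(slope * (mid - x)).mean() < need:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_bone_proteome(config: SimulationConfig) -> GroundTruth:
    """Draw one complete synthetic dataset from the configured model.

    The seed fully determines the output: identical configs give identical
    ground truths, tables and (via :func:`emit_search_report`) report files.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- design: one run per donor per arm, replicate sets A/B -----------
    acq = cfg.acquisition_by_group or {g: "DIA" for g in cfg.groups}
    rows = []
    donors = [f"donor{d + 1:03d}" for d in range(cfg.n_donors)]
    for d in donors:
        for gi, g in enumerate(cfg.groups):
            rep = "AB"[gi]
            rows.append({
                "run_id": f"{d}_{rep}",
                "donor_id": d,
                "replicate_set": rep,
                "group": g,
                "acquisition": acq.get(g, "DIA"),
            })
    design = pd.DataFrame(rows)

    # ---- proteins and peptides ------------------------------------------
    n_coll = max(1, round(cfg.collagen_fraction * cfg.n_proteins))
    prot_ids = [f"COL{i + 1:03d}" if i < n_coll else f"PROT{i + 1:03d}"
                for i in range(cfg.n_proteins)]
    is_coll = np.arange(cfg.n_proteins) < n_coll
    base = np.where(
        is_coll,
        rng.normal(cfg.mu_collagen, cfg.sigma_collagen, cfg.n_proteins),
        rng.normal(cfg.mu_noncollagen, cfg.sigma_noncollagen, cfg.n_proteins),
    )

    diff_idx = rng.choice(cfg.n_proteins, size=cfg.n_differential, replace=False)
    fc = np.zeros(cfg.n_proteins)
    fc[diff_idx] = cfg.log2_fc
    differential = {prot_ids[i]: float(cfg.log2_fc) for i in sorted(diff_idx)}

    lo_pp, hi_pp = cfg.peptides_per_protein
    pep_rows = []
    seen: set[str] = set()
    for pi, prot in enumerate(prot_ids):
        n_pep = int(rng.integers(lo_pp, hi_pp + 1))
        for _ in range(n_pep):
            for _attempt in range(100):
                seq, deam, ox, cys = _random_peptide(rng, cfg)
                if seq not in seen:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a unique peptide sequence")
            seen.add(seq)
            occ_lo, occ_hi = cfg.occupancy_range
            pep_rows.append({
                "protein": prot,
                "stripped_sequence": seq,
                "offset": float(rng.normal(0.0, cfg.peptide_offset_sd)),
                "deam_site": deam,
                "ox_site": ox,
                "cys_sites": cys,
                "deam_occupancy": float(rng.uniform(occ_lo, occ_hi)) if deam else 0.0,
                "ox_occupancy": float(rng.uniform(occ_lo, occ_hi)) if ox else 0.0,
            })
    peptides = pd.DataFrame(pep_rows)

    # ---- latent protein log2 abundance per run ---------------------------
    n_runs = len(design)
    donor_of_run = design["donor_id"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    arm_of_run = design["group"].map({g: i for i, g in enumerate(cfg.groups)}).to_numpy()

    u = rng.normal(0.0, cfg.donor_shift_sd, cfg.n_donors)            # donor global
    v = rng.normal(0.0, cfg.protein_donor_sd, (cfg.n_proteins, cfg.n_donors))
    w = rng.normal(0.0, cfg.run_shift_sd, n_runs)                    # run loading
    eps = rng.normal(0.0, cfg.noise_sd, (cfg.n_proteins, n_runs))

    log2_prot = (
        base[:, None]
        + fc[:, None] * (arm_of_run[None, :] == 1)
        + u[donor_of_run][None, :]
        + v[:, donor_of_run]
        + w[None, :]
        + eps
    )
    prot_index = {p: i for i, p in enumerate(prot_ids)}

    # ---- expand to modified-form rows ------------------------------------
    occ_lo_clip, occ_hi_clip = 0.01, 0.99
    form_rows = []
    occ_records = []
    run_ids = design["run_id"].to_numpy()
    groups_of_run = design["group"].to_numpy()
    donors_of_run = design["donor_id"].to_numpy()

    # iterate over the raw dicts: a DataFrame round-trip would coerce the
    # None site markers to NaN and break the `is None` form logic
    for pep_d in pep_rows:
        pep = SimpleNamespace(**pep_d)
        pi = prot_index[pep.protein]
        pep_ab = np.exp2(log2_prot[pi] + pep.offset)  # per-run total
        # per-run occupancies (arm drift applies to deamidation only)
        p_d = np.zeros(n_runs)
        if pep.deam_site is not None:
            p_d = np.clip(
                pep.deam_occupancy
                + cfg.deamidation_drift * (groups_of_run == cfg.groups[1]),
                occ_lo_clip, occ_hi_clip,
            )
        p_o = np.zeros(n_runs)
        if pep.ox_site is not None:
            p_o = np.full(n_runs, np.clip(pep.ox_occupancy, occ_lo_clip, occ_hi_clip))

        charge = 2 if len(pep.stripped_sequence) <= 12 else 3
        forms = []
        for d_flag in (0, 1):
            if d_flag and pep.deam_site is None:
                continue
            for o_flag in (0, 1):
                if o_flag and pep.ox_site is None:
                    continue
                frac = (p_d if d_flag else 1.0 - p_d) * (p_o if o_flag else 1.0 - p_o)
                forms.append((d_flag, o_flag, frac))
        for d_flag, o_flag, frac in forms:
            tag = []
            if d_flag:
                tag.append("deamidation:1")
            if o_flag:
                tag.append("oxidation:1")
            fid = pep.stripped_sequence + (f"[{';'.join(tag)}]" if tag else "")
            ab = pep_ab * frac
            for ri in range(n_runs):
                form_rows.append({
                    "run_id": run_ids[ri],
                    "donor_id": donors_of_run[ri],
                    "group": groups_of_run[ri],
                    "protein": pep.protein,
                    "stripped_sequence": pep.stripped_sequence,
                    "feature_id": fid,
                    "n_deamidation": d_flag,
                    "n_oxidation": o_flag,
                    "charge": charge,
                    "abundance": float(ab[ri]),
                })
        if pep.deam_site is not None:
            for ri in range(n_runs):
                occ_records.append({
                    "stripped_sequence": pep.stripped_sequence,
                    "ptm_class": "deamidation",
                    "run_id": run_ids[ri],
                    "occupancy": float(p_d[ri]),
                })
        if pep.ox_site is not None:
            for ri in range(n_runs):
                occ_records.append({
                    "stripped_sequence": pep.stripped_sequence,
                    "ptm_class": "oxidation",
                    "run_id": run_ids[ri],
                    "occupancy": float(p_o[ri]),
                })

    table = pd.DataFrame(form_rows)
    occupancy = (
        pd.DataFrame(occ_records)
        .pivot(index=["stripped_sequence", "ptm_class"], columns="run_id", values="occupancy")
        .reindex(columns=list(run_ids))
        if occ_records
        else pd.DataFrame()
    )
    if not occupancy.empty:
        occupancy.columns.name = None

    # ---- missingness ------------------------------------------------------
    table["missing"] = False
    targets = {g: (cfg.mode_missingness or {}).get(g, cfg.target_missingness)
               for g in cfg.groups}
    if cfg.missing_unit == "protein":
        cell = table.groupby(["protein", "run_id"], sort=True).agg(
            log2_ab=("abundance", lambda s: np.log2(s.sum())),
            group=("group", "first"),
        ).reset_index()
        cell["missing"] = _draw_missing(cell, rng, cfg, targets)
        masked = set(map(tuple, cell.loc[cell["missing"], ["protein", "run_id"]].to_numpy()))
        table["missing"] = [
            (p, r) in masked for p, r in zip(table["protein"], table["run_id"])
        ]
    else:
        cell = pd.DataFrame({
            "log2_ab": np.log2(table["abundance"].to_numpy()),
            "group": table["group"].to_numpy(),
        })
        table["missing"] = _draw_missing(cell, rng, cfg, targets)

    return GroundTruth(
        config=cfg,
        design=design,
        table=table,
        peptides=peptides,
        occupancy=occupancy,
        differential=differential,
    )


def _draw_missing(cell: pd.DataFrame, rng: np.random.Generator,
                  cfg: SimulationConfig, targets: dict) -> np.ndarray:
    """Bernoulli missingness per cell: MCAR floor + calibrated MNAR logistic."""
    p = np.full(len(cell), cfg.mcar_rate)
    for g, t in targets.items():
        sel = (cell["group"] == g).to_numpy()
        if not sel.any():
            continue
        x = cell.loc[sel, "log2_ab"].to_numpy()
        x0 = _calibrate_intercept(x, t, cfg.mcar_rate, cfg.mnar_slope)
        if x0 is not None:
            p[sel] = cfg.mcar_rate + (1.0 - cfg.mcar_rate) * expit(cfg.mnar_slope * (x0 - x))
    return rng.random(len(cell)) < p


# ---------------------------------------------------------------------------
# engine-dialect emission
# ---------------------------------------------------------------------------


def _annotate(seq: str, deam_site, ox_site, cys_sites, d_flag: int, o_flag: int,
              engine: str) -> str:
    """Render one form in an engine's modified-sequence notation.

    DIA-NN reports the fixed carbamidomethyl with a UniMod token; MaxQuant
    leaves fixed modifications out of the annotated sequence.
    """
    tokens: dict[int, str] = {}
    if engine == "diann":
        if d_flag:
            tokens[deam_site] = "(UniMod:7)"
        if o_flag:
            tokens[ox_site] = "(UniMod:35)"
        for c in cys_sites:
            tokens[c] = "(UniMod:4)"
    else:
        if d_flag:
            tokens[deam_site] = "(Deamidation (NQ))"
        if o_flag:
            tokens[ox_site] = "(Oxidation (M))"
    out = []
    for i, ch in enumerate(seq, start=1):
        out.append(ch)
        if i in tokens:
            out.append(tokens[i])
    body = "".join(out)
    return f"_{body}_" if engine == "maxquant" else body


def emit_search_report(truth: GroundTruth, engine: str, outdir) -> dict:
    """Write the observed precursors as a DIA-NN report.tsv or MaxQuant
    evidence.txt, plus the design table.  Returns the paths written."""
    if engine not in ("diann", "maxquant"):
        raise ValueError(f"unsupported engine {engine!r}")
    os.makedirs(outdir, exist_ok=True)
    obs = truth.table[~truth.table["missing"]]
    pep_info = truth.peptides.set_index("stripped_sequence")

    rows = []
    for r in obs.itertuples(index=False):
        info = pep_info.loc[r.stripped_sequence]
        deam_site = None if pd.isna(info["deam_site"]) else int(info["deam_site"])
        ox_site = None if pd.isna(info["ox_site"]) else int(info["ox_site"])
        modseq = _annotate(
            r.stripped_sequence, deam_site, ox_site,
            info["cys_sites"], r.n_deamidation, r.n_oxidation, engine,
        )
        if engine == "diann":
            rows.append({
                "Run": r.run_id,
                "Protein.Group": r.protein,
                "Stripped.Sequence": r.stripped_sequence,
                "Modified.Sequence": modseq,
                "Precursor.Charge": r.charge,
                "Precursor.Quantity": repr(float(r.abundance)),
            })
        else:
            mods = []
            if r.n_deamidation:
                mods.append("Deamidation (NQ)")
            if r.n_oxidation:
                mods.append("Oxidation (M)")
            rows.append({
                "Sequence": r.stripped_sequence,
                "Modified sequence": modseq,
                "Modifications": ",".join(mods) if mods else "Unmodified",
                "Proteins": r.protein,
                "Charge": r.charge,
                "Intensity": repr(float(r.abundance)),
                "Raw file": r.run_id,
                "Reverse": "",
                "Potential contaminant": "",
            })
    fname = "report.tsv" if engine == "diann" else "evidence.txt"
    report_path = os.path.join(outdir, fname)
    pd.DataFrame(rows).to_csv(report_path, sep="\t", index=False)
    design_path = os.path.join(outdir, "design.csv")
    truth.design.to_csv(design_path, index=False)
    return {"report": report_path, "design": design_path}


def write_truth(truth: GroundTruth, outdir) -> dict:
    """Serialize the ground truth next to an emitted dataset."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for level in ("protein", "peptide_sequence", "modified_sequence"):
        p = os.path.join(outdir, f"truth_latent_{level}.tsv")
        truth.latent_matrix(level).to_tsv(p)
        paths[f"latent_{level}"] = p
    tab = os.path.join(outdir, "truth_precursors.tsv")
    truth.table.to_csv(tab, sep="\t", index=False)
    paths["precursors"] = tab
    if not truth.occupancy.empty:
        occ = os.path.join(outdir, "truth_occupancy.tsv")
        truth.occupancy.to_csv(occ, sep="\t")
        paths["occupancy"] = occ
    meta = {
        "differential": truth.differential,
        "realized_missingness": truth.realized_missingness(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(truth.config).items()},
    }
    mpath = os.path.join(outdir, "truth.json")
    with open(mpath, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    paths["meta"] = mpath
    return paths
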