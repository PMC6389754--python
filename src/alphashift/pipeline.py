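"""End-to-end orchestration: simulate-or-load through to classification.

A :class:`RunConfig` fully determines one run: input paths or a
simulation design, spectral and map parameters, permutation and
classification settings, and a master seed.  ``run_pipeline`` executes
spectra -> shifts -> grand-average statistics -> scalp maps ->
permutation inference -> effect sizes -> classification, writes every
intermediate artifact as delimited text, and returns a manifest with a
config hash so identical configs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm_stats, io
from .classify import auc_z_test, cross_validate
from .montage import standard_1020_layout
from .permmap import (PermutationSpec, effect_size_map, freedman_lane,
                      nearest_electrode)
from .scalpmap import interpolate_map, smooth_map, subject_maps_matrix
from .spectra import alpha_shift, power_spectrum, rereference_common_average
from .synthcohort import (CohortDesign, OscillatorSpec, default_design,
                          generate_cohort)

log = logging.getLogger("alphashift")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    # inputs: either a directory of EEG files + covariate table, or simulate
    eeg_dir: str | None = None
    covariates: str | None = None
    simulate: bool = True
    n_per_group: dict = field(
        default_factory=lambda: {"HS": 39, "GSC": 25, "PSC": 38})
    peak_freq: dict = field(
        default_factory=lambda: {"HS": 10.5, "GSC": 10.0, "PSC": 8.0})
    anterior_spread: dict = field(
        default_factory=lambda: {"HS": 0.15, "GSC": 0.25, "PSC": 0.60})
    # spectral parameters
    pad_factor: int = 2
    epoch_len: float = 1.0
    overlap: float = 0.9
    low_band: tuple = (6, 9)
    high_band: tuple = (10, 11)
    # maps
    grid_n: int = 32
    smooth_sigma_mm: float = 8.0
    # inference
    n_perm: int = 1000
    n_boot: int = 1000
    # classification
    n_folds: int = 10
    n_repeats: int = 100
    # misc
    seed: int = 0
    expected_fs: float = 256.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.low_band = tuple(cfg.low_band)
        cfg.high_band = tuple(cfg.high_band)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def design(self) -> CohortDesign:
        base = default_design(seed=self.seed)
        oscs = {}
        for g, osc in base.group_oscillators.items():
            oscs[g] = dataclasses.replace(
                osc, peak_freq=self.peak_freq.get(g, osc.peak_freq),
                anterior_spread=self.anterior_spread.get(
                    g, osc.anterior_spread))
        groups = {g: int(n) for g, n in self.n_per_group.items()}
        return dataclasses.replace(base, n_per_group=groups,
                                   group_oscillators=oscs, seed=self.seed)


def _load_inputs(cfg: RunConfig):
    layout = standard_1020_layout()
    if cfg.simulate:
        segments, table = generate_cohort(cfg.design(), layout)
        return segments, table, layout
    if not cfg.eeg_dir or not cfg.covariates:
        raise ValueError("non-simulated run requires eeg_dir and covariates")
    table = io.read_covariates(cfg.covariates)
    eeg_dir = Path(cfg.eeg_dir)
    files = {p.stem: p for p in sorted(eeg_dir.iterdir())
             if p.suffix.lower() in (".edf", ".tsv", ".txt")}
    ids = list(table["subject_id"].astype(str))
    missing = sorted(set(ids) - set(files))
    extra = sorted(set(files) - set(ids))
    if missing or extra:
        raise ValueError(
            f"EEG/covariate mismatch; missing EEG for {missing}, "
            f"EEG without covariates for {extra}")
    segments = []
    for sid in ids:
        seg = io.read_eeg(files[sid])
        if abs(seg.fs - cfg.expected_fs) > 1e-6:
            raise ValueError(
                f"{files[sid].name}: sampling rate {seg.fs} Hz differs from "
                f"{cfg.expected_fs} Hz; resampling is not supported")
        segments.append(seg)
    if "cohort_group" not in table.columns:
        table = table.copy()
        table["cohort_group"] = np.where(
            table["group"] == "HS", "HS", table["seizure_control"])
    return segments, table, layout


def _stratum(table: pd.DataFrame) -> np.ndarray:
    return table["cohort_group"].to_numpy()


def _two_group_design(table, a_mask, b_mask, covariate_cols):
    """Effects-coded two-group design: [intercept, group(+1=a), covs]."""
    sel = a_mask | b_mask
    sub = table.loc[sel]
    X = pd.DataFrame({"intercept": np.ones(sel.sum())}, index=sub.index)
    X["group"] = np.where(a_mask[sel], 1.0, -1.0)
    for c in covariate_cols:
        if c == "gender":
            X[c] = np.where(sub[c] == "F", 1.0, -1.0)
        else:
            X[c] = sub[c].to_numpy(dtype=float)
    return X.to_numpy(), sel


def _map_contrasts(table):
    """The three pair-wise map comparisons: (name, a, b, covariates)."""
    strat = _stratum(table)
    is_pat = (table["group"] == "patient").to_numpy()
    return [
        ("PAT_gt_HS", is_pat, strat == "HS", ["age", "gender"]),
        ("PSC_gt_GSC", strat == "PSC", strat == "GSC",
         ["age", "gender", "aed_load"]),
        ("FE_gt_IGE", (table["syndrome"] == "FE").to_numpy(),
         (table["syndrome"] == "IGE").to_numpy(),
         ["age", "gender", "aed_load"]),
    ]


def cohort_table_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Demographics tests across the three strata (cohort-table style)."""
    strat = _stratum(table)
    rows = []
    counts = pd.crosstab(table["gender"], strat)
    chi2, df, p = glm_stats.chi_square_independence(counts.to_numpy())
    rows.append({"variable": "female_sex", "test": "chi2",
                 "statistic": chi2, "df": df, "p": p})
    ages = [table.loc[strat == g, "age"] for g in ("HS", "GSC", "PSC")]
    H, p = glm_stats.kruskal_wallis(ages)
    rows.append({"variable": "age", "test": "kruskal", "statistic": H,
                 "df": np.nan, "p": p})
    aed = [table.loc[strat == g, "aed_load"] for g in ("GSC", "PSC")]
    U, p = glm_stats.mann_whitney_u(*aed)
    rows.append({"variable": "aed_load", "test": "mannwhitney",
                 "statistic": U, "df": np.nan, "p": p})
    pat = table[table["group"] == "patient"]
    syn = pd.crosstab(pat["syndrome"] == "FE", pat["seizure_control"])
    chi2, df, p = glm_stats.chi_square_independence(syn.to_numpy())
    rows.append({"variable": "fe_syndrome", "test": "chi2",
                 "statistic": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)


def grand_average_stats(table: pd.DataFrame, global_shift: np.ndarray,
                        n_boot: int = 1000, seed: int = 0) -> dict:
    """One-way + factorial ANCOVA with assumption checks and contrasts."""
    strat = _stratum(table)
    shift = np.asarray(global_shift, dtype=float)
    age = table["age"].to_numpy(dtype=float)
    gender = table["gender"].to_numpy()

    oneway = glm_stats.ancova_oneway(shift, strat, age, gender)
    levene = glm_stats.levene_test(shift, strat)
    slopes_age = glm_stats.slope_homogeneity(shift, strat, age)
    is_pat = (table["group"] == "patient").to_numpy()
    contrasts = {
        "PAT_vs_HS": glm_stats.pooled_t(shift[is_pat], shift[~is_pat],
                                        n_boot=n_boot, seed=seed),
        "PSC_vs_GSC": glm_stats.pooled_t(shift[strat == "PSC"],
                                         shift[strat == "GSC"],
                                         n_boot=n_boot, seed=seed + 1),
    }
    bonferroni = len(contrasts)
    for r in contrasts.values():
        r.p = min(1.0, r.p * bonferroni)

    pat = table[is_pat]
    try:
        factorial = glm_stats.ancova_factorial(
            shift[is_pat], pat["syndrome"].to_numpy(),
            pat["seizure_control"].to_numpy(),
            pat["age"].to_numpy(dtype=float), pat["gender"].to_numpy(),
            pat["aed_load"].to_numpy(dtype=float))
    except ValueError as err:  # e.g. an empty syndrome x control cell
        log.warning("factorial ANCOVA skipped: %s", err)
        factorial = []
    fe = (pat["syndrome"] == "FE").to_numpy()
    if 2 <= fe.sum() <= len(fe) - 2:
        contrasts["FE_vs_IGE"] = glm_stats.pooled_t(
            shift[is_pat][fe], shift[is_pat][~fe], n_boot=n_boot,
            seed=seed + 2)
    return {"oneway": oneway, "levene": levene,
            "slope_homogeneity_age": slopes_age, "contrasts": contrasts,
            "factorial": factorial}


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the manifest (also written)."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def _mark(stage):
        timings[stage] = round(time.time() - t0, 2)
        log.info("stage %-14s done at %6.1fs", stage, timings[stage])

    segments, table, layout = _load_inputs(cfg)
    ids = list(table["subject_id"].astype(str))
    _mark("inputs")

    spectra = []
    profiles = []
    for seg in segments:
        ps = power_spectrum(rereference_common_average(seg),
                            pad_factor=cfg.pad_factor,
                            epoch_len=cfg.epoch_len, overlap=cfg.overlap)
        spectra.append(ps)
        profiles.append(alpha_shift(ps, cfg.low_band, cfg.high_band))
    io.write_covariates(table, out / "cohort.tsv")
    io.write_spectra(spectra, ids, out / "spectra.tsv")
    io.write_shifts(profiles, ids, out / "shifts.tsv")
    _mark("spectra")

    cohort_table_stats(table).to_csv(out / "cohort_stats.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    global_shift = np.array([p.global_log2_shift for p in profiles])
    stats = grand_average_stats(table, global_shift, n_boot=cfg.n_boot,
                                seed=cfg.seed)
    rows = [dataclasses.asdict(stats["oneway"])]
    rows += [dataclasses.asdict(r) for r in stats["factorial"]]
    pd.DataFrame(rows).to_csv(out / "ancova.tsv", sep="\t", index=False,
                              float_format="%.6g")
    crows = []
    for name, r in stats["contrasts"].items():
        crows.append({"contrast": name, "t": r.t, "df": r.df, "p": r.p,
                      "g": r.g, "g_ci_low": r.g_ci[0] if r.g_ci else np.nan,
                      "g_ci_high": r.g_ci[1] if r.g_ci else np.nan})
    pd.DataFrame(crows).to_csv(out / "contrasts.tsv", sep="\t", index=False,
                               float_format="%.6g")
    _mark("stats")

    maps = [smooth_map(interpolate_map(p.per_channel_log2_shift, layout,
                                       cfg.grid_n), cfg.smooth_sigma_mm)
            for p in profiles]
    Y = subject_maps_matrix(maps)
    template = maps[0]
    strat = _stratum(table)
    summary_rows = []
    for k, (name, a, b, covs) in enumerate(_map_contrasts(table)):
        X, sel = _two_group_design(table, a, b, covs)
        contrast = np.zeros(X.shape[1])
        contrast[1] = 1.0
        vg = np.where(a[sel], "a", "b")
        res = freedman_lane(
            Y[sel], X, contrast,
            PermutationSpec(n_perm=cfg.n_perm, seed=cfg.seed + 100 + k),
            variance_groups=vg, layout=layout)
        res.template = template
        res.peak_xy = template.node_xy()[res.peak_index]
        res.peak_electrode = nearest_electrode(res.peak_xy, layout)
        g, ci, _ = effect_size_map(Y[sel][a[sel]], Y[sel][b[sel]],
                                   n_boot=cfg.n_boot, seed=cfg.seed + 200 + k)
        io.write_map(res.t_map(), out / f"map_{name}_t")
        io.write_map(res.p_fwe_map(), out / f"map_{name}_pfwe")
        io.write_map(template.with_values(g), out / f"map_{name}_g")
        pk = res.peak_index
        summary_rows.append({
            "contrast": name, "peak_t": res.peak_stat,
            "peak_df": res.peak_df, "p_fwe": res.p_fwe[pk],
            "g": g[pk], "g_ci_low": ci[0, pk], "g_ci_high": ci[1, pk],
            "nearest_electrode": res.peak_electrode,
            "n_sig_nodes_fwe05": int((res.p_fwe < 0.05).sum())})
    pd.DataFrame(summary_rows).to_csv(out / "map_summary.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    _mark("maps")

    pat_sel = np.isin(strat, ["GSC", "PSC"])
    feats = np.stack([p.per_channel_log2_shift for p in profiles])[pat_sel]
    labels = (strat[pat_sel] == "PSC").astype(int)
    report = cross_validate(feats, labels, n_folds=cfg.n_folds,
                            n_repeats=cfg.n_repeats, seed=cfg.seed)
    # out-of-fold scores from one deterministic repeat for the AUC z-test
    from sklearn.model_selection import StratifiedKFold

    from .classify import lda_train
    scores = np.empty(len(labels))
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=cfg.seed)
    for train, test in skf.split(feats, labels):
        scores[test] = lda_train(feats[train], labels[train]).scores(
            feats[test])
    z, zp = auc_z_test(scores, labels)
    cls = {"sensitivity": report.sensitivity, "specificity":
           report.specificity, "auc": report.auc,
           "n_folds": report.n_folds, "n_repeats": report.n_repeats,
           "auc_z": z, "auc_z_p": zp}
    (out / "classification.json").write_text(json.dumps(cls, indent=1))
    _mark("classify")

    manifest = {
        "config": cfg.to_dict(), "config_hash": cfg.hash(),
        "seed": cfg.seed, "n_subjects": len(ids),
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "manifest.json"),
    }
    log.info("stage timings (s): %s", timings)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
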