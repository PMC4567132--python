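"""Synthetic endometrial-carcinoma cohorts with known ground-truth XCI states.

The generator emulates the joint structure the inference pipeline exploits:

* **preserved Xi** — X CpG islands about half-methylated (one methylated Xi
  plus one unmethylated Xa), high XIST;
* **Xa+** (partial reactivation of Xi) — partially demethylated X islands,
  XIST still high;
* **two Xa** — X-wide island hypomethylation, low XIST, and *no* whole-X
  deletion;
* a small fraction of preserved-Xi tumors carry a deletion of one arm of the
  inactive X: that arm's island probes drop to two-Xa methylation levels and
  the copy-number profile shows an arm-level loss, while XIST stays high;
* global (autosomal) CpG-island methylation decreases along
  preserved > Xa+ > two Xa, and cancer-testis-antigen expression is log-linear
  in global *hypo*methylation — not in XCI state per se — so that the CTA/XCI
  association downstream is confounded by global methylation, by construction;
* survival is exponential with clinical stage as a confounder plus a
  proportional-hazards effect of XCI loss (default hazard ratio 1.6).

Beta values are drawn from Beta distributions parameterized by a mean and a
concentration (pseudo-count) so state separation is tunable; XIST and CTA
expression are log-normal on the log2(RSEM+1) scale. Everything is generated
from a single :class:`numpy.random.Generator`, so a config plus seed is fully
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    AUTOSOMES,
    ClinicalTable,
    CnvSegmentSet,
    CTAPanel,
    ExpressionMatrix,
    HISTOLOGIES,
    MethylationMatrix,
    ProbeManifest,
    ValidationError,
    XCI_GROUPS,
)

#: Default per-state stage distribution (I_II, III, IV): stage is the survival
#: confounder, more advanced in the XCI-loss states.
_DEFAULT_STAGE_DIST: dict[str, tuple[float, float, float]] = {
    "preserved_Xi": (0.744, 0.203, 0.053),
    "Xa_plus": (0.667, 0.294, 0.039),
    "two_Xa": (0.632, 0.263, 0.105),
}

_DEFAULT_AGE: dict[str, tuple[float, float]] = {
    "preserved_Xi": (62.2, 11.4),
    "Xa_plus": (69.8, 9.1),
    "two_Xa": (68.9, 8.8),
}

_DEFAULT_MENOPAUSE: dict[str, tuple[float, float, float]] = {
    # (post, pre, peri)
    "preserved_Xi": (0.841, 0.099, 0.060),
    "Xa_plus": (0.980, 0.020, 0.0),
    "two_Xa": (0.970, 0.0, 0.030),
}

_DEFAULT_RACE: dict[str, tuple[float, float, float]] = {
    # (white, black, asian)
    "preserved_Xi": (0.782, 0.165, 0.053),
    "Xa_plus": (0.729, 0.229, 0.042),
    "two_Xa": (0.778, 0.222, 0.0),
}

_DEFAULT_ETHNICITY: dict[str, float] = {
    # P(hispanic)
    "preserved_Xi": 0.024,
    "Xa_plus": 0.053,
    "two_Xa": 0.065,
}

_DEFAULT_RESIDUAL: dict[str, tuple[float, float, float, float]] = {
    # (R0, R1, R2, RX)
    "preserved_Xi": (0.823, 0.053, 0.040, 0.084),
    "Xa_plus": (0.783, 0.043, 0.065, 0.109),
    "two_Xa": (0.788, 0.121, 0.030, 0.061),
}

_DEFAULT_SUBTYPE: dict[str, tuple[float, float, float, float]] = {
    # (CN_high, CN_low, MSI, POLE) by histology
    "endometrioid": (0.10, 0.50, 0.30, 0.10),
    "serous": (0.85, 0.05, 0.05, 0.05),
}

XCTA_PANEL_SIZE = 48
CTA_AUTOSOMAL_PANEL_SIZE = 8


def _default_cell_counts() -> dict[tuple[str, str], int]:
    return {(h, s): 60 for h in HISTOLOGIES for s in XCI_GROUPS}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions.

    ``n_samples`` maps (histology, true state) to a sample count. XIST log
    means per state (7.9 / 8.3 / 5.4 on the log2(RSEM+1) scale) and the
    XCI-loss log hazard ratio (ln 1.6) anchor the generated cohort to typical
    endometrial-carcinoma values.
    """

    seed: int
    n_samples: Mapping[tuple[str, str], int] = field(default_factory=_default_cell_counts)
    # probe layout
    n_x_island_probes: int = 500
    n_x_nonisland_probes: int = 50
    n_autosomal_island_probes: int = 2000
    centromere_bp: int = 60_000_000
    chromosome_length: int = 155_000_000
    # X CpG-island methylation per true state
    preserved_xi_x_mean: float = 0.45
    xa_plus_x_mean: float = 0.25
    two_xa_x_mean: float = 0.10
    beta_concentration: float = 50.0
    # XIST expression (log2(RSEM+1) scale)
    xist_log_mean: Mapping[str, float] = field(
        default_factory=lambda: {"preserved_Xi": 7.9, "Xa_plus": 8.3, "two_Xa": 5.4}
    )
    xist_log_sd: float = 1.0
    # autosomal (global) CpG-island methylation per state
    autosomal_island_mean: Mapping[str, float] = field(
        default_factory=lambda: {"preserved_Xi": 0.35, "Xa_plus": 0.28, "two_Xa": 0.25}
    )
    # CTA expression: log2(RSEM+1) = cta_slope * (1 - global methylation) + noise
    cta_slope: float = 6.0
    cta_noise_sd: float = 0.5
    # Xi-arm deletions (within the preserved-Xi state)
    xi_arm_deletion_fraction: float = 0.05
    seg_mean_deleted: float = -0.8
    seg_mean_neutral_sd: float = 0.05
    # survival
    baseline_hazard_per_day: float = 2.5e-4
    log_hr_stage_iii: float = math.log(4.24)
    log_hr_stage_iv: float = math.log(7.31)
    log_hr_xci_loss: float = math.log(1.6)
    stage_dist: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_STAGE_DIST)
    )
    censor_low_days: float = 365.0
    censor_high_days: float = 3650.0
    # optional missingness (off by default)
    missing_beta_fraction: float = 0.0
    missing_xist_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("preserved_xi_x_mean", "xa_plus_x_mean", "two_xa_x_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (0, 1)")
        for state, m in self.autosomal_island_mean.items():
            if not 0.0 < m < 1.0:
                raise ValidationError(f"autosomal mean for {state} must lie in (0, 1)")
        if any(n < 0 for n in self.n_samples.values()):
            raise ValidationError("sample counts must be >= 0")
        if sum(self.n_samples.values()) == 0:
            raise ValidationError("every cohort cell is empty")
        if not 0.0 <= self.xi_arm_deletion_fraction <= 1.0:
            raise ValidationError("xi_arm_deletion_fraction must lie in [0, 1]")

    @property
    def x_state_mean(self) -> dict[str, float]:
        return {
            "preserved_Xi": self.preserved_xi_x_mean,
            "Xa_plus": self.xa_plus_x_mean,
            "two_Xa": self.two_xa_x_mean,
        }


@dataclass(frozen=True)
class TrueState:
    """Ground truth of a generated cohort: one row per sample.

    Columns: ``true_xci`` (state label) and ``xi_arm_deleted``
    (``none``/``p``/``q``), indexed by sample id.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in TrueState")
        bad = set(self.df["true_xci"]) - set(XCI_GROUPS)
        if bad:
            raise ValidationError(f"unknown true state(s) {sorted(bad)}")


def truth_table(state: TrueState) -> pd.DataFrame:
    """Ground truth as a plain table (sample_id, true_xci, xi_arm_deleted)."""
    return state.df.reset_index().rename(columns={"index": "sample_id"})


def default_panels() -> tuple[CTAPanel, CTAPanel]:
    """The two CTA panels every generated cohort expresses."""
    xcta = CTAPanel(
        name="XCTA",
        gene_ids=tuple(f"XCTA_{i:02d}" for i in range(1, XCTA_PANEL_SIZE + 1)),
        location="X_linked",
    )
    cta_auto = CTAPanel(
        name="CTA_autosomal",
        gene_ids=tuple(f"CTA_A{i:02d}" for i in range(1, CTA_AUTOSOMAL_PANEL_SIZE + 1)),
        location="autosomal",
    )
    return xcta, cta_auto


def _build_manifest(cfg: SimulationConfig) -> ProbeManifest:
    rows = []
    x_pos = np.linspace(1, cfg.chromosome_length, cfg.n_x_island_probes)
    for i, pos in enumerate(x_pos):
        rows.append(
            {"probe_id": f"cgX{i:05d}", "chromosome": "chrX",
             "position": int(round(pos)), "cpg_island": True}
        )
    ni_pos = np.linspace(1000, cfg.chromosome_length - 1000, max(cfg.n_x_nonisland_probes, 1))
    for i in range(cfg.n_x_nonisland_probes):
        rows.append(
            {"probe_id": f"cgXn{i:05d}", "chromosome": "chrX",
             "position": int(round(ni_pos[i])) + 13, "cpg_island": False}
        )
    for i in range(cfg.n_autosomal_island_probes):
        chrom = AUTOSOMES[i % len(AUTOSOMES)]
        rows.append(
            {"probe_id": f"cgA{i:05d}", "chromosome": chrom,
             "position": 1_000_000 + 1_000 * (i // len(AUTOSOMES)), "cpg_island": True}
        )
    return ProbeManifest(pd.DataFrame(rows))


def _draw_beta(rng: np.random.Generator, mean: np.ndarray, concentration: float) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, ExpressionMatrix, CnvSegmentSet, ClinicalTable, ProbeManifest, TrueState]:
    """Generate a complete synthetic cohort from ``config``.

    Returns methylation, expression, copy-number segments, clinical table,
    probe manifest and ground-truth state. Deterministic given the config
    (including its seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    manifest = _build_manifest(cfg)

    # --- sample sheet ------------------------------------------------------
    records = []
    for hist in HISTOLOGIES:
        for state in XCI_GROUPS:
            n = cfg.n_samples.get((hist, state), 0)
            for _ in range(n):
                records.append({"histology": hist, "true_xci": state})
    samples = pd.DataFrame(records)
    samples["sample_id"] = [f"S{i + 1:04d}" for i in range(len(samples))]
    samples = samples.set_index("sample_id")

    # Xi-arm deletions occur only in preserved-Xi tumors: the deletion removes
    # one arm of the *inactive* X, so the remaining Xi is intact and the truth
    # label stays preserved_Xi.
    deleted_arm = np.full(len(samples), "none", dtype=object)
    preserved_idx = np.flatnonzero((samples["true_xci"] == "preserved_Xi").to_numpy())
    if cfg.xi_arm_deletion_fraction > 0 and len(preserved_idx):
        hit = preserved_idx[
            rng.random(len(preserved_idx)) < cfg.xi_arm_deletion_fraction
        ]
        deleted_arm[hit] = rng.choice(["p", "q"], size=len(hit))
    samples["xi_arm_deleted"] = deleted_arm

    n_samples = len(samples)
    state_arr = samples["true_xci"].to_numpy()

    # --- methylation -------------------------------------------------------
    mdf = manifest.df
    x_island = mdf[(mdf["chromosome"] == "chrX") & mdf["cpg_island"]]
    x_nonisland = mdf[(mdf["chromosome"] == "chrX") & ~mdf["cpg_island"]]
    auto_island = mdf[(mdf["chromosome"] != "chrX") & mdf["cpg_island"]]

    x_mean = np.empty((len(x_island), n_samples))
    state_mean = cfg.x_state_mean
    for j in range(n_samples):
        x_mean[:, j] = state_mean[state_arr[j]]
        arm = deleted_arm[j]
        if arm != "none":
            on_p = (x_island["position"] <= cfg.centromere_bp).to_numpy()
            arm_mask = on_p if arm == "p" else ~on_p
            x_mean[arm_mask, j] = cfg.two_xa_x_mean
    x_beta = _draw_beta(rng, x_mean, cfg.beta_concentration)

    # non-island X probes carry no XCI signal
    xn_beta = _draw_beta(
        rng, np.full((len(x_nonisland), n_samples), 0.5), 10.0
    )

    auto_mean = np.empty((len(auto_island), n_samples))
    for j in range(n_samples):
        auto_mean[:, j] = cfg.autosomal_island_mean[state_arr[j]]
    auto_beta = _draw_beta(rng, auto_mean, cfg.beta_concentration)

    beta = np.vstack([x_beta, xn_beta, auto_beta])
    probe_order = list(x_island["probe_id"]) + list(x_nonisland["probe_id"]) + list(auto_island["probe_id"])
    if cfg.missing_beta_fraction > 0:
        mask = rng.random(beta.shape) < cfg.missing_beta_fraction
        beta = beta.copy()
        beta[mask] = np.nan
    methylation = MethylationMatrix(
        pd.DataFrame(beta, index=probe_order, columns=samples.index)
    )

    # global (autosomal-island) methylation per sample drives CTA expression
    global_meth = np.nanmean(auto_beta, axis=0)

    # --- expression --------------------------------------------------------
    xist_log = np.array(
        [rng.normal(cfg.xist_log_mean[s], cfg.xist_log_sd) for s in state_arr]
    )
    xist_rsem = np.maximum(np.exp2(xist_log) - 1.0, 0.0)
    if cfg.missing_xist_fraction > 0:
        drop = rng.random(n_samples) < cfg.missing_xist_fraction
        xist_rsem[drop] = np.nan

    xcta_panel, cta_auto_panel = default_panels()
    cta_genes = list(xcta_panel.gene_ids) + list(cta_auto_panel.gene_ids)
    cta_log = (
        cfg.cta_slope * (1.0 - global_meth)[None, :]
        + rng.normal(0.0, cfg.cta_noise_sd, size=(len(cta_genes), n_samples))
    )
    cta_rsem = np.maximum(np.exp2(cta_log) - 1.0, 0.0)

    bg_genes = [f"BG_{i:03d}" for i in range(1, 51)]
    bg_rsem = np.maximum(
        np.exp2(rng.normal(5.0, 1.0, size=(len(bg_genes), n_samples))) - 1.0, 0.0
    )

    expr = pd.DataFrame(
        np.vstack([xist_rsem[None, :], cta_rsem, bg_rsem]),
        index=["XIST"] + cta_genes + bg_genes,
        columns=samples.index,
    )
    expression = ExpressionMatrix(expr)

    # --- copy number -------------------------------------------------------
    seg_rows = []
    for j, sid in enumerate(samples.index):
        arm = deleted_arm[j]
        if arm == "none":
            seg_rows.append(
                (sid, "chrX", 1, cfg.chromosome_length,
                 float(rng.normal(0.0, cfg.seg_mean_neutral_sd)))
            )
        else:
            p_mean = (
                cfg.seg_mean_deleted if arm == "p"
                else float(rng.normal(0.0, cfg.seg_mean_neutral_sd))
            )
            q_mean = (
                cfg.seg_mean_deleted if arm == "q"
                else float(rng.normal(0.0, cfg.seg_mean_neutral_sd))
            )
            seg_rows.append((sid, "chrX", 1, cfg.centromere_bp, p_mean))
            seg_rows.append(
                (sid, "chrX", cfg.centromere_bp + 1, cfg.chromosome_length, q_mean)
            )
    segments = CnvSegmentSet(
        pd.DataFrame(seg_rows, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])
    )

    # --- clinical + survival ----------------------------------------------
    from .types import MENOPAUSE_LEVELS, RACE_LEVELS, RESIDUAL_LEVELS, STAGES, TCGA_SUBTYPES

    age = np.array(
        [rng.normal(*_DEFAULT_AGE[s]) for s in state_arr]
    ).clip(30, 95)
    stage = np.array(
        [rng.choice(STAGES, p=np.asarray(cfg.stage_dist[s]) / sum(cfg.stage_dist[s]))
         for s in state_arr],
        dtype=object,
    )
    menopause = np.array(
        [rng.choice(MENOPAUSE_LEVELS, p=np.asarray(_DEFAULT_MENOPAUSE[s]) / sum(_DEFAULT_MENOPAUSE[s]))
         for s in state_arr],
        dtype=object,
    )
    race = np.array(
        [rng.choice(RACE_LEVELS, p=np.asarray(_DEFAULT_RACE[s]) / sum(_DEFAULT_RACE[s]))
         for s in state_arr],
        dtype=object,
    )
    ethnicity = np.array(
        ["hispanic" if rng.random() < _DEFAULT_ETHNICITY[s] else "non_hispanic"
         for s in state_arr],
        dtype=object,
    )
    residual = np.array(
        [rng.choice(RESIDUAL_LEVELS, p=np.asarray(_DEFAULT_RESIDUAL[s]) / sum(_DEFAULT_RESIDUAL[s]))
         for s in state_arr],
        dtype=object,
    )
    subtype = np.array(
        [rng.choice(TCGA_SUBTYPES,
                    p=np.asarray(_DEFAULT_SUBTYPE[h]) / sum(_DEFAULT_SUBTYPE[h]))
         for h in samples["histology"]],
        dtype=object,
    )

    log_hr = np.zeros(n_samples)
    log_hr += np.where(stage == "III", cfg.log_hr_stage_iii, 0.0)
    log_hr += np.where(stage == "IV", cfg.log_hr_stage_iv, 0.0)
    log_hr += np.where(state_arr != "preserved_Xi", cfg.log_hr_xci_loss, 0.0)
    rate = cfg.baseline_hazard_per_day * np.exp(log_hr)

    def _survival_pair() -> tuple[np.ndarray, np.ndarray]:
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(cfg.censor_low_days, cfg.censor_high_days, n_samples)
        event = event_time <= censor_time
        time = np.minimum(event_time, censor_time)
        return np.round(time, 1), event

    os_time, os_event = _survival_pair()
    dfs_time, dfs_event = _survival_pair()

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "histology": samples["histology"],
                "tcga_subtype": subtype,
                "age": np.round(age, 1),
                "stage": stage,
                "menopause": menopause,
                "race": race,
                "ethnicity": ethnicity,
                "residual": residual,
                "os_time": os_time,
                "os_event": os_event,
                "dfs_time": dfs_time,
                "dfs_event": dfs_event,
            },
            index=samples.index,
        )
    )

    truth = TrueState(samples[["true_xci", "xi_arm_deleted"]].copy())
    return methylation, expression, segments, clinical, manifest, truth
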