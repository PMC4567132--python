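"""End-to-end orchestration: simulate -> classify -> associate -> outcomes.

A single YAML config drives the run; all randomness flows from its root
``seed``. Each stage writes plain-text artifacts into ``outdir`` and the run
ends with a JSON manifest recording the package version, seed, a hash of the
config, and per-stage output files with row counts — reruns of the same
config + seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io_formats as iof
from .association_stats import expression_by_group_table, compare_groups, mean_cpg_methylation
from .clinical_outcomes import (
    anova_by_group,
    cox_stage_adjusted,
    crosstab,
    fisher_exact_rxc,
    km_logrank,
)
from .synthetic_cohort import SimulationConfig, default_panels, generate_cohort, truth_table
from .types import ValidationError
from .xci_inference import InferenceConfig, classify_cohort, select_probes

logger = logging.getLogger(__name__)

_CATEGORICAL_FIELDS = (
    "histology",
    "tcga_subtype",
    "stage",
    "menopause",
    "race",
    "ethnicity",
    "residual",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    seed: int
    outdir: Path
    simulate: bool = True
    simulation: SimulationConfig | None = None
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    paths: Mapping[str, str] = field(default_factory=dict)
    raw: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValidationError("pipeline config requires a seed")
        if "outdir" not in raw:
            raise ValidationError("pipeline config requires an outdir")
        seed = int(raw["seed"])
        simulate = bool(raw.get("simulate", True))
        sim_cfg = None
        if simulate:
            sim_block = dict(raw.get("simulation", {}))
            cells = sim_block.pop("n_samples", None)
            kwargs: dict[str, Any] = {"seed": seed}
            if cells is not None:
                kwargs["n_samples"] = {
                    (h, s): int(n)
                    for h, states in cells.items()
                    for s, n in states.items()
                }
            known = {f.name for f in dataclasses.fields(SimulationConfig)}
            unknown = set(sim_block) - known
            if unknown:
                raise ValidationError(f"unknown simulation keys {sorted(unknown)}")
            kwargs.update(sim_block)
            sim_cfg = SimulationConfig(**kwargs)
        inf_block = dict(raw.get("inference", {}))
        known = {f.name for f in dataclasses.fields(InferenceConfig)}
        unknown = set(inf_block) - known
        if unknown:
            raise ValidationError(f"unknown inference keys {sorted(unknown)}")
        inference = InferenceConfig(**inf_block)
        paths = dict(raw.get("paths", {}))
        if not simulate:
            required = ("methylation", "manifest", "seg", "expression", "clinical")
            missing = [p for p in required if p not in paths]
            if missing:
                raise ValidationError(f"config missing input path(s) {missing}")
            for key in required:
                if not Path(paths[key]).exists():
                    raise ValidationError(f"input file for {key!r} not found: {paths[key]}")
        return cls(
            seed=seed,
            outdir=Path(raw["outdir"]),
            simulate=simulate,
            simulation=sim_cfg,
            inference=inference,
            paths=paths,
            raw=dict(raw),
        )


def _config_hash(raw: Mapping[str, Any]) -> str:
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and return (and write) the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config.raw),
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {
                    name: {"path": str(p), "rows": _count_rows(p)}
                    for name, p in outputs.items()
                },
            }
        )

    # --- simulate ----------------------------------------------------------
    if config.simulate:
        assert config.simulation is not None
        meth, expr, seg, clin, man, truth = generate_cohort(config.simulation)
        paths = {
            "methylation": outdir / "methylation.tsv",
            "manifest": outdir / "probe_manifest.tsv",
            "seg": outdir / "copy_number.seg",
            "expression": outdir / "expression.tsv",
            "clinical": outdir / "clinical.csv",
            "truth": outdir / "truth.tsv",
        }
        iof.write_methylation(meth, paths["methylation"])
        iof.write_manifest(man, paths["manifest"])
        iof.write_seg(seg, paths["seg"])
        iof.write_expression(expr, paths["expression"])
        iof.write_clinical(clin, paths["clinical"])
        truth_table(truth).to_csv(paths["truth"], sep="\t", index=False)
        panel_paths = []
        for panel in default_panels():
            p = outdir / f"panel_{panel.name}.txt"
            iof.write_panel(panel, p)
            panel_paths.append(str(p))
        record("simulate", paths)
    else:
        paths = {k: Path(v) for k, v in config.paths.items()}
        panel_paths = list(config.paths.get("panels", []))

    # --- classify ----------------------------------------------------------
    man = iof.read_manifest(paths["manifest"])
    meth = iof.read_methylation(paths["methylation"], man)
    seg = iof.read_seg(paths["seg"])
    expr = iof.read_expression(paths["expression"])
    clin = iof.read_clinical(paths["clinical"])
    calls = classify_cohort(meth, man, seg, expr, clin, config.inference)
    calls_path = outdir / "xci_calls.tsv"
    iof.write_calls(calls, calls_path)
    record("classify", {"calls": calls_path})

    # --- associate ---------------------------------------------------------
    panels = [iof.read_panel(p) for p in panel_paths] or list(default_panels())
    assoc, _ = expression_by_group_table(calls, expr, panels, clinical=clin.df)
    # global (autosomal CpG-island) methylation across XCI groups
    auto_probes = select_probes(man, "autosomes", cpg_island_only=True)
    global_meth = mean_cpg_methylation(meth, auto_probes)
    groups = calls.set_index("sample_id")["xci_group"]
    by_group = {
        g: global_meth.loc[idx].dropna().to_numpy()
        for g, idx in groups.groupby(groups).groups.items()
    }
    by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(by_group) >= 2:
        comp = compare_groups(by_group, grouping="xci_group", measure="global_methylation")
        assoc = pd.concat(
            [
                assoc,
                pd.DataFrame(
                    [
                        {
                            "panel": "global_methylation",
                            "grouping": "xci_group",
                            "test": comp.test,
                            "statistic": comp.statistic,
                            "p_value": comp.p_value,
                            "band": comp.band,
                            "groups": ";".join(
                                f"{g}:n={len(v)}" for g, v in by_group.items()
                            ),
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    assoc_path = outdir / "associations.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False)
    record("associate", {"associations": assoc_path})

    # --- outcomes ----------------------------------------------------------
    outputs: dict[str, Path] = {}
    test_rows = []
    for fld in _CATEGORICAL_FIELDS:
        if fld not in clin.df.columns:
            continue
        tab = crosstab(clin.df[fld], calls)
        tab_path = outdir / f"crosstab_{fld}.tsv"
        tab.counts.to_csv(tab_path, sep="\t")
        outputs[f"crosstab_{fld}"] = tab_path
        if tab.degenerate:
            continue
        res = fisher_exact_rxc(tab, seed=config.seed)
        test_rows.append(
            {
                "field": fld,
                "test": f"fisher_exact_{res.method}",
                "statistic": float("nan"),
                "p_value": res.p_value,
                "n": tab.n,
            }
        )
    if "age" in clin.df.columns:
        f, p = anova_by_group(clin.df["age"], calls)
        test_rows.append(
            {"field": "age", "test": "anova_oneway", "statistic": f, "p_value": p,
             "n": int(clin.df["age"].notna().sum())}
        )

    merged = calls.set_index("sample_id").join(clin.df, how="inner", rsuffix="_clin")
    for endpoint in ("os", "dfs"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if tcol not in merged.columns:
            continue
        surv = merged[[tcol, ecol, "xci_group", "stage"]].dropna(subset=[tcol, ecol])
        km = km_logrank(surv[tcol], surv[ecol], surv["xci_group"])
        test_rows.append(
            {"field": f"{endpoint}_logrank", "test": "logrank",
             "statistic": km.logrank_statistic, "p_value": km.logrank_p, "n": len(surv)}
        )
        cox = cox_stage_adjusted(surv[tcol], surv[ecol], surv["xci_group"], surv["stage"])
        cox_path = outdir / f"cox_{endpoint}.tsv"
        cox.cox.to_csv(cox_path, sep="\t", index_label="term")
        outputs[f"cox_{endpoint}"] = cox_path
    tests_path = outdir / "tests.tsv"
    pd.DataFrame(test_rows).to_csv(tests_path, sep="\t", index=False)
    outputs["tests"] = tests_path
    record("outcomes", outputs)

    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
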