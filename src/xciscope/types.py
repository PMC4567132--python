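"""In-memory containers shared by every pipeline stage.

All tabular data is held in :class:`pandas.DataFrame` objects wrapped in thin
dataclasses whose constructors validate the domain invariants (beta values in
[0, 1], non-overlapping copy-number segments, known chromosome names, ...).
Readers in :mod:`xciscope.io_formats` produce these types; analysis modules
never touch files directly.

Coordinates are 1-based and inclusive throughout (array-annotation and SEG
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Chromosomes the pipeline models: the 22 autosomes plus the X. The Y is
#: deliberately absent — XCI analysis concerns female karyotypes only.
ALLOWED_CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
AUTOSOMES: tuple[str, ...] = ALLOWED_CHROMOSOMES[:-1]

XCI_GROUPS: tuple[str, ...] = ("preserved_Xi", "Xa_plus", "two_Xa")
HISTOLOGIES: tuple[str, ...] = ("endometrioid", "serous")
TCGA_SUBTYPES: tuple[str, ...] = ("CN_high", "CN_low", "MSI", "POLE")
STAGES: tuple[str, ...] = ("I_II", "III", "IV")
MENOPAUSE_LEVELS: tuple[str, ...] = ("post", "pre", "peri")
RACE_LEVELS: tuple[str, ...] = ("white", "black", "asian")
ETHNICITY_LEVELS: tuple[str, ...] = ("hispanic", "non_hispanic")
RESIDUAL_LEVELS: tuple[str, ...] = ("R0", "R1", "R2", "RX")

METH_CLASSES: tuple[str, ...] = ("hyper", "partial", "hypo")
XIST_CLASSES: tuple[str, ...] = ("high", "low", "unknown")
CNV_CALLS: tuple[str, ...] = ("deleted", "neutral", "gained")
ARM_METH_CALLS: tuple[str, ...] = ("hypo", "not_hypo", "no_probes")


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


def normalize_chromosome(raw: str) -> str:
    """Canonicalize a chromosome label to the ``chr``-prefixed form.

    Accepts ``"chrX"``, ``"X"``, ``"x"``, ``"23"`` and ``"chr23"`` for the X
    chromosome and plain or prefixed numerals for autosomes.
    """
    name = str(raw).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in ("23", "X", "x"):
        return "chrX"
    canonical = f"chr{name}"
    if canonical not in ALLOWED_CHROMOSOMES:
        raise ValidationError(f"unknown chromosome {raw!r}")
    return canonical


@dataclass(frozen=True)
class ProbeManifest:
    """Methylation-array probe annotation: locus and CpG-island membership.

    ``df`` columns: ``probe_id`` (unique), ``chromosome`` (canonical name),
    ``position`` (1-based bp), ``cpg_island`` (bool).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "chromosome", "position", "cpg_island"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns {missing}")
        dup = self.df["probe_id"][self.df["probe_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate probe_id {dup.iloc[0]!r} in manifest")
        bad = set(self.df["chromosome"]) - set(ALLOWED_CHROMOSOMES)
        if bad:
            raise ValidationError(f"unknown chromosome(s) {sorted(bad)} in manifest")
        if (self.df["position"] < 1).any():
            raise ValidationError("manifest positions must be >= 1")

    @property
    def probe_ids(self) -> pd.Series:
        return self.df["probe_id"]

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class MethylationMatrix:
    """Probes x samples matrix of beta values in [0, 1]; NaN marks missing."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in methylation matrix")
        if self.beta.index.duplicated().any():
            raise ValidationError("duplicate probe ids in methylation matrix")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = (vals < 0.0) | (vals > 1.0)
        if out_of_range.any():
            i, j = np.argwhere(out_of_range)[0]
            raise ValidationError(
                f"beta value {vals[i, j]} out of [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


@dataclass(frozen=True)
class CnvSegmentSet:
    """Per-sample copy-number segments with log2 tumor/normal seg-means.

    ``segments`` columns: ``sample_id``, ``chromosome``, ``start``, ``end``
    (1-based inclusive bp), ``seg_mean``. Segments for a given sample and
    chromosome must not overlap.
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "chromosome", "start", "end", "seg_mean"]
        missing = [c for c in required if c not in self.segments.columns]
        if missing:
            raise ValidationError(f"segment table missing columns {missing}")
        seg = self.segments
        if len(seg) == 0:
            return
        if (seg["start"] >= seg["end"]).any():
            row = seg[seg["start"] >= seg["end"]].iloc[0]
            raise ValidationError(
                f"segment start >= end for sample {row['sample_id']!r} "
                f"({row['start']}-{row['end']})"
            )
        if not np.isfinite(seg["seg_mean"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite seg_mean in segment table")
        bad = set(seg["chromosome"]) - set(ALLOWED_CHROMOSOMES)
        if bad:
            raise ValidationError(f"unknown chromosome(s) {sorted(bad)} in segments")
        for (sample, chrom), grp in seg.groupby(["sample_id", "chromosome"], sort=False):
            ordered = grp.sort_values("start")
            starts = ordered["start"].to_numpy()
            ends = ordered["end"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise ValidationError(
                    f"overlapping segments on {chrom} for sample {sample!r}"
                )

    def for_sample(self, sample_id: str, chromosome: str | None = None) -> pd.DataFrame:
        mask = self.segments["sample_id"] == sample_id
        if chromosome is not None:
            mask &= self.segments["chromosome"] == chromosome
        return self.segments[mask]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of normalized RSEM values (non-negative)."""

    rsem: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rsem.index.duplicated().any():
            dup = self.rsem.index[self.rsem.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in expression matrix")
        vals = self.rsem.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if (vals < 0).any():
                i, j = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative RSEM at gene {self.rsem.index[i]!r}, "
                    f"sample {self.rsem.columns[j]!r}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.rsem.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.rsem.columns


_CLINICAL_ENUMS = {
    "histology": HISTOLOGIES,
    "tcga_subtype": TCGA_SUBTYPES,
    "stage": STAGES,
    "menopause": MENOPAUSE_LEVELS,
    "race": RACE_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "residual": RESIDUAL_LEVELS,
}

CLINICAL_COLUMNS = (
    "sample_id",
    "histology",
    "tcga_subtype",
    "age",
    "stage",
    "menopause",
    "race",
    "ethnicity",
    "residual",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample covariates and outcome data.

    Indexed by ``sample_id``; categorical fields use the enumerations in this
    module, continuous fields are floats; missing values are NaN (``histology``
    may never be missing). Survival times are in days.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        if "histology" not in self.df.columns:
            raise ValidationError("clinical table lacks histology column")
        if self.df["histology"].isna().any():
            sid = self.df.index[self.df["histology"].isna()][0]
            raise ValidationError(f"histology missing for sample {sid!r}")
        for col, levels in _CLINICAL_ENUMS.items():
            if col not in self.df.columns:
                continue
            observed = set(self.df[col].dropna())
            bad = observed - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s) {sorted(bad)}")
        for col in ("age", "os_time", "dfs_time"):
            if col in self.df.columns:
                vals = pd.to_numeric(self.df[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise ValidationError(f"negative values in clinical column {col!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index


@dataclass(frozen=True)
class CTAPanel:
    """A named cancer-testis-antigen gene panel (X-linked or autosomal)."""

    name: str
    gene_ids: tuple[str, ...]
    location: str  # "X_linked" or "autosomal"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"panel {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"panel {self.name!r} lists duplicate genes")
        if self.location not in ("X_linked", "autosomal"):
            raise ValidationError(f"panel location {self.location!r} unknown")


@dataclass(frozen=True)
class ArmDefinition:
    """Synthetic/real chrX geometry used to split p and q arms."""

    centromere_bp: int = 60_000_000
    chromosome_length: int = 155_000_000

    def arm_bounds(self, arm: str) -> tuple[int, int]:
        if arm == "p":
            return 1, self.centromere_bp
        if arm == "q":
            return self.centromere_bp + 1, self.chromosome_length
        raise ValueError(f"unknown arm {arm!r}")

    def arm_length(self, arm: str) -> int:
        lo, hi = self.arm_bounds(arm)
        return hi - lo + 1


@dataclass(frozen=True)
class ArmCall:
    """Copy-number and methylation evidence for one chrX arm of one sample."""

    sample_id: str
    arm: str  # "p" | "q"
    cnv: str  # "deleted" | "neutral" | "gained"
    meth: str  # "hypo" | "not_hypo" | "no_probes"

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValidationError(f"arm must be p or q, got {self.arm!r}")
        if self.cnv not in CNV_CALLS:
            raise ValidationError(f"unknown cnv call {self.cnv!r}")
        if self.meth not in ARM_METH_CALLS:
            raise ValidationError(f"unknown arm meth call {self.meth!r}")


@dataclass(frozen=True)
class ClusterProfile:
    """Summary of one methylation cluster used for group assignment."""

    cluster_id: str
    histology: str
    member_samples: tuple[str, ...]
    median_sample_mean_beta: float
    meth_class: str  # hyper | partial | hypo
    xist_class: str  # high | low | unknown
    median_xist_log: float = float("nan")

    def __post_init__(self) -> None:
        if not self.member_samples:
            raise ValidationError(f"cluster {self.cluster_id!r} has no members")
        if self.meth_class not in METH_CLASSES:
            raise ValidationError(f"unknown meth_class {self.meth_class!r}")
        if self.xist_class not in XIST_CLASSES:
            raise ValidationError(f"unknown xist_class {self.xist_class!r}")


@dataclass(frozen=True)
class XciCall:
    """Final XCI-status call for one sample, with its evidence trail."""

    sample_id: str
    histology: str
    cluster_id: str
    meth_class: str
    xist_class: str
    p_arm_cnv: str
    q_arm_cnv: str
    p_arm_meth: str
    q_arm_meth: str
    xci_group: str
    override_applied: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.xci_group not in XCI_GROUPS:
            raise ValidationError(f"unknown xci_group {self.xci_group!r}")


CALLS_COLUMNS = (
    "sample_id",
    "histology",
    "cluster",
    "meth_class",
    "xist_class",
    "p_arm_cnv",
    "q_arm_cnv",
    "p_arm_meth",
    "q_arm_meth",
    "xci_group",
    "override_applied",
    "flags",
)


def calls_to_frame(calls: Sequence[XciCall]) -> pd.DataFrame:
    """Tabulate a sequence of :class:`XciCall` as a calls DataFrame."""
    rows = [
        {
            "sample_id": c.sample_id,
            "histology": c.histology,
            "cluster": c.cluster_id,
            "meth_class": c.meth_class,
            "xist_class": c.xist_class,
            "p_arm_cnv": c.p_arm_cnv,
            "q_arm_cnv": c.q_arm_cnv,
            "p_arm_meth": c.p_arm_meth,
            "q_arm_meth": c.q_arm_meth,
            "xci_group": c.xci_group,
            "override_applied": c.override_applied,
            "flags": ";".join(c.flags),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=list(CALLS_COLUMNS))


def frame_to_calls(df: pd.DataFrame) -> list[XciCall]:
    """Inverse of :func:`calls_to_frame`."""
    calls = []
    for _, row in df.iterrows():
        flags = tuple(f for f in str(row.get("flags", "") or "").split(";") if f)
        calls.append(
            XciCall(
                sample_id=row["sample_id"],
                histology=row["histology"],
                cluster_id=row["cluster"],
                meth_class=row["meth_class"],
                xist_class=row["xist_class"],
                p_arm_cnv=row["p_arm_cnv"],
                q_arm_cnv=row["q_arm_cnv"],
                p_arm_meth=row["p_arm_meth"],
                q_arm_meth=row["q_arm_meth"],
                xci_group=row["xci_group"],
                override_applied=bool(row["override_applied"]),
                flags=flags,
            )
        )
    return calls
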