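"""XCI-status inference from X CpG-island methylation, XIST and copy number.

The procedure mirrors how a pathologist-analyst would read a stratified
methylation heatmap:

1. per histology stratum, hierarchically cluster samples (complete linkage,
   Euclidean distance) on X-chromosome CpG-island beta values and cut the
   dendrogram to ``k`` clusters (default 3);
2. characterize each cluster by its median sample-mean beta (hyper / partial /
   hypo) and its median XIST level (high / low);
3. call arm-level chrX copy number per sample from SEG-style segments and
   arm-level hypomethylation from the same beta values;
4. assign each sample an XCI group — preserved Xi, partial reactivation (Xa+),
   or two active X copies — from the cluster signature, with a per-sample
   override: selective hypomethylation of one arm that coincides with a
   deletion of the *same* arm marks loss of an arm of the inactive X, so the
   sample keeps its Xi and is reassigned to preserved Xi.

A fixed dendrogram cut can fuse two biologically distinct groups — most often
Xa+ with two-Xa tumors, which sit closer to each other in methylation space
than either does to preserved-Xi tumors — whenever a handful of Xi-arm-deleted
samples occupy a cluster of their own. The classifier therefore refines the
initial ``k``-cut: a cluster is treated as heterogeneous, and split along its
top merge, when its two subtrees carry *different* evidence signatures
(methylation class or XIST class) or when its own signature is biologically
contradictory (island hypomethylation with high XIST, or hypermethylation with
low XIST). Refinement recurses until every cluster is signature-homogeneous or
too small to split; residual contradictions are flagged on the emitted calls.

Classification thresholds (``t_hyper``, ``t_hypo``, ``t_xist``, the arm
seg-mean cutoff) are calibration choices exposed in
:class:`InferenceConfig`, not quantities estimated from data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .types import (
    ArmDefinition,
    ClinicalTable,
    ClusterProfile,
    CnvSegmentSet,
    ExpressionMatrix,
    MethylationMatrix,
    ProbeManifest,
    ValidationError,
    XciCall,
    calls_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceConfig:
    """Thresholds and knobs of the XCI classifier.

    ``t_hyper`` / ``t_hypo`` split clusters into hyper / partial / hypo by the
    median over members of each sample's mean X-island beta; ``t_xist`` splits
    XIST-high from XIST-low on the log2(RSEM+1) scale. All are calibration
    choices (cluster assignment in the underlying study design is visual).
    """

    k: int = 3
    t_hyper: float = 0.35
    t_hypo: float = 0.18
    t_xist: float = 6.5
    arm_cnv_cutoff: float = 0.3
    centromere_bp: int = 60_000_000
    chromosome_length: int = 155_000_000
    min_arm_probes: int = 5
    min_arm_coverage: float = 0.5
    #: smallest conflicted cluster the refinement step will still split
    min_split_size: int = 4
    #: classify each sample on its own evidence instead of cluster-level
    per_sample_assignment: bool = False

    def __post_init__(self) -> None:
        if self.t_hypo >= self.t_hyper:
            raise ValidationError(
                f"t_hypo ({self.t_hypo}) must be below t_hyper ({self.t_hyper})"
            )
        if self.k < 2:
            raise ValidationError("k must be >= 2")

    @property
    def arm_definition(self) -> ArmDefinition:
        return ArmDefinition(self.centromere_bp, self.chromosome_length)


# ---------------------------------------------------------------------------
# probe selection and imputation


def select_probes(
    manifest: ProbeManifest,
    chromosome_filter: str | Iterable[str],
    cpg_island_only: bool = True,
) -> list[str]:
    """Probe ids matching a chromosome filter (and CpG-island flag), in
    manifest order.

    ``chromosome_filter`` is a chromosome name, an iterable of names, or the
    shorthand ``"autosomes"``.
    """
    df = manifest.df
    if isinstance(chromosome_filter, str):
        if chromosome_filter == "autosomes":
            chroms = set(df["chromosome"]) - {"chrX"}
        else:
            chroms = {chromosome_filter}
    else:
        chroms = set(chromosome_filter)
    mask = df["chromosome"].isin(chroms)
    if cpg_island_only:
        mask &= df["cpg_island"]
    probes = list(df.loc[mask, "probe_id"])
    if not probes:
        raise ValidationError(
            f"no probes match chromosome filter {chromosome_filter!r} "
            f"(cpg_island_only={cpg_island_only})"
        )
    return probes


def impute_missing(beta: pd.DataFrame) -> pd.DataFrame:
    """Replace missing betas by the per-probe median over the given samples.

    Probes with no observed value are dropped (count logged).
    """
    all_missing = beta.isna().all(axis=1)
    if all_missing.any():
        logger.info("impute_missing: dropped %d all-missing probes", int(all_missing.sum()))
        beta = beta.loc[~all_missing]
    if not beta.isna().any().any():
        return beta
    medians = beta.median(axis=1)
    return beta.apply(lambda col: col.fillna(medians))


# ---------------------------------------------------------------------------
# clustering


def _complete_linkage(beta: pd.DataFrame) -> np.ndarray:
    """Complete-linkage dendrogram over samples (columns) of ``beta``."""
    x = beta.to_numpy(dtype=float).T
    if np.isnan(x).any():
        raise ValidationError("clustering input contains missing values; impute first")
    return hierarchy.linkage(x, method="complete", metric="euclidean")


def _cut_nodes(root: hierarchy.ClusterNode, k: int) -> list[hierarchy.ClusterNode]:
    """Cut a (monotone) dendrogram into ``k`` subtrees, splitting the highest
    merge first; ties broken by smallest node id."""
    nodes = [root]
    while len(nodes) < k:
        splittable = [n for n in nodes if not n.is_leaf()]
        if not splittable:
            break
        target = max(splittable, key=lambda n: (n.dist, -n.id))
        nodes.remove(target)
        nodes.extend([target.get_left(), target.get_right()])
    return nodes


def cluster_samples(beta: pd.DataFrame, k: int) -> pd.Series:
    """Complete-linkage / Euclidean clustering of samples, cut to ``k`` groups.

    Returns a sample -> label series; labels are 1..k in order of each
    cluster's smallest column index, so the labeling does not depend on
    internal merge bookkeeping.
    """
    n = beta.shape[1]
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} samples available")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        link = _complete_linkage(beta)
        nodes = _cut_nodes(hierarchy.to_tree(link), k)
        raw = np.empty(n, dtype=int)
        for lab, node in enumerate(nodes, start=1):
            raw[node.pre_order(lambda leaf: leaf.id)] = lab
    # canonical labels by first appearance
    seen: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return pd.Series(labels, index=beta.columns, name="cluster")


# ---------------------------------------------------------------------------
# cluster characterization


def xist_log_expression(expression: ExpressionMatrix | None, gene: str = "XIST") -> pd.Series:
    """Per-sample XIST level on the log2(RSEM+1) scale; NaN where unavailable."""
    if expression is None or gene not in expression.rsem.index:
        return pd.Series(dtype=float)
    vals = expression.rsem.loc[gene]
    return np.log2(vals.astype(float) + 1.0)


def profile_cluster(
    cluster_id: str,
    histology: str,
    members: Sequence[str],
    sample_mean_beta: pd.Series,
    xist_log: pd.Series,
    config: InferenceConfig,
) -> ClusterProfile:
    """Characterize a cluster by methylation level and XIST expression.

    ``meth_class`` comes from the median over members of the sample-mean
    X-island beta (>= ``t_hyper`` hyper, <= ``t_hypo`` hypo, else partial);
    ``xist_class`` from the median member XIST log2(RSEM+1), or ``unknown``
    when more than half the members lack expression data.
    """
    if not len(members):
        raise ValidationError(f"cluster {cluster_id!r} has no members")
    med_beta = float(sample_mean_beta.loc[list(members)].median())
    if med_beta >= config.t_hyper:
        meth_class = "hyper"
    elif med_beta <= config.t_hypo:
        meth_class = "hypo"
    else:
        meth_class = "partial"

    member_xist = xist_log.reindex(list(members))
    n_obs = int(member_xist.notna().sum())
    if n_obs * 2 < len(members):
        xist_class, med_xist = "unknown", float("nan")
    else:
        med_xist = float(member_xist.median())
        xist_class = "high" if med_xist >= config.t_xist else "low"
    return ClusterProfile(
        cluster_id=cluster_id,
        histology=histology,
        member_samples=tuple(members),
        median_sample_mean_beta=med_beta,
        meth_class=meth_class,
        xist_class=xist_class,
        median_xist_log=med_xist,
    )


# ---------------------------------------------------------------------------
# arm-level evidence


def call_arm_cnv(
    segments: CnvSegmentSet,
    sample_id: str,
    arm_def: ArmDefinition,
    cutoff: float = 0.3,
) -> dict[str, str]:
    """Arm-level chrX copy-number call from the length-weighted mean seg-mean.

    ``deleted`` at or below ``-cutoff``, ``gained`` at or above ``+cutoff``,
    else ``neutral``. An arm with less than half its length covered by
    segments — including the no-data case — is called neutral (absence of
    evidence) with a warning.
    """
    seg = segments.for_sample(sample_id, "chrX")
    calls: dict[str, str] = {}
    for arm in ("p", "q"):
        lo, hi = arm_def.arm_bounds(arm)
        starts = np.maximum(seg["start"].to_numpy(int), lo) if len(seg) else np.array([], int)
        ends = np.minimum(seg["end"].to_numpy(int), hi) if len(seg) else np.array([], int)
        lengths = np.maximum(ends - starts + 1, 0)
        covered = int(lengths.sum())
        if covered < arm_def.arm_length(arm) * 0.5:
            if covered == 0:
                logger.warning("no chrX %s-arm segments for %s; calling neutral", arm, sample_id)
            else:
                logger.warning(
                    "chrX %s arm of %s only %.0f%% covered; calling neutral",
                    arm, sample_id, 100 * covered / arm_def.arm_length(arm),
                )
            calls[arm] = "neutral"
            continue
        wmean = float(np.dot(lengths, seg["seg_mean"].to_numpy(float)) / covered)
        if wmean <= -cutoff:
            calls[arm] = "deleted"
        elif wmean >= cutoff:
            calls[arm] = "gained"
        else:
            calls[arm] = "neutral"
    return calls


def detect_arm_hypomethylation(
    sample_beta: pd.Series,
    manifest: ProbeManifest,
    arm_def: ArmDefinition,
    t_hypo: float = 0.18,
    min_probes: int = 5,
) -> dict[str, str]:
    """Per-arm methylation call from chrX island probes of one sample.

    ``hypo`` when the mean beta over the arm's island probes is at or below
    ``t_hypo``; arms with fewer than ``min_probes`` informative probes are
    ``no_probes``.
    """
    mdf = manifest.df
    x_island = mdf[(mdf["chromosome"] == "chrX") & mdf["cpg_island"]]
    pos = x_island.set_index("probe_id")["position"]
    common = sample_beta.index.intersection(pos.index)
    calls: dict[str, str] = {}
    for arm in ("p", "q"):
        lo, hi = arm_def.arm_bounds(arm)
        on_arm = common[(pos.loc[common] >= lo) & (pos.loc[common] <= hi)]
        vals = sample_beta.loc[on_arm].dropna()
        if len(vals) < min_probes:
            calls[arm] = "no_probes"
        else:
            calls[arm] = "hypo" if float(vals.mean()) <= t_hypo else "not_hypo"
    return calls


def selective_arm_event(arm_meth: Mapping[str, str]) -> str | None:
    """The arm showing *selective* hypomethylation (one arm hypo, the other
    informative and not), or None."""
    p, q = arm_meth["p"], arm_meth["q"]
    if p == "hypo" and q == "not_hypo":
        return "p"
    if q == "hypo" and p == "not_hypo":
        return "q"
    return None


# ---------------------------------------------------------------------------
# group assignment

_BASE_GROUP = {
    ("hyper", "high"): ("preserved_Xi", ()),
    ("partial", "high"): ("Xa_plus", ()),
    ("hypo", "low"): ("two_Xa", ()),
    ("hypo", "high"): ("two_Xa", ("conflict_meth_xist",)),
    ("hyper", "low"): ("preserved_Xi", ("conflict_meth_xist",)),
    ("partial", "low"): ("Xa_plus", ("conflict_meth_xist",)),
    ("hyper", "unknown"): ("preserved_Xi", ("low_confidence_no_xist",)),
    ("partial", "unknown"): ("Xa_plus", ("low_confidence_no_xist",)),
    ("hypo", "unknown"): ("two_Xa", ("low_confidence_no_xist",)),
}


def rederive_group(
    meth_class: str,
    xist_class: str,
    p_arm_cnv: str,
    q_arm_cnv: str,
    p_arm_meth: str,
    q_arm_meth: str,
) -> tuple[str, bool, tuple[str, ...]]:
    """Pure assignment rule: evidence fields -> (group, override?, flags).

    Used both by :func:`assign_status` and to audit emitted calls (a call is
    valid only if its stored evidence re-derives its group).
    """
    group, flags = _BASE_GROUP[(meth_class, xist_class)]
    flags = tuple(flags)
    arm_meth = {"p": p_arm_meth, "q": q_arm_meth}
    arm_cnv = {"p": p_arm_cnv, "q": q_arm_cnv}
    if meth_class in ("partial", "hypo"):
        sel = selective_arm_event(arm_meth)
        if sel is not None and arm_cnv[sel] == "deleted":
            # deletion of one arm of the Xi: the remaining Xi is intact
            return "preserved_Xi", True, flags + ("xi_arm_loss",)
    if (
        meth_class == "hypo"
        and p_arm_cnv == "deleted"
        and q_arm_cnv == "deleted"
    ):
        # whole-X loss leaves a single Xa: no dosage increase, report as
        # preserved-Xi-equivalent with a distinguishing flag
        return "preserved_Xi", False, flags + ("whole_X_loss",)
    return group, False, flags


def assign_status(
    profile: ClusterProfile,
    arm_calls: Mapping[str, Mapping[str, str]],
) -> list[XciCall]:
    """Assign XCI groups to every member of a profiled cluster.

    ``arm_calls`` maps each member sample to a dict with keys ``p_cnv``,
    ``q_cnv``, ``p_meth``, ``q_meth``.
    """
    calls = []
    for sid in profile.member_samples:
        ev = arm_calls.get(sid, {})
        p_cnv = ev.get("p_cnv", "neutral")
        q_cnv = ev.get("q_cnv", "neutral")
        p_meth = ev.get("p_meth", "no_probes")
        q_meth = ev.get("q_meth", "no_probes")
        group, override, flags = rederive_group(
            profile.meth_class, profile.xist_class, p_cnv, q_cnv, p_meth, q_meth
        )
        calls.append(
            XciCall(
                sample_id=sid,
                histology=profile.histology,
                cluster_id=profile.cluster_id,
                meth_class=profile.meth_class,
                xist_class=profile.xist_class,
                p_arm_cnv=p_cnv,
                q_arm_cnv=q_cnv,
                p_arm_meth=p_meth,
                q_arm_meth=q_meth,
                xci_group=group,
                override_applied=override,
                flags=flags,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# cohort orchestration


def _is_conflicted(profile: ClusterProfile) -> bool:
    return (profile.meth_class, profile.xist_class) in (
        ("hypo", "high"),
        ("hyper", "low"),
    )


def _stratum_partition(
    beta: pd.DataFrame,
    sample_mean_beta: pd.Series,
    xist_log: pd.Series,
    histology: str,
    config: InferenceConfig,
) -> list[tuple[list[str], ClusterProfile]]:
    """Cluster one histology stratum and return (members, profile) pairs.

    Cuts the dendrogram at ``config.k``, then recursively splits clusters
    that are conflicted or whose two subtrees carry different evidence
    signatures (see module docstring), down to ``min_split_size`` members.
    """
    samples = list(beta.columns)
    n = len(samples)
    if n < config.k:
        raise ValidationError(
            f"stratum {histology!r} has {n} samples, fewer than k={config.k}; "
            "use a smaller k"
        )
    link = _complete_linkage(beta)
    root = hierarchy.to_tree(link)
    nodes = _cut_nodes(root, config.k)

    def members_of(node: hierarchy.ClusterNode) -> list[str]:
        return [samples[i] for i in sorted(node.pre_order(lambda leaf: leaf.id))]

    def profiled(node, idx):
        mem = members_of(node)
        return profile_cluster(
            f"tmp{idx}", histology, mem, sample_mean_beta, xist_log, config
        )

    def signature(node) -> tuple[str, str]:
        prof = profiled(node, 0)
        return prof.meth_class, prof.xist_class

    # heterogeneity-driven refinement
    work = list(nodes)
    for _ in range(2 * n):
        split_at = None
        for i, nd in enumerate(work):
            if nd.is_leaf() or nd.get_count() < config.min_split_size:
                continue
            prof = profiled(nd, i)
            left, right = nd.get_left(), nd.get_right()
            if _is_conflicted(prof) or signature(left) != signature(right):
                split_at = i
                break
        if split_at is None:
            break
        nd = work.pop(split_at)
        logger.info(
            "%s: splitting heterogeneous cluster of %d samples", histology, nd.get_count()
        )
        work.extend([nd.get_left(), nd.get_right()])

    result = []
    for nd in work:
        mem = members_of(nd)
        result.append(
            (mem, profile_cluster("tmp", histology, mem, sample_mean_beta, xist_log, config))
        )
    # stable cluster ids: descending methylation (hypermethylated first), as
    # heatmap cluster labels conventionally read
    result.sort(key=lambda mp: (-mp[1].median_sample_mean_beta, mp[0][0]))
    prefix = histology[:1].upper()
    final = []
    for i, (mem, prof) in enumerate(result, start=1):
        cid = f"{prefix}{i}"
        final.append(
            (
                mem,
                ClusterProfile(
                    cluster_id=cid,
                    histology=prof.histology,
                    member_samples=prof.member_samples,
                    median_sample_mean_beta=prof.median_sample_mean_beta,
                    meth_class=prof.meth_class,
                    xist_class=prof.xist_class,
                    median_xist_log=prof.median_xist_log,
                ),
            )
        )
    return final


def classify_cohort(
    methylation: MethylationMatrix,
    manifest: ProbeManifest,
    segments: CnvSegmentSet,
    expression: ExpressionMatrix | None,
    clinical: ClinicalTable,
    config: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Run the full XCI classification and return the calls table.

    Samples are the intersection of the methylation matrix and the clinical
    table (which supplies histology); the intersection is logged. Every such
    sample receives exactly one call.
    """
    config = config or InferenceConfig()
    shared = [s for s in methylation.sample_ids if s in set(clinical.sample_ids)]
    dropped = len(methylation.sample_ids) - len(shared)
    if dropped:
        logger.info("classify_cohort: %d methylation samples lack clinical data", dropped)
    if not shared:
        raise ValidationError("no samples shared between methylation and clinical inputs")

    probes = select_probes(manifest, "chrX", cpg_island_only=True)
    probes = [p for p in probes if p in set(methylation.probe_ids)]
    if not probes:
        raise ValidationError("no chrX island probes present in the methylation matrix")
    xist_log = xist_log_expression(expression).reindex(shared)
    arm_def = config.arm_definition

    histology = clinical.df.loc[shared, "histology"]
    all_calls: list[XciCall] = []
    for hist in sorted(histology.unique()):
        stratum = [s for s in shared if histology.loc[s] == hist]
        sub = impute_missing(methylation.beta.loc[probes, stratum])
        sample_mean = sub.mean(axis=0)

        arm_calls: dict[str, dict[str, str]] = {}
        for sid in stratum:
            cnv = call_arm_cnv(segments, sid, arm_def, config.arm_cnv_cutoff)
            meth = detect_arm_hypomethylation(
                sub[sid], manifest, arm_def, config.t_hypo, config.min_arm_probes
            )
            arm_calls[sid] = {
                "p_cnv": cnv["p"],
                "q_cnv": cnv["q"],
                "p_meth": meth["p"],
                "q_meth": meth["q"],
            }

        if config.per_sample_assignment:
            for sid in stratum:
                prof = profile_cluster(
                    f"{hist[:1].upper()}?", hist, [sid], sample_mean, xist_log, config
                )
                all_calls.extend(assign_status(prof, arm_calls))
        else:
            for members, profile in _stratum_partition(
                sub, sample_mean, xist_log, hist, config
            ):
                all_calls.extend(assign_status(profile, arm_calls))

    order = {s: i for i, s in enumerate(shared)}
    all_calls.sort(key=lambda c: order[c.sample_id])
    return calls_to_frame(all_calls)
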