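"""Unit and property tests for the XCI classifier and its evidence calls."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from xciscope import (
    InferenceConfig,
    assign_status,
    call_arm_cnv,
    classify_cohort,
    cluster_samples,
    detect_arm_hypomethylation,
    generate_cohort,
    impute_missing,
    profile_cluster,
    select_probes,
)
from xciscope.types import (
    ArmDefinition,
    ClinicalTable,
    ClusterProfile,
    CnvSegmentSet,
    MethylationMatrix,
    ProbeManifest,
    ValidationError,
)
from xciscope.xci_inference import rederive_group

from conftest import small_config

ARM = ArmDefinition(centromere_bp=60_000_000, chromosome_length=155_000_000)


def toy_manifest():
    rows = []
    for i in range(3):
        rows.append({"probe_id": f"xi{i}", "chromosome": "chrX",
                     "position": 10 + i, "cpg_island": True})
    for i in range(2):
        rows.append({"probe_id": f"xn{i}", "chromosome": "chrX",
                     "position": 100 + i, "cpg_island": False})
    for i in range(4):
        rows.append({"probe_id": f"a{i}", "chromosome": "chr1",
                     "position": 10 + i, "cpg_island": True})
    return ProbeManifest(pd.DataFrame(rows))


class TestSelectProbes:
    def test_x_island_filter(self):
        assert select_probes(toy_manifest(), "chrX") == ["xi0", "xi1", "xi2"]

    def test_autosomal_filter(self):
        assert select_probes(toy_manifest(), "autosomes") == [f"a{i}" for i in range(4)]

    def test_empty_selection_is_an_error(self):
        man = ProbeManifest(
            pd.DataFrame(
                [{"probe_id": "a0", "chromosome": "chr1", "position": 1, "cpg_island": True}]
            )
        )
        with pytest.raises(ValidationError):
            select_probes(man, "chrX")


class TestImpute:
    def test_median_fills_missing(self):
        df = pd.DataFrame([[0.2, np.nan, 0.4]], index=["p"], columns=list("abc"))
        out = impute_missing(df)
        assert out.loc["p", "b"] == pytest.approx(0.3)

    def test_complete_matrix_unchanged(self):
        df = pd.DataFrame([[0.2, 0.3]], index=["p"], columns=["a", "b"])
        pd.testing.assert_frame_equal(impute_missing(df), df)

    def test_all_missing_probe_dropped(self):
        df = pd.DataFrame(
            [[0.2, 0.3], [np.nan, np.nan]], index=["p", "q"], columns=["a", "b"]
        )
        out = impute_missing(df)
        assert list(out.index) == ["p"]


def naive_complete_linkage(x: np.ndarray, k: int) -> np.ndarray:
    """O(n^3) reference agglomeration: merge the pair of clusters with the
    smallest maximum pairwise Euclidean distance until k remain."""
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or dist < best[0]:
                best = (dist, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


class TestClusterSamples:
    def test_separated_blocks_recovered(self):
        beta = pd.DataFrame(
            np.column_stack([np.full(5, 0.1)] * 3 + [np.full(5, 0.9)] * 3),
            columns=list("abcdef"),
        )
        labels = cluster_samples(beta, k=2)
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]
        assert labels["a"] != labels["d"]

    def test_identical_samples_split_deterministically(self):
        beta = pd.DataFrame(np.full((4, 4), 0.5), columns=list("abcd"))
        l1 = cluster_samples(beta, k=2)
        l2 = cluster_samples(beta, k=2)
        pd.testing.assert_series_equal(l1, l2)
        assert set(l1) == {1, 2}

    def test_k_larger_than_n_rejected(self):
        beta = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        with pytest.raises(ValidationError):
            cluster_samples(beta, k=5)

    @pytest.mark.parametrize("seed,n,k", [(0, 8, 2), (1, 15, 3), (2, 22, 4), (3, 30, 3)])
    def test_agrees_with_naive_oracle(self, seed, n, k):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 6))
        beta = pd.DataFrame(x.T, columns=[f"s{i}" for i in range(n)])
        ours = cluster_samples(beta, k).to_numpy()
        ref = naive_complete_linkage(x, k)
        assert adjusted_rand_score(ours, ref) == 1.0

    def test_three_generator_states_perfectly_separated(self):
        cfg = small_config(seed=5, n=2, xi_arm_deletion_fraction=0.0)
        meth, _, _, clin, man, truth = generate_cohort(cfg)
        endo = clin.df[clin.df["histology"] == "endometrioid"].index
        probes = select_probes(man, "chrX")
        labels = cluster_samples(meth.beta.loc[probes, endo], k=3)
        truth_labels = truth.df.loc[endo, "true_xci"]
        assert adjusted_rand_score(labels, pd.factorize(truth_labels)[0]) == 1.0


class TestProfileCluster:
    CFG = InferenceConfig()

    def run(self, betas, xists):
        members = [f"s{i}" for i in range(len(betas))]
        return profile_cluster(
            "C1", "serous", members,
            pd.Series(betas, index=members),
            pd.Series(xists, index=members),
            self.CFG,
        )

    def test_hypermethylated_high_xist(self):
        prof = self.run([0.45, 0.5, 0.42], [8.0, 7.5, 8.2])
        assert (prof.meth_class, prof.xist_class) == ("hyper", "high")

    def test_hypomethylated_low_xist(self):
        prof = self.run([0.10, 0.10, 0.10], [5.0, 5.0, 5.0])
        assert (prof.meth_class, prof.xist_class) == ("hypo", "low")

    def test_partial_with_high_xist_is_the_xa_plus_signature(self):
        prof = self.run([0.25, 0.25], [8.3, 8.3])
        assert (prof.meth_class, prof.xist_class) == ("partial", "high")

    def test_mostly_missing_xist_is_unknown(self):
        prof = self.run([0.45, 0.45, 0.45], [8.0, np.nan, np.nan])
        assert prof.xist_class == "unknown"

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            InferenceConfig(t_hyper=0.1, t_hypo=0.2)

    def test_meth_class_monotone_under_uniform_decrease(self):
        """Uniformly lowering betas never moves a cluster toward hyper."""
        order = {"hypo": 0, "partial": 1, "hyper": 2}
        betas = np.array([0.40, 0.38, 0.36])
        prev = order[self.run(list(betas), [8.0] * 3).meth_class]
        for shift in (0.1, 0.2, 0.3):
            cur = order[self.run(list(betas - shift), [8.0] * 3).meth_class]
            assert cur <= prev
            prev = cur


class TestArmCnv:
    def seg(self, rows):
        return CnvSegmentSet(
            pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])
        )

    def test_whole_p_arm_deletion(self):
        seg = self.seg([("s", "chrX", 1, 60_000_000, -0.8),
                        ("s", "chrX", 60_000_001, 155_000_000, 0.0)])
        assert call_arm_cnv(seg, "s", ARM) == {"p": "deleted", "q": "neutral"}

    def test_weighted_mean_boundary_is_inclusive(self):
        # two equal-length q segments at -0.8 and +0.2 average to exactly -0.3
        mid = 60_000_000 + (155_000_000 - 60_000_000) // 2
        seg = self.seg([("s", "chrX", 1, 60_000_000, 0.0),
                        ("s", "chrX", 60_000_001, mid, -0.8),
                        ("s", "chrX", mid + 1, 155_000_000, 0.2)])
        call = call_arm_cnv(seg, "s", ARM)
        assert call["q"] == "deleted"

    def test_flat_profile_is_neutral(self):
        seg = self.seg([("s", "chrX", 1, 155_000_000, 0.0)])
        assert call_arm_cnv(seg, "s", ARM) == {"p": "neutral", "q": "neutral"}

    def test_no_segments_neutral_with_absence_of_evidence(self):
        seg = self.seg([("other", "chrX", 1, 155_000_000, -0.9)])
        assert call_arm_cnv(seg, "s", ARM) == {"p": "neutral", "q": "neutral"}

    def test_low_coverage_arm_falls_back_to_neutral(self):
        seg = self.seg([("s", "chrX", 1, 10_000_000, -0.9),
                        ("s", "chrX", 60_000_001, 155_000_000, 0.0)])
        assert call_arm_cnv(seg, "s", ARM)["p"] == "neutral"


class TestArmHypomethylation:
    def manifest(self, n_per_arm=6):
        rows = []
        for i in range(n_per_arm):
            rows.append({"probe_id": f"p{i}", "chromosome": "chrX",
                         "position": 1_000 + i, "cpg_island": True})
            rows.append({"probe_id": f"q{i}", "chromosome": "chrX",
                         "position": 100_000_000 + i, "cpg_island": True})
        return ProbeManifest(pd.DataFrame(rows))

    def test_selective_q_arm_event(self):
        man = self.manifest()
        beta = pd.Series(
            {f"p{i}": 0.45 for i in range(6)} | {f"q{i}": 0.10 for i in range(6)}
        )
        assert detect_arm_hypomethylation(beta, man, ARM) == {"p": "not_hypo", "q": "hypo"}

    def test_uniformly_methylated_sample_has_no_event(self):
        man = self.manifest()
        beta = pd.Series({f"{a}{i}": 0.45 for a in "pq" for i in range(6)})
        assert detect_arm_hypomethylation(beta, man, ARM) == {"p": "not_hypo", "q": "not_hypo"}

    def test_underpowered_arm_reports_no_probes(self):
        man = self.manifest(n_per_arm=2)
        beta = pd.Series({f"{a}{i}": 0.45 for a in "pq" for i in range(2)})
        assert detect_arm_hypomethylation(beta, man, ARM)["p"] == "no_probes"


class TestAssignStatus:
    def profile(self, meth, xist, members=("s1",)):
        med = {"hyper": 0.45, "partial": 0.25, "hypo": 0.10}[meth]
        return ClusterProfile("C", "serous", tuple(members), med, meth, xist)

    def ev(self, p_cnv="neutral", q_cnv="neutral", p_meth="not_hypo", q_meth="not_hypo"):
        return {"s1": {"p_cnv": p_cnv, "q_cnv": q_cnv, "p_meth": p_meth, "q_meth": q_meth}}

    def test_hyper_high_is_preserved_xi(self):
        [call] = assign_status(self.profile("hyper", "high"), self.ev())
        assert call.xci_group == "preserved_Xi" and not call.override_applied

    def test_hypo_low_without_deletion_is_two_xa(self):
        [call] = assign_status(self.profile("hypo", "low"), self.ev())
        assert call.xci_group == "two_Xa"

    def test_selective_arm_loss_override_rescues_preserved_xi(self):
        [call] = assign_status(
            self.profile("partial", "high"),
            self.ev(q_cnv="deleted", q_meth="hypo"),
        )
        assert call.xci_group == "preserved_Xi"
        assert call.override_applied
        assert "xi_arm_loss" in call.flags

    def test_arm_hypomethylation_without_deletion_is_not_overridden(self):
        [call] = assign_status(self.profile("partial", "high"), self.ev(q_meth="hypo"))
        assert call.xci_group == "Xa_plus" and not call.override_applied

    def test_whole_x_deletion_reports_preserved_xi_equivalent(self):
        [call] = assign_status(
            self.profile("hypo", "low"),
            self.ev(p_cnv="deleted", q_cnv="deleted", p_meth="hypo", q_meth="hypo"),
        )
        assert call.xci_group == "preserved_Xi"
        assert "whole_X_loss" in call.flags

    def test_conflicting_evidence_assigned_by_methylation_and_flagged(self):
        [call] = assign_status(self.profile("hypo", "high"), self.ev())
        assert call.xci_group == "two_Xa"
        assert "conflict_meth_xist" in call.flags

    def test_unknown_xist_assigned_by_methylation_with_low_confidence(self):
        [call] = assign_status(self.profile("partial", "unknown"), self.ev())
        assert call.xci_group == "Xa_plus"
        assert "low_confidence_no_xist" in call.flags


class TestClassifyCohort:
    def test_every_sample_called_and_single_histology_works(self):
        cfg = small_config(seed=9, n_samples={("serous", s): 10 for s in
                                              ("preserved_Xi", "Xa_plus", "two_Xa")})
        meth, expr, seg, clin, man, truth = generate_cohort(cfg)
        calls = classify_cohort(meth, man, seg, expr, clin)
        assert len(calls) == 30
        assert set(calls["sample_id"]) == set(truth.df.index)

    def test_sample_order_invariance(self, small_cohort):
        meth, expr, seg, clin, man, truth = small_cohort
        calls = classify_cohort(meth, man, seg, expr, clin)
        rng = np.random.default_rng(0)
        perm = rng.permutation(meth.beta.columns)
        meth2 = MethylationMatrix(meth.beta[perm])
        clin2 = ClinicalTable(clin.df.loc[perm])
        calls2 = classify_cohort(meth2, man, seg, expr, clin2)
        a = calls.sort_values("sample_id").reset_index(drop=True)
        b = calls2.sort_values("sample_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_emitted_calls_are_auditable(self, small_cohort):
        """Re-applying the assignment rule to each call's stored evidence
        reproduces its group: calls carry their own justification."""
        meth, expr, seg, clin, man, truth = small_cohort
        calls = classify_cohort(meth, man, seg, expr, clin)
        for _, row in calls.iterrows():
            group, override, _ = rederive_group(
                row["meth_class"], row["xist_class"],
                row["p_arm_cnv"], row["q_arm_cnv"],
                row["p_arm_meth"], row["q_arm_meth"],
            )
            assert group == row["xci_group"]
            assert override == row["override_applied"]

    def test_small_cohort_recovery_and_misclassification_structure(self, small_cohort):
        """Misclassification, when present, stays on the preserved/Xa+ boundary;
        preserved-Xi and two-Xa are never confused at default separation."""
        meth, expr, seg, clin, man, truth = small_cohort
        calls = classify_cohort(meth, man, seg, expr, clin)
        merged = calls.set_index("sample_id").join(truth.df)
        acc = (merged["xci_group"] == merged["true_xci"]).mean()
        assert acc >= 0.95
        confused = merged[
            (merged["true_xci"] == "preserved_Xi") & (merged["xci_group"] == "two_Xa")
            | (merged["true_xci"] == "two_Xa") & (merged["xci_group"] == "preserved_Xi")
        ]
        # two-Xa tumors rescued as whole-X loss are not confusion errors
        confused = confused[~confused["flags"].str.contains("whole_X_loss")]
        assert len(confused) == 0

    def test_missing_xist_cohort_still_classified_with_flags(self):
        cfg = small_config(seed=13, missing_xist_fraction=0.7)
        meth, expr, seg, clin, man, truth = generate_cohort(cfg)
        calls = classify_cohort(meth, man, seg, expr, clin)
        assert len(calls) == len(truth.df)
        merged = calls.set_index("sample_id").join(truth.df)
        acc = (merged["xci_group"] == merged["true_xci"]).mean()
        assert acc >= 0.9  # methylation + CNV alone still carry the signal

    def test_per_sample_mode_recovers_states_without_clustering(self, small_cohort):
        meth, expr, seg, clin, man, truth = small_cohort
        calls = classify_cohort(
            meth, man, seg, expr, clin, InferenceConfig(per_sample_assignment=True)
        )
        merged = calls.set_index("sample_id").join(truth.df)
        assert (merged["xci_group"] == merged["true_xci"]).mean() >= 0.9

    def test_stratum_smaller_than_k_is_an_error(self):
        cfg = small_config(seed=1, n_samples={("serous", "preserved_Xi"): 2})
        meth, expr, seg, clin, man, truth = generate_cohort(cfg)
        with pytest.raises(ValidationError, match="smaller k"):
            classify_cohort(meth, man, seg, expr, clin)
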