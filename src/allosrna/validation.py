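"""Ground-truth evaluation of a pipeline run on simulated data.

Matches planted features to pipeline calls (miRNAs by name, siRNA loci by
genomic overlap with a called cluster) and computes recovery metrics for the
non-additivity classifier: recall of truly non-additive features, direction
(activated vs repressed) accuracy among recovered true positives, and the
false-positive count among truly additive features.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pipeline import RunResult
from .simulate import SimData


@dataclass
class RecoveryMetrics:
    n_true_nonadditive: int
    n_recovered: int
    n_sign_correct: int
    n_false_positive: int
    n_additive_true: int
    table: pd.DataFrame  # feature, kind, true category, called category

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_true_nonadditive if self.n_true_nonadditive else float("nan")

    @property
    def sign_accuracy(self) -> float:
        return self.n_sign_correct / self.n_recovered if self.n_recovered else float("nan")


def match_calls_to_truth(sim: SimData, result: RunResult,
                         f2_sample: str | None = None) -> pd.DataFrame:
    """Per planted feature, the pipeline's category call for one F2 sample.

    miRNA features are matched by name; siRNA features by >= 1 nt overlap of
    the planted locus with a called cluster (in merged-genome coordinates).
    Features without a matching call are labelled 'missing'.
    """
    mcalls = result.mirna_results.calls
    ccalls = result.sirna_results.calls
    if f2_sample is None:
        f2_sample = sorted(mcalls["sample"].unique())[0]
    mcalls = mcalls[mcalls["sample"] == f2_sample].set_index("feature")
    ccalls = ccalls[ccalls["sample"] == f2_sample].set_index("feature")

    rows = []
    truth_by_feature = sim.truth.drop_duplicates("feature_id").set_index("feature_id")
    for fid, row in sim.features.set_index("feature_id").iterrows():
        if row["kind"] == "mirna":
            called = (mcalls.loc[fid, "category"]
                      if fid in mcalls.index else "missing")
        else:
            locus = truth_by_feature.loc[fid]
            chrom = f"{locus.subgenome}_{locus.chrom}"
            overlapping = [c.cluster_id for c in result.clusters
                           if c.chrom == chrom and c.start < locus.end
                           and c.end > locus.start]
            called = (ccalls.loc[overlapping[0], "category"]
                      if overlapping and overlapping[0] in ccalls.index
                      else "missing")
        rows.append((fid, row["kind"], row["category"], called))
    return pd.DataFrame(rows, columns=["feature", "kind", "true", "called"])


def recovery_metrics(sim: SimData, result: RunResult,
                     f2_sample: str | None = None) -> RecoveryMetrics:
    table = match_calls_to_truth(sim, result, f2_sample)
    nonadd = table[table["true"] != "additive"]
    recovered = nonadd[nonadd["called"].isin(["activated", "repressed"])]
    additive = table[table["true"] == "additive"]
    fp = additive[additive["called"].isin(["activated", "repressed"])]
    return RecoveryMetrics(
        n_true_nonadditive=len(nonadd),
        n_recovered=len(recovered),
        n_sign_correct=int((recovered["true"] == recovered["called"]).sum()),
        n_false_positive=len(fp),
        n_additive_true=len(additive),
        table=table,
    )
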