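"""Mid-parent-value (MPV) non-additivity testing and classification.

The additive expectation for a hybrid is the arithmetic mean of its parents'
expression (the MPV). Each F2 sample is compared with the MPV per feature:

* miRNA counts use a DEGseq-style two-proportion binomial z-test on pooled
  library counts. The MPV pseudo-sample rescales each parent's pooled count to
  the F2 pooled depth and combines them (pseudo-depth = twice the F2 depth),
  so the estimated pseudo-proportion is exactly the average of the parental
  proportions while the test's assumed variance matches the sampling variance.
* siRNA cluster RPMs use a two-sample pooled-variance Student t-test of the
  F2 replicates against per-replicate MPVs (replicate-paired parent means).

P-values are Benjamini-Hochberg adjusted per F2 sample; a feature is called
non-additive when both p <= alpha and FDR <= fdr_alpha, and is *activated*
(F2 > MPV) or *repressed* (F2 < MPV). Dominance (high-parent / low-parent /
intermediate) is recorded for every feature regardless of significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
FDR_ALPHA = 0.05
LOG2_OFFSET = 0.25

CATEGORIES = ("additive", "activated", "repressed")
DOMINANCE = ("high-parent", "low-parent", "intermediate")


@dataclass(frozen=True)
class MPVRecord:
    feature_id: str
    p1_rpm: float
    p2_rpm: float
    mpv_pseudo_count: int   # parent counts rescaled to F2 depth, combined
    mpv_pseudo_total: int   # 2 x pooled F2 depth

    @property
    def mpv(self) -> float:
        return (self.p1_rpm + self.p2_rpm) / 2.0


@dataclass(frozen=True)
class NonAdditivityCall:
    feature_id: str
    sample_id: str
    log2_ratio: float
    statistic: float
    pvalue: float
    fdr: float
    category: str
    dominance: str


def binomial_z_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test p-value (DEGseq-style).

    Pooled p = (k1+k2)/(n1+n2); z = (k1/n1 - k2/n2) / sqrt(p(1-p)(1/n1+1/n2)).
    Both counts zero (or both proportions saturated) give p = 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("library totals must be positive")
        if k < 0 or k > n:
            raise ValueError(f"count {k} outside [0, {n}]")
    z, p = _binomial_z_vec(np.array([k1]), n1, np.array([k2]), n2)
    return float(p[0])


def _binomial_z_vec(k1: np.ndarray, n1: float, k2: np.ndarray,
                    n2: float) -> tuple[np.ndarray, np.ndarray]:
    k1 = np.asarray(k1, float)
    k2 = np.asarray(k2, float)
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    diff = k1 / n1 - k2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.clip(p, 0.0, 1.0)


def t_test(rep_a, rep_b) -> float:
    """Two-sided pooled-variance Student t-test p-value.

    Degenerate conventions: zero pooled variance with equal means -> p = 1;
    zero pooled variance with unequal means -> p = 0.
    """
    a = np.asarray(rep_a, float)
    b = np.asarray(rep_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group; use the count-level "
                         "z-test for unreplicated comparisons")
    t, p = _t_test_vec(a[None, :], b[None, :])
    return float(p[0])


def _t_test_vec(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se == 0
    p = np.where(zero_var & (diff == 0), 1.0, p)
    p = np.where(zero_var & (diff != 0), 0.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (diff != 0),
                     np.where(diff > 0, np.inf, -np.inf), t)
    return t, np.clip(p, 0.0, 1.0)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(f2_rpm: float, p1_rpm: float, p2_rpm: float, pvalue: float,
             fdr: float, alpha: float = ALPHA, fdr_alpha: float = FDR_ALPHA,
             log2_offset: float = LOG2_OFFSET) -> tuple[str, str, float]:
    """Non-additivity category, dominance class, and offset log2(F2/MPV)."""
    mpv = (p1_rpm + p2_rpm) / 2.0
    log2fc = float(np.log2((f2_rpm + log2_offset) / (mpv + log2_offset)))
    if pvalue <= alpha and fdr <= fdr_alpha and f2_rpm > mpv:
        category = "activated"
    elif pvalue <= alpha and fdr <= fdr_alpha and f2_rpm < mpv:
        category = "repressed"
    else:
        category = "additive"
    if f2_rpm > max(p1_rpm, p2_rpm):
        dominance = "high-parent"
    elif f2_rpm < min(p1_rpm, p2_rpm):
        dominance = "low-parent"
    else:
        dominance = "intermediate"
    return category, dominance, log2fc


class NonAdditivityModel:
    """F2-vs-MPV non-additivity model over an expression count matrix.

    Parameters
    ----------
    counts : DataFrame
        Features x samples raw counts (one column per replicate library).
    sample_info : DataFrame
        Indexed by sample (column) name, with columns ``genotype`` (P1 / P2 /
        F2), ``group`` (F2 plant id; parents may reuse the genotype) and
        ``replicate``.
    library_sizes : Series
        Clean-read totals per sample, the RPM denominator.
    method : {"ztest", "ttest"}
        Count-level binomial z-test (miRNAs) or replicate t-test on RPMs
        (siRNA clusters).
    """

    def __init__(self, counts: pd.DataFrame, sample_info: pd.DataFrame,
                 library_sizes: pd.Series, method: str = "ztest",
                 log2_offset: float = LOG2_OFFSET):
        if method not in ("ztest", "ttest"):
            raise ValueError("method must be 'ztest' or 'ttest'")
        missing = set(counts.columns) - set(sample_info.index)
        if missing:
            raise ValueError(f"samples missing from sample_info: {sorted(missing)}")
        self.counts = counts
        self.info = sample_info.loc[list(counts.columns)].copy()
        if "group" not in self.info:
            self.info["group"] = self.info["genotype"]
        self.lib = library_sizes.astype(float)
        self.method = method
        self.log2_offset = log2_offset
        for parent in ("P1", "P2"):
            if not (self.info["genotype"] == parent).any():
                raise ValueError(f"no {parent} samples in design")
        self.f2_groups = sorted(self.info.loc[self.info["genotype"] == "F2", "group"].unique())
        if not self.f2_groups:
            raise ValueError("no F2 samples in design")

    def _cols(self, genotype: str, group: str | None = None) -> list[str]:
        m = self.info["genotype"] == genotype
        if group is not None:
            m &= self.info["group"] == group
        cols = self.info.index[m]
        # replicate-ordered for stable parent pairing in the t-test path
        return list(cols[np.argsort(self.info.loc[cols, "replicate"].to_numpy())])

    def fit(self, alpha: float = ALPHA, fdr_alpha: float = FDR_ALPHA) -> "NonAdditivityResults":
        frames = [self._fit_group(g, alpha, fdr_alpha) for g in self.f2_groups]
        calls = pd.concat(frames, ignore_index=True)
        return NonAdditivityResults(self, calls, alpha, fdr_alpha)

    # -- per-group fitting ------------------------------------------------

    def _rpm_matrix(self, cols: list[str]) -> np.ndarray:
        return (self.counts[cols].to_numpy(float)
                / self.lib[cols].to_numpy(float)) * 1e6

    def _fit_group(self, group: str, alpha: float, fdr_alpha: float) -> pd.DataFrame:
        p1_cols = self._cols("P1")
        p2_cols = self._cols("P2")
        f2_cols = self._cols("F2", group)

        k_p1 = self.counts[p1_cols].sum(axis=1).to_numpy(float)
        k_p2 = self.counts[p2_cols].sum(axis=1).to_numpy(float)
        k_f2 = self.counts[f2_cols].sum(axis=1).to_numpy(float)
        n_p1 = float(self.lib[p1_cols].sum())
        n_p2 = float(self.lib[p2_cols].sum())
        n_f2 = float(self.lib[f2_cols].sum())

        p1_rpm = k_p1 / n_p1 * 1e6
        p2_rpm = k_p2 / n_p2 * 1e6
        f2_rpm = k_f2 / n_f2 * 1e6
        mpv_rpm = (p1_rpm + p2_rpm) / 2.0

        if self.method == "ztest":
            # MPV pseudo-sample: parent counts rescaled to the F2 depth and
            # combined over a pseudo-depth of 2 x nF2
            k_mpv = np.round(k_p1 * n_f2 / n_p1 + k_p2 * n_f2 / n_p2)
            testable = ~((k_f2 == 0) & (k_mpv == 0))
            stat, pval = _binomial_z_vec(k_f2, n_f2, k_mpv, 2.0 * n_f2)
        else:
            f2_reps = self._rpm_matrix(f2_cols)
            p1_reps = self._rpm_matrix(p1_cols)
            p2_reps = self._rpm_matrix(p2_cols)
            n_pairs = min(p1_reps.shape[1], p2_reps.shape[1])
            if n_pairs < 2 or f2_reps.shape[1] < 2:
                raise ValueError("t-test path needs >= 2 replicates per side; "
                                 "use method='ztest' for unreplicated designs")
            mpv_reps = (p1_reps[:, :n_pairs] + p2_reps[:, :n_pairs]) / 2.0
            testable = ~((f2_reps.sum(axis=1) == 0) & (mpv_reps.sum(axis=1) == 0))
            stat, pval = _t_test_vec(f2_reps, mpv_reps)

        fdr = np.full(len(pval), np.nan)
        if testable.any():
            fdr[testable] = bh_fdr(pval[testable])
        pval = np.where(testable, pval, np.nan)
        stat = np.where(testable, stat, np.nan)

        rows = []
        for i, feature in enumerate(self.counts.index):
            if testable[i]:
                category, dominance, log2fc = classify(
                    f2_rpm[i], p1_rpm[i], p2_rpm[i], pval[i], fdr[i],
                    alpha, fdr_alpha, self.log2_offset)
            else:
                category, dominance, log2fc = "untestable", "intermediate", 0.0
            rows.append((feature, group, p1_rpm[i], p2_rpm[i], mpv_rpm[i],
                         f2_rpm[i], log2fc, stat[i], pval[i], fdr[i],
                         category, dominance, bool(testable[i])))
        return pd.DataFrame(rows, columns=[
            "feature", "sample", "p1_rpm", "p2_rpm", "mpv_rpm", "f2_rpm",
            "log2fc", "statistic", "pvalue", "fdr", "category", "dominance",
            "tested"])


class NonAdditivityResults:
    """Fitted non-additivity calls with summary tables."""

    def __init__(self, model: NonAdditivityModel, calls: pd.DataFrame,
                 alpha: float, fdr_alpha: float):
        self.model = model
        self.calls = calls
        self.alpha = alpha
        self.fdr_alpha = fdr_alpha

    def category_counts(self) -> pd.DataFrame:
        """Per-F2-sample activated / repressed / additive counts."""
        tested = self.calls[self.calls["tested"]]
        table = (tested.groupby(["sample", "category"]).size().unstack(fill_value=0)
                 .reindex(columns=list(CATEGORIES), fill_value=0))
        table.columns.name = None
        return table

    def dominance_counts(self) -> pd.DataFrame:
        tested = self.calls[self.calls["tested"]]
        table = (tested.groupby(["sample", "dominance"]).size().unstack(fill_value=0)
                 .reindex(columns=list(DOMINANCE), fill_value=0))
        table.columns.name = None
        return table

    def log2fc_distribution(self, edges=(-np.inf, -4, -3, -2, -1, 0, 1, 2, 3, 4, np.inf)
                            ) -> pd.DataFrame:
        """Counts of tested features per log2(F2/MPV) bin, per F2 sample."""
        tested = self.calls[self.calls["tested"]].copy()
        labels = [f"[{lo},{hi})" for lo, hi in zip(edges[:-1], edges[1:])]
        tested["bin"] = pd.cut(tested["log2fc"], bins=list(edges), labels=labels,
                               right=False)
        table = (tested.groupby(["sample", "bin"], observed=False).size()
                 .unstack(fill_value=0))
        table.columns.name = None
        return table

    def nonadditive(self) -> pd.DataFrame:
        return self.calls[self.calls["category"].isin(["activated", "repressed"])]

    def summary(self) -> str:
        lines = [
            "Non-additive expression vs mid-parent value",
            "=" * 60,
            f"method: {'binomial z-test (count level)' if self.model.method == 'ztest' else 'Student t-test (replicate RPM)'}",
            f"features: {self.calls['feature'].nunique()}   "
            f"F2 samples: {len(self.model.f2_groups)}",
            f"thresholds: p <= {self.alpha}, BH FDR <= {self.fdr_alpha}",
            "",
            "category counts (tested features)",
            self.category_counts().to_string(),
            "",
            "dominance classes",
            self.dominance_counts().to_string(),
        ]
        untestable = int((~self.calls["tested"]).sum())
        if untestable:
            lines.append("")
            lines.append(f"untestable feature/sample pairs (F2 = MPV = 0): {untestable}")
        return "\n".join(lines)
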