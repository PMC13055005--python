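"""Allelic-imbalance classification across flower stages.

Per stage, the pooled hap1 count of each allele pair is tested against the
library-size expectation with an exact two-sided binomial test; significance
requires a Benjamini–Hochberg FDR below alpha AND a fold-change of at least
``min_fc`` after library-size normalization. Pairs significant in every
stage with the same favored haplotype are "consistent", pairs never
significant are "noASE", everything else is "inconsistent".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rpkm(count: float, library_total: float, gene_length_bp: float) -> float:
    """Reads per kilobase per million mapped reads: 1e9*C/(N*L)."""
    if library_total <= 0 or gene_length_bp <= 0:
        raise ValueError("library total and gene length must be positive")
    return 1e9 * count / (library_total * gene_length_bp)


@dataclass
class StageTestResult:
    pair_id: str
    stage: int
    count1: int
    count2: int
    ratio: float
    log2fc: float
    p: float
    fdr: float
    significant: bool
    favored: str  # hap1 | hap2 | none
    tested: bool = True


@dataclass
class ASECall:
    pair_id: str
    ase_class: str  # consistent | inconsistent | noASE
    favored: str | None
    n_significant: int
    incomplete: bool = False
    stage_results: list[StageTestResult] = field(default_factory=list)


def pool_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate counts to (gene_id, haplotype, stage) pooled counts."""
    pooled = (counts.groupby(["gene_id", "haplotype", "stage"], sort=True)["count"]
              .sum().unstack("haplotype").reset_index())
    pooled.columns.name = None
    return pooled.rename(columns={"hap1": "count1", "hap2": "count2"})


def stage_test(counts: pd.DataFrame, stage: int, alpha: float = 0.05,
               min_fc: float = 2.0) -> list[StageTestResult]:
    """Exact binomial ASE test for one stage, FDR across pairs within it.

    The null proportion p0 = T1/(T1+T2) uses the haplotype library totals of
    the stage, so a global mapping imbalance is not called as ASE. log2FC is
    computed from library-size-normalized pooled counts with pseudocount 0.5.
    """
    pooled = pool_counts(counts)
    sub = pooled[pooled["stage"] == stage]
    if sub.empty:
        return []
    T1, T2 = float(sub["count1"].sum()), float(sub["count2"].sum())
    if T1 + T2 <= 0:
        return [StageTestResult(r.gene_id, stage, 0, 0, np.nan, np.nan, np.nan,
                                np.nan, False, "none", tested=False)
                for r in sub.itertuples(index=False)]
    p0 = T1 / (T1 + T2)
    results: list[StageTestResult] = []
    pvals, tested_idx = [], []
    for i, r in enumerate(sub.itertuples(index=False)):
        c1, c2 = int(r.count1), int(r.count2)
        if c1 + c2 == 0:
            results.append(StageTestResult(r.gene_id, stage, 0, 0, np.nan, np.nan,
                                           np.nan, np.nan, False, "none", tested=False))
            continue
        p = stats.binomtest(c1, c1 + c2, p0, alternative="two-sided").pvalue
        norm1 = (c1 + 0.5) / T1
        norm2 = (c2 + 0.5) / T2
        l2fc = float(np.log2(norm1 / norm2))
        res = StageTestResult(r.gene_id, stage, c1, c2, norm1 / norm2, l2fc,
                              float(p), np.nan, False, "none")
        tested_idx.append(len(results))
        pvals.append(p)
        results.append(res)
    if pvals:
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for k, i in enumerate(tested_idx):
            r = results[i]
            r.fdr = float(fdr[k])
            if r.fdr < alpha and abs(r.log2fc) >= np.log2(min_fc):
                r.significant = True
                r.favored = "hap1" if r.log2fc > 0 else "hap2"
    return results


def classify_ase(stage_results: list[StageTestResult],
                 n_stages: int = 4) -> list[ASECall]:
    """Trichotomy per pair: consistent / inconsistent / noASE.

    Consistent requires significance in all stages with one favored
    haplotype; pairs with untested stages are flagged incomplete and can
    never be consistent.
    """
    by_pair: dict[str, list[StageTestResult]] = {}
    for r in stage_results:
        by_pair.setdefault(r.pair_id, []).append(r)
    calls = []
    for pair_id in sorted(by_pair):
        rs = sorted(by_pair[pair_id], key=lambda r: r.stage)
        tested = [r for r in rs if r.tested]
        sig = [r for r in tested if r.significant]
        incomplete = len(tested) < n_stages
        favored = None
        if not sig:
            cls = "noASE"
        elif (not incomplete and len(sig) == n_stages
              and len({r.favored for r in sig}) == 1):
            cls = "consistent"
            favored = sig[0].favored
        else:
            cls = "inconsistent"
        calls.append(ASECall(pair_id, cls, favored, len(sig), incomplete, rs))
    return calls


def classify_from_counts(counts: pd.DataFrame, n_stages: int = 4,
                         alpha: float = 0.05, min_fc: float = 2.0) -> list[ASECall]:
    results: list[StageTestResult] = []
    for stage in range(1, n_stages + 1):
        results.extend(stage_test(counts, stage, alpha=alpha, min_fc=min_fc))
    return classify_ase(results, n_stages=n_stages)


def summarize_classes(calls) -> dict:
    """Counts and 2-decimal percentages per class.

    ``calls`` may be ASECall objects or plain class-label strings.
    """
    labels = [c.ase_class if isinstance(c, ASECall) else str(c) for c in calls]
    if not labels:
        raise ValueError("no calls to summarize")
    total = len(labels)
    out = {"total": total, "counts": {}, "percent": {}}
    for cls in ("consistent", "inconsistent", "noASE"):
        k = labels.count(cls)
        out["counts"][cls] = k
        out["percent"][cls] = round(100.0 * k / total, 2)
    return out


def calls_table(calls: list[ASECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.pair_id, c.ase_class, c.favored or "", c.n_significant, c.incomplete)
         for c in calls],
        columns=["pair_id", "class", "favored", "n_significant", "incomplete"],
    )


def stage_results_table(results: list[StageTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pair_id, r.stage, r.count1, r.count2, r.log2fc, r.p, r.fdr,
          r.significant, r.favored, r.tested) for r in results],
        columns=["pair_id", "stage", "count1", "count2", "log2fc", "p", "fdr",
                 "significant", "favored", "tested"],
    )
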