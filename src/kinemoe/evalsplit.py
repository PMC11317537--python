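"""Splitting, evaluation metrics, significance tests and subtest partitions.

Splits are stratified by label pattern (both / kcat-only / Km-only) at an
8:1:1 train/validation/test ratio, so the three patterns stay balanced
across the splits.  Metrics are the Pearson correlation coefficient,
coefficient of determination and root-mean-squared error computed on the
log10 scale, plus a two-sided t-test p-value for the PCC and a two-sided
Wilcoxon rank-sum test for group comparisons.  Subtest partitions mirror
the evaluation protocol: wild-type vs mutant, promiscuity (preferred vs
alternative substrates of multi-substrate enzymes), mutant fold-change
categories relative to the wild-type, and a strict subset of test entries
whose enzyme sequence and substrate are both unseen in training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import CuratedEntry, EnzymeType, ParamKind

__all__ = [
    "SplitSpec",
    "MetricReport",
    "CaseStudyResult",
    "stratified_split",
    "pcc",
    "r2",
    "rmse",
    "pcc_p_value",
    "rank_sum_test",
    "metric_report",
    "partition_enzyme_type",
    "partition_promiscuity",
    "FoldChange",
    "classify_fold_change",
    "strict_unseen_subset",
    "hit_ratio",
    "relative_improvement",
]


@dataclass
class SplitSpec:
    """8:1:1 stratified split specification."""

    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.ratios), 1.0, abs_tol=1e-9):
            raise ValueError("split ratios must sum to 1")


def _largest_remainder(n: int, ratios: Sequence[float]) -> List[int]:
    """Integer allocation of n by floor + largest remainder."""
    raw = [n * r for r in ratios]
    base = [int(math.floor(x)) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(
    entries: Sequence[CuratedEntry], spec: SplitSpec
) -> Tuple[List[CuratedEntry], List[CuratedEntry], List[CuratedEntry]]:
    """Split each label-pattern stratum 8:1:1 independently, then union.

    Strata with fewer than 3 entries go entirely to the training split.
    """
    rng = np.random.default_rng(spec.seed)
    strata: Dict[str, List[CuratedEntry]] = {}
    for e in entries:
        strata.setdefault(e.label_pattern, []).append(e)
    train: List[CuratedEntry] = []
    val: List[CuratedEntry] = []
    test: List[CuratedEntry] = []
    for pattern in sorted(strata):
        grp = strata[pattern]
        if len(grp) < 3:
            train.extend(grp)
            continue
        sizes = _largest_remainder(len(grp), spec.ratios)
        perm = rng.permutation(len(grp))
        cut1, cut2 = sizes[0], sizes[0] + sizes[1]
        train.extend(grp[i] for i in perm[:cut1])
        val.extend(grp[i] for i in perm[cut1:cut2])
        test.extend(grp[i] for i in perm[cut2:])
    return train, val, test


# ----------------------------------------------------------------------
# metrics


def _as_pair(y_e, y_p) -> Tuple[np.ndarray, np.ndarray]:
    y_e = np.asarray(y_e, dtype=float)
    y_p = np.asarray(y_p, dtype=float)
    if y_e.shape != y_p.shape or y_e.ndim != 1:
        raise ValueError("metric inputs must be 1-D vectors of equal length")
    return y_e, y_p


def pcc(y_e: Sequence[float], y_p: Sequence[float]) -> float:
    """Pearson correlation between experimental and predicted values."""
    y_e, y_p = _as_pair(y_e, y_p)
    if y_e.size < 2:
        raise ValueError("PCC requires n >= 2")
    de = y_e - y_e.mean()
    dp = y_p - y_p.mean()
    denom = math.sqrt((de**2).sum()) * math.sqrt((dp**2).sum())
    if denom == 0:
        raise ValueError("PCC undefined for zero-variance input")
    return float((de * dp).sum() / denom)


def r2(y_e: Sequence[float], y_p: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot; can be negative."""
    y_e, y_p = _as_pair(y_e, y_p)
    if y_e.size < 2:
        raise ValueError("R^2 requires n >= 2")
    ss_tot = ((y_e - y_e.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant experimental values")
    return float(1.0 - ((y_e - y_p) ** 2).sum() / ss_tot)


def rmse(y_e: Sequence[float], y_p: Sequence[float]) -> float:
    """Root-mean-squared error."""
    y_e, y_p = _as_pair(y_e, y_p)
    if y_e.size == 0:
        raise ValueError("RMSE requires n >= 1")
    return float(math.sqrt(((y_p - y_e) ** 2).mean()))


def pcc_p_value(pcc_value: float, n: int) -> float:
    """Two-sided Student t-test p-value for a Pearson correlation.

    t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; |r| = 1
    returns 0 by convention.
    """
    if n < 3:
        raise ValueError("p-value for PCC requires n >= 3")
    if abs(pcc_value) >= 1.0:
        return 0.0
    t = pcc_value * math.sqrt(n - 2) / math.sqrt(1.0 - pcc_value**2)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration over all C(n1+n2, n1) assignments of the pooled
    midranks when min(n1, n2) <= 8; otherwise the tie-corrected normal
    approximation.  Degenerate pooled samples (everything tied) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if min(n1, n2) <= 8 and math.comb(n1 + n2, n1) <= 500_000:
        dev_obs = abs(w_obs - mean_w)
        total = 0
        hits = 0
        for comb in combinations(range(n1 + n2), n1):
            total += 1
            w = ranks[list(comb)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-9:
                hits += 1
        return hits / total

    # tie-corrected normal approximation
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    n = n1 + n2
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w == 0:
        return 1.0
    z = (w_obs - mean_w) / math.sqrt(var_w)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class MetricReport:
    """Evaluation summary for one (task, subset) pair."""

    task: str
    subset: str
    n: int
    pcc: float
    r2: float
    rmse: float
    p_value: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def metric_report(
    task: str, subset: str, y_e: Sequence[float], y_p: Sequence[float]
) -> MetricReport:
    """All three metrics plus the PCC t-test p-value for one subset."""
    r = pcc(y_e, y_p)
    return MetricReport(
        task=task,
        subset=subset,
        n=len(y_e),
        pcc=r,
        r2=r2(y_e, y_p),
        rmse=rmse(y_e, y_p),
        p_value=pcc_p_value(r, len(y_e)),
    )


# ----------------------------------------------------------------------
# subtest partitions


def partition_enzyme_type(
    test_entries: Sequence[CuratedEntry],
) -> Dict[str, List[CuratedEntry]]:
    """Disjoint wild-type / mutant cover of the test set."""
    out = {"wild_type": [], "mutant": []}
    for e in test_entries:
        out[e.enzyme_type.value].append(e)
    return out


def partition_promiscuity(
    wild_test_entries: Sequence[CuratedEntry], task: ParamKind
) -> Dict[str, List[CuratedEntry]]:
    """Preferred vs alternative substrates of promiscuous wild-type enzymes.

    Enzymes (grouped by sequence) acting on >= 2 substrates are promiscuous;
    the substrate with the highest experimental kcat (or lowest Km) is
    preferred, the rest alternative.  Ties for the extremum make all tied
    substrates preferred.  Single-substrate enzymes are excluded.
    """
    label = (
        (lambda e: e.log10_kcat) if task == ParamKind.KCAT else (lambda e: e.log10_km)
    )
    by_seq: Dict[str, List[CuratedEntry]] = {}
    for e in wild_test_entries:
        if label(e) is None:
            continue
        by_seq.setdefault(e.sequence, []).append(e)
    out = {"preferred": [], "alternative": [], "non_promiscuous": []}
    for seq, grp in by_seq.items():
        substrates = {g.canonical_smiles for g in grp}
        if len(substrates) < 2:
            out["non_promiscuous"].extend(grp)
            continue
        values = [label(g) for g in grp]
        best = max(values) if task == ParamKind.KCAT else min(values)
        for g in grp:
            if label(g) == best:
                out["preferred"].append(g)
            else:
                out["alternative"].append(g)
    return out


class FoldChange(str, Enum):
    WILD_TYPE_LIKE = "wild_type_like"
    INCREASED = "increased"
    DECREASED = "decreased"


def classify_fold_change(mutant_value: float, wild_value: float) -> FoldChange:
    """Category of a mutant's linear-scale value relative to the wild-type.

    Ratio in [0.5, 2.0] is wild-type-like; above 2.0 increased; below 0.5
    decreased.  Both values must be positive (linear scale).
    """
    if mutant_value <= 0 or wild_value <= 0:
        raise ValueError("fold change requires positive linear-scale values")
    ratio = mutant_value / wild_value
    if ratio > 2.0:
        return FoldChange.INCREASED
    if ratio < 0.5:
        return FoldChange.DECREASED
    return FoldChange.WILD_TYPE_LIKE


def match_wild_type(
    mutant: CuratedEntry, wild_entries: Sequence[CuratedEntry]
) -> Optional[CuratedEntry]:
    """Closest wild-type reference for a mutant entry.

    Candidates share (EC number, organism, canonical substrate); the one with
    the closest (pH, temperature) pair wins.  None if no candidate exists.
    """
    cands = [
        w
        for w in wild_entries
        if w.ec_number == mutant.ec_number
        and w.organism == mutant.organism
        and w.canonical_smiles == mutant.canonical_smiles
    ]
    if not cands:
        return None
    return min(
        cands,
        key=lambda w: (w.ph - mutant.ph) ** 2 + (w.temperature - mutant.temperature) ** 2,
    )


def strict_unseen_subset(
    test_entries: Sequence[CuratedEntry], train_entries: Sequence[CuratedEntry]
) -> List[CuratedEntry]:
    """Test entries whose sequence AND substrate never occur in training."""
    train_seqs = {e.sequence for e in train_entries}
    train_subs = {e.canonical_smiles for e in train_entries}
    return [
        e
        for e in test_entries
        if e.sequence not in train_seqs and e.canonical_smiles not in train_subs
    ]


# ----------------------------------------------------------------------
# case-study hit ratio and comparison arithmetic


@dataclass
class CaseStudyResult:
    """Direction-match outcome of one mining / directed-evolution case."""

    reference_id: str
    hits: List[Tuple[str, int]]  # (variant id, hit in {0,1})
    excluded: List[str]  # variants tied with the reference
    hr: float


def hit_ratio(
    reference: Tuple[float, float],
    variants: Sequence[Tuple[str, float, float]],
    reference_id: str = "reference",
) -> CaseStudyResult:
    """Fraction of variants whose predicted efficiency change matches experiment.

    ``reference`` is (experimental efficiency, predicted efficiency) on the
    log10 scale (log10 kcat - log10 Km); each variant is
    (id, experimental efficiency, predicted efficiency).  A variant scores a
    hit when sign(pred - pred_ref) == sign(exp - exp_ref).  Exact ties with
    the reference on either scale are excluded and logged.
    """
    exp_ref, pred_ref = reference
    hits: List[Tuple[str, int]] = []
    excluded: List[str] = []
    for vid, exp_v, pred_v in variants:
        d_exp = exp_v - exp_ref
        d_pred = pred_v - pred_ref
        if d_exp == 0 or d_pred == 0:
            excluded.append(vid)
            continue
        hits.append((vid, int(np.sign(d_exp) == np.sign(d_pred))))
    if not hits:
        raise ValueError("no scorable variants (all tied with the reference)")
    hr = sum(h for _, h in hits) / len(hits)
    return CaseStudyResult(reference_id, hits, excluded, hr)


def relative_improvement(metric_new: float, metric_old: float) -> float:
    """Percent improvement of a metric over a baseline: 100*(new-old)/old."""
    if metric_old <= 0:
        raise ValueError("baseline metric must be positive")
    return 100.0 * (metric_new - metric_old) / metric_old
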