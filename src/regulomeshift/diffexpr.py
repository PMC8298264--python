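"""Differential expression / representation statistics.

Per-gene Student's t tests on replicate abundances (pooled-variance by
default, Welch by flag), log2 fold change on condition means with a
zero-handling floor, strict ``|log2FC| > 2`` selection at raw ``P < 0.05``,
qPCR ddCt fold changes, SWATH total-area-sum (TAS) normalization and the
minimum-peptide filter.

No multiple-testing correction is applied by default (selection uses raw
p-values); a Benjamini-Hochberg column is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ExpressionMatrix, KO, WT

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_CUT = 2.0
DEFAULT_FLOOR = 1.0


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    degenerate: bool = False  # zero variance in both groups


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    mean_wt: float
    mean_ko: float
    log2fc: float  # KO/WT scale
    t_stat: float
    p_value: float
    significant: bool
    selected: bool
    direction: str  # "up", "down" or ""


@dataclass
class QPCRRecord:
    """Target and reference Ct values for one group's replicates."""

    ct_target: Sequence[float]
    ct_reference: Sequence[float]
    group: str = ""

    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


@dataclass
class ProteinQuantTable:
    """Per-protein extracted-ion-chromatogram peak areas across samples."""

    areas: pd.DataFrame  # protein_id x sample
    peptide_count: pd.Series  # protein_id -> int

    def __post_init__(self) -> None:
        self.peptide_count = self.peptide_count.reindex(self.areas.index)
        arr = self.areas.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("areas must be finite and non-negative")


def condition_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean abundance per gene within each condition.

    Returns a frame indexed by gene with columns ``mean_wt`` and ``mean_ko``.
    """
    return pd.DataFrame(
        {
            "mean_wt": m.values[m.samples(WT)].mean(axis=1),
            "mean_ko": m.values[m.samples(KO)].mean(axis=1),
        }
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_variance: bool = True
) -> TTestResult:
    """Two-sided two-sample t test.

    Pooled-variance df is ``len(x)+len(y)-2``; the Welch variant uses the
    Welch-Satterthwaite df.  When both groups have zero variance the t
    statistic is undefined: equal means yield ``(t=0, p=1)`` and unequal
    means ``(t=+/-inf, p=0)``, both flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("replicate values must be finite")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        diff = x.mean() - y.mean()
        if diff == 0.0:
            return TTestResult(0.0, 1.0, np.nan, degenerate=True)
        return TTestResult(np.sign(diff) * np.inf, 0.0, np.nan,
                           degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       float(res.df), degenerate=False)


def log2_fold_change(mean_ko: float, mean_wt: float,
                     floor: float = DEFAULT_FLOOR) -> float:
    """log2(KO/WT) of condition means.

    The pseudo-value ``floor`` is added to both means only when either is
    zero, so fold changes of strictly positive means are exact.
    """
    if mean_ko < 0 or mean_wt < 0:
        raise ValueError("means must be non-negative")
    if mean_ko == 0.0 or mean_wt == 0.0:
        mean_ko, mean_wt = mean_ko + floor, mean_wt + floor
    return float(np.log2(mean_ko / mean_wt))


def differential_expression(
    m: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    lfc_cut: float = DEFAULT_LFC_CUT,
    equal_variance: bool = True,
    log_transform: bool = False,
    floor: float = DEFAULT_FLOOR,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene t test, log2 fold change and selection flags.

    ``log_transform`` tests log2(x+1)-transformed replicates instead of raw
    abundances.  ``bh_correct`` adds a Benjamini-Hochberg ``q_value`` column
    (selection still uses the raw p-value).
    """
    wt_cols, ko_cols = m.samples(WT), m.samples(KO)
    wt = m.values[wt_cols].to_numpy(dtype=float)
    ko = m.values[ko_cols].to_numpy(dtype=float)
    means = condition_means(m)
    txw, txk = (np.log2(wt + 1.0), np.log2(ko + 1.0)) if log_transform \
        else (wt, ko)
    rows = []
    for i, gene in enumerate(m.gene_ids):
        tt = two_sample_t(txk[i], txw[i], equal_variance=equal_variance)
        lfc = log2_fold_change(means.iloc[i]["mean_ko"],
                               means.iloc[i]["mean_wt"], floor=floor)
        rows.append((gene, means.iloc[i]["mean_wt"], means.iloc[i]["mean_ko"],
                     lfc, tt.t, tt.p))
    df = pd.DataFrame(
        rows, columns=["gene_id", "mean_wt", "mean_ko", "log2fc", "t", "p"]
    )
    df["significant"] = df["p"] < alpha
    df["selected"] = df["significant"] & (df["log2fc"].abs() > lfc_cut)
    df["direction"] = np.where(
        ~df["selected"], "", np.where(df["log2fc"] > 0, "up", "down")
    )
    if bh_correct:
        df["q_value"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out


def select_de_genes(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Significantly regulated genes with ``|log2FC|`` strictly above the cut.

    Keeps rows with ``p < alpha`` and ``log2fc < -lfc_cut or log2fc >
    +lfc_cut`` (boundary values excluded), labelling direction by the sign
    of the fold change.
    """
    if len(results) == 0:
        return results.copy()
    keep = (results["p"] < alpha) & (results["log2fc"].abs() > lfc_cut)
    out = results[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def ddct_fold_change(test: QPCRRecord, control: QPCRRecord) -> float:
    """Relative expression by the ddCt method: fold = 2^-(ddCt).

    ddCt = (mean target Ct - mean reference Ct) in the test group minus the
    same quantity in the control group.
    """
    ddct = test.delta_ct() - control.delta_ct()
    return float(2.0 ** (-ddct))


def tas_normalize(t: ProteinQuantTable) -> ProteinQuantTable:
    """Global normalization by Total Area Sums.

    Each sample's areas are rescaled so its column total equals the mean of
    the original per-sample totals; within-sample relative abundances are
    unchanged.
    """
    totals = t.areas.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total area")
    target = totals.mean()
    scaled = t.areas * (target / totals)
    return ProteinQuantTable(scaled, t.peptide_count.copy())


def filter_by_peptide_count(
    t: ProteinQuantTable, min_peptides: int = 3
) -> ProteinQuantTable:
    """Keep proteins quantified from at least ``min_peptides`` peptides."""
    keep = t.peptide_count >= min_peptides
    return ProteinQuantTable(t.areas[keep.to_numpy()].copy(),
                             t.peptide_count[keep].copy())
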