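"""Peptide-array analytics: background normalization and spot statistics.

Arrays carry relative fluorescence units (RFUs) per peptide spot plus a set
of empty control spots.  Normalization subtracts (default) or divides by the
mean empty-spot background; peptides are then compared between a test
protein and a negative-control protein by per-peptide two-sample t tests,
with a one-way ANOVA available for multi-group layouts.

With only two technical replicates per spot, zero-variance comparisons are
common; they are flagged (p set to 1 for equal means) rather than raised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import two_sample_t

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["peptide_id", "replicate", "rfu", "is_empty_control"]


@dataclass
class PeptideArray:
    """One protein's array: spot table plus label.

    ``spots`` columns: peptide_id, replicate, rfu (>= 0 before
    normalization; subtract-mode output is floored at 0), is_empty_control.
    """

    spots: pd.DataFrame
    protein_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns {missing}")
        if not self.spots["is_empty_control"].any():
            raise ValueError("array must contain >=1 empty control spot")

    def background(self) -> float:
        empty = self.spots[self.spots["is_empty_control"].astype(bool)]
        return float(empty["rfu"].mean())

    def replicates_of(self, peptide_id: str) -> np.ndarray:
        s = self.spots
        mask = (~s["is_empty_control"].astype(bool)) & \
            (s["peptide_id"] == peptide_id)
        return s.loc[mask, "rfu"].to_numpy(dtype=float)

    def peptide_ids(self) -> list[str]:
        s = self.spots[~self.spots["is_empty_control"].astype(bool)]
        return sorted(s["peptide_id"].unique())


def read_array(path, protein_label: str = "") -> PeptideArray:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"is_empty": "is_empty_control"})
    return PeptideArray(df, protein_label)


def write_array(a: PeptideArray, path) -> None:
    a.spots.to_csv(path, sep="\t", index=False)


def normalize_empty_spots(a: PeptideArray,
                          mode: str = "subtract") -> PeptideArray:
    """Normalize RFUs against the mean of the empty control spots.

    subtract: rfu - background, floored at 0 (background correction).
    ratio: rfu / background (requires background > 0).
    """
    b = a.background()
    out = a.spots.copy()
    if mode == "subtract":
        out["rfu"] = np.maximum(out["rfu"] - b, 0.0)
    elif mode == "ratio":
        if b <= 0:
            raise ValueError("ratio normalization needs background > 0")
        out["rfu"] = out["rfu"] / b
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PeptideArray(out, a.protein_label)


def compare_arrays(
    test: PeptideArray,
    control: PeptideArray,
    alpha: float = 0.05,
    equal_variance: bool = True,
) -> pd.DataFrame:
    """Per-peptide two-sided t test between test and control arrays.

    Peptides missing from either array are skipped with a warning.  Columns:
    peptide_id, mean_test, mean_control, t, p, significant, zero_variance.
    """
    rows = []
    control_ids = set(control.peptide_ids())
    for pep in test.peptide_ids():
        if pep not in control_ids:
            warnings.warn(f"peptide {pep!r} missing from control array; "
                          "skipped", stacklevel=2)
            continue
        x = test.replicates_of(pep)
        y = control.replicates_of(pep)
        tt = two_sample_t(x, y, equal_variance=equal_variance)
        rows.append({
            "peptide_id": pep,
            "mean_test": float(x.mean()),
            "mean_control": float(y.mean()),
            "t": tt.t,
            "p": tt.p,
            "significant": tt.p < alpha,
            "zero_variance": tt.degenerate,
        })
    return pd.DataFrame(rows, columns=[
        "peptide_id", "mean_test", "mean_control", "t", "p", "significant",
        "zero_variance",
    ])


def one_way_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float, int, int]:
    """Classical one-way fixed-effects ANOVA.

    Returns (F, p, df_between, df_within) with F = MSB/MSW,
    df_between = k - 1, df_within = N - k.  All-identical data yield
    (F=0, p=1); zero within-group variance with distinct means yields
    (F=inf, p=0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0, df_b, df_w
        return float("inf"), 0.0, df_b, df_w
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p, df_b, df_w
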