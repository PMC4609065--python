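"""The integrated minor-allele predictive index.

The index of a sample is its total minor-allele count over a small set of
predictive SNPs (for two SNPs: values 0-4; the motivating case is a
two-polymorphism index over EGFR- and ANXA3-linked SNPs).  Samples missing any
constituent genotype get a missing index and are excluded from the tables.
The module tabulates per-level response rates
RR = 100 * (CR+PR) / (CR+PR + NC+PD), tests the level x response table with
the exact r x c test, and dichotomizes at a configurable threshold
(default: index >= 2) for a 2x2 Fisher test and ROC analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import GenotypeDataset
from .models import RocCurve, roc_curve
from .stats import fisher_exact_2x2, fisher_exact_rxc

__all__ = ["IndexResult", "compute_index", "index_contingency", "dichotomize", "index_roc"]


@dataclass
class IndexResult:
    """Per-level contingency of the allele-count index against response."""

    levels: pd.DataFrame  # columns: level, n_resp, n_nonresp, rr_pct
    p_levels: float
    max_level: int
    n_analyzed: int

    def level_counts(self, level: int) -> tuple[int, int]:
        row = self.levels.loc[self.levels["level"] == level]
        if row.empty:
            return (0, 0)
        return int(row["n_resp"].iloc[0]), int(row["n_nonresp"].iloc[0])


def compute_index(genotypes: GenotypeDataset, snp_ids: list[str]) -> pd.Series:
    """Per-sample total minor-allele count over ``snp_ids``.

    Missing if any constituent genotype is missing; bounded by
    2 * len(snp_ids).
    """
    missing = [s for s in snp_ids if s not in genotypes.snp_ids]
    if missing:
        raise KeyError(f"SNP(s) not in dataset: {missing}")
    doses = genotypes.dose_frame(list(snp_ids))
    return doses.sum(axis=1, skipna=False).rename("index")


def index_contingency(index: pd.Series, responses: pd.Series) -> IndexResult:
    """Level x response-group table with per-level response rates.

    Rows span index levels 0..max observed; levels with no samples are
    omitted (flagged via a warning).  ``p_levels`` is the exact conditional
    p over the observed levels x (CR+PR, NC+PD) table.
    """
    df = pd.DataFrame({"index": index, "response": responses.loc[index.index]}).dropna()
    if df.empty:
        raise ValueError("index is missing for every sample")
    if df["response"].nunique() < 2:
        raise ValueError("both response groups must be present")
    df["index"] = df["index"].astype(int)
    max_level = int(df["index"].max())
    rows = []
    empty_levels = []
    for level in range(max_level + 1):
        sub = df[df["index"] == level]
        if len(sub) == 0:
            empty_levels.append(level)
            continue
        n_resp = int((sub["response"] == 1).sum())
        n_non = int((sub["response"] == 0).sum())
        rows.append(
            {
                "level": level,
                "n_resp": n_resp,
                "n_nonresp": n_non,
                "rr_pct": 100.0 * n_resp / (n_resp + n_non),
            }
        )
    if empty_levels:
        warnings.warn(f"index level(s) {empty_levels} have no samples; rows omitted", stacklevel=2)
    levels = pd.DataFrame(rows)
    table = levels[["n_resp", "n_nonresp"]].to_numpy()
    p = fisher_exact_rxc(table)
    return IndexResult(levels, p, max_level, int(len(df)))


def dichotomize(result: IndexResult, threshold: int = 2) -> tuple[np.ndarray, float]:
    """Collapse levels into (index >= threshold, index < threshold) x response.

    Returns the 2x2 table (rows: high index, low index; columns: responders,
    non-responders) and its two-sided Fisher p.  The threshold must split
    the observed levels into two non-empty groups.
    """
    lv = result.levels
    if threshold <= int(lv["level"].min()) or threshold > int(lv["level"].max()):
        raise ValueError(
            f"threshold {threshold} does not split the observed index levels"
        )
    high = lv[lv["level"] >= threshold]
    low = lv[lv["level"] < threshold]
    table = np.array(
        [
            [high["n_resp"].sum(), high["n_nonresp"].sum()],
            [low["n_resp"].sum(), low["n_nonresp"].sum()],
        ],
        dtype=np.int64,
    )
    return table, fisher_exact_2x2(table)


def index_roc(index: pd.Series, responses: pd.Series) -> RocCurve:
    """ROC treating the allele-count index as the predictive score."""
    df = pd.DataFrame({"index": index, "response": responses.loc[index.index]}).dropna()
    return roc_curve(df["index"].to_numpy(), df["response"].to_numpy(dtype=int))
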