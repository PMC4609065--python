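"""Basic genotype quality filtering and the knowledge-based SNP prefilter.

The knowledge-based step keeps SNPs with at least one literature (PubMed)
link and, optionally, removes SNPs already flagged as cancer-related — the
prefilter that shrinks a genome-wide panel to a literature-supported
candidate set before association screening.  The basic QC step applies the
conventional per-marker criteria: call rate, minor-allele frequency and an
exact Hardy-Weinberg test on the full cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import GenotypeDataset
from .stats import hwe_exact_test

__all__ = ["FilterConfig", "FilterReport", "knowledge_filter", "basic_qc", "apply_filters"]


@dataclass
class FilterConfig:
    """Thresholds for QC and the knowledge-based filter.

    Defaults are conventional GWAS per-marker QC values; they are explicit
    configuration, not study-derived constants.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    require_pubmed: bool = True
    exclude_cancer: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-SNP pass/fail per criterion plus stage survival counts."""

    per_snp: pd.DataFrame
    n_input: int
    n_pass_qc: int
    n_pass_kb: int | None = None
    n_retained: int | None = None

    @property
    def retained(self) -> set[str]:
        mask = self.per_snp["pass_all"]
        return set(self.per_snp.loc[mask, "snp_id"])


def knowledge_filter(annotations: pd.DataFrame, config: FilterConfig) -> set[str]:
    """Literature-based retention: PubMed-linked SNPs minus cancer-flagged ones.

    SNPs absent from the annotation table count as having no links.  With
    ``require_pubmed`` off, only the cancer exclusion applies (and vice
    versa).
    """
    if len(annotations) == 0:
        warnings.warn("empty annotation table: no SNPs retained", stacklevel=2)
        return set()
    keep = pd.Series(True, index=annotations.index)
    if config.require_pubmed:
        keep &= annotations["pubmed_ids"].map(len) > 0
    if config.exclude_cancer:
        keep &= ~annotations["cancer_flag"]
    return set(annotations.loc[keep, "snp_id"])


def basic_qc(genotypes: GenotypeDataset, config: FilterConfig) -> FilterReport:
    """Per-SNP call rate, MAF and HWE exact test against the config thresholds.

    MAF and HWE are computed on the non-missing calls of the supplied
    dataset (by design the full cohort, so orientation and QC agree).
    """
    if genotypes.n_samples == 0:
        raise ValueError("cannot run QC on a dataset with zero samples")
    calls = genotypes.calls
    n = genotypes.n_samples
    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        col = calls[:, j]
        ok = np.isfinite(col)
        n_called = int(ok.sum())
        call_rate = n_called / n
        if n_called:
            counts = [int((col[ok] == k).sum()) for k in (0, 1, 2)]
            maf = (counts[1] + 2 * counts[2]) / (2 * n_called)
            maf = min(maf, 1 - maf)
            hwe_p = hwe_exact_test(*counts)
        else:
            maf, hwe_p = 0.0, 1.0
        rows.append(
            {
                "snp_id": snp,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "pass_call_rate": call_rate >= config.min_call_rate,
                "pass_maf": maf >= config.min_maf,
                "pass_hwe": hwe_p >= config.hwe_alpha,
            }
        )
    df = pd.DataFrame(rows)
    df["pass_all"] = df["pass_call_rate"] & df["pass_maf"] & df["pass_hwe"]
    return FilterReport(df, n_input=len(df), n_pass_qc=int(df["pass_all"].sum()))


def apply_filters(
    genotypes: GenotypeDataset, annotations: pd.DataFrame, config: FilterConfig
) -> FilterReport:
    """QC intersected with the knowledge-based filter (order-independent)."""
    report = basic_qc(genotypes, config)
    kb = knowledge_filter(annotations, config)
    df = report.per_snp
    df["pass_kb"] = df["snp_id"].isin(kb)
    df["pass_all"] = (
        df["pass_call_rate"] & df["pass_maf"] & df["pass_hwe"] & df["pass_kb"]
    )
    report.n_pass_kb = int(df["pass_kb"].sum())
    report.n_retained = int(df["pass_all"].sum())
    return report
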