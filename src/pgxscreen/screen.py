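"""Two-stage association screening with permutation family-wise control.

The screen tests each SNP in a nested pair of datasets: a discovery subset
(the S-1-treated patients in the study design) and the full cohort.  Per
SNP the combined statistic is T = max(p_stage1, p_stage2), i.e. a SNP is
only as significant as its weaker stage.  Family-wise adjusted p-values come
from a min-T permutation scheme: response labels are permuted once across
the full cohort and the discovery-stage labels are the induced restriction,
which preserves the nesting (independent permutation of the two stages would
break their dependence).  The adjusted p uses the add-one estimator
(1 + #{T*_min <= T_s}) / (n_perm + 1), so it is bounded below by
1/(n_perm + 1).

For panels without missing calls the permutation loop is fully vectorized:
for a fixed genetic model every 2x2 table's margins are determined by the
permuted responder count, so two-sided Fisher p-values come from
hypergeometric lookup tables shared across permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import GenotypeDataset
from .stats import bh_adjust, fisher_exact_2x2, fisher_p_lookup, model_table_from_doses

__all__ = ["PermutationConfig", "stage_pvalues", "permutation_adjusted_p", "screen"]

_MODEL_CODING = {
    "allele": (lambda d: d, 2),  # contribution per sample, units per sample
    "dominant": (lambda d: (d >= 1).astype(float), 1),
    "recessive": (lambda d: (d == 2).astype(float), 1),
}


@dataclass
class PermutationConfig:
    n_perm: int = 1000
    seed: int = 0
    model: str = "allele"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if self.model not in _MODEL_CODING:
            raise ValueError(f"screening model must be one of {tuple(_MODEL_CODING)}")


def _aligned_doses(
    genotypes: GenotypeDataset, snp_ids: list[str], sample_ids: list[str]
) -> np.ndarray:
    pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    rows = [pos[s] for s in sample_ids]
    cols = [genotypes.snp_index(s) for s in snp_ids]
    return genotypes.calls[np.ix_(rows, cols)]


def stage_pvalues(
    genotypes: GenotypeDataset,
    responses: pd.Series,
    snp_ids: list[str],
    dataset_ids: list[str],
    model: str = "allele",
) -> pd.Series:
    """Per-SNP two-sided Fisher p on one dataset under one genetic model.

    ``responses`` is indexed by sample id.  Missing doses are excluded
    pairwise; a SNP with no non-missing call in the dataset gets NaN.
    """
    doses = _aligned_doses(genotypes, snp_ids, dataset_ids)
    y = responses.loc[dataset_ids].to_numpy(dtype=int)
    out = np.full(len(snp_ids), np.nan)
    for j in range(len(snp_ids)):
        col = doses[:, j]
        ok = np.isfinite(col)
        if not ok.any():
            continue
        tab = model_table_from_doses(col[ok], y[ok], model).cells
        out[j] = fisher_exact_2x2(tab)
    return pd.Series(out, index=snp_ids, name=f"p_{model}")


def _perm_matrix(
    responses: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """(n_perm + 1) x n boolean matrix; row 0 is the observed labelling."""
    rng = np.random.default_rng(seed)
    n = len(responses)
    perms = np.empty((n_perm + 1, n), dtype=bool)
    perms[0] = responses.astype(bool)
    base = responses.astype(bool)
    for i in range(1, n_perm + 1):
        perms[i] = base[rng.permutation(n)]
    return perms


def _fast_stage_p(
    contrib: np.ndarray, perms_stage: np.ndarray, unit: int
) -> np.ndarray:
    """Fisher p per (permutation, SNP) for one stage without missing data.

    ``contrib``: (n_stage, m) integer contributions per sample (allele dose
    or carrier indicator); ``perms_stage``: (P, n_stage) permuted responder
    masks restricted to the stage; ``unit``: units contributed per sample
    (2 for the allele model, 1 otherwise).
    """
    n_stage, m = contrib.shape
    N = unit * n_stage
    K = contrib.sum(axis=0).astype(np.int64)  # per-SNP "minor" margin
    A = (perms_stage.astype(float) @ contrib).astype(np.int64)  # (P, m)
    r = perms_stage.sum(axis=1).astype(np.int64)  # responders per permutation
    P = perms_stage.shape[0]
    out = np.empty((P, m))
    for r_val in np.unique(r):
        n1 = unit * int(r_val)
        lookup, _ = fisher_p_lookup(N, K, n1)  # (m, n1 + 1)
        rows = np.nonzero(r == r_val)[0]
        a_block = A[rows]  # (n_rows, m)
        out[rows] = lookup[np.arange(m)[None, :], a_block]
    return out


def permutation_adjusted_p(
    genotypes: GenotypeDataset,
    responses: pd.Series,
    snp_ids: list[str],
    first_ids: list[str],
    second_ids: list[str],
    config: PermutationConfig,
) -> pd.DataFrame:
    """Stage p-values, combined T and min-T permutation-adjusted p per SNP.

    Labels are permuted jointly across the second (full) dataset; the first
    dataset sees the induced restriction.  Returns a frame indexed by SNP
    with columns ``p_stage1``, ``p_stage2``, ``combined_T``, ``perm_p``.
    """
    if not set(first_ids) <= set(second_ids):
        raise ValueError("first dataset must be nested in the second")
    coding, unit = _MODEL_CODING[config.model]
    doses = _aligned_doses(genotypes, snp_ids, second_ids)
    y = responses.loc[second_ids].to_numpy(dtype=int)
    first_pos = [second_ids.index(s) for s in first_ids]
    perms = _perm_matrix(y, config.n_perm, config.seed)

    if np.isfinite(doses).all():
        contrib = coding(doses)
        p2 = _fast_stage_p(contrib, perms, unit)
        p1 = _fast_stage_p(contrib[first_pos], perms[:, first_pos], unit)
    else:
        p1 = np.empty((config.n_perm + 1, len(snp_ids)))
        p2 = np.empty_like(p1)
        for i in range(config.n_perm + 1):
            yi = perms[i].astype(int)
            for j in range(len(snp_ids)):
                col = doses[:, j]
                ok = np.isfinite(col)
                sub = np.asarray(first_pos)
                ok1 = ok[sub]
                p2[i, j] = (
                    fisher_exact_2x2(
                        model_table_from_doses(col[ok], yi[ok], config.model).cells
                    )
                    if ok.any()
                    else np.nan
                )
                p1[i, j] = (
                    fisher_exact_2x2(
                        model_table_from_doses(
                            col[sub][ok1], yi[sub][ok1], config.model
                        ).cells
                    )
                    if ok1.any()
                    else np.nan
                )

    T = np.fmax(p1, p2)  # NaN-propagating max would drop SNPs; fmax keeps info
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        T_min_null = np.nanmin(T[1:], axis=1)  # min over SNPs, per permutation
    T_obs = T[0]
    exceed = (T_min_null[:, None] <= T_obs[None, :]).sum(axis=0)
    perm_p = (1.0 + exceed) / (config.n_perm + 1.0)
    perm_p = np.where(np.isnan(T_obs), np.nan, perm_p)
    return pd.DataFrame(
        {
            "p_stage1": p1[0],
            "p_stage2": p2[0],
            "combined_T": T_obs,
            "perm_p": perm_p,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


def screen(
    genotypes: GenotypeDataset,
    samples,
    snp_ids: list[str],
    first_ids: list[str],
    second_ids: list[str],
    config: PermutationConfig,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    perm_alpha: float = 0.05,
) -> pd.DataFrame:
    """Full two-stage screen over a prefiltered SNP set.

    Candidates must pass both stage thresholds and the permutation
    family-wise threshold.  ``q_stage1`` is the Benjamini-Hochberg q-value
    over the stage-1 p-values of the screened set.
    """
    if not snp_ids:
        warnings.warn("empty SNP set: nothing to screen", stacklevel=2)
        return pd.DataFrame(
            columns=["p_stage1", "p_stage2", "combined_T", "perm_p", "q_stage1", "candidate"]
        )
    responses = samples.response_series()
    result = permutation_adjusted_p(
        genotypes, responses, snp_ids, first_ids, second_ids, config
    )
    result["q_stage1"] = bh_adjust(result["p_stage1"].to_numpy())
    result["candidate"] = (
        (result["p_stage1"] < alpha1)
        & (result["p_stage2"] < alpha2)
        & (result["perm_p"] < perm_alpha)
    )
    return result
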