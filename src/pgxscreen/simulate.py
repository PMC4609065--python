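"""Study-shaped synthetic data generation.

Emulates the structure of the pharmacogenomic cohort the pipeline is built
for: 119 fluoropyrimidine-treated patients with a nested 58-patient S-1
discovery subset, a scaled-down SNP panel under Hardy-Weinberg equilibrium,
a four-level ordered RECIST response produced by a latent proportional-odds
model (logistic noise, so ordinal fits are correctly specified), clinical
covariates (creatinine grade, prior-chemotherapy flag), and an annotation
table with configurable PubMed-link and cancer-flag fractions.

SNPs are independent by default — the genotyping chip the study used carries
non-tag SNPs without useful LD structure — but a simple haplotype-frequency
LD pair generator is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import REGIMENS, GenotypeDataset, SampleTable

__all__ = [
    "CausalSnp",
    "SimConfig",
    "simulate_genotypes",
    "simulate_response",
    "simulate_annotation",
    "make_study_fixture",
]

_NUCS = np.array(list("ACGT"))


@dataclass
class CausalSnp:
    """A SNP with a per-minor-allele effect on the latent response score.

    ``allele_or`` is the per-allele odds ratio on the ordered response:
    values below 1 shift carriers toward better response (CR/PR), i.e. the
    minor allele is protective.  ``model`` chooses the dose coding of the
    effect: additive (dose), dominant (dose >= 1) or recessive (dose == 2).
    """

    index: int
    allele_or: float
    model: str = "additive"

    def effect(self, dose: np.ndarray) -> np.ndarray:
        beta = float(np.log(self.allele_or))
        if not np.isfinite(beta):
            raise ValueError("causal effect must be finite")
        if self.model == "additive":
            coded = dose
        elif self.model == "dominant":
            coded = (dose >= 1).astype(float)
        elif self.model == "recessive":
            coded = (dose == 2).astype(float)
        else:
            raise ValueError(f"unknown causal model {self.model!r}")
        # centred so the cutpoints keep setting the marginal RECIST mix
        return beta * (coded - coded.mean())


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the study conditions.

    Cohort shape 119 with a 58-sample S-1 subset; the panel is a scaled-down
    stand-in (2,000 SNPs) for the genome-wide chip.  Cutpoints place the
    baseline RECIST distribution at roughly 3 % CR, 25 % PR, 45 % NC, 27 %
    PD — a realistic fluoropyrimidine response mix with ~28 % responders.
    Missingness defaults to zero: the study's per-SNP missingness is unknown
    and its printed tables are consistent with complete calls.
    """

    n_samples: int = 119
    n_first_subset: int = 58
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: list[CausalSnp] = field(default_factory=list)
    cr_grade_effect: float = 0.0
    chem_history_effect: float = 0.0
    cutpoints: tuple[float, float, float] = (-3.48, -0.94, 0.99)
    cr_grade_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.04, 0.01)
    chem_history_prob: float = 0.3
    missing_rate: float = 0.0
    pubmed_fraction: float = 0.05
    cancer_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_first_subset > self.n_samples:
            raise ValueError("n_first_subset cannot exceed n_samples")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for c in self.causal_snps:
            if not 0 <= c.index < self.n_snps:
                raise ValueError(f"causal SNP index {c.index} outside panel")
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("cutpoints must be non-decreasing")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def simulate_genotypes(config: SimConfig, rng=None) -> GenotypeDataset:
    """HWE genotypes: per SNP draw MAF ~ U(maf_range), doses multinomial
    (p^2, 2pq, q^2), then Bernoulli missingness."""
    rng = config.rng(1) if rng is None else rng
    n, m = config.n_samples, config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    u = rng.random((n, m))
    p_hom_major = (1 - maf) ** 2
    p_het = 2 * maf * (1 - maf)
    calls = np.where(
        u < p_hom_major, 0.0, np.where(u < p_hom_major + p_het, 1.0, 2.0)
    )
    if config.missing_rate > 0:
        calls[rng.random((n, m)) < config.missing_rate] = np.nan
    sample_ids = [f"GC{i + 1:04d}" for i in range(n)]
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    labels = []
    for _ in range(m):
        major, minor = rng.choice(4, size=2, replace=False)
        labels.append((str(_NUCS[major]), str(_NUCS[minor])))
    positions = np.arange(1, m + 1) * 1000
    mono = np.array(
        [not np.nansum(calls[:, j]) > 0 for j in range(m)], dtype=bool
    )
    return GenotypeDataset(sample_ids, snp_ids, calls, labels, positions, mono)


def simulate_ld_pair(
    n: int, maf_a: float, maf_b: float, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Doses for two SNPs in LD at correlation ``r`` (haplotype-frequency model).

    Off by default in the pipeline (independent SNPs); provided for
    sensitivity checks.  ``r`` is clipped to the range the allele
    frequencies admit.
    """
    pa, pb = maf_a, maf_b
    d_max = min(pa * (1 - pb), pb * (1 - pa))
    d_min = -min(pa * pb, (1 - pa) * (1 - pb))
    d = np.clip(r * np.sqrt(pa * (1 - pa) * pb * (1 - pb)), d_min, d_max)
    # haplotype frequencies for (minor_a, minor_b), (minor_a, major_b), ...
    h = np.array(
        [pa * pb + d, pa * (1 - pb) - d, (1 - pa) * pb - d, (1 - pa) * (1 - pb) + d]
    )
    h = np.clip(h, 0, None)
    h /= h.sum()
    hap = rng.choice(4, size=(n, 2), p=h)
    dose_a = (hap < 2).sum(axis=1).astype(float)
    dose_b = ((hap == 0) | (hap == 2)).sum(axis=1).astype(float)
    return dose_a, dose_b


def simulate_response(
    genotypes: GenotypeDataset, config: SimConfig, rng=None
) -> SampleTable:
    """Ordered RECIST response from a latent proportional-odds model.

    latent = sum_j beta_j * coded dose_j + gamma_cr * cr_grade
             + gamma_chem * chem_history + logistic noise;
    RECIST = CR if latent <= c1, PR if <= c2, NC if <= c3, else PD.
    Missing doses contribute their HWE expectation (2*MAF estimate), so the
    latent score is defined for every sample.
    """
    rng = config.rng(2) if rng is None else rng
    n = genotypes.n_samples
    cr_grade = rng.choice(
        len(config.cr_grade_probs), size=n, p=np.asarray(config.cr_grade_probs)
    )
    chem = rng.random(n) < config.chem_history_prob

    latent = rng.logistic(size=n)
    latent += config.cr_grade_effect * cr_grade
    latent += config.chem_history_effect * chem
    for causal in config.causal_snps:
        dose = genotypes.calls[:, causal.index].copy()
        if np.isnan(dose).any():
            fill = np.nanmean(dose)
            dose[np.isnan(dose)] = 0.0 if np.isnan(fill) else fill
        latent += causal.effect(dose)

    c1, c2, c3 = config.cutpoints
    recist = np.where(
        latent <= c1, "CR", np.where(latent <= c2, "PR", np.where(latent <= c3, "NC", "PD"))
    )
    if len(np.unique(recist)) == 1:
        import warnings

        warnings.warn("cutpoints produced a single RECIST category", stacklevel=2)

    regimen = _assign_regimens(n, config.n_first_subset)
    df = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "regimen": regimen,
            "recist": recist,
            "cr_grade": cr_grade,
            "chem_history": chem,
        }
    )
    return SampleTable(df)


def _assign_regimens(n: int, n_first: int) -> list[str]:
    """First ``n_first`` samples on S-1; the rest split across the other
    regimens in the study's observed 27:33:1 proportions."""
    out = [REGIMENS[0]] * n_first
    rest = n - n_first
    weights = np.array([27, 33, 1], dtype=float)
    alloc = np.floor(weights / weights.sum() * rest).astype(int)
    while alloc.sum() < rest:
        alloc[int(np.argmax(weights / weights.sum() * rest - alloc))] += 1
    for regimen, k in zip(REGIMENS[1:], alloc):
        out += [regimen] * int(k)
    return out


def simulate_annotation(config: SimConfig, rng=None) -> pd.DataFrame:
    """Annotation table with Bernoulli PubMed-link and cancer flags."""
    rng = config.rng(3) if rng is None else rng
    m = config.n_snps
    linked = rng.random(m) < config.pubmed_fraction
    cancer = rng.random(m) < config.cancer_fraction
    pubmed = [
        [str(10_000_000 + int(x)) for x in rng.integers(0, 9_999_999, size=rng.integers(1, 4))]
        if flag
        else []
        for flag in linked
    ]
    return pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1:06d}" for j in range(m)],
            "gene": [f"GENE{j // 10 + 1}" for j in range(m)],
            "pubmed_ids": pubmed,
            "cancer_flag": cancer,
        }
    )


def make_study_fixture(
    config: SimConfig,
) -> tuple[GenotypeDataset, SampleTable, pd.DataFrame]:
    """End-to-end bundle: genotypes, phenotypes, annotations (seeded)."""
    genotypes = simulate_genotypes(config)
    samples = simulate_response(genotypes, config)
    annotations = simulate_annotation(config)
    return genotypes, samples, annotations
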