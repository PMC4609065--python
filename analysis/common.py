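"""Shared configuration for the numbered analysis scripts.

One study-shaped synthetic cohort is used throughout: 119 patients (58 on
S-1), a 2,000-SNP Hardy-Weinberg panel standing in for the genome-wide
chip, and two injected protective SNPs playing the roles of the ANXA3- and
EGFR-linked polymorphisms the real study screened out of its data.  Every
script regenerates the cohort deterministically from this config, so the
scripts can be run independently and in any order.
"""

from pathlib import Path

from pgxscreen.simulate import CausalSnp, SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "cohort"

SEED = 20150701

#: indices of the two injected causal SNPs in the panel
CAUSAL_A, CAUSAL_B = 0, 1
SNP_A, SNP_B = "rs000001", "rs000002"

STUDY_CONFIG = SimConfig(
    n_samples=119,
    n_first_subset=58,
    n_snps=2000,
    maf_range=(0.05, 0.5),
    causal_snps=[CausalSnp(CAUSAL_A, 0.01), CausalSnp(CAUSAL_B, 0.01)],
    pubmed_fraction=0.05,
    cancer_fraction=0.30,
    seed=SEED,
)


def ensure_causal_retainable(annotations):
    """Force annotation links for the injected SNPs so the knowledge filter
    keeps them (their real-study counterparts were literature-linked)."""
    for snp in (SNP_A, SNP_B):
        i = annotations.index[annotations["snp_id"] == snp][0]
        if not annotations.at[i, "pubmed_ids"]:
            annotations.at[i, "pubmed_ids"] = ["10000001"]
        annotations.at[i, "cancer_flag"] = False
    return annotations
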