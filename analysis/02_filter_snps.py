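"""Knowledge-based prefilter + basic QC of the synthetic panel.

Reproduces the funnel of the screening design: of the full panel, keep
SNPs that are literature-linked but not cancer-flagged, then apply call
rate / MAF / Hardy-Weinberg QC.  The surviving set is what the two-stage
screen will test.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import RESULTS, SCRATCH, STUDY_CONFIG, ensure_causal_retainable
from pgxscreen.qc import FilterConfig, apply_filters
from pgxscreen.simulate import make_study_fixture


def main() -> None:
    genotypes, samples, annotations = make_study_fixture(STUDY_CONFIG)
    annotations = ensure_causal_retainable(annotations)
    config = FilterConfig()  # 0.95 call rate, 0.05 MAF, 1e-6 HWE
    report = apply_filters(genotypes, annotations, config)

    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    report.per_snp.to_csv(SCRATCH / "filter_report_full.tsv", sep="\t", index=False)
    funnel = pd.DataFrame(
        [
            ("panel", report.n_input),
            ("pass basic QC", report.n_pass_qc),
            ("pubmed-linked, not cancer-flagged", report.n_pass_kb),
            ("retained for screening", report.n_retained),
        ],
        columns=["stage", "n_snps"],
    )
    funnel.to_csv(RESULTS / "02_filter_funnel.tsv", sep="\t", index=False)
    retained = sorted(report.retained)
    pd.Series(retained, name="snp_id").to_csv(
        RESULTS / "02_retained_snps.tsv", sep="\t", index=False
    )
    print(funnel.to_string(index=False))
    print(f"injected causal SNPs retained: "
          f"{'rs000001' in report.retained and 'rs000002' in report.retained}")


if __name__ == "__main__":
    main()
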