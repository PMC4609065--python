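"""Domain containers and text readers/writers for genotype, phenotype and SNP
annotation data.

Genotypes are held as minor-allele dose matrices (samples x SNPs, values 0/1/2,
NaN = missing call).  Orientation to the minor allele is always relative to an
explicit reference sample set, so that downstream allele counts, carrier tables
and the integrated allele-count index all agree on which allele is "minor".

Phenotypes follow the fluoropyrimidine study design: a four-level ordered
RECIST response (CR < PR < NC < PD), a binary responder grouping
(CR+PR vs NC+PD), the treatment regimen that defines the nested discovery
subset (S-1 only), and two clinical covariates (creatinine grade, prior
chemotherapy).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RECIST_LEVELS",
    "REGIMENS",
    "GenotypeDataset",
    "SampleTable",
    "DataError",
    "FormatError",
    "read_plink_text",
    "write_plink_text",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotations",
    "write_annotations",
    "orient_minor_allele",
    "split_datasets",
]

#: Ordered RECIST categories, best response first.
RECIST_LEVELS = ("CR", "PR", "NC", "PD")

#: Treatment regimens of the study; "S-1" defines the discovery subset.
REGIMENS = ("S-1", "5-FU/MTX", "high-dose 5-FU", "low-dose 5-FU")

_VALID_ALLELES = set("ACGT12")


class DataError(ValueError):
    """Raised when input values violate the data contract."""


class FormatError(ValueError):
    """Raised when an input file is structurally malformed."""


@dataclass
class GenotypeDataset:
    """Samples x SNPs minor-allele dose matrix.

    Attributes
    ----------
    sample_ids, snp_ids
        Ordered identifiers for the two axes.
    calls
        Float array of shape ``(n_samples, n_snps)``; entries are minor-allele
        doses in {0, 1, 2} or NaN for a missing call.
    allele_labels
        Per SNP ``(major, minor)`` allele pair.
    positions
        1-based chromosome coordinate per SNP (0 when unknown).
    monomorphic
        Boolean flag per SNP: True when the SNP had a single allele in the
        orientation reference set (all doses 0 by construction).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    allele_labels: list[tuple[str, str]]
    positions: np.ndarray | None = None
    monomorphic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.calls.shape != (n, m):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {m} SNPs"
            )
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise DataError("non-missing calls must be minor-allele doses 0/1/2")
        if len(self.allele_labels) != m:
            raise DataError("one (major, minor) allele pair required per SNP")
        for sid, (a, b) in zip(self.snp_ids, self.allele_labels):
            if a == b:
                raise DataError(f"SNP {sid}: major and minor allele identical")
        if self.positions is None:
            self.positions = np.zeros(m, dtype=int)
        if self.monomorphic is None:
            self.monomorphic = np.zeros(m, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in dataset") from None

    def dose(self, snp_id: str) -> pd.Series:
        """Minor-allele dose of one SNP, indexed by sample id."""
        return pd.Series(
            self.calls[:, self.snp_index(snp_id)], index=self.sample_ids, name=snp_id
        )

    def dose_frame(self, snp_ids: list[str] | None = None) -> pd.DataFrame:
        cols = snp_ids if snp_ids is not None else self.snp_ids
        idx = [self.snp_index(s) for s in cols]
        return pd.DataFrame(self.calls[:, idx], index=self.sample_ids, columns=cols)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeDataset(
            list(sample_ids),
            list(self.snp_ids),
            self.calls[rows],
            list(self.allele_labels),
            None if self.positions is None else self.positions.copy(),
            None if self.monomorphic is None else self.monomorphic.copy(),
        )


@dataclass
class SampleTable:
    """Per-sample phenotype records.

    Wraps a DataFrame with columns ``sample_id`` (unique), ``regimen``,
    ``recist``, ``response`` (1 iff recist in {CR, PR}), ``cr_grade`` (0-4)
    and ``chem_history`` (bool).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = ["sample_id", "regimen", "recist", "cr_grade", "chem_history"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample_id {dup!r}")
        bad = set(df["recist"]) - set(RECIST_LEVELS)
        if bad:
            raise DataError(f"unknown RECIST code(s): {sorted(bad)}")
        bad = set(df["regimen"]) - set(REGIMENS)
        if bad:
            raise DataError(f"unknown regimen(s): {sorted(bad)}")
        if not df["cr_grade"].isin(range(5)).all():
            raise DataError("cr_grade must be an NCI-CTC grade 0-4")
        df["chem_history"] = df["chem_history"].astype(bool)
        df["response"] = df["recist"].isin(("CR", "PR")).astype(int)
        df["recist"] = pd.Categorical(df["recist"], categories=RECIST_LEVELS, ordered=True)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def response_series(self) -> pd.Series:
        return self.frame.set_index("sample_id")["response"]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# raw (allele-pair) genotypes and minor-allele orientation
# ---------------------------------------------------------------------------

def orient_minor_allele(
    raw_calls: np.ndarray,
    snp_ids: list[str],
    sample_ids: list[str],
    reference_sample_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> GenotypeDataset:
    """Re-express raw allele-pair calls as minor-allele doses.

    Parameters
    ----------
    raw_calls
        Object array of shape ``(n_samples, n_snps, 2)`` of single-character
        allele codes; ``"0"`` marks a missing allele (both alleles of a
        missing genotype are ``"0"``).
    reference_sample_ids
        Samples used to determine the minor allele (allele frequency computed
        on their non-missing calls).  Defaults to all samples, so the full
        cohort is the orientation reference.  Frequency ties are broken by
        labelling the lexicographically smaller allele minor.  A SNP that is
        monomorphic in the reference keeps dose 0 everywhere non-missing and
        is flagged in ``monomorphic``.
    """
    raw = np.asarray(raw_calls, dtype=object)
    n, m, two = raw.shape
    if two != 2:
        raise FormatError("raw calls must have two alleles per genotype")
    if reference_sample_ids is None:
        reference_sample_ids = list(sample_ids)
    if not reference_sample_ids:
        raise DataError("reference sample set must be non-empty")
    pos = {s: i for i, s in enumerate(sample_ids)}
    ref_rows = [pos[s] for s in reference_sample_ids]

    calls = np.full((n, m), np.nan)
    labels: list[tuple[str, str]] = []
    mono = np.zeros(m, dtype=bool)
    for j in range(m):
        col = raw[:, j, :]
        flat = col.ravel()
        observed = sorted({a for a in flat if a != "0"})
        if any(a not in _VALID_ALLELES for a in observed):
            bad = [a for a in observed if a not in _VALID_ALLELES]
            raise DataError(f"SNP {snp_ids[j]}: invalid allele code(s) {bad}")
        if len(observed) > 2:
            raise DataError(
                f"SNP {snp_ids[j]} is not biallelic: alleles {observed}"
            )
        ref = col[ref_rows].ravel()
        counts = {a: int((ref == a).sum()) for a in observed}
        if len(observed) == 0:
            # no calls anywhere: placeholder labels, flagged monomorphic
            labels.append(("N", "M"))
            mono[j] = True
            continue
        # minor = less frequent in reference; tie -> lexicographically smaller
        if len(observed) == 1:
            major, minor = observed[0], "N" if observed[0] != "N" else "M"
            mono[j] = True
        else:
            a1, a2 = observed
            c1, c2 = counts.get(a1, 0), counts.get(a2, 0)
            if c1 == c2:
                minor, major = (a1, a2) if a1 < a2 else (a2, a1)
            elif c1 < c2:
                minor, major = a1, a2
            else:
                minor, major = a2, a1
            if counts.get(minor, 0) == 0:
                mono[j] = True
        labels.append((major, minor))
        missing = (col[:, 0] == "0") | (col[:, 1] == "0")
        dose = (col[:, 0] == minor).astype(float) + (col[:, 1] == minor).astype(float)
        dose[missing] = np.nan
        calls[:, j] = dose
    return GenotypeDataset(
        list(sample_ids), list(snp_ids), calls, labels, positions, mono
    )


# ---------------------------------------------------------------------------
# PLINK text .ped/.map
# ---------------------------------------------------------------------------

def _as_lines(source) -> list[str]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, io.IOBase):
        text = source.read()
    else:
        text = str(source)
    return [ln for ln in text.splitlines() if ln.strip()]


def read_plink_text(
    ped_source, map_source, reference_sample_ids: list[str] | None = None
) -> GenotypeDataset:
    """Read whitespace-delimited PLINK text pedigree + map files.

    The individual id (column 2) is used as the sample id; allele code 0
    marks a missing allele.  Calls are oriented to the minor allele via
    :func:`orient_minor_allele`.
    """
    map_rows = [ln.split() for ln in _as_lines(map_source)]
    snp_ids = [r[1] for r in map_rows]
    positions = np.array([int(r[3]) for r in map_rows], dtype=int)
    m = len(snp_ids)

    sample_ids: list[str] = []
    raw = []
    for ln in _as_lines(ped_source):
        fields = ln.split()
        if len(fields) != 6 + 2 * m:
            raise FormatError(
                f"ped row for {fields[1] if len(fields) > 1 else '?'} has "
                f"{len(fields) - 6} allele fields, expected {2 * m} "
                f"(map lists {m} SNPs)"
            )
        sample_ids.append(fields[1])
        alleles = np.array(fields[6:], dtype=object).reshape(m, 2)
        raw.append(alleles)
    raw_arr = np.array(raw, dtype=object) if raw else np.empty((0, m, 2), object)
    return orient_minor_allele(
        raw_arr, snp_ids, sample_ids, reference_sample_ids, positions
    )


def write_plink_text(ds: GenotypeDataset, ped_path, map_path, chrom: int = 1) -> None:
    with open(map_path, "w") as fh:
        for sid, bp in zip(ds.snp_ids, ds.positions):
            fh.write(f"{chrom}\t{sid}\t0\t{int(bp)}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(ds.sample_ids):
            fields = [sample.split()[0], sample, "0", "0", "0", "-9"]
            for j, (major, minor) in enumerate(ds.allele_labels):
                d = ds.calls[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [major, major]
                elif d == 1:
                    fields += [major, minor]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_genotype_tsv(ds: GenotypeDataset, path_or_buf) -> None:
    """Dose-matrix TSV: header of snp_ids, one row per sample (NA = missing)."""
    df = pd.DataFrame(ds.calls, columns=ds.snp_ids)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path_or_buf, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_genotype_tsv(
    source,
    allele_labels: list[tuple[str, str]] | None = None,
    positions: np.ndarray | None = None,
) -> GenotypeDataset:
    """Read the dose-matrix TSV dialect written by :func:`write_genotype_tsv`.

    Allele labels are not carried by this dialect; generic ``(A, B)`` labels
    are supplied unless given explicitly.
    """
    df = pd.read_csv(source, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise FormatError("genotype TSV must start with a sample_id column")
    snp_ids = list(df.columns[1:])
    calls = df[snp_ids].to_numpy(dtype=float)
    if allele_labels is None:
        allele_labels = [("A", "B")] * len(snp_ids)
    return GenotypeDataset(
        df["sample_id"].tolist(), snp_ids, calls, allele_labels, positions
    )


def read_phenotypes(source) -> SampleTable:
    """Read the phenotype TSV (sample_id, regimen, recist, cr_grade, chem_history)."""
    df = pd.read_csv(source, sep="\t", dtype={"sample_id": str})
    if "chem_history" in df.columns and df["chem_history"].dtype == object:
        df["chem_history"] = df["chem_history"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
    return SampleTable(df)


def write_phenotypes(table: SampleTable, path_or_buf) -> None:
    cols = ["sample_id", "regimen", "recist", "cr_grade", "chem_history"]
    out = table.frame[cols].copy()
    out["recist"] = out["recist"].astype(str)
    out.to_csv(path_or_buf, sep="\t", index=False)


def read_annotations(source) -> pd.DataFrame:
    """SNP annotation TSV: snp_id, gene, pubmed_ids (semicolon list), cancer_flag."""
    df = pd.read_csv(
        source, sep="\t", dtype={"snp_id": str, "gene": str}, keep_default_na=False
    )
    for col in ("snp_id", "pubmed_ids", "cancer_flag"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing column {col!r}")
    if df["snp_id"].duplicated().any():
        raise DataError("duplicate snp_id in annotation table")
    df["pubmed_ids"] = [
        [t for t in str(v).split(";") if t] for v in df["pubmed_ids"]
    ]
    df["cancer_flag"] = (
        df["cancer_flag"].astype(str).str.lower().isin(("1", "true", "yes"))
    )
    return df


def write_annotations(annotations: pd.DataFrame, path_or_buf) -> None:
    out = annotations.copy()
    out["pubmed_ids"] = [";".join(map(str, v)) for v in out["pubmed_ids"]]
    out["cancer_flag"] = out["cancer_flag"].astype(int)
    out.to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_datasets(
    samples: SampleTable, first_regimen: str = "S-1"
) -> tuple[list[str], list[str]]:
    """Split into the nested study datasets.

    The first (discovery) dataset contains the samples on ``first_regimen``;
    the second dataset is the full cohort, so the first is always nested in
    the second.
    """
    df = samples.frame
    first = df.loc[df["regimen"] == first_regimen, "sample_id"].tolist()
    second = df["sample_id"].tolist()
    if not first:
        warnings.warn(
            f"no samples on regimen {first_regimen!r}: first dataset is empty",
            stacklevel=2,
        )
    return first, second
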