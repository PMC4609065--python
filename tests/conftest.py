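import numpy as np
import pandas as pd
import pytest

from pgxscreen.core_data import GenotypeDataset, SampleTable


def make_genotypes(calls, snp_ids=None, sample_ids=None) -> GenotypeDataset:
    """Small dose-matrix dataset with generic allele labels."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    snp_ids = snp_ids or [f"rs{j + 1}" for j in range(m)]
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    return GenotypeDataset(sample_ids, snp_ids, calls, [("A", "G")] * m)


def make_samples(recist, regimen=None, cr_grade=None, chem=None) -> SampleTable:
    n = len(recist)
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i + 1}" for i in range(n)],
                "regimen": regimen or ["S-1"] * n,
                "recist": list(recist),
                "cr_grade": cr_grade if cr_grade is not None else [0] * n,
                "chem_history": chem if chem is not None else [False] * n,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def brute_force_fisher_2x2(table) -> float:
    """Independent oracle: enumerate all 2x2 tables at the observed margins
    with exact rational hypergeometric probabilities."""
    from fractions import Fraction
    from math import comb

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    N, K, n1 = a + b + c + d, a + c, a + b
    if N == 0 or K in (0, N) or n1 in (0, N):
        return 1.0
    denom = comb(N, n1)
    probs = {}
    for aa in range(max(0, n1 - (N - K)), min(n1, K) + 1):
        probs[aa] = Fraction(comb(K, aa) * comb(N - K, n1 - aa), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def brute_force_fisher_rxc(table) -> float:
    """Independent oracle: enumerate every r x c table with the observed
    margins using exact rational probabilities."""
    from fractions import Fraction
    from itertools import product
    from math import factorial

    t = [list(map(int, row)) for row in table]
    row_m = [sum(r) for r in t]
    col_m = [sum(c) for c in zip(*t)]
    norm = Fraction(
        int(np.prod([factorial(r) for r in row_m]))
        * int(np.prod([factorial(c) for c in col_m])),
        factorial(sum(row_m)),
    )

    def prob(tab):
        denom = 1
        for row in tab:
            for cell in row:
                denom *= factorial(cell)
        return norm / denom

    def tables(rows_left, cols_left):
        if len(rows_left) == 1:
            if all(v >= 0 for v in cols_left):
                yield [list(cols_left)]
            return
        r = rows_left[0]
        ranges = [range(0, min(r, c) + 1) for c in cols_left]
        for combo in product(*ranges):
            if sum(combo) != r:
                continue
            rest = [c - v for c, v in zip(cols_left, combo)]
            for tail in tables(rows_left[1:], rest):
                yield [list(combo)] + tail

    p_obs = prob(t)
    total = Fraction(0)
    for tab in tables(row_m, col_m):
        pr = prob(tab)
        if pr <= p_obs:
            total += pr
    return float(total)


def brute_force_hwe(n0, n1, n2) -> float:
    """Independent oracle: full enumeration over heterozygote counts with
    exact rational conditional probabilities."""
    from fractions import Fraction
    from math import factorial

    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    n_minor = n1 + 2 * n2
    probs = {}
    for het in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        probs[het] = Fraction(
            2**het * factorial(n),
            factorial(hom_maj) * factorial(het) * factorial(hom_min),
        )
    total = sum(probs.values())
    p_obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)
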