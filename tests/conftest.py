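import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

# --------------------------------------------------------------------------
# published worked-example data used across test modules

# Detox-gene call table: per-contrast (signed FC, P) triplets in contrast
# order (Funchal vs Rockefeller, Funchal vs New Orleans, Paul do Mar vs
# Rockefeller), with the published classification.
DETOX_CALL_TABLE = {
    "Cyp9J32": ([(41, 0.006), (53, 0.004), (10, 0.060)], "potential"),
    "Cyp9J28": ([(31, 0.028), (30, 0.019), (10, 0.008)], "significant"),
    "Cyp6BB2": ([(15, 0.005), (19, 7e-4), (3.6, 0.006)], "significant"),
    "Cyp9J27_AAEL014607": ([(14, 0.021), (18, 0.018), (3.5, 0.023)], "significant"),
    "Cyp9J27_AAEL014616": ([(14, 0.020), (16, 0.016), (4.6, 0.006)], "significant"),
    "Cyp9M5": ([(6.6, 6e-4), (8.5, 0.009), (2.3, 0.001)], "significant"),
    "Cyp9M6": ([(5.4, 0.015), (4.7, 0.006), (4, 0.031)], "significant"),
    "Cyp6N12": ([(5.1, 3e-4), (6.3, 0.003), (2.2, 0.002)], "significant"),
    "Cyp6M9": ([(4.2, 0.007), (3.7, 0.001), (3, 0.047)], "significant"),
    "CCEae3a": ([(2.7, 0.009), (3.4, 0.012), (2.1, 0.001)], "significant"),
    "GSTd4": ([(24, 4e-4), (22, 2e-4), (9.8, 0.004)], "significant"),
    "GSTs1": ([(4.9, 2e-4), (2.5, 7e-5), (2.2, 0.032)], "significant"),
}

# kdr genotype counts (wild-type hom, het, mutant hom) at V1016I
KDR_COUNTS = {
    ("Funchal", "cyfluthrin resistant"): (20, 10, 2),
    ("Funchal", "cyfluthrin susceptible"): (15, 4, 0),
    ("Funchal", "permethrin resistant"): (21, 11, 0),
    ("Funchal", "permethrin susceptible"): (6, 2, 0),
    ("Funchal", "all"): (62, 27, 2),
    ("PaulDoMar", "cyfluthrin resistant"): (6, 5, 1),
    ("PaulDoMar", "cyfluthrin susceptible"): (21, 15, 0),
    ("PaulDoMar", "permethrin resistant"): (18, 11, 1),
    ("PaulDoMar", "permethrin susceptible"): (0, 2, 0),
    ("PaulDoMar", "all"): (45, 33, 2),
}


# --------------------------------------------------------------------------
# independent exact-test oracle: rational arithmetic over all tables with
# the observed margins (never calls irtools code)

def exact_fisher_oracle(table) -> float:
    """Two-sided probability-ordering exact test by brute-force enumeration
    with exact rational arithmetic."""
    t = [list(map(int, row)) for row in table]
    row_totals = [sum(r) for r in t]
    col_totals = [sum(c) for c in zip(*t)]
    n = sum(row_totals)

    def prob(tab) -> Fraction:
        num = Fraction(1)
        for rt in row_totals:
            num *= math.factorial(rt)
        for ct in col_totals:
            num *= math.factorial(ct)
        den = Fraction(math.factorial(n))
        for row in tab:
            for cell in row:
                den *= math.factorial(cell)
        return num / den

    def tables(rows_left, cols_left):
        if len(rows_left) == 1:
            yield [list(cols_left)]
            return
        total = rows_left[0]
        ranges = [range(min(total, c) + 1) for c in cols_left]
        for cells in itertools.product(*ranges):
            if sum(cells) != total:
                continue
            rest = [c - x for c, x in zip(cols_left, cells)]
            for tail in tables(rows_left[1:], rest):
                yield [list(cells)] + tail

    p_obs = prob(t)
    total = Fraction(0)
    for tab in tables(row_totals, col_totals):
        p = prob(tab)
        if p <= p_obs:
            total += p
    return float(total)


@pytest.fixture(scope="session")
def bioassay_table() -> pd.DataFrame:
    """Hand-built tube table covering controls and both synergist arms."""
    rows = [
        # population, insecticide, synergist, tube, exposed, dead
        ("Funchal", "permethrin", "none", "t1", 25, 5),
        ("Funchal", "permethrin", "none", "t2", 25, 6),
        ("Funchal", "permethrin", "none", "t3", 25, 4),
        ("Funchal", "permethrin", "none", "t4", 25, 7),
        ("Funchal", "permethrin", "PBO", "t1", 25, 22),
        ("Funchal", "permethrin", "PBO", "t2", 25, 24),
        ("Funchal", "permethrin", "PBO", "t3", 25, 23),
        ("Funchal", "permethrin", "PBO", "t4", 25, 21),
        ("Funchal", "control", "none", "t1", 25, 0),
        ("Funchal", "control", "none", "t2", 25, 0),
    ]
    return pd.DataFrame(rows, columns=[
        "population", "insecticide", "synergist", "tube_id",
        "n_exposed", "n_dead_24h"])
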