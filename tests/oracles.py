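"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: closed forms, exhaustive enumeration and per-pair
library calls, sharing no code with the package's vectorised paths.
"""

from __future__ import annotations

import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats


def closed_form_spearman(x, y) -> float:
    """1 - 6 sum(d^2) / (n (n^2 - 1)); valid for distinct values only."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
    return 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))


def brute_rank_neighbors(query: pd.Series, reference: pd.DataFrame) -> list[tuple[str, float]]:
    """Per-pair scipy Spearman, python sort by (-rho, sample id)."""
    rhos = {}
    for sample in reference.columns:
        col = reference[sample]
        if col.nunique() == 1:
            continue  # undefined correlation: excluded
        rho = stats.spearmanr(query.to_numpy(), col.to_numpy()).statistic
        rhos[sample] = float(rho)
    return sorted(rhos.items(), key=lambda item: (-item[1], item[0]))


def brute_vote(neighbor_labels: list[str], k: int) -> tuple[str, int]:
    """Plurality vote with the drop-worst-and-revote tie-break, by definition."""
    window = list(neighbor_labels[:k])
    removed = 0
    while True:
        counts = Counter(window).most_common()
        if len(counts) == 1 or counts[0][1] > counts[1][1]:
            return counts[0][0], removed
        window.pop()
        removed += 1


def exhaustive_fisher(a: int, b: int, c: int, d: int) -> tuple[Fraction, Fraction]:
    """Fisher's exact p-values by enumerating every table with the margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    tables = []
    for a2 in range(0, min(r1, c1) + 1):
        b2, c2 = r1 - a2, c1 - a2
        d2 = r2 - c2
        if min(b2, c2, d2) < 0:
            continue
        prob = Fraction(
            math.comb(r1, a2) * math.comb(r2, c2), math.comb(n, c1)
        )
        tables.append((a2, prob))
    observed = dict(tables)[a]
    if a * d >= b * c:
        one_sided = sum(p for a2, p in tables if a2 >= a)
    else:
        one_sided = sum(p for a2, p in tables if a2 <= a)
    two_sided = sum(p for _, p in tables if p <= observed)
    return one_sided, two_sided


def brute_variant_survivors(table: pd.DataFrame) -> set[tuple[str, str]]:
    """(variant_key, sample_id) pairs surviving the filters, by definition."""

    def whitelisted(row) -> bool:
        roles = set(str(row.cgc_role or "").split(","))
        return "tumor_suppressor" in roles or (
            "oncogene" in roles and bool(row.cosmic_exact_match)
        )

    def pop_removed(row) -> bool:
        if whitelisted(row):
            return False
        high = any(
            af is not None and not pd.isna(af) and af > 0.001
            for af in (row.gnomad_af, row.exac_af)
        )
        return high or bool(str(row.dbsnp_id or "").strip())

    survivors = [row for row in table.itertuples() if not pop_removed(row)]
    pdx_samples: dict[str, set[str]] = {}
    biopsy_keys = set()
    for row in survivors:
        if row.sample_class == "pdx":
            pdx_samples.setdefault(row.variant_key, set()).add(row.sample_id)
        elif row.sample_class == "biopsy":
            biopsy_keys.add(row.variant_key)
    recurrent = {
        key for key, samples in pdx_samples.items()
        if len(samples) >= 2 and key not in biopsy_keys
    }
    return {
        (row.variant_key, row.sample_id)
        for row in survivors
        if row.variant_key not in recurrent
    }
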