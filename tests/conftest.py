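"""Shared fixtures and the independent brute-force oracle.

The oracle computes fragment masses and isomer signatures from first
principles (explicit loops over residue sums using the pyteomics mass
table) without touching the package's enumeration code, so it can serve
as an independent cross-check of the uniqueness analysis.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from pyteomics import mass as ptmass

import pcovms as pm

WATER = ptmass.calculate_mass(formula="H2O")
PROTON = 1.00727646677
AA = ptmass.std_aa_mass
ACETYL_DELTA = 42.010565


# --- brute-force oracle -----------------------------------------------------


def oracle_fragment_mzs(seq: str, mod_sites: set[int]) -> dict:
    """All singly charged b / y / internal-b fragment m/z values, computed
    by direct summation.  ``mod_sites`` are 1-based acetylated positions."""
    n = len(seq)

    def seg(lo: int, hi: int) -> float:  # inclusive residue span
        m = 0.0
        for i in range(lo, hi + 1):
            m += AA[seq[i - 1]]
            if i in mod_sites:
                m += ACETYL_DELTA
        return m

    out = {}
    for i in range(1, n):
        out[("b", (1, i))] = seg(1, i) + PROTON
        out[("y", (n - i + 1, n))] = seg(n - i + 1, n) + WATER + PROTON
    for s in range(2, n - 1):
        for e in range(s + 1, n):
            out[("internal_b", (s, e))] = seg(s, e) + PROTON
    return out


def oracle_signatures(seq: str, site_combos: list[tuple[int, ...]], mode: str):
    """Per-isomer signature sets (rounded to 1e-6) by brute force.

    1d: all b/y fragment m/z.  2d: every unordered pair of fragments with
    disjoint spans, b/y-with-b/y restricted to b-vs-y, plus terminal with
    internal-b."""
    sigs = []
    for sites in site_combos:
        frags = oracle_fragment_mzs(seq, set(sites))
        if mode == "1d":
            sigs.append(
                {round(mz, 6) for (k, _), mz in frags.items() if k in ("b", "y")}
            )
            continue
        pairs = set()
        items = list(frags.items())
        for (ka, spa), mza in items:
            for (kb, spb), mzb in items:
                if (ka, spa) >= (kb, spb):
                    continue
                if not (spa[1] < spb[0] or spb[1] < spa[0]):
                    continue
                kinds = {ka, kb}
                if kinds == {"b"} or kinds == {"y"}:
                    continue  # same-terminus pairs can never have disjoint spans anyway
                if "internal_b" in kinds and kinds == {"internal_b"}:
                    continue  # internal/internal excluded
                pairs.add(tuple(sorted((round(mza, 6), round(mzb, 6)))))
        sigs.append(pairs)
    return sigs


def oracle_unique(sigs: list[set]) -> list[set]:
    return [
        s - set().union(*(o for j, o in enumerate(sigs) if j != i))
        for i, s in enumerate(sigs)
    ]


# --- fixtures ---------------------------------------------------------------


@pytest.fixture(scope="session")
def h4_p1_p4() -> pm.IsomerSet:
    return pm.h4_diacetyl_isomers(("P1", "P2", "P3", "P4"))


@pytest.fixture(scope="session")
def h4_all() -> pm.IsomerSet:
    return pm.h4_diacetyl_isomers(("P1", "P2", "P3", "P4", "P5", "P6"))


@pytest.fixture(scope="session")
def p4() -> pm.ModifiedPeptide:
    return pm.ModifiedPeptide.from_sites(pm.H4_4_17, pm.ACETYL, (5, 13), 4)


def random_peptide(rng: np.random.Generator, length: int, n_k: int) -> str:
    """Random peptide with exactly ``n_k`` lysines, no R/P edge cases."""
    others = list("ACDEFGHILMNQSTVWY")
    seq = [str(rng.choice(others)) for _ in range(length)]
    for pos in rng.choice(length, size=n_k, replace=False):
        seq[pos] = "K"
    return "".join(seq)
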