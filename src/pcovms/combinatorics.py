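"""Digestion, combinatorial-isomer enumeration, and marker uniqueness analysis.

A *combinatorial isomer set* holds every way of placing ``m`` copies of one
modification on a peptide's eligible sites; all members share the same
precursor mass, so they co-isolate and cofragment in tandem MS.  The
analyses here ask, per isomer, whether any single fragment m/z (1D) or any
unordered fragment-pair (m/z, m/z) correlation (2D) is produced by that
isomer alone — the "marker ion" vs "marker ion correlation" comparison.

In-silico uniqueness is an exact mass-degeneracy question, so the default
tolerance is 1e-6 Da; matching unit-resolution experimental peaks uses the
separate, wider tolerance carried by the pcov module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    ACETYL,
    FragmentIon,
    Modification,
    ModifiedPeptide,
    generate_fragments,
    peptide_neutral_mass,
)

#: exact in-silico m/z degeneracy tolerance (Da); isomer degeneracy is exact
EXACT_TOL = 1e-6

ENZYMES = ("trypsin", "glu-c")


@dataclass(frozen=True)
class DigestSpec:
    """Proteolysis rule set.

    trypsin: cleave C-terminal to K/R unless followed by P.
    glu-c: cleave C-terminal to E (and D when ``glu_c_cleaves_d``).
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    min_length: int = 2
    max_length: int = 50
    glu_c_cleaves_d: bool = False

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}; choose from {ENZYMES}")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def cleavage_sites(sequence: str, spec: DigestSpec) -> list[int]:
    """0-based indices i such that the bond between sequence[i-1] and
    sequence[i] is cleaved; excludes the termini."""
    sites = []
    for i in range(1, len(sequence)):
        prev = sequence[i - 1]
        if spec.enzyme == "trypsin":
            if prev in "KR" and sequence[i] != "P":
                sites.append(i)
        else:
            targets = "ED" if spec.glu_c_cleaves_d else "E"
            if prev in targets:
                sites.append(i)
    return sites


@dataclass(frozen=True)
class DigestPeptide:
    """One candidate proteolytic peptide with its modifiable sites.

    ``start`` is the 1-based position of the peptide in the parent protein.
    ``eligible_sites`` are 1-based peptide coordinates of modifiable residues;
    ``blocked_internal_sites`` are the eligible sites that coincide with an
    internal cleavage site, i.e. the peptide form exists only when enough of
    them carry a cleavage-blocking modification.
    """

    sequence: str
    start: int
    eligible_sites: tuple[int, ...]
    internal_cleavage_sites: tuple[int, ...]  # peptide coords of residue before cut

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def digest(
    protein_sequence: str,
    spec: DigestSpec,
    modification: Modification | None = None,
) -> list[DigestPeptide]:
    """Enumerate candidate peptides under the enzyme rule.

    When ``modification`` blocks cleavage (e.g. acetyl-K under trypsin),
    spans whose internal cleavage sites are modifiable residues are also
    candidates: a specific isomer's modification pattern decides whether
    the span is a consistent digestion product
    (see :func:`isomer_consistent_with_digest`).
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    protein_sequence = protein_sequence.upper()
    cuts = cleavage_sites(protein_sequence, spec)
    bounds = [0] + cuts + [len(protein_sequence)]

    blocking = modification is not None and modification.blocks_cleavage

    out: list[DigestPeptide] = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            start, end = bounds[a], bounds[b]  # 0-based half-open
            seq = protein_sequence[start:end]
            if len(seq) > spec.max_length:
                break
            internal = [c for c in cuts if start < c < end]
            if blocking:
                # internal cut sites at a modifiable residue may be blocked
                blockable = sum(
                    1
                    for c in internal
                    if modification.targets(protein_sequence[c - 1])
                )
                budget = spec.missed_cleavages + blockable
            else:
                budget = spec.missed_cleavages
            if len(internal) > budget:
                break
            if len(seq) < spec.min_length:
                continue
            eligible = tuple(
                i + 1
                for i, r in enumerate(seq)
                if modification is not None and modification.targets(r)
            )
            out.append(
                DigestPeptide(
                    sequence=seq,
                    start=start + 1,
                    eligible_sites=eligible,
                    internal_cleavage_sites=tuple(c - start for c in internal),
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def isomer_consistent_with_digest(
    pep: DigestPeptide, modified_sites: Iterable[int], spec: DigestSpec,
    modification: Modification,
) -> bool:
    """True when this modification pattern makes the peptide a plausible
    digestion product: every unblocked internal cleavage site counts as a
    missed cleavage, and those must not exceed the allowance."""
    modded = set(modified_sites)
    unblocked = sum(
        1
        for c in pep.internal_cleavage_sites
        if not (modification.blocks_cleavage and c in modded)
    )
    return unblocked <= spec.missed_cleavages


@dataclass
class IsomerSet:
    """All C(k, m) placements of m modification copies on k eligible sites."""

    peptide: str
    modification: Modification
    multiplicity: int
    isomers: list[ModifiedPeptide]
    parent_offset: int = 1

    def __len__(self) -> int:
        return len(self.isomers)

    @property
    def labels(self) -> list[str]:
        return [iso.label for iso in self.isomers]

    def precursor_mass(self) -> float:
        return peptide_neutral_mass(self.isomers[0])

    def subset(self, indices: Sequence[int]) -> "IsomerSet":
        return IsomerSet(
            peptide=self.peptide,
            modification=self.modification,
            multiplicity=self.multiplicity,
            isomers=[self.isomers[i] for i in indices],
            parent_offset=self.parent_offset,
        )


def enumerate_isomers(
    peptide: str,
    modification: Modification = ACETYL,
    m: int = 1,
    parent_offset: int = 1,
    eligible_sites: Sequence[int] | None = None,
) -> IsomerSet:
    """Enumerate every site combination, in lexicographic site order."""
    if eligible_sites is None:
        eligible_sites = [
            i + 1 for i, r in enumerate(peptide) if modification.targets(r)
        ]
    k = len(eligible_sites)
    if m > k:
        raise ValueError(f"multiplicity {m} exceeds {k} eligible sites")
    if m < 0:
        raise ValueError("multiplicity must be >= 0")
    isomers = [
        ModifiedPeptide.from_sites(peptide, modification, combo, parent_offset)
        for combo in itertools.combinations(sorted(eligible_sites), m)
    ]
    assert len(isomers) == comb(k, m)
    return IsomerSet(
        peptide=peptide,
        modification=modification,
        multiplicity=m,
        isomers=isomers,
        parent_offset=parent_offset,
    )


# --- the canonical worked system: histone H4 tryptic peptide 4-17 -----------

H4_4_17 = "GKGGKGLGKGGAKR"
H4_4_17_OFFSET = 4

#: diacetyl isomers named by acetylated protein-position pairs, in the
#: customary order P1=K5/K16, P2=K8/K12, P3=K5/K12, P4=K8/K16,
#: P5=K5/K8, P6=K12/K16 (peptide sites 2/5/9/13).
H4_DIACETYL_SITES: Mapping[str, tuple[int, int]] = {
    "P1": (2, 13),
    "P2": (5, 9),
    "P3": (2, 9),
    "P4": (5, 13),
    "P5": (2, 5),
    "P6": (9, 13),
}


def h4_diacetyl_isomers(names: Sequence[str] = ("P1", "P2", "P3", "P4")) -> IsomerSet:
    """The diacetylated H4 4-17 positional isomers, selected by P-name."""
    isomers = [
        ModifiedPeptide.from_sites(
            H4_4_17, ACETYL, H4_DIACETYL_SITES[n], H4_4_17_OFFSET
        )
        for n in names
    ]
    return IsomerSet(
        peptide=H4_4_17,
        modification=ACETYL,
        multiplicity=2,
        isomers=isomers,
        parent_offset=H4_4_17_OFFSET,
    )


# --- signatures -------------------------------------------------------------


def _dedup_sorted(values: list[float], tol: float) -> tuple[float, ...]:
    values = sorted(values)
    out: list[float] = []
    for v in values:
        if not out or v - out[-1] > tol:
            out.append(v)
    return tuple(out)


def signature_1d(
    iso_set: IsomerSet,
    kinds: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
    tol: float = EXACT_TOL,
) -> list[tuple[float, ...]]:
    """Per isomer: the deduplicated set of fragment m/z values it can emit."""
    return [
        _dedup_sorted([f.mz for f in generate_fragments(iso, kinds, max_charge)], tol)
        for iso in iso_set.isomers
    ]


def spans_disjoint(a: FragmentIon, b: FragmentIon) -> bool:
    return a.span[1] < b.span[0] or b.span[1] < a.span[0]


def correlation_pairs(
    iso: ModifiedPeptide,
    pair_kinds: Sequence[str] = ("terminal/terminal", "terminal/internal"),
    max_charge: int = 1,
    internal_kind: str = "internal_b",
) -> list[tuple[FragmentIon, FragmentIon]]:
    """Fragment pairs with disjoint residue spans that one precursor
    dissociation can co-produce: complementary-and-shorter b/y pairs
    (terminal/terminal) and terminal-with-internal pairs from secondary
    fragmentation.  Internal/internal pairs are excluded."""
    terminals = generate_fragments(iso, ("b", "y"), max_charge)
    internals = (
        generate_fragments(iso, (internal_kind,), max_charge)
        if "terminal/internal" in pair_kinds
        else []
    )
    pairs: list[tuple[FragmentIon, FragmentIon]] = []
    if "terminal/terminal" in pair_kinds:
        bs = [f for f in terminals if f.kind == "b"]
        ys = [f for f in terminals if f.kind == "y"]
        pairs.extend(
            (fb, fy) for fb in bs for fy in ys if spans_disjoint(fb, fy)
        )
    for ft in terminals:
        pairs.extend((ft, fi) for fi in internals if spans_disjoint(ft, fi))
    return pairs


def signature_2d(
    iso_set: IsomerSet,
    pair_kinds: Sequence[str] = ("terminal/terminal", "terminal/internal"),
    max_charge: int = 1,
    tol: float = EXACT_TOL,
) -> list[tuple[tuple[float, float], ...]]:
    """Per isomer: the set of unordered (m/z, m/z) correlation pairs,
    canonical smaller-first, deduplicated at ``tol`` per coordinate."""
    out = []
    for iso in iso_set.isomers:
        raw = sorted(
            tuple(sorted((a.mz, b.mz)))
            for a, b in correlation_pairs(iso, pair_kinds, max_charge)
        )
        dedup: list[tuple[float, float]] = []
        for p in raw:
            if not any(
                abs(p[0] - q[0]) <= tol and abs(p[1] - q[1]) <= tol for q in dedup[-8:]
            ):
                dedup.append(p)
        out.append(tuple(dedup))
    return out


# --- uniqueness -------------------------------------------------------------


@dataclass
class MarkerReport:
    """Per-isomer unique signals and identifiability verdicts."""

    isomer_labels: list[str]
    mode: str  # "1d" or "2d"
    unique: list[tuple]  # per isomer: unique m/z values or m/z pairs
    tolerance: float

    @property
    def identifiable(self) -> list[bool]:
        return [len(u) > 0 for u in self.unique]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isomer": self.isomer_labels,
                "mode": self.mode,
                "n_unique": [len(u) for u in self.unique],
                "identifiable": self.identifiable,
                "unique_signals": [
                    ";".join(
                        f"{u:.4f}" if isinstance(u, float) else f"{u[0]:.4f}x{u[1]:.4f}"
                        for u in uu
                    )
                    for uu in self.unique
                ],
            }
        )


def _unique_values(
    signatures: list[tuple[float, ...]], tol: float
) -> list[tuple[float, ...]]:
    uniq = []
    for i, sig in enumerate(signatures):
        others = [s for j, s in enumerate(signatures) if j != i]
        mine = tuple(
            v
            for v in sig
            if not any(any(abs(v - w) <= tol for w in o) for o in others)
        )
        uniq.append(mine)
    return uniq


def _unique_pairs(
    signatures: list[tuple[tuple[float, float], ...]], tol: float
) -> list[tuple[tuple[float, float], ...]]:
    uniq = []
    for i, sig in enumerate(signatures):
        others = [s for j, s in enumerate(signatures) if j != i]
        mine = tuple(
            p
            for p in sig
            if not any(
                any(abs(p[0] - q[0]) <= tol and abs(p[1] - q[1]) <= tol for q in o)
                for o in others
            )
        )
        uniq.append(mine)
    return uniq


def find_unique_markers(
    iso_set: IsomerSet,
    mode: str = "2d",
    tolerance: float = EXACT_TOL,
    kinds_1d: Sequence[str] = ("b", "y"),
    pair_kinds: Sequence[str] = ("terminal/terminal", "terminal/internal"),
    max_charge: int = 1,
) -> MarkerReport:
    """A signal is a marker for an isomer iff no other isomer of the set
    produces the same m/z value (1d) or the same m/z pair, both coordinates
    within tolerance (2d)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if len(iso_set) < 2:
        raise ValueError("uniqueness analysis needs >= 2 isomers")
    if mode == "1d":
        sigs = signature_1d(iso_set, kinds_1d, max_charge, tolerance)
        unique = _unique_values(sigs, tolerance)
    elif mode == "2d":
        sigs2 = signature_2d(iso_set, pair_kinds, max_charge, tolerance)
        unique = _unique_pairs(sigs2, tolerance)
    else:
        raise ValueError("mode must be '1d' or '2d'")
    return MarkerReport(
        isomer_labels=iso_set.labels, mode=mode, unique=unique, tolerance=tolerance
    )


# --- whole-FASTA survey -----------------------------------------------------

SURVEY_COLUMNS = [
    "protein_id",
    "peptide",
    "start",
    "m",
    "n_isomers",
    "n_id_1d",
    "n_id_2d",
]


def count_identifiable(
    proteins: Mapping[str, str],
    spec: DigestSpec,
    modification: Modification = ACETYL,
    m_values: Sequence[int] = (2,),
    kinds_1d: Sequence[str] = ("b", "y"),
    pair_kinds: Sequence[str] = ("terminal/terminal", "terminal/internal"),
    max_charge: int = 1,
    max_sites: int = 10,
) -> pd.DataFrame:
    """Per digest peptide and modification multiplicity, count how many of
    its combinatorial isomers are identifiable by a unique single fragment
    (1D MS/MS) vs by a unique fragment-pair correlation (2D).

    Only isomers whose modification pattern is consistent with the digestion
    rule are counted (a cleavage-blocking modification must cover internal
    cut sites not absorbed by the missed-cleavage allowance).
    ``max_sites`` caps combinatorial blow-up per peptide.
    """
    rows = []
    for pid, seq in proteins.items():
        for pep in digest(seq, spec, modification):
            k = len(pep.eligible_sites)
            if k > max_sites:
                continue
            for m in m_values:
                if m > k:
                    continue
                iso_set = enumerate_isomers(
                    pep.sequence,
                    modification,
                    m,
                    parent_offset=pep.start,
                    eligible_sites=pep.eligible_sites,
                )
                keep = [
                    i
                    for i, iso in enumerate(iso_set.isomers)
                    if isomer_consistent_with_digest(
                        pep, iso.sites, spec, modification
                    )
                ]
                if len(keep) < 2:
                    continue
                sub = iso_set.subset(keep)
                rep1 = find_unique_markers(
                    sub, "1d", kinds_1d=kinds_1d, max_charge=max_charge
                )
                rep2 = find_unique_markers(
                    sub, "2d", pair_kinds=pair_kinds, max_charge=max_charge
                )
                rows.append(
                    {
                        "protein_id": pid,
                        "peptide": pep.sequence,
                        "start": pep.start,
                        "m": m,
                        "n_isomers": len(sub),
                        "n_id_1d": sum(rep1.identifiable),
                        "n_id_2d": sum(rep2.identifiable),
                    }
                )
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    return df.sort_values(["protein_id", "start", "peptide", "m"]).reset_index(
        drop=True
    )
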