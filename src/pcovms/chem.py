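"""Monoisotopic mass bookkeeping and exhaustive backbone fragment generation.

Fragment kinds follow standard low-energy CID nomenclature: terminal ``b``
and ``y`` ions, and internal ions produced by two backbone cleavages.
Internal ions are b-type by default (no terminal water, no CO loss);
a-type internals (b-type minus CO) are available behind a flag.

Coordinates are 1-based inclusive residue indices in *peptide* space.
Protein-space site labels (e.g. the histone H4 lysines K5/K8/K12/K16 of
the 4-17 tryptic peptide) are derived from ``parent_offset`` for display
only and never enter the mass arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _ptmass

# Monoisotopic constants (pyteomics nist_mass).
PROTON_MASS = _ptmass.nist_mass["H+"][0][0]
WATER_MASS = _ptmass.calculate_mass(formula="H2O")
CO_MASS = _ptmass.calculate_mass(formula="CO")

#: single-letter residue code -> monoisotopic residue (chain) mass, Da
RESIDUE_MASSES: Mapping[str, float] = dict(_ptmass.std_aa_mass)

FRAGMENT_KINDS = ("b", "y", "internal_b", "internal_a")
TERMINAL_KINDS = ("b", "y")
INTERNAL_KINDS = ("internal_b", "internal_a")


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a residue code outside the mass table."""


@dataclass(frozen=True)
class Modification:
    """A fixed-mass covalent modification attached to specific residue types.

    ``blocks_cleavage`` marks modifications (such as lysine acetylation)
    that abolish enzymatic cleavage at the modified residue.
    """

    name: str
    delta_mass: float
    target_residues: frozenset[str]
    blocks_cleavage: bool = False

    def __post_init__(self) -> None:
        if not self.target_residues:
            raise ValueError("modification needs at least one target residue")
        import math

        if not math.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")

    def targets(self, residue: str) -> bool:
        return residue in self.target_residues


#: lysine epsilon-acetylation; suppresses tryptic cleavage at the modified K
ACETYL = Modification(
    name="acetyl",
    delta_mass=42.010565,
    target_residues=frozenset({"K"}),
    blocks_cleavage=True,
)


def _check_sequence(sequence: str) -> None:
    for ch in sequence:
        if ch not in RESIDUE_MASSES:
            raise UnknownResidueError(f"unknown residue code {ch!r}")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence plus one specific assignment of modifications to
    sites — a single combinatorial isomer.

    ``mod_sites`` maps 1-based peptide site index -> Modification.
    ``parent_offset`` is the parent-protein position of residue 1, used
    to render display labels like ``K8ac``.
    """

    sequence: str
    mod_sites: tuple[tuple[int, Modification], ...] = ()
    parent_offset: int = 1

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        n = len(self.sequence)
        sites = [s for s, _ in self.mod_sites]
        if sites != sorted(sites) or len(set(sites)) != len(sites):
            object.__setattr__(
                self, "mod_sites", tuple(sorted(set(self.mod_sites), key=lambda t: t[0]))
            )
        for site, mod in self.mod_sites:
            if not 1 <= site <= n:
                raise ValueError(f"mod site {site} outside peptide [1, {n}]")
            if not mod.targets(self.sequence[site - 1]):
                raise ValueError(
                    f"residue {self.sequence[site - 1]!r} at site {site} is not a "
                    f"target of modification {mod.name!r}"
                )

    @classmethod
    def from_sites(
        cls,
        sequence: str,
        modification: Modification | None = None,
        sites: Iterable[int] = (),
        parent_offset: int = 1,
    ) -> "ModifiedPeptide":
        mods = tuple((s, modification) for s in sorted(sites)) if modification else ()
        return cls(sequence=sequence, mod_sites=mods, parent_offset=parent_offset)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.mod_sites)

    def modification_at(self, site: int) -> Modification | None:
        for s, m in self.mod_sites:
            if s == site:
                return m
        return None

    def site_label(self, site: int) -> str:
        """Protein-space display label, e.g. site 5 with parent_offset 4 -> 'K8'."""
        return f"{self.sequence[site - 1]}{site + self.parent_offset - 1}"

    @property
    def label(self) -> str:
        """Canonical display name, e.g. 'GKGGKGLGKGGAKR[K8ac,K16ac]'."""
        if not self.mod_sites:
            return self.sequence
        tags = ",".join(f"{self.site_label(s)}{m.name[:2]}" for s, m in self.mod_sites)
        return f"{self.sequence}[{tags}]"


def peptide_neutral_mass(p: ModifiedPeptide | str) -> float:
    """Monoisotopic neutral mass: residue chain masses + water + mod deltas."""
    if isinstance(p, str):
        p = ModifiedPeptide(p)
    _check_sequence(p.sequence)
    m = sum(RESIDUE_MASSES[r] for r in p.sequence) + WATER_MASS
    m += sum(mod.delta_mass for _, mod in p.mod_sites)
    return m


@dataclass(frozen=True)
class FragmentIon:
    """One backbone fragment: kind, residue span, retained mods, mass, m/z."""

    kind: str
    span: tuple[int, int]
    retained_mods: tuple[int, ...]
    charge: int
    neutral_mass: float
    mz: float

    def annotation(self, peptide: ModifiedPeptide | None = None) -> str:
        s, e = self.span
        n = len(peptide) if peptide is not None else None
        if self.kind == "b":
            core = f"b{e}"
        elif self.kind == "y" and n is not None:
            core = f"y{n - s + 1}"
        elif self.kind == "y":
            core = f"y({s}-{e})"
        else:
            core = f"{'bi' if self.kind == 'internal_b' else 'ai'}({s}-{e})"
        charge = "+" * self.charge
        return f"{core}{charge}"


def _validate_span(kind: str, span: tuple[int, int], n: int) -> None:
    s, e = span
    if kind == "b":
        ok = s == 1 and 1 <= e < n
    elif kind == "y":
        ok = e == n and 1 < s <= n
    elif kind in INTERNAL_KINDS:
        ok = 2 <= s < e <= n - 1
    else:
        raise ValueError(f"unknown fragment kind {kind!r}")
    if not ok:
        raise ValueError(f"span {span} invalid for kind {kind!r} (peptide length {n})")


def fragment_neutral_mass(
    p: ModifiedPeptide, kind: str, span: tuple[int, int]
) -> float:
    """Neutral monoisotopic mass of one backbone fragment.

    b: sum of residue masses in span (+ retained mod deltas);
    y: sum + water; internal_b: bare sum; internal_a: internal_b - CO.
    """
    _validate_span(kind, span, len(p))
    s, e = span
    m = sum(RESIDUE_MASSES[r] for r in p.sequence[s - 1 : e])
    m += sum(mod.delta_mass for site, mod in p.mod_sites if s <= site <= e)
    if kind == "y":
        m += WATER_MASS
    elif kind == "internal_a":
        m -= CO_MASS
    return m


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


def fragment_mz(
    p: ModifiedPeptide, kind: str, span: tuple[int, int], charge: int = 1
) -> float:
    """m/z of a backbone fragment at the given positive charge state."""
    return mz_from_neutral(fragment_neutral_mass(p, kind, span), charge)


def make_fragment(
    p: ModifiedPeptide, kind: str, span: tuple[int, int], charge: int = 1
) -> FragmentIon:
    neutral = fragment_neutral_mass(p, kind, span)
    s, e = span
    retained = tuple(site for site, _ in p.mod_sites if s <= site <= e)
    return FragmentIon(
        kind=kind,
        span=span,
        retained_mods=retained,
        charge=charge,
        neutral_mass=neutral,
        mz=mz_from_neutral(neutral, charge),
    )


def generate_fragments(
    p: ModifiedPeptide,
    kinds: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Exhaustive, duplicate-free backbone fragment enumeration.

    b_i for i = 1..n-1; y_j for j = 1..n-1; internal spans all
    (start, end) with 2 <= start < end <= n-1; each at charges
    1..max_charge. Deterministic order: (kind, start, end, charge).
    """
    n = len(p)
    if n < 2:
        raise ValueError("fragment generation needs a peptide of length >= 2")
    for k in kinds:
        if k not in FRAGMENT_KINDS:
            raise ValueError(f"unknown fragment kind {k!r}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    spans: list[tuple[str, tuple[int, int]]] = []
    for kind in sorted(set(kinds), key=FRAGMENT_KINDS.index):
        if kind == "b":
            spans.extend(("b", (1, i)) for i in range(1, n))
        elif kind == "y":
            spans.extend(("y", (s, n)) for s in range(2, n + 1))
        else:
            spans.extend(
                (kind, (s, e)) for s in range(2, n - 1) for e in range(s + 1, n)
            )
    out = [
        make_fragment(p, kind, span, z)
        for kind, span in spans
        for z in range(1, max_charge + 1)
    ]
    out.sort(key=lambda f: (FRAGMENT_KINDS.index(f.kind), f.span, f.charge))
    return out
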