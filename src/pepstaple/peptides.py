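"""Peptide data model and staple-variant design operations.

Peptides are short synthetic sequences numbered by their position in the
parent protein (1-based, inclusive on both ends: a peptide named 73-94 spans
parent residues 73..94).  Sequences use the twenty canonical one-letter codes
plus ``pS`` for phosphoserine, and carry terminal modification state
(N-terminal acetyl or FAM-Ahx fluorophore, C-terminal primary amide).

A covalent i,i+4 side-chain constraint is modelled as a :class:`ConstraintSpec`
on a cysteine pair, in one of three chemical states: ``red`` (free thiols),
``ox`` (disulfide) or ``mal`` (dibromomaleimide-bridged, which adds a
maleimide chromophore).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "CANONICAL_RESIDUES",
    "RESIDUE_CODES",
    "ConstraintSpec",
    "PeptideSpec",
    "ChromophoreTable",
    "DEFAULT_CHROMOPHORES",
    "PeptideError",
    "PeptideParseError",
    "parse_peptide",
    "truncate",
    "substitute",
    "enumerate_cys_pair_variants",
    "count_backbone_amides",
    "molar_extinction",
    "concentration_from_absorbance",
    "average_mass",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: All accepted residue codes; "pS" is phosphoserine, counted as one residue.
RESIDUE_CODES = CANONICAL_RESIDUES | {"pS"}

N_TERMINI = ("acetyl", "FAM-Ahx", "free")
C_TERMINI = ("amide", "free")
CONSTRAINT_STATES = ("red", "ox", "mal")


class PeptideError(ValueError):
    """Invalid peptide definition or operation."""


class PeptideParseError(PeptideError):
    """Sequence string could not be tokenized."""


@dataclass(frozen=True)
class ConstraintSpec:
    """An i,i+spacing side-chain constraint between two cysteines.

    Positions are parent-protein numbering.  ``state`` is ``red`` (free
    thiols), ``ox`` (disulfide) or ``mal`` (maleimide bridge).
    """

    position_i: int
    position_j: int
    spacing: int = 4
    state: str = "red"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise PeptideError(f"constraint spacing must be positive, got {self.spacing}")
        if self.position_j - self.position_i != self.spacing:
            raise PeptideError(
                f"constraint positions {self.position_i}/{self.position_j} do not "
                f"match declared spacing {self.spacing}"
            )
        if self.state not in CONSTRAINT_STATES:
            raise PeptideError(f"constraint state must be one of {CONSTRAINT_STATES}, got {self.state!r}")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence with parent numbering, termini and optional constraint."""

    name: str
    residues: tuple[str, ...]
    numbering_offset: int = 1
    n_term: str = "acetyl"
    c_term: str = "amide"
    constraint: Optional[ConstraintSpec] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideError("peptide must contain at least one residue")
        if self.numbering_offset < 1:
            raise PeptideError(f"numbering_offset must be >= 1, got {self.numbering_offset}")
        for k, res in enumerate(self.residues):
            if res not in RESIDUE_CODES:
                raise PeptideParseError(
                    f"unknown residue code {res!r} at local position {k} "
                    f"(parent {self.numbering_offset + k})"
                )
        if self.n_term not in N_TERMINI:
            raise PeptideError(f"n_term must be one of {N_TERMINI}, got {self.n_term!r}")
        if self.c_term not in C_TERMINI:
            raise PeptideError(f"c_term must be one of {C_TERMINI}, got {self.c_term!r}")
        if self.constraint is not None:
            for pos in (self.constraint.position_i, self.constraint.position_j):
                if not (self.parent_start <= pos <= self.parent_end):
                    raise PeptideError(f"constraint position {pos} outside peptide range "
                                       f"{self.parent_start}-{self.parent_end}")
                if self.residue_at(pos) != "C":
                    raise PeptideError(
                        f"constraint position {pos} is {self.residue_at(pos)!r}, not Cys"
                    )

    # -- numbering helpers ------------------------------------------------

    @property
    def parent_start(self) -> int:
        return self.numbering_offset

    @property
    def parent_end(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def local_index(self, parent_position: int) -> int:
        """0-based index into ``residues`` for a parent-numbering position."""
        if not (self.parent_start <= parent_position <= self.parent_end):
            raise PeptideError(
                f"position {parent_position} outside peptide range "
                f"{self.parent_start}-{self.parent_end}"
            )
        return parent_position - self.numbering_offset

    def residue_at(self, parent_position: int) -> str:
        return self.residues[self.local_index(parent_position)]

    @property
    def sequence(self) -> str:
        """Sequence string with pS rendered as the two-character token."""
        return "".join(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


#: Molar extinction coefficients (M^-1 cm^-1) used for concentration
#: determination by UV-Vis: tryptophan 5600 and, for maleimide-constrained
#: peptides, an additional maleimide chromophore at 1700.
DEFAULT_CHROMOPHORES: Mapping[str, float] = {"Trp": 5600.0, "maleimide": 1700.0}

ChromophoreTable = Mapping[str, float]


def _validated_table(table: ChromophoreTable) -> ChromophoreTable:
    for name, eps in table.items():
        if eps <= 0:
            raise PeptideError(f"extinction coefficient for {name!r} must be > 0, got {eps}")
    return table


def parse_peptide(
    text: str,
    offset: int,
    name: str = "",
    constraint: Optional[ConstraintSpec] = None,
) -> PeptideSpec:
    """Parse a sequence string like ``"Ac-EPPSWVTEMLLENELWG-NH2"``.

    Recognises an optional ``Ac-`` or ``FAM-Ahx-`` prefix, an optional
    ``-NH2`` suffix and the two-character ``pS`` phosphoserine token;
    termini without a modifier are recorded as free.
    """
    s = text.strip()
    if not s:
        raise PeptideParseError("empty sequence string")
    n_term = "free"
    c_term = "free"
    if s.startswith("FAM-Ahx-"):
        n_term = "FAM-Ahx"
        s = s[len("FAM-Ahx-"):]
    elif s.startswith("Ac-"):
        n_term = "acetyl"
        s = s[len("Ac-"):]
    if s.endswith("-NH2"):
        c_term = "amide"
        s = s[: -len("-NH2")]
    if not s:
        raise PeptideParseError(f"no residues in sequence string {text!r}")

    residues: list[str] = []
    i = 0
    while i < len(s):
        if s.startswith("pS", i):
            residues.append("pS")
            i += 2
            continue
        tok = s[i]
        if tok not in CANONICAL_RESIDUES:
            raise PeptideParseError(f"unknown residue token {tok!r} at sequence position {i}")
        residues.append(tok)
        i += 1

    return PeptideSpec(
        name=name or f"peptide_{offset}-{offset + len(residues) - 1}",
        residues=tuple(residues),
        numbering_offset=offset,
        n_term=n_term,
        c_term=c_term,
        constraint=constraint,
    )


def truncate(p: PeptideSpec, start: int, end: int, name: str = "") -> PeptideSpec:
    """Contiguous sub-peptide spanning parent positions ``start..end`` inclusive.

    The result is renumbered from ``start``; termini are preserved (a
    truncated synthetic peptide is still made with the same capping
    chemistry).  A constraint whose anchors fall outside the new range is
    dropped.
    """
    if start > end:
        raise PeptideError(f"start {start} > end {end}")
    i = p.local_index(start)
    j = p.local_index(end)
    constraint = p.constraint
    if constraint is not None and not (
        start <= constraint.position_i and constraint.position_j <= end
    ):
        constraint = None
    return PeptideSpec(
        name=name or f"{p.name}_{start}-{end}",
        residues=p.residues[i: j + 1],
        numbering_offset=start,
        n_term=p.n_term,
        c_term=p.c_term,
        constraint=constraint,
    )


def substitute(p: PeptideSpec, position: int, new_residue: str, name: str = "") -> PeptideSpec:
    """Replace the residue at a parent-numbering position."""
    if new_residue not in RESIDUE_CODES:
        raise PeptideError(f"invalid residue code {new_residue!r}")
    k = p.local_index(position)
    residues = list(p.residues)
    residues[k] = new_residue
    return replace(p, residues=tuple(residues), name=name or p.name)


def enumerate_cys_pair_variants(
    p: PeptideSpec,
    region_start: int,
    region_end: int,
    hotspots: Iterable[int] = (),
    spacing: int = 4,
    state: str = "red",
) -> list[PeptideSpec]:
    """Cysteine-pair scan: one variant per (i, i+spacing) pair in the region.

    Both positions must lie inside ``[region_start, region_end]``, avoid the
    hot-spot set (interface residues whose mutation abolishes binding), and
    not already be cysteine.  Each variant carries a :class:`ConstraintSpec`
    in the given state.  Ordered by i ascending.
    """
    if spacing <= 0:
        raise PeptideError(f"spacing must be positive, got {spacing}")
    # validates the region against the peptide's parent range
    p.local_index(region_start)
    p.local_index(region_end)
    hot = set(hotspots)
    variants: list[PeptideSpec] = []
    for i in range(region_start, region_end - spacing + 1):
        j = i + spacing
        if i in hot or j in hot:
            continue
        if p.residue_at(i) == "C" or p.residue_at(j) == "C":
            continue
        mutated = substitute(substitute(p, i, "C"), j, "C")
        constraint = ConstraintSpec(position_i=i, position_j=j, spacing=spacing, state=state)
        variants.append(
            replace(
                mutated,
                name=f"{p.name}-{p.residue_at(i)}{i}C/{p.residue_at(j)}{j}C",
                constraint=constraint,
            )
        )
    return variants


def count_backbone_amides(p: PeptideSpec) -> int:
    """Number of backbone amide bonds, counting terminal capping amides.

    An r-residue peptide has r−1 inter-residue amide bonds; an acetyl (or
    FAM-Ahx, also amide-linked) N-terminal cap and a C-terminal primary amide
    each add one more, so the common Ac/NH2 peptide has r+1.  This is the
    ``n`` that enters the helicity formula's chain-length correction.
    """
    n = len(p.residues) - 1
    if p.n_term in ("acetyl", "FAM-Ahx"):
        n += 1
    if p.c_term == "amide":
        n += 1
    return n


def molar_extinction(p: PeptideSpec, table: ChromophoreTable = DEFAULT_CHROMOPHORES) -> float:
    """Molar extinction coefficient (M^-1 cm^-1) for UV-Vis concentration.

    Tryptophans contribute 5600 each; a maleimide-constrained peptide gains
    one 1700 maleimide term.  Disulfide (ox) and free-thiol (red) states do
    not change the coefficient.
    """
    table = _validated_table(table)
    eps = p.residues.count("W") * table["Trp"]
    if p.constraint is not None and p.constraint.state == "mal":
        eps += table["maleimide"]
    return eps


def concentration_from_absorbance(absorbance: float, epsilon: float, pathlength_cm: float = 1.0) -> float:
    """Beer-Lambert molar concentration: A / (epsilon * pathlength)."""
    if epsilon <= 0:
        raise PeptideError(f"extinction coefficient must be > 0, got {epsilon}")
    if pathlength_cm <= 0:
        raise PeptideError(f"pathlength must be > 0, got {pathlength_cm}")
    return absorbance / (epsilon * pathlength_cm)


# Average-mass deltas (g/mol) for modifications on top of the free peptide:
# acetylation replaces an N-terminal H with acetyl (+42.04); C-terminal
# amidation replaces OH with NH2 (-0.98); phospho adds HPO3 (+79.98);
# FAM-Ahx is 5(6)-carboxyfluorescein amide-coupled through aminohexanoic
# acid (+471.5); a maleimide bridge adds the maleimide core across two
# thiols (+94.04); a disulfide loses two hydrogens.
_MOD_MASS = {
    "acetyl": 42.04,
    "amide": -0.98,
    "pS": 79.98,
    "FAM-Ahx": 471.50,
    "mal": 94.04,
    "ox": -2.02,
}


def average_mass(p: PeptideSpec) -> float:
    """Approximate average molecular mass (g/mol), for CD normalisation.

    Canonical backbone mass comes from biopython; terminal caps, phospho
    groups and the constraint chemistry are added as nominal deltas.  Good
    to ~0.1 g/mol, which is ample for mean-residue-ellipticity work.
    """
    from Bio.SeqUtils import molecular_weight

    plain = "".join("S" if r == "pS" else r for r in p.residues)
    mass = molecular_weight(plain, seq_type="protein", monoisotopic=False)
    mass += p.residues.count("pS") * _MOD_MASS["pS"]
    if p.n_term in ("acetyl", "FAM-Ahx"):
        mass += _MOD_MASS[p.n_term]
    if p.c_term == "amide":
        mass += _MOD_MASS["amide"]
    if p.constraint is not None and p.constraint.state in ("mal", "ox"):
        mass += _MOD_MASS[p.constraint.state]
    return mass
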