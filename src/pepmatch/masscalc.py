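"""Theoretical peptide masses for singly protonated ions.

MALDI produces predominantly singly charged peptide ions, so a peak's m/z can
be compared directly with the theoretical [M+H]+ of every peptide identified
by LC-MS/MS.  This module provides that theoretical side of the comparison:
residue-mass bookkeeping, variable modifications (oxidation, deamidation) and
the [M+H]+ summation

    mz = (sum(residue masses) + water + sum(modification deltas)
          + charge * proton) / charge

Monoisotopic masses are the default; average masses are available for
low-resolution work.  Non-canonical residue letters (B, Z, X, U, O) are
rejected rather than approximated, because a silently wrong theoretical mass
corrupts the downstream delta-mass score.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import InvalidModificationError, InvalidSequenceError

logger = logging.getLogger(__name__)

MassType = Literal["monoisotopic", "average"]

#: (monoisotopic, average) residue masses in Da for the 20 canonical amino
#: acids (residue = amino acid minus water).
RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    "G": (57.02146, 57.0513),
    "A": (71.03711, 71.0779),
    "S": (87.03203, 87.0773),
    "P": (97.05276, 97.1152),
    "V": (99.06841, 99.1311),
    "T": (101.04768, 101.1039),
    "C": (103.00919, 103.1429),
    "L": (113.08406, 113.1576),
    "I": (113.08406, 113.1576),
    "N": (114.04293, 114.1026),
    "D": (115.02694, 115.0874),
    "Q": (128.05858, 128.1292),
    "K": (128.09496, 128.1723),
    "E": (129.04259, 129.1140),
    "M": (131.04049, 131.1961),
    "H": (137.05891, 137.1393),
    "F": (147.06841, 147.1739),
    "R": (156.10111, 156.1857),
    "Y": (163.06333, 163.1733),
    "W": (186.07931, 186.2099),
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.007276

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)


@dataclass(frozen=True)
class ModificationSpec:
    """One variable modification applied to a peptide.

    ``positions`` are 1-based residue indices; an empty tuple means "any
    residue in ``target_residues``" (the mass contribution is positional
    either way, one delta per application).
    """

    name: str
    target_residues: frozenset[str]
    mass_delta: float
    positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.target_residues:
            raise InvalidModificationError(f"{self.name}: empty target residue set")

    def validate_against(self, sequence: str) -> None:
        """Check each stated position points at a residue this mod targets."""
        for pos in self.positions:
            if not 1 <= pos <= len(sequence):
                raise InvalidModificationError(
                    f"{self.name}: position {pos} outside sequence of length {len(sequence)}"
                )
            residue = sequence[pos - 1]
            if residue not in self.target_residues:
                raise InvalidModificationError(
                    f"{self.name}: residue {residue!r} at position {pos} is not in "
                    f"targets {sorted(self.target_residues)}"
                )


#: Built-in variable-modification registry matching the database-search
#: settings used upstream (oxidation on M, deamidation on N/Q).  Keys are
#: lower-case; user configs may extend this at run time.
MODIFICATION_REGISTRY: dict[str, tuple[float, frozenset[str]]] = {
    "oxidation": (15.994915, frozenset("M")),
    "deamidated": (0.984016, frozenset("NQ")),
    "deamidation": (0.984016, frozenset("NQ")),
}


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise InvalidSequenceError("empty peptide sequence")
    sequence = sequence.upper()
    for i, ch in enumerate(sequence, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise InvalidSequenceError(
                f"unknown residue {ch!r} at position {i} in {sequence!r}"
            )
    return sequence


def compute_peptide_mh(
    sequence: str,
    modifications: Sequence[ModificationSpec] = (),
    mass_type: MassType = "monoisotopic",
    charge: int = 1,
) -> float:
    """Theoretical m/z of a peptide ion (default: singly protonated, [M+H]+).

    Parameters
    ----------
    sequence
        Peptide over the 20 canonical one-letter residues (case-insensitive).
    modifications
        Variable modifications to add; each contributes its ``mass_delta``
        once per stated position (or once if positions are unstated).
    mass_type
        ``"monoisotopic"`` (default) or ``"average"``.
    charge
        Positive charge state; MALDI ions are singly charged by default.

    Returns
    -------
    float
        (neutral peptide mass + charge * proton) / charge, in Da.
    """
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    sequence = _check_sequence(sequence)
    idx = 0 if mass_type == "monoisotopic" else 1
    water = WATER_MONO if mass_type == "monoisotopic" else WATER_AVG
    mass = sum(RESIDUE_MASSES[ch][idx] for ch in sequence) + water
    for mod in modifications:
        mod.validate_against(sequence)
        n_applications = max(len(mod.positions), 1)
        mass += mod.mass_delta * n_applications
    return (mass + charge * PROTON) / charge


@dataclass
class ModificationParseResult:
    """Parsed modifications plus every token that could not be interpreted."""

    modifications: list[ModificationSpec] = field(default_factory=list)
    skipped_tokens: list[str] = field(default_factory=list)


# e.g. "1xOxidation [M7]", "2xDeamidated [N3; Q5]", "Oxidation [M7]"
_MOD_TOKEN = re.compile(
    r"^\s*(?:(?P<count>\d+)x)?(?P<name>[A-Za-z][\w\-]*)\s*(?:\[(?P<sites>[^\]]*)\])?\s*$"
)
_SITE = re.compile(r"^\s*([A-Z])(\d+)\s*$")


def parse_modification_annotation(text: str, sequence: str) -> ModificationParseResult:
    """Parse a search-export modification string against its peptide sequence.

    Accepts the common ``"1xOxidation [M7]; 1xDeamidated [N3]"`` notation.
    Unrecognized tokens are skipped with a logged warning and recorded in the
    returned report — never silently dropped.  Positions are validated against
    the sequence; a token whose position is illegal is likewise skipped.
    """
    result = ModificationParseResult()
    if not text or not text.strip():
        return result
    sequence = sequence.upper()
    for token in re.split(r"[;,](?![^\[]*\])", text):
        token = token.strip()
        if not token:
            continue
        m = _MOD_TOKEN.match(token)
        if m is None or m.group("name").lower() not in MODIFICATION_REGISTRY:
            logger.warning("unparseable modification token %r (skipped)", token)
            result.skipped_tokens.append(token)
            continue
        delta, targets = MODIFICATION_REGISTRY[m.group("name").lower()]
        positions: list[int] = []
        bad_site = False
        sites_text = m.group("sites")
        if sites_text:
            for site in sites_text.split(";"):
                sm = _SITE.match(site)
                if sm is None:
                    # N-term / C-term or ambiguous site notation — not modelled
                    bad_site = True
                    break
                positions.append(int(sm.group(2)))
        if bad_site:
            logger.warning("unparseable modification site in %r (skipped)", token)
            result.skipped_tokens.append(token)
            continue
        spec = ModificationSpec(
            name=m.group("name"),
            target_residues=targets,
            mass_delta=delta,
            positions=tuple(positions),
        )
        try:
            spec.validate_against(sequence)
        except InvalidModificationError as exc:
            logger.warning("modification %r rejected: %s", token, exc)
            result.skipped_tokens.append(token)
            continue
        result.modifications.append(spec)
    return result


def peptide_mh_with_annotation(
    sequence: str, annotation: str = "", mass_type: MassType = "monoisotopic"
) -> float:
    """[M+H]+ of a peptide given its raw search-export modification string."""
    parsed = parse_modification_annotation(annotation, sequence)
    return compute_peptide_mh(sequence, parsed.modifications, mass_type=mass_type)


@dataclass(frozen=True)
class PeptideIon:
    """A peptide with its theoretical ion m/z, computed on construction."""

    sequence: str
    modifications: tuple[ModificationSpec, ...] = ()
    charge: int = 1
    mass_type: MassType = "monoisotopic"
    mz: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))
        object.__setattr__(
            self,
            "mz",
            compute_peptide_mh(
                self.sequence,
                self.modifications,
                mass_type=self.mass_type,
                charge=self.charge,
            ),
        )
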