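"""Peptide chemistry: residues, modifications, notation parsing, monoisotopic mass.

The unit of everything downstream is the :class:`Peptide` — an ordered list of
residues, each an elemental composition, with optional side-chain and terminal
modifications.  Masses are computed from compositions with a fixed monoisotopic
element table so that results are reproducible to the sub-ppm level; nothing in
the package ever stores a residue as a bare mass.

Sequence notation follows the bracketed convention used for FRET substrates,
e.g. ``KY(NO2)TESESRGK(Abz)IYYKKG`` or ``Abz-TESE↓SRGAIY-Dpa-KK-NH2``:

* ``(MOD)`` binds a side-chain modification to the preceding residue;
* a leading ``Abz-`` or ``Mca-`` is an N-terminal acyl group;
* a trailing ``-NH2`` marks a C-terminal amide (default is the free acid);
* ``↓`` (or ``|``) marks the scissile bond and is recorded, not counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "WATER",
    "formula_mass",
    "parse_formula",
    "ResidueSpec",
    "ModificationSpec",
    "Residue",
    "Peptide",
    "Registry",
    "default_registry",
    "parse_peptide",
    "monoisotopic_mass",
    "mz",
    "PeptideSyntaxError",
    "UnknownTokenError",
]

# Monoisotopic element masses (Da).  Fixed constants: the package's mass
# arithmetic must be bit-reproducible across environments.
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}
PROTON_MASS: float = 1.00727646688

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(-?\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``"C6H12N2O"`` or signed ``"+N O2 -H"`` into element counts.

    The signed form is used for modification deltas: each whitespace-separated
    group carries an optional leading ``+``/``-`` applying to the whole group.
    """
    counts: dict[str, int] = {}
    for group in text.split():
        sign = 1
        if group.startswith("+"):
            group = group[1:]
        elif group.startswith("-"):
            sign = -1
            group = group[1:]
        pos = 0
        for m in _FORMULA_RE.finditer(group):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"malformed formula {text!r}")
            pos = m.end()
            elem, num = m.group(1), m.group(2)
            if elem not in ELEMENT_MASSES:
                raise ValueError(f"unknown element {elem!r} in formula {text!r}")
            counts[elem] = counts.get(elem, 0) + sign * int(num or 1)
        if pos != len(group):
            raise ValueError(f"malformed formula {text!r}")
    return {e: c for e, c in counts.items() if c != 0}


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition (signed compositions allowed)."""
    return sum(ELEMENT_MASSES[e] * c for e, c in formula.items())


def _add(*formulas: Mapping[str, int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for f in formulas:
        for e, c in f.items():
            out[e] = out.get(e, 0) + c
    return {e: c for e, c in out.items() if c != 0}


WATER: Mapping[str, int] = {"H": 2, "O": 1}


class PeptideSyntaxError(ValueError):
    """Malformed sequence notation (dangling modification, empty input, ...)."""


class UnknownTokenError(ValueError):
    """A residue or modification token absent from the registry."""

    def __init__(self, token: str, offset: int | None = None):
        self.token = token
        self.offset = offset
        at = f" at offset {offset}" if offset is not None else ""
        super().__init__(f"unknown token {token!r}{at}")


@dataclass(frozen=True)
class ResidueSpec:
    """A residue type: token plus elemental composition (amino acid − water)."""

    token: str
    formula: Mapping[str, int]

    def __post_init__(self):
        if not self.formula or any(c < 0 for c in self.formula.values()):
            raise ValueError(f"residue {self.token!r}: formula must be nonnegative and nonempty")
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"residue {self.token!r}: nonpositive mass")

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self.formula)


@dataclass(frozen=True)
class ModificationSpec:
    """A mass-shifting group with a signed elemental delta and allowed attachment sites."""

    name: str
    attachments: tuple[str, ...]  # subset of {"side_chain", "n_terminus", "c_terminus"}
    delta_formula: Mapping[str, int]

    @property
    def delta_mass(self) -> float:
        return formula_mass(self.delta_formula)


@dataclass(frozen=True)
class Residue:
    """A residue instance in a chain, with at most one side-chain modification."""

    spec: ResidueSpec
    modification: ModificationSpec | None = None

    @property
    def formula(self) -> dict[str, int]:
        if self.modification is None:
            return dict(self.spec.formula)
        return _add(self.spec.formula, self.modification.delta_formula)

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self.formula)

    @property
    def token(self) -> str:
        if self.modification is None:
            return self.spec.token
        return f"{self.spec.token}({self.modification.name})"


@dataclass(frozen=True)
class Peptide:
    """An ordered residue chain with terminal state and optional scissile-bond marker.

    ``cleavage_marker`` counts residues N-terminal of the scissile bond, so the
    P1 residue is ``residues[cleavage_marker - 1]`` and P1' is
    ``residues[cleavage_marker]``.
    """

    residues: tuple[Residue, ...]
    n_terminal_acyl: ModificationSpec | None = None
    c_terminal_amide: bool = False
    amide_delta: Mapping[str, int] = field(default_factory=lambda: {"N": 1, "H": 1, "O": -1})
    cleavage_marker: int | None = None

    def __post_init__(self):
        if len(self.residues) < 1:
            raise PeptideSyntaxError("peptide must contain at least one residue")
        if self.cleavage_marker is not None and not (0 < self.cleavage_marker < len(self.residues)):
            raise PeptideSyntaxError(
                f"cleavage marker {self.cleavage_marker} not strictly inside chain of "
                f"length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def formula(self) -> dict[str, int]:
        parts = [r.formula for r in self.residues] + [dict(WATER)]
        if self.n_terminal_acyl is not None:
            parts.append(dict(self.n_terminal_acyl.delta_formula))
        if self.c_terminal_amide:
            parts.append(dict(self.amide_delta))
        return _add(*parts)

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass M (Da)."""
        return formula_mass(self.formula)

    def sequence(self, marker: bool = True) -> str:
        """Canonical bracketed-notation string; round-trips through :func:`parse_peptide`.

        With ``marker=False`` the scissile-bond ``↓`` is omitted, which is the
        form to use when comparing a library member against a plain sequence.
        """
        parts: list[str] = []
        run: list[str] = []
        for i, r in enumerate(self.residues):
            if marker and self.cleavage_marker is not None and i == self.cleavage_marker:
                run.append("↓")
            if len(r.spec.token) > 1:  # multi-letter tokens are hyphen-delimited
                if run:
                    parts.append("".join(run))
                    run = []
                parts.append(r.token)
            else:
                run.append(r.token)
        if run:
            parts.append("".join(run))
        body = "-".join(parts)
        if self.n_terminal_acyl is not None:
            body = f"{self.n_terminal_acyl.name}-{body}"
        if self.c_terminal_amide:
            body = f"{body}-NH2"
        return body

    def __str__(self) -> str:
        return self.sequence()


class Registry:
    """Token → :class:`ResidueSpec` / :class:`ModificationSpec` lookup.

    Built from a YAML mapping (see ``data/residues.yaml``); user files with the
    same schema can extend or override the defaults.
    """

    def __init__(self, residues: Mapping[str, ResidueSpec], modifications: Mapping[str, ModificationSpec]):
        self.residues = dict(residues)
        self.modifications = dict(modifications)

    @classmethod
    def from_dict(cls, data: Mapping) -> "Registry":
        residues = {
            tok: ResidueSpec(tok, parse_formula(f)) for tok, f in data.get("residues", {}).items()
        }
        mods = {}
        for name, m in data.get("modifications", {}).items():
            att = m["attachment"]
            if isinstance(att, str):
                att = [att]
            mods[name] = ModificationSpec(name, tuple(att), parse_formula(m["delta"]))
        return cls(residues, mods)

    @classmethod
    def from_file(cls, path) -> "Registry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def residue(self, token: str, modification: str | None = None) -> Residue:
        if token not in self.residues:
            raise UnknownTokenError(token)
        mod = None
        if modification is not None:
            if modification not in self.modifications:
                raise UnknownTokenError(modification)
            mod = self.modifications[modification]
            if "side_chain" not in mod.attachments:
                raise PeptideSyntaxError(f"modification {modification!r} cannot attach to a side chain")
        return Residue(self.residues[token], mod)

    def acyl(self, name: str) -> ModificationSpec:
        mod = self.modifications.get(name)
        if mod is None or "n_terminus" not in mod.attachments:
            raise UnknownTokenError(name)
        return mod


def default_registry() -> Registry:
    """The shipped registry (canonical + library residues, Abz/Mca/NO2/amide)."""
    with resources.files("fretscreen.data").joinpath("residues.yaml").open() as fh:
        return Registry.from_dict(yaml.safe_load(fh))


_DEFAULT: Registry | None = None


def _registry(registry: Registry | None) -> Registry:
    global _DEFAULT
    if registry is not None:
        return registry
    if _DEFAULT is None:
        _DEFAULT = default_registry()
    return _DEFAULT


_TOKEN_RE = re.compile(r"(?P<res>[A-Z])(?:\((?P<mod>[A-Za-z0-9]+)\))?|(?P<cleave>[↓|])")


def parse_peptide(notation: str, registry: Registry | None = None) -> Peptide:
    """Parse bracketed sequence notation into a :class:`Peptide`.

    Raises :class:`PeptideSyntaxError` for malformed input and
    :class:`UnknownTokenError` (with the offending token and offset) for
    tokens missing from the registry.
    """
    reg = _registry(registry)
    notation = notation.strip()
    if not notation:
        raise PeptideSyntaxError("empty sequence")

    segments = notation.split("-")
    acyl: ModificationSpec | None = None
    amide = False
    if len(segments) > 1 and segments[0] in reg.modifications:
        acyl = reg.acyl(segments[0])
        segments = segments[1:]
    if len(segments) > 1 and segments[-1] == "NH2":
        amide = True
        segments = segments[:-1]
    if not segments or not all(segments):
        raise PeptideSyntaxError(f"malformed notation {notation!r}")

    residues: list[Residue] = []
    marker: int | None = None
    offset = 0
    for seg in segments:
        if seg in reg.residues and len(seg) > 1:  # multi-letter residue token, e.g. Dpa
            residues.append(reg.residue(seg))
            offset += len(seg) + 1
            continue
        pos = 0
        while pos < len(seg):
            m = _TOKEN_RE.match(seg, pos)
            if m is None:
                raise PeptideSyntaxError(f"cannot parse {seg[pos:]!r} at offset {offset + pos}")
            if m.group("cleave"):
                if marker is not None:
                    raise PeptideSyntaxError("multiple cleavage markers")
                marker = len(residues)
            else:
                tok, mod = m.group("res"), m.group("mod")
                if tok not in reg.residues:
                    raise UnknownTokenError(tok, offset + pos)
                if mod is not None and mod not in reg.modifications:
                    raise UnknownTokenError(mod, offset + pos)
                residues.append(reg.residue(tok, mod))
            pos = m.end()
        offset += len(seg) + 1

    if marker is not None and not (0 < marker < len(residues)):
        raise PeptideSyntaxError("cleavage marker must lie strictly inside the chain")
    return Peptide(
        residues=tuple(residues),
        n_terminal_acyl=acyl,
        c_terminal_amide=amide,
        cleavage_marker=marker,
    )


def monoisotopic_mass(peptide: Peptide | str, registry: Registry | None = None) -> float:
    """Neutral monoisotopic mass of a peptide (Da); accepts notation strings."""
    if isinstance(peptide, str):
        peptide = parse_peptide(peptide, registry)
    return peptide.monoisotopic_mass


def mz(
    peptide: Peptide | str,
    charge: int = 1,
    neutral_losses: Iterable[Mapping[str, int] | str] = (),
    registry: Registry | None = None,
) -> float:
    """m/z of ``[M − losses + charge·H]^charge+``.

    ``neutral_losses`` are elemental compositions (dicts or formula strings,
    e.g. ``"O"`` for the single-oxygen loss seen on nitro-tyrosine peptides).
    """
    if isinstance(peptide, str):
        peptide = parse_peptide(peptide, registry)
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    m = peptide.monoisotopic_mass
    loss = sum(
        formula_mass(parse_formula(f) if isinstance(f, str) else f) for f in neutral_losses
    )
    if loss >= m:
        raise ValueError(f"neutral loss {loss:.4f} Da exceeds peptide mass {m:.4f} Da")
    return (m - loss + charge * PROTON_MASS) / charge
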