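"""Positional combinatorial libraries: size, enumeration, precursor-constrained search.

A :class:`PositionalLibrary` is an ordered list of positions, each with a
non-empty set of allowed residue tokens (fixed positions have exactly one).
Position labels follow Schechter–Berger P-notation counted outward from the
scissile bond.  Enumeration is position-major (the last position varies
fastest) and deterministic; the precursor-constrained search prunes on partial
mass bounds but is contractually identical to brute-force filtering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

from .chem import (
    PROTON_MASS,
    WATER,
    Peptide,
    Registry,
    Residue,
    _registry,
    formula_mass,
    parse_formula,
    parse_peptide,
)

__all__ = [
    "PositionalLibrary",
    "load_library",
    "packaged_library",
    "library_size",
    "enumerate_members",
    "candidates_for_precursor",
    "LibraryValidationError",
    "LibraryTooLargeError",
]

ENUMERATION_CAP = 10_000_000


class LibraryValidationError(ValueError):
    """The library definition violates its own declared constraints."""


class LibraryTooLargeError(RuntimeError):
    """Exhaustive enumeration refused; use candidates_for_precursor instead."""


def _parse_option(token: str, registry: Registry) -> Residue:
    """Resolve an option token like ``K`` or ``Y(NO2)`` to a Residue."""
    if "(" in token:
        base, mod = token[: token.index("(")], token[token.index("(") + 1 : -1]
        return registry.residue(base, mod)
    return registry.residue(token)


@dataclass(frozen=True)
class LibraryPosition:
    label: str
    options: tuple[str, ...]

    def __post_init__(self):
        if not self.options:
            raise LibraryValidationError(f"position {self.label}: empty option set")
        if len(set(self.options)) != len(self.options):
            raise LibraryValidationError(f"position {self.label}: duplicate options")


@dataclass(frozen=True)
class PositionalLibrary:
    """Ordered positions (N→C) with allowed residue tokens and a scissile bond."""

    positions: tuple[LibraryPosition, ...]
    scissile_index: int | None = None
    name: str = ""

    def __post_init__(self):
        if not self.positions:
            raise LibraryValidationError("library has no positions")
        if self.scissile_index is not None and not (0 < self.scissile_index < len(self.positions)):
            raise LibraryValidationError("scissile bond must lie strictly inside the chain")

    @property
    def size(self) -> int:
        n = 1
        for p in self.positions:
            n *= len(p.options)
        return n

    def resolved_options(self, registry: Registry | None = None) -> list[list[Residue]]:
        reg = _registry(registry)
        return [[_parse_option(tok, reg) for tok in p.options] for p in self.positions]

    def contains(self, sequence: str, registry: Registry | None = None) -> bool:
        """Whether a notation string is a member (free-acid, unacylated chains only)."""
        try:
            pep = parse_peptide(sequence, registry)
        except ValueError:
            return False
        if pep.n_terminal_acyl is not None or pep.c_terminal_amide:
            return False
        if len(pep) != len(self.positions):
            return False
        return all(
            r.token in pos.options for r, pos in zip(pep.residues, self.positions)
        )


def load_library(source, registry: Registry | None = None) -> PositionalLibrary:
    """Load a library definition from a YAML path or parsed mapping.

    Validates every token against the registry.  If the definition declares
    ``expected_size`` or ``required_members`` these are enforced and loading
    fails when they do not hold.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    reg = _registry(registry)
    positions = tuple(
        LibraryPosition(str(p["label"]), tuple(str(t) for t in p["options"]))
        for p in data["positions"]
    )
    lib = PositionalLibrary(
        positions=positions,
        scissile_index=data.get("scissile_index"),
        name=str(data.get("name", "")),
    )
    lib.resolved_options(reg)  # raises UnknownTokenError on bad tokens
    expected = data.get("expected_size")
    if expected is not None and lib.size != int(expected):
        raise LibraryValidationError(
            f"{lib.name or 'library'}: size {lib.size} != declared {expected}"
        )
    for seq in data.get("required_members", []):
        if not lib.contains(seq, reg):
            raise LibraryValidationError(f"{lib.name or 'library'}: {seq!r} is not a member")
    return lib


def packaged_library(name: str = "adamts5_fig4a", registry: Registry | None = None) -> PositionalLibrary:
    """Load a library design shipped with the package."""
    with resources.files("fretscreen.data").joinpath(f"{name}.yaml").open() as fh:
        return load_library(yaml.safe_load(fh), registry)


def library_size(library: PositionalLibrary) -> int:
    """Exact number of unique members (product of per-position option counts)."""
    return library.size


def _assemble(combo: Sequence[Residue], scissile: int | None) -> Peptide:
    return Peptide(residues=tuple(combo), cleavage_marker=scissile)


def enumerate_members(
    library: PositionalLibrary,
    registry: Registry | None = None,
    cap: int = ENUMERATION_CAP,
) -> Iterator[Peptide]:
    """Yield every member exactly once, position-major (last position fastest)."""
    if library.size > cap:
        raise LibraryTooLargeError(
            f"library has {library.size} members (> cap {cap}); "
            "use candidates_for_precursor for mass-constrained search"
        )
    opts = library.resolved_options(registry)
    for combo in itertools.product(*opts):
        yield _assemble(combo, library.scissile_index)


def candidates_for_precursor(
    library: PositionalLibrary,
    precursor_mz: float,
    charge: int = 1,
    tol_ppm: float = 5.0,
    losses: Sequence[Mapping[str, int] | str] = (),
    registry: Registry | None = None,
) -> list[Peptide]:
    """Members whose ion m/z (given charge and neutral losses) matches the precursor.

    Depth-first branch-and-bound over partial residue-mass sums: a branch is
    cut as soon as the attainable mass interval of its completions misses the
    target window.  Results are in enumeration order and identical to
    brute-force filtering of :func:`enumerate_members`.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    loss_mass = sum(
        formula_mass(parse_formula(f) if isinstance(f, str) else f) for f in losses
    )
    # target neutral residue-sum window
    neutral = precursor_mz * charge - charge * PROTON_MASS + loss_mass
    tol_da = precursor_mz * tol_ppm * 1e-6 * charge
    target = neutral - formula_mass(WATER)
    lo, hi = target - tol_da, target + tol_da

    opts = library.resolved_options(registry)
    masses = [np.array([r.monoisotopic_mass for r in col]) for col in opts]
    # attainable residue-mass range of the remaining suffix at each depth
    min_rest = np.zeros(len(opts) + 1)
    max_rest = np.zeros(len(opts) + 1)
    for d in range(len(opts) - 1, -1, -1):
        min_rest[d] = min_rest[d + 1] + masses[d].min()
        max_rest[d] = max_rest[d + 1] + masses[d].max()

    out: list[Peptide] = []
    combo: list[Residue] = []

    def descend(depth: int, partial: float) -> None:
        if depth == len(opts):
            if lo <= partial <= hi:
                out.append(_assemble(combo, library.scissile_index))
            return
        for k in range(len(opts[depth])):
            m = partial + masses[depth][k]
            if m + min_rest[depth + 1] > hi or m + max_rest[depth + 1] < lo:
                continue
            combo.append(opts[depth][k])
            descend(depth + 1, m)
            combo.pop()

    descend(0, 0.0)
    return out
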