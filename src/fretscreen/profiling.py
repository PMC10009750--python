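"""Position-frequency profiling of cleavage-annotated substrate sequences.

Positions use Schechter–Berger P-notation: P1 is the residue immediately
N-terminal of the scissile bond, P1' immediately C-terminal, counting outward
on both sides.  Internally a position is an integer offset: P_k ↔ −k and
Pk' ↔ +k, so the residue index of position ``p`` in a record with cleavage
index ``c`` (residues N-terminal of the bond) is ``c + p`` for primed
positions and ``c + p`` (negative p) for unprimed ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubstrateRecord",
    "parse_position",
    "format_position",
    "position_window",
    "position_frequencies",
    "rank_consensus",
]


@dataclass(frozen=True)
class SubstrateRecord:
    """A substrate sequence with its scissile-bond position.

    ``cleavage_index`` counts residues N-terminal of the bond (so it is also
    the 0-based index of the P1' residue).
    """

    sequence: str
    cleavage_index: int
    source: str = ""

    def __post_init__(self):
        if not (1 <= self.cleavage_index < len(self.sequence)):
            raise ValueError(
                f"cleavage index {self.cleavage_index} outside 1..{len(self.sequence) - 1}"
            )

    @classmethod
    def from_bar_notation(cls, text: str, source: str = "") -> "SubstrateRecord":
        """Parse ``"ABCD|EFGH"`` with the bar marking the scissile bond."""
        if text.count("|") != 1:
            raise ValueError(f"expected exactly one '|' in {text!r}")
        left, right = text.split("|")
        return cls(left + right, len(left), source)

    def residue_at(self, position: int) -> str | None:
        """Residue at a signed P-position offset, or None if out of range."""
        # unprimed P_k is offset -k: index = cleavage_index - k; primed Pk' is
        # offset +k: index = cleavage_index + k - 1
        idx = self.cleavage_index + position - (0 if position < 0 else 1)
        if 0 <= idx < len(self.sequence):
            return self.sequence[idx]
        return None


_P_RE = re.compile(r"^P(\d+)(['pP′]?)$")


def parse_position(label: str) -> int:
    """``"P4"`` → −4 (unprimed), ``"P9'"``/``"P9p"`` → +9 (primed)."""
    m = _P_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse position label {label!r}")
    k = int(m.group(1))
    if k == 0:
        raise ValueError("P0 does not exist")
    return k if m.group(2) else -k


def format_position(offset: int) -> str:
    return f"P{offset}'" if offset > 0 else f"P{-offset}"


def position_window(start: str, stop: str) -> list[int]:
    """Inclusive window of P-positions, e.g. ("P4", "P9'") → P4..P1, P1'..P9'."""
    a, b = parse_position(start), parse_position(stop)
    if a > b:
        a, b = b, a
    return [p for p in range(a, b + 1) if p != 0]


def position_frequencies(
    records: list[SubstrateRecord],
    window: tuple[str, str] = ("P4", "P9'"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Percent frequency of each residue at each window position.

    Records too short to cover a position are excluded from that position's
    denominator.  Returns (frequency table in %, per-position denominators);
    table rows are residues, columns position labels, and each column sums to
    100% over its denominator.
    """
    if not records:
        raise ValueError("empty record set")
    offsets = position_window(*window)
    counts: dict[str, dict[str, int]] = {}
    denominators: dict[str, int] = {}
    for off in offsets:
        label = format_position(off)
        col: dict[str, int] = {}
        n = 0
        for rec in records:
            residue = rec.residue_at(off)
            if residue is None:
                continue
            n += 1
            col[residue] = col.get(residue, 0) + 1
        counts[label] = col
        denominators[label] = n
    residues = sorted({r for col in counts.values() for r in col})
    table = pd.DataFrame(
        {
            label: [100.0 * counts[label].get(r, 0) / denominators[label] if denominators[label] else np.nan for r in residues]
            for label in counts
        },
        index=residues,
    )
    return table, pd.Series(denominators, name="n")


def rank_consensus(freq_table: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Most common residue(s) per position with their percentage.

    Ties within ``tol`` percentage points are reported jointly (slash-joined).
    """
    rows = []
    for label in freq_table.columns:
        col = freq_table[label].dropna()
        if col.empty:
            rows.append({"position": label, "residues": "", "percent": np.nan})
            continue
        top = float(col.max())
        winners = sorted(col.index[col >= top - tol])
        rows.append({"position": label, "residues": "/".join(winners), "percent": top})
    return pd.DataFrame(rows)
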