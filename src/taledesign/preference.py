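"""RVD-base preference matrix and the per-mismatch score components.

Each (RVD, base) pair carries a preference in [0, 1] summarizing how well
the repeat tolerates that base (1 = cognate, 0 = fully disfavored).  A
mismatch at EBE position p between the designed RVD and the genomic base
contributes

    S_M = (preference - 0.5) * (-2)        in [-1, 1]
    F_P = 1 / sqrt(p)

to the additive off-target score, so disfavored bases near T0 raise the
score most (high scores = disruptive mismatches = safer candidate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from taledesign.tale_code import BASE_FOR_RVD, CANONICAL_RVDS

__all__ = [
    "PreferenceMatrix",
    "default_preference_matrix",
    "load_preference_matrix",
    "write_preference_matrix",
    "mismatch_score",
    "position_factor",
    "T0_MISMATCH_PREFERENCE",
]

BASES = ("A", "C", "G", "T")

#: Preference applied when the mismatch sits at T0 itself (position 1),
#: where no canonical repeat exists.  A non-T base at T0 abolishes binding,
#: so it is maximally disfavored by default.
T0_MISMATCH_PREFERENCE = 0.0


@dataclass(frozen=True)
class PreferenceMatrix:
    """(RVD, base) -> preference in [0, 1], complete over its RVD set."""

    entries: dict[tuple[str, str], float]
    provenance: str = ""

    def __post_init__(self) -> None:
        rvds = {rvd for rvd, _ in self.entries}
        for rvd in rvds:
            for base in BASES:
                if (rvd, base) not in self.entries:
                    raise ValueError(f"missing entry for ({rvd}, {base})")
        for key, value in self.entries.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"preference {value} for {key} outside [0, 1]")
        for rvd in rvds & set(BASE_FOR_RVD):
            cognate = BASE_FOR_RVD[rvd]
            row_max = max(self.entries[rvd, b] for b in BASES)
            if self.entries[rvd, cognate] < row_max:
                raise ValueError(
                    f"cognate base {cognate} of {rvd} is not the row maximum"
                )

    @property
    def rvds(self) -> tuple[str, ...]:
        return tuple(sorted({rvd for rvd, _ in self.entries}))

    def __getitem__(self, key: tuple[str, str]) -> float:
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"no preference entry for (RVD, base) = {key}") from None


def default_preference_matrix() -> PreferenceMatrix:
    """Built-in matrix derived from the canonical RVD code.

    Cognate bases score 1.0; NN:A scores 0.6 as the documented weaker
    second preference of NN; every other pairing scores 0.0.  Users with a
    published quantitative preference table can substitute it via
    :func:`load_preference_matrix` without code changes.
    """
    entries = {
        (rvd, base): 0.0 for rvd in CANONICAL_RVDS for base in BASES
    }
    for rvd, base in BASE_FOR_RVD.items():
        entries[rvd, base] = 1.0
    entries["NN", "A"] = 0.6
    return PreferenceMatrix(entries, provenance="builtin canonical code")


def load_preference_matrix(path: str | Path) -> PreferenceMatrix:
    """Read a TSV with header ``RVD<TAB>A<TAB>C<TAB>G<TAB>T``.

    Raises ``ValueError`` on a missing cell, an out-of-range value, or an
    unknown base column.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty preference matrix file {path}")
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "RVD":
        raise ValueError(f"first header column must be 'RVD', got {header[0]!r}")
    bases = tuple(header[1:])
    unknown = set(bases) - set(BASES)
    if unknown:
        raise ValueError(f"unknown base column(s) {sorted(unknown)}")
    if set(bases) != set(BASES):
        raise ValueError(f"header must list all of A,C,G,T; got {bases}")
    entries: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != len(bases) + 1:
            raise ValueError(f"row {cells[0]!r} has {len(cells) - 1} cells, expected {len(bases)}")
        rvd = cells[0]
        for base, cell in zip(bases, cells[1:]):
            if cell.strip() == "":
                raise ValueError(f"missing cell for ({rvd}, {base})")
            entries[rvd, base] = float(cell)
    return PreferenceMatrix(entries, provenance=str(path))


def write_preference_matrix(matrix: PreferenceMatrix, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`load_preference_matrix`."""
    lines = ["RVD\t" + "\t".join(BASES)]
    for rvd in matrix.rvds:
        lines.append(
            rvd + "\t" + "\t".join(repr(matrix[rvd, b]) for b in BASES)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def mismatch_score(matrix: PreferenceMatrix, rvd: str, base: str) -> float:
    """S_M = (preference - 0.5) * (-2): 1 for preference 0, -1 for 1."""
    return (matrix[rvd, base] - 0.5) * -2.0


def position_factor(position: int) -> float:
    """F_P = 1/sqrt(position); strictly decreasing, so T0-proximal
    mismatches weigh more than T0-distal ones."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return 1.0 / math.sqrt(position)
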