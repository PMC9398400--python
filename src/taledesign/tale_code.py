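"""The TALE RVD-base code: EBE validity, RVD translation, mismatch profiling.

An effector-binding element (EBE) is the DNA sequence bound by a TALE.
Natural and designer TALE binding sites start with an invariant thymine
(T0) that is coordinated by degenerate repeats in the protein's N-terminal
region rather than by the canonical repeat array; every subsequent base is
read by one canonical repeat whose repeat-variable diresidue (RVD) sets its
base specificity.

Positions are 1-based over the full EBE with T0 at position 1.  (The field
names T0 "position 0", but the scoring system's position factor 1/sqrt(p)
must be finite at the first base, and published off-target tables mark
first-base mismatches, so the scoring coordinate starts at 1.)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "EBESequence",
    "RVDArray",
    "MismatchProfile",
    "EBEValidationError",
    "WrongLengthError",
    "AlphabetError",
    "T0Error",
    "validate_ebe",
    "ebe_to_rvds",
    "rvds_to_ebe",
    "mismatch_profile",
    "read_ebe",
    "RVD_FOR_BASE",
    "BASE_FOR_RVD",
    "CANONICAL_RVDS",
]

DNA_ALPHABET = frozenset("ACGT")

#: Canonical RVD for each base.  NN is used for G; it also binds A more
#: weakly, which the preference matrix (not this map) accounts for.
RVD_FOR_BASE = {"C": "HD", "G": "NN", "A": "NI", "T": "NG"}

#: Preferred (cognate) base of each canonical RVD.
BASE_FOR_RVD = {"HD": "C", "NN": "G", "NI": "A", "NG": "T"}

CANONICAL_RVDS = ("HD", "NN", "NI", "NG")


class EBEValidationError(ValueError):
    """Base class for EBE validation failures."""


class WrongLengthError(EBEValidationError):
    """Sequence length does not match the configured EBE length."""


class AlphabetError(EBEValidationError):
    """Sequence contains a character outside {A, C, G, T}."""


class T0Error(EBEValidationError):
    """First base is not the invariant thymine T0."""


@dataclass(frozen=True)
class EBESequence:
    """A validated candidate binding element: T-initial, unambiguous DNA.

    Construct through :func:`validate_ebe`; direct construction skips
    validation.
    """

    sequence: str
    length: int = 19

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", len(self.sequence))

    def __str__(self) -> str:
        return self.sequence

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class RVDArray:
    """Ordered RVD codes for the canonical repeat array of a dTALE.

    One RVD per EBE base from position 2 onward; T0 has no repeat.
    """

    rvds: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.rvds)

    def __str__(self) -> str:
        return "-".join(self.rvds)

    def __len__(self) -> int:
        return len(self.rvds)

    @classmethod
    def from_string(cls, text: str) -> "RVDArray":
        """Parse a hyphen-joined serialization such as ``"HD-NN-NI"``."""
        return cls(tuple(text.strip().split("-")))


@dataclass(frozen=True)
class MismatchProfile:
    """Sorted 1-based positions where an EBE and a genomic site differ."""

    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


def validate_ebe(sequence: str, length: int = 19) -> EBESequence:
    """Validate and normalize a candidate EBE.

    Parameters
    ----------
    sequence
        Raw DNA text; case-insensitive, surrounding whitespace ignored.
    length
        Required EBE length (default 19; must be >= 12).

    Returns
    -------
    EBESequence

    Raises
    ------
    WrongLengthError, AlphabetError, T0Error
    """
    if length < 12:
        raise ValueError(f"EBE length must be >= 12, got {length}")
    seq = sequence.strip().upper()
    if len(seq) != length:
        raise WrongLengthError(
            f"expected length {length}, got {len(seq)}: {seq!r}"
        )
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGT character(s) {sorted(bad)} in {seq!r}")
    if seq[0] != "T":
        raise T0Error(f"EBE must start with T0 (thymine), got {seq[0]!r}")
    return EBESequence(seq, length)


def ebe_to_rvds(ebe: EBESequence) -> RVDArray:
    """Translate an EBE into its canonical repeat array.

    One RVD per base from position 2 through the end (C->HD, G->NN,
    A->NI, T->NG); T0 is coordinated by the N-terminal region and has no
    canonical repeat.
    """
    return RVDArray(tuple(RVD_FOR_BASE[b] for b in ebe.sequence[1:]))


def rvds_to_ebe(rvds: RVDArray) -> EBESequence:
    """Reverse translation: prepend T0 and map each RVD to its cognate base."""
    try:
        tail = "".join(BASE_FOR_RVD[r] for r in rvds.rvds)
    except KeyError as e:
        raise ValueError(f"unknown RVD code {e.args[0]!r}") from None
    return validate_ebe("T" + tail, length=len(rvds) + 1)


def mismatch_profile(ebe: EBESequence | str, site: str) -> MismatchProfile:
    """Positions (1-based, T0 = 1) where the EBE and a genomic site differ.

    Symmetric in its two sequence arguments; both must have equal length
    and be plain ACGT.
    """
    a = str(ebe).upper()
    b = site.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    for s in (a, b):
        bad = set(s) - DNA_ALPHABET
        if bad:
            raise AlphabetError(f"non-ACGT character(s) {sorted(bad)} in {s!r}")
    return MismatchProfile(
        tuple(i for i, (x, y) in enumerate(zip(a, b), start=1) if x != y)
    )


def read_ebe(path: str | Path, length: int = 19) -> EBESequence:
    """Read an EBE from single-record FASTA or bare-text file."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single FASTA record in {path}, found {len(records)}"
            )
        return validate_ebe(str(records[0].seq), length=length)
    return validate_ebe(text, length=length)
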