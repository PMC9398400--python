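"""Published validation vectors for the dTALE1/dTALE2 designs.

dTALE1 and dTALE2 are two deployed designer TALEs for rice whose
genome-wide off-target audits are published; their reported off-target
site sequences and census counts serve as in-package test vectors so the
scanner and scoring code can be validated without downloading the
~380 Mb rice genome.

The dTALE1 EBE is fully determined by its five reported off-target sites:
at every position left unmarked (non-mismatched) in at least one site,
the reported sites agree, and together they cover all 19 positions
exactly once over — the intersection is unique and internally consistent
(checked by :func:`reconstruct_ebe_from_sites` in the test suite).  The
dTALE2 EBE is reconstructible the same way except at positions 6 and 8,
where both reported sites carry a mismatch; those positions are left as
``N`` in the template and excluded from checks.
"""

from __future__ import annotations

from taledesign.tale_code import EBESequence, validate_ebe

__all__ = [
    "DTALE1_EBE",
    "DTALE1_OFFTARGET_SITES",
    "DTALE2_EBE_TEMPLATE",
    "DTALE2_OFFTARGET_SITES",
    "DTALE2_UNDETERMINED_POSITIONS",
    "RICE_CENSUS_DTALE1",
    "RICE_CENSUS_DTALE2",
    "reconstruct_ebe_from_sites",
]

#: dTALE1 binding element, reconstructed from its five published
#: off-target sites (unique intersection of non-mismatched positions).
DTALE1_EBE: EBESequence = validate_ebe("TCCCCGCATAGCTGAACAT")

#: Published dTALE1 off-target sites in the rice KitaakeX genome:
#: (associated gene, site sequence, 1-based mismatch positions vs the EBE).
DTALE1_OFFTARGET_SITES: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("OsKitaake03g369100", "ACCCCGCATAGCTGGACAA", (1, 15, 19)),
    ("OsKitaake02g392000", "TCCCCACATATTTGATCAT", (6, 11, 12, 16)),
    ("OsKitaake07g118833", "TCCCAGAATAGATGAACAT", (5, 7, 12)),
    ("OsKitaake06g213800", "TCCCAGCATGGCTGTCCAT", (5, 10, 15, 16)),
    ("OsKitaake04g082200", "TGCCCGCGTTGCTGGACAT", (2, 8, 10, 15)),
)

#: Positions of the dTALE2 EBE that its two published sites both mismatch,
#: leaving the designed base unrecoverable from the site sequences alone.
DTALE2_UNDETERMINED_POSITIONS: tuple[int, ...] = (6, 8)

#: dTALE2 binding element template; 'N' marks the undetermined positions.
DTALE2_EBE_TEMPLATE: str = "TGACGNGNGATAGTTTCCA"

#: Published dTALE2 off-target sites with their full reported mismatch
#: position sets; both sites mismatch at positions 6 and 8, which is why
#: those EBE positions are undetermined.
DTALE2_OFFTARGET_SITES: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("OsKitaake11g227500", "TGACGAGAGATAGCTTTCA", (6, 8, 14, 17)),
    ("OsKitaake08g030300", "AGACGTGACATAGTTTCCA", (1, 6, 8, 9)),
)

#: Published mismatch census of each design against the rice KitaakeX
#: genome (distinct sites per mismatch count; >=5 mismatches, i.e. <75%
#: identity, were not considered).  Reproducing these requires the rice
#: genome itself; in-package tests use them only for arithmetic checks
#: (e.g. total scorable sites) and treat them as printed inputs.
RICE_CENSUS_DTALE1: dict[int, int] = {0: 0, 1: 0, 2: 2, 3: 36, 4: 475}
RICE_CENSUS_DTALE2: dict[int, int] = {0: 0, 1: 0, 2: 0, 3: 23, 4: 1361}


def reconstruct_ebe_from_sites(
    sites: tuple[tuple[str, str, tuple[int, ...]], ...],
) -> str:
    """Rebuild an EBE from sites annotated with their mismatch positions.

    Every non-mismatched position of every site must agree on the base;
    positions mismatched in all sites come out as 'N'.  Raises
    ``ValueError`` on an internal inconsistency.
    """
    length = len(sites[0][1])
    bases: list[str | None] = [None] * length
    for _, seq, mismatches in sites:
        if len(seq) != length:
            raise ValueError("site lengths differ")
        for pos, base in enumerate(seq, start=1):
            if pos in mismatches:
                continue
            if bases[pos - 1] is None:
                bases[pos - 1] = base
            elif bases[pos - 1] != base:
                raise ValueError(
                    f"sites disagree at position {pos}: {bases[pos - 1]} vs {base}"
                )
    return "".join(b or "N" for b in bases)
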