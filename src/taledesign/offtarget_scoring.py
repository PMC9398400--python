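"""Per-site off-target scores, per-candidate neverword scores, and ranking.

The off-target score of one near-match genomic site is

    S_OFF = sum over mismatch positions p of  F_P(p) * S_M(rvd_p, base_p)

with the RVD taken from the candidate's designed repeat array at p and the
base from the genomic site.  Over a candidate's 200 closest off-targets,
the mean S_OFF is its "neverword" score S_N (higher = mismatches more
disruptive everywhere = more orthogonal), and the ratio between the mean
of the 100 lowest and the mean of the remaining 100 scores flags uneven
distributions: a ratio near 1 means no dangerous low-score tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from taledesign.preference import (
    PreferenceMatrix,
    T0_MISMATCH_PREFERENCE,
    mismatch_score,
    position_factor,
)
from taledesign.tale_code import EBESequence, RVDArray, ebe_to_rvds, mismatch_profile

__all__ = [
    "OffTargetScore",
    "CandidateReport",
    "NeverwordResult",
    "score_offtarget",
    "neverword_score",
    "rank_candidates",
    "write_reports_tsv",
    "write_reports_json",
]


@dataclass(frozen=True)
class OffTargetScore:
    """S_OFF of one site, with its per-mismatch (position, F_P, S_M) terms."""

    site_id: str
    s_off: float
    contributions: tuple[tuple[int, float, float], ...]


@dataclass
class CandidateReport:
    """Scoring summary for one candidate EBE.

    ``ratio`` is None when undefined (fewer than two scored sites, or an
    all-zero upper half).  ``short_set`` flags candidates scored on fewer
    than the requested number of off-targets.
    """

    ebe: EBESequence
    s_n: float
    ratio: float | None
    n_offtargets_by_mismatch: dict[int, int] = field(default_factory=dict)
    n_scored: int = 0
    short_set: bool = False
    rank: int | None = None


@dataclass(frozen=True)
class NeverwordResult:
    s_n: float
    ratio: float | None
    n: int


def score_offtarget(
    ebe: EBESequence,
    rvds: RVDArray | None,
    site: str,
    matrix: PreferenceMatrix,
    t0_mismatch_preference: float = T0_MISMATCH_PREFERENCE,
) -> OffTargetScore:
    """Score one genomic site against a candidate EBE.

    Matched positions contribute nothing; a perfect match scores 0.  A
    mismatch at T0 (position 1), where no repeat exists, uses the fixed
    ``t0_mismatch_preference`` instead of a matrix row.
    """
    if rvds is None:
        rvds = ebe_to_rvds(ebe)
    if len(site) != len(ebe):
        raise ValueError(f"site length {len(site)} != EBE length {len(ebe)}")
    profile = mismatch_profile(ebe, site)
    contributions = []
    total = 0.0
    for pos in profile.positions:
        fp = position_factor(pos)
        if pos == 1:
            sm = (t0_mismatch_preference - 0.5) * -2.0
        else:
            sm = mismatch_score(matrix, rvds.rvds[pos - 2], site[pos - 1])
        contributions.append((pos, fp, sm))
        total += fp * sm
    return OffTargetScore(site_id=site, s_off=total, contributions=tuple(contributions))


def neverword_score(scores: list[OffTargetScore | float]) -> NeverwordResult:
    """Mean S_OFF (S_N) and low-half/high-half distribution ratio.

    With n scores the lowest floor(n/2) form the numerator's half and the
    remaining ceil(n/2) the denominator's (100/100 at the standard n=200).
    The ratio is None when undefined — lower half empty (n < 2) or
    upper-half mean zero; S_N is always defined for non-empty input.
    """
    if not scores:
        raise ValueError("cannot compute a neverword score from no off-targets")
    values = sorted(s.s_off if isinstance(s, OffTargetScore) else float(s) for s in scores)
    n = len(values)
    s_n = sum(values) / n
    half = n // 2
    ratio: float | None
    if half == 0:
        ratio = None
    else:
        low = sum(values[:half]) / half
        up = sum(values[half:]) / (n - half)
        ratio = None if up == 0.0 else low / up
    return NeverwordResult(s_n=s_n, ratio=ratio, n=n)


def rank_candidates(
    reports: list[CandidateReport],
    s_n_tolerance: float = 1e-9,
    top_k: int | None = None,
) -> list[CandidateReport]:
    """Order candidates: highest S_N first, near-ties broken by |ratio - 1|.

    Two S_N values within ``s_n_tolerance`` (absolute) are treated as tied
    and ordered by closeness of the distribution ratio to 1 (an undefined
    ratio sorts last among ties); remaining ties break lexicographically on
    the sequence.  Rank 1 is the selected design.

    With ``top_k`` set, an alternative selection rule is applied: the
    ``top_k`` candidates by S_N are reordered by |ratio - 1| alone.
    """
    def ratio_distance(r: CandidateReport) -> float:
        return float("inf") if r.ratio is None else abs(r.ratio - 1.0)

    ordered = sorted(reports, key=lambda r: (-r.s_n, str(r.ebe)))
    # group near-ties on s_n and reorder each group by ratio distance
    result: list[CandidateReport] = []
    i = 0
    while i < len(ordered):
        j = i
        while j + 1 < len(ordered) and abs(ordered[j + 1].s_n - ordered[i].s_n) <= s_n_tolerance:
            j += 1
        group = sorted(ordered[i : j + 1], key=lambda r: (ratio_distance(r), str(r.ebe)))
        result.extend(group)
        i = j + 1

    if top_k is not None:
        head = sorted(result[:top_k], key=lambda r: (ratio_distance(r), -r.s_n, str(r.ebe)))
        result = head + result[top_k:]

    for rank, report in enumerate(result, start=1):
        report.rank = rank
    return result


def write_reports_tsv(reports: list[CandidateReport], path: str | Path) -> None:
    """Flat TSV: one row per candidate with rank, scores and census counts."""
    mm_classes = sorted({k for r in reports for k in r.n_offtargets_by_mismatch})
    header = ["# rank", "sequence", "s_n", "ratio", "n_scored", "short_set"]
    header += [f"n_{k}mm" for k in mm_classes]
    lines = ["\t".join(header)]
    for r in reports:
        row = [
            str(r.rank),
            str(r.ebe),
            repr(r.s_n),
            "NA" if r.ratio is None else repr(r.ratio),
            str(r.n_scored),
            str(int(r.short_set)),
        ]
        row += [str(r.n_offtargets_by_mismatch.get(k, 0)) for k in mm_classes]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports_json(reports: list[CandidateReport], path: str | Path) -> None:
    payload = [
        {
            "rank": r.rank,
            "sequence": str(r.ebe),
            "s_n": r.s_n,
            "ratio": r.ratio,
            "n_scored": r.n_scored,
            "short_set": r.short_set,
            "n_offtargets_by_mismatch": {str(k): v for k, v in sorted(r.n_offtargets_by_mismatch.items())},
        }
        for r in reports
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
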