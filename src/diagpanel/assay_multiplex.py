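"""Tail-length design for single-base-extension (SNaPshot) multiplexes.

SNaPshot genotyping reads one fluorescent base extended from an internal
primer that ends immediately next to the SNP. When several SNPs are typed
in one reaction, the extension products are separated electrophoretically
by length, so each internal primer receives a 5' tail built from a
repeated 4-nt unit ("gact" by convention, possibly truncated) chosen so
that all total primer lengths are pairwise separated by a minimum spacing.

``assign_tails`` implements the deterministic greedy scheme: sort primers
by core length, give the shortest no tail, then give each subsequent
primer the smallest tail that keeps it ``min_spacing`` nt longer than the
previous one. ``validate_set`` checks an existing (possibly hand-designed)
set for spacing and tail-pattern violations; thermodynamic cross-dimer
screening is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

__all__ = ["TailedPrimer", "TailedPrimerSet", "assign_tails", "validate_set"]

_IUPAC = frozenset("ACGTRYSWKMBDHVN")


def _repeat_tail(unit: str, length: int) -> str:
    """Prefix of the infinitely repeated unit, of exactly ``length`` nt."""
    if length <= 0:
        return ""
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


@dataclass(frozen=True)
class TailedPrimer:
    marker_id: str
    core: str  # the hybridising primer sequence, uppercase
    sense: str = "F"  # F or R relative to the tag consensus
    tail: str = ""  # 5' tail, lowercase by convention

    def __post_init__(self) -> None:
        if not self.core:
            raise ValueError(f"primer {self.marker_id}: empty core sequence")
        bad = set(self.core.upper()) - _IUPAC
        if bad:
            raise ValueError(
                f"primer {self.marker_id}: invalid nucleotides {sorted(bad)}"
            )
        if self.sense not in ("F", "R"):
            raise ValueError(f"primer {self.marker_id}: sense must be F or R")

    @property
    def total_length(self) -> int:
        return len(self.tail) + len(self.core)

    @property
    def sequence(self) -> str:
        """Full tailed primer, tail lowercase + core uppercase."""
        return self.tail.lower() + self.core.upper()


@dataclass
class TailedPrimerSet:
    entries: list[TailedPrimer] = field(default_factory=list)
    tail_unit: str = "gact"
    min_spacing: int = 4


def assign_tails(
    core_primers: Sequence[tuple[str, str] | tuple[str, str, str]],
    min_spacing: int = 4,
    tail_unit: str = "gact",
) -> TailedPrimerSet:
    """Assign 5' tails so all total lengths are pairwise >= min_spacing apart.

    ``core_primers`` holds (marker_id, sequence) or (marker_id, sequence,
    sense) tuples. Primers are processed shortest core first (ties broken
    by marker id, so the result is independent of input order); the
    shortest gets a zero tail and each subsequent primer the smallest tail
    reaching the previous total plus ``min_spacing``.
    """
    if min_spacing < 1:
        raise ValueError("min_spacing must be >= 1")
    if not tail_unit:
        raise ValueError("tail_unit must be non-empty")
    seen: set[str] = set()
    primers = []
    for entry in core_primers:
        marker_id, seq = entry[0], entry[1]
        sense = entry[2] if len(entry) > 2 else "F"
        if marker_id in seen:
            raise ValueError(f"duplicate marker id {marker_id!r}")
        seen.add(marker_id)
        primers.append(TailedPrimer(marker_id, seq.upper(), sense))

    primers.sort(key=lambda p: (len(p.core), p.marker_id))
    out: list[TailedPrimer] = []
    prev_total: int | None = None
    for p in primers:
        if prev_total is None:
            tail_len = 0
        else:
            tail_len = max(0, prev_total + min_spacing - len(p.core))
        out.append(
            TailedPrimer(p.marker_id, p.core, p.sense, _repeat_tail(tail_unit, tail_len))
        )
        prev_total = out[-1].total_length
    return TailedPrimerSet(entries=out, tail_unit=tail_unit, min_spacing=min_spacing)


def validate_set(primer_set: TailedPrimerSet) -> list[str]:
    """Return human-readable violations; an empty list means the set is
    electrophoretically separable and its tails follow the repeat unit."""
    violations: list[str] = []
    for a, b in combinations(primer_set.entries, 2):
        gap = abs(a.total_length - b.total_length)
        if gap < primer_set.min_spacing:
            violations.append(
                f"spacing: {a.marker_id} ({a.total_length} nt) and "
                f"{b.marker_id} ({b.total_length} nt) differ by {gap} "
                f"< {primer_set.min_spacing} nt"
            )
    unit = primer_set.tail_unit.lower()
    for p in primer_set.entries:
        if p.tail and p.tail.lower() != _repeat_tail(unit, len(p.tail)):
            violations.append(
                f"tail pattern: {p.marker_id} tail {p.tail!r} is not a prefix "
                f"of repeated {unit!r}"
            )
    return violations
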