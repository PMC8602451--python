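"""SUMO-interacting motif (SIM) detection and SIM-density statistics.

A SIM is a short hydrophobic stretch that docks into the SIM-binding
groove of SUMO.  Three core patterns are scanned::

    psi-psi-x-psi   (length 4)
    psi-x-psi-psi   (length 4)
    psi-psi-psi     (length 3)

where ``psi`` is exactly one of L, I or V and ``x`` is any residue
(nonstandard residues such as U or X satisfy ``x`` but never ``psi``).

Per-protein SIM content is length-normalized to **STAA** — SIMs per
thousand amino acids, ``1000 * sim_count / length`` — so that long
proteins do not dominate list-level comparisons.  List-level summaries
(:class:`ListStatistics`) report the median member STAA and the
percentage of members with at least one (``pct_single``) and at least
two (``pct_multiple``) SIMs.

Two counting modes are exposed:

``all_matches``
    every (position, pattern) window that satisfies a pattern.
``collapsed`` (pipeline default)
    a greedy left-to-right non-overlapping subset, so one hydrophobic
    run counts as one SIM instance.  At equal start, the longer / more
    specific pattern wins (psi-psi-x-psi > psi-x-psi-psi > psi-psi-psi).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .io import ProteinRecord

__all__ = [
    "PatternClass",
    "SimMatch",
    "ProteinSimProfile",
    "ListStatistics",
    "scan_sequence",
    "annotate_flanks",
    "profile_protein",
    "list_statistics",
]

PSI_RESIDUES = frozenset("LIV")
FLANK_RESIDUES = frozenset("DES")


class PatternClass(str, Enum):
    """The three SIM core patterns, in collapse-priority order."""

    PSI_PSI_X_PSI = "psi-psi-x-psi"
    PSI_X_PSI_PSI = "psi-x-psi-psi"
    PSI_PSI_PSI = "psi-psi-psi"

    @property
    def length(self) -> int:
        return 3 if self is PatternClass.PSI_PSI_PSI else 4

    @property
    def psi_offsets(self) -> tuple[int, ...]:
        return _PSI_OFFSETS[self]


_PSI_OFFSETS = {
    PatternClass.PSI_PSI_X_PSI: (0, 1, 3),
    PatternClass.PSI_X_PSI_PSI: (0, 2, 3),
    PatternClass.PSI_PSI_PSI: (0, 1, 2),
}
# collapse priority: 4-residue patterns before the bare psi-psi-psi core
_PRIORITY = {
    PatternClass.PSI_PSI_X_PSI: 0,
    PatternClass.PSI_X_PSI_PSI: 1,
    PatternClass.PSI_PSI_PSI: 2,
}


@dataclass(frozen=True)
class SimMatch:
    """One SIM occurrence; coordinates are 0-based half-open."""

    start: int
    end: int
    pattern_class: PatternClass
    subsequence: str
    accession: str = ""
    acidic_or_ser_flank: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.pattern_class.length:
            raise ValueError("match span does not equal pattern length")


@dataclass(frozen=True)
class ProteinSimProfile:
    """Per-protein SIM count and length-normalized density (STAA)."""

    accession: str
    length: int
    sim_count: int
    staa: float

    @property
    def has_single(self) -> bool:
        """True if the protein carries at least one SIM."""
        return self.sim_count >= 1

    @property
    def has_multiple(self) -> bool:
        """True if the protein carries at least two SIMs."""
        return self.sim_count >= 2


@dataclass(frozen=True)
class ListStatistics:
    """List-level SIM summary: presence percentages and the STAA median."""

    label: str
    n_proteins: int
    pct_single: float
    pct_multiple: float
    staa_value: float
    total_sims: int
    total_length: int


def _validate_mode(mode: str) -> str:
    if mode in ("all", "all_matches"):
        return "all_matches"
    if mode == "collapsed":
        return "collapsed"
    raise ValueError(f"unknown scan mode {mode!r}")


def scan_sequence(sequence: str, mode: str = "collapsed",
                  accession: str = "") -> list[SimMatch]:
    """Scan an amino-acid sequence for SIM core motifs.

    Parameters
    ----------
    sequence
        Uppercase amino-acid string, length >= 1.
    mode
        ``"all_matches"`` — every satisfying (position, pattern) window,
        sorted by start then pattern priority; ``"collapsed"`` — greedy
        left-to-right non-overlapping subset (default).

    Returns
    -------
    list of :class:`SimMatch`, flank flag unset (see
    :func:`annotate_flanks`).
    """
    mode = _validate_mode(mode)
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    n = len(sequence)
    is_psi = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    psi_mask = (is_psi == ord("L")) | (is_psi == ord("I")) | (is_psi == ord("V"))

    matches: list[SimMatch] = []
    for pattern in PatternClass:
        plen = pattern.length
        if n < plen:
            continue
        ok = np.ones(n - plen + 1, dtype=bool)
        for off in pattern.psi_offsets:
            ok &= psi_mask[off: off + n - plen + 1]
        for start in np.flatnonzero(ok):
            s = int(start)
            matches.append(
                SimMatch(start=s, end=s + plen, pattern_class=pattern,
                         subsequence=sequence[s: s + plen], accession=accession)
            )
    matches.sort(key=lambda m: (m.start, _PRIORITY[m.pattern_class]))
    if mode == "all_matches":
        return matches
    collapsed: list[SimMatch] = []
    cursor = 0  # first position not yet consumed
    for m in matches:
        if m.start >= cursor:
            collapsed.append(m)
            cursor = m.end
    return collapsed


def annotate_flanks(sequence: str, matches: Iterable[SimMatch],
                    window: int = 4) -> list[SimMatch]:
    """Set the acidic/serine flank flag on each match.

    The flag is true iff any residue within ``window`` positions
    immediately before the match start or after its end (truncated at
    the sequence boundaries) is D, E or S.  Acidic or phosphorylatable
    flanks strengthen SUMO–SIM binding, which is why the flag is
    reported.
    """
    if window < 1:
        raise ValueError("flank window must be >= 1")
    out = []
    for m in matches:
        if m.subsequence != sequence[m.start:m.end]:
            raise ValueError("match does not belong to this sequence")
        before = sequence[max(0, m.start - window): m.start]
        after = sequence[m.end: m.end + window]
        flag = any(c in FLANK_RESIDUES for c in before + after)
        out.append(replace(m, acidic_or_ser_flank=flag))
    return out


def profile_protein(record: ProteinRecord, mode: str = "collapsed") -> ProteinSimProfile:
    """Compute the SIM profile of one protein.

    STAA is evaluated as the exact rational ``1000 * count / length``
    before conversion to float.
    """
    matches = scan_sequence(record.sequence, mode=mode, accession=record.accession)
    count = len(matches)
    staa = float(Fraction(1000 * count, len(record.sequence)))
    return ProteinSimProfile(accession=record.accession, length=len(record.sequence),
                             sim_count=count, staa=staa)


def list_statistics(profiles: Sequence[ProteinSimProfile],
                    label: str = "") -> ListStatistics:
    """Summarize a collection of per-protein profiles.

    ``staa_value`` is the median of the member STAA values (mean of the
    two central order statistics for even n).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile collection")
    n = len(profiles)
    n_single = sum(p.has_single for p in profiles)
    n_multiple = sum(p.has_multiple for p in profiles)
    staas = np.array([p.staa for p in profiles], dtype=float)
    return ListStatistics(
        label=label,
        n_proteins=n,
        pct_single=100.0 * n_single / n,
        pct_multiple=100.0 * n_multiple / n,
        staa_value=float(np.median(staas)),
        total_sims=int(sum(p.sim_count for p in profiles)),
        total_length=int(sum(p.length for p in profiles)),
    )
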