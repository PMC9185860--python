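"""Brute-force reference scanner for circular ORFs.

This module is the independent ground-truth route for the ORF engine: it
unrolls four copies of the circle, walks every reading frame codon by
codon, and counts backsplice-junction passages explicitly base by base
instead of using the engine's closed form.  Fixture ground truth is
computed here, never by the engine under test, and the test suite demands
exact agreement between the two routes.

It shares no code with :mod:`circkit.orfs` beyond the genetic code being
the genetic code (a local codon table is used on purpose).
"""

from __future__ import annotations

from dataclasses import dataclass

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


@dataclass(frozen=True)
class OracleOrf:
    start: int  # circle position of the A of ATG
    length_nt: int  # stop included; 0 for endless
    crossings: int | None  # None = infinite
    endless: bool
    peptide: str


def _count_passages(start: int, length: int, L: int) -> int:
    """Count junction passages by stepping base to base.

    The junction sits between circle positions L-1 and 0; in unrolled
    coordinates a passage happens whenever the reading moves onto a
    position that is a multiple of L.
    """
    passages = 0
    for pos in range(start + 1, start + length):
        if pos % L == 0:
            passages += 1
    return passages


def scan_circle(seq: str, min_peptide: int = 1) -> list[OracleOrf]:
    """Enumerate maximal ORFs of a circular sequence by brute force."""
    L = len(seq)
    if L < 3:
        raise ValueError("circle shorter than one codon")
    unrolled = seq * 4 + seq[:2]
    results: dict[tuple[int, int], OracleOrf] = {}

    for frame in range(3):
        open_at = None
        p = frame
        while p + 3 <= len(unrolled):
            codon = unrolled[p : p + 3]
            aa = CODON_TABLE.get(codon, "X")
            if open_at is None:
                if codon == "ATG":
                    open_at = p
            elif aa == "*":
                if open_at < L:
                    length = p + 3 - open_at
                    pep = "".join(
                        CODON_TABLE.get(unrolled[q : q + 3], "X")
                        for q in range(open_at, p, 3)
                    )
                    key = (open_at % L, length)
                    if key not in results:
                        results[key] = OracleOrf(
                            open_at % L,
                            length,
                            _count_passages(open_at, length, L),
                            False,
                            pep,
                        )
                open_at = None
            p += 3
        if open_at is not None and open_at < L:
            period = L // 3 if L % 3 == 0 else L
            pep = "".join(
                CODON_TABLE.get(unrolled[q : q + 3], "X")
                for q in range(open_at, open_at + 3 * period, 3)
            )
            key = (open_at % L, 0)
            if key not in results:
                results[key] = OracleOrf(open_at % L, 0, None, True, pep)

    out = [
        o for o in results.values()
        if o.endless or len(o.peptide) >= min_peptide
    ]
    out.sort(key=lambda o: (o.start, o.length_nt))
    return out


def frame_is_stop_free(seq: str, frame: int) -> bool:
    """For L % 3 == 0: does the frame's codon cycle avoid every stop?"""
    L = len(seq)
    if L % 3 != 0:
        raise ValueError("frame cycles only exist when L % 3 == 0")
    doubled = seq * 2
    return all(
        CODON_TABLE[doubled[p : p + 3]] != "*"
        for p in range(frame, frame + L, 3)
    )


def frame_has_start(seq: str, frame: int) -> bool:
    """For L % 3 == 0: does the frame's codon cycle contain an ATG?"""
    L = len(seq)
    doubled = seq * 2
    return any(
        doubled[p : p + 3] == "ATG" for p in range(frame, frame + L, 3)
    )
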