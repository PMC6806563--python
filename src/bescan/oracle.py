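"""Naive brute-force guide enumerator used as ground truth.

This module intentionally shares no code with :mod:`bescan.targeting`: it has
its own complement table and IUPAC sets, and instead of jumping straight to
the placements implied by each window position it slides a window over every
possible protospacer start on both representations of the sequence and tests
window membership and PAM match from first principles. Synthetic fixtures use
it to record ground-truth targetability, and the test suite compares the fast
implementation against it placement-for-placement.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _rc(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def _pam_ok(pattern: str, observed: str) -> bool:
    if len(pattern) != len(observed):
        return False
    return all(o in _CODES[p] for p, o in zip(pattern.upper(), observed.upper()))


def oracle_enumerate(sequence: str, target_offset: int, target_strand: str,
                     pam_pattern: str, pam_side: str, spacer_length: int,
                     window_start: int, window_end: int):
    """All valid placements for one target C, by exhaustive sliding.

    ``target_strand`` is "+" or "-"; ``pam_side`` is "three_prime" or
    "five_prime". Returns tuples
    ``(plus_start, plus_end, spacer, pam, window_pos, bystanders)`` with the
    protospacer interval 0-based half-open in plus-strand coordinates,
    ordered by window position. Placements containing any non-ACGT base are
    rejected.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if target_strand == "+":
        view, t = sequence, target_offset
    else:
        view, t = _rc(sequence), n - 1 - target_offset
    if view[t] != "C":
        raise ValueError("target base does not read C on the stated strand")

    plen = len(pam_pattern)
    hits = []
    for start in range(0, n - spacer_length + 1):
        end = start + spacer_length
        # window position of the target under this placement, if any
        if not (start <= t < end):
            continue
        pos = t - start + 1
        if not (window_start <= pos <= window_end):
            continue
        if pam_side == "three_prime":
            pam_lo, pam_hi = end, end + plen
        else:
            pam_lo, pam_hi = start - plen, start
        if pam_lo < 0 or pam_hi > n:
            continue
        proto = view[start:end]
        pam = view[pam_lo:pam_hi]
        if any(b not in "ACGT" for b in proto + pam):
            continue
        if not _pam_ok(pam_pattern, pam):
            continue
        bystanders = tuple(
            q for q in range(window_start, window_end + 1)
            if q != pos and proto[q - 1] == "C"
        )
        if target_strand == "+":
            interval = (start, end)
        else:
            interval = (n - end, n - start)
        hits.append((interval[0], interval[1], proto, pam, pos, bystanders))
    hits.sort(key=lambda h: h[4])
    return hits


def oracle_scan(sequence: str, pam_pattern: str, pam_side: str,
                spacer_length: int, window_start: int, window_end: int):
    """Scan every C/G in a sequence; returns (position, strand, placement)."""
    sequence = sequence.upper()
    out = []
    for i, base in enumerate(sequence):
        if base == "C":
            strand = "+"
        elif base == "G":
            strand = "-"
        else:
            continue
        for hit in oracle_enumerate(sequence, i, strand, pam_pattern,
                                    pam_side, spacer_length,
                                    window_start, window_end):
            out.append((i, strand, hit))
    return out


def oracle_verdict(sequence: str, target_offset: int, target_strand: str,
                   pam_pattern: str, pam_side: str, spacer_length: int,
                   window_start: int, window_end: int) -> tuple[bool, bool]:
    """(targetable, preferential) flags for one target under one editor."""
    hits = oracle_enumerate(sequence, target_offset, target_strand,
                            pam_pattern, pam_side, spacer_length,
                            window_start, window_end)
    return bool(hits), any(not h[5] for h in hits)
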