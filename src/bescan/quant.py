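"""Editing-outcome metrics from targeted amplicon deep sequencing.

Given reads aligned over an amplicon, the module tallies per-position base
counts and derives the standard base-editing readouts:

* substitution frequency — reads carrying a given substitution divided by
  *total* reads at the amplicon;
* indel frequency — reads whose alignment contains at least one inserted or
  deleted nucleotide overlapping the region, divided by *mapped* reads;
* product purity — among edited reads at a target C, the fraction carrying
  the intended C-to-T outcome rather than C-to-A/C-to-G;
* normalisation of per-editor frequencies to a reference editor (= 100%).

The denominators differ deliberately: substitutions are divided by total
reads and indels by mapped reads. ``denominator="mapped"`` switches the
substitution denominator for pipelines that prefer symmetry.

Input is either a SAM alignment (counted via pysam) or a simplified pileup
TSV (see :func:`read_pileup`) that is convenient for tests and small
fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats as _st

__all__ = [
    "AmpliconQuant",
    "quantify_sam",
    "read_pileup",
    "write_pileup",
    "indel_frequency",
    "substitution_frequency",
    "product_purity",
    "normalize_to_reference",
    "rank_sum_one_tailed",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class AmpliconQuant:
    """Read-count tallies over one amplicon region.

    ``base_counts[pos]`` maps a 1-based reference position inside the region
    to A/C/G/T counts among mapped reads. ``reference_sequence`` covers the
    region (index 0 = position ``region_start``).
    """

    chrom: str
    region_start: int  # 1-based inclusive
    region_end: int    # 1-based inclusive
    total_reads: int
    mapped_reads: int
    indel_reads: int
    base_counts: dict[int, dict[str, int]]
    reference_sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.indel_reads <= self.mapped_reads <= self.total_reads):
            raise ValueError(
                "require indel_reads <= mapped_reads <= total_reads, got "
                f"{self.indel_reads}/{self.mapped_reads}/{self.total_reads}"
            )
        if len(self.reference_sequence) != self.region_end - self.region_start + 1:
            raise ValueError("reference_sequence length != region width")
        for pos, counts in self.base_counts.items():
            if sum(counts.values()) > self.mapped_reads:
                raise ValueError(f"position {pos}: counts exceed mapped reads")

    def reference_base(self, pos: int) -> str:
        if not (self.region_start <= pos <= self.region_end):
            raise ValueError(f"position {pos} outside region")
        return self.reference_sequence[pos - self.region_start].upper()


def quantify_sam(path: Union[str, Path],
                 chrom: str,
                 region_start: int,
                 region_end: int,
                 reference_sequence: str,
                 min_mapq: int = 0) -> AmpliconQuant:
    """Tally an AmpliconQuant from a SAM/BAM alignment.

    A read is *mapped* if it is a mapped primary alignment overlapping the
    region with MAPQ >= ``min_mapq``; it *contains an indel* iff its CIGAR has
    an insertion or deletion operation overlapping the region. Unmapped and
    sub-threshold reads still count toward ``total_reads``.
    """
    import pysam

    lo, hi = region_start - 1, region_end  # 0-based half-open
    total = mapped = indels = 0
    counts: dict[int, dict[str, int]] = {
        p: {b: 0 for b in _BASES} for p in range(region_start, region_end + 1)
    }
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam:
            if read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if read.reference_name != chrom or \
                    read.reference_end <= lo or read.reference_start >= hi:
                continue
            mapped += 1
            if _has_indel_in(read, lo, hi):
                indels += 1
            seq = read.query_sequence or ""
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if lo <= rpos < hi:
                    base = seq[qpos].upper()
                    if base in counts[rpos + 1]:
                        counts[rpos + 1][base] += 1
    return AmpliconQuant(chrom=chrom, region_start=region_start,
                         region_end=region_end, total_reads=total,
                         mapped_reads=mapped, indel_reads=indels,
                         base_counts=counts,
                         reference_sequence=reference_sequence)


def _has_indel_in(read, lo: int, hi: int) -> bool:
    """CIGAR insertion/deletion overlapping [lo, hi) in reference coords."""
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op == 1:  # insertion: anchored between rpos-1 and rpos
            if lo < rpos < hi or lo == rpos:
                return True
        elif op in (2, 3):  # deletion / skip consume reference
            if rpos < hi and rpos + length > lo and op == 2:
                return True
            rpos += length
        elif op in (0, 7, 8):
            rpos += length
    return False


_PILEUP_META = ("chrom", "region_start", "region_end",
                "total_reads", "mapped_reads", "indel_reads")


def read_pileup(path: Union[str, Path]) -> AmpliconQuant:
    """Read the simplified pileup TSV.

    Format: ``#key=value`` metadata lines for chrom, region bounds and the
    three read totals, then a header ``pos ref A C G T`` and one row per
    position (1-based).
    """
    meta: dict[str, str] = {}
    rows: list[tuple[int, str, dict[str, int]]] = []
    header_seen = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if not header_seen:
            if parts[:2] != ["pos", "ref"]:
                raise ValueError(f"{path}: bad pileup header {parts!r}")
            header_seen = True
            continue
        pos = int(parts[0])
        rows.append((pos, parts[1].upper(),
                     dict(zip(_BASES, map(int, parts[2:6])))))
    missing = [k for k in _PILEUP_META if k not in meta]
    if missing:
        raise ValueError(f"{path}: pileup missing metadata {missing}")
    rows.sort(key=lambda r: r[0])
    return AmpliconQuant(
        chrom=meta["chrom"],
        region_start=int(meta["region_start"]),
        region_end=int(meta["region_end"]),
        total_reads=int(meta["total_reads"]),
        mapped_reads=int(meta["mapped_reads"]),
        indel_reads=int(meta["indel_reads"]),
        base_counts={pos: counts for pos, _, counts in rows},
        reference_sequence="".join(ref for _, ref, _ in rows),
    )


def write_pileup(q: AmpliconQuant, path: Union[str, Path]) -> None:
    """Write the simplified pileup TSV read back by :func:`read_pileup`."""
    lines = [f"#{k}={getattr(q, k)}" for k in _PILEUP_META]
    lines.append("pos\tref\t" + "\t".join(_BASES))
    for pos in range(q.region_start, q.region_end + 1):
        counts = q.base_counts.get(pos, {b: 0 for b in _BASES})
        lines.append("\t".join(
            [str(pos), q.reference_base(pos)] +
            [str(counts.get(b, 0)) for b in _BASES]
        ))
    Path(path).write_text("\n".join(lines) + "\n")


def indel_frequency(q: AmpliconQuant) -> float:
    """Reads with >= 1 inserted/deleted nucleotide over mapped reads."""
    if q.mapped_reads == 0:
        raise ZeroDivisionError("indel frequency undefined with 0 mapped reads")
    return q.indel_reads / q.mapped_reads


def substitution_frequency(q: AmpliconQuant, position: int,
                           from_base: str, to_base: str,
                           denominator: str = "total") -> float:
    """Frequency of the ``from_base``->``to_base`` substitution at ``position``.

    ``denominator`` is ``"total"`` (default, total reads) or ``"mapped"``.
    """
    from_base, to_base = from_base.upper(), to_base.upper()
    ref = q.reference_base(position)
    if ref != from_base:
        raise ValueError(
            f"position {position}: reference base is {ref!r}, not {from_base!r}"
        )
    denom = q.total_reads if denominator == "total" else q.mapped_reads
    if denom == 0:
        raise ZeroDivisionError("substitution frequency undefined with 0 reads")
    return q.base_counts.get(position, {}).get(to_base, 0) / denom


def product_purity(q: AmpliconQuant, position: int,
                   denominator: str = "edited") -> float:
    """C-to-T fraction among edited reads at a reference-C position.

    With the default ``denominator="edited"`` this is
    ``T / (T + A + G)`` over non-reference base calls at the position;
    ``denominator="total"`` divides by total reads instead. Returns ``nan``
    (the undefined marker, which propagates through arithmetic) when no
    edited read exists — never silently 0.
    """
    if q.reference_base(position) != "C":
        raise ValueError(
            f"position {position}: product purity is defined at reference-C "
            f"positions, found {q.reference_base(position)!r}"
        )
    counts = q.base_counts.get(position, {})
    edited = sum(counts.get(b, 0) for b in ("A", "G", "T"))
    if denominator == "total":
        if q.total_reads == 0:
            raise ZeroDivisionError("0 total reads")
        return counts.get("T", 0) / q.total_reads
    if edited == 0:
        return math.nan
    return counts.get("T", 0) / edited


def normalize_to_reference(freqs: Mapping[str, float],
                           reference_editor: str) -> dict[str, float]:
    """Express per-editor frequencies as percentages of a reference editor."""
    if reference_editor not in freqs:
        raise KeyError(f"reference editor {reference_editor!r} not in input")
    ref = freqs[reference_editor]
    if ref == 0:
        raise ZeroDivisionError(
            f"reference editor {reference_editor!r} has frequency 0"
        )
    return {name: 100.0 * v / ref for name, v in freqs.items()}


def rank_sum_one_tailed(a: Sequence[float], b: Sequence[float],
                        alternative: str = "less") -> float:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``alternative="less"`` tests whether ``a`` is stochastically smaller than
    ``b``; ``"greater"`` the reverse. For combined n <= 20 without ties the
    p-value is exact, by enumeration of all rank assignments; otherwise the
    normal approximation with tie correction and continuity correction is
    used.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    pooled = a + b
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = _st.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    has_ties = len(set(pooled)) < n

    if n <= 20 and not has_ties:
        # exact null distribution of the rank sum of sample a
        obs = round(r1)
        count = 0
        total = 0
        for comb in combinations(range(1, n + 1), n1):
            total += 1
            s = sum(comb)
            if alternative == "less":
                count += s <= obs
            else:
                count += s >= obs
        return count / total

    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = math.sqrt(var)
    if sd == 0:
        return 1.0  # all observations identical: no evidence either way
    if alternative == "greater":
        z = (u1 - mu - 0.5) / sd
        return float(_st.norm.sf(z))
    z = (u1 - mu + 0.5) / sd
    return float(_st.norm.cdf(z))
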