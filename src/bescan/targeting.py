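"""Guide enumeration and targetability assessment.

A cytosine base editor can act on a target C only if a protospacer placement
exists that (a) puts the C inside the editor's editing window and (b) carries
a matching PAM on the correct side. For each window position p the placement
is fully determined: on the target-strand view of the flank (the strand where
the editable base reads C), the protospacer starts ``p - 1`` bases 5' of the
target. This module enumerates every such placement, records the other window
cytosines as bystanders, and flags placements with no bystander as
*preferential* — the target is then the only editable base in the window, so
editing is expected to be clean.

Verdicts are aggregated per variant into a :class:`TargetabilityReport`, and
across a panel by union (targetable by at least one editor) or intersection
(targetable by all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from ._sequence import IUPAC, Strand, revcomp
from .panel import CombineMode, EditorPanel, EditorSpec
from .variants import EditClass, FlankedTarget, VariantRecord, classify_edit, extract_flank

__all__ = [
    "GuideCandidate",
    "TargetabilityReport",
    "ScanHit",
    "match_pam",
    "enumerate_guides",
    "classify_preferential",
    "assess_variant",
    "combine_panel",
    "panel_statistics",
    "scan_sequence",
]

logger = logging.getLogger(__name__)


def match_pam(pattern: str, observed: str) -> bool:
    """True iff ``observed`` matches the IUPAC ``pattern`` base-for-base.

    Conservative on ambiguity: any non-ACGT base in ``observed`` (an N in the
    genome, say) fails the match, whatever the pattern allows.
    """
    if len(pattern) != len(observed):
        raise ValueError(
            f"pattern length {len(pattern)} != observed length {len(observed)}"
        )
    for pc, oc in zip(pattern.upper(), observed.upper()):
        try:
            allowed = IUPAC[pc]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {pc!r} in pattern") from None
        if oc not in "ACGT" or oc not in allowed:
            return False
    return True


@dataclass(frozen=True)
class GuideCandidate:
    """One valid protospacer+PAM placement for a target C.

    ``protospacer_interval`` is 0-based half-open in plus-strand coordinates
    of the flank sequence. ``spacer_sequence`` is the protospacer 5'->3' on
    the protospacer strand — the sequence one orders as the gRNA spacer.
    ``target_window_position`` and ``bystander_positions`` are 1-based
    protospacer positions (5'-most base = 1).
    """

    editor_name: str
    strand: Strand
    protospacer_interval: tuple[int, int]
    spacer_sequence: str
    pam_observed: str
    target_window_position: int
    bystander_positions: tuple[int, ...]

    @property
    def preferential(self) -> bool:
        return not self.bystander_positions


def classify_preferential(candidate: GuideCandidate) -> bool:
    """True iff the target is the only window cytosine (no bystanders)."""
    return candidate.preferential


def enumerate_guides(target: FlankedTarget,
                     editor: EditorSpec,
                     diagnostics: Optional[dict[str, int]] = None,
                     ) -> list[GuideCandidate]:
    """Enumerate every valid placement of ``editor`` on ``target``.

    Works on the target-strand view ``s`` of the flank (reverse complement
    when the C sits on the minus strand). For each window position p the
    protospacer is ``s[t-(p-1) : t-(p-1)+L]`` with the PAM immediately 3'
    (Cas9-family) or 5' (Cpf1-family) of it; out-of-bounds placements are
    skipped, placements whose protospacer or PAM contains a non-ACGT base are
    rejected (tallied in ``diagnostics["ambiguous_rejected"]``), and the PAM
    must match the editor's IUPAC pattern. Candidates are returned ordered by
    window position ascending. An empty list is a valid, non-targetable
    result.
    """
    n = len(target.sequence)
    if target.target_strand is Strand.PLUS:
        s = target.sequence
        t = target.target_offset
    else:
        s = revcomp(target.sequence)
        t = n - 1 - target.target_offset
    L = editor.spacer_length
    plen = editor.pam_length

    out: list[GuideCandidate] = []
    for p in range(editor.window_start, editor.window_end + 1):
        start = t - (p - 1)
        end = start + L
        if editor.pam_side.value == "three_prime":
            pam_lo, pam_hi = end, end + plen
        else:
            pam_lo, pam_hi = start - plen, start
        if start < 0 or end > n or pam_lo < 0 or pam_hi > n:
            continue
        proto = s[start:end]
        pam = s[pam_lo:pam_hi]
        if any(b not in "ACGT" for b in proto + pam):
            if diagnostics is not None:
                diagnostics["ambiguous_rejected"] = \
                    diagnostics.get("ambiguous_rejected", 0) + 1
            continue
        if not match_pam(editor.pam_pattern, pam):
            continue
        bystanders = tuple(
            q for q in range(editor.window_start, editor.window_end + 1)
            if q != p and proto[q - 1] == "C"
        )
        if target.target_strand is Strand.PLUS:
            interval = (start, end)
        else:  # map back to plus-strand coordinates
            interval = (n - end, n - start)
        out.append(GuideCandidate(
            editor_name=editor.name,
            strand=target.target_strand,
            protospacer_interval=interval,
            spacer_sequence=proto,
            pam_observed=pam,
            target_window_position=p,
            bystander_positions=bystanders,
        ))
    return out


@dataclass
class TargetabilityReport:
    """Per-variant targetability across a panel."""

    variant_id: str
    edit_class: EditClass
    candidates: dict[str, list[GuideCandidate]]  # editor name -> placements
    target: Optional[FlankedTarget] = None       # flank the candidates refer to

    @property
    def targetable_editors(self) -> frozenset[str]:
        return frozenset(n for n, c in self.candidates.items() if c)

    @property
    def preferential_editors(self) -> frozenset[str]:
        return frozenset(
            n for n, c in self.candidates.items()
            if any(g.preferential for g in c)
        )

    @property
    def any_targetable(self) -> bool:
        return bool(self.targetable_editors)


def required_flank(panel: Union[EditorPanel, Iterable[EditorSpec]]) -> int:
    """Smallest flank guaranteeing every panel placement fits in bounds."""
    return max(ed.spacer_length + ed.pam_length - 1 for ed in panel)


def assess_variant(record: VariantRecord,
                   genome,
                   panel: EditorPanel,
                   flank: int = 30,
                   edit_class: Optional[EditClass] = None,
                   diagnostics: Optional[dict[str, int]] = None,
                   ) -> TargetabilityReport:
    """Extract the flank for ``record`` and enumerate guides per panel editor.

    The flank is widened automatically (with a log message) when 30 nt cannot
    accommodate the longest spacer+PAM in the panel. An editor is *targetable*
    for the variant iff at least one placement exists, *preferential* iff at
    least one placement has no bystander.
    """
    if edit_class is None:
        edit_class = classify_edit(record)
    if edit_class is EditClass.NOT_APPLICABLE:
        raise ValueError(
            f"{record.variant_id or record.chrom}:{record.pos} is neither a "
            "C-to-T/G-to-A nor a T-to-C/A-to-G SNV"
        )
    need = required_flank(panel)
    if flank < need:
        logger.info("widening flank from %d to %d nt to fit the panel",
                    flank, need)
        flank = need
    target = extract_flank(genome, record, edit_class, flank=flank)
    cands = {ed.name: enumerate_guides(target, ed, diagnostics=diagnostics)
             for ed in panel}
    return TargetabilityReport(
        variant_id=record.variant_id or f"{record.chrom}:{record.pos}",
        edit_class=edit_class,
        candidates=cands,
        target=target,
    )


def combine_panel(reports: Sequence[TargetabilityReport],
                  mode: Union[CombineMode, str] = CombineMode.UNION,
                  editors: Optional[Sequence[str]] = None,
                  ) -> pd.DataFrame:
    """Combine per-editor verdicts into one flag per variant.

    Union: targetable by >= 1 selected editor; intersection: by all of them.
    The same rule applies to the preferential flag.

    Returns a DataFrame indexed by variant_id with boolean columns
    ``targetable`` and ``preferential``.
    """
    if not isinstance(mode, CombineMode):
        mode = CombineMode(mode)
    if editors is None:
        if not reports:
            raise ValueError("no reports to combine")
        editors = sorted(reports[0].candidates)
    editors = list(editors)
    if not editors:
        raise ValueError("empty editor selection")
    for rep in reports:
        missing = set(editors) - set(rep.candidates)
        if missing:
            raise ValueError(
                f"report {rep.variant_id} lacks editors {sorted(missing)}"
            )
    rows = []
    for rep in reports:
        tgt = [e in rep.targetable_editors for e in editors]
        pref = [e in rep.preferential_editors for e in editors]
        if mode is CombineMode.UNION:
            rows.append((rep.variant_id, any(tgt), any(pref)))
        else:
            rows.append((rep.variant_id, all(tgt), all(pref)))
    return pd.DataFrame(rows, columns=["variant_id", "targetable",
                                       "preferential"]).set_index("variant_id")


def panel_statistics(reports: Sequence[TargetabilityReport]) -> pd.DataFrame:
    """Per-editor and any-editor targetable/preferential counts and fractions.

    Returns a DataFrame indexed by editor name (plus a final ``any`` row for
    the at-least-one-editor aggregate) with columns ``n_targetable``,
    ``frac_targetable``, ``n_preferential``, ``frac_preferential``; fractions
    are of the number of reports.
    """
    if not reports:
        raise ValueError("panel_statistics requires at least one report")
    editors = list(reports[0].candidates)
    total = len(reports)
    rows = []
    for ed in editors:
        nt = sum(ed in rep.targetable_editors for rep in reports)
        np_ = sum(ed in rep.preferential_editors for rep in reports)
        rows.append((ed, nt, nt / total, np_, np_ / total))
    nt_any = sum(rep.any_targetable for rep in reports)
    np_any = sum(bool(rep.preferential_editors) for rep in reports)
    rows.append(("any", nt_any, nt_any / total, np_any, np_any / total))
    return pd.DataFrame(
        rows, columns=["editor", "n_targetable", "frac_targetable",
                       "n_preferential", "frac_preferential"],
    ).set_index("editor")


@dataclass(frozen=True)
class ScanHit:
    """One guide candidate found while scanning a free sequence.

    ``position`` is the 0-based plus-strand index of the target base in the
    scanned sequence (a C on the plus strand, or a G — i.e. a minus-strand C).
    The candidate's protospacer interval is in the same coordinates.
    """

    position: int
    strand: Strand
    candidate: GuideCandidate


def scan_sequence(seq: str,
                  editors: Union[EditorPanel, EditorSpec, Iterable[EditorSpec]],
                  diagnostics: Optional[dict[str, int]] = None,
                  ) -> list[ScanHit]:
    """Design guides for every editable C/G in an arbitrary sequence.

    Every plus-strand C and every G (a C on the minus strand) is tried as a
    target with each editor. Hits are ordered by target position, then strand
    (plus first), then editor order, then window position.
    """
    seq = seq.upper()
    bad = [i for i, b in enumerate(seq) if b not in "ACGTN"]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(
            f"non-nucleotide characters at 0-based positions {shown}{more}"
        )
    if isinstance(editors, EditorSpec):
        editors = [editors]
    editors = list(editors)
    min_len = min(ed.spacer_length + ed.pam_length for ed in editors)
    if len(seq) < min_len:
        raise ValueError(
            f"sequence length {len(seq)} is shorter than the smallest "
            f"spacer+PAM footprint ({min_len} nt)"
        )
    hits: list[ScanHit] = []
    for i, base in enumerate(seq):
        if base == "C":
            strand = Strand.PLUS
        elif base == "G":
            strand = Strand.MINUS
        else:
            continue
        target = FlankedTarget(sequence=seq, target_offset=i,
                               target_strand=strand)
        for ed in editors:
            for cand in enumerate_guides(target, ed, diagnostics=diagnostics):
                hits.append(ScanHit(position=i, strand=strand, candidate=cand))
    return hits
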