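"""Variant input, ClinVar-style filtering, edit classification, flank extraction.

The filtering pipeline keeps single-nucleotide variants whose clinical
significance is the exact label "pathogenic" (case-insensitive) on assembly
GRCh38, then deduplicates by (chrom, pos, ref, alt). A variant is classed as

* ``CREATE_C_TO_T`` - its name carries "C>T" or "G>A": a cytosine base editor
  can install the pathogenic allele to model the disease;
* ``CORRECT_T_TO_C`` - its name carries "T>C" or "A>G": the patient allele is
  a C (or a G on the plus strand) that an editor can revert.

For guide design the local sequence around the variant is extracted from the
reference genome (30 nt each side by default). In correction mode the
pathogenic alt allele is substituted into the flank first, because the
sequence to be edited is the patient's, not the reference. The flank is always
stored on the plus strand; ``target_strand`` records the strand on which the
editable base reads C.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pyfaidx

from ._sequence import Strand

__all__ = [
    "EditClass",
    "VariantRecord",
    "FlankedTarget",
    "FilterStats",
    "SchemaError",
    "ReferenceMismatchError",
    "filter_clinvar",
    "read_vcf",
    "classify_edit",
    "extract_flank",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class SchemaError(ValueError):
    """Input table lacks a required column."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the genome FASTA.

    Treated as a hard error: a mismatch means the coordinates or assembly are
    wrong, and silently designing guides against drifted coordinates is the
    worst possible failure mode.
    """


class EditClass(enum.Enum):
    CREATE_C_TO_T = "create_c_to_t"
    CORRECT_T_TO_C = "correct_t_to_c"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class VariantRecord:
    """One SNV with clinical annotations."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_id: str = ""
    name: str = ""
    significance: str = ""
    phenotype: str = ""
    gene_symbol: str = ""
    assembly: str = ""

    def __post_init__(self) -> None:
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(
                f"{self.variant_id or self.chrom}:{self.pos}: SNV alleles must "
                f"be single unambiguous bases, got {self.ref_allele!r}>"
                f"{self.alt_allele!r}"
            )
        if ref == alt:
            raise ValueError(
                f"{self.chrom}:{self.pos}: ref and alt alleles are identical"
            )
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)


@dataclass(frozen=True)
class FlankedTarget:
    """Plus-strand local sequence with the editable C located.

    ``sequence[target_offset]`` reads C on ``target_strand`` (i.e. it is C for
    plus, G for minus). ``start`` is the 1-based genomic coordinate of
    ``sequence[0]`` when the flank came from a genome.
    """

    sequence: str
    target_offset: int
    target_strand: Strand
    edited_sequence_applied: bool = False
    chrom: str = ""
    start: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.target_offset < len(self.sequence)):
            raise ValueError("target_offset outside sequence")
        base = self.sequence[self.target_offset]
        want = "C" if self.target_strand is Strand.PLUS else "G"
        if base != want:
            raise ValueError(
                f"target base is {base!r} but must read C on the "
                f"{self.target_strand.value} strand (plus-strand {want!r})"
            )


@dataclass
class FilterStats:
    """Per-step row counts of the filtering pipeline."""

    input_rows: int = 0
    snv: int = 0
    pathogenic: int = 0
    grch38: int = 0
    deduplicated: int = 0
    skipped_unparsable: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


#: default column names of the ClinVar variant_summary.txt dialect
CLINVAR_COLUMNS: Mapping[str, str] = {
    "type": "Type",
    "name": "Name",
    "significance": "ClinicalSignificance",
    "assembly": "Assembly",
    "chrom": "Chromosome",
    "pos": "Start",
    "ref": "ReferenceAlleleVCF",
    "alt": "AlternateAlleleVCF",
    "variant_id": "VariationID",
    "phenotype": "PhenotypeIDS",
    "gene": "GeneSymbol",
}

_SNV_LABEL = "single nucleotide variant"


def filter_clinvar(records: Union[pd.DataFrame, str, Path],
                   *,
                   assembly: str = "GRCh38",
                   exact_significance: bool = True,
                   dedup: bool = True,
                   column_map: Optional[Mapping[str, str]] = None,
                   stats: Optional[FilterStats] = None,
                   ) -> list[VariantRecord]:
    """Filter a ClinVar variant_summary-style table down to pathogenic SNVs.

    Keeps rows whose type is the single-nucleotide-variant label, whose
    clinical significance is "pathogenic" (exact label, case-insensitive;
    ``exact_significance=False`` widens to any label containing the word,
    e.g. "Pathogenic/Likely pathogenic"), and whose assembly matches
    ``assembly``. Rows are deduplicated by (chrom, pos, ref, alt) unless
    ``dedup=False``. Rows with unparsable coordinates or alleles are skipped
    and counted in ``stats.skipped_unparsable``.

    Parameters
    ----------
    records:
        DataFrame, or path to a tab-separated file with a header row.
    stats:
        Optional :class:`FilterStats` mutated in place with per-step counts.

    Returns
    -------
    list of :class:`VariantRecord`
    """
    cols = dict(CLINVAR_COLUMNS)
    if column_map:
        cols.update(column_map)
    if isinstance(records, (str, Path)):
        df = pd.read_csv(records, sep="\t", dtype=str, comment=None)
    else:
        df = records.copy()
    df.columns = [str(c) for c in df.columns]

    required = ["type", "significance", "name", "assembly", "chrom", "pos",
                "ref", "alt"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise SchemaError(f"input table is missing required columns {missing}")

    if stats is None:
        stats = FilterStats()
    stats.input_rows = len(df)

    def norm(s: pd.Series) -> pd.Series:
        return s.astype(str).str.strip().str.lower()

    df = df[norm(df[cols["type"]]) == _SNV_LABEL]
    stats.snv = len(df)

    sig = norm(df[cols["significance"]])
    if exact_significance:
        df = df[sig == "pathogenic"]
    else:
        df = df[sig.str.contains("pathogenic", regex=False)]
    stats.pathogenic = len(df)

    df = df[df[cols["assembly"]].astype(str).str.strip() == assembly]
    stats.grch38 = len(df)

    out: list[VariantRecord] = []
    seen: set[tuple[str, int, str, str]] = set()
    for _, row in df.iterrows():
        try:
            pos = int(str(row[cols["pos"]]).strip())
            rec = VariantRecord(
                chrom=str(row[cols["chrom"]]).strip(),
                pos=pos,
                ref_allele=str(row[cols["ref"]]).strip(),
                alt_allele=str(row[cols["alt"]]).strip(),
                variant_id=str(row.get(cols["variant_id"], "") or ""),
                name=str(row[cols["name"]] or ""),
                significance=str(row[cols["significance"]]),
                phenotype=str(row.get(cols["phenotype"], "") or ""),
                gene_symbol=str(row.get(cols["gene"], "") or ""),
                assembly=str(row[cols["assembly"]]),
            )
        except (ValueError, TypeError) as exc:
            stats.skipped_unparsable += 1
            logger.warning("skipping unparsable row: %s", exc)
            continue
        key = (rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele)
        if dedup:
            if key in seen:
                continue
            seen.add(key)
        out.append(rec)
    stats.deduplicated = len(out)
    logger.info("filter_clinvar: %s", stats.as_dict())
    return out


def read_vcf(path: Union[str, Path]) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF (v4, 1-based) via pysam.

    Multi-allelic records are split; non-SNV alleles are skipped with a
    warning counter in the log.
    """
    import pysam

    out: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or \
                        ref not in _BASES or alt not in _BASES:
                    skipped += 1
                    continue
                out.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref_allele=ref,
                    alt_allele=alt,
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}{ref}>{alt}",
                ))
    if skipped:
        logger.warning("read_vcf: skipped %d non-SNV alleles", skipped)
    return out


_CREATE_PATTERNS = ("C>T", "G>A")
_CORRECT_PATTERNS = ("T>C", "A>G")


def classify_edit(record: VariantRecord) -> EditClass:
    """Assign the create/correct class from the variant name.

    The name-substring rule: a name containing "C>T" or "G>A" is a pathogenic
    C-to-T change (creatable); "T>C" or "A>G" is a pathogenic T-to-C change
    (correctable). A name matching both families is ambiguous and returns
    ``NOT_APPLICABLE`` with a warning. When the record has no name, the
    ref/alt alleles are used with the same mapping.
    """
    if record.name:
        create = any(p in record.name for p in _CREATE_PATTERNS)
        correct = any(p in record.name for p in _CORRECT_PATTERNS)
        if create and correct:
            warnings.warn(
                f"{record.variant_id or record.name}: name matches both "
                "C-to-T and T-to-C patterns; treating as not applicable",
                stacklevel=2,
            )
            return EditClass.NOT_APPLICABLE
        if create:
            return EditClass.CREATE_C_TO_T
        if correct:
            return EditClass.CORRECT_T_TO_C
        return EditClass.NOT_APPLICABLE
    change = f"{record.ref_allele}>{record.alt_allele}"
    if change in _CREATE_PATTERNS:
        return EditClass.CREATE_C_TO_T
    if change in _CORRECT_PATTERNS:
        return EditClass.CORRECT_T_TO_C
    return EditClass.NOT_APPLICABLE


def extract_flank(genome: Union[pyfaidx.Fasta, str, Path],
                  record: VariantRecord,
                  edit_class: EditClass,
                  flank: int = 30) -> FlankedTarget:
    """Extract the plus-strand flank around the SNV and locate the target C.

    For creation the editable base is the *reference* C (target_strand plus if
    ref is C, minus if ref is G — the C then sits on the reverse strand). For
    correction the pathogenic alt allele is substituted into the flank first
    and the strand chosen so the substituted base reads C.

    The window is truncated at contig ends (with a warning); ``start`` records
    the 1-based genomic coordinate of the first returned base.

    Raises
    ------
    ReferenceMismatchError
        if the genome base at ``record.pos`` differs from ``record.ref_allele``.
    ValueError
        if ``edit_class`` is ``NOT_APPLICABLE`` or the alleles are
        incompatible with the class.
    """
    if edit_class is EditClass.NOT_APPLICABLE:
        raise ValueError("cannot extract a flank for a not_applicable variant")
    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(str(genome))

    contig = genome[record.chrom]
    contig_len = len(contig)
    if not (1 <= record.pos <= contig_len):
        raise ValueError(
            f"{record.chrom}:{record.pos} outside contig (length {contig_len})"
        )
    lo = max(0, record.pos - 1 - flank)          # 0-based inclusive
    hi = min(contig_len, record.pos + flank)     # 0-based exclusive
    if hi - lo < 2 * flank + 1:
        logger.warning("%s:%d flank truncated at contig bounds",
                       record.chrom, record.pos)
    seq = str(contig[lo:hi]).upper()
    offset = record.pos - 1 - lo

    if seq[offset] != record.ref_allele:
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos}: genome has {seq[offset]!r} but the "
            f"variant states reference allele {record.ref_allele!r}"
        )

    if edit_class is EditClass.CREATE_C_TO_T:
        base, applied = record.ref_allele, False
    else:  # CORRECT_T_TO_C: edit the patient allele
        base, applied = record.alt_allele, True
        seq = seq[:offset] + base + seq[offset + 1:]
    if base == "C":
        strand = Strand.PLUS
    elif base == "G":
        strand = Strand.MINUS
    else:
        raise ValueError(
            f"{record.chrom}:{record.pos}: edit class {edit_class.value} "
            f"requires the editable allele to be C or G, got {base!r}"
        )
    return FlankedTarget(sequence=seq, target_offset=offset,
                         target_strand=strand, edited_sequence_applied=applied,
                         chrom=record.chrom, start=lo + 1)
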