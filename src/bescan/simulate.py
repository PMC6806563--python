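"""Synthetic fixtures with recorded ground truth.

Everything the test-suite and the worked examples consume is generated here:
random genomes, ClinVar-like variant tables of known composition, planted
SNVs whose per-editor targetability is recorded by the independent
brute-force enumerator (:mod:`bescan.oracle`), and amplicon read sets with
planted editing/indel rates. All randomness flows from one integer seed per
artefact, and regenerating with the same seed reproduces the files
byte-for-byte.

A note on the read simulator: the 1-bp indel and the target-base substitution
are drawn *independently* per read, and the indel is placed immediately 3' of
the target base (never deleting it). Independent draws keep the marginal
substitution frequency equal to the requested editing rate, so estimates can
be checked directly against the planted parameters; an exclusive
either-indel-or-edit scheme would bias the observed substitution frequency
downward by the indel rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pyfaidx

from .oracle import oracle_verdict
from .panel import EditorPanel, default_panel

__all__ = [
    "FixtureManifest",
    "generate_genome",
    "plant_variants",
    "generate_clinvar_table",
    "simulate_reads",
    "make_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureManifest:
    """Replay record for one generated fixture."""

    seed: int
    genome: str = ""
    variants: str = ""
    ground_truth: dict = field(default_factory=dict)
    sim_params: dict = field(default_factory=dict)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FixtureManifest":
        return cls(**json.loads(Path(path).read_text()))


def generate_genome(n_contigs: int, length: int, gc_fraction: float,
                    seed: int, out_fasta: Union[str, Path],
                    line_width: int = 60) -> Path:
    """Write a reproducible random genome as FASTA (+ .fai index).

    Bases are i.i.d. with P(C) = P(G) = gc_fraction/2. Contigs are named
    ``chr1..chrN``.
    """
    if length < 200:
        raise ValueError("contig length must be >= 200")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    out_fasta = Path(out_fasta)
    with out_fasta.open("w") as fh:
        for i in range(1, n_contigs + 1):
            seq = "".join(rng.choice(_BASES, size=length, p=p))
            fh.write(f">chr{i}\n")
            for j in range(0, length, line_width):
                fh.write(seq[j:j + line_width] + "\n")
    faidx = pyfaidx.Fasta(str(out_fasta), build_index=True)
    faidx.close()
    return out_fasta


_CREATE_SITES = {"C": "T", "G": "A"}      # pathogenic C>T / G>A (creatable)
_CORRECT_SITES = {"T": "C", "A": "G"}     # pathogenic T>C / A>G (correctable)


def _clinvar_row(vid: int, chrom: str, pos: int, ref: str, alt: str,
                 sig: str = "Pathogenic", vtype: str = "single nucleotide variant",
                 assembly: str = "GRCh38", gene: str = "GENE1",
                 phenotype: str = "MONDO:0000001") -> dict:
    return {
        "VariationID": str(vid),
        "Type": vtype,
        "Name": f"NM_{vid:06d}.1({gene}):c.{pos}{ref}>{alt}",
        "ClinicalSignificance": sig,
        "Assembly": assembly,
        "Chromosome": chrom,
        "Start": str(pos),
        "ReferenceAlleleVCF": ref,
        "AlternateAlleleVCF": alt,
        "GeneSymbol": gene,
        "PhenotypeIDS": phenotype,
    }


def plant_variants(genome: Union[pyfaidx.Fasta, str, Path],
                   n_variants: int,
                   class_mix: Mapping[str, float],
                   seed: int,
                   panel: Optional[EditorPanel] = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Plant SNVs at random eligible sites and record oracle ground truth.

    ``class_mix`` gives the fraction of variants per edit class, keys
    ``"create"`` (pathogenic C>T/G>A, to be installed) and ``"correct"``
    (pathogenic T>C/A>G, to be reverted). For every planted variant the
    brute-force oracle enumerates all placements of every panel editor and
    records ``{"targetable": bool, "preferential": bool}`` flags.

    Returns the ClinVar-style table (pathogenic SNVs, GRCh38) and the ground
    truth dict keyed by VariationID.
    """
    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(str(genome))
    if panel is None:
        panel = default_panel()
    mix = {k: float(v) for k, v in class_mix.items()}
    if set(mix) - {"create", "correct"} or abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must map {'create','correct'} to "
                         "fractions summing to 1")
    rng = np.random.default_rng(seed)
    reach = max(ed.spacer_length + ed.pam_length for ed in panel)

    n_create = int(round(n_variants * mix.get("create", 0.0)))
    wanted = ["create"] * n_create + ["correct"] * (n_variants - n_create)

    contigs = list(genome.keys())
    rows: list[dict] = []
    truth: dict[str, dict] = {}
    used: set[tuple[str, int]] = set()
    attempts = 0
    vid = 0
    for kind in wanted:
        site_map = _CREATE_SITES if kind == "create" else _CORRECT_SITES
        while True:
            attempts += 1
            if attempts > 200 * n_variants:
                raise RuntimeError("not enough eligible sites in the genome")
            chrom = contigs[int(rng.integers(len(contigs)))]
            clen = len(genome[chrom])
            if clen < 2 * reach + 1:
                continue
            pos = int(rng.integers(reach, clen - reach)) + 1  # 1-based
            ref = str(genome[chrom][pos - 1]).upper()
            if ref not in site_map or (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            break
        alt = site_map[ref]
        vid += 1
        rows.append(_clinvar_row(vid, chrom, pos, ref, alt))

        flank = str(genome[chrom][pos - 1 - reach:pos + reach]).upper()
        offset = reach
        if kind == "create":
            base = ref
        else:  # correction edits the patient allele
            base = alt
            flank = flank[:offset] + base + flank[offset + 1:]
        strand = "+" if base == "C" else "-"
        truth[str(vid)] = {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "class": kind,
            "editors": {
                ed.name: dict(zip(("targetable", "preferential"),
                                  oracle_verdict(flank, offset, strand,
                                                 ed.pam_pattern,
                                                 ed.pam_side.value,
                                                 ed.spacer_length,
                                                 ed.window_start,
                                                 ed.window_end)))
                for ed in panel
            },
        }
    return pd.DataFrame(rows), truth


def generate_clinvar_table(composition: Mapping[str, int],
                           seed: int) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build a shuffled ClinVar-like table of exactly known composition.

    ``composition`` maps category names to row counts:

    - ``pathogenic_create`` — pathogenic GRCh38 SNVs named C>T or G>A
    - ``pathogenic_correct`` — pathogenic GRCh38 SNVs named T>C or A>G
    - ``pathogenic_other`` — pathogenic GRCh38 SNVs of another change (A>T...)
    - ``likely_pathogenic`` — SNVs labelled "Likely pathogenic"
    - ``compound`` — SNVs labelled "Pathogenic/Likely pathogenic"
    - ``benign`` — benign SNVs
    - ``indel`` — pathogenic GRCh38 rows typed Deletion
    - ``grch37`` — pathogenic SNVs on the other assembly

    Returns the table and a copy of the composition as ground truth.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    vid = 0

    def changes(kind: str) -> list[tuple[str, str]]:
        return {"create": [("C", "T"), ("G", "A")],
                "correct": [("T", "C"), ("A", "G")],
                "other": [("A", "T"), ("C", "G"), ("G", "T"), ("T", "A")],
                }[kind]

    def add(n: int, kind: str, **kw) -> None:
        nonlocal vid
        opts = changes(kind)
        for _ in range(n):
            vid += 1
            ref, alt = opts[int(rng.integers(len(opts)))]
            pos = int(rng.integers(1_000, 1_000_000))
            rows.append(_clinvar_row(vid, f"chr{int(rng.integers(1, 23))}",
                                     pos, ref, alt, **kw))

    add(composition.get("pathogenic_create", 0), "create")
    add(composition.get("pathogenic_correct", 0), "correct")
    add(composition.get("pathogenic_other", 0), "other")
    add(composition.get("likely_pathogenic", 0), "create",
        sig="Likely pathogenic")
    add(composition.get("compound", 0), "create",
        sig="Pathogenic/Likely pathogenic")
    add(composition.get("benign", 0), "create", sig="Benign")
    add(composition.get("indel", 0), "create", vtype="Deletion")
    add(composition.get("grch37", 0), "create", assembly="GRCh37")

    df = pd.DataFrame(rows)
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df, dict(composition)


def simulate_reads(reference: str,
                   edit_position: int,
                   editing_rate: float,
                   purity: float,
                   indel_rate: float,
                   n_reads: int,
                   seed: int,
                   out_sam: Union[str, Path],
                   chrom: str = "amplicon") -> Path:
    """Simulate aligned amplicon reads with planted outcome rates.

    Every read spans the whole ``reference`` (1-based ``edit_position`` must
    hold a C). Independently per read: with probability ``indel_rate`` a 1-bp
    indel is introduced immediately 3' of the target base (insertion or
    deletion, 50/50 — overlapping the editing window but never removing the
    target); with probability ``editing_rate`` the target C is substituted,
    becoming T with probability ``purity`` and A or G (equal split)
    otherwise. Writes a SAM file; same seed, same bytes.
    """
    reference = reference.upper()
    for name, r in (("editing_rate", editing_rate), ("purity", purity),
                    ("indel_rate", indel_rate)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if not (1 <= edit_position <= len(reference)):
        raise ValueError("edit_position outside reference")
    if reference[edit_position - 1] != "C":
        raise ValueError("reference base at edit_position must be C")
    if edit_position >= len(reference):
        raise ValueError("need one reference base 3' of the target for indels")

    rng = np.random.default_rng(seed)
    n = len(reference)
    t = edit_position - 1  # 0-based target index

    has_indel = rng.random(n_reads) < indel_rate
    is_del = rng.random(n_reads) < 0.5
    edited = rng.random(n_reads) < editing_rate
    to_t = rng.random(n_reads) < purity
    a_not_g = rng.random(n_reads) < 0.5

    out_sam = Path(out_sam)
    with out_sam.open("w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{n}\n")
        for i in range(n_reads):
            seq = list(reference)
            if edited[i]:
                seq[t] = "T" if to_t[i] else ("A" if a_not_g[i] else "G")
            if has_indel[i]:
                if is_del[i]:  # delete the base immediately 3' of the target
                    del seq[t + 1]
                    cigar = f"{t + 1}M1D{n - t - 2}M" if n - t - 2 else f"{t + 1}M1D"
                else:          # insert an A immediately 3' of the target
                    seq.insert(t + 1, "A")
                    cigar = f"{t + 1}M1I{n - t - 1}M"
            else:
                cigar = f"{n}M"
            read = "".join(seq)
            fh.write(f"read{i}\t0\t{chrom}\t1\t60\t{cigar}\t*\t0\t0\t"
                     f"{read}\t{'I' * len(read)}\n")
    return out_sam


def make_fixture(out_dir: Union[str, Path],
                 seed: int,
                 n_contigs: int = 2,
                 contig_length: int = 5_000,
                 gc_fraction: float = 0.45,
                 n_variants: int = 20,
                 class_mix: Optional[Mapping[str, float]] = None,
                 panel: Optional[EditorPanel] = None) -> FixtureManifest:
    """Generate a complete genome+variants fixture with manifest on disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if class_mix is None:
        class_mix = {"create": 0.5, "correct": 0.5}
    rng = np.random.default_rng(seed)
    genome_seed = int(rng.integers(2 ** 31))
    variant_seed = int(rng.integers(2 ** 31))
    genome_path = generate_genome(n_contigs, contig_length, gc_fraction,
                                  genome_seed, out_dir / "genome.fa")
    table, truth = plant_variants(genome_path, n_variants, class_mix,
                                  variant_seed, panel=panel)
    variants_path = out_dir / "variants.tsv"
    table.to_csv(variants_path, sep="\t", index=False)
    manifest = FixtureManifest(
        seed=seed, genome=str(genome_path), variants=str(variants_path),
        ground_truth=truth,
        sim_params={"n_contigs": n_contigs, "contig_length": contig_length,
                    "gc_fraction": gc_fraction, "n_variants": n_variants,
                    "class_mix": dict(class_mix),
                    "genome_seed": genome_seed, "variant_seed": variant_seed},
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
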