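"""Genotype containers, VCF/label I/O, and query-panel merging.

The workflow operates on biallelic autosomal SNVs only.  Genotypes are held
as alt-allele dosages (0, 1, 2) in a samples x variants integer matrix; a
sentinel of -1 marks a missing genotype.  Merging a query sample into the
reference panel fills every missing or absent genotype with homozygous
reference (dosage 0), so all downstream stages operate on complete data.
This hom-ref fill is what pushes patient-private somatic calls to a very low
minor-allele frequency, letting the MAF filter remove them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from cyvcf2 import VCF

from .config import POPULATIONS, normalize_population
from .errors import ContractError, EmptyInputError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")
_AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Strand-ambiguous allele pairs (indistinguishable from a strand flip).
_AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


class Variant(NamedTuple):
    """A biallelic autosomal SNV keyed by (chrom, pos, ref, alt)."""

    chrom: int
    pos: int
    ref: str
    alt: str
    id: str | None = None

    @property
    def key(self) -> tuple[int, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _validate_variant(v: Variant) -> None:
    if not 1 <= v.chrom <= 22:
        raise ValidationError(f"variant {v} is not autosomal")
    if v.ref == v.alt:
        raise ValidationError(f"variant {v} has identical ref/alt")
    if v.ref not in _NUCLEOTIDES or v.alt not in _NUCLEOTIDES:
        raise ValidationError(f"variant {v} alleles must be single nucleotides")


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix.

    Variants are unique by (chrom, pos, ref, alt) and sorted by (chrom, pos).
    """

    variants: list[Variant]
    samples: list[str]
    dosages: np.ndarray  # (n_samples, n_variants), int16, entries {0,1,2,-1}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ContractError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.variants)})")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ContractError("variant keys are not unique")
        order = [(v.chrom, v.pos) for v in self.variants]
        if order != sorted(order):
            raise ContractError("variants are not sorted by (chrom, pos)")
        if len(set(self.samples)) != len(self.samples):
            raise ContractError("sample ids are not unique")
        for v in self.variants:
            _validate_variant(v)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[tuple[int, int, str, str], int]:
        return {v.key: j for j, v in enumerate(self.variants)}

    def subset_variants(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            variants=[self.variants[j] for j in idx],
            samples=list(self.samples),
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise ContractError(f"unknown samples: {missing}")
        rows = [pos[s] for s in wanted]
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=wanted,
            dosages=self.dosages[rows, :].copy(),
        )


@dataclass
class ReferencePanel:
    """A genotype matrix whose every sample carries one population label."""

    genotypes: GenotypeMatrix
    labels: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.genotypes.samples:
            if s not in self.labels:
                raise ValidationError(f"panel sample {s!r} has no label")
        self.labels = {s: normalize_population(self.labels[s])
                       for s in self.genotypes.samples}
        if len(set(self.labels.values())) < 2:
            raise ValidationError("reference panel needs >= 2 populations")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.genotypes.samples])


def _parse_chrom(chrom: str) -> int | None:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return int(c) if c in _AUTOSOMES else None


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic autosomal SNVs from a VCF into a dosage matrix.

    Multiallelic, non-autosomal and indel records are dropped (counts
    logged); duplicate (chrom,pos,ref,alt) keys keep the first occurrence.
    Partial or absent GT calls map to :data:`MISSING`.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[tuple[Variant, np.ndarray]] = []
    n_dropped = {"non_autosomal": 0, "multiallelic": 0, "non_snv": 0,
                 "duplicate": 0}
    seen: set[tuple[int, int, str, str]] = set()
    for rec in vcf:
        chrom = _parse_chrom(rec.CHROM)
        if chrom is None:
            n_dropped["non_autosomal"] += 1
            continue
        if len(rec.ALT) != 1:
            n_dropped["multiallelic"] += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or not (
                ref in _NUCLEOTIDES and alt in _NUCLEOTIDES):
            n_dropped["non_snv"] += 1
            continue
        var = Variant(chrom, rec.POS, ref, alt,
                      rec.ID if rec.ID not in (None, ".") else None)
        if var.key in seen:
            n_dropped["duplicate"] += 1
            continue
        seen.add(var.key)
        row = np.full(len(samples), MISSING, dtype=np.int16)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) == 2 and alleles[0] >= 0 and alleles[1] >= 0:
                row[i] = alleles[0] + alleles[1]
        records.append((var, row))
    if any(n_dropped.values()):
        logger.info("read_vcf(%s): dropped %s", path.name, n_dropped)
    if not records:
        raise EmptyInputError(f"no usable SNV records in {path}")
    records.sort(key=lambda t: (t[0].chrom, t[0].pos))
    variants = [t[0] for t in records]
    dosages = np.stack([t[1] for t in records], axis=1)
    return GenotypeMatrix(variants=variants, samples=samples, dosages=dosages)


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal uncompressed VCF 4.2 with GT only."""
    gt_repr = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in m.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for j, v in enumerate(m.variants):
            gts = "\t".join(gt_repr[int(d)] for d in m.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→population table (TSV with header)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ValidationError(f"label file {path} is empty")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns")
            sample, pop = parts
            try:
                pop = normalize_population(pop)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if sample in labels:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate sample {sample!r}")
            labels[sample] = pop
    if not labels:
        raise EmptyInputError(f"label file {path} has no rows")
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in labels.items():
            fh.write(f"{sample}\t{pop}\n")


def _is_ambiguous(ref: str, alt: str) -> bool:
    return frozenset({ref, alt}) in _AMBIGUOUS_PAIRS


def merge_query_with_panel(query: GenotypeMatrix,
                           panel: ReferencePanel) -> GenotypeMatrix:
    """Append the single query sample to the panel on a harmonized
    variant universe.

    The merged universe is the union of variant keys.  Ref/alt swaps at a
    shared (chrom, pos) are reconciled by complementing the query dosage
    (d -> 2 - d) unless the allele pair is strand-ambiguous (A/T, C/G), in
    which case the query record is dropped and logged.  Every absent or
    missing genotype becomes homozygous reference (dosage 0), so the output
    contains no missing codes.
    """
    if query.n_samples != 1:
        raise ContractError(
            f"query must contain exactly 1 sample, got {query.n_samples}")
    query_id = query.samples[0]
    pg = panel.genotypes
    if query_id in pg.samples:
        raise ContractError(f"query sample {query_id!r} already in panel")

    panel_by_key = pg.variant_index()
    panel_by_pos: dict[tuple[int, int], list[int]] = {}
    for j, v in enumerate(pg.variants):
        panel_by_pos.setdefault((v.chrom, v.pos), []).append(j)

    # query dosage aligned to panel variants; -2 marks "not covered"
    q_on_panel = np.full(pg.n_variants, -2, dtype=np.int16)
    extra: list[tuple[Variant, int]] = []
    n_flipped = n_conflict = 0
    for j, v in enumerate(query.variants):
        d = int(query.dosages[0, j])
        if v.key in panel_by_key:
            q_on_panel[panel_by_key[v.key]] = d
            continue
        candidates = panel_by_pos.get((v.chrom, v.pos), [])
        swapped = [p for p in candidates
                   if pg.variants[p].ref == v.alt and pg.variants[p].alt == v.ref]
        if swapped:
            if _is_ambiguous(v.ref, v.alt):
                n_conflict += 1
                continue
            if d != MISSING:
                q_on_panel[swapped[0]] = 2 - d
            else:
                q_on_panel[swapped[0]] = MISSING
            n_flipped += 1
        elif candidates:
            n_conflict += 1  # same position, irreconcilable alleles
        else:
            extra.append((v, d))
    if n_flipped or n_conflict:
        logger.info("merge: reconciled %d allele swaps, dropped %d conflicts",
                    n_flipped, n_conflict)

    # assemble: panel variants then query-only variants, re-sorted
    all_variants = list(pg.variants) + [v for v, _ in extra]
    order = sorted(range(len(all_variants)),
                   key=lambda i: (all_variants[i].chrom, all_variants[i].pos))
    n_total = len(all_variants)
    dosages = np.zeros((pg.n_samples + 1, n_total), dtype=np.int16)
    dosages[:-1, :pg.n_variants] = np.where(
        pg.dosages == MISSING, 0, pg.dosages)
    qrow = np.zeros(n_total, dtype=np.int16)
    covered = q_on_panel != -2
    qrow[:pg.n_variants][covered] = np.where(
        q_on_panel[covered] == MISSING, 0, q_on_panel[covered])
    for k, (_, d) in enumerate(extra):
        qrow[pg.n_variants + k] = 0 if d == MISSING else d
    dosages[-1, :] = qrow
    return GenotypeMatrix(
        variants=[all_variants[i] for i in order],
        samples=list(pg.samples) + [query_id],
        dosages=dosages[:, order],
    )
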