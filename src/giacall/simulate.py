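"""Synthetic genotype data under the Balding-Nichols model.

Population allele frequencies are Beta-distributed around an ancestral
frequency with variance F_ST * p * (1 - p); reference dosages are binomial
draws from the population frequency, and admixed queries are binomial
draws from the q-weighted mixture frequency — exactly the generative model
the supervised-admixture likelihood assumes, which makes parameter-recovery
tests sharp.  No linkage disequilibrium is simulated; LD pruning is tested
separately on constructed correlated columns.  Related pairs (duplicate,
parent-offspring, full-sib, unrelated) are produced by explicit Mendelian
transmission for the kinship tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractError, ValidationError
from .genotype_io import (GenotypeMatrix, ReferencePanel, Variant,
                          write_labels, write_vcf)

#: Population labels assigned to simulated populations, in order.
POP_ORDER: tuple[str, ...] = (
    "AFR", "EUR", "EAS", "SAS", "AMR", "MEA", "CAS_SIB", "OCN",
)

#: Unambiguous ref/alt pairs cycled across simulated variants.
_ALLELE_CYCLE = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"))

RELATIONSHIPS = ("duplicate", "parent_offspring", "full_sib", "unrelated")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic panel."""

    n_pops: int = 3
    fst: float | tuple[float, ...] = 0.1
    n_ref_per_pop: int = 100
    n_variants: int = 2000
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    queries: list[tuple[float, ...]] = field(default_factory=list)
    pedigree_pairs: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_pops <= len(POP_ORDER):
            raise ValidationError(f"n_pops must be in [1, {len(POP_ORDER)}]")
        fst = self.fst if isinstance(self.fst, (tuple, list)) else \
            (self.fst,) * self.n_pops
        if len(fst) != self.n_pops or any(not 0 < f < 1 for f in fst):
            raise ValidationError("fst values must lie in (0, 1), one per pop")
        self.fst = tuple(float(f) for f in fst)
        lo, hi = self.anc_freq_range
        if not 0 < lo < hi < 1:
            raise ValidationError("anc_freq_range must be within (0, 1)")
        if self.n_variants < 1 or self.n_ref_per_pop < 1:
            raise ValidationError("n_variants and n_ref_per_pop must be >= 1")
        for q in self.queries:
            q = np.asarray(q, dtype=float)
            if q.size != self.n_pops or abs(q.sum() - 1) > 1e-9 or (q < 0).any():
                raise ValidationError(f"query q {q} is not on the simplex")
        for tag in self.pedigree_pairs:
            if tag not in RELATIONSHIPS:
                raise ValidationError(f"unknown relationship tag {tag!r}")

    @property
    def populations(self) -> tuple[str, ...]:
        return POP_ORDER[: self.n_pops]


def _variant_grid(n_variants: int) -> list[Variant]:
    """Deterministic variant coordinates: blocks across autosomes 1-22."""
    variants = []
    for j in range(n_variants):
        chrom = 1 + (j * 22) // n_variants
        variants.append(Variant(chrom=chrom, pos=10_000 + j * 1_000,
                                ref=_ALLELE_CYCLE[j % 4][0],
                                alt=_ALLELE_CYCLE[j % 4][1],
                                id=f"snv{j:05d}"))
    return variants


def simulate_panel(cfg: SimulationConfig
                   ) -> tuple[ReferencePanel, np.ndarray]:
    """Draw a labeled multi-population reference panel.

    Returns the panel and the realized per-population frequency matrix
    (n_pops x n_variants) so oracle tests can condition on it.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.anc_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_variants)
    freqs = np.empty((cfg.n_pops, cfg.n_variants))
    for k, f_k in enumerate(cfg.fst):
        a = p_anc * (1.0 - f_k) / f_k
        b = (1.0 - p_anc) * (1.0 - f_k) / f_k
        freqs[k] = rng.beta(a, b)
    samples: list[str] = []
    labels: dict[str, str] = {}
    rows = []
    for k, pop in enumerate(cfg.populations):
        dos = rng.binomial(2, freqs[k],
                           size=(cfg.n_ref_per_pop, cfg.n_variants))
        rows.append(dos)
        for i in range(cfg.n_ref_per_pop):
            sid = f"{pop}_{i:04d}"
            samples.append(sid)
            labels[sid] = pop
    gm = GenotypeMatrix(variants=_variant_grid(cfg.n_variants),
                        samples=samples,
                        dosages=np.vstack(rows).astype(np.int16))
    if cfg.n_pops < 2:
        raise ValidationError("a reference panel needs >= 2 populations")
    return ReferencePanel(genotypes=gm, labels=labels), freqs


def simulate_query(true_q: np.ndarray, freqs: np.ndarray,
                   seed: int) -> np.ndarray:
    """Dosages of one admixed query: Binomial(2, sum_k q_k f_kj)."""
    true_q = np.asarray(true_q, dtype=np.float64)
    if true_q.size != freqs.shape[0]:
        raise ContractError("q length must match the frequency matrix rows")
    p = true_q @ freqs
    rng = np.random.default_rng(seed)
    return rng.binomial(2, p).astype(np.int16)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per locus transmitted from a parent genotype."""
    return rng.binomial(1, parent / 2.0)


def simulate_pair(relationship: str, freq_row: np.ndarray,
                  seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A pair of dosage vectors with a known pedigree relationship."""
    if relationship not in RELATIONSHIPS:
        raise ContractError(f"unknown relationship tag {relationship!r}")
    rng = np.random.default_rng(seed)
    f = np.asarray(freq_row, dtype=np.float64)
    if relationship == "duplicate":
        g = rng.binomial(2, f)
        return g.astype(np.int16), g.astype(np.int16).copy()
    if relationship == "unrelated":
        return (rng.binomial(2, f).astype(np.int16),
                rng.binomial(2, f).astype(np.int16))
    if relationship == "parent_offspring":
        parent = rng.binomial(2, f)
        child = _transmit(parent, rng) + rng.binomial(1, f)
        return parent.astype(np.int16), child.astype(np.int16)
    # full siblings: Mendelian transmission from two simulated parents
    p1 = rng.binomial(2, f)
    p2 = rng.binomial(2, f)
    sib1 = _transmit(p1, rng) + _transmit(p2, rng)
    sib2 = _transmit(p1, rng) + _transmit(p2, rng)
    return sib1.astype(np.int16), sib2.astype(np.int16)


def query_matrix(query_id: str, dosages: np.ndarray,
                 panel: ReferencePanel) -> GenotypeMatrix:
    """Wrap a simulated query dosage vector on the panel's variant grid."""
    return GenotypeMatrix(variants=list(panel.genotypes.variants),
                          samples=[query_id],
                          dosages=np.asarray(dosages, dtype=np.int16)[None, :])


def write_simulation(cfg: SimulationConfig, out_dir: str | Path
                     ) -> dict[str, Path]:
    """Materialize a simulation as VCF + label + truth files.

    Writes ``panel.vcf``, one ``query_<i>.vcf`` per configured query,
    ``labels.tsv`` and ``truth.tsv`` (sample, true population at argmax q,
    then the q vector).  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, freqs = simulate_panel(cfg)
    paths: dict[str, Path] = {}
    paths["panel"] = out / "panel.vcf"
    write_vcf(panel.genotypes, paths["panel"])
    paths["labels"] = out / "labels.tsv"
    write_labels(panel.labels, paths["labels"])
    truth_lines = ["sample\ttruth\t" + "\t".join(cfg.populations)]
    for i, q in enumerate(cfg.queries):
        qid = f"query_{i:03d}"
        dos = simulate_query(np.asarray(q), freqs, seed=cfg.seed + 1_000 + i)
        qpath = out / f"{qid}.vcf"
        write_vcf(query_matrix(qid, dos, panel), qpath)
        paths[qid] = qpath
        truth = cfg.populations[int(np.argmax(q))]
        truth_lines.append(
            qid + "\t" + truth + "\t" + "\t".join(f"{x:.6f}" for x in q))
    paths["truth"] = out / "truth.tsv"
    paths["truth"].write_text("\n".join(truth_lines) + "\n")
    return paths
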