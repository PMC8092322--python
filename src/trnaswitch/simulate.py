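"""Synthetic-data generators with exported ground truth.

Every input the pipeline consumes can be generated here at a small scale
with known truth: tRNA gene pools with injected anticodon switches, toy
genomes with multi-sample VCFs carrying variants at known anticodon
coordinates, expression time courses with a codon-enriched induced gene
set, and peptide quantification tables with planted substitution rates,
intensity-dependent missingness and a planted differential-protein set.

Generators are deterministic under their seed, and each returns (or writes)
a :class:`GroundTruth` sufficient to score its consumer stage exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    AA_THREE_TO_ONE,
    GenomicInterval,
    STANDARD_CODE,
    TRNAGene,
    decode_anticodon,
    normalize_rna,
    reverse_complement,
)
from .stability import SYNTHETIC_TRT2_STRUCTURE

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_WC = ("AU", "UA", "GC", "CG")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    planted_switches: list[dict] = field(default_factory=list)
    planted_variants: list[dict] = field(default_factory=list)
    decoy_variants: list[dict] = field(default_factory=list)
    induced_genes: list[str] = field(default_factory=list)
    codon_enrichment: Optional[float] = None
    focal_codon: Optional[str] = None
    substitution_rates: dict = field(default_factory=dict)
    differential_proteins: list[str] = field(default_factory=list)
    differential_rows: list[int] = field(default_factory=list)
    differential_effect: Optional[float] = None
    thr_downshift: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# --- tRNA pools --------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """A tRNA gene family: isotype (3-letter), anticodon (RNA), copy number."""

    isotype: str
    anticodon: str
    copy_number: int

    def __post_init__(self) -> None:
        codon, aa = decode_anticodon(self.anticodon)
        expect = AA_THREE_TO_ONE.get(self.isotype)
        if expect is not None and aa != expect:
            raise ValueError(
                f"anticodon {self.anticodon} decodes {aa}, not {self.isotype}"
            )


@dataclass(frozen=True)
class PlantedSwitch:
    """Replace the anticodon of one family copy (1-based copy index)."""

    family_index: int
    copy_index: int
    to_anticodon: str


TEMPLATE_STRUCTURE = SYNTHETIC_TRT2_STRUCTURE
_PAIRS_0BASED: list[tuple[int, int]] = []
_stack: list[int] = []
for _i, _c in enumerate(TEMPLATE_STRUCTURE):
    if _c == "(":
        _stack.append(_i)
    elif _c == ")":
        _PAIRS_0BASED.append((_stack.pop(), _i))
_UNPAIRED = [i for i, c in enumerate(TEMPLATE_STRUCTURE) if c == "."]
ANTICODON_SPAN_0BASED = (32, 33, 34)  # middle of the second hairpin loop
_FREE_POSITIONS = [p for p in _UNPAIRED if p not in ANTICODON_SPAN_0BASED]


def _random_template(rng: np.random.Generator) -> str:
    """A random sequence folding on the shared cloverleaf template."""
    seq = [""] * len(TEMPLATE_STRUCTURE)
    for p in _UNPAIRED:
        seq[p] = "ACGU"[rng.integers(4)]
    for i, j in _PAIRS_0BASED:
        pair = _WC[rng.integers(4)]
        seq[i], seq[j] = pair[0], pair[1]
    return "".join(seq)


def gen_trna_pool(
    families: Sequence[FamilySpec],
    mutation_rate: float = 0.01,
    planted_switches: Sequence[PlantedSwitch] = (),
    seed: int = 0,
    signature_size: int = 6,
    force_stop_anticodons: bool = False,
    distinct_copies: bool = False,
) -> tuple[list[TRNAGene], GroundTruth]:
    """Generate a tRNA gene pool with known anticodon switches.

    All genes share one cloverleaf template.  Each family carries a private
    signature of ``signature_size`` fixed substitutions at unpaired,
    non-anticodon positions, so cross-family distances exceed within-family
    distances by construction.  Copies within a family differ by
    Poisson(mutation_rate * L) substitutions at free positions outside any
    signature.  Planted switches substitute anticodon bases only, leaving
    the family header intact (the hallmark of a real anticodon switch).

    With ``distinct_copies`` the within-family variation is deterministic
    instead of Poisson: copy k differs from the family consensus at exactly
    k - 1 fixed positions (cyclic base shift), so copies j and k are
    |j - k| substitutions apart.  Planting one switch per family on a copy
    index c with 3 <= c <= copies - 2 then makes nearest-nonequal-neighbor
    recovery of the planted set exact: every non-switched gene has a
    same-amino-acid neighbor strictly closer than any switched gene.
    """
    rng = np.random.default_rng(seed)
    template = _random_template(rng)
    n_fam = len(families)
    if n_fam * signature_size > len(_FREE_POSITIONS):
        raise ValueError("too many families for the signature budget")
    sig_positions = rng.permutation(_FREE_POSITIONS)[: n_fam * signature_size]
    noise_positions = [p for p in _FREE_POSITIONS if p not in set(sig_positions)]

    switch_lookup = {
        (s.family_index, s.copy_index): s.to_anticodon for s in planted_switches
    }
    for s in planted_switches:
        _, aa = decode_anticodon(s.to_anticodon)
        if aa == "*" and not force_stop_anticodons:
            raise ValueError(
                f"planted anticodon {s.to_anticodon} decodes a stop codon"
            )

    genes: list[TRNAGene] = []
    truth = GroundTruth()
    for f_idx, fam in enumerate(families):
        consensus = list(template)
        for p in sig_positions[f_idx * signature_size:(f_idx + 1) * signature_size]:
            current = consensus[p]
            consensus[p] = rng.choice([b for b in "ACGU" if b != current])
        for k, p in enumerate(ANTICODON_SPAN_0BASED):
            consensus[p] = normalize_rna(fam.anticodon)[k]
        if distinct_copies:
            # deterministic within-family ladder: positions usable for the
            # cyclic shift exclude anticodon and every family signature
            ladder = [p for p in range(len(template))
                      if p not in ANTICODON_SPAN_0BASED
                      and p not in set(sig_positions)]
            ladder = list(rng.permutation(ladder))
            if fam.copy_number - 1 > len(ladder):
                raise ValueError("family too large for distinct_copies mode")
        for copy in range(1, fam.copy_number + 1):
            body = list(consensus)
            if distinct_copies:
                for p in ladder[: copy - 1]:
                    body[p] = "ACGU"[("ACGU".index(body[p]) + 1) % 4]
            else:
                n_mut = rng.poisson(mutation_rate * len(body))
                if n_mut > 0:
                    hit = rng.choice(len(noise_positions),
                                     size=min(n_mut, len(noise_positions)),
                                     replace=False)
                    for h in hit:
                        p = noise_positions[h]
                        body[p] = rng.choice([b for b in "ACGU" if b != body[p]])
            to_ac = switch_lookup.get((f_idx, copy))
            gene_id = (
                f"tRNA-{fam.isotype}-{fam.anticodon.replace('U', 'T')}"
                f"-{f_idx + 1}-{copy}"
            )
            if to_ac is not None:
                to_ac = normalize_rna(to_ac)
                from_ac = "".join(body[p] for p in ANTICODON_SPAN_0BASED)
                for k, p in enumerate(ANTICODON_SPAN_0BASED):
                    body[p] = to_ac[k]
                truth.planted_switches.append({
                    "gene_id": gene_id,
                    "from_anticodon": from_ac,
                    "to_anticodon": to_ac,
                })
            genes.append(TRNAGene(
                gene_id=gene_id,
                sequence="".join(body),
                structure=TEMPLATE_STRUCTURE,
                species_tag="synthetic",
            ))
    return genes, truth


# --- genomes with planted variants -------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    """A substitution at an anticodon base of a pool gene.

    ``anticodon_offset`` is 1-3 in transcript orientation; ``alt_base`` is
    the new transcript (RNA) base; ``carriers`` are strain indices
    (0-based) that receive a heterozygous alternate genotype.
    """

    gene_id: str
    anticodon_offset: int
    alt_base: str
    carriers: tuple[int, ...]


def gen_genome_with_trnas(
    pool: Sequence[TRNAGene],
    chrom_sizes: dict[str, int],
    n_strains: int = 6,
    planted_variants: Sequence[PlantedVariant] = (),
    n_decoys: int = 5,
    seed: int = 0,
    strands: Optional[Sequence[str]] = None,
) -> tuple[list[TRNAGene], dict[str, str], pd.DataFrame, list[str], GroundTruth]:
    """Place pool genes on a random genome and plant VCF variants.

    Returns (located genes, genome dict chrom->DNA, BED frame, VCF lines,
    ground truth).  Decoy variants fall inside tRNA genes but outside
    anticodon spans, or intergenic.  Carrier strains get 0/1 genotypes.
    """
    rng = np.random.default_rng(seed)
    genome = {
        chrom: "".join(rng.choice(list("ACGT"), size=size))
        for chrom, size in chrom_sizes.items()
    }
    chroms = list(chrom_sizes)
    placed: list[TRNAGene] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g_idx, gene in enumerate(pool):
        length = len(gene.sequence)
        strand = (strands[g_idx] if strands is not None
                  else ("+" if rng.random() < 0.5 else "-"))
        for _attempt in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            span = (start, start + length)
            if all(span[1] <= s or span[0] >= e for s, e in occupied[chrom]):
                occupied[chrom].append(span)
                break
        else:
            raise RuntimeError("genome too small to place all genes")
        dna = gene.sequence.replace("U", "T")
        genomic = dna if strand == "+" else dna.translate(_DNA_COMPLEMENT)[::-1]
        genome[chrom] = (
            genome[chrom][:start] + genomic + genome[chrom][start + length:]
        )
        placed.append(TRNAGene(
            gene_id=gene.gene_id,
            sequence=gene.sequence,
            structure=gene.structure,
            location=GenomicInterval(chrom, start, start + length, strand),
            species_tag=gene.species_tag,
        ))

    strains = [f"strain{k + 1:03d}" for k in range(n_strains)]
    truth = GroundTruth()
    vcf_rows: list[tuple[str, int, str, str, tuple[int, ...]]] = []

    from .genetics import locate_anticodon
    from .variants import anticodon_genomic_coordinates

    by_id = {g.gene_id: g for g in placed}
    anticodon_genomic: set[tuple[str, int]] = set()
    for g in placed:
        span = locate_anticodon(g).span
        for gp in anticodon_genomic_coordinates(g, span):
            anticodon_genomic.add((g.location.chrom, gp))

    for pv in planted_variants:
        gene = by_id[pv.gene_id]
        call = locate_anticodon(gene)
        gpos = anticodon_genomic_coordinates(gene, call.span)[pv.anticodon_offset - 1]
        loc = gene.location
        ref_genome = genome[loc.chrom][gpos - 1]
        alt_t = normalize_rna(pv.alt_base)
        if alt_t == gene.sequence[call.span[pv.anticodon_offset - 1]]:
            raise ValueError(f"{pv.gene_id}: alt equals the reference base")
        alt_dna = alt_t.replace("U", "T")
        alt_genome = (alt_dna if loc.strand == "+"
                      else alt_dna.translate(_DNA_COMPLEMENT))
        vcf_rows.append((loc.chrom, gpos, ref_genome, alt_genome, pv.carriers))
        truth.planted_variants.append({
            "gene_id": pv.gene_id,
            "chrom": loc.chrom,
            "pos": gpos,
            "ref": ref_genome,
            "alt": alt_genome,
            "anticodon_offset": pv.anticodon_offset,
            "alt_transcript_base": alt_t,
            "carriers": [strains[i] for i in pv.carriers],
        })

    planted_pos = {(c, p) for c, p, *_ in vcf_rows}
    n_placed_decoys = 0
    while n_placed_decoys < n_decoys:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, chrom_sizes[chrom] + 1))
        if (chrom, pos) in anticodon_genomic or (chrom, pos) in planted_pos:
            continue
        ref = genome[chrom][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        carriers = tuple(
            int(i) for i in rng.choice(n_strains,
                                       size=rng.integers(1, n_strains + 1),
                                       replace=False)
        )
        vcf_rows.append((chrom, pos, ref, alt, carriers))
        planted_pos.add((chrom, pos))
        truth.decoy_variants.append({"chrom": chrom, "pos": pos, "ref": ref,
                                     "alt": alt})
        n_placed_decoys += 1

    vcf_rows.sort(key=lambda r: (r[0], r[1]))
    vcf_lines = ["##fileformat=VCFv4.2"]
    for chrom, size in chrom_sizes.items():
        vcf_lines.append(f"##contig=<ID={chrom},length={size}>")
    vcf_lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    vcf_lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(strains)
    )
    for chrom, pos, ref, alt, carriers in vcf_rows:
        gts = ["0/1" if k in carriers else "0/0" for k in range(n_strains)]
        vcf_lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t99\tPASS\t.\tGT\t" + "\t".join(gts)
        )

    bed = pd.DataFrame([
        {
            "chrom": g.location.chrom, "start": g.location.start,
            "end": g.location.end, "name": g.gene_id, "score": 0,
            "strand": g.location.strand,
        }
        for g in placed
    ]).sort_values(["chrom", "start"]).reset_index(drop=True)
    return placed, genome, bed, vcf_lines, truth


def write_genome_fixture(outdir, genome, bed, vcf_lines, truth) -> dict[str, str]:
    """Write genome FASTA, BED, VCF and ground-truth JSON; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "bed": os.path.join(outdir, "trna_genes.bed"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "truth": os.path.join(outdir, "ground_truth.json"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")
    bed.to_csv(paths["bed"], sep="\t", header=False, index=False)
    with open(paths["vcf"], "w") as fh:
        fh.write("\n".join(vcf_lines) + "\n")
    truth.to_json(paths["truth"])
    return paths


def read_trna_bed(bed_path, genome_path=None,
                  sequences: Optional[dict[str, str]] = None) -> list[TRNAGene]:
    """Load tRNA genes from BED + genome (FASTA path or chrom->DNA dict)."""
    if sequences is None:
        from Bio import SeqIO

        sequences = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome_path), "fasta")
        }
    genes = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split()[:6]
            start, end = int(start), int(end)
            dna = sequences[chrom][start:end]
            if strand == "-":
                dna = dna.translate(_DNA_COMPLEMENT)[::-1]
            genes.append(TRNAGene(
                gene_id=name, sequence=dna,
                structure=TEMPLATE_STRUCTURE if end - start == len(
                    TEMPLATE_STRUCTURE) else None,
                location=GenomicInterval(chrom, start, end, strand),
            ))
    return genes


# --- expression time courses -------------------------------------------------

BACKGROUND_THR_SHARES = {"ACU": 0.35, "ACC": 0.25, "ACA": 0.25, "ACG": 0.15}
DEFAULT_TIMEPOINTS = ("t04", "t11", "t16", "t26", "t40")  # minutes after shift

_NON_THR_CODONS = [
    c for c in STANDARD_CODE.sense_codons if STANDARD_CODE[c] != "T"
]


def gen_expression_timecourse(
    n_genes: int = 200,
    induced_set_size: int = 25,
    codon_enrichment: float = 2.0,
    focal_codon: str = "ACG",
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    noise_sd: float = 0.0,
    induced_lfc: float = 4.0,
    n_thr_per_gene: int = 60,
    n_codons_per_gene: int = 300,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, GroundTruth]:
    """Generate CDS sequences and a log2FC time course with known demand.

    Induced genes carry the focal codon at ``codon_enrichment`` times the
    background share within its synonymous family (other family members
    scaled down); their log2FC is elevated by ``induced_lfc`` with Gaussian
    noise of ``noise_sd``.  With zero noise the demand ratio recovers the
    enrichment up to integer rounding of codon counts.
    """
    focal_codon = normalize_rna(focal_codon)
    if focal_codon not in BACKGROUND_THR_SHARES:
        raise ValueError("focal codon must be a Thr codon in this generator")
    base_share = BACKGROUND_THR_SHARES[focal_codon]
    if codon_enrichment * base_share > 1:
        raise ValueError("enrichment pushes the focal share above 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{k + 1:04d}" for k in range(n_genes)]
    induced = sorted(rng.choice(gene_ids, size=induced_set_size, replace=False))
    induced_set = set(induced)

    cds: dict[str, str] = {}
    for gid in gene_ids:
        share = base_share * (codon_enrichment if gid in induced_set else 1.0)
        n_focal = round(share * n_thr_per_gene)
        others = [c for c in BACKGROUND_THR_SHARES if c != focal_codon]
        other_w = np.array([BACKGROUND_THR_SHARES[c] for c in others])
        other_counts = _largest_remainder(
            other_w / other_w.sum(), n_thr_per_gene - n_focal
        )
        codons = [focal_codon] * n_focal
        for c, n in zip(others, other_counts):
            codons += [c] * n
        n_rest = n_codons_per_gene - len(codons)
        codons += list(rng.choice(_NON_THR_CODONS, size=n_rest))
        rng.shuffle(codons)
        cds[gid] = "".join(codons).replace("U", "T")

    lfc = pd.DataFrame(index=gene_ids, columns=list(timepoints), dtype=float)
    for tp in timepoints:
        base = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else \
            np.zeros(n_genes)
        lfc[tp] = base + np.where(
            [g in induced_set for g in gene_ids], induced_lfc, 0.0
        )
    truth = GroundTruth(
        induced_genes=list(induced),
        codon_enrichment=codon_enrichment,
        focal_codon=focal_codon,
    )
    return cds, lfc, truth


def _largest_remainder(weights: np.ndarray, total: int) -> list[int]:
    raw = weights * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:rem]:
        counts[i] += 1
    return counts.tolist()


# --- peptide tables ----------------------------------------------------------

_AA_POOL = list("ACDEFGHIKLMNPQRSVWY")  # T added separately


def gen_peptide_table(
    strains: Sequence[str] = ("control", "host", "switch1", "switch2"),
    n_replicates: int = 3,
    n_peptides: int = 600,
    thr_fraction: float = 0.5,
    substitution_rates: Optional[dict[str, float]] = None,
    missing_rate: float = 0.1,
    n_differential: int = 0,
    differential_strain: Optional[str] = None,
    differential_effect: float = 1.2,
    thr_downshift: Optional[dict[str, float]] = None,
    replicate_sd: float = 0.3,
    seed: int = 0,
):
    """Generate a peptide quantification table with planted truth.

    Returns (PeptideQuantTable, GroundTruth).  Intensities are log-normal
    (log2 means ~ Normal(25, 2), replicate noise ``replicate_sd``);
    missingness is intensity-dependent (logistic in log2 intensity, overall
    rate ~= ``missing_rate``) so detection-limit imputation is exercised.
    ``substitution_rates`` plants T>K / T>M variant observations per strain
    at the stated fraction of observations.  ``n_differential`` peptides
    get ``differential_effect`` added in ``differential_strain``.
    ``thr_downshift`` lowers Thr-peptide intensities per strain (for the
    distribution-shift test).
    """
    from .proteome import PeptideQuantTable

    rng = np.random.default_rng(seed)
    substitution_rates = substitution_rates or {}
    thr_downshift = thr_downshift or {}
    samples = [f"{s}_r{r + 1}" for s in strains for r in range(n_replicates)]
    groups = pd.Series(
        [s for s in strains for _ in range(n_replicates)], index=samples
    )

    n_thr = int(round(thr_fraction * n_peptides))
    rows_meta = []
    for k in range(n_peptides):
        has_thr = k < n_thr
        length = int(rng.integers(8, 15))
        letters = list(rng.choice(_AA_POOL, size=length))
        site = -1
        if has_thr:
            site = int(rng.integers(length))
            letters[site] = "T"
        rows_meta.append({
            "sequence": "".join(letters),
            "protein": f"P{k // 3 + 1:04d}",   # ~3 peptides per protein
            "variant_class": "base",
            "site": site,
        })

    base_mu = rng.normal(25.0, 2.0, size=n_peptides)
    diff_idx = []
    if n_differential:
        if differential_strain is None:
            raise ValueError("differential set needs a target strain")
        diff_idx = sorted(rng.choice(n_peptides, size=n_differential,
                                     replace=False).tolist())
    diff_set = set(diff_idx)

    values = np.empty((n_peptides, len(samples)))
    for j, sample in enumerate(samples):
        strain = groups[sample]
        mu = base_mu.copy()
        if strain == differential_strain:
            for i in diff_set:
                mu[i] = mu[i] + differential_effect
        shift = thr_downshift.get(strain, 0.0)
        if shift:
            mu[:n_thr] = mu[:n_thr] - shift
        values[:, j] = rng.normal(mu, replicate_sd)

    # substituted variant rows: observations only in the planted strain
    sub_meta = []
    sub_rows = []
    truth_rates = {}
    n_base_obs_per_strain = n_thr * n_replicates  # Thr-containing base obs
    strain_cols = {s: [j for j, smp in enumerate(samples) if groups[smp] == s]
                   for s in strains}
    for strain, rate in substitution_rates.items():
        truth_rates[strain] = {}
        for sub, repl_aa in (("T>K", "K"), ("T>M", "M")):
            if rate <= 0:
                truth_rates[strain][sub] = 0.0
                continue
            # per-type target: fraction f means n_sub = f/(1-f) * n_base;
            # observations are spread over rows so small rates resolve
            n_sub_obs = int(round(rate / (1 - rate) * n_base_obs_per_strain))
            n_rows = int(np.ceil(n_sub_obs / n_replicates))
            picks = rng.choice(n_thr, size=n_rows, replace=False)
            remaining = n_sub_obs
            for i in picks:
                parent = rows_meta[i]
                seq = list(parent["sequence"])
                seq[parent["site"]] = repl_aa
                sub_meta.append({
                    "sequence": "".join(seq),
                    "protein": parent["protein"],
                    "variant_class": sub,
                    "site": parent["site"],
                })
                row = np.full(len(samples), np.nan)
                n_here = min(n_replicates, remaining)
                for j in strain_cols[strain][:n_here]:
                    row[j] = rng.normal(base_mu[i] - 3.0, replicate_sd)
                remaining -= n_here
                sub_rows.append(row)
            truth_rates[strain][sub] = (
                n_sub_obs / (n_sub_obs + n_base_obs_per_strain)
            )

    all_meta = rows_meta + sub_meta
    all_values = np.vstack([values] + [np.array(sub_rows)]) if sub_rows else values

    # intensity-dependent missingness on base rows only (logistic in log2)
    if missing_rate > 0:
        flat = values.ravel()
        x0 = np.quantile(flat, missing_rate)
        w = 0.8
        p_missing = 1.0 / (1.0 + np.exp((values - x0) / w))
        p_missing *= missing_rate / max(p_missing.mean(), 1e-12)
        drop = rng.random(values.shape) < np.clip(p_missing, 0, 0.95)
        all_values = all_values.copy()
        all_values[: n_peptides][drop] = np.nan

    index = pd.RangeIndex(len(all_meta))
    table = PeptideQuantTable(
        values=pd.DataFrame(all_values, index=index, columns=samples),
        meta=pd.DataFrame(all_meta, index=index),
        groups=groups,
    )
    truth = GroundTruth(
        substitution_rates=truth_rates,
        differential_proteins=[rows_meta[i]["protein"] for i in diff_idx],
        differential_rows=diff_idx,
        differential_effect=differential_effect if n_differential else None,
        thr_downshift=dict(thr_downshift),
    )
    return table, truth
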