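"""Scan multi-sample variant sets for hits on tRNA anticodon bases.

Given tRNA gene annotations with genomic locations and a VCF, report every
single-nucleotide substitution falling on an anticodon base, with the
ref/alt anticodon, the decoded amino-acid change, and the carrier samples —
the machinery for screening large strain panels for naturally occurring
anticodon switches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from cyvcf2 import VCF

from .genetics import (
    AA_ONE_TO_THREE,
    GeneticCode,
    GenomicInterval,
    STANDARD_CODE,
    TRNAGene,
    decode_anticodon,
    locate_anticodon,
    normalize_rna,
)

logger = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AnticodonVariant:
    """A variant on an anticodon base of a tRNA gene."""

    gene_id: str
    chrom: str
    genomic_pos: int        # 1-based, VCF convention
    transcript_pos: int     # 1-based c. coordinate
    anticodon_offset: int   # 1, 2 or 3 within the anticodon
    ref_anticodon: str
    alt_anticodon: str
    ref_aa: str
    alt_aa: str
    carrier_samples: tuple[str, ...]

    @property
    def synonymous(self) -> bool:
        """Anticodon changed but decoded amino acid did not."""
        return self.ref_aa == self.alt_aa


@dataclass
class ScanLog:
    """Records skipped: indels, chromosome mismatches."""

    skipped_indels: list[tuple[str, int]] = field(default_factory=list)
    unmatched_chroms: set[str] = field(default_factory=set)


def anticodon_genomic_coordinates(
    gene: TRNAGene, span: tuple[int, int, int]
) -> tuple[int, int, int]:
    """Map the anticodon's 0-based transcript indices to 1-based genomic
    positions, in anticodon (5'->3' transcript) order.

    On the minus strand transcript order maps to descending genomic
    coordinates.  Intron-containing genes are not supported.
    """
    loc = gene.location
    if loc is None:
        raise ValueError(f"{gene.gene_id}: no genomic location")
    if loc.strand == "+":
        return tuple(loc.start + t + 1 for t in span)  # type: ignore[return-value]
    return tuple(loc.end - t for t in span)  # type: ignore[return-value]


def _transcript_index(loc: GenomicInterval, genomic_pos: int) -> int:
    """0-based transcript index of a 1-based genomic position inside loc."""
    if loc.strand == "+":
        return genomic_pos - 1 - loc.start
    return loc.end - genomic_pos


def scan_variants(
    vcf_path,
    genes: Sequence[TRNAGene],
    code: GeneticCode = STANDARD_CODE,
    min_allele_count: int = 1,
    include_uncarried: bool = False,
    scan_log: Optional[ScanLog] = None,
) -> list[AnticodonVariant]:
    """Report VCF substitutions that fall on anticodon bases.

    Multi-allelic records are decomposed per alternate allele.  A sample
    carries an event when its genotype contains at least ``min_allele_count``
    copies of that alternate allele (heterozygous carriers count by
    default).  Indels are logged and skipped; variants outside anticodon
    spans are ignored.
    """
    log = scan_log if scan_log is not None else ScanLog()
    by_pos: dict[tuple[str, int], list[tuple[TRNAGene, int, tuple[int, ...]]]] = {}
    known_chroms: set[str] = set()
    for gene in genes:
        if gene.location is None:
            raise ValueError(f"{gene.gene_id}: annotation lacks location")
        known_chroms.add(gene.location.chrom)
        call = locate_anticodon(gene, code)
        gpos = anticodon_genomic_coordinates(gene, call.span)
        for offset, (g, t) in enumerate(zip(gpos, call.span), start=1):
            by_pos.setdefault((gene.location.chrom, g), []).append(
                (gene, offset, call.span)
            )

    events: list[AnticodonVariant] = []
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    for rec in vcf:
        if rec.CHROM not in known_chroms:
            if rec.CHROM not in log.unmatched_chroms:
                logger.warning("chromosome %s absent from annotation", rec.CHROM)
                log.unmatched_chroms.add(rec.CHROM)
            continue
        hits = by_pos.get((rec.CHROM, rec.POS))
        if hits is None:
            continue
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            if len(rec.REF) != 1 or len(alt) != 1 or alt in ("*", "<NON_REF>"):
                log.skipped_indels.append((rec.CHROM, rec.POS))
                continue
            carriers = _carriers(rec, samples, alt_idx, min_allele_count)
            if not carriers and not include_uncarried:
                continue
            for gene, offset, span in hits:
                ev = _make_event(
                    gene, span, offset, rec.CHROM, rec.POS, rec.REF, alt,
                    carriers, code,
                )
                if ev is not None:
                    events.append(ev)
    events.sort(key=lambda e: (e.chrom, e.genomic_pos, e.alt_anticodon, e.gene_id))
    return events


def _carriers(rec, samples, alt_idx: int, min_allele_count: int) -> tuple[str, ...]:
    out = []
    for sample, gt in zip(samples, rec.genotypes):
        alleles = [a for a in gt[:-1] if a >= 0]
        if sum(a == alt_idx for a in alleles) >= min_allele_count:
            out.append(sample)
    return tuple(out)


def _make_event(
    gene: TRNAGene,
    span: tuple[int, int, int],
    offset: int,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    carriers: tuple[str, ...],
    code: GeneticCode,
) -> Optional[AnticodonVariant]:
    loc = gene.location
    t_idx = _transcript_index(loc, pos)
    if loc.strand == "+":
        ref_t, alt_t = ref, alt
    else:
        ref_t = ref.translate(_DNA_COMPLEMENT)
        alt_t = alt.translate(_DNA_COMPLEMENT)
    ref_t = normalize_rna(ref_t)
    alt_t = normalize_rna(alt_t)
    if gene.sequence[t_idx] != ref_t:
        logger.warning(
            "%s: VCF ref %s does not match transcript base %s at c.%d; skipped",
            gene.gene_id, ref, gene.sequence[t_idx], t_idx + 1,
        )
        return None
    ref_ac = "".join(gene.sequence[k] for k in span)
    ac = list(ref_ac)
    ac[offset - 1] = alt_t
    alt_ac = "".join(ac)
    _, ref_aa = decode_anticodon(ref_ac, code)
    _, alt_aa = decode_anticodon(alt_ac, code)
    return AnticodonVariant(
        gene_id=gene.gene_id,
        chrom=chrom,
        genomic_pos=pos,
        transcript_pos=t_idx + 1,
        anticodon_offset=offset,
        ref_anticodon=ref_ac,
        alt_anticodon=alt_ac,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        carrier_samples=carriers,
    )


# --- reporting ---------------------------------------------------------------

_YEAST_NAME_RE = re.compile(
    r"^t(?P<aa>[A-Z])\((?P<ac>[ACGTU]{3})\)(?P<suffix>.*)$"
)


def rename_for_anticodon(gene_id: str, alt_anticodon: str, alt_aa: str) -> str:
    """Rewrite a tRNA gene name for a mutated anticodon.

    Yeast systematic names ``tK(CUU)K`` become ``tT(CGU)K``; gtRNAdb names
    ``tRNA-Lys-CTT-1-1`` become ``tRNA-Thr-CGT-1-1``.  Unrecognized names
    gain a ``>`` annotated suffix.
    """
    m = _YEAST_NAME_RE.match(gene_id)
    if m:
        return f"t{alt_aa}({alt_anticodon}){m.group('suffix')}"
    if gene_id.startswith("tRNA-"):
        parts = gene_id.split("-")
        if len(parts) >= 3:
            parts[1] = AA_ONE_TO_THREE.get(alt_aa, alt_aa)
            parts[2] = alt_anticodon.replace("U", "T")
            return "-".join(parts)
    return f"{gene_id}>{alt_aa}({alt_anticodon})"


def tabulate_anticodon_switches(events: Sequence[AnticodonVariant]) -> list[dict]:
    """Report rows: original tRNA, mutated name, new amino acid, strains.

    Rows are grouped per (gene, alt anticodon) with carrier strains joined,
    ordered by (chromosome, position).
    """
    grouped: dict[tuple, AnticodonVariant] = {}
    carriers: dict[tuple, list[str]] = {}
    for ev in events:
        key = (ev.chrom, ev.genomic_pos, ev.gene_id, ev.alt_anticodon)
        grouped.setdefault(key, ev)
        carriers.setdefault(key, [])
        for c in ev.carrier_samples:
            if c not in carriers[key]:
                carriers[key].append(c)
    rows = []
    for key in sorted(grouped, key=lambda k: (k[0], k[1], k[2], k[3])):
        ev = grouped[key]
        rows.append({
            "original_trna": ev.gene_id,
            "original_aa": AA_ONE_TO_THREE.get(ev.ref_aa, ev.ref_aa),
            "mutated_trna": rename_for_anticodon(
                ev.gene_id, ev.alt_anticodon, ev.alt_aa
            ),
            "new_aa": AA_ONE_TO_THREE.get(ev.alt_aa, ev.alt_aa),
            "anticodon_change": f"{ev.ref_anticodon}>{ev.alt_anticodon}",
            "synonymous": ev.synonymous,
            "strains": ",".join(sorted(carriers[key])),
        })
    return rows
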