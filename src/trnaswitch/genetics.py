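"""Core tRNA domain model.

The genetic code, tRNA gene records with gtRNAdb-style headers, cloverleaf
secondary-structure parsing, anticodon localization/decoding, and application
of point mutations in transcript (``c.``) coordinates.

All sequence handling is in the RNA alphabet; DNA input (``T``) is normalized
to ``U`` on ingest.  The standard nuclear genetic code is the only table
shipped; alternative codes can be supplied to any function that takes a
:class:`GeneticCode`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_rna_by_id

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

STOP = "*"

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "iMet": "M", "eMet": "M", "SeC": "U", "Sup": STOP, "Und": "X",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items() if len(k) == 3}


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside the RNA alphabet."""


class StructureParseError(ValueError):
    """Dot-bracket string is unbalanced or inconsistent with the sequence."""


class PseudoknotError(StructureParseError):
    """Base pairs cross, which the cloverleaf model does not allow."""


class AmbiguousAnticodonError(ValueError):
    """The anticodon loop is too short to carry a 3-nt anticodon."""


class AnticodonInconsistencyError(ValueError):
    """Header-declared anticodon absent from the gene sequence."""


class ReferenceMismatchError(ValueError):
    """A mutation's stated reference base does not match the sequence."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject anything non-ACGU."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise InvalidAlphabetError(f"non-RNA characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _standard_code_table() -> dict[str, str]:
    table = dict(unambiguous_rna_by_id[1].forward_table)
    for stop in unambiguous_rna_by_id[1].stop_codons:
        table[stop] = STOP
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table mapping RNA codons to one-letter amino acids.

    ``STOP`` codons map to ``"*"``.  The shipped default is the standard
    nuclear code: 61 sense codons and 3 stops.
    """

    table: dict[str, str] = field(default_factory=_standard_code_table)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"codon table has {len(self.table)} entries, need 64")

    @property
    def stop_set(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa != STOP)

    def __getitem__(self, codon: str) -> str:
        return self.table[normalize_rna(codon)]


STANDARD_CODE = GeneticCode()


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TRNAGene:
    """A tRNA gene: sequence, optional dot-bracket structure and location.

    ``gene_id`` follows the gtRNAdb dialect (``tRNA-Thr-CGT-1-1``); the
    isotype and anticodon are parsed from the second and third dash-separated
    tokens when present.
    """

    gene_id: str
    sequence: str
    structure: Optional[str] = None
    location: Optional[GenomicInterval] = None
    species_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not 60 <= len(self.sequence) <= 100:
            raise ValueError(
                f"{self.gene_id}: tRNA length {len(self.sequence)} outside [60, 100]"
            )
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise StructureParseError(
                f"{self.gene_id}: structure length != sequence length"
            )
        if self.location is not None and len(self.location) != len(self.sequence):
            raise ValueError(f"{self.gene_id}: location span != sequence length")

    @property
    def annotated_isotype(self) -> Optional[str]:
        """One-letter amino acid parsed from the gene_id, or None."""
        parsed = parse_gtrnadb_id(self.gene_id)
        if parsed is None:
            return None
        return AA_THREE_TO_ONE.get(parsed[0])

    @property
    def annotated_anticodon(self) -> Optional[str]:
        parsed = parse_gtrnadb_id(self.gene_id)
        if parsed is None:
            return None
        try:
            return normalize_rna(parsed[1])
        except InvalidAlphabetError:
            return None


_GTRNADB_RE = re.compile(
    r"tRNA-(?P<iso>[A-Za-z]{3,4})-(?P<ac>[ACGTUacgtu]{3})(?:-|$)"
)


def parse_gtrnadb_id(gene_id: str) -> Optional[tuple[str, str]]:
    """Extract (isotype token, anticodon token) from a gtRNAdb-style id.

    Returns None for headers that do not follow the dialect, in which case
    callers fall back to structure-based anticodon localization.
    """
    m = _GTRNADB_RE.search(gene_id)
    if m is None:
        return None
    return m.group("iso"), m.group("ac")


@dataclass(frozen=True)
class CloverleafStructure:
    """Nested base pairs plus derived hairpin loops and helices.

    ``pairs`` are 0-based (i, j) with i < j; ``hairpin_loops`` are
    (start, end) half-open spans of unpaired loop bases in 5'->3' order;
    ``helices`` are maximal runs of stacked pairs.
    """

    pairs: tuple[tuple[int, int], ...]
    hairpin_loops: tuple[tuple[int, int], ...]
    helices: tuple[tuple[tuple[int, int], ...], ...]
    length: int

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def parse_cloverleaf(sequence: str, dotbracket: str) -> CloverleafStructure:
    """Parse a dot-bracket string into pairs, helices and hairpin loops.

    Only ``(``, ``)`` and ``.`` are accepted: crossing pairs cannot be
    expressed, so any well-formed input is pseudoknot-free by construction.
    Brackets of additional types (pseudoknot notation) raise
    :class:`PseudoknotError`.
    """
    sequence = normalize_rna(sequence)
    if len(sequence) != len(dotbracket):
        raise StructureParseError("sequence and structure lengths differ")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unmatched ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch == ".":
            continue
        elif ch in "[]{}<>":
            raise PseudoknotError(f"pseudoknot bracket {ch!r} at position {idx}")
        else:
            raise StructureParseError(f"invalid structure character {ch!r}")
    if stack:
        raise StructureParseError(f"unmatched '(' at position {stack[-1]}")
    pairs.sort()
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    helices: list[tuple[tuple[int, int], ...]] = []
    used: set[tuple[int, int]] = set()
    for i, j in pairs:
        if (i, j) in used:
            continue
        run = [(i, j)]
        used.add((i, j))
        a, b = i + 1, j - 1
        while partner.get(a) == b and a < b:
            run.append((a, b))
            used.add((a, b))
            a, b = a + 1, b - 1
        helices.append(tuple(run))

    hairpins: list[tuple[int, int]] = []
    for i, j in pairs:
        if all(k not in partner for k in range(i + 1, j)):
            hairpins.append((i + 1, j))
    hairpins.sort()
    return CloverleafStructure(
        pairs=tuple(pairs),
        hairpin_loops=tuple(hairpins),
        helices=tuple(helices),
        length=len(sequence),
    )


@dataclass(frozen=True)
class AnticodonCall:
    """A located anticodon: the 34-36 triplet, its codon, and decoding."""

    gene_id: str
    anticodon: str
    span: tuple[int, int, int]  # 0-based indices in the gene sequence
    codon: str
    decoded_aa: str

    @property
    def decodes_stop(self) -> bool:
        return self.decoded_aa == STOP


def decode_anticodon(
    anticodon: str, code: GeneticCode = STANDARD_CODE
) -> tuple[str, str]:
    """Return (codon, amino acid) read by an anticodon.

    The codon is the reverse complement of the anticodon (antiparallel
    pairing, wobble base first in the anticodon).  Anticodons whose codon is
    a stop decode to ``"*"``; callers decide whether that is an error.
    """
    ac = normalize_rna(anticodon)
    if len(ac) != 3:
        raise ValueError(f"anticodon must be 3 nt, got {len(ac)}")
    codon = reverse_complement(ac)
    return codon, code[codon]


def locate_anticodon(
    gene: TRNAGene, code: GeneticCode = STANDARD_CODE
) -> AnticodonCall:
    """Locate and decode the anticodon of a tRNA gene.

    With a structure, the anticodon is the middle three bases of the second
    hairpin loop in 5'->3' order (the anticodon loop of the cloverleaf): for
    the canonical 7-nt loop these are loop positions 3-5, i.e. positions
    34-36 of the standard numbering.  A loop-based rule is used instead of a
    fixed offset because tRNA gene lengths vary.  Without a structure, the
    anticodon is parsed from the gtRNAdb-style header and verified to occur
    in the sequence.
    """
    if gene.structure is not None:
        cloverleaf = parse_cloverleaf(gene.sequence, gene.structure)
        if len(cloverleaf.hairpin_loops) < 2:
            raise AmbiguousAnticodonError(
                f"{gene.gene_id}: fewer than 2 hairpin loops"
            )
        start, end = cloverleaf.hairpin_loops[1]
        loop_len = end - start
        if loop_len < 5:
            raise AmbiguousAnticodonError(
                f"{gene.gene_id}: anticodon loop of {loop_len} nt is too short"
            )
        mid = start + (loop_len - 3) // 2
        span = (mid, mid + 1, mid + 2)
    else:
        header_ac = gene.annotated_anticodon
        if header_ac is None:
            raise AnticodonInconsistencyError(
                f"{gene.gene_id}: no structure and unparseable header"
            )
        pos = gene.sequence.find(header_ac)
        if pos < 0:
            raise AnticodonInconsistencyError(
                f"{gene.gene_id}: header anticodon {header_ac} not in sequence"
            )
        span = (pos, pos + 1, pos + 2)
    anticodon = "".join(gene.sequence[k] for k in span)
    codon, aa = decode_anticodon(anticodon, code)
    return AnticodonCall(
        gene_id=gene.gene_id, anticodon=anticodon, span=span, codon=codon,
        decoded_aa=aa,
    )


_HGVS_RE = re.compile(
    r"^c\.(?P<pos>\d+)\s*(?P<ref>[ACGTUacgtu])>(?P<alt>[ACGTUacgtu])$"
)

EFFECT_ANTICODON = "anticodon_change"
EFFECT_STEM = "stem_change"
EFFECT_OTHER = "other"


def apply_point_mutation(
    gene: TRNAGene, change: str, code: GeneticCode = STANDARD_CODE
) -> tuple[TRNAGene, AnticodonCall, AnticodonCall, str]:
    """Apply an HGVS-like substitution (``c.35 T>G``) to a tRNA gene.

    Returns (mutated gene, anticodon call before, call after, effect), where
    effect is ``anticodon_change`` if the mutated position lies in the
    anticodon triplet, ``stem_change`` if it lies in a helix of the
    structure, and ``other`` otherwise.
    """
    m = _HGVS_RE.match(change.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation {change!r}")
    pos = int(m.group("pos"))  # 1-based transcript coordinate
    ref = normalize_rna(m.group("ref"))
    alt = normalize_rna(m.group("alt"))
    if not 1 <= pos <= len(gene.sequence):
        raise IndexError(f"position {pos} outside 1..{len(gene.sequence)}")
    idx = pos - 1
    if gene.sequence[idx] != ref:
        raise ReferenceMismatchError(
            f"{gene.gene_id} c.{pos}: reference is {gene.sequence[idx]}, "
            f"mutation states {ref}"
        )
    before = locate_anticodon(gene, code)
    new_seq = gene.sequence[:idx] + alt + gene.sequence[idx + 1:]
    mutated = replace(gene, sequence=new_seq)
    after = locate_anticodon(mutated, code)
    if idx in before.span:
        effect = EFFECT_ANTICODON
    elif gene.structure is not None and _in_helix(gene, idx):
        effect = EFFECT_STEM
    else:
        effect = EFFECT_OTHER
    return mutated, before, after, effect


def _in_helix(gene: TRNAGene, idx: int) -> bool:
    cloverleaf = parse_cloverleaf(gene.sequence, gene.structure)
    return idx in cloverleaf.partner()


# --- FASTA + sidecar dot-bracket I/O -----------------------------------------

def read_trna_fasta(
    fasta_path, structure_path=None, species_tag: str = ""
) -> list[TRNAGene]:
    """Read tRNA genes from FASTA, optionally with a sidecar structure file.

    The sidecar has one dot-bracket line per FASTA record, in the same order.
    Headers are preserved verbatim as gene ids (first whitespace token).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    structures: Sequence[Optional[str]]
    if structure_path is not None:
        with open(structure_path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if len(lines) != len(records):
            raise StructureParseError(
                f"{len(lines)} structures for {len(records)} records"
            )
        structures = lines
    else:
        structures = [None] * len(records)
    return [
        TRNAGene(
            gene_id=rec.id, sequence=str(rec.seq), structure=st,
            species_tag=species_tag,
        )
        for rec, st in zip(records, structures)
    ]


def write_trna_fasta(genes: Iterable[TRNAGene], fasta_path, structure_path=None):
    """Write genes to FASTA (+ optional sidecar dot-bracket file)."""
    genes = list(genes)
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")
    if structure_path is not None:
        with open(structure_path, "w") as fh:
            for g in genes:
                if g.structure is None:
                    raise ValueError(f"{g.gene_id} has no structure to write")
                fh.write(g.structure + "\n")
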