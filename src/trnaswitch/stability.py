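"""Temperature-dependent folding stability of a fixed tRNA secondary structure.

A nearest-neighbor dH/dS model evaluates the Gibbs energy of a *given*
cloverleaf at any temperature via dG(T) = sum(dH) - T * sum(dS) over helix
stacks and loop penalties.  This is not a folding engine: the structure is
fixed and only its energy is scored, which is what comparing variants of the
same tRNA requires.  The shipped parameter table carries Turner-style
magnitudes and commits to sign and ordering contracts (a destabilizing
mutation raises dG at every temperature), not to literal published energies.
Dangling ends and coaxial stacking are omitted.

Destabilization beyond the rapid-tRNA-decay (RTD) threshold — an increase in
dG of folding larger than 2.65 kcal/mol over the reference allele — flags a
variant as a likely RTD substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

from .genetics import CloverleafStructure, normalize_rna, parse_cloverleaf

KELVIN_OFFSET = 273.15
T37_K = 310.15
GAS_CONSTANT = 0.0019872  # kcal / (mol K)

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

RTD_THRESHOLD = 2.65  # kcal/mol, dG increase above which RTD degrades the tRNA

DEFAULT_TEMPERATURES = (30.0, 35.0, 42.0)


class ModelIncompletenessError(KeyError):
    """A stack doublet has no parameter entry."""


def _canonical_stack_key(a: str, b: str, c: str, d: str) -> str:
    k1 = f"{a}{b}/{c}{d}"
    k2 = f"{c}{d}/{a}{b}"
    return min(k1, k2)


@dataclass(frozen=True)
class EnergyModel:
    """dH/dS nearest-neighbor parameters (kcal/mol and kcal/mol/K)."""

    stack_params: dict[str, tuple[float, float]]
    hairpin_params: dict[int, tuple[float, float]]
    bulge_params: dict[int, tuple[float, float]]
    internal_params: dict[int, tuple[float, float]]
    multibranch_params: dict[str, tuple[float, float]]

    def stack(self, a: str, b: str, c: str, d: str) -> tuple[float, float]:
        key = _canonical_stack_key(a, b, c, d)
        try:
            return self.stack_params[key]
        except KeyError:
            raise ModelIncompletenessError(
                f"no stack parameters for doublet {key}"
            ) from None

    def _loop(self, table: dict[int, tuple[float, float]], size: int,
              min_size: int) -> tuple[float, float]:
        size = max(size, min_size)
        if size in table:
            return table[size]
        # Jacobson-Stockmayer entropic extrapolation beyond the table
        largest = max(table)
        dh, ds = table[largest]
        extra_dg37 = 1.75 * GAS_CONSTANT * T37_K * math.log(size / largest)
        return dh, ds - extra_dg37 / T37_K

    def hairpin(self, size: int) -> tuple[float, float]:
        return self._loop(self.hairpin_params, size, 3)

    def bulge(self, size: int) -> tuple[float, float]:
        return self._loop(self.bulge_params, size, 1)

    def internal(self, size: int) -> tuple[float, float]:
        return self._loop(self.internal_params, size, 2)


def load_energy_model(path=None) -> EnergyModel:
    """Load the packaged parameter table, or a user override.

    The table stores dH and dG37; dS is derived as (dH - dG37) / 310.15 so
    that dG(310.15 K) reproduces the tabulated dG37 exactly.
    """
    if path is None:
        source = resources.files("trnaswitch.data") / "nn_energy_params.tsv"
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    tables: dict[str, dict] = {
        "stack": {}, "hairpin": {}, "bulge": {}, "internal": {},
        "multibranch": {},
    }
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, dh_s, dg37_s = line.split("\t")
        dh, dg37 = float(dh_s), float(dg37_s)
        ds = (dh - dg37) / T37_K
        if kind == "stack":
            tables[kind][key] = (dh, ds)
        elif kind in ("hairpin", "bulge", "internal"):
            tables[kind][int(key)] = (dh, ds)
        elif kind == "multibranch":
            tables[kind][key] = (dh, ds)
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
    return EnergyModel(
        stack_params=tables["stack"],
        hairpin_params=tables["hairpin"],
        bulge_params=tables["bulge"],
        internal_params=tables["internal"],
        multibranch_params=tables["multibranch"],
    )


_DEFAULT_MODEL: Optional[EnergyModel] = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


def _canonical_pairs(sequence: str, pairs) -> list[tuple[int, int]]:
    """Drop pairs that are not Watson-Crick or G.U.

    A dissolved pair's bases become unpaired, enlarging the surrounding
    loop — this is how a stem mismatch (e.g. U.C) is represented.
    """
    return [
        (i, j) for i, j in pairs
        if sequence[i] + sequence[j] in CANONICAL_PAIRS
    ]


def _loop_decomposition(
    pairs: Sequence[tuple[int, int]]
) -> list[tuple[tuple[int, int], list[tuple[int, int]]]]:
    """(closing pair, directly nested child pairs) for every pair."""
    pairs = sorted(pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    return [(p, children[p]) for p in pairs]


def dg_fold(
    sequence: str,
    structure: Union[str, CloverleafStructure],
    t_celsius: float,
    model: Optional[EnergyModel] = None,
) -> float:
    """Gibbs energy (kcal/mol) of a fixed structure at a temperature in C.

    Sums dH - T*dS over helix stacks and hairpin / bulge / internal /
    multibranch loop penalties.  Non-canonical pairs are dissolved into the
    surrounding loop before scoring.  A structure with no pairs closes no
    loops and scores 0.
    """
    if model is None:
        model = default_energy_model()
    sequence = normalize_rna(sequence)
    if isinstance(structure, str):
        structure = parse_cloverleaf(sequence, structure)
    pairs = _canonical_pairs(sequence, structure.pairs)
    if not pairs:
        return 0.0
    t_kelvin = t_celsius + KELVIN_OFFSET
    paired = {i for p in pairs for i in p}

    def g(dh_ds: tuple[float, float]) -> float:
        dh, ds = dh_ds
        return dh - t_kelvin * ds

    total = 0.0
    for (i, j), kids in _loop_decomposition(pairs):
        if not kids:
            total += g(model.hairpin(j - i - 1))
            continue
        if len(kids) == 1:
            (k, l), = kids
            left = k - i - 1
            right = j - l - 1
            if left == 0 and right == 0:
                total += g(model.stack(sequence[i], sequence[k],
                                       sequence[l], sequence[j]))
            elif left == 0 or right == 0:
                total += g(model.bulge(left + right))
            else:
                total += g(model.internal(left + right))
            continue
        # multibranch: affine a + b*(branches incl. closing) + c*unpaired
        unpaired = sum(1 for k in range(i + 1, j) if k not in paired)
        a = g(model.multibranch_params["a"])
        b = g(model.multibranch_params["b"])
        c = g(model.multibranch_params["c"])
        total += a + b * (len(kids) + 1) + c * unpaired
    return total


@dataclass(frozen=True)
class StabilityProfile:
    """dG of a variant across temperatures, with ddG against a reference."""

    label: str
    temperatures: tuple[float, ...]      # Celsius
    dg: tuple[float, ...]                # kcal/mol
    ddg: tuple[float, ...]               # variant minus reference
    rtd_flagged: bool


def rtd_flag(ddg_max: float, threshold: float = RTD_THRESHOLD) -> bool:
    """True when the worst destabilization strictly exceeds the threshold."""
    return ddg_max > threshold


def ddg_variants(
    ref_sequence: str,
    variant_sequence: str,
    structure: Union[str, CloverleafStructure],
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    model: Optional[EnergyModel] = None,
    label: str = "variant",
    threshold: float = RTD_THRESHOLD,
) -> StabilityProfile:
    """ddG(T) = dG_variant(T) - dG_ref(T) on a shared structure template.

    Pairs broken by the variant (non-canonical after mutation) are dissolved
    into loops, so a stem mismatch shows up as a positive ddG.  The profile
    is RTD-flagged when ddG at any requested temperature strictly exceeds
    ``threshold`` (default 2.65 kcal/mol).
    """
    if len(ref_sequence) != len(variant_sequence):
        raise ValueError("reference and variant must be equal length")
    dgs = []
    ddgs = []
    for t in temperatures:
        g_ref = dg_fold(ref_sequence, structure, t, model)
        g_var = dg_fold(variant_sequence, structure, t, model)
        dgs.append(g_var)
        ddgs.append(g_var - g_ref)
    return StabilityProfile(
        label=label,
        temperatures=tuple(temperatures),
        dg=tuple(dgs),
        ddg=tuple(ddgs),
        rtd_flagged=rtd_flag(max(ddgs), threshold),
    )


# --- packaged Trt2-like fixtures ---------------------------------------------

# Synthetic stand-ins for the three Trt2 isoforms: a constructed 72-nt
# cloverleaf (not the real TRT2 gene sequence) with the anticodon CGU and an
# anticodon stem in which transcript position 28 pairs with position 40.
# The reference allele carries G28:C40; the destabilized allele has 28 G>U
# (U.C mismatch, pair dissolved); the suppressor additionally has 40 C>A,
# restoring a U:A pair.
SYNTHETIC_TRT2_STRUCTURE = (
    "(((((((..((((.......)))).(((((.......)))))....(((((.......)))))..)))))))"
)
SYNTHETIC_TRT2_REFERENCE = (
    "GGCUCGUAGGCUCGAUUAAGGAGCACGGAGCUCGUAACUCCGAGGUCGUGGUUCGAUUCCACGCAACGAGCC"
)


def synthetic_trt2_variants() -> dict[str, str]:
    """Constructed (synthetic) sequences of the three anticodon-stem alleles.

    Returns a mapping with keys ``reference`` (G28:C40 pair, stable),
    ``stem_mismatch`` (28 G>U, U.C mismatch) and ``suppressor``
    (28 G>U + 40 C>A, U:A pair restored).  These emulate the geometry of the
    S288C / ER18A / OEA28 Trt2 alleles; they are not the natural sequences.
    """
    ref = SYNTHETIC_TRT2_REFERENCE
    mism = ref[:27] + "U" + ref[28:]
    supp = mism[:39] + "A" + mism[40:]
    return {"reference": ref, "stem_mismatch": mism, "suppressor": supp}
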