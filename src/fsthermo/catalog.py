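"""Slippery-sequence variants, codon–anticodon pairing and the signed design matrix.

A −1 programmed ribosomal frameshifting (−1PRF) site is a heptamer
``X XXY YYZ`` (positions numbered 1–7).  Before translocation the P-site and
A-site tRNAs read the 0-frame codons (positions 2–4 and 5–7); after slippage
into the −1 frame they read positions 1–3 and 4–6.  Anticodons are stored
3′→5′ so that element ``k`` pairs with codon position ``k``; a base pair is
written codon·anticodon (mRNA base first).

The free-energy model assigns one variable ΔG_bp to every distinct base-pair
change (e.g. ``P1 A·U→G·U``); the signed design matrix M maps variants to
those variables: entry +1 when the canonical change occurs on frameshifting,
−1 when its reverse occurs, 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "NucleotideRegistry",
    "DEFAULT_REGISTRY",
    "Anticodon",
    "SlipperyHeptamer",
    "MRNAVariant",
    "BasePair",
    "BasePairChange",
    "ChangeVariableRegistry",
    "DesignMatrix",
    "SITE_POSITIONS",
    "LYS_ANTICODON",
    "PHE_ANTICODON",
    "pair_frames",
    "derive_changes",
    "canonicalize",
    "build_design_matrix",
    "matrix_rank",
    "enumerate_invitro_design",
    "invitro_change_registry",
    "tsuchihashi_change_registry",
]

CANONICAL_BASES = ("A", "C", "G", "U")

#: Modified anticodon nucleotides, single-character codes as used in the
#: field's shorthand (mnm5s2U is U34 of E. coli tRNA-Lys, etc.).
MODIFIED_NUCLEOTIDES: Mapping[str, str] = {
    "S": "mnm5s2U",
    "{": "mnm5U",
    ")": "cmnm5U",
    "Q": "queuosine",
    "V": "cmo5U",
    "M": "ac4C",
    "}": "2-lysidine",
}

SITE_POSITIONS = ("P1", "P2", "P3", "A1", "A2", "A3")


class UnknownNucleotideError(KeyError):
    """A base code absent from the nucleotide registry."""


class UnknownVariableError(KeyError):
    """A base-pair change present in neither canonical nor reverse direction."""


class NucleotideRegistry:
    """Registry of valid nucleotide codes (canonical mRNA alphabet + modified)."""

    def __init__(self, extra: Optional[Mapping[str, str]] = None) -> None:
        self._codes: dict[str, str] = {b: b for b in CANONICAL_BASES}
        self._codes.update(MODIFIED_NUCLEOTIDES)
        if extra:
            self._codes.update(extra)

    def __contains__(self, code: str) -> bool:
        return code in self._codes

    def describe(self, code: str) -> str:
        try:
            return self._codes[code]
        except KeyError:
            raise UnknownNucleotideError(f"unknown nucleotide code {code!r}") from None

    def validate(self, code: str) -> str:
        if code not in self._codes:
            raise UnknownNucleotideError(f"unknown nucleotide code {code!r}")
        return code

    def items(self):
        return self._codes.items()


DEFAULT_REGISTRY = NucleotideRegistry()


@dataclass(frozen=True)
class Anticodon:
    """tRNA anticodon written 3′→5′, so ``bases_3to5[k]`` pairs codon position k+1."""

    bases_3to5: tuple[str, str, str]
    trna_name: str = field(default="", compare=False)  # display metadata only

    def __post_init__(self) -> None:
        if len(self.bases_3to5) != 3:
            raise ValueError("anticodon must have exactly three bases")
        for b in self.bases_3to5:
            DEFAULT_REGISTRY.validate(b)

    @classmethod
    def from_string(cls, s: str, trna_name: str = "") -> "Anticodon":
        return cls(tuple(s), trna_name)  # type: ignore[arg-type]

    def __str__(self) -> str:
        return "".join(self.bases_3to5)


#: E. coli tRNA-Lys, single isoacceptor, anticodon 3'UUS5' (S = mnm5s2U at
#: position 34); reads both AAA and AAG.
LYS_ANTICODON = Anticodon(("U", "U", "S"), "tRNA-Lys")
#: E. coli tRNA-Phe, anticodon 3'AAG5'; reads UUU (wobble U·G) and UUC.
PHE_ANTICODON = Anticodon(("A", "A", "G"), "tRNA-Phe")


@dataclass(frozen=True)
class SlipperyHeptamer:
    """Seven mRNA bases, positions 1–7; alphabet restricted to A/C/G/U."""

    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != 7:
            raise ValueError(f"heptamer must have 7 bases, got {self.bases!r}")
        for b in self.bases:
            if b not in CANONICAL_BASES:
                raise UnknownNucleotideError(
                    f"heptamer base {b!r} outside canonical mRNA alphabet"
                )

    def codon(self, start: int) -> str:
        """Codon at 1-based heptamer positions ``start..start+2``."""
        return self.bases[start - 1 : start + 2]

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class MRNAVariant:
    variant_id: str
    heptamer: SlipperyHeptamer
    p_anticodon: Anticodon
    a_anticodon: Anticodon
    fs_experiment: Optional[float] = None
    sigma_experiment: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fs_experiment is not None:
            if not 0.0 <= self.fs_experiment <= 1.0:
                raise ValueError(
                    f"{self.variant_id}: fs_experiment must be a fraction in [0, 1]"
                )
            if self.sigma_experiment is None:
                raise ValueError(
                    f"{self.variant_id}: sigma_experiment required with fs_experiment"
                )
        if self.sigma_experiment is not None and self.sigma_experiment < 0:
            raise ValueError(f"{self.variant_id}: sigma_experiment must be >= 0")


@dataclass(frozen=True)
class BasePair:
    site_position: str
    codon_base: str
    anticodon_base: str

    def __post_init__(self) -> None:
        if self.site_position not in SITE_POSITIONS:
            raise ValueError(f"bad site position {self.site_position!r}")

    def __str__(self) -> str:
        return f"{self.codon_base}·{self.anticodon_base}"


@dataclass(frozen=True)
class BasePairChange:
    """A 0-frame → −1-frame substitution of the pair at one codon position."""

    site_position: str
    from_pair: BasePair
    to_pair: BasePair

    def __post_init__(self) -> None:
        if not (
            self.from_pair.site_position
            == self.to_pair.site_position
            == self.site_position
        ):
            raise ValueError("site positions of from/to pairs must agree")
        if self.from_pair == self.to_pair:
            raise ValueError("identity changes are dropped, not represented")

    @property
    def label(self) -> str:
        return f"{self.site_position} {self.from_pair}→{self.to_pair}"

    def reversed(self) -> "BasePairChange":
        return BasePairChange(self.site_position, self.to_pair, self.from_pair)


def _parse_label(label: str) -> BasePairChange:
    """Parse ``"P1 A·U→G·U"`` (ASCII ``"P1 A.U->G.U"`` accepted)."""
    text = label.replace("->", "→").replace(".", "·")
    try:
        site, rest = text.split(" ", 1)
        frm, to = rest.split("→")
        cf, af = frm.split("·")
        ct, at = to.split("·")
    except ValueError:
        raise ValueError(f"malformed change label {label!r}") from None
    return BasePairChange(
        site, BasePair(site, cf, af), BasePair(site, ct, at)
    )


class ChangeVariableRegistry:
    """Ordered set of canonical change variables.

    A change and its reverse map to the same variable; the reverse direction
    carries sign −1 in the design matrix.
    """

    def __init__(self, labels: Iterable[str]) -> None:
        self._changes: dict[str, BasePairChange] = {}
        for lab in labels:
            change = _parse_label(lab)
            if change.label in self._changes:
                raise ValueError(f"duplicate change variable {change.label!r}")
            self._changes[change.label] = change

    @property
    def labels(self) -> list[str]:
        return list(self._changes)

    def __len__(self) -> int:
        return len(self._changes)

    def __contains__(self, label: str) -> bool:
        return label in self._changes

    def canonicalize(self, change: BasePairChange) -> tuple[str, int]:
        """Return (canonical label, sign) for a change or its reverse."""
        if change.label in self._changes:
            return change.label, +1
        rev = change.reversed()
        if rev.label in self._changes:
            return rev.label, -1
        raise UnknownVariableError(
            f"base-pair change {change.label!r} not in registry "
            f"(neither direction)"
        )


def canonicalize(
    change: BasePairChange, registry: ChangeVariableRegistry
) -> tuple[str, int]:
    return registry.canonicalize(change)


def pair_frames(
    variant: MRNAVariant,
) -> tuple[tuple[BasePair, ...], tuple[BasePair, ...]]:
    """Base pairs at P1..P3, A1..A3 in the 0-frame and the −1-frame.

    0-frame codons sit at heptamer positions 2–4 (P) and 5–7 (A); −1-frame
    codons at 1–3 and 4–6.  Anticodon element k pairs codon position k.
    """
    hept = variant.heptamer

    def pairs(p_start: int, a_start: int) -> tuple[BasePair, ...]:
        out = []
        for site, start, anticodon in (
            ("P", p_start, variant.p_anticodon),
            ("A", a_start, variant.a_anticodon),
        ):
            codon = hept.codon(start)
            for k in range(3):
                out.append(
                    BasePair(f"{site}{k + 1}", codon[k], anticodon.bases_3to5[k])
                )
        return tuple(out)

    return pairs(2, 5), pairs(1, 4)


def derive_changes(variant: MRNAVariant) -> list[BasePairChange]:
    """Base-pair changes on shifting 0-frame → −1-frame (unchanged sites omitted)."""
    zero, minus1 = pair_frames(variant)
    changes = []
    for bp0, bp1 in zip(zero, minus1):
        if bp0 != bp1:
            changes.append(BasePairChange(bp0.site_position, bp0, bp1))
    return changes


@dataclass
class DesignMatrix:
    """Signed incidence matrix M (variants × change variables), entries in {−1,0,+1}."""

    entries: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    variants: list[MRNAVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=int)
        if self.entries.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("design matrix shape does not match labels")
        if not np.isin(self.entries, (-1, 0, 1)).all():
            raise ValueError("design matrix entries must be in {-1, 0, +1}")

    @property
    def n_variants(self) -> int:
        return self.entries.shape[0]

    @property
    def n_variables(self) -> int:
        return self.entries.shape[1]

    def row(self, variant_id: str) -> np.ndarray:
        return self.entries[self.row_labels.index(variant_id)]

    def subset(self, keep: Sequence[int]) -> "DesignMatrix":
        keep = list(keep)
        return DesignMatrix(
            self.entries[keep],
            [self.row_labels[i] for i in keep],
            list(self.col_labels),
            [self.variants[i] for i in keep] if self.variants else [],
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=self.row_labels, columns=self.col_labels)


def matrix_rank(design: DesignMatrix, rtol: float = 1e-8) -> int:
    """Numerical rank by SVD; singular values below ``rtol * s_max`` count as zero."""
    s = np.linalg.svd(design.entries.astype(float), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def build_design_matrix(
    variants: Sequence[MRNAVariant], registry: ChangeVariableRegistry
) -> DesignMatrix:
    """Signed design matrix over the registry's variables, in input order."""
    labels = registry.labels
    col_index = {lab: j for j, lab in enumerate(labels)}
    m = np.zeros((len(variants), len(labels)), dtype=int)
    for i, var in enumerate(variants):
        for change in derive_changes(var):
            lab, sign = registry.canonicalize(change)
            m[i, col_index[lab]] += sign
    return DesignMatrix(m, [v.variant_id for v in variants], labels, list(variants))


# --- shipped designs -------------------------------------------------------

_LYS_CODONS = ("AAA", "AAG")
_PHE_CODONS = ("UUU", "UUC")
_TRNA_PAIRS = (
    ("Lys", "Lys"),
    ("Phe", "Phe"),
    ("Lys", "Phe"),
    ("Phe", "Lys"),
)
_AA_TO_CODONS = {"Lys": _LYS_CODONS, "Phe": _PHE_CODONS}
_AA_TO_ANTICODON = {"Lys": LYS_ANTICODON, "Phe": PHE_ANTICODON}


def variant_id(first: str, codon1: str, codon2: str, p_aa: str, a_aa: str) -> str:
    return f"{first}1 {codon1}4 {codon2}7 / {p_aa}-{a_aa}"


def enumerate_invitro_design() -> list[MRNAVariant]:
    """All 64 dnaX-style slippery variants encoding Lys/Phe codon combinations.

    Cartesian product: 4 tRNA pairs × 4 first-position nucleotides × 2 synonymous
    choices for each slippery codon.  FS values are left unset.
    """
    variants = []
    for (p_aa, a_aa), first, in product(_TRNA_PAIRS, CANONICAL_BASES):
        for codon1, codon2 in product(_AA_TO_CODONS[p_aa], _AA_TO_CODONS[a_aa]):
            hept = SlipperyHeptamer(first + codon1 + codon2)
            variants.append(
                MRNAVariant(
                    variant_id(first, codon1, codon2, p_aa, a_aa),
                    hept,
                    _AA_TO_ANTICODON[p_aa],
                    _AA_TO_ANTICODON[a_aa],
                )
            )
    return variants


#: The 16 canonical change variables spanned by the 64-variant in-vitro design:
#: six first-position changes at each of P1/A1, two wobble-position changes at
#: each of P3/A3.  P2/A2 never change in this design.
INVITRO_VARIABLE_LABELS = tuple(
    f"{site} {change}"
    for site in ("P1", "A1")
    for change in (
        "A·U→C·U",
        "A·U→U·U",
        "A·U→G·U",
        "U·A→A·A",
        "U·A→C·A",
        "U·A→G·A",
    )
) + tuple(
    f"{site} {change}" for site in ("P3", "A3") for change in ("G·S→A·S", "C·G→U·G")
)


def invitro_change_registry() -> ChangeVariableRegistry:
    return ChangeVariableRegistry(INVITRO_VARIABLE_LABELS)


#: The 26 change variables of the in-vivo (Tsuchihashi) catalogue: the larger
#: variant set breaks codon identity, recruiting further tRNAs whose anticodons
#: carry the modified nucleotides S, {, ), Q, V, M, }.
TSUCHIHASHI_VARIABLE_LABELS = (
    "P1 A·U→C·U",
    "P1 A·U→U·U",
    "P1 A·U→G·U",
    "P1 G·C→A·C",
    "P2 A·U→G·U",
    "P2 U·A→A·A",
    "P2 G·C→A·C",
    "P2 C·G→A·G",
    "P3 G·S→A·S",
    "P3 A·}→U·}",
    "P3 A·{→G·{",
    "P3 A·V→C·V",
    "P3 C·Q→A·Q",
    "P3 U·Q→A·Q",
    "P3 A·)→U·)",
    "A1 A·U→U·U",
    "A1 A·U→G·U",
    "A1 A·U→C·U",
    "A1 G·C→A·C",
    "A2 A·U→G·U",
    "A2 U·A→A·A",
    "A3 G·S→A·S",
    "A3 C·Q→A·Q",
    "A3 G·M→U·M",
    "A3 U·Q→A·Q",
    "A3 A·{→G·{",
)


def tsuchihashi_change_registry() -> ChangeVariableRegistry:
    return ChangeVariableRegistry(TSUCHIHASHI_VARIABLE_LABELS)
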