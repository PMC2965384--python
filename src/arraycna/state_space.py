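"""Tumor-state model: the 21 joint copy-number / genotype classes and genotype arithmetic.

Each tumor state pairs an integer tumor copy number with the set of allowable
(tumor, constitutional) genotype combinations.  Constitutional genotypes are
always diploid (AA / AB / BB); the tumor genotype may range from the null
genotype ``-`` (homozygous deletion) up to six allele copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional


class InvalidGenotypeError(ValueError):
    """Raised when a genotype string contains characters other than A/B or '-'."""


@dataclass(frozen=True, order=True)
class Genotype:
    """An unphased genotype: ``b_count`` B alleles out of ``copies`` total copies."""

    b_count: int
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 0 or not (0 <= self.b_count <= self.copies):
            raise InvalidGenotypeError(
                f"invalid genotype (b_count={self.b_count}, copies={self.copies})"
            )

    @property
    def is_null(self) -> bool:
        return self.copies == 0

    @property
    def is_het(self) -> bool:
        return 0 < self.b_count < self.copies

    @property
    def is_hom(self) -> bool:
        """Homozygous: all-A or all-B (the null genotype is not homozygous)."""
        return self.copies > 0 and (self.b_count == 0 or self.b_count == self.copies)

    def swap(self) -> "Genotype":
        """A<->B allele swap."""
        return Genotype(self.copies - self.b_count, self.copies)

    def __str__(self) -> str:
        if self.is_null:
            return "-"
        return "A" * (self.copies - self.b_count) + "B" * self.b_count


def parse_genotype_string(text: str) -> Genotype:
    """Parse an allele string such as ``"AAB"`` (or ``"-"`` for the null genotype)."""
    if text == "-":
        return Genotype(0, 0)
    if not text or any(ch not in "AB" for ch in text):
        raise InvalidGenotypeError(f"invalid genotype string: {text!r}")
    return Genotype(text.count("B"), len(text))


@dataclass(frozen=True)
class GenotypePair:
    """A (constitutional, tumor) genotype combination allowed under some tumor state."""

    normal: Genotype
    tumor: Genotype

    def __post_init__(self) -> None:
        if self.normal.copies != 2:
            raise InvalidGenotypeError("constitutional genotypes must be diploid")

    @property
    def genotype_class(self) -> int:
        """Class index of the constitutional genotype: AA -> 0, AB -> 1, BB -> 2."""
        return self.normal.b_count


    def swap(self) -> "GenotypePair":
        return GenotypePair(self.normal.swap(), self.tumor.swap())

    def __str__(self) -> str:
        return f"({self.tumor}, {self.normal})"


@dataclass(frozen=True)
class TumorState:
    """One of the 21 tumor states: a copy number plus its allowable genotype pairs."""

    id: int
    tumor_copy_number: int
    description: str
    pairs: tuple[GenotypePair, ...]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.tumor.copies != self.tumor_copy_number:
                raise ValueError(
                    f"state {self.id}: pair {p} has tumor copies {p.tumor.copies}, "
                    f"expected {self.tumor_copy_number}"
                )


# Rows as (id, tumor copy number, [(tumor, normal) genotype strings], description).
# The published table contains a handful of typographical inconsistencies which are
# normalized here (and unit-tested):
#   * the "Normal" row (3) lists 4-copy tumor genotypes; its copy-number column and
#     description imply {(AA,AA),(AB,AB),(BB,BB)};
#   * the three 6n rows print one 5-copy "BBBBB" tumor genotype each, normalized to
#     "BBBBBB" so the allele-swap symmetry of the pair set holds;
#   * the "3n..6n germline LOH" rows list copy number 2; the genotype string length
#     (3..6) is taken as authoritative.
_TABLE: list[tuple[int, int, list[tuple[str, str]], str]] = [
    (1, 0, [("-", "AA"), ("-", "AB"), ("-", "BB")], "Homozygous deletion"),
    (2, 1, [("A", "AA"), ("A", "AB"), ("B", "AB"), ("B", "BB")], "Hemizygous deletion"),
    (3, 2, [("AA", "AA"), ("AB", "AB"), ("BB", "BB")], "Normal"),
    (4, 3, [("AAA", "AA"), ("AAB", "AB"), ("ABB", "AB"), ("BBB", "BB")],
     "Single copy duplication"),
    (5, 4, [("AAAA", "AA"), ("AAAB", "AB"), ("ABBB", "AB"), ("BBBB", "BB")],
     "4n monoallelic amplification"),
    (6, 4, [("AAAA", "AA"), ("AABB", "AB"), ("BBBB", "BB")],
     "4n balanced amplification"),
    (7, 5, [("AAAAA", "AA"), ("AAAAB", "AB"), ("ABBBB", "AB"), ("BBBBB", "BB")],
     "5n monoallelic amplification"),
    (8, 5, [("AAAAA", "AA"), ("AAABB", "AB"), ("AABBB", "AB"), ("BBBBB", "BB")],
     "5n unbalanced amplification"),
    (9, 6, [("AAAAAA", "AA"), ("AAAAAB", "AB"), ("ABBBBB", "AB"), ("BBBBBB", "BB")],
     "6n unbalanced amplification"),
    (10, 6, [("AAAAAA", "AA"), ("AAAABB", "AB"), ("AABBBB", "AB"), ("BBBBBB", "BB")],
     "6n unbalanced amplification"),
    (11, 6, [("AAAAAA", "AA"), ("AAABBB", "AB"), ("BBBBBB", "BB")],
     "6n unbalanced amplification"),
    (12, 2, [("AA", "AA"), ("AA", "AB"), ("BB", "AB"), ("BB", "BB")], "2n somatic LOH"),
    (13, 3, [("AAA", "AA"), ("AAA", "AB"), ("BBB", "AB"), ("BBB", "BB")],
     "3n somatic LOH"),
    (14, 4, [("AAAA", "AA"), ("AAAA", "AB"), ("BBBB", "AB"), ("BBBB", "BB")],
     "4n somatic LOH"),
    (15, 5, [("AAAAA", "AA"), ("AAAAA", "AB"), ("BBBBB", "AB"), ("BBBBB", "BB")],
     "5n somatic LOH"),
    (16, 6, [("AAAAAA", "AA"), ("AAAAAA", "AB"), ("BBBBBB", "AB"), ("BBBBBB", "BB")],
     "6n somatic LOH"),
    (17, 2, [("AA", "AA"), ("BB", "BB")], "2n germline LOH"),
    (18, 3, [("AAA", "AA"), ("BBB", "BB")], "3n germline LOH"),
    (19, 4, [("AAAA", "AA"), ("BBBB", "BB")], "4n germline LOH"),
    (20, 5, [("AAAAA", "AA"), ("BBBBB", "BB")], "5n germline LOH"),
    (21, 6, [("AAAAAA", "AA"), ("BBBBBB", "BB")], "6n germline LOH"),
]

NORMAL_STATE_ID = 3

#: States flagged as LOH because single-allele loss removes heterozygosity.
COPY_LOSS_LOH_IDS = frozenset({1, 2})


def build_state_table() -> list[TumorState]:
    """Return the 21 tumor states (deterministic; a fresh list on each call)."""
    states = []
    for sid, cn, raw_pairs, desc in _TABLE:
        pairs = tuple(
            GenotypePair(parse_genotype_string(n), parse_genotype_string(t))
            for t, n in raw_pairs
        )
        states.append(TumorState(id=sid, tumor_copy_number=cn, description=desc,
                                 pairs=pairs))
    return states


def is_loh(state: TumorState) -> bool:
    """Whether a state implies loss of heterozygosity.

    True when every pair with a heterozygous constitutional genotype carries a
    homozygous or null tumor genotype, or when the state admits no heterozygous
    constitution at all (germline LOH).
    """
    het_pairs = [p for p in state.pairs if p.normal.is_het]
    if not het_pairs:
        return True
    return all(p.tumor.is_hom or p.tumor.is_null for p in het_pairs)


def is_copy_loss_loh(state: TumorState) -> bool:
    """Whether the LOH arises from copy loss (homozygous/hemizygous deletion)."""
    return state.id in COPY_LOSS_LOH_IDS


def state_table_tsv(states: Optional[Iterable[TumorState]] = None) -> str:
    """Render the state table as a TSV mirroring the published layout."""
    if states is None:
        states = build_state_table()
    lines = ["state\ttumor_copy_number\tgenotype_pairs\tdescription\tloh\tcopy_loss_loh"]
    for s in states:
        pairs = ", ".join(str(p) for p in s.pairs)
        lines.append(
            f"{s.id}\t{s.tumor_copy_number}\t{pairs}\t{s.description}\t"
            f"{int(is_loh(s))}\t{int(is_copy_loss_loh(s))}"
        )
    return "\n".join(lines) + "\n"
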