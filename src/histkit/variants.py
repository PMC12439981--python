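"""Nomination of histone substitution variants from homolog sequence sets.

The workflow mirrors how evolutionary variant libraries for core histones are
built in practice: collect homolog protein sequences for a histone family,
discard fragments / annotated enzymes / off-length entries, keep homologs
within a divergence ceiling of the human reference, and read off every single
amino-acid substitution the surviving homologs carry.  The resulting singles
are augmented with a full alanine scan plus an R/E/M panel at every lysine,
and a random subset of position-compatible double mutants can be drawn for
combinatorial ("epistatic") libraries.

Positions are 1-based on the reference sequence exactly as supplied; variants
use the compact ``G4D`` notation (wild-type residue, position, alternative).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: description keywords marking non-histone enzymes/chaperones to exclude
DEFAULT_KEYWORD_BLOCKLIST = frozenset(
    {
        "acetyltransferase",
        "methyltransferase",
        "chaperone",
        "deacetylase",
        "demethylase",
        "kinase",
    }
)

_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantError(ValueError):
    """Base class for variant-notation and variant-application errors."""


class VariantSyntaxError(VariantError):
    """The variant string does not match ``<wt><position><alt>``."""


class VariantPositionError(VariantError):
    """The variant position falls outside the reference sequence."""


class VariantMismatchError(VariantError):
    """The stated wild-type residue disagrees with the reference."""


def _check_protein(seq: str) -> None:
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - _CANONICAL_SET
    if bad:
        raise ValueError(f"non-canonical amino-acid letters: {sorted(bad)}")


@dataclass(frozen=True)
class ReferenceHistone:
    """A histone family reference protein (1-based residue coordinates)."""

    family: str
    sequence: str
    accession: str = ""

    def __post_init__(self) -> None:
        _check_protein(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self.sequence):
            raise VariantPositionError(
                f"position {position} outside reference of length {len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class HomologRecord:
    """One homolog protein pulled from a sequence database."""

    id: str
    sequence: str
    description: str = ""
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")


@dataclass(frozen=True, order=True)
class SubstitutionVariant:
    """A single amino-acid substitution in ``G4D`` notation."""

    position: int
    wt_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in _CANONICAL_SET or self.alt_aa not in _CANONICAL_SET:
            raise VariantError(f"non-canonical residue in {self.wt_aa}/{self.alt_aa}")
        if self.wt_aa == self.alt_aa:
            raise VariantError(f"self-substitution {self.wt_aa}{self.position}{self.alt_aa}")
        if self.position < 1:
            raise VariantPositionError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.alt_aa}"


@dataclass
class VariantLibrary:
    """A deduplicated set of substitutions with homolog support counts.

    ``support`` counts the number of *unique* homolog sequences exhibiting a
    variant; ``provenance`` records, per variant, how it entered the library
    (``evolutionary``, ``alanine_scan``, ``lysine_panel`` or ``designed``).
    """

    reference: ReferenceHistone
    variants: set[SubstitutionVariant] = field(default_factory=set)
    support: dict[SubstitutionVariant, int] = field(default_factory=dict)
    provenance: dict[SubstitutionVariant, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.variants:
            ref_aa = self.reference.residue(v.position)
            if v.wt_aa != ref_aa:
                raise VariantMismatchError(
                    f"{v}: reference residue at {v.position} is {ref_aa}"
                )

    def sorted_variants(self) -> list[SubstitutionVariant]:
        return sorted(self.variants)


@dataclass
class DoubleMutantLibrary:
    """A sampled subset of position-compatible pairs of single mutants."""

    singles: list[SubstitutionVariant]
    pairs: list[tuple[SubstitutionVariant, SubstitutionVariant]]
    seed: int


@dataclass
class FilterReport:
    """Counts of homologs removed by each filtering rule."""

    n_input: int = 0
    fragment: int = 0
    keyword: int = 0
    non_canonical: int = 0
    length: int = 0
    divergence: int = 0
    kept: int = 0


def parse_variant_notation(s: str, reference: ReferenceHistone) -> SubstitutionVariant:
    """Parse ``"G4D"`` against a reference, checking the wild-type residue."""
    m = _VARIANT_RE.match(s.strip())
    if m is None:
        raise VariantSyntaxError(f"malformed variant string: {s!r}")
    wt, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    ref_aa = reference.residue(pos)  # raises VariantPositionError out of range
    if wt != ref_aa:
        raise VariantMismatchError(
            f"{s}: reference {reference.family} has {ref_aa} at position {pos}, not {wt}"
        )
    return SubstitutionVariant(position=pos, wt_aa=wt, alt_aa=alt)


def apply_variants(
    reference: ReferenceHistone, variants: set[SubstitutionVariant] | list[SubstitutionVariant]
) -> str:
    """Apply substitutions to the reference, returning the mutant sequence."""
    seq = list(reference.sequence)
    seen: dict[int, SubstitutionVariant] = {}
    for v in variants:
        if v.position in seen:
            raise VariantError(f"conflicting variants at position {v.position}")
        ref_aa = reference.residue(v.position)
        if v.wt_aa != ref_aa:
            raise VariantMismatchError(
                f"{v}: reference residue at {v.position} is {ref_aa}"
            )
        seen[v.position] = v
        seq[v.position - 1] = v.alt_aa
    return "".join(seq)


def fraction_difference(a: str, b: str) -> float:
    """Hamming distance divided by length, for equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    mismatches = sum(x != y for x, y in zip(a, b))
    return mismatches / len(a)


def filter_homologs(
    records: list[HomologRecord],
    reference: ReferenceHistone,
    max_diff: float = 0.20,
    keyword_blocklist: frozenset[str] | set[str] = DEFAULT_KEYWORD_BLOCKLIST,
) -> tuple[list[HomologRecord], FilterReport]:
    """Apply the homolog filtering cascade, preserving input order.

    Rules, in order: drop fragments; drop records whose description matches
    the enzyme/chaperone keyword blocklist; drop records with non-canonical
    residues; drop records whose length differs from the reference; drop
    records more than ``max_diff`` different from the reference by amino-acid
    content.  Each removed record is tallied under the first rule it fails.
    """
    report = FilterReport(n_input=len(records))
    blocklist = {k.lower() for k in keyword_blocklist}
    kept: list[HomologRecord] = []
    for rec in records:
        desc = rec.description.lower()
        if rec.is_fragment:
            report.fragment += 1
            continue
        if any(k in desc for k in blocklist):
            report.keyword += 1
            continue
        if set(rec.sequence) - _CANONICAL_SET:
            report.non_canonical += 1
            continue
        if len(rec.sequence) != len(reference.sequence):
            report.length += 1
            continue
        if fraction_difference(rec.sequence, reference.sequence) > max_diff:
            report.divergence += 1
            continue
        kept.append(rec)
    report.kept = len(kept)
    return kept, report


def call_substitutions(
    record: HomologRecord, reference: ReferenceHistone
) -> list[SubstitutionVariant]:
    """List the substitutions a same-length homolog carries, by position."""
    if len(record.sequence) != len(reference.sequence):
        raise ValueError(
            f"{record.id}: length {len(record.sequence)} != reference {len(reference.sequence)}"
        )
    out = []
    for i, (ref_aa, aa) in enumerate(zip(reference.sequence, record.sequence), start=1):
        if aa != ref_aa:
            out.append(SubstitutionVariant(position=i, wt_aa=ref_aa, alt_aa=aa))
    return out


def build_variant_library(
    records: list[HomologRecord],
    reference: ReferenceHistone,
    max_diff: float = 0.20,
    keyword_blocklist: frozenset[str] | set[str] = DEFAULT_KEYWORD_BLOCKLIST,
) -> tuple[VariantLibrary, FilterReport]:
    """Filter homologs, call substitutions and count support.

    Identical homolog sequences are deduplicated before support counting, so
    database redundancy does not inflate a variant's support.
    """
    kept, report = filter_homologs(records, reference, max_diff, keyword_blocklist)
    unique_seqs: dict[str, HomologRecord] = {}
    for rec in kept:
        unique_seqs.setdefault(rec.sequence, rec)
    lib = VariantLibrary(reference=reference)
    for seq, rec in unique_seqs.items():
        for v in call_substitutions(rec, reference):
            if v not in lib.variants:
                lib.variants.add(v)
                lib.provenance[v] = "evolutionary"
                lib.support[v] = 0
            lib.support[v] += 1
    return lib, report


def augment_library(library: VariantLibrary) -> VariantLibrary:
    """Add the alanine scan and the K->R/E/M lysine panel to a library.

    Alanine substitutions are added at every non-alanine position; lysine
    positions additionally receive arginine, glutamate and methionine
    substitutions.  Existing variants keep their provenance and support;
    the operation is idempotent.
    """
    out = VariantLibrary(
        reference=library.reference,
        variants=set(library.variants),
        support=dict(library.support),
        provenance=dict(library.provenance),
    )

    def _add(v: SubstitutionVariant, label: str) -> None:
        if v not in out.variants:
            out.variants.add(v)
            out.provenance[v] = label
            out.support[v] = out.support.get(v, 0)

    for pos, aa in enumerate(library.reference.sequence, start=1):
        if aa != "A":
            _add(SubstitutionVariant(pos, aa, "A"), "alanine_scan")
        if aa == "K":
            for alt in "REM":
                _add(SubstitutionVariant(pos, "K", alt), "lysine_panel")
    return out


def compatible_pairs(
    singles: list[SubstitutionVariant],
) -> list[tuple[SubstitutionVariant, SubstitutionVariant]]:
    """All unordered pairs of singles at distinct positions, canonical order."""
    uniq = sorted(set(singles))
    return [
        (a, b)
        for a, b in itertools.combinations(uniq, 2)
        if a.position != b.position
    ]


def design_double_library(
    singles: list[SubstitutionVariant], n_pairs: int, seed: int
) -> DoubleMutantLibrary:
    """Sample ``n_pairs`` distinct-position pairs uniformly without replacement."""
    pool = compatible_pairs(singles)
    if n_pairs > len(pool):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds the {len(pool)} position-compatible pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_pairs, replace=False)
    pairs = [pool[i] for i in sorted(idx)]
    return DoubleMutantLibrary(singles=sorted(set(singles)), pairs=pairs, seed=seed)


def sequence_space_size(length: int, alphabet_size: int = 20) -> int:
    """Exact count of sequences of a given length over an alphabet.

    For the 30-residue H4 tail over the 20 canonical amino acids this is
    20**30 ~ 1.07e39, the combinatorial space the design search navigates.
    """
    if length < 1 or alphabet_size < 1:
        raise ValueError("length and alphabet_size must be positive")
    return alphabet_size**length


def order_of_magnitude(n: int) -> int:
    """Floor of log10 of a positive integer, exactly (big-int safe)."""
    if n < 1:
        raise ValueError("n must be positive")
    return len(str(n)) - 1


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces
# ---------------------------------------------------------------------------

def read_homolog_fasta(path: str, fragment_token: str = "fragment") -> list[HomologRecord]:
    """Read homologs from FASTA; a description containing ``fragment``
    (case-insensitive) marks the record as a fragment."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        desc = rec.description
        records.append(
            HomologRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                description=desc,
                is_fragment=fragment_token.lower() in desc.lower(),
            )
        )
    return records


def read_reference_fasta(
    path: str, family: str = "", strip_init_met: bool = False
) -> ReferenceHistone:
    rec = next(SeqIO.parse(path, "fasta"))
    seq = str(rec.seq).upper()
    if strip_init_met and seq.startswith("M"):
        seq = seq[1:]
    return ReferenceHistone(family=family or rec.id, sequence=seq, accession=rec.id)


def library_to_table(library: VariantLibrary):
    """Variant library as a tidy table (variant, position, wt, alt, support)."""
    import pandas as pd

    rows = [
        {
            "variant": str(v),
            "position": v.position,
            "wt_aa": v.wt_aa,
            "alt_aa": v.alt_aa,
            "support": library.support.get(v, 0),
            "provenance": library.provenance.get(v, "designed"),
        }
        for v in library.sorted_variants()
    ]
    return pd.DataFrame(rows)


def doubles_to_table(doubles: DoubleMutantLibrary):
    import pandas as pd

    return pd.DataFrame(
        [
            {"variant_a": str(a), "variant_b": str(b), "seed": doubles.seed}
            for a, b in doubles.pairs
        ]
    )
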