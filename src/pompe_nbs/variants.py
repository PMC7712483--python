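"""GAA variant representation, genotype parsing, and pathogenicity lookup.

Variants are cDNA-level (HGVS ``c.`` notation) on transcript NM_000152.3.
A :class:`VariantKB` maps variant spellings to one of seven pathogenicity
classes; genotype strings as reported by the screening laboratory are parsed
into primary (disease-relevant) alleles plus in-cis pseudodeficiency/benign
"rider" variants whose phase is not asserted.

Genotype grammar, as printed by the reporting laboratory:

* ``/`` separates allele segments (usually one per chromosome);
* ``;`` within a segment separates variants reported in cis;
* ``c.(A;B)`` groups two in-cis variants under a single ``c.`` prefix;
* a trailing single-base segment (``.../C``) is multi-allelic shorthand for
  the preceding substitution and is kept as one opaque token (``c.700A>G/C``).

Pseudodeficiency and benign/likely-benign variants never count toward the
primary allele number that drives referral and diagnosis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

from .errors import MalformedGenotypeError, VariantParseError

TRANSCRIPT = "NM_000152.3"

#: The common "leaky" intron-1 splice-site variant associated with late-onset
#: Pompe disease.  Laboratory reports spell it with and without the leading
#: "-" of the negative cDNA offset; both map to this canonical form.
SPLICE_VARIANT = "c.-32-13T>G"


class VariantClass(str, Enum):
    """Pathogenicity classification of a single GAA variant."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    PSEUDODEFICIENCY = "pseudodeficiency"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes that make an allele disease-causing.
DISEASE_CAUSING = frozenset({VariantClass.PATHOGENIC, VariantClass.LIKELY_PATHOGENIC})

#: Classes that ride along in cis and never count as primary alleles.
RIDER_CLASSES = frozenset(
    {VariantClass.PSEUDODEFICIENCY, VariantClass.BENIGN, VariantClass.LIKELY_BENIGN}
)

# Spellings of the intron-1 splice variant missing the leading "-" (a
# recurring typographical variant in laboratory reports).
_SPLICE_RESPELL = {"c.32-13T>G": SPLICE_VARIANT}


def normalize_variant_string(s: str) -> str:
    """Normalize a raw variant token to its canonical spelling.

    Removes all internal whitespace, maps the intron-1 splice-site variant
    spelled without its leading ``-`` onto :data:`SPLICE_VARIANT`, and leaves
    every other token otherwise unchanged.

    Raises
    ------
    VariantParseError
        If the token is empty (or whitespace only).
    """
    if s is None:
        raise VariantParseError("variant token is None")
    token = re.sub(r"\s+", "", s)
    if not token:
        raise VariantParseError(f"empty variant token: {s!r}")
    return _SPLICE_RESPELL.get(token, token)


@dataclass(frozen=True)
class Variant:
    """A single GAA cDNA variant with its pathogenicity class."""

    hgvs_c: str
    classification: VariantClass = VariantClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.hgvs_c or not self.hgvs_c.strip():
            raise VariantParseError("Variant.hgvs_c must be non-empty")
        if not isinstance(self.classification, VariantClass):
            object.__setattr__(
                self, "classification", VariantClass(self.classification)
            )

    @property
    def is_rider(self) -> bool:
        return self.classification in RIDER_CLASSES

    @property
    def is_disease_causing(self) -> bool:
        return self.classification in DISEASE_CAUSING


@dataclass(frozen=True)
class Allele:
    """One chromosome's reported variant content: usually a single variant,
    occasionally two variants in cis (e.g. ``c.266G>A;c.1377C>G``)."""

    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise VariantParseError("Allele must carry at least one variant")

    @property
    def classification(self) -> VariantClass:
        """Most severe constituent class; ``unknown`` dominates so that an
        uncurated constituent forces KB curation downstream."""
        classes = {v.classification for v in self.variants}
        if VariantClass.UNKNOWN in classes:
            return VariantClass.UNKNOWN
        if VariantClass.PATHOGENIC in classes:
            return VariantClass.PATHOGENIC
        if VariantClass.LIKELY_PATHOGENIC in classes:
            return VariantClass.LIKELY_PATHOGENIC
        return VariantClass.VUS

    def __str__(self) -> str:
        return ";".join(v.hgvs_c for v in self.variants)


@dataclass
class VariantKB:
    """Lookup table mapping variant spellings to pathogenicity classes.

    Lookup is case-sensitive after whitespace normalization.  A handful of
    entries are stored under their verbatim printed spelling (internal space
    preserved) where the same normalized string was reported with different
    classifications in different patients; :meth:`classify_token` consults
    the verbatim spelling first, then the normalized form.
    """

    entries: dict[str, VariantClass] = field(default_factory=dict)
    transcript: str = TRANSCRIPT

    def __post_init__(self) -> None:
        self.entries = {k: VariantClass(v) for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, hgvs_c: str) -> bool:
        return hgvs_c in self.entries

    def classify(self, hgvs_c: str) -> VariantClass:
        """Classification for a normalized variant string; ``unknown`` when
        absent (absence is a value, never an error, and never pathogenic)."""
        return self.entries.get(hgvs_c, VariantClass.UNKNOWN)

    def classify_token(self, raw_token: str) -> tuple[str, VariantClass]:
        """Classify a raw genotype token.

        Returns ``(normalized_spelling, classification)``.  The verbatim
        (outer-stripped) spelling takes precedence over the normalized one so
        that distinct printed spellings of one position can carry the
        laboratory's distinct classifications.
        """
        verbatim = raw_token.strip()
        normalized = normalize_variant_string(raw_token)
        if verbatim != normalized and verbatim in self.entries:
            return normalized, self.entries[verbatim]
        return normalized, self.classify(normalized)


def classify_variant(hgvs_c: str, kb: VariantKB) -> VariantClass:
    """Pure KB lookup of a (raw or normalized) variant string."""
    return kb.classify(normalize_variant_string(hgvs_c))


@dataclass(frozen=True)
class Genotype:
    """Parsed allele structure of one newborn's GAA sequencing result."""

    primary_alleles: tuple[Allele, ...] = ()
    in_cis_extras: tuple[Variant, ...] = ()
    raw: str = ""

    def __post_init__(self) -> None:
        for allele in self.primary_alleles:
            if allele.classification in RIDER_CLASSES:
                raise MalformedGenotypeError(
                    f"primary allele {allele} has rider class"
                )

    @property
    def n_primary(self) -> int:
        return len(self.primary_alleles)

    def all_variants(self) -> Iterator[Variant]:
        for allele in self.primary_alleles:
            yield from allele.variants
        yield from self.in_cis_extras

    def tokens(self) -> list[str]:
        """Normalized spellings of every variant, primaries first."""
        return [v.hgvs_c for v in self.all_variants()]

    def count_primary(self, hgvs_c: str) -> int:
        """Number of primary alleles carrying the given (normalized) variant."""
        return sum(
            any(v.hgvs_c == hgvs_c for v in allele.variants)
            for allele in self.primary_alleles
        )

    def has_allele(self, hgvs_c: str) -> bool:
        return self.count_primary(hgvs_c) >= 1

    def is_homozygous_for(self, hgvs_c: str) -> bool:
        return self.n_primary == 2 and all(
            any(v.hgvs_c == hgvs_c for v in allele.variants)
            for allele in self.primary_alleles
        )

    @property
    def has_pseudodeficiency(self) -> bool:
        return any(
            v.classification is VariantClass.PSEUDODEFICIENCY
            for v in self.in_cis_extras
        )

    @property
    def is_empty(self) -> bool:
        return not self.primary_alleles and not self.in_cis_extras


_CIS_GROUP_RE = re.compile(r"^c\.\((?P<inner>.+)\)$")
_BARE_BASE_RE = re.compile(r"^[ACGT]$")


def _split_segments(s: str) -> list[str]:
    """Split a genotype string on '/', re-joining trailing single-base
    segments (multi-allelic shorthand like ``c.700A>G/C``)."""
    parts = [p for p in (seg.strip() for seg in s.split("/")) if p]
    merged: list[str] = []
    for part in parts:
        if merged and _BARE_BASE_RE.match(part):
            merged[-1] = merged[-1] + "/" + part
        else:
            merged.append(part)
    return merged


def _segment_tokens(segment: str) -> list[str]:
    """Tokens reported in cis within one segment."""
    m = _CIS_GROUP_RE.match(segment.strip())
    if m:
        tokens = []
        for tok in m.group("inner").split(";"):
            tok = tok.strip()
            if not tok:
                continue
            if not tok.startswith("c."):
                tok = "c." + tok
            tokens.append(tok)
        return tokens
    return [t for t in (tok.strip() for tok in segment.split(";")) if t]


def parse_genotype(s: str | None, kb: VariantKB) -> Genotype:
    """Parse a laboratory genotype string against a variant knowledge base.

    Each ``/``-separated segment contributes at most one primary allele:
    pseudodeficiency and benign/likely-benign tokens are routed to
    ``in_cis_extras`` (phase is not asserted), and the remaining tokens in
    the segment — one variant, or several reported in cis — form the allele.
    An empty or missing string is a negative sequencing result.

    Raises
    ------
    MalformedGenotypeError
        If more than two segments carry a primary allele.
    VariantParseError
        If a token is unparseable.
    """
    raw = "" if s is None else s
    if not raw.strip():
        return Genotype(raw=raw)

    alleles: list[Allele] = []
    extras: list[Variant] = []
    for segment in _split_segments(raw):
        # opaque multi-allelic shorthand is classified as a single token
        if "/" in segment:
            seg_tokens = [segment]
        else:
            seg_tokens = _segment_tokens(segment)
        allele_variants: list[Variant] = []
        for token in seg_tokens:
            normalized, classification = kb.classify_token(token)
            variant = Variant(normalized, classification)
            if variant.is_rider:
                extras.append(variant)
            else:
                allele_variants.append(variant)
        if allele_variants:
            alleles.append(Allele(tuple(allele_variants)))

    if len(alleles) > 2:
        raise MalformedGenotypeError(
            f"genotype {raw!r} carries {len(alleles)} primary alleles (max 2)"
        )
    return Genotype(tuple(alleles), tuple(extras), raw)


def build_kb(
    entries: Mapping[str, VariantClass | str] | Iterable[tuple[str, VariantClass | str]],
    transcript: str = TRANSCRIPT,
) -> VariantKB:
    """Construct a KB from (spelling, class) pairs, normalizing whitespace in
    keys only at the outer edges (verbatim internal spacing is significant)."""
    mapping = dict(entries) if isinstance(entries, Mapping) else dict(entries)
    cleaned = {k.strip(): VariantClass(v) for k, v in mapping.items()}
    return VariantKB(cleaned, transcript)
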