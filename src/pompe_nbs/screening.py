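"""The two-tier screening algorithm and per-newborn triage outcome.

Tier 1: a repeat dried-blood-spot specimen is requested when the first GAA
activity is below the cutoff (message code 1).  Tier 2: a second activity
below the cutoff reflexes the specimen to full GAA gene sequencing.
Sequencing triage: at least one primary allele (pathogenic, likely
pathogenic, or VUS) triggers referral to a metabolic specialist (code 2);
pseudodeficiency-only or variant-negative sequencing yields a consult
recommendation (code 3).

Records missing the first-tier activity (as printed for several confirmed
patients) enter the algorithm at the first tier for which data exist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .assay import CutoffConfig, below_cutoff
from .errors import DomainError, MissingDataError
from .variants import Genotype, VariantKB, parse_genotype

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Measurement:
    """A confirmatory laboratory value with its (site-specific) reference
    range.  ``censored`` preserves a printed "<x" style bound; the numeric
    value then carries the bound itself."""

    value: float
    ref_low: float | None = None
    ref_high: float | None = None
    censored: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise DomainError(f"measurement value must be finite and >= 0, got {self.value!r}")

    @property
    def above_reference(self) -> bool | None:
        """True/False against the upper reference limit; None if no limit."""
        if self.ref_high is None:
            return None
        return self.value > self.ref_high


@dataclass(frozen=True)
class ScreeningRecord:
    """One newborn's screening and confirmatory data.

    GAA activities in µmol/L/h; AST/ALT/CK in U/L; BNP in pg/mL; Hex4 in
    mmol/mol creatinine.  ``None`` marks a value missing at source.
    ``genotype_raw`` is ``None`` when sequencing was not performed and the
    empty string when sequencing was negative.
    """

    id: str
    gaa1: float | None = None
    gaa2: float | None = None
    genotype_raw: str | None = None
    confirmatory_gaa: Measurement | None = None
    ast: Measurement | None = None
    alt: Measurement | None = None
    ck: Measurement | None = None
    bnp: Measurement | None = None
    hex4: Measurement | None = None
    cardiomyopathy_or_symptoms: bool = False
    deldup_negative: bool | None = None
    note: str = ""

    def __post_init__(self) -> None:
        for name in ("gaa1", "gaa2"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def sequenced(self) -> bool:
        return self.genotype_raw is not None


class OutcomeState(str, Enum):
    SCREEN_NEGATIVE = "screen_negative"
    REPEAT_REQUESTED = "repeat_requested"
    REFERRAL = "referral"
    CONSULT_PSEUDODEFICIENCY = "consult_pseudodeficiency"
    CONSULT_NO_VARIANT = "consult_no_variant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_MESSAGE_CODES = {
    OutcomeState.SCREEN_NEGATIVE: None,
    OutcomeState.REPEAT_REQUESTED: 1,
    OutcomeState.REFERRAL: 2,
    OutcomeState.CONSULT_PSEUDODEFICIENCY: 3,
    OutcomeState.CONSULT_NO_VARIANT: 3,
}


@dataclass(frozen=True)
class ScreeningOutcome:
    """Triage state plus the report message code it carries.

    ``fast_track`` annotates the symptom prompt (cardiomyopathy or symptoms
    of Pompe disease reported at the first abnormal result): it raises the
    workflow urgency but never alters the state itself.
    """

    state: OutcomeState
    message_code: int | None = field(default=None)
    fast_track: bool = False

    def __post_init__(self) -> None:
        expected = _MESSAGE_CODES[self.state]
        if self.message_code is None and expected is not None:
            object.__setattr__(self, "message_code", expected)
        elif self.message_code != expected:
            raise DomainError(
                f"state {self.state} requires message code {expected}, got {self.message_code}"
            )

    @property
    def is_positive(self) -> bool:
        return self.state in (
            OutcomeState.REFERRAL,
            OutcomeState.CONSULT_PSEUDODEFICIENCY,
            OutcomeState.CONSULT_NO_VARIANT,
        )


def first_tier(gaa1: float | None, cfg: CutoffConfig | None = None) -> OutcomeState:
    """First-specimen decision: repeat requested iff activity < cutoff."""
    if gaa1 is None:
        raise MissingDataError("first-tier GAA activity missing")
    return (
        OutcomeState.REPEAT_REQUESTED
        if below_cutoff(gaa1, cfg)
        else OutcomeState.SCREEN_NEGATIVE
    )


def second_tier(gaa2: float | None, cfg: CutoffConfig | None = None) -> bool:
    """Repeat-specimen decision: True iff the record reflexes to sequencing."""
    if gaa2 is None:
        raise MissingDataError("second-tier GAA activity missing")
    return below_cutoff(gaa2, cfg)


def sequencing_triage(g: Genotype) -> ScreeningOutcome:
    """Post-sequencing triage of a reflexed record.

    Referral (code 2) when at least one primary allele is present;
    otherwise a metabolic consult (code 3) distinguishing pseudodeficiency-
    only from variant-negative sequencing.
    """
    if g.n_primary >= 1:
        return ScreeningOutcome(OutcomeState.REFERRAL)
    if g.has_pseudodeficiency:
        return ScreeningOutcome(OutcomeState.CONSULT_PSEUDODEFICIENCY)
    return ScreeningOutcome(OutcomeState.CONSULT_NO_VARIANT)


def run_screening(
    rec: ScreeningRecord,
    kb: VariantKB,
    cfg: CutoffConfig | None = None,
) -> ScreeningOutcome:
    """Run one record through the full two-tier algorithm.

    Short-circuits to screen-negative at either enzyme tier.  Records with
    a missing tier value fall through to the next tier for which data exist
    (confirmed patients are reported this way); a record with no usable data
    at any tier raises :class:`MissingDataError`.
    """
    cfg = cfg or CutoffConfig()
    fast = rec.cardiomyopathy_or_symptoms

    if rec.gaa1 is not None:
        if first_tier(rec.gaa1, cfg) is OutcomeState.SCREEN_NEGATIVE:
            return ScreeningOutcome(OutcomeState.SCREEN_NEGATIVE, fast_track=fast)
    elif rec.gaa2 is None and not rec.sequenced:
        raise MissingDataError(f"record {rec.id}: no usable screening data")

    if rec.gaa2 is not None:
        if not second_tier(rec.gaa2, cfg):
            return ScreeningOutcome(OutcomeState.SCREEN_NEGATIVE, fast_track=fast)
    elif not rec.sequenced:
        # first tier abnormal (or absent) and nothing further yet
        return ScreeningOutcome(OutcomeState.REPEAT_REQUESTED, fast_track=fast)

    if not rec.sequenced:
        raise MissingDataError(
            f"record {rec.id}: reflexed to sequencing but no sequencing result"
        )
    genotype = parse_genotype(rec.genotype_raw, kb)
    outcome = sequencing_triage(genotype)
    logger.debug("record %s -> %s (code %s)", rec.id, outcome.state, outcome.message_code)
    return ScreeningOutcome(outcome.state, fast_track=fast)


def screen_records(
    records: Iterable[ScreeningRecord],
    kb: VariantKB,
    cfg: CutoffConfig | None = None,
) -> list[ScreeningOutcome]:
    """Vector convenience: one outcome per record, in order."""
    cfg = cfg or CutoffConfig()
    return [run_screening(rec, kb, cfg) for rec in records]
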