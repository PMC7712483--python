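"""Final diagnostic classification of screen-positive, sequenced newborns.

Labels partition the referred/consulted population:

* **IOPD** — two disease-causing alleles plus infantile cardiac disease
  (cardiomyopathy) or the marked biomarker triad (CK, Hex4 and BNP all
  above their reference limits);
* **LOPD** — two disease-causing alleles without those findings;
* **suspected LOPD** — two primary alleles of which at least one is a VUS;
* **carrier** — exactly one primary allele (deletion/duplication testing,
  when reported positive rather than negative, downgrades confidence via a
  warning but not the label);
* **pseudodeficiency** — no primary allele, at least one pseudodeficiency
  variant (homo- and heterozygous alike);
* **false positive** — variant-negative sequencing.

Confirmatory enzyme activity never gates the label: confirmed LOPD patients
with normal confirmatory levels are on record, so genotype decides and the
enzyme result is reported alongside.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .assay import CutoffConfig
from .errors import UnresolvedGenotypeError
from .screening import Measurement, ScreeningRecord
from .variants import DISEASE_CAUSING, Genotype, VariantClass, VariantKB, parse_genotype

logger = logging.getLogger(__name__)


class DiagnosisLabel(str, Enum):
    IOPD = "IOPD"
    LOPD = "LOPD"
    SUSPECTED_LOPD = "suspected_LOPD"
    CARRIER = "carrier"
    PSEUDODEFICIENCY = "pseudodeficiency"
    FALSE_POSITIVE = "false_positive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClinicalContext:
    """Clinical findings that separate infantile- from late-onset disease."""

    cardiomyopathy: bool = False
    markedly_elevated_ck_hex4_bnp: bool = False

    @classmethod
    def from_record(cls, rec: ScreeningRecord) -> "ClinicalContext":
        """Derive the context from a record; missing data count as False."""

        def elevated(m: Measurement | None) -> bool:
            return m is not None and m.above_reference is True

        triad = elevated(rec.ck) and elevated(rec.hex4) and elevated(rec.bnp)
        return cls(
            cardiomyopathy=rec.cardiomyopathy_or_symptoms,
            markedly_elevated_ck_hex4_bnp=triad,
        )

    @property
    def infantile_presentation(self) -> bool:
        return self.cardiomyopathy or self.markedly_elevated_ck_hex4_bnp


def assign_diagnosis(
    g: Genotype,
    ctx: ClinicalContext | None = None,
    confirmatory_gaa_present_normal: bool | None = None,
    deldup_negative: bool | None = None,
) -> DiagnosisLabel:
    """Diagnostic label for one sequenced, screen-positive genotype.

    Raises
    ------
    UnresolvedGenotypeError
        If any primary allele carries an uncurated (``unknown``) variant;
        curation of the knowledge base is required rather than guessing.
    """
    ctx = ctx or ClinicalContext()
    classes = [allele.classification for allele in g.primary_alleles]
    if any(c is VariantClass.UNKNOWN for c in classes):
        unknowns = [
            v.hgvs_c
            for allele in g.primary_alleles
            for v in allele.variants
            if v.classification is VariantClass.UNKNOWN
        ]
        raise UnresolvedGenotypeError(
            f"genotype {g.raw!r} has uncurated variant(s): {', '.join(unknowns)}"
        )

    if len(classes) == 2:
        if all(c in DISEASE_CAUSING for c in classes):
            if ctx.infantile_presentation:
                return DiagnosisLabel.IOPD
            return DiagnosisLabel.LOPD
        # at least one VUS (pathogenic+VUS or VUS+VUS)
        return DiagnosisLabel.SUSPECTED_LOPD
    if len(classes) == 1:
        if deldup_negative is False:
            logger.warning(
                "genotype %r: deletion/duplication testing not negative; "
                "carrier label retained with reduced confidence",
                g.raw,
            )
        return DiagnosisLabel.CARRIER
    if g.has_pseudodeficiency:
        return DiagnosisLabel.PSEUDODEFICIENCY
    if confirmatory_gaa_present_normal is False:
        logger.warning(
            "variant-negative sequencing with low confirmatory enzyme activity; "
            "reported as false positive per algorithm"
        )
    return DiagnosisLabel.FALSE_POSITIVE


def diagnose_record(
    rec: ScreeningRecord, kb: VariantKB, cfg: CutoffConfig | None = None
) -> DiagnosisLabel:
    """Parse, contextualize and label one record."""
    cfg = cfg or CutoffConfig()
    genotype = parse_genotype(rec.genotype_raw, kb)
    ctx = ClinicalContext.from_record(rec)
    normal_conf: bool | None = None
    if rec.confirmatory_gaa is not None and rec.confirmatory_gaa.ref_low is not None:
        normal_conf = rec.confirmatory_gaa.value >= rec.confirmatory_gaa.ref_low
    return assign_diagnosis(genotype, ctx, normal_conf, rec.deldup_negative)


def classify_cohort(
    records: Sequence[ScreeningRecord],
    kb: VariantKB,
    cfg: CutoffConfig | None = None,
) -> list[DiagnosisLabel]:
    """Label every record; errors propagate annotated with the record id."""
    cfg = cfg or CutoffConfig()
    labels: list[DiagnosisLabel] = []
    for rec in records:
        try:
            labels.append(diagnose_record(rec, kb, cfg))
        except UnresolvedGenotypeError as exc:
            raise UnresolvedGenotypeError(f"record {rec.id}: {exc}") from exc
    if labels:
        logger.info("cohort classified: %s", dict(Counter(l.value for l in labels)))
    return labels


def label_counts(labels: Iterable[DiagnosisLabel]) -> dict[DiagnosisLabel, int]:
    counts = Counter(labels)
    return {label: counts.get(label, 0) for label in DiagnosisLabel}
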