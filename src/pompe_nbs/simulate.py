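"""Synthetic birth-cohort generator with the statistical structure of the
screening program, plus a parameter-recovery harness that closes the loop
through the full pipeline.

Every newborn is assigned a hidden true category: one of the six final
diagnostic labels, a *transient-low* category (first specimen below the
cutoff, repeat specimen normal — these newborns leave the funnel at tier 2),
or screen-negative.  Category prevalences default to the program's observed
counts over 531,139 births.  Label-conditional GAA activities and
confirmatory biomarkers are drawn from bounded triangular distributions
anchored at the printed (min, median, max) order statistics — the minimal
bounded choice given only three order statistics; the screen-negative
majority draws its activity from a log-normal with mean ``cutoff/0.18``
(the fixed cutoff sits at ~18% of the apparently-normal newborn mean).

Genotypes are sampled from label-specific pools: the confirmed and
suspected pools are the programs' reported genotypes; carrier,
pseudodeficiency and false-positive pools are synthetic single-allele /
pseudodeficiency-only / sequencing-negative strings constructed from the
same variant spellings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import CutoffConfig
from .diagnosis import DiagnosisLabel, diagnose_record
from .errors import DomainError
from .io import REPORTED_COUNTS, TOTAL_SCREENED, load_default_kb, load_fixtures
from .screening import Measurement, OutcomeState, ScreeningRecord, run_screening
from .stats import cohort_report
from .variants import VariantKB

TRANSIENT_LOW = "transient_low"
SCREEN_NEGATIVE = "screen_negative"

#: (min, mode, max) anchors per label for the two screening activities;
#: modes are the printed medians.  Bounds for the positive categories sit
#: below the cutoff, so a true positive always completes the funnel.
_GAA_ANCHORS: dict[str, dict[str, tuple[float, float, float]]] = {
    "IOPD": {"gaa1": (0.55, 0.65, 0.75), "gaa2": (0.22, 0.28, 0.34)},
    "LOPD": {"gaa1": (0.56, 1.08, 1.86), "gaa2": (0.19, 0.77, 1.44)},
    "suspected_LOPD": {"gaa1": (0.19, 1.19, 2.06), "gaa2": (0.12, 1.03, 2.06)},
    "carrier": {"gaa1": (1.01, 1.62, 2.06), "gaa2": (0.43, 1.42, 2.04)},
    "pseudodeficiency": {"gaa1": (1.01, 1.62, 2.06), "gaa2": (0.43, 1.42, 2.04)},
    "false_positive": {"gaa1": (1.01, 1.62, 2.06), "gaa2": (1.61, 1.70, 1.78)},
    TRANSIENT_LOW: {"gaa1": (1.01, 1.62, 2.06)},
}

#: (min, mode, max) anchors per label for confirmatory biomarkers.
_ANALYTE_ANCHORS: dict[str, dict[str, tuple[float, float, float]]] = {
    "IOPD": {
        "conf_gaa": (0.4, 2.4, 4.4), "ast": (103, 146, 189), "alt": (91, 91, 91),
        "ck": (846, 884, 923), "bnp": (1080, 1156, 1232.5), "hex4": (24.7, 27.5, 30.2),
    },
    "LOPD": {
        "conf_gaa": (0.7, 2.4, 6.9), "ast": (21, 72.5, 168), "alt": (23, 42.5, 104),
        "ck": (48, 265, 617), "bnp": (10, 52, 103), "hex4": (2.6, 5.23, 12.6),
    },
    "suspected_LOPD": {
        "conf_gaa": (0.43, 2.0, 6.05), "ast": (23, 64, 156), "alt": (19, 36, 103),
        "ck": (65, 123, 668), "bnp": (13, 44, 408), "hex4": (2.4, 4.5, 15.7),
    },
    "carrier": {
        "conf_gaa": (1.7, 3.5, 12.4), "ast": (39, 63.5, 105), "alt": (9, 32, 69),
        "ck": (35, 107, 344), "bnp": (10, 50, 100), "hex4": (2.3, 3.95, 17.6),
    },
    "pseudodeficiency": {
        "conf_gaa": (1.7, 3.5, 12.4), "ast": (39, 63.5, 105), "alt": (9, 32, 69),
        "ck": (35, 107, 344), "bnp": (10, 50, 100), "hex4": (2.3, 3.95, 17.6),
    },
    "false_positive": {
        "conf_gaa": (4.6, 5.1, 5.6), "ast": (39, 63.5, 105), "alt": (9, 32, 69),
        "ck": (35, 107, 344), "bnp": (10, 50, 100), "hex4": (2.3, 3.95, 17.6),
    },
}

#: Per-label, per-column missingness rates for the confirmatory biomarkers,
#: measured from the packaged fixture tables (missing-completely-at-random;
#: the source reports no missingness mechanism).  Screening activities are
#: never dropped so the two-tier funnel stays well defined.  Applied only
#: when ``apply_missingness`` is on.
_MISSINGNESS: dict[str, dict[str, float]] = {
    "LOPD": {"conf_gaa": 8 / 31, "ast": 9 / 31, "alt": 9 / 31,
             "ck": 6 / 31, "bnp": 25 / 31, "hex4": 10 / 31},
    "suspected_LOPD": {"conf_gaa": 7 / 30, "ast": 6 / 30,
                       "alt": 6 / 30, "ck": 5 / 30, "bnp": 17 / 30, "hex4": 6 / 30},
}

_SYNTHETIC_CARRIER_POOL = [
    "c.-32-13T>G", "c.2238G>C", "c.525delT", "c.1551+1G>C", "c.2560C>T",
    "c.-32-13T>G/ c.2065G>A",
]
_SYNTHETIC_PSEUDO_POOL = ["c.2065G>A", "c.2065G>A/c.2065G>A", "c.1726G>A",
                          "c.(1726G>A;c.2065G>A)"]

_REF_HIGH = {"ast": 71.0, "alt": 50.0, "ck": 305.0, "bnp": 100.0, "hex4": 20.0}
_CONF_GAA_LOWER = 3.88


def _default_prevalence() -> dict[str, float]:
    return {k: v / TOTAL_SCREENED for k, v in REPORTED_COUNTS.items()}


def _default_pools() -> dict[str, list[str]]:
    fixtures = load_fixtures()
    pools: dict[str, list[str]] = {"IOPD": [], "LOPD": [], "suspected_LOPD": []}
    for rec in fixtures.table2:
        key = "IOPD" if rec.cardiomyopathy_or_symptoms else "LOPD"
        pools[key].append(rec.genotype_raw or "")
    for rec in fixtures.table3:
        pools["suspected_LOPD"].append(rec.genotype_raw or "")
    pools["carrier"] = list(_SYNTHETIC_CARRIER_POOL)
    pools["pseudodeficiency"] = list(_SYNTHETIC_PSEUDO_POOL)
    pools["false_positive"] = [""]
    return pools


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort.

    ``category_prevalence`` maps final-diagnosis labels to per-birth
    probabilities (defaults: observed counts / 531,139).
    ``transient_low_rate`` is the rate of newborns abnormal on the first
    specimen only (default ``65/531,139``, the observed tier-1/tier-2 gap).
    The screen-negative remainder absorbs the residual probability.
    """

    total_n: int = 100_000
    category_prevalence: Mapping[str, float] = field(default_factory=_default_prevalence)
    transient_low_rate: float = 65 / TOTAL_SCREENED
    negative_mean: float | None = None  # default: cutoff / normal-mean fraction
    negative_cv: float = 0.35
    apply_missingness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_n < 0:
            raise DomainError("total_n must be >= 0")
        prev = dict(self.category_prevalence)
        bad = set(prev) - {l.value for l in DiagnosisLabel}
        if bad:
            raise DomainError(f"unknown prevalence categories: {sorted(bad)}")
        if any(p < 0 for p in prev.values()) or self.transient_low_rate < 0:
            raise DomainError("prevalences must be >= 0")
        if sum(prev.values()) + self.transient_low_rate > 1:
            raise DomainError("prevalences sum above 1")
        if self.negative_cv <= 0:
            raise DomainError("negative_cv must be > 0")

    def prevalence_vector(self) -> tuple[list[str], np.ndarray]:
        prev = dict(self.category_prevalence)
        names = [l.value for l in DiagnosisLabel] + [TRANSIENT_LOW, SCREEN_NEGATIVE]
        probs = [prev.get(l.value, 0.0) for l in DiagnosisLabel]
        probs.append(self.transient_low_rate)
        probs.append(1.0 - sum(probs))
        return names, np.asarray(probs)


def _triangular(rng: np.random.Generator, anchor: tuple[float, float, float],
                size: int) -> np.ndarray:
    lo, mode, hi = anchor
    if not lo <= mode <= hi:
        raise DomainError(f"triangular anchor out of order: {anchor}")
    if lo == hi:
        return np.full(size, lo)
    return rng.triangular(lo, mode, hi, size)


def _negative_lognormal(rng: np.random.Generator, mean: float, cv: float,
                        size: int) -> np.ndarray:
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def simulate_cohort(params: SimulationParams, cfg: CutoffConfig | None = None,
                    genotype_pools: Mapping[str, Sequence[str]] | None = None,
                    ) -> pd.DataFrame:
    """Generate a cohort of ``params.total_n`` newborns.

    Returns a DataFrame with one row per newborn: screening activities,
    genotype string (NaN = not sequenced in truth-generation terms; the
    pipeline decides what is actually sequenced), confirmatory biomarkers,
    cardiomyopathy flag, and the hidden ``true_label`` column for recovery
    testing.  Identical ``params`` (including seed) give identical output.
    """
    cfg = cfg or CutoffConfig()
    pools = {k: list(v) for k, v in (genotype_pools or _default_pools()).items()}
    rng = np.random.default_rng(params.seed)
    names, probs = params.prevalence_vector()
    counts = rng.multinomial(params.total_n, probs)
    neg_mean = params.negative_mean or cfg.implied_normal_mean

    frames: list[pd.DataFrame] = []
    for name, n in zip(names, counts):
        if n == 0:
            continue
        block: dict[str, object] = {"true_label": np.repeat(name, n)}
        if name == SCREEN_NEGATIVE:
            gaa1 = _negative_lognormal(rng, neg_mean, params.negative_cv, n)
            block["gaa1"] = gaa1
            # the rare negative below the cutoff gets a normal repeat
            gaa2 = np.full(n, np.nan)
            retest = gaa1 < cfg.gaa_cutoff
            if retest.any():
                draws = _negative_lognormal(rng, neg_mean, params.negative_cv,
                                            int(retest.sum()))
                gaa2[retest] = np.maximum(draws, cfg.gaa_cutoff)
            block["gaa2"] = gaa2
        elif name == TRANSIENT_LOW:
            block["gaa1"] = _triangular(rng, _GAA_ANCHORS[name]["gaa1"], n)
            draws = _negative_lognormal(rng, neg_mean, params.negative_cv, n)
            block["gaa2"] = np.maximum(draws, cfg.gaa_cutoff)
        else:
            block["gaa1"] = _triangular(rng, _GAA_ANCHORS[name]["gaa1"], n)
            block["gaa2"] = _triangular(rng, _GAA_ANCHORS[name]["gaa2"], n)
            pool = pools.get(name) or [""]
            block["genotype"] = np.asarray(pool, dtype=object)[
                rng.integers(0, len(pool), n)
            ]
            for analyte, anchor in _ANALYTE_ANCHORS[name].items():
                block[analyte] = _triangular(rng, anchor, n)
            if params.apply_missingness and name in _MISSINGNESS:
                for col, rate in _MISSINGNESS[name].items():
                    mask = rng.random(n) < rate
                    values = np.asarray(block[col], dtype=float)
                    values[mask] = np.nan
                    block[col] = values
        df = pd.DataFrame(block)
        df["cardiomyopathy"] = name == "IOPD"
        frames.append(df)

    cohort = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["true_label", "gaa1", "gaa2", "cardiomyopathy"])
    )
    for col in ("genotype", "conf_gaa", "ast", "alt", "ck", "bnp", "hex4"):
        if col not in cohort.columns:
            cohort[col] = np.nan
    # shuffle so record order carries no information about the category
    order = rng.permutation(len(cohort))
    cohort = cohort.iloc[order].reset_index(drop=True)
    cohort.insert(0, "id", [f"N{i + 1:07d}" for i in range(len(cohort))])
    return cohort


def record_from_row(row: pd.Series) -> ScreeningRecord:
    """Convert one simulated cohort row to a :class:`ScreeningRecord`."""

    def num(name: str) -> float | None:
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    def meas(name: str) -> Measurement | None:
        v = num(name)
        if v is None:
            return None
        return Measurement(v, ref_high=_REF_HIGH[name])

    geno = row.get("genotype")
    genotype_raw = None if geno is None or (isinstance(geno, float) and math.isnan(geno)) else str(geno)
    conf = num("conf_gaa")
    return ScreeningRecord(
        id=str(row.get("id", "")),
        gaa1=num("gaa1"),
        gaa2=num("gaa2"),
        genotype_raw=genotype_raw,
        confirmatory_gaa=Measurement(conf, ref_low=_CONF_GAA_LOWER) if conf is not None else None,
        ast=meas("ast"), alt=meas("alt"), ck=meas("ck"), bnp=meas("bnp"),
        hex4=meas("hex4"),
        cardiomyopathy_or_symptoms=bool(row.get("cardiomyopathy", False)),
    )


@dataclass(frozen=True)
class PipelineCounts:
    """Funnel and diagnosis tallies of a simulated cohort run end-to-end."""

    total: int
    first_tier_low: int
    second_tier_low: int
    diagnosed: dict[str, int]

    @property
    def first_tier_rate_percent(self) -> float:
        return 100.0 * self.first_tier_low / self.total if self.total else 0.0

    @property
    def second_tier_rate_percent(self) -> float:
        return 100.0 * self.second_tier_low / self.total if self.total else 0.0


def run_pipeline(cohort: pd.DataFrame, kb: VariantKB | None = None,
                 cfg: CutoffConfig | None = None) -> tuple[PipelineCounts, pd.DataFrame]:
    """Screen and classify every simulated newborn.

    Tier decisions are vectorized; only the (rare) reflexed rows pass
    through the per-record genotype path.  Returns the funnel counts and the
    cohort with ``outcome`` and ``diagnosis`` columns added.
    """
    kb = kb or load_default_kb()
    cfg = cfg or CutoffConfig()
    df = cohort.copy()
    gaa1 = df["gaa1"].to_numpy(dtype=float)
    gaa2 = df["gaa2"].to_numpy(dtype=float)
    tier1_low = gaa1 < cfg.gaa_cutoff  # NaN compares False
    tier2_low = tier1_low & (gaa2 < cfg.gaa_cutoff)

    outcome = np.where(tier1_low, OutcomeState.REPEAT_REQUESTED.value,
                       OutcomeState.SCREEN_NEGATIVE.value).astype(object)
    outcome[tier1_low & ~tier2_low & ~np.isnan(gaa2)] = OutcomeState.SCREEN_NEGATIVE.value
    diagnosis = np.full(len(df), None, dtype=object)

    for i in np.flatnonzero(tier2_low):
        rec = record_from_row(df.iloc[i])
        out = run_screening(rec, kb, cfg)
        outcome[i] = out.state.value
        if out.is_positive:
            diagnosis[i] = diagnose_record(rec, kb, cfg).value

    df["outcome"] = outcome
    df["diagnosis"] = diagnosis
    diagnosed = pd.Series(diagnosis[diagnosis != None]).value_counts().to_dict()  # noqa: E711
    counts = PipelineCounts(
        total=len(df),
        first_tier_low=int(tier1_low.sum()),
        second_tier_low=int(tier2_low.sum()),
        diagnosed={str(k): int(v) for k, v in diagnosed.items()},
    )
    return counts, df


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline estimates vs. simulation truth."""

    total_n: int
    expected: dict[str, float]
    observed: dict[str, int]
    z_scores: dict[str, float]
    within_3sigma: bool
    label_recovery: float
    n_labelled: int
    first_tier_rate_percent: float
    second_tier_rate_percent: float

    def to_dict(self) -> dict:
        return {
            "total_n": self.total_n,
            "expected": self.expected,
            "observed": self.observed,
            "z_scores": self.z_scores,
            "within_3sigma": self.within_3sigma,
            "label_recovery": self.label_recovery,
            "n_labelled": self.n_labelled,
            "first_tier_rate_percent": self.first_tier_rate_percent,
            "second_tier_rate_percent": self.second_tier_rate_percent,
        }


def recover_parameters(params: SimulationParams, kb: VariantKB | None = None,
                       cfg: CutoffConfig | None = None) -> RecoveryReport:
    """Simulate, run the full pipeline, and compare estimates to truth.

    Per-category observed counts are compared to ``n * prevalence`` with
    binomial standard errors; label recovery is the fraction of diagnosed
    records whose pipeline label equals the hidden true label (the genotype
    pools are label-unambiguous, so this is 100% when the rules engine is
    faithful).
    """
    kb = kb or load_default_kb()
    cfg = cfg or CutoffConfig()
    cohort = simulate_cohort(params, cfg)
    counts, df = run_pipeline(cohort, kb, cfg)

    expected: dict[str, float] = {}
    observed: dict[str, int] = {}
    z_scores: dict[str, float] = {}
    prev = dict(params.category_prevalence)
    for label, p in prev.items():
        mean = params.total_n * p
        sd = math.sqrt(params.total_n * p * (1 - p))
        obs = counts.diagnosed.get(label, 0)
        expected[label] = mean
        observed[label] = obs
        z_scores[label] = (obs - mean) / sd if sd > 0 else 0.0

    labelled = df[df["diagnosis"].notna()]
    matches = int((labelled["diagnosis"] == labelled["true_label"]).sum())
    recovery = matches / len(labelled) if len(labelled) else 1.0

    return RecoveryReport(
        total_n=params.total_n,
        expected=expected,
        observed=observed,
        z_scores=z_scores,
        within_3sigma=all(abs(z) <= 3 for z in z_scores.values()),
        label_recovery=recovery,
        n_labelled=int(len(labelled)),
        first_tier_rate_percent=counts.first_tier_rate_percent,
        second_tier_rate_percent=counts.second_tier_rate_percent,
    )


def summarize_simulated(df: pd.DataFrame, total_screened: int | None = None):
    """Cohort report of a pipeline-annotated simulated cohort."""
    labels = [DiagnosisLabel(v) for v in df["diagnosis"].dropna()]
    return cohort_report(labels, total_screened or len(df))
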