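"""Readers/writers for screening-record tables, the packaged variant
knowledge base, and the packaged confirmed/suspected patient fixtures.

Table conventions: one row per newborn; empty cells, ``-`` and ``ND`` are
missing; ``<x`` is a censored value carried at its bound ``x``; an empty
genotype cell means sequencing was not performed, the literal token
``negative`` means sequencing was performed and found no variant.  The
packaged fixtures preserve the source report's verbatim spellings
(normalization happens at parse time, keeping provenance auditable) and are
checksum-pinned so that transcription edits are deliberate.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FixtureIntegrityError, FormatError
from .screening import Measurement, ScreeningRecord
from .variants import VariantClass, VariantKB, build_kb

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "-", "nd", "na", "n/a", "."}

#: sha256 digests of the packaged data files; edits must be deliberate.
_FIXTURE_SHA256 = {
    "gaa_variant_kb.tsv": "df0efe31c388908bce32e90ac9910b1bd1c624596160032d736c2e3c07fa0e83",
    "table2_confirmed.tsv": "7d6c0cbf59fbc24e5ae6edfae125d9ba23bfaa78ee3942765f37dbd1e28925e7",
    "table3_suspected.tsv": "d3e5acc1e70528d48edd81e8e4f2745007a9d29c12c9a4950d16e17575c1a469",
}

_RECORD_COLUMNS = [
    "id", "group", "cardiomyopathy", "gaa1", "gaa2", "genotype",
    "conf_gaa", "conf_gaa_limit", "ast", "ast_ref", "alt", "alt_ref",
    "ck", "ck_ref", "bnp", "bnp_ref", "hex4", "hex4_ref", "note",
]


def _is_missing(cell: str | None) -> bool:
    if cell is None:
        return True
    return cell.strip().lower() in _MISSING_TOKENS


def parse_cell(cell: str | None, *, where: str = "") -> tuple[float | None, str | None]:
    """Parse one numeric cell → (value, censor-marker).

    ``<x``/``>x`` style bounds return ``(x, "<"|">")``.  Non-numeric text is
    reported as missing with a warning (e.g. a printed "ND").
    """
    if _is_missing(cell):
        return None, None
    text = cell.strip()
    censor = None
    if text[0] in "<>≤≥":
        censor = "<" if text[0] in "<≤" else ">"
        text = text[1:].strip()
    # drop a printed unit suffix if any ("1.84 umol/L/h")
    text = text.split()[0] if text else text
    try:
        value = float(text)
    except ValueError:
        logger.warning("unparseable numeric cell %r%s; treated as missing",
                       cell, f" at {where}" if where else "")
        return None, None
    if not math.isfinite(value):
        return None, None
    return value, censor


def _parse_ref(cell: str | None) -> tuple[float | None, float | None]:
    """Parse a 'low-high' reference-range cell."""
    if _is_missing(cell):
        return None, None
    text = cell.strip()
    if "-" in text[1:]:  # allow a leading minus
        lo_s, hi_s = text[1:].split("-", 1)
        lo_s = text[0] + lo_s
        try:
            return float(lo_s), float(hi_s)
        except ValueError:
            return None, None
    try:
        return None, float(text)
    except ValueError:
        return None, None


def _measurement(row: dict, name: str, *, where: str) -> Measurement | None:
    value, censor = parse_cell(row.get(name), where=f"{where}:{name}")
    if value is None:
        return None
    lo, hi = _parse_ref(row.get(f"{name}_ref"))
    return Measurement(value, lo, hi, censor)


def _record_from_row(row: dict, where: str) -> ScreeningRecord:
    gaa1, _ = parse_cell(row.get("gaa1"), where=f"{where}:gaa1")
    gaa2, _ = parse_cell(row.get("gaa2"), where=f"{where}:gaa2")
    geno_cell = row.get("genotype")
    if _is_missing(geno_cell):
        genotype_raw = None
    elif geno_cell.strip().lower() == "negative":
        genotype_raw = ""
    else:
        genotype_raw = geno_cell.strip()

    conf_value, conf_censor = parse_cell(row.get("conf_gaa"), where=f"{where}:conf_gaa")
    confirmatory = None
    if conf_value is not None:
        limit, _ = parse_cell(row.get("conf_gaa_limit"))
        confirmatory = Measurement(conf_value, ref_low=limit, censored=conf_censor)

    cardio_cell = (row.get("cardiomyopathy") or "").strip()
    cardio = cardio_cell in {"1", "true", "True", "yes"}

    return ScreeningRecord(
        id=str(row.get("id")),
        gaa1=gaa1,
        gaa2=gaa2,
        genotype_raw=genotype_raw,
        confirmatory_gaa=confirmatory,
        ast=_measurement(row, "ast", where=where),
        alt=_measurement(row, "alt", where=where),
        ck=_measurement(row, "ck", where=where),
        bnp=_measurement(row, "bnp", where=where),
        hex4=_measurement(row, "hex4", where=where),
        cardiomyopathy_or_symptoms=cardio,
        note=(row.get("note") or "").strip(),
    )


def read_records(path: str | Path, dialect: str = "auto") -> list[ScreeningRecord]:
    """Read screening records from a CSV/TSV file (``#`` comments allowed).

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``"auto"`` (by file suffix).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r and not r[0].startswith("#")]
    if not rows:
        raise FormatError(f"{path}: empty table")
    header = [h.strip() for h in rows[0]]
    if "id" not in header:
        raise FormatError(f"{path}: mandatory 'id' column missing")
    records = []
    for i, raw in enumerate(rows[1:], start=2):
        row = dict(zip(header, (c for c in raw)))
        records.append(_record_from_row(row, where=f"{path.name}:{i}"))
    return records


def _fmt(value: float | None, censor: str | None = None) -> str:
    if value is None:
        return ""
    return f"{censor or ''}{value:g}"


def _fmt_ref(m: Measurement | None) -> str:
    if m is None or (m.ref_low is None and m.ref_high is None):
        return ""
    if m.ref_low is None:
        return f"{m.ref_high:g}"
    return f"{m.ref_low:g}-{m.ref_high:g}"


def write_records(records: Sequence[ScreeningRecord], path: str | Path,
                  dialect: str = "auto",
                  extra_columns: dict[str, Sequence] | None = None) -> None:
    """Write records back to CSV/TSV, inverse of :func:`read_records`.

    ``extra_columns`` appends per-record output columns (e.g. ``outcome``).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    extra = extra_columns or {}
    for name, column in extra.items():
        if len(column) != len(records):
            raise FormatError(f"extra column {name!r} has wrong length")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(_RECORD_COLUMNS + list(extra))
        for j, r in enumerate(records):
            geno = "" if r.genotype_raw is None else (r.genotype_raw or "negative")
            writer.writerow([
                r.id, "", "1" if r.cardiomyopathy_or_symptoms else "0",
                _fmt(r.gaa1), _fmt(r.gaa2), geno,
                _fmt(r.confirmatory_gaa.value, r.confirmatory_gaa.censored) if r.confirmatory_gaa else "",
                _fmt(r.confirmatory_gaa.ref_low) if r.confirmatory_gaa else "",
                _fmt(r.ast.value, r.ast.censored) if r.ast else "", _fmt_ref(r.ast),
                _fmt(r.alt.value, r.alt.censored) if r.alt else "", _fmt_ref(r.alt),
                _fmt(r.ck.value, r.ck.censored) if r.ck else "", _fmt_ref(r.ck),
                _fmt(r.bnp.value, r.bnp.censored) if r.bnp else "", _fmt_ref(r.bnp),
                _fmt(r.hex4.value, r.hex4.censored) if r.hex4 else "", _fmt_ref(r.hex4),
                r.note,
            ] + [extra[name][j] for name in extra])


# ---------------------------------------------------------------------------
# packaged data
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("pompe_nbs").joinpath("data", name)))


def _verify_checksum(path: Path, expected: str) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise FixtureIntegrityError(
            f"{path.name}: sha256 {digest} != pinned {expected}; "
            "packaged data was modified"
        )


def load_kb(path: str | Path) -> VariantKB:
    """Load a variant KB from a two-column TSV (hgvs_c, classification)."""
    entries: list[tuple[str, VariantClass]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed KB line {line!r}")
            spelling, cls = parts[0].strip(), parts[1].strip()
            if spelling == "hgvs_c":
                continue
            entries.append((spelling, VariantClass(cls)))
    return build_kb(entries)


def load_default_kb(verify: bool = True) -> VariantKB:
    """The packaged KB covering every variant spelling in the fixture tables."""
    path = _data_path("gaa_variant_kb.tsv")
    if verify:
        _verify_checksum(path, _FIXTURE_SHA256["gaa_variant_kb.tsv"])
    return load_kb(path)


@dataclass(frozen=True)
class FixtureTables:
    """The packaged confirmed (IOPD+LOPD) and suspected-LOPD patient tables."""

    table2: tuple[ScreeningRecord, ...]
    table3: tuple[ScreeningRecord, ...]

    @property
    def all_records(self) -> tuple[ScreeningRecord, ...]:
        return self.table2 + self.table3

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for source, recs in (("confirmed", self.table2), ("suspected", self.table3)):
            for r in recs:
                rows.append({
                    "id": r.id, "source": source, "gaa1": r.gaa1, "gaa2": r.gaa2,
                    "genotype": r.genotype_raw,
                    "conf_gaa": r.confirmatory_gaa.value if r.confirmatory_gaa else None,
                    "ast": r.ast.value if r.ast else None,
                    "alt": r.alt.value if r.alt else None,
                    "ck": r.ck.value if r.ck else None,
                    "bnp": r.bnp.value if r.bnp else None,
                    "hex4": r.hex4.value if r.hex4 else None,
                    "cardiomyopathy": r.cardiomyopathy_or_symptoms,
                })
        return pd.DataFrame(rows)


def load_fixtures(verify: bool = True) -> FixtureTables:
    """Load the packaged patient tables (33 confirmed + 30 suspected rows).

    Raises
    ------
    FixtureIntegrityError
        If a packaged file's checksum does not match its pinned value.
    """
    paths = {name: _data_path(name) for name in
             ("table2_confirmed.tsv", "table3_suspected.tsv")}
    if verify:
        for name, path in paths.items():
            _verify_checksum(path, _FIXTURE_SHA256[name])
    table2 = read_records(paths["table2_confirmed.tsv"], dialect="tsv")
    table3 = read_records(paths["table3_suspected.tsv"], dialect="tsv")
    if len(table2) != 33 or len(table3) != 30:
        raise FixtureIntegrityError(
            f"fixture row counts {len(table2)}/{len(table3)}, expected 33/30"
        )
    return FixtureTables(tuple(table2), tuple(table3))


#: Program-level constants of the reported screening cohort.
TOTAL_SCREENED = 531_139
FIRST_TIER_POSITIVE = 180
SECOND_TIER_POSITIVE = 115

#: Reported final-category counts for the categories whose per-patient data
#: are not tabulated (used for whole-cohort summaries and as simulation
#: prevalence anchors).
REPORTED_COUNTS = {
    "IOPD": 2,
    "LOPD": 31,
    "suspected_LOPD": 30,
    "carrier": 35,
    "pseudodeficiency": 15,
    "false_positive": 2,
}
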