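"""Referral-level cohort containers, TOP clinical-feature stratification and CSV I/O.

A *referral* is one primary-care presentation of a female patient to a
specialist breast clinic.  Repeat referrals of the same patient are
independent rows by design.  Each record carries the referral route
(``urgent`` two-week-wait vs ``cb`` choose-and-book), demographics, the
three non-exclusive TOP clinical-feature flags (Tumour / Observation /
somatosensory Perception), and the cancer outcome.

Missing values are represented as ``None`` on records and ``NaN`` in the
tabular view; only ``gravidity``, ``breastfeeding`` and ``family_history``
may be missing — the outcome, route and age never are.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, fields as _dc_fields
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferralRecord",
    "Cohort",
    "CohortError",
    "UnrecognizedTermWarning",
    "stratify_top",
    "read_cohort",
    "write_cohort",
    "complete_cases",
    "CSV_COLUMNS",
    "MISSABLE_FIELDS",
    "FAMILY_HISTORY_LEVELS",
]

ROUTE_URGENT = "urgent"
ROUTE_CB = "cb"
ROUTES = (ROUTE_URGENT, ROUTE_CB)
FAMILY_HISTORY_LEVELS = ("none_other", "second_degree", "first_degree")

CSV_COLUMNS = [
    "id", "age", "route", "top_t", "top_o", "top_p", "gravidity",
    "previous_bc", "menopause", "breastfeeding", "family_history",
    "hrt", "cancer",
]

#: binary 0/1 fields
BINARY_FIELDS = (
    "top_t", "top_o", "top_p", "gravidity", "previous_bc", "menopause",
    "breastfeeding", "hrt", "cancer",
)
#: fields where an empty CSV cell / None is a legal "unknown" state
MISSABLE_FIELDS = frozenset({"gravidity", "breastfeeding", "family_history"})

AGE_BOUNDS = (0.0, 120.0)


class CohortError(ValueError):
    """Malformed cohort data (bad field value, duplicate id, bad CSV row)."""


class UnrecognizedTermWarning(UserWarning):
    """A free-text symptom term matched no TOP category keyword."""


# --------------------------------------------------------------------------
# TOP stratification
# --------------------------------------------------------------------------
# Keyword table for the three clinical-feature categories.  T covers
# anything palpable, O anything visible on inspection, P any subjective
# sensation.  Categories are not mutually exclusive.  Matching is
# case-insensitive whole-word with light stemming (plural -s and -ing
# suffixes only); "skin thickening" is a visible skin sign (O) while bare
# "thickening" is palpable (T), handled as a phrase rule.
TOP_KEYWORDS = {
    "top_t": frozenset({
        "lump", "thickening", "nodularity", "firmness", "hardness",
    }),
    "top_o": frozenset({
        # nipple signs
        "discharge", "inversion", "flattening", "creasing", "retraction",
        "shrinkage",
        # skin signs
        "tethering", "dimpling", "puckering", "oedema", "edema", "redness",
        "discoloration", "discolouration", "bruising",
        # skin lesions
        "eczema", "cyst", "rash", "ulcer", "abscess", "boil", "cellulitis",
        # shape
        "swelling", "enlargement", "asymmetry", "distortion",
    }),
    "top_p": frozenset({
        "pain", "tenderness", "awareness", "itch", "discomfort",
        "sensitivity", "heaviness", "tingling", "burning",
    }),
}

#: phrase rules applied before single-word matching; matched tokens are
#: consumed so they cannot double-match another category.
TOP_PHRASES = {
    "top_o": (("skin", "thickening"),),
}


def _stem(token: str) -> str:
    token = token.lower()
    if token.endswith("ing") and len(token) > 5:
        return token[:-3]
    if token.endswith("s") and not token.endswith("ss") and len(token) > 3:
        return token[:-1]
    return token


_STEMMED_KEYWORDS = {
    cat: frozenset(_stem(w) for w in words) for cat, words in TOP_KEYWORDS.items()
}


def _tokenize(term: str) -> list[str]:
    out, cur = [], []
    for ch in term.lower():
        if ch.isalpha():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def stratify_top(terms: Sequence[str]) -> tuple[int, int, int]:
    """Map free-text symptom/sign terms onto the (T, O, P) binary triple.

    Each flag is set iff any token (or phrase) in ``terms`` matches that
    category's keyword list.  Unrecognized terms leave all flags unchanged
    and raise an :class:`UnrecognizedTermWarning`.  Idempotent and
    insensitive to term order.
    """
    flags = {"top_t": 0, "top_o": 0, "top_p": 0}
    for term in terms:
        tokens = [_stem(t) for t in _tokenize(str(term))]
        consumed = [False] * len(tokens)
        matched = False
        for cat, phrases in TOP_PHRASES.items():
            for phrase in phrases:
                stemmed = tuple(_stem(w) for w in phrase)
                k = len(stemmed)
                for i in range(len(tokens) - k + 1):
                    if tuple(tokens[i:i + k]) == stemmed and not any(consumed[i:i + k]):
                        flags[cat] = 1
                        matched = True
                        for j in range(i, i + k):
                            consumed[j] = True
        for tok, used in zip(tokens, consumed):
            if used:
                continue
            for cat, words in _STEMMED_KEYWORDS.items():
                if tok in words:
                    flags[cat] = 1
                    matched = True
        if not matched:
            warnings.warn(
                f"symptom term {term!r} matched no TOP category",
                UnrecognizedTermWarning,
                stacklevel=2,
            )
    return flags["top_t"], flags["top_o"], flags["top_p"]


# --------------------------------------------------------------------------
# Records and cohorts
# --------------------------------------------------------------------------
@dataclass
class ReferralRecord:
    """One referral: demographics, route, TOP flags and cancer outcome."""

    id: str
    age: float
    route: str
    top_t: int
    top_o: int
    top_p: int
    gravidity: Optional[int]
    previous_bc: int
    menopause: int
    breastfeeding: Optional[int]
    family_history: Optional[str]
    hrt: int
    cancer: int

    def __post_init__(self) -> None:
        if not self.id:
            raise CohortError("record id must be a non-empty string")
        try:
            self.age = float(self.age)
        except (TypeError, ValueError):
            raise CohortError(f"record {self.id}: age {self.age!r} is not a number")
        if not (AGE_BOUNDS[0] <= self.age <= AGE_BOUNDS[1]):
            raise CohortError(f"record {self.id}: age {self.age} outside {AGE_BOUNDS}")
        if self.route not in ROUTES:
            raise CohortError(f"record {self.id}: route {self.route!r} not in {ROUTES}")
        for name in BINARY_FIELDS:
            value = getattr(self, name)
            if value is None:
                if name in MISSABLE_FIELDS:
                    continue
                raise CohortError(f"record {self.id}: field '{name}' may not be missing")
            if value not in (0, 1):
                raise CohortError(
                    f"record {self.id}: field '{name}' must be 0 or 1, got {value!r}"
                )
            setattr(self, name, int(value))
        if self.family_history is not None and self.family_history not in FAMILY_HISTORY_LEVELS:
            raise CohortError(
                f"record {self.id}: family_history {self.family_history!r} "
                f"not in {FAMILY_HISTORY_LEVELS}"
            )


def _records_to_frame(records: Sequence[ReferralRecord]) -> pd.DataFrame:
    data: dict[str, list] = {c: [] for c in CSV_COLUMNS}
    for r in records:
        for c in CSV_COLUMNS:
            v = getattr(r, c)
            data[c].append(np.nan if v is None else v)
    df = pd.DataFrame(data, columns=CSV_COLUMNS)
    if len(df):
        df["age"] = df["age"].astype(float)
        for b in BINARY_FIELDS:
            df[b] = df[b].astype(float)
    return df


def _validate_frame(df: pd.DataFrame) -> None:
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort frame lacks columns {missing_cols}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise CohortError(f"duplicate record id {dup!r}")
    if len(df) == 0:
        return
    age = df["age"].to_numpy(float)
    if np.isnan(age).any():
        raise CohortError("field 'age' may not be missing")
    if ((age < AGE_BOUNDS[0]) | (age > AGE_BOUNDS[1])).any():
        raise CohortError(f"age outside {AGE_BOUNDS}")
    if not df["route"].isin(ROUTES).all():
        bad = df.loc[~df["route"].isin(ROUTES), "route"].iloc[0]
        raise CohortError(f"route {bad!r} not in {ROUTES}")
    for b in BINARY_FIELDS:
        col = df[b].to_numpy(float)
        isnan = np.isnan(col)
        if isnan.any() and b not in MISSABLE_FIELDS:
            raise CohortError(f"field '{b}' may not be missing")
        ok = isnan | (col == 0) | (col == 1)
        if not ok.all():
            raise CohortError(f"field '{b}' must be 0 or 1")
    fh = df["family_history"]
    bad_fh = fh.notna() & ~fh.isin(FAMILY_HISTORY_LEVELS)
    if bad_fh.any():
        raise CohortError(
            f"family_history {fh[bad_fh].iloc[0]!r} not in {FAMILY_HISTORY_LEVELS}"
        )


class Cohort:
    """Ordered collection of :class:`ReferralRecord` with unique ids.

    Internally backed by a :class:`pandas.DataFrame` (column schema
    :data:`CSV_COLUMNS`) so downstream statistics operate vectorised;
    iteration materialises records on demand.
    """

    def __init__(self, records: Iterable[ReferralRecord] = (), provenance: str = ""):
        records = list(records)
        self._df = _records_to_frame(records)
        _validate_frame(self._df)
        self.provenance = provenance

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        obj = cls.__new__(cls)
        df = df.reset_index(drop=True)[CSV_COLUMNS].copy()
        df["id"] = df["id"].astype(str)
        if len(df):
            df["age"] = df["age"].astype(float)
            for b in BINARY_FIELDS:
                df[b] = df[b].astype(float)
        _validate_frame(df)
        obj._df = df
        obj.provenance = provenance
        return obj

    @property
    def frame(self) -> pd.DataFrame:
        """Tabular view (copy); missing values are NaN."""
        return self._df.copy()

    def size(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return len(self._df)

    def _record_at(self, i: int) -> ReferralRecord:
        row = self._df.iloc[i]

        def _get(name):
            v = row[name]
            if isinstance(v, float) and np.isnan(v):
                return None
            return v

        kwargs = {}
        for c in CSV_COLUMNS:
            v = _get(c)
            if c in BINARY_FIELDS and v is not None:
                v = int(v)
            kwargs[c] = v
        return ReferralRecord(**kwargs)

    def __getitem__(self, i: int) -> ReferralRecord:
        return self._record_at(int(i))

    def __iter__(self) -> Iterator[ReferralRecord]:
        for i in range(len(self)):
            yield self._record_at(i)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cohort(n={len(self)}, provenance={self.provenance!r})"


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------
def _parse_cell(name: str, raw: str, line: int):
    raw = raw.strip()
    if raw == "":
        if name in MISSABLE_FIELDS:
            return None
        raise CohortError(f"row {line}: missing value in non-missable field '{name}'")
    if name == "id":
        return raw
    if name == "age":
        try:
            return float(raw)
        except ValueError:
            raise CohortError(f"row {line}: field 'age': {raw!r} is not a number")
    if name == "route":
        if raw not in ROUTES:
            raise CohortError(f"row {line}: field 'route': {raw!r} not in {ROUTES}")
        return raw
    if name == "family_history":
        if raw not in FAMILY_HISTORY_LEVELS:
            raise CohortError(
                f"row {line}: field 'family_history': {raw!r} "
                f"not in {FAMILY_HISTORY_LEVELS}"
            )
        return raw
    # binary
    if raw not in ("0", "1"):
        raise CohortError(f"row {line}: field '{name}': {raw!r} must be 0 or 1")
    return int(raw)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (schema :data:`CSV_COLUMNS`; empty cell = missing)."""
    records: list[ReferralRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortError(f"{path}: empty file")
        if [h.strip() for h in header] != CSV_COLUMNS:
            raise CohortError(
                f"{path}: bad header {header!r}; expected {CSV_COLUMNS}"
            )
        for line, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(CSV_COLUMNS):
                raise CohortError(
                    f"row {line}: expected {len(CSV_COLUMNS)} cells, got {len(row)}"
                )
            values = {
                name: _parse_cell(name, cell, line)
                for name, cell in zip(CSV_COLUMNS, row)
            }
            try:
                records.append(ReferralRecord(**values))
            except CohortError as exc:
                raise CohortError(f"row {line}: {exc}") from exc
    return Cohort(records, provenance=str(path))


def _format_cell(name: str, value) -> str:
    if value is None:
        return ""
    if name == "age":
        return repr(float(value))
    if name in BINARY_FIELDS:
        return str(int(value))
    return str(value)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV; round-trips exactly through :func:`read_cohort`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in cohort:
            writer.writerow(_format_cell(c, getattr(rec, c)) for c in CSV_COLUMNS)


# --------------------------------------------------------------------------
# Complete cases
# --------------------------------------------------------------------------
def complete_cases(cohort: Cohort, fields: Iterable[str]) -> Cohort:
    """Keep only records with no missing value among ``fields`` (order kept)."""
    fields = list(fields)
    known = {f.name for f in _dc_fields(ReferralRecord)}
    unknown = [f for f in fields if f not in known]
    if unknown:
        raise CohortError(f"unknown field name(s) {unknown}")
    df = cohort.frame
    if not fields or len(df) == 0:
        return Cohort.from_frame(df, provenance=cohort.provenance)
    mask = np.ones(len(df), dtype=bool)
    for f in fields:
        mask &= df[f].notna().to_numpy()
    return Cohort.from_frame(df.loc[mask], provenance=cohort.provenance)
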