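"""Corrected per-number frequency tables from raw n-gram-style inputs.

The corpus pipeline: list the numeral spellings of a language
(``generate_numerals``), average raw per-year n-gram frequencies over
a time window (``average_years``), sum the spelling variants of each
value (``merge_variants``), and remove the double counting of
component words that occur inside larger composite numerals
(``containment_correction`` — e.g. raw counts of "twenty" include
every "twenty-one", "twenty-two", ...).  Tables are plain TSV.

An optional online adapter (``fetch_ngrams``) queries the public
n-gram service; it is a convenience for live data only and nothing in
the offline pipeline depends on it.
"""

from __future__ import annotations

import json
import logging
import re
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import numerals
from .numerals import LANGUAGE_MAX, SUPPORTED_LANGUAGES

__all__ = [
    "NumeralEntry",
    "RawNgramTable",
    "CorrectedTable",
    "TableParseError",
    "generate_numerals",
    "average_years",
    "merge_variants",
    "containment_correction",
    "read_table",
    "write_table",
    "fetch_ngrams",
]

logger = logging.getLogger(__name__)

DEFAULT_YEAR_WINDOW = (1950, 2000)


class TableParseError(ValueError):
    """A frequency table file failed validation; carries the line number."""


@dataclass(frozen=True)
class NumeralEntry:
    """One numeral of one language: value, spellings, tokens, length."""

    language: str
    value: int
    surface_forms: tuple[str, ...]
    tokens: tuple[str, ...]
    char_length: int

    @property
    def canonical(self) -> str:
        return self.surface_forms[0]


@dataclass
class RawNgramTable:
    """Raw per-surface-form frequencies, per-year or already averaged.

    ``rows`` maps a surface form to either a single ppm value or a
    ``{year: ppm}`` mapping.
    """

    language: str
    rows: dict[str, float | dict[int, float]]
    year_window: tuple[int, int] | None = None


@dataclass
class CorrectedTable:
    """Per-value frequencies (ppm) after variant merging and correction."""

    language: str
    freqs: dict[int, float]
    provenance: str = ""
    corrected: bool = True

    @property
    def values(self) -> list[int]:
        return sorted(self.freqs)

    def __getitem__(self, value: int) -> float:
        return self.freqs[value]

    def __len__(self) -> int:
        return len(self.freqs)

    def log10(self) -> dict[int, float]:
        return {v: float(np.log10(f)) for v, f in self.freqs.items()}


def generate_numerals(
    language: str, value_range: range | None = None
) -> list[NumeralEntry]:
    """Numeral entries for a language, 1..99 by default (French 1..97).

    Surface forms include dash and dash-free spellings where the
    language allows both, plus common gender variants; tokens are the
    component words of the canonical form; ``char_length`` counts every
    character of the canonical form, dashes and spaces included.
    """
    if language not in SUPPORTED_LANGUAGES:
        raise ValueError(
            f"unsupported language {language!r}; supported: "
            f"{', '.join(SUPPORTED_LANGUAGES)}"
        )
    top = LANGUAGE_MAX[language]
    if value_range is None:
        value_range = range(1, top + 1)
    entries = []
    for v in value_range:
        if not (1 <= v <= top):
            continue  # e.g. 98/99 fall outside the French range
        forms = numerals.spell(language, v)
        entries.append(
            NumeralEntry(
                language=language,
                value=v,
                surface_forms=tuple(forms),
                tokens=tuple(numerals.tokens(language, v)),
                char_length=len(forms[0]),
            )
        )
    return entries


def average_years(
    row: dict[int, float] | float,
    year_start: int = DEFAULT_YEAR_WINDOW[0],
    year_end: int = DEFAULT_YEAR_WINDOW[1],
) -> float:
    """Arithmetic mean of per-year frequencies over an inclusive window.

    Years missing from the record are dropped from the denominator
    rather than zero-filled.  A bare number is returned unchanged
    (already-averaged input).
    """
    if isinstance(row, (int, float)):
        return float(row)
    in_window = [f for y, f in row.items() if year_start <= y <= year_end]
    if not in_window:
        raise ValueError(f"no years within [{year_start}, {year_end}] in record")
    return float(np.mean(in_window))


def merge_variants(
    entries: list[NumeralEntry], raw_table: RawNgramTable
) -> dict[int, float]:
    """Per-value raw frequency: sum of averaged frequencies of all spellings.

    A spelling absent from the raw table contributes 0 and is logged.
    """
    window = raw_table.year_window or DEFAULT_YEAR_WINDOW
    merged: dict[int, float] = {}
    for entry in entries:
        total = 0.0
        for form in entry.surface_forms:
            if form in raw_table.rows:
                total += average_years(raw_table.rows[form], *window)
            else:
                logger.warning(
                    "surface form %r (value %d, %s) missing from raw table; counted as 0",
                    form, entry.value, entry.language,
                )
        merged[entry.value] = total
    return merged


def _contains(container: tuple[str, ...], part: tuple[str, ...]) -> bool:
    """True if ``part`` occurs as a contiguous token run inside ``container``."""
    k = len(part)
    if k >= len(container):
        return False
    return any(container[i : i + k] == part for i in range(len(container) - k + 1))


def containment_correction(
    raw_by_value: dict[int, float], entries: list[NumeralEntry]
) -> CorrectedTable:
    """Remove double counting of numerals occurring inside larger numerals.

    ``corrected(v) = raw(v) - sum of raw(u)`` over every other in-range
    numeral ``u`` whose token sequence contains ``v``'s full token
    sequence (whole component words, e.g. "twenty" inside
    "twenty-one" but never "six" inside "sixty").  The correction is a
    single pass over raw values, not iterated on corrected ones.
    """
    by_value = {e.value: e for e in entries}
    missing = sorted(set(by_value) - set(raw_by_value))
    if missing:
        raise ValueError(f"raw table missing values: {missing}")
    corrected: dict[int, float] = {}
    for v, entry in by_value.items():
        containers = [
            u
            for u, other in by_value.items()
            if u != v and _contains(other.tokens, entry.tokens)
        ]
        corrected[v] = raw_by_value[v] - sum(raw_by_value[u] for u in containers)
        if corrected[v] <= 0:
            raise ValueError(
                f"containment correction drove value {v} ({entry.canonical!r}) "
                f"to {corrected[v]:.6g} <= 0; raw input looks malformed"
            )
    language = entries[0].language if entries else "?"
    return CorrectedTable(
        language=language,
        freqs=dict(sorted(corrected.items())),
        provenance="containment_correction(single pass, token-level)",
        corrected=True,
    )


_YEAR_COL = re.compile(r"^year_(\d{4})$")


def read_table(path: str | Path) -> CorrectedTable:
    """Read a TSV frequency table (language, value, frequency_ppm[, year_YYYY...]).

    Per-year columns, when present, are averaged over the default
    window on read.  Malformed rows raise :class:`TableParseError`
    naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"language", "value"}
    if not required <= set(df.columns):
        raise TableParseError(
            f"{path}: missing required column(s) {sorted(required - set(df.columns))}"
        )
    year_cols = {c: int(_YEAR_COL.match(c).group(1)) for c in df.columns if _YEAR_COL.match(c)}
    if not year_cols and "frequency_ppm" not in df.columns:
        raise TableParseError(f"{path}: need frequency_ppm or year_YYYY columns")
    freqs: dict[int, float] = {}
    language = None
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header line
        try:
            value = int(row["value"])
        except (TypeError, ValueError):
            raise TableParseError(
                f"{path}:{line}: non-integer value cell {row['value']!r}"
            ) from None
        try:
            if year_cols:
                series = {
                    y: float(row[c]) for c, y in year_cols.items() if pd.notna(row[c])
                }
                freq = average_years(series)
            else:
                freq = float(row["frequency_ppm"])
        except (TypeError, ValueError):
            raise TableParseError(
                f"{path}:{line}: non-numeric frequency cell"
            ) from None
        freqs[value] = freq
        language = row["language"]
    return CorrectedTable(
        language=str(language),
        freqs=dict(sorted(freqs.items())),
        provenance=f"read_table({path.name})",
    )


def write_table(table: CorrectedTable, path: str | Path) -> None:
    """Write a CorrectedTable as TSV (language, value, frequency_ppm)."""
    df = pd.DataFrame(
        {
            "language": table.language,
            "value": table.values,
            "frequency_ppm": [table.freqs[v] for v in table.values],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# --- optional online adapter (live corpus queries; not used offline) -------

NGRAM_ENDPOINT = "https://books.google.com/ngrams/json"
_NGRAM_CORPORA = {"en": "en-2019", "fr": "fr-2019", "it": "it-2019",
                  "de": "de-2019", "es": "es-2019", "ru": "ru-2019"}


def fetch_ngrams(
    language: str,
    forms: list[str],
    window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
    cache_dir: str | Path | None = None,
    _opener=urllib.request.urlopen,
) -> RawNgramTable:
    """Query the public n-gram service for per-year frequencies (ppm).

    Results are cached to ``cache_dir`` as JSON keyed by query; the
    corpus version string is recorded in the cache.  Arabic-numeral
    queries (digit strings) go through the same path; no containment
    correction applies to them since each digit string is one token.
    This adapter needs the network and is outside the offline pipeline.
    """
    corpus = _NGRAM_CORPORA.get(language)
    if corpus is None:
        raise ValueError(f"no n-gram corpus mapping for language {language!r}")
    cache_path = None
    if cache_dir is not None:
        key = f"{corpus}_{window[0]}-{window[1]}_{'_'.join(sorted(forms))}"
        cache_path = Path(cache_dir) / (re.sub(r"[^\w\-]", "-", key)[:200] + ".json")
        if cache_path.exists():
            rows = {
                form: {int(y): f for y, f in series.items()}
                for form, series in json.loads(cache_path.read_text()).items()
            }
            return RawNgramTable(language, rows, window)
    query = urllib.parse.urlencode(
        {
            "content": ",".join(forms),
            "year_start": window[0],
            "year_end": window[1],
            "corpus": corpus,
            "smoothing": 0,
        }
    )
    with _opener(f"{NGRAM_ENDPOINT}?{query}") as resp:
        payload = json.loads(resp.read().decode("utf-8"))
    rows: dict[str, float | dict[int, float]] = {}
    for item in payload:
        years = range(window[0], window[1] + 1)
        # service returns fractional frequencies; convert to ppm
        rows[item["ngram"]] = {
            y: f * 1e6 for y, f in zip(years, item["timeseries"])
        }
    for form in forms:
        rows.setdefault(form, {})
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(json.dumps(rows))
    return RawNgramTable(language, rows, window)
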