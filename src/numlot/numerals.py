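"""Numeral spellings for 1-99 in six languages.

Rule-based spell-out of cardinal numerals in English, French, Italian,
German, Spanish and Russian, including the orthographic variants the
corpus work needs: dash vs space spellings where a language writes
compounds as separate words, and the common gender variants (uno/una,
un/une, veintiuno/veintiuna, один/одна/одно, ...).  The first form
returned for each value is the canonical one; its split on dashes and
spaces yields the component-word tokens used by the containment
correction.

French covers 1-97 only: 98 and 99 are four-word numerals, beyond the
5-gram window of the corpus interface this package mirrors, and are
excluded from the French range throughout.

The Russian gender/case coverage is curated best-effort: nominative
masculine/feminine/neuter for 1 and masculine/feminine for 2, the
forms that dominate corpus counts; oblique cases are not enumerated.
"""

from __future__ import annotations

SUPPORTED_LANGUAGES = ("en", "fr", "it", "de", "es", "ru")

#: inclusive upper end of each language's numeral range
LANGUAGE_MAX = {lang: 99 for lang in SUPPORTED_LANGUAGES}
LANGUAGE_MAX["fr"] = 97


def spell(language: str, value: int) -> list[str]:
    """All surface forms for ``value``, canonical form first."""
    if language not in SUPPORTED_LANGUAGES:
        raise ValueError(
            f"unsupported language {language!r}; supported: {', '.join(SUPPORTED_LANGUAGES)}"
        )
    if not (1 <= value <= LANGUAGE_MAX[language]):
        raise ValueError(
            f"value {value} outside the {language} range 1..{LANGUAGE_MAX[language]}"
        )
    return _SPELLERS[language](value)


def tokens(language: str, value: int) -> list[str]:
    """Component words of the canonical form (split on dashes and spaces)."""
    return spell(language, value)[0].replace("-", " ").split()


# --- English ---------------------------------------------------------------

_EN_SMALL = (
    "one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen"
).split()
_EN_TENS = {
    20: "twenty", 30: "thirty", 40: "forty", 50: "fifty",
    60: "sixty", 70: "seventy", 80: "eighty", 90: "ninety",
}


def _spell_en(v: int) -> list[str]:
    if v < 20:
        return [_EN_SMALL[v - 1]]
    tens, unit = divmod(v, 10)
    if unit == 0:
        return [_EN_TENS[tens * 10]]
    t, u = _EN_TENS[tens * 10], _EN_SMALL[unit - 1]
    return [f"{t}-{u}", f"{t} {u}"]


# --- French ----------------------------------------------------------------

_FR_SMALL = (
    "un deux trois quatre cinq six sept huit neuf dix onze douze treize "
    "quatorze quinze seize dix-sept dix-huit dix-neuf"
).split()
_FR_TENS = {20: "vingt", 30: "trente", 40: "quarante", 50: "cinquante", 60: "soixante"}


def _spell_fr(v: int) -> list[str]:
    if v == 1:
        return ["un", "une"]
    if v < 20:
        return [_FR_SMALL[v - 1]]
    if v < 70:
        tens, unit = divmod(v, 10)
        t = _FR_TENS[tens * 10]
        if unit == 0:
            return [t]
        if unit == 1:  # "vingt et un" (+ 1990-reform dashed spelling, + feminine)
            return [f"{t} et un", f"{t}-et-un", f"{t} et une"]
        u = _FR_SMALL[unit - 1]
        return [f"{t}-{u}", f"{t} {u}"]
    if v < 80:  # 70..79 built on soixante + 10..19
        if v == 71:
            return ["soixante et onze", "soixante-et-onze"]
        u = _FR_SMALL[v - 60 - 1]
        return [f"soixante-{u}", f"soixante {u}"]
    if v == 80:
        return ["quatre-vingts", "quatre vingts"]
    if v < 90:  # 81..89: quatre-vingt-un .. quatre-vingt-neuf (no "et")
        u = _FR_SMALL[v - 80 - 1]
        forms = [f"quatre-vingt-{u}", f"quatre vingt {u}"]
        if v == 81:
            forms.append("quatre-vingt-une")
        return forms
    # 90..97: quatre-vingt-dix .. quatre-vingt-dix-sept
    u = _FR_SMALL[v - 80 - 1]
    return [f"quatre-vingt-{u}", f"quatre vingt {u}"]


# --- Italian ---------------------------------------------------------------

_IT_SMALL = (
    "uno due tre quattro cinque sei sette otto nove dieci undici dodici "
    "tredici quattordici quindici sedici diciassette diciotto diciannove"
).split()
_IT_TENS = {
    20: "venti", 30: "trenta", 40: "quaranta", 50: "cinquanta",
    60: "sessanta", 70: "settanta", 80: "ottanta", 90: "novanta",
}


def _spell_it(v: int) -> list[str]:
    if v == 1:
        return ["uno", "una"]
    if v < 20:
        return [_IT_SMALL[v - 1]]
    tens, unit = divmod(v, 10)
    t = _IT_TENS[tens * 10]
    if unit == 0:
        return [t]
    if unit in (1, 8):  # vowel elision: ventuno, ventotto
        t = t[:-1]
    u = "tré" if unit == 3 else _IT_SMALL[unit - 1]  # ventitré takes the accent
    forms = [f"{t}{u}"]
    if unit == 1:
        forms.append(f"{t}una")
    return forms


# --- German ----------------------------------------------------------------

_DE_SMALL = (
    "eins zwei drei vier fünf sechs sieben acht neun zehn elf zwölf "
    "dreizehn vierzehn fünfzehn sechzehn siebzehn achtzehn neunzehn"
).split()
_DE_TENS = {
    20: "zwanzig", 30: "dreißig", 40: "vierzig", 50: "fünfzig",
    60: "sechzig", 70: "siebzig", 80: "achtzig", 90: "neunzig",
}


def _spell_de(v: int) -> list[str]:
    if v == 1:
        return ["eins", "ein", "eine"]
    if v < 20:
        return [_DE_SMALL[v - 1]]
    tens, unit = divmod(v, 10)
    t = _DE_TENS[tens * 10]
    if unit == 0:
        return [t]
    u = "ein" if unit == 1 else _DE_SMALL[unit - 1]  # einundzwanzig, not eins-
    if unit == 7:
        u = "sieben"
    return [f"{u}und{t}"]


# --- Spanish ---------------------------------------------------------------

_ES_SMALL = (
    "uno dos tres cuatro cinco seis siete ocho nueve diez once doce trece "
    "catorce quince dieciséis diecisiete dieciocho diecinueve"
).split()
_ES_TENS = {
    30: "treinta", 40: "cuarenta", 50: "cincuenta",
    60: "sesenta", 70: "setenta", 80: "ochenta", 90: "noventa",
}
_ES_VEINTI = {
    1: ["veintiuno", "veintiuna"], 2: ["veintidós"], 3: ["veintitrés"],
    4: ["veinticuatro"], 5: ["veinticinco"], 6: ["veintiséis"],
    7: ["veintisiete"], 8: ["veintiocho"], 9: ["veintinueve"],
}


def _spell_es(v: int) -> list[str]:
    if v == 1:
        return ["uno", "una"]
    if v < 20:
        return [_ES_SMALL[v - 1]]
    if v == 20:
        return ["veinte"]
    if v < 30:
        return list(_ES_VEINTI[v - 20])
    tens, unit = divmod(v, 10)
    t = _ES_TENS[tens * 10]
    if unit == 0:
        return [t]
    u = _ES_SMALL[unit - 1]
    forms = [f"{t} y {u}"]
    if unit == 1:
        forms.append(f"{t} y una")
    return forms


# --- Russian ---------------------------------------------------------------

_RU_SMALL = (
    "один два три четыре пять шесть семь восемь девять десять одиннадцать "
    "двенадцать тринадцать четырнадцать пятнадцать шестнадцать семнадцать "
    "восемнадцать девятнадцать"
).split()
_RU_TENS = {
    20: "двадцать", 30: "тридцать", 40: "сорок", 50: "пятьдесят",
    60: "шестьдесят", 70: "семьдесят", 80: "восемьдесят", 90: "девяносто",
}
_RU_GENDER = {1: ["один", "одна", "одно"], 2: ["два", "две"]}


def _spell_ru(v: int) -> list[str]:
    if v in _RU_GENDER:
        return list(_RU_GENDER[v])
    if v < 20:
        return [_RU_SMALL[v - 1]]
    tens, unit = divmod(v, 10)
    t = _RU_TENS[tens * 10]
    if unit == 0:
        return [t]
    if unit in _RU_GENDER:
        return [f"{t} {u}" for u in _RU_GENDER[unit]]
    return [f"{t} {_RU_SMALL[unit - 1]}"]


_SPELLERS = {
    "en": _spell_en,
    "fr": _spell_fr,
    "it": _spell_it,
    "de": _spell_de,
    "es": _spell_es,
    "ru": _spell_ru,
}
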