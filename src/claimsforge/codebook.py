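"""Diagnosis/procedure code-list notation: parsing, matching, and built-in code sets.

Administrative-claims phenotypes are defined as lists of ICD-9 diagnosis
codes, CPT procedure codes, or pharmacy therapeutic-class codes, written in
the compact notation used in the claims literature:

* exact codes          — ``733.42``, ``29914``, ``280808``
* wildcards            — ``295.xx`` (any subdivision of category 295),
                         ``338.2x`` (any fifth digit under 338.2)
* decimal ranges       — ``278.00-278.03`` (fixed-width numeric comparison of
                         the decimal part)
* category ranges      — ``401.xx-405.xx`` (whole categories 401 through 405)
* bare categories      — ``820`` (the category and every subdivision)

The ``.xx`` convention means "any integer after the preceding number is
included".  V-codes are compared case-insensitively and stored upper-case.
Decimal ranges treat the fractional part as a fixed-width integer, so
``278.00-278.03`` does not match ``278.8`` (one- and two-digit decimals are
distinct ICD-9 codes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence


class CodeSystem(str, Enum):
    ICD9_DX = "ICD9_DX"
    CPT = "CPT"
    THERAPEUTIC_CLASS = "THERAPEUTIC_CLASS"


class PatternKind(str, Enum):
    EXACT = "exact"
    WILDCARD = "wildcard"
    DECIMAL_RANGE = "decimal_range"
    CATEGORY_RANGE = "category_range"
    BARE_CATEGORY = "bare_category"


class CodePatternError(ValueError):
    """Raised for malformed pattern text or a code/pattern system mismatch."""


def normalize_code(code: str) -> str:
    """Trim and upper-case the leading V/E of an ICD-9-style code."""
    c = code.strip()
    if c and c[0] in "vVeE":
        c = c[0].upper() + c[1:]
    return c


def split_code(code: str) -> tuple[str, Optional[str]]:
    """Split a normalized code into (category, decimal-part-or-None)."""
    if "." in code:
        cat, dec = code.split(".", 1)
        return cat, dec
    return code, None


_BARE_CATEGORY_RE = re.compile(r"^(\d{3}|V\d{2}|E\d{3})$")


@dataclass(frozen=True)
class CodePattern:
    """One parsed match expression against a single coding system.

    ``raw_text`` is preserved byte-for-byte as printed in the source code
    list; all matching happens on normalized forms.
    """

    raw_text: str
    kind: PatternKind
    system: CodeSystem
    # normalized matching fields (populated per kind)
    category: Optional[str] = None
    decimal_prefix: str = ""
    exact: Optional[str] = None
    cat_lo: Optional[int] = None
    cat_hi: Optional[int] = None
    dec_lo: Optional[int] = None
    dec_hi: Optional[int] = None
    dec_width: Optional[int] = None

    def matches(self, code: str, system: Optional[CodeSystem] = None) -> bool:
        return code_matches(self, code, system=system)


def _parse_wildcard_end(text: str) -> Optional[tuple[str, str]]:
    """Return (category, fixed decimal prefix) if text is a wildcard form."""
    if "." not in text:
        return None
    cat, dec = text.split(".", 1)
    m = re.match(r"^([0-9]*)(x+)$", dec)
    if m is None:
        return None
    return cat, m.group(1)


def parse_pattern(text: str, system: CodeSystem) -> CodePattern:
    """Parse one printed code expression into a :class:`CodePattern`.

    The pattern kind is fully determined by the syntax of ``text``; callers
    never disambiguate.  Malformed text (blank, reversed range, range ends in
    different categories/widths) raises :class:`CodePatternError` naming the
    offending text.
    """
    raw = text
    t = normalize_code(text)
    if not t:
        raise CodePatternError("blank code pattern")
    system = CodeSystem(system)

    if system in (CodeSystem.CPT, CodeSystem.THERAPEUTIC_CLASS):
        if "-" in t or "x" in t.lower():
            raise CodePatternError(
                f"{system.value} patterns must be exact codes: {raw!r}"
            )
        return CodePattern(raw_text=raw, kind=PatternKind.EXACT, system=system, exact=t)

    if "-" in t:
        parts = [normalize_code(p) for p in t.split("-")]
        if len(parts) != 2 or not all(parts):
            raise CodePatternError(f"malformed range: {raw!r}")
        lo_txt, hi_txt = parts
        lo_w, hi_w = _parse_wildcard_end(lo_txt), _parse_wildcard_end(hi_txt)
        if lo_w is not None and hi_w is not None:
            # e.g. 401.xx-405.xx: whole categories, inclusive
            (lo_cat, lo_pre), (hi_cat, hi_pre) = lo_w, hi_w
            if lo_pre or hi_pre:
                raise CodePatternError(f"category range with fixed digits: {raw!r}")
            if not (lo_cat.isdigit() and hi_cat.isdigit()):
                raise CodePatternError(f"non-numeric category range: {raw!r}")
            lo_i, hi_i = int(lo_cat), int(hi_cat)
            if lo_i > hi_i:
                raise CodePatternError(f"reversed range: {raw!r}")
            return CodePattern(
                raw_text=raw, kind=PatternKind.CATEGORY_RANGE, system=system,
                cat_lo=lo_i, cat_hi=hi_i,
            )
        if lo_w is None and hi_w is None and "." in lo_txt and "." in hi_txt:
            lo_cat, lo_dec = split_code(lo_txt)
            hi_cat, hi_dec = split_code(hi_txt)
            if lo_cat != hi_cat:
                raise CodePatternError(
                    f"decimal range must stay within one category: {raw!r}"
                )
            if len(lo_dec) != len(hi_dec) or not (lo_dec.isdigit() and hi_dec.isdigit()):
                raise CodePatternError(f"range ends differ in width: {raw!r}")
            lo_i, hi_i = int(lo_dec), int(hi_dec)
            if lo_i > hi_i:
                raise CodePatternError(f"reversed range: {raw!r}")
            return CodePattern(
                raw_text=raw, kind=PatternKind.DECIMAL_RANGE, system=system,
                category=lo_cat, dec_lo=lo_i, dec_hi=hi_i, dec_width=len(lo_dec),
            )
        raise CodePatternError(f"range ends of different forms: {raw!r}")

    w = _parse_wildcard_end(t)
    if w is not None:
        cat, prefix = w
        return CodePattern(
            raw_text=raw, kind=PatternKind.WILDCARD, system=system,
            category=cat, decimal_prefix=prefix,
        )

    if _BARE_CATEGORY_RE.match(t):
        return CodePattern(
            raw_text=raw, kind=PatternKind.BARE_CATEGORY, system=system, category=t
        )

    return CodePattern(raw_text=raw, kind=PatternKind.EXACT, system=system, exact=t)


def code_matches(
    pattern: CodePattern, code: str, system: Optional[CodeSystem] = None
) -> bool:
    """Test one code against one pattern.

    A system mismatch (when the caller states the code's system) raises
    rather than silently returning False.
    """
    if system is not None and CodeSystem(system) is not pattern.system:
        raise CodePatternError(
            f"code {code!r} is {CodeSystem(system).value}, pattern "
            f"{pattern.raw_text!r} is {pattern.system.value}"
        )
    c = normalize_code(code)
    if not c:
        return False
    cat, dec = split_code(c)

    if pattern.kind is PatternKind.EXACT:
        return c == pattern.exact
    if pattern.kind is PatternKind.BARE_CATEGORY:
        return cat == pattern.category
    if pattern.kind is PatternKind.WILDCARD:
        if cat != pattern.category:
            return False
        if not pattern.decimal_prefix:
            return True
        return dec is not None and dec.startswith(pattern.decimal_prefix)
    if pattern.kind is PatternKind.CATEGORY_RANGE:
        return cat.isdigit() and pattern.cat_lo <= int(cat) <= pattern.cat_hi
    if pattern.kind is PatternKind.DECIMAL_RANGE:
        if cat != pattern.category or dec is None:
            return False
        if len(dec) != pattern.dec_width or not dec.isdigit():
            return False
        return pattern.dec_lo <= int(dec) <= pattern.dec_hi
    raise AssertionError(f"unhandled kind {pattern.kind}")  # pragma: no cover


@dataclass(frozen=True)
class CodeSet:
    """A labelled, ordered collection of patterns sharing one coding system."""

    label: str
    system: CodeSystem
    patterns: tuple[CodePattern, ...]

    def __post_init__(self):
        if not self.patterns:
            raise CodePatternError(f"code set {self.label!r} is empty")
        for p in self.patterns:
            if p.system is not self.system:
                raise CodePatternError(
                    f"pattern {p.raw_text!r} in set {self.label!r} has system "
                    f"{p.system.value}, expected {self.system.value}"
                )

    @classmethod
    def from_text(
        cls, label: str, texts: Sequence[str], system: CodeSystem
    ) -> "CodeSet":
        return cls(
            label=label,
            system=CodeSystem(system),
            patterns=tuple(parse_pattern(t, system) for t in texts),
        )

    def pattern_texts(self) -> List[str]:
        return [p.raw_text for p in self.patterns]

    def matches_code(self, code: str) -> bool:
        return any(code_matches(p, code) for p in self.patterns)

    def matches_any(self, codes: Iterable[str]) -> bool:
        return any(self.matches_code(c) for c in codes)


def set_matches(code_set: CodeSet, codes: Iterable[str]) -> bool:
    """True iff any code matches any pattern of the set; empty input is False."""
    return code_set.matches_any(codes)


def merge_sets(label: str, sets: Sequence[CodeSet]) -> CodeSet:
    """Union several same-system sets into one labelled set."""
    systems = {s.system for s in sets}
    if len(systems) != 1:
        raise CodePatternError("cannot merge sets across coding systems")
    pats: List[CodePattern] = []
    for s in sets:
        pats.extend(s.patterns)
    return CodeSet(label=label, system=systems.pop(), patterns=tuple(pats))


def expand_pattern(pattern: CodePattern, max_decimal_digits: int = 2) -> List[str]:
    """Enumerate the concrete printed-format codes a pattern covers.

    The enumeration universe per category is the bare category plus every
    one- and two-decimal-digit subdivision (the formats ICD-9 actually
    prints).  Exact patterns expand to themselves.  Used by the synthetic
    generator to draw concrete codes when planting a phenotype.
    """
    if pattern.kind is PatternKind.EXACT:
        return [pattern.exact]
    if pattern.kind is PatternKind.CATEGORY_RANGE:
        cats = [f"{c:03d}" for c in range(pattern.cat_lo, pattern.cat_hi + 1)]
    else:
        cats = [pattern.category]
    out: List[str] = []
    for cat in cats:
        for cand in _category_universe(cat, max_decimal_digits):
            if code_matches(pattern, cand):
                out.append(cand)
    return out


def _category_universe(category: str, max_decimal_digits: int = 2) -> List[str]:
    u = [category]
    if max_decimal_digits >= 1:
        u += [f"{category}.{d}" for d in range(10)]
    if max_decimal_digits >= 2:
        u += [f"{category}.{d:02d}" for d in range(100)]
    return u


# ---------------------------------------------------------------------------
# Built-in registry: the published FAI-surgery inclusion CPT codes, the
# non-FAI exclusion diagnoses, the eight comorbidity definitions, and the
# opiate therapeutic classes.  Pattern strings are kept verbatim as printed
# in the source code lists (including mixed-case v-codes and two entries,
# 227.4 and 320.20, that sit oddly among the 327-series sleep codes and are
# retained as printed; see docs/methods.md).
# ---------------------------------------------------------------------------

FAI_INCLUSION_LABEL = "FAI inclusion CPT"
OPIOID_LABEL = "Opioid classes"

_FAI_INCLUSION_CPT = ["29914", "29915", "29916", "29862"]

EXCLUSION_LABELS = (
    "Hip Osteoarthritis",
    "Avascular Necrosis of the Hip",
    "Hip Fracture",
    "Osteomyelitis of the Hip",
    "Malignant Neoplasm of Pelvis, Hip, or Lower Extremity",
    "Other Hip Arthritic Condition",
)

_EXCLUSIONS = {
    "Hip Osteoarthritis": ["715.15", "715.25", "715.35", "715.95"],
    "Avascular Necrosis of the Hip": ["733.42"],
    "Hip Fracture": ["820", "821"],
    "Osteomyelitis of the Hip": ["730.85"],
    "Malignant Neoplasm of Pelvis, Hip, or Lower Extremity": ["170.6", "170.7", "171.3"],
    "Other Hip Arthritic Condition": ["714.0", "711.05"],
}

COMORBIDITY_LABELS = (
    "Sleep Disorders",
    "Mental Health",
    "Substance Abuse",
    "Tobacco Use",
    "Metabolic Syndromes",
    "Chronic Pain",
    "Cardiovascular",
    "Systemic Arthropathies",
)

_COMORBIDITIES = {
    # six sub-lists (insomnia, sleep-related breathing, hypersomnias,
    # circadian rhythm, parasomnias, sleep-related movement) merged
    "Sleep Disorders": [
        "307.41", "307.42", "327.00", "327.01", "780.52", "v69.4",
        "320.20", "327.21", "327.22", "327.23", "327.24", "327.25",
        "327.26", "327.27", "327.29", "768.04", "770.81",
        "307.44", "327.10", "327.11", "327.12", "327.13", "327.14",
        "327.15", "347.00", "347.01", "347.10", "780.54",
        "327.31", "327.32", "327.33", "327.34", "327.35", "327.36",
        "327.37", "327.39",
        "307.46", "307.47", "327.41", "327.42", "327.43", "227.4",
        "300.15", "327.44", "327.49", "368.16", "788.36",
        "327.51", "327.52", "327.53", "327.59", "333.49",
    ],
    "Mental Health": [
        "295.xx", "296.xx", "297.x", "298.x", "300.xx", "301.xx",
        "307.8x", "308.xx", "309.xx", "311.xx", "v11.x", "v15.52", "v40.9",
    ],
    "Substance Abuse": ["303.xx", "304.xx", "305.xx"],
    "Tobacco Use": ["V15.82"],
    "Metabolic Syndromes": [
        "249.xx", "250.xx", "255.0", "272.0", "272.2", "272.4",
        "278.00-278.03", "278.8", "v85.30-v85.39", "v85.41-v85.45",
    ],
    "Chronic Pain": ["338.2x", "338.3", "338.4", "729.1", "780.71", "780.79"],
    "Cardiovascular": ["348.2", "401.xx-405.xx", "410.xx-414.xx", "420.xx-429.xx"],
    "Systemic Arthropathies": [
        "099.3", "274.xx", "696.0-696.8", "710.0", "710.2",
        "711.15", "711.25", "711.35", "711.45", "711.55", "711.65",
        "711.75", "711.85",
        "712.15", "712.25", "712.35", "712.85", "712.95",
        "714.0", "714.1", "714.2", "714.4", "714.89",
        "716.25", "718.55", "719.35",
        "720.0", "720.81", "720.89", "720.9", "725", "729.0",
    ],
}

_OPIOID_CLASSES = ["280808", "280812"]


def builtin_registry(
    overrides: Optional[Dict[str, Sequence[str]]] = None,
) -> Dict[str, CodeSet]:
    """Build the shipped label → :class:`CodeSet` registry.

    ``overrides`` maps a label to a replacement pattern list, letting a study
    configuration swap any built-in definition (e.g. to correct the two
    sleep-code entries implemented as printed) without code changes.  The
    coding system of an overridden label is preserved.
    """
    systems: Dict[str, CodeSystem] = {FAI_INCLUSION_LABEL: CodeSystem.CPT}
    texts: Dict[str, Sequence[str]] = {FAI_INCLUSION_LABEL: _FAI_INCLUSION_CPT}
    for label, pats in _EXCLUSIONS.items():
        systems[label] = CodeSystem.ICD9_DX
        texts[label] = pats
    for label, pats in _COMORBIDITIES.items():
        systems[label] = CodeSystem.ICD9_DX
        texts[label] = pats
    systems[OPIOID_LABEL] = CodeSystem.THERAPEUTIC_CLASS
    texts[OPIOID_LABEL] = _OPIOID_CLASSES

    if overrides:
        for label, pats in overrides.items():
            if label not in texts:
                raise KeyError(f"unknown registry label: {label!r}")
            texts[label] = list(pats)

    return {
        label: CodeSet.from_text(label, texts[label], systems[label])
        for label in texts
    }


def exclusion_union(registry: Optional[Dict[str, CodeSet]] = None) -> CodeSet:
    """The six exclusion diagnosis sets merged into one screening set."""
    reg = registry if registry is not None else builtin_registry()
    return merge_sets("Non-FAI exclusions", [reg[l] for l in EXCLUSION_LABELS])


# ---------------------------------------------------------------------------
# Plain-text serialization: one block per set, "[label|SYSTEM]" header then
# one pattern per line; blank lines separate sets.
# ---------------------------------------------------------------------------

def codesets_to_text(sets: Iterable[CodeSet]) -> str:
    blocks = []
    for s in sets:
        lines = [f"[{s.label}|{s.system.value}]"] + s.pattern_texts()
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def codesets_from_text(text: str) -> Dict[str, CodeSet]:
    out: Dict[str, CodeSet] = {}
    header: Optional[tuple[str, CodeSystem]] = None
    pats: List[str] = []

    def flush():
        nonlocal header, pats
        if header is not None:
            label, system = header
            out[label] = CodeSet.from_text(label, pats, system)
        header, pats = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            body = line[1:-1]
            if "|" not in body:
                raise CodePatternError(f"malformed set header: {line!r}")
            label, system_name = body.rsplit("|", 1)
            header = (label, CodeSystem(system_name))
        else:
            if header is None:
                raise CodePatternError(f"pattern before any set header: {line!r}")
            pats.append(line)
    flush()
    return out
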